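"""96-context mutational spectra, strand bias and between-sample comparison.

Every SNV is represented in the pyrimidine convention: the substitution is
read off the strand on which the mutated base is C or T, collapsing the 12
possible substitutions into 6 types, each in 16 trinucleotide contexts
(96 classes, e.g. ``T[C>T]A``).  For melanoma cfDNA the expected picture is
the ultraviolet-damage signature: a dominance of C>T transitions, enriched
on the untranscribed strand of genes because transcription-coupled repair
preferentially clears pyrimidine dimers from the template strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cftrace._seq import COMPLEMENT, revcomp

PYRIMIDINES = "CT"
#: the six base-pair substitution types in conventional order
SUBSTITUTION_TYPES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
#: the 96 trinucleotide classes in conventional (COSMIC) order
SBS96_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in "ACGT"
    for three in "ACGT"
)

STRANDS = ("untranscribed", "transcribed", "intergenic", "ambiguous")


def classify_substitution(ref_triplet: str, alt_base: str) -> str:
    """Map a trinucleotide context + alternate base to its 96-class label.

    Purine-centred contexts are reverse-complemented first so the mutated
    base is always a pyrimidine.
    """
    triplet = ref_triplet.upper()
    alt = alt_base.upper()
    if len(triplet) != 3:
        raise ValueError(f"ref_triplet must have length 3, got {ref_triplet!r}")
    if any(b not in "ACGT" for b in triplet) or alt not in "ACGT":
        raise ValueError(f"ambiguous or non-ACGT base in {ref_triplet!r}>{alt_base!r}")
    if triplet[1] == alt:
        raise ValueError("reference and alternate base are identical")
    if triplet[1] not in PYRIMIDINES:
        triplet = revcomp(triplet)
        alt = COMPLEMENT[alt]
    return f"{triplet[0]}[{triplet[1]}>{alt}]{triplet[2]}"


def class_components(label: str) -> tuple[str, str, str, str]:
    """Split ``5'[REF>ALT]3'`` into (five, ref, alt, three)."""
    return label[0], label[2], label[4], label[6]


def substitution_type(label: str) -> str:
    return label[2:5]


@dataclass
class MutationSpectrum:
    """96-class (and strand-stratified 192-class) substitution counts."""

    sample_id: str
    counts96: dict[str, int] = field(default_factory=lambda: {c: 0 for c in SBS96_CLASSES})
    counts_stranded: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts96.values())

    def type_counts(self) -> dict[str, int]:
        """Counts collapsed to the 6 substitution types."""
        out = {t: 0 for t in SUBSTITUTION_TYPES}
        for cls, n in self.counts96.items():
            out[substitution_type(cls)] += n
        return out

    def fraction(self, sub_type: str) -> float:
        tc = self.type_counts()
        tot = self.total
        return tc[sub_type] / tot if tot else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": list(SBS96_CLASSES),
             "count": [self.counts96[c] for c in SBS96_CLASSES]}
        )

    def stranded_frame(self) -> pd.DataFrame:
        rows = [
            {"class": cls, "strand": strand, "count": n}
            for (cls, strand), n in sorted(self.counts_stranded.items())
        ]
        return pd.DataFrame(rows, columns=["class", "strand", "count"])


def _strand_label(ref_base: str, gene_strands: set[str]) -> str:
    """Strand category of a variant given the strands of overlapping genes.

    The pyrimidine of the substitution lies on the plus strand iff the
    reference base is itself a pyrimidine.  A pyrimidine on the coding
    (sense) strand of a gene is an "untranscribed"-strand event; on the
    template strand a "transcribed"-strand event.
    """
    if not gene_strands:
        return "intergenic"
    if len(gene_strands) > 1:
        return "ambiguous"
    gene_strand = next(iter(gene_strands))
    pyr_plus = ref_base.upper() in PYRIMIDINES
    if (gene_strand == "+") == pyr_plus:
        return "untranscribed"
    return "transcribed"


def build_spectrum(
    variants: Iterable[tuple[str, int, str, str]],
    reference,
    annotation: Sequence[tuple[str, int, int, str]] | None = None,
    sample_id: str = "sample",
) -> MutationSpectrum:
    """Tally SNVs into a 96-class spectrum with transcriptional strand labels.

    Parameters
    ----------
    variants
        Iterable of ``(chrom, pos, ref, alt)`` with 1-based positions.
    reference
        ``{chrom: sequence}`` dict, FASTA path or pyfaidx.Fasta.
    annotation
        Optional gene intervals ``(chrom, start, end, strand)``, 1-based
        inclusive, used to assign transcribed / untranscribed strand.
        Variants covered by genes on both strands are labelled "ambiguous"
        and excluded from strand-bias counts (but kept in counts96).
    """
    from cftrace._pileup import reference_dict

    refdict = reference_dict(reference)
    genes = list(annotation) if annotation else []
    spectrum = MutationSpectrum(sample_id=sample_id)
    for chrom, pos, ref, alt in variants:
        seq = refdict[chrom]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"variant position {chrom}:{pos} outside reference")
        if pos == 1 or pos == len(seq):
            raise ValueError(f"variant at contig edge has no trinucleotide context: {chrom}:{pos}")
        triplet = seq[pos - 2: pos + 1]
        if triplet[1] != ref.upper():
            raise ValueError(f"reference mismatch at {chrom}:{pos}: {triplet[1]} != {ref}")
        cls = classify_substitution(triplet, alt)
        spectrum.counts96[cls] = spectrum.counts96.get(cls, 0) + 1
        strands = {s for (c, start, end, s) in genes if c == chrom and start <= pos <= end}
        strand = _strand_label(ref, strands)
        key = (cls, strand)
        spectrum.counts_stranded[key] = spectrum.counts_stranded.get(key, 0) + 1
    return spectrum


def strand_bias_test(spectrum: MutationSpectrum) -> pd.DataFrame:
    """Exact binomial test of untranscribed vs transcribed counts per type.

    Counts are aggregated over the 16 contexts of each of the 6 substitution
    types; the null is strand symmetry (p=0.5).  Types with no genic counts
    yield p = 1.
    """
    rows = []
    for sub_type in SUBSTITUTION_TYPES:
        unt = sum(
            n for (cls, strand), n in spectrum.counts_stranded.items()
            if substitution_type(cls) == sub_type and strand == "untranscribed"
        )
        tra = sum(
            n for (cls, strand), n in spectrum.counts_stranded.items()
            if substitution_type(cls) == sub_type and strand == "transcribed"
        )
        total = unt + tra
        p = stats.binomtest(unt, total, 0.5).pvalue if total > 0 else 1.0
        rows.append({"type": sub_type, "untranscribed": unt, "transcribed": tra,
                     "p_value": float(p)})
    return pd.DataFrame(rows)


def compare_spectra(s1: MutationSpectrum, s2: MutationSpectrum) -> pd.DataFrame:
    """Per-type relative change between two spectra with BH-corrected Fisher tests.

    For each of the 6 substitution types a 2x2 table (type count vs the rest,
    per sample) is tested with a two-sided Fisher exact test; the six
    p-values are Benjamini-Hochberg adjusted.  Relative change is
    (proportion2 - proportion1) / proportion1.
    """
    t1, t2 = s1.total, s2.total
    if t1 == 0 or t2 == 0:
        raise ValueError("cannot compare spectra with zero total counts")
    tc1, tc2 = s1.type_counts(), s2.type_counts()
    rows = []
    for sub_type in SUBSTITUTION_TYPES:
        c1, c2 = tc1[sub_type], tc2[sub_type]
        _, p = stats.fisher_exact([[c1, t1 - c1], [c2, t2 - c2]], alternative="two-sided")
        p1, p2 = c1 / t1, c2 / t2
        rel = (p2 - p1) / p1 if p1 > 0 else np.inf if p2 > 0 else 0.0
        rows.append({"type": sub_type, "count1": c1, "count2": c2,
                     "proportion1": p1, "proportion2": p2,
                     "relative_change": rel, "p_value": float(p)})
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def plot_spectrum(spectrum: MutationSpectrum, path: str | Path) -> None:
    """Render the 96-class spectrum as percentages, grouped by type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    total = max(spectrum.total, 1)
    values = [100.0 * spectrum.counts96[c] / total for c in SBS96_CLASSES]
    colors = {"C>A": "#03bcee", "C>G": "#010101", "C>T": "#e32926",
              "T>A": "#cac9c9", "T>C": "#a1ce63", "T>G": "#ebc6c4"}
    fig, ax = plt.subplots(figsize=(14, 3))
    ax.bar(range(96), values,
           color=[colors[substitution_type(c)] for c in SBS96_CLASSES])
    ax.set_xticks(range(96))
    ax.set_xticklabels(SBS96_CLASSES, rotation=90, fontsize=4)
    ax.set_ylabel("% of mutations")
    ax.set_title(spectrum.sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
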