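"""File-format adapters: FASTA, VCF, BED, GFF/GTF, TSV, YAML.

Conventions: VCF and all user-facing coordinates are 1-based inclusive;
BED is consumed 0-based half-open.  VCF handling goes through pysam so the
required INFO/FILTER headers are declared properly.
"""

from __future__ import annotations

import textwrap
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from cftrace.caller import CandidateVariant


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, width)) + "\n")
    try:  # a .fai index lets pyfaidx/pysam memory-map the reference
        pysam.faidx(str(path))
    except pysam.SamtoolsError:
        pass
    return path


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end[/name/strand]."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = names[: len(df.columns)]
    return df


def bed_to_sites(df: pd.DataFrame) -> set[tuple[str, int]]:
    """Expand BED intervals into 1-based (chrom, pos) site tuples."""
    sites: set[tuple[str, int]] = set()
    for row in df.itertuples():
        sites.update((row.chrom, p) for p in range(int(row.start) + 1, int(row.end) + 1))
    return sites


def read_gene_annotation(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Gene intervals (chrom, start, end, strand), 1-based inclusive.

    Accepts GFF3/GTF (``gene`` features) or stranded BED6 (converted from
    0-based half-open).
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = read_bed(path)
        if "strand" not in df.columns:
            raise ValueError("stranded BED6 required for gene annotation")
        return [
            (r.chrom, int(r.start) + 1, int(r.end), r.strand) for r in df.itertuples()
        ]
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"malformed GFF/GTF line: {line!r}")
            if fields[2].lower() != "gene":
                continue
            genes.append((fields[0], int(fields[3]), int(fields[4]), fields[6]))
    return genes


# ---------------------------------------------------------------------------
# VCF

_INFO_FIELDS = [
    ("DP", "1", "Integer", "Total read depth"),
    ("HQDP", "1", "Integer", "High-quality read depth"),
    ("ALTC", "1", "Integer", "High-quality alternate read count"),
    ("VAF", "1", "Float", "Variant allele frequency (alt / high-quality depth)"),
    ("PFREQ", "1", "Float", "Exact binomial tail p-value under the error model"),
    ("POSTERIOR", "1", "Float", "Posterior probability of a somatic allele"),
    ("FHAT", "1", "Float", "Grid estimate of the somatic allele fraction"),
    ("VERDICT", "1", "String", "Haplotype-verification verdict"),
    ("CFSUP", "1", "Integer", "cfDNA molecules supporting the variant haplotype"),
    ("GLSUP", "1", "Integer", "Germline molecules supporting the variant haplotype"),
]

_FILTER_FIELDS = [
    ("multiallelic", "More than one alternate base above the candidate floor"),
    ("p_freq", "Frequentist p-value above the calling threshold"),
    ("posterior", "Somatic posterior below the calling threshold"),
    ("coverage", "Depth outside the accepted coverage band"),
    ("error-model-floor", "Error rate below the model floor; p-value unreliable"),
    ("germline_contaminated", "Variant haplotype present in the germline reads"),
    ("assembly_artefact", "Haplotype not supported by local assembly / divergent background"),
    ("insufficient", "Too few supporting cfDNA molecules"),
]


def _vcf_header(contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for fid, num, ftype, desc in _INFO_FIELDS:
        header.info.add(fid, num, ftype, desc)
    for fid, desc in _FILTER_FIELDS:
        header.filters.add(fid, None, None, desc)
    return header


def write_candidate_vcf(
    candidates: Sequence[CandidateVariant],
    contigs: Mapping[str, int],
    path: str | Path,
    verdicts: Mapping[str, object] | None = None,
) -> Path:
    """Write scored candidates (and optional verification evidence) as VCF."""
    path = Path(path)
    header = _vcf_header(contigs)
    verdicts = verdicts or {}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for cand in sorted(candidates, key=lambda c: (c.chrom, c.pos)):
            rec = vcf.new_record(
                contig=cand.chrom, start=cand.pos - 1, stop=cand.pos,
                alleles=(cand.ref, cand.alt),
            )
            rec.info["DP"] = cand.depth
            rec.info["HQDP"] = cand.hq_depth
            rec.info["ALTC"] = cand.alt_count
            rec.info["VAF"] = round(cand.vaf, 6)
            if cand.p_freq is not None:
                rec.info["PFREQ"] = float(cand.p_freq)
            if cand.posterior is not None:
                rec.info["POSTERIOR"] = float(cand.posterior)
            if cand.f_hat is not None:
                rec.info["FHAT"] = float(cand.f_hat)
            ev = verdicts.get(cand.key)
            if ev is not None:
                rec.info["VERDICT"] = ev.verdict
                rec.info["CFSUP"] = ev.cfdna_support
                rec.info["GLSUP"] = ev.germline_support
                if ev.verdict != "verified":
                    rec.filter.add(ev.verdict)
            known = {f for f, _ in _FILTER_FIELDS}
            for f in sorted(cand.filters & known):
                rec.filter.add(f)
            if not list(rec.filter):
                rec.filter.add("PASS")
            vcf.write(rec)
    return path


def read_variants_vcf(path: str | Path) -> list[tuple[str, int, str, str]]:
    """SNV records as (chrom, pos, ref, alt), 1-based."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1:
                    out.append((rec.chrom, rec.pos, rec.ref, alt))
    return out


def read_germline_genotypes(path: str | Path) -> dict[tuple[str, int], frozenset[str]]:
    """Germline genotypes from a VCF: (chrom, pos) -> allele set."""
    genotypes: dict[tuple[str, int], frozenset[str]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alleles = {rec.ref}
            sample_values = list(rec.samples.values())
            if sample_values:
                for sv in sample_values:
                    alleles.update(a for a in (sv.alleles or ()) if a)
            else:
                alleles.update(a for a in (rec.alts or ()))
            genotypes[(rec.chrom, rec.pos)] = frozenset(alleles)
    return genotypes


# ---------------------------------------------------------------------------
# truth / observation tables


def write_truth_tables(truth, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    germ = pd.DataFrame(
        [{"chrom": truth.chrom, "pos": pos, "ref": ref, "alt": alt}
         for pos, (ref, alt) in sorted(truth.germline.items())]
    )
    som = pd.DataFrame(
        [{"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
          "group": v.group, "carriers": ",".join(v.carriers),
          **{f"vaf_{lab}": vaf for lab, vaf in v.expected_vaf.items()}}
         for v in truth.somatic]
    )
    paths = {
        "germline": out_dir / "truth_germline.tsv",
        "somatic": out_dir / "truth_somatic.tsv",
    }
    germ.to_csv(paths["germline"], sep="\t", index=False)
    som.to_csv(paths["somatic"], sep="\t", index=False)
    return paths


def read_observations(path: str | Path) -> pd.DataFrame:
    """Long-format (variant, timepoint, day, alt, depth) observation TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant", "timepoint", "day", "alt", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation table lacks columns: {sorted(missing)}")
    return df


def genotype_germline_bam(
    bam: str | Path,
    reference,
    matrix,
    min_depth: int = 10,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> dict[tuple[str, int], frozenset[str]]:
    """Naive germline genotyper: allele-fraction banding on hq base counts."""
    from cftrace import _pileup
    import numpy as np
    from cftrace._seq import BASES

    refdict = _pileup.reference_dict(reference)
    genotypes: dict[tuple[str, int], frozenset[str]] = {}
    for chrom, refseq in refdict.items():
        piled = _pileup.accumulate_base_counts(
            bam, chrom, len(refseq), matrix.quality_bins
        )
        hq = piled.hq_counts
        total = hq.sum(axis=0)
        refcodes = piled.ref_codes(refseq)
        nonref = hq.copy()
        idx = np.arange(len(refseq))
        ok = refcodes < 4
        nonref[refcodes[ok], idx[ok]] = 0
        top = nonref.max(axis=0)
        cand = np.flatnonzero((total >= min_depth) & (top >= 2))
        for p0 in cand:
            frac = top[p0] / total[p0]
            alt = BASES[int(np.argmax(nonref[:, p0]))]
            ref = refseq[p0]
            if frac > het_band[1]:
                genotypes[(chrom, int(p0) + 1)] = frozenset({alt})
            elif frac >= het_band[0]:
                genotypes[(chrom, int(p0) + 1)] = frozenset({ref, alt})
    return genotypes
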