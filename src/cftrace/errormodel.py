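"""Empirical substitution-error model for cfDNA alignments.

Sequencing errors, not biology, dominate the non-reference signal at the
allele fractions where circulating tumour DNA lives.  All calling statistics
in this package therefore condition on an empirical confusion matrix: a
per-sample, quality-binned 4x4 matrix of P(observed base | true base)
estimated directly from the alignments, taking the reference base as the
truth proxy at sites believed to be variant-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from cftrace._seq import BASES, BASE_INDEX
from cftrace import _pileup

#: default base-quality bins (inclusive ranges)
DEFAULT_QUALITY_BINS: tuple[tuple[int, int], ...] = ((0, 19), (20, 29), (30, 93))


@dataclass
class ConfusionMatrix:
    """Per-sample quality-binned substitution error-probability matrix.

    ``matrices[b][t, o]`` is P(observed base ``o`` | true base ``t``) for
    base-quality bin ``b``; rows are normalised to 1 with an additive
    pseudocount.  Base order is A, C, G, T.
    """

    sample_id: str
    quality_bins: tuple[tuple[int, int], ...]
    matrices: np.ndarray  # (n_bins, 4, 4)
    site_count: int = 0
    pseudocount: float = 1.0
    counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.shape != (len(self.quality_bins), 4, 4):
            raise ValueError(
                f"matrix shape {self.matrices.shape} does not match "
                f"{len(self.quality_bins)} quality bins"
            )
        rowsums = self.matrices.sum(axis=2)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("confusion-matrix rows must sum to 1")
        if (self.matrices < 0).any():
            raise ValueError("confusion-matrix entries must be non-negative")

    # -- lookup ---------------------------------------------------------

    def bin_index(self, quality: int) -> int:
        for i, (lo, hi) in enumerate(self.quality_bins):
            if lo <= quality <= hi:
                return i
        raise ValueError(f"base quality {quality} falls outside all quality bins")

    def error_rate(self, true_base: str, observed_base: str, quality: int = 30) -> float:
        """P(observe ``observed_base`` | template base ``true_base``) at ``quality``."""
        try:
            t = BASE_INDEX[true_base.upper()]
            o = BASE_INDEX[observed_base.upper()]
        except KeyError as exc:
            raise ValueError(f"base outside ACGT alphabet: {exc}") from exc
        return float(self.matrices[self.bin_index(quality), t, o])

    # -- constructors ---------------------------------------------------

    @classmethod
    def identity(cls, sample_id: str = "identity",
                 quality_bins: Sequence[tuple[int, int]] = DEFAULT_QUALITY_BINS) -> "ConfusionMatrix":
        """Error-free matrix (diagonal 1)."""
        m = np.broadcast_to(np.eye(4), (len(quality_bins), 4, 4)).copy()
        return cls(sample_id, tuple(tuple(b) for b in quality_bins), m, pseudocount=0.0)

    @classmethod
    def uniform(cls, rate: float, sample_id: str = "uniform",
                quality_bins: Sequence[tuple[int, int]] = DEFAULT_QUALITY_BINS) -> "ConfusionMatrix":
        """Matrix with total substitution rate ``rate``, split evenly over the 3 wrong bases."""
        if not 0.0 <= rate < 1.0:
            raise ValueError("rate must be in [0, 1)")
        m = np.full((4, 4), rate / 3.0)
        np.fill_diagonal(m, 1.0 - rate)
        m = np.broadcast_to(m, (len(quality_bins), 4, 4)).copy()
        return cls(sample_id, tuple(tuple(b) for b in quality_bins), m, pseudocount=0.0)

    # -- serialisation --------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sample_id": self.sample_id,
            "quality_bins": [list(b) for b in self.quality_bins],
            "bases": BASES,
            "matrices": self.matrices.tolist(),
            "site_count": self.site_count,
            "pseudocount": self.pseudocount,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ConfusionMatrix":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        return cls(
            sample_id=payload["sample_id"],
            quality_bins=tuple(tuple(b) for b in payload["quality_bins"]),
            matrices=np.asarray(payload["matrices"], dtype=float),
            site_count=int(payload["site_count"]),
            pseudocount=float(payload["pseudocount"]),
        )


def estimate_confusion_matrix(
    alignments: str | Path,
    reference,
    excluded_sites: Iterable[tuple[str, int]] = (),
    quality_bins: Sequence[tuple[int, int]] = DEFAULT_QUALITY_BINS,
    pseudocount: float = 1.0,
    sample_id: str | None = None,
    min_mapping_quality: int = 20,
    end_trim: int = 5,
) -> ConfusionMatrix:
    """Estimate a quality-binned confusion matrix from a coordinate-sorted BAM/SAM.

    The reference base is used as the true-base proxy at every site not in
    ``excluded_sites`` (1-based ``(chrom, pos)`` pairs; pass germline-variant
    and candidate positions here).  Sites that look like unlisted variants —
    a non-reference base on more than one read at allele fraction >= 0.2, or
    several distinct multiply-observed non-reference bases — are additionally
    skipped, so that genuine variants do not contaminate the error estimate.  Reads are filtered (mapping quality, duplicates, secondary /
    supplementary alignments) and the ``end_trim`` outermost aligned bases
    of every read are ignored.

    Raises ``ValueError`` when no usable site remains: an all-pseudocount
    matrix would be a silent lie.
    """
    quality_bins = tuple(tuple(b) for b in quality_bins)
    refdict = _pileup.reference_dict(reference)
    excl: dict[str, set[int]] = {}
    for chrom, pos in excluded_sites:
        excl.setdefault(chrom, set()).add(int(pos) - 1)

    nbins = len(quality_bins)
    tallies = np.zeros((nbins, 4, 4), dtype=np.int64)
    site_count = 0

    for chrom, refseq in refdict.items():
        piled = _pileup.accumulate_base_counts(
            alignments, chrom, len(refseq), quality_bins,
            min_mapping_quality=min_mapping_quality, end_trim=end_trim,
        )
        refcodes = piled.ref_codes(refseq)
        totals = piled.bin_counts.sum(axis=0)  # (4, L)
        covered = totals.sum(axis=0) > 0

        include = covered & (refcodes < 4)
        if chrom in excl:
            idx = np.fromiter(excl[chrom], dtype=np.int64)
            idx = idx[(idx >= 0) & (idx < len(refseq))]
            include[idx] = False

        # skip sites that look like unlisted variants rather than errors:
        # a non-reference base on >1 read at variant-like allele fraction,
        # or >1 distinct non-reference base each backed by >1 read
        nonref = totals.copy()
        pos_idx = np.arange(len(refseq))
        ok = refcodes < 4
        nonref[refcodes[ok], pos_idx[ok]] = 0
        depth_tot = np.maximum(totals.sum(axis=0), 1)
        top_nonref = nonref.max(axis=0)
        variant_like = (top_nonref > 1) & (top_nonref / depth_tot >= 0.2)
        multi = (nonref > 1).sum(axis=0) > 1
        include &= ~(variant_like | multi)

        site_count += int(include.sum())
        for b in range(nbins):
            for t in range(4):
                sel = include & (refcodes == t)
                if sel.any():
                    tallies[b, t] += piled.bin_counts[b][:, sel].sum(axis=1)

    if site_count == 0:
        raise ValueError("no usable sites to estimate the confusion matrix from")

    mats = tallies.astype(float) + pseudocount
    rowsums = mats.sum(axis=2, keepdims=True)
    # rows without any observation or pseudocount (e.g. an unused quality
    # bin) carry no information; they default to the error-free row
    empty = np.broadcast_to(rowsums == 0, mats.shape)
    mats = np.where(empty, np.eye(4)[None, :, :], mats / np.maximum(rowsums, 1e-300))
    return ConfusionMatrix(
        sample_id=sample_id or Path(str(alignments)).stem,
        quality_bins=quality_bins,
        matrices=mats,
        site_count=site_count,
        pseudocount=pseudocount,
        counts=tallies,
    )
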