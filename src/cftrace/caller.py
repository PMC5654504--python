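"""Stage 1 of the two-stage somatic caller: candidate scan and scoring.

Candidate positions are pileup columns carrying at least ``min_alt_reads``
(default 3) high-quality non-genomic alleles — bases absent from the matched
germline genotype — while columns with unexpectedly high or low total
coverage are ignored outright.  Each candidate is then scored under the
empirical confusion-matrix error model with

* an exact upper binomial tail P(K >= k | n, e) against the relevant
  ref->alt error rate (frequentist), and
* a two-hypothesis Bayesian model: H0, all alternate reads are sequencing
  error; H1, a somatic allele at fraction f contributes reads, with f
  marginalised over a grid.  The reported posterior uses a somatic prior
  appropriate to a high-burden tumour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from cftrace._seq import BASES, BASE_INDEX
from cftrace import _pileup
from cftrace.errormodel import ConfusionMatrix

DEFAULT_F_GRID: np.ndarray = np.round(np.arange(0.01, 0.501, 0.01), 4)
DEFAULT_PRIOR_SOMATIC = 1e-4
DEFAULT_ALPHA = 1e-6
DEFAULT_MIN_POSTERIOR = 0.95
ERROR_RATE_FLOOR = 1e-6


@dataclass
class CandidateVariant:
    """A pileup-derived candidate somatic SNV."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int          # total read depth (n)
    hq_depth: int       # high-quality read depth used for statistics
    alt_count: int      # high-quality alternate reads (k)
    modal_quality: int  # representative base quality of the column
    vaf: float = 0.0
    p_freq: float | None = None
    posterior: float | None = None
    f_hat: float | None = None
    filters: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.hq_depth:
            raise ValueError("alt count must satisfy 0 <= k <= hq depth")
        self.vaf = self.alt_count / self.hq_depth if self.hq_depth else 0.0

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class ScanResult:
    candidates: list[CandidateVariant]
    median_depth: float
    n_ignored_coverage: int


def scan_candidates(
    alignments: str | Path,
    reference,
    germline_genotypes: Mapping[tuple[str, int], frozenset[str]] | None,
    matrix: ConfusionMatrix,
    coverage_bounds: tuple[float, float] = (0.25, 2.0),
    min_alt_reads: int = 3,
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
    end_trim: int = 5,
    assume_hom_ref: bool = True,
) -> ScanResult:
    """Scan pileups for candidate somatic SNVs.

    A column is emitted iff a single alternate base outside the germline
    genotype is carried by >= ``min_alt_reads`` high-quality reads (base
    quality, mapping quality, duplicate/secondary filtering, end trimming)
    and the total depth lies within ``coverage_bounds`` times the
    genome-wide median depth.  Columns outside the coverage band are
    counted as ignored and never emitted.
    """
    germline_genotypes = germline_genotypes or {}
    refdict = _pileup.reference_dict(reference)
    piles: dict[str, _pileup.PiledCounts] = {}
    for chrom, refseq in refdict.items():
        piles[chrom] = _pileup.accumulate_base_counts(
            alignments, chrom, len(refseq), matrix.quality_bins,
            min_mapping_quality=min_mapping_quality,
            min_base_quality=min_base_quality,
            end_trim=end_trim,
        )

    all_depth = np.concatenate([p.depth for p in piles.values()])
    covered = all_depth[all_depth > 0]
    if covered.size == 0:
        return ScanResult([], 0.0, 0)
    median_depth = float(np.median(covered))
    lo = coverage_bounds[0] * median_depth
    hi = coverage_bounds[1] * median_depth

    candidates: list[CandidateVariant] = []
    n_ignored = 0
    for chrom, piled in piles.items():
        refseq = refdict[chrom]
        refcodes = piled.ref_codes(refseq)
        L = piled.length
        hq = piled.hq_counts  # (4, L)

        # mask genotype alleles, then find the top non-genomic base per column
        nongeno = hq.astype(np.int64).copy()
        idx = np.arange(L)
        ok = refcodes < 4
        nongeno[refcodes[ok], idx[ok]] = -1
        het_positions = [
            (pos, alleles) for (c, pos), alleles in germline_genotypes.items() if c == chrom
        ]
        for pos1, alleles in het_positions:
            for a in alleles:
                if a in BASE_INDEX and 1 <= pos1 <= L:
                    nongeno[BASE_INDEX[a], pos1 - 1] = -1
        if not assume_hom_ref:
            known = {p for p, _ in het_positions}
            # columns with no genotype available are skipped entirely
            unknown_mask = np.ones(L, dtype=bool)
            for pos1 in known:
                if 1 <= pos1 <= L:
                    unknown_mask[pos1 - 1] = False
            nongeno[:, unknown_mask] = -1

        top_alt = nongeno.max(axis=0)
        hits = np.flatnonzero(top_alt >= min_alt_reads)
        bin_depth = piled.bin_depth  # (n_bins, L)
        for p0 in hits:
            depth = int(piled.depth[p0])
            if not lo <= depth <= hi:
                n_ignored += 1
                continue
            ref = refseq[p0]
            if ref not in BASE_INDEX:
                continue
            col = nongeno[:, p0]
            alt_code = int(np.argmax(col))
            filters: set[str] = set()
            if np.sum(col >= min_alt_reads) > 1:
                filters.add("multiallelic")
            modal_bin = int(np.argmax(bin_depth[:, p0]))
            modal_quality = matrix.quality_bins[modal_bin][0]
            candidates.append(
                CandidateVariant(
                    chrom=chrom,
                    pos=int(p0) + 1,
                    ref=ref,
                    alt=BASES[alt_code],
                    depth=depth,
                    hq_depth=int(hq[:, p0].sum()),
                    alt_count=int(col[alt_code]),
                    modal_quality=modal_quality,
                    filters=filters,
                )
            )
    return ScanResult(candidates, median_depth, n_ignored)


def score_frequentist(candidate: CandidateVariant, matrix: ConfusionMatrix) -> float:
    """Exact upper binomial tail P(K >= k | n_hq, e(ref->alt)).

    ``e`` is the confusion-matrix entry for the candidate's ref->alt
    substitution in the quality bin of the column's modal base quality.
    An error rate below the floor (or zero) is flagged, since the tail then
    reflects the pseudocount more than the data.
    """
    e = matrix.error_rate(candidate.ref, candidate.alt, candidate.modal_quality)
    if e < ERROR_RATE_FLOOR:
        candidate.filters.add("error-model-floor")
    k, n = candidate.alt_count, candidate.hq_depth
    p = float(stats.binom.sf(k - 1, n, e)) if k > 0 else 1.0
    candidate.p_freq = p
    return p


def score_bayesian(
    candidate: CandidateVariant,
    matrix: ConfusionMatrix,
    prior_somatic: float = DEFAULT_PRIOR_SOMATIC,
    f_grid: Sequence[float] | np.ndarray = DEFAULT_F_GRID,
) -> tuple[float, float]:
    """Posterior probability of a somatic allele and its fraction estimate.

    H0: every alternate read is a ref->alt sequencing error (rate ``e``).
    H1: a somatic allele at fraction f is present; an observed alternate
    read arises either from a true alternate template read off correctly or
    from a reference template misread, so the per-read alternate probability
    is ``f * (1 - e_alt->ref) + (1 - f) * e_ref->alt``.  f is marginalised
    uniformly over ``f_grid``; ``f_hat`` is the grid argmax of the H1
    likelihood.
    """
    if not 0.0 < prior_somatic < 1.0:
        raise ValueError("prior_somatic must lie in (0, 1)")
    grid = np.asarray(list(f_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("f_grid must be non-empty")
    if ((grid <= 0) | (grid > 1)).any():
        raise ValueError("f_grid values must lie in (0, 1]")

    q = candidate.modal_quality
    e_ra = matrix.error_rate(candidate.ref, candidate.alt, q)
    e_ar = matrix.error_rate(candidate.alt, candidate.ref, q)
    k, n = candidate.alt_count, candidate.hq_depth

    p1 = np.clip(grid * (1.0 - e_ar) + (1.0 - grid) * e_ra, 1e-12, 1.0 - 1e-12)
    log_l1 = stats.binom.logpmf(k, n, p1)
    log_l1_marg = float(np.logaddexp.reduce(log_l1) - np.log(grid.size))
    e0 = min(max(e_ra, 0.0), 1.0)
    log_l0 = float(stats.binom.logpmf(k, n, e0)) if 0 < e0 < 1 else (
        0.0 if (e0 == 0.0 and k == 0) or (e0 == 1.0 and k == n) else -np.inf
    )

    log_odds = np.log(prior_somatic) - np.log1p(-prior_somatic) + log_l1_marg - log_l0
    posterior = float(1.0 / (1.0 + np.exp(-log_odds))) if np.isfinite(log_odds) else (
        1.0 if log_odds > 0 else 0.0
    )
    f_hat = float(grid[int(np.argmax(log_l1))])
    candidate.posterior = posterior
    candidate.f_hat = f_hat
    return posterior, f_hat


def score_candidates(
    candidates: Sequence[CandidateVariant],
    matrix: ConfusionMatrix,
    prior_somatic: float = DEFAULT_PRIOR_SOMATIC,
    f_grid: Sequence[float] | np.ndarray = DEFAULT_F_GRID,
) -> list[CandidateVariant]:
    """Attach frequentist and Bayesian scores to every candidate."""
    for cand in candidates:
        score_frequentist(cand, matrix)
        score_bayesian(cand, matrix, prior_somatic, f_grid)
    return list(candidates)


def call_somatic(
    candidates: Sequence[CandidateVariant],
    alpha: float = DEFAULT_ALPHA,
    min_posterior: float = DEFAULT_MIN_POSTERIOR,
    blocking_filters: frozenset[str] = frozenset({"coverage"}),
) -> tuple[list[CandidateVariant], list[CandidateVariant]]:
    """Final somatic calls: p_freq <= alpha, posterior >= min_posterior,
    no blocking filter.  Returns (passed, rejected); rejected candidates
    carry the filter labels that removed them.
    """
    passed: list[CandidateVariant] = []
    rejected: list[CandidateVariant] = []
    for cand in candidates:
        if cand.p_freq is None or cand.posterior is None:
            raise ValueError(f"candidate {cand.key} has not been scored")
        fails = set()
        if cand.p_freq > alpha:
            fails.add("p_freq")
        if cand.posterior < min_posterior:
            fails.add("posterior")
        fails |= cand.filters & blocking_filters
        if fails:
            cand.filters |= fails
            rejected.append(cand)
        else:
            passed.append(cand)
    return passed, rejected
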