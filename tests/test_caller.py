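"""Candidate scanning and scoring tests."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cftrace import _pileup, caller
from cftrace.caller import CandidateVariant, call_somatic, scan_candidates
from cftrace.errormodel import ConfusionMatrix
from tests.conftest import write_sam


def make_candidate(k: int, n: int, ref: str = "C", alt: str = "T",
                   quality: int = 30) -> CandidateVariant:
    return CandidateVariant(
        chrom="c", pos=100, ref=ref, alt=alt, depth=n, hq_depth=n,
        alt_count=k, modal_quality=quality,
    )


def binom_tail_oracle(k: int, n: int, e: float) -> float:
    """Brute-force summation of the upper binomial tail."""
    return sum(math.comb(n, i) * e**i * (1 - e) ** (n - i) for i in range(k, n + 1))


def _sweep_sam(tmp_path, depth: int = 40, max_alt: int = 10, spacing: int = 100):
    """One clean column per alt count 0..max_alt, constant depth."""
    chrom = "c"
    L = (max_alt + 2) * spacing
    ref = ("ACGT" * ((L // 4) + 1))[:L]
    reads = []
    positions = {}
    rid = 0
    for j, k in enumerate(range(max_alt + 1)):
        centre = (j + 1) * spacing  # 0-based column position
        positions[k] = centre + 1
        start = centre - 30
        for i in range(depth):
            seq = list(ref[start: start + 61])
            if i < k:
                seq[30] = "T" if ref[centre] != "T" else "G"
            reads.append((f"r{rid}", start, "".join(seq), 30, 60, 0))
            rid += 1
    sam = write_sam(tmp_path / "sweep.sam", chrom, L, reads)
    return sam, {chrom: ref}, positions


class TestScan:
    def test_three_read_candidate_floor(self, tmp_path):
        """Columns gain candidacy at exactly 3 high-quality alt reads."""
        sam, refdict, positions = _sweep_sam(tmp_path)
        matrix = ConfusionMatrix.uniform(0.001)
        result = scan_candidates(sam, refdict, {}, matrix)
        emitted = {c.pos for c in result.candidates}
        for k, pos in positions.items():
            assert (pos in emitted) == (k >= 3)
        assert min(
            c.alt_count for c in result.candidates
        ) == 3

    def test_germline_alleles_are_not_candidates(self, tmp_path):
        """Bases in the germline genotype are genomic, never candidate alts."""
        sam, refdict, positions = _sweep_sam(tmp_path)
        matrix = ConfusionMatrix.uniform(0.001)
        chrom = "c"
        ref = refdict[chrom]
        genotypes = {
            (chrom, pos): frozenset({ref[pos - 1], "T" if ref[pos - 1] != "T" else "G"})
            for pos in positions.values()
        }
        result = scan_candidates(sam, refdict, genotypes, matrix)
        assert result.candidates == []

    def test_coverage_outliers_ignored(self, tmp_path):
        """A 5x-median column is ignored no matter how many alt reads."""
        chrom, L = "c", 2000
        ref = ("ACGT" * 500)
        reads = []
        rid = 0
        # 20 normal columns at depth 20 to pin the median
        for j in range(20):
            start = j * 80
            for i in range(20):
                reads.append((f"n{rid}", start, ref[start: start + 61], 30, 60, 0))
                rid += 1
        # one deep column: depth 100 with 10 alt reads
        start = 1800
        for i in range(100):
            seq = list(ref[start: start + 61])
            if i < 10:
                seq[30] = "T" if ref[start + 30] != "T" else "G"
            reads.append((f"d{rid}", start, "".join(seq), 30, 60, 0))
            rid += 1
        sam = write_sam(tmp_path / "cov.sam", chrom, L, reads)
        result = scan_candidates(sam, {chrom: ref}, {}, ConfusionMatrix.uniform(0.001))
        assert result.candidates == []
        assert result.n_ignored_coverage == 1

    def test_low_quality_reads_do_not_count(self, tmp_path):
        """Alt reads below the mapping-quality floor are not high-quality."""
        chrom, L = "c", 400
        ref = "ACGT" * 100
        start, centre = 170, 200
        reads = []
        for i in range(30):
            seq = list(ref[start: start + 61])
            if i < 5:
                seq[30] = "T" if ref[centre] != "T" else "G"
            mapq = 5 if i < 5 else 60  # alt reads poorly mapped
            reads.append((f"r{i}", start, "".join(seq), 30, mapq, 0))
        sam = write_sam(tmp_path / "mq.sam", chrom, L, reads)
        result = scan_candidates(sam, {chrom: ref}, {}, ConfusionMatrix.uniform(0.001))
        assert result.candidates == []


class TestFrequentist:
    def test_no_alt_reads_p_one(self):
        cand = make_candidate(0, 50)
        assert caller.score_frequentist(cand, ConfusionMatrix.uniform(0.003)) == 1.0

    def test_matches_summation_oracle_example(self):
        cand = make_candidate(3, 100)
        m = ConfusionMatrix.uniform(0.003)  # e(C->T) = 0.001
        p = caller.score_frequentist(cand, m)
        assert p == pytest.approx(binom_tail_oracle(3, 100, 0.001), rel=1e-9)
        assert p == pytest.approx(1.504e-4, rel=1e-3)

    def test_certain_error_gives_p_one(self):
        row = np.zeros((3, 4, 4))
        row[:, :, 3] = 1.0  # every template base read as T
        m = ConfusionMatrix("sure", ConfusionMatrix.uniform(0).quality_bins, row)
        cand = make_candidate(40, 100, ref="C", alt="T")
        assert caller.score_frequentist(cand, m) == 1.0

    def test_zero_error_flagged_and_p_zero(self):
        m = ConfusionMatrix.identity()
        cand = make_candidate(3, 100)
        p = caller.score_frequentist(cand, m)
        assert p == 0.0
        assert "error-model-floor" in cand.filters

    @pytest.mark.parametrize("n,e", [(10, 0.001), (17, 0.01), (20, 0.2), (5, 0.3)])
    def test_exact_tail_equals_enumeration_for_small_n(self, n, e):
        m = ConfusionMatrix.uniform(3 * e)
        for k in range(n + 1):
            p = caller.score_frequentist(make_candidate(k, n), m)
            assert p == pytest.approx(binom_tail_oracle(k, n, e), rel=1e-9, abs=1e-300)

    def test_monotone_nonincreasing_in_k(self):
        rng = np.random.default_rng(2)
        m = ConfusionMatrix.uniform(0.003)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            ps = [caller.score_frequentist(make_candidate(k, n), m) for k in range(n + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestBayesian:
    def test_hand_computed_posterior(self):
        """n=10, k=2, e=0.01 both directions, prior 0.5, f grid {0.1}."""
        m = ConfusionMatrix.uniform(0.03)  # per-pair rate 0.01
        cand = make_candidate(2, 10)
        post, f_hat = caller.score_bayesian(cand, m, prior_somatic=0.5, f_grid=[0.1])
        p1 = 0.1 * 0.99 + 0.9 * 0.01
        l1 = math.comb(10, 2) * p1**2 * (1 - p1) ** 8
        l0 = math.comb(10, 2) * 0.01**2 * 0.99**8
        assert post == pytest.approx(l1 / (l1 + l0), rel=1e-6)
        assert post == pytest.approx(0.981, abs=0.001)
        assert f_hat == 0.1

    def test_no_evidence_inflates_weakly(self):
        m = ConfusionMatrix.uniform(0.003)
        cand = make_candidate(0, 100)
        post, _ = caller.score_bayesian(cand, m, prior_somatic=1e-5)
        assert post < 1e-5 * 10

    def test_monotone_in_alt_count(self):
        m = ConfusionMatrix.uniform(0.003)
        p3, _ = caller.score_bayesian(make_candidate(3, 100), m)
        p10, _ = caller.score_bayesian(make_candidate(10, 100), m)
        assert p10 > p3

    def test_f_hat_tracks_the_allele_fraction(self):
        m = ConfusionMatrix.uniform(0.003)
        _, f_hat = caller.score_bayesian(make_candidate(20, 100), m)
        assert abs(f_hat - 0.2) <= 0.02

    def test_invalid_inputs(self):
        m = ConfusionMatrix.uniform(0.003)
        with pytest.raises(ValueError):
            caller.score_bayesian(make_candidate(1, 10), m, f_grid=[])
        with pytest.raises(ValueError):
            caller.score_bayesian(make_candidate(1, 10), m, prior_somatic=0.0)


class TestCallSomatic:
    def test_strong_candidate_retained(self):
        cand = make_candidate(20, 100)
        cand.p_freq, cand.posterior = 1e-9, 0.999
        passed, rejected = call_somatic([cand])
        assert passed == [cand] and rejected == []

    def test_blocking_filter_removes_with_label(self):
        cand = make_candidate(20, 100)
        cand.p_freq, cand.posterior = 1e-9, 0.999
        cand.filters.add("coverage")
        passed, rejected = call_somatic([cand])
        assert passed == []
        assert rejected[0].filters >= {"coverage"}

    def test_threshold_failures_labelled(self):
        weak = make_candidate(3, 100)
        weak.p_freq, weak.posterior = 0.01, 0.5
        _, rejected = call_somatic([weak])
        assert rejected[0].filters >= {"p_freq", "posterior"}

    def test_empty_input(self):
        assert call_somatic([]) == ([], [])

    def test_unscored_candidate_rejected_loudly(self):
        with pytest.raises(ValueError, match="not been scored"):
            call_somatic([make_candidate(3, 100)])


class TestVafEstimation:
    def test_vaf_unbiased_over_planted_variants(self, recovery_sim):
        """Mean (vaf - truth) over >=500 variants is within its 95% CI of 0.

        VAFs are measured at every planted position from the high-quality
        base counts directly, without the candidate selection step (which
        would censor low-count draws and bias the comparison).
        """
        bundle = recovery_sim
        label = bundle.config.scenario.labels[0]
        piled = _pileup.accumulate_base_counts(
            bundle.cfdna, bundle.config.chrom, len(bundle.reference),
            bundle.matrix.quality_bins,
        )
        from cftrace._seq import BASE_INDEX

        diffs = []
        for v in bundle.truth.somatic:
            col = piled.hq_counts[:, v.pos - 1]
            n = int(col.sum())
            if n == 0:
                continue
            vaf = col[BASE_INDEX[v.alt]] / n
            diffs.append(vaf - v.expected_vaf[label])
        diffs = np.asarray(diffs)
        assert len(diffs) >= 500
        ci = 1.96 * diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < ci
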