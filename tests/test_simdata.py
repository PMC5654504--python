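"""Simulator tests: reference, fragment model, truth planting, reads, timecourse."""

from __future__ import annotations

import numpy as np
import pysam
import pytest
from scipy import stats

from cftrace import errormodel, simdata
from cftrace._seq import seq_to_codes


class TestReference:
    def test_length_and_gc(self):
        seq = simdata.simulate_reference(10_000, 0.41, 7)
        assert len(seq) == 10_000
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.41) < 0.02

    def test_seed_determinism(self):
        assert simdata.simulate_reference(1000, 0.5, 1) == simdata.simulate_reference(1000, 0.5, 1)
        assert simdata.simulate_reference(1000, 0.5, 1) != simdata.simulate_reference(1000, 0.5, 2)

    def test_extreme_gc(self):
        seq = simdata.simulate_reference(10_000, 0.99, 3)
        gc = sum(b in "GC" for b in seq) / len(seq)  # direct base tally
        assert gc > 0.95

    def test_rejects_short_or_degenerate(self):
        with pytest.raises(ValueError):
            simdata.simulate_reference(10, 0.5, 1)
        with pytest.raises(ValueError):
            simdata.simulate_reference(5000, 0.0, 1)


class TestFragmentModel:
    def test_empty_and_negative(self):
        assert simdata.sample_fragment_lengths(0).size == 0
        with pytest.raises(ValueError):
            simdata.sample_fragment_lengths(-1)

    def test_minimum_length_floor(self):
        lengths = simdata.sample_fragment_lengths(20_000, simdata.SimConfig(seed=2))
        assert lengths.min() >= 30

    def test_determinism(self):
        cfg = simdata.SimConfig(seed=11)
        a = simdata.sample_fragment_lengths(5000, cfg)
        b = simdata.sample_fragment_lengths(5000, cfg)
        assert np.array_equal(a, b)

    def test_pmf_mode_and_subpeaks(self):
        lengths, pmf = simdata.fragment_length_pmf(simdata.SimConfig())
        assert lengths[np.argmax(pmf)] == 167
        # analytic sub-peaks of the modulated pmf sit 10 bases apart
        sub = pmf[(lengths >= 130) & (lengths < 167)]
        subl = lengths[(lengths >= 130) & (lengths < 167)]
        local_max = [
            int(subl[i]) for i in range(1, len(sub) - 1)
            if sub[i] > sub[i - 1] and sub[i] > sub[i + 1]
        ]
        # envelope slope can shift a far sub-peak by one base toward the mode
        assert len(local_max) == 3
        assert all(abs(p - q) <= 1 for p, q in zip(local_max, [137, 147, 157]))


class TestPlantVariants:
    def test_signature_weighted_planting(self):
        cfg = simdata.SimConfig(
            reference_length=300_000, somatic_count=1000,
            signature_weights=simdata.uv_signature_weights(0.8), seed=4,
        )
        ref = simdata.simulate_reference(cfg.reference_length, 0.41, cfg.seed)
        truth = simdata.plant_variants(ref, cfg)
        assert len(truth.somatic) == 1000
        is_ct = [
            (v.ref, v.alt) in {("C", "T"), ("G", "A")} for v in truth.somatic
        ]
        assert abs(np.mean(is_ct) - 0.8) < 0.04  # multinomial oracle band

    def test_class_frequencies_follow_weights(self):
        """Chi-square goodness of fit of planted classes vs weights (n=10000)."""
        from cftrace.signatures import SBS96_CLASSES, classify_substitution

        cfg = simdata.SimConfig(
            reference_length=500_000, somatic_count=10_000,
            germline_het_rate=0.0, seed=9,
        )
        ref = simdata.simulate_reference(cfg.reference_length, 0.41, cfg.seed)
        truth = simdata.plant_variants(ref, cfg)
        observed = {c: 0 for c in SBS96_CLASSES}
        for v in truth.somatic:
            triplet = ref[v.pos - 2: v.pos + 1]
            observed[classify_substitution(triplet, v.alt)] += 1
        weights = np.array([cfg.signature_weights[c] for c in SBS96_CLASSES])
        exp = weights * len(truth.somatic)
        obs = np.array([observed[c] for c in SBS96_CLASSES])
        keep = exp >= 5
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_degenerate_counts(self):
        ref = simdata.simulate_reference(20_000, 0.41, 5)
        none = simdata.plant_variants(
            ref, simdata.SimConfig(reference_length=20_000, somatic_count=0, seed=5)
        )
        assert none.somatic == []
        assert len(none.germline) > 0
        only_somatic = simdata.plant_variants(
            ref,
            simdata.SimConfig(
                reference_length=20_000, somatic_count=10,
                germline_het_rate=0.0, seed=5,
            ),
        )
        assert len(only_somatic.somatic) == 10
        assert only_somatic.germline == {}

    def test_somatic_disjoint_from_germline(self):
        cfg = simdata.SimConfig(
            reference_length=100_000, somatic_count=300,
            germline_het_rate=5e-3, seed=6,
        )
        ref = simdata.simulate_reference(cfg.reference_length, 0.41, cfg.seed)
        truth = simdata.plant_variants(ref, cfg)
        assert not ({v.pos for v in truth.somatic} & set(truth.germline))

    def test_expected_vaf_is_half_carrier_fraction(self):
        cfg = simdata.SimConfig(reference_length=50_000, somatic_count=50, seed=7)
        ref = simdata.simulate_reference(cfg.reference_length, 0.41, cfg.seed)
        truth = simdata.plant_variants(ref, cfg)
        scenario = cfg.scenario
        for v in truth.somatic:
            expected = 0.5 * sum(
                scenario.fraction(c)[0] for c in v.carriers
            )
            assert v.expected_vaf[scenario.labels[0]] == pytest.approx(expected)

    def test_impossible_class_demand_raises(self):
        from cftrace.signatures import SBS96_CLASSES

        # a GC-free reference has no C-centred contexts at all
        ref = "AT" * 5000
        cfg = simdata.SimConfig(
            reference_length=10_000, somatic_count=10,
            germline_het_rate=0.0,
            signature_weights={
                c: (1.0 if c == "A[C>T]A" else 0.0) for c in SBS96_CLASSES
            },
            seed=1,
        )
        with pytest.raises(ValueError, match="matching contexts"):
            simdata.plant_variants(ref, cfg)


class TestAlignments:
    def test_errorfree_mismatches_are_truth_variants(self, errorfree_sim):
        bundle = errorfree_sim
        truth_pos = {v.pos - 1 for v in bundle.truth.somatic}
        truth_pos |= {p - 1 for p in bundle.truth.germline}
        refcodes = seq_to_codes(bundle.reference)
        with pysam.AlignmentFile(str(bundle.cfdna)) as bam:
            n_checked = 0
            for read in bam.fetch(bundle.config.chrom):
                codes = seq_to_codes(read.query_sequence)
                span = refcodes[read.reference_start: read.reference_end]
                mism = np.flatnonzero(codes != span) + read.reference_start
                assert set(mism.tolist()) <= truth_pos
                n_checked += 1
        assert n_checked > 1000

    def test_mean_depth_within_five_percent(self, tmp_path):
        cfg = simdata.SimConfig(
            reference_length=100_000, somatic_count=0, germline_het_rate=0.0,
            scenario=simdata.null_scenario(), mean_depth=50.0, seed=3,
        )
        ref = simdata.simulate_reference(cfg.reference_length, 0.41, cfg.seed)
        truth = simdata.plant_variants(ref, cfg)
        paths = simdata.generate_alignments(ref, truth, cfg, tmp_path, germline=False)
        cov = np.zeros(cfg.reference_length)
        with pysam.AlignmentFile(str(paths["cfdna_tp1"])) as bam:
            for read in bam.fetch(cfg.chrom):
                cov[read.reference_start: read.reference_end] += 1
        assert abs(cov.mean() / cfg.mean_depth - 1) < 0.05

    def test_sam_output_is_byte_identical_across_runs(self, tmp_path):
        cfg = simdata.SimConfig(
            reference_length=5_000, somatic_count=5, mean_depth=20.0, seed=8,
        )
        ref = simdata.simulate_reference(cfg.reference_length, 0.41, cfg.seed)
        truth = simdata.plant_variants(ref, cfg)
        p1 = simdata.generate_alignments(ref, truth, cfg, tmp_path / "a", fmt="sam")
        p2 = simdata.generate_alignments(ref, truth, cfg, tmp_path / "b", fmt="sam")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_alt_fraction_matches_expected_vaf(self, tmp_path):
        """Single het somatic variant, tumour fraction 0.10, no errors."""
        chrom = "sim1"
        cfg = simdata.SimConfig(
            reference_length=5_000, somatic_count=0, germline_het_rate=0.0,
            scenario=simdata.Scenario(
                name="one-clone",
                timepoints=(("t", 0),),
                subclones=(simdata.Subclone("A", (0.10,)),),
                groups=(simdata.VariantGroup("A", ("A",), 1.0),),
            ),
            mean_depth=1000.0,
            error_matrix=errormodel.ConfusionMatrix.identity(),
            seed=12,
        )
        ref = simdata.simulate_reference(cfg.reference_length, 0.41, cfg.seed)
        pos = 2500
        variant = simdata.SomaticVariant(
            chrom=chrom, pos=pos, ref=ref[pos - 1],
            alt="A" if ref[pos - 1] != "A" else "C",
            group="A", carriers=("A",), expected_vaf={"t": 0.05},
        )
        truth = simdata.TruthSet(chrom=chrom, germline={}, somatic=[variant])
        paths = simdata.generate_alignments(ref, truth, cfg, tmp_path, germline=False)
        alt = depth = 0
        with pysam.AlignmentFile(str(paths["cfdna_t"])) as bam:
            for read in bam.fetch(chrom, pos - 1, pos):
                base = read.query_sequence[pos - 1 - read.reference_start]
                depth += 1
                alt += base == variant.alt
        lo, hi = stats.binom.interval(0.99, depth, 0.05)
        assert lo <= alt <= hi

    def test_zero_depth_rejected(self, tmp_path):
        cfg = simdata.SimConfig(reference_length=5_000, mean_depth=0.0, seed=1)
        ref = simdata.simulate_reference(5_000, 0.41, 1)
        truth = simdata.plant_variants(ref, cfg)
        with pytest.raises(ValueError):
            simdata.generate_alignments(ref, truth, cfg, tmp_path)


class TestTimecourse:
    def test_single_clone_constant_fraction(self):
        sc = simdata.Scenario(
            name="flat",
            timepoints=(("t1", 0), ("t2", 10), ("t3", 20)),
            subclones=(simdata.Subclone("A", (0.1, 0.1, 0.1)),),
            groups=(simdata.VariantGroup("A", ("A",), 1.0),),
        )
        tc = simdata.simulate_timecourse(sc, n_variants=5)
        assert np.allclose(tc.vaf.to_numpy(), 0.05)

    def test_relapse_scenario_driver_vafs(self):
        tc = simdata.simulate_timecourse(simdata.relapse_scenario(), n_variants=60)
        driver = tc.vaf.loc[tc.driver]
        assert driver.iloc[0] == pytest.approx(0.05)   # pre-treatment
        assert driver.iloc[-1] == pytest.approx(0.08)  # final draw
        assert driver.iloc[3] == 0.0                   # on-therapy nadir
        assert tc.imaging_day == 207

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum above 1"):
            simdata.Scenario(
                name="bad",
                timepoints=(("t", 0),),
                subclones=(simdata.Subclone("A", (0.7,)), simdata.Subclone("B", (0.5,))),
                groups=(simdata.VariantGroup("A", ("A",), 1.0),),
            )

    def test_counts_table_deterministic_and_binomial_modes(self):
        tc = simdata.simulate_timecourse(simdata.relapse_scenario(), n_variants=10)
        det = tc.to_counts(depth=5000)
        assert (det["alt"] == (tc.vaf.stack().reindex(
            det.set_index(["variant", "timepoint"]).index) * 5000).round().astype(int).to_numpy()).all()
        rng = np.random.default_rng(0)
        noisy = tc.to_counts(depth=5000, rng=rng)
        assert (noisy["depth"] == 5000).all()
        assert not noisy.equals(det)
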