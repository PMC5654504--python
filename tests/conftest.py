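"""Shared fixtures: simulated cfDNA datasets generated once per session."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pysam
import pytest

from cftrace import errormodel, simdata


@dataclass
class SimBundle:
    config: simdata.SimConfig
    reference: str
    truth: simdata.TruthSet
    paths: dict[str, Path]
    matrix: errormodel.ConfusionMatrix

    @property
    def refdict(self) -> dict[str, str]:
        return {self.config.chrom: self.reference}

    @property
    def cfdna(self) -> Path:
        label = self.config.scenario.labels[0]
        return self.paths[f"cfdna_{label}"]

    @property
    def germline(self) -> Path:
        return self.paths["germline"]


def _simulate(config: simdata.SimConfig, out_dir: Path) -> SimBundle:
    reference = simdata.simulate_reference(
        config.reference_length, config.gc_fraction, config.seed
    )
    truth = simdata.plant_variants(reference, config)
    paths = simdata.generate_alignments(reference, truth, config, out_dir)
    excluded = {(truth.chrom, v.pos) for v in truth.somatic}
    excluded |= {(truth.chrom, p) for p in truth.germline}
    matrix = errormodel.estimate_confusion_matrix(
        paths["germline"], {config.chrom: reference}, excluded_sites=excluded,
        sample_id="germline",
    )
    return SimBundle(config, reference, truth, paths, matrix)


@pytest.fixture(scope="session")
def recovery_sim(tmp_path_factory) -> SimBundle:
    """Post-relapse snapshot at 100x cfDNA / 34x germline with 0.1% error.

    150 kb genome, 600 somatic SNVs split 60/25/15 between truncal,
    A-private and B-private groups (subclone fractions 0.16 / ~0.042), so
    heterozygous VAFs sit at ~10.1%, 8% and 2.1%.
    """
    config = simdata.SimConfig(
        reference_length=150_000,
        somatic_count=600,
        scenario=simdata.snapshot_scenario("relapse"),
        mean_depth=100.0,
        germline_depth=34.0,
        error_matrix=errormodel.ConfusionMatrix.uniform(0.001),
        seed=11,
    )
    return _simulate(config, tmp_path_factory.mktemp("recovery"))


@pytest.fixture(scope="session")
def null_sim(tmp_path_factory) -> SimBundle:
    """Tumour-fraction-zero genome: germline hets only, 0.1% error."""
    config = simdata.SimConfig(
        reference_length=150_000,
        somatic_count=0,
        scenario=simdata.null_scenario(),
        mean_depth=100.0,
        germline_depth=34.0,
        error_matrix=errormodel.ConfusionMatrix.uniform(0.001),
        seed=11,
    )
    return _simulate(config, tmp_path_factory.mktemp("null"))


@pytest.fixture(scope="session")
def errorfree_sim(tmp_path_factory) -> SimBundle:
    """Small error-free dataset for exactness properties."""
    config = simdata.SimConfig(
        reference_length=40_000,
        somatic_count=60,
        scenario=simdata.snapshot_scenario("relapse"),
        mean_depth=80.0,
        germline_depth=40.0,
        error_matrix=errormodel.ConfusionMatrix.identity(),
        seed=11,
    )
    return _simulate(config, tmp_path_factory.mktemp("errorfree"))


def write_sam(path: Path, chrom: str, length: int, reads, sample: str = "s") -> Path:
    """Write hand-constructed reads as a SAM file.

    ``reads`` is an iterable of (name, pos0, seq, baseq, mapq, flag).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": length}],
        "RG": [{"ID": sample, "SM": sample}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, pos0, seq, baseq, mapq, flag in sorted(reads, key=lambda r: r[1]):
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = mapq
            a.cigarstring = f"{len(seq)}M"
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(chr(baseq + 33) * len(seq))
            a.flag = flag
            a.set_tag("RG", sample)
            out.write(a)
    return path
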