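"""End-to-end pipeline driver: simulate -> error model -> call -> verify ->
signature -> track, with a checksummed run manifest.

The pipeline operates on a simulated patient by default (no external data
needed): cfDNA timepoints plus a germline sample are generated, the error
model is estimated from the germline alignments, stage-1 candidates are
called on the first cfDNA timepoint, verified against the germline, the
mutation spectrum is built from the verified calls, and the expected
trajectory table is tracked for subclones and molecular progression.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger("cftrace")

_KNOWN_KEYS = {
    "seed", "out_dir", "log_level",
    "reference_length", "gc_fraction", "germline_het_rate", "somatic_count",
    "mean_depth", "germline_depth", "error_rate", "scenario",
    "timecourse_depth", "n_tracked_variants",
    "alpha", "min_posterior", "prior_somatic",
    "min_alt_reads", "coverage_bounds",
    "window", "kmer", "min_support", "germline_tolerance",
    "detection_min_alt", "detection_min_vaf",
    "rise_threshold", "preceding_undetected", "min_fraction",
}


@dataclass
class RunConfig:
    """Pipeline configuration; every field mirrors a module default."""

    seed: int = 11
    out_dir: str = "cftrace_run"
    log_level: str = "INFO"
    reference_length: int = 150_000
    gc_fraction: float = 0.41
    germline_het_rate: float = 8e-4
    somatic_count: int = 300
    mean_depth: float = 100.0
    germline_depth: float = 34.0
    error_rate: float = 0.001
    scenario: str = "relapse"  # snapshot used for read simulation
    timecourse_depth: int = 5000
    n_tracked_variants: int = 60
    alpha: float = 1e-6
    min_posterior: float = 0.95
    prior_somatic: float = 1e-4
    min_alt_reads: int = 3
    coverage_bounds: tuple[float, float] = (0.25, 2.0)
    window: int = 30
    kmer: int = 31
    min_support: int = 3
    germline_tolerance: int = 0
    detection_min_alt: int = 3
    detection_min_vaf: float = 0.002
    rise_threshold: float = 0.01
    preceding_undetected: int = 2
    min_fraction: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "coverage_bounds" in payload:
            payload["coverage_bounds"] = tuple(payload["coverage_bounds"])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["coverage_bounds"] = list(self.coverage_bounds)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    from cftrace import caller, errormodel, haploverify, io, signatures, simdata, tracking

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    logging.basicConfig(level=config.log_level)
    artefacts: dict[str, Path] = {"config": out / "config.yaml"}
    stage = "simulate"
    try:
        simcfg = simdata.SimConfig(
            reference_length=config.reference_length,
            gc_fraction=config.gc_fraction,
            germline_het_rate=config.germline_het_rate,
            somatic_count=config.somatic_count,
            scenario=simdata.snapshot_scenario(config.scenario),
            mean_depth=config.mean_depth,
            germline_depth=config.germline_depth,
            error_matrix=errormodel.ConfusionMatrix.uniform(config.error_rate),
            seed=config.seed,
        )
        reference = simdata.simulate_reference(
            simcfg.reference_length, simcfg.gc_fraction, simcfg.seed
        )
        truth = simdata.plant_variants(reference, simcfg)
        refpath = io.write_fasta({simcfg.chrom: reference}, out / "reference.fa")
        artefacts["reference"] = refpath
        artefacts.update(io.write_truth_tables(truth, out))
        bams = simdata.generate_alignments(reference, truth, simcfg, out)
        artefacts.update(bams)
        label = simcfg.scenario.labels[0]
        cf_bam, gl_bam = bams[f"cfdna_{label}"], bams["germline"]
        log.info("stage=simulate reference=%s cfdna=%s", refpath, cf_bam)

        stage = "error-model"
        excluded = {(truth.chrom, v.pos) for v in truth.somatic}
        excluded |= {(truth.chrom, p) for p in truth.germline}
        matrix = errormodel.estimate_confusion_matrix(
            gl_bam, {simcfg.chrom: reference}, excluded_sites=excluded,
            sample_id="germline",
        )
        matrix.to_json(out / "error_model.json")
        artefacts["error_model"] = out / "error_model.json"
        log.info("stage=error-model sites=%d", matrix.site_count)

        stage = "call"
        genotypes = truth.germline_genotypes()
        scan = caller.scan_candidates(
            cf_bam, {simcfg.chrom: reference}, genotypes, matrix,
            coverage_bounds=config.coverage_bounds,
            min_alt_reads=config.min_alt_reads,
        )
        caller.score_candidates(scan.candidates, matrix,
                                prior_somatic=config.prior_somatic)
        passed, rejected = caller.call_somatic(
            scan.candidates, alpha=config.alpha, min_posterior=config.min_posterior
        )
        log.info("stage=call candidates=%d passed=%d", len(scan.candidates), len(passed))

        stage = "verify"
        verdicts = {}
        for cand in passed:
            verdicts[cand.key] = haploverify.verify_candidate(
                cand, cf_bam, gl_bam, {simcfg.chrom: reference}, genotypes,
                w=config.window, k=config.kmer,
                min_support=config.min_support,
                germline_tolerance=config.germline_tolerance,
            )
        verified = [c for c in passed if verdicts[c.key].verdict == "verified"]
        vcf_path = io.write_candidate_vcf(
            passed + rejected, {simcfg.chrom: len(reference)},
            out / "somatic.vcf", verdicts,
        )
        artefacts["vcf"] = vcf_path
        log.info("stage=verify verified=%d", len(verified))

        stage = "signature"
        spectrum = signatures.build_spectrum(
            [(c.chrom, c.pos, c.ref, c.alt) for c in verified],
            {simcfg.chrom: reference}, sample_id=label,
        )
        spectrum.to_frame().to_csv(out / "spectrum96.tsv", sep="\t", index=False)
        artefacts["spectrum"] = out / "spectrum96.tsv"

        stage = "track"
        tc = simdata.simulate_timecourse(
            simdata.relapse_scenario(), n_variants=config.n_tracked_variants
        )
        obs = tc.to_counts(depth=config.timecourse_depth)
        obs.to_csv(out / "observations.tsv", sep="\t", index=False)
        artefacts["observations"] = out / "observations.tsv"
        vm = tracking.build_vaf_matrix(
            obs, min_alt=config.detection_min_alt, min_vaf=config.detection_min_vaf
        )
        vm.vaf.to_csv(out / "vaf_matrix.tsv", sep="\t")
        artefacts["vaf_matrix"] = out / "vaf_matrix.tsv"
        clusters = tracking.cluster_trajectories(vm)
        cluster_rows = [{"variant": v, "cluster": c} for v, c in clusters.assignments.items()]
        pd.DataFrame(cluster_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
        artefacts["clusters"] = out / "clusters.tsv"
        call = tracking.detect_progression(
            vm,
            rise_threshold=config.rise_threshold,
            preceding_undetected=config.preceding_undetected,
            min_fraction=config.min_fraction,
            imaging_day=tc.imaging_day,
        )
        progression = {
            "call_day": call.call_day,
            "imaging_day": call.imaging_day,
            "lead_time_days": call.lead_time_days,
            "rule_trace": call.rule_trace,
        }
        (out / "progression.json").write_text(json.dumps(progression, indent=2))
        artefacts["progression"] = out / "progression.json"
    except FileNotFoundError as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: missing file {exc}") from exc
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "stages": ["simulate", "error-model", "call", "verify", "signature", "track"],
        "n_candidates": len(scan.candidates),
        "n_passed": len(passed),
        "n_verified": len(verified),
        "progression_call_day": call.call_day,
        "lead_time_days": call.lead_time_days,
        "artefacts": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in artefacts.items()
            if Path(p).is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
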