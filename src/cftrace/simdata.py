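"""Synthetic cfDNA data with the statistical structure the caller assumes.

The module generates references, germline/somatic truth sets, error-bearing
aligned reads and multi-timepoint subclone VAF trajectories:

* fragment lengths follow the canonical plasma cfDNA distribution — a
  unimodal peak at 167 bp with sub-peaks every 10 bp below the mode,
  reflecting nucleosomal protection and its helical-pitch trimming;
* somatic variants are planted with trinucleotide-context probabilities
  proportional to a 96-class signature (UV-dominated C>T by default);
* circulating tumour DNA is a minority population: each subclone contributes
  tumour fraction 5-20% depending on timepoint, so heterozygous somatic
  VAFs sit in the few-percent range where the caller has to work;
* a deterministic "relapse trajectory" scenario reproduces the qualitative
  clinical course the tracker is designed to detect: two subclones present
  before treatment, suppressed on therapy, re-emerging at day 119 with
  radiological confirmation only at day 207.

Everything is driven by one integer seed; per-sample substreams are derived
by fixed offsets so outputs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cftrace._seq import BASES, BASE_INDEX, COMPLEMENT, seq_to_codes
from cftrace.errormodel import ConfusionMatrix
from cftrace.signatures import SBS96_CLASSES, class_components

# fixed offsets for per-purpose random substreams
_STREAM_REFERENCE = 0
_STREAM_VARIANTS = 1
_STREAM_FRAGMENTS = 2
_STREAM_READS_BASE = 100  # + sample index


# ---------------------------------------------------------------------------
# scenarios: subclone tumour-fraction dynamics


@dataclass(frozen=True)
class Subclone:
    """A tumour subpopulation with one tumour fraction per timepoint."""

    name: str
    fractions: tuple[float, ...]


@dataclass(frozen=True)
class VariantGroup:
    """A set of variants sharing carrier subclones (e.g. truncal, private)."""

    name: str
    carriers: tuple[str, ...]
    proportion: float


@dataclass(frozen=True)
class Scenario:
    """Timepoints plus subclone dynamics plus variant-group composition."""

    name: str
    timepoints: tuple[tuple[str, int], ...]  # (label, day)
    subclones: tuple[Subclone, ...]
    groups: tuple[VariantGroup, ...]
    imaging_day: int | None = None

    def __post_init__(self) -> None:
        if not self.subclones or not self.timepoints:
            raise ValueError("scenario needs at least one subclone and one timepoint")
        for sc in self.subclones:
            if len(sc.fractions) != len(self.timepoints):
                raise ValueError(f"subclone {sc.name}: fraction count != timepoint count")
        totals = np.sum([sc.fractions for sc in self.subclones], axis=0)
        if (totals > 1.0 + 1e-12).any():
            raise ValueError("subclone tumour fractions sum above 1 at some timepoint")
        props = sum(g.proportion for g in self.groups)
        if self.groups and abs(props - 1.0) > 1e-9:
            raise ValueError("variant-group proportions must sum to 1")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.timepoints]

    @property
    def days(self) -> list[int]:
        return [day for _, day in self.timepoints]

    def fraction(self, subclone: str) -> np.ndarray:
        for sc in self.subclones:
            if sc.name == subclone:
                return np.asarray(sc.fractions, dtype=float)
        raise KeyError(subclone)

    def expected_vaf(self, carriers: Sequence[str]) -> np.ndarray:
        """Heterozygous somatic VAF trajectory: half the carrier tumour fraction."""
        return 0.5 * np.sum([self.fraction(c) for c in carriers], axis=0)


#: sampling days of the default relapse-trajectory scenario
RELAPSE_DAYS: tuple[int, ...] = (-7, 0, 17, 42, 70, 100, 119, 150, 280, 343)
#: radiological progression date of the default scenario
RELAPSE_IMAGING_DAY = 207


def _clone_a_fraction(day: int) -> float:
    """Driver-bearing subclone: 10% pre-treatment, cleared on therapy,
    re-emerging linearly from 2% at day 119 to 16% at day 343."""
    if day <= 0:
        return 0.10
    if day < 119:
        return 0.0
    return 0.02 + (0.16 - 0.02) * (day - 119) / (343 - 119)


def relapse_scenario() -> Scenario:
    """Default two-subclone relapse trajectory over ten sampling days.

    Subclone A carries the driver; subclone B follows the same shape scaled
    by 0.7 but collapses to half its day-280 fraction at the final draw.
    Imaging confirms progression only at day 207, well after the molecular
    re-emergence at day 119.
    """
    a = tuple(_clone_a_fraction(d) for d in RELAPSE_DAYS)
    b = []
    for d in RELAPSE_DAYS:
        if d <= 280:
            b.append(0.7 * _clone_a_fraction(d))
        else:
            b.append(0.5 * 0.7 * _clone_a_fraction(280))
    return Scenario(
        name="relapse-trajectory",
        timepoints=tuple((f"tp{i + 1}", d) for i, d in enumerate(RELAPSE_DAYS)),
        subclones=(Subclone("A", a), Subclone("B", tuple(b))),
        groups=(VariantGroup("A", ("A",), 0.5), VariantGroup("B", ("B",), 0.5)),
        imaging_day=RELAPSE_IMAGING_DAY,
    )


def snapshot_scenario(which: str = "relapse") -> Scenario:
    """Single-timepoint composition for WGS-style read simulation.

    ``"pretreatment"`` is the day-0 composition of the relapse trajectory
    (A=0.10, B=0.07); ``"relapse"`` the day-343 composition (A=0.16,
    B~0.042).  Variants are 60% truncal (carried by both subclones), 25%
    private to A and 15% private to B.
    """
    rel = relapse_scenario()
    idx = {"pretreatment": 1, "relapse": len(RELAPSE_DAYS) - 1}[which]
    label, day = rel.timepoints[idx]
    return Scenario(
        name=f"snapshot-{which}",
        timepoints=((label, day),),
        subclones=tuple(
            Subclone(sc.name, (sc.fractions[idx],)) for sc in rel.subclones
        ),
        groups=(
            VariantGroup("truncal", ("A", "B"), 0.60),
            VariantGroup("A", ("A",), 0.25),
            VariantGroup("B", ("B",), 0.15),
        ),
        imaging_day=None,
    )


def null_scenario(timepoints: int = 1) -> Scenario:
    """Tumour-fraction-zero scenario (pure germline cfDNA)."""
    return Scenario(
        name="tumour-free",
        timepoints=tuple((f"tp{i + 1}", i) for i in range(timepoints)),
        subclones=(Subclone("A", (0.0,) * timepoints),),
        groups=(VariantGroup("A", ("A",), 1.0),),
    )


# ---------------------------------------------------------------------------
# configuration and truth


def uv_signature_weights(ct_mass: float = 0.8) -> dict[str, float]:
    """UV-damage-dominated 96-class weights.

    ``ct_mass`` of the probability lands on C>T classes, with 5'-pyrimidine
    (dipyrimidine) contexts weighted three-fold — the hallmark of pyrimidine
    dimer formation; the remainder is spread evenly over the other classes.
    """
    if not 0 < ct_mass < 1:
        raise ValueError("ct_mass must be in (0, 1)")
    weights: dict[str, float] = {}
    ct_classes = [c for c in SBS96_CLASSES if c[2:5] == "C>T"]
    raw = {c: (3.0 if c[0] in "CT" else 1.0) for c in ct_classes}
    norm = sum(raw.values())
    rest = [c for c in SBS96_CLASSES if c not in raw]
    for c in SBS96_CLASSES:
        weights[c] = ct_mass * raw[c] / norm if c in raw else (1 - ct_mass) / len(rest)
    return weights


@dataclass
class SimConfig:
    """Parameters of the cfDNA simulation.

    Fragment-model defaults (mode 167 bp, 10 bp periodicity) follow the
    canonical plasma cfDNA size structure; the spread (sd 25 bp) and
    sub-peak amplitude (0.3) are pinned package choices.  ``mean_depth`` is
    read-base coverage of the cfDNA sample; the germline is shallower, as
    typical for a buffy-coat control.
    """

    reference_length: int = 200_000
    gc_fraction: float = 0.41
    germline_het_rate: float = 8e-4
    somatic_count: int = 400
    signature_weights: Mapping[str, float] = field(default_factory=uv_signature_weights)
    scenario: Scenario = field(default_factory=lambda: snapshot_scenario("relapse"))
    mean_depth: float = 100.0
    germline_depth: float = 34.0
    read_length: int = 100
    fragment_mode: int = 167
    fragment_sd: float = 25.0
    periodicity: float = 10.0
    periodicity_amplitude: float = 0.3
    min_fragment_length: int = 30
    error_matrix: ConfusionMatrix = field(default_factory=lambda: ConfusionMatrix.uniform(0.001))
    base_quality: int = 30
    mapping_quality: int = 60
    chrom: str = "sim1"
    seed: int = 11

    def __post_init__(self) -> None:
        if self.fragment_mode <= 0:
            raise ValueError("fragment_mode must be positive")
        total = sum(self.signature_weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("signature_weights must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SomaticVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    group: str
    carriers: tuple[str, ...]
    expected_vaf: dict[str, float]  # timepoint label -> VAF

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class TruthSet:
    """Planted ground truth: germline genotypes and somatic variants."""

    chrom: str
    germline: dict[int, tuple[str, str]]  # 1-based pos -> (ref, alt), het
    somatic: list[SomaticVariant]

    def germline_genotypes(self) -> dict[tuple[str, int], frozenset[str]]:
        return {
            (self.chrom, pos): frozenset(alleles)
            for pos, alleles in self.germline.items()
        }

    def somatic_by_pos(self) -> dict[int, SomaticVariant]:
        return {v.pos: v for v in self.somatic}


# ---------------------------------------------------------------------------
# reference and fragment model


def simulate_reference(length: int, gc: float = 0.41, seed: int = 11) -> str:
    """Random reference sequence with expected G+C fraction ``gc``."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng([seed, _STREAM_REFERENCE])
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs)
    return "".join(BASES[c] for c in codes)


def fragment_length_pmf(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, probabilities) of the cfDNA fragment-length model.

    A discretised normal centred at the mode, multiplicatively modulated by
    ``1 + amplitude * cos(2*pi*(L - mode)/period)`` so sub-peaks appear at
    mode-10, mode-20, ...; truncated below ``min_fragment_length``.
    """
    lo = config.min_fragment_length
    hi = int(np.ceil(config.fragment_mode + 8 * config.fragment_sd))
    lengths = np.arange(lo, hi + 1)
    base = stats.norm.pdf(lengths, loc=config.fragment_mode, scale=config.fragment_sd)
    mod = 1.0 + config.periodicity_amplitude * np.cos(
        2 * np.pi * (lengths - config.fragment_mode) / config.periodicity
    )
    pmf = np.clip(base * mod, 0.0, None)
    return lengths, pmf / pmf.sum()


def sample_fragment_lengths(
    n: int, config: SimConfig | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` fragment lengths from the cfDNA size distribution."""
    if n < 0:
        raise ValueError("n must be non-negative")
    config = config or SimConfig()
    if rng is None:
        rng = config.rng(_STREAM_FRAGMENTS)
    lengths, pmf = fragment_length_pmf(config)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(lengths, size=n, p=pmf)


def fragment_length_peaks(samples: np.ndarray, smooth: int = 3) -> dict:
    """Histogram mode and sub-modal peak spacing of sampled fragment lengths.

    Builds an integer histogram, smooths it with a centred ``smooth``-bin
    moving average, locates local maxima below the (unsmoothed) global mode
    and reports the median spacing between consecutive sub-peaks.
    """
    samples = np.asarray(samples)
    lo, hi = int(samples.min()), int(samples.max())
    values = np.arange(lo, hi + 1)
    hist = np.bincount(samples - lo, minlength=hi - lo + 1).astype(float)
    mode = int(values[np.argmax(hist)])
    kernel = np.ones(smooth) / smooth
    smoothed = np.convolve(hist, kernel, mode="same")

    from scipy.signal import find_peaks

    below = values < mode
    floor = 0.01 * smoothed.max()  # ignore noise peaks in the far tail
    peaks, _ = find_peaks(smoothed[below], distance=max(2, smooth), height=floor)
    sub_peaks = values[below][peaks]
    spacings = np.diff(np.sort(np.append(sub_peaks, mode)))
    spacing = float(np.median(spacings)) if spacings.size else float("nan")
    return {"mode": mode, "sub_peaks": sub_peaks.tolist(), "median_spacing": spacing}


# ---------------------------------------------------------------------------
# truth planting


def _context_positions(codes: np.ndarray) -> dict[int, np.ndarray]:
    """Interior positions (0-based) grouped by canonical trinucleotide context.

    Context ids encode (5' base, pyrimidine C/T, 3' base) on the pyrimidine
    strand: ``id = five*8 + (4 if T else 0) + three``.
    """
    left, mid, right = codes[:-2], codes[1:-1], codes[2:]
    known = (left < 4) & (mid < 4) & (right < 4)
    pyr = (mid == 1) | (mid == 3)
    five = np.where(pyr, left, 3 - right)
    three = np.where(pyr, right, 3 - left)
    midc = np.where(pyr, mid, 3 - mid)  # 1 (C) or 3 (T)
    ctx = five * 8 + np.where(midc == 3, 4, 0) + three
    out: dict[int, np.ndarray] = {}
    pos = np.arange(1, len(codes) - 1)
    for cid in range(32):
        sel = known & (ctx == cid)
        out[cid] = pos[sel]
    return out


def _class_context_id(label: str) -> tuple[int, str]:
    five, ref, alt, three = class_components(label)
    cid = BASE_INDEX[five] * 8 + (4 if ref == "T" else 0) + BASE_INDEX[three]
    return cid, alt


def plant_variants(
    reference: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Plant germline hets and signature-weighted somatic SNVs.

    Germline heterozygous sites are placed uniformly at
    ``germline_het_rate``; somatic SNVs are drawn with trinucleotide-context
    probabilities proportional to ``signature_weights`` and assigned to a
    variant group (subclone carrier set) of the scenario.  Somatic and
    germline positions are disjoint.
    """
    if rng is None:
        rng = config.rng(_STREAM_VARIANTS)
    codes = seq_to_codes(reference)
    L = len(reference)

    # germline hets
    het_mask = rng.random(L) < config.germline_het_rate
    germline: dict[int, tuple[str, str]] = {}
    for p0 in np.flatnonzero(het_mask):
        ref = reference[p0]
        if ref not in BASES:
            continue
        alt = rng.choice([b for b in BASES if b != ref])
        germline[int(p0) + 1] = (ref, str(alt))

    # somatic SNVs, signature-weighted
    scenario = config.scenario
    weights = np.array([config.signature_weights.get(c, 0.0) for c in SBS96_CLASSES])
    weights = weights / weights.sum()
    class_counts = rng.multinomial(config.somatic_count, weights)

    pools = _context_positions(codes)
    het_pos0 = {p - 1 for p in germline}
    for cid in pools:
        pool = pools[cid]
        pools[cid] = pool[~np.isin(pool, list(het_pos0))] if het_pos0 else pool

    group_names = [g.name for g in scenario.groups]
    group_probs = np.array([g.proportion for g in scenario.groups])
    carriers = {g.name: g.carriers for g in scenario.groups}

    somatic: list[SomaticVariant] = []
    used: dict[int, set[int]] = {cid: set() for cid in range(32)}
    for ci, label in enumerate(SBS96_CLASSES):
        count = int(class_counts[ci])
        if count == 0:
            continue
        cid, alt_pyr = _class_context_id(label)
        available = np.array([p for p in pools[cid] if p not in used[cid]])
        if len(available) < count:
            raise ValueError(
                f"signature class {label}: {count} events requested but only "
                f"{len(available)} matching contexts available"
            )
        chosen = rng.choice(available, size=count, replace=False)
        used[cid].update(int(p) for p in chosen)
        for p0 in np.sort(chosen):
            ref = reference[p0]
            alt = alt_pyr if ref in "CT" else COMPLEMENT[alt_pyr]
            grp = group_names[rng.choice(len(group_names), p=group_probs)]
            vaf = scenario.expected_vaf(carriers[grp])
            somatic.append(
                SomaticVariant(
                    chrom=config.chrom,
                    pos=int(p0) + 1,
                    ref=ref,
                    alt=alt,
                    group=grp,
                    carriers=carriers[grp],
                    expected_vaf={lab: float(v) for lab, v in zip(scenario.labels, vaf)},
                )
            )
    return TruthSet(chrom=config.chrom, germline=germline, somatic=somatic)


# ---------------------------------------------------------------------------
# read generation


def _mean_covered_bases(config: SimConfig) -> float:
    # both mates are written, so a fragment contributes r1+r2 read bases
    # (overlapping mate bases count twice, as in samtools depth)
    lengths, pmf = fragment_length_pmf(config)
    return float(np.sum(pmf * 2 * np.minimum(config.read_length, lengths)))


def _simulate_sample(
    reference: str,
    config: SimConfig,
    vaf_by_pos: Mapping[int, float],
    alt_by_pos: Mapping[int, str],
    het_by_pos: Mapping[int, tuple[str, str]],
    depth: float,
    rng: np.random.Generator,
    sample_id: str,
    path: Path,
) -> None:
    """Write one sample's paired cfDNA reads as coordinate-sorted SAM/BAM."""
    import pysam

    L = len(reference)
    rl = config.read_length
    n_frag = int(round(depth * L / _mean_covered_bases(config)))
    frag_len = sample_fragment_lengths(n_frag, config, rng)
    frag_len = np.minimum(frag_len, L)
    starts = (rng.random(n_frag) * (L - frag_len + 1)).astype(np.int64)
    order = np.argsort(starts, kind="stable")
    starts, frag_len = starts[order], frag_len[order]
    ends = starts + frag_len

    # per-fragment alternate-allele assignment at variant positions
    frag_subs: dict[int, list[tuple[int, str]]] = {}

    def assign(pos1: int, alt: str, prob: float) -> None:
        p0 = pos1 - 1
        i0 = np.searchsorted(starts, p0, side="right")
        cover = np.flatnonzero(ends[:i0] > p0)
        if cover.size == 0:
            return
        take = cover[rng.random(cover.size) < prob]
        for fi in take:
            frag_subs.setdefault(int(fi), []).append((p0, alt))

    for pos1, (_ref, alt) in het_by_pos.items():
        assign(pos1, alt, 0.5)
    for pos1, vaf in vaf_by_pos.items():
        if vaf > 0:
            assign(pos1, alt_by_pos[pos1], vaf)

    # sequencing-error parameters at the constant simulated base quality
    mat = config.error_matrix.matrices[config.error_matrix.bin_index(config.base_quality)]
    err_total = 1.0 - np.diag(mat)
    alt_codes = np.array([[o for o in range(4) if o != t] for t in range(4)])
    alt_cum = np.zeros((4, 3))
    for t in range(4):
        off = mat[t, alt_codes[t]]
        alt_cum[t] = np.cumsum(off / off.sum()) if off.sum() > 0 else np.array([1 / 3, 2 / 3, 1.0])

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom, "LN": L}],
        "RG": [{"ID": sample_id, "SM": sample_id}],
    }
    ref_codes = seq_to_codes(reference)

    def make_read_seq(r_start: int, r_len: int, subs: list[tuple[int, str]]) -> str:
        codes = ref_codes[r_start: r_start + r_len].copy()
        for p0, alt in subs:
            if r_start <= p0 < r_start + r_len:
                codes[p0 - r_start] = BASE_INDEX[alt]
        u = rng.random(r_len)
        err = u < err_total[codes]
        if err.any():
            idx = np.flatnonzero(err)
            for i in idx:
                t = codes[i]
                pick = np.searchsorted(alt_cum[t], rng.random())
                codes[i] = alt_codes[t, pick]
        return "".join(BASES[c] for c in codes)

    mode = "wh" if str(path).endswith(".sam") else "wb"
    records: list[tuple[int, int, int, str, bool]] = []  # (pos, frag, rlen, seq, is_read2)
    for fi in range(n_frag):
        fl = int(frag_len[fi])
        start = int(starts[fi])
        subs = frag_subs.get(fi, [])
        r1_len = min(rl, fl)
        r2_len = min(rl, fl)
        r2_start = start + fl - r2_len
        records.append((start, fi, r1_len, make_read_seq(start, r1_len, subs), False))
        records.append((r2_start, fi, r2_len, make_read_seq(r2_start, r2_len, subs), True))
    records.sort(key=lambda r: (r[0], r[1], r[4]))

    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for pos, fi, r_len, seq, is_read2 in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{sample_id}.frag{fi}"
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = config.mapping_quality
            a.cigarstring = f"{r_len}M"
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(chr(config.base_quality + 33) * r_len)
            fl = int(frag_len[fi])
            start = int(starts[fi])
            a.flag = 147 if is_read2 else 99
            a.next_reference_id = 0
            a.next_reference_start = start if is_read2 else start + fl - r_len
            a.template_length = -fl if is_read2 else fl
            a.set_tag("RG", sample_id)
            out.write(a)
    if mode == "wb":
        pysam.index(str(path))


def generate_alignments(
    reference: str,
    truth: TruthSet,
    config: SimConfig,
    out_dir: str | Path,
    timepoints: Sequence[str] | None = None,
    germline: bool = True,
    fmt: str = "bam",
) -> dict[str, Path]:
    """Simulate aligned read sets: cfDNA per timepoint plus a germline sample.

    Fragments are placed uniformly; each fragment overlapping a somatic
    variant carries the alternate allele with probability equal to that
    timepoint's expected VAF; germline hets are carried with probability
    0.5 in every sample.  Base errors follow ``config.error_matrix``.
    Returns a mapping of sample id to SAM/BAM path.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario
    labels = list(timepoints) if timepoints is not None else scenario.labels
    paths: dict[str, Path] = {}

    somatic_alt = {v.pos: v.alt for v in truth.somatic}

    def run(sample_id: str, vafs: Mapping[int, float], depth: float, stream: int) -> None:
        path = out_dir / f"{sample_id}.{fmt}"
        rng = config.rng(_STREAM_READS_BASE + stream)
        _simulate_sample(
            reference, config, vafs, somatic_alt, truth.germline,
            depth, rng, sample_id, path,
        )
        paths[sample_id] = path

    for si, label in enumerate(labels):
        vafs = {v.pos: v.expected_vaf[label] for v in truth.somatic}
        run(f"cfdna_{label}", vafs, config.mean_depth, si + 1)
    if germline:
        run("germline", {}, config.germline_depth, 0)
    return paths


# ---------------------------------------------------------------------------
# timecourse tables


@dataclass
class Timecourse:
    """Expected-VAF trajectories for a set of tracked variants."""

    vaf: pd.DataFrame  # variants x timepoint labels
    days: list[int]
    groups: dict[str, str]
    driver: str | None
    imaging_day: int | None

    def to_counts(
        self, depth: int = 5000, rng: np.random.Generator | None = None
    ) -> pd.DataFrame:
        """Long-format (variant, timepoint, day, alt, depth) observation table.

        With ``rng`` the alternate-read counts are binomial draws at the
        given depth (amplicon-like resampling); without, they are the
        deterministic expectation rounded to the nearest read.
        """
        rows = []
        for variant in self.vaf.index:
            for label, day in zip(self.vaf.columns, self.days):
                vaf = float(self.vaf.loc[variant, label])
                if rng is None:
                    alt = int(round(vaf * depth))
                else:
                    alt = int(rng.binomial(depth, vaf))
                rows.append(
                    {"variant": variant, "timepoint": label, "day": day,
                     "alt": alt, "depth": depth}
                )
        return pd.DataFrame(rows)


def simulate_timecourse(
    scenario: Scenario | SimConfig | None = None,
    n_variants: int = 60,
) -> Timecourse:
    """Deterministic expected-VAF table for a scenario's variant groups.

    Variants are apportioned to groups by their proportions (largest-
    remainder rounding); the first variant of the first driver-carrying
    group is labelled the driver.
    """
    if scenario is None:
        scenario = relapse_scenario()
    if isinstance(scenario, SimConfig):
        scenario = scenario.scenario
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")

    props = np.array([g.proportion for g in scenario.groups])
    counts = np.floor(props * n_variants).astype(int)
    remainder = n_variants - counts.sum()
    order = np.argsort(-(props * n_variants - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1

    rows, groups = {}, {}
    driver = None
    for g, cnt in zip(scenario.groups, counts):
        vaf = scenario.expected_vaf(g.carriers)
        for i in range(cnt):
            key = f"{g.name}_{i + 1:03d}"
            rows[key] = vaf
            groups[key] = g.name
            if driver is None and "A" in g.carriers:
                driver = key
    vaf_df = pd.DataFrame.from_dict(rows, orient="index", columns=scenario.labels)
    vaf_df = vaf_df.sort_index()
    return Timecourse(
        vaf=vaf_df,
        days=scenario.days,
        groups=groups,
        driver=driver,
        imaging_day=scenario.imaging_day,
    )


def timecourse_from_truth(truth: TruthSet, scenario: Scenario) -> Timecourse:
    """Expected-VAF trajectories of a planted truth set."""
    rows = {v.key: [v.expected_vaf[lab] for lab in scenario.labels] for v in truth.somatic}
    vaf_df = pd.DataFrame.from_dict(rows, orient="index", columns=scenario.labels).sort_index()
    groups = {v.key: v.group for v in truth.somatic}
    return Timecourse(
        vaf=vaf_df, days=scenario.days, groups=groups, driver=None,
        imaging_day=scenario.imaging_day,
    )
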