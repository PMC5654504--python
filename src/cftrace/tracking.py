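"""Longitudinal ctDNA layer: VAF matrices, subclones, progression, depth planning.

Per-timepoint variant observations are assembled into a variant x timepoint
VAF matrix with detection flags (a variant is "detected" only above a
read-count and frequency floor, mirroring the amplicon detection limit).
Variant trajectories are grouped into subclones by hierarchical
agglomerative clustering, molecular progression is called when a fraction
of tracked variants re-emerges after a run of undetected timepoints, and
the planner inverts the depth-requirement relation X = kappa / (alpha * f)
to ask how deep one must sequence to see a target allele fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

DEFAULT_DETECTION_MIN_ALT = 3
DEFAULT_DETECTION_MIN_VAF = 0.002
DEFAULT_RISE_THRESHOLD = 0.01
DEFAULT_PRECEDING_UNDETECTED = 2
DEFAULT_MIN_FRACTION = 0.25


@dataclass
class VAFMatrix:
    """Variant x timepoint allele-frequency matrix with detection flags.

    ``vaf`` holds 0 where ``detected`` is False; the read depth is retained
    so detection limits stay auditable.
    """

    vaf: pd.DataFrame       # variants x timepoint labels, floats
    detected: pd.DataFrame  # same shape, bool
    depth: pd.DataFrame     # same shape, int
    alt: pd.DataFrame       # same shape, int
    days: list[int]

    def __post_init__(self) -> None:
        vals = self.vaf.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("VAF entries must lie in [0, 1]")
        if ((~self.detected.to_numpy()) & (vals != 0)).any():
            raise ValueError("undetected entries must store VAF 0")

    @property
    def variants(self) -> list[str]:
        return list(self.vaf.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.vaf.columns)


def build_vaf_matrix(
    observations: pd.DataFrame | Iterable[Mapping],
    min_alt: int = DEFAULT_DETECTION_MIN_ALT,
    min_vaf: float = DEFAULT_DETECTION_MIN_VAF,
) -> VAFMatrix:
    """Assemble per-timepoint counts into a VAF matrix.

    ``observations`` is a long-format table with columns
    ``variant, timepoint, day, alt, depth`` (one row per variant per
    timepoint; variants absent from a timepoint's calls simply have no row
    and become undetected zeros — union semantics).  A variant is detected
    when ``alt >= min_alt`` and ``alt/depth >= min_vaf``.
    """
    df = pd.DataFrame(observations)
    required = {"variant", "timepoint", "day", "alt", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation table lacks columns: {sorted(missing)}")
    tp = df[["timepoint", "day"]].drop_duplicates()
    if tp["timepoint"].duplicated().any():
        raise ValueError("duplicate timepoint labels with conflicting days")
    tp = tp.sort_values("day")
    labels = tp["timepoint"].tolist()
    days = tp["day"].astype(int).tolist()
    variants = sorted(df["variant"].unique())

    shape = (len(variants), len(labels))
    alt = pd.DataFrame(np.zeros(shape, dtype=int), index=variants, columns=labels)
    depth = pd.DataFrame(np.zeros(shape, dtype=int), index=variants, columns=labels)
    dup = df.duplicated(subset=["variant", "timepoint"])
    if dup.any():
        raise ValueError("duplicate (variant, timepoint) observations")
    for row in df.itertuples():
        alt.loc[row.variant, row.timepoint] = int(row.alt)
        depth.loc[row.variant, row.timepoint] = int(row.depth)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(depth.to_numpy() > 0, alt.to_numpy() / np.maximum(depth.to_numpy(), 1), 0.0)
    detected = (alt.to_numpy() >= min_alt) & (raw >= min_vaf)
    vaf = np.where(detected, raw, 0.0)
    return VAFMatrix(
        vaf=pd.DataFrame(vaf, index=variants, columns=labels),
        detected=pd.DataFrame(detected, index=variants, columns=labels),
        depth=depth,
        alt=alt,
        days=days,
    )


@dataclass
class SubcloneCluster:
    """Hierarchical-clustering result over variant trajectories."""

    assignments: dict[str, int]
    linkage: np.ndarray
    n_clusters: int
    variants: list[str]

    def members(self, cluster_id: int) -> list[str]:
        return [v for v, c in self.assignments.items() if c == cluster_id]

    def major_clusters(self, min_size: int = 2) -> list[int]:
        sizes = pd.Series(list(self.assignments.values())).value_counts()
        return sorted(int(c) for c, n in sizes.items() if n >= min_size)


def cluster_trajectories(
    matrix: VAFMatrix,
    metric: str = "euclidean",
    linkage_method: str = "average",
    cut: tuple[str, float] = ("maxclust", 2),
) -> SubcloneCluster:
    """Agglomerative clustering of variant VAF trajectories.

    Rows are ordered lexicographically by variant key before linkage, which
    makes the result invariant to input row order (ties in the merge
    sequence resolve identically).  ``cut`` is ``("maxclust", k)`` for a
    fixed cluster count or ``("distance", h)`` for a dendrogram height.
    """
    if len(matrix.variants) < 2:
        raise ValueError("clustering needs at least 2 variants")
    if len(matrix.timepoints) < 2:
        raise ValueError("clustering needs at least 2 timepoints")
    ordered = sorted(matrix.variants)
    data = matrix.vaf.loc[ordered].to_numpy(dtype=float)
    dist = pdist(data, metric=metric)
    Z = hierarchy.linkage(dist, method=linkage_method)
    criterion, value = cut
    labels = hierarchy.fcluster(Z, t=value, criterion=criterion)
    assignments = {v: int(c) for v, c in zip(ordered, labels)}
    return SubcloneCluster(
        assignments=assignments,
        linkage=Z,
        n_clusters=int(len(set(labels))),
        variants=ordered,
    )


@dataclass
class ProgressionCall:
    """Result of molecular-progression detection on a VAF matrix."""

    call_day: int | None
    call_timepoint: str | None
    rule_trace: list[dict] = field(default_factory=list)
    lead_time_days: int | None = None
    imaging_day: int | None = None


def detect_progression(
    matrix: VAFMatrix,
    driver_set: Sequence[str] | None = None,
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
    preceding_undetected: int = DEFAULT_PRECEDING_UNDETECTED,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    imaging_day: int | None = None,
) -> ProgressionCall:
    """Call the earliest timepoint at which tracked variants re-emerge.

    A variant "rises" at timepoint t when it is detected with
    VAF >= ``rise_threshold`` after being undetected at all of the
    ``preceding_undetected`` immediately preceding timepoints.  Progression
    is called at the earliest sampling day where at least ``min_fraction``
    of the tracked variants rise; the lead time is the gap to the supplied
    imaging (radiological progression) day.
    """
    days = matrix.days
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("timepoint days must be strictly increasing")
    tracked = list(driver_set) if driver_set else matrix.variants
    unknown = set(tracked) - set(matrix.variants)
    if unknown:
        raise ValueError(f"driver_set variants not in matrix: {sorted(unknown)}")

    det = matrix.detected.loc[tracked].to_numpy()
    vaf = matrix.vaf.loc[tracked].to_numpy()
    r = preceding_undetected
    call_idx = None
    trace: list[dict] = []
    for t in range(r, len(days)):
        prior_clear = ~det[:, t - r: t].any(axis=1)
        rising = prior_clear & det[:, t] & (vaf[:, t] >= rise_threshold)
        frac = float(rising.sum()) / len(tracked)
        triggered = frac >= min_fraction
        trace.append(
            {"timepoint": matrix.timepoints[t], "day": days[t],
             "n_rising": int(rising.sum()), "n_tracked": len(tracked),
             "fraction": frac, "triggered": triggered}
        )
        if triggered and call_idx is None:
            call_idx = t
    call_day = days[call_idx] if call_idx is not None else None
    lead = (imaging_day - call_day) if (imaging_day is not None and call_day is not None) else None
    return ProgressionCall(
        call_day=call_day,
        call_timepoint=matrix.timepoints[call_idx] if call_idx is not None else None,
        rule_trace=trace,
        lead_time_days=lead,
        imaging_day=imaging_day,
    )


def sample_similarity(
    matrix: VAFMatrix,
    extra_samples: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of samples over shared variants.

    Samples are the matrix timepoints plus any extra VAF profiles (e.g. a
    tumour biopsy, keyed by variant).  Pairs sharing fewer than 2 variants,
    or with zero variance in either profile, get NaN rather than a silent 0.
    Returns (correlation matrix, shared-variant counts).
    """
    profiles: dict[str, pd.Series] = {
        tp: matrix.vaf[tp] for tp in matrix.timepoints
    }
    for name, vafs in (extra_samples or {}).items():
        profiles[name] = pd.Series(dict(vafs), dtype=float)
    names = list(profiles)
    if len(names) < 2:
        raise ValueError("similarity needs at least 2 samples")
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    shared = pd.DataFrame(0, index=names, columns=names)
    for i, a in enumerate(names):
        shared.loc[a, a] = len(profiles[a])
        for b in names[i + 1:]:
            common = profiles[a].index.intersection(profiles[b].index)
            shared.loc[a, b] = shared.loc[b, a] = len(common)
            if len(common) < 2:
                corr.loc[a, b] = corr.loc[b, a] = np.nan
                continue
            x = profiles[a][common].to_numpy(dtype=float)
            y = profiles[b][common].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                corr.loc[a, b] = corr.loc[b, a] = np.nan
                continue
            corr.loc[a, b] = corr.loc[b, a] = float(np.corrcoef(x, y)[0, 1])
    return corr, shared


@dataclass(frozen=True)
class DepthScalingParams:
    """The (X, kappa, alpha, f) depth-requirement tuple: X * alpha * f = kappa."""

    f: float
    alpha: float
    kappa: float
    X: float

    def __post_init__(self) -> None:
        if not np.isclose(self.X * self.alpha * self.f, self.kappa, rtol=1e-12):
            raise ValueError("inconsistent depth-scaling parameters: X*alpha*f != kappa")


def required_depth(f: float, alpha: float = 1.0, kappa: float = 1.0) -> DepthScalingParams:
    """Depth of coverage needed to see mutation frequency ``f``.

    ``alpha`` is the library efficiency (fraction of input molecules that
    yield usable reads) and ``kappa`` the read-count scaling efficiency
    (>= 1; grows with PCR duplication and coverage dispersion):
    ``X = kappa / (alpha * f)``.
    """
    if not 0 < f <= 1:
        raise ValueError("f must lie in (0, 1]")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    return DepthScalingParams(f=f, alpha=alpha, kappa=kappa, X=kappa / (alpha * f))
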