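"""ROI summaries, artifact exclusion, and group statistics.

Descriptive statistics are reported as "mean +/- SD; median, min-max" with
the sample (n-1) standard deviation.  Comparative analysis follows classical
parametric practice: one-way ANOVA, then pairwise pooled-variance t tests
with Bonferroni correction and Tukey HSD via the studentized range.  The
unit of analysis is the ROI mean (ten structure-specific ROIs per
structure), not the raw voxel.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ROIRole",
    "ROISet",
    "ROISummary",
    "GroupComparison",
    "AgeTrend",
    "summarize_roi",
    "summarize_roiset",
    "exclude_artifact_rois",
    "anova_oneway",
    "anova_posthoc",
    "contrast_structures",
    "age_trend",
    "plant_cubic_rois",
]


@dataclass(frozen=True)
class ROIRole:
    """What an ROI label code stands for."""

    structure: str  # "bone" | "sediment" | "healthy" | "diseased"
    specimen: str
    age_ma: float = 0.0
    habitat: str = "terrestrial"


@dataclass
class ROISet:
    """Integer label volume plus the role of each positive code.

    ``excluded`` maps codes flagged by artifact screening to the reason.
    """

    labels: np.ndarray
    roles: dict[int, ROIRole]
    excluded: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code in self.roles:
            if code <= 0:
                raise ValueError("ROI codes must be positive")

    @property
    def codes(self) -> list[int]:
        return sorted(self.roles)

    @property
    def active_codes(self) -> list[int]:
        return [c for c in self.codes if c not in self.excluded]

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass(frozen=True)
class ROISummary:
    """Descriptive statistics over one ROI's voxels."""

    mean: float
    sd: float
    median: float
    vmin: float
    vmax: float
    n_voxels: int
    excluded: bool = False
    reason: str | None = None

    def report(self) -> str:
        """Printed form, e.g. ``"1 ± 4 HU; 0, 0–14 HU"``."""
        return (
            f"{self.mean:.0f} ± {self.sd:.0f} HU; "
            f"{self.median:.0f}, {self.vmin:.0f}–{self.vmax:.0f} HU"
        )


def _values(image) -> np.ndarray:
    return np.asarray(getattr(image, "values", image), dtype=np.float64)


def summarize_roi(image, roi: np.ndarray) -> ROISummary:
    """Descriptive statistics of an image (map or HU volume) over an ROI.

    ``roi`` is a boolean mask on the image grid; empty ROIs are an error.
    """
    arr = _values(image)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != arr.shape:
        raise ValueError(f"ROI shape {roi.shape} does not match image {arr.shape}")
    vals = arr[roi]
    if vals.size == 0:
        raise ValueError("empty ROI")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return ROISummary(
        mean=float(np.mean(vals)),
        sd=sd,
        median=float(np.median(vals)),
        vmin=float(np.min(vals)),
        vmax=float(np.max(vals)),
        n_voxels=int(vals.size),
    )


def summarize_roiset(image, rois: ROISet) -> pd.DataFrame:
    """Per-ROI summary table (one row per code, roles and flags attached)."""
    records = []
    for code in rois.codes:
        s = summarize_roi(image, rois.mask(code))
        role = rois.roles[code]
        records.append(
            {
                "code": code,
                "structure": role.structure,
                "specimen": role.specimen,
                "age_ma": role.age_ma,
                "habitat": role.habitat,
                "mean": s.mean,
                "sd": s.sd,
                "median": s.median,
                "min": s.vmin,
                "max": s.vmax,
                "n_voxels": s.n_voxels,
                "excluded": code in rois.excluded,
                "reason": rois.excluded.get(code, ""),
            }
        )
    return pd.DataFrame.from_records(records)


def exclude_artifact_rois(
    rois: ROISet, artifact_mask: np.ndarray, max_fraction: float = 0.05
) -> ROISet:
    """Flag ROIs whose artifact-voxel fraction strictly exceeds the cap.

    Mirrors the practice of analyzing only ROIs placed in artifact-free
    areas; an ROI at exactly the threshold fraction is retained.
    """
    if not 0 <= max_fraction <= 1:
        raise ValueError("max_fraction must be in [0, 1]")
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if artifact_mask.shape != rois.labels.shape:
        raise ValueError("artifact mask shape does not match ROI labels")
    excluded = dict(rois.excluded)
    for code in rois.codes:
        m = rois.mask(code)
        n = int(m.sum())
        if n == 0:
            continue
        frac = float((m & artifact_mask).sum()) / n
        if frac > max_fraction:
            excluded[code] = (
                f"artifact fraction {frac:.3f} exceeds {max_fraction:.3f}"
            )
    return replace(rois, excluded=excluded)


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def _anova_components(groups: list[np.ndarray]):
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least two observations")
    n = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ssb = float((n * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    dfb = len(groups) - 1
    dfw = int(n.sum()) - len(groups)
    return n, means, ssb, ssw, dfb, dfw


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    Degenerate inputs follow the conventions: zero between-group variation
    gives (F, p) = (0, 1); zero within-group variation with real separation
    gives (inf, 0).
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    _, _, ssb, ssw, dfb, dfw = _anova_components(groups)
    if ssb == 0.0:
        return 0.0, 1.0
    if ssw == 0.0:
        return math.inf, 0.0
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return f, p


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA plus pairwise post-hoc comparisons.

    ``pairwise`` has one row per unordered pair with raw pooled-t,
    Bonferroni-adjusted and Tukey-HSD p values.
    """

    labels: tuple[str, ...]
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def anova_posthoc(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> GroupComparison:
    """ANOVA with Bonferroni and Tukey HSD post-hoc testing.

    Both post-hoc procedures share the ANOVA's pooled error variance (MSE,
    df = N - k), as in classical post-hoc practice: the raw pairwise p
    comes from t = (mean_i - mean_j)/sqrt(MSE (1/n_i + 1/n_j)), Bonferroni
    multiplies it by the number of pairs, and Tukey HSD refers sqrt(2)|t|
    to the studentized range.  With a shared statistic Tukey is never more
    conservative than Bonferroni (union bound).
    """
    labels = tuple(groups)
    arrays = [np.asarray(groups[k], dtype=np.float64) for k in labels]
    f, p = anova_oneway(arrays)
    n, means, _, ssw, _, dfw = _anova_components(arrays)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    m = len(pairs)
    rows = []
    mse = ssw / dfw
    if mse == 0.0:
        raw = {
            (i, j): 1.0 if means[i] == means[j] else 0.0 for i, j in pairs
        }
        tukey_p = dict(raw)
    else:
        hsd = stats.tukey_hsd(*arrays)
        tukey_p = {(i, j): float(hsd.pvalue[i, j]) for i, j in pairs}
        raw = {}
        for i, j in pairs:
            se = math.sqrt(mse * (1.0 / n[i] + 1.0 / n[j]))
            t = (means[i] - means[j]) / se
            raw[(i, j)] = float(2.0 * stats.t.sf(abs(t), dfw))
    for i, j in pairs:
        p_raw = raw[(i, j)]
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, m * p_raw),
                "p_tukey": tukey_p[(i, j)],
            }
        )
    pairwise = pd.DataFrame.from_records(rows)
    pairwise["significant_bonferroni"] = pairwise["p_bonferroni"] < alpha
    pairwise["significant_tukey"] = pairwise["p_tukey"] < alpha
    return GroupComparison(labels=labels, f_stat=f, p_value=p,
                           pairwise=pairwise, alpha=alpha)


def contrast_structures(
    roi_means: pd.DataFrame, alpha: float = 0.05
) -> dict[str, GroupComparison]:
    """Per-specimen structure contrast (e.g. bone vs sediment) on ROI means.

    ``roi_means`` needs columns ``specimen``, ``structure``, ``value`` (one
    row per ROI).  Specimens missing a second structure are skipped with a
    logged warning.
    """
    required = {"specimen", "structure", "value"}
    if not required <= set(roi_means.columns):
        raise ValueError(f"need columns {sorted(required)}")
    out: dict[str, GroupComparison] = {}
    for specimen, sub in roi_means.groupby("specimen", sort=False):
        structures = sub["structure"].unique()
        if len(structures) < 2:
            logger.warning(
                "specimen %r has a single structure (%s); skipping contrast",
                specimen, ", ".join(structures),
            )
            continue
        groups = {
            s: sub.loc[sub["structure"] == s, "value"].to_numpy()
            for s in structures
        }
        out[str(specimen)] = anova_posthoc(groups, alpha=alpha)
    return out


@dataclass(frozen=True)
class AgeTrend:
    """Ordered fluorine-vs-age report for terrestrial specimens."""

    order: tuple[tuple[str, float, float], ...]  # (specimen, age_ma, mean)
    monotone: bool
    violations: tuple[tuple[str, str], ...]
    comparison: GroupComparison | None


def age_trend(roi_means: pd.DataFrame, alpha: float = 0.05) -> AgeTrend:
    """Check that terrestrial fluorine means rise with geological age.

    ``roi_means`` needs columns ``specimen``, ``age_ma``, ``habitat`` and
    ``value`` (one row per ROI mean).  Specimens are sorted by age; the
    trend is monotone if per-specimen means never decrease from younger to
    older; every violating adjacent pair is reported.  Pairwise ANOVA /
    post-hoc comparisons across specimens are attached when each specimen
    has at least two ROI values.
    """
    required = {"specimen", "age_ma", "habitat", "value"}
    if not required <= set(roi_means.columns):
        raise ValueError(f"need columns {sorted(required)}")
    terr = roi_means[roi_means["habitat"] == "terrestrial"]
    per = (
        terr.groupby("specimen", sort=False)
        .agg(age_ma=("age_ma", "first"), mean=("value", "mean"), n=("value", "size"))
        .reset_index()
        .sort_values("age_ma", kind="stable")
    )
    if len(per) < 2:
        raise ValueError("need at least two terrestrial specimens")
    order = tuple(
        (str(r.specimen), float(r.age_ma), float(r.mean)) for r in per.itertuples()
    )
    violations = tuple(
        (order[i][0], order[i + 1][0])
        for i in range(len(order) - 1)
        if order[i + 1][2] < order[i][2]
    )
    comparison = None
    if (per["n"] >= 2).all():
        groups = {
            str(s): terr.loc[terr["specimen"] == s, "value"].to_numpy()
            for s in per["specimen"]
        }
        comparison = anova_posthoc(groups, alpha=alpha)
    return AgeTrend(
        order=order,
        monotone=not violations,
        violations=violations,
        comparison=comparison,
    )


# --------------------------------------------------------------------------
# ROI placement helper
# --------------------------------------------------------------------------

def plant_cubic_rois(
    mask: np.ndarray,
    n_rois: int,
    size: int,
    rng: np.random.Generator,
    start_code: int = 1,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Place ``n_rois`` disjoint cubes of edge ``size`` inside a region mask.

    Returns an integer label volume with codes ``start_code ..
    start_code + n_rois - 1``.  Raises if the region cannot host the ROIs.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    shape = mask.shape
    placed = 0
    tries = 0
    while placed < n_rois:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_rois} ROIs of size {size} (placed {placed})"
            )
        tries += 1
        corner = [int(rng.integers(0, max(shape[a] - size, 1))) for a in range(3)]
        sl = tuple(slice(c, c + size) for c in corner)
        if mask[sl].all() and (labels[sl] == 0).all() and labels[sl].size == size**3:
            labels[sl] = start_code + placed
            placed += 1
    return labels
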