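"""Classical single-slice volume estimation and two-group morphometrics.

Covers the sphere-from-diameter estimator (volume from the maximal in-plane
extent of one xy cross-section), its comparison against true 3D voxel
volumes, and group summaries/comparisons of per-cell measurements with
Student's t-test and significance tiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from wallvol.segmentation import CellMeasurement, measurements_to_dataframe

__all__ = [
    "SphereEstimate",
    "GroupSummary",
    "GroupComparison",
    "sphere_volume_from_diameter",
    "sphere_volume_from_slice",
    "compare_methods",
    "summarize_group",
    "compare_groups",
    "two_sample_t",
    "significance_tier",
    "wall_cell_ratio",
    "QUANTITIES",
]

QUANTITIES = ("cell_volume_um3", "wall_volume_um3", "ratio")


def sphere_volume_from_diameter(diameter_um: float) -> float:
    """V = (4/3)·π·(d/2)³."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return 4.0 / 3.0 * math.pi * (diameter_um / 2.0) ** 3


@dataclass
class SphereEstimate:
    """Single-slice diameter reading and the sphere volume derived from it."""

    diameter_um: float
    volume_um3: float
    slice_index: int

    def __post_init__(self) -> None:
        expected = sphere_volume_from_diameter(self.diameter_um)
        if not math.isclose(self.volume_um3, expected, rel_tol=1e-9):
            raise ValueError("volume inconsistent with diameter")


def _max_extent_um(points: np.ndarray) -> float:
    """Maximal pairwise distance between pixel centres (μm), via the convex
    hull when enough points are available."""
    if len(points) == 1:
        return 0.0
    if len(points) > 10:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (collinear) sets: brute force below
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def sphere_volume_from_slice(
    mask: np.ndarray,
    slice_index: int,
    spacing: Sequence[float],
) -> SphereEstimate:
    """Sphere-from-diameter estimate using one xy plane of a 3D mask.

    The diameter is the maximal in-plane (Feret-like) extent of the binary
    cross-section, measured between pixel centres (over all directions this
    approaches the true diameter from below by a fraction of a pixel).
    """
    mask = np.asarray(mask, dtype=bool)
    if not 0 <= slice_index < mask.shape[0]:
        raise IndexError(f"slice {slice_index} outside stack of depth {mask.shape[0]}")
    section = mask[slice_index]
    ys, xs = np.nonzero(section)
    if ys.size == 0:
        raise ValueError(f"slice {slice_index} does not intersect the object")
    sy, sx = float(spacing[1]), float(spacing[2])
    pts = np.column_stack([ys * sy, xs * sx])
    diameter = _max_extent_um(pts)
    if diameter == 0.0:  # single-pixel section: fall back to the pixel size
        diameter = 0.5 * (sy + sx)
    return SphereEstimate(
        diameter_um=diameter,
        volume_um3=sphere_volume_from_diameter(diameter),
        slice_index=slice_index,
    )


def _pick_slice(
    mask: np.ndarray,
    policy: Literal["middle", "equatorial", "random"],
    rng: np.random.Generator | None,
) -> int:
    areas = mask.reshape(mask.shape[0], -1).sum(axis=1)
    nonzero = np.nonzero(areas)[0]
    if nonzero.size == 0:
        raise ValueError("mask is empty")
    if policy == "middle":
        return int(mask.shape[0] // 2)
    if policy == "equatorial":
        return int(np.argmax(areas))
    if policy == "random":
        if rng is None:
            raise ValueError("random slice policy requires an rng")
        return int(rng.choice(nonzero))
    raise ValueError(f"unknown slice policy {policy!r}")


def compare_methods(
    masks: Sequence[np.ndarray],
    spacing: Sequence[float],
    slice_policy: Literal["middle", "equatorial", "random"] = "middle",
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cell table of the classical sphere estimate vs the 3D voxel volume.

    The slice policy mimics how the single focal plane is chosen:
    ``middle`` (centre of the stack — a microscopist's fixed focal plane),
    ``equatorial`` (largest cross-section — the best case), or ``random``
    (seeded, uniform over slices that intersect the cell).  The returned
    frame carries ``sphere_volume_um3``, ``volume_3d_um3`` and their ratio;
    the mean ratio is stored in ``df.attrs['mean_ratio']``.
    """
    if len(masks) == 0:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed) if slice_policy == "random" else None
    voxel_volume = float(np.prod(spacing))
    rows = []
    for i, mask in enumerate(masks):
        mask = np.asarray(mask, dtype=bool)
        idx = _pick_slice(mask, slice_policy, rng)
        est = sphere_volume_from_slice(mask, idx, spacing)
        v3d = float(mask.sum()) * voxel_volume
        rows.append(
            {
                "cell_id": i,
                "slice_index": est.slice_index,
                "diameter_um": est.diameter_um,
                "sphere_volume_um3": est.volume_um3,
                "volume_3d_um3": v3d,
                "ratio_sphere_to_3d": est.volume_um3 / v3d,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mean_ratio"] = float(df["ratio_sphere_to_3d"].mean())
    return df


@dataclass
class GroupSummary:
    """Mean ± SD of the three morphometric quantities over surviving cells."""

    n: int
    mean_cell_volume_um3: float
    sd_cell_volume_um3: float
    mean_wall_volume_um3: float
    sd_wall_volume_um3: float
    mean_ratio: float
    sd_ratio: float
    n_excluded_dead: int = 0
    n_excluded_border: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a group summary needs at least one cell")
        for sd in (self.sd_cell_volume_um3, self.sd_wall_volume_um3, self.sd_ratio):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")


def _as_frame(
    measurements: Sequence[CellMeasurement] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        return measurements
    return measurements_to_dataframe(list(measurements))


def _surviving(
    df: pd.DataFrame, exclude_dead: bool, exclude_border: bool
) -> tuple[pd.DataFrame, int, int]:
    keep = pd.Series(True, index=df.index)
    n_dead = n_border = 0
    if exclude_dead and "dead" in df:
        dead = df["dead"].astype(bool)
        n_dead = int(dead.sum())
        keep &= ~dead
    if exclude_border and "touches_border" in df:
        border = df["touches_border"].astype(bool) & keep
        n_border = int(border.sum())
        keep &= ~border
    return df[keep], n_dead, n_border


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def summarize_group(
    measurements: Sequence[CellMeasurement] | pd.DataFrame,
    exclude_dead: bool = True,
    exclude_border: bool = True,
) -> GroupSummary:
    """Mean and SD per quantity, after excluding dead and border cells."""
    df, n_dead, n_border = _surviving(_as_frame(measurements), exclude_dead, exclude_border)
    if len(df) == 0:
        raise ValueError("all cells were excluded; nothing to summarize")
    cv = df["cell_volume_um3"].to_numpy(dtype=float)
    wv = df["wall_volume_um3"].to_numpy(dtype=float)
    ratio = df["ratio"].to_numpy(dtype=float)
    return GroupSummary(
        n=len(df),
        mean_cell_volume_um3=float(cv.mean()),
        sd_cell_volume_um3=_sd(cv),
        mean_wall_volume_um3=float(wv.mean()),
        sd_wall_volume_um3=_sd(wv),
        mean_ratio=float(ratio.mean()),
        sd_ratio=_sd(ratio),
        n_excluded_dead=n_dead,
        n_excluded_border=n_border,
    )


def wall_cell_ratio(wall_volume_um3: float, cell_volume_um3: float) -> float:
    """Wall-to-cell volume ratio V_wall / V_cell."""
    if not 0 < wall_volume_um3 <= cell_volume_um3:
        raise ValueError("need 0 < wall volume <= cell volume")
    return wall_volume_um3 / cell_volume_um3


def two_sample_t(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sample t-test (pooled-variance Student by default), two-sided.

    Degenerate zero-variance groups short-circuit to an exact-equality
    decision: equal means give (0, 1), unequal means (±inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, b.mean() - a.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def significance_tier(p_value: float) -> str:
    """'+++' for p<0.001, '++' for p<0.01, '+' for p<0.05, else 'none'."""
    if not 0 <= p_value <= 1:
        raise ValueError("p-value must be in [0, 1]")
    if p_value < 0.001:
        return "+++"
    if p_value < 0.01:
        return "++"
    if p_value < 0.05:
        return "+"
    return "none"


@dataclass
class GroupComparison:
    """Treated-vs-control comparison of one morphometric quantity."""

    quantity: str
    relative_percent: float
    t_statistic: float
    p_value: float
    tier: str
    n_control: int
    n_treated: int


def compare_groups(
    control: Sequence[CellMeasurement] | pd.DataFrame,
    treated: Sequence[CellMeasurement] | pd.DataFrame,
    exclude_dead: bool = True,
    exclude_border: bool = True,
    welch: bool = False,
) -> dict[str, GroupComparison]:
    """Compare the two groups on cell volume, wall volume, and ratio.

    For each quantity: the treated mean as a percent of the control mean, a
    two-sided two-sample t-test (pooled Student by default, Welch behind
    the flag), and the significance tier.
    """
    dfc, _, _ = _surviving(_as_frame(control), exclude_dead, exclude_border)
    dft, _, _ = _surviving(_as_frame(treated), exclude_dead, exclude_border)
    if len(dfc) < 2 or len(dft) < 2:
        raise ValueError("both groups need at least 2 surviving cells")
    out: dict[str, GroupComparison] = {}
    for quantity in QUANTITIES:
        a = dfc[quantity].to_numpy(dtype=float)
        b = dft[quantity].to_numpy(dtype=float)
        t, p = two_sample_t(a, b, welch=welch)
        out[quantity] = GroupComparison(
            quantity=quantity,
            relative_percent=100.0 * b.mean() / a.mean(),
            t_statistic=t,
            p_value=p,
            tier=significance_tier(p),
            n_control=len(a),
            n_treated=len(b),
        )
    return out


def comparison_to_dataframe(comparison: dict[str, GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "quantity": c.quantity,
                "relative_percent": c.relative_percent,
                "t_statistic": c.t_statistic,
                "p_value": c.p_value,
                "tier": c.tier,
                "n_control": c.n_control,
                "n_treated": c.n_treated,
            }
            for c in comparison.values()
        ]
    )
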