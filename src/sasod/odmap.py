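"""Orthostatic-dysregulation positioning map.

Each subject's active standing test is reduced to two Pearson correlations
between systolic blood pressure and heart rate — one supine, one standing —
and plotted as a point (r_supine, r_standing) against the healthy reference
square [0.59 - 0.11, 0.59 + 0.11] on both axes (the literature value for
healthy BP-HR coupling, 0.59 +/- 0.11).  A point inside the square is
consistent with healthy coupling; outside, its minimal Euclidean distance
to the square's boundary is reported (positive, reducing to the
perpendicular axis gap for axis-aligned exterior points).

The square is a screening reference taken from population values, not a
validated decision boundary; the calls are labelled accordingly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import OrthostaticRecord

HEALTHY_COUPLING_R = 0.59
HEALTHY_COUPLING_HALF_WIDTH = 0.11
STANDARD_DT_S = 3.0


class Phase(str, enum.Enum):
    SUPINE = "SUPINE"
    STANDING = "STANDING"


class ScreeningCall(str, enum.Enum):
    CONSISTENT_WITH_HEALTHY_COUPLING = "CONSISTENT_WITH_HEALTHY_COUPLING"
    OD_PATTERN = "OD_PATTERN"


@dataclass(frozen=True)
class PositioningPoint:
    r_supine: float
    r_standing: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        for name in ("r_supine", "r_standing"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")


@dataclass(frozen=True)
class ReferenceSquare:
    """Healthy-coupling reference band applied on both axes."""

    center: float = HEALTHY_COUPLING_R
    half_width: float = HEALTHY_COUPLING_HALF_WIDTH

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise ValueError("half_width must be > 0")
        if not (-1.0 <= self.center - self.half_width
                and self.center + self.half_width <= 1.0):
            raise ValueError("square must lie within [-1, 1]^2")

    def distance(self, x: float, y: float) -> float:
        """Minimal Euclidean distance to the closed square (0 inside)."""
        dx = max(abs(x - self.center) - self.half_width, 0.0)
        dy = max(abs(y - self.center) - self.half_width, 0.0)
        return float(np.hypot(dx, dy))

    def contains(self, x: float, y: float) -> bool:
        return self.distance(x, y) == 0.0


def phase_correlation(record: OrthostaticRecord, phase: Phase | str) -> float:
    """Pearson correlation of (SBP, HR) pairs within one phase.

    Series sampled at other than 3-s spacing are linearly resampled to
    3-s spacing first.
    """
    phase = Phase(phase)
    arr = record.supine if phase is Phase.SUPINE else record.standing
    if record.dt_s != STANDARD_DT_S:
        t_old = np.arange(arr.shape[0]) * record.dt_s
        t_new = np.arange(0.0, t_old[-1] + 1e-9, STANDARD_DT_S)
        arr = np.column_stack(
            [np.interp(t_new, t_old, arr[:, j]) for j in range(2)]
        )
    if arr.shape[0] < 3:
        raise ValueError(f"{phase.value} phase needs >= 3 samples for a correlation")
    bp, hr = arr[:, 0], arr[:, 1]
    if np.ptp(bp) == 0 or np.ptp(hr) == 0:
        raise ValueError(
            f"{phase.value} phase has a constant BP or HR series: correlation undefined"
        )
    r = stats.pearsonr(bp, hr).statistic
    return float(np.clip(r, -1.0, 1.0))


def position_and_classify(
    record: OrthostaticRecord,
    square: ReferenceSquare = ReferenceSquare(),
    fisher_z: bool = False,
) -> tuple[PositioningPoint, float, ScreeningCall]:
    """Place a record on the map and screen it against the square.

    With ``fisher_z=True`` (sensitivity analysis) point and band are
    compared on the Fisher z = atanh(r) scale, the half-width being
    interpreted in z units.
    """
    point = PositioningPoint(
        r_supine=phase_correlation(record, Phase.SUPINE),
        r_standing=phase_correlation(record, Phase.STANDING),
        subject_id=record.subject_id,
    )
    if fisher_z:
        sq = ReferenceSquare.__new__(ReferenceSquare)  # skip [-1,1] bound check
        object.__setattr__(sq, "center", float(np.arctanh(square.center)))
        object.__setattr__(sq, "half_width", square.half_width)
        dist = sq.distance(np.arctanh(point.r_supine), np.arctanh(point.r_standing))
    else:
        dist = square.distance(point.r_supine, point.r_standing)
    call = (
        ScreeningCall.CONSISTENT_WITH_HEALTHY_COUPLING
        if dist == 0.0
        else ScreeningCall.OD_PATTERN
    )
    return point, dist, call


def plot_positioning_map(
    points: list[PositioningPoint],
    square: ReferenceSquare = ReferenceSquare(),
    ax=None,
):
    """Scatter of subjects with the dashed band lines and shaded square."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    lo, hi = square.center - square.half_width, square.center + square.half_width
    for v in (lo, hi):
        ax.axvline(v, ls="--", c="gray", lw=0.8)
        ax.axhline(v, ls="--", c="gray", lw=0.8)
    ax.add_patch(Rectangle((lo, lo), 2 * square.half_width, 2 * square.half_width,
                           facecolor="red", alpha=0.2, edgecolor="red"))
    xs = [p.r_supine for p in points]
    ys = [p.r_standing for p in points]
    ax.scatter(xs, ys, c="tab:blue", zorder=3)
    ax.set_xlim(-1, 1)
    ax.set_ylim(-1, 1)
    ax.set_xlabel("r (supine)")
    ax.set_ylabel("r (standing)")
    return ax
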