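"""Length-angle curves, quartic smoothing and tendon-excursion moment arms.

For each fibre the musculotendon length l(theta) is sampled over a
single-coordinate pose sweep, interpolated with a 4th-order polynomial
(in radians, for well-scaled coefficients), and the moment arm obtained by
the tendon-excursion method as the analytic derivative of the fit:

    r_ij = sign * dl_i/dtheta_j

Sign convention: the derivative itself is positive for a muscle that
lengthens as the coordinate grows, i.e. one that generates a *negative*
moment about the coordinate axis.  The default ``sign = -1`` therefore
reports moment-generating moment arms (a flexor gets a positive flexion
moment arm); pass ``sign=+1`` for the raw derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .decomposition import FiberSet
from .errors import NumericalError, ValidationError
from .kinematics import (
    DEFAULT_COORD_RANGES,
    JointPose,
    Skeleton,
    pose_transforms,
    update_fibers,
)

DEFAULT_STEP_DEG = 2.0


def pose_grid(coordinate: str, rng=None, step: float = DEFAULT_STEP_DEG) -> np.ndarray:
    """Sweep grid in degrees: lo, lo+step, ..., hi (inclusive)."""
    if step <= 0:
        raise ValidationError("pose_grid: step must be > 0")
    if rng is None:
        rng = DEFAULT_COORD_RANGES[coordinate]
    lo, hi = float(rng[0]), float(rng[1])
    if hi <= lo:
        raise ValidationError("pose_grid: range must have hi > lo")
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


@dataclass
class LengthCurve:
    """Per-fibre length samples over a pose sweep (and their quartic fit)."""

    coordinate: str
    theta_deg: np.ndarray
    lengths: np.ndarray  # (n_fibers, n_poses), metres
    coeffs: np.ndarray | None = None  # (5, n_fibers), power basis in radians
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, dtype=np.float64)
        self.lengths = np.atleast_2d(np.asarray(self.lengths, dtype=np.float64))
        if np.any(np.diff(self.theta_deg) <= 0):
            raise ValidationError("LengthCurve: theta samples must be strictly increasing")
        if self.lengths.shape[1] != len(self.theta_deg):
            raise ValidationError("LengthCurve: sample count mismatch")
        if np.any(self.lengths <= 0):
            raise ValidationError("LengthCurve: lengths must be positive")


@dataclass
class MomentArmCurve:
    """Per-fibre, per-pose moment arms (metres internally, reported in cm)."""

    coordinate: str
    theta_deg: np.ndarray
    values: np.ndarray  # (n_fibers, n_poses), metres
    sign: int = -1

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, dtype=np.float64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("MomentArmCurve: non-finite values")


@dataclass
class FanSummary:
    """Envelope and global statistics of a moment-arm fan, in cm."""

    coordinate: str
    per_pose_min: np.ndarray
    per_pose_max: np.ndarray
    min: float
    max: float
    mean: float
    sd: float

    def as_row(self) -> dict:
        return {
            "coordinate": self.coordinate,
            "min_cm": round(self.min, 1),
            "max_cm": round(self.max, 1),
            "mean_cm": round(self.mean, 1),
            "sd_cm": round(self.sd, 1),
        }


def sweep_lengths(
    fibers: FiberSet,
    skeleton: Skeleton,
    coordinate: str,
    rng=None,
    step: float = DEFAULT_STEP_DEG,
) -> LengthCurve:
    """Per-fibre polyline length at every pose of a single-coordinate sweep
    (the other coordinates held at zero)."""
    grid = pose_grid(coordinate, rng, step)
    lengths = np.empty((fibers.n_fibers, len(grid)))
    for k, th in enumerate(grid):
        pose = JointPose(**{coordinate: float(th)})
        try:
            transforms = pose_transforms(skeleton, pose)
            posed = update_fibers(fibers, transforms)
        except Exception as exc:
            raise ValidationError(
                f"sweep_lengths: kinematics failed at {coordinate}={th}°: {exc}"
            ) from exc
        lengths[:, k] = posed.lengths()
    return LengthCurve(coordinate=coordinate, theta_deg=grid, lengths=lengths)


def fit_quartic(curve: LengthCurve) -> np.ndarray:
    """Least-squares degree-4 polynomial fit of every fibre's l(theta),
    theta in radians.  Stores and returns the (5, n_fibers) coefficient
    array (ascending powers) and records residuals on the curve."""
    if len(curve.theta_deg) < 5:
        raise ValidationError("fit_quartic: need >= 5 samples")
    x = np.deg2rad(curve.theta_deg)
    V = np.vander(x, 5, increasing=True)  # columns 1, x, ..., x^4
    coeffs, res, rank, _ = np.linalg.lstsq(V, curve.lengths.T, rcond=None)
    if rank < 5:
        raise NumericalError("fit_quartic: rank-deficient design matrix")
    curve.coeffs = coeffs
    fit = V @ coeffs
    curve.residuals = np.sqrt(((fit - curve.lengths.T) ** 2).mean(axis=0))
    return coeffs


def excursion_moment_arms(curve: LengthCurve, sign: int = -1) -> MomentArmCurve:
    """Tendon-excursion moment arms: the analytic derivative of the quartic
    fit evaluated on the pose grid, times ``sign`` (default -1: the
    moment-generating convention)."""
    if sign not in (1, -1):
        raise ValidationError("excursion_moment_arms: sign must be +1 or -1")
    if curve.coeffs is None:
        fit_quartic(curve)
    x = np.deg2rad(curve.theta_deg)
    c = curve.coeffs  # (5, F)
    dV = np.vander(x, 4, increasing=True) * np.array([1.0, 2.0, 3.0, 4.0])
    deriv = dV @ c[1:]  # (n_poses, F); metres per radian == metres
    return MomentArmCurve(
        coordinate=curve.coordinate,
        theta_deg=curve.theta_deg,
        values=sign * deriv.T,
        sign=sign,
    )


def summarize_fan(ma: MomentArmCurve) -> FanSummary:
    """Per-pose envelope plus global min/max/mean/sd over all fibre-pose
    samples, converted to cm."""
    if ma.values.size == 0:
        raise ValidationError("summarize_fan: empty moment-arm curve")
    v_cm = ma.values * 100.0
    return FanSummary(
        coordinate=ma.coordinate,
        per_pose_min=v_cm.min(axis=0),
        per_pose_max=v_cm.max(axis=0),
        min=float(v_cm.min()),
        max=float(v_cm.max()),
        mean=float(v_cm.mean()),
        sd=float(v_cm.std()),
    )


def range_agreement(fan: MomentArmCurve, reference) -> int:
    """Percentage of poses at which the reference moment arm lies inside the
    fibre fan's [min, max] envelope (inclusive), rounded to the nearest
    integer percent."""
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape != fan.theta_deg.shape:
        raise ValidationError("range_agreement: reference grid mismatch")
    lo = fan.values.min(axis=0)
    hi = fan.values.max(axis=0)
    included = (reference >= lo) & (reference <= hi)
    pct = 100.0 * included.sum() / len(reference)
    return int(np.floor(pct + 0.5))


def moment_arm_table(ma: MomentArmCurve) -> "pandas.DataFrame":  # noqa: F821
    """Long-format table (coordinate, pose_deg, fiber_id, moment_arm_cm)."""
    import pandas as pd

    F, n = ma.values.shape
    return pd.DataFrame(
        {
            "coordinate": np.repeat(ma.coordinate, F * n),
            "pose_deg": np.tile(ma.theta_deg, F),
            "fiber_id": np.repeat(np.arange(F), n),
            "moment_arm_cm": (ma.values * 100.0).ravel(),
        }
    )
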