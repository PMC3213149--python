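"""Anchor-rotation normalization of scaling relationships across conditions.

To compare experimental scaling relationships measured at different rearing
temperatures against a single control relationship, each non-reference
condition is (1) rigidly translated in log-log size space so that the
bivariate mean of its anchor subset (the un-starved control flies) lands on
the reference condition's anchor mean, then (2) rigidly rotated about that
anchor until the control subset's SMA slope equals the reference control
slope.  Experimental rows ride along under the same rigid motions, so
their geometry relative to their own controls is preserved exactly.

Both steps act in log-size coordinates: slope-matching by rotation is only
angle-consistent in a fixed coordinate frame, and the rigid rotation is the
natural reading of rotating data about an anchor (a shear would also
equalize slopes but does not preserve distances).  Because the SMA slope of
a noisy cloud is not exactly tan of its rotated angle, a single rotation by
arctan(target) − arctan(current) leaves a residual slope mismatch; the
rotation therefore refits after rotating and runs a bounded fixed-point
iteration on the angle until the control slope matches the target to 1e-9.
The iteration count is recorded on the transform for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import atan, cos, sin
from typing import Mapping

import numpy as np

from .core_io import ConfigurationError
from .sma import fit_sma

__all__ = [
    "AnchorTransform",
    "translate_to_anchor",
    "rotate_about_anchor",
    "normalize_across_conditions",
]

SLOPE_TOL = 1e-9


@dataclass(frozen=True)
class AnchorTransform:
    """Audit record of one condition's rigid normalization."""

    anchor: tuple[float, float]
    translation: tuple[float, float]
    rotation_angle: float
    source_label: str
    reference_label: str
    control_slope_before: float
    control_slope_after: float
    reference_slope: float
    n_refit_iterations: int = 0


def _as_xy(data) -> np.ndarray:
    arr = np.asarray(data, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ConfigurationError("bivariate data must have shape (n, 2): (log body, log organ)")
    return arr


def translate_to_anchor(
    data, subset_mask, reference_mean: tuple[float, float]
) -> tuple[np.ndarray, tuple[float, float]]:
    """Rigidly translate all rows so the subset's bivariate mean hits reference_mean.

    The subset (un-starved controls) defines the offset; the same offset is
    applied to every row, experimental and control alike.
    """
    arr = _as_xy(data)
    mask = np.asarray(subset_mask, bool)
    if mask.shape != (len(arr),):
        raise ConfigurationError("subset_mask must have one entry per row")
    if not mask.any():
        raise ConfigurationError("anchor-defining subset is empty")
    offset = np.asarray(reference_mean, float) - arr[mask].mean(axis=0)
    return arr + offset, (float(offset[0]), float(offset[1]))


def _rotate(arr: np.ndarray, anchor: np.ndarray, theta: float) -> np.ndarray:
    c, s = cos(theta), sin(theta)
    rel = arr - anchor
    return anchor + rel @ np.array([[c, s], [-s, c]])  # row-vector rotation by +theta


def _sma_slope(arr: np.ndarray) -> float:
    return fit_sma(arr[:, 0], arr[:, 1]).slope_b


def rotate_about_anchor(
    data,
    anchor: tuple[float, float],
    current_slope: float,
    target_slope: float,
    control_mask=None,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, int]:
    """Rigidly rotate data about the anchor so the control SMA slope equals target.

    Returns (rotated data, total rotation angle, refit iterations).  When
    ``control_mask`` is given, the slope is re-fit on that subset after the
    initial arctan rotation and the angle is refined by fixed-point
    iteration until |slope − target| <= 1e-9; without a mask a single exact
    arctan rotation is applied (sufficient for collinear data).
    """
    arr = _as_xy(data)
    anchor_pt = np.asarray(anchor, float)
    for name, v in (("current_slope", current_slope), ("target_slope", target_slope)):
        if not np.isfinite(v):
            raise ConfigurationError(f"{name} must be finite")
    if not np.all(np.isfinite(anchor_pt)):
        raise ConfigurationError("anchor must be finite")

    theta = atan(target_slope) - atan(current_slope)
    out = _rotate(arr, anchor_pt, theta)
    iters = 0
    if control_mask is not None:
        mask = np.asarray(control_mask, bool)
        for iters in range(1, max_iter + 1):
            slope = _sma_slope(out[mask])
            delta = atan(target_slope) - atan(slope)
            if abs(slope - target_slope) <= SLOPE_TOL:
                break
            theta += delta
            out = _rotate(arr, anchor_pt, theta)
        else:
            raise RuntimeError(
                f"rotation did not converge to the target slope in {max_iter} iterations"
            )
    return out, float(theta), iters


def normalize_across_conditions(
    data_by_condition: Mapping[str, tuple[np.ndarray, np.ndarray]],
    reference_condition: str,
    strict: bool = True,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], list[AnchorTransform]]:
    """Normalize every condition's scaling data onto the reference condition.

    ``data_by_condition`` maps a condition label (e.g. rearing temperature)
    to a pair (experimental rows, control rows), each an (n, 2) array of
    (log body, log organ).  The reference condition is returned untouched;
    every other condition is translated so its control bivariate mean equals
    the reference control mean, then rotated about that anchor so its
    control SMA slope equals the reference control slope.  Experimental
    rows undergo the identical rigid motions.
    """
    if reference_condition not in data_by_condition:
        raise ConfigurationError(f"reference condition {reference_condition!r} not present")
    ref_exp, ref_ctrl = data_by_condition[reference_condition]
    ref_ctrl = _as_xy(ref_ctrl)
    if len(ref_ctrl) < 3:
        raise ConfigurationError("reference condition needs >= 3 control rows")
    ref_mean = ref_ctrl.mean(axis=0)
    ref_slope = _sma_slope(ref_ctrl)

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    transforms: list[AnchorTransform] = []
    for label, (exp_rows, ctrl_rows) in data_by_condition.items():
        if label == reference_condition:
            out[label] = (np.asarray(exp_rows, float), ref_ctrl.copy())
            continue
        exp_arr = _as_xy(exp_rows) if len(np.asarray(exp_rows)) else np.empty((0, 2))
        ctrl_arr = _as_xy(ctrl_rows)
        if strict and len(ctrl_arr) < 3:
            raise ConfigurationError(f"condition {label!r} has fewer than 3 control rows")

        stacked = np.vstack([exp_arr, ctrl_arr])
        ctrl_mask = np.zeros(len(stacked), bool)
        ctrl_mask[len(exp_arr):] = True

        translated, offset = translate_to_anchor(stacked, ctrl_mask, tuple(ref_mean))
        slope_before = _sma_slope(translated[ctrl_mask])
        rotated, theta, iters = rotate_about_anchor(
            translated, tuple(ref_mean), slope_before, ref_slope, control_mask=ctrl_mask
        )
        slope_after = _sma_slope(rotated[ctrl_mask])
        out[label] = (rotated[~ctrl_mask], rotated[ctrl_mask])
        transforms.append(
            AnchorTransform(
                anchor=(float(ref_mean[0]), float(ref_mean[1])),
                translation=offset,
                rotation_angle=theta,
                source_label=str(label),
                reference_label=str(reference_condition),
                control_slope_before=float(slope_before),
                control_slope_after=float(slope_after),
                reference_slope=float(ref_slope),
                n_refit_iterations=iters,
            )
        )
    return out, transforms
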