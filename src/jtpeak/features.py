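"""Geometric features of a peak-slur candidate pair on the vector magnitude lead.

A candidate's limbs are straight-line fits between its bounding derivative
extrema and its apex; the features below are ratios, distances and angles of
those limb lines, the signal, and their intersections. Angles are inverse
tangents in degrees with time in ms and amplitude in uV (they are therefore
unit-convention dependent; the package fixes ms/uV throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FeatureError

#: minimum voltage amplitude for detections (uV)
MIN_VOLTAGE_UV = 100.0

FEATURE_NAMES = (
    "amp_ratio_peak_slur",          # Y[p]/Y[s]
    "peak_slur_origin_ratio",       # Y[p]/Yorigin[s]
    "origin_ratio",                 # Yorigin[p]/Yorigin[s]
    "time_ratio_peak_slur",         # X[p]/X[s]
    "amp_diff_peak_slur",           # Y[p]-Y[s]
    "junction_peak_amp_diff",       # |Y(junctionX)-Y[p]|
    "junction_slur_amp_diff",       # |Y(junctionX)-Y[s]|
    "junction_peak_amp_ratio",      # |Y(junctionX)/Y[p]|
    "junction_slur_amp_ratio",      # |Y(junctionX)/Y[s]|
    "time_ratio_peak_junction",     # X[p]/junctionX
    "time_ratio_slur_junction",     # X[s]/junctionX
    "time_ratio_peak_slur_junction",    # |X[p]-junctionX|/|X[s]-junctionX|
    "amp_ratio_peak_slur_junction",     # |Y[p]-Y(junctionX)|/|Y[s]-Y(junctionX)|
    "peak_floor_ratio",             # (Y[p]-minVoltage)/divisor
    "slur_floor_ratio",             # (Y[s]-minVoltage)/divisor
    "peak_slope_angle",             # |atand[p_rising]-atand[p_falling]|
    "slur_slope_angle",             # |atand[s_rising]-atand[s_falling]|
    "peak_slur_angle",              # |atand[p_falling]-atand[s_rising]|
    "peak_rotation_atand",          # atand(Rotation[p])
    "slur_rotation_atand",          # atand(Rotation[s])
)


@dataclass
class SlurFeatures:
    """The 20 candidate-pair features, keyed by :data:`FEATURE_NAMES`."""

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise FeatureError(f"missing features: {sorted(missing)}")
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise FeatureError(f"non-finite feature {name}")

    def __getitem__(self, name):
        return self.values[name]

    def as_dict(self):
        return dict(self.values)


def _fit_limb(vm, a_ms, b_ms, deriv):
    """Line (slope uV/ms, intercept uV) through the limb between ``a_ms`` and ``b_ms``.

    Least squares over the samples when the span allows it; degenerate spans
    (< 3 ms, e.g. a trailing slur whose apex coincides with its rise) fall
    back to the smoothed-derivative slope at the midpoint over a 5 ms window.
    """
    a, b = int(round(min(a_ms, b_ms))), int(round(max(a_ms, b_ms)))
    if a < 0 or b >= len(vm):
        raise FeatureError("limb extends beyond the beat")
    if b - a >= 3:
        t = np.arange(a, b + 1, dtype=float)
        slope, intercept = np.polyfit(t, vm[a : b + 1], 1)
        return float(slope), float(intercept)
    mid = (a + b) // 2
    lo, hi = max(0, mid - 2), min(len(vm) - 1, mid + 2)
    if hi <= lo:
        raise FeatureError("limb at the beat edge")
    slope = float(np.mean(deriv[lo : hi + 1]))
    return slope, float(vm[mid] - slope * mid)


def _limb_lines(cand, vm, deriv):
    rising = _fit_limb(vm, cand.rise_ms, cand.apex_ms, deriv)
    falling = _fit_limb(vm, cand.apex_ms, cand.fall_ms, deriv)
    return rising, falling


def _intersect(line1, line2):
    (m1, b1), (m2, b2) = line1, line2
    if abs(m1 - m2) < 1e-12:
        raise FeatureError("parallel limb lines have no intersection")
    x = (b2 - b1) / (m1 - m2)
    return x, m1 * x + b1


def _vm_at(vm, x_ms):
    if not 0 <= x_ms <= len(vm) - 1:
        raise FeatureError("intersection outside the beat")
    return float(np.interp(x_ms, np.arange(len(vm), dtype=float), vm))


def _bisector_angle_rad(rising, falling):
    """Mean of the limb-line angles (radians); the downward bisector direction."""
    return (np.arctan(rising[0]) + np.arctan(falling[0])) / 2.0


def _y_origin(cand, vm, deriv):
    """Amplitude where the downward bisector of the limb lines meets the signal.

    The bisector ray starts at the limb-line intersection (above the apex for
    a convex candidate) and points down along the mean limb direction; for a
    symmetric peak this is the vertical through the apex, so Yorigin equals
    the apex amplitude.
    """
    rising, falling = _limb_lines(cand, vm, deriv)
    xi, yi = _intersect(rising, falling)
    theta = _bisector_angle_rad(rising, falling)
    dx, dy = np.sin(theta), -np.cos(theta)
    step = 0.25
    prev = _vm_at(vm, xi) - yi if 0 <= xi <= len(vm) - 1 else None
    if prev is not None and prev >= 0:
        return float(yi)
    t = step
    while t <= 4.0 * max(cand.width_ms, 10.0):
        x, y = xi + dx * t, yi + dy * t
        if not 0 <= x <= len(vm) - 1:
            break
        f = _vm_at(vm, x) - y
        if prev is not None and f >= 0:
            frac = 0.0 if f == prev else (0 - prev) / (f - prev)
            return float((yi + dy * (t - step)) + dy * step * frac)
        prev = f
        t += step
    raise FeatureError("bisector does not meet the signal")


def compute_slur_features(peak, slur, vm, deriv=None, min_voltage=MIN_VOLTAGE_UV):
    """Compute all candidate-pair features for a slur following a peak.

    Parameters
    ----------
    peak, slur : Candidate
        The peak and the following slur (``slur.rise_ms > peak.rise_ms``).
    vm : ndarray
        Vector magnitude beat at 1 ms resolution (uV).
    deriv : ndarray, optional
        Smoothed first derivative (uV/ms); central differences of ``vm``
        are used when omitted.

    Raises
    ------
    FeatureError
        On degenerate geometry (coincident points, parallel lines, zero
        denominators); callers treat such slurs as irrelevant.
    """
    vm = np.asarray(vm, dtype=float)
    if deriv is None:
        deriv = np.gradient(vm)
    if not slur.rise_ms > peak.rise_ms:
        raise FeatureError("slur must follow the peak")

    p_rising, p_falling = _limb_lines(peak, vm, deriv)
    s_rising, s_falling = _limb_lines(slur, vm, deriv)

    xp, yp = peak.apex_ms, peak.apex_uv
    xs, ys = slur.apex_ms, slur.apex_uv
    if min(xp, xs) <= 0 or ys == 0:
        raise FeatureError("degenerate candidate position/amplitude")

    # junction: falling limb of the peak meets the rising limb of the next
    # candidate -- the line-geometry analogue of the valley between them
    jx, _ = _intersect(p_falling, s_rising)
    yj = _vm_at(vm, jx)
    if jx == 0 or yj == 0:
        raise FeatureError("degenerate junction")

    y_origin_p = _y_origin(peak, vm, deriv)
    y_origin_s = _y_origin(slur, vm, deriv)
    if y_origin_s == 0 or y_origin_p == 0:
        raise FeatureError("zero bisector-origin amplitude")

    divisor = abs(yj - min_voltage)
    if divisor == 0:
        raise FeatureError("zero divisor")
    if abs(xs - jx) == 0 or abs(ys - yj) == 0:
        raise FeatureError("slur coincides with junction")

    atand = lambda m: float(np.degrees(np.arctan(m)))
    # Rotation: 90 deg minus the downward-bisector angle from horizontal,
    # i.e. the tilt of the candidate; the published feature then applies the
    # inverse tangent to that degree value, which is kept literally.
    rot_p = float(np.degrees(_bisector_angle_rad(p_rising, p_falling)))
    rot_s = float(np.degrees(_bisector_angle_rad(s_rising, s_falling)))

    values = {
        "amp_ratio_peak_slur": yp / ys,
        "peak_slur_origin_ratio": yp / y_origin_s,
        "origin_ratio": y_origin_p / y_origin_s,
        "time_ratio_peak_slur": xp / xs,
        "amp_diff_peak_slur": yp - ys,
        "junction_peak_amp_diff": abs(yj - yp),
        "junction_slur_amp_diff": abs(yj - ys),
        "junction_peak_amp_ratio": abs(yj / yp),
        "junction_slur_amp_ratio": abs(yj / ys),
        "time_ratio_peak_junction": xp / jx,
        "time_ratio_slur_junction": xs / jx,
        "time_ratio_peak_slur_junction": abs(xp - jx) / abs(xs - jx),
        "amp_ratio_peak_slur_junction": abs(yp - yj) / abs(ys - yj),
        "peak_floor_ratio": (yp - min_voltage) / divisor,
        "slur_floor_ratio": (ys - min_voltage) / divisor,
        "peak_slope_angle": abs(atand(p_rising[0]) - atand(p_falling[0])),
        "slur_slope_angle": abs(atand(s_rising[0]) - atand(s_falling[0])),
        "peak_slur_angle": abs(atand(p_falling[0]) - atand(s_rising[0])),
        "peak_rotation_atand": atand(rot_p),
        "slur_rotation_atand": atand(rot_s),
    }
    return SlurFeatures(values)
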