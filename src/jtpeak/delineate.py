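"""Two-stage T-wave delineation on the vector magnitude lead.

Stage one finds the T-peak: within a heart-rate dependent search window
(J-point + 25 ms to 40% of the RR interval), every local-maximum/local-minimum
pair of the smoothed first derivative is a candidate; candidates narrower than
10 ms or below the 100 uV amplitude floor are discarded; a candidate whose
derivative crosses zero is a peak, otherwise a slur. Slurs that follow a peak
are kept only if the relevance tree accepts them; a short rule set then merges
near-equal peaks, removes dwarfed peaks and demotes one-sided-flat peaks to
slurs, after which the T-peak is the highest surviving peak.

Stage two finds the T-wave offset: the tangent at the steepest descending
slope after the last surviving candidate gives an initial offset; local minima
of a normalized cumulative energy signal over the tail then compete with it
under a cost that weighs distance from the T-peak against residual energy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import (
    ConfigError,
    DegenerateWindowError,
    FeatureError,
    REASON_DEGENERATE_WINDOW,
    REASON_NO_CANDIDATES,
    REASON_NO_OFFSET,
    REASON_NO_PEAK,
)
from .features import MIN_VOLTAGE_UV, compute_slur_features
from .relevance import IRRELEVANT, RelevanceTree, classify_slur_relevance
from .vm_lead import VmBeat


@dataclass(frozen=True)
class DelineationConfig:
    """Tunable parameters of the delineator (times ms, amplitudes uV)."""

    lowpass_hz: float = 25.0
    filter_order: int = 4
    window_start_offset_ms: float = 25.0
    window_rr_fraction: float = 0.40
    min_width_ms: float = 10.0
    min_voltage_uv: float = MIN_VOLTAGE_UV
    merge_valley_fraction: float = 0.90
    remove_fraction: float = 0.50
    horizontal_angle_deg: float = 5.0
    w_distance: float = 0.5
    w_energy: float = 0.5
    min_refine_ms: float = 5.0
    baseline_uv: float = 0.0

    @classmethod
    def from_file(cls, path):
        """Load overrides from a JSON or TOML file."""
        path = str(path)
        if path.endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = json.load(fh)
        known = set(cls.__dataclass_fields__)
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


@dataclass(frozen=True)
class SearchWindow:
    """Half-open T-peak search interval [start_ms, end_ms), beat coordinates."""

    start_ms: float
    end_ms: float


@dataclass
class Candidate:
    """One derivative max-min pair on the vector-magnitude T-wave."""

    rise_ms: float   # time of the local maximum of the smoothed derivative
    fall_ms: float   # time of the following local minimum
    apex_ms: float   # time of the highest amplitude within [rise, fall]
    apex_uv: float
    label: str       # "peak" | "slur"

    @property
    def width_ms(self):
        return self.fall_ms - self.rise_ms


@dataclass
class EnergySignal:
    """Normalized cumulative energy over an offset-search interval."""

    start_ms: int
    values: np.ndarray
    candidate_minima_ms: np.ndarray

    def at(self, t_ms):
        idx = int(round(t_ms)) - self.start_ms
        idx = min(max(idx, 0), len(self.values) - 1)
        return float(self.values[idx])


@dataclass
class FiducialSet:
    """Delineation result for one median beat (times in ms from beat start)."""

    qrs_onset_ms: float | None
    qrs_offset_ms: float
    t_peak_ms: float | None = None
    secondary_peak_ms: float | None = None
    notched: bool = False
    t_end_ms: float | None = None
    measurable: bool = True
    reason: str | None = None
    diagnostics: dict = field(default_factory=dict)


def define_search_window(j_point_ms, alignment_ms, median_rr_ms, config=None):
    """T-peak search window: J-point + 25 ms to 40% of the RR past the trigger.

    Raises :class:`DegenerateWindowError` when the rate-dependent end falls at
    or before the start (extreme tachycardia / late J-point); callers flag the
    beat unmeasurable.
    """
    config = config or DelineationConfig()
    if median_rr_ms <= 0:
        raise ConfigError("median RR must be positive")
    start = j_point_ms + config.window_start_offset_ms
    end = alignment_ms + config.window_rr_fraction * median_rr_ms
    if end <= start:
        raise DegenerateWindowError(
            f"search window [{start:g}, {end:g}) is empty"
        )
    return SearchWindow(start, end)


def smooth_signal(vm, config=None):
    """Zero-phase low-pass filtered beat (uV); the signal all stages measure on."""
    config = config or DelineationConfig()
    sig = np.asarray(vm.vm if hasattr(vm, "vm") else vm, dtype=float)
    b, a = butter(config.filter_order, config.lowpass_hz / 500.0)
    return filtfilt(b, a, sig)


def smooth_derivative(vm, config=None):
    """First derivative (uV/ms) of the zero-phase low-pass filtered beat."""
    return np.gradient(smooth_signal(vm, config))


def _local_extrema(x):
    """Indices of strict local maxima and minima of ``x``."""
    interior = np.arange(1, len(x) - 1)
    maxima = interior[(x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])]
    minima = interior[(x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])]
    return maxima, minima


def classify_candidate(rise_ms, fall_ms, deriv):
    """"peak" if the derivative crosses zero inside the candidate, else "slur"."""
    return "peak" if deriv[int(rise_ms)] > 0 and deriv[int(fall_ms)] < 0 else "slur"


def find_candidates(vm, window, deriv, config=None):
    """Enumerate labeled candidates inside the search window.

    Every local maximum of the smoothed derivative is paired with the next
    local minimum; pairs outside the window, narrower than the width floor or
    whose apex is below the voltage floor are discarded. Candidates are
    returned in rise-time order.
    """
    config = config or DelineationConfig()
    sig = np.asarray(vm.vm if hasattr(vm, "vm") else vm, dtype=float)
    maxima, minima = _local_extrema(deriv)
    out = []
    for rise in maxima:
        nxt = minima[minima > rise]
        if nxt.size == 0:
            continue
        fall = int(nxt[0])
        if not (window.start_ms <= rise and fall < window.end_ms):
            continue
        if fall - rise < config.min_width_ms:
            continue
        apex_off = int(np.argmax(sig[rise : fall + 1]))
        apex = rise + apex_off
        apex_uv = float(sig[apex])
        if apex_uv < config.min_voltage_uv:
            continue
        out.append(
            Candidate(
                rise_ms=float(rise),
                fall_ms=float(fall),
                apex_ms=float(apex),
                apex_uv=apex_uv,
                label=classify_candidate(rise, fall, deriv),
            )
        )
    return out


def _limb_angle_deg(sig, a_ms, b_ms):
    a, b = int(round(a_ms)), int(round(b_ms))
    if b - a < 1:
        return 0.0
    t = np.arange(a, b + 1, dtype=float)
    slope = np.polyfit(t, sig[a : b + 1], 1)[0]
    return float(np.degrees(np.arctan(slope)))


def apply_cleanup_rules(candidates, vm, config=None):
    """Final cleanup: merge -> remove -> convert, preserving time order.

    * merge: adjacent peaks whose inter-peak valley reaches 90% of the lower
      apex become one candidate with the higher apex;
    * remove: a peak dwarfed by more than 50% of the largest peak's amplitude
      is dropped;
    * convert: a peak with one nearly horizontal limb (< 5 deg) is demoted to
      a slur.
    """
    config = config or DelineationConfig()
    sig = np.asarray(vm.vm if hasattr(vm, "vm") else vm, dtype=float)
    cands = sorted(candidates, key=lambda c: c.rise_ms)

    # merge adjacent peaks across shallow valleys
    merged = True
    while merged:
        merged = False
        for i in range(len(cands) - 1):
            a, b = cands[i], cands[i + 1]
            if a.label != "peak" or b.label != "peak":
                continue
            valley = float(np.min(sig[int(a.apex_ms) : int(b.apex_ms) + 1]))
            if valley >= config.merge_valley_fraction * min(a.apex_uv, b.apex_uv):
                hi = a if a.apex_uv >= b.apex_uv else b
                cands[i] = Candidate(a.rise_ms, b.fall_ms, hi.apex_ms, hi.apex_uv, "peak")
                del cands[i + 1]
                merged = True
                break

    # remove dwarfed peaks
    peak_amps = [c.apex_uv for c in cands if c.label == "peak"]
    if len(peak_amps) > 1:
        top = max(peak_amps)
        cands = [
            c
            for c in cands
            if c.label != "peak" or (top - c.apex_uv) <= config.remove_fraction * top
        ]

    # convert one-sided-flat peaks to slurs
    out = []
    for c in cands:
        if c.label == "peak":
            rising = abs(_limb_angle_deg(sig, c.rise_ms, c.apex_ms))
            falling = abs(_limb_angle_deg(sig, c.apex_ms, c.fall_ms))
            if min(rising, falling) < config.horizontal_angle_deg:
                c = Candidate(c.rise_ms, c.fall_ms, c.apex_ms, c.apex_uv, "slur")
        out.append(c)
    return out


def select_tpeak(candidates):
    """T-peak = apex of the highest surviving peak.

    Returns ``(t_peak_ms, secondary_peak_ms, notched)``; ``(None, None,
    False)`` when no peak survives. With two or more surviving peaks the beat
    is notched and the highest non-selected peak is reported as secondary.
    """
    peaks = [c for c in candidates if c.label == "peak"]
    if not peaks:
        return None, None, False
    primary = max(peaks, key=lambda c: (c.apex_uv, -c.apex_ms))
    others = [c for c in peaks if c is not primary]
    secondary = max(others, key=lambda c: (c.apex_uv, -c.apex_ms)) if others else None
    return (
        primary.apex_ms,
        None if secondary is None else secondary.apex_ms,
        len(peaks) >= 2,
    )


def tangent_offset(vm, last_candidate, deriv=None, search_end_ms=None, config=None):
    """Initial T-wave offset by the tangent method.

    The tangent at the steepest descending slope after the last candidate's
    apex is intersected with the isoelectric level (0 uV after baseline
    removal; configurable). Returns the intersection time in ms; raises
    :class:`FeatureError` when no descending limb exists.
    """
    config = config or DelineationConfig()
    sig = np.asarray(vm.vm if hasattr(vm, "vm") else vm, dtype=float)
    if deriv is None:
        deriv = smooth_derivative(sig, config)
    apex = int(round(last_candidate.apex_ms))
    end = len(sig) - 1 if search_end_ms is None else int(round(search_end_ms))
    end = min(end, len(sig) - 1)
    if end - apex < 2:
        raise FeatureError("no room after the last candidate for a tangent")
    seg = deriv[apex + 1 : end + 1]
    t_star = apex + 1 + int(np.argmin(seg))
    slope = float(deriv[t_star])
    if slope >= 0:
        raise FeatureError("no descending limb after the last candidate")
    t_end = t_star - (sig[t_star] - config.baseline_uv) / slope
    if t_end <= last_candidate.apex_ms:
        raise FeatureError("tangent intersects before the candidate apex")
    return float(t_end)


def energy_signal(vm, deriv, start_ms, end_ms, config=None):
    """Cumulative energy over [start_ms, end_ms] with offset-candidate minima.

    The raw signal accumulates the derivative magnitude with the sign of the
    derivative's sample-to-sample change (up: add, otherwise: subtract); the
    normalization ``(max - E)/(max - min)`` orients it so the maximum value
    (1) sits at the beginning of a decaying tail and the lowest (0) at its
    end. Offset candidates are the strict local minima of the normalized
    signal. Returns ``None`` when the interval is shorter than the refinement
    floor or the raw signal is constant (callers keep the tangent offset).
    """
    config = config or DelineationConfig()
    start, end = int(round(start_ms)), int(round(end_ms))
    sig_len = len(vm.vm if hasattr(vm, "vm") else vm)
    end = min(end, sig_len - 1)
    if end - start < config.min_refine_ms:
        return None
    d = deriv[start : end + 1]
    delta = np.diff(d)
    steps = np.where(delta > 0, np.abs(d[1:]), -np.abs(d[1:]))
    raw = np.concatenate([[0.0], np.cumsum(steps)])
    if raw.max() == raw.min():
        return None
    values = (raw.max() - raw) / (raw.max() - raw.min())
    minima = _local_extrema(values)[1]
    return EnergySignal(start, values, start + minima)


def refine_offset(energy, t_peak_ms, next_qrs_ms, tangent_ms, config=None):
    """Choose the offset minimizing distance-to-peak vs residual-energy cost.

    ``cost(c) = w1 * (c - t_peak)/(next_qrs - t_peak) + w2 * E(c)`` over the
    energy minima plus the tangent offset itself; ties break to the earliest
    candidate, and the result never precedes the T-peak.
    """
    config = config or DelineationConfig()
    if energy is None:
        return float(tangent_ms)
    cands = [float(c) for c in energy.candidate_minima_ms] + [float(tangent_ms)]
    cands = sorted(c for c in cands if c > t_peak_ms)
    if not cands:
        return float(tangent_ms)
    span = next_qrs_ms - t_peak_ms
    if span <= 0:
        return float(tangent_ms)
    best, best_cost = None, np.inf
    for c in cands:
        cost = config.w_distance * (c - t_peak_ms) / span + config.w_energy * energy.at(c)
        if cost < best_cost:  # strict: earliest candidate wins ties
            best, best_cost = c, cost
    return float(best)


def _unmeasurable(annotations, reason, diagnostics):
    return FiducialSet(
        qrs_onset_ms=annotations.qrs_onset_ms,
        qrs_offset_ms=annotations.qrs_offset_ms,
        measurable=False,
        reason=reason,
        diagnostics=diagnostics,
    )


def delineate_twave(vm, annotations, config=None, tree=None):
    """Full two-stage delineation of one vector-magnitude median beat.

    Parameters
    ----------
    vm : VmBeat
    annotations : AnnotationSet
        Must carry the QRS offset (J-point) in beat coordinates.
    config : DelineationConfig, optional
    tree : RelevanceTree, optional
        Defaults to the bundled tree.

    Returns
    -------
    FiducialSet
        Flagged unmeasurable (with a reason code) instead of raising when the
        beat has no usable T-wave. Deterministic for fixed input and config.
    """
    config = config or DelineationConfig()
    if tree is None:
        tree = RelevanceTree.load_default()
    diagnostics = {}

    try:
        window = define_search_window(
            annotations.qrs_offset_ms, vm.alignment_ms, vm.median_rr_ms, config
        )
    except DegenerateWindowError:
        return _unmeasurable(annotations, REASON_DEGENERATE_WINDOW, diagnostics)

    # all amplitude measurements are made on the filtered signal, consistent
    # with the derivative the candidates come from
    smooth = smooth_signal(vm, config)
    deriv = np.gradient(smooth)
    vm = VmBeat(smooth, vm.alignment_ms, vm.median_rr_ms)
    candidates = find_candidates(vm, window, deriv, config)
    diagnostics["n_candidates"] = len(candidates)
    if not candidates:
        return _unmeasurable(annotations, REASON_NO_CANDIDATES, diagnostics)

    # keep only slurs that follow a peak and that the tree accepts
    kept = []
    last_peak = None
    for cand in candidates:
        if cand.label == "peak":
            kept.append(cand)
            last_peak = cand
        else:
            if last_peak is None:
                continue
            try:
                feats = compute_slur_features(
                    last_peak, cand, vm.vm, deriv, config.min_voltage_uv
                )
            except FeatureError:
                continue
            if classify_slur_relevance(feats, tree) != IRRELEVANT:
                kept.append(cand)

    kept = apply_cleanup_rules(kept, vm, config)
    t_peak, secondary, notched = select_tpeak(kept)
    peaks = [c for c in kept if c.label == "peak"]
    diagnostics["n_peaks"] = len(peaks)
    diagnostics["peak_amplitudes_uv"] = [round(c.apex_uv, 3) for c in peaks]
    if t_peak is None:
        return _unmeasurable(annotations, REASON_NO_PEAK, diagnostics)

    # stage two: offset from the last surviving candidate
    last = kept[-1]
    next_qrs = vm.alignment_ms + vm.median_rr_ms
    try:
        t_end_initial = tangent_offset(
            vm, last, deriv, search_end_ms=min(next_qrs, vm.n_ms - 1), config=config
        )
    except FeatureError:
        return _unmeasurable(annotations, REASON_NO_OFFSET, diagnostics)
    diagnostics["tangent_offset_ms"] = round(t_end_initial, 3)

    energy = energy_signal(vm, deriv, last.fall_ms, t_end_initial, config)
    diagnostics["n_offset_candidates"] = (
        0 if energy is None else len(energy.candidate_minima_ms)
    )
    t_end = refine_offset(energy, t_peak, next_qrs, t_end_initial, config)
    if not t_peak < t_end:
        return _unmeasurable(annotations, REASON_NO_OFFSET, diagnostics)

    return FiducialSet(
        qrs_onset_ms=annotations.qrs_onset_ms,
        qrs_offset_ms=annotations.qrs_offset_ms,
        t_peak_ms=float(t_peak),
        secondary_peak_ms=None if secondary is None else float(secondary),
        notched=bool(notched),
        t_end_ms=float(t_end),
        diagnostics=diagnostics,
    )
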