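"""Synthetic median beats and 10 s ECG segments with analytic ground truth.

T-waves are sums of Gaussian bumps; the QRS is three narrow Gaussians (only
the region past the J-point is ever delineated, so a stylized QRS suffices).
Each generated beat carries a :class:`GroundTruth` derived from the bump
parameters on a dense grid -- never from the delineator -- including the
tangent-method T-wave end, which for an isolated terminal Gaussian has the
closed form ``center + 2 * width``.

Four morphology classes are covered: ``normal`` (single bump), ``flat``
(single low-amplitude bump), ``notched`` (two well-separated bumps) and
``slurred`` (a shoulder component on the descending limb). The canonical
parameters below are the package's reference test-bed conditions; the
``random_*`` helpers draw per-beat variants within physiological ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .ecg_io import EcgRecord, AnnotationSet, INDEPENDENT_LEADS
from .errors import ConfigError
from .features import MIN_VOLTAGE_UV
from .preprocess import BeatTriggers
from .vm_lead import VmBeat, load_transform_matrix

#: QRS template as (amplitude uV, center offset from trigger ms, width ms)
DEFAULT_QRS = ((-150.0, -15.0, 4.0), (900.0, 0.0, 6.0), (-200.0, 17.0, 5.0))
#: trigger (R apex) position within the beat
ALIGNMENT_MS = 300.0
#: analytic QRS onset / offset (J-point) of the template, beat coordinates
QRS_ONSET_MS = ALIGNMENT_MS - 35.0
QRS_OFFSET_MS = ALIGNMENT_MS + 40.0

MORPHOLOGIES = ("normal", "flat", "notched", "slurred")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic beat (all times in beat coordinates, ms)."""

    morphology: str
    t_components: tuple  # ((amplitude uV, center ms, width ms), ...)
    qrs_components: tuple = DEFAULT_QRS
    rr_ms: float = 1000.0
    noise_sd_uv: float = 0.0
    baseline_wander: tuple = (0.0, 0.0)  # (amplitude uV, frequency Hz)
    seed: int | None = None
    alignment_ms: float = ALIGNMENT_MS
    beat_len_ms: int = 1000

    def __post_init__(self):
        if self.morphology not in MORPHOLOGIES:
            raise ConfigError(f"unknown morphology {self.morphology!r}")
        comps = self.t_components
        if self.morphology in ("normal", "flat") and len(comps) != 1:
            raise ConfigError(f"{self.morphology} T-wave needs exactly 1 component")
        if self.morphology == "flat" and comps[0][0] > 150.0:
            raise ConfigError("flat T-wave amplitude must be <= 150 uV")
        if self.morphology == "notched":
            if len(comps) != 2:
                raise ConfigError("notched T-wave needs exactly 2 components")
            sep = abs(comps[1][1] - comps[0][1])
            if sep <= 2.0 * min(comps[0][2], comps[1][2]):
                raise ConfigError("notch separation must exceed twice the min width")
        if self.morphology == "slurred":
            if len(comps) != 2:
                raise ConfigError("slurred T-wave needs main + shoulder components")
            if comps[1][0] >= comps[0][0]:
                raise ConfigError("shoulder amplitude must be below the main peak")
        if self.rr_ms <= 0:
            raise ConfigError("RR must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic fiducials of a synthetic beat (ms, beat coordinates)."""

    qrs_onset_ms: float
    qrs_offset_ms: float
    t_peak_true_ms: float
    t_end_true_ms: float
    t_end_closed_form_ms: float
    secondary_peak_true_ms: float | None = None
    notched: bool = False

    def annotations(self):
        return AnnotationSet(self.qrs_onset_ms, self.qrs_offset_ms, source="external")


def _gauss_sum(components, t):
    out = np.zeros_like(t, dtype=float)
    for amp, center, width in components:
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def _gauss_sum_deriv(components, t):
    out = np.zeros_like(t, dtype=float)
    for amp, center, width in components:
        out += (
            amp
            * np.exp(-0.5 * ((t - center) / width) ** 2)
            * (-(t - center) / width**2)
        )
    return out


def ground_truth(spec, min_voltage=MIN_VOLTAGE_UV):
    """Dense-grid analytic fiducials from the T components of ``spec``.

    T-peaks are local maxima of the noiseless T-wave at or above the
    detection floor (primary = highest). The T-end is the tangent at the
    steepest descending slope past the center of the terminal component,
    intersected with the zero line.
    """
    comps = sorted(spec.t_components, key=lambda c: c[1])
    widths = [c[2] for c in comps]
    t0 = comps[0][1] - 6.0 * max(widths)
    t1 = comps[-1][1] + 6.0 * comps[-1][2]
    t = np.arange(t0, t1, 0.05)
    s = _gauss_sum(comps, t)

    interior = np.arange(1, len(t) - 1)
    is_max = (s[1:-1] > s[:-2]) & (s[1:-1] >= s[2:])
    peaks = interior[is_max & (s[1:-1] >= min_voltage)]
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(s))])
    order = np.argsort(s[peaks])[::-1]
    primary = float(t[peaks[order[0]]])
    secondary = float(t[peaks[order[1]]]) if peaks.size > 1 else None

    # tangent past the terminal component's center
    terminal_center, terminal_width = comps[-1][1], comps[-1][2]
    tail = t > terminal_center
    d = _gauss_sum_deriv(comps, t[tail])
    i_star = int(np.argmin(d))
    t_star = t[tail][i_star]
    slope = d[i_star]
    amp = s[tail][i_star]
    t_end = float(t_star - amp / slope)

    return GroundTruth(
        qrs_onset_ms=spec.alignment_ms - 35.0,
        qrs_offset_ms=spec.alignment_ms + 40.0,
        t_peak_true_ms=primary,
        t_end_true_ms=t_end,
        t_end_closed_form_ms=float(terminal_center + 2.0 * terminal_width),
        secondary_peak_true_ms=secondary,
        notched=peaks.size > 1,
    )


def _beat_waveform(spec, t_ms, rng=None):
    """Signed orthogonal-lead waveform of one beat on grid ``t_ms``."""
    qrs = [(a, spec.alignment_ms + c, w) for a, c, w in spec.qrs_components]
    x = _gauss_sum(list(qrs) + list(spec.t_components), t_ms)
    if rng is not None:
        if spec.noise_sd_uv > 0:
            x = x + rng.normal(0.0, spec.noise_sd_uv, size=len(t_ms))
        amp, freq = spec.baseline_wander
        if amp > 0 and freq > 0:
            phase = rng.uniform(0, 2 * math.pi)
            x = x + amp * np.sin(2 * math.pi * freq * t_ms / 1000.0 + phase)
    return x


def generate_beat(spec):
    """Deterministic (VmBeat, GroundTruth) pair for one synthetic median beat."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.beat_len_ms, dtype=float)
    x = _beat_waveform(spec, t, rng)
    beat = VmBeat(np.abs(x), spec.alignment_ms, spec.rr_ms)
    return beat, ground_truth(spec)


def generate_record(spec, duration_s=10.0, fs=500.0, transform=None):
    """A 12-lead-style 10 s ECG segment realizing ``spec`` beat after beat.

    The eight independent leads are scaled copies of the beat waveform with
    weights chosen so the bundled (or supplied) orthogonal transform maps them
    onto the X lead exactly; per-lead white noise and baseline wander are then
    added. Returns ``(EcgRecord, GroundTruth, BeatTriggers)`` with the true
    trigger positions.
    """
    if transform is None:
        transform = load_transform_matrix()
    weights = np.linalg.pinv(transform) @ np.array([1.0, 0.0, 0.0])

    rng = np.random.default_rng(spec.seed)
    n = int(round(duration_s * fs))
    t_ms = np.arange(n) * 1000.0 / fs
    clean = np.zeros(n)
    triggers = []
    t_r = 400.0
    while t_r + (spec.beat_len_ms - spec.alignment_ms) < duration_s * 1000.0 - 100.0:
        shift = t_r - spec.alignment_ms
        comps = [(a, c + shift + spec.alignment_ms, w) for a, c, w in spec.qrs_components]
        comps += [(a, c + shift, w) for a, c, w in spec.t_components]
        clean += _gauss_sum(comps, t_ms)
        triggers.append(int(round(t_r / 1000.0 * fs)))
        t_r += spec.rr_ms

    leads = np.outer(weights, clean)
    if spec.noise_sd_uv > 0:
        leads = leads + rng.normal(0.0, spec.noise_sd_uv, size=leads.shape)
    amp, freq = spec.baseline_wander
    if amp > 0 and freq > 0:
        for i in range(leads.shape[0]):
            phase = rng.uniform(0, 2 * math.pi)
            leads[i] += amp * np.sin(2 * math.pi * freq * t_ms / 1000.0 + phase)

    record = EcgRecord(leads, fs, INDEPENDENT_LEADS)
    return record, ground_truth(spec), BeatTriggers(np.asarray(triggers), fs)


# --- canonical and randomized morphology parameters -------------------------

_AL = ALIGNMENT_MS

_CANONICAL = {
    "normal": ((400.0, _AL + 270.0, 30.0),),
    "flat": ((130.0, _AL + 265.0, 42.0),),
    "notched": ((350.0, _AL + 245.0, 20.0), (420.0, _AL + 320.0, 22.0)),
    "slurred": ((420.0, _AL + 245.0, 26.0), (227.0, _AL + 310.0, 38.0)),
}


def canonical_spec(morphology, rr_ms=1000.0, noise_sd_uv=0.0, baseline_wander=(0.0, 0.0), seed=None):
    """The fixed reference parameter set for one morphology class."""
    return SyntheticSpec(
        morphology,
        _CANONICAL[morphology],
        rr_ms=rr_ms,
        noise_sd_uv=noise_sd_uv,
        baseline_wander=baseline_wander,
        seed=seed,
    )


def random_spec(morphology, rng, noise_sd_uv=0.0, baseline_wander=(0.0, 0.0)):
    """Draw a physiological per-beat variant of one morphology class."""
    u = rng.uniform
    rr = u(950.0, 1100.0)
    if morphology == "normal":
        comps = ((u(250.0, 500.0), _AL + u(240.0, 310.0), u(25.0, 38.0)),)
    elif morphology == "flat":
        comps = ((u(105.0, 150.0), _AL + u(230.0, 280.0), u(35.0, 50.0)),)
    elif morphology == "notched":
        a1 = u(250.0, 400.0)
        ratio = u(1.1, 1.4) if rng.random() < 0.5 else u(0.65, 0.9)
        c1 = _AL + u(225.0, 250.0)
        comps = ((a1, c1, u(18.0, 24.0)), (a1 * ratio, c1 + u(60.0, 85.0), u(18.0, 24.0)))
    elif morphology == "slurred":
        a = u(350.0, 480.0)
        sigma = u(24.0, 28.0)
        c = _AL + u(235.0, 255.0)
        comps = (
            (a, c, sigma),
            (a * u(0.5, 0.58), c + u(2.45, 2.55) * sigma, u(36.0, 40.0)),
        )
    else:
        raise ConfigError(f"unknown morphology {morphology!r}")
    return SyntheticSpec(
        morphology,
        comps,
        rr_ms=rr,
        noise_sd_uv=noise_sd_uv,
        baseline_wander=baseline_wander,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def apply_effect(spec, shift_ms=0.0, widen_terminal_ms=0.0):
    """Emulate a drug effect: delay all T components, widen the terminal one."""
    comps = [(a, c + shift_ms, w) for a, c, w in spec.t_components]
    a, c, w = comps[-1]
    comps[-1] = (a, c, w + widen_terminal_ms)
    return replace(spec, t_components=tuple(comps))


def generate_slur_corpus(n=500, seed=7, max_beats=None):
    """Labeled slur-feature corpus for relevance-tree training.

    Two geometric populations with generator-truth labels:

    * ``relevant`` -- the slurred morphology's pronounced terminal shoulder
      (it carries the terminal decay of the T-wave and should anchor the
      offset search);
    * ``irrelevant`` -- a tiny, narrow trailing bump riding the descending
      limb (amplitude 8-18% of the main peak), the kind of shoulder a reader
      would ignore when placing the T-wave end.

    Each beat contributes the slur candidate detected inside its constructed
    shoulder's domain; beats whose shoulder goes undetected are skipped.
    Labels come from the construction, never from the classifier. Returns
    ``(examples, labels)`` with one :class:`SlurFeatures` per example,
    balanced between the classes.
    """
    from .delineate import (
        DelineationConfig,
        define_search_window,
        find_candidates,
        smooth_derivative,
    )
    from .errors import FeatureError
    from .features import compute_slur_features

    config = DelineationConfig()
    rng = np.random.default_rng(seed)
    examples, labels = [], []
    quota = {"relevant": n - n // 2, "irrelevant": n // 2}
    beats = 0
    if max_beats is None:
        max_beats = 60 * n
    while sum(quota.values()) > 0 and beats < max_beats:
        beats += 1
        u = rng.uniform
        if rng.random() < 0.5:
            spec = random_spec("slurred", rng, noise_sd_uv=float(u(0.0, 4.0)))
            label = "relevant"
        else:
            a, sig = u(350.0, 480.0), u(24.0, 28.0)
            c = _AL + u(235.0, 255.0)
            comps = (
                (a, c, sig),
                (a * u(0.08, 0.18), c + u(1.7, 2.0) * sig, u(11.0, 15.0)),
            )
            spec = SyntheticSpec(
                "slurred",
                comps,
                rr_ms=float(u(950.0, 1100.0)),
                noise_sd_uv=float(u(0.0, 4.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            label = "irrelevant"
        _, c_s, s_s = spec.t_components[1]
        domain = (c_s - 2.0 * s_s, c_s + 1.0 * s_s)

        beat, truth = generate_beat(spec)
        try:
            window = define_search_window(
                truth.qrs_offset_ms, beat.alignment_ms, beat.median_rr_ms, config
            )
        except Exception:
            continue
        deriv = smooth_derivative(beat, config)
        last_peak = None
        for cand in find_candidates(beat, window, deriv, config):
            if cand.label == "peak":
                last_peak = cand
                continue
            if last_peak is None or not domain[0] <= cand.rise_ms <= domain[1]:
                continue
            try:
                feats = compute_slur_features(last_peak, cand, beat.vm, deriv)
            except FeatureError:
                continue
            if quota[label] > 0:
                quota[label] -= 1
                examples.append(feats)
                labels.append(label)
            break
    return examples, labels


def generate_study(
    n_subjects,
    n_timepoints,
    n_replicates,
    effect_profile=None,
    seed=0,
    morphology="normal",
    noise_sd_uv=5.0,
):
    """Synthetic crossover-style study: subjects x time points x replicates.

    Each subject gets one randomized morphology parameter set; the effect
    profile (one T-wave delay in ms per time point) shifts the true fiducials
    over time; replicates share the spec (hence the GroundTruth) and differ
    only in their noise seed. Returns a list of dicts with keys ``subject``,
    ``timepoint``, ``replicate``, ``spec``, ``beat``, ``truth``.
    """
    if min(n_subjects, n_timepoints, n_replicates) < 1:
        raise ConfigError("all counts must be >= 1")
    if effect_profile is None:
        effect_profile = [0.0] * n_timepoints
    if len(effect_profile) != n_timepoints:
        raise ConfigError("effect_profile must have one entry per time point")

    master = np.random.default_rng(seed)
    rows = []
    for subj in range(n_subjects):
        base = random_spec(morphology, master, noise_sd_uv=noise_sd_uv)
        for tp in range(n_timepoints):
            spec_tp = apply_effect(base, shift_ms=float(effect_profile[tp]))
            truth = ground_truth(spec_tp)
            for rep in range(n_replicates):
                spec_rep = replace(
                    spec_tp, seed=int(master.integers(0, 2**31 - 1))
                )
                beat, _ = generate_beat(spec_rep)
                rows.append(
                    {
                        "subject": subj,
                        "timepoint": tp,
                        "replicate": rep,
                        "spec": spec_rep,
                        "beat": beat,
                        "truth": truth,
                    }
                )
    return rows
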