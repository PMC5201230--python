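"""Interval computation and heart-rate correction.

QT runs from QRS onset to the T-wave end, J-Tpeak from the QRS offset
(J-point) to the T-peak, and Tpeak-Tend from the T-peak to the T-wave end, so
``QT = (QRSoff - QRSon) + JTpeak + TpeakTend`` by construction. QT is
corrected with Fridericia's cube-root formula by default; J-Tpeak with a
power-law correction ``interval / (RR/1000)^e`` whose exponent defaults to
0.58, the value established for this interval in prior clinical-ECG work.
Tpeak-Tend is reported uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError, IncompleteMeasurementError

#: default exponent of the J-Tpeak power-law rate correction
JTPEAK_EXPONENT = 0.58


@dataclass(frozen=True)
class IntervalSet:
    """Raw and rate-corrected repolarization intervals (ms)."""

    rr_ms: float
    qt_ms: float
    jtpeak_ms: float
    tpeak_tend_ms: float
    qtc_ms: float
    jtpeakc_ms: float
    correction_method: str


def rate_correct(interval_ms, rr_ms, method="fridericia_qt", exponent=JTPEAK_EXPONENT):
    """Heart-rate correct an interval; identity at RR = 1000 ms.

    ``fridericia_qt``: interval / (RR/1000)^(1/3).
    ``jtpeak_power``: interval / (RR/1000)^exponent.
    """
    if rr_ms <= 0:
        raise ConfigError("RR must be positive")
    rr_s = rr_ms / 1000.0
    if method == "fridericia_qt":
        return interval_ms / rr_s ** (1.0 / 3.0)
    if method == "jtpeak_power":
        return interval_ms / rr_s**exponent
    raise ConfigError(f"unknown correction method {method!r}")


def measure_intervals(
    fiducials,
    rr_ms,
    qt_method="fridericia_qt",
    jtpeak_exponent=JTPEAK_EXPONENT,
):
    """Compute the interval set from a complete fiducial set.

    Raises :class:`IncompleteMeasurementError` when a required fiducial is
    missing or an interval would be non-positive.
    """
    if rr_ms <= 0:
        raise ConfigError("RR must be positive")
    required = {
        "qrs_onset_ms": fiducials.qrs_onset_ms,
        "qrs_offset_ms": fiducials.qrs_offset_ms,
        "t_peak_ms": fiducials.t_peak_ms,
        "t_end_ms": fiducials.t_end_ms,
    }
    missing = [k for k, v in required.items() if v is None]
    if missing or not getattr(fiducials, "measurable", True):
        raise IncompleteMeasurementError(f"missing fiducials: {missing}")

    qt = fiducials.t_end_ms - fiducials.qrs_onset_ms
    jtpeak = fiducials.t_peak_ms - fiducials.qrs_offset_ms
    tpeak_tend = fiducials.t_end_ms - fiducials.t_peak_ms
    if min(qt, jtpeak, tpeak_tend) <= 0:
        raise IncompleteMeasurementError("non-positive interval from fiducials")

    return IntervalSet(
        rr_ms=float(rr_ms),
        qt_ms=float(qt),
        jtpeak_ms=float(jtpeak),
        tpeak_tend_ms=float(tpeak_tend),
        qtc_ms=float(rate_correct(qt, rr_ms, qt_method)),
        jtpeakc_ms=float(
            rate_correct(jtpeak, rr_ms, "jtpeak_power", jtpeak_exponent)
        ),
        correction_method=f"{qt_method}+jtpeak_power(e={jtpeak_exponent:g})",
    )
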