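"""End-to-end convenience chain: record -> median beat -> vm -> fiducials."""

from __future__ import annotations

from .delineate import delineate_twave
from .errors import IncompleteMeasurementError
from .intervals import measure_intervals
from .preprocess import build_median_beat, detect_qrs_triggers, remove_baseline
from .vm_lead import transform_xyz, vector_magnitude


def measure_record(
    record,
    annotations,
    triggers=None,
    config=None,
    tree=None,
    transform=None,
):
    """Delineate one 10 s record and measure its intervals.

    Parameters
    ----------
    record : EcgRecord
    annotations : AnnotationSet
        QRS onset/offset in median-beat coordinates (trigger at 300 ms).
    triggers : BeatTriggers, optional
        Externally supplied QRS triggers; detected automatically if omitted.

    Returns
    -------
    (FiducialSet, IntervalSet or None, VmBeat)
        Intervals are None when the beat is unmeasurable.
    """
    if triggers is None:
        triggers = detect_qrs_triggers(record)
    clean = remove_baseline(record, triggers)
    median = build_median_beat(clean, triggers)
    vm = vector_magnitude(transform_xyz(median, transform))
    fiducials = delineate_twave(vm, annotations, config=config, tree=tree)
    intervals = None
    if fiducials.measurable:
        try:
            intervals = measure_intervals(fiducials, median.median_rr_ms)
        except IncompleteMeasurementError:
            intervals = None
    return fiducials, intervals, vm
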