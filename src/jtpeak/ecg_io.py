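"""Reading and writing 12-lead ECG segments, annotations and results.

Conventions used throughout the package:

* time is in milliseconds from the start of the record (or beat), 0-based
  sample indexing, half-open windows ``[start, end)``;
* amplitudes are in microvolts (uV);
* CSV records are comma-separated with a header row of lead names, one column
  per lead, preceded by a metadata comment line ``# fs=<Hz> duration_s=<s>``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _wfdb
from .errors import FormatError, UnsupportedInputError

#: The eight linearly independent leads every record must contain, in the
#: column order expected by the orthogonal-lead transform.
INDEPENDENT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class EcgRecord:
    """A multi-lead sampled ECG segment.

    Attributes
    ----------
    samples : ndarray, shape (n_leads, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    lead_names : tuple of str
        Ordered lead labels; must include the 8 independent leads.
    """

    samples: np.ndarray
    fs: float
    lead_names: tuple

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.lead_names = tuple(self.lead_names)
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")
        if self.samples.shape[0] != len(self.lead_names):
            raise FormatError("one row of samples per lead name required")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("amplitudes must be finite")
        missing = [ld for ld in INDEPENDENT_LEADS if ld not in self.lead_names]
        if missing:
            raise FormatError(f"record is missing required leads: {', '.join(missing)}")

    @property
    def n_samples(self):
        return self.samples.shape[1]

    @property
    def duration(self):
        """Record length in seconds."""
        return self.n_samples / self.fs

    def lead(self, name):
        """Return the samples of one lead by label."""
        try:
            return self.samples[self.lead_names.index(name)]
        except ValueError:
            raise FormatError(f"no lead named {name!r}") from None

    def independent_leads(self):
        """Samples of the 8 independent leads as an (8, n_samples) array."""
        return np.stack([self.lead(ld) for ld in INDEPENDENT_LEADS])


@dataclass
class AnnotationSet:
    """Externally supplied or automated fiducial annotations (ms)."""

    qrs_onset_ms: float
    qrs_offset_ms: float
    t_peak_ms: float | None = None
    t_end_ms: float | None = None
    source: str = "external"

    def __post_init__(self):
        if not self.qrs_onset_ms < self.qrs_offset_ms:
            raise FormatError("qrs_onset must precede qrs_offset")
        if self.t_peak_ms is not None and not self.qrs_offset_ms < self.t_peak_ms:
            raise FormatError("t_peak must follow qrs_offset")
        if (
            self.t_peak_ms is not None
            and self.t_end_ms is not None
            and not self.t_peak_ms <= self.t_end_ms
        ):
            raise FormatError("t_end must not precede t_peak")


def read_ecg(path, format="csv", fs=None):
    """Read an ECG segment from ``path`` in the named dialect.

    Parameters
    ----------
    path : str
        File path; for WFDB either the ``.hea`` file or the record base name.
    format : {"csv", "wfdb"}
    fs : float, optional
        Sampling rate for CSV files without a metadata line.
    """
    if format == "wfdb":
        samples, fs_read, leads = _wfdb.read_record(str(path))
        return EcgRecord(samples, fs_read, leads)
    if format != "csv":
        raise UnsupportedInputError(f"unknown format {format!r}")

    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                meta[key] = float(val)
    df = pd.read_csv(path, comment="#")
    if "fs" in meta:
        if fs is not None and abs(fs - meta["fs"]) > 1e-9:
            raise FormatError("fs argument disagrees with file metadata")
        fs = meta["fs"]
    if fs is None:
        raise FormatError("CSV input requires a sampling rate (fs)")
    record = EcgRecord(df.to_numpy(dtype=float).T, fs, tuple(df.columns))
    if "duration_s" in meta:
        declared = meta["duration_s"]
        if declared <= 0 or abs(record.duration - declared) / declared > 1e-3:
            raise FormatError(
                f"declared duration {declared:g}s disagrees with "
                f"{record.n_samples} samples at {fs:g} Hz by more than 0.1%"
            )
    return record


def write_ecg(record, path, format="csv"):
    """Write a record as CSV (with metadata line) or WFDB format 16."""
    if format == "wfdb":
        base = str(path)
        if base.endswith(".hea"):
            base = base[:-4]
        _wfdb.write_record(base, record.samples, record.fs, record.lead_names)
        return
    if format != "csv":
        raise UnsupportedInputError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g} duration_s={record.duration:.6g}\n")
        fh.write(",".join(record.lead_names) + "\n")
        np.savetxt(fh, record.samples.T, fmt="%.6g", delimiter=",")


def read_annotations(path):
    """Read per-record annotations from CSV.

    Columns: ``record_id, qrs_onset_ms, qrs_offset_ms`` (extra columns are
    ignored). Returns ``{record_id: AnnotationSet}``.
    """
    df = pd.read_csv(path, comment="#")
    required = {"record_id", "qrs_onset_ms", "qrs_offset_ms"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation CSV must have columns {sorted(required)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["record_id"])] = AnnotationSet(
            float(row["qrs_onset_ms"]), float(row["qrs_offset_ms"])
        )
    return out


RESULT_HEADER = (
    "# jtpeak delineation results; times in ms from the start of the median beat\n"
    "# (0-based samples, half-open windows); amplitudes in uV; empty fiducial\n"
    "# fields with a reason code mark unmeasurable beats\n"
    "record_id,qrs_onset_ms,qrs_offset_ms,t_peak_ms,t_end_ms,secondary_peak_ms,"
    "notched,rr_ms,qt_ms,jtpeak_ms,tpeak_tend_ms,qtc_ms,jtpeakc_ms,reason\n"
)


def _fmt(x):
    return "" if x is None else f"{x:.3f}"


def write_results(results, path):
    """Write delineation results as delimited text, one row per beat.

    Parameters
    ----------
    results : iterable of (record_id, FiducialSet, IntervalSet or None)
        Intervals may be None for unmeasurable beats.
    path : str
    """
    rows = []
    for record_id, fid, ivl in results:
        if fid.measurable:
            fields = [
                record_id,
                _fmt(fid.qrs_onset_ms),
                _fmt(fid.qrs_offset_ms),
                _fmt(fid.t_peak_ms),
                _fmt(fid.t_end_ms),
                _fmt(fid.secondary_peak_ms),
                "1" if fid.notched else "0",
                _fmt(None if ivl is None else ivl.rr_ms),
                _fmt(None if ivl is None else ivl.qt_ms),
                _fmt(None if ivl is None else ivl.jtpeak_ms),
                _fmt(None if ivl is None else ivl.tpeak_tend_ms),
                _fmt(None if ivl is None else ivl.qtc_ms),
                _fmt(None if ivl is None else ivl.jtpeakc_ms),
                "",
            ]
        else:
            fields = [record_id, _fmt(fid.qrs_onset_ms), _fmt(fid.qrs_offset_ms)] + [
                ""
            ] * 10 + [fid.reason or "unmeasurable"]
        rows.append(",".join(fields))
    try:
        with open(path, "w", newline="\n") as fh:
            fh.write(RESULT_HEADER)
            fh.write("\n".join(rows) + ("\n" if rows else ""))
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path):
    """Read a results file written by :func:`write_results` as a DataFrame."""
    return pd.read_csv(path, comment="#")
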