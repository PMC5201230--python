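"""Minimal WFDB header + format-16 signal file support.

Covers exactly what this package needs: multi-lead records written by the
fixture generator and read back for delineation. Only format 16 (16-bit
little-endian two's complement, sample-interleaved), a single .dat file per
record, gain/baseline per signal, and physical units of microvolts or
millivolts are supported. Checksums are written and verified.
"""

from __future__ import annotations

import os

import numpy as np

from .errors import FormatError, UnsupportedInputError

__all__ = ["read_record", "write_record"]

# ADC units per microvolt; 0.4 adu/uV == 2.5 uV amplitude resolution.
DEFAULT_GAIN_PER_UV = 0.4


def write_record(path_base, samples_uv, fs, lead_names, gain_per_uv=DEFAULT_GAIN_PER_UV):
    """Write ``samples_uv`` (n_leads x n_samples, microvolts) as <base>.hea/.dat.

    Amplitudes are quantized to ``1/gain_per_uv`` microvolt steps; the default
    gain of 0.4 adu/uV gives the 2.5 uV resolution of clinical digitizers.
    """
    samples_uv = np.asarray(samples_uv, dtype=float)
    if samples_uv.ndim != 2 or samples_uv.shape[0] != len(lead_names):
        raise FormatError("samples must be (n_leads, n_samples) matching lead_names")
    record = os.path.basename(path_base)
    n_sig, n_samp = samples_uv.shape
    adc = np.rint(samples_uv * gain_per_uv)
    if np.any(np.abs(adc) > 32767):
        raise UnsupportedInputError("amplitude exceeds 16-bit range at this gain")
    adc = adc.astype("<i2")
    checksums = (adc.astype(np.int64).sum(axis=1) & 0xFFFF).astype(np.int64)
    # stored as signed 16-bit in the header
    checksums = np.where(checksums > 32767, checksums - 65536, checksums)

    lines = [f"{record} {n_sig} {fs:g} {n_samp}"]
    for i, name in enumerate(lead_names):
        lines.append(
            f"{record}.dat 16 {gain_per_uv * 1000:g}(0)/mV 16 0 "
            f"{int(adc[i, 0])} {int(checksums[i])} 0 {name}"
        )
    with open(path_base + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(path_base + ".dat", "wb") as fh:
        fh.write(adc.T.tobytes())  # sample-interleaved


def read_record(path_base):
    """Read <base>.hea/.dat; returns (samples_uv, fs, lead_names)."""
    if path_base.endswith(".hea"):
        path_base = path_base[:-4]
    try:
        with open(path_base + ".hea") as fh:
            lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    except OSError as exc:
        raise FormatError(f"cannot read header: {exc}") from exc
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError("header line must be 'record n_sig fs n_samples'")
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    if len(lines) - 1 < n_sig:
        raise FormatError("header lists fewer signal lines than n_sig")

    lead_names, gains, checks = [], [], []
    for ln in lines[1 : n_sig + 1]:
        parts = ln.split()
        if parts[1] != "16":
            raise UnsupportedInputError("only WFDB format 16 is supported")
        gain_field = parts[2]
        units = "mV"
        if "/" in gain_field:
            gain_field, units = gain_field.split("/")
        gain = float(gain_field.split("(")[0])
        if units == "mV":
            gain_per_uv = gain / 1000.0
        elif units == "uV":
            gain_per_uv = gain
        else:
            raise UnsupportedInputError(f"unsupported units {units!r}")
        gains.append(gain_per_uv)
        # fields: file fmt gain adcres adczero initval checksum blocksize name
        checks.append(int(parts[6]) if len(parts) > 8 else None)
        lead_names.append(parts[-1])

    raw = np.fromfile(path_base + ".dat", dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise FormatError("dat file size does not match header dimensions")
    adc = raw.reshape(n_samp, n_sig).T
    for i, chk in enumerate(checks):
        if chk is not None:
            got = int(adc[i].astype(np.int64).sum() & 0xFFFF)
            got = got - 65536 if got > 32767 else got
            if got != chk:
                raise FormatError(f"checksum mismatch on signal {lead_names[i]}")
    samples_uv = adc.astype(float) / np.asarray(gains)[:, None]
    return samples_uv, fs, lead_names
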