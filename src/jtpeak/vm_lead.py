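"""Vector magnitude lead via a linear orthogonal-lead (XYZ) transform.

The vector magnitude lead is the Euclidean norm of the orthogonal X, Y, Z
leads reconstructed from the 8 independent leads of the 12-lead ECG by a
fixed 3x8 coefficient matrix. The bundled default is the Kors regression
matrix; any alternative matrix (e.g. a Guldenring variant) can be supplied as
a plain-text 3x8 table or array.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ConfigError
from .ecg_io import INDEPENDENT_LEADS

#: column order of the transform matrix
TRANSFORM_LEAD_ORDER = INDEPENDENT_LEADS


@dataclass
class XyzBeat:
    """Orthogonal-lead median beat at 1 kHz (uV)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    alignment_ms: float
    median_rr_ms: float

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ConfigError("x, y, z must have equal length")


@dataclass
class VmBeat:
    """Vector-magnitude median beat at 1 kHz (uV, nonnegative)."""

    vm: np.ndarray
    alignment_ms: float
    median_rr_ms: float

    def __post_init__(self):
        self.vm = np.asarray(self.vm, dtype=float)

    @property
    def n_ms(self):
        return len(self.vm)


def load_transform_matrix(path=None):
    """Load a 3x8 transform matrix from a plain-text table.

    With no ``path`` the bundled default (Kors) matrix is returned.
    """
    if path is None:
        ref = resources.files("jtpeak.data") / "orthogonal_transform.txt"
        with resources.as_file(ref) as p:
            matrix = np.loadtxt(p, comments="#")
    else:
        matrix = np.loadtxt(path, comments="#")
    if matrix.shape != (3, 8):
        raise ConfigError(f"transform matrix must be 3x8, got {matrix.shape}")
    return matrix


def transform_xyz(beat, coefficients=None):
    """Apply the 3x8 orthogonal-lead transform to a median beat.

    ``coefficients`` columns follow :data:`TRANSFORM_LEAD_ORDER`
    (I, II, V1-V6); defaults to the bundled matrix.
    """
    if coefficients is None:
        coefficients = load_transform_matrix()
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (3, 8):
        raise ConfigError(f"transform matrix must be 3x8, got {coefficients.shape}")
    leads = np.stack([beat.lead(ld) for ld in TRANSFORM_LEAD_ORDER])
    xyz = coefficients @ leads
    return XyzBeat(xyz[0], xyz[1], xyz[2], beat.alignment_ms, beat.median_rr_ms)


def vector_magnitude(xyz):
    """Sample-wise Euclidean norm of the X, Y, Z leads."""
    vm = np.sqrt(xyz.x**2 + xyz.y**2 + xyz.z**2)
    return VmBeat(vm, xyz.alignment_ms, xyz.median_rr_ms)
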