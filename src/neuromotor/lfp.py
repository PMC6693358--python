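"""Extracellular potential forward models: point-source and line-source
volume-conductor approximations with an optional low-pass RC filter.

Potentials are computed in an infinite homogeneous isotropic medium of
conductivity σ (S/m).  Sources are per-compartment transmembrane currents
(nA); positions are μm; returned potentials are volts.

For a compartmental cell whose membrane currents sum to zero at every
instant (axial currents redistribute charge but do not create it), the
far field is dipolar and decays faster than 1/r.  Point (integrate-and-
fire) cells lack distributed currents; when included, their net input
current is emitted as a monopole — a documented approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from neuromotor.model_def import ModelError

logger = logging.getLogger(__name__)

#: minimum source–electrode distance (μm): closer sources are clamped
EPSILON_UM = 1.0

#: default extracellular conductivity (S/m), gray-matter value
DEFAULT_SIGMA = 0.3


@dataclass(frozen=True)
class LFPElectrode:
    """A recording electrode: position (μm), method, conductivity, filter."""

    position: tuple[float, float, float]
    method: str = "point_source"
    sigma: float = DEFAULT_SIGMA
    rc_cutoff_hz: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ModelError("sigma must be > 0")
        if self.method not in ("point_source", "line_source"):
            raise ModelError(f"unknown LFP method {self.method!r}")


def _clamped_distance_um(src: np.ndarray, electrode: LFPElectrode) -> float:
    r = float(np.linalg.norm(np.asarray(electrode.position) - src))
    if r < EPSILON_UM:
        logger.warning("electrode within %.1f μm of a source; distance "
                       "clamped", EPSILON_UM)
        return EPSILON_UM
    return r


def lfp_point_source(sources: Sequence[tuple[Sequence[float], np.ndarray]],
                     electrode: LFPElectrode) -> np.ndarray:
    """V(t) = 1/(4πσ) Σᵢ Iᵢ(t)/rᵢ, in volts.

    ``sources``: list of (position μm, membrane current trace nA).
    """
    if not sources:
        raise ModelError("at least one source required")
    total = None
    for pos, current in sources:
        r_m = _clamped_distance_um(np.asarray(pos, dtype=float), electrode) * 1e-6
        contrib = np.asarray(current, dtype=float) * 1e-9 / (4 * math.pi
                                                             * electrode.sigma
                                                             * r_m)
        total = contrib if total is None else total + contrib
    return total


def lfp_line_source(segments: Sequence[tuple[Sequence[float], Sequence[float],
                                             np.ndarray]],
                    electrode: LFPElectrode) -> np.ndarray:
    """Line-source approximation, summed over segments; volts.

    ``segments``: list of (endpoint_a μm, endpoint_b μm, current trace nA);
    the current is spread uniformly along each segment and the potential
    uses the analytic log-form solution of the line integral.
    """
    if not segments:
        raise ModelError("at least one segment required")
    e = np.asarray(electrode.position, dtype=float)
    total = None
    for a, b, current in segments:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        axis = b - a
        length = float(np.linalg.norm(axis))
        if length <= 0:
            raise ModelError("line-source segment must have positive length")
        u = axis / length
        rel = e - a
        h = float(np.dot(rel, u))           # axial foot, measured from a
        r = float(np.linalg.norm(rel - h * u))
        if r < EPSILON_UM and 0 <= h <= length:
            logger.warning("electrode on a line-source axis; offset by ε")
            r = EPSILON_UM
        factor = _line_factor_standard(r, h, length)
        contrib = (np.asarray(current, dtype=float) * 1e-9 * factor
                   / (4 * math.pi * electrode.sigma))
        total = contrib if total is None else total + contrib
    return total


def _line_factor_standard(r_um: float, h_um: float, length_um: float) -> float:
    """∫₀ᴸ ds / |x − s| per unit length (1/m), electrode at axial foot h,
    radial distance r from the axis (all μm in, SI out)."""
    r = max(r_um, EPSILON_UM) * 1e-6
    h = h_um * 1e-6
    L = length_um * 1e-6
    # antiderivative of 1/sqrt(r² + (s − h)²) is asinh((s − h)/r)
    integral = math.asinh((L - h) / r) - math.asinh((0.0 - h) / r)
    return integral / L


def rc_lowpass(trace: np.ndarray, dt_ms: float, cutoff_hz: float) -> np.ndarray:
    """First-order RC low-pass (linear, causal), cutoff in Hz."""
    if cutoff_hz <= 0:
        raise ModelError("cutoff must be > 0")
    fs = 1000.0 / dt_ms
    b, a = signal.butter(1, cutoff_hz, fs=fs, btype="low")
    return signal.lfilter(b, a, np.asarray(trace, dtype=float))


def compartment_membrane_currents(batch) -> list[np.ndarray]:
    """Per-compartment transmembrane currents (nA) of a motoneuron batch at
    its current state: the two compartments carry opposite axial coupling
    currents, so each cell's currents sum to zero (dipole source)."""
    i_axial = batch.g_c * (batch.v_d - batch.v_s)   # into soma, nA
    return [i_axial, -i_axial]
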