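"""Electrophysiological summaries: FI curves, rheobase, spike-rate
adaptation, orderly recruitment, FI hysteresis, and EES reflex recruitment
curves.

Conventions: instantaneous frequency is 1000/ISI (ms → Hz) assigned to the
second spike of each interval; rheobase of a ramp protocol is the injected
current at the first spike; the basal (steady-state) rate of a step
protocol is the mean instantaneous frequency over the last half of the
step.  Evoked responses to an EES pulse are classified by latency:
*early* < 3 ms (direct motoneuron recruitment), *medium* 4.5–5 ms, *late*
9–11 ms; the *medium-late* reflex response is analyzed jointly over the
bracketing 3–12 ms window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from neuromotor.cell_models import (
    CellTemplate,
    StimulusSpec,
    iclamp_value,
    make_batch,
)
from neuromotor.model_def import ModelError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Single-cell protocol runner
# ---------------------------------------------------------------------------


def run_single_cell(template: CellTemplate, stimulus: StimulusSpec,
                    duration: float, dt: float = 0.025) -> np.ndarray:
    """Run one cell under a current-clamp stimulus; returns spike times."""
    spikes = run_cells([template], [stimulus], duration, dt)[0]
    return spikes


def run_cells(templates: Sequence[CellTemplate],
              stimuli: Sequence[StimulusSpec],
              duration: float, dt: float = 0.025) -> list[np.ndarray]:
    """Vectorized current-clamp runs: one (template, stimulus) per cell."""
    if len(templates) != len(stimuli):
        raise ModelError("one stimulus per template required")
    batch = make_batch(list(templates))
    batch.settle()
    n_steps = int(round(duration / dt))
    spikes: list[list[float]] = [[] for _ in templates]
    amps = np.zeros(len(templates))
    for i in range(n_steps):
        t = i * dt
        for j, stim in enumerate(stimuli):
            amps[j] = iclamp_value(stim, t)
        st = batch.step(t, dt, amps)
        for j in np.flatnonzero(~np.isnan(st)):
            spikes[j].append(float(st[j]))
    return [np.asarray(s) for s in spikes]


def step_stimulus(amplitude: float, onset: float = 100.0,
                  end: float = 1000.0) -> StimulusSpec:
    """Step current: 0 before onset, ``amplitude`` from onset to end."""
    eps = 1e-9
    return StimulusSpec.iclamp([(0.0, 0.0), (onset - eps, 0.0),
                                (onset, amplitude), (end, amplitude)])


# ---------------------------------------------------------------------------
# Basic measures
# ---------------------------------------------------------------------------


def instantaneous_frequency(spikes: Sequence[float]) -> np.ndarray:
    """(t, Hz) pairs: each ISI's 1000/ISI at the second spike time."""
    sp = np.asarray(spikes, dtype=float)
    if sp.size < 2:
        return np.empty((0, 2))
    isi = np.diff(sp)
    return np.column_stack([sp[1:], 1000.0 / isi])


def fi_curve(template: CellTemplate, ramp: StimulusSpec,
             duration: float | None = None, dt: float = 0.025,
             ) -> tuple[np.ndarray, float | None]:
    """FI relationship under a ramp: [(I at second spike, Hz)], rheobase.

    Rheobase is the injected current at the first spike; ``None`` when the
    cell never fires.
    """
    times = [t for t, _ in ramp.breakpoints]
    if duration is None:
        duration = max(times)
    spikes = run_single_cell(template, ramp, duration, dt)
    if spikes.size == 0:
        return np.empty((0, 2)), None
    rheobase = float(iclamp_value(ramp, spikes[0]))
    inst = instantaneous_frequency(spikes)
    currents = iclamp_value(ramp, inst[:, 0]) if inst.size else np.empty(0)
    pairs = np.column_stack([currents, inst[:, 1]]) if inst.size else np.empty((0, 2))
    return pairs, rheobase


def sra_curve(template: CellTemplate, step: StimulusSpec,
              duration: float | None = None, dt: float = 0.025,
              ) -> tuple[np.ndarray, float]:
    """Spike-rate adaptation under a step: [(spike index, Hz)], basal rate.

    Basal rate = mean instantaneous frequency over the last half of the
    step.  Raises on insufficient firing (< 3 spikes).
    """
    times = [t for t, _ in step.breakpoints]
    if duration is None:
        duration = max(times)
    spikes = run_single_cell(template, step, duration, dt)
    if spikes.size < 3:
        raise ModelError("insufficient firing for spike-rate adaptation")
    inst = instantaneous_frequency(spikes)
    series = np.column_stack([np.arange(1, len(spikes)), inst[:, 1]])
    onset = next((t for t, a in step.breakpoints if a > 0), 0.0)
    mid = onset + (duration - onset) / 2
    tail = inst[inst[:, 0] >= mid, 1]
    basal = basal_rate_from_spikes(spikes, mid)
    if tail.size == 0:
        raise ModelError("insufficient firing in the last half of the step")
    return series, basal


def basal_rate_from_spikes(spikes: Sequence[float], t_from: float) -> float:
    """Mean instantaneous frequency over spikes at/after ``t_from``."""
    inst = instantaneous_frequency(spikes)
    tail = inst[inst[:, 0] >= t_from, 1]
    if tail.size == 0:
        return 0.0
    return float(np.mean(tail))


def recruitment_thresholds(templates: Sequence[CellTemplate],
                           amplitude_grid: Sequence[float],
                           duration: float = 1000.0, onset: float = 100.0,
                           dt: float = 0.025,
                           ) -> dict[str, float | None]:
    """Lowest grid amplitude at which each template fires repetitively.

    Repetitive firing = at least two spikes during a 1 s step.  Templates
    that never fire map to ``None``.  All (template × amplitude) runs are
    integrated as one vectorized batch.
    """
    grid = list(amplitude_grid)
    if grid != sorted(grid):
        raise ModelError("amplitude grid must be ascending")
    tpls, stims, owners = [], [], []
    for tpl in templates:
        for a in grid:
            tpls.append(tpl)
            stims.append(step_stimulus(a, onset, duration))
            owners.append((tpl.name, a))
    all_spikes = run_cells(tpls, stims, duration, dt)
    out: dict[str, float | None] = {t.name: None for t in templates}
    for (name, a), sp in zip(owners, all_spikes):
        if len(sp) >= 2 and out[name] is None:
            out[name] = a
    return out


# ---------------------------------------------------------------------------
# EES reflex recruitment curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatencyWindows:
    """Post-pulse latency windows (ms) for evoked-response classification."""

    early: tuple[float, float] = (0.0, 3.0)
    medium: tuple[float, float] = (4.5, 5.0)
    late: tuple[float, float] = (9.0, 11.0)
    medium_late: tuple[float, float] = (3.0, 12.0)

    def classify(self, latency: float) -> list[str]:
        out = []
        for name in ("early", "medium", "late", "medium_late"):
            lo, hi = getattr(self, name)
            if lo <= latency < hi or (latency == hi and name != "early"):
                out.append(name)
        return out


@dataclass
class RecruitmentCurve:
    """Normalized early / medium-late responses vs amplitude.

    ``amplitudes`` are in motor-threshold units; each response series is
    normalized to its own maximum; responses are zero below threshold.
    """

    amplitudes: np.ndarray
    early: np.ndarray
    medium_late: np.ndarray
    motor_threshold: float
    raw_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))

    def medium_late_at(self, mt_multiple: float) -> float:
        """Interpolated normalized medium-late response at a multiple of
        motor threshold."""
        return float(np.interp(mt_multiple, self.amplitudes, self.medium_late))


#: responses smaller than this peak-to-peak deflection (mV) of the
#: group-averaged soma potential are treated as absent
RESPONSE_FLOOR_MV = 0.05


def window_response(time: np.ndarray, mean_trace: np.ndarray,
                    pulse_times: Sequence[float],
                    window: tuple[float, float]) -> float:
    """Peak-to-peak deflection inside ``window`` after each pulse, averaged
    over pulses; deflections below the noise floor count as zero."""
    if len(pulse_times) == 0:
        raise ModelError("no stimulation pulse delivered")
    vals = []
    for p in pulse_times:
        lo, hi = p + window[0], p + window[1]
        sel = (time >= lo) & (time <= hi)
        if not sel.any():
            continue
        seg = mean_trace[sel]
        p2p = float(seg.max() - seg.min())
        vals.append(p2p if p2p >= RESPONSE_FLOOR_MV else 0.0)
    if not vals:
        raise ModelError("latency window outside the recorded trace")
    return float(np.mean(vals))


def reflex_recruitment_curve(
    responses_per_amplitude: Sequence[tuple[float, np.ndarray, np.ndarray]],
    pulse_times: Sequence[float],
    windows: LatencyWindows | None = None,
) -> RecruitmentCurve:
    """Build the spinal reflex recruitment curve from an amplitude sweep.

    ``responses_per_amplitude``: list of (amplitude, time array,
    group-averaged motoneuron soma trace).  The early and medium-late
    response magnitudes are the windowed peak-to-peak deflections after
    each pulse; each series is normalized to its own maximum; the motor
    threshold is the lowest amplitude with a nonzero early response, and
    the amplitude axis is re-expressed in motor-threshold units.
    """
    windows = windows or LatencyWindows()
    amps, early, ml = [], [], []
    for amplitude, time, trace in sorted(responses_per_amplitude,
                                         key=lambda r: r[0]):
        amps.append(float(amplitude))
        early.append(window_response(time, trace, pulse_times, windows.early))
        ml.append(window_response(time, trace, pulse_times, windows.medium_late))
    amps_arr = np.asarray(amps)
    early_arr = np.asarray(early)
    ml_arr = np.asarray(ml)
    nonzero = np.flatnonzero(early_arr > 0)
    if nonzero.size == 0:
        raise ModelError("no early response at any amplitude; "
                         "motor threshold undefined")
    motor_threshold = float(amps_arr[nonzero[0]])
    if early_arr.max() > 0:
        early_arr = early_arr / early_arr.max()
    if ml_arr.max() > 0:
        ml_arr = ml_arr / ml_arr.max()
    return RecruitmentCurve(
        amplitudes=amps_arr / motor_threshold,
        early=early_arr,
        medium_late=ml_arr,
        motor_threshold=motor_threshold,
        raw_amplitudes=amps_arr,
    )


# ---------------------------------------------------------------------------
# FI hysteresis
# ---------------------------------------------------------------------------


def hysteresis_metric(ascending: np.ndarray, descending: np.ndarray,
                      n_grid: int = 50) -> tuple[tuple[float, float], float, str]:
    """Compare FI pairs from the two limbs of a triangular ramp.

    Returns ``((I_lo, I_hi), mean Δf, direction)`` where Δf = descending −
    ascending interpolated on the common current support and direction is
    ``"counterclockwise"`` when mean Δf > 0 (plateau-driven facilitation)
    else ``"clockwise"``.  Raises when the supports are disjoint.
    """
    asc = np.asarray(ascending, dtype=float)
    dsc = np.asarray(descending, dtype=float)
    if asc.size == 0 or dsc.size == 0:
        raise ModelError("both FI branches must be nonempty")
    lo = max(asc[:, 0].min(), dsc[:, 0].min())
    hi = min(asc[:, 0].max(), dsc[:, 0].max())
    if hi <= lo:
        raise ModelError("ascending/descending current supports are disjoint")
    grid = np.linspace(lo, hi, n_grid)
    ia = np.argsort(asc[:, 0])
    idx = np.argsort(dsc[:, 0])
    fa = np.interp(grid, asc[ia, 0], asc[ia, 1])
    fd = np.interp(grid, dsc[idx, 0], dsc[idx, 1])
    delta = float(np.mean(fd - fa))
    direction = "counterclockwise" if delta > 0 else "clockwise"
    return (float(lo), float(hi)), delta, direction


def triangular_ramp_fi(template: CellTemplate, i_peak: float = 12.0,
                       t_ramp: float = 2000.0, dt: float = 0.025,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Ascending and descending FI pairs under a symmetric triangular ramp."""
    ramp = StimulusSpec.iclamp([(0.0, 0.0), (t_ramp, i_peak),
                                (2 * t_ramp, 0.0)])
    spikes = run_single_cell(template, ramp, 2 * t_ramp, dt)
    inst = instantaneous_frequency(spikes)
    asc, dsc = [], []
    for t, f in inst:
        pair = (float(iclamp_value(ramp, t)), float(f))
        (asc if t < t_ramp else dsc).append(pair)
    return np.asarray(asc).reshape(-1, 2), np.asarray(dsc).reshape(-1, 2)
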