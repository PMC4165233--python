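"""Measurement protocols: input resistance, normalized current step, spike
detection, and firing-pattern classification.

A model cell's input resistance is measured from the steady-state voltage
deflection under a 500 ms, 0.1 nA hyperpolarizing somatic pulse. The
excitatory step for the firing assay is scaled by the ratio of the cell's
input resistance to that of a fixed control cell, times the 0.35 nA at
which the control cell first spikes:

    as-worded (default):  I = 0.35 nA * Rin_cell / Rin_control
    equal-dv:             I = 0.35 nA * Rin_control / Rin_cell

The two conventions differ in which cells receive more current. Under
``equal-dv`` the steady somatic depolarization ``I * Rin`` is identical for
every cell; under ``as-worded`` low-input-resistance (electrically large)
cells receive proportionally less current. The ``as-worded`` form is the
default here: it reproduces the characteristic dependence of the firing
dichotomy on dendritic load (large cells regular-spiking, small ones
bursting), including its reversal when a compact apical tree replaces an
extensive one. Both are exposed via ``normalization=``.

Firing categories follow the first-interspike-interval rule: a cell is
intrinsic-bursting (IB) if the interval between its first two spikes is
strictly smaller than 20 ms, regular-spiking (RS) otherwise, and quiescent
(Q) with fewer than two spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import (
    CompartmentGraph,
    VoltageTrace,
    run,
    step_protocol,
)

__all__ = [
    "FiringLabel",
    "SteadyStateError",
    "measure_input_resistance",
    "normalized_step",
    "detect_spikes",
    "classify_firing",
    "firing_assay",
    "ISI_THRESHOLD_MS",
    "STEP_FACTOR_NA",
]

ISI_THRESHOLD_MS = 20.0
STEP_FACTOR_NA = 0.35


class SteadyStateError(RuntimeError):
    """The voltage had not converged at the end of the measurement pulse."""


@dataclass(frozen=True)
class FiringLabel:
    """Outcome of the firing assay for one model cell.

    ``category`` is ``"RS"``, ``"IB"`` or ``"Q"``; ``first_isi`` is ``None``
    for quiescent cells (fewer than two spikes).
    """

    category: str
    spike_times: tuple[float, ...]
    first_isi: float | None
    rin: float | None = None  # MOhm
    injected_current: float | None = None  # nA

    def as_dict(self) -> dict:
        return {
            "category": self.category,
            "spike_times_ms": list(self.spike_times),
            "first_isi_ms": self.first_isi,
            "rin_mohm": self.rin,
            "injected_na": self.injected_current,
        }


def measure_input_resistance(
    graph: CompartmentGraph,
    amplitude_na: float = -0.1,
    dur_ms: float = 500.0,
    dt: float = 0.05,
    settle_ms: float = 200.0,
    dvdt_tol: float = 5e-3,
) -> float:
    """Input resistance (MOhm) from a hyperpolarizing somatic pulse.

    The deflection is read at the end of the pulse relative to the
    pre-pulse baseline; ``|dV/dt|`` at pulse end must be below ``dvdt_tol``
    mV/ms or a :class:`SteadyStateError` is raised.
    """
    if amplitude_na == 0:
        raise ValueError("pulse amplitude must be non-zero")
    t_on = 20.0
    tr = run(
        graph,
        step_protocol(amplitude_na, t_on_ms=t_on, dur_ms=dur_ms, tail_ms=10.0),
        dt=dt,
        settle_ms=settle_ms,
    )
    i_on = np.searchsorted(tr.t, t_on) - 1
    i_off = np.searchsorted(tr.t, t_on + dur_ms) - 1
    dvdt = abs(tr.v[i_off] - tr.v[i_off - 4]) / (4 * dt)
    if dvdt > dvdt_tol:
        raise SteadyStateError(
            f"|dV/dt| = {dvdt:.4f} mV/ms at pulse end exceeds {dvdt_tol}"
        )
    rin = abs(tr.v[i_off] - tr.v[i_on]) / abs(amplitude_na)
    return float(rin)


def normalized_step(
    rin_cell: float,
    rin_control: float,
    factor_na: float = STEP_FACTOR_NA,
    normalization: str = "as-worded",
) -> float:
    """Step amplitude (nA) for a cell, normalized to the control cell."""
    if rin_cell <= 0 or rin_control <= 0:
        raise ValueError("input resistances must be positive")
    if normalization == "as-worded":
        return factor_na * rin_cell / rin_control
    if normalization == "equal-dv":
        return factor_na * rin_control / rin_cell
    raise ValueError(
        f"normalization must be 'as-worded' or 'equal-dv', "
        f"got {normalization!r}"
    )


def detect_spikes(
    trace: VoltageTrace,
    threshold: float = 0.0,
    refractory_ms: float = 2.0,
) -> tuple[float, ...]:
    """Spike times (ms) as upward threshold crossings.

    Crossing times are linearly interpolated; crossings closer than
    ``refractory_ms`` to the previous accepted spike are ignored. A plateau
    above threshold yields a single spike (no re-trigger without a
    re-crossing from below).
    """
    t, v = trace.t, trace.v
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    out: list[float] = []
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        ts = t[i] + frac * (t[i + 1] - t[i])
        if not out or ts - out[-1] >= refractory_ms:
            out.append(float(ts))
    return tuple(out)


def classify_firing(
    spike_times,
    isi_threshold_ms: float = ISI_THRESHOLD_MS,
    rin: float | None = None,
    injected_current: float | None = None,
) -> FiringLabel:
    """Label a spike train RS / IB / Q by its first interspike interval.

    IB requires the first ISI to be *strictly* below the threshold; an ISI
    of exactly 20 ms is RS. Fewer than two spikes (including exactly one)
    is quiescent, since the ISI rule is undefined there.
    """
    st = tuple(float(s) for s in spike_times)
    if any(b < a for a, b in zip(st[:-1], st[1:])):
        raise ValueError("spike times must be sorted")
    if len(st) < 2:
        return FiringLabel("Q", st, None, rin, injected_current)
    isi = st[1] - st[0]
    cat = "IB" if isi < isi_threshold_ms else "RS"
    return FiringLabel(cat, st, isi, rin, injected_current)


def firing_assay(
    graph: CompartmentGraph,
    rin_control: float,
    dt: float = 0.025,
    stim_dur_ms: float = 1000.0,
    settle_ms: float = 200.0,
    normalization: str = "as-worded",
    isi_threshold_ms: float = ISI_THRESHOLD_MS,
    threshold_mv: float = 0.0,
) -> FiringLabel:
    """The full per-cell protocol: Rin, normalized step, classification."""
    rin = measure_input_resistance(graph, settle_ms=settle_ms)
    amp = normalized_step(rin, rin_control, normalization=normalization)
    tr = run(
        graph,
        step_protocol(amp, t_on_ms=20.0, dur_ms=stim_dur_ms, tail_ms=20.0),
        dt=dt,
        settle_ms=settle_ms,
    )
    spikes = detect_spikes(tr, threshold=threshold_mv)
    return classify_firing(
        spikes, isi_threshold_ms=isi_threshold_ms,
        rin=rin, injected_current=amp,
    )
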