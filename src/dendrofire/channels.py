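"""Hodgkin-Huxley-style ion-channel kinetics for the pyramidal-cell model.

The channel roster covers the currents of a layer V PFC pyramidal cell:
transient and persistent Na+ (Naf, Nap), delayed-rectifier / A-type / D-type
K+ (Kdr, KA, KD), fast and slow Ca2+-activated K+ (fAHP, sAHP), the
hyperpolarization-activated cation current (h), and low- and high-voltage
activated Ca2+ currents (CaT, CaN, CaR, CaL).

Each gate follows first-order kinetics ``ds/dt = (s_inf - s) / tau`` with one
of three steady-state forms:

* voltage Boltzmann, ``s_inf = 1 / (1 + exp((vh - V)/k))`` (negative ``k``
  makes an inactivation gate) with an optionally bell-shaped
  ``tau(V) = tau_min + tau_amp / (exp((V-vb)/ks1) + exp(-(V-vb)/ks2))``;
* calcium Hill, ``s_inf = ca^n / (ca^n + kd^n)`` at constant tau (sAHP);
* voltage x calcium product (BK-like fAHP).

The kinetic constants here are standard textbook formulations, not a
reproduction of any published parameter table; conductance densities live in
:mod:`dendrofire.biophysics` and are the tunable layer. Calcium currents
share a single intracellular pool per compartment with first-order decay,
and their reversal is computed by the Nernst relation at each step.

Gates are also exported as packed numeric tables for the compiled
integrator: see :func:`pack_kinetics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GateSpec",
    "ChannelKinetics",
    "CHANNEL_NAMES",
    "default_kinetics",
    "pack_kinetics",
    "GATE_VOLTAGE",
    "GATE_CA_HILL",
    "GATE_V_CA",
]

GATE_VOLTAGE = 0
GATE_CA_HILL = 1
GATE_V_CA = 2

_NPARAMS = 8


@dataclass(frozen=True)
class GateSpec:
    """One activation or inactivation gate raised to an integer power."""

    kind: int
    power: int
    params: tuple[float, ...]  # layout depends on kind; see pack_kinetics

    @staticmethod
    def voltage(vh, k, tau_min, tau_amp=0.0, vb=0.0, ks1=1.0, ks2=1.0,
                power=1) -> "GateSpec":
        return GateSpec(GATE_VOLTAGE, power,
                        (vh, k, tau_min, tau_amp, vb, ks1, ks2, 0.0))

    @staticmethod
    def ca_hill(kd_um, n, tau, power=1) -> "GateSpec":
        return GateSpec(GATE_CA_HILL, power,
                        (kd_um, n, tau, 0.0, 0.0, 0.0, 0.0, 0.0))

    @staticmethod
    def v_ca(vh, k, kd_um, tau, power=1) -> "GateSpec":
        return GateSpec(GATE_V_CA, power,
                        (vh, k, kd_um, tau, 0.0, 0.0, 0.0, 0.0))


@dataclass(frozen=True)
class ChannelKinetics:
    """Kinetic definition of one current.

    ``erev`` is the fixed reversal potential in mV, or ``None`` for calcium
    channels whose reversal is Nernst-computed from the instantaneous
    intracellular concentration. ``is_ca`` marks currents that feed the
    calcium pool.
    """

    name: str
    gates: tuple[GateSpec, ...]
    erev: float | None
    is_ca: bool = False


def default_kinetics() -> dict[str, ChannelKinetics]:
    """The shipped kinetics roster, keyed by channel name."""
    g = GateSpec
    return {
        "Naf": ChannelKinetics(
            "Naf",
            (
                g.voltage(-35.0, 6.5, 0.08, power=3),
                g.voltage(-48.0, -6.5, 0.4, tau_amp=6.0, vb=-60.0,
                          ks1=15.0, ks2=15.0),
            ),
            erev=55.0,
        ),
        "Nap": ChannelKinetics(
            "Nap", (g.voltage(-48.0, 5.0, 1.0),), erev=55.0
        ),
        "Kdr": ChannelKinetics(
            "Kdr",
            (g.voltage(-20.0, 9.0, 0.8, tau_amp=4.0, vb=-40.0,
                       ks1=20.0, ks2=20.0, power=2),),
            erev=-80.0,
        ),
        "KA": ChannelKinetics(
            "KA",
            (
                g.voltage(-35.0, 10.0, 0.25),
                g.voltage(-75.0, -6.0, 15.0),
            ),
            erev=-80.0,
        ),
        # D-type slow K+: high activation threshold and slow deactivation,
        # so each (back-propagated) spike leaves a decaying K+ tail that
        # paces the early interspike intervals.
        "KD": ChannelKinetics(
            "KD", (g.voltage(-30.0, 6.0, 20.0),), erev=-80.0
        ),
        "fAHP": ChannelKinetics(
            "fAHP", (g.v_ca(-10.0, 12.0, 0.8, 2.0),), erev=-80.0
        ),
        "sAHP": ChannelKinetics(
            "sAHP", (g.ca_hill(0.5, 2.0, 80.0),), erev=-80.0
        ),
        "h": ChannelKinetics(
            "h", (g.voltage(-82.0, -9.0, 50.0),), erev=-30.0
        ),
        "CaT": ChannelKinetics(
            "CaT",
            (
                g.voltage(-40.0, 5.5, 2.0, power=2),
                g.voltage(-70.0, -5.5, 25.0),
            ),
            erev=None,
            is_ca=True,
        ),
        "CaN": ChannelKinetics(
            "CaN",
            (
                g.voltage(-20.0, 7.0, 1.5, power=2),
                g.voltage(-50.0, -10.0, 80.0),
            ),
            erev=None,
            is_ca=True,
        ),
        "CaR": ChannelKinetics(
            "CaR",
            (
                g.voltage(-15.0, 8.0, 1.0, power=2),
                g.voltage(-55.0, -9.0, 50.0),
            ),
            erev=None,
            is_ca=True,
        ),
        "CaL": ChannelKinetics(
            "CaL", (g.voltage(-15.0, 6.0, 1.5, power=2),), erev=None,
            is_ca=True
        ),
    }


CHANNEL_NAMES = tuple(default_kinetics().keys())


@dataclass(frozen=True)
class PackedKinetics:
    """Flat numeric tables for the compiled integrator."""

    names: tuple[str, ...]
    erev: np.ndarray  # (C,) fixed reversal; NaN for Nernst-Ca channels
    is_ca: np.ndarray  # (C,) uint8
    gate_chan: np.ndarray  # (G,) channel index of each gate row
    gate_kind: np.ndarray  # (G,)
    gate_power: np.ndarray  # (G,)
    gate_params: np.ndarray = field(default=None)  # (G, 8)


def pack_kinetics(kinetics: dict[str, ChannelKinetics]) -> PackedKinetics:
    names = tuple(kinetics.keys())
    erev = np.array(
        [np.nan if kinetics[n].erev is None else kinetics[n].erev
         for n in names]
    )
    is_ca = np.array([kinetics[n].is_ca for n in names], dtype=np.uint8)
    gc, gk, gp, prm = [], [], [], []
    for ci, n in enumerate(names):
        for gate in kinetics[n].gates:
            gc.append(ci)
            gk.append(gate.kind)
            gp.append(gate.power)
            prm.append(gate.params)
    return PackedKinetics(
        names=names,
        erev=erev,
        is_ca=is_ca,
        gate_chan=np.array(gc, dtype=np.int64),
        gate_kind=np.array(gk, dtype=np.int64),
        gate_power=np.array(gp, dtype=np.int64),
        gate_params=np.array(prm, dtype=np.float64),
    )
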