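"""Cell assembly: passive profiles and channel conductance distributions.

The passive membrane follows the layer V PFC pyramidal-cell convention:
membrane resistance is 30 kOhm cm^2 in soma and axon and decreases
sigmoidally with path distance ``x`` (um) from the soma toward half the
somatic value in the dendrites,

    basal:  Rm(x) = 30 - 15 / (1 + exp((10  - x) / 5))
    apical: Rm(x) = 30 - 15 / (1 + exp((300 - x) / 50))

with axial resistivity 210 Ohm cm, specific capacitance 1.2 uF cm^-2 and a
resting potential of -66 mV throughout.

Active channel densities are assigned per region through
:class:`DistributionRule` objects (uniform, sigmoidal in ``x``, linear in
``x``, or stepped). The shipped defaults respect the qualitative ordering
constraints of the cell class — Naf highest in the axon, then soma >= apical
> basal; every K+ current weaker in the apical tree than at the soma; AHP
currents somatic and reduced apically; the h conductance rising sigmoidally
along the apical tree to ten times its somatic density with no such rise in
basal dendrites — and :func:`build_cell_spec` re-validates them for any
user-supplied configuration.

Basal dendrites come in two modes: ``uniform`` (densities independent of
``x``) and ``nonuniform`` (a linear distance-dependent scaling of the basal
Na+/K+ densities). The two modes differ only in basal compartments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import CHANNEL_NAMES, ChannelKinetics, default_kinetics
from .morphology import APICAL, AXON, BASAL, SOMA, Morphology

__all__ = [
    "PassiveProfile",
    "DistributionRule",
    "CellSpec",
    "ConfigError",
    "rm_at",
    "build_cell_spec",
    "default_channel_config",
    "load_channel_config",
    "dump_channel_config",
    "REGION_NAMES",
]

REGION_NAMES = {SOMA: "soma", AXON: "axon", BASAL: "basal", APICAL: "apical"}


class ConfigError(ValueError):
    """A channel configuration violates a structural or ordering constraint."""


@dataclass(frozen=True)
class PassiveProfile:
    """Passive membrane parameters.

    Units: ``rm_*`` kOhm cm^2, ``ra`` Ohm cm, ``cm`` uF cm^-2, ``v_rest`` mV.
    """

    rm_soma_axon: float = 30.0
    rm_drop: float = 15.0  # dendritic asymptotic drop (half the somatic Rm)
    basal_xhalf: float = 10.0
    basal_slope: float = 5.0
    apical_xhalf: float = 300.0
    apical_slope: float = 50.0
    ra: float = 210.0
    cm: float = 1.2
    v_rest: float = -66.0


def rm_at(profile: PassiveProfile, region: int, x: float) -> float:
    """Membrane resistance (kOhm cm^2) at path distance ``x`` um from soma.

    Soma and axon are uniform; basal and apical dendrites decrease
    sigmoidally toward half the somatic value.
    """
    if x < 0:
        raise ValueError(f"path distance must be >= 0, got {x}")
    p = profile
    if region in (SOMA, AXON):
        return p.rm_soma_axon
    if region == BASAL:
        return p.rm_soma_axon - p.rm_drop / (
            1.0 + np.exp((p.basal_xhalf - x) / p.basal_slope)
        )
    if region == APICAL:
        return p.rm_soma_axon - p.rm_drop / (
            1.0 + np.exp((p.apical_xhalf - x) / p.apical_slope)
        )
    raise ValueError(f"unknown region code {region}")


@dataclass(frozen=True)
class DistributionRule:
    """Conductance density (S cm^-2) as a function of path distance x (um).

    shapes
    ------
    uniform
        ``g0`` everywhere.
    sigmoidal
        ``g0 + (gmax - g0) / (1 + exp((xhalf - x) / slope))`` — rises from
        ``g0`` to the ``gmax`` asymptote.
    linear
        ``g0 * clip(1 + slope * x, floor, ceil)``.
    stepped
        ``g0`` for ``x < xstep`` else ``g1``.
    """

    shape: str = "uniform"
    g0: float = 0.0
    gmax: float = 0.0
    xhalf: float = 0.0
    slope: float = 0.0
    floor: float = 0.0
    ceil: float = np.inf
    xstep: float = 0.0
    g1: float = 0.0

    def density(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.shape == "uniform":
            out = np.full_like(x, self.g0)
        elif self.shape == "sigmoidal":
            out = self.g0 + (self.gmax - self.g0) / (
                1.0 + np.exp((self.xhalf - x) / self.slope)
            )
        elif self.shape == "linear":
            out = self.g0 * np.clip(1.0 + self.slope * x, self.floor,
                                    self.ceil)
        elif self.shape == "stepped":
            out = np.where(x < self.xstep, self.g0, self.g1)
        else:
            raise ConfigError(f"unknown distribution shape {self.shape!r}")
        if np.any(out < 0):
            raise ConfigError("distribution rule produced a negative density")
        return out

    def reference(self) -> float:
        """Density at the region's proximal end (x = 0)."""
        return float(self.density(0.0))

    def asymptote(self) -> float:
        if self.shape == "uniform":
            return self.g0
        if self.shape == "sigmoidal":
            return self.gmax
        if self.shape == "stepped":
            return self.g1
        return float(self.density(1e6))

    def to_dict(self) -> dict:
        d = {"shape": self.shape, "g0": self.g0}
        for k in ("gmax", "xhalf", "slope", "floor", "ceil", "xstep", "g1"):
            v = getattr(self, k)
            if v not in (0.0, np.inf):
                d[k] = v
        return d

    @staticmethod
    def from_dict(d: dict) -> "DistributionRule":
        return DistributionRule(**d)


# channel config: {channel_name: {region_name: DistributionRule}}
ChannelConfig = dict


def default_channel_config() -> ChannelConfig:
    """The shipped conductance-density configuration (S cm^-2).

    Densities were tuned so that the reduced reference cell fires
    repetitively under the normalized somatic step, with a burst-generating
    somatic after-depolarization (persistent Na+ plus low-threshold Ca2+)
    that a large basal load dampens — small basal trees burst, large ones
    spike regularly.
    """
    u = lambda g: DistributionRule("uniform", g0=g)  # noqa: E731
    cfg = {
        "Naf": {
            "soma": u(0.100), "axon": u(0.15),
            "basal": u(0.010), "apical": u(0.020),
        },
        "Nap": {
            "soma": u(5e-4), "axon": u(0.0),
            "basal": u(0.0), "apical": u(0.0),
        },
        "Kdr": {
            "soma": u(0.030), "axon": u(0.030),
            "basal": u(0.004), "apical": u(0.010),
        },
        "KA": {
            "soma": u(3.5e-3), "axon": u(0.0),
            "basal": u(0.002), "apical": u(1.75e-3),
        },
        "KD": {
            "soma": u(5e-3), "axon": u(0.0),
            "basal": u(2.5e-3), "apical": u(1e-3),
        },
        "fAHP": {
            "soma": u(2e-3), "axon": u(0.0),
            "basal": u(0.0), "apical": u(3e-4),
        },
        "sAHP": {
            "soma": u(1e-3), "axon": u(0.0),
            "basal": u(0.0), "apical": u(2e-4),
        },
        "h": {
            "soma": u(5e-5), "axon": u(0.0),
            "basal": u(5e-5),
            "apical": DistributionRule(
                "sigmoidal", g0=5e-5, gmax=5e-4, xhalf=300.0, slope=50.0
            ),
        },
        "CaT": {
            "soma": u(1e-3), "axon": u(0.0),
            "basal": u(0.0), "apical": u(0.0),
        },
        "CaN": {
            "soma": u(5e-4), "axon": u(0.0),
            "basal": u(0.0), "apical": u(2e-4),
        },
        "CaR": {
            "soma": u(3e-4), "axon": u(0.0),
            "basal": u(0.0), "apical": u(1e-4),
        },
        "CaL": {
            "soma": u(3e-4), "axon": u(0.0),
            "basal": u(0.0), "apical": u(1e-4),
        },
    }
    return cfg


# channels whose basal densities acquire the distance-dependent scaling in
# non-uniform mode (the Na+ and K+ currents present in basal dendrites)
_NONUNIFORM_SCALED = ("Naf", "Nap", "Kdr", "KA", "KD")
_NONUNIFORM_SLOPE = -0.002  # per um; halves the density by 250 um
_NONUNIFORM_FLOOR = 0.5


def _apply_basal_mode(cfg: ChannelConfig, basal_mode: str) -> ChannelConfig:
    if basal_mode == "uniform":
        return cfg
    if basal_mode != "nonuniform":
        raise ConfigError(
            f"basal_mode must be 'uniform' or 'nonuniform', got {basal_mode!r}"
        )
    out = {}
    for name, regions in cfg.items():
        regions = dict(regions)
        rule = regions.get("basal")
        if name in _NONUNIFORM_SCALED and rule is not None \
                and rule.shape == "uniform" and rule.g0 > 0:
            regions["basal"] = DistributionRule(
                "linear", g0=rule.g0, slope=_NONUNIFORM_SLOPE,
                floor=_NONUNIFORM_FLOOR, ceil=1.0,
            )
        out[name] = regions
    return out


@dataclass(frozen=True)
class CellSpec:
    """A morphology with its passive profile and channel distributions."""

    morphology: Morphology
    passive: PassiveProfile
    channel_config: ChannelConfig
    kinetics: dict = field(default_factory=default_kinetics)
    basal_mode: str = "uniform"
    # calcium pool parameters
    ca0_um: float = 0.05  # resting intracellular Ca2+, uM
    ca_out_mm: float = 2.0  # extracellular Ca2+, mM
    ca_tau_ms: float = 20.0  # pool decay time constant
    ca_shell_um: float = 0.2  # submembrane shell depth

    def density(self, channel: str, region: int, x) -> np.ndarray:
        rule = self.channel_config.get(channel, {}).get(REGION_NAMES[region])
        if rule is None:
            return np.zeros_like(np.asarray(x, dtype=float))
        return rule.density(x)


def _check_orderings(cfg: ChannelConfig) -> None:
    def ref(name, region):
        rule = cfg.get(name, {}).get(region)
        return 0.0 if rule is None else rule.reference()

    checks = [
        (ref("Naf", "axon") > ref("Naf", "soma"),
         "g_Naf(axon) > g_Naf(soma)"),
        (ref("Naf", "soma") >= ref("Naf", "apical"),
         "g_Naf(soma) >= g_Naf(apical)"),
        (ref("Naf", "apical") > ref("Naf", "basal"),
         "g_Naf(apical) > g_Naf(basal)"),
    ]
    for k in ("Kdr", "KA", "KD"):
        checks.append(
            (ref(k, "apical") < ref(k, "soma") or ref(k, "soma") == 0.0,
             f"g_{k}(apical) < g_{k}(soma)")
        )
    for k in ("fAHP", "sAHP"):
        checks.append((ref(k, "soma") > 0.0, f"g_{k}(soma) > 0"))
        checks.append(
            (ref(k, "apical") < ref(k, "soma"),
             f"g_{k}(apical) < g_{k}(soma)")
        )
    # h-current: apical rise to ~10x the somatic density, no basal rise
    h_soma = ref("h", "soma")
    h_ap = cfg.get("h", {}).get("apical")
    h_ba = cfg.get("h", {}).get("basal")
    if h_soma > 0 and h_ap is not None:
        checks.append(
            (np.isclose(h_ap.asymptote(), 10.0 * h_soma, rtol=0.05),
             "g_h(apical) asymptote = 10 * g_h(soma)")
        )
        xs = np.linspace(0.0, 1500.0, 64)
        dens = h_ap.density(xs)
        checks.append(
            (bool(np.all(np.diff(dens) >= -1e-15)),
             "g_h(apical, x) non-decreasing")
        )
    if h_ba is not None:
        checks.append(
            (h_ba.asymptote() <= h_soma * 1.0 + 1e-12,
             "g_h(basal) shows no distance-dependent increase")
        )
    for ok, label in checks:
        if not ok:
            raise ConfigError(f"channel ordering constraint violated: {label}")


def build_cell_spec(
    m: Morphology,
    basal_mode: str = "uniform",
    channel_config: ChannelConfig | None = None,
    passive: PassiveProfile | None = None,
    kinetics: dict[str, ChannelKinetics] | None = None,
    **ca_kwargs,
) -> CellSpec:
    """Assemble and validate a :class:`CellSpec` on a morphology.

    The configuration (shipped defaults if ``None``) is checked against the
    qualitative ordering constraints of the cell class; a violation raises
    :class:`ConfigError` naming the constraint. ``basal_mode='nonuniform'``
    rewrites only the basal Na+/K+ rules into a linear distance-dependent
    scaling; all non-basal parameters are identical between modes.
    """
    cfg = channel_config if channel_config is not None \
        else default_channel_config()
    unknown = set(cfg) - set(CHANNEL_NAMES)
    if unknown:
        raise ConfigError(f"unknown channel name(s): {sorted(unknown)}")
    _check_orderings(cfg)
    cfg = _apply_basal_mode(cfg, basal_mode)
    return CellSpec(
        morphology=m,
        passive=passive or PassiveProfile(),
        channel_config=cfg,
        kinetics=kinetics or default_kinetics(),
        basal_mode=basal_mode,
        **ca_kwargs,
    )


def passive_cell_spec(
    m: Morphology,
    passive: PassiveProfile | None = None,
    **ca_kwargs,
) -> CellSpec:
    """A cell with all active channels off (leak membrane only).

    Used for analytic validation: with no channels the simulated cell must
    reproduce closed-form RC and finite-cable behaviour. Bypasses the
    ordering checks, which only constrain active configurations.
    """
    return CellSpec(
        morphology=m,
        passive=passive or PassiveProfile(),
        channel_config={},
        basal_mode="uniform",
        **ca_kwargs,
    )


# ----------------------------------------------------------------------
# JSON configuration round trip
# ----------------------------------------------------------------------

def dump_channel_config(cfg: ChannelConfig, path) -> None:
    """Write a density configuration as versioned JSON."""
    doc = {
        "schema": "dendrofire-channels/1",
        "channels": {
            name: {region: rule.to_dict() for region, rule in regions.items()}
            for name, regions in cfg.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_channel_config(path) -> ChannelConfig:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != "dendrofire-channels/1":
        raise ConfigError("unrecognized channel config schema")
    return {
        name: {
            region: DistributionRule.from_dict(rule)
            for region, rule in regions.items()
        }
        for name, regions in doc["channels"].items()
    }
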