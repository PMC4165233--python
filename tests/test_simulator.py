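"""Cable integration against closed-form passive physics and a
high-accuracy reference integrator."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dendrofire.biophysics import (
    CellSpec,
    DistributionRule,
    PassiveProfile,
    passive_cell_spec,
)
from dendrofire.channels import default_kinetics
from dendrofire.morphology import BASAL, SOMA, Morphology, SwcPoint
from dendrofire.protocols import detect_spikes
from dendrofire.simulator import (
    DiscretizationError,
    _gate_inf_tau,
    discretize,
    run,
    step_protocol,
)

RM, RA, CM = 30e3, 210.0, 1.2  # Ohm cm^2, Ohm cm, uF/cm^2


def _iso_soma(area_cm2=1e-4):
    r_um = math.sqrt(area_cm2 / (4 * math.pi)) * 1e4
    return Morphology.from_points([SwcPoint(1, SOMA, 0, 0, 0, r_um, -1)])


def _stick_cell(length_um=600.0, diam_um=2.0, soma_r_um=2.0, npts=30):
    pts = [SwcPoint(1, SOMA, 0, 0, 0, soma_r_um, -1)]
    for i in range(npts):
        pts.append(
            SwcPoint(i + 2, BASAL, (i + 1) * length_um / npts, 0, 0,
                     diam_um / 2, i + 1)
        )
    return Morphology.from_points(pts)


def _uniform_passive(**kw):
    return PassiveProfile(rm_drop=0.0, **kw)


def test_discretize_compartment_count():
    m = _stick_cell(length_um=100.0, npts=2)
    g = discretize(passive_cell_spec(m), max_seg_length=10.0)
    non_soma = g.n - 1
    assert non_soma == 10


def test_discretize_conserves_membrane_area():
    m = _stick_cell(length_um=500.0, diam_um=1.4, npts=25)
    spec = passive_cell_spec(m)
    g = discretize(spec, max_seg_length=7.0)
    soma_len, soma_diam = m.soma_equivalent_cylinder()
    analytic = (
        math.pi * soma_diam * soma_len
        + sum(math.pi * s.diameter * s.length for s in m.sections)
    ) * 1e-8
    assert g.total_area == pytest.approx(analytic, rel=1e-6)


def test_discretize_rejects_bad_seg_length():
    with pytest.raises(DiscretizationError):
        discretize(passive_cell_spec(_iso_soma()), max_seg_length=0.0)


def test_rc_charging_matches_closed_form():
    """Isopotential passive soma: V(t) = V_rest + IR(1 - e^(-t/tau))."""
    g = discretize(passive_cell_spec(_iso_soma(1e-4)))
    tr = run(g, step_protocol(0.1, t_on_ms=10, dur_ms=300, tail_ms=10),
             dt=0.025)
    tau = RM * CM * 1e-3  # 36 ms
    assert tau == pytest.approx(36.0)
    dv = 0.1e-9 * RM / 1e-4 * 1e3  # I*Rm/A in mV = 30
    mask = (tr.t > 10) & (tr.t <= 310)
    expected = -66.0 + dv * (1 - np.exp(-(tr.t[mask] - 10) / tau))
    err = np.max(np.abs(tr.v[mask] - expected)) / dv
    assert err < 0.01


def test_sealed_stick_rin_matches_cable_formula():
    """Somatic Rin of a finite sealed cable: R_inf * coth(L/lambda),
    in parallel with the (small) somatic leak."""
    length_um, diam_um, soma_r = 600.0, 2.0, 2.0
    m = _stick_cell(length_um, diam_um, soma_r)
    spec = passive_cell_spec(m, passive=_uniform_passive())
    g = discretize(spec, max_seg_length=5.0)
    r_cm = diam_um / 2 * 1e-4
    lam = math.sqrt(r_cm * RM / (2 * RA))
    r_inf = math.sqrt(RM * RA / 2) / (math.pi * r_cm**1.5)
    g_stick = math.tanh(length_um * 1e-4 / lam) / r_inf
    g_soma = 4 * math.pi * (soma_r * 1e-4) ** 2 / RM
    rin_expected = 1 / (g_stick + g_soma) / 1e6  # MOhm
    tr = run(g, step_protocol(-0.1, t_on_ms=20, dur_ms=500, tail_ms=20),
             dt=0.05)
    v0 = tr.v[np.searchsorted(tr.t, 20.0) - 1]
    v1 = tr.v[np.searchsorted(tr.t, 520.0) - 1]
    rin_sim = abs(v1 - v0) / 0.1
    assert rin_sim == pytest.approx(rin_expected, rel=0.01)


def test_spatial_refinement_converges():
    m = _stick_cell(800.0, 1.5, 2.0, npts=40)
    spec = passive_cell_spec(m, passive=_uniform_passive())

    def rin(max_seg):
        g = discretize(spec, max_seg_length=max_seg)
        tr = run(g, step_protocol(-0.1, t_on_ms=10, dur_ms=400, tail_ms=10),
                 dt=0.05)
        v0 = tr.v[np.searchsorted(tr.t, 10.0) - 1]
        v1 = tr.v[np.searchsorted(tr.t, 410.0) - 1]
        return abs(v1 - v0) / 0.1

    coarse, fine = rin(20.0), rin(10.0)
    assert abs(fine - coarse) / coarse < 0.005


def test_passive_superposition():
    g = discretize(passive_cell_spec(_stick_cell()), max_seg_length=20.0)
    tr1 = run(g, step_protocol(0.05, dur_ms=200, tail_ms=20), dt=0.05)
    tr2 = run(g, step_protocol(0.10, dur_ms=200, tail_ms=20), dt=0.05)
    rest = -66.0
    assert np.allclose(tr2.v - rest, 2 * (tr1.v - rest), atol=1e-9)


def _soma_hh_spec():
    u = lambda gg: DistributionRule("uniform", g0=gg)  # noqa: E731
    cfg = {"Naf": {"soma": u(0.055)}, "Kdr": {"soma": u(0.020)}}
    kin = {k: v for k, v in default_kinetics().items() if k in cfg}
    return CellSpec(
        morphology=_iso_soma(1e-4), passive=PassiveProfile(),
        channel_config=cfg, kinetics=kin,
    )


@pytest.mark.parametrize("dt", [0.0125, 0.025, 0.05])
def test_unconditional_stability_and_voltage_bounds(dt):
    g = discretize(_soma_hh_spec())
    tr = run(g, step_protocol(0.35, t_on_ms=20, dur_ms=300, tail_ms=20),
             dt=dt)
    assert np.all(np.isfinite(tr.v))
    assert np.all(tr.v > -120.0) and np.all(tr.v < 80.0)


def test_deterministic_traces():
    g = discretize(_soma_hh_spec())
    proto = step_protocol(0.35, t_on_ms=20, dur_ms=200, tail_ms=20)
    tr1 = run(g, proto, dt=0.025)
    tr2 = run(g, proto, dt=0.025)
    assert np.array_equal(tr1.v, tr2.v)


def test_spike_times_match_reference_integrator():
    """Soma-only HH cell: backward-Euler spike times within 1 ms of an
    adaptive LSODA reference, with error decreasing under dt refinement."""
    spec = _soma_hh_spec()
    g = discretize(spec)
    pk = g.kinetics
    gp, cap, gb = g.g_pas[0], g.cap_nf[0], g.gbar[:, 0]

    def rhs(t, y):
        v, s = y[0], y[1:]
        stim = 0.35 if 20 < t <= 220 else 0.0
        dy = np.zeros_like(y)
        opening = np.ones(len(pk.names))
        for gi in range(pk.gate_chan.size):
            inf, tau = _gate_inf_tau(
                int(pk.gate_kind[gi]), pk.gate_params[gi], v, 0.05
            )
            dy[1 + gi] = (inf - s[gi]) / tau
            opening[pk.gate_chan[gi]] *= s[gi] ** pk.gate_power[gi]
        gsum, gesum = gp, gp * -66.0
        for ci in range(len(pk.names)):
            gg = gb[ci] * opening[ci]
            gsum += gg
            gesum += gg * pk.erev[ci]
        dy[0] = (-(gsum * v - gesum) + stim) / cap
        return dy

    y0 = np.zeros(1 + pk.gate_chan.size)
    y0[0] = -66.0
    for gi in range(pk.gate_chan.size):
        y0[1 + gi], _ = _gate_inf_tau(
            int(pk.gate_kind[gi]), pk.gate_params[gi], -66.0, 0.05
        )
    sol = solve_ivp(rhs, (0, 240), y0, method="LSODA", rtol=1e-8,
                    atol=1e-8, max_step=0.25, dense_output=True)
    tt = np.arange(0, 240, 0.002)

    def spikes(t, v):
        out = []
        for i in range(1, len(v)):
            if v[i - 1] < 0.0 <= v[i]:
                out.append(
                    t[i - 1] - v[i - 1] * (t[i] - t[i - 1]) / (v[i] - v[i - 1])
                )
        return out

    ref = spikes(tt, sol.sol(tt)[0])
    errs = {}
    for dt in (0.025, 0.0125):
        tr = run(g, step_protocol(0.35, t_on_ms=20, dur_ms=200, tail_ms=20),
                 dt=dt, settle_ms=0.0)
        st = detect_spikes(tr)
        assert len(st) == len(ref)
        errs[dt] = max(abs(a - b) for a, b in zip(st, ref))
    assert errs[0.025] < 1.0
    assert errs[0.0125] < errs[0.025]
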