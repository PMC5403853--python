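"""Electrical-chemical test-case models and synthetic two-timescale benchmarks.

Two families of coupled problems are provided.

**The neuron test case** couples an electrical and a biochemical component:

* The electrical component is a multi-compartment neuron — a soma, fifteen
  passive dendrite segments and a spine — with the minimal Hodgkin-Huxley
  channel set of a regular-spiking cortical cell (fast Na+, delayed-rectifier
  K+, slow non-inactivating K+ "M" current, leak; kinetics after Pospischil et
  al. 2008).  The spine carries a high-threshold Ca2+ current, a
  phenomenological single-pool calcium concentration, and a K+ conductance
  whose availability is set by the biochemical component.
* The biochemical component is a reduced MAPK cascade: calcium activates an
  upstream kinase which phosphorylates MAPK; phosphorylated MAPK (P-MAPK)
  feeds back on its own activator — zero-order ultrasensitivity plus positive
  feedback make the cascade bistable — and phosphorylates (inactivates) the
  spine K+ channel.  Total MAPK and total channel are conserved moieties.

The two coupling variants differ only in the electrical-to-biochemical
signal: *TC-fast* communicates the instantaneous calcium flux (fast,
spike-shaped, microsecond time course; the calcium pool then lives on the
biochemical side) while *TC-slow* solves the calcium concentration on the
electrical side and communicates the concentration (millisecond-smooth
signal).  The reverse signal is in both cases the fraction of active
(non-phosphorylated) K+ channels, ``C1 * [K_A]``.

All model parameters are package defaults chosen for the qualitative
behaviors the test case is meant to exhibit (regular spiking near 2 Hz under
weak pulses, ~100 Hz firing under strong current, bistable switching of
P-MAPK by calcium, tens-of-seconds biochemical response); every parameter is
overridable through the dataclasses or the shipped parameter files.

**The synthetic benchmark** is a linear two-timescale system with an exact
closed-form solution, used wherever a cheap, analytically known two-rate
problem is preferable to the neuron: a slow relaxer driven by the output of a
stiff fast subsystem that carries both a fast and a slow sinusoidal forcing
plus a low-pass-filtered copy of its own fast state.  Selecting the fast
state as the exchanged signal emulates the flux-like coupling of TC-fast;
selecting the filtered state emulates the smooth concentration signal of
TC-slow.

Units: time s, voltage mV, current nA, conductance uS, capacitance nF,
concentrations uM, flux molecules/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElectricalParams",
    "BiochemicalParams",
    "ElectricalModel",
    "BiochemicalModel",
    "PulseProtocol",
    "CouplingSpec",
    "CoupledTestCase",
    "build_testcase",
    "SyntheticTwoRateProblem",
    "make_synthetic_problem",
    "detect_spikes",
    "firing_rates",
    "TC_FAST",
    "TC_SLOW",
]

TC_FAST = "TC-fast"
TC_SLOW = "TC-slow"

FARADAY = 96485.33212  # C/mol
N_AVOGADRO = 6.02214076e23  # 1/mol
#: molecules/s of Ca2+ carried by 1 nA of Ca2+ current (divalent ion)
FLUX_PER_NA = 1e-9 / (2.0 * FARADAY) * N_AVOGADRO


class ModelConfigError(ValueError):
    """Raised for missing or inconsistent model parameters."""


def _zexpm1(z):
    """Numerically stable z / (exp(z) - 1) (limit 1 at z = 0)."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < 1e-8
    safe = np.where(small, 1.0, z)
    with np.errstate(over="ignore"):
        out = np.where(small, 1.0 - z / 2.0, safe / np.expm1(safe))
    return out


# ===========================================================================
# electrical component
# ===========================================================================


@dataclass
class ElectricalParams:
    """Morphology, passive properties and channel densities of the neuron.

    Channel densities and kinetics follow the minimal regular-spiking
    cortical-neuron parameter set of Pospischil et al. (2008); morphology and
    the spine/calcium parameters are package defaults.
    """

    # morphology (um)
    soma_diameter: float = 20.0
    dend_diameter: float = 3.0
    dend_length: float = 25.0
    n_dend: int = 15
    spine_area_um2: float = 1.0
    axial_resistivity: float = 150.0  # ohm cm
    spine_neck_radius_um: float = 0.05
    spine_neck_length_um: float = 1.0

    # passive
    cm_uf_per_cm2: float = 1.0
    g_leak_s_per_cm2: float = 2.05e-5
    e_leak: float = -70.3

    # soma channels (S/cm2) and reversal potentials (mV)
    g_na_s_per_cm2: float = 0.056
    g_kd_s_per_cm2: float = 0.006
    g_m_s_per_cm2: float = 7.5e-5
    e_na: float = 50.0
    e_k: float = -90.0
    v_t: float = -56.2  # spike-threshold shift of the rate functions
    tau_max_adapt: float = 0.608  # s, M-current time-constant ceiling

    # spine channels (absolute, uS)
    g_k_spine: float = 2e-3
    g_ca_spine: float = 5e-4
    e_ca: float = 120.0
    tau_m_ca: float = 3e-4  # s
    v_half_ca: float = -35.0
    k_ca_slope: float = 7.0

    # phenomenological spine calcium pool
    ca_rest: float = 0.08  # uM
    tau_ca: float = 0.1  # s
    ca_per_na: float = 4e4  # uM/s of concentration rise per nA of inward I_Ca

    # resting K-channel availability used when the biochemical partner is absent
    u_rest: float = 1.0


class ElectricalModel:
    """Right-hand side and output function of the electrical component.

    State layout: ``[V_soma, m, h, n, p, V_d1..V_d{nd}, V_spine, m_Ca(, Ca)]``
    with the calcium concentration present only in the TC-slow variant (in
    TC-fast the pool is solved on the biochemical side).
    """

    def __init__(
        self,
        params: ElectricalParams | None = None,
        variant: str = TC_SLOW,
        protocol=None,
    ):
        if variant not in (TC_FAST, TC_SLOW):
            raise ModelConfigError(f"unknown variant {variant!r}")
        self.p = params if params is not None else ElectricalParams()
        self.variant = variant
        self.protocol = protocol if protocol is not None else (lambda t: 0.0)
        p = self.p

        # absolute quantities (uS, nF) from densities and geometry
        area_soma = math.pi * p.soma_diameter**2 * 1e-8  # cm2
        area_dend = math.pi * p.dend_diameter * p.dend_length * 1e-8
        area_spine = p.spine_area_um2 * 1e-8
        self.c_soma = p.cm_uf_per_cm2 * area_soma * 1e3  # nF
        self.c_dend = p.cm_uf_per_cm2 * area_dend * 1e3
        self.c_spine = p.cm_uf_per_cm2 * area_spine * 1e3
        self.g_na = p.g_na_s_per_cm2 * area_soma * 1e6  # uS
        self.g_kd = p.g_kd_s_per_cm2 * area_soma * 1e6
        self.g_m = p.g_m_s_per_cm2 * area_soma * 1e6
        self.g_leak_soma = p.g_leak_s_per_cm2 * area_soma * 1e6
        self.g_leak_dend = p.g_leak_s_per_cm2 * area_dend * 1e6
        self.g_leak_spine = p.g_leak_s_per_cm2 * area_spine * 1e6
        r_dend = p.dend_diameter / 2.0 * 1e-4  # cm
        self.g_axial = (
            math.pi * r_dend**2 / (p.axial_resistivity * p.dend_length * 1e-4) * 1e6
        )
        r_neck = p.spine_neck_radius_um * 1e-4
        self.g_neck = (
            math.pi
            * r_neck**2
            / (p.axial_resistivity * p.spine_neck_length_um * 1e-4)
            * 1e6
        )

        nd = p.n_dend
        self.i_v_soma = 0
        self.i_gates = slice(1, 5)  # m, h, n, p
        self.i_v_dend = slice(5, 5 + nd)
        self.i_v_spine = 5 + nd
        self.i_m_ca = 6 + nd
        self.i_ca = 7 + nd if variant == TC_SLOW else None
        self.dim = (8 if variant == TC_SLOW else 7) + nd

        self.state_names = (
            ["V_soma", "m", "h", "n", "p"]
            + [f"V_dend{i + 1}" for i in range(nd)]
            + ["V_spine", "m_ca"]
            + (["Ca"] if variant == TC_SLOW else [])
        )

    # -- channel kinetics (rates per second, V in mV) ----------------------

    def _gate_rates(self, v):
        p = self.p
        vs = v - p.v_t
        a_m = 1e3 * 1.28 * _zexpm1(-(vs - 13.0) / 4.0)
        b_m = 1e3 * 1.4 * _zexpm1((vs - 40.0) / 5.0)
        a_h = 1e3 * 0.128 * np.exp(-(vs - 17.0) / 18.0)
        b_h = 1e3 * 4.0 / (1.0 + np.exp(-(vs - 40.0) / 5.0))
        a_n = 1e3 * 0.16 * _zexpm1(-(vs - 15.0) / 5.0)
        b_n = 1e3 * 0.25 * np.exp(-(vs - 10.0) / 40.0)
        return a_m, b_m, a_h, b_h, a_n, b_n

    def _adapt_gate(self, v):
        p_inf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
        tau_p = self.p.tau_max_adapt / (
            3.3 * np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0)
        )
        return p_inf, tau_p

    def _m_ca_inf(self, v):
        return 1.0 / (1.0 + np.exp(-(v - self.p.v_half_ca) / self.p.k_ca_slope))

    def i_ca_spine(self, x) -> float:
        """Spine Ca2+ current (nA; negative = inward)."""
        v_sp = x[self.i_v_spine]
        m_ca = x[self.i_m_ca]
        return self.g_ca_abs_current(v_sp, m_ca)

    def g_ca_abs_current(self, v_sp, m_ca):
        return self.p.g_ca_spine * m_ca * m_ca * (v_sp - self.p.e_ca)

    # -- right-hand side ---------------------------------------------------

    def rhs(self, t, x, u=None):
        """dx/dt of the electrical component.

        ``u`` maps partner ids to exchanged vectors; the biochemical entry is
        the K-channel availability fraction in the spine (defaults to the
        resting value when the partner is absent).
        """
        p = self.p
        u_b = p.u_rest
        if u:
            val = u.get("biochemical")
            if val is not None:
                u_b = float(np.atleast_1d(val)[0])

        dx = np.empty_like(x)
        v_s = x[self.i_v_soma]
        m, h, n, pg = x[self.i_gates]
        v_d = x[self.i_v_dend]
        v_sp = x[self.i_v_spine]
        m_ca = x[self.i_m_ca]

        # soma: HH currents + axial coupling to first dendrite segment
        i_na = self.g_na * m**3 * h * (v_s - p.e_na)
        i_kd = self.g_kd * n**4 * (v_s - p.e_k)
        i_m = self.g_m * pg * (v_s - p.e_k)
        i_leak = self.g_leak_soma * (v_s - p.e_leak)
        i_inj = self.protocol(t)
        i_ax_soma = self.g_axial * (v_d[0] - v_s)
        dx[self.i_v_soma] = 1e3 * (-(i_na + i_kd + i_m + i_leak) + i_ax_soma + i_inj) / self.c_soma

        a_m, b_m, a_h, b_h, a_n, b_n = self._gate_rates(v_s)
        p_inf, tau_p = self._adapt_gate(v_s)
        dx[1] = a_m * (1.0 - m) - b_m * m
        dx[2] = a_h * (1.0 - h) - b_h * h
        dx[3] = a_n * (1.0 - n) - b_n * n
        dx[4] = (p_inf - pg) / tau_p

        # passive dendrite chain: soma - d1 - ... - d15 - spine
        v_prev = np.concatenate(([v_s], v_d[:-1]))
        v_next = np.concatenate((v_d[1:], [v_sp]))
        g_next = np.full(p.n_dend, self.g_axial)
        g_next[-1] = self.g_neck
        i_ax = self.g_axial * (v_prev - v_d) + g_next * (v_next - v_d)
        dx[self.i_v_dend] = 1e3 * (
            -self.g_leak_dend * (v_d - p.e_leak) + i_ax
        ) / self.c_dend

        # spine: leak + modulated K + Ca current
        i_leak_sp = self.g_leak_spine * (v_sp - p.e_leak)
        i_k2 = p.g_k_spine * u_b * (v_sp - p.e_k)
        i_ca = self.g_ca_abs_current(v_sp, m_ca)
        i_ax_sp = self.g_neck * (v_d[-1] - v_sp)
        dx[self.i_v_spine] = 1e3 * (-(i_leak_sp + i_k2 + i_ca) + i_ax_sp) / self.c_spine
        dx[self.i_m_ca] = (self._m_ca_inf(v_sp) - m_ca) / p.tau_m_ca

        if self.i_ca is not None:
            ca = x[self.i_ca]
            dx[self.i_ca] = -(ca - p.ca_rest) / p.tau_ca + p.ca_per_na * (-i_ca)
        return dx

    # -- output (transformation) function ---------------------------------

    def output(self, x):
        """Exchanged variable: [Ca] (uM, TC-slow) or Ca flux (molecules/s, TC-fast)."""
        if self.variant == TC_SLOW:
            return np.array([x[self.i_ca]])
        return np.array([-self.i_ca_spine(x) * FLUX_PER_NA])

    # -- initial / resting state ------------------------------------------

    def initial_state(self, v0: float | None = None) -> np.ndarray:
        p = self.p
        v = p.e_leak if v0 is None else v0
        x = np.empty(self.dim)
        x[self.i_v_soma] = v
        a_m, b_m, a_h, b_h, a_n, b_n = self._gate_rates(v)
        x[1] = a_m / (a_m + b_m)
        x[2] = a_h / (a_h + b_h)
        x[3] = a_n / (a_n + b_n)
        x[4] = self._adapt_gate(v)[0]
        x[self.i_v_dend] = v
        x[self.i_v_spine] = v
        x[self.i_m_ca] = self._m_ca_inf(v)
        if self.i_ca is not None:
            x[self.i_ca] = p.ca_rest
        return x

    def resting_state(self, u_b: float | None = None) -> np.ndarray:
        """Resting fixed point located by root-finding on the full rhs
        (injected current at baseline, availability at its resting value)."""
        from scipy.optimize import root

        u = {"biochemical": np.array([self.p.u_rest if u_b is None else u_b])}
        saved = self.protocol
        self.protocol = lambda t: 0.0
        try:
            sol = root(lambda x: self.rhs(0.0, x, u), self.initial_state(), tol=1e-12)
        finally:
            self.protocol = saved
        if not sol.success:
            raise ModelConfigError(f"resting-state search failed: {sol.message}")
        return sol.x

    def default_tolerances(self, rel_tol: float):
        """Per-variable absolute tolerances scaled to typical magnitudes
        (100 mV for potentials, 1 for gates, 1 uM for calcium)."""
        typ = np.ones(self.dim)
        typ[self.i_v_soma] = 100.0
        typ[self.i_v_dend] = 100.0
        typ[self.i_v_spine] = 100.0
        if self.i_ca is not None:
            typ[self.i_ca] = 1.0
        return rel_tol * typ


# ===========================================================================
# biochemical component
# ===========================================================================


@dataclass
class BiochemicalParams:
    """Rate constants and totals of the reduced MAPK cascade (uM, s).

    The cascade is bistable: calcium (Hill) and P-MAPK (positive feedback)
    activate an upstream kinase; MAPK (de)phosphorylation runs near
    zero-order saturation.  Response times are set by the 0.01-0.1 /s rates,
    i.e. tens of seconds.
    """

    a_total: float = 1.0  # upstream kinase, uM
    m_total: float = 1.0  # MAPK, uM
    k_total: float = 1.0  # spine K channel, uM

    k_act: float = 0.3  # /s, calcium-driven activation
    k_ca_half: float = 0.35  # uM, calcium Hill constant
    hill: float = 4.0
    k_fb: float = 0.4  # /s, P-MAPK positive feedback
    k_fb_half: float = 0.3  # uM
    k_inact: float = 0.1  # /s

    k_cat: float = 0.3  # /(uM s), MAPK phosphorylation by active kinase
    km_phos: float = 0.1  # uM
    v_dephos: float = 0.1  # uM/s, phosphatase Vmax
    km_dephos: float = 0.1  # uM

    k_channel_p: float = 0.2  # /(uM s), channel phosphorylation by P-MAPK
    k_channel_d: float = 0.1  # /s, channel dephosphorylation

    ca_rest: float = 0.08  # uM
    tau_ca: float = 0.1  # s (TC-fast pool, matches the electrical pool)
    ca_per_molecule_rate: float | None = None  # uM/s per (molecule/s); derived

    #: scaling of the exchanged availability signal g2 = C1 * [K_A]
    c1: float | None = None  # derived: 1/k_total


class BiochemicalModel:
    """Reduced MAPK pathway: upstream kinase, MAPK phosphoforms, K channel.

    State layout: ``[A, Ap, M, Mp, K_A, K_P(, Ca)]`` with the calcium pool as
    a state only in the TC-fast variant.  ``A + Ap``, ``M + Mp`` and
    ``K_A + K_P`` are conserved by construction.
    """

    #: tolerated Newton-iteration undershoot below zero (uM)
    NEGATIVE_SLACK = 1e-6

    def __init__(
        self,
        params: BiochemicalParams | None = None,
        variant: str = TC_SLOW,
        elec_params: ElectricalParams | None = None,
    ):
        if variant not in (TC_FAST, TC_SLOW):
            raise ModelConfigError(f"unknown variant {variant!r}")
        self.p = params if params is not None else BiochemicalParams()
        self.variant = variant
        if self.p.c1 is None:
            self.p.c1 = 1.0 / self.p.k_total
        if self.p.ca_per_molecule_rate is None:
            # chosen so that a given Ca current raises the TC-fast pool at the
            # same rate as the electrical-side pool in TC-slow
            ep = elec_params if elec_params is not None else ElectricalParams()
            self.p.ca_per_molecule_rate = ep.ca_per_na / FLUX_PER_NA
        self.i_a, self.i_ap, self.i_m, self.i_mp, self.i_ka, self.i_kp = range(6)
        self.i_ca = 6 if variant == TC_FAST else None
        self.dim = 7 if variant == TC_FAST else 6
        self.state_names = ["A", "Ap", "M", "Mp", "K_A", "K_P"] + (
            ["Ca"] if variant == TC_FAST else []
        )

    def rhs(self, t, x, u=None):
        """dx/dt of the cascade; ``u`` carries the electrical signal
        ([Ca] in uM for TC-slow, Ca flux in molecules/s for TC-fast)."""
        p = self.p
        x = np.asarray(x, dtype=float)
        if np.min(x) < -self.NEGATIVE_SLACK:
            raise ModelConfigError(
                f"negative concentration in biochemical state: min={np.min(x):g}"
            )
        a, ap, m, mp, ka, kp = x[:6]

        if self.variant == TC_SLOW:
            ca = p.ca_rest
            if u:
                val = u.get("electrical")
                if val is not None:
                    ca = float(np.atleast_1d(val)[0])
            ca = max(ca, 0.0)
        else:
            ca = max(x[self.i_ca], 0.0)

        hill = ca**p.hill / (p.k_ca_half**p.hill + ca**p.hill)
        fb = mp * mp / (p.k_fb_half**2 + mp * mp)
        v_act = (p.k_act * hill + p.k_fb * fb) * a
        v_inact = p.k_inact * ap

        v_phos = p.k_cat * ap * m / (p.km_phos + m)
        v_dephos = p.v_dephos * mp / (p.km_dephos + mp)

        v_ch_p = p.k_channel_p * mp * ka
        v_ch_d = p.k_channel_d * kp

        dx = np.empty_like(x)
        dx[self.i_a] = -v_act + v_inact
        dx[self.i_ap] = v_act - v_inact
        dx[self.i_m] = -v_phos + v_dephos
        dx[self.i_mp] = v_phos - v_dephos
        dx[self.i_ka] = -v_ch_p + v_ch_d
        dx[self.i_kp] = v_ch_p - v_ch_d

        if self.i_ca is not None:
            flux = 0.0
            if u:
                val = u.get("electrical")
                if val is not None:
                    flux = float(np.atleast_1d(val)[0])
            dx[self.i_ca] = (
                p.ca_per_molecule_rate * flux - (x[self.i_ca] - p.ca_rest) / p.tau_ca
            )
        return dx

    def output(self, x):
        """Exchanged variable: K-channel availability fraction C1 * [K_A]."""
        return np.array([self.p.c1 * x[self.i_ka]])

    def initial_state(self) -> np.ndarray:
        p = self.p
        x = np.zeros(self.dim)
        x[self.i_a] = p.a_total
        x[self.i_m] = p.m_total
        x[self.i_ka] = p.k_total
        if self.i_ca is not None:
            x[self.i_ca] = p.ca_rest
        return x

    def conserved_totals(self, x) -> np.ndarray:
        """The three conserved moieties [A+Ap, M+Mp, K_A+K_P]."""
        x = np.asarray(x)
        return np.array(
            [
                x[..., self.i_a] + x[..., self.i_ap],
                x[..., self.i_m] + x[..., self.i_mp],
                x[..., self.i_ka] + x[..., self.i_kp],
            ]
        )

    def default_tolerances(self, rel_tol: float):
        typ = np.array(
            [self.p.a_total, self.p.a_total, self.p.m_total, self.p.m_total,
             self.p.k_total, self.p.k_total]
            + ([1.0] if self.i_ca is not None else [])
        )
        return rel_tol * typ


# ===========================================================================
# stimulation protocol
# ===========================================================================


@dataclass
class PulseProtocol:
    """Piecewise-constant injected-current protocol (nA into the soma).

    Phase 1 (regular spiking): brief suprathreshold pulses delivered at
    ``pulse_rate`` so the cell fires one spike per pulse, i.e. at the pulse
    rate.  Phase 2 (burst firing): a sustained strong step driving fast
    repetitive firing.  Defaults target ~2 Hz in phase 1 and ~100 Hz in
    phase 2 over a 5 s protocol.
    """

    t_total: float = 5.0
    burst_start: float = 4.0
    pulse_rate: float = 2.0  # Hz
    pulse_onset: float = 0.05  # s, first pulse
    pulse_width: float = 0.005  # s
    pulse_amplitude: float = 0.35  # nA
    burst_amplitude: float = 0.15  # nA
    baseline: float = 0.0  # nA

    def __call__(self, t: float) -> float:
        if self.burst_start <= t < self.t_total:
            return self.burst_amplitude
        if 0.0 <= t < self.burst_start:
            period = 1.0 / self.pulse_rate
            tau = (t - self.pulse_onset) % period
            if t >= self.pulse_onset and 0.0 <= tau < self.pulse_width:
                return self.pulse_amplitude
        return self.baseline

    @property
    def phases(self) -> dict:
        return {
            "regular": (0.0, self.burst_start),
            "burst": (self.burst_start, self.t_total),
        }


def detect_spikes(times, v, threshold: float = 0.0) -> np.ndarray:
    """Times of upward threshold crossings of a voltage trace."""
    times = np.asarray(times, dtype=float)
    v = np.asarray(v, dtype=float)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    # linear interpolation of the crossing time inside the step
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    return times[idx] + frac * (times[idx + 1] - times[idx])


def firing_rates(times, v, protocol: PulseProtocol, threshold: float = 0.0) -> dict:
    """Mean firing rate (Hz) per protocol phase from a soma voltage trace."""
    spikes = detect_spikes(times, v, threshold)
    rates = {}
    for name, (t0, t1) in protocol.phases.items():
        n = int(np.sum((spikes >= t0) & (spikes < t1)))
        rates[name] = n / (t1 - t0)
    return rates


# ===========================================================================
# coupled test case
# ===========================================================================


@dataclass
class CouplingSpec:
    """Which signals the two components exchange in each variant."""

    variant: str
    forward: str  # electrical -> biochemical signal
    backward: str = "K-channel availability C1*[K_A]"


class CoupledTestCase:
    """The electrical-chemical test case wired for the co-simulation engine.

    Provides the two :class:`~mrcosim.engine.Component` objects, the
    monolithic combined right-hand side for reference solves, and named
    observables (V = spine potential, Ca, K_A, P-MAPK).
    """

    def __init__(
        self,
        variant: str = TC_SLOW,
        elec_params: ElectricalParams | None = None,
        bioch_params: BiochemicalParams | None = None,
        protocol: PulseProtocol | None = None,
    ):
        self.variant = variant
        self.protocol = protocol if protocol is not None else PulseProtocol()
        self.electrical = ElectricalModel(
            elec_params, variant=variant, protocol=self.protocol
        )
        self.biochemical = BiochemicalModel(
            bioch_params, variant=variant, elec_params=self.electrical.p
        )
        self.coupling = CouplingSpec(
            variant=variant,
            forward="calcium concentration [uM]"
            if variant == TC_SLOW
            else "calcium flux [molecules/s]",
        )
        self.n_elec = self.electrical.dim
        self.n_bioch = self.biochemical.dim

        obs = {
            "V": ("electrical", self.electrical.i_v_spine),
            "K_A": ("biochemical", self.biochemical.i_ka),
            "P_MAPK": ("biochemical", self.biochemical.i_mp),
        }
        if variant == TC_SLOW:
            obs["Ca"] = ("electrical", self.electrical.i_ca)
        else:
            obs["Ca"] = ("biochemical", self.biochemical.i_ca)
        self.observables = obs

    # -- engine components -------------------------------------------------

    def components(self, rel_tol: float = 1e-5, retention: int = 8):
        from .engine import Component

        # cap the electrical step at half the stimulus pulse width so brief
        # current pulses cannot fall inside a single accepted step unseen
        elec = Component(
            "electrical",
            rhs=self.electrical.rhs,
            x0=self.electrical.initial_state(),
            output=self.electrical.output,
            rel_tol=rel_tol,
            abs_tol=self.electrical.default_tolerances(rel_tol),
            retention=retention,
            h_max=self.protocol.pulse_width / 2.0,
        )
        bioch = Component(
            "biochemical",
            rhs=self.biochemical.rhs,
            x0=self.biochemical.initial_state(),
            output=self.biochemical.output,
            rel_tol=rel_tol,
            abs_tol=self.biochemical.default_tolerances(rel_tol),
            retention=retention,
        )
        return [elec, bioch]

    # -- monolithic system for reference solutions ------------------------

    def x0_monolithic(self) -> np.ndarray:
        return np.concatenate(
            [self.electrical.initial_state(), self.biochemical.initial_state()]
        )

    def monolithic_rhs(self, t, x):
        """Combined rhs with exact (unapproximated) coupling."""
        xe = x[: self.n_elec]
        xb = x[self.n_elec :]
        u_e = {"biochemical": self.biochemical.output(xb)}
        u_b = {"electrical": self.electrical.output(xe)}
        return np.concatenate(
            [self.electrical.rhs(t, xe, u_e), self.biochemical.rhs(t, xb, u_b)]
        )

    def observable_monolithic_index(self, name: str) -> int:
        comp, idx = self.observables[name]
        return idx if comp == "electrical" else self.n_elec + idx


def build_testcase(variant: str = TC_SLOW, **kwargs) -> CoupledTestCase:
    """Construct the electrical-chemical test case (TC-fast or TC-slow)."""
    return CoupledTestCase(variant=variant, **kwargs)


# ===========================================================================
# synthetic two-rate benchmark
# ===========================================================================


class SyntheticTwoRateProblem:
    """Linear two-timescale benchmark with an exact closed-form solution.

    Slow subsystem (one state, time constant tau_slow):

        dx1/dt = (-x1 + c * u2(t)) / tau_slow

    Fast subsystem (two states, stiff time constant tau_fast):

        dy/dt = (-y + b * u1 + F(t)) / tau_fast
        dz/dt = (y - z) / tau_filt

    where u1 = g1(x_slow) = x1 and u2 = g2(x_fast) is either the raw fast
    state y (``signal_speed="fast"``, flux-like) or its low-pass-filtered
    copy z (``signal_speed="slow"``, concentration-like).  The forcing

        F(t) = a_f sin(w_f t) + a_s sin(w_s t) + a_p * pulse_train(t)

    combines two sinusoids with a train of narrow Gaussian pulses (period
    ``pulse_period``, width ``pulse_sigma``) that emulates the spike-shaped
    calcium-flux signal of the neuron test case: the fast state carries
    sparse sub-millisecond features while its low-pass filtered copy is
    smooth.  The system is linear throughout; without pulses (``a_p = 0``)
    the exact solution is available in closed form from the
    eigendecomposition of the system matrix plus sinusoidal particular
    solutions, and ``reference`` evaluates it.  With pulses the reference is
    a monolithic stiff solve at tight tolerance (see
    :func:`mrcosim.evaluation.compute_reference`).
    """

    def __init__(
        self,
        stiffness_ratio: float = 1000.0,
        coupling_strength: float = 0.5,
        signal_speed: str = "slow",
        tau_slow: float = 1.0,
        tau_filter: float = 0.2,
        b_coupling: float = 1.0,
        forcing_fast: tuple = (1.0, 200.0),
        forcing_slow: tuple = (1.0, 3.0),
        pulse_amplitude: float = 0.3,
        pulse_period: float = 0.02,
        pulse_sigma: float = 1e-4,
        pulse_onset: float = 0.01,
        x0=(1.0, 1.0, 1.0),
    ):
        if not stiffness_ratio >= 1.0:
            raise ModelConfigError(
                f"stiffness_ratio must be >= 1, got {stiffness_ratio}"
            )
        if signal_speed not in ("fast", "slow"):
            raise ModelConfigError(f"signal_speed must be 'fast' or 'slow'")
        self.stiffness_ratio = float(stiffness_ratio)
        self.c = float(coupling_strength)
        self.signal_speed = signal_speed
        self.tau_slow = float(tau_slow)
        self.tau_fast = self.tau_slow / self.stiffness_ratio
        self.tau_filter = float(tau_filter)
        self.b = float(b_coupling)
        self.a_f, self.w_f = map(float, forcing_fast)
        self.a_s, self.w_s = map(float, forcing_slow)
        self.a_p = float(pulse_amplitude)
        self.pulse_period = float(pulse_period)
        self.pulse_sigma = float(pulse_sigma)
        self.pulse_onset = float(pulse_onset)
        self.x0 = np.asarray(x0, dtype=float)

        sel = np.array([1.0, 0.0]) if signal_speed == "fast" else np.array([0.0, 1.0])
        self._sel = sel
        ts, tf, tz = self.tau_slow, self.tau_fast, self.tau_filter
        self.matrix = np.array(
            [
                [-1.0 / ts, self.c * sel[0] / ts, self.c * sel[1] / ts],
                [self.b / tf, -1.0 / tf, 0.0],
                [0.0, 1.0 / tz, -1.0 / tz],
            ]
        )
        # sinusoidal forcing terms acting on y
        self._forcings = [
            (self.a_f / tf, self.w_f),
            (self.a_s / tf, self.w_s),
        ]
        self._prepare_closed_form()

        self.observables = {"slow": ("slow", 0), "fast": ("fast", 0)}

    # -- closed form --------------------------------------------------------

    def _prepare_closed_form(self):
        M = self.matrix
        self._eigvals, self._eigvecs = np.linalg.eig(M)
        self._eigvecs_inv = np.linalg.inv(self._eigvecs)
        # particular solution x_p(t) = sum_k Im(v_k e^{i w_k t})
        self._particular = []
        n = M.shape[0]
        for amp, w in self._forcings:
            if amp == 0.0:
                continue
            fvec = np.zeros(n, dtype=complex)
            fvec[1] = amp
            v = np.linalg.solve(1j * w * np.eye(n) - M, fvec)
            self._particular.append((v, w))
        xp0 = np.zeros(n)
        for v, w in self._particular:
            xp0 = xp0 + np.imag(v)  # Im(v e^{i*0}) = Im(v)
        self._c_hom = self._eigvecs_inv @ (self.x0 - xp0)

    @property
    def has_closed_form(self) -> bool:
        return self.a_p == 0.0

    def forcing(self, t):
        """Scalar forcing F(t) acting on the fast state y."""
        f = self.a_f * math.sin(self.w_f * t) + self.a_s * math.sin(self.w_s * t)
        if self.a_p != 0.0:
            # nearest pulse dominates; sigma << period makes others negligible,
            # but the two neighbours are included for smoothness
            k = round((t - self.pulse_onset) / self.pulse_period)
            for kk in (k - 1, k, k + 1):
                tk = self.pulse_onset + kk * self.pulse_period
                arg = (t - tk) / self.pulse_sigma
                if abs(arg) < 12.0:
                    f += self.a_p * math.exp(-0.5 * arg * arg)
        return f

    def reference(self, t):
        """Exact closed-form solution at time(s) ``t`` (shape (3,) or (nt, 3)).

        Only available without the pulse train (``pulse_amplitude = 0``);
        with pulses use a monolithic tight-tolerance solve instead.
        """
        if not self.has_closed_form:
            raise ModelConfigError(
                "closed form requires pulse_amplitude = 0; use "
                "evaluation.compute_reference for the pulsed problem"
            )
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tv = np.atleast_1d(t)
        ew = np.exp(np.outer(tv, self._eigvals))  # (nt, 3)
        hom = (ew * self._c_hom) @ self._eigvecs.T
        part = np.zeros_like(hom)
        for v, w in self._particular:
            part = part + np.imag(np.outer(np.exp(1j * w * tv), v))
        out = np.real(hom) + part
        return out[0] if scalar else out

    # -- split system for the engine ----------------------------------------

    def slow_rhs(self, t, x, u=None):
        u2 = 0.0
        if u:
            val = u.get("fast")
            if val is not None:
                u2 = float(np.atleast_1d(val)[0])
        return np.array([(-x[0] + self.c * u2) / self.tau_slow])

    def fast_rhs(self, t, x, u=None):
        u1 = 0.0
        if u:
            val = u.get("slow")
            if val is not None:
                u1 = float(np.atleast_1d(val)[0])
        dy = (-x[0] + self.b * u1 + self.forcing(t)) / self.tau_fast
        dz = (x[0] - x[1]) / self.tau_filter
        return np.array([dy, dz])

    def g_slow(self, x):
        return np.array([x[0]])

    def g_fast(self, x):
        return np.array([x[0] if self.signal_speed == "fast" else x[1]])

    def components(self, rel_tol: float = 1e-6, abs_scale: float = 1e-2):
        from .engine import Component

        slow = Component(
            "slow",
            rhs=self.slow_rhs,
            x0=self.x0[:1],
            output=self.g_slow,
            rel_tol=rel_tol,
            abs_tol=abs_scale * rel_tol,
        )
        fast = Component(
            "fast",
            rhs=self.fast_rhs,
            x0=self.x0[1:],
            output=self.g_fast,
            rel_tol=rel_tol,
            abs_tol=abs_scale * rel_tol,
        )
        return [slow, fast]

    # -- monolithic system ---------------------------------------------------

    def x0_monolithic(self):
        return self.x0.copy()

    def monolithic_rhs(self, t, x):
        forcing = np.array([0.0, self.forcing(t) / self.tau_fast, 0.0])
        return self.matrix @ x + forcing

    def observable_monolithic_index(self, name: str) -> int:
        comp, idx = self.observables[name]
        return idx if comp == "slow" else 1 + idx


def make_synthetic_problem(
    stiffness_ratio: float = 1000.0,
    coupling_strength: float = 0.5,
    signal_speed: str = "slow",
    **kwargs,
) -> SyntheticTwoRateProblem:
    """Build the synthetic two-rate benchmark.

    ``signal_speed="fast"`` exposes the rapidly oscillating fast state as the
    exchanged signal (the flux-like case); ``"slow"`` exposes the
    low-pass-filtered state (the concentration-like case).
    """
    return SyntheticTwoRateProblem(
        stiffness_ratio=stiffness_ratio,
        coupling_strength=coupling_strength,
        signal_speed=signal_speed,
        **kwargs,
    )
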