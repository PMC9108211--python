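"""Membrane calcium kinetics at the channel zone.

Composite membrane flux = voltage-gated calcium channel (VGCC) influx
(Goldman-Hodgkin-Katz flux gated by Hodgkin-Huxley-style variables in the
Borg-Graham rate parameterization) + PMCA / NCX Hill-type extrusion pumps
+ a constant leak calibrated so the net flux vanishes at rest.

Unit conventions
----------------
Voltages are in mV at the public surface, concentrations in μM, per-channel
currents in A, per-pump turnover in mol/s.  Composite surface flux densities
are inward-positive in μM·μm/s, using 1 mol = 1e21 μM·μm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PhysicalConstants",
    "GateParams",
    "ChannelParams",
    "PumpParams",
    "GatingState",
    "APTrainSpec",
    "MOL_TO_UM_UM3",
    "ghk_flux",
    "gating_curves",
    "init_gating",
    "step_gating",
    "vgcc_current",
    "vgcc_molar_influx",
    "pmca_flux",
    "ncx_flux",
    "total_membrane_flux",
    "calibrate_leak",
    "ap_voltage",
    "nernst_potential",
]

#: 1 mol expressed in μM·μm³ (1 mol/L = 1e6 μM, 1 L = 1e15 μm³)
MOL_TO_UM_UM3 = 1.0e21

#: μM to mol/m³ (= mM)
_UM_TO_MOL_M3 = 1.0e-3


@dataclass(frozen=True)
class PhysicalConstants:
    F: float = 9.648e4     # Faraday constant, C/mol
    R: float = 8.314       # gas constant, V C / (K mol)
    T: float = 300.0       # temperature, K
    z: int = 2             # calcium valence

    def __post_init__(self):
        if min(self.F, self.R, self.T) <= 0:
            raise ValueError("physical constants must be positive")

    @property
    def vt(self) -> float:
        """Thermal voltage RT/F in volts."""
        return self.R * self.T / self.F


@dataclass(frozen=True)
class GateParams:
    """One Borg-Graham gating variable.

    ``z_gate`` is the effective gating charge (sign gives activation vs
    inactivation), ``v_half`` the half-activation voltage in mV, ``gamma``
    the rate partition, ``base_rate`` the shared forward/backward rate scale
    in 1/s and ``tau_min`` the floor of the time constant in s.
    """

    name: str
    z_gate: float
    v_half: float
    power: int
    gamma: float = 0.5
    base_rate: float = 500.0
    tau_min: float = 1.5e-3

    def __post_init__(self):
        if self.power < 0:
            raise ValueError("gate power must be non-negative")
        if self.tau_min <= 0 or self.base_rate <= 0:
            raise ValueError("rates and tau floor must be positive")


def _default_gates() -> tuple[GateParams, ...]:
    # N-type calcium channel preset (Borg-Graham-style parameterization):
    # m^2 activation, h inactivation with a slow tau floor.
    return (
        GateParams(name="m", z_gate=3.4, v_half=-21.0, power=2,
                   gamma=0.5, base_rate=500.0, tau_min=1.5e-3),
        GateParams(name="h", z_gate=-2.0, v_half=-40.0, power=1,
                   gamma=0.5, base_rate=10.0, tau_min=75.0e-3),
    )


@dataclass(frozen=True)
class ChannelParams:
    """N-type VGCC: single-channel GHK permeability plus gating preset."""

    p_x: float = 3.8e-19          # single-channel permeability, m^3/s
    gates: tuple[GateParams, ...] = None
    n_channels: int = 6
    rho_vgcc: float | None = None  # μm^-2; None -> derived from the C area

    def __post_init__(self):
        if self.gates is None:
            object.__setattr__(self, "gates", _default_gates())
        if self.p_x <= 0:
            raise ValueError("permeability must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")

    def with_(self, **kw) -> "ChannelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PumpParams:
    """PMCA / NCX Hill extrusion and the calibrated leak.

    ``I_p``, ``I_x`` are single-transporter turnovers in mol/s; ``H_p``,
    ``H_x`` half-saturation concentrations in μM.  The NCX denominator
    exponent is configurable separately from ``n_x``.
    """

    I_p: float = 8.0e-24
    H_p: float = 0.06          # 60 nM
    n_p: int = 2
    I_x: float = 2.5e-21
    H_x: float = 1.8
    n_x: int = 1
    ncx_denom_exp: int | None = None   # None -> n_x
    rho_pmca: float = 75_000.0  # μm^-2
    rho_ncx: float = 2_500.0    # μm^-2
    leak_density: float = 0.0   # μM·μm/s inward, set by calibrate_leak

    def __post_init__(self):
        if self.n_p < 1 or self.n_x < 1:
            raise ValueError("Hill coefficients must be >= 1")
        if self.rho_pmca < 0 or self.rho_ncx < 0:
            raise ValueError("pump densities must be non-negative")

    def with_(self, **kw) -> "PumpParams":
        return replace(self, **kw)


@dataclass
class GatingState:
    """Values of the gating variables, aligned with ``ChannelParams.gates``."""

    x: np.ndarray

    def copy(self) -> "GatingState":
        return GatingState(x=self.x.copy())


@dataclass(frozen=True)
class APTrainSpec:
    """Periodic action-potential train felt by the channels.

    One spike per period; between spikes the membrane sits at ``v_rest``.
    The waveform is a difference of exponentials with an onset delay within
    each period (the delay places the calcium peak of the default
    parameterization at about 4.2 ms after stimulus onset).
    """

    frequency: float = 40.0      # Hz
    v_rest: float = -70.0        # mV
    v_peak: float = 20.0         # mV
    tau_rise: float = 1.0e-4     # s
    tau_decay: float = 6.0e-4    # s
    t_delay: float = 3.1e-3      # s, onset-to-depolarization delay
    # optional sampled waveform (time s, voltage mV) pairs replacing the
    # analytic template within each period; V_rest outside the samples
    waveform: tuple | None = None

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not (0 < self.tau_rise < self.tau_decay):
            raise ValueError("require 0 < tau_rise < tau_decay")
        if self.waveform is not None:
            object.__setattr__(self, "waveform",
                               tuple((float(t), float(v)) for t, v in self.waveform))
            tt = [t for t, _ in self.waveform]
            if len(tt) < 2 or any(b <= a for a, b in zip(tt, tt[1:])):
                raise ValueError("waveform samples must be strictly increasing in time")
            if tt[-1] >= self.period:
                raise ValueError("waveform support exceeds the spike period")
        else:
            support = self.t_delay + 6 * self.tau_decay
            if support >= self.period:
                raise ValueError("waveform support exceeds the spike period")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def amplitude(self) -> float:
        return self.v_peak - self.v_rest

    def with_(self, **kw) -> "APTrainSpec":
        return replace(self, **kw)

    def spike_onsets(self, t_end: float) -> np.ndarray:
        """Spike onset times k/f in [0, t_end)."""
        n = int(math.floor(t_end / self.period)) + 1
        on = np.arange(n) * self.period
        return on[on < t_end]


def nernst_potential(ca_i: float, ca_e: float, consts: PhysicalConstants | None = None) -> float:
    """Calcium reversal potential (mV)."""
    consts = consts or PhysicalConstants()
    return 1e3 * consts.vt / consts.z * math.log(ca_e / ca_i)


def ghk_flux(v_mv, ca_i_um, ca_e_um, channel: ChannelParams,
             consts: PhysicalConstants | None = None):
    """Goldman-Hodgkin-Katz single-channel current (A).

    Inward current is negative (electrophysiological convention); the flux
    vanishes at the Nernst potential.  A first-order series branch is used
    near V = 0 to avoid the 0/0 of the exponential form.
    """
    consts = consts or PhysicalConstants()
    v = np.asarray(v_mv, dtype=float) * 1e-3
    ci = np.asarray(ca_i_um, dtype=float) * _UM_TO_MOL_M3
    ce = np.asarray(ca_e_um, dtype=float) * _UM_TO_MOL_M3
    z, F = consts.z, consts.F
    u = z * v / consts.vt  # dimensionless

    pzF = channel.p_x * z * F
    small = np.abs(u) < 1e-6
    u_safe = np.where(small, 1.0, u)
    # full GHK: p z F u (ci - ce e^{-u}) / (1 - e^{-u})
    em = -np.expm1(-u_safe)  # 1 - e^{-u}
    full = pzF * u_safe * (ci - ce * np.exp(-u_safe)) / em
    # series: p z F [ (ci-ce) + u (ci+ce)/2 + O(u^2) ]
    series = pzF * ((ci - ce) + 0.5 * u * (ci + ce))
    out = np.where(small, series, full)
    return out if out.ndim else float(out)


def gating_curves(v_mv, gate: GateParams, consts: PhysicalConstants | None = None):
    """Steady state x_inf in (0, 1) and time constant tau >= tau_min (s)."""
    consts = consts or PhysicalConstants()
    v = np.asarray(v_mv, dtype=float) * 1e-3
    d = gate.z_gate * (v - gate.v_half * 1e-3) / consts.vt
    x_inf = 1.0 / (1.0 + np.exp(-d))
    alpha = gate.base_rate * np.exp(gate.gamma * d)
    beta = gate.base_rate * np.exp(-(1.0 - gate.gamma) * d)
    tau = gate.tau_min + 1.0 / (alpha + beta)
    if x_inf.ndim:
        return x_inf, tau
    return float(x_inf), float(tau)


def init_gating(v_mv: float, channel: ChannelParams,
                consts: PhysicalConstants | None = None) -> GatingState:
    """Gating state equilibrated at a holding voltage."""
    vals = [gating_curves(v_mv, g, consts)[0] for g in channel.gates]
    return GatingState(x=np.array(vals, dtype=float))


def step_gating(state: GatingState, v_mv: float, dt: float,
                channel: ChannelParams,
                consts: PhysicalConstants | None = None) -> GatingState:
    """Exact exponential relaxation of each gate for frozen voltage."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    new = np.empty_like(state.x)
    for i, g in enumerate(channel.gates):
        x_inf, tau = gating_curves(v_mv, g, consts)
        new[i] = x_inf + (state.x[i] - x_inf) * math.exp(-dt / tau)
    return GatingState(x=np.clip(new, 0.0, 1.0))


def gating_open_fraction(state: GatingState, channel: ChannelParams) -> float:
    """G = prod_j x_j^{p_j} (the m^a h^b product)."""
    g = 1.0
    for xi, gate in zip(state.x, channel.gates):
        g *= xi ** gate.power
    return float(g)


def vgcc_current(v_mv, state: GatingState, ca_i_um, ca_e_um,
                 channel: ChannelParams, consts: PhysicalConstants | None = None):
    """Per-channel gated current (A): gating product times GHK flux."""
    return gating_open_fraction(state, channel) * ghk_flux(v_mv, ca_i_um, ca_e_um, channel, consts)


def vgcc_molar_influx(v_mv, state, ca_i_um, ca_e_um, channel,
                      consts: PhysicalConstants | None = None):
    """Per-channel inward molar flux in μM·μm³/s (positive into the cell)."""
    consts = consts or PhysicalConstants()
    i_amp = vgcc_current(v_mv, state, ca_i_um, ca_e_um, channel, consts)
    return -i_amp / (consts.z * consts.F) * MOL_TO_UM_UM3


def pmca_flux(ca_i_um, pumps: PumpParams):
    """Per-pump PMCA efflux (mol/s), Hill form with coefficient n_p."""
    c = np.asarray(ca_i_um, dtype=float)
    cn = c ** pumps.n_p
    out = pumps.I_p * cn / (pumps.H_p ** pumps.n_p + cn)
    return out if out.ndim else float(out)


def ncx_flux(ca_i_um, pumps: PumpParams):
    """Per-exchanger NCX efflux (mol/s), Hill numerator n_x."""
    c = np.asarray(ca_i_um, dtype=float)
    nd = pumps.ncx_denom_exp if pumps.ncx_denom_exp is not None else pumps.n_x
    out = pumps.I_x * c ** pumps.n_x / (pumps.H_x ** nd + c ** nd)
    return out if out.ndim else float(out)


def total_membrane_flux(v_mv, state: GatingState, ca_i_um, channel: ChannelParams,
                        pumps: PumpParams, ca_e_um: float,
                        consts: PhysicalConstants | None = None):
    """Composite membrane flux density on the channel zone, μM·μm/s inward.

    rho_VGCC * VGCC influx - rho_PMCA * PMCA - rho_NCX * NCX + leak.
    ``channel.rho_vgcc`` must be set (the scenario layer derives it from the
    discretized channel-zone area).
    """
    if channel.rho_vgcc is None:
        raise ValueError("rho_vgcc is unset; derive it from the channel-zone area first")
    influx = channel.rho_vgcc * vgcc_molar_influx(v_mv, state, ca_i_um, ca_e_um, channel, consts)
    efflux = (pumps.rho_pmca * pmca_flux(ca_i_um, pumps)
              + pumps.rho_ncx * ncx_flux(ca_i_um, pumps)) * MOL_TO_UM_UM3
    return influx - efflux + pumps.leak_density


def calibrate_leak(channel: ChannelParams, pumps: PumpParams, ca_i0_um: float,
                   ca_e_um: float, v_rest_mv: float,
                   consts: PhysicalConstants | None = None) -> PumpParams:
    """Return pump params with the constant leak set so the net membrane flux
    at rest (gates at x_inf(V_rest), Ca at its resting value) is exactly zero.
    """
    zero_leak = pumps.with_(leak_density=0.0)
    state = init_gating(v_rest_mv, channel, consts)
    rest = total_membrane_flux(v_rest_mv, state, ca_i0_um, channel, zero_leak,
                               ca_e_um, consts)
    return pumps.with_(leak_density=-float(rest))


def ap_voltage(t, train: APTrainSpec):
    """Membrane voltage (mV) of the periodic action-potential train."""
    t = np.asarray(t, dtype=float)
    phase = t - np.floor(t * train.frequency) * train.period
    if train.waveform is not None:
        wt = np.array([p[0] for p in train.waveform])
        wv = np.array([p[1] for p in train.waveform])
        v = np.interp(phase, wt, wv, left=train.v_rest, right=train.v_rest)
        return v if v.ndim else float(v)
    s = phase - train.t_delay
    tr, td = train.tau_rise, train.tau_decay
    # normalize the double-exponential to unit peak
    t_pk = math.log(td / tr) / (1.0 / tr - 1.0 / td)
    norm = math.exp(-t_pk / td) - math.exp(-t_pk / tr)
    w = np.where(s > 0, np.exp(-np.maximum(s, 0.0) / td) - np.exp(-np.maximum(s, 0.0) / tr), 0.0)
    v = train.v_rest + train.amplitude * w / norm
    return v if v.ndim else float(v)
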