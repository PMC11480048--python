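"""Digital twin of a hypoxic, carbon-limited fed-batch bioreactor.

The culture is modelled as a two-reaction black box.  Per C-mol of glucose:

* an **oxidative** reaction producing biomass and CO2, consuming O2, and
* a **fermentative** reaction producing biomass, CO2 and a fixed-ratio
  pool of ethanol / arabitol / succinate, consuming no O2.

The stoichiometric coefficients of both reactions are solved from the
configured biomass yields, the biomass elemental formula and the
by-product carbon split, under exact carbon and degree-of-reduction
closure.  Oxygen supply is transfer-limited: kLa follows a power law in
agitation speed, dissolved oxygen is quasi-steady (~0 under hypoxia), and
whatever glucose flux cannot be respired within the transfer capacity is
routed through the fermentative reaction.  The respiratory quotient
RQ = qCO2/qO2 therefore rises above its oxidative value (~1.02) as soon
as oxygen transfer caps the oxidative pathway, which is exactly the
handle the controllers act on through the agitation speed.

Gas measurements pass through a first-order analyser/headspace lag and
multiplicative Gaussian noise; the true state is integrated separately so
that soft sensors can be validated against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .config import (
    MOLAR_VOLUME_L,
    M_C,
    M_H,
    M_N,
    M_O,
    N_MIN_RPM,
    ConfigError,
    Disturbance,
    TwinParams,
)

__all__ = [
    "Stoichiometry",
    "GasBlend",
    "RateVector",
    "ProcessState",
    "FullyAnaerobicError",
    "feed_rate",
    "kla",
    "otr",
    "inlet_blend",
    "metabolic_split",
    "steady_state_rq",
    "required_agitation",
    "calibrate_kla_coefficient",
    "step",
    "simulate",
]

# degrees of reduction per C-mol (O2 per mol): C=+4, H=+1, O=-2, N=-3
GAMMA_GLUCOSE = 4.0
GAMMA_ETHANOL = 6.0
GAMMA_ARABITOL = 4.4
GAMMA_SUCCINATE = 3.5
GAMMA_O2 = 4.0  # electrons accepted per mol O2

# molar masses per C-mol, g
CMOL_MASS = {
    "glucose": (6 * M_C + 12 * M_H + 6 * M_O) / 6,
    "ethanol": (2 * M_C + 6 * M_H + 1 * M_O) / 2,
    "arabitol": (5 * M_C + 12 * M_H + 5 * M_O) / 5,
    "succinate": (4 * M_C + 6 * M_H + 4 * M_O) / 4,
}


class FullyAnaerobicError(RuntimeError):
    """No oxygen transfer while glucose is being consumed: RQ undefined."""


class SimulationError(RuntimeError):
    """A state invariant was violated during integration."""


@dataclass(frozen=True)
class Stoichiometry:
    """Solved coefficients of the oxidative and fermentative reactions.

    All coefficients are per C-mol of glucose.
    """

    biomass_cmol_mass: float   # g/C-mol
    gamma_X: float             # degree of reduction of biomass
    Yc_ox: float               # oxidative biomass carbon yield
    o2_per_cmol_S: float       # O2 demand of fully oxidative growth, mol/C-mol S
    co2_ox: float              # CO2 of the oxidative reaction
    rq_ox: float               # RQ of purely oxidative growth
    Yc_ferm: float             # fermentative biomass carbon yield
    byp_carbon: float          # total by-product carbon, fermentative reaction
    co2_ferm: float            # CO2 of the fermentative reaction
    split: dict                # by-product carbon split (ethanol/arabitol/succinate)

    @classmethod
    def from_params(cls, params: TwinParams) -> "Stoichiometry":
        h, o, n = params.biomass_formula
        m_x = M_C + h * M_H + o * M_O + n * M_N
        gamma_x = 4.0 + h - 2.0 * o - 3.0 * n
        m_s = CMOL_MASS["glucose"]

        yc_ox = params.Y_XS_ox * m_s / m_x
        if not 0 < yc_ox < 1:
            raise ConfigError("oxidative yield gives a carbon yield outside (0, 1)")
        b_o2 = (GAMMA_GLUCOSE - yc_ox * gamma_x) / GAMMA_O2
        if b_o2 <= 0:
            raise ConfigError("oxidative yield too high: negative O2 demand")
        co2_ox = 1.0 - yc_ox
        rq_ox = co2_ox / b_o2
        if not 1.0 <= rq_ox <= 1.1:
            raise ConfigError(
                f"oxidative RQ {rq_ox:.3f} outside the physiological 1.0-1.1 window; "
                "adjust Y_XS_ox or the biomass formula"
            )

        yc_ferm = params.Y_XS_ferm * m_s / m_x
        split = dict(params.byproduct_split)
        gamma_byp = (
            split["ethanol"] * GAMMA_ETHANOL
            + split["arabitol"] * GAMMA_ARABITOL
            + split["succinate"] * GAMMA_SUCCINATE
        )
        byp = (GAMMA_GLUCOSE - yc_ferm * gamma_x) / gamma_byp
        co2_ferm = 1.0 - yc_ferm - byp
        if byp <= 0 or co2_ferm <= 0:
            raise ConfigError(
                "fermentative stoichiometry does not close with positive "
                "by-product and CO2 coefficients; lower Y_XS_ferm"
            )
        return cls(
            biomass_cmol_mass=m_x,
            gamma_X=gamma_x,
            Yc_ox=yc_ox,
            o2_per_cmol_S=b_o2,
            co2_ox=co2_ox,
            rq_ox=rq_ox,
            Yc_ferm=yc_ferm,
            byp_carbon=byp,
            co2_ferm=co2_ferm,
            split=split,
        )

    def rq_of_fraction(self, f_ox: float) -> float:
        """RQ when a fraction ``f_ox`` of glucose is respired oxidatively."""
        if f_ox <= 0:
            raise FullyAnaerobicError("no oxidative flux: RQ undefined")
        qco2 = f_ox * self.co2_ox + (1.0 - f_ox) * self.co2_ferm
        return qco2 / (f_ox * self.o2_per_cmol_S)

    def fraction_for_rq(self, rq: float) -> float:
        """Oxidative glucose fraction achieving a target RQ (inverse map)."""
        if rq < self.rq_ox:
            raise ValueError(f"RQ {rq} below the oxidative limit {self.rq_ox:.3f}")
        denom = rq * self.o2_per_cmol_S - self.co2_ox + self.co2_ferm
        return min(1.0, self.co2_ferm / denom)


@dataclass(frozen=True)
class GasBlend:
    """Inlet gas composition from blending air with pure oxygen."""

    F_air: float          # L/min
    F_O2: float           # L/min
    y_O2_in: float        # molar fraction, dry
    y_CO2_in: float       # molar fraction, dry
    humidity_in: float = 0.0  # %

    @property
    def F_total(self) -> float:
        return self.F_air + self.F_O2


@dataclass(frozen=True)
class RateVector:
    """The seven specific rates plus the product rate, per g DCW per h.

    mu 1/h; qS, qEtOH, qAra, qSuc g/g/h; qO2, qCO2 mol/g/h; qP kAU/g/h.
    """

    mu: float
    qS: float
    qO2: float
    qCO2: float
    qEtOH: float
    qAra: float
    qSuc: float
    qP: float

    @property
    def rq(self) -> float:
        if self.qO2 <= 0:
            return math.nan
        return self.qCO2 / self.qO2


ZERO_RATES = RateVector(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class ProcessState:
    """Instantaneous true state of the simulated culture."""

    t: float                      # h since fed-batch start
    V: float                      # L
    X: float                      # g DCW/L
    S: float                      # residual glucose, g/L
    EtOH: float                   # g/L
    Ara: float                    # g/L
    Suc: float                    # g/L
    P: float                      # product, kAU/L
    N: float                      # agitation, rpm
    DO: float                     # dissolved O2, mol/L
    blend: GasBlend
    rates: RateVector = ZERO_RATES
    y_O2_out: float = 0.0         # true instantaneous dry off-gas fraction
    y_CO2_out: float = 0.0
    y_O2_lag: float = 0.0         # analyser-lagged (noise-free) fractions
    y_CO2_lag: float = 0.0
    y_O2_in_lag: float = 0.0      # inlet reference seen by the off-gas train
    y_CO2_in_lag: float = 0.0
    cum_CO2: float = 0.0          # mol evolved since t=0
    cum_O2: float = 0.0           # mol consumed since t=0
    cum_fed: float = 0.0          # g glucose fed since t=0

    def check(self) -> None:
        conc = (self.V, self.X, self.S, self.EtOH, self.Ara, self.Suc, self.P)
        if any(c < -1e-12 for c in conc):
            raise SimulationError(f"negative concentration/volume at t={self.t:.3f} h")
        for y in (self.y_O2_out, self.y_CO2_out, self.y_O2_lag, self.y_CO2_lag):
            if not -1e-12 <= y <= 1.0 + 1e-12:
                raise SimulationError(f"gas fraction out of [0,1] at t={self.t:.3f} h")


# ----------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------

def feed_rate(t: float, params: TwinParams) -> float:
    """Exponential pre-programmed glucose feed, L/h.

    The base rate F0 = X0*V0*mu_set / (Y_XS_ox*S_feed) delivers the glucose
    demanded by the initial biomass growing oxidatively at mu_set; the
    exponential then tracks the programmed growth.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    f0 = params.X0 * params.V0 * params.mu_set / (params.Y_XS_ox * params.S_feed)
    return f0 * math.exp(params.mu_set * t)


def kla(N: float, params: TwinParams) -> float:
    """Volumetric mass-transfer coefficient, 1/h, power law in agitation."""
    if N <= 0:
        raise ValueError("agitation speed must be positive")
    a, b = params.kla_coeff
    return a * N**b


def otr(kla_val: float, O2_sat: float, DO: float) -> float:
    """Oxygen transfer rate kLa*(O2_sat - DO), mol O2/L/h."""
    if DO < 0 or DO > O2_sat:
        raise ValueError("DO must lie in [0, O2_sat]")
    return kla_val * (O2_sat - DO)


def inlet_blend(F_air: float, F_O2: float, params: TwinParams) -> GasBlend:
    """Blend air with pure O2; inlet fractions are flow-weighted means."""
    if F_air < 0 or F_O2 < 0:
        raise ValueError("flows must be non-negative")
    total = F_air + F_O2
    if total <= 0:
        raise ValueError("total inlet flow must be positive")
    y_o2 = (F_air * params.air_O2_frac + F_O2) / total
    y_co2 = F_air * params.air_CO2_frac / total
    return GasBlend(F_air=F_air, F_O2=F_O2, y_O2_in=y_o2, y_CO2_in=y_co2)


def o2_saturation(params: TwinParams, blend: GasBlend) -> float:
    """Henry-law DO saturation for the current inlet O2 partial pressure."""
    return params.O2_sat * blend.y_O2_in / params.air_O2_frac


#: fraction of the molar O2 supply that uptake may never exceed (the gas
#: phase cannot be driven below ~2% of its inlet O2 content)
SUPPLY_CAP = 0.98


def effective_o2_saturation(params: TwinParams, blend: GasBlend, y_O2_out: float) -> float:
    """DO saturation against the mean of inlet and off-gas O2 partial pressure.

    At high cell densities the gas phase is measurably depleted along the
    reactor, so the transfer driving force falls below the inlet-based
    value; the arithmetic-mean partial pressure is the usual single-tank
    approximation.
    """
    y_mean = 0.5 * (blend.y_O2_in + max(0.0, y_O2_out))
    return params.O2_sat * y_mean / params.air_O2_frac


def _supply_cap_vol(blend: GasBlend, V: float) -> float:
    """Upper bound on volumetric O2 uptake set by the molar supply, mol/L/h."""
    n_in = blend.F_total * 60.0 / MOLAR_VOLUME_L
    return SUPPLY_CAP * n_in * blend.y_O2_in / V


def metabolic_split(
    qS_in: float, otr_cap: float, X: float, params: TwinParams
) -> RateVector:
    """Partition the glucose flux between respiration and fermentation.

    ``qS_in`` is the specific glucose uptake (g/g DCW/h), ``otr_cap`` the
    volumetric oxygen transfer capacity (mol O2/L/h) and ``X`` the biomass
    concentration.  Oxygen uptake is the lesser of the fully-oxidative
    demand and the transfer capacity; the oxidatively unservable glucose
    fraction runs through the fermentative reaction.  Carbon and electron
    balances close exactly by construction.
    """
    if qS_in <= 0 or X <= 0:
        raise ValueError("qS_in and X must be positive")
    if otr_cap < 0:
        raise ValueError("otr_cap must be non-negative")
    st = Stoichiometry.from_params(params)
    qs_c = qS_in / CMOL_MASS["glucose"]          # C-mol/g/h
    demand = st.o2_per_cmol_S * qs_c             # mol O2/g/h, fully oxidative
    cap = otr_cap / X
    if cap <= 0:
        raise FullyAnaerobicError(
            "zero oxygen transfer with ongoing glucose uptake (RQ undefined)"
        )
    f_ox = min(1.0, cap / demand)
    q_o2 = f_ox * demand
    q_co2 = qs_c * (f_ox * st.co2_ox + (1.0 - f_ox) * st.co2_ferm)
    byp = qs_c * (1.0 - f_ox) * st.byp_carbon
    mu = qs_c * (f_ox * st.Yc_ox + (1.0 - f_ox) * st.Yc_ferm) * st.biomass_cmol_mass
    return RateVector(
        mu=mu,
        qS=qS_in,
        qO2=q_o2,
        qCO2=q_co2,
        qEtOH=byp * st.split["ethanol"] * CMOL_MASS["ethanol"],
        qAra=byp * st.split["arabitol"] * CMOL_MASS["arabitol"],
        qSuc=byp * st.split["succinate"] * CMOL_MASS["succinate"],
        qP=params.Y_PX * mu,
    )


def steady_state_rq(
    N: float,
    X: float,
    qS_mass: float,
    params: TwinParams,
    V: float | None = None,
    blend: GasBlend | None = None,
) -> float:
    """RQ of the steady metabolic split at agitation ``N``.

    With ``V`` and ``blend`` given, the transfer capacity accounts for
    gas-side O2 depletion (solved by damped fixed-point iteration on the
    off-gas fraction); otherwise the inlet-based driving force is used.
    """
    if blend is None:
        blend = GasBlend(params.F_air, 0.0, params.air_O2_frac, params.air_CO2_frac)
    if V is None:
        cap = kla(N, params) * o2_saturation(params, blend)
        return metabolic_split(qS_mass, cap, X, params).rq
    k = kla(N, params)
    y_out = blend.y_O2_in
    rates = None
    for _ in range(200):
        cap = min(k * effective_o2_saturation(params, blend, y_out),
                  _supply_cap_vol(blend, V))
        rates = metabolic_split(qS_mass, cap, X, params)
        y_new, _ = _off_gas(blend, rates.qO2 * X * V, rates.qCO2 * X * V)
        if abs(y_new - y_out) < 1e-12:
            y_out = y_new
            break
        y_out = 0.5 * (y_out + y_new)
    return rates.rq


def required_agitation(
    rq_target: float,
    X: float,
    qS_mass: float,
    params: TwinParams,
    V: float | None = None,
    blend: GasBlend | None = None,
    y_O2_in: float | None = None,
) -> float:
    """Agitation speed whose steady-state RQ equals ``rq_target`` (rpm).

    Closed-form inversion of the kLa/OTR/metabolic-split map: the target
    RQ fixes the oxidative glucose fraction, hence the O2 uptake, hence
    (through the gas balance) the off-gas fraction and driving force, and
    finally the kLa and agitation speed.  This is the ground-truth
    supervision signal for the adaptive gain model.
    """
    st = Stoichiometry.from_params(params)
    if blend is None:
        frac = y_O2_in if y_O2_in is not None else params.air_O2_frac
        blend = GasBlend(params.F_air, 0.0, frac, params.air_CO2_frac)
    f_req = st.fraction_for_rq(rq_target)
    qs_c = qS_mass / CMOL_MASS["glucose"]
    q_o2 = f_req * st.o2_per_cmol_S * qs_c       # mol/g/h
    if V is not None:
        if q_o2 * X > _supply_cap_vol(blend, V):
            raise ValueError("target RQ needs more O2 than the gas supply provides")
        q_co2 = qs_c * (f_req * st.co2_ox + (1.0 - f_req) * st.co2_ferm)
        y_out, _ = _off_gas(blend, q_o2 * X * V, q_co2 * X * V)
        sat = effective_o2_saturation(params, blend, y_out)
    else:
        sat = o2_saturation(params, blend)
    kla_req = q_o2 * X / sat
    a, b = params.kla_coeff
    return (kla_req / a) ** (1.0 / b)


def calibrate_kla_coefficient(
    params: TwinParams, N_ref: float = 575.0, rq_ref: float = 1.4
) -> float:
    """Solve the kLa prefactor so the initial state sits at ``rq_ref``.

    At fed-batch start the specific glucose uptake equals
    mu_set/Y_XS_ox; the prefactor is chosen so that agitating at
    ``N_ref`` rpm then yields exactly the reference RQ.  The shipped
    default (a = 5.0391e-4 with b = 2) was frozen from this calibration
    at N_ref = 575 rpm.
    """
    qs0 = params.mu_set / params.Y_XS_ox
    blend = inlet_blend(params.F_air, 0.0, params)
    n_req = required_agitation(rq_ref, params.X0, qs0, params, V=params.V0, blend=blend)
    a, b = params.kla_coeff
    return a * (n_req / N_ref) ** b


# ----------------------------------------------------------------------
# dynamics
# ----------------------------------------------------------------------

def initial_state(params: TwinParams, N0: float, blend: GasBlend | None = None) -> ProcessState:
    if blend is None:
        blend = inlet_blend(params.F_air, 0.0, params)
    # analyser starts reading the inlet composition (fresh headspace)
    return ProcessState(
        t=0.0, V=params.V0, X=params.X0, S=0.0, EtOH=0.0, Ara=0.0, Suc=0.0,
        P=0.0, N=N0, DO=0.0, blend=blend,
        y_O2_out=blend.y_O2_in, y_CO2_out=blend.y_CO2_in,
        y_O2_lag=blend.y_O2_in, y_CO2_lag=blend.y_CO2_in,
        y_O2_in_lag=blend.y_O2_in, y_CO2_in_lag=blend.y_CO2_in,
    )


def _off_gas(blend: GasBlend, our_total: float, cer_total: float) -> tuple[float, float]:
    """True dry off-gas fractions from the gas-phase mole balance.

    ``our_total``/``cer_total`` in mol/h for the whole broth volume.
    """
    n_in = blend.F_total * 60.0 / MOLAR_VOLUME_L  # mol/h
    o2_out = n_in * blend.y_O2_in - our_total
    co2_out = n_in * blend.y_CO2_in + cer_total
    inert = n_in * (1.0 - blend.y_O2_in - blend.y_CO2_in)
    n_out = o2_out + co2_out + inert
    return o2_out / n_out, co2_out / n_out


def step(
    state: ProcessState,
    action,  # ControlAction | None
    params: TwinParams,
    dt: float,
    rng: np.random.Generator | None = None,
    substeps: int = 4,
) -> tuple[ProcessState, dict]:
    """Advance the twin by ``dt`` hours.

    Returns the new true state together with the noisy *measured*
    channels (wet-basis gas fractions, humidity) sampled at the end of
    the interval.  The measured channels are the only place noise enters;
    the true state is integrated deterministically.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = replace(state)
    if action is not None and getattr(action, "delta_rpm", 0.0):
        s.N = max(N_MIN_RPM, s.N + action.delta_rpm)
    h = dt / substeps
    tau_h = params.gas_lag_tau_min / 60.0
    for _ in range(substeps):
        f = feed_rate(s.t, params)
        fed = f * params.S_feed * h                      # g glucose this substep
        available = fed + s.S * s.V
        uptake = min(params.qS_max * s.X * s.V * h, available)
        v_new = s.V + f * h

        if uptake > 0:
            qs_mass = uptake / (s.X * s.V * h)
            # driving force against the (one-substep-lagged) off-gas fraction
            sat = effective_o2_saturation(params, s.blend, s.y_O2_out)
            cap = min(kla(s.N, params) * sat, _supply_cap_vol(s.blend, s.V))
            rates = metabolic_split(qs_mass, cap, s.X, params)
            uptake_vol = rates.qO2 * s.X
            if uptake_vol < cap:                         # transfer not limiting
                s.DO = max(0.0, sat - uptake_vol / kla(s.N, params))
            else:
                s.DO = 0.0
        else:
            rates = ZERO_RATES
            s.DO = o2_saturation(params, s.blend)

        xv = s.X * s.V
        biomass = xv + rates.mu * xv * h
        s.EtOH = (s.EtOH * s.V + rates.qEtOH * xv * h) / v_new
        s.Ara = (s.Ara * s.V + rates.qAra * xv * h) / v_new
        s.Suc = (s.Suc * s.V + rates.qSuc * xv * h) / v_new
        s.P = (s.P * s.V + rates.qP * xv * h) / v_new
        s.S = max(0.0, available - uptake) / v_new
        s.cum_CO2 += rates.qCO2 * xv * h
        s.cum_O2 += rates.qO2 * xv * h
        s.cum_fed += fed
        s.V = v_new
        s.X = biomass / v_new
        s.rates = rates

        our_tot = rates.qO2 * s.X * s.V
        cer_tot = rates.qCO2 * s.X * s.V
        s.y_O2_out, s.y_CO2_out = _off_gas(s.blend, our_tot, cer_tot)
        # first-order analyser/headspace lag; the inlet reference used by
        # the soft sensor relaxes with the same time constant, since the
        # analysed off-gas corresponds to inlet gas from ~tau earlier
        s.y_O2_lag += (s.y_O2_out - s.y_O2_lag) * h / tau_h
        s.y_CO2_lag += (s.y_CO2_out - s.y_CO2_lag) * h / tau_h
        s.y_O2_in_lag += (s.blend.y_O2_in - s.y_O2_in_lag) * h / tau_h
        s.y_CO2_in_lag += (s.blend.y_CO2_in - s.y_CO2_in_lag) * h / tau_h
        s.t += h
    s.check()

    wet = 1.0 - params.humidity_out / 100.0
    noise = {"o2_signal": 0.0, "co2_signal": 0.0, "humidity": 0.0}
    if rng is not None:
        for key in noise:
            noise[key] = params.noise_rsd.get(key, 0.0) * rng.standard_normal()
    # noise perturbs the respiration *signals* (depletion/enrichment against
    # the inlet reference), so the derived OUR/CER carry the configured RSD
    o2_signal = (s.y_O2_in_lag - s.y_O2_lag) * (1.0 + noise["o2_signal"])
    co2_signal = (s.y_CO2_lag - s.y_CO2_in_lag) * (1.0 + noise["co2_signal"])
    measured = {
        "y_O2_meas": (s.y_O2_in_lag - o2_signal) * wet,
        "y_CO2_meas": (s.y_CO2_in_lag + co2_signal) * wet,
        "humidity_meas": params.humidity_out * (1.0 + noise["humidity"]),
        "y_O2_in_meas": s.y_O2_in_lag,
        "y_CO2_in_meas": s.y_CO2_in_lag,
    }
    return s, measured


def simulate(
    controller,
    params: TwinParams,
    horizon_h: float,
    seed: int | None = 0,
    disturbances: Sequence[Disturbance] = (),
    noise: bool = True,
    sample_min: float = 1.0,
    substeps: int = 4,
):
    """Run the closed loop at 1-min sampling and return a FermLog.

    ``controller`` follows the policy protocol of
    :mod:`rqcontrol.controllers` (``reset()`` and ``decide(t, rq, ctx)``).
    Identical seed and configuration give bit-identical logs.  If the
    controller raises, the partial log is returned with the error
    recorded in its metadata.
    """
    from .io import FermLog
    from .soft_sensors import CalibRecord, GasReading, correct_reading, off_gas_rates

    if horizon_h <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(seed) if noise else None
    controller.reset()
    n0 = controller.initial_N
    state = initial_state(params, n0)
    dist = sorted(disturbances, key=lambda d: d.t)
    next_dist = 0

    dt = sample_min / 60.0
    n_steps = int(round(horizon_h / dt))
    rows = []
    rq_window: list[float] = []
    smooth_w = getattr(controller, "rq_smoothing_window", 1)
    error: str | None = None

    # initial measured snapshot (no respiration has reached the analyser yet)
    wet = 1.0 - params.humidity_out / 100.0
    measured = {
        "y_O2_meas": state.y_O2_lag * wet,
        "y_CO2_meas": state.y_CO2_lag * wet,
        "humidity_meas": params.humidity_out,
        "y_O2_in_meas": state.y_O2_in_lag,
        "y_CO2_in_meas": state.y_CO2_in_lag,
    }

    for i in range(n_steps + 1):
        t = i * dt
        while next_dist < len(dist) and t >= dist[next_dist].t - 1e-9:
            d = dist[next_dist]
            state.blend = inlet_blend(d.F_air, d.F_O2, params)
            next_dist += 1

        sensor_blend = GasBlend(
            F_air=state.blend.F_air,
            F_O2=state.blend.F_O2,
            y_O2_in=measured["y_O2_in_meas"],
            y_CO2_in=measured["y_CO2_in_meas"],
        )
        reading = GasReading(
            t=t,
            y_O2_out=measured["y_O2_meas"],
            y_CO2_out=measured["y_CO2_meas"],
            humidity_out=measured["humidity_meas"],
            blend=sensor_blend,
            F_total_in=state.blend.F_total,
            calib=CalibRecord(),
        )
        gas = off_gas_rates(correct_reading(reading), state.V, our_floor=params.our_floor)
        rq_window.append(gas.RQ)
        if len(rq_window) > smooth_w:
            rq_window.pop(0)
        finite = [v for v in rq_window if math.isfinite(v)]
        rq_ctrl = float(np.mean(finite)) if finite else math.nan

        f_now = feed_rate(t, params)
        ctx = {
            "t": t,
            "N": state.N,
            "RQ": rq_ctrl,
            "OUR": gas.OUR,
            "CER": gas.CER,
            "feed_rate": f_now,
            "cum_glucose_fed": state.cum_fed,
            "y_O2_in": state.blend.y_O2_in,
            "total_biomass": state.X * state.V,
        }
        try:
            act = controller.decide(t, rq_ctrl, ctx)
        except Exception as exc:  # abort with partial log
            error = f"controller raised at t={t:.3f} h: {exc!r}"
            act = None

        rows.append(
            {
                "t": t,
                "N": state.N,
                "feed_rate": f_now,
                "V": state.V,
                "X": state.X,
                "S": state.S,
                "EtOH": state.EtOH,
                "Ara": state.Ara,
                "Suc": state.Suc,
                "P": state.P,
                "DO": state.DO,
                "F_air": state.blend.F_air,
                "F_O2": state.blend.F_O2,
                "y_O2_in": state.blend.y_O2_in,
                "y_CO2_in": state.blend.y_CO2_in,
                "qS_true": state.rates.qS,
                "y_O2_true": state.y_O2_out,
                "y_CO2_true": state.y_CO2_out,
                "OUR_true": state.rates.qO2 * state.X,
                "CER_true": state.rates.qCO2 * state.X,
                "RQ_true": state.rates.rq,
                "y_O2_meas": measured["y_O2_meas"],
                "y_CO2_meas": measured["y_CO2_meas"],
                "humidity_meas": measured["humidity_meas"],
                "OUR_meas": gas.OUR,
                "CER_meas": gas.CER,
                "RQ_meas": gas.RQ,
                "RQ_ctrl": rq_ctrl,
                "cum_fed": state.cum_fed,
                "cum_CO2": state.cum_CO2,
                "cum_O2": state.cum_O2,
                "action_delta": act.delta_rpm if act is not None else 0.0,
                "action_rule": act.rule if act is not None else "NONE",
                "epsilon": act.epsilon if act is not None else math.nan,
                "K_P": act.K_P if act is not None else math.nan,
            }
        )
        if error is not None or i == n_steps:
            break
        state, measured = step(state, act, params, dt, rng=rng, substeps=substeps)

    import pandas as pd

    meta = {
        "seed": seed,
        "controller": type(controller).__name__,
        "mu_set": params.mu_set,
        "noise": noise,
    }
    if error is not None:
        meta["error"] = error
    return FermLog(pd.DataFrame(rows), meta=meta)
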