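"""Configuration objects for the twin, controllers, and analysis modules.

All tunable quantities of the package live here as frozen-by-convention
dataclasses with validated defaults.  A run is fully described by a
:class:`RunConfig`, which can be round-tripped through YAML and hashed so
that every fermentation log records the exact configuration that produced
it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import yaml

# Atomic masses (g/mol) used for all C-mol bookkeeping.
M_C, M_H, M_O, M_N = 12.011, 1.008, 15.999, 14.007

#: Molar gas volume (L/mol) at the reference conditions of the gas
#: analyser train: 1 atm, 25 degC (the cultivation temperature).
MOLAR_VOLUME_L = 24.466

#: Agitation floor (rpm); controllers may never drive the stirrer below it.
N_MIN_RPM = 100.0


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class TwinParams:
    """Parameters of the digital-twin fed-batch bioreactor.

    The twin represents a carbon-limited *Pichia pastoris* fed-batch
    driven into hypoxia: an exponential glucose feed fixes the specific
    growth rate, while the oxygen transfer capacity (set by agitation
    through kLa) decides how much of the glucose flux is respired versus
    fermented to ethanol/arabitol/succinate.

    Units follow bioprocess convention: concentrations g/L, rates per
    gram dry cell weight per hour, gas quantities in moles.
    """

    mu_set: float = 0.10          # target specific growth rate, 1/h
    S_feed: float = 400.0         # feed glucose concentration, g/L
    X0: float = 25.0              # biomass at batch end, g DCW/L
    V0: float = 2.0               # initial broth volume, L
    Y_XS_ox: float = 0.50         # oxidative biomass yield, g DCW/g glucose
    Y_XS_ferm: float = 0.25       # fermentative biomass yield, g DCW/g glucose
    # carbon fractions of the fermentative by-product pool
    byproduct_split: Mapping[str, float] = field(
        default_factory=lambda: {"ethanol": 0.85, "arabitol": 0.10, "succinate": 0.05}
    )
    Y_PX: float = 3.8             # growth-associated product yield, kAU/g DCW
    kla_coeff: tuple[float, float] = (5.0391e-4, 2.0)  # kLa = a * N**b, 1/h with N in rpm
    O2_sat: float = 2.5e-4        # DO at air saturation, mol O2/L
    gas_lag_tau_min: float = 7.0  # analyser + headspace first-order lag, min
    # multiplicative RSD of the measured respiration signals (inlet-outlet
    # O2 depletion and CO2 enrichment) and of the humidity channel; sized so
    # the calculated OUR/CER carry ~1.5% RSD and RQ ~2%
    noise_rsd: Mapping[str, float] = field(
        default_factory=lambda: {"o2_signal": 0.015, "co2_signal": 0.015, "humidity": 0.02}
    )
    air_O2_frac: float = 0.2097   # dry-air O2 molar fraction
    air_CO2_frac: float = 0.0004  # dry-air CO2 molar fraction
    humidity_out: float = 2.0     # off-gas molar water content after drying, %
    # biomass elemental formula C H_x O_y N_z (literature-typical yeast;
    # the organism's measured composition is not published)
    biomass_formula: tuple[float, float, float] = (1.761, 0.636, 0.143)
    qS_max: float = 0.30          # glucose uptake saturation, g/g DCW/h
    F_air: float = 2.0            # default airflow, L/min
    our_floor: float = 2e-3       # OUR below which RQ is reported undefined, mol/L/h

    def __post_init__(self) -> None:
        if self.mu_set <= 0:
            raise ConfigError("mu_set must be positive")
        if not 0 < self.Y_XS_ferm < self.Y_XS_ox:
            raise ConfigError("need 0 < Y_XS_ferm < Y_XS_ox")
        if not 0 < self.air_O2_frac < 1:
            raise ConfigError("air_O2_frac must be a molar fraction in (0, 1)")
        if self.gas_lag_tau_min <= 0:
            raise ConfigError("gas_lag_tau_min must be positive")
        split_sum = sum(self.byproduct_split.values())
        if abs(split_sum - 1.0) > 1e-9:
            raise ConfigError(f"byproduct_split must sum to 1, got {split_sum}")
        a, b = self.kla_coeff
        if a <= 0 or b <= 0:
            raise ConfigError("kla_coeff entries must be positive")
        if not 0 <= self.humidity_out < 100:
            raise ConfigError("humidity_out must be in [0, 100) %")
        # Solving the two-reaction stoichiometry validates that the yields
        # admit carbon- and electron-closed reactions (raises otherwise).
        from .twin import Stoichiometry  # local import to avoid a cycle

        Stoichiometry.from_params(self)


@dataclass
class StepScheduleConfig:
    """Piecewise-constant agitation step magnitude over fed-batch time."""

    breakpoints: Sequence[tuple[float, float]] = ((0.0, 10.0),)

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.breakpoints]
        if ts != sorted(ts) or (ts and ts[0] != 0.0):
            raise ConfigError("schedule breakpoints must start at 0 and increase")
        if any(d <= 0 for _, d in self.breakpoints):
            raise ConfigError("schedule step magnitudes must be positive")


@dataclass
class ControllerConfig:
    """Settings shared by the three RQ control policies."""

    type: str = "blc"             # one of {"mhc", "blc", "apc", "none"}
    set_point: float = 1.4
    initial_N: float | None = None  # rpm; policy default used when None
    # manual-heuristic policy
    mhc_threshold: float = 1.6
    mhc_check_interval_min: float = 30.0
    # step escalates with the exponential demand (roughly N/8 over the run),
    # mirroring how manual actions grow through a fed-batch
    mhc_schedule: StepScheduleConfig = field(
        default_factory=lambda: StepScheduleConfig(((0.0, 50.0), (5.0, 100.0)))
    )
    # Boolean-logic policy
    blc_up_threshold: float = 1.4
    blc_down_threshold: float = 1.3
    blc_check_interval_min: float = 10.0
    blc_up_schedule: StepScheduleConfig = field(
        default_factory=lambda: StepScheduleConfig(((0.0, 10.0), (7.0, 15.0), (14.0, 25.0)))
    )
    blc_down_step: float = 10.0
    # adaptive-proportional policy
    apc_min_action_gap_min: float = 7.0
    apc_deadband_rpm: float = 2.0
    apc_kp_range: tuple[float, float] = (0.0, 600.0)
    rq_smoothing_window: int = 3  # per-minute samples averaged before control

    def __post_init__(self) -> None:
        if self.type not in {"mhc", "blc", "apc", "none"}:
            raise ConfigError(f"unknown controller type {self.type!r}")
        if self.set_point <= 0:
            raise ConfigError("set_point must be positive")
        if self.blc_down_threshold >= self.blc_up_threshold:
            raise ConfigError("BLC deadband requires down < up threshold")
        if self.apc_kp_range[0] < 0 or self.apc_kp_range[0] >= self.apc_kp_range[1]:
            raise ConfigError("apc_kp_range must be a non-negative increasing pair")
        if self.rq_smoothing_window < 1:
            raise ConfigError("rq_smoothing_window must be >= 1")

    def default_initial_N(self) -> float:
        if self.initial_N is not None:
            return self.initial_N
        return 600.0 if self.type == "mhc" else 550.0


@dataclass
class GainModelConfig:
    """Training protocol of the random-forest adaptive gain."""

    n_trees: int = 100
    min_samples_leaf: int = 2
    max_features: str = "sqrt"
    corpus_mu_values: Sequence[float] = (0.08, 0.10, 0.12)
    corpus_strategies: Sequence[str] = ("mhc", "blc")
    row_interval_min: float = 10.0  # one training row per control instant
    min_time_h: float = 0.5         # skip the low-signal startup window
    features: Sequence[str] = (
        "t",
        "N",
        "RQ",
        "OUR",
        "CER",
        "feed_rate",
        "cum_glucose_fed",
        "y_O2_in",
        "total_biomass",
    )

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if len(self.corpus_mu_values) < 2 or len(self.corpus_strategies) < 2:
            raise ConfigError("training corpus needs >=2 mu values and >=2 strategies")


@dataclass
class MetricsConfig:
    """Evaluation windows and bands for controller statistics."""

    band: tuple[float, float] = (1.2, 1.6)
    recovery_band: tuple[float, float] = (1.3, 1.5)
    recovery_dwell_min: float = 10.0
    exclusion_start_h: float = 0.0  # samples before this time are ignored


@dataclass
class ReconciliationConfig:
    """Measurement RSDs and test level for rate reconciliation."""

    confidence: float = 0.95
    rate_rsd: Mapping[str, float] = field(
        default_factory=lambda: {
            "mu": 0.05,     # dry-cell-weight based
            "qS": 0.02,     # HPLC
            "qO2": 0.05,    # gas analysis
            "qCO2": 0.05,   # gas analysis
            "qEtOH": 0.02,  # HPLC
            "qAra": 0.02,   # HPLC
            "qSuc": 0.02,   # HPLC
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise ConfigError("confidence must be in (0, 1)")
        if any(v <= 0 for v in self.rate_rsd.values()):
            raise ConfigError("rate RSDs must be positive")


@dataclass
class Disturbance:
    """A scheduled change of the inlet gas blend."""

    t: float          # fed-batch time, h
    F_air: float      # L/min
    F_O2: float       # L/min


#: The inlet O2-enrichment step used in the adaptive-control experiment:
#: at t = 13.3 h air is cut to 1.8 L/min and 0.2 L/min pure O2 is added.
O2_ENRICHMENT = Disturbance(t=13.3, F_air=1.8, F_O2=0.2)


@dataclass
class RunConfig:
    """Everything needed to reproduce a closed-loop run bit-for-bit."""

    twin: TwinParams = field(default_factory=TwinParams)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    gain_model: GainModelConfig = field(default_factory=GainModelConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    reconciliation: ReconciliationConfig = field(default_factory=ReconciliationConfig)
    seed: int = 0
    horizon_h: float = 20.0
    disturbances: Sequence[Disturbance] = ()

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTION_TYPES = {
    "twin": TwinParams,
    "controller": ControllerConfig,
    "gain_model": GainModelConfig,
    "metrics": MetricsConfig,
    "reconciliation": ReconciliationConfig,
}


def _build_section(cls, data: dict):
    import dataclasses

    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = known[key].type
        if "StepScheduleConfig" in str(ftype):
            if isinstance(value, dict):
                value = value.get("breakpoints", ())
            value = StepScheduleConfig(tuple(tuple(bp) for bp in value))
        elif isinstance(value, list) and key in {"kla_coeff", "apc_kp_range",
                                                 "band", "recovery_band",
                                                 "biomass_formula"}:
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str) -> RunConfig:
    """Read a RunConfig from a YAML file, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - (set(_SECTION_TYPES) | {"seed", "horizon_h", "disturbances"})
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name] or {})
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "horizon_h" in raw:
        kwargs["horizon_h"] = float(raw["horizon_h"])
    if "disturbances" in raw:
        kwargs["disturbances"] = tuple(
            Disturbance(**d) for d in raw["disturbances"]
        )
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def with_mu(params: TwinParams, mu: float) -> TwinParams:
    """Copy of ``params`` with a different feed-programmed growth rate."""
    return replace(params, mu_set=mu)
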