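"""Off-gas soft sensors: OUR, CER and the respiratory quotient.

Given calibrated, humidity-corrected inlet and outlet gas fractions, the
outlet molar flow is recovered from the inert (N2) balance — the only
formulation that stays correct when the inlet is enriched with pure
oxygen — and the volumetric uptake/evolution rates follow from the O2 and
CO2 mole balances.  A configurable OUR floor guards the early fed-batch
regime where both respiration signals are so small that the RQ quotient
would amplify analyser errors: below the floor the RQ is reported as
undefined (NaN) instead of a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .config import MOLAR_VOLUME_L
from .twin import GasBlend

__all__ = [
    "CalibRecord",
    "GasReading",
    "GasRates",
    "correct_reading",
    "off_gas_rates",
    "rq_simple_ratio",
    "specific_rates",
]


@dataclass(frozen=True)
class CalibRecord:
    """Per-channel offset/span of the gas analyser (identity by default)."""

    offset_O2: float = 0.0
    span_O2: float = 1.0
    offset_CO2: float = 0.0
    span_CO2: float = 1.0

    def __post_init__(self) -> None:
        if self.span_O2 <= 0 or self.span_CO2 <= 0:
            raise ValueError("calibration spans must be positive")


@dataclass
class GasReading:
    """One off-gas analyser sample plus the inlet blend it refers to."""

    t: float                  # h
    y_O2_out: float           # measured molar fraction (wet unless corrected)
    y_CO2_out: float
    humidity_out: float       # molar % water in the analysed stream
    blend: GasBlend
    F_total_in: float         # L/min at reference conditions
    calib: CalibRecord = field(default_factory=CalibRecord)
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.F_total_in <= 0:
            raise ValueError("inlet flow must be positive")


@dataclass(frozen=True)
class GasRates:
    """Volumetric respiration rates; RQ is NaN when OUR is below the floor."""

    OUR: float  # mol O2/L/h
    CER: float  # mol CO2/L/h
    RQ: float


def correct_reading(raw: GasReading) -> GasReading:
    """Apply span/offset calibration and convert wet to dry fractions."""
    if raw.humidity_out >= 100.0:
        raise ValueError("humidity must be < 100 %")
    dry = 1.0 - raw.humidity_out / 100.0
    y_o2 = (raw.calib.offset_O2 + raw.calib.span_O2 * raw.y_O2_out) / dry
    y_co2 = (raw.calib.offset_CO2 + raw.calib.span_CO2 * raw.y_CO2_out) / dry
    return replace(
        raw, y_O2_out=y_o2, y_CO2_out=y_co2, humidity_out=0.0, corrected=True
    )


def off_gas_rates(reading: GasReading, V: float, our_floor: float = 0.0) -> GasRates:
    """OUR, CER and RQ from the inert-gas (N2) balance.

    F_out = F_in * (1 - y_O2_in - y_CO2_in) / (1 - y_O2_out - y_CO2_out);
    rates are normalised by the broth volume ``V`` (L) using the molar
    volume at reference conditions.
    """
    if V <= 0:
        raise ValueError("broth volume must be positive")
    blend = reading.blend
    inert_out = 1.0 - reading.y_O2_out - reading.y_CO2_out
    if inert_out <= 0:
        raise ValueError("outlet fractions leave no inert gas")
    n_in = reading.F_total_in * 60.0 / MOLAR_VOLUME_L  # mol/h
    n_out = n_in * (1.0 - blend.y_O2_in - blend.y_CO2_in) / inert_out
    our = (n_in * blend.y_O2_in - n_out * reading.y_O2_out) / V
    cer = (n_out * reading.y_CO2_out - n_in * blend.y_CO2_in) / V
    rq = cer / our if our > our_floor else math.nan
    return GasRates(OUR=our, CER=cer, RQ=rq)


def rq_simple_ratio(reading: GasReading) -> float:
    """RQ from the raw fraction differences, ignoring the flow change.

    Provided as the naive alternative to the inert-balance estimate; it
    is biased whenever OUR and CER differ (i.e. whenever RQ != 1).
    """
    d_o2 = reading.blend.y_O2_in - reading.y_O2_out
    if d_o2 <= 0:
        return math.nan
    return (reading.y_CO2_out - reading.blend.y_CO2_in) / d_o2


def specific_rates(rates: GasRates, X: float) -> tuple[float, float]:
    """Per-biomass rates (qO2, qCO2) in mol/g DCW/h."""
    if X <= 0:
        raise ValueError("biomass must be positive")
    return rates.OUR / X, rates.CER / X
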