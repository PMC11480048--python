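"""Consistency checking and reconciliation of the seven specific rates.

The black-box description of the culture measures growth, glucose uptake,
O2 uptake, CO2 evolution and the three by-product rates.  Two linear
constraints must hold exactly for a consistent data set: the carbon
balance and the degree-of-reduction (electron) balance (the lipase rate
is negligible for both).  Measured rates are adjusted by the standard
weighted-least-squares projection onto the constraint null space, with a
chi-square test on the balance residuals deciding, at a configurable
confidence level, whether the raw measurements contain gross errors.

Degrees of reduction use the convention C=+4, H=+1, O=-2, N=-3 (ammonia
as nitrogen source, so NH3 carries zero reducing power).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from scipy import stats

from .config import M_C, M_H, M_N, M_O, ReconciliationConfig
from .twin import RateVector

__all__ = [
    "SpeciesComposition",
    "load_composition_table",
    "MeasuredRates",
    "ReconciliationResult",
    "carbon_balance_gap",
    "electron_balance_gap",
    "reconcile",
    "measured_from_rates",
]

#: rates entering the balances, in order (qP excluded: negligible carbon)
RATE_NAMES = ("mu", "qS", "qO2", "qCO2", "qEtOH", "qAra", "qSuc")

#: species carried by each rate
RATE_SPECIES = {
    "mu": "biomass",
    "qS": "glucose",
    "qO2": "o2",
    "qCO2": "co2",
    "qEtOH": "ethanol",
    "qAra": "arabitol",
    "qSuc": "succinate",
}

#: balance sign: substrates consumed (-1), products formed (+1); O2 enters
#: the electron balance on the product side (electrons transferred to O2)
RATE_SIGN = {"mu": 1, "qS": -1, "qO2": 1, "qCO2": 1, "qEtOH": 1, "qAra": 1, "qSuc": 1}


@dataclass(frozen=True)
class SpeciesComposition:
    """Elemental composition per C-mol (per mol for carbon-free species)."""

    c: float
    h: float
    o: float
    n: float

    @property
    def gamma(self) -> float:
        return 4.0 * self.c + self.h - 2.0 * self.o - 3.0 * self.n

    @property
    def cmol_mass(self) -> float:
        mass = self.c * M_C + self.h * M_H + self.o * M_O + self.n * M_N
        return mass / self.c if self.c > 0 else mass


def load_composition_table() -> dict[str, SpeciesComposition]:
    """Read the packaged species composition table."""
    table: dict[str, SpeciesComposition] = {}
    path = resources.files("rqcontrol").joinpath("data/species_composition.csv")
    with path.open() as fh:
        for row in csv.DictReader(fh):
            table[row["species"]] = SpeciesComposition(
                c=float(row["c"]), h=float(row["h"]),
                o=float(row["o"]), n=float(row["n"]),
            )
    return table


@dataclass
class MeasuredRates:
    """Measured specific rates with their standard deviations.

    ``values`` uses the natural units of :class:`~rqcontrol.twin.RateVector`
    (mu 1/h; qS/qEtOH/qAra/qSuc g/g/h; qO2/qCO2 mol/g/h); all are
    positive magnitudes — consumption signs live in the balance matrix.
    """

    values: Mapping[str, float]
    sd: Mapping[str, float]
    composition: Mapping[str, SpeciesComposition] = field(
        default_factory=load_composition_table
    )

    def __post_init__(self) -> None:
        missing = set(RATE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing rates: {sorted(missing)}")
        for name in RATE_NAMES:
            if self.values[name] != 0 and RATE_SPECIES[name] not in self.composition:
                raise ValueError(f"no composition for species of {name}")
            if self.sd.get(name, 0.0) <= 0:
                raise ValueError(f"standard deviation for {name} must be positive")

    def vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in RATE_NAMES], dtype=float)

    def sd_vector(self) -> np.ndarray:
        return np.array([self.sd[n] for n in RATE_NAMES], dtype=float)


@dataclass(frozen=True)
class ReconciliationResult:
    reconciled: RateVector
    residual: np.ndarray      # adjustments applied, natural units
    chi2: float
    dof: int
    consistent: bool
    confidence: float


def _balance_matrix(composition: Mapping[str, SpeciesComposition]) -> np.ndarray:
    """Rows: carbon and electron balance; columns: RATE_NAMES.

    Coefficients convert each rate from its natural unit to C-mol (or mol
    O2) per g DCW per h, signed by consumption/production.
    """
    rows = []
    for balance in ("carbon", "electron"):
        row = []
        for name in RATE_NAMES:
            comp = composition[RATE_SPECIES[name]]
            if name in ("qO2", "qCO2"):
                per_cmol = 1.0  # already molar
            else:
                per_cmol = 1.0 / comp.cmol_mass
            if balance == "carbon":
                coeff = comp.c * per_cmol
            else:
                coeff = comp.gamma * per_cmol if name != "qO2" else 4.0
            row.append(RATE_SIGN[name] * coeff)
        rows.append(row)
    return np.asarray(rows)


def carbon_balance_gap(m: MeasuredRates) -> float:
    """Relative carbon-balance closure gap |C_in - C_out| / C_in."""
    if m.values["qS"] <= 0:
        raise ValueError("carbon gap undefined without substrate uptake")
    a = _balance_matrix(m.composition)[0]
    r = m.vector()
    c_in = -a[RATE_NAMES.index("qS")] * r[RATE_NAMES.index("qS")]
    residual = float(a @ r)
    return abs(residual) / c_in


def electron_balance_gap(m: MeasuredRates) -> float:
    """Relative degree-of-reduction gap, normalised by substrate electrons."""
    if m.values["qS"] <= 0:
        raise ValueError("electron gap undefined without substrate uptake")
    a = _balance_matrix(m.composition)[1]
    r = m.vector()
    e_in = -a[RATE_NAMES.index("qS")] * r[RATE_NAMES.index("qS")]
    return abs(float(a @ r)) / e_in


def reconcile(m: MeasuredRates, confidence: float = 0.95) -> ReconciliationResult:
    """Weighted-least-squares projection onto the balance subspace.

    Minimises (r - m)' diag(sd)^-2 (r - m) subject to A r = 0 and tests
    chi2 = (A m)' (A Sigma A')^-1 (A m) against the chi-square quantile
    with dof equal to the number of independent balances.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    a = _balance_matrix(m.composition)
    if np.linalg.matrix_rank(a) < a.shape[0]:
        raise ValueError("balance constraints are rank deficient")
    r = m.vector()
    sigma = np.diag(m.sd_vector() ** 2)
    gram = a @ sigma @ a.T
    residual_balance = a @ r
    adjust = sigma @ a.T @ np.linalg.solve(gram, residual_balance)
    reconciled = r - adjust
    chi2 = float(residual_balance @ np.linalg.solve(gram, residual_balance))
    dof = a.shape[0]
    threshold = stats.chi2.ppf(confidence, dof)
    vals = dict(zip(RATE_NAMES, reconciled))
    rec = RateVector(**vals, qP=0.0)
    return ReconciliationResult(
        reconciled=rec,
        residual=adjust,
        chi2=chi2,
        dof=dof,
        consistent=bool(chi2 <= threshold),
        confidence=confidence,
    )


def measured_from_rates(
    rates: RateVector,
    config: ReconciliationConfig | None = None,
    rng: np.random.Generator | None = None,
    composition: Mapping[str, SpeciesComposition] | None = None,
) -> MeasuredRates:
    """Wrap a twin rate vector as measured data at the configured RSDs.

    With ``rng`` given, each rate is perturbed by independent multiplicative
    Gaussian noise at its RSD — the synthetic analogue of one round of
    offline analytics on a physically consistent culture state.
    """
    config = config or ReconciliationConfig()
    values = {}
    sds = {}
    for name in RATE_NAMES:
        true = getattr(rates, name)
        rsd = config.rate_rsd[name]
        sd = max(rsd * abs(true), 1e-12)
        noisy = true * (1.0 + rsd * rng.standard_normal()) if rng is not None else true
        values[name] = noisy
        sds[name] = sd
    kwargs = {} if composition is None else {"composition": composition}
    return MeasuredRates(values=values, sd=sds, **kwargs)
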