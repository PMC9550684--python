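"""Drug pharmacokinetics and pharmacodynamics.

Plasma PK is linear multi-dose superposition of one- or two-compartment
bolus decays; the cell-kill response to local drug concentration is a Hill
law bounded by kill_max.  All internal time is hours; regimen calendars are
authored in days and converted on ingestion (24 h/day).

The shipped drug library (data/drugs.yaml) carries literature-order default
parameters authored for this package; every value is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

HOURS_PER_DAY = 24.0


@dataclass
class DrugModel:
    """PK/PD parameters for one agent.

    k_el : elimination rate (1/h); V_d : distribution volume (L);
    kill_max : maximal specific kill rate (1/h); IC50 : half-maximal
    inhibitory concentration (mg/L, tissue scale); hill : Hill coefficient;
    relative_permeability scales Ktrans for this species; D : diffusion
    coefficient in tissue (mm²/h).  Two-compartment kinetics add (k12, k21).
    """

    name: str
    k_el: float
    V_d: float
    kill_max: float
    IC50: float
    hill: float = 1.0
    n_compartments: int = 1
    k12: float = 0.0
    k21: float = 0.0
    relative_permeability: float = 1.0
    D: float = 0.5
    growth_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if min(self.k_el, self.kill_max, self.k12, self.k21) < 0:
            raise ValueError(f"{self.name}: rates must be >= 0")
        if self.IC50 <= 0 or self.hill <= 0 or self.V_d <= 0:
            raise ValueError(f"{self.name}: IC50, hill, V_d must be > 0")
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")

    def _biexp_coeffs(self) -> tuple[float, float, float, float]:
        """Hybrid rate constants (A-frac, alpha, B-frac, beta) for 2-compartment."""
        s = self.k12 + self.k21 + self.k_el
        disc = np.sqrt(max(s * s - 4 * self.k21 * self.k_el, 0.0))
        alpha = (s + disc) / 2
        beta = (s - disc) / 2
        if alpha == beta:
            return 1.0, alpha, 0.0, beta
        A = (alpha - self.k21) / (alpha - beta)
        B = (self.k21 - beta) / (alpha - beta)
        return A, alpha, B, beta

    def unit_decay(self, dt) -> np.ndarray:
        """Plasma concentration at time dt after a unit (1 mg/L initial) bolus."""
        dt = np.asarray(dt, dtype=float)
        if self.n_compartments == 1:
            out = np.exp(-self.k_el * np.clip(dt, 0, None))
        else:
            A, alpha, B, beta = self._biexp_coeffs()
            cdt = np.clip(dt, 0, None)
            out = A * np.exp(-alpha * cdt) + B * np.exp(-beta * cdt)
        return np.where(dt >= 0, out, 0.0)


@dataclass
class Administration:
    drug: str
    dose_mg: float
    day: float
    reduction: float = 1.0

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("administration day must be >= 0")
        if not (0 < self.reduction <= 1):
            raise ValueError("dose-reduction fraction must be in (0, 1]")
        if self.dose_mg < 0:
            raise ValueError("dose must be >= 0")


@dataclass
class Regimen:
    """Ordered dosing calendar plus the surgery (assessment) day."""

    administrations: list[Administration]
    surgery_day: float | None = None
    name: str = ""

    DEFAULT_SURGERY_LAG_DAYS = 21.0

    def __post_init__(self) -> None:
        self.administrations = sorted(self.administrations, key=lambda a: a.day)
        last = self.administrations[-1].day if self.administrations else 0.0
        if self.surgery_day is None:
            self.surgery_day = last + self.DEFAULT_SURGERY_LAG_DAYS
        if self.surgery_day < last:
            raise ValueError("surgery_day must be >= last administration day")

    def drugs(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.administrations:
            seen.setdefault(a.drug, None)
        return list(seen)

    def calendar(self, standard_dose: bool = False) -> list[tuple[str, float, float]]:
        """(drug, time_h, effective_dose_mg) rows; standard_dose ignores reductions."""
        return [(a.drug, a.day * HOURS_PER_DAY,
                 a.dose_mg * (1.0 if standard_dose else a.reduction))
                for a in self.administrations]


def plasma_drug_concentration(drug: DrugModel, regimen: Regimen, t_h,
                              standard_dose: bool = False) -> np.ndarray:
    """Plasma concentration (mg/L) of `drug` at time t_h (hours) by superposition."""
    t_h = np.asarray(t_h, dtype=float)
    names = regimen.drugs()
    if drug.name not in names:
        raise KeyError(f"drug {drug.name!r} not in regimen (has {names})")
    out = np.zeros_like(t_h, dtype=float)
    for name, t_dose, dose in regimen.calendar(standard_dose):
        if name != drug.name:
            continue
        out = out + (dose / drug.V_d) * drug.unit_decay(t_h - t_dose)
    return out


def kill_rate(drug: DrugModel, local_conc) -> np.ndarray:
    """Hill-law specific kill rate (1/h): kill_max * C^h / (C^h + IC50^h)."""
    C = np.asarray(local_conc, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be >= 0")
    Ch = np.power(C, drug.hill)
    return drug.kill_max * Ch / (Ch + drug.IC50 ** drug.hill)


def combined_kill(drugs_and_concs, rule: str = "additive") -> np.ndarray:
    """Combined specific kill rate over agents.

    'additive' (independent action, default) sums individual Hill rates;
    'max' takes the largest.  Empty list -> 0.
    """
    if not drugs_and_concs:
        return np.asarray(0.0)
    rates = [kill_rate(d, c) for d, c in drugs_and_concs]
    if rule == "additive":
        return np.sum(rates, axis=0)
    if rule == "max":
        return np.max(rates, axis=0)
    raise ValueError(f"unknown combination rule {rule!r}")


def load_drug_library(path=None) -> dict[str, DrugModel]:
    """Load the drug library from YAML (defaults to the packaged library)."""
    if path is None:
        text = resources.files("tumorsim.data").joinpath("drugs.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    lib: dict[str, DrugModel] = {}
    for name, p in raw["drugs"].items():
        lib[name] = DrugModel(name=name, **p)
    return lib
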