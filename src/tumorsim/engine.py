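"""Single-case simulation engine.

Couples perfusion delivery, reaction–diffusion transport, Monod growth,
PK/PD kill and tissue mechanics over a dosing calendar, and applies the
pCR decision rule to the resulting volume trajectory: predicted pCR iff
final volume < 0.01 cm³ (strict) or percent reduction >= 99.9 (inclusive)
at the surgery date.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lattice import TissueLattice, CellDensityField, tumor_volume
from .perfusion import PerfusionMap, exchange_relax
from .pkpd import (DrugModel, Regimen, plasma_drug_concentration, kill_rate,
                   HOURS_PER_DAY)
from .transport import (SpeciesField, MetabolicParameters, diffusion_step,
                        monod_rates, density_update, SteadyStateSolver)
from . import mechanics as mech

SUBTYPES = ("HR+/HER2-", "HR+/HER2+", "HR-/HER2+", "TNBC")

#: pCR decision thresholds
PCR_VOLUME_CM3 = 0.01
PCR_REDUCTION_PCT = 99.9

#: minutes per hour: Ktrans is per-minute, transport runs in hours
KTRANS_TO_PER_H = 60.0


@dataclass
class CaseRecord:
    """Clinical inputs for one tumor.

    Covariates (age, race, stages, grade, histology) ride through to the
    outputs and the clinical comparator model; only the subtype-linked
    per-drug sensitivity multipliers enter the mechanistic core.
    """

    case_id: str
    age: float
    race: str
    t_stage: str
    n_stage: str
    er_percent: float
    pr_percent: float
    her2_status: bool
    grade: int
    histology: str
    subtype: str
    sensitivity: dict = field(default_factory=dict)  # drug -> kill multiplier
    lattice: TissueLattice | None = None
    perfusion: PerfusionMap | None = None
    density: CellDensityField | None = None
    regimen: Regimen | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.er_percent <= 100 and 0 <= self.pr_percent <= 100):
            raise ValueError("ER/PR percent staining must be in [0, 100]")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        hr_pos = self.er_percent >= 1 or self.pr_percent >= 1  # 1% positivity convention
        want = {"HR+/HER2-": (True, False), "HR+/HER2+": (True, True),
                "HR-/HER2+": (False, True), "TNBC": (False, False)}[self.subtype]
        if (hr_pos, self.her2_status) != want:
            raise ValueError(
                f"subtype {self.subtype} inconsistent with ER={self.er_percent}, "
                f"PR={self.pr_percent}, HER2={self.her2_status}")


@dataclass
class SpeciesConfig:
    plasma_level: float
    D: float  # mm²/h


@dataclass
class SimConfig:
    """Engine settings.  Times in hours; the outer step defaults to 6 h with
    mechanics every 4 outer steps."""

    outer_dt_h: float = 6.0
    mechanics_every: int = 4
    mechanics_mode: str = "mesh"  # or "bookkeeping"
    oxygen_qss: bool = True
    nutrient_qss: bool = True  # quasi-steady glucose/amino pool (constant plasma)
    nutrient_update_every: int = 4  # outer steps between nutrient/O2 refreshes
    # (nutrient plasma levels are constant, so those fields sit near steady
    # state; drug fields update every outer step)
    combination_rule: str = "additive"
    standard_dose: bool = False
    include_secondary_species: bool = True  # amino-acid pool + lactate
    metabolic: MetabolicParameters = field(default_factory=MetabolicParameters)
    species: dict = field(default_factory=lambda: {
        "glucose": SpeciesConfig(plasma_level=5.0, D=1.0),
        "oxygen": SpeciesConfig(plasma_level=0.1, D=6.0),
        "amino_acids": SpeciesConfig(plasma_level=1.0, D=0.8),
        "lactate": SpeciesConfig(plasma_level=0.0, D=1.0),
    })
    clip_abort_fraction: float = 0.05  # clipped mass / delivered mass budget
    relax_tol: float = 1e-3
    relax_max_iter: int = 200

    def __post_init__(self) -> None:
        if self.outer_dt_h <= 0 or self.mechanics_every < 1:
            raise ValueError("steps must be positive")
        if self.mechanics_mode not in ("mesh", "bookkeeping"):
            raise ValueError("mechanics_mode must be 'mesh' or 'bookkeeping'")


@dataclass
class SimulationTrajectory:
    times_days: np.ndarray
    volumes_cm3: np.ndarray
    case_id: str = ""
    snapshots: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.volumes_cm3 = np.asarray(self.volumes_cm3, dtype=float)
        if np.any(np.diff(self.times_days) < 0):
            raise ValueError("trajectory times must be sorted")
        if np.any(self.volumes_cm3 < 0):
            raise ValueError("volumes must be >= 0")

    @property
    def v_initial(self) -> float:
        return float(self.volumes_cm3[0])

    @property
    def v_final(self) -> float:
        return float(self.volumes_cm3[-1])

    @property
    def percent_reduction(self) -> float:
        if self.v_initial <= 0:
            return float("nan")
        return 100.0 * (1.0 - self.v_final / self.v_initial)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.times_days, "volume_cm3": self.volumes_cm3})


@dataclass
class ResponsePrediction:
    predicted_class: str  # "pCR" | "residual"
    v_initial: float
    v_final: float
    percent_reduction: float
    rule_fired: str  # "absolute_volume" | "percent_reduction" | "none"
    flag: str = ""


def classify_pcr(traj: SimulationTrajectory) -> ResponsePrediction:
    """Apply the pCR decision rule to a volume trajectory.

    pCR iff V_final < 0.01 cm³ (strict) OR percent reduction >= 99.9
    (inclusive).  A tumor already under the absolute threshold at baseline
    is classified pCR with a degenerate-input flag.
    """
    v0, vf = traj.v_initial, traj.v_final
    if v0 < 0 or vf < 0:
        raise ValueError("volumes must be >= 0")
    flag = "" if v0 >= PCR_VOLUME_CM3 else "degenerate: baseline below threshold"
    red = traj.percent_reduction if v0 > 0 else float("nan")
    if vf < PCR_VOLUME_CM3:
        return ResponsePrediction("pCR", v0, vf, red, "absolute_volume", flag)
    if v0 > 0 and red >= PCR_REDUCTION_PCT:
        return ResponsePrediction("pCR", v0, vf, red, "percent_reduction", flag)
    return ResponsePrediction("residual", v0, vf, red, "none", flag)


def compare_to_followups(traj: SimulationTrajectory, followups) -> pd.DataFrame:
    """Per-scan error table: 100*|V_pred(day) - V_obs| / V_initial.

    followups is a list of (day, observed cm³).  Days outside the trajectory
    snap to the nearest recorded day (flagged in the table).
    """
    if traj.v_initial <= 0:
        raise ValueError("degenerate case: V_initial = 0")
    rows = []
    for day, v_obs in followups:
        idx = int(np.argmin(np.abs(traj.times_days - day)))
        nearest = traj.times_days[idx]
        v_pred = traj.volumes_cm3[idx]
        rows.append({
            "day": day, "matched_day": nearest, "v_pred_cm3": v_pred,
            "v_obs_cm3": v_obs,
            "error_pct_of_initial": 100.0 * abs(v_pred - v_obs) / traj.v_initial,
            "flag": "" if np.isclose(nearest, day, atol=0.5) else "nearest-day",
        })
    return pd.DataFrame(rows, columns=["day", "matched_day", "v_pred_cm3",
                                       "v_obs_cm3", "error_pct_of_initial", "flag"])


def _growth_suppression(drug: DrugModel, C: np.ndarray) -> np.ndarray:
    """Smooth growth-rate multiplier for cytostatic action (antibody agents)."""
    if drug.growth_multiplier >= 1.0:
        return np.ones_like(C)
    occ = C / (C + drug.IC50)
    return 1.0 - (1.0 - drug.growth_multiplier) * occ


def run_case(case: CaseRecord, config: SimConfig | None = None,
             drug_library: dict | None = None,
             snapshot_days: tuple = ()) -> SimulationTrajectory:
    """Simulate one case over its regimen; returns the daily volume trajectory.

    Deterministic: no randomness enters the forward model.
    """
    config = config or SimConfig()
    if case.lattice is None or case.perfusion is None or case.density is None \
            or case.regimen is None:
        raise ValueError("case must carry lattice, perfusion map, density, regimen")
    if drug_library is None:
        from .pkpd import load_drug_library
        drug_library = load_drug_library()

    lat, pmap, regimen = case.lattice, case.perfusion, case.regimen
    rho = case.density.copy()
    drugs = {name: drug_library[name] for name in regimen.drugs()}

    # species state: nutrients start at the perfusion equilibrium ve*Cp;
    # drugs start at zero tissue concentration
    fields: dict[str, SpeciesField] = {}
    active = ["glucose", "oxygen"] + (
        ["amino_acids", "lactate"] if config.include_secondary_species else [])
    for name in active:
        sc = config.species[name]
        init = pmap.ve * sc.plasma_level
        init[~lat.body_mask] = 0.0
        init[pmap.macrovascular_mask] = sc.plasma_level
        fields[name] = SpeciesField(name, init, sc.D, sc.plasma_level)
    for name, d in drugs.items():
        fields[f"drug:{name}"] = SpeciesField(f"drug:{name}", np.zeros(lat.shape), d.D, 0.0)

    # quasi-steady nutrients: sparse Helmholtz solve with Picard Monod sink.
    # beta (exchange relaxation rate) is shared across species; alpha scales
    # with the species' plasma level.
    ve_qss = np.where(pmap.ve > 0, pmap.ve, 1.0)
    micro_qss = lat.body_mask & ~pmap.macrovascular_mask
    beta_qss = np.where(micro_qss, pmap.Ktrans * KTRANS_TO_PER_H / ve_qss, 0.0)

    def qss_alpha(plasma_level: float) -> np.ndarray:
        return np.where(micro_qss,
                        pmap.Ktrans * KTRANS_TO_PER_H * plasma_level, 0.0)

    o2_solver = None
    if config.oxygen_qss:
        o2_solver = SteadyStateSolver(lat, config.species["oxygen"].D, beta_qss,
                                      dirichlet_mask=pmap.macrovascular_mask)
        alpha_o2 = qss_alpha(config.species["oxygen"].plasma_level)
    nutrient_solver = None
    if config.nutrient_qss:
        nutrient_solver = SteadyStateSolver(
            lat, config.species["glucose"].D, beta_qss,
            dirichlet_mask=pmap.macrovascular_mask)

    dt = config.outer_dt_h
    t_end_h = regimen.surgery_day * HOURS_PER_DAY
    n_steps = int(np.ceil(t_end_h / dt))
    clip_log: list[float] = []
    delivered = 1e-12  # running scale for the clip-abort diagnostic

    # fixed outer step -> exchange relaxation factors and plasma PK series
    # can be precomputed once per case
    micro = lat.body_mask & ~pmap.macrovascular_mask
    ve_safe = np.where(pmap.ve > 0, pmap.ve, 1.0)

    def relax_factor(rel_perm: float) -> np.ndarray:
        return np.exp(-rel_perm * pmap.Ktrans * KTRANS_TO_PER_H / ve_safe * dt)

    fac_nutrient = relax_factor(1.0)
    fac_drug = {name: relax_factor(d.relative_permeability)
                for name, d in drugs.items()}

    def exchange_cached(C: np.ndarray, Cp: float, fac: np.ndarray) -> np.ndarray:
        target = ve_safe * Cp
        out = C.copy()
        out[micro] = (target + (C - target) * fac)[micro]
        out[pmap.macrovascular_mask] = Cp
        return out

    t_mids = np.arange(1, n_steps + 1) * dt - dt / 2.0
    plasma_series = {name: np.asarray(plasma_drug_concentration(
        d, regimen, t_mids, config.standard_dose))
        for name, d in drugs.items()}

    mesh0 = None
    if config.mechanics_mode == "mesh":
        mesh0 = mech.build_mesh(lat.shape, lat.voxel_side)
    net_rate_accum = np.zeros(lat.shape)  # (mu - delta) integrated since last relax

    times = [0.0]
    vols = [tumor_volume(rho, lat)]
    snapshots: dict = {}
    next_record_day = 1.0
    met = config.metabolic

    for step in range(1, n_steps + 1):
        t_h = step * dt

        # ---- plasma PK per drug (precomputed at step midpoints)
        plasma = {name: float(series[step - 1])
                  for name, series in plasma_series.items()}

        # ---- metabolic rates from current fields
        mu, uptake, lactate_prod = monod_rates(
            met, fields["glucose"].C, fields["oxygen"].C, rho.rho)

        # ---- nutrient transport.  Plasma nutrient levels are constant, so
        # glucose sits near the balance of perfusion delivery, diffusion and
        # Monod uptake: by default it is relaxed to quasi-steady state on the
        # same cadence as oxygen (uptake follows the slowly-evolving density).
        # The non-limiting amino-acid pool has no sink and is solved once.
        if step == 1 or step % config.nutrient_update_every == 0:
            fg = fields["glucose"]
            if config.nutrient_qss:
                def g_uptake(C):
                    return (met.uptake_max.get("glucose", 0.0)
                            * C / (C + met.K_G) * rho.rho)

                C = nutrient_solver.solve(qss_alpha(fg.plasma_level), g_uptake,
                                          dirichlet_value=fg.plasma_level,
                                          C0=fg.C, tol=1e-5)
                fields["glucose"] = SpeciesField("glucose", C, fg.D, fg.plasma_level)
            else:
                dt_nut = dt * (1 if step == 1 else config.nutrient_update_every)
                fac_window = fac_nutrient if step == 1 else \
                    fac_nutrient ** config.nutrient_update_every
                names = ("glucose",) + (
                    ("amino_acids",) if "amino_acids" in fields else ())
                for name in names:
                    f = fields[name]
                    C = exchange_cached(f.C, f.plasma_level, fac_window)
                    sink = uptake["glucose"] if name == "glucose" else None
                    fields[name] = diffusion_step(
                        SpeciesField(name, C, f.D, f.plasma_level), lat, dt_nut,
                        sinks=sink, dirichlet_mask=pmap.macrovascular_mask,
                        dirichlet_value=f.plasma_level, clip_log=clip_log)
                    delivered += float(np.abs(C - f.C).sum())
        if step == 1 and config.nutrient_qss and "amino_acids" in fields:
            fa = fields["amino_acids"]
            aa_solver = SteadyStateSolver(lat, fa.D, beta_qss,
                                          dirichlet_mask=pmap.macrovascular_mask)
            C = aa_solver.solve(qss_alpha(fa.plasma_level),
                                dirichlet_value=fa.plasma_level, C0=fa.C)
            fields["amino_acids"] = SpeciesField("amino_acids", C, fa.D,
                                                 fa.plasma_level)

        # ---- oxygen: quasi-steady-state (default, refreshed every few steps
        # since density evolves slowly) or explicit split
        fo = fields["oxygen"]
        if config.oxygen_qss:
            if step == 1 or step % config.nutrient_update_every == 0:
                def o2_uptake(C):
                    return (met.uptake_max.get("oxygen", 0.0)
                            * C / (C + met.K_O) * rho.rho)

                C = o2_solver.solve(alpha_o2, o2_uptake,
                                    dirichlet_value=fo.plasma_level, C0=fo.C,
                                    tol=1e-5)
                fields["oxygen"] = SpeciesField("oxygen", C, fo.D, fo.plasma_level)
        else:
            C = exchange_relax(fo.C, pmap, fo.plasma_level, dt)
            fields["oxygen"] = diffusion_step(
                SpeciesField("oxygen", C, fo.D, fo.plasma_level), lat, dt,
                sinks=uptake["oxygen"], dirichlet_mask=pmap.macrovascular_mask,
                dirichlet_value=fo.plasma_level, clip_log=clip_log)

        # ---- lactate: produced under hypoxia, cleared to plasma
        if "lactate" in fields:
            f = fields["lactate"]
            C = exchange_cached(f.C, f.plasma_level, fac_nutrient)
            fields["lactate"] = diffusion_step(
                SpeciesField("lactate", C, f.D, f.plasma_level), lat, dt,
                sources=lactate_prod, dirichlet_mask=pmap.macrovascular_mask,
                dirichlet_value=f.plasma_level, clip_log=clip_log)

        # ---- drug transport
        for name, d in drugs.items():
            f = fields[f"drug:{name}"]
            C = exchange_cached(f.C, plasma[name], fac_drug[name])
            fields[f"drug:{name}"] = diffusion_step(
                SpeciesField(f.name, C, f.D, plasma[name]), lat, dt,
                dirichlet_mask=pmap.macrovascular_mask,
                dirichlet_value=plasma[name], clip_log=clip_log)
            delivered += float(np.abs(C - f.C).sum())

        # ---- growth & kill fields
        mu_eff = mu.copy()
        delta = np.zeros(lat.shape)
        for name, d in drugs.items():
            C = fields[f"drug:{name}"].C
            mult = case.sensitivity.get(name, 1.0)
            delta += mult * kill_rate(d, C)
            mu_eff *= _growth_suppression(d, C)
        if config.combination_rule == "max":
            # recompute under the max rule
            rates = [case.sensitivity.get(n, 1.0) * kill_rate(d, fields[f"drug:{n}"].C)
                     for n, d in drugs.items()]
            delta = np.max(rates, axis=0) if rates else delta
        mu_eff[~lat.tumor_mask] = 0.0
        delta[~lat.tumor_mask] = 0.0

        rho = density_update(rho, mu_eff, delta, dt)
        net_rate_accum += (mu_eff - delta) * dt

        # ---- mechanics
        if config.mechanics_mode == "mesh" and step % config.mechanics_every == 0:
            g = np.exp(np.clip(net_rate_accum, -2.0, 2.0))
            if not np.allclose(g, 1.0, atol=1e-6):
                deformed, _diag = mech.relax(mesh0, g, tol=config.relax_tol,
                                             max_iter=config.relax_max_iter)
                rho, _info = mech.remap_density(rho, mesh0, deformed)
            net_rate_accum[:] = 0.0

        if sum(clip_log) > config.clip_abort_fraction * delivered:
            raise RuntimeError(
                f"unstable configuration: clipped mass {sum(clip_log):.3g} exceeds "
                f"{config.clip_abort_fraction:.0%} of delivered mass at t={t_h:.1f} h")

        # ---- daily volume recording
        day = t_h / HOURS_PER_DAY
        while next_record_day <= day + 1e-9:
            times.append(next_record_day)
            vols.append(tumor_volume(rho, lat))
            if any(abs(next_record_day - s) < 0.5 for s in snapshot_days):
                snapshots[next_record_day] = {k: f.C.copy() for k, f in fields.items()}
                snapshots[next_record_day]["rho"] = rho.rho.copy()
            next_record_day += 1.0

    if times[-1] < regimen.surgery_day - 1e-9:
        times.append(regimen.surgery_day)
        vols.append(tumor_volume(rho, lat))

    return SimulationTrajectory(np.asarray(times), np.asarray(vols),
                                case_id=case.case_id, snapshots=snapshots)
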