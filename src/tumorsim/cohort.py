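"""Synthetic phantoms and cohorts.

No patient imaging ships with this package, so every downstream layer is
exercised on synthetic data with the statistical structure of a neoadjuvant
breast-cancer cohort: phantom tumors with spatially correlated perfusion
and optional necrotic cores; subtype-linked regimens and drug-sensitivity
distributions; "observed" outcomes produced by re-simulating each case with
perturbed parameters plus label noise (so prediction errors arise from the
generator, never from the predictor itself); follow-up scan volumes; and
exponential-hazard survival endpoints concentrated in residual-disease
cases.

All generation is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .lattice import (TissueLattice, CellDensityField, build_lattice,
                      FAT, FIBROGLANDULAR, VESSEL, TUMOR)
from .perfusion import AIFModel, PerfusionMap, tofts_forward_map
from .pkpd import Administration, Regimen
from .engine import CaseRecord

GEOMETRIES = ("ellipsoid", "multifocal", "rim")

#: cohort composition template (subtype marginals of the target population)
DEFAULT_SUBTYPE_MIX = {"TNBC": 0.41, "HR-/HER2+": 0.174,
                       "HR+/HER2+": 0.167, "HR+/HER2-": 0.25}

#: per-subtype log-mean of the lognormal kill-sensitivity multiplier,
#: calibrated once so the simulated cohort pCR rate sits near 35% with the
#: qualitative subtype ordering (HER2+ most responsive, HR+/HER2- least)
SENSITIVITY_LOG_MEAN = {"TNBC": 0.19, "HR-/HER2+": -0.20,
                        "HR+/HER2+": -0.96, "HR+/HER2-": -0.38}
SENSITIVITY_LOG_SD = 0.55


@dataclass
class PhantomSpec:
    """One synthetic tumor: geometry, size, perfusion texture, necrosis."""

    geometry: str = "ellipsoid"
    diameter_mm: float = 20.0
    semi_axes_mm: tuple | None = None  # overrides diameter-derived axes
    voxel_side_mm: float = 2.0
    margin_voxels: int = 4
    ktrans_mean: float = 0.08
    ktrans_sd: float = 0.03
    correlation_length_mm: float = 4.0
    necrotic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be > 0")
        if not (0 <= self.necrotic_fraction <= 1):
            raise ValueError("necrotic_fraction must be in [0, 1]")
        if self.diameter_mm < 2 * self.voxel_side_mm:
            raise ValueError("tumor diameter must span at least 2 voxels")

    def axes(self) -> tuple[float, float, float]:
        if self.semi_axes_mm is not None:
            return tuple(self.semi_axes_mm)  # type: ignore[return-value]
        r = self.diameter_mm / 2.0
        return (r, 0.85 * r, 0.7 * r)


def _ellipsoid_mask(shape, center, axes, h) -> np.ndarray:
    idx = np.indices(shape).astype(float)
    pos = (idx + 0.5) * h  # cell centers in mm
    q = sum(((pos[i] - center[i]) / axes[i]) ** 2 for i in range(3))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[TissueLattice, PerfusionMap, CellDensityField]:
    """Build one phantom: labeled lattice, Tofts parameter map, density field.

    Tumor voxels start at carrying capacity except inside the necrotic core
    (innermost voxels by distance to the tumor surface, sized to the
    requested fraction).  Ktrans is Gaussian-filtered white noise rescaled
    to the requested mean/sd; a straight vessel track runs from the domain
    boundary to the tumor margin.  Deterministic under (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    h = spec.voxel_side_mm
    axes = np.asarray(spec.axes())
    extent = int(np.ceil(2 * max(axes) / h)) + 2 * spec.margin_voxels
    shape = (extent, extent, extent)
    center = np.asarray(shape) * h / 2.0

    labels = np.full(shape, FAT, dtype=np.int16)
    # fibroglandular band around the tumor bed
    fib = _ellipsoid_mask(shape, center, axes * 1.8 + 2 * h, h)
    labels[fib] = FIBROGLANDULAR

    if spec.geometry == "ellipsoid" or spec.geometry == "rim":
        tmask = _ellipsoid_mask(shape, center, axes, h)
    else:  # multifocal: a dominant focus plus 1-2 satellites
        tmask = _ellipsoid_mask(shape, center, axes * 0.75, h)
        n_sat = int(rng.integers(1, 3))
        for _ in range(n_sat):
            off = rng.uniform(-0.8, 0.8, 3) * axes
            tmask |= _ellipsoid_mask(shape, center + off, axes * 0.45, h)
    labels[tmask] = TUMOR

    # vessel track from the x- boundary to the tumor margin
    cz = np.round(center / h).astype(int)
    xs = np.arange(0, max(cz[0] - int(axes[0] / h), 1))
    labels[xs, cz[1], cz[2]] = np.where(
        tmask[xs, cz[1], cz[2]], TUMOR, VESSEL).astype(np.int16)

    lat = build_lattice(labels, h)

    # density: capacity everywhere in-tumor, zero in the necrotic core
    rho = np.zeros(shape)
    rho[tmask] = 1.0
    frac = spec.necrotic_fraction if spec.geometry != "rim" else max(
        spec.necrotic_fraction, 0.4)
    if frac > 0 and tmask.sum() > 4:
        # zero exactly the k innermost voxels (depth ties broken stably)
        dist = ndimage.distance_transform_edt(tmask)
        coords = np.argwhere(tmask)
        order = np.argsort(-dist[tmask], kind="stable")
        k = int(round(frac * len(coords)))
        core = coords[order[:k]]
        rho[core[:, 0], core[:, 1], core[:, 2]] = 0.0
    density = CellDensityField(rho, rho_max=1.0, rho_detect=0.10)

    # spatially correlated Ktrans, rescaled to the requested moments
    noise = rng.standard_normal(shape)
    sigma = max(spec.correlation_length_mm / h, 0.5)
    sm = ndimage.gaussian_filter(noise, sigma)
    sd = sm.std() if sm.std() > 0 else 1.0
    ktrans = spec.ktrans_mean + spec.ktrans_sd * (sm - sm.mean()) / sd
    ktrans = np.clip(ktrans, 0.0, None)
    ve = np.clip(0.30 + 0.05 * rng.standard_normal(shape), 0.05, 0.6)
    vp = np.full(shape, 0.02)
    pmap = PerfusionMap(lat, ktrans, ve, vp)
    return lat, pmap, density


def generate_dce_series(pmap: PerfusionMap, aif: AIFModel, times_min,
                        noise_sd: float, seed: int = 0) -> np.ndarray:
    """Per-voxel tissue concentration series (shape lattice + (T,)).

    Supports the sparse 3-point clinical schedule (pre, early, late
    post-contrast) as well as dense research sampling.  Gaussian noise with
    the given sd is added; background voxels stay zero.
    """
    times_min = np.asarray(times_min, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if times_min[0] != 0 or times_min.size < 3:
        raise ValueError("need time 0 plus at least two post-contrast points")
    ct = tofts_forward_map(pmap.Ktrans, pmap.ve, pmap.vp, aif, times_min)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ct = np.clip(ct + rng.normal(0, noise_sd, ct.shape), 0.0, None)
    ct[~pmap.lattice.body_mask] = 0.0
    return ct


# ---------------------------------------------------------------------------
# regimen templates (four regimen classes)

def _regimen_ddac_t(reduction_on: bool) -> Regimen:
    red = 0.75 if reduction_on else 1.0
    ad = []
    for c in range(4):
        ad += [Administration("doxorubicin", 100.0, 14.0 * c),
               Administration("cyclophosphamide", 1000.0, 14.0 * c)]
    for c in range(4):
        ad.append(Administration("paclitaxel", 135.0, 56.0 + 14.0 * c,
                                 reduction=red if c >= 2 else 1.0))
    return Regimen(ad, name="ddAC-T")


def _regimen_tc(reduction_on: bool) -> Regimen:
    red = 0.75 if reduction_on else 1.0
    ad = []
    for c in range(4):
        ad += [Administration("docetaxel", 120.0, 21.0 * c,
                              reduction=red if c >= 2 else 1.0),
               Administration("cyclophosphamide", 1000.0, 21.0 * c)]
    return Regimen(ad, name="TC")


def _regimen_tchp(reduction_on: bool) -> Regimen:
    red = 0.75 if reduction_on else 1.0
    ad = []
    for c in range(6):
        day = 21.0 * c
        ad += [Administration("docetaxel", 120.0, day,
                              reduction=red if c >= 3 else 1.0),
               Administration("carboplatin", 600.0, day),
               Administration("trastuzumab", 420.0, day),
               Administration("pertuzumab", 420.0, day)]
    return Regimen(ad, name="TCHP")


def _regimen_ac_thp(reduction_on: bool) -> Regimen:
    red = 0.75 if reduction_on else 1.0
    ad = []
    for c in range(4):
        ad += [Administration("doxorubicin", 100.0, 14.0 * c),
               Administration("cyclophosphamide", 1000.0, 14.0 * c)]
    for c in range(4):
        day = 56.0 + 14.0 * c
        ad += [Administration("paclitaxel", 135.0, day,
                              reduction=red if c >= 2 else 1.0),
               Administration("trastuzumab", 420.0, day),
               Administration("pertuzumab", 420.0, day)]
    return Regimen(ad, name="AC-THP")


REGIMEN_CLASSES = {
    "chemo_anthra": _regimen_ddac_t,
    "chemo_no_anthra": _regimen_tc,
    "her2_no_anthra": _regimen_tchp,
    "her2_anthra": _regimen_ac_thp,
}

HER2_DIRECTED = {"trastuzumab", "pertuzumab"}


@dataclass
class CohortSpec:
    """Cohort-level generation settings."""

    n: int = 144
    subtype_mix: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_MIX))
    sensitivity_log_mean: dict = field(
        default_factory=lambda: dict(SENSITIVITY_LOG_MEAN))
    sensitivity_log_sd: float = SENSITIVITY_LOG_SD
    voxel_side_mm: float = 2.0
    diameter_range_mm: tuple = (12.0, 30.0)
    dose_reduction_rate: float = 0.2
    obs_perturbation_sd: float = 0.25  # lognormal sd on re-simulated sensitivity
    label_noise: float = 0.05
    followup_days: tuple = (42.0, 84.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        total = sum(self.subtype_mix.values())
        if not np.isclose(total, 1.0, atol=0.01):
            raise ValueError("subtype mixture must sum to 1")
        self.subtype_mix = {k: v / total for k, v in self.subtype_mix.items()}


_SUBTYPE_FIELDS = {
    "HR+/HER2-": dict(er=(40, 100), pr=(10, 100), her2=False),
    "HR+/HER2+": dict(er=(10, 100), pr=(0, 100), her2=True),
    "HR-/HER2+": dict(er=(0, 0.99), pr=(0, 0.99), her2=True),
    "TNBC": dict(er=(0, 0.99), pr=(0, 0.99), her2=False),
}

T_STAGES = (("T1", 0.19), ("T2", 0.60), ("T3", 0.19), ("T4", 0.02))
N_STAGES = (("N0", 0.50), ("N1", 0.41), ("N2", 0.07), ("N3", 0.02))
RACES = (("African American", 0.50), ("Caucasian", 0.35), ("Asian", 0.03),
         ("Other", 0.12))


def _draw_cat(rng, table):
    names, probs = zip(*table)
    return names[rng.choice(len(names), p=np.asarray(probs) / sum(probs))]


def _make_case(i: int, subtype: str, spec: CohortSpec, rng) -> tuple[CaseRecord, float]:
    fs = _SUBTYPE_FIELDS[subtype]
    er = float(rng.uniform(*fs["er"]))
    pr = float(rng.uniform(*fs["pr"]))
    her2 = fs["her2"]
    if her2:
        reg_class = "her2_anthra" if rng.random() < 0.35 else "her2_no_anthra"
    else:
        reg_class = "chemo_anthra" if rng.random() < 0.93 else "chemo_no_anthra"
    regimen = REGIMEN_CLASSES[reg_class](rng.random() < spec.dose_reduction_rate)

    pspec = PhantomSpec(
        geometry=str(rng.choice(GEOMETRIES, p=[0.6, 0.25, 0.15])),
        diameter_mm=float(rng.uniform(*spec.diameter_range_mm)),
        voxel_side_mm=spec.voxel_side_mm,
        margin_voxels=3,
        ktrans_mean=float(np.clip(rng.normal(0.08, 0.025), 0.02, 0.2)),
        ktrans_sd=0.03,
        necrotic_fraction=float(rng.uniform(0.0, 0.35)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    lat, pmap, density = generate_phantom(pspec)

    s = float(np.exp(rng.normal(spec.sensitivity_log_mean[subtype],
                                spec.sensitivity_log_sd)))
    sens = {}
    for drug in regimen.drugs():
        if drug in HER2_DIRECTED:
            sens[drug] = s if her2 else 0.0
        else:
            sens[drug] = s

    case = CaseRecord(
        case_id=f"case_{i:04d}",
        age=float(np.clip(rng.normal(52, 13), 25, 85)),
        race=_draw_cat(rng, RACES),
        t_stage=_draw_cat(rng, T_STAGES),
        n_stage=_draw_cat(rng, N_STAGES),
        er_percent=er, pr_percent=pr, her2_status=her2,
        grade=int(rng.choice([1, 2, 3], p=[0.02, 0.21, 0.77])),
        histology=str(rng.choice(
            ["Invasive Ductal Carcinoma", "Invasive Lobular Carcinoma", "Other"],
            p=[0.96, 0.03, 0.01])),
        subtype=subtype, sensitivity=sens,
        lattice=lat, perfusion=pmap, density=density, regimen=regimen,
    )
    return case, s


REGIMEN_CLASS_LABELS = {
    "ddAC-T": "chemo_anthra", "TC": "chemo_no_anthra",
    "TCHP": "her2_no_anthra", "AC-THP": "her2_anthra",
}


def generate_cohort(spec: CohortSpec, sim_config=None, drug_library=None,
                    progress: bool = False) -> tuple[list[CaseRecord], pd.DataFrame]:
    """Generate n cases plus the ground-truth table.

    Observed outcomes come from re-simulating each case with sensitivity
    multipliers perturbed by lognormal noise (sd = obs_perturbation_sd) and
    flipping the resulting pCR label with probability label_noise.  The
    truth table carries observed pCR, follow-up scan volumes, and synthetic
    DFI/EFS/OS endpoints whose events concentrate in residual-disease cases.
    """
    from .engine import run_case, classify_pcr, SimConfig

    rng = np.random.default_rng(spec.seed)
    if sim_config is None:
        sim_config = SimConfig(mechanics_mode="bookkeeping",
                               include_secondary_species=False)
    subtypes = list(spec.subtype_mix)
    probs = np.asarray([spec.subtype_mix[s] for s in subtypes])
    cases: list[CaseRecord] = []
    rows = []
    for i in range(spec.n):
        subtype = subtypes[int(rng.choice(len(subtypes), p=probs))]
        case, s = _make_case(i, subtype, spec, rng)
        cases.append(case)

        # ground truth: perturbed-parameter re-simulation + label noise
        pert = float(np.exp(rng.normal(0.0, spec.obs_perturbation_sd)))
        truth_case = replace(case, sensitivity={
            k: v * pert for k, v in case.sensitivity.items()})
        traj = run_case(truth_case, sim_config, drug_library)
        pred = classify_pcr(traj)
        observed_pcr = pred.predicted_class == "pCR"
        if rng.random() < spec.label_noise:
            observed_pcr = not observed_pcr

        fu_days, fu_vols = [], []
        for d in spec.followup_days:
            if d <= traj.times_days[-1]:
                idx = int(np.argmin(np.abs(traj.times_days - d)))
                fu_days.append(float(traj.times_days[idx]))
                fu_vols.append(float(traj.volumes_cm3[idx]
                                     * np.exp(rng.normal(0, 0.10))))

        # survival endpoints: exponential hazards, lower for observed pCR
        hazards = {"dfi": (0.002, 0.05), "efs": (0.004, 0.055), "os": (0.004, 0.045)}
        censor = float(rng.uniform(3.0, 8.0))
        surv = {}
        for name, (h_pcr, h_res) in hazards.items():
            lam = h_pcr if observed_pcr else h_res
            t_event = float(rng.exponential(1.0 / lam))
            surv[f"{name}_years"] = min(t_event, censor)
            surv[f"{name}_event"] = int(t_event <= censor)

        rows.append({
            "case_id": case.case_id, "subtype": subtype,
            "regimen_class": REGIMEN_CLASS_LABELS[case.regimen.name],
            "age": case.age, "race": case.race, "t_stage": case.t_stage,
            "n_stage": case.n_stage, "grade": case.grade,
            "histology": case.histology, "er_percent": case.er_percent,
            "pr_percent": case.pr_percent, "her2_status": case.her2_status,
            "sensitivity_factor": s,
            "observed_pcr": bool(observed_pcr),
            "truth_v_initial_cm3": pred.v_initial,
            "truth_v_final_cm3": pred.v_final,
            "followup_days": ";".join(f"{d:g}" for d in fu_days),
            "followup_volumes_cm3": ";".join(f"{v:.6g}" for v in fu_vols),
            **surv,
        })
        if progress:
            print(f"  generated {case.case_id} ({subtype})")
    return cases, pd.DataFrame(rows)
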