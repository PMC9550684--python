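"""Extended Tofts perfusion model: AIF, forward solution, voxelwise fitting,
and the per-voxel source/sink coupling used by species transport.

Tissue concentration under the extended (two-compartment) Tofts model:

    C_t(t) = vp * Cp(t) + Ktrans * ∫0..t Cp(τ) exp(-(Ktrans/ve)(t-τ)) dτ

with Cp a population biexponential arterial input function.  For a
biexponential AIF the convolution has a closed form, used both by the
forward solver and the least-squares fit.  Vessel-labeled voxels are
treated as macrovascular Dirichlet sources (clamped to plasma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .lattice import TissueLattice, LatticeError


@dataclass
class AIFModel:
    """Biexponential arterial input function.

    Cp(t) = a1*exp(-m1*(t-t0)) + a2*exp(-m2*(t-t0)) for t >= t0, else 0.
    Default constants are the classic population (Weinmann-type) values for
    a standard gadolinium dose: a1, a2 in mM; m1, m2 in 1/min.
    """

    a1: float = 3.99
    a2: float = 4.78
    m1: float = 0.144
    m2: float = 0.0111
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("AIF amplitudes must be >= 0")
        if not (self.m1 > self.m2 > 0):
            raise ValueError("require m1 > m2 > 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        dt = t - self.t0
        out = self.a1 * np.exp(-self.m1 * np.clip(dt, 0, None)) + \
            self.a2 * np.exp(-self.m2 * np.clip(dt, 0, None))
        return np.where(dt >= 0, out, 0.0)


@dataclass
class PerfusionParameters:
    """Tofts parameters for one voxel: Ktrans (1/min), ve, vp (fractions)."""

    Ktrans: float
    ve: float
    vp: float = 0.0

    def __post_init__(self) -> None:
        if self.Ktrans < 0:
            raise ValueError("Ktrans must be >= 0")
        if not (0 < self.ve <= 1):
            raise ValueError("ve must be in (0, 1]")
        if not (0 <= self.vp < 1):
            raise ValueError("vp must be in [0, 1)")
        if self.ve + self.vp > 1 + 1e-12:
            raise ValueError("ve + vp must be <= 1")


def plasma_concentration(aif: AIFModel, t) -> np.ndarray:
    """Plasma concentration Cp(t); zero before onset t0."""
    return aif(t)


def _biexp_convolution(Ktrans, ve, aif: AIFModel, t):
    """Closed-form Ktrans * ∫ Cp(τ) exp(-kep (t-τ)) dτ for biexponential Cp."""
    t = np.asarray(t, dtype=float)
    if Ktrans == 0:
        return np.zeros_like(t)
    kep = Ktrans / ve
    dt = np.clip(t - aif.t0, 0, None)
    out = np.zeros_like(dt)
    for a, m in ((aif.a1, aif.m1), (aif.a2, aif.m2)):
        if abs(kep - m) < 1e-12 * max(kep, m, 1.0):
            term = a * dt * np.exp(-m * dt)
        else:
            term = a * (np.exp(-m * dt) - np.exp(-kep * dt)) / (kep - m)
        out += term
    return Ktrans * np.where(t >= aif.t0, out, 0.0)


def tofts_forward(params: PerfusionParameters, aif: AIFModel, times) -> np.ndarray:
    """Tissue concentration series at the given times (min, strictly increasing)."""
    times = np.asarray(times, dtype=float)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    ct = params.vp * aif(times) + _biexp_convolution(params.Ktrans, params.ve, aif, times)
    return np.clip(ct, 0.0, None)


def tofts_forward_map(Ktrans: np.ndarray, ve: np.ndarray, vp: np.ndarray,
                      aif: AIFModel, times) -> np.ndarray:
    """Vectorized extended-Tofts forward model over a parameter map.

    Returns an array of shape Ktrans.shape + (len(times),).  Closed-form
    convolution for the biexponential AIF, broadcast over voxels.
    """
    times = np.asarray(times, dtype=float)
    K = np.asarray(Ktrans, dtype=float)[..., None]
    ve_ = np.clip(np.asarray(ve, dtype=float), 1e-6, None)[..., None]
    vp_ = np.asarray(vp, dtype=float)[..., None]
    dt = np.clip(times - aif.t0, 0, None)  # (T,)
    kep = K / ve_
    conv = np.zeros(np.broadcast_shapes(K.shape, dt.shape))
    for a, m in ((aif.a1, aif.m1), (aif.a2, aif.m2)):
        diff = kep - m
        safe = np.where(np.abs(diff) < 1e-12, 1.0, diff)
        gen = a * (np.exp(-m * dt) - np.exp(-kep * dt)) / safe
        lim = a * dt * np.exp(-m * dt)
        conv = conv + np.where(np.abs(diff) < 1e-12, lim, gen)
    ct = vp_ * aif(times) + K * conv
    return np.clip(np.where(times >= aif.t0, ct, 0.0), 0.0, None)


@dataclass
class FitResult:
    params: PerfusionParameters
    residual_norm: float
    converged: bool
    flag: str = ""


#: fit bounds: Ktrans (1/min), ve, vp
FIT_BOUNDS = ((0.0, 1e-6, 0.0), (5.0, 1.0, 0.5))
FIT_INIT = (0.1, 0.3, 0.02)


def tofts_fit(tissue_series, aif: AIFModel, times,
              bounds=FIT_BOUNDS, init=FIT_INIT) -> FitResult:
    """Bounded trust-region least-squares fit of (Ktrans, ve, vp).

    Requires >= 3 time points.  An all-zero series short-circuits to
    Ktrans = 0, vp = 0 with a flag; non-convergence is flagged, never raised.
    """
    y = np.asarray(tissue_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if y.shape != times.shape:
        raise ValueError("tissue series and times must have equal length")
    if times.size < 3:
        raise ValueError("need at least 3 time points to fit Tofts parameters")
    if np.allclose(y, 0.0):
        return FitResult(PerfusionParameters(0.0, 0.3, 0.0), 0.0, True, flag="zero-uptake")

    def resid(p):
        return tofts_forward(PerfusionParameters(*p), aif, times) - y

    try:
        sol = least_squares(resid, x0=np.asarray(init, dtype=float),
                            bounds=(np.asarray(bounds[0]), np.asarray(bounds[1])),
                            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        ok = bool(sol.success)
        p = PerfusionParameters(*np.clip(sol.x, bounds[0], bounds[1]))
        rn = float(np.linalg.norm(sol.fun))
        return FitResult(p, rn, ok, flag="" if ok else "non-convergence")
    except Exception as exc:  # degenerate numerics -> flagged result, not an exception
        return FitResult(PerfusionParameters(*init), float("nan"), False,
                         flag=f"fit-error: {exc}")


class PerfusionMap:
    """Per-voxel Tofts parameters on a lattice.

    Parameters are defined on non-background voxels; vessel voxels are
    flagged macrovascular and act as fixed plasma-concentration sources.
    """

    def __init__(self, lattice: TissueLattice, Ktrans: np.ndarray,
                 ve: np.ndarray, vp: np.ndarray | None = None,
                 residual_norm: np.ndarray | None = None):
        shape = lattice.shape
        for name, arr in (("Ktrans", Ktrans), ("ve", ve)):
            if np.asarray(arr).shape != shape:
                raise LatticeError(f"{name} shape mismatch with lattice")
        self.lattice = lattice
        self.Ktrans = np.asarray(Ktrans, dtype=float)
        self.ve = np.asarray(ve, dtype=float)
        self.vp = np.zeros(shape) if vp is None else np.asarray(vp, dtype=float)
        self.residual_norm = residual_norm
        bg = ~lattice.body_mask
        self.Ktrans[bg] = 0.0
        if np.any(self.Ktrans < 0) or np.any(self.ve[lattice.body_mask] <= 0):
            raise ValueError("invalid perfusion parameters (Ktrans<0 or ve<=0)")

    @property
    def macrovascular_mask(self) -> np.ndarray:
        return self.lattice.vessel_mask


def perfusion_sources(pmap: PerfusionMap, species_plasma_conc: float,
                      tissue_field: np.ndarray,
                      relative_permeability: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel microvascular exchange rate plus the macrovascular clamp mask.

    exchange(x) = k * Ktrans(x) * (Cp - C(x)/ve(x)) on non-vessel body
    voxels (per minute, with k the species' relative permeability);
    background contributes 0.  Vessel voxels are returned as a Dirichlet
    mask: transport clamps their concentration to the plasma value.
    """
    C = np.asarray(tissue_field, dtype=float)
    if C.shape != pmap.lattice.shape:
        raise LatticeError("tissue field shape mismatch with perfusion map")
    ve = np.where(pmap.ve > 0, pmap.ve, 1.0)
    rate = relative_permeability * pmap.Ktrans * (species_plasma_conc - C / ve)
    rate = np.where(pmap.lattice.body_mask & ~pmap.macrovascular_mask, rate, 0.0)
    return rate, pmap.macrovascular_mask


def exchange_relax(tissue_field: np.ndarray, pmap: PerfusionMap,
                   species_plasma_conc: float, dt_h: float,
                   relative_permeability: float = 1.0) -> np.ndarray:
    """Exact integrator for the microvascular exchange term over dt_h hours.

    The exchange ODE dC/dt = k*Ktrans*(Cp - C/ve) is linear, so it is
    integrated exactly: C relaxes toward ve*Cp with rate k*Ktrans/ve.  Using
    the closed form keeps the outer operator split stable even though the
    exchange rate (per hour) is much faster than the outer step.  Vessel
    voxels clamp to the plasma value; background voxels are untouched.
    Ktrans is per minute; dt_h is hours.
    """
    C = np.asarray(tissue_field, dtype=float).copy()
    ve = np.where(pmap.ve > 0, pmap.ve, 1.0)
    kep_h = relative_permeability * pmap.Ktrans * 60.0 / ve
    target = ve * species_plasma_conc
    micro = pmap.lattice.body_mask & ~pmap.macrovascular_mask
    C[micro] = (target + (C - target) * np.exp(-kep_h * dt_h))[micro]
    C[pmap.macrovascular_mask] = species_plasma_conc
    return C
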