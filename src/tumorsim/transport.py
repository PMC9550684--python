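"""Reaction–diffusion transport of nutrients, lactate and drugs, coupled to
Monod-type uptake/growth — a reduced, fully documented surrogate for
genome-scale voxel metabolism.

Numerics: explicit forward-time centered-space (FTCS) scheme, 6-neighbor
(von Neumann) Laplacian, zero-flux (Neumann) boundaries via edge mirroring.
The update is automatically substepped so every substep satisfies the 3D
stability bound dt <= h²/(6D).  Negative values produced by stiff sinks are
clipped to 0 and the clipped mass is logged; a clean run has an empty log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import TissueLattice, CellDensityField

#: safety factor applied to the explicit stability bound
CFL_SAFETY = 0.9


@dataclass
class SpeciesField:
    """One chemical species on the lattice.

    name in {glucose, oxygen, amino_acids, lactate, drug:<name>};
    C : per-voxel concentration (>= 0); D : diffusion coefficient (mm²/h);
    plasma_level : systemic concentration (scalar; time-varying for drugs).
    """

    name: str
    C: np.ndarray
    D: float
    plasma_level: float = 0.0

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.D < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if np.any(self.C < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass
class MetabolicParameters:
    """Reduced Monod kinetics: growth limited by glucose and oxygen, with
    hypoxia-weighted lactate production.

    mu_max : maximal specific growth rate (1/h); K_G, K_O : half-saturation
    constants (mM); uptake_max : maximal specific uptake per nutrient
    (mmol per unit cell density per h, normalized-density scale); Y_L :
    lactate yield per glucose under full hypoxia (stoichiometric cap 2).
    """

    mu_max: float = 0.005
    K_G: float = 1.0
    K_O: float = 0.02
    uptake_max: dict = field(default_factory=lambda: {"glucose": 0.05, "oxygen": 0.1})
    Y_L: float = 2.0

    def __post_init__(self) -> None:
        if min(self.mu_max, self.K_G, self.K_O) <= 0:
            raise ValueError("mu_max, K_G, K_O must be > 0")
        if not (0 <= self.Y_L <= 2):
            raise ValueError("lactate yield must be in [0, 2]")


def _laplacian(C: np.ndarray) -> np.ndarray:
    """6-neighbor Laplacian (unscaled by h²) with zero-flux boundaries.

    Zero flux is imposed by mirroring: a boundary voxel's missing neighbor
    contributes the voxel's own value, cancelling one -C term.
    """
    L = -6.0 * C
    L[:-1] += C[1:]; L[1:] += C[:-1]; L[0] += C[0]; L[-1] += C[-1]
    L[:, :-1] += C[:, 1:]; L[:, 1:] += C[:, :-1]
    L[:, 0] += C[:, 0]; L[:, -1] += C[:, -1]
    L[:, :, :-1] += C[:, :, 1:]; L[:, :, 1:] += C[:, :, :-1]
    L[:, :, 0] += C[:, :, 0]; L[:, :, -1] += C[:, :, -1]
    return L


def diffusion_step(fieldv: SpeciesField, lattice: TissueLattice, dt: float,
                   sources: np.ndarray | None = None,
                   sinks: np.ndarray | None = None,
                   dirichlet_mask: np.ndarray | None = None,
                   dirichlet_value: float | None = None,
                   clip_log: list | None = None) -> SpeciesField:
    """Advance C by dt (hours) of FTCS diffusion with explicit source/sink rates.

    sources/sinks are rate fields (concentration per hour, both >= 0 by
    convention).  Voxels in dirichlet_mask are clamped to dirichlet_value
    after every substep (macrovascular plasma clamp).  Substeps internally
    whenever dt exceeds the stability bound.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    C = fieldv.C.copy()
    h2 = lattice.voxel_side ** 2
    net = 0.0 if sources is None and sinks is None else (
        (0.0 if sources is None else np.asarray(sources, dtype=float))
        - (0.0 if sinks is None else np.asarray(sinks, dtype=float)))
    if fieldv.D > 0:
        dt_max = CFL_SAFETY * h2 / (6.0 * fieldv.D)
        nsub = max(1, int(np.ceil(dt / dt_max))) if dt > 0 else 1
    else:
        nsub = 1
    sub = dt / nsub
    coef = fieldv.D * sub / h2
    for _ in range(nsub):
        if fieldv.D > 0:
            C = C + coef * _laplacian(C)
        if np.ndim(net) or net != 0.0:
            C = C + sub * net
        if dirichlet_mask is not None:
            C[dirichlet_mask] = dirichlet_value
        neg = C < 0
        if np.any(neg):
            if clip_log is not None:
                clip_log.append(float(-C[neg].sum()))
            C[neg] = 0.0
    return SpeciesField(fieldv.name, C, fieldv.D, fieldv.plasma_level)


def monod_rates(params: MetabolicParameters, glucose: np.ndarray,
                oxygen: np.ndarray, rho: np.ndarray
                ) -> tuple[np.ndarray, dict, np.ndarray]:
    """Per-voxel growth, nutrient uptake and lactate production rates.

    mu = mu_max * G/(G+K_G) * O/(O+K_O)          (1/h)
    uptake_s = uptake_max_s * (Monod term)_s * rho
    lactate  = Y_L * glucose_uptake * K_O/(O+K_O)   (hypoxia-weighted)
    """
    G = np.asarray(glucose, dtype=float)
    O = np.asarray(oxygen, dtype=float)
    if np.any(G < 0) or np.any(O < 0) or np.any(np.asarray(rho) < 0):
        raise ValueError("concentrations and density must be >= 0")
    fG = G / (G + params.K_G)
    fO = O / (O + params.K_O)
    mu = params.mu_max * fG * fO
    uptake = {
        "glucose": params.uptake_max.get("glucose", 0.0) * fG * rho,
        "oxygen": params.uptake_max.get("oxygen", 0.0) * fO * rho,
    }
    w_hypoxia = params.K_O / (O + params.K_O)
    lactate_prod = params.Y_L * uptake["glucose"] * w_hypoxia
    return mu, uptake, lactate_prod


def density_update(density: CellDensityField, mu: np.ndarray, delta: np.ndarray,
                   dt: float) -> CellDensityField:
    """Logistic-limited growth/kill update of tumor cell density.

    rho' = rho + dt * (mu*(1 - rho/rho_max) - delta) * rho, clamped to
    [0, rho_max].  rho = 0 is a fixed point (no spontaneous seeding).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    mu = np.asarray(mu, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(mu < 0) or np.any(delta < 0):
        raise ValueError("growth and kill rates must be >= 0")
    rho = density.rho
    new = rho + dt * (mu * (1.0 - rho / density.rho_max) - delta) * rho
    new = np.clip(new, 0.0, density.rho_max)
    return CellDensityField(new, density.rho_max, density.rho_detect)


def build_neumann_laplacian(shape: tuple[int, int, int]):
    """Sparse 6-neighbor Laplacian (unscaled by h²) with zero-flux boundaries."""
    from scipy import sparse

    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    rows, cols = [], []
    for axis in range(3):
        a = np.swapaxes(idx, 0, axis)
        lo, hi = a[:-1].ravel(), a[1:].ravel()
        rows += [lo, hi]
        cols += [hi, lo]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    off = sparse.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    deg = np.asarray(off.sum(axis=1)).ravel()
    return (off - sparse.diags(deg)).tocsr()


class SteadyStateSolver:
    """Quasi-steady-state solver for a diffusing species with linear plasma
    exchange and a nonlinear (Monod) consumption term:

        0 = D ∇²C + alpha - beta*C - uptake(C)

    Oxygen equilibrates orders of magnitude faster than the tissue evolves,
    so the engine relaxes it to steady state once per outer step.  The
    linear operator (beta*I - D*L/h², Dirichlet rows on vessel voxels) is
    factorized once per case; the Monod sink is handled by Picard iteration.
    """

    def __init__(self, lattice: TissueLattice, D: float, beta: np.ndarray,
                 dirichlet_mask: np.ndarray | None = None):
        from scipy import sparse

        self.shape = lattice.shape
        self.D = D
        L = build_neumann_laplacian(self.shape) * (D / lattice.voxel_side ** 2)
        A = sparse.diags(np.asarray(beta, dtype=float).ravel()) - L
        self.dirichlet = (np.zeros(self.shape, bool) if dirichlet_mask is None
                          else np.asarray(dirichlet_mask, bool))
        self._coupling = None
        if self.dirichlet.any():
            # symmetric Dirichlet elimination: zero the clamped rows/columns,
            # pin them with a unit diagonal, and keep the free-row coupling to
            # clamped voxels so it can be moved to the right-hand side
            free = (~self.dirichlet).ravel().astype(float)
            F = sparse.diags(free)
            Dm = sparse.diags(1.0 - free)
            self._coupling = (F @ A @ Dm).tocsr()
            A = F @ A @ F + Dm
        # beta vanishes outside the body; regularize so the SPD system stays
        # nonsingular (those voxels relax to ~0 anyway)
        diag = A.diagonal()
        fix = np.abs(diag) < 1e-12
        if fix.any():
            A = A + sparse.diags(np.where(fix, 1e-9, 0.0))
        self.A = A.tocsr()
        self._Minv = 1.0 / self.A.diagonal()

    def _linear_solve(self, rhs: np.ndarray, x0: np.ndarray) -> np.ndarray:
        from scipy.sparse.linalg import cg, LinearOperator

        n = rhs.size
        M = LinearOperator((n, n), matvec=lambda v: self._Minv * v)
        x, info = cg(self.A, rhs, x0=x0, M=M, rtol=1e-8, atol=0.0, maxiter=2000)
        if info != 0:  # fall back to a direct solve on CG breakdown
            from scipy.sparse.linalg import spsolve
            x = spsolve(self.A.tocsc(), rhs)
        return x

    def solve(self, alpha: np.ndarray, uptake_fn=None,
              dirichlet_value: float = 0.0, C0: np.ndarray | None = None,
              tol: float = 1e-6, max_picard: int = 30) -> np.ndarray:
        """Relax to steady state: Picard on the Monod sink, warm-started CG
        on the symmetric positive-definite linear system."""
        dmask = self.dirichlet.ravel()
        rhs0 = np.asarray(alpha, dtype=float).ravel().copy()
        if self._coupling is not None:
            xd = np.where(dmask, dirichlet_value, 0.0)
            rhs0 -= self._coupling @ xd
        rhs0[dmask] = dirichlet_value
        C = (np.zeros(self.shape) if C0 is None else np.asarray(C0, float)).copy()
        C.ravel()[dmask] = dirichlet_value
        for _ in range(max_picard):
            rhs = rhs0.copy()
            if uptake_fn is not None:
                u = np.asarray(uptake_fn(C), dtype=float).ravel()
                u[dmask] = 0.0
                rhs -= u
            x = self._linear_solve(rhs, C.ravel())
            C_new = np.clip(x.reshape(self.shape), 0.0, None)
            change = float(np.max(np.abs(C_new - C)))
            scale = max(float(np.max(np.abs(C_new))), 1e-12)
            C = C_new
            if uptake_fn is None or change < tol * scale:
                break
        return C
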