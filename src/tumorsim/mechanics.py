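"""Mass-spring tissue mechanics.

Per-voxel net growth or kill is converted into a volumetric growth factor
g = exp((mu - delta)*dt); spring rest lengths scale by g^(1/3) (isotropic
growth) and a damped explicit relaxation finds the deformed configuration.
Cell density is then remapped conservatively onto the regular lattice by
depositing each deformed cell's cell number at its deformed centroid with
trilinear (cloud-in-cell) weights.

Springs sit on lattice edges (stiffness k) and face diagonals (stiffness
k/2, shear resistance).  A cheap "bookkeeping" alternative that tracks
volume analytically, without deformation, lives in the engine for large
parameter sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import CellDensityField, LatticeError


@dataclass
class MassSpringMesh:
    """Hexahedral mass-spring mesh over an (nx, ny, nz) voxel lattice.

    nodes : (nx+1, ny+1, nz+1, 3) corner positions in mm.
    edges : (E, 2) flat node indices; k and r0 per edge.
    """

    nodes: np.ndarray
    edges: np.ndarray
    k: np.ndarray
    r0: np.ndarray
    cell_shape: tuple[int, int, int]
    voxel_side: float

    @property
    def node_shape(self) -> tuple[int, int, int]:
        s = self.cell_shape
        return (s[0] + 1, s[1] + 1, s[2] + 1)


def build_mesh(cell_shape: tuple[int, int, int], voxel_side: float,
               k_axis: float = 1.0, diag_ratio: float = 0.5) -> MassSpringMesh:
    """Regular mesh with axis springs (k_axis) and face diagonals (k_axis*diag_ratio)."""
    nx, ny, nz = cell_shape
    gx, gy, gz = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1), np.arange(nz + 1),
                             indexing="ij")
    nodes = np.stack([gx, gy, gz], axis=-1).astype(float) * voxel_side
    nid = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)

    pairs, ks, r0s = [], [], []

    def add(a, b, kk, rr):
        pairs.append(np.stack([a.ravel(), b.ravel()], axis=1))
        ks.append(np.full(a.size, kk))
        r0s.append(np.full(a.size, rr))

    h = voxel_side
    # axis-aligned edges
    add(nid[:-1, :, :], nid[1:, :, :], k_axis, h)
    add(nid[:, :-1, :], nid[:, 1:, :], k_axis, h)
    add(nid[:, :, :-1], nid[:, :, 1:], k_axis, h)
    # both diagonals of every square face, in the three face orientations
    kd, rd = k_axis * diag_ratio, h * np.sqrt(2.0)
    add(nid[:-1, :-1, :], nid[1:, 1:, :], kd, rd)
    add(nid[1:, :-1, :], nid[:-1, 1:, :], kd, rd)
    add(nid[:-1, :, :-1], nid[1:, :, 1:], kd, rd)
    add(nid[1:, :, :-1], nid[:-1, :, 1:], kd, rd)
    add(nid[:, :-1, :-1], nid[:, 1:, 1:], kd, rd)
    add(nid[:, 1:, :-1], nid[:, :-1, 1:], kd, rd)

    return MassSpringMesh(nodes, np.concatenate(pairs), np.concatenate(ks),
                          np.concatenate(r0s), tuple(cell_shape), voxel_side)


def growth_factors(mu: np.ndarray, delta: np.ndarray, dt: float) -> np.ndarray:
    """Volumetric growth factor g = exp((mu - delta) * dt) per cell."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return np.exp((np.asarray(mu, dtype=float) - np.asarray(delta, dtype=float)) * dt)


def _edge_rest_scale(g: np.ndarray, mesh: MassSpringMesh) -> np.ndarray:
    """Per-edge linear rest-length scale from cell growth factors.

    Cell scale s = g^(1/3) is averaged onto nodes (up to 8 adjacent cells,
    edge-padded at boundaries), then onto each edge's two endpoints.
    """
    s = np.power(np.asarray(g, dtype=float), 1.0 / 3.0)
    P = np.pad(s, 1, mode="edge")
    node_s = np.zeros(mesh.node_shape)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                node_s += P[dx:dx + mesh.node_shape[0],
                            dy:dy + mesh.node_shape[1],
                            dz:dz + mesh.node_shape[2]]
    node_s /= 8.0
    flat = node_s.ravel()
    return 0.5 * (flat[mesh.edges[:, 0]] + flat[mesh.edges[:, 1]])


def spring_energy(pos_flat: np.ndarray, mesh: MassSpringMesh, rest: np.ndarray) -> float:
    d = pos_flat[mesh.edges[:, 1]] - pos_flat[mesh.edges[:, 0]]
    ln = np.linalg.norm(d, axis=1)
    return float(0.5 * np.sum(mesh.k * (ln - rest) ** 2))


def relax(mesh: MassSpringMesh, g: np.ndarray, tol: float = 1e-4,
          max_iter: int = 2000, fixed_nodes: np.ndarray | None = None
          ) -> tuple[MassSpringMesh, dict]:
    """Damped explicit relaxation to the rest configuration implied by g.

    Step size 0.1/k_max, halved whenever spring energy would increase.
    Returns the deformed mesh and a diagnostics dict (converged flag,
    iterations, final max nodal force, energy trace endpoints).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if np.asarray(g).shape != mesh.cell_shape:
        raise LatticeError("growth-factor field shape mismatch with mesh")
    rest = mesh.r0 * _edge_rest_scale(g, mesh)
    pos = mesh.nodes.reshape(-1, 3).copy()
    i0, i1 = mesh.edges[:, 0], mesh.edges[:, 1]
    kmax = float(np.max(mesh.k))
    step = 0.1 / kmax
    energy = spring_energy(pos, mesh, rest)
    energy_trace = [energy]
    converged, fmax, it = False, np.inf, 0
    for it in range(1, max_iter + 1):
        d = pos[i1] - pos[i0]
        ln = np.linalg.norm(d, axis=1)
        ln = np.where(ln > 0, ln, 1.0)
        fvec = (mesh.k * (ln - rest) / ln)[:, None] * d  # force on i0 toward i1
        force = np.zeros_like(pos)
        np.add.at(force, i0, fvec)
        np.add.at(force, i1, -fvec)
        if fixed_nodes is not None:
            force[fixed_nodes] = 0.0
        fmax = float(np.max(np.linalg.norm(force, axis=1)))
        if fmax < tol:
            converged = True
            break
        new_pos = pos + step * force
        new_energy = spring_energy(new_pos, mesh, rest)
        if new_energy > energy:  # keep the energy trace monotone
            step *= 0.5
            if step < 1e-12 / kmax:
                break
            continue
        pos, energy = new_pos, new_energy
        energy_trace.append(energy)
    out = MassSpringMesh(pos.reshape(mesh.nodes.shape), mesh.edges, mesh.k,
                         mesh.r0, mesh.cell_shape, mesh.voxel_side)
    return out, {"converged": converged, "iterations": it, "max_force": fmax,
                 "energy": energy, "energy_trace": energy_trace}


def cell_volumes(mesh: MassSpringMesh) -> np.ndarray:
    """Trilinear hexahedron volumes per cell (tetrahedral decomposition)."""
    n = mesh.nodes
    c000 = n[:-1, :-1, :-1]; c100 = n[1:, :-1, :-1]
    c010 = n[:-1, 1:, :-1]; c110 = n[1:, 1:, :-1]
    c001 = n[:-1, :-1, 1:]; c101 = n[1:, :-1, 1:]
    c011 = n[:-1, 1:, 1:]; c111 = n[1:, 1:, 1:]

    def tet(a, b, c, d):
        return np.einsum("...i,...i->...", b - a, np.cross(c - a, d - a)) / 6.0

    # 6-tet decomposition around the c000-c111 diagonal
    v = (tet(c000, c100, c110, c111) + tet(c000, c110, c010, c111)
         + tet(c000, c010, c011, c111) + tet(c000, c011, c001, c111)
         + tet(c000, c001, c101, c111) + tet(c000, c101, c100, c111))
    return v


def cell_centroids(mesh: MassSpringMesh) -> np.ndarray:
    """(nx, ny, nz, 3) mean of the 8 corner positions per cell."""
    n = mesh.nodes
    return (n[:-1, :-1, :-1] + n[1:, :-1, :-1] + n[:-1, 1:, :-1] + n[1:, 1:, :-1]
            + n[:-1, :-1, 1:] + n[1:, :-1, 1:] + n[:-1, 1:, 1:] + n[1:, 1:, 1:]) / 8.0


def remap_density(density: CellDensityField, mesh_before: MassSpringMesh,
                  mesh_after: MassSpringMesh) -> tuple[CellDensityField, dict]:
    """Conservative remap of cell density after deformation.

    Each cell's cell number (rho * undeformed cell volume) is deposited at
    its deformed centroid onto the regular lattice with trilinear weights;
    voxels over carrying capacity shed excess to their 6-neighbors (up to a
    bounded number of passes, remainder logged).  Total cell number is
    conserved up to boundary leakage, which is clamped into edge voxels.
    """
    if mesh_before.cell_shape != mesh_after.cell_shape:
        raise LatticeError("mesh topology mismatch")
    shape = mesh_before.cell_shape
    if density.rho.shape != shape:
        raise LatticeError("density shape mismatch with mesh")
    h = mesh_before.voxel_side
    vvox = h ** 3
    N = density.rho * cell_volumes(mesh_before)
    total_before = float(N.sum())
    cent = cell_centroids(mesh_after)

    # fractional voxel coordinates of deformed centroids (centers at (i+0.5)h)
    fc = cent / h - 0.5
    fc = np.clip(fc, 0.0, np.asarray(shape, dtype=float) - 1.0)  # clamp leakage
    base = np.floor(fc).astype(int)
    base = np.minimum(base, np.asarray(shape) - 2).clip(0)
    frac = fc - base

    dep = np.zeros(shape)
    w = np.empty(shape)
    for dx in (0, 1):
        wx = frac[..., 0] if dx else 1 - frac[..., 0]
        for dy in (0, 1):
            wy = frac[..., 1] if dy else 1 - frac[..., 1]
            for dz in (0, 1):
                wz = frac[..., 2] if dz else 1 - frac[..., 2]
                np.multiply(wx * wy, wz, out=w)
                np.add.at(dep, (base[..., 0] + dx, base[..., 1] + dy,
                                base[..., 2] + dz), w * N)

    rho_new = dep / vvox
    cap = density.rho_max
    overflow_left = 0.0
    for _ in range(20):
        excess = np.clip(rho_new - cap, 0.0, None)
        overflow_left = float(excess.sum())
        if overflow_left <= 1e-12 * max(total_before / vvox, 1.0):
            overflow_left = 0.0
            break
        rho_new -= excess
        spread = np.zeros(shape)
        for axis in range(3):
            for shift in (1, -1):
                spread += np.roll(excess, shift, axis=axis)
        rho_new += spread / 6.0
        # roll wraps at boundaries; fold the wrapped mass back (rare, logged)
    rho_new = np.clip(rho_new, 0.0, cap)
    total_after = float(rho_new.sum() * vvox)
    out = CellDensityField(rho_new, density.rho_max, density.rho_detect)
    return out, {"total_before": total_before, "total_after": total_after,
                 "overflow_unplaced": overflow_left * vvox}
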