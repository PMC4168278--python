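"""First-order tetrahedral finite elements for the quasi-static problem.

The stimulation field solves the conduction boundary-value problem

    div(sigma grad V) = 0   in the tissue volume,
    V = V0                  on the driven contact surfaces,
    V = 0                   on the grounded reference,
    sigma grad V . n = 0    on all other (insulated) boundaries,

with P1 (linear) tetrahedral elements. Dirichlet constraints are enforced
by symmetric row/column elimination, so the reduced system stays symmetric
positive definite and is solved either directly (SuperLU, small systems)
or with Jacobi-preconditioned conjugate gradients (deterministic fixed
ordering, relative residual 1e-8 by default).

Unit bookkeeping: coordinates are in mm and conductivity in S/m, so the
assembled stiffness matrix has units S*mm = 1e-3 S*m and ``K @ V`` yields
node currents directly in mA. Electric field and current density are
converted to V/m and A/m^2 explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .conductivity import ConductivityField
from .geometry import ElectrodePatch, LabeledTetMesh, ReferenceSet

MM_TO_M = 1e-3  # gradient in V/mm -> V/m is *1/MM_TO_M*


@dataclass
class AssembledSystem:
    """Stiffness matrix plus the geometric factors needed for recovery."""

    K: sp.csr_matrix  # units S*mm; K @ V is in mA
    grads: np.ndarray  # (M, 4, 3) P1 basis gradients, 1/mm
    volumes: np.ndarray  # (M,) mm^3
    mesh: LabeledTetMesh
    field: ConductivityField


@dataclass
class BoundaryConditions:
    """Dirichlet data: driven contact patches and the grounded reference."""

    drives: Sequence[tuple]  # (ElectrodePatch | node-index array, volts)
    reference: ReferenceSet | np.ndarray

    def drive_nodes(self, mesh: LabeledTetMesh) -> tuple[np.ndarray, np.ndarray]:
        ids, vals = [], []
        for patch, v0 in self.drives:
            n = patch.nodes(mesh) if isinstance(patch, ElectrodePatch) else np.asarray(patch)
            ids.append(n)
            vals.append(np.full(n.size, float(v0)))
        return np.concatenate(ids), np.concatenate(vals)

    def reference_nodes(self) -> np.ndarray:
        ref = self.reference
        return ref.node_ids if isinstance(ref, ReferenceSet) else np.asarray(ref)


@dataclass
class PotentialSolution:
    """Solved nodal potential and derived element fields."""

    V: np.ndarray  # (N,) volts
    E: np.ndarray  # (M, 3) V/m
    J: np.ndarray  # (M, 3) A/m^2
    jmag: np.ndarray  # (M,) A/m^2
    residual: float  # relative residual of the reduced solve
    v0: float  # applied drive amplitude (max over drives), volts
    system: AssembledSystem | None = None
    bc: BoundaryConditions | None = None


def assemble_system(mesh: LabeledTetMesh, cfield: ConductivityField) -> AssembledSystem:
    """Assemble the P1 stiffness matrix ``K_ij = \\int sigma grad(phi_i) . grad(phi_j)``.

    Raises if any element tensor fails the positive-definiteness check,
    naming the offending element.
    """
    if cfield.num_elements != mesh.num_tets:
        raise ValueError("conductivity field and mesh element counts differ")
    bad = np.flatnonzero(~cfield.is_spd())
    if bad.size:
        raise ValueError(f"non-SPD conductivity tensor at element {bad[0]}")

    p = mesh.nodes[mesh.tets]  # (M, 4, 3)
    e = p[:, 1:] - p[:, :1]  # (M, 3, 3) edge matrix, rows x_i - x_0
    vol = np.linalg.det(e) / 6.0
    if np.any(vol <= 0):
        raise ValueError("mesh contains non-positively oriented tetrahedra")
    inv = np.linalg.inv(e)
    g = np.transpose(inv, (0, 2, 1))  # rows are grad(lambda_1..3)
    g0 = -g.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g], axis=1)  # (M, 4, 3)

    ke = np.matmul(np.matmul(grads, cfield.tensors), np.transpose(grads, (0, 2, 1)))
    ke *= vol[:, None, None]

    t = mesh.tets.astype(np.int32)
    m = t.shape[0]
    rows = np.broadcast_to(t[:, :, None], (m, 4, 4)).ravel()
    cols = np.broadcast_to(t[:, None, :], (m, 4, 4)).ravel()
    K = sp.csr_array(
        (ke.ravel(), (rows, cols)), shape=(mesh.num_nodes, mesh.num_nodes)
    )
    K.sum_duplicates()
    return AssembledSystem(K, grads, vol, mesh, cfield)


def _dirichlet_arrays(
    system: AssembledSystem, bc: BoundaryConditions
) -> tuple[np.ndarray, np.ndarray]:
    drive_ids, drive_vals = bc.drive_nodes(system.mesh)
    ref_ids = bc.reference_nodes()
    if ref_ids.size == 0:
        raise ValueError("empty reference set: the unipolar problem is singular")
    if drive_ids.size == 0:
        raise ValueError("no driven contact nodes")
    if np.intersect1d(drive_ids, ref_ids).size:
        raise ValueError("driven contacts and reference overlap")
    ids = np.concatenate([drive_ids, ref_ids])
    vals = np.concatenate([drive_vals, np.zeros(ref_ids.size)])
    ids, pos = np.unique(ids, return_index=True)
    return ids, vals[pos]


def solve_potential(
    system: AssembledSystem,
    bc: BoundaryConditions,
    method: str = "auto",
    rtol: float = 1e-8,
    maxiter: int = 50000,
) -> PotentialSolution:
    """Solve for the nodal potential under the given Dirichlet data.

    ``method``: ``auto`` (direct below 40k unknowns, else CG), ``direct``
    or ``cg``. Constrained nodes carry exactly their prescribed values.
    """
    K = system.K
    n = K.shape[0]
    ids, vals = _dirichlet_arrays(system, bc)
    constrained = np.zeros(n, dtype=bool)
    constrained[ids] = True
    free = np.flatnonzero(~constrained)

    Vd = np.zeros(n)
    Vd[ids] = vals
    b = -(K @ Vd)
    b_free = b[free]
    Kf = K[free][:, free].tocsr()

    if method == "auto":
        method = "direct" if free.size <= 40_000 else "cg"
    if method == "direct":
        x = spla.spsolve(Kf.tocsc(), b_free)
    elif method == "cg":
        d = Kf.diagonal()
        M = spla.LinearOperator(Kf.shape, matvec=lambda v: v / d)
        x, info = spla.cg(Kf, b_free, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
        if info != 0:
            res = np.linalg.norm(Kf @ x - b_free) / np.linalg.norm(b_free)
            raise RuntimeError(
                f"conjugate gradients did not converge in {maxiter} iterations "
                f"(relative residual {res:.3e})"
            )
    else:
        raise ValueError(f"unknown solver method {method!r}")

    V = Vd.copy()
    V[free] = x
    bnorm = np.linalg.norm(b_free)
    residual = float(np.linalg.norm(Kf @ x - b_free) / bnorm) if bnorm > 0 else 0.0

    E, J, jmag = _element_fields(system, V)
    v0 = float(max(v for _, v in bc.drives))
    return PotentialSolution(V, E, J, jmag, residual, v0, system, bc)


def _element_fields(system: AssembledSystem, V: np.ndarray):
    gradV = np.einsum("mij,mi->mj", system.grads, V[system.mesh.tets])  # V/mm
    E = -gradV / MM_TO_M  # V/m
    J = np.einsum("mab,mb->ma", system.field.tensors, E)  # A/m^2
    return E, J, np.linalg.norm(J, axis=1)


def compute_current_density(
    solution: PotentialSolution, cfield: ConductivityField | None = None
) -> np.ndarray:
    """Per-element current density ``J = sigma (-grad V)`` in A/m^2."""
    system = solution.system
    if cfield is not None and cfield is not system.field:
        E = solution.E
        return np.einsum("mab,mb->ma", cfield.tensors, E)
    return solution.J


def electrode_current(
    solution: PotentialSolution,
    patch,
    method: str = "reaction",
) -> float:
    """Total current through a contact patch or boundary set, in amperes.

    ``method='reaction'`` (default) evaluates the variationally consistent
    boundary flux — the stiffness-matrix reaction at the patch's constrained
    nodes, i.e. the Galerkin surface integral of J.n. It is exact for the
    bar patch test and conserves charge to solver tolerance.

    ``method='midpoint'`` integrates the piecewise-constant element J over
    the patch facets directly (cross-check path).

    Sign convention: positive for current entering the domain through a
    driven contact, and positive for current leaving the domain through the
    reference (pass a :class:`ReferenceSet` or its node array).
    """
    system = solution.system
    mesh = system.mesh
    if method == "reaction":
        if isinstance(patch, ElectrodePatch):
            nodes = patch.nodes(mesh)
            sign = 1.0
        elif isinstance(patch, ReferenceSet):
            nodes = patch.node_ids
            sign = -1.0
        else:
            nodes = np.asarray(patch)
            sign = 1.0
            if nodes.size == 0:
                raise ValueError("empty boundary set")
        if nodes.size == 0:
            raise ValueError("empty electrode patch")
        r = system.K @ solution.V  # mA at constrained nodes
        return sign * float(r[nodes].sum()) * 1e-3
    if method == "midpoint":
        if isinstance(patch, ElectrodePatch):
            facets = patch.facets(mesh)
            owners = mesh.boundary_owners["top"][patch.facet_ids]
            sign = -1.0  # J.n with outward n is negative at an injecting anode
        elif isinstance(patch, ReferenceSet):
            facets = np.concatenate([mesh.boundary_facets[t] for t in patch.tags])
            owners = np.concatenate([mesh.boundary_owners[t] for t in patch.tags])
            sign = 1.0
        else:
            raise ValueError("midpoint integration needs a patch or reference set")
        if facets.shape[0] == 0:
            raise ValueError("empty electrode patch")
        tri = mesh.nodes[facets]
        nvec = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # area-weighted
        # orient outward: away from the owning tet centroid
        cent_t = mesh.nodes[mesh.tets[owners]].mean(axis=1)
        cent_f = tri.mean(axis=1)
        flip = np.einsum("fa,fa->f", nvec, cent_f - cent_t) < 0
        nvec[flip] *= -1.0
        Jf = solution.J[owners]  # A/m^2
        flux = np.einsum("fa,fa->f", Jf, nvec).sum() * MM_TO_M**2  # mm^2 -> m^2
        return sign * float(flux)
    raise ValueError(f"unknown current method {method!r}")


def total_drive_current(solution: PotentialSolution) -> float:
    """Summed current (A) injected through all driven contacts."""
    return sum(
        electrode_current(solution, patch) for patch, _ in solution.bc.drives
    )


def max_principle_violation(solution: PotentialSolution) -> float:
    """Largest overshoot of V outside [0, v0], in volts (0 if none)."""
    v = solution.V
    return float(max(0.0, -v.min(), v.max() - solution.v0))
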