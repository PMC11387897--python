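"""Linear elastostatic solver for four-node (constant-strain) tetrahedra.

The solver implements the textbook small-strain pipeline: per-element
stiffness ``K_e = V_e B^T D B`` with the constant-strain B-matrix and the
isotropic elasticity matrix D(E, nu); sparse assembly; Dirichlet constraints
by row/column elimination (so constrained displacements are exactly zero);
direct sparse factorization with a conjugate-gradient fallback for large
systems; and element-wise stress/strain recovery with von Mises stress and
principal strains.

Units: mm / N / MPa.  Bone is modeled as a single homogeneous isotropic
material (the comparative analyses this package supports use E = 15000 MPa,
nu = 0.29 throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh_io import TetMesh

__all__ = [
    "MaterialProperties",
    "LoadCase",
    "SolutionField",
    "SolverError",
    "element_stiffness",
    "solve",
    "von_mises_from_tensor",
    "principal_strains",
]

# default material: sub-adult Alligator mississippiensis skull bone
DEFAULT_E_MPA = 15000.0
DEFAULT_NU = 0.29

# DOF count above which the direct factorization gives way to CG
CG_DOF_THRESHOLD = 300_000
CG_TOL = 1e-10


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class MaterialProperties:
    """Isotropic linear elasticity: Young's modulus (MPa), Poisson ratio."""

    youngs_modulus: float = DEFAULT_E_MPA
    poisson_ratio: float = DEFAULT_NU

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (-1, 0.5)")

    def d_matrix(self) -> np.ndarray:
        """6x6 isotropic elasticity matrix in Voigt order (xx,yy,zz,xy,yz,zx)."""
        E, nu = self.youngs_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


@dataclass
class LoadCase:
    """Constraints and loads for one analysis.

    ``constraints`` maps node index -> iterable of fixed directions (0,1,2);
    ``point_loads`` holds non-muscle loads (bite forces); ``muscle_loads``
    holds per-node muscle force vectors keyed by group name, kept separate so
    sensitivity perturbation can rescale muscles without touching bite loads.
    """

    constraints: dict[int, tuple[int, ...]] = field(default_factory=dict)
    point_loads: dict[int, np.ndarray] = field(default_factory=dict)
    muscle_loads: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)

    def total_nodal_forces(self, n_nodes: int) -> np.ndarray:
        """(n,3) array summing bite and muscle loads per node."""
        f = np.zeros((n_nodes, 3))
        for node, vec in self.point_loads.items():
            f[node] += vec
        for group in self.muscle_loads.values():
            for node, vec in group.items():
                f[node] += vec
        return f

    def copy(self) -> "LoadCase":
        return LoadCase(
            constraints={k: tuple(v) for k, v in self.constraints.items()},
            point_loads={k: np.array(v) for k, v in self.point_loads.items()},
            muscle_loads={
                g: {k: np.array(v) for k, v in grp.items()}
                for g, grp in self.muscle_loads.items()
            },
        )


@dataclass
class SolutionField:
    """Solved displacement field and recovered element quantities."""

    displacements: np.ndarray  # (n,3) mm
    element_strain: np.ndarray  # (m,3,3)
    element_stress: np.ndarray  # (m,3,3) MPa
    von_mises: np.ndarray  # (m,) MPa
    max_principal_strain: np.ndarray  # (m,)
    reactions: dict[int, np.ndarray]  # constrained node -> (3,) N
    element_volumes: np.ndarray  # (m,) mm^3


def _b_matrix(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Constant-strain B (6x12) and volume for one tet (coords 4x3)."""
    a, b, c, d = coords
    J = np.stack([b - a, c - a, d - a])  # rows are edge vectors
    detJ = np.linalg.det(J)
    vol = abs(detJ) / 6.0
    if vol == 0.0:
        raise SolverError("zero-volume tetrahedron")
    # shape-function gradients: rows of inv(J) give grad of (L2,L3,L4)
    grad_rest = np.linalg.inv(J)  # columns? -> grad(N_i) = inv(J).T rows
    gN = np.empty((4, 3))
    gN[1:] = grad_rest.T
    gN[0] = -gN[1:].sum(axis=0)
    B = np.zeros((6, 12))
    for i in range(4):
        gx, gy, gz = gN[i]
        col = 3 * i
        B[0, col] = gx
        B[1, col + 1] = gy
        B[2, col + 2] = gz
        B[3, col] = gy
        B[3, col + 1] = gx
        B[4, col + 1] = gz
        B[4, col + 2] = gy
        B[5, col] = gz
        B[5, col + 2] = gx
    return B, vol


def element_stiffness(
    tet_coords: np.ndarray, material: MaterialProperties
) -> np.ndarray:
    """12x12 stiffness ``V_e B^T D B`` of a single constant-strain tet."""
    B, vol = _b_matrix(np.asarray(tet_coords, dtype=float))
    D = material.d_matrix()
    K = vol * B.T @ D @ B
    return (K + K.T) / 2.0  # enforce exact symmetry


def _all_b_matrices(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized B matrices (m,6,12) and volumes (m,) for the whole mesh."""
    coords = mesh.nodes[mesh.tets]  # (m,4,3)
    J = coords[:, 1:] - coords[:, :1]  # (m,3,3)
    detJ = np.linalg.det(J)
    vols = np.abs(detJ) / 6.0
    if np.any(vols == 0.0):
        raise SolverError("zero-volume tetrahedron in mesh")
    invJ = np.linalg.inv(J)
    gN = np.empty((len(mesh.tets), 4, 3))
    gN[:, 1:] = np.transpose(invJ, (0, 2, 1))
    gN[:, 0] = -gN[:, 1:].sum(axis=1)
    B = np.zeros((len(mesh.tets), 6, 12))
    for i in range(4):
        gx, gy, gz = gN[:, i, 0], gN[:, i, 1], gN[:, i, 2]
        col = 3 * i
        B[:, 0, col] = gx
        B[:, 1, col + 1] = gy
        B[:, 2, col + 2] = gz
        B[:, 3, col] = gy
        B[:, 3, col + 1] = gx
        B[:, 4, col + 1] = gz
        B[:, 4, col + 2] = gy
        B[:, 5, col] = gz
        B[:, 5, col + 2] = gx
    return B, vols


def _assemble(mesh: TetMesh, material: MaterialProperties) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    B, vols = _all_b_matrices(mesh)
    D = material.d_matrix()
    # K_e = V_e B^T D B, batched
    Ke = np.einsum("e,eji,jk,ekl->eil", vols, B, D, B, optimize=True)
    Ke = (Ke + np.transpose(Ke, (0, 2, 1))) / 2.0
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)
    ).tocsr()
    return K, B, vols


def von_mises_from_tensor(stress: np.ndarray) -> float | np.ndarray:
    """Von Mises equivalent stress of symmetric tensor(s) (…,3,3).

    Rotation-invariant: sqrt(1/2 [(s1-s2)^2 + (s2-s3)^2 + (s3-s1)^2]) in
    terms of principal stresses, computed here directly from components.
    """
    s = np.asarray(stress, dtype=float)
    sx, sy, sz = s[..., 0, 0], s[..., 1, 1], s[..., 2, 2]
    txy, tyz, tzx = s[..., 0, 1], s[..., 1, 2], s[..., 2, 0]
    vm2 = 0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2) + 3.0 * (
        txy**2 + tyz**2 + tzx**2
    )
    return np.sqrt(np.maximum(vm2, 0.0))


def principal_strains(strain: np.ndarray) -> np.ndarray:
    """Eigenvalues of symmetric strain tensor(s), sorted descending."""
    w = np.linalg.eigvalsh(np.asarray(strain, dtype=float))
    return w[..., ::-1]


def _voigt_to_tensor(v: np.ndarray, shear_half: bool) -> np.ndarray:
    """(…,6) Voigt (xx,yy,zz,xy,yz,zx) -> (…,3,3); engineering shear halved
    for strain."""
    t = np.zeros(v.shape[:-1] + (3, 3))
    t[..., 0, 0] = v[..., 0]
    t[..., 1, 1] = v[..., 1]
    t[..., 2, 2] = v[..., 2]
    h = 0.5 if shear_half else 1.0
    t[..., 0, 1] = t[..., 1, 0] = h * v[..., 3]
    t[..., 1, 2] = t[..., 2, 1] = h * v[..., 4]
    t[..., 2, 0] = t[..., 0, 2] = h * v[..., 5]
    return t


def solve(
    mesh: TetMesh,
    material: MaterialProperties,
    loads: LoadCase,
    cg_dof_threshold: int = CG_DOF_THRESHOLD,
) -> SolutionField:
    """Solve K u = f with Dirichlet elimination; recover element fields.

    Raises :class:`SolverError` if the constraint set leaves rigid-body
    modes (singular reduced system).
    """
    n = mesh.n_nodes
    ndof = 3 * n
    K, B, vols = _assemble(mesh, material)

    f = loads.total_nodal_forces(n).ravel()

    fixed = np.zeros(ndof, dtype=bool)
    for node, dirs in loads.constraints.items():
        for d in dirs:
            fixed[3 * node + d] = True
    if not fixed.any():
        if f.any():
            raise SolverError("no constraints: rigid-body modes unconstrained")
    free = ~fixed

    u = np.zeros(ndof)
    if free.any() and f[free].any():
        Kff = K[free][:, free]
        ff = f[free]
        nf = int(free.sum())
        if nf <= cg_dof_threshold:
            try:
                lu = spla.splu(Kff.tocsc())
            except RuntimeError as exc:
                raise SolverError(f"singular stiffness (insufficient constraints): {exc}")
            uf = lu.solve(ff)
            if not np.all(np.isfinite(uf)):
                raise SolverError("singular stiffness: non-finite solution "
                                  "(constraints leave a rigid-body mode)")
        else:
            M = sp.diags(1.0 / Kff.diagonal())
            uf, info = spla.cg(Kff, ff, M=M, rtol=CG_TOL, maxiter=20 * nf)
            if info != 0:
                res = np.linalg.norm(Kff @ uf - ff)
                raise SolverError(f"CG did not converge (info={info}, residual={res:.3e})")
        u[free] = uf
        # sanity: a singular factorization can silently return garbage
        fnorm = np.linalg.norm(ff)
        if fnorm > 0:
            res = np.linalg.norm(Kff @ uf - ff) / fnorm
            if not np.isfinite(res) or res > 1e-6:
                raise SolverError(
                    f"solution residual {res:.3e} too large: system likely "
                    "singular (check constraints)"
                )

    # element recovery: strain = B u_e (Voigt, engineering shear)
    ue = u.reshape(n, 3)[mesh.tets].reshape(len(mesh.tets), 12)
    eps_voigt = np.einsum("eij,ej->ei", B, ue)
    D = material.d_matrix()
    sig_voigt = eps_voigt @ D.T
    strain = _voigt_to_tensor(eps_voigt, shear_half=True)
    stress = _voigt_to_tensor(sig_voigt, shear_half=False)
    vm = np.asarray(von_mises_from_tensor(stress))
    mps = principal_strains(strain)[..., 0]

    # reactions at constrained DOFs: r = (K u - f_applied) there
    r_full = K @ u - f
    reactions: dict[int, np.ndarray] = {}
    for node, dirs in loads.constraints.items():
        vec = np.zeros(3)
        for d in dirs:
            vec[d] = r_full[3 * node + d]
        reactions[node] = vec

    return SolutionField(
        displacements=u.reshape(n, 3),
        element_strain=strain,
        element_stress=stress,
        von_mises=vm,
        max_principal_strain=np.asarray(mps),
        reactions=reactions,
        element_volumes=vols,
    )
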