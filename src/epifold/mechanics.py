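"""3D vertex mechanics of the monolayer: tissue potential, forces, overdamped dynamics.

The tissue potential is

    U = sum_i K_a^i (P_a^i - P_o^i)^2  +  sum_i lambda_b^i A_b^i
      + sum_k lambda_l^k A_l^k        +  sum_i K_V^i (V_i - V_o^i)^2

where i runs over cells and k over registered lateral faces.  A boundary face
carries its owning cell's lateral tension (the "outer" value); a face shared
by two cells is registered once and carries the sum of the two owners'
contributions, so the default per-cell contribution 0.0207 yields the inner
tension 0.0414.  Vertices follow overdamped dynamics
dr_j/dt = -(1/eta) dU/dr_j, with the gradient estimated by central finite
differences of U (component-wise), and explicit Euler updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import TissueMesh

#: Reference (homeostatic) mechanical parameters of the columnar cell.
TABLE_K_A = 0.0172
TABLE_P_HAT_O = 2.16
TABLE_LAMBDA_B = 0.0477
TABLE_LAMBDA_L = 0.0207  # per owning cell; shared faces sum to 0.0414


@dataclass
class MechanicalState:
    """Per-cell mechanical parameters plus their normalized modulations q.

    The stored arrays are the homeostatic (initial) values; the effective
    parameters used by the solver are ``initial * q`` component-wise, with
    q = (K_a/K_a^h, P_o/P_o^h, lambda_b/lambda_b^h, lambda_l/lambda_l^h).
    ``lambda_ell`` is the per-owning-cell contribution to a lateral face.
    """

    K_a: np.ndarray
    P_hat_o: np.ndarray
    lambda_b: np.ndarray
    lambda_ell: np.ndarray
    K_V: np.ndarray
    V_o: np.ndarray
    eta: float = 1.0
    q: np.ndarray = field(default=None)

    def __post_init__(self):
        n = self.K_a.shape[0]
        if self.q is None:
            self.q = np.ones((n, 4))
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if np.any(self.K_a < 0) or np.any(self.K_V < 0):
            raise ValueError("elastic moduli must be >= 0")
        if np.any(self.V_o <= 0):
            raise ValueError("preferred volumes must be positive")

    @classmethod
    def uniform(cls, n_cells: int, K_a: float = TABLE_K_A,
                P_hat_o: float = TABLE_P_HAT_O, lambda_b: float = TABLE_LAMBDA_B,
                lambda_ell: float = TABLE_LAMBDA_L, K_V: float = 1.0,
                V_o: float = 1.0, eta: float = 1.0) -> "MechanicalState":
        full = np.full
        return cls(full(n_cells, K_a), full(n_cells, P_hat_o),
                   full(n_cells, lambda_b), full(n_cells, lambda_ell),
                   full(n_cells, K_V), full(n_cells, V_o), eta)

    def copy(self) -> "MechanicalState":
        return MechanicalState(self.K_a.copy(), self.P_hat_o.copy(),
                               self.lambda_b.copy(), self.lambda_ell.copy(),
                               self.K_V.copy(), self.V_o.copy(), self.eta,
                               self.q.copy())

    # effective (modulated) parameters
    @property
    def eff_K_a(self) -> np.ndarray:
        return self.K_a * self.q[:, 0]

    @property
    def eff_P_hat_o(self) -> np.ndarray:
        return self.P_hat_o * self.q[:, 1]

    @property
    def eff_lambda_b(self) -> np.ndarray:
        return self.lambda_b * self.q[:, 2]

    @property
    def eff_lambda_ell(self) -> np.ndarray:
        return self.lambda_ell * self.q[:, 3]

    def face_tensions(self, mesh: TissueMesh) -> np.ndarray:
        """Effective tension per registered lateral face (owners' contributions summed)."""
        lam = self.eff_lambda_ell
        owners = mesh.face_owners
        t = lam[owners[:, 0]].copy()
        shared = owners[:, 1] >= 0
        t[shared] += lam[owners[shared, 1]]
        return t


def _solver_arrays(mesh: TissueMesh, mech: MechanicalState):
    vc_ptr, vc_idx, vf_ptr, vf_idx = mesh.vertex_incidence()
    return (mesh.positions, mesh.apical, mesh.basal, mesh.lateral_faces,
            mech.face_tensions(mesh), mech.eff_K_a, mech.eff_P_hat_o,
            mech.eff_lambda_b, mech.K_V, mech.V_o,
            vc_ptr, vc_idx, vf_ptr, vf_idx)


def tissue_potential(mesh: TissueMesh, mech: MechanicalState) -> float:
    (pos, ap, bp, faces, flam, Ka, Po, lb, KV, Vo, *_cfg) = _solver_arrays(mesh, mech)
    if not np.isfinite(pos).all():
        raise ValueError("non-finite vertex positions")
    return float(_kernels.total_potential(pos, ap, bp, faces, flam, Ka, Po, lb, KV, Vo))


def vertex_forces(mesh: TissueMesh, mech: MechanicalState,
                  fd_step: float = 1e-6) -> np.ndarray:
    """Per-vertex force -dU/dr_j by central finite differences."""
    if fd_step <= 0:
        raise ValueError("fd_step must be positive")
    arrays = _solver_arrays(mesh, mech)
    return _kernels.forces_fd(*arrays, fd_step)


def step_mechanics(mesh: TissueMesh, mech: MechanicalState, dt: float,
                   constraint_mask: np.ndarray | None = None,
                   fd_step: float = 1e-6) -> TissueMesh:
    """One explicit Euler step r <- r + (dt/eta) F.  Updates the mesh in place."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    F = vertex_forces(mesh, mech, fd_step)
    if constraint_mask is not None:
        F[constraint_mask, 2] = 0.0
    mesh.positions += (dt / mech.eta) * F
    if not np.isfinite(mesh.positions).all():
        raise FloatingPointError("vertex positions diverged (NaN/Inf)")
    return mesh


def relax_to_balance(mesh: TissueMesh, mech: MechanicalState, dt: float = 0.05,
                     tol: float = 1e-8, max_steps: int = 200_000,
                     constraint_mask: np.ndarray | None = None,
                     fd_step: float = 1e-6) -> tuple[TissueMesh, bool]:
    """Gradient descent on U until the maximum force component is below tol."""
    arrays = _solver_arrays(mesh, mech)
    zmask = (np.zeros(mesh.n_vertices, dtype=np.bool_) if constraint_mask is None
             else constraint_mask.astype(np.bool_))
    steps = _kernels.relax(*arrays, fd_step, dt / mech.eta, tol, max_steps, zmask)
    if not np.isfinite(mesh.positions).all():
        raise FloatingPointError("vertex positions diverged during relaxation")
    return mesh, steps >= 0
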