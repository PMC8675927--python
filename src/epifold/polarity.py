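"""1D membrane reaction-diffusion of the aPKC / Par-1 / Bazooka polarity network.

Each epithelial cell carries three membrane concentration fields A(s), P(s),
B(s) on the half-perimeter path s in [0, L], L = a + ell + b, running from the
apical centre (s = 0) over the apical surface [0, a), down the lateral surface
[a, a + ell), to the basal centre.  The membrane exchanges material with a
well-mixed cytosolic pool through association/dissociation kinetics; the
cytosolic concentration follows from mass conservation,
rho_cyto = rho_total - psi * mean(rho), with psi the cell's surface-to-volume
ratio.

The default boundary condition is ``reflect``: the path [0, L] is the
mirror-symmetric half of the closed cross-section loop of length 2L, so a
symmetric no-flux condition at both ends represents the full periodic loop
exactly.  A literal ``periodic`` treatment of [0, L] is available; it carries
two interface fronts instead of one and therefore responds to pool
perturbations with half the peak displacement.

Time stepping is forward-time centred-space (FTCS) on 512 equidistant nodes by
default, with the stability bound max(D) * dt / ds^2 <= 1/2 enforced.
Concentration units: amount per unit length of membrane path; 1 length unit =
10 um, 1 time unit = 1 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels


class StabilityError(ValueError):
    """FTCS stability bound violated for the requested time step."""


class DivergenceError(RuntimeError):
    """The numerical solution produced NaN/Inf or exhausted a cytosolic pool."""


@dataclass
class PolarityParams:
    """Kinetic parameters of the A-B-P network (defaults: the model's reference set).

    Rates are per second; concentrations are per unit length (membrane) or per
    unit volume (totals) in model units.
    """

    D_A: float = 1e-4
    D_P: float = 1e-4
    D_B: float = 1e-4
    kon_A: float = 8.58e-4
    koff_A: float = 5.40e-3
    k_AB: float = 0.50e-2
    k_AP: float = 5.80e-4
    kon_P: float = 4.74e-3
    koff_P: float = 7.30e-3
    k_PA: float = 0.20e-4
    kon_B: float = 4.29e-3
    koff_B: float = 5.40e-3
    k_BA: float = 0.40e-4
    k_BP: float = 0.14e-4
    alpha: float = 1.0
    beta: float = 2.0
    gamma: float = 2.0
    zeta: float = 2.0
    eps: float = 1.0
    A_total: float = 1.30e3
    P_total: float = 1.00e3
    B_total: float = 1.40e3

    def __post_init__(self):
        for name in ("D_A", "D_P", "D_B", "kon_A", "koff_A", "k_AB", "k_AP",
                     "kon_P", "koff_P", "k_PA", "kon_B", "koff_B", "k_BA",
                     "k_BP", "A_total", "P_total", "B_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("alpha", "beta", "gamma", "zeta", "eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def rate_vector(self) -> np.ndarray:
        """Parameter vector in the layout the numba kernels expect."""
        return np.array([
            self.D_A, self.D_P, self.D_B,
            self.kon_A, self.koff_A, self.k_AB, self.k_AP,
            self.kon_P, self.koff_P, self.k_PA,
            self.kon_B, self.koff_B, self.k_BA, self.k_BP,
            self.alpha, self.beta, self.gamma, self.zeta, self.eps,
        ])

    @property
    def max_D(self) -> float:
        return max(self.D_A, self.D_P, self.D_B)


@dataclass
class MembraneField:
    """Discretised membrane concentrations of one cell.

    Nodes are cell-centred: node i sits at s_i = (i + 1/2) * ds, ds = L / n.
    ``a`` and ``ell`` locate the apical/lateral junction (s = a) and the
    lateral/basal junction (s = a + ell).
    """

    L: float
    a: float
    ell: float
    A: np.ndarray
    P: np.ndarray
    B: np.ndarray
    bc: str = "reflect"

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.bc not in ("reflect", "periodic"):
            raise ValueError(f"unknown boundary condition {self.bc!r}")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def ds(self) -> float:
        return self.L / self.n_nodes

    @property
    def s(self) -> np.ndarray:
        return (np.arange(self.n_nodes) + 0.5) * self.ds

    @property
    def region_bounds(self) -> tuple[float, float]:
        return self.a, self.a + self.ell

    def copy(self) -> "MembraneField":
        return replace(self, A=self.A.copy(), P=self.P.copy(), B=self.B.copy())

    def membrane_means(self) -> tuple[float, float, float]:
        return float(self.A.mean()), float(self.P.mean()), float(self.B.mean())


def initial_condition(n_nodes: int, L: float, a: float, ell: float,
                      params: PolarityParams, psi: float,
                      style: str = "heaviside_B", bc: str = "reflect") -> MembraneField:
    """Initial membrane profiles.

    ``heaviside_B`` emulates the apical accumulation of Bazooka at the end of
    cellularisation: B is a step confined to the apical region [0, a), with
    height chosen so that half of the B pool starts on the membrane; A and P
    start entirely cytosolic (zero membrane concentration), as in the low
    initial profiles from which the polarized state is established.  Starting
    A and P with substantial membrane loading instead relaxes to the
    unpolarized uniform state, so the membrane-empty start is part of the
    model definition here.

    ``uniform`` places half of each pool on the membrane uniformly.
    """
    if psi <= 0:
        raise ValueError("psi must be positive")
    s = (np.arange(n_nodes) + 0.5) * (L / n_nodes)
    if style == "heaviside_B":
        A = np.zeros(n_nodes)
        P = np.zeros(n_nodes)
        n_on = int(np.count_nonzero(s < a))
        if n_on == 0:
            raise ValueError("apical region does not cover any grid node")
        # height chosen on the discrete grid so that exactly half of the
        # Bazooka pool starts on the membrane
        height = params.B_total * n_nodes / (2.0 * psi * n_on)
        B = np.where(s < a, height, 0.0)
    elif style == "uniform":
        A = np.full(n_nodes, params.A_total / (2.0 * psi))
        P = np.full(n_nodes, params.P_total / (2.0 * psi))
        B = np.full(n_nodes, params.B_total / (2.0 * psi))
    else:
        raise ValueError(f"unknown initial-condition style {style!r}")
    return MembraneField(L=L, a=a, ell=ell, A=A, P=P, B=B, bc=bc)


def cytosolic_concentration(field: MembraneField, params: PolarityParams,
                            psi: float) -> tuple[float, float, float]:
    """Cytosolic concentrations by mass conservation: rho_total - psi * mean(rho)."""
    if psi <= 0:
        raise ValueError("psi must be positive")
    Am, Pm, Bm = field.membrane_means()
    return (params.A_total - psi * Am,
            params.P_total - psi * Pm,
            params.B_total - psi * Bm)


def reaction_rates(field: MembraneField, params: PolarityParams,
                   cytosolic: tuple[float, float, float]):
    """Nodewise net membrane association rates R_A, R_P, R_B."""
    n = field.n_nodes
    RA = np.empty(n)
    RP = np.empty(n)
    RB = np.empty(n)
    Ac, Pc, Bc = cytosolic
    _kernels.reaction_terms(field.A, field.P, field.B, Ac, Pc, Bc,
                            params.rate_vector(), RA, RP, RB)
    return RA, RP, RB


def check_stability(field: MembraneField, params: PolarityParams, dt: float) -> None:
    if params.max_D * dt / field.ds ** 2 > 0.5 + 1e-12:
        raise StabilityError(
            f"FTCS unstable: max(D)*dt/ds^2 = {params.max_D * dt / field.ds ** 2:.3f} > 0.5")


def step_rd(field: MembraneField, params: PolarityParams, psi: float,
            dt: float, n_steps: int = 1) -> MembraneField:
    """Advance the field by explicit FTCS steps; returns a new field.

    The cytosolic pool is recomputed from the pre-step membrane field at every
    step.  If a step would drive a cytosolic pool negative the step is retried
    with a halved dt (up to 20 halvings) before giving up.
    """
    check_stability(field, params, dt)
    out = field.copy()
    par = params.rate_vector()
    periodic = field.bc == "periodic"
    status = _kernels.rd_run(out.A, out.P, out.B, params.A_total, params.P_total,
                             params.B_total, field.L, psi, dt, n_steps, par, periodic)
    if status != 0:
        # retry the whole span at half dt, a few times
        for k in range(1, 21):
            out = field.copy()
            sub = dt / 2 ** k
            status = _kernels.rd_run(out.A, out.P, out.B, params.A_total,
                                     params.P_total, params.B_total, field.L,
                                     psi, sub, n_steps * 2 ** k, par, periodic)
            if status == 0:
                break
        else:
            raise DivergenceError("cytosolic pool driven negative at any tried dt")
    if not (np.isfinite(out.A).all() and np.isfinite(out.P).all() and np.isfinite(out.B).all()):
        raise DivergenceError("non-finite concentrations")
    return out


def rescale_for_length_change(field: MembraneField, L_prev: float,
                              L_new: float) -> MembraneField:
    """Concentration correction for a change of domain length.

    The number of molecules on the membrane is unchanged while L varies, so
    every nodal concentration is multiplied by L_prev / L_new.
    """
    if L_prev <= 0 or L_new <= 0:
        raise ValueError("lengths must be positive")
    f = L_prev / L_new
    out = field.copy()
    out.A *= f
    out.P *= f
    out.B *= f
    out.L = L_new
    return out


def integrate_to_steady_state(field: MembraneField, params: PolarityParams,
                              psi: float, dt: float = 0.05, tol: float = 1e-9,
                              max_steps: int = 20_000_000,
                              check_every: int = 20_000) -> tuple[MembraneField, bool]:
    """Iterate FTCS steps until max |d rho / dt| < tol for all species.

    The convergence check is applied every ``check_every`` steps as the mean
    rate of change over the block, which is robust to the slow creep of the
    interface front toward its stall position.
    """
    check_stability(field, params, dt)
    out = field.copy()
    par = params.rate_vector()
    periodic = field.bc == "periodic"
    done = 0
    while done < max_steps:
        block = min(check_every, max_steps - done)
        A0, P0, B0 = out.A.copy(), out.P.copy(), out.B.copy()
        status = _kernels.rd_run(out.A, out.P, out.B, params.A_total,
                                 params.P_total, params.B_total, out.L, psi,
                                 dt, block, par, periodic)
        if status != 0:
            raise DivergenceError("cytosolic pool driven negative")
        if not np.isfinite(out.A).all():
            raise DivergenceError("non-finite concentrations")
        done += block
        span = block * dt
        resid = max(np.abs(out.A - A0).max(), np.abs(out.P - P0).max(),
                    np.abs(out.B - B0).max()) / span
        if resid < tol:
            return out, True
    return out, False


def bazooka_peak_position(field: MembraneField, refine: bool = False) -> tuple[float, float]:
    """Position s* of the Bazooka maximum and the apical domain size.

    The apical (aPKC) domain size ell_domain = max(0, s* - a) is the distance
    from the apical/lateral junction to the peak along the membrane.  Exact
    ties resolve to the first (apical-most) node.  With ``refine`` a parabolic
    sub-grid correction around the peak node is applied.
    """
    B = field.B
    if not np.any(B > 0):
        raise ValueError("Bazooka field is identically zero; peak undefined")
    i = int(np.argmax(B))
    s_star = float(field.s[i])
    if refine and 0 < i < field.n_nodes - 1:
        y0, y1, y2 = B[i - 1], B[i], B[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            s_star += 0.5 * (y0 - y2) / denom * field.ds
    return s_star, max(0.0, s_star - field.a)
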