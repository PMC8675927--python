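"""Closed-form single-cell force balance, shape stability, and deformation metrics.

For a regular hexagonal prism of height h and radius r (= apical length a =
basal length b), with K_V = V_o = 1, the single-cell energy is

    U_single = (V - 1)^2 + K_a (P_a - P_o)^2 + lambda_b A_b + lambda_l (6 A_l)

with V = (3 sqrt(3)/2) r^2 h, P_a = 6 r, A_b = (3 sqrt(3)/2) r^2 and
A_l = h r.  Requiring dU/dh = dU/dr = 0 together with the frustum-preventing
condition (sqrt(3)/2) lambda_b P_a = 12 K_a (P_a - P_o) determines the unique
balanced parameters

    lambda_l = sqrt(3) P_V r / 4,   lambda_b = P_V h / 4,
    K_a = sqrt(3) P_V h r / (16 (6 r - P_o)),

where P_V = 2 (1 - V) is the pressure from volume elasticity; balanced cells
must be volume-compressed (V < 1) for the tensions to be positive.  Shape
stability follows from the 2x2 Hessian of U_single in (h, r): stable iff
trace(M) > 0 and det(M) > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SQRT3 = np.sqrt(3.0)


class SingularShapeError(ValueError):
    """P_o = 6 r: the apical-elasticity balance condition is singular."""


class InfeasibleShapeError(ValueError):
    """The balanced parameters would require a negative tension or modulus."""


@dataclass
class PrismShape:
    """Regular hexagonal prism: height h, hexagon radius r, preferred apical perimeter."""

    h: float
    r: float
    P_hat_o: float

    def __post_init__(self):
        if self.h <= 0 or self.r <= 0:
            raise ValueError("h and r must be positive")

    @property
    def volume(self) -> float:
        return 1.5 * SQRT3 * self.r ** 2 * self.h

    @property
    def P_hat_a(self) -> float:
        return 6.0 * self.r

    @property
    def P_V(self) -> float:
        """Pressure from volume elasticity, 2 (1 - V) with K_V = V_o = 1."""
        return 2.0 * (1.0 - self.volume)


def single_cell_potential(shape: PrismShape, K_a: float, lambda_b: float,
                          lambda_ell: float) -> float:
    """U_single of the regular prism (6-lateral-face convention, K_V = V_o = 1)."""
    V = shape.volume
    A_b = 1.5 * SQRT3 * shape.r ** 2
    A_l = shape.h * shape.r
    return ((V - 1.0) ** 2 + K_a * (shape.P_hat_a - shape.P_hat_o) ** 2
            + lambda_b * A_b + lambda_ell * 6.0 * A_l)


def derive_balanced_parameters(shape: PrismShape) -> tuple[float, float, float]:
    """The unique (K_a, lambda_b, lambda_l) holding the prism in force balance.

    Solves dU/dh = 0, dU/dr = 0 and the frustum condition in closed form.
    Raises for the singular configuration P_o = 6r and for shapes whose
    balance would require negative tensions (volume-expanded cells).
    """
    h, r, Po = shape.h, shape.r, shape.P_hat_o
    denom = 6.0 * r - Po
    if abs(denom) < 1e-12:
        raise SingularShapeError("P_hat_o equals the apical perimeter 6r")
    P_V = shape.P_V
    lam_l = SQRT3 * P_V * r / 4.0
    lam_b = P_V * h / 4.0
    K_a = SQRT3 * P_V * h * r / (16.0 * denom)
    if lam_l < 0 or lam_b < 0 or K_a < 0:
        raise InfeasibleShapeError(
            f"balanced parameters infeasible: K_a={K_a:.4g}, "
            f"lambda_b={lam_b:.4g}, lambda_l={lam_l:.4g}")
    return K_a, lam_b, lam_l


def shape_hessian(shape: PrismShape, K_a: float, lambda_b: float,
                  lambda_ell: float) -> np.ndarray:
    """Hessian M of U_single with respect to (h, r)."""
    h, r = shape.h, shape.r
    M11 = 13.5 * r ** 4
    M22 = 72.0 * K_a + 81.0 * h ** 2 * r ** 2 - 6.0 * SQRT3 * h + 3.0 * SQRT3 * lambda_b
    M12 = 54.0 * h * r ** 3 + 6.0 * lambda_ell - 6.0 * SQRT3 * r
    return np.array([[M11, M12], [M12, M22]])


def stability_check(shape: PrismShape, K_a: float, lambda_b: float,
                    lambda_ell: float) -> tuple[bool, float, float]:
    """Mechanical stability of the prism: trace and determinant of the Hessian."""
    M = shape_hessian(shape, K_a, lambda_b, lambda_ell)
    tr = float(np.trace(M))
    det = float(np.linalg.det(M))
    return (tr > 0.0 and det > 0.0), tr, det


def frustum_energy(x, K_a, P_hat_o, lambda_b, lambda_ell6, K_V=1.0, V_o=1.0):
    """Energy of an isolated hexagonal frustum with apical radius a, basal
    radius b and height h (x = (a, b, h)); lambda_ell6 is the cell's lateral
    tension applied to its six faces.  Reduces to U_single at a = b = r."""
    a, b, h = x
    V = 0.5 * SQRT3 * h * (a * a + a * b + b * b)
    A_b = 1.5 * SQRT3 * b * b
    slant = np.sqrt(h * h + 0.75 * (b - a) ** 2)
    A_l = 0.5 * (a + b) * slant
    return (K_V * (V - V_o) ** 2 + K_a * (6.0 * a - P_hat_o) ** 2
            + lambda_b * A_b + lambda_ell6 * 6.0 * A_l)


def frustum_gradient(x, args, eps=1e-6):
    g = np.empty(3)
    x = np.asarray(x, dtype=float)
    for i in range(3):
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (frustum_energy(xp, *args) - frustum_energy(xm, *args)) / (2 * eps)
    return g


def frustum_hessian(x, args, eps=1e-5):
    x = np.asarray(x, dtype=float)
    H = np.empty((3, 3))
    for i in range(3):
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        H[i] = (frustum_gradient(xp, args) - frustum_gradient(xm, args)) / (2 * eps)
    return 0.5 * (H + H.T)


def full_shape_stability(shape: PrismShape, K_a: float, lambda_b: float,
                         lambda_ell: float) -> tuple[bool, np.ndarray]:
    """Stability of the prism against all three shape modes (a, b, h).

    The closed 2x2 criterion tests the symmetric (h, r) modes only; slender
    columns can instead escape through the asymmetric apical/basal (frustum)
    mode, which this full 3-dof Hessian captures.  Returns the verdict and
    the Hessian eigenvalues.
    """
    args = (K_a, shape.P_hat_o, lambda_b, lambda_ell)
    H = frustum_hessian((shape.r, shape.r, shape.h), args)
    w = np.linalg.eigvalsh(H)
    return bool(w[0] > 0.0), w


def balanced_shape_from_mechanics(K_a: float, lambda_b: float, lambda_ell: float,
                                  P_hat_o: float, guess=(1.8, 0.45)) -> PrismShape:
    """Invert the balance relations: the (h, r) a given parameter set holds in place."""
    from scipy.optimize import fsolve

    def eqs(x):
        h, r = x
        PV = 2.0 * (1.0 - 1.5 * SQRT3 * r ** 2 * h)
        return [PV * h / 4.0 - lambda_b, SQRT3 * PV * r / 4.0 - lambda_ell]

    h, r = fsolve(eqs, guess)
    shape = PrismShape(h=float(h), r=float(r), P_hat_o=P_hat_o)
    Ka_chk, _, _ = derive_balanced_parameters(shape)
    if not np.isclose(Ka_chk, K_a, rtol=5e-3):
        raise InfeasibleShapeError("mechanical parameters are not a balanced set")
    return shape


# ---------------------------------------------------------------------------
# deformation metrics
# ---------------------------------------------------------------------------


def cell_deformation_delta(a: float, b: float, h: float,
                           a_c: float, b_c: float, h_c: float) -> float:
    """Final cell deformation relative to the unperturbed reference cell.

    delta = sqrt((a - a_c)^2 + (b - b_c)^2 + (h - h_c)^2) / (a_c + b_c + h_c).
    """
    if a_c <= 0 or b_c <= 0 or h_c <= 0:
        raise ValueError("reference dimensions must be positive")
    return float(np.sqrt((a - a_c) ** 2 + (b - b_c) ** 2 + (h - h_c) ** 2)
                 / (a_c + b_c + h_c))


def tissue_deformation_Delta(D_a: float, D_b: float, D_ac: float, D_bc: float,
                             h_c: float) -> float:
    """Final tissue deformation: fold-depth changes of both surfaces over cell height.

    Delta = sqrt((D_a - D_ac)^2 + (D_b - D_bc)^2) / h_c.
    """
    if h_c <= 0:
        raise ValueError("h_c must be positive")
    return float(np.sqrt((D_a - D_ac) ** 2 + (D_b - D_bc) ** 2) / h_c)


def fold_depth(mesh, surface: str = "apical") -> float:
    """Fold depth D = z_max - z_min over the chosen surface's vertices.

    The apical side sits at larger z, so an inward (toward-basal) indentation
    of the apical surface registers as D > 0.
    """
    if surface == "apical":
        idx = np.unique(mesh.apical)
    elif surface == "basal":
        idx = np.unique(mesh.basal)
    else:
        raise ValueError(f"unknown surface {surface!r}")
    z = mesh.positions[idx, 2]
    return float(z.max() - z.min())


# ---------------------------------------------------------------------------
# scenario runners
# ---------------------------------------------------------------------------


@dataclass
class DeformationReport:
    """Cell- and tissue-scale deformation for one perturbation strength."""

    perturbation_strength: float
    delta: float
    Delta: float
    D_a: float
    D_b: float
    converged: bool


def perturbation_scan(parameter: str = "P_hat_o",
                      strengths=(0.0, 10.0, 20.0, 40.0, 60.0),
                      feedback: bool = True,
                      n_rings: int = 1,
                      duration: float = 1500.0,
                      dt: float = 0.1,
                      n_nodes: int = 256,
                      K_a_factor: float = 9.0,
                      c_o=(1.0, 1.0, 5.5, 5.5),
                      seed: int = 0) -> list[DeformationReport]:
    """Deformation response to graded perturbations of the central cell.

    In the apical-mechanics mode the whole tissue first gets a stiffened
    apical spring: K_a is multiplied by ``K_a_factor`` and P_hat_o is moved to
    6r - (6r - P_hat_o)/K_a_factor, which is force-balanced for the same
    prism shape (the frustum condition is invariant under this pair), so the
    s = 0 configuration is an exact equilibrium.  Each strength s (percent)
    then reduces the central cell's P_hat_o to (1 - s/100) of that baseline
    at t = 0.  In the biochemical mode the central cell's total Par-1 pool is
    reduced instead, from the plain baseline.  With feedback the full
    mechano-polarity loop runs; without it the mechanical parameters stay
    fixed and the tissue simply relaxes to force balance.  delta and Delta
    are measured against the unperturbed flat reference.  The default
    conversion rates are the all-positive (purely corrective) set used for
    threshold-response studies, not the folding set.
    """
    from .coupling import (prepare_homeostatic_tissue, CouplingConfig,
                           PerturbationEvent, run_coupled_simulation)
    from .geometry import cell_shape_summary, central_cell_id
    from .mechanics import relax_to_balance

    if parameter not in ("P_hat_o", "P_total"):
        raise ValueError(f"unsupported scan parameter {parameter!r}")

    def make_state():
        st = prepare_homeostatic_tissue(n_rings=n_rings, n_nodes=n_nodes)
        if parameter == "P_hat_o":
            r = st.geom[0, 0]
            st.mech.P_hat_o[:] = 6.0 * r - (6.0 * r - st.mech.P_hat_o) / K_a_factor
            st.mech.K_a *= K_a_factor
        return st

    ref_state = make_state()
    center = central_cell_id(ref_state.mesh)
    ref = cell_shape_summary(ref_state.mesh, center)
    a_c, b_c, h_c = ref.a, ref.b, ref.ell
    D_ac = fold_depth(ref_state.mesh, "apical")
    D_bc = fold_depth(ref_state.mesh, "basal")

    reports = []
    for s in strengths:
        if not 0.0 <= s < 100.0:
            raise ValueError("strengths must lie in [0, 100)")
        state = make_state()
        events = []
        if s > 0:
            events.append(PerturbationEvent(
                0.0, (center,), parameter, 1.0 - s / 100.0))
        if feedback:
            cfg = CouplingConfig(c_o=tuple(c_o), seed=seed)
            traj = run_coupled_simulation(state, cfg, events, duration=duration, dt=dt)
            converged = True
        else:
            for ev in events:
                from .coupling import apply_perturbation
                apply_perturbation(state, ev)
            _, converged = relax_to_balance(state.mesh, state.mech, dt=0.05,
                                            tol=1e-6, max_steps=100_000,
                                            constraint_mask=state.constraint)
        cs = cell_shape_summary(state.mesh, center)
        D_a = fold_depth(state.mesh, "apical")
        D_b = fold_depth(state.mesh, "basal")
        reports.append(DeformationReport(
            perturbation_strength=float(s),
            delta=cell_deformation_delta(cs.a, cs.b, cs.ell, a_c, b_c, h_c),
            Delta=tissue_deformation_Delta(D_a, D_b, D_ac, D_bc, h_c),
            D_a=D_a, D_b=D_b, converged=bool(converged)))
    return reports


#: aspect ratios (a/h) of the conventional epithelial cell types
CELL_TYPES = {"columnar": 0.25, "cuboidal": 0.50, "squamous": 1.50}


def reference_shape_for(cell_type: str) -> PrismShape:
    """A balanced prism of the given type: same volume and P_o/(6r) ratio as
    the columnar reference cell, with the type's aspect ratio."""
    ar = CELL_TYPES[cell_type]
    r2h = 0.3644582  # r^2 h of the columnar reference cell (V = 0.947)
    h = (r2h / ar ** 2) ** (1.0 / 3.0)
    r = ar * h
    return PrismShape(h=h, r=r, P_hat_o=0.8 * 6.0 * r)


def deformation_correlation_study(cell_type: str = "columnar",
                                  modulated_surface: str = "apical",
                                  rel_range: float = 0.3,
                                  n_points: int = 7,
                                  n_rings: int = 1) -> dict:
    """Correlation pattern of steady-state cell dimensions under mechanical modulation.

    Sweeps the named surface's mechanics (P_hat_o for apical, lambda_b for
    basal, lambda_ell for lateral) uniformly in all cells of a small patch
    around the balanced state, relaxes to force balance, and regresses the
    central cell's basal length b and height h on its apical length a.
    Returns the least-squares slopes and their signs.
    """
    from .geometry import build_hexagonal_tissue, cell_shape_summary, central_cell_id
    from .mechanics import MechanicalState, relax_to_balance

    shape = reference_shape_for(cell_type)
    K_a, lam_b, lam_l = derive_balanced_parameters(shape)
    param = {"apical": "P_hat_o", "basal": "lambda_b", "lateral": "lambda_ell"}[modulated_surface]

    avals, bvals, hvals = [], [], []
    for f in np.linspace(1.0 - rel_range, 1.0 + rel_range, n_points):
        mesh = build_hexagonal_tissue(n_rings, apical_radius=shape.r, height=shape.h)
        mech = MechanicalState.uniform(mesh.n_cells, K_a=K_a, P_hat_o=shape.P_hat_o,
                                       lambda_b=lam_b, lambda_ell=lam_l)
        if param == "P_hat_o":
            mech.P_hat_o *= f
        elif param == "lambda_b":
            mech.lambda_b *= f
        else:
            mech.lambda_ell *= f
        relax_to_balance(mesh, mech, dt=0.05, tol=3e-7, max_steps=100_000)
        cs = cell_shape_summary(mesh, central_cell_id(mesh))
        avals.append(cs.a)
        bvals.append(cs.b)
        hvals.append(cs.ell)
    avals = np.array(avals)
    slope_ab = float(np.polyfit(avals, bvals, 1)[0])
    slope_ah = float(np.polyfit(avals, hvals, 1)[0])
    return {"slope_ab": slope_ab, "slope_ah": slope_ah,
            "sign_ab": int(np.sign(slope_ab)), "sign_ah": int(np.sign(slope_ah)),
            "a": avals, "b": np.array(bvals), "h": np.array(hvals)}
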