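"""Mechano-polarity feedback: apical-domain homeostasis drives cell mechanics.

Each cell's normalized mechanical parameters q = (K_a, P_o, lambda_b,
lambda_l) / (initial values) follow the gradient-descent law

    dq_k/dt = -c_k * d/dq_k (ell_domain - ell_domain_o)^2,

so mechanics are modulated in whichever direction shrinks the deviation of
the apical (aPKC) domain size from its homeostatic value.  The sensitivity
d ell_domain / dq_k is estimated side-effect-free in one of two ways:

* ``equilibrium`` (default): the quasi-static response, from a linearisation
  of the isolated cell's closed-form frustum energy around its current shape
  (a 3x3 Hessian solve); validated against a brute-force relax-to-balance
  probe of the vertex model.
* ``step``: a virtual finite-difference probe that perturbs q_k by +/- dq,
  advances the probed cell's vertices over a short horizon, remeasures its
  geometry, rescales the membrane field to the new half perimeter and locates
  the Bazooka peak.  This captures the transient rather than the equilibrium
  response; for the basal-tension channel the two differ in sign.

The conversion rates c_k carry optional
multiplicative Gaussian noise, c = c_o * (1 + xi), xi ~ N(0, sigma), redrawn
once per coupling interval per cell and held constant in between.

`run_coupled_simulation` orchestrates the full loop per iteration: mechanics
step -> geometry update -> membrane-field rescale -> reaction-diffusion step
-> (every coupling interval) sensitivity probes, noise draw, q update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import (TissueMesh, build_hexagonal_tissue, cell_shape_summary,
                       boundary_constraint_mask)
from .mechanics import MechanicalState, _solver_arrays, step_mechanics
from .polarity import PolarityParams, MembraneField, initial_condition, \
    integrate_to_steady_state, check_stability
from .analysis import derive_balanced_parameters, PrismShape, fold_depth

Q_NAMES = ("K_a", "P_hat_o", "lambda_b", "lambda_ell")

# reference steady states are deterministic and expensive; memoise per process
_STEADY_CACHE: dict = {}


@dataclass
class CouplingConfig:
    """Settings of the polarity-to-mechanics feedback loop.

    ``c_o`` are the deterministic conversion rates per q component; ``sigma``
    the relative noise strength on those rates; ``interval`` the number of
    iterations between feedback updates; ``probe_dq`` the (absolute) step used
    for the sensitivity probe on the order-one modulations q; ``probe_dt``
    the virtual time horizon over which the probe lets the cell shape respond
    (the probe advances the probed cell's vertices by one Euler step of this
    size, independent of the main loop's dt);
    ``gain`` converts the sensitivity-weighted drive into a modulation rate;
    it sets the feedback timescale relative to mechanical relaxation (the
    explicit closed-loop update destabilises well above the default).
    ``threshold_frac`` defines the homeostasis band used for the relaxation
    time tau.  ``ell_domain_o = None`` means each cell's pre-perturbation
    steady-state apical domain size.
    """

    c_o: tuple = (0.2, -0.8, 2.0, 2.0)
    sigma: float = 0.0
    ell_domain_o: np.ndarray | None = None
    probe_mode: str = "equilibrium"
    probe_dq: float = 0.05
    probe_dt: float = 1.0
    interval: int = 10
    gain: float = 0.02
    threshold_frac: float = 0.05
    q_floor: float = 0.2
    q_cap: float = 4.0
    max_dq: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.probe_mode not in ("equilibrium", "step"):
            raise ValueError(f"unknown probe_mode {self.probe_mode!r}")
        if self.probe_dq <= 0:
            raise ValueError("probe_dq must be positive")
        if self.probe_dt < 0:
            raise ValueError("probe_dt must be >= 0")
        if not 0.0 < self.threshold_frac < 1.0:
            raise ValueError("threshold_frac must be in (0, 1)")
        if self.interval < 1:
            raise ValueError("interval must be >= 1")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass
class PerturbationEvent:
    """Multiplicative change of a parameter in selected cells at a given time.

    ``param`` is one of P_total, B_total, K_a, P_hat_o, lambda_b, lambda_ell.
    """

    time: float
    cells: tuple
    param: str
    factor: float


@dataclass
class Trajectory:
    """Recorded time series of a coupled run."""

    times: np.ndarray
    psi: np.ndarray          # (T, n_cells)
    L: np.ndarray            # (T, n_cells)
    ell_domain: np.ndarray   # (T, n_cells)
    q: np.ndarray            # (T, n_cells, 4)
    fold_depth: np.ndarray   # (T,)
    tau: float | None
    mesh: TissueMesh
    state: "CoupledState"

    def to_dataframe(self):
        """Long-format per-cell series (one row per time x cell)."""
        import pandas as pd
        T, N = self.psi.shape
        rows = {
            "time": np.repeat(self.times, N),
            "cell": np.tile(np.arange(N), T),
            "psi": self.psi.ravel(),
            "L": self.L.ravel(),
            "ell_domain": self.ell_domain.ravel(),
        }
        for k, name in enumerate(Q_NAMES):
            rows[f"q_{name}"] = self.q[:, :, k].ravel()
        rows["fold_depth"] = np.repeat(self.fold_depth, N)
        return pd.DataFrame(rows)


@dataclass
class CoupledState:
    """Full mutable state of the coupled tissue simulation."""

    mesh: TissueMesh
    mech: MechanicalState
    params: PolarityParams
    A: np.ndarray            # (n_cells, n_nodes) membrane concentrations
    P: np.ndarray
    B: np.ndarray
    A_total: np.ndarray      # per-cell totals (perturbable)
    P_total: np.ndarray
    B_total: np.ndarray
    geom: np.ndarray         # (n_cells, 7): a, b, ell, L, A_surf, V, psi
    bc: str = "reflect"
    constraint: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.mesh.n_cells

    @property
    def n_nodes(self) -> int:
        return self.A.shape[1]

    def update_geometry(self) -> None:
        _kernels.cell_summaries(self.mesh.positions, self.mesh.apical,
                                self.mesh.basal, self.geom)

    def ell_domain(self) -> np.ndarray:
        """Apical domain size per cell: distance from the apical/lateral
        junction to the Bazooka maximum along the membrane."""
        idx = np.argmax(self.B, axis=1)
        s_star = (idx + 0.5) * self.geom[:, 3] / self.n_nodes
        return np.maximum(0.0, s_star - self.geom[:, 0])

    def field_of(self, cell: int) -> MembraneField:
        g = self.geom[cell]
        return MembraneField(L=g[3], a=g[0], ell=g[2], A=self.A[cell].copy(),
                             P=self.P[cell].copy(), B=self.B[cell].copy(), bc=self.bc)


def prepare_homeostatic_tissue(n_rings: int = 2,
                               params: PolarityParams | None = None,
                               n_nodes: int = 512,
                               boundary: str = "free",
                               bc: str = "reflect",
                               rd_dt: float = 0.05,
                               steady_tol: float = 1e-8) -> CoupledState:
    """Flat balanced tissue with every cell at the polarized RD steady state.

    All cells are congruent, so the steady state is solved once on the
    reference cell and copied.  Mechanical parameters are the exact balanced
    set of the reference prism, making the flat tissue a true fixed point of
    the coupled dynamics.
    """
    params = params or PolarityParams()
    mesh = build_hexagonal_tissue(n_rings)
    cs = cell_shape_summary(mesh, 0)
    Ka, lb, ll = derive_balanced_parameters(
        PrismShape(h=cs.ell, r=cs.a, P_hat_o=2.16))
    mech = MechanicalState.uniform(mesh.n_cells, K_a=Ka, P_hat_o=2.16,
                                   lambda_b=lb, lambda_ell=ll)
    key = (n_nodes, bc, rd_dt, steady_tol, round(cs.L, 12), round(cs.psi, 12),
           tuple(sorted(params.__dict__.items())))
    cached = _STEADY_CACHE.get(key)
    if cached is None:
        f0 = initial_condition(n_nodes, cs.L, cs.a, cs.ell, params, cs.psi,
                               style="heaviside_B", bc=bc)
        f0, ok = integrate_to_steady_state(f0, params, cs.psi, dt=rd_dt,
                                           tol=steady_tol)
        if not ok:
            raise RuntimeError("reference cell did not reach a polarized steady state")
        _STEADY_CACHE[key] = f0
    else:
        f0 = cached.copy()
    n = mesh.n_cells
    state = CoupledState(
        mesh=mesh, mech=mech, params=params,
        A=np.tile(f0.A, (n, 1)), P=np.tile(f0.P, (n, 1)), B=np.tile(f0.B, (n, 1)),
        A_total=np.full(n, params.A_total),
        P_total=np.full(n, params.P_total),
        B_total=np.full(n, params.B_total),
        geom=np.empty((n, 7)), bc=bc,
        constraint=boundary_constraint_mask(mesh, boundary),
    )
    state.update_geometry()
    return state


def sample_coupling_rate(config: CouplingConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the (possibly noisy) conversion rates c = c_o * (1 + xi)."""
    c_o = np.asarray(config.c_o, dtype=float)
    if config.sigma == 0.0:
        return c_o.copy()
    xi = rng.normal(0.0, config.sigma, size=c_o.shape)
    return c_o * (1.0 + xi)


def homeostasis_update(q: np.ndarray, ell_domain: float, ell_domain_o: float,
                       sensitivity: np.ndarray, c: np.ndarray, dt: float,
                       q_floor: float = 0.05, max_dq: float = np.inf,
                       q_cap: float = np.inf) -> np.ndarray:
    """One explicit update of the modulations q for a single cell.

    If the update would exceed ``max_dq`` in any component the whole step is
    rescaled uniformly (a rate limiter that preserves the direction of the
    modulation vector; it keeps strongly noisy coupling rates from
    destabilising the explicit update).  q is clipped to [q_floor, q_cap] so
    moduli can neither change sign nor grow without bound.
    """
    dq = -dt * c * 2.0 * (ell_domain - ell_domain_o) * sensitivity
    m = np.abs(dq).max()
    if m > max_dq:
        dq *= max_dq / m
    return np.clip(q + dq, q_floor, q_cap)


def apical_domain_sensitivity(state: CoupledState, cell: int, component: int,
                              dq: float = 0.05, dt: float = 0.05,
                              fd_step: float = 1e-6) -> float:
    """Central-difference estimate of d ell_domain / d q_k for one cell.

    The probe perturbs q_k by +/- dq, advances only the probed cell's vertices
    by one mechanics step under the perturbed parameters, remeasures that
    cell's geometry, rescales the membrane field to the new half perimeter and
    reads off the apical domain size.  The main state is untouched.  With
    dt = 0 the cell shape cannot respond and the sensitivity is zero.
    """
    if dq <= 0:
        raise ValueError("probe step must be positive")
    if dt == 0.0:
        return 0.0
    mesh = state.mesh
    verts = np.unique(np.concatenate([mesh.apical[cell], mesh.basal[cell]]))
    n = state.n_nodes
    idx_peak = int(np.argmax(state.B[cell]))
    L0 = state.geom[cell, 3]
    # substep the virtual relaxation: one large explicit Euler step would
    # exceed the stability limit of the stiffest shape mode and corrupt the
    # sensitivity sign
    n_sub = max(1, int(np.ceil(dt / 0.05)))
    sub = dt / n_sub
    ells = []
    for sgn in (+1.0, -1.0):
        mech_p = state.mech.copy()
        mech_p.q[cell, component] = max(mech_p.q[cell, component] + sgn * dq, 1e-6)
        arrays = _solver_arrays(mesh, mech_p)
        pos_save = mesh.positions[verts].copy()
        for _ in range(n_sub):
            F = _kernels.forces_fd_subset(mesh.positions, verts, *arrays[1:], fd_step)
            if state.constraint is not None:
                F[state.constraint[verts], 2] = 0.0
            mesh.positions[verts] += (sub / mech_p.eta) * F
        out = np.empty((1, 7))
        _kernels.cell_summaries(mesh.positions, mesh.apical[cell:cell + 1],
                                mesh.basal[cell:cell + 1], out)
        mesh.positions[verts] = pos_save
        a_new, L_new = out[0, 0], out[0, 3]
        # rescaling multiplies B uniformly, so the peak node is unchanged;
        # only the node spacing and the junction position move.
        s_star = (idx_peak + 0.5) * L_new / n
        ells.append(max(0.0, s_star - a_new))
    if L0 <= 0:
        raise ValueError("degenerate probe geometry")
    return (ells[0] - ells[1]) / (2.0 * dq)


def apply_perturbation(state: CoupledState, event: PerturbationEvent) -> None:
    cells = np.asarray(event.cells, dtype=int)
    if event.param == "P_total":
        state.P_total[cells] *= event.factor
    elif event.param == "B_total":
        state.B_total[cells] *= event.factor
    elif event.param == "A_total":
        state.A_total[cells] *= event.factor
    elif event.param == "K_a":
        state.mech.K_a[cells] *= event.factor
    elif event.param == "P_hat_o":
        state.mech.P_hat_o[cells] *= event.factor
    elif event.param == "lambda_b":
        state.mech.lambda_b[cells] *= event.factor
    elif event.param == "lambda_ell":
        state.mech.lambda_ell[cells] *= event.factor
    else:
        raise ValueError(f"unknown perturbation parameter {event.param!r}")


def run_coupled_simulation(state: CoupledState,
                           config: CouplingConfig,
                           schedule: list[PerturbationEvent] = (),
                           duration: float = 1000.0,
                           dt: float = 0.05,
                           fd_step: float = 1e-6,
                           record_every: int = 50,
                           feedback: bool = True,
                           progress: bool = False) -> Trajectory:
    """Run the fully coupled mechano-biochemical simulation.

    Per iteration: (1) explicit mechanics step for all vertices; (2) per-cell
    geometry update; (3) membrane-concentration rescale for the new half
    perimeter; (4) one FTCS reaction-diffusion step with the current psi;
    (5) every ``config.interval`` iterations, sensitivity probes, a fresh
    noise draw, and the homeostasis update of q (skipped for cells already at
    their homeostatic apical domain size).

    tau is the first time after the last scheduled perturbation at which all
    perturbed cells satisfy |ell_domain - ell_o| < threshold_frac * ell_o.
    """
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(config.seed)
    par = state.params.rate_vector()
    periodic = state.bc == "periodic"
    # FTCS stability on the current geometry (L shrinks during folding, which
    # only loosens the bound, but check the start)
    f_chk = MembraneField(L=float(state.geom[:, 3].min()), a=1.0, ell=1.0,
                          A=state.A[0], P=state.P[0], B=state.B[0])
    check_stability(f_chk, state.params, dt)

    ell0 = state.ell_domain()
    ell_o = (np.asarray(config.ell_domain_o, dtype=float).copy()
             if config.ell_domain_o is not None else ell0.copy())
    perturbed = sorted({c for ev in schedule for c in ev.cells})
    t_last_pert = max((ev.time for ev in schedule), default=0.0)
    pending = sorted(schedule, key=lambda e: e.time)

    n_rec = n_steps // record_every + 1
    N = state.n_cells
    times = np.empty(n_rec)
    psi_r = np.empty((n_rec, N))
    L_r = np.empty((n_rec, N))
    ell_r = np.empty((n_rec, N))
    q_r = np.empty((n_rec, N, 4))
    depth_r = np.empty(n_rec)
    tau = None
    tau_armed = False  # the deviation must first exceed the threshold band
    rec = 0

    L_prev = state.geom[:, 3].copy()
    act_tol = 1e-9

    def record(t):
        nonlocal rec
        times[rec] = t
        psi_r[rec] = state.geom[:, 6]
        L_r[rec] = state.geom[:, 3]
        ell_r[rec] = state.ell_domain()
        q_r[rec] = state.mech.q
        depth_r[rec] = fold_depth(state.mesh, "apical")
        rec += 1

    record(0.0)
    for it in range(n_steps):
        t = it * dt
        while pending and pending[0].time <= t + 1e-12:
            apply_perturbation(state, pending.pop(0))
        # (1) mechanics
        step_mechanics(state.mesh, state.mech, dt, state.constraint, fd_step)
        # (2) geometry
        state.update_geometry()
        L_new = state.geom[:, 3]
        # (3) concentration correction for membrane length change
        f = (L_prev / L_new)[:, None]
        state.A *= f
        state.P *= f
        state.B *= f
        L_prev = L_new.copy()
        # (4) reaction-diffusion
        # strict_cyto off: a shortening cell can transiently concentrate its
        # membrane pool past the total; the kinetics then act as net
        # dissociation and restore the balance.
        _kernels.rd_run_cells(state.A, state.P, state.B,
                              state.A_total, state.P_total,
                              state.B_total, L_new,
                              state.geom[:, 6], dt, 1, par, periodic, False)
        if not np.isfinite(state.A).all() or not np.isfinite(state.B).all()                 or not np.isfinite(state.P).all():
            raise FloatingPointError("membrane concentrations diverged")
        # (5) feedback
        if feedback and (it + 1) % config.interval == 0:
            ells = state.ell_domain()
            dev = np.abs(ells - ell_o)
            for c in np.flatnonzero(dev > act_tol):
                if config.probe_mode == "equilibrium":
                    sens = equilibrium_sensitivities(state, c)
                else:
                    sens = np.array([
                        apical_domain_sensitivity(state, c, k, config.probe_dq,
                                                  config.probe_dt, fd_step)
                        for k in range(4)])
                c_rate = sample_coupling_rate(config, rng)
                state.mech.q[c] = homeostasis_update(
                    state.mech.q[c], ells[c], ell_o[c], sens, c_rate,
                    config.gain * dt * config.interval,
                    config.q_floor, config.max_dq, config.q_cap)
        if (it + 1) % record_every == 0:
            record((it + 1) * dt)
            if progress:
                print(f"t={((it + 1) * dt):9.1f}  depth={depth_r[rec - 1]:.4f}")
        if tau is None and perturbed and t > t_last_pert:
            ells_now = state.ell_domain()
            dev_now = np.abs(ells_now[perturbed] - ell_o[perturbed])
            band = config.threshold_frac * ell_o[perturbed]
            if not tau_armed:
                if np.any(dev_now >= band):
                    tau_armed = True
            elif np.all(dev_now < band):
                tau = t - t_last_pert

    return Trajectory(times[:rec], psi_r[:rec], L_r[:rec], ell_r[:rec],
                      q_r[:rec], depth_r[:rec], tau, state.mesh, state)


# ---------------------------------------------------------------------------
# quasi-static sensitivity via the closed-form frustum energy
# ---------------------------------------------------------------------------


from .analysis import frustum_gradient as _frustum_grad  # noqa: E402


def equilibrium_sensitivity(a: float, b: float, h: float, peak_frac: float,
                            Ka: float, Po: float, lam_b: float, lam_l: float,
                            KV: float = 1.0, Vo: float = 1.0,
                            dq: float = 0.05) -> np.ndarray:
    """Quasi-static d ell_domain / dq for all four q components.

    Linearises the equilibrium of the isolated-cell frustum energy around the
    current shape: dx/dq_k = -H^{-1} d(grad U)/dq_k, with H the 3x3 shape
    Hessian.  The apical domain size responds through the geometric scaling of
    the membrane path, d ell = peak_frac * dL - da, where peak_frac = s*/L is
    the fractional Bazooka-peak position (unchanged by a pure rescale).
    """
    from .analysis import frustum_hessian
    x0 = np.array([a, b, h])
    base = (Ka, Po, lam_b, lam_l, KV, Vo)
    H = frustum_hessian(x0, base, eps=1e-5 * max(a, b, h))
    # regularise if a mode has gone soft/unstable under modulation
    w = np.linalg.eigvalsh(H)
    if w[0] < 1e-3:
        H = H + (1e-3 - w[0]) * np.eye(3)
    sens = np.empty(4)
    for k in range(4):
        scale = [1.0, 1.0, 1.0, 1.0]
        scale[k] = 1.0 + dq
        up = (Ka * scale[0], Po * scale[1], lam_b * scale[2], lam_l * scale[3], KV, Vo)
        scale[k] = 1.0 - dq
        dn = (Ka * scale[0], Po * scale[1], lam_b * scale[2], lam_l * scale[3], KV, Vo)
        dgrad = (_frustum_grad(x0, up) - _frustum_grad(x0, dn)) / (2 * dq)
        dx = -np.linalg.solve(H, dgrad)
        slant = np.sqrt(x0[2] ** 2 + 0.75 * (x0[1] - x0[0]) ** 2)
        dslant = (x0[2] * dx[2] + 0.75 * (x0[1] - x0[0]) * (dx[1] - dx[0])) / slant
        dL = dx[0] + dx[1] + dslant
        sens[k] = peak_frac * dL - dx[0]
    return sens


def equilibrium_sensitivities(state: CoupledState, cell: int) -> np.ndarray:
    """Quasi-static sensitivities of one cell from its current shape and mechanics."""
    g = state.geom[cell]
    idx = int(np.argmax(state.B[cell]))
    peak_frac = (idx + 0.5) / state.n_nodes
    m = state.mech
    return equilibrium_sensitivity(
        g[0], g[1], g[2], peak_frac,
        m.eff_K_a[cell], m.eff_P_hat_o[cell], m.eff_lambda_b[cell],
        m.eff_lambda_ell[cell], m.K_V[cell], m.V_o[cell])
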