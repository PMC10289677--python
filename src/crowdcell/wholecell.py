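"""Five-variable whole-cell balanced-growth model with crowding.

A self-replicating model cell: a membrane transporter T imports an external
nutrient (ordinary Michaelis-Menten kinetics, no crowding), an N-step
metabolic pathway (enzymes M, intermediates s) converts it into the protein
precursor p (a ternary-complex-like species), and the ribosome R polymerises
p into the three protein species at costs l_T, l_M, l_R precursors each.
The metabolic and ribosomal reactions follow crowding-adjusted kinetics:
their substrates, catalysts and complexes form the hard-sphere background
that sets Gamma and the diffusion slowdown; T is membrane-integrated and
excluded from crowding and from the occupancy.

Balanced growth at growth rate mu requires production to offset consumption
plus dilution for s and p, and the growth rate itself is the ribosomal flux
per total protein:

    mu = kcatR [p][R] / (KM*_R + [p]) / (l_T [T] + l_M [M] + l_R [R]).

At a fixed cytosolic occupancy rho the five concentrations are chosen to
maximize mu subject to the two balance equations and the occupancy
constraint; the solver is multi-start SLSQP in log-concentration space with
a crowding-unaware warm start and a Newton feasibility polish.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .crowding import (
    DEFAULT_CONSTANTS,
    CrowdingConstants,
    ReactionKinetics,
    SphereSpecies,
    diffusion_exponent_g,
)
from .results import ScanResult, argmax_with_ties
from .units import SECONDS_PER_HOUR, UM_TO_NM3

logger = logging.getLogger(__name__)

__all__ = [
    "WholeCellParams",
    "WholeCellState",
    "GBASolution",
    "transporter_flux",
    "evaluate_state",
    "growth_rate",
    "balance_residuals",
    "solve_at_occupancy",
    "optimal_occupancy",
    "derived_observables",
    "heatmap_scan",
    "METABOLIC_ENZYME_PRESETS",
]

#: Active metabolic enzyme counts per nutritional environment, obtained in
#: the source analysis by enzyme-concentration-constrained flux balance
#: analysis of the iAF1260 E. coli network: glucose minimal medium (259),
#: glucose + amino acids (206), rich medium (174), extremely rich medium
#: (140); 150 and 250 are the rounded values used in the sensitivity scans.
METABOLIC_ENZYME_PRESETS = (140, 150, 174, 206, 250, 259)


def _metabolic_kinetics(theta: float = 2.3) -> ReactionKinetics:
    return ReactionKinetics(
        kcat=13.7, KM0=130.0, theta=theta,
        substrate=SphereSpecies("s", 0.34), catalyst=SphereSpecies("M", 2.4))


def _ribosomal_kinetics(theta: float = 2.3) -> ReactionKinetics:
    return ReactionKinetics(
        kcat=22.0, KM0=120.0, theta=theta,
        substrate=SphereSpecies("p", 2.4), catalyst=SphereSpecies("R", 13.0))


@dataclass(frozen=True)
class WholeCellParams:
    """Kinetics, molecule sizes and protein costs of the model cell."""

    N: int = 250
    s_ext: float = 1.0                   # uM
    kcat_T: float = 13.7                 # s^-1
    KM_T: float = 1.0                    # uM
    metabolic: ReactionKinetics = field(default_factory=_metabolic_kinetics)
    ribosomal: ReactionKinetics = field(default_factory=_ribosomal_kinetics)
    l_T: float = 300.0
    l_M: float = 300.0
    l_R: float = 7459.0
    crowding: bool = True
    constants: CrowdingConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.s_ext <= 0:
            raise ValueError("s_ext must be > 0")
        for name in ("kcat_T", "KM_T", "l_T", "l_M", "l_R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class WholeCellState:
    """One evaluated concentration vector of the model cell."""

    conc: tuple[float, float, float, float, float]   # (s, p, T, M, R), uM
    complex_M: float      # per-reaction metabolic complex, uM
    complex_R: float      # ribosomal complex, uM
    rho: float
    mu: float             # h^-1
    v_T: float            # uM/s
    v_M: float
    v_R: float
    km_star_M: float      # uM
    km_star_R: float      # uM
    Gamma_M: float
    Gamma_R: float
    res_s: float          # normalized balance residuals
    res_p: float
    fixed_point_iterations: int
    fixed_point_converged: bool


@dataclass(frozen=True)
class GBASolution:
    """Best feasible state found at one occupancy."""

    state: WholeCellState
    mu: float             # h^-1
    residuals: tuple[float, float, float]   # (res_s, res_p, res_rho), normalized
    restarts_run: int
    feasible_candidates: int
    converged: bool


class _Ctx:
    """Precomputed geometry/kinetics in internal units for the hot path."""

    __slots__ = ("N", "sat_T", "kcat_T", "kcat_M", "kcat_R", "th_M", "th_R",
                 "km0_M", "km0_R", "g_M", "g_R", "lT", "lM", "lR", "crowding",
                 "radii", "surf", "vol")

    def __init__(self, p: WholeCellParams):
        self.N = p.N
        self.sat_T = p.s_ext / (p.s_ext + p.KM_T)
        self.kcat_T = p.kcat_T
        self.kcat_M = p.metabolic.kcat
        self.kcat_R = p.ribosomal.kcat
        self.th_M = p.metabolic.theta
        self.th_R = p.ribosomal.theta
        self.km0_M = p.metabolic.KM0 * UM_TO_NM3
        self.km0_R = p.ribosomal.KM0 * UM_TO_NM3
        self.g_M = diffusion_exponent_g(p.metabolic.substrate.radius, p.constants)
        self.g_R = diffusion_exponent_g(p.ribosomal.substrate.radius, p.constants)
        self.lT, self.lM, self.lR = p.l_T, p.l_M, p.l_R
        self.crowding = p.crowding
        species = (p.metabolic.substrate, p.metabolic.catalyst, p.metabolic.complex,
                   p.ribosomal.substrate, p.ribosomal.catalyst, p.ribosomal.complex)
        self.radii = tuple(sp.radius for sp in species)
        self.surf = tuple(sp.surface for sp in species)
        self.vol = tuple(sp.volume for sp in species)


def _ln_gamma(r, S, V, m0, m_r, m_r2, m_S, omv):
    """Scalar SPT ln gamma from precomputed moments; omv = 1 - <<V>>."""
    return (-math.log(omv)
            + (r * m_S + S * m_r + V * m0) / omv
            + (r * r * m_S * m_S + 2.0 * V * m_r * m_S) / (2.0 * omv * omv)
            + V * m_r2 * m_S * m_S / (3.0 * omv * omv * omv))


def _binding_root(e_tot, s_tot, km):
    b = e_tot + s_tot + km
    disc = b * b - 4.0 * e_tot * s_tot
    return 0.5 * (b - math.sqrt(disc if disc > 0.0 else 0.0))


def _fixed_point(ctx: _Ctx, s, p, T, M, R, rel_tol=1e-5, max_iter=500):
    """Self-consistent (KM*_M, KM*_R) and complex split; inputs in nm^-3.

    Both reactions see the same crowding background: free s, free M, the
    Ms complex (N replicas each), free p, free R, the Rp complex.  Returns
    (es_M, es_R, km_M, km_R, Gamma_M, Gamma_R, rho, iters, converged).
    """
    N = ctx.N
    r_s, r_m, r_cm, r_p, r_r, r_cr = ctx.radii
    S_s, S_m, S_cm, S_p, S_r, S_cr = ctx.surf
    V_s, V_m, V_cm, V_p, V_r, V_cr = ctx.vol
    st, mt = s / N, M / N
    rho = s * V_s + M * V_m + p * V_p + R * V_r
    if rho >= 0.999:
        raise ValueError("over-packed")
    if not ctx.crowding:
        es_m = _binding_root(mt, st, ctx.km0_M)
        es_r = _binding_root(R, p, ctx.km0_R)
        return es_m, es_r, ctx.km0_M, ctx.km0_R, 1.0, 1.0, rho, 0, True
    omv = 1.0 - rho
    DM = math.exp(-ctx.g_M * rho)
    DR = math.exp(-ctx.g_R * rho)
    km_m, km_r = ctx.km0_M, ctx.km0_R
    es_m = es_r = 0.0
    for it in range(1, max_iter + 1):
        es_m = _binding_root(mt, st, km_m)
        es_r = _binding_root(R, p, km_r)
        w_s, w_m, w_cm = s - N * es_m, M - N * es_m, N * es_m
        w_p, w_r, w_cr = p - es_r, R - es_r, es_r
        m0 = w_s + w_m + w_cm + w_p + w_r + w_cr
        m_r = (w_s * r_s + w_m * r_m + w_cm * r_cm
               + w_p * r_p + w_r * r_r + w_cr * r_cr)
        m_r2 = (w_s * r_s * r_s + w_m * r_m * r_m + w_cm * r_cm * r_cm
                + w_p * r_p * r_p + w_r * r_r * r_r + w_cr * r_cr * r_cr)
        m_S = (w_s * S_s + w_m * S_m + w_cm * S_cm
               + w_p * S_p + w_r * S_r + w_cr * S_cr)
        gam_M = math.exp(min(
            _ln_gamma(r_s, S_s, V_s, m0, m_r, m_r2, m_S, omv)
            + _ln_gamma(r_m, S_m, V_m, m0, m_r, m_r2, m_S, omv)
            - _ln_gamma(r_cm, S_cm, V_cm, m0, m_r, m_r2, m_S, omv), 700.0))
        gam_R = math.exp(min(
            _ln_gamma(r_p, S_p, V_p, m0, m_r, m_r2, m_S, omv)
            + _ln_gamma(r_r, S_r, V_r, m0, m_r, m_r2, m_S, omv)
            - _ln_gamma(r_cr, S_cr, V_cr, m0, m_r, m_r2, m_S, omv), 700.0))
        new_m = ctx.km0_M * (gam_M + ctx.th_M * DM) / ((1.0 + ctx.th_M) * gam_M * DM)
        new_r = ctx.km0_R * (gam_R + ctx.th_R * DR) / ((1.0 + ctx.th_R) * gam_R * DR)
        done = (abs(new_m - km_m) <= rel_tol * km_m
                and abs(new_r - km_r) <= rel_tol * km_r)
        km_m, km_r = new_m, new_r
        if done:
            es_m = _binding_root(mt, st, km_m)
            es_r = _binding_root(R, p, km_r)
            return es_m, es_r, km_m, km_r, gam_M, gam_R, rho, it, True
    return es_m, es_r, km_m, km_r, gam_M, gam_R, rho, max_iter, False


_TINY = 1e-300


def _eval_raw(ctx: _Ctx, s, p, T, M, R):
    """mu (s^-1), normalized residuals and diagnostics; inputs in nm^-3."""
    es_m, es_r, km_m, km_r, gam_M, gam_R, rho, iters, ok = _fixed_point(
        ctx, s, p, T, M, R)
    v_T = ctx.kcat_T * ctx.sat_T * T
    v_M = ctx.kcat_M * es_m
    v_R = ctx.kcat_R * es_r
    protein = ctx.lT * T + ctx.lM * M + ctx.lR * R
    mu = v_R / protein if protein > 0 else 0.0
    res_s = (v_T - v_M - mu * s) / (v_T + v_M + mu * s + _TINY)
    res_p = (v_M - v_R - mu * p) / (v_M + v_R + mu * p + _TINY)
    return mu, res_s, res_p, rho, es_m, es_r, km_m, km_r, gam_M, gam_R, iters, ok


def transporter_flux(T_conc: float, params: WholeCellParams) -> float:
    """Transport flux v_T = kcat_T s_ext [T] / (s_ext + KM_T) in uM/s."""
    if T_conc < 0:
        raise ValueError("transporter concentration must be >= 0")
    return params.kcat_T * params.s_ext * T_conc / (params.s_ext + params.KM_T)


def evaluate_state(conc_um: Sequence[float], params: WholeCellParams) -> WholeCellState:
    """Evaluate fluxes, growth rate and residuals at (s, p, T, M, R) in uM."""
    s, p, T, M, R = (c * UM_TO_NM3 for c in conc_um)
    ctx = _Ctx(params)
    mu, res_s, res_p, rho, es_m, es_r, km_m, km_r, gm, gr, iters, ok = _eval_raw(
        ctx, s, p, T, M, R)
    v_T = ctx.kcat_T * ctx.sat_T * T
    return WholeCellState(
        conc=tuple(float(c) for c in conc_um),
        complex_M=es_m / UM_TO_NM3, complex_R=es_r / UM_TO_NM3,
        rho=rho, mu=mu * SECONDS_PER_HOUR,
        v_T=v_T / UM_TO_NM3, v_M=ctx.kcat_M * es_m / UM_TO_NM3,
        v_R=ctx.kcat_R * es_r / UM_TO_NM3,
        km_star_M=km_m / UM_TO_NM3, km_star_R=km_r / UM_TO_NM3,
        Gamma_M=gm, Gamma_R=gr, res_s=res_s, res_p=res_p,
        fixed_point_iterations=iters, fixed_point_converged=ok)


def growth_rate(state: WholeCellState, params: WholeCellParams) -> float:
    """Growth rate mu (h^-1): ribosomal flux over total protein cost."""
    _, _, T, M, R = state.conc
    protein = params.l_T * T + params.l_M * M + params.l_R * R
    if protein <= 0:
        raise ValueError("growth rate undefined without protein")
    return state.v_R / protein * SECONDS_PER_HOUR


def balance_residuals(state: WholeCellState, params: WholeCellParams) -> tuple[float, float]:
    """Normalized balance residuals (res_s, res_p) of an evaluated state."""
    return state.res_s, state.res_p


# ---------------------------------------------------------------------------
# Constrained growth maximization at fixed occupancy
# ---------------------------------------------------------------------------

# Hard variable bounds (uM, log scale).  Wide on purpose: optimal states
# can hold molar-range metabolite pools, and a binding upper bound would
# cap the metabolic saturation and distort the occupancy tradeoff.
_LOG_LB, _LOG_UB = math.log(1e-6), math.log(1e9)
# Random initial points are sampled log-uniformly from this narrower,
# physiological range.
_INIT_LB, _INIT_UB = math.log(1e-6), math.log(1e5)


class _Problem:
    """Cached evaluation of objective and constraints over z = ln(conc)."""

    def __init__(self, params: WholeCellParams, rho_target: float):
        self.ctx = _Ctx(params)
        self.rho_target = rho_target
        self._z = None
        self._val = None

    def _compute(self, z):
        key = tuple(z)
        if key == self._z:
            return self._val
        c = np.exp(np.clip(z, _LOG_LB - 2, _LOG_UB + 2)) * UM_TO_NM3
        try:
            mu, res_s, res_p, rho, *_ = _eval_raw(self.ctx, *c)
        except ValueError:   # over-packed trial point
            vols = self.ctx.vol
            rho = c[0] * vols[0] + c[3] * vols[1] + c[1] * vols[3] + c[4] * vols[4]
            mu, res_s, res_p = 0.0, 0.0, 0.0
        self._z = key
        self._val = (mu, res_s, res_p, rho / self.rho_target - 1.0)
        return self._val

    def objective(self, z):
        return -self._compute(z)[0] * SECONDS_PER_HOUR

    def constraints(self, z):
        v = self._compute(z)
        return np.array([v[1], v[2], v[3]])


def _deterministic_start(params: WholeCellParams, rho_target: float) -> np.ndarray:
    """Heuristic composition: split the occupancy between the sectors."""
    shares = dict(s=0.10, M=0.35, p=0.15, R=0.40)
    ctx = _Ctx(params)
    V = dict(s=ctx.vol[0], M=ctx.vol[1], p=ctx.vol[3], R=ctx.vol[4])
    c = {k: shares[k] * rho_target / V[k] / UM_TO_NM3 for k in shares}
    T = 0.05 * c["M"] + 1e-4
    vec = np.array([c["s"], c["p"], T, c["M"], c["R"]])
    return np.log(np.clip(vec, 1e-6, 1e5))


def _polish(problem: _Problem, z: np.ndarray) -> np.ndarray | None:
    """Newton feasibility projection: drive the three constraints to zero
    by adjusting (T, M, R) at fixed (s, p)."""

    def fun(y):
        zz = z.copy()
        zz[2:5] = y
        return problem.constraints(zz)

    sol = optimize.root(fun, z[2:5], method="hybr", tol=1e-13)
    if not sol.success:
        return None
    out = z.copy()
    out[2:5] = sol.x
    return out


def solve_at_occupancy(params: WholeCellParams, rho_target: float,
                       n_restarts: int = 20, seed: int = 0,
                       warm_start: np.ndarray | None = None,
                       feas_tol: float = 1e-9) -> GBASolution:
    """Maximize mu over (s, p, T, M, R) >= 0 at a fixed occupancy.

    Two phases: (i) the crowding-unaware model (KM* = KM0) is solved from a
    deterministic and a few random log-uniform starting points; (ii) at
    least ``n_restarts`` SLSQP runs of the crowding-adjusted model start
    from the warm start and log-normal perturbations of it.  Every
    candidate is polished by a Newton feasibility projection; the feasible
    candidate with the highest mu wins.  Deterministic under ``seed``.

    Raises
    ------
    RuntimeError
        If no feasible point is found (e.g. rho_target too small to hold
        any growth machinery).
    """
    if not 0.0 < rho_target < 1.0:
        raise ValueError("rho_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    bounds = [(_LOG_LB, _LOG_UB)] * 5
    slsqp = dict(method="SLSQP", bounds=bounds,
                 options=dict(maxiter=300, ftol=1e-14))

    def run(problem, z0):
        res = optimize.minimize(problem.objective, z0,
                                constraints=[dict(type="eq", fun=problem.constraints)],
                                **slsqp)
        return res.x

    # Phase (i): crowding-unaware warm start.
    if warm_start is None:
        plain = _Problem(replace(params, crowding=False), rho_target)
        starts = [_deterministic_start(params, rho_target)]
        for _ in range(3):
            starts.append(rng.uniform(_INIT_LB, _INIT_UB, size=5))
        best_w, best_mu_w = None, -np.inf
        for z0 in starts:
            z = run(plain, z0)
            mu = -plain.objective(z)
            if np.all(np.abs(plain.constraints(z)) < 1e-6) and mu > best_mu_w:
                best_w, best_mu_w = z, mu
        warm_start = best_w if best_w is not None else starts[0]

    # Phase (ii): crowding-adjusted multi-start.
    problem = _Problem(params, rho_target)
    starts = [warm_start]
    for _ in range(n_restarts - 1):
        starts.append(warm_start + rng.normal(0.0, 0.4, size=5))
    best_z, best_mu, n_feasible = None, -np.inf, 0
    for z0 in starts:
        try:
            z = run(problem, z0)
        except (ValueError, FloatingPointError):   # pragma: no cover
            continue
        zp = _polish(problem, z)
        if zp is None:
            continue
        mu = -problem.objective(zp)
        resid = problem.constraints(zp)
        if np.max(np.abs(resid)) <= feas_tol and mu > 0:
            n_feasible += 1
            if mu > best_mu:
                best_z, best_mu = zp, mu
    if best_z is None:
        raise RuntimeError(
            f"no feasible growth state found at rho = {rho_target} "
            f"({n_restarts} restarts)")
    conc = np.exp(best_z)
    state = evaluate_state(conc, params)
    resid = problem.constraints(best_z)
    return GBASolution(state=state, mu=best_mu,
                       residuals=tuple(float(r) for r in resid),
                       restarts_run=len(starts), feasible_candidates=n_feasible,
                       converged=True)


def default_wholecell_rho_grid() -> np.ndarray:
    """Occupancy grid matching the pathway scans: step 0.01 on 0.01..0.80,
    refined to 0.001 on 0.10..0.36."""
    coarse = np.round(np.arange(0.01, 0.801, 0.01), 3)
    fine = np.round(np.arange(0.100, 0.3601, 0.001), 3)
    return np.unique(np.concatenate([coarse, fine]))


def optimal_occupancy(params: WholeCellParams,
                      rho_grid: np.ndarray | None = None,
                      n_restarts: int = 20, seed: int = 0,
                      refine_step: float | None = None,
                      refine_halfwidth: float = 0.02) -> ScanResult:
    """mu(rho) over an occupancy grid and the growth-optimal occupancy.

    Solves :func:`solve_at_occupancy` at every grid point, warm-starting
    each point with the previous solution (continuation) in addition to
    the random restarts.  If ``refine_step`` is given, a second pass scans
    ``rho_opt +/- refine_halfwidth`` at that resolution.  Ties break
    toward smaller rho.
    """
    if rho_grid is None:
        rho_grid = default_wholecell_rho_grid()
    rho_grid = np.asarray(rho_grid, dtype=float)

    def sweep(grid, seed_offset=0):
        rows, warm = [], None
        for k, rho in enumerate(grid):
            try:
                sol = solve_at_occupancy(params, rho, n_restarts=n_restarts,
                                         seed=seed + seed_offset + k,
                                         warm_start=warm)
            except RuntimeError:
                logger.warning("infeasible at rho=%.3f; skipped", rho)
                continue
            warm = np.log(np.asarray(sol.state.conc))
            rows.append(_solution_row(sol, params, rho))
        return rows

    rows = sweep(rho_grid)
    if not rows:
        raise RuntimeError("no feasible occupancy in the grid")
    table = pd.DataFrame(rows)
    if refine_step is not None:
        rho0 = float(table.loc[argmax_with_ties(table, "mu"), "rho"])
        lo = max(rho0 - refine_halfwidth, float(rho_grid[0]))
        hi = min(rho0 + refine_halfwidth, float(rho_grid[-1]))
        fine = np.round(np.arange(lo, hi + refine_step / 2, refine_step), 6)
        fine = np.setdiff1d(fine, np.round(rho_grid, 6))
        rows += sweep(fine, seed_offset=10_000)
        table = pd.DataFrame(rows).sort_values("rho", ignore_index=True)
    table["mu_over_mumax"] = table["mu"] / table["mu"].max()
    i_opt = argmax_with_ties(table, "mu")
    opt = table.loc[i_opt]
    return ScanResult(table=table, objective="mu",
                      optimum=dict(rho=float(opt["rho"]), mu=float(opt["mu"]),
                                   km_star_M=float(opt["km_star_M"]),
                                   km_star_R=float(opt["km_star_R"])))


def derived_observables(solution: GBASolution, params: WholeCellParams) -> dict:
    """Sector volume fractions, saturations and ribosome allocation.

    Complexes are assigned to sectors by their constituents, which is exact
    under volume additivity.  Allocation fractions mu l_i [i] / v_R sum to
    one in balanced growth.
    """
    st = solution.state
    s, p, T, M, R = st.conc
    kin_m, kin_r = params.metabolic, params.ribosomal
    vol_metab = (s * kin_m.substrate.volume + M * kin_m.catalyst.volume) * UM_TO_NM3
    vol_ribo = (p * kin_r.substrate.volume + R * kin_r.catalyst.volume) * UM_TO_NM3
    mu_s = st.mu / SECONDS_PER_HOUR
    alloc = {i: mu_s * l * c / st.v_R for i, l, c in
             (("T", params.l_T, T), ("M", params.l_M, M), ("R", params.l_R, R))}
    return dict(
        volfrac_metab=vol_metab / st.rho, volfrac_ribo=vol_ribo / st.rho,
        sat_M=(s / params.N) / (s / params.N + st.km_star_M),
        sat_R=p / (p + st.km_star_R),
        km_star_M=st.km_star_M, km_star_R=st.km_star_R,
        alloc_T=alloc["T"], alloc_M=alloc["M"], alloc_R=alloc["R"])


def heatmap_scan(N_values: Sequence[int], s_ext_values: Sequence[float],
                 params: WholeCellParams | None = None,
                 rho_grid: np.ndarray | None = None,
                 n_restarts: int = 8, seed: int = 0,
                 refine_step: float | None = None) -> ScanResult:
    """rho_opt(N, s_ext) over a grid of pathway lengths and nutrient levels.

    rho_opt is expected to be nondecreasing in N at fixed s_ext and
    nonincreasing in s_ext at fixed N (within grid resolution).
    """
    if len(N_values) == 0 or len(s_ext_values) == 0:
        raise ValueError("grids must be nonempty")
    base = params or WholeCellParams()
    rows = []
    for N in N_values:
        for s_ext in s_ext_values:
            p = replace(base, N=int(N), s_ext=float(s_ext))
            scan = optimal_occupancy(p, rho_grid=rho_grid, n_restarts=n_restarts,
                                     seed=seed, refine_step=refine_step)
            rows.append(dict(N=int(N), s_ext=float(s_ext), rho_opt=scan.rho_opt,
                             mu_max=scan.optimum["mu"],
                             km_star_M=scan.optimum["km_star_M"],
                             km_star_R=scan.optimum["km_star_R"]))
    table = pd.DataFrame(rows)
    i_best = int(table["mu_max"].idxmax())
    return ScanResult(table=table, objective="rho_opt",
                      optimum=dict(rho=float(table.loc[i_best, "rho_opt"])))


def _solution_row(sol: GBASolution, params: WholeCellParams, rho: float) -> dict:
    st = sol.state
    obs = derived_observables(sol, params)
    return dict(
        N=params.N, s_ext=params.s_ext, rho=rho, mu=sol.mu,
        conc_s=st.conc[0], conc_p=st.conc[1], conc_T=st.conc[2],
        conc_M=st.conc[3], conc_R=st.conc[4],
        km_star_M=st.km_star_M, km_star_R=st.km_star_R,
        sat_M=obs["sat_M"], sat_R=obs["sat_R"],
        volfrac_metab=obs["volfrac_metab"], volfrac_ribo=obs["volfrac_ribo"],
        alloc_T=obs["alloc_T"], alloc_M=obs["alloc_M"], alloc_R=obs["alloc_R"],
        res_s=sol.residuals[0], res_p=sol.residuals[1], res_rho=sol.residuals[2],
        restarts=sol.restarts_run, converged=sol.converged)
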