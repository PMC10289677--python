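"""N-step pathway models with crowding-adjusted kinetics.

A linear pathway of N identical enzyme-catalysed reactions at steady state
(the metabolic system), or N parallel reactions (the ribosomal system,
e.g. one ribosome species per anticodon).  All substrates share one radius,
all catalysts another; with identical kinetics the pathway collapses to a
single reaction with rescaled parameters: per-reaction concentrations are
[s]/N and [E]/N, the pathway flux is

    v = (kcat / N) [s][E] / (N KM* + [s]),

and the growth proxy is the flux per unit dry mass mu = v / rho (times N
for the parallel topology).  KM* is solved self-consistently: the free
substrates, free catalysts and complexes of all N reactions form the
crowding background that determines Gamma and the diffusion slowdown.

Scans tabulate the objective over a (rho, substrate volume share) grid and
report the envelope over shares and the occupancy optimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .crowding import (
    DEFAULT_CONSTANTS,
    CrowdingConstants,
    KMStarMode,
    ReactionKinetics,
    SphereSpecies,
    diffusion_exponent_g,
    km_star_value,
    spt_ln_gamma,
)
from .results import ScanResult, argmax_with_ties
from .units import UM_TO_NM3

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayParams",
    "PathwayState",
    "ScanGrid",
    "metabolic_preset",
    "ribosomal_preset",
    "pathway_occupancy",
    "evaluate_composition",
    "specific_flux",
    "scan_optimal_occupancy",
    "km_star_decomposition_scan",
    "vazquez_flux",
    "vazquez_scan",
]

Topology = Literal["linear", "parallel"]

# Hard-sphere radii (nm) of the two size presets: metabolites/enzymes and
# ternary complexes/ribosomes.
METABOLIC_RADII = (0.34, 2.4)
RIBOSOMAL_RADII = (2.4, 13.0)


@dataclass(frozen=True)
class PathwayParams:
    """Pathway length, topology and per-reaction kinetics."""

    N: int = 20
    kinetics: ReactionKinetics = None  # type: ignore[assignment]
    topology: Topology = "linear"
    constants: CrowdingConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.kinetics is None:
            object.__setattr__(self, "kinetics", _default_kinetics(*METABOLIC_RADII))


def _default_kinetics(r_s: float, r_e: float, theta: float = 2.3,
                      kcat: float = 1.0, KM0: float = 130.0) -> ReactionKinetics:
    sub = SphereSpecies("substrate", r_s)
    cat = SphereSpecies("catalyst", r_e)
    return ReactionKinetics(kcat=kcat, KM0=KM0, theta=theta,
                            substrate=sub, catalyst=cat)


def metabolic_preset(N: int = 20, theta: float = 2.3) -> PathwayParams:
    """Linear pathway of small molecules: r_s = 0.34 nm, r_E = 2.4 nm."""
    return PathwayParams(N=N, kinetics=_default_kinetics(*METABOLIC_RADII, theta=theta),
                         topology="linear")


def ribosomal_preset(N: int = 20, theta: float = 2.3) -> PathwayParams:
    """Parallel system of large molecules: r_s = 2.4 nm (tRNA-sized ternary
    complexes), r_E = 13 nm (ribosomes)."""
    return PathwayParams(N=N, kinetics=_default_kinetics(*RIBOSOMAL_RADII, theta=theta),
                         topology="parallel")


def default_rho_grid() -> np.ndarray:
    """Occupancy grid: 0.01..0.80 step 0.01, refined 0.100..0.360 step 0.001."""
    coarse = np.round(np.arange(0.01, 0.801, 0.01), 3)
    fine = np.round(np.arange(0.100, 0.3601, 0.001), 3)
    return np.unique(np.concatenate([coarse, fine]))


def default_share_grid() -> np.ndarray:
    """Geometric grid of the substrate share of occupied volume.

    From 0.1% to 97.7%, increasing by a factor 1.0023 per step.
    """
    n = int(math.floor(math.log(0.977 / 0.001) / math.log(1.0023))) + 1
    return 0.001 * 1.0023 ** np.arange(n + 1)


@dataclass(frozen=True)
class ScanGrid:
    """The (rho, substrate volume share) grid of a pathway scan."""

    rho_values: np.ndarray = field(default_factory=default_rho_grid)
    substrate_share_values: np.ndarray = field(default_factory=default_share_grid)

    def __post_init__(self) -> None:
        for name, g in (("rho_values", self.rho_values),
                        ("substrate_share_values", self.substrate_share_values)):
            g = np.asarray(g, dtype=float)
            object.__setattr__(self, name, g)
            if g.ndim != 1 or len(g) == 0:
                raise ValueError(f"{name} must be a non-empty 1-d grid")
            if np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if g[0] <= 0 or g[-1] >= 1:
                raise ValueError(f"{name} must lie within (0, 1)")


@dataclass(frozen=True)
class PathwayState:
    """One evaluated composition of the pathway."""

    s_total: float        # summed substrate concentration, uM
    E_total: float        # summed catalyst concentration, uM
    rho: float            # occupancy
    complex_conc: float   # per-reaction complex concentration, uM
    KM_star: float        # uM
    flux: float           # pathway (or summed parallel) flux, uM/s
    mu: float             # flux per unit dry mass, uM/s per volume fraction
    converged: bool


def pathway_occupancy(s_total: float, E_total: float, params: PathwayParams) -> float:
    """Occupancy from summed substrate/catalyst concentrations (uM).

    rho = N_A (4 pi / 3) ([s] r_s^3 + [E] r_E^3); by volume additivity the
    free/bound split leaves rho unchanged.
    """
    if s_total < 0 or E_total < 0:
        raise ValueError("concentrations must be non-negative")
    kin = params.kinetics
    rho = (s_total * UM_TO_NM3 * kin.substrate.volume
           + E_total * UM_TO_NM3 * kin.catalyst.volume)
    if rho >= 1.0:
        raise ValueError(f"over-packed: rho = {rho:.3f} >= 1")
    return rho


def _solve_pathway_equilibrium(params: PathwayParams, n_s: np.ndarray,
                               n_E: np.ndarray, mode: KMStarMode = "full",
                               rel_tol: float = 1e-5, max_iter: int = 500):
    """Vectorized self-consistent KM* over compositions.

    ``n_s``/``n_E`` are summed number densities (nm^-3) of substrates and
    catalysts.  Returns (es, km, converged): per-reaction complex density,
    KM* (nm^-3), and a convergence flag, each of the broadcast shape.
    """
    kin = params.kinetics
    N = params.N
    r_s, r_e = kin.substrate.radius, kin.catalyst.radius
    cplx = kin.complex
    r_c = cplx.radius
    g = diffusion_exponent_g(r_s, params.constants)
    km0 = kin.KM0 * UM_TO_NM3

    st = n_s / N          # per-reaction totals
    et = n_E / N
    rho = n_s * kin.substrate.volume + n_E * kin.catalyst.volume

    es = np.zeros_like(st)
    km = np.full_like(st, km0)
    converged = np.zeros(st.shape, dtype=bool)
    for _ in range(max_iter):
        # crowding background: N replicas of (free substrate, free catalyst,
        # complex); moments are linear, so the replicas enter via totals
        w_s, w_e, w_c = n_s - N * es, n_E - N * es, N * es
        m0 = w_s + w_e + w_c
        m_r = w_s * r_s + w_e * r_e + w_c * r_c
        m_r2 = w_s * r_s**2 + w_e * r_e**2 + w_c * r_c**2
        m_S = w_s * kin.substrate.surface + w_e * kin.catalyst.surface + w_c * cplx.surface
        ln_gamma_sum = (spt_ln_gamma(r_s, m0, m_r, m_r2, m_S, rho)
                        + spt_ln_gamma(r_e, m0, m_r, m_r2, m_S, rho)
                        - spt_ln_gamma(r_c, m0, m_r, m_r2, m_S, rho))
        Gamma = np.exp(np.minimum(ln_gamma_sum, 700.0))
        km_new = km_star_value(km0, kin.theta, Gamma, g, rho, mode)
        b = et + st + km_new
        es = 0.5 * (b - np.sqrt(np.maximum(b * b - 4.0 * et * st, 0.0)))
        converged = np.abs(km_new - km) <= rel_tol * km
        km = km_new
        if converged.all():
            break
    return es, km, converged


def evaluate_composition(params: PathwayParams, s_total: float, E_total: float,
                         mode: KMStarMode = "full") -> PathwayState:
    """Solve one composition (uM totals) and return fluxes and mu."""
    rho = pathway_occupancy(s_total, E_total, params)
    n_s = np.asarray(s_total * UM_TO_NM3)
    n_E = np.asarray(E_total * UM_TO_NM3)
    es, km, ok = _solve_pathway_equilibrium(params, n_s, n_E, mode)
    kin = params.kinetics
    v = float(kin.kcat * es)                     # per-reaction flux, nm^-3/s
    if params.topology == "parallel":
        v *= params.N
    if rho == 0.0:
        raise ValueError("flux per dry mass undefined at rho = 0")
    return PathwayState(
        s_total=s_total, E_total=E_total, rho=rho,
        complex_conc=float(es) / UM_TO_NM3, KM_star=float(km) / UM_TO_NM3,
        flux=v / UM_TO_NM3, mu=(v / UM_TO_NM3) / rho, converged=bool(ok))


def specific_flux(state: PathwayState, params: PathwayParams) -> float:
    """Flux per unit dry mass of an evaluated composition."""
    return state.mu


def _composition_from_grid(params: PathwayParams, rho: float, shares: np.ndarray):
    """Map (rho, substrate share of occupied volume) to number densities."""
    kin = params.kinetics
    n_s = shares * rho / kin.substrate.volume
    n_E = (1.0 - shares) * rho / kin.catalyst.volume
    return n_s, n_E


def scan_optimal_occupancy(params: PathwayParams, grid: ScanGrid | None = None,
                           objective: str = "mu", mode: KMStarMode = "full",
                           keep_full: bool = False) -> ScanResult:
    """Scan the (rho, share) grid and locate the occupancy optimum.

    For each grid point the composition implied by the occupancy split is
    solved self-consistently and the objective (``'mu'``: flux per dry
    mass, or ``'flux'``: total flux) evaluated.  The returned table holds
    the per-rho envelope (objective maximized over the substrate share);
    ``keep_full=True`` attaches the full table as ``result.full_table``.
    Non-converged grid points are excluded from the envelope with a
    warning.
    """
    if objective not in ("mu", "flux"):
        raise ValueError(f"objective must be 'mu' or 'flux', got {objective!r}")
    grid = grid or ScanGrid()
    kin = params.kinetics
    rows = []
    full_rows = []
    for rho in grid.rho_values:
        shares = grid.substrate_share_values
        n_s, n_E = _composition_from_grid(params, rho, shares)
        es, km, ok = _solve_pathway_equilibrium(params, n_s, n_E, mode)
        v = kin.kcat * es
        if params.topology == "parallel":
            v = v * params.N
        v_um = v / UM_TO_NM3
        mu = v_um / rho
        if not ok.all():
            logger.warning("%d/%d non-converged points at rho=%.3f excluded",
                           (~ok).sum(), ok.size, rho)
        obj = np.where(ok, mu if objective == "mu" else v_um, -np.inf)
        if not ok.any():
            continue
        i = int(np.argmax(obj))
        rows.append(dict(rho=rho, substrate_share=shares[i], flux=v_um[i],
                         mu=mu[i], km_star=km[i] / UM_TO_NM3,
                         s_total=n_s[i] / UM_TO_NM3, E_total=n_E[i] / UM_TO_NM3,
                         converged=bool(ok[i])))
        if keep_full:
            full_rows.append(pd.DataFrame(dict(
                rho=rho, substrate_share=shares, flux=v_um, mu=mu,
                km_star=km / UM_TO_NM3, converged=ok)))
    if not rows:
        raise ValueError("all grid points over-packed or non-converged")
    table = pd.DataFrame(rows)
    i_opt = argmax_with_ties(table, objective)
    opt = table.loc[i_opt]
    result = ScanResult(table=table, objective=objective,
                        optimum=dict(rho=float(opt["rho"]),
                                     value=float(opt[objective]),
                                     substrate_share=float(opt["substrate_share"])))
    if keep_full:
        result.full_table = pd.concat(full_rows, ignore_index=True)
    return result


def km_star_decomposition_scan(params: PathwayParams,
                               grid: ScanGrid | None = None) -> ScanResult:
    """KM*/KM0 versus rho for the full, diffusion-only and transition-only
    variants, evaluated at the per-rho mu-optimal composition.

    The diffusion-only variant (Gamma = 1) rises monotonically with rho;
    the transition-only variant (g = 0) falls toward the plateau
    KM0/(1+theta); their combination is dominated by diffusion at high rho.
    """
    grid = grid or ScanGrid()
    envelope = scan_optimal_occupancy(params, grid, objective="mu")
    kin = params.kinetics
    rows = []
    for _, row in envelope.table.iterrows():
        n_s = np.asarray(row["s_total"] * UM_TO_NM3)
        n_E = np.asarray(row["E_total"] * UM_TO_NM3)
        entry = dict(rho=row["rho"], substrate_share=row["substrate_share"])
        for mode in ("full", "diffusion_only", "transition_only"):
            _, km, ok = _solve_pathway_equilibrium(params, n_s, n_E, mode)
            entry[f"km_ratio_{mode}"] = float(km) / (kin.KM0 * UM_TO_NM3)
            entry[f"converged_{mode}"] = bool(ok)
        rows.append(entry)
    table = pd.DataFrame(rows)
    return ScanResult(table=table, objective="km_ratio_full",
                      optimum=dict(rho=envelope.rho_opt))


# --- Alternative crowding treatment (saturation vs diffusion regimes) ----

def vazquez_flux(s: float, E: float, rho: float, regime: str,
                 kin: ReactionKinetics, N: int = 1) -> float:
    """Pathway flux under the two-regime crowding description.

    Reactions in the saturation regime are sped up by the contact factor
    1/(1-rho); reactions in the diffusion regime carry the extra slowdown
    exp(-5.8 rho).  ``s``/``E`` are summed concentrations in uM; the
    returned flux is per reaction (uM/s), as in the self-consistent model.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if regime not in ("saturated", "diffusion"):
        raise ValueError(f"regime must be 'saturated' or 'diffusion', got {regime!r}")
    v = (kin.kcat / N) * s * E / (N * kin.KM0 + s) / (1.0 - rho)
    if regime == "diffusion":
        v *= math.exp(-5.8 * rho)
    return v


def vazquez_scan(params: PathwayParams, grid: ScanGrid | None = None,
                 regime: str = "saturated", objective: str = "mu") -> ScanResult:
    """Envelope scan of the two-regime model over the (rho, share) grid."""
    grid = grid or ScanGrid()
    kin = params.kinetics
    rows = []
    for rho in grid.rho_values:
        shares = grid.substrate_share_values
        n_s, n_E = _composition_from_grid(params, rho, shares)
        s_um, e_um = n_s / UM_TO_NM3, n_E / UM_TO_NM3
        v = (kin.kcat / params.N) * s_um * e_um / (params.N * kin.KM0 + s_um) / (1.0 - rho)
        if regime == "diffusion":
            v = v * math.exp(-5.8 * rho)
        if params.topology == "parallel":
            v = v * params.N
        mu = v / rho
        obj = mu if objective == "mu" else v
        i = int(np.argmax(obj))
        rows.append(dict(rho=rho, substrate_share=shares[i], flux=v[i], mu=mu[i]))
    table = pd.DataFrame(rows)
    i_opt = argmax_with_ties(table, objective)
    opt = table.loc[i_opt]
    return ScanResult(table=table, objective=objective,
                      optimum=dict(rho=float(opt["rho"]), value=float(opt[objective])))
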