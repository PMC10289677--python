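"""Widom particle-insertion oracle for hard-sphere activity coefficients.

Independent Monte-Carlo estimate of ln gamma = beta * mu_excess for a probe
sphere in a periodic hard-sphere fluid: equilibrate the fluid with
single-particle Metropolis moves, then estimate the insertion probability
p = <exp(-beta dU)> (for hard spheres: the fraction of random trial
positions with no overlap) so that ln gamma = -ln p.  The standard error
is taken over per-configuration batches, which accounts for correlation
between insertions into the same configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class WidomEstimate:
    ln_gamma: float
    se: float
    n_insertions: int
    acceptance: float


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def widom_ln_gamma(r_probe: float, r_bg: float, occupancy: float,
                   n_spheres: int = 512, n_batches: int = 14,
                   insertions_per_batch: int = 12_000,
                   equilibration_sweeps: int = 120,
                   decorrelation_sweeps: int = 8,
                   seed: int = 0) -> WidomEstimate:
    """Monte-Carlo ln gamma of a probe sphere in a monodisperse background."""
    rng = np.random.default_rng(seed)
    v_bg = (4.0 / 3.0) * math.pi * r_bg**3
    box = (n_spheres * v_bg / occupancy) ** (1.0 / 3.0)
    sigma = 2.0 * r_bg                       # background contact distance
    contact = r_probe + r_bg                 # probe-background contact

    # start from a simple cubic lattice with no overlaps
    n_side = math.ceil(n_spheres ** (1.0 / 3.0))
    if box / n_side < sigma:
        raise ValueError("occupancy too high for lattice initialisation")
    grid = (np.arange(n_side) + 0.5) * (box / n_side)
    pos = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T[:n_spheres]
    pos = np.ascontiguousarray(pos)

    step = 0.35 * r_bg
    accepted = attempted = 0

    def sweep() -> None:
        nonlocal accepted, attempted
        order = rng.permutation(n_spheres)
        trials = rng.uniform(-step, step, size=(n_spheres, 3))
        for k, i in enumerate(order):
            new = (pos[i] + trials[k]) % box
            d = _min_image(pos - new, box)
            d2 = np.einsum("ij,ij->i", d, d)
            d2[i] = np.inf
            attempted += 1
            if d2.min() >= sigma * sigma:
                pos[i] = new
                accepted += 1

    for _ in range(equilibration_sweeps):
        sweep()

    batch_hits = np.empty(n_batches)
    for b in range(n_batches):
        for _ in range(decorrelation_sweeps):
            sweep()
        points = rng.uniform(0.0, box, size=(insertions_per_batch, 3))
        ok = np.ones(insertions_per_batch, dtype=bool)
        # chunk the distance test to bound memory
        for lo in range(0, insertions_per_batch, 2000):
            hi = lo + 2000
            d = _min_image(points[lo:hi, None, :] - pos[None, :, :], box)
            d2 = np.einsum("ijk,ijk->ij", d, d)
            ok[lo:hi] = d2.min(axis=1) >= contact * contact
        batch_hits[b] = ok.mean()
    p = batch_hits.mean()
    if p <= 0:
        raise RuntimeError("no successful insertions; probe too large")
    ln_gamma = -math.log(p)
    se_p = batch_hits.std(ddof=1) / math.sqrt(n_batches)
    return WidomEstimate(ln_gamma=ln_gamma, se=se_p / p,
                         n_insertions=n_batches * insertions_per_batch,
                         acceptance=accepted / max(attempted, 1))
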