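"""Compact memetic NSGA-II for the model inversion.

Standard components: fast non-dominated sorting, crowding distance,
binary-tournament selection on (rank, crowding), simulated binary crossover
(SBX) and polynomial mutation, with a (µ + λ) environmental selection.
Two additions improve convergence on the smooth, low-noise landscapes this
package inverts: half of each brood is produced by a differential-evolution
move toward the current best-compromise member (plus a few random
immigrants against premature convergence), and the final front is refined
by a parallel (1+1)-evolution-strategy polish in which every member
descends its own weighted scalarization of the two objectives — so each
member is refined toward its own position on the front, not a common
optimum.  All randomness flows from a single seeded generator, so runs are
bit-reproducible.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["nsga2", "nondominated_sort", "crowding_distance"]


def nondominated_sort(f: np.ndarray) -> np.ndarray:
    """Pareto rank (0 = non-dominated) of each row of objectives ``f``."""
    n = f.shape[0]
    # dominates[i, j]: i dominates j
    le = (f[:, None, :] <= f[None, :, :]).all(axis=2)
    lt = (f[:, None, :] < f[None, :, :]).any(axis=2)
    dominates = le & lt
    n_dom = dominates.sum(axis=0)  # how many dominate j
    rank = np.full(n, -1, dtype=int)
    current = np.where(n_dom == 0)[0]
    r = 0
    n_dom = n_dom.copy()
    while current.size:
        rank[current] = r
        n_dom[current] = -1
        released = dominates[current].sum(axis=0)
        n_dom = n_dom - released
        current = np.where(n_dom == 0)[0]
        r += 1
    return rank


def crowding_distance(f: np.ndarray) -> np.ndarray:
    """Crowding distance within one front (rows of ``f``)."""
    n, m = f.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(f[:, j], kind="stable")
        fj = f[order, j]
        span = fj[-1] - fj[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return dist


def _rank_and_crowd(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rank = nondominated_sort(f)
    crowd = np.zeros(len(f))
    for r in np.unique(rank):
        idx = np.where(rank == r)[0]
        crowd[idx] = crowding_distance(f[idx])
    return rank, crowd


def _sbx(parents: np.ndarray, lo, hi, rng, eta=15.0, p_cross=0.9) -> np.ndarray:
    """Simulated binary crossover on consecutive parent pairs."""
    child = parents.copy()
    n, d = parents.shape
    for i in range(0, n - 1, 2):
        if rng.random() > p_cross:
            continue
        u = rng.random(d)
        beta = np.where(
            u <= 0.5,
            (2.0 * u) ** (1.0 / (eta + 1.0)),
            (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)),
        )
        swap = rng.random(d) < 0.5
        beta = np.where(swap, 1.0 / np.maximum(beta, 1e-12), beta)
        p1, p2 = parents[i], parents[i + 1]
        child[i] = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
        child[i + 1] = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return np.clip(child, lo, hi)


def _poly_mutation(pop: np.ndarray, lo, hi, rng, eta=20.0, p_mut=None) -> np.ndarray:
    n, d = pop.shape
    if p_mut is None:
        p_mut = 1.0 / d
    span = hi - lo
    mask = rng.random((n, d)) < p_mut
    u = rng.random((n, d))
    delta = np.where(
        u < 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0,
        1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0)),
    )
    out = np.where(mask & (span > 0), pop + delta * span, pop)
    return np.clip(out, lo, hi)


def _polish(evaluate, x, f, lo, hi, rng, rounds=250, restarts=2):
    """Parallel (1+1)-ES refinement of a non-dominated set.

    Each member minimizes its own scalarization w·f1' + (1−w)·f2' (primes:
    objectives normalized by the front's span; w from the member's position
    on the front), with a per-member step size adapted by a 1/5-style
    success rule.  A sigma restart between stages helps escape flat valleys.
    """
    scale = np.maximum(f.max(axis=0), 1e-30)
    fn = f / scale
    w1 = fn[:, 1] + 1e-6
    w2 = fn[:, 0] + 1e-6
    tot = w1 + w2
    w1, w2 = w1 / tot, w2 / tot
    loss = w1 * fn[:, 0] + w2 * fn[:, 1]
    span = hi - lo
    for _ in range(restarts):
        sigma = np.full((len(x), 1), 0.05)
        for _ in range(rounds):
            prop = np.clip(x + sigma * span * rng.standard_normal(x.shape), lo, hi)
            fp = evaluate(prop) / scale
            lp = w1 * fp[:, 0] + w2 * fp[:, 1]
            acc = lp < loss
            x = np.where(acc[:, None], prop, x)
            f = np.where(acc[:, None], fp * scale, f)
            loss = np.where(acc, lp, loss)
            sigma = np.clip(sigma * np.where(acc[:, None], 1.3, 0.92), 1e-9, 0.2)
    return x, f


def nsga2(
    evaluate: Callable[[np.ndarray], np.ndarray],
    bounds: np.ndarray,
    population: int = 200,
    generations: int = 300,
    seed: int = 0,
    polish_rounds: int = 250,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize a vector objective; return the final non-dominated set.

    ``evaluate`` maps an (n, d) array of candidates to an (n, m) array of
    objective values (all minimized).  ``bounds`` is (d, 2).  Returns
    ``(x_front, f_front)``.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = len(lo)
    rng = np.random.default_rng(seed)
    pop = lo + (hi - lo) * rng.random((population, d))
    f = evaluate(pop)
    rank, crowd = _rank_and_crowd(f)
    n_imm = max(population // 20, 1)

    for _ in range(generations):
        # binary tournament on (rank, -crowding)
        cand = rng.integers(0, population, size=(2, population))
        a, b = cand
        better = (rank[a] < rank[b]) | ((rank[a] == rank[b]) & (crowd[a] > crowd[b]))
        parents = pop[np.where(better, a, b)]
        # brood: SBX+mutation half, DE-toward-best half, random immigrants
        half = (population - n_imm) // 2
        off1 = _sbx(parents[:half], lo, hi, rng)
        off1 = _poly_mutation(off1, lo, hi, rng)
        fn = f / np.maximum(f.max(axis=0), 1e-30)
        best = pop[np.argmin(fn.sum(axis=1))]
        base = parents[half:population - n_imm]
        r1 = pop[rng.integers(0, population, size=len(base))]
        r2 = pop[rng.integers(0, population, size=len(base))]
        f_de = 0.3 + 0.5 * rng.random((len(base), 1))
        mut = base + f_de * (best - base) + f_de * (r1 - r2)
        cross = rng.random(base.shape) < 0.9
        off2 = np.clip(np.where(cross, mut, base), lo, hi)
        imm = lo + (hi - lo) * rng.random((n_imm, d))
        off = np.vstack([off1, off2, imm])
        f_off = evaluate(off)

        pool = np.vstack([pop, off])
        f_pool = np.vstack([f, f_off])
        r_pool, c_pool = _rank_and_crowd(f_pool)
        order = np.lexsort((-c_pool, r_pool))[:population]
        pop, f = pool[order], f_pool[order]
        rank, crowd = _rank_and_crowd(f)

    keep = rank == 0
    x_fin, f_fin = _polish(
        evaluate, pop[keep], f[keep], lo, hi, rng, rounds=polish_rounds
    )
    rank_fin = nondominated_sort(f_fin)
    return x_fin[rank_fin == 0], f_fin[rank_fin == 0]
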