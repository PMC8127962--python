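"""Independent brute-force oracles used to check the package's fast paths.

These deliberately re-derive results by enumeration or simulation and must not
import the implementation routines they are checking.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def otsu_brute_force(values) -> float:
    """Exhaustive scan over candidate levels maximizing between-class variance
    with classes {x <= t} and {x > t}; lowest maximizing level wins ties."""
    x = np.asarray(values, dtype=float).ravel()
    levels = np.unique(x)
    assert levels.size >= 2
    n = x.size
    best_t, best_v = None, -np.inf
    for t in levels[:-1]:  # splitting at the top level leaves one class empty
        lo = x[x <= t]
        hi = x[x > t]
        w0, w1 = lo.size / n, hi.size / n
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-15:
            best_t, best_v = t, v
    return float(best_t)


def exhaustive_matching(
    a_pts: np.ndarray, b_pts: np.ndarray, cutoff: float
) -> set[tuple[int, int]]:
    """Optimal one-to-one matching: maximum cardinality, then minimum total
    distance, over all injective assignments under the cutoff."""
    na, nb = len(a_pts), len(b_pts)
    d = np.linalg.norm(a_pts[:, None, :] - b_pts[None, :, :], axis=2)
    best: set[tuple[int, int]] = set()
    best_card, best_cost = -1, np.inf
    if na <= nb:
        for perm in permutations(range(nb), na):
            pairs = [(i, j) for i, j in enumerate(perm) if d[i, j] <= cutoff]
            cost = sum(d[i, j] for i, j in pairs)
            if len(pairs) > best_card or (len(pairs) == best_card and cost < best_cost):
                best, best_card, best_cost = set(pairs), len(pairs), cost
    else:
        for perm in permutations(range(na), nb):
            pairs = [(i, j) for j, i in enumerate(perm) if d[i, j] <= cutoff]
            cost = sum(d[i, j] for i, j in pairs)
            if len(pairs) > best_card or (len(pairs) == best_card and cost < best_cost):
                best, best_card, best_cost = set(pairs), len(pairs), cost
    return best


def flood_fill_components(binary: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components of a boolean image by explicit flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    comps = []
    h, w = binary.shape
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            stack, comp = [(r0, c0)], set()
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < h
                            and 0 <= cc < w
                            and binary[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(comp)
    return comps


def mc_t_pvalue(t_obs: float, df: float, n_draws: int, seed: int) -> float:
    """Two-sided tail of the Student-t null by Monte-Carlo draws."""
    rng = np.random.default_rng(seed)
    count = 0
    left = n_draws
    while left > 0:
        chunk = min(left, 2_000_000)
        count += int((np.abs(rng.standard_t(df, size=chunk)) >= abs(t_obs)).sum())
        left -= chunk
    return count / n_draws


def mc_studentized_range_sf(q_obs: np.ndarray, k: int, df: int, n_draws: int, seed: int):
    """Upper tail of the studentized range of k means over a chi-based scale."""
    rng = np.random.default_rng(seed)
    q_obs = np.atleast_1d(np.asarray(q_obs, dtype=float))
    counts = np.zeros(q_obs.size, dtype=np.int64)
    left = n_draws
    while left > 0:
        chunk = min(left, 500_000)
        z = rng.standard_normal((chunk, k))
        s = np.sqrt(rng.chisquare(df, size=chunk) / df)
        q = (z.max(axis=1) - z.min(axis=1)) / s
        for i, qo in enumerate(q_obs):
            counts[i] += int((q >= qo).sum())
        left -= chunk
    return counts / n_draws
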