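"""Independent oracle implementations used only by the test suite.

Each oracle recomputes a quantity by a deliberately different route from the
library (exhaustive enumeration, brute-force double sums, grid search,
integer-partition combinatorics) so that agreement is informative.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

UNAMBIGUOUS = set("ACGT")


# --- brute-force distance oracles -----------------------------------------


def brute_raw_differences(a: str, b: str) -> int:
    assert len(a) == len(b)
    count = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS and x != y:
            count += 1
    return count


def brute_nei_D(pop_a: list[str], pop_b: list[str]) -> float:
    total = 0
    for sa in pop_a:
        for sb in pop_b:
            total += brute_raw_differences(sa, sb)
    return total / (len(pop_a) * len(pop_b))


def brute_pi_within(pop: list[str]) -> float:
    n = len(pop)
    if n < 2:
        return 0.0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += brute_raw_differences(pop[i], pop[j])
    return total / (n * (n - 1) / 2)


def brute_fst(pop_a: list[str], pop_b: list[str]) -> float | None:
    pi_b = brute_nei_D(pop_a, pop_b)
    if pi_b == 0:
        return None
    pi_w = (brute_pi_within(pop_a) + brute_pi_within(pop_b)) / 2
    return min(1.0, max(0.0, (pi_b - pi_w) / pi_b))


# --- exhaustive Mantel oracle ----------------------------------------------


def _triangle_r(gen: np.ndarray, geo: np.ndarray) -> float:
    n = gen.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.corrcoef(gen[iu], geo[iu])[0, 1])


def mantel_exhaustive(gen: np.ndarray, geo: np.ndarray) -> tuple[float, float]:
    """Observed r and the exact fraction of joint permutations with
    r_perm >= r_obs (identity included), enumerating all n! permutations."""
    n = gen.shape[0]
    r_obs = _triangle_r(gen, geo)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = _triangle_r(gen[np.ix_(p, p)], geo)
        if r >= r_obs - 1e-12:
            count += 1
        total += 1
    return r_obs, count / total


# --- statistical-parsimony connection-limit oracle --------------------------


def _partitions(n: int, max_part: int | None = None):
    """Integer partitions of n as non-increasing lists."""
    if max_part is None:
        max_part = n
    if n == 0:
        yield []
        return
    for first in range(min(n, max_part), 0, -1):
        for rest in _partitions(n - first, first):
            yield [first] + rest


def _visible_fraction(k: int) -> Fraction:
    return Fraction(3, 4) * (1 - Fraction(-1, 3) ** k)


def oracle_p_j_given_u(j: int, u: int, L: int) -> float:
    """P(exactly j visibly different sites | u Jukes-Cantor mutations on L
    sites), by enumeration over integer partitions of u (hit multiplicities).
    """
    if u < j:
        return 0.0
    total = 0.0
    for lam in _partitions(u):
        s = len(lam)
        if s < j or s > L:
            continue
        # number of ways: choose which sites get which hit counts, and which
        # labeled mutations land where
        mult: dict[int, int] = {}
        for part in lam:
            mult[part] = mult.get(part, 0) + 1
        ways = math.comb(L, s) * math.factorial(s)
        for m in mult.values():
            ways //= math.factorial(m)
        assign = math.factorial(u)
        for part in lam:
            assign //= math.factorial(part)
        # probability of exactly j of the s hit sites being visible
        poly = [Fraction(1)]
        for part in lam:
            v = _visible_fraction(part)
            new = [Fraction(0)] * (len(poly) + 1)
            for d, c in enumerate(poly):
                new[d] += c * (1 - v)
                new[d + 1] += c * v
            poly = new
        if j < len(poly):
            total += float(Fraction(ways * assign, L**u) * poly[j])
    return total


def oracle_parsimony_probability(j: int, L: int, max_extra: int = 6) -> float:
    if j == 0:
        return 1.0
    if 3 * L <= 4 * j:
        return 0.0
    theta = -0.75 * L * math.log1p(-4.0 * j / (3.0 * L))
    weights = []
    for u in range(j, j + max_extra + 1):
        prior = theta**u / math.factorial(u)
        weights.append(prior * oracle_p_j_given_u(j, u, L))
    return weights[0] / sum(weights)


def oracle_connection_limit(L: int, confidence: float) -> int:
    limit = 0
    for j in range(1, L + 1):
        if oracle_parsimony_probability(j, L) >= confidence:
            limit = j
        else:
            break
    return limit


# --- network component oracle -----------------------------------------------


def oracle_network_components(seqs: dict[str, str], limit: int) -> list[frozenset]:
    """Transitive closure of 'raw distance <= limit' over observed haplotypes."""
    ids = sorted(seqs)
    parent = {h: h for h in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(ids, 2):
        if brute_raw_differences(seqs[a], seqs[b]) <= limit:
            parent[find(a)] = find(b)
    groups: dict[str, set] = {}
    for h in ids:
        groups.setdefault(find(h), set()).add(h)
    return sorted((frozenset(g) for g in groups.values()), key=sorted)


# --- Firth grid-search oracle -------------------------------------------------


def firth_penalized_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_grid_fit(
    y: np.ndarray,
    X: np.ndarray,
    lo: float = -6.0,
    hi: float = 6.0,
    points: int = 41,
    refinements: int = 9,
) -> np.ndarray:
    """Maximize the Firth-penalized log-likelihood of a two-column design by
    dense grid search with iterative refinement (final grid ~1e-6 wide)."""
    assert X.shape[1] == 2
    b0_lo, b0_hi = lo, hi
    b1_lo, b1_hi = lo, hi
    best = np.zeros(2)
    for _ in range(refinements):
        b0s = np.linspace(b0_lo, b0_hi, points)
        b1s = np.linspace(b1_lo, b1_hi, points)
        vals = np.empty((points, points))
        for i, b0 in enumerate(b0s):
            for k, b1 in enumerate(b1s):
                vals[i, k] = firth_penalized_loglik(y, X, np.array([b0, b1]))
        i, k = np.unravel_index(np.argmax(vals), vals.shape)
        best = np.array([b0s[i], b1s[k]])
        span0 = (b0_hi - b0_lo) / (points - 1)
        span1 = (b1_hi - b1_lo) / (points - 1)
        b0_lo, b0_hi = best[0] - 2 * span0, best[0] + 2 * span0
        b1_lo, b1_hi = best[1] - 2 * span1, best[1] + 2 * span1
    return best
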