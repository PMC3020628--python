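"""Statistical-parsimony haplotype networks.

Two haplotypes that differ at j of L aligned sites are connected in the
network only when j is within the *connection limit*: the largest number of
steps for which the estimated probability that the observed differences
represent the true number of mutational steps (no superimposed, invisible
changes) still reaches the requested confidence (conventionally 95%, or 90%
for more permissive joins).

Probability model
-----------------
Mutations are placed uniformly over the L sites with symmetric (Jukes-Cantor)
base changes.  A site hit k times differs from its original base with
probability v(k) = (3/4)(1 - (-1/3)^k); in particular v(1) = 1 and
v(2) = 2/3 (one chance in three that a second hit reverts the first).
Given the true number of mutations u, the probability that exactly j sites
are visibly different, P(j | u), follows from coincident-hit counting.  The
number of mutations u >= j gets a Poisson prior whose mean is the
Jukes-Cantor-corrected expected number of substitutions for the observed
divergence j/L.  The probability of parsimony is the posterior

    P(u = j | j observed differences)
        = w_j / sum_{u >= j} w_u,   w_u = Poisson(u; theta) * P(j | u),

with the sum truncated at u = j + 6 (each additional superimposed mutation
costs roughly a factor j^2/(3L) < 1/3 anywhere near the limit, so the
truncated tail is negligible).  The connection limit at confidence c is the
largest j with P(u = j | j) >= c.

Network assembly is a greedy agglomeration over haplotype pairs in order of
increasing raw distance: a pair at distance d within the limit joining two
different components is connected through d - 1 hypothetical intermediate
nodes; pairs whose components are already joined are recorded as ambiguous
alternative connections when the direct path would tie the existing graph
distance.  Component membership — the only network property the downstream
analysis uses — depends only on pairwise distances versus the limit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import networkx as nx

from .distances import raw_differences
from .exceptions import ParameterError
from .seqio import HaplotypeTable


def _visible_prob(k: int) -> float:
    """P(site differs from its original base after k Jukes-Cantor hits)."""
    return 0.75 * (1.0 - (-1.0 / 3.0) ** k)


def _poly_mul(a: list[float], b: list[float], max_deg: int) -> list[float]:
    out = [0.0] * (min(len(a) + len(b) - 2, max_deg) + 1)
    for i, ai in enumerate(a):
        if ai == 0.0:
            continue
        for j, bj in enumerate(b):
            if i + j > max_deg:
                break
            out[i + j] += ai * bj
    return out


def _poly_pow(base: list[float], exp: int, max_deg: int) -> list[float]:
    result = [1.0]
    acc = base
    while exp:
        if exp & 1:
            result = _poly_mul(result, acc, max_deg)
        exp >>= 1
        if exp:
            acc = _poly_mul(acc, acc, max_deg)
    return result


def prob_j_visible_given_u(j: int, u: int, seq_length: int) -> float:
    """P(exactly j visibly different sites | u mutations on seq_length sites).

    Computed exactly via exponential generating functions: a visible hit
    site contributes sum_k v(k) x^k / k!, an invisible hit site (>= 2 hits
    that cancel) contributes sum_k (1 - v(k)) x^k / k!.
    """
    if u < j or j < 0:
        return 0.0
    L = seq_length
    fact = [math.factorial(k) for k in range(u + 1)]
    A = [0.0] + [_visible_prob(k) / fact[k] for k in range(1, u + 1)]
    B = [0.0, 0.0] + [(1.0 - _visible_prob(k)) / fact[k] for k in range(2, u + 1)]

    total = 0.0
    a_pow = _poly_pow(A, j, u)
    poly = a_pow
    max_invisible = (u - j) // 2  # an invisible site needs >= 2 hits
    for i in range(max_invisible + 1):
        if i > 0:
            poly = _poly_mul(poly, B, u)
        coef = poly[u] if u < len(poly) else 0.0
        if coef == 0.0:
            continue
        # exact integer combinatorics kept as a rational to avoid overflow
        num = math.comb(L, j) * math.comb(L - j, i) * fact[u]
        total += coef * _big_ratio(num, L**u)
    return total


def _big_ratio(num: int, den: int) -> float:
    """num / den for arbitrarily large ints, returned as float."""
    if num == 0:
        return 0.0
    shift = max(num.bit_length(), den.bit_length()) - 900
    if shift > 0:
        num >>= shift
        den >>= shift
    return num / den


_MAX_EXTRA = 6  # truncation of the posterior sum over superimposed mutations


def parsimony_probability(n_differences: int, seq_length: int) -> float:
    """Posterior probability that j observed differences equal the true steps."""
    j, L = n_differences, seq_length
    if j == 0:
        return 1.0
    if 3 * L <= 4 * j:
        return 0.0  # beyond Jukes-Cantor saturation
    theta = -0.75 * L * math.log1p(-4.0 * j / (3.0 * L))
    # weights relative to u = j for numerical stability:
    # w_u / w_j = theta^(u-j) * j! / u! * P(j|u) / P(j|j)
    p_jj = prob_j_visible_given_u(j, j, L)
    if p_jj == 0.0:
        return 0.0
    total = 1.0
    scale = 1.0
    for extra in range(1, _MAX_EXTRA + 1):
        u = j + extra
        scale *= theta / u
        total += scale * prob_j_visible_given_u(j, u, L) / p_jj
    return 1.0 / total


@lru_cache(maxsize=None)
def connection_limit(seq_length: int, confidence: float) -> int:
    """Largest number of steps connectable at the stated confidence."""
    if seq_length < 1:
        raise ParameterError("seq_length must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ParameterError("confidence must be in (0, 1)")
    limit = 0
    for j in range(1, seq_length + 1):
        if parsimony_probability(j, seq_length) >= confidence:
            limit = j
        else:
            break
    return limit


@dataclass
class ParsimonyNetwork:
    """Observed + hypothetical haplotype nodes with single-step edges."""

    graph: nx.Graph
    observed: list[str]
    connection_limit: int
    confidence: float | None = None
    ambiguous_links: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def hypothetical(self) -> list[str]:
        return [n for n in self.graph.nodes if not self.graph.nodes[n]["observed"]]

    def components(self) -> list[set[str]]:
        """Connected components restricted to observed haplotypes."""
        comps = []
        for comp in nx.connected_components(self.graph):
            obs = {n for n in comp if self.graph.nodes[n]["observed"]}
            if obs:
                comps.append(obs)
        return comps

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def write_edges_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("a\tb\n")
            for a, b in sorted(self.graph.edges):
                fh.write(f"{a}\t{b}\n")

    def write_nodes_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tobserved\tfrequency\n")
            for n in self.graph.nodes:
                d = self.graph.nodes[n]
                fh.write(f"{n}\t{int(d['observed'])}\t{d['frequency']}\n")

    def write_components_json(self, path: str | Path) -> None:
        comps = [sorted(c) for c in self.components()]
        with open(path, "w") as fh:
            json.dump(
                {
                    "connection_limit": self.connection_limit,
                    "confidence": self.confidence,
                    "components": comps,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def build_network(
    ht: HaplotypeTable, limit: int, confidence: float | None = None
) -> ParsimonyNetwork:
    """Greedy statistical-parsimony network over a haplotype table.

    Pairs are considered in order of increasing raw distance (ties: higher
    combined frequency first, then lexicographic IDs).  Hypothetical
    intermediates are named x1, x2, ... in creation order; their sequences
    are not imputed.
    """
    if limit < 1:
        raise ParameterError("connection limit must be >= 1")
    ids = list(ht.haplotype_ids)
    if not ids:
        raise ParameterError("need at least one haplotype")
    freq = {h: int(ht.total_counts()[h]) for h in ids}

    g = nx.Graph()
    for h in ids:
        g.add_node(h, observed=True, frequency=freq[h])

    pairs = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = raw_differences(ht.haplotype_seqs[a], ht.haplotype_seqs[b])
            pairs.append((d, -(freq[a] + freq[b]), a, b))
    pairs.sort()

    ambiguous: list[tuple[str, str, int]] = []
    next_hyp = 1
    for d, _, a, b in pairs:
        if d > limit:
            continue
        if nx.has_path(g, a, b):
            if nx.shortest_path_length(g, a, b) == d:
                ambiguous.append((a, b, d))
            continue
        prev = a
        for _step in range(d - 1):
            hyp = f"x{next_hyp}"
            next_hyp += 1
            g.add_node(hyp, observed=False, frequency=0)
            g.add_edge(prev, hyp)
            prev = hyp
        g.add_edge(prev, b)

    return ParsimonyNetwork(g, ids, limit, confidence, ambiguous)


def subnetworks(net: ParsimonyNetwork, ht: HaplotypeTable) -> list[list[str]]:
    """Observed-haplotype components, ordered by total frequency descending."""
    totals = ht.total_counts()
    comps = net.components()

    def comp_key(comp: set[str]):
        return (-sum(int(totals[h]) for h in comp), sorted(comp))

    ordered = sorted(comps, key=comp_key)
    return [
        sorted(c, key=lambda h: (-int(totals[h]), h)) for c in ordered
    ]
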