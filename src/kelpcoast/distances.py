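"""Raw pairwise differences, p-distances, Nei's average pairwise D and FST.

The central between-population statistic is Nei's *raw* average pairwise
difference D: the mean count of differing sites over all between-population
sample pairs, uncorrected and not divided by alignment length.  Keeping D on
the raw count scale is what makes the "D >= 1.0" genetic-disjunction
threshold meaningful (one whole fixed difference between average samples).

Sites where either sequence carries a gap or an ambiguity code are excluded
from all comparisons.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    EmptyInputError,
    LabelError,
    OrderingError,
    UndefinedDistanceError,
)
from .seqio import UNAMBIGUOUS, HaplotypeTable


def _check_equal_length(seq_a: str, seq_b: str) -> None:
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"sequences of unequal length: {len(seq_a)} vs {len(seq_b)}"
        )


def raw_differences(seq_a: str, seq_b: str) -> int:
    """Count sites where both sequences are unambiguous and differ."""
    _check_equal_length(seq_a, seq_b)
    a, b = seq_a.upper(), seq_b.upper()
    return sum(
        1
        for x, y in zip(a, b)
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS and x != y
    )


def comparable_sites(seq_a: str, seq_b: str) -> int:
    """Count sites where both sequences carry an unambiguous base."""
    _check_equal_length(seq_a, seq_b)
    a, b = seq_a.upper(), seq_b.upper()
    return sum(1 for x, y in zip(a, b) if x in UNAMBIGUOUS and y in UNAMBIGUOUS)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected distance: differing sites / comparable sites."""
    n_comp = comparable_sites(seq_a, seq_b)
    if n_comp == 0:
        raise UndefinedDistanceError("no comparable sites between sequences")
    return raw_differences(seq_a, seq_b) / n_comp


def as_percent(fraction: float, decimals: int = 1) -> float:
    """Format a fraction as a percentage, rounding half-up (report style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


def nei_average_pairwise_D(pop_a: list[str], pop_b: list[str]) -> float:
    """Nei's raw average pairwise difference over all between-population pairs.

    D = (1 / (n_a * n_b)) * sum over all cross pairs of raw_differences.
    Computed over sample pairs; collapsing each population to haplotype
    frequencies first gives the identical frequency-weighted value.
    """
    if not pop_a or not pop_b:
        raise EmptyInputError("both populations must be non-empty")
    ca, cb = Counter(pop_a), Counter(pop_b)
    total = 0.0
    for ha, na in ca.items():
        for hb, nb in cb.items():
            if ha != hb:
                total += na * nb * raw_differences(ha, hb)
    return total / (len(pop_a) * len(pop_b))


def pi_within(pop: list[str]) -> float:
    """Mean raw differences over distinct unordered sample pairs (i < j).

    A single-sample population has pi = 0 by convention.
    """
    if not pop:
        raise EmptyInputError("population must be non-empty")
    n = len(pop)
    if n < 2:
        return 0.0
    c = Counter(pop)
    haps = list(c)
    total = 0.0
    for i, ha in enumerate(haps):
        for hb in haps[i + 1 :]:
            total += c[ha] * c[hb] * raw_differences(ha, hb)
    return total / (n * (n - 1) / 2)


@dataclass
class PopPairStats:
    """Diversity decomposition for one pair of populations.

    ``fst`` is the simple pi-based estimator
    (pi_between - mean(pi_within)) / pi_between, clamped to [0, 1];
    it is None (undefined) when pi_between = 0, including the degenerate
    case of two populations fixed for the same haplotype.  Two populations
    each fixed for different haplotypes give fst = 1.
    """

    locality_a: str
    locality_b: str
    pi_between: float
    pi_within_a: float
    pi_within_b: float
    fst: Optional[float]


def pop_pair_stats(
    pop_a: list[str], pop_b: list[str], label_a: str = "a", label_b: str = "b"
) -> PopPairStats:
    pi_b = nei_average_pairwise_D(pop_a, pop_b)
    wa = pi_within(pop_a)
    wb = pi_within(pop_b)
    if pi_b == 0:
        fst: Optional[float] = None
    else:
        fst = min(1.0, max(0.0, (pi_b - (wa + wb) / 2) / pi_b))
    return PopPairStats(label_a, label_b, pi_b, wa, wb, fst)


def pairwise_fst(pop_a: list[str], pop_b: list[str]) -> Optional[float]:
    """Pi-based pairwise FST; None when pi_between = 0 (undefined)."""
    return pop_pair_stats(pop_a, pop_b).fst


@dataclass
class DistanceMatrix:
    """Symmetric labeled distance matrix (genetic D, p-distance or coastal km)."""

    labels: list[str]
    values: np.ndarray
    kind: str  # genetic_D | genetic_p | coastal_km

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise LabelError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise LabelError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise LabelError("matrix diagonal is not zero")
        if (self.values < 0).any():
            raise LabelError("matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise LabelError(f"labels not in matrix: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def loc(self, a: str, b: str) -> float:
        try:
            return float(self.values[self.labels.index(a), self.labels.index(b)])
        except ValueError as exc:
            raise LabelError(str(exc)) from exc

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", lineterminator="\n")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for label, row in zip(self.labels, self.values):
                name = label[:10].ljust(10)
                fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "genetic_D") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float), kind)


def haplotype_distance_matrix(ht: HaplotypeTable) -> np.ndarray:
    """Raw pairwise differences between haplotype sequences (k x k)."""
    seqs = ht.sequences_in_order()
    k = len(seqs)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = raw_differences(seqs[i], seqs[j])
    return d


def population_distance_matrix(
    ht: HaplotypeTable, kind: str = "genetic_D"
) -> DistanceMatrix:
    """Nei's raw average pairwise D between every pair of localities.

    Localities with zero samples are excluded with a warning.
    """
    if kind != "genetic_D":
        raise ValueError(f"unsupported kind: {kind}")
    counts = ht.counts
    sizes = counts.sum(axis=1)
    empty = list(sizes.index[sizes == 0])
    if empty:
        warnings.warn(f"excluding zero-sample localities: {empty}", stacklevel=2)
        counts = counts.drop(index=empty)
        sizes = sizes.drop(index=empty)
    if len(counts) < 2:
        raise EmptyInputError("need >= 2 localities with samples")
    dh = haplotype_distance_matrix(ht)
    c = counts.to_numpy(dtype=float)
    n = sizes.to_numpy(dtype=float)
    between = c @ dh @ c.T / np.outer(n, n)
    np.fill_diagonal(between, 0.0)
    between = (between + between.T) / 2  # exact symmetry against float noise
    return DistanceMatrix(list(counts.index), between, kind)


def coastal_distance_matrix(locality_table: pd.DataFrame) -> DistanceMatrix:
    """|position_i - position_j| along the coast, labels in coastal order."""
    df = locality_table.sort_values("order_index")
    pos = df["coastal_position_km"].to_numpy(dtype=float)
    if (np.diff(pos) < 0).any():
        raise OrderingError(
            "coastal_position_km must be monotone non-decreasing in coastal order"
        )
    values = np.abs(pos[:, None] - pos[None, :])
    return DistanceMatrix(list(df["locality"]), values, "coastal_km")
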