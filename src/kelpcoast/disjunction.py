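"""Genetic-disjunction classification and beach-length logistic regression.

Adjacent locality pairs along the coast are classified as genetically
disjunct when Nei's raw average pairwise difference D between them reaches a
threshold (default 1.0, i.e. on average a full fixed difference per sample
pair).  Haplotype sharing is computed independently from the count matrix as
a cross-check: a pair that is disjunct yet shares haplotypes is flagged, not
silently accepted.  Disjunction is then modelled by Firth-penalized logistic
regression on the maximum uninterrupted beach length between the pair and
the total coastal distance between the pair, optionally refit after
excluding outlier pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .distances import DistanceMatrix, pop_pair_stats
from .exceptions import CoverageError, LabelError, ParameterError
from .firth import FirthLogit, FirthLogitResults
from .seqio import HaplotypeTable


@dataclass
class PairRecord:
    """One adjacent locality pair with its genetic and geographic covariates."""

    locality_a: str
    locality_b: str
    coastal_km: float
    max_beach_km: float = math.nan
    nei_D: Optional[float] = None
    pi_within_a: Optional[float] = None
    pi_within_b: Optional[float] = None
    fst: Optional[float] = None
    shares_haplotypes: Optional[bool] = None
    disjunct: Optional[bool] = None

    @property
    def pair_id(self) -> str:
        return f"{self.locality_a}--{self.locality_b}"


def adjacent_pairs(
    locality_table: pd.DataFrame,
    beach_table: pd.DataFrame | None = None,
    region_filter: Optional[Sequence[str]] = None,
) -> list[PairRecord]:
    """Consecutive locality pairs in coastal order, with beach lengths joined.

    ``region_filter`` restricts to the named localities before pairing, so
    excluding an interior locality re-pairs its neighbours.  When a beach
    table is supplied it must cover every adjacent pair (CoverageError
    otherwise); without one, beach lengths are left NaN and only pair
    geometry is available.
    """
    df = locality_table.sort_values("order_index").reset_index(drop=True)
    if region_filter is not None:
        region = set(region_filter)
        df = df[df["locality"].isin(region)].reset_index(drop=True)

    beach: dict[frozenset, float] = {}
    if beach_table is not None:
        for _, row in beach_table.iterrows():
            beach[frozenset((row["locality_a"], row["locality_b"]))] = float(
                row["max_beach_km"]
            )

    pairs: list[PairRecord] = []
    for i in range(len(df) - 1):
        a, b = df.loc[i, "locality"], df.loc[i + 1, "locality"]
        coastal = float(
            df.loc[i + 1, "coastal_position_km"] - df.loc[i, "coastal_position_km"]
        )
        record = PairRecord(a, b, coastal_km=coastal)
        if beach_table is not None:
            key = frozenset((a, b))
            if key not in beach:
                raise CoverageError(f"no beach entry for adjacent pair {a}/{b}")
            record.max_beach_km = beach[key]
            if record.max_beach_km > record.coastal_km + 1e-9:
                raise CoverageError(
                    f"beach length exceeds coastal distance for pair {a}/{b}"
                )
        pairs.append(record)
    return pairs


@dataclass
class ClassificationResult:
    """Classified pairs plus the disjunct-yet-sharing consistency report."""

    pairs: list[PairRecord]
    threshold: float
    inconsistent_pairs: list[str] = field(default_factory=list)


def classify_disjunct(
    pairs: Iterable[PairRecord],
    D_matrix: DistanceMatrix,
    ht: HaplotypeTable,
    threshold: float = 1.0,
) -> ClassificationResult:
    """Fill genetic fields and classify each pair (disjunct iff D >= threshold).

    Haplotype sharing is computed independently of D; any pair that is both
    disjunct and shares haplotypes lands in the inconsistency report.
    """
    pairs = list(pairs)
    inconsistent = []
    for rec in pairs:
        for loc in (rec.locality_a, rec.locality_b):
            if loc not in D_matrix.labels:
                raise LabelError(f"locality {loc!r} absent from distance matrix")
        rec.nei_D = D_matrix.loc(rec.locality_a, rec.locality_b)
        stats = pop_pair_stats(
            ht.sequences_for_locality(rec.locality_a),
            ht.sequences_for_locality(rec.locality_b),
            rec.locality_a,
            rec.locality_b,
        )
        rec.pi_within_a = stats.pi_within_a
        rec.pi_within_b = stats.pi_within_b
        rec.fst = stats.fst
        rec.shares_haplotypes = ht.shares_haplotypes(rec.locality_a, rec.locality_b)
        rec.disjunct = rec.nei_D >= threshold
        if rec.disjunct and rec.shares_haplotypes:
            inconsistent.append(rec.pair_id)
    return ClassificationResult(pairs, threshold, inconsistent)


def exclude_pairs(
    pairs: Iterable[PairRecord], exclude: Sequence[str]
) -> list[PairRecord]:
    """Drop pairs whose pair_id appears in ``exclude``."""
    excluded = set(exclude)
    kept = [p for p in pairs if p.pair_id not in excluded]
    unknown = excluded - {p.pair_id for p in pairs}
    if unknown:
        raise LabelError(f"unknown pair ids in exclusion list: {sorted(unknown)}")
    return kept


def pairs_to_dataframe(pairs: Iterable[PairRecord]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "pair_id": p.pair_id,
                "locality_a": p.locality_a,
                "locality_b": p.locality_b,
                "nei_D": p.nei_D,
                "max_beach_km": p.max_beach_km,
                "coastal_km": p.coastal_km,
                "pi_within_a": p.pi_within_a,
                "pi_within_b": p.pi_within_b,
                "fst": p.fst,
                "shares_haplotypes": p.shares_haplotypes,
                "disjunct": p.disjunct,
            }
        )
    return pd.DataFrame(rows)


def read_pair_table(path) -> list[PairRecord]:
    """Read a pair table written by :func:`pairs_to_dataframe`/`to_csv`."""
    df = pd.read_csv(path, sep="\t")
    required = {"locality_a", "locality_b", "nei_D", "max_beach_km", "coastal_km"}
    missing = required - set(df.columns)
    if missing:
        raise CoverageError(f"pair table missing columns: {sorted(missing)}")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PairRecord(
                locality_a=str(row["locality_a"]),
                locality_b=str(row["locality_b"]),
                coastal_km=float(row["coastal_km"]),
                max_beach_km=float(row["max_beach_km"]),
                nei_D=float(row["nei_D"]),
                disjunct=bool(row["disjunct"]) if "disjunct" in df.columns else None,
            )
        )
    return pairs


@dataclass
class DisjunctionResult:
    """Pair table plus full and (optional) outlier-excluded Firth fits."""

    table: pd.DataFrame
    fit_full: FirthLogitResults
    fit_excluded: Optional[FirthLogitResults]
    excluded_pair_ids: list[str]
    degenerate_response: bool

    def to_dict(self) -> dict:
        out = {
            "n_pairs": int(len(self.table)),
            "excluded_pair_ids": list(self.excluded_pair_ids),
            "degenerate_response": self.degenerate_response,
            "fit_full": self.fit_full.to_dict(),
        }
        if self.fit_excluded is not None:
            out["fit_excluded"] = self.fit_excluded.to_dict()
        return out


def _fit(pairs: list[PairRecord], threshold: float | None = None) -> FirthLogitResults:
    df = pairs_to_dataframe(pairs)
    if df["disjunct"].isna().any():
        if threshold is None:
            raise ParameterError("pairs must be classified before regression")
        df["disjunct"] = df["nei_D"] >= threshold
    df = df.assign(disjunct=df["disjunct"].astype(int))
    model = FirthLogit.from_dataframe(
        df, "disjunct", ["max_beach_km", "coastal_km"], add_intercept=True
    )
    return model.fit()


def disjunction_analysis(
    pairs: Iterable[PairRecord],
    exclude: Sequence[str] = (),
    threshold: float | None = None,
) -> DisjunctionResult:
    """Fit 'disjunct ~ max beach length + coastal distance' by Firth logistic.

    When ``exclude`` is non-empty, both the full fit and the fit on the
    remaining pairs are returned (the outlier-exclusion refit).  A response
    that is constant (all disjunct or none) is flagged as degenerate; the
    Firth fit still returns finite estimates.
    """
    pairs = list(pairs)
    kept = exclude_pairs(pairs, exclude) if exclude else pairs
    if len(kept) < 4:
        raise ParameterError("need at least 4 pairs after exclusion")
    for rec in pairs:
        if math.isnan(rec.max_beach_km):
            raise CoverageError(f"pair {rec.pair_id} has no beach length")

    fit_full = _fit(pairs, threshold)
    fit_excluded = _fit(kept, threshold) if exclude else None
    table = pairs_to_dataframe(pairs)
    responses = set(table["disjunct"].dropna().astype(bool))
    return DisjunctionResult(
        table=table,
        fit_full=fit_full,
        fit_excluded=fit_excluded,
        excluded_pair_ids=list(exclude),
        degenerate_response=len(responses) < 2,
    )
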