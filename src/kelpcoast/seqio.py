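"""Aligned sequence input, haplotype collapsing and variable-site summaries.

The analyses in this package start from a pre-computed multiple sequence
alignment of a single organellar marker (e.g. a 629 bp mitochondrial COI
fragment or an 886 bp chloroplast rbcL fragment), a sample table assigning
each sequence to a sampling locality, and two small geographic tables
(ordered localities with cumulative coastal positions; maximum uninterrupted
beach length between adjacent localities).

Samples with byte-identical sequences (after uppercasing) collapse into a
haplotype; all downstream statistics operate on the resulting
locality x haplotype count matrix.  Alignment columns containing a gap or any
non-ACGT ambiguity code in any haplotype are excluded from variable-site and
distance computations: that is the conservative convention for clean Sanger
haplotype data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .exceptions import (
    AlignmentError,
    EmptyInputError,
    FormatError,
    MappingError,
)

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")

TRANSITION_PAIRS = ({"A", "G"}, {"C", "T"})


@dataclass
class LabeledAlignment:
    """An equal-length DNA alignment with a locality label per sample.

    One gene per instance.  Validated on construction: unique sample IDs,
    identical sequence lengths, IUPAC characters only, and a locality
    assignment for every sample.
    """

    gene_name: str
    sample_ids: list[str]
    sequences: list[str]
    locality_of: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise EmptyInputError("alignment contains no sequences")
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise FormatError("duplicate sample IDs in alignment")
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in length")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        if self.length == 0:
            raise AlignmentError("zero-length alignment")
        for sid, seq in zip(self.sample_ids, self.sequences):
            bad = set(seq) - IUPAC_CODES
            if bad:
                raise FormatError(
                    f"sequence {sid!r} contains non-IUPAC characters {sorted(bad)}"
                )
        missing = [s for s in self.sample_ids if s not in self.locality_of]
        if missing:
            raise MappingError(
                f"samples missing from sample table: {missing}"
            )

    @property
    def length(self) -> int:
        """Alignment length in bp."""
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        """Number of samples."""
        return len(self.sample_ids)

    def sequences_for_locality(self, locality: str) -> list[str]:
        return [
            seq
            for sid, seq in zip(self.sample_ids, self.sequences)
            if self.locality_of[sid] == locality
        ]


@dataclass
class HaplotypeTable:
    """Distinct sequences plus a locality x haplotype count matrix.

    Haplotype IDs are assigned deterministically: descending total count,
    ties broken by first occurrence in the input.  ``rename`` attaches
    user-supplied names (e.g. the C-I...C-XIV style used in field studies)
    without touching the counts.
    """

    haplotype_ids: list[str]
    haplotype_seqs: dict[str, str]
    counts: pd.DataFrame  # index = localities, columns = haplotype_ids

    def __post_init__(self) -> None:
        seqs = [self.haplotype_seqs[h] for h in self.haplotype_ids]
        if len(set(seqs)) != len(seqs):
            raise FormatError("haplotype sequences are not pairwise distinct")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative haplotype counts")
        if (self.counts.sum(axis=0) < 1).any():
            raise FormatError("haplotype with total count 0")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def n_samples(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def localities(self) -> list[str]:
        return list(self.counts.index)

    @property
    def length(self) -> int:
        return len(self.haplotype_seqs[self.haplotype_ids[0]])

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def sequences_in_order(self) -> list[str]:
        return [self.haplotype_seqs[h] for h in self.haplotype_ids]

    def sequences_for_locality(self, locality: str) -> list[str]:
        """Expand the count row for one locality back to a sequence multiset."""
        row = self.counts.loc[locality]
        out: list[str] = []
        for hap, c in row.items():
            out.extend([self.haplotype_seqs[hap]] * int(c))
        return out

    def shares_haplotypes(self, locality_a: str, locality_b: str) -> bool:
        a = self.counts.loc[locality_a] > 0
        b = self.counts.loc[locality_b] > 0
        return bool((a & b).any())

    def rename(self, mapping: dict[str, str]) -> "HaplotypeTable":
        """Return a copy with haplotype IDs renamed via ``mapping``."""
        ids = [mapping.get(h, h) for h in self.haplotype_ids]
        seqs = {mapping.get(h, h): s for h, s in self.haplotype_seqs.items()}
        counts = self.counts.rename(columns=mapping)
        return HaplotypeTable(ids, seqs, counts)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "haplotype_id": self.haplotype_ids,
                "sequence": [self.haplotype_seqs[h] for h in self.haplotype_ids],
            }
        )
        for loc in self.counts.index:
            df[loc] = [int(self.counts.loc[loc, h]) for h in self.haplotype_ids]
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"haplotype_id": str})
        required = {"haplotype_id", "sequence"}
        if not required.issubset(df.columns):
            raise FormatError(f"haplotype table must have columns {sorted(required)}")
        ids = list(df["haplotype_id"])
        seqs = dict(zip(ids, (s.upper() for s in df["sequence"])))
        loc_cols = [c for c in df.columns if c not in required]
        counts = pd.DataFrame(
            df[loc_cols].to_numpy().T, index=loc_cols, columns=ids, dtype=int
        )
        return cls(ids, seqs, counts)


@dataclass
class SiteSummary:
    """Variable alignment positions with codon position and change class.

    Positions are 1-based on the trimmed fragment.  A site is a transition
    if its two observed bases are A/G or C/T, a transversion for any other
    two-base pair, and ``complex`` when more than two unambiguous bases occur.
    """

    variable_positions: list[int] = field(default_factory=list)
    codon_position_of: dict[int, int] = field(default_factory=dict)
    substitution_class_of: dict[int, str] = field(default_factory=dict)

    @property
    def n_variable(self) -> int:
        return len(self.variable_positions)

    def class_counts(self) -> dict[str, int]:
        out = {"transition": 0, "transversion": 0, "complex": 0}
        for cls in self.substitution_class_of.values():
            out[cls] += 1
        return out

    def codon_position_counts(self) -> dict[int, int]:
        out = {1: 0, 2: 0, 3: 0}
        for cp in self.codon_position_of.values():
            out[cp] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.variable_positions,
                "codon_position": [
                    self.codon_position_of[p] for p in self.variable_positions
                ],
                "class": [
                    self.substitution_class_of[p] for p in self.variable_positions
                ],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_alignment(
    fasta_path: str | Path, sample_table_path: str | Path, gene_name: str
) -> LabeledAlignment:
    """Read a FASTA alignment and its sample table into a LabeledAlignment.

    The sample table is TSV with columns ``sample_id`` and ``locality``;
    every FASTA record ID must appear in it.
    """
    table = read_sample_table(sample_table_path)
    locality_of = dict(zip(table["sample_id"], table["locality"]))
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise EmptyInputError(f"no FASTA records in {fasta_path}")
    return LabeledAlignment(gene_name, ids, seqs, locality_of)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "locality"}.issubset(df.columns):
        raise FormatError("sample table needs columns: sample_id, locality")
    return df


def read_locality_table(path: str | Path) -> pd.DataFrame:
    """Locality table: locality, order_index, coastal_position_km [+ extras]."""
    df = pd.read_csv(path, sep="\t")
    required = {"locality", "order_index", "coastal_position_km"}
    if not required.issubset(df.columns):
        raise FormatError(f"locality table needs columns: {sorted(required)}")
    return df.sort_values("order_index").reset_index(drop=True)


def read_beach_table(path: str | Path) -> pd.DataFrame:
    """Beach table: locality_a, locality_b, max_beach_km for adjacent pairs."""
    df = pd.read_csv(path, sep="\t")
    required = {"locality_a", "locality_b", "max_beach_km"}
    if not required.issubset(df.columns):
        raise FormatError(f"beach table needs columns: {sorted(required)}")
    return df


def collapse_haplotypes(aln: LabeledAlignment) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes with per-locality counts.

    Sequences collapse only when identical as strings (uppercased); IDs are
    H1..Hk ranked by descending total count, ties by first occurrence.
    """
    if aln.n == 0:  # defensive; LabeledAlignment forbids this
        raise EmptyInputError("cannot collapse an empty alignment")

    first_seen: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    loc_order: list[str] = []
    for i, (sid, seq) in enumerate(zip(aln.sample_ids, aln.sequences)):
        if seq not in first_seen:
            first_seen[seq] = i
            members[seq] = []
        members[seq].append(sid)
        loc = aln.locality_of[sid]
        if loc not in loc_order:
            loc_order.append(loc)

    ranked = sorted(members, key=lambda s: (-len(members[s]), first_seen[s]))
    ids = [f"H{i + 1}" for i in range(len(ranked))]
    seqs = dict(zip(ids, ranked))

    counts = pd.DataFrame(0, index=loc_order, columns=ids, dtype=int)
    for hap_id, seq in zip(ids, ranked):
        for sid in members[seq]:
            counts.loc[aln.locality_of[sid], hap_id] += 1
    return HaplotypeTable(ids, seqs, counts)


def variable_sites(sequences: list[str]) -> list[tuple[int, set[str]]]:
    """1-based positions with >= 2 distinct unambiguous bases, with the bases.

    Positions at which any sequence carries a gap or ambiguity code are
    excluded entirely.
    """
    if not sequences:
        return []
    length = len(sequences[0])
    out: list[tuple[int, set[str]]] = []
    for i in range(length):
        column = {s[i] for s in sequences}
        if not column.issubset(UNAMBIGUOUS):
            continue
        if len(column) >= 2:
            out.append((i + 1, column))
    return out


def classify_substitution(bases: set[str]) -> str:
    """Transition / transversion / complex for the base set at one site."""
    if len(bases) > 2:
        return "complex"
    if bases in TRANSITION_PAIRS:
        return "transition"
    return "transversion"


def site_summary(ht: HaplotypeTable, frame_offset: int = 0) -> SiteSummary:
    """Summarize variable sites among haplotypes.

    ``frame_offset`` in {0,1,2} places position 1 at codon position
    ``frame_offset + 1``; the reading frame of a trimmed fragment is a user
    input, not something the alignment itself can supply.
    """
    if frame_offset not in (0, 1, 2):
        raise FormatError("frame_offset must be 0, 1 or 2")
    if ht.n_haplotypes < 2:
        warnings.warn(
            "fewer than 2 haplotypes: empty site summary", stacklevel=2
        )
        return SiteSummary()
    sites = variable_sites(ht.sequences_in_order())
    summary = SiteSummary()
    for pos, bases in sites:
        summary.variable_positions.append(pos)
        summary.codon_position_of[pos] = ((pos - 1 + frame_offset) % 3) + 1
        summary.substitution_class_of[pos] = classify_substitution(bases)
    return summary
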