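"""Synthetic coastal phylogeography generator.

Generates seeded datasets (alignment FASTA + sample/locality/beach tables +
a truth JSON) carrying the three signals the analysis pipeline is built to
detect:

* a deeply divergent, completely monomorphic southern clade (every southern
  sample identical), emulating postglacial recolonisation of ice-scoured
  shores by a single rafted haplotype;
* isolation by distance among northern localities, produced by gradual
  haplotype turnover along the coast;
* genetic disjunctions planted exactly where a long (> 20 km by default)
  beach interrupts rocky-shore habitat between adjacent northern localities.

The generator is a forward haplotype-pool model, not a coalescent simulator:
the downstream analyses consume only haplotype frequencies and pairwise
distances, so a minimal, fully controllable model is preferable to realism.

Northern model.  Haplotypes form a mutational chain h0, h1, h2, ... in which
consecutive haplotypes differ at exactly one (always fresh) site, so the raw
distance between chain haplotypes equals their index difference.  Each
northern locality k carries a continuous drift coordinate t_k; its samples
draw haplotype index floor(t_k) or floor(t_k)+1 with probability given by the
fractional part, i.e. adjacent localities mix the same two chain neighbours
at shifted frequencies.  Between adjacent non-barrier localities, with
probability ``ibd_step_prob`` one new chain haplotype enters the pool at
intermediate frequency (t advances by Uniform(0.2, 0.8)), so neighbours keep
sharing haplotypes and their expected Nei D stays well below 1.  A long-beach barrier advances t by exactly 2 whole
steps, which makes the two pools provably disjoint (their chain supports
cannot overlap) and every cross-barrier sample pair differ at >= 1 site, so
the pair's Nei D is >= 1 by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .seqio import LabeledAlignment

BASES = "ACGT"
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class SimConfig:
    """Study-scale defaults: a 629 bp marker, 16 northern + 5 southern
    localities 90 km apart, 8 samples per locality, 5% between-clade
    divergence, and a 30% chance that any adjacent gap is a long beach."""

    seq_length: int = 629
    n_localities_north: int = 16
    n_localities_south: int = 5
    samples_per_locality: int = 8
    between_clade_divergence: float = 0.05
    max_within_clade_steps: int = 8
    locality_spacing_km: float = 90.0
    long_beach_prob: float = 0.3
    short_beach_range: tuple[float, float] = (0.0, 15.0)
    long_beach_range: tuple[float, float] = (25.0, 70.0)
    barrier_threshold_km: float = 20.0
    ibd_step_prob: float = 0.5
    ts_weight: float = 9.0
    tv_weight: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.seq_length < 1:
            raise ConfigError("seq_length must be positive")
        if self.max_within_clade_steps > self.seq_length:
            raise ConfigError("max_within_clade_steps exceeds sequence length")
        if not 0.0 <= self.between_clade_divergence <= 0.75:
            raise ConfigError("between_clade_divergence outside [0, 0.75]")
        if self.n_localities_north < 2 or self.n_localities_south < 1:
            raise ConfigError("need >= 2 northern and >= 1 southern localities")
        if self.samples_per_locality < 1:
            raise ConfigError("samples_per_locality must be >= 1")
        if not 0.0 <= self.long_beach_prob <= 1.0:
            raise ConfigError("long_beach_prob outside [0, 1]")
        if self.long_beach_range[0] <= self.barrier_threshold_km:
            raise ConfigError("long beaches must exceed the barrier threshold")
        if self.short_beach_range[1] >= self.barrier_threshold_km:
            raise ConfigError("short beaches must stay below the barrier threshold")
        if self.long_beach_range[1] > 0.85 * self.locality_spacing_km:
            raise ConfigError(
                "beach length cannot exceed the shortest locality spacing "
                "(0.85 x locality_spacing_km)"
            )
        if not 0.0 < self.ibd_step_prob <= 1.0:
            raise ConfigError("ibd_step_prob outside (0, 1]")
        if self.ts_weight < 0 or self.tv_weight < 0 or (
            self.ts_weight + self.tv_weight
        ) <= 0:
            raise ConfigError("transition/transversion weights must be non-negative")
        # worst case chain usage: smooth drift cap + 2 steps per possible barrier
        worst_chain = self.max_within_clade_steps + 2 * (self.n_localities_north - 1)
        expected_between = self.seq_length * self.between_clade_divergence
        if worst_chain + 6 * np.sqrt(expected_between) + expected_between >= (
            self.seq_length
        ):
            raise ConfigError("sequence too short for the requested divergences")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("short_beach_range", "long_beach_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _change_base(base: str, rng: np.random.Generator, ts_w: float, tv_w: float) -> str:
    total = ts_w + tv_w
    if rng.random() < ts_w / total:
        return TRANSITION[base]
    return TRANSVERSIONS[base][rng.integers(2)]


def mutate_positions(
    seq: str,
    positions: np.ndarray,
    rng: np.random.Generator,
    ts_weight: float = 9.0,
    tv_weight: float = 1.0,
) -> str:
    """Change exactly the given (distinct, 0-based) positions."""
    chars = list(seq)
    for pos in positions:
        chars[pos] = _change_base(chars[pos], rng, ts_weight, tv_weight)
    return "".join(chars)


def mutate_sequence(
    seq: str,
    n_steps: int,
    rng: np.random.Generator,
    ts_weight: float = 9.0,
    tv_weight: float = 1.0,
) -> str:
    """Mutate exactly ``n_steps`` distinct positions (drawn without
    replacement), each to a different base, transitions favoured
    ``ts_weight : tv_weight`` (default 9:1)."""
    if n_steps > len(seq):
        raise ConfigError("n_steps exceeds sequence length")
    if n_steps < 0:
        raise ConfigError("n_steps must be non-negative")
    positions = rng.choice(len(seq), size=n_steps, replace=False)
    return mutate_positions(seq, positions, rng, ts_weight, tv_weight)


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus (optionally) the files written."""

    alignment: LabeledAlignment
    sample_table: pd.DataFrame
    locality_table: pd.DataFrame
    beach_table: pd.DataFrame
    truth: dict
    paths: dict = field(default_factory=dict)


def _write_fasta(aln: LabeledAlignment, path: Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.sample_ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


def generate_dataset(cfg: SimConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate one synthetic coast; deterministic (byte-identical files)
    given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length

    root = "".join(rng.choice(list(BASES), size=L))

    # Southern clade haplotype: a binomial number of fresh-site changes.
    n_between = int(rng.binomial(L, cfg.between_clade_divergence))
    all_positions = rng.permutation(L)  # disjoint position pools, south first
    south_positions = all_positions[:n_between]
    south_hap = mutate_positions(
        root, south_positions, rng, cfg.ts_weight, cfg.tv_weight
    )
    chain_positions = all_positions[n_between:]

    # Northern chain haplotypes h0=root, h1, ...: one fresh site per step.
    chain = [root]

    def chain_hap(index: int) -> str:
        while len(chain) <= index:
            pos = chain_positions[len(chain) - 1]
            new = mutate_positions(
                chain[-1], np.array([pos]), rng, cfg.ts_weight, cfg.tv_weight
            )
            chain.append(new)
        return chain[index]

    north_names = [f"N{i + 1:02d}" for i in range(cfg.n_localities_north)]
    south_names = [f"S{i + 1:02d}" for i in range(cfg.n_localities_south)]
    localities = north_names + south_names
    # coastal gaps jittered +/-15% around the mean spacing so coastal distance
    # is a non-degenerate regression predictor (a perfectly even coast would
    # make it collinear with the intercept)
    gaps = cfg.locality_spacing_km * rng.uniform(0.85, 1.15, size=len(localities) - 1)
    positions_km = [0.0]
    for gap in gaps:
        positions_km.append(round(positions_km[-1] + float(gap), 2))

    # Beach lengths for every adjacent pair (mixture of short and long).
    beach_rows = []
    beach_of_pair: dict[tuple[str, str], float] = {}
    for a, b in zip(localities[:-1], localities[1:]):
        if rng.random() < cfg.long_beach_prob:
            beach = float(rng.uniform(*cfg.long_beach_range))
        else:
            beach = float(rng.uniform(*cfg.short_beach_range))
        beach = round(beach, 2)
        beach_rows.append({"locality_a": a, "locality_b": b, "max_beach_km": beach})
        beach_of_pair[(a, b)] = beach

    # Drift coordinates for northern localities.
    t = [0.0]
    drift_used = 0.0
    barrier_pairs = []
    for a, b in zip(north_names[:-1], north_names[1:]):
        if beach_of_pair[(a, b)] > cfg.barrier_threshold_km:
            t.append(t[-1] + 2.0)  # whole-step jump => provably disjoint pools
            barrier_pairs.append(f"{a}--{b}")
        else:
            delta = 0.0
            if rng.random() < cfg.ibd_step_prob:
                # partial advance: the new chain haplotype enters the pool at
                # intermediate frequency, so neighbours keep sharing haplotypes
                delta = float(rng.uniform(0.2, 0.8))
                delta = min(delta, max(0.0, cfg.max_within_clade_steps - drift_used))
                drift_used += delta
            t.append(t[-1] + delta)

    sample_ids: list[str] = []
    sequences: list[str] = []
    locality_of: dict[str, str] = {}

    for name, tk in zip(north_names, t):
        base_idx = int(np.floor(tk))
        frac = tk - base_idx
        for i in range(cfg.samples_per_locality):
            idx = base_idx + (1 if rng.random() < frac else 0)
            sid = f"{name}_{i + 1:02d}"
            sample_ids.append(sid)
            sequences.append(chain_hap(idx))
            locality_of[sid] = name

    for name in south_names:
        for i in range(cfg.samples_per_locality):
            sid = f"{name}_{i + 1:02d}"
            sample_ids.append(sid)
            sequences.append(south_hap)
            locality_of[sid] = name

    aln = LabeledAlignment("synthetic_marker", sample_ids, sequences, locality_of)
    sample_table = pd.DataFrame(
        {"sample_id": sample_ids, "locality": [locality_of[s] for s in sample_ids]}
    )
    locality_table = pd.DataFrame(
        {
            "locality": localities,
            "order_index": list(range(1, len(localities) + 1)),
            "coastal_position_km": positions_km,
            "region": ["north"] * len(north_names) + ["south"] * len(south_names),
        }
    )
    beach_table = pd.DataFrame(beach_rows)

    truth = {
        "seed": cfg.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "north_localities": north_names,
        "south_localities": south_names,
        "between_clade_steps": n_between,
        "barrier_pairs": barrier_pairs,
        "expected_disjunct_pairs": barrier_pairs,
        "drift_coordinate": {name: tk for name, tk in zip(north_names, t)},
    }

    paths: dict[str, str] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": str(out / "alignment.fasta"),
            "sample_table": str(out / "samples.tsv"),
            "locality_table": str(out / "localities.tsv"),
            "beach_table": str(out / "beaches.tsv"),
            "truth": str(out / "truth.json"),
        }
        _write_fasta(aln, Path(paths["fasta"]))
        sample_table.to_csv(
            paths["sample_table"], sep="\t", index=False, lineterminator="\n"
        )
        locality_table.to_csv(
            paths["locality_table"], sep="\t", index=False, lineterminator="\n"
        )
        beach_table.to_csv(
            paths["beach_table"], sep="\t", index=False, lineterminator="\n"
        )
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return SyntheticDataset(aln, sample_table, locality_table, beach_table, truth, paths)
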