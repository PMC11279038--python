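"""Seeded synthetic small RNA-seq study generator.

Emulates a two-group (4 control vs 3 frozen) small RNA sequencing design:
mature-miRNA and non-miRNA ("negative") reference sequences, negative-
binomial miRNA counts with a small planted differentially expressed
fraction, 100-nt single-end reads carrying a 3' adapter, contaminant and
low-quality artifact reads, a miRNA->mRNA target map, and gene-set
collections with planted enrichment of known direction. Every generator
draws from its own RNG stream derived from the master seed, so regenerating
one artifact never perturbs another.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CONTROL, FROZEN, CountMatrix, GeneSet, TargetMap

# Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

READ_LENGTH = 100
GOOD_QUALITY = 36
LOW_QUALITY = 20
MATURE_MIN = 20
MATURE_MAX = 25
SEED_LEN = 20

# Fixed per-generator stream offsets off the master seed.
_STREAMS = {"references": 1, "counts": 2, "fastq": 3, "targets": 4, "gene_sets": 5}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design
    (4 vs 3 samples, 49 mature miRNAs, 5 planted DE of which 2 up)."""

    seed: int = 0
    n_control: int = 4
    n_frozen: int = 3
    n_mirna: int = 49
    n_de: int = 5
    n_de_up: int = 2
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    lib_size_mean: int = 50_000
    adapter: str = DEFAULT_ADAPTER
    frac_contaminant: float = 0.05
    frac_low_quality: float = 0.02
    n_mrna: int = 2_000
    targets_per_mirna: int = 40
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (10, 60)
    n_enriched_sets: int = 4

    def __post_init__(self) -> None:
        if self.n_de > self.n_mirna:
            raise ValueError("n_de must not exceed n_mirna")
        if self.n_de_up > self.n_de:
            raise ValueError("n_de_up must not exceed n_de")
        for name in ("frac_contaminant", "frac_low_quality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_control < 1 or self.n_frozen < 1:
            raise ValueError("need at least one sample per group")
        if self.targets_per_mirna > self.n_mrna:
            raise ValueError("targets_per_mirna must not exceed n_mrna")
        lo, hi = self.set_size_range
        if not (0 < lo <= hi <= self.n_mrna):
            raise ValueError("set_size_range must satisfy 0 < min <= max <= n_mrna")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted truth for downstream recovery tests."""

    de_mirnas: dict[str, int]          # miRNA id -> true log2FC sign (+1/-1)
    true_counts: CountMatrix | None = None
    enriched_sets: dict[str, int] = field(default_factory=dict)  # set id -> expected coefficient sign


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _windows(seq: str, k: int = SEED_LEN):
    return (seq[i : i + k] for i in range(len(seq) - k + 1))


def generate_references(config: SimulationConfig):
    """Generate positive (mature miRNA) and negative (non-miRNA small RNA)
    reference sequences.

    Positive sequences are 20-25 nt; every 20-nt window across all positive
    sequences is globally unique, so a read prefix identifies exactly one
    miRNA. Negative sequences (60-200 nt) share no 20-nt substring with any
    positive sequence.

    Returns two lists of ``(id, sequence)`` pairs.
    """
    if config.n_mirna > 4 ** SEED_LEN:
        raise ValueError(
            f"cannot construct {config.n_mirna} distinct {SEED_LEN}-mers"
        )
    rng = _rng(config, "references")
    positive: list[tuple[str, str]] = []
    seen_windows: set[str] = set()
    attempts = 0
    while len(positive) < config.n_mirna:
        attempts += 1
        if attempts > 100 * config.n_mirna + 1000:
            raise ValueError("reference capacity exhausted: too many window collisions")
        length = int(rng.integers(MATURE_MIN, MATURE_MAX + 1))
        seq = _random_seq(rng, length)
        wins = list(_windows(seq))
        if len(set(wins)) != len(wins) or any(w in seen_windows for w in wins):
            continue
        seen_windows.update(wins)
        positive.append((f"syn-mir-{len(positive) + 1:03d}", seq))

    negative: list[tuple[str, str]] = []
    n_negative = 12
    attempts = 0
    while len(negative) < n_negative:
        attempts += 1
        if attempts > 100 * n_negative + 1000:
            raise ValueError("negative reference construction failed repeatedly")
        length = int(rng.integers(60, 201))
        seq = _random_seq(rng, length)
        if any(w in seen_windows for w in _windows(seq)):
            continue
        negative.append((f"syn-neg-{len(negative) + 1:03d}", seq))
    return positive, negative


def simulate_counts(config: SimulationConfig):
    """Draw the true miRNA count matrix and plant differential expression.

    Counts are negative binomial with variance mu + dispersion * mu^2
    (Poisson when dispersion < 1e-8). Planted DE miRNAs have their frozen-
    group mean scaled by 2**(+/-de_log2fc).

    Returns ``(CountMatrix, GroundTruth)``.
    """
    rng = _rng(config, "counts")
    mirna_ids = [f"syn-mir-{i + 1:03d}" for i in range(config.n_mirna)]
    sample_ids = [f"control_{j + 1}" for j in range(config.n_control)] + [
        f"frozen_{j + 1}" for j in range(config.n_frozen)
    ]
    groups = {
        s: (CONTROL if s.startswith("control") else FROZEN) for s in sample_ids
    }

    # Base relative abundances: log-normal weights normalized to proportions.
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_mirna)
    base_prop = weights / weights.sum()
    lib_sizes = rng.poisson(config.lib_size_mean, size=len(sample_ids)).astype(float)

    de_idx = rng.choice(config.n_mirna, size=config.n_de, replace=False)
    signs = np.array([1] * config.n_de_up + [-1] * (config.n_de - config.n_de_up))
    de_mirnas = {mirna_ids[i]: int(s) for i, s in zip(de_idx, signs)}

    mu = np.outer(base_prop, lib_sizes)
    frozen_cols = np.array([groups[s] == FROZEN for s in sample_ids])
    for i, s in zip(de_idx, signs):
        mu[i, frozen_cols] *= 2.0 ** (s * config.de_log2fc)

    if config.nb_dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / config.nb_dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=mirna_ids, columns=sample_ids),
        groups=groups,
    )
    truth = GroundTruth(de_mirnas=de_mirnas, true_counts=matrix)
    return matrix, truth


def _make_read(rng, core: str, adapter: str, quality: int):
    seq = core + adapter
    if len(seq) < READ_LENGTH:
        seq += _random_seq(rng, READ_LENGTH - len(seq))
    seq = seq[:READ_LENGTH]
    return seq, [quality] * len(seq)


def synthesize_fastq(counts: CountMatrix, positive_reference, negative_reference,
                     config: SimulationConfig) -> dict[str, list[tuple[str, str, list[int]]]]:
    """Turn the true count matrix into per-sample FASTQ read lists.

    Each count becomes one 100-nt read: mature sequence, then the 3'
    adapter, then random filler, all at Q36. Contaminant reads (a 20-30 nt
    slice of a negative-reference sequence plus adapter) and low-quality
    reads (Q20 throughout) are emitted in addition, as fractions of the
    sample's miRNA read total. Read order is shuffled deterministically.
    """
    if counts.counts.empty or not counts.counts.to_numpy().any():
        raise ValueError("empty count matrix: no reads to synthesize")
    pos_by_id = dict(positive_reference)
    missing = set(counts.mirna_ids) - set(pos_by_id)
    if missing:
        raise ValueError(f"count matrix miRNAs absent from positive reference: {sorted(missing)}")

    rng = _rng(config, "fastq")
    out: dict[str, list[tuple[str, str, list[int]]]] = {}
    for sample in counts.sample_ids:
        reads: list[tuple[str, str, list[int]]] = []
        col = counts.counts[sample]
        for mirna_id, c in col.items():
            mature = pos_by_id[mirna_id]
            for _ in range(int(c)):
                seq, qual = _make_read(rng, mature, config.adapter, GOOD_QUALITY)
                reads.append((f"{sample}_r{len(reads):07d}", seq, qual))
        n_mirna_reads = int(col.sum())
        n_contam = round(config.frac_contaminant * n_mirna_reads)
        for _ in range(n_contam):
            _, neg_seq = negative_reference[rng.integers(len(negative_reference))]
            length = int(rng.integers(20, 31))
            start = int(rng.integers(0, len(neg_seq) - length + 1))
            seq, qual = _make_read(rng, neg_seq[start : start + length],
                                   config.adapter, GOOD_QUALITY)
            reads.append((f"{sample}_r{len(reads):07d}", seq, qual))
        n_lowq = round(config.frac_low_quality * n_mirna_reads)
        for _ in range(n_lowq):
            core = _random_seq(rng, int(rng.integers(MATURE_MIN, MATURE_MAX + 1)))
            seq, qual = _make_read(rng, core, config.adapter, LOW_QUALITY)
            reads.append((f"{sample}_r{len(reads):07d}", seq, qual))
        order = rng.permutation(len(reads))
        out[sample] = [reads[i] for i in order]
    return out


def generate_target_map(config: SimulationConfig, ground_truth: GroundTruth) -> TargetMap:
    """Assign each miRNA ``targets_per_mirna`` distinct mRNA targets sampled
    from a universe of ``n_mrna`` mRNA ids."""
    rng = _rng(config, "targets")
    universe = tuple(f"mrna_{i + 1:05d}" for i in range(config.n_mrna))
    mirna_ids = (
        ground_truth.true_counts.mirna_ids
        if ground_truth.true_counts is not None
        else [f"syn-mir-{i + 1:03d}" for i in range(config.n_mirna)]
    )
    targets = {
        mirna: tuple(
            universe[k]
            for k in sorted(rng.choice(config.n_mrna, size=config.targets_per_mirna,
                                       replace=False))
        )
        for mirna in mirna_ids
    }
    return TargetMap(targets=targets, universe=universe)


def generate_gene_sets(config: SimulationConfig, target_map: TargetMap,
                       ground_truth: GroundTruth) -> list[GeneSet]:
    """Build gene-set collections with ``n_enriched_sets`` planted sets.

    A planted set draws at least 70% of its members from the targets of
    planted DE miRNAs of one direction. Targets of UPregulated miRNAs are
    under increased negative regulation, so the expected enrichment
    coefficient is negative; downregulated miRNAs give the mirror sign.
    Planted directions are recorded in ``ground_truth.enriched_sets``.
    """
    rng = _rng(config, "gene_sets")
    universe = list(target_map.universe)
    lo, hi = config.set_size_range

    up_pool = sorted(
        {m for mi, sign in ground_truth.de_mirnas.items() if sign > 0
         for m in target_map.targets.get(mi, ())}
    )
    down_pool = sorted(
        {m for mi, sign in ground_truth.de_mirnas.items() if sign < 0
         for m in target_map.targets.get(mi, ())}
    )

    directions: list[int] = []
    for k in range(config.n_enriched_sets):
        want_up = (k % 2 == 0 and up_pool) or not down_pool
        directions.append(-1 if want_up else +1)  # expected coefficient sign

    gene_sets: list[GeneSet] = []
    ground_truth.enriched_sets = {}
    for i in range(config.n_gene_sets):
        set_id = f"SET{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if i < config.n_enriched_sets:
            coef_sign = directions[i]
            pool = up_pool if coef_sign < 0 else down_pool
            n_planted = math.ceil(0.7 * size)
            if len(pool) < n_planted:
                raise ValueError(
                    f"DE miRNA target pool ({len(pool)}) smaller than required "
                    f"planted members ({n_planted}) for {set_id}"
                )
            planted = [pool[k] for k in rng.choice(len(pool), size=n_planted, replace=False)]
            rest_pool = [m for m in universe if m not in set(planted)]
            rest = [rest_pool[k] for k in rng.choice(len(rest_pool), size=size - n_planted,
                                                    replace=False)]
            members = tuple(planted + rest)
            ground_truth.enriched_sets[set_id] = coef_sign
            desc = "planted enriched set"
        else:
            members = tuple(universe[k] for k in rng.choice(len(universe), size=size,
                                                            replace=False))
            desc = "background set"
        gene_sets.append(GeneSet(set_id, desc, members))
    return gene_sets


def simulate_study(config: SimulationConfig):
    """Run every generator and return all study artifacts.

    Returns ``(positive_ref, negative_ref, counts, reads_by_sample,
    target_map, gene_sets, ground_truth)``.
    """
    positive, negative = generate_references(config)
    counts, truth = simulate_counts(config)
    reads = synthesize_fastq(counts, positive, negative, config)
    target_map = generate_target_map(config, truth)
    gene_sets = generate_gene_sets(config, target_map, truth)
    return positive, negative, counts, reads, target_map, gene_sets, truth
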