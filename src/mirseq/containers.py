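"""Core in-memory containers shared across pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CONTROL = "control"
FROZEN = "frozen"
GROUP_LABELS = (CONTROL, FROZEN)


@dataclass
class CountMatrix:
    """Integer miRNA x sample read counts with sample group labels.

    ``counts`` is a pandas DataFrame indexed by miRNA id with one column per
    sample; ``groups`` maps each sample id to ``"control"`` or ``"frozen"``.
    """

    counts: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate miRNA ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        labels = {self.groups[s] for s in self.counts.columns}
        bad = labels - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if labels != set(GROUP_LABELS):
            raise ValueError("both control and frozen samples are required")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_vector(self) -> pd.Series:
        """0/1 indicator per sample: 1 for frozen, 0 for control."""
        return pd.Series(
            [1 if self.groups[s] == FROZEN else 0 for s in self.counts.columns],
            index=self.counts.columns,
            name="frozen",
        )

    def to_tsv(self, counts_path, groups_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="mirna_id")
        pd.Series(
            {s: self.groups[s] for s in self.counts.columns}, name="group"
        ).to_csv(groups_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path, groups_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="mirna_id")
        groups = (
            pd.read_csv(groups_path, sep="\t", index_col="sample_id")["group"]
            .to_dict()
        )
        return cls(counts=counts, groups=groups)


@dataclass
class ProcessingStats:
    """Per-sample read tallies at every stage of the processing pipeline.

    Counts are monotone non-increasing from input through the negative
    filter, and aligned + unaligned equals the post-negative-filter count.
    """

    sample_id: str
    n_input: int = 0
    n_post_trim: int = 0
    n_post_quality: int = 0
    n_post_negative: int = 0
    n_aligned: int = 0
    n_unaligned: int = 0

    def validate(self) -> None:
        seq = (self.n_input, self.n_post_trim, self.n_post_quality, self.n_post_negative)
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"stage counts increased for sample {self.sample_id}: {seq}")
        if self.n_aligned + self.n_unaligned != self.n_post_negative:
            raise ValueError(
                f"aligned + unaligned != post-negative-filter for {self.sample_id}"
            )


@dataclass
class TargetMap:
    """miRNA -> mRNA target incidence plus the mRNA universe.

    The universe holds every mRNA id the enrichment regression may use as
    background, including mRNAs targeted by no miRNA (their aggregated
    score is zero).
    """

    targets: dict[str, tuple[str, ...]]
    universe: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.universe:
            seen: dict[str, None] = {}
            for mrnas in self.targets.values():
                for m in mrnas:
                    seen.setdefault(m)
            self.universe = tuple(seen)

    def pairs(self) -> list[tuple[str, str]]:
        return [(mi, mr) for mi, mrnas in self.targets.items() for mr in mrnas]

    def mrna_to_mirnas(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {m: [] for m in self.universe}
        for mirna, mrnas in self.targets.items():
            for m in mrnas:
                out.setdefault(m, []).append(mirna)
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("mirna_id\tmrna_id\n")
            for mirna, mrna in self.pairs():
                fh.write(f"{mirna}\t{mrna}\n")

    @classmethod
    def from_tsv(cls, path, universe=None) -> "TargetMap":
        df = pd.read_csv(path, sep="\t")
        targets: dict[str, list[str]] = {}
        for mirna, mrna in zip(df["mirna_id"], df["mrna_id"]):
            targets.setdefault(str(mirna), []).append(str(mrna))
        return cls(
            targets={k: tuple(v) for k, v in targets.items()},
            universe=tuple(universe) if universe is not None else (),
        )


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]
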