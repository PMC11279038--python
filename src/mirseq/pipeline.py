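"""End-to-end orchestration: simulate -> process -> DE -> GSA, with every
intermediate table written to disk and a run summary mirroring the result
surfaces (DE tallies, per-collection enrichment counts, volcano tables)."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, gsa, io, reads
from .containers import CountMatrix, TargetMap
from .simulate import DEFAULT_ADAPTER, SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

MODES = ("simulate", "process", "de", "gsa", "all")


@dataclass
class RunConfig:
    """Paths and stage parameters for one reproducible run."""

    outdir: str = "mirseq_run"
    mode: str = "all"
    seed: int = 0
    # simulation
    simulation: SimulationConfig | None = None
    # read processing
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = reads.DEFAULT_MIN_OVERLAP
    max_error_rate: float = reads.DEFAULT_MAX_ERROR_RATE
    qual_threshold: float = reads.DEFAULT_QUAL_THRESHOLD
    min_length: int = reads.DEFAULT_MIN_LENGTH
    seed_len: int = reads.DEFAULT_SEED_LEN
    min_total_count: int = reads.DEFAULT_MIN_TOTAL
    # differential expression
    alpha: float = diffexp.DEFAULT_ALPHA
    fc_threshold: float = diffexp.DEFAULT_FC_THRESHOLD
    use_weights: bool = True
    # gene-set analysis
    p_floor: float = gsa.DEFAULT_P_FLOOR
    min_set_size: int = gsa.DEFAULT_MIN_SET_SIZE
    # external inputs for non-simulated runs (sample -> fastq path, etc.)
    fastq: dict[str, str] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    positive_reference: str | None = None
    negative_reference: str | None = None
    counts_table: str | None = None
    groups_table: str | None = None
    de_table: str | None = None
    target_map: str | None = None
    gene_sets: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed, adapter=self.adapter)


def _require(path, what: str) -> Path:
    p = Path(path) if path else None
    if p is None or not p.exists():
        raise FileNotFoundError(f"missing input for this stage: {what} ({path!r})")
    return p


def _sim_paths(outdir: Path) -> dict[str, Path]:
    return {
        "positive": outdir / "reference_positive.fasta",
        "negative": outdir / "reference_negative.fasta",
        "reads": outdir / "reads",
        "true_counts": outdir / "true_counts.tsv",
        "groups": outdir / "sample_groups.tsv",
        "target_map": outdir / "target_map.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "ground_truth": outdir / "ground_truth.json",
    }


def stage_simulate(config: RunConfig, outdir: Path) -> dict[str, Path]:
    paths = _sim_paths(outdir)
    sim = config.simulation
    positive, negative, counts, reads_by_sample, target_map, gene_sets, truth = (
        simulate_study(sim)
    )
    io.write_fasta(positive, paths["positive"])
    io.write_fasta(negative, paths["negative"])
    paths["reads"].mkdir(parents=True, exist_ok=True)
    for sample, rs in reads_by_sample.items():
        io.write_fastq(rs, paths["reads"] / f"{sample}.fastq")
    counts.to_tsv(paths["true_counts"], paths["groups"])
    target_map.to_tsv(paths["target_map"])
    io.write_gmt(gene_sets, paths["gene_sets"])
    io.write_ground_truth(truth, paths["ground_truth"])
    logger.info("simulated %d samples, %d miRNAs", len(counts.sample_ids),
                len(counts.mirna_ids))
    return paths


def stage_process(config: RunConfig, outdir: Path) -> Path:
    sim_paths = _sim_paths(outdir)
    if config.fastq:
        fastq = {s: str(_require(p, f"FASTQ for sample {s}"))
                 for s, p in config.fastq.items()}
        groups = dict(config.groups)
    else:
        reads_dir = _require(sim_paths["reads"], "simulated reads directory")
        groups = (
            pd.read_csv(_require(sim_paths["groups"], "sample groups"),
                        sep="\t", index_col="sample_id")["group"].to_dict()
        )
        fastq = {s: str(reads_dir / f"{s}.fastq") for s in groups}
    positive = io.read_fasta(
        _require(config.positive_reference or sim_paths["positive"],
                 "positive reference FASTA"))
    negative = io.read_fasta(
        _require(config.negative_reference or sim_paths["negative"],
                 "negative reference FASTA"))
    counts, stats = reads.count_samples(
        fastq, groups, config.adapter, positive, negative,
        min_overlap=config.min_overlap, max_error_rate=config.max_error_rate,
        qual_threshold=config.qual_threshold, min_length=config.min_length,
        seed_len=config.seed_len,
    )
    counts.to_tsv(outdir / "counts.tsv", outdir / "sample_groups.tsv")
    reads.stats_frame(stats).to_csv(outdir / "processing_stats.tsv", sep="\t")
    return outdir / "counts.tsv"


def stage_de(config: RunConfig, outdir: Path) -> Path:
    counts_path = _require(config.counts_table or outdir / "counts.tsv",
                           "count matrix TSV")
    groups_path = _require(config.groups_table or outdir / "sample_groups.tsv",
                           "sample groups TSV")
    counts = CountMatrix.from_tsv(counts_path, groups_path)
    filtered = reads.apply_min_count(counts, config.min_total_count)
    table = diffexp.run_diffexp(filtered, alpha=config.alpha,
                                fc_threshold=config.fc_threshold,
                                use_weights=config.use_weights)
    table.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    export_volcano_data(table, outdir / "volcano_mirna.tsv",
                        p_floor=config.p_floor)
    return outdir / "de_table.tsv"


def stage_gsa(config: RunConfig, outdir: Path) -> Path:
    sim_paths = _sim_paths(outdir)
    de_path = _require(config.de_table or outdir / "de_table.tsv", "DE table TSV")
    de_table = pd.read_csv(de_path, sep="\t")
    tmap_path = _require(config.target_map or sim_paths["target_map"],
                         "target map TSV")
    target_map = TargetMap.from_tsv(tmap_path)
    if config.gene_sets:
        collections = {
            name: io.read_gmt(_require(p, f"GMT for collection {name}"))
            for name, p in config.gene_sets.items()
        }
    else:
        collections = {
            "custom": io.read_gmt(_require(sim_paths["gene_sets"], "GMT file"))
        }
    table = gsa.run_gsa(de_table, target_map, collections, alpha=config.alpha,
                        p_floor=config.p_floor, min_set_size=config.min_set_size)
    table.to_csv(outdir / "gsa_table.tsv", sep="\t", index=False)
    export_volcano_data(table, outdir / "volcano_sets.tsv",
                        p_floor=config.p_floor)
    return outdir / "gsa_table.tsv"


def export_volcano_data(table: pd.DataFrame, path,
                        p_floor: float = gsa.DEFAULT_P_FLOOR) -> pd.DataFrame:
    """Plot-ready volcano table.

    For miRNA DE tables: (id, log2fc, neg_log10_p, significant) using the
    raw p-value on the y axis; for gene-set tables: (set_id, coefficient,
    neg_log10_p_adj, significant, direction). p-values are floored so every
    exported value is finite.
    """
    if "mirna_id" in table.columns:
        out = pd.DataFrame(
            {
                "id": table["mirna_id"],
                "log2fc": table["log2fc"],
                "neg_log10_p": -np.log10(np.maximum(table["p_raw"], p_floor)),
                "significant": table["significant"],
            }
        )
    elif "set_id" in table.columns:
        out = pd.DataFrame(
            {
                "set_id": table["set_id"],
                "coefficient": table["coefficient"],
                "neg_log10_p_adj": -np.log10(np.maximum(table["p_adj"], p_floor)),
                "significant": table["significant"],
                "direction": table["direction"],
            }
        )
    else:
        raise ValueError("table is neither a miRNA DE table nor a gene-set table")
    out.to_csv(path, sep="\t", index=False)
    return out


def summarize(outdir: Path) -> dict:
    """RunSummary tallies recomputed directly from the exported tables."""
    summary: dict = {}
    de_path = outdir / "de_table.tsv"
    if de_path.exists():
        de = pd.read_csv(de_path, sep="\t")
        sig = de[de["significant"]]
        summary.update(
            n_mirna_evaluated=int(len(de)),
            n_de=int(len(sig)),
            n_de_up=int((sig["log2fc"] > 0).sum()),
            n_de_down=int((sig["log2fc"] < 0).sum()),
        )
    gsa_path = outdir / "gsa_table.tsv"
    if gsa_path.exists():
        g = pd.read_csv(gsa_path, sep="\t")
        per = {}
        for name, sub in g.groupby("collection"):
            sig = sub[sub["significant"]]
            per[str(name)] = {
                "n_sets_tested": int(len(sub)),
                "n_significant": int(len(sig)),
                "n_positive_coef": int((sig["coefficient"] > 0).sum()),
                "n_negative_coef": int((sig["coefficient"] < 0).sum()),
            }
        summary["collections"] = per
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages, write artifacts, return the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _echo_config(config, outdir / "effective_config.yaml")
    mode = config.mode
    if mode in ("simulate", "all"):
        stage_simulate(config, outdir)
    if mode in ("process", "all"):
        stage_process(config, outdir)
    if mode in ("de", "all"):
        stage_de(config, outdir)
    if mode in ("gsa", "all"):
        stage_gsa(config, outdir)
    summary = summarize(outdir)
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _echo_config(config: RunConfig, path: Path) -> None:
    payload = dataclasses.asdict(config)
    payload["simulation"] = dataclasses.asdict(config.simulation)
    payload["simulation"]["set_size_range"] = list(
        payload["simulation"]["set_size_range"]
    )
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
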