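"""Score-based logistic-regression gene-set analysis.

Each miRNA receives a signed significance score
``S_miRNA = -log10(p) * signum(log2 FC)`` (p being the FDR-adjusted
p-value from the differential-expression stage). Each mRNA aggregates the
scores of the miRNAs targeting it with a sign flip,
``S_mRNA = -sum_i S_miRNA_i``, reflecting negative regulation: targets of
upregulated miRNAs score negative. Gene-set enrichment is then a logistic
regression of set membership on S_mRNA over the whole mRNA universe; a
negative slope means the set's members sit at low (repressed) scores —
increased negative regulation by miRNA — and a positive slope the reverse.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSet, TargetMap

logger = logging.getLogger(__name__)

DEFAULT_P_FLOOR = 1e-300
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_SET_SIZE = 5
SEPARATION_SLOPE = 50.0
DIRECTION_POSITIVE = "decreased negative regulation"
DIRECTION_NEGATIVE = "increased negative regulation"

COLLECTIONS = ("GO_MF", "GO_BP", "GO_CC", "KEGG", "custom")


def mirna_score(p_adj: float, log2fc: float,
                p_floor: float = DEFAULT_P_FLOOR) -> float:
    """Signed miRNA significance score: -log10(max(p, floor)) * signum(lfc)."""
    if not 0.0 <= p_adj <= 1.0:
        raise ValueError(f"p_adj must be in [0, 1], got {p_adj}")
    p = max(p_adj, p_floor)
    return -math.log10(p) * float(np.sign(log2fc))


def mirna_scores(de_table: pd.DataFrame,
                 p_floor: float = DEFAULT_P_FLOOR) -> pd.Series:
    """Per-miRNA scores from a DE table with mirna_id, p_adj, log2fc."""
    return pd.Series(
        [mirna_score(p, l, p_floor) for p, l in
         zip(de_table["p_adj"], de_table["log2fc"])],
        index=list(de_table["mirna_id"]),
        name="s_mirna",
    )


def mrna_scores(scores: pd.Series, target_map: TargetMap) -> pd.DataFrame:
    """Aggregate miRNA scores over targets: s_mrna = -sum of targeting
    scores; untargeted mRNAs score 0 with zero contributors.

    miRNAs scored but absent from the target map contribute nothing and are
    logged (they mirror species without a mappable ortholog).
    """
    if not target_map.targets:
        raise ValueError("empty target map")
    unmapped = set(scores.index) - set(target_map.targets)
    if unmapped:
        logger.info("%d scored miRNAs absent from the target map: %s",
                    len(unmapped), sorted(unmapped)[:5])
    acc: dict[str, float] = {m: 0.0 for m in target_map.universe}
    contributors: dict[str, list[str]] = {m: [] for m in target_map.universe}
    for mirna, mrnas in target_map.targets.items():
        if mirna not in scores.index:
            continue
        s = scores[mirna]
        for m in mrnas:
            acc[m] = acc.get(m, 0.0) + s
            contributors.setdefault(m, []).append(mirna)
    out = pd.DataFrame(
        {
            "mrna_id": list(acc),
            "s_mrna": [-acc[m] for m in acc],
            "n_targeting": [len(contributors[m]) for m in acc],
            "mirnas": [",".join(contributors[m]) for m in acc],
        }
    ).set_index("mrna_id")
    return out


@dataclass
class LogisticFit:
    coefficient: float
    std_error: float
    p_raw: float
    converged: bool
    separation: bool

    @property
    def usable(self) -> bool:
        return self.converged and not self.separation


def fit_logistic_gsa(s_mrna: np.ndarray, membership: np.ndarray,
                     max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """IRLS fit of membership ~ intercept + s_mrna.

    Returns the slope, its standard error from the inverse observed
    information, and a two-sided Wald-z p-value. A fit whose slope exceeds
    50 in magnitude, fails to converge, or hits a singular information
    matrix is flagged as separated/degenerate.
    """
    x = np.asarray(s_mrna, dtype=float)
    y = np.asarray(membership, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("s_mrna and membership must be equal-length 1-D arrays")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    singular = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        info = X.T @ (w[:, None] * X)
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            singular = True
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if abs(beta[1]) > SEPARATION_SLOPE:
            break
    separation = singular or abs(beta[1]) > SEPARATION_SLOPE or not converged
    if separation:
        return LogisticFit(float(beta[1]), math.inf, 1.0, converged, True)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = X.T @ (w[:, None] * X)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return LogisticFit(float(beta[1]), math.inf, 1.0, converged, True)
    se = math.sqrt(cov[1, 1])
    z = beta[1] / se
    p = 2.0 * stats.norm.sf(abs(z))
    return LogisticFit(float(beta[1]), se, float(p), converged, False)


def gsa_collection(mrna_score_table: pd.DataFrame, gene_sets: list[GeneSet],
                   collection: str = "custom", alpha: float = DEFAULT_ALPHA,
                   min_set_size: int = DEFAULT_MIN_SET_SIZE,
                   max_iter: int = 100, tol: float = 1e-8) -> pd.DataFrame:
    """Enrichment table for one gene-set collection.

    Sets with fewer than ``min_set_size`` members inside the mRNA universe
    (or fewer non-members) are skipped; separated/degenerate fits are
    excluded from the FDR adjustment. BH adjustment runs within the
    collection, significance at adjusted p < alpha; output is sorted by
    adjusted p.
    """
    from .diffexp import bh_adjust

    universe = list(mrna_score_table.index)
    uni_set = set(universe)
    x = mrna_score_table["s_mrna"].to_numpy(dtype=float)
    rows = []
    for gs in gene_sets:
        members = set(gs.members) & uni_set
        n_in = len(members)
        if n_in < min_set_size or len(universe) - n_in < min_set_size:
            logger.warning("set %s skipped: %d usable members of %d mRNAs",
                           gs.set_id, n_in, len(universe))
            continue
        y = np.fromiter((m in members for m in universe), dtype=float,
                        count=len(universe))
        fit = fit_logistic_gsa(x, y, max_iter=max_iter, tol=tol)
        if not fit.usable:
            logger.warning("set %s: separated or non-converged fit, excluded from FDR",
                           gs.set_id)
            continue
        rows.append(
            {
                "collection": collection,
                "set_id": gs.set_id,
                "coefficient": fit.coefficient,
                "std_error": fit.std_error,
                "p_raw": fit.p_raw,
                "n_members_in_universe": n_in,
            }
        )
    columns = ["collection", "set_id", "coefficient", "std_error", "p_raw",
               "p_adj", "n_members_in_universe", "direction", "significant"]
    if not rows:
        logger.warning("collection %s: no fit-eligible gene set", collection)
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table["direction"] = np.where(
        table["coefficient"] > 0, DIRECTION_POSITIVE, DIRECTION_NEGATIVE
    )
    table["significant"] = table["p_adj"] < alpha
    table = table.sort_values(["p_adj", "set_id"], kind="stable").reset_index(drop=True)
    return table[columns]


def run_gsa(de_table: pd.DataFrame, target_map: TargetMap,
            collections: dict[str, list[GeneSet]],
            alpha: float = DEFAULT_ALPHA, p_floor: float = DEFAULT_P_FLOOR,
            min_set_size: int = DEFAULT_MIN_SET_SIZE) -> pd.DataFrame:
    """Score miRNAs and mRNAs, then run enrichment per collection."""
    scores = mirna_scores(de_table, p_floor=p_floor)
    mrna_table = mrna_scores(scores, target_map)
    parts = [
        gsa_collection(mrna_table, sets, collection=name, alpha=alpha,
                       min_set_size=min_set_size)
        for name, sets in collections.items()
    ]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return gsa_collection(mrna_table, [], collection="custom")
    return pd.concat(parts, ignore_index=True)
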