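"""Differential methylation analysis.

Per-locus two-sample t-tests on the centered log2(HpaII/MspI) matrix,
DMR calling under joint P-value / effect-size filters, direction
summaries, volcano coordinates and hierarchical clustering of the top
loci.

Direction convention: *hypomethylated in cases* means a higher
HpaII/MspI ratio in cases, i.e. a positive case − control difference
(delta > 0) of the centered log2 ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage, fcluster

logger = logging.getLogger(__name__)

__all__ = [
    "DMRSet",
    "ClusterResult",
    "locus_differential_test",
    "call_dmrs",
    "summarize_directions",
    "select_and_cluster_heatmap",
    "volcano_table",
]

P_FLOOR = 1e-300  # volcano floor for p-value underflow


@dataclass
class DMRSet:
    """Loci surviving the joint P / effect filters, ranked by |t|."""

    table: pd.DataFrame  # LocusStat rows + direction, sorted by |t| desc
    p_threshold: float
    delta_threshold: float
    fold_change_scale: str = "log"

    def __len__(self) -> int:
        return len(self.table)

    @property
    def hypo_fraction(self) -> float:
        if len(self.table) == 0:
            return float("nan")
        return float((self.table["delta"] > 0).mean())


@dataclass
class ClusterResult:
    loci: list
    sample_linkage: np.ndarray
    locus_linkage: np.ndarray
    sample_order: list
    locus_order: list

    def sample_bipartition(self) -> pd.Series:
        """Cluster labels from the first split of the sample dendrogram."""
        labels = fcluster(self.sample_linkage, t=2, criterion="maxclust")
        return pd.Series(labels, index=self.sample_order_index)

    sample_order_index: pd.Index = field(default_factory=pd.Index)


def locus_differential_test(
    matrix_values: pd.DataFrame,
    groups: pd.Series,
    equal_var: bool = True,
    min_per_group: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Two-sample t per locus: case vs control centered log ratios.

    Pooled-variance t by default (``equal_var=False`` gives Welch),
    two-tailed p, ``delta`` = mean(case) − mean(control).  Loci with
    fewer than ``min_per_group`` finite values in either group are
    skipped and counted in the returned QC dict.
    """
    groups = groups.reindex(matrix_values.columns)
    if groups.isna().any():
        raise ValueError("group label missing for some samples")
    is_case = (groups == "case").to_numpy()
    is_ctl = (groups == "control").to_numpy()
    X = matrix_values.to_numpy(dtype=float)
    A = X[:, is_ctl]  # control
    B = X[:, is_case]  # case

    def _mstats(M: np.ndarray):
        n = np.isfinite(M).sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.where(np.isfinite(M), M, np.nan), axis=1)
            var = np.full(len(M), np.nan)
            ok = n >= 2
            if ok.any():
                var[ok] = np.nanvar(
                    np.where(np.isfinite(M), M, np.nan)[ok], axis=1, ddof=1
                )
        return n, mean, var

    n1, m1, v1 = _mstats(A)
    n2, m2, v2 = _mstats(B)
    usable = (n1 >= min_per_group) & (n2 >= min_per_group)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("skipping %d loci with <%d values in a group", n_skipped, min_per_group)

    delta = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        else:
            se2 = v1 / n1 + v2 / n2
            se = np.sqrt(se2)
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = delta / se
    # zero spread and zero difference: no evidence, t = 0, p = 1
    degenerate = usable & (se == 0) & (delta == 0)
    t[degenerate] = 0.0
    p = np.full(len(t), np.nan)
    finite_t = usable & np.isfinite(t)
    p[finite_t] = 2.0 * sps.t.sf(np.abs(t[finite_t]), df[finite_t])
    p[usable & np.isinf(t)] = 0.0

    stats = pd.DataFrame(
        {
            "fragment_id": matrix_values.index,
            "delta": delta,
            "t": t,
            "p_value": p,
            "n_control": n1,
            "n_case": n2,
        }
    )
    stats = stats[usable].reset_index(drop=True)
    qc = {"n_tested": int(usable.sum()), "n_skipped": n_skipped}
    return stats, qc


def _effect_passes(delta: np.ndarray, threshold: float, scale: str) -> np.ndarray:
    if scale == "log":
        return np.abs(delta) > threshold
    if scale == "ratio":
        # "more than 50% difference in methylation ratio" on the raw scale
        return np.abs(2.0**delta - 1.0) > threshold
    raise ValueError("fold_change_scale must be 'log' or 'ratio'")


def call_dmrs(
    stats: pd.DataFrame,
    p_threshold: float = 0.01,
    delta_threshold: float = 0.5,
    fold_change_scale: str = "log",
) -> DMRSet:
    """Strict joint filter p < p_threshold and effect > delta_threshold.

    The effect filter defaults to the log scale (|delta| of group
    means of log2 ratios); ``fold_change_scale="ratio"`` interprets
    the threshold on the raw ratio scale instead.  The output is
    ranked by |t| descending.
    """
    if p_threshold <= 0 or delta_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    if stats.empty:
        table = stats.copy()
        table["direction"] = pd.Series(dtype=object)
        return DMRSet(table, p_threshold, delta_threshold, fold_change_scale)
    keep = (stats["p_value"].to_numpy() < p_threshold) & _effect_passes(
        stats["delta"].to_numpy(), delta_threshold, fold_change_scale
    )
    table = stats[keep].copy()
    table["direction"] = np.where(table["delta"] > 0, "hypo", "hyper")
    table = table.iloc[np.argsort(-np.abs(table["t"].to_numpy()), kind="mergesort")]
    return DMRSet(
        table.reset_index(drop=True), p_threshold, delta_threshold, fold_change_scale
    )


def summarize_directions(
    dmrs: DMRSet | pd.DataFrame, categories: pd.Series | None = None
) -> dict:
    """Hypo/hyper counts and fractions, overall and per category."""
    table = dmrs.table if isinstance(dmrs, DMRSet) else dmrs
    n = len(table)
    n_hypo = int((table["delta"] > 0).sum()) if n else 0
    summary = {
        "n_dmrs": n,
        "n_hypo": n_hypo,
        "n_hyper": n - n_hypo,
        "hypo_fraction": (n_hypo / n) if n else float("nan"),
    }
    if categories is not None:
        cats = categories.reindex(table["fragment_id"])
        per = (
            pd.DataFrame(
                {
                    "category": cats.to_numpy(),
                    "hypo": (table["delta"] > 0).to_numpy(),
                }
            )
            .groupby("category", dropna=False)
            .agg(n=("hypo", "size"), n_hypo=("hypo", "sum"))
            .reset_index()
        )
        per["hypo_fraction"] = per["n_hypo"] / per["n"]
        summary["per_category"] = per
    return summary


# ---------------------------------------------------------------------------
# clustering and volcano
# ---------------------------------------------------------------------------

def _nan_sqeuclidean_condensed(M: np.ndarray) -> np.ndarray:
    """Condensed squared-Euclidean distances, missing pairwise-excluded.

    The sum of squared differences over jointly finite coordinates is
    rescaled to the full dimension so rows with different missingness
    remain comparable.
    """
    n, d = M.shape
    out = []
    finite = np.isfinite(M)
    for i in range(n - 1):
        diff = M[i] - M[i + 1 :]
        shared = finite[i] & finite[i + 1 :]
        diff = np.where(shared, diff, 0.0)
        cnt = shared.sum(axis=1)
        ss = (diff**2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = ss * (d / cnt)
        scaled[cnt == 0] = np.nan
        out.append(scaled)
    dist = np.concatenate(out) if out else np.empty(0)
    if np.isnan(dist).any():
        raise ValueError("pairs with no shared finite entries cannot be clustered")
    return dist


def select_and_cluster_heatmap(
    matrix_values: pd.DataFrame,
    stats: pd.DataFrame,
    p_cut: float = 1.5e-4,
    delta_cut: float = 0.5,
    linkage_method: str = "average",
) -> ClusterResult:
    """Cluster samples and loci on the heatmap selection.

    Selection keeps loci with p < ``p_cut`` and |delta| >=
    ``delta_cut``; both dendrograms are agglomerated under
    squared-Euclidean dissimilarity (missing entries
    pairwise-excluded) with average linkage.
    """
    keep = stats[
        (stats["p_value"] < p_cut) & (stats["delta"].abs() >= delta_cut)
    ]["fragment_id"]
    loci = [f for f in matrix_values.index if f in set(keep)]
    if len(loci) < 2:
        raise ValueError("fewer than 2 loci survive the clustering selection")
    sub = matrix_values.loc[loci]

    sample_link = linkage(_nan_sqeuclidean_condensed(sub.to_numpy().T), linkage_method)
    locus_link = linkage(_nan_sqeuclidean_condensed(sub.to_numpy()), linkage_method)
    sample_order = [sub.columns[i] for i in leaves_list(sample_link)]
    locus_order = [loci[i] for i in leaves_list(locus_link)]
    return ClusterResult(
        loci=loci,
        sample_linkage=sample_link,
        locus_linkage=locus_link,
        sample_order=sample_order,
        locus_order=locus_order,
        sample_order_index=sub.columns,
    )


def volcano_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Per-locus volcano coordinates: x = delta, y = −log2(p).

    p-values of exactly 0 (t-statistic overflow) are floored at a tiny
    positive constant so the y coordinate stays finite.
    """
    p = stats["p_value"].to_numpy(dtype=float)
    if (p == 0).any():
        logger.info("flooring %d p-values of 0 at %g", int((p == 0).sum()), P_FLOOR)
    p = np.maximum(p, P_FLOOR)
    return pd.DataFrame(
        {
            "fragment_id": stats["fragment_id"],
            "delta": stats["delta"],
            "neg_log2_p": -np.log2(p),
        }
    )
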