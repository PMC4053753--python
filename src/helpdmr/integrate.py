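"""Methylation-expression integration and external validation.

Differential expression with an expression-level pre-filter and
Benjamini-Hochberg control; overlap and sign concordance between DMR
genes and differentially expressed genes (convention: hypomethylation
in cases pairs with up-regulation in cases); concordance of discovery
DMR directions with a replication platform's signed methylation
differences; and Pearson correlation of absolute (percent)
methylation against the relative log2(HpaII/MspI) ratio, which is
expected to be negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceResult",
    "differential_expression",
    "dmr_expression_concordance",
    "replication_concordance",
    "absolute_relative_correlation",
]


@dataclass
class ConcordanceResult:
    n_dmr_genes: int
    n_de_genes: int
    n_overlap: int
    fraction: float
    per_gene: pd.DataFrame  # gene, directions, concordant flag
    n_concordant: int = 0
    concordant_fraction: float = float("nan")


def differential_expression(
    expression: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    expression_percentile: float = 20.0,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sample t with an expression floor and BH control.

    Genes whose larger group mean sits below the global
    ``expression_percentile`` of all pooled gene-level group means are
    excluded before testing; BH step-up runs over the tested genes
    only and ``passes_filter`` marks adjusted p < ``alpha``.
    """
    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("sample_id")["group"]
    groups = groups.reindex(expression.columns)
    if groups.isna().any():
        raise ValueError("group label missing for some samples")
    is_case = (groups == "case").to_numpy()
    is_ctl = (groups == "control").to_numpy()
    if is_case.sum() < 2 or is_ctl.sum() < 2:
        raise ValueError("need >= 2 samples per group")

    X = expression.to_numpy(dtype=float)
    mean_ctl = X[:, is_ctl].mean(axis=1)
    mean_case = X[:, is_case].mean(axis=1)
    pooled_means = np.concatenate([mean_ctl, mean_case])
    cutoff = np.percentile(pooled_means, expression_percentile)
    tested = np.maximum(mean_ctl, mean_case) >= cutoff
    if not tested.any():
        logger.warning("every gene fell below the expression filter")

    t = np.full(len(X), np.nan)
    p = np.full(len(X), np.nan)
    if tested.any():
        res = sps.ttest_ind(
            X[tested][:, is_case], X[tested][:, is_ctl], axis=1, equal_var=equal_var
        )
        t[tested] = res.statistic
        p[tested] = res.pvalue

    adj = np.full(len(X), np.nan)
    if tested.any():
        adj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "gene": expression.index,
            "mean_control": mean_ctl,
            "mean_case": mean_case,
            "log_fc": mean_case - mean_ctl,
            "t": t,
            "p_value": p,
            "bh_adjusted_p": adj,
            "tested": tested,
            "passes_filter": tested & (adj < alpha),
        }
    )
    return out.reset_index(drop=True)


def _collapse_dmr_genes(dmr_genes: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: the DMR with the largest |delta| represents it."""
    df = dmr_genes.copy()
    if "delta" in df.columns:
        df = df.iloc[np.argsort(-df["delta"].abs().to_numpy(), kind="mergesort")]
    return df.drop_duplicates("gene", keep="first")


def dmr_expression_concordance(
    dmr_genes: pd.DataFrame, de_results: pd.DataFrame
) -> ConcordanceResult:
    """Overlap and sign agreement between DMR genes and DE genes.

    ``dmr_genes`` needs columns ``gene`` and ``direction``
    (hypo/hyper), optionally ``delta`` to resolve genes with several
    DMRs.  Concordant: hypomethylated (in cases) gene up-regulated in
    cases, or hypermethylated gene down-regulated.
    """
    if dmr_genes.empty:
        raise ValueError("empty DMR-gene mapping")
    collapsed = _collapse_dmr_genes(dmr_genes)
    de = de_results[de_results["passes_filter"]]
    merged = collapsed.merge(de[["gene", "log_fc"]], on="gene", how="inner")
    merged = merged.sort_values("gene", kind="mergesort").reset_index(drop=True)
    up = merged["log_fc"].to_numpy() > 0
    hypo = merged["direction"].to_numpy() == "hypo"
    merged["concordant"] = (hypo & up) | (~hypo & ~up)

    n_dmr_genes = collapsed["gene"].nunique()
    n_overlap = len(merged)
    n_conc = int(merged["concordant"].sum())
    return ConcordanceResult(
        n_dmr_genes=n_dmr_genes,
        n_de_genes=int(de["gene"].nunique()),
        n_overlap=n_overlap,
        fraction=n_overlap / n_dmr_genes,
        per_gene=merged[["gene", "direction", "log_fc", "concordant"]],
        n_concordant=n_conc,
        concordant_fraction=(n_conc / n_overlap) if n_overlap else float("nan"),
    )


def replication_concordance(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    p_threshold: float = 0.05,
    require_significance: bool | None = None,
    drop_missing_from_denominator: bool = False,
) -> ConcordanceResult:
    """Direction agreement with a replication platform.

    ``discovery`` needs ``gene`` and ``direction``; ``replication``
    needs ``gene`` (or ``probe``) and a signed ``difference`` on the
    absolute methylation scale, optionally ``p_value``.  Probes are
    collapsed to genes by the largest |difference|.  A gene is
    concordant when its replication difference is nonzero, significant
    under the rule (unadjusted p < ``p_threshold`` whenever p-values
    are present, unless ``require_significance=False``) and
    sign-matched: discovery *hypo* (less methylation in cases) pairs
    with a negative replication difference.
    """
    disc = _collapse_dmr_genes(discovery)
    rep = replication.copy()
    if "gene" not in rep.columns and "probe" in rep.columns:
        raise ValueError("replication table needs a 'gene' column")
    rep = rep.iloc[np.argsort(-rep["difference"].abs().to_numpy(), kind="mergesort")]
    rep = rep.drop_duplicates("gene", keep="first")

    merged = disc.merge(rep, on="gene", how="left", indicator=True)
    missing = merged[merged["_merge"] == "left_only"]["gene"].tolist()
    if missing:
        logger.info("%d discovery genes absent from the replication table", len(missing))
    present = merged[merged["_merge"] == "both"].copy()

    has_p = "p_value" in rep.columns and present["p_value"].notna().any()
    if require_significance is None:
        require_significance = has_p
    diff = present["difference"].to_numpy(dtype=float)
    significant = np.ones(len(present), dtype=bool)
    if require_significance and has_p:
        significant = present["p_value"].to_numpy(dtype=float) < p_threshold
    disc_sign = np.where(present["direction"].to_numpy() == "hypo", -1.0, 1.0)
    concordant = (diff != 0) & significant & (np.sign(diff) == disc_sign)
    present["concordant"] = concordant

    denominator = len(present) if drop_missing_from_denominator else len(merged)
    n_conc = int(concordant.sum())
    return ConcordanceResult(
        n_dmr_genes=len(merged),
        n_de_genes=len(present),
        n_overlap=len(present),
        fraction=(len(present) / len(merged)) if len(merged) else float("nan"),
        per_gene=present[["gene", "direction", "difference", "concordant"]],
        n_concordant=n_conc,
        concordant_fraction=(n_conc / denominator) if denominator else float("nan"),
    )


def absolute_relative_correlation(
    absolute: pd.DataFrame,
    relative: pd.DataFrame | None = None,
    absolute_col: str = "absolute_pct",
    relative_col: str = "log2_ratio",
) -> tuple[float, pd.DataFrame]:
    """Pearson r of absolute methylation (%) vs relative log2 ratio.

    Accepts either one table holding both columns or two tables joined
    on ``locus``.  More methylation suppresses the HpaII channel, so
    the expected correlation is negative.  With fewer than 3 matched
    pairs an error is raised; a zero-variance side yields NaN
    (reported missing) with the pairing table still returned.
    """
    if relative is not None:
        paired = absolute.merge(relative, on="locus", how="inner")
    else:
        paired = absolute.copy()
    paired = paired[["locus", absolute_col, relative_col]].dropna()
    if len(paired) < 3:
        raise ValueError("need >= 3 matched pairs")
    a = paired[absolute_col].to_numpy(dtype=float)
    r = paired[relative_col].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(r) == 0:
        logger.warning("constant values: correlation undefined")
        return float("nan"), paired
    return float(sps.pearsonr(a, r).statistic), paired
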