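"""HELP two-channel array processing.

Turns probe-level HpaII/MspI intensities into a normalized, per-array
centered log2(HpaII/MspI) methylation matrix:

1. per-fragment, per-channel summarization as a robust (25% trimmed)
   mean of the component probe intensities;
2. a background threshold per array, set a configurable number of
   MADs above the median of the dedicated random-probe signals;
3. fragment status calls — *failed* (MspI at background: the fragment
   did not amplify), *methylated* (HpaII at background while MspI is
   real signal) or *amplifying*;
4. intra-array quantile normalization of the log2 ratios of
   amplifying fragments across sliding windows of fragment
   size-sorted data;
5. per-array centering, with entries labelled methylated (centered
   ratio < 0) or hypomethylated (> 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessingParams",
    "MethylationMatrix",
    "trimmed_mean",
    "summarize_fragment_signals",
    "background_threshold",
    "background_thresholds",
    "classify_fragment_status",
    "window_quantile_normalize",
    "build_methylation_matrix",
    "process_probes",
]

STATUSES = ("failed", "methylated", "amplifying")


@dataclass
class ProcessingParams:
    """Tunable knobs of the processing stage.

    ``robust_scale`` selects the absolute-deviation convention for the
    background threshold: ``"median"`` (median absolute deviation, the
    default) or ``"mean"`` (mean absolute deviation from the median).
    """

    trim_fraction: float = 0.25
    mad_multiplier: float = 2.5
    robust_scale: str = "median"
    window_size: int = 1000
    window_step: int | None = None  # default: half the window
    epsilon: float = 1e-6  # floor for intensities before log2
    max_failed_fraction: float = 0.5  # locus dropped if exceeded in either group

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be > 0")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.robust_scale not in ("median", "mean"):
            raise ValueError("robust_scale must be 'median' or 'mean'")


@dataclass
class MethylationMatrix:
    """Fragments x samples of centered log2(HpaII/MspI).

    ``values`` holds finite entries only for amplifying
    (fragment, sample) pairs; ``labels`` classifies each finite entry
    as ``methylated`` (centered ratio < 0) or ``hypomethylated``
    (> 0).  ``sizes`` is the fragment length in bp, ``groups`` maps
    sample id to clinical group, ``dropped_loci`` lists fragments
    removed because they failed in too many samples of one group.
    """

    values: pd.DataFrame
    sizes: pd.Series
    groups: pd.Series
    labels: pd.DataFrame
    dropped_loci: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# summarization
# ---------------------------------------------------------------------------

def trimmed_mean(values, trim_fraction: float = 0.25) -> float:
    """Robust mean: sort, drop ``floor(trim_fraction*n)`` from each end, average.

    Falls back to the median in the degenerate case where trimming
    would empty the set.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("trimmed_mean of empty set")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    cut = int(np.floor(trim_fraction * v.size))
    if 2 * cut >= v.size:
        return float(np.median(v))
    v = np.sort(v)
    return float(v[cut : v.size - cut].mean())


def summarize_fragment_signals(
    probes: pd.DataFrame, trim_fraction: float = 0.25
) -> pd.DataFrame:
    """Per (fragment, sample) trimmed-mean intensity of each channel.

    Expects the long probe table (columns ``probe_id, fragment_id,
    sample_id, group, channel, intensity``); random probes
    (``fragment_id == "RANDOM"``) are excluded.  Returns one row per
    (fragment, sample) with ``hpaii`` and ``mspi`` columns.
    """
    df = probes[probes["fragment_id"] != "RANDOM"]
    if df.empty:
        raise ValueError("no fragment probes to summarize")
    f_codes, f_idx = pd.factorize(df["fragment_id"], sort=False)
    s_codes, s_idx = pd.factorize(df["sample_id"], sort=False)
    c_codes, c_idx = pd.factorize(df["channel"], sort=False)
    n_s, n_c = len(s_idx), len(c_idx)
    group = (f_codes.astype(np.int64) * n_s + s_codes) * n_c + c_codes
    values = df["intensity"].to_numpy(dtype=float)

    n_groups = len(f_idx) * n_s * n_c
    counts = np.bincount(group, minlength=n_groups)
    if counts.min() == 0:
        raise ValueError("missing probe measurements for some (fragment, sample, channel)")

    order = np.lexsort((values, group))
    sorted_vals = values[order]
    uniq = np.unique(counts)
    if len(uniq) == 1:
        k = int(uniq[0])
        mat = sorted_vals.reshape(n_groups, k)  # each row sorted ascending
        cut = int(np.floor(trim_fraction * k))
        if 2 * cut >= k:
            summarized = np.median(mat, axis=1)
        else:
            summarized = mat[:, cut : k - cut].mean(axis=1)
    else:  # ragged probe counts: per-group python path
        offsets = np.concatenate(([0], np.cumsum(counts)))
        summarized = np.empty(n_groups)
        for g in range(n_groups):
            summarized[g] = trimmed_mean(
                sorted_vals[offsets[g] : offsets[g + 1]], trim_fraction
            )

    gi = np.arange(n_groups)
    out = pd.DataFrame(
        {
            "fragment_id": f_idx[gi // (n_s * n_c)],
            "sample_id": s_idx[(gi // n_c) % n_s],
            "channel": c_idx[gi % n_c],
            "intensity": summarized,
        }
    )
    wide = out.pivot_table(
        index=["fragment_id", "sample_id"], columns="channel", values="intensity",
        sort=False,
    ).reset_index()
    wide.columns.name = None
    wide = wide.rename(columns={"HpaII": "hpaii", "MspI": "mspi"})
    return wide[["fragment_id", "sample_id", "hpaii", "mspi"]]


# ---------------------------------------------------------------------------
# background threshold and status calls
# ---------------------------------------------------------------------------

def background_threshold(
    random_signals, mad_multiplier: float = 2.5, robust_scale: str = "median"
) -> float:
    """Background ceiling = median + multiplier * absolute-deviation scale.

    The scale is the median (default) or mean of absolute deviations
    from the median of the random-probe signals.
    """
    v = np.asarray(random_signals, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 random-probe signals")
    med = float(np.median(v))
    dev = np.abs(v - med)
    scale = float(np.median(dev)) if robust_scale == "median" else float(np.mean(dev))
    return med + mad_multiplier * scale


def background_thresholds(
    probes: pd.DataFrame, mad_multiplier: float = 2.5, robust_scale: str = "median"
) -> pd.Series:
    """Per-sample background threshold from that array's random probes.

    Both channels' random-probe signals are pooled: the random probes
    measure hybridization background, which is channel-agnostic.
    """
    rand = probes[probes["fragment_id"] == "RANDOM"]
    if rand.empty:
        raise ValueError("probe table has no random probes")
    return rand.groupby("sample_id")["intensity"].apply(
        lambda v: background_threshold(v, mad_multiplier, robust_scale)
    )


def classify_fragment_status(
    signals: pd.DataFrame, thresholds: Mapping[str, float] | float
) -> pd.DataFrame:
    """Call failed / methylated / amplifying per (fragment, sample).

    MspI at or below background means the fragment did not amplify
    (*failed*); otherwise HpaII at or below background means the locus
    is fully *methylated*; otherwise it is *amplifying* and usable as
    a continuous log-ratio.
    """
    if np.isscalar(thresholds):
        thr = np.full(len(signals), float(thresholds))
    else:
        thr = signals["sample_id"].map(pd.Series(thresholds)).to_numpy(dtype=float)
        if np.isnan(thr).any():
            raise ValueError("missing threshold for some samples")
    if (thr <= 0).any():
        raise ValueError("thresholds must be > 0")
    mspi = signals["mspi"].to_numpy(dtype=float)
    hpaii = signals["hpaii"].to_numpy(dtype=float)
    status = np.where(
        mspi <= thr, "failed", np.where(hpaii <= thr, "methylated", "amplifying")
    )
    out = signals[["fragment_id", "sample_id"]].copy()
    out["status"] = status
    return out


# ---------------------------------------------------------------------------
# intra-array sliding-window quantile normalization
# ---------------------------------------------------------------------------

def _window_starts(n: int, window_size: int, step: int) -> list[int]:
    if window_size >= n:
        return [0]
    starts = list(range(0, n - window_size + 1, step))
    if starts[-1] + window_size < n:
        starts.append(n - window_size)
    return starts


def window_quantile_normalize(
    ratios: pd.DataFrame,
    sizes: pd.Series,
    window_size: int = 1000,
    window_step: int | None = None,
) -> pd.DataFrame:
    """Align per-sample ratio distributions across size-sorted windows.

    Fragments are sorted by size; within each sliding window every
    sample's values are replaced by the across-sample mean of the
    order statistics at their (within-sample) rank, interpolating when
    samples contribute different numbers of finite values.  Fragments
    covered by several overlapping windows get the average of the
    window results.  Within-sample rank order is preserved inside each
    window; with a single sample the data are returned unchanged.
    """
    X = ratios.to_numpy(dtype=float).copy()
    n, n_samples = X.shape
    if n_samples <= 1 or n == 0:
        return ratios.copy()
    size_vals = sizes.reindex(ratios.index).to_numpy(dtype=float)
    if np.isnan(size_vals).any():
        raise ValueError("every fragment needs a size")
    order = np.argsort(size_vals, kind="mergesort")
    step = window_step if window_step is not None else max(1, window_size // 2)
    if window_size >= n:
        logger.info(
            "window_size %d >= %d fragments; degrading to a single window",
            window_size, n,
        )

    acc = np.zeros_like(X)
    cnt = np.zeros_like(X)
    for s in _window_starts(n, min(window_size, n), step):
        idx = order[s : s + window_size]
        W = X[idx, :]
        finite = np.isfinite(W)
        sorted_cols = [np.sort(W[finite[:, j], j]) for j in range(n_samples)]
        lens = np.array([len(a) for a in sorted_cols])
        if (lens == 0).all():
            continue
        for j in range(n_samples):
            nj = lens[j]
            if nj == 0:
                continue
            vals = W[finite[:, j], j]
            ranks = rankdata(vals, method="average")
            pos = (ranks - 1.0) / (nj - 1.0) if nj > 1 else np.full(len(ranks), 0.5)
            ref = np.zeros(len(ranks))
            used = 0
            for t in range(n_samples):
                nt = lens[t]
                if nt == 0:
                    continue
                if nt == 1:
                    ref += sorted_cols[t][0]
                else:
                    ref += np.interp(pos * (nt - 1), np.arange(nt), sorted_cols[t])
                used += 1
            ref /= used
            rows = idx[finite[:, j]]
            acc[rows, j] += ref
            cnt[rows, j] += 1.0

    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), X)
    return pd.DataFrame(out, index=ratios.index, columns=ratios.columns)


# ---------------------------------------------------------------------------
# methylation matrix
# ---------------------------------------------------------------------------

def _log_ratios(
    signals: pd.DataFrame, statuses: pd.DataFrame, epsilon: float
) -> pd.DataFrame:
    """Wide fragments x samples log2(HpaII/MspI); NaN where not amplifying."""
    merged = signals.merge(statuses, on=["fragment_id", "sample_id"], validate="1:1")
    h = np.maximum(merged["hpaii"].to_numpy(dtype=float), epsilon)
    m = np.maximum(merged["mspi"].to_numpy(dtype=float), epsilon)
    lr = np.log2(h / m)
    lr[merged["status"].to_numpy() != "amplifying"] = np.nan
    merged["log_ratio"] = lr
    wide = merged.pivot(index="fragment_id", columns="sample_id", values="log_ratio")
    # preserve first-appearance order of fragments and samples
    frag_order = pd.unique(signals["fragment_id"])
    samp_order = pd.unique(signals["sample_id"])
    return wide.reindex(index=frag_order, columns=samp_order)


def build_methylation_matrix(
    normalized: pd.DataFrame,
    statuses: pd.DataFrame,
    sizes: pd.Series,
    groups: pd.Series,
    max_failed_fraction: float = 0.5,
) -> MethylationMatrix:
    """Center per array and label entries by the sign of the ratio.

    Each column is centered to zero mean over its amplifying entries.
    Loci failed in more than ``max_failed_fraction`` of the samples of
    either group are dropped (and logged) before testing.
    """
    values = normalized.copy()
    # drop loci with too many failures in either clinical group
    failed = (
        statuses.assign(is_failed=statuses["status"] == "failed")
        .pivot(index="fragment_id", columns="sample_id", values="is_failed")
        .reindex(index=values.index, columns=values.columns)
        .fillna(False)
    )
    dropped: list[str] = []
    for grp in pd.unique(groups):
        cols = groups.index[groups == grp]
        frac = failed[cols].mean(axis=1)
        dropped.extend(values.index[frac > max_failed_fraction])
    dropped = sorted(set(dropped))
    if dropped:
        logger.info("dropping %d loci failed in >%.0f%% of samples of a group",
                    len(dropped), 100 * max_failed_fraction)
        values = values.drop(index=dropped)

    centered = values - values.mean(axis=0, skipna=True)
    labels = pd.DataFrame(
        np.where(
            centered.isna(), None,
            np.where(centered.to_numpy() < 0, "methylated", "hypomethylated"),
        ),
        index=centered.index,
        columns=centered.columns,
    )
    return MethylationMatrix(
        values=centered,
        sizes=sizes.reindex(centered.index),
        groups=groups,
        labels=labels,
        dropped_loci=dropped,
    )


def process_probes(
    probes: pd.DataFrame,
    fragments: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    params: ProcessingParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, MethylationMatrix]:
    """Full processing stage: probes -> (signals, statuses, matrix).

    ``fragments`` is the fragment map (``fragment_id, chrom, start,
    end, size``); ``groups`` maps sample_id to group (control/case).
    """
    params = params or ProcessingParams()
    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("sample_id")["group"]
    signals = summarize_fragment_signals(probes, params.trim_fraction)
    thresholds = background_thresholds(
        probes, params.mad_multiplier, params.robust_scale
    )
    statuses = classify_fragment_status(signals, thresholds)
    ratios = _log_ratios(signals, statuses, params.epsilon)
    sizes = fragments.set_index("fragment_id")["size"].reindex(ratios.index)
    normalized = window_quantile_normalize(
        ratios, sizes, params.window_size, params.window_step
    )
    matrix = build_methylation_matrix(
        normalized, statuses, sizes, groups, params.max_failed_fraction
    )
    return signals, statuses, matrix
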