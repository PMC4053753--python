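"""Genomic context of DMRs.

Three views of where differentially methylated fragments fall:

* RefSeq-style categories (promoter, 5'UTR, exon, intron, 3'UTR,
  transcription termination site, intergenic) with enrichment ratios
  against the composition of the whole array;
* chromatin-state overlap against a segmentation that partitions each
  chromosome, counting any overlap of at least 1 bp;
* DNase-hypersensitive-site enrichment via a permutation test whose
  null sets are random loci matched on count and mean fragment size.

All coordinates are 0-based half-open (BED convention); all inputs
must share one genome assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationParams",
    "DhsEnrichment",
    "CATEGORY_PRIORITY",
    "parse_gene_models",
    "nearest_genes",
    "assign_refseq_categories",
    "refseq_enrichment_ratios",
    "chromatin_state_overlap",
    "matched_random_loci",
    "count_overlapping",
    "dhs_enrichment_test",
]

#: Exclusive category priority: small regulatory categories first so
#: gene-body overlap never swallows them.
CATEGORY_PRIORITY = (
    "promoter",
    "five_prime_utr",
    "three_prime_utr",
    "tts",
    "exon",
    "intron",
    "intergenic",
)


@dataclass
class AnnotationParams:
    """Windows used by the RefSeq category assignment (bp).

    Promoter: strand-aware TSS −upstream/+downstream window.
    TTS: symmetric window around the transcription termination site.
    """

    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    tts_window: int = 500
    min_overlap: int = 1


@dataclass
class DhsEnrichment:
    observed: int
    null_counts: np.ndarray
    p_value: float
    n_permutations: int
    n_loci: int
    mean_size: int


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def parse_gene_models(genes: pd.DataFrame) -> pd.DataFrame:
    """Normalize a refFlat-style table: exon lists parsed, cds optional.

    Expects columns ``gene, chrom, strand, txStart, txEnd, exonStarts,
    exonEnds`` with comma-separated exon coordinates; ``cdsStart`` /
    ``cdsEnd`` are optional (absent or degenerate coding bounds
    collapse the UTR categories into exon).
    """
    out = genes.copy()

    def _parse(v):
        if isinstance(v, str):
            return [int(x) for x in v.rstrip(",").split(",") if x != ""]
        return list(v)

    out["exon_starts"] = out["exonStarts"].map(_parse)
    out["exon_ends"] = out["exonEnds"].map(_parse)
    for s, e, g in zip(out["exon_starts"], out["exon_ends"], out["gene"]):
        if len(s) != len(e) or any(b <= a for a, b in zip(s, e)):
            raise ValueError(f"malformed exons for gene {g}")
        if any(s2 < e1 for e1, s2 in zip(e, s[1:])):
            raise ValueError(f"overlapping exons for gene {g}")
    if "cdsStart" not in out.columns or "cdsEnd" not in out.columns:
        out["cdsStart"] = out["txStart"]
        out["cdsEnd"] = out["txStart"]  # degenerate -> non-coding
    out["tss"] = np.where(out["strand"] == "+", out["txStart"], out["txEnd"])
    out["tts"] = np.where(out["strand"] == "+", out["txEnd"], out["txStart"])
    return out


def _overlaps(a_start, a_end, b_start, b_end, min_overlap=1) -> bool:
    return min(a_end, b_end) - max(a_start, b_start) >= min_overlap


def _gene_flags(row, start: int, end: int, params: AnnotationParams) -> set[str]:
    """Which categories of one gene the interval [start, end) touches."""
    flags: set[str] = set()
    mo = params.min_overlap
    # promoter window, strand-aware
    if row.strand == "+":
        prom = (row.tss - params.promoter_upstream, row.tss + params.promoter_downstream)
    else:
        prom = (row.tss - params.promoter_downstream, row.tss + params.promoter_upstream)
    if _overlaps(start, end, prom[0], prom[1], mo):
        flags.add("promoter")
    if _overlaps(start, end, row.tts - params.tts_window, row.tts + params.tts_window, mo):
        flags.add("tts")

    coding = row.cdsStart < row.cdsEnd
    if row.strand == "+":
        utr5 = (row.txStart, row.cdsStart)
        utr3 = (row.cdsEnd, row.txEnd)
    else:
        utr5 = (row.cdsEnd, row.txEnd)
        utr3 = (row.txStart, row.cdsStart)

    in_exon = False
    for es, ee in zip(row.exon_starts, row.exon_ends):
        if not _overlaps(start, end, es, ee, mo):
            continue
        in_exon = True
        if coding:
            if _overlaps(max(start, es), min(end, ee), utr5[0], utr5[1], mo):
                flags.add("five_prime_utr")
            if _overlaps(max(start, es), min(end, ee), utr3[0], utr3[1], mo):
                flags.add("three_prime_utr")
    if in_exon:
        flags.add("exon")
    elif _overlaps(start, end, row.txStart, row.txEnd, mo):
        flags.add("intron")
    return flags


def nearest_genes(intervals: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene per interval: |midpoint − TSS| minimized.

    Ties go to the lexicographically smaller gene name.  Intervals on
    chromosomes without genes get a missing nearest gene.
    """
    gm = parse_gene_models(genes) if "tss" not in genes.columns else genes
    by_chrom = {c: g.sort_values("gene", kind="mergesort") for c, g in gm.groupby("chrom")}
    names, dists = [], []
    for iv in intervals.itertuples(index=False):
        chrom_genes = by_chrom.get(iv.chrom)
        if chrom_genes is None:
            names.append(None)
            dists.append(np.nan)
            continue
        mid = (iv.start + iv.end) / 2.0
        d = np.abs(mid - chrom_genes["tss"].to_numpy(dtype=float))
        j = int(np.argmin(d))  # genes name-sorted: first argmin = lexicographic tie-break
        names.append(chrom_genes["gene"].iat[j])
        dists.append(float(d[j]))
    out = intervals[["chrom", "start", "end"]].copy()
    out["nearest_gene"] = names
    out["tss_distance"] = dists
    return out


def assign_refseq_categories(
    intervals: pd.DataFrame,
    genes: pd.DataFrame,
    params: AnnotationParams | None = None,
) -> pd.DataFrame:
    """Exhaustive, exclusive category + nearest gene per interval.

    Category is the highest-priority one any gene supports; the
    nearest gene minimizes |interval midpoint − TSS| with ties broken
    by the lexicographically smaller gene name.
    """
    params = params or AnnotationParams()
    if genes.empty:
        raise ValueError("gene models must be non-empty")
    gm = parse_gene_models(genes) if "tss" not in genes.columns else genes
    reach = max(params.promoter_upstream, params.promoter_downstream, params.tts_window)

    nearest = nearest_genes(intervals, gm)
    by_chrom: dict[str, pd.DataFrame] = {
        c: g.sort_values("gene", kind="mergesort") for c, g in gm.groupby("chrom")
    }
    rows = []
    for pos, iv in enumerate(intervals.itertuples(index=False)):
        chrom_genes = by_chrom.get(iv.chrom)
        category = "intergenic"
        if chrom_genes is not None:
            near = chrom_genes[
                (chrom_genes["txStart"] - reach < iv.end)
                & (chrom_genes["txEnd"] + reach > iv.start)
            ]
            flags: set[str] = set()
            for g in near.itertuples(index=False):
                flags |= _gene_flags(g, iv.start, iv.end, params)
            for cat in CATEGORY_PRIORITY:
                if cat in flags:
                    category = cat
                    break
        name = getattr(iv, "name", None) or getattr(iv, "fragment_id", None)
        rows.append(
            (
                name, iv.chrom, iv.start, iv.end, category,
                nearest["nearest_gene"].iat[pos], nearest["tss_distance"].iat[pos],
            )
        )
    return pd.DataFrame(
        rows,
        columns=["name", "chrom", "start", "end", "category", "nearest_gene", "tss_distance"],
    )


def refseq_enrichment_ratios(
    dmr_categories: pd.Series, background_categories: pd.Series
) -> pd.DataFrame:
    """Observed vs array composition per category.

    ratio = (DMR fraction in category) / (array fraction in
    category); undefined (NaN, logged) when the array background
    lacks the category.
    """
    cats = list(CATEGORY_PRIORITY)
    n_dmr = len(dmr_categories)
    n_bg = len(background_categories)
    if n_dmr == 0 or n_bg == 0:
        raise ValueError("need non-empty category vectors")
    rows = []
    for cat in cats:
        obs = int((dmr_categories == cat).sum())
        bg = int((background_categories == cat).sum())
        obs_frac = obs / n_dmr
        bg_frac = bg / n_bg
        ratio = obs_frac / bg_frac if bg_frac > 0 else np.nan
        if bg_frac == 0 and obs:
            logger.warning("category %s absent from the array background", cat)
        rows.append((cat, obs, obs_frac, bg, bg_frac, ratio))
    return pd.DataFrame(
        rows,
        columns=[
            "category", "n_dmr", "dmr_fraction",
            "n_background", "background_fraction", "enrichment_ratio",
        ],
    )


# ---------------------------------------------------------------------------
# chromatin states
# ---------------------------------------------------------------------------

def chromatin_state_overlap(
    dmrs: pd.DataFrame, states: pd.DataFrame, min_overlap: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """State assignment of each DMR by >= ``min_overlap`` bp.

    DMRs spanning several segments are counted once per overlapped
    state (multi-assignments logged); the distribution is reported
    over assignments.  Returns (assignments, distribution).
    """
    by_chrom = {
        c: g.sort_values("start", kind="mergesort").reset_index(drop=True)
        for c, g in states.groupby("chrom")
    }
    rows = []
    unassigned = 0
    for iv in dmrs.itertuples(index=False):
        seg = by_chrom.get(iv.chrom)
        name = getattr(iv, "name", None) or getattr(iv, "fragment_id", None)
        hit_states: list[tuple[str, int]] = []
        if seg is not None:
            starts = seg["start"].to_numpy()
            ends = seg["end"].to_numpy()
            lo = int(np.searchsorted(ends, iv.start, side="right"))
            hi = int(np.searchsorted(starts, iv.end, side="left"))
            for k in range(lo, hi):
                bp = min(iv.end, ends[k]) - max(iv.start, starts[k])
                if bp >= min_overlap:
                    hit_states.append((seg["state"].iat[k], int(bp)))
        if not hit_states:
            unassigned += 1
        for state, bp in hit_states:
            rows.append((name, iv.chrom, iv.start, iv.end, state, bp))
    if unassigned:
        logger.warning("%d DMRs overlap no state segment (gaps?)", unassigned)
    assignments = pd.DataFrame(
        rows, columns=["name", "chrom", "start", "end", "state", "overlap_bp"]
    )
    multi = assignments["name"].duplicated().sum()
    if multi:
        logger.info("%d multi-state assignments", int(multi))
    if assignments.empty:
        distribution = pd.DataFrame(columns=["state", "n", "fraction"])
    else:
        distribution = (
            assignments.groupby("state").size().rename("n").reset_index()
        )
        distribution["fraction"] = distribution["n"] / distribution["n"].sum()
    return assignments, distribution


# ---------------------------------------------------------------------------
# matched random loci and DHS enrichment
# ---------------------------------------------------------------------------

def matched_random_loci(
    n: int,
    mean_size: int,
    genome: Mapping[str, int],
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """``n`` random loci of fixed size, chromosomes ~ length.

    Chromosomes shorter than ``mean_size`` are excluded (logged); each
    locus lies fully inside its chromosome.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if n < 0:
        raise ValueError("n must be >= 0")
    usable = {c: L for c, L in genome.items() if L >= mean_size}
    dropped = set(genome) - set(usable)
    if dropped:
        logger.warning("chromosomes shorter than %d bp excluded: %s",
                       mean_size, sorted(dropped))
    if n == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if not usable:
        raise ValueError("no chromosome can hold a locus of the requested size")
    chroms = sorted(usable)
    lengths = np.array([usable[c] for c in chroms], dtype=float)
    picks = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    starts = np.empty(n, dtype=np.int64)
    for i, c in enumerate(picks):
        starts[i] = rng.integers(0, usable[chroms[c]] - mean_size + 1)
    return pd.DataFrame(
        {
            "chrom": [chroms[c] for c in picks],
            "start": starts,
            "end": starts + int(mean_size),
        }
    )


def _merge_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, g in df.groupby("chrom"):
        s = g["start"].to_numpy(dtype=np.int64)
        e = g["end"].to_numpy(dtype=np.int64)
        order = np.argsort(s, kind="mergesort")
        s, e = s[order], e[order]
        ms, me = [s[0]], [e[0]]
        for a, b in zip(s[1:], e[1:]):
            if a <= me[-1]:
                me[-1] = max(me[-1], b)
            else:
                ms.append(a)
                me.append(b)
        merged[chrom] = (np.asarray(ms), np.asarray(me))
    return merged


def count_overlapping(
    query: pd.DataFrame, subject: pd.DataFrame, min_overlap: int = 1
) -> pd.Series:
    """Boolean per query interval: overlaps any subject by >= min_overlap bp.

    Subject intervals are merged per chromosome; a query [s, e)
    overlaps the merged set iff some merged interval has
    start <= e − min_overlap and end >= s + min_overlap.
    """
    if subject.empty or query.empty:
        return pd.Series(np.zeros(len(query), dtype=bool), index=query.index)
    merged = _merge_intervals(subject)
    out = np.zeros(len(query), dtype=bool)
    for chrom, g in query.groupby("chrom"):
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        qs = g["start"].to_numpy(dtype=np.int64)
        qe = g["end"].to_numpy(dtype=np.int64)
        if min_overlap == 1:
            # fast path: the last interval with ms < qe is the only one that
            # can end past qs (merged intervals are disjoint and sorted)
            j = np.searchsorted(ms, qe - 1, side="right") - 1
            ok = j >= 0
            hit = np.zeros(len(g), dtype=bool)
            hit[ok] = me[j[ok]] > qs[ok]
        else:
            hit = np.zeros(len(g), dtype=bool)
            lo = np.searchsorted(me, qs, side="right")
            hi = np.searchsorted(ms, qe, side="left")
            for i in range(len(g)):
                for k in range(lo[i], hi[i]):
                    if min(qe[i], me[k]) - max(qs[i], ms[k]) >= min_overlap:
                        hit[i] = True
                        break
        out[query.index.get_indexer(g.index)] = hit
    return pd.Series(out, index=query.index)


def dhs_enrichment_test(
    dmrs: pd.DataFrame,
    peaks: pd.DataFrame,
    genome: Mapping[str, int],
    n_permutations: int = 999,
    seed: int = 0,
    mean_size: int | None = None,
    min_overlap: int = 1,
) -> DhsEnrichment:
    """Permutation test of DMR/DHS overlap against matched random loci.

    Observed statistic: number of DMRs overlapping at least one peak
    by >= ``min_overlap`` bp.  Null: the same statistic on
    ``n_permutations`` random locus sets matched on count and mean
    fragment size.  Empirical p uses the add-one rule, so it is never
    0 and never exceeds 1.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = len(dmrs)
    if mean_size is None:
        mean_size = int(round((dmrs["end"] - dmrs["start"]).mean())) if n else 0
    observed = int(count_overlapping(dmrs, peaks, min_overlap).sum())
    rng = np.random.default_rng(int(seed))
    null_counts = np.empty(n_permutations, dtype=np.int64)
    for b in range(n_permutations):
        rand = matched_random_loci(n, mean_size, genome, rng)
        null_counts[b] = int(count_overlapping(rand, peaks, min_overlap).sum())
    p = (1.0 + (null_counts >= observed).sum()) / (n_permutations + 1.0)
    return DhsEnrichment(
        observed=observed,
        null_counts=null_counts,
        p_value=float(p),
        n_permutations=n_permutations,
        n_loci=n,
        mean_size=int(mean_size),
    )
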