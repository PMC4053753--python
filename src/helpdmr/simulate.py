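"""Synthetic HELP-assay data with known ground truth.

The generator emulates the observables of a two-channel HpaII/MspI
(HELP) methylation microarray experiment on case/control tissue:

* a map of HpaII-amplifiable fragments (HAFs), the unit locus of the
  assay — genomic intervals of 200–2,000 bp placed disjointly on a
  small synthetic genome;
* probe-level intensities for both channels (HpaII = methylation
  sensitive, MspI = insensitive reference), with multiplicative
  (log-normal) noise, a low-intensity background population measured
  by dedicated random probes, and a configurable fraction of "failed"
  fragments whose PCR did not amplify;
* a planted case/control difference in the per-fragment
  log2(HpaII/MspI) ratio at a chosen number of loci (the ground-truth
  DMRs), with a configurable hypo/hyper direction mix;
* annotation tracks (refFlat-style gene models, a 10-label
  chromatin-state segmentation partitioning each chromosome, DHS
  peaks with configurable preference for planted DMR loci);
* an expression matrix whose differential genes are sign-coupled to
  planted methylation changes, a per-gene replication
  methylation-difference table, and a paired absolute-vs-relative
  methylation table.

All randomness derives from one master seed; each output table uses
its own child stream so regenerating one table never perturbs another.
The same configuration always produces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimData",
    "SimulationError",
    "generate_fragment_map",
    "simulate_methylation_truth",
    "simulate_probe_intensities",
    "generate_annotation_tracks",
    "couple_genes_to_dmrs",
    "simulate_expression",
    "simulate_replication_table",
    "simulate_massarray_table",
    "simulate_dataset",
    "write_dataset",
]

#: 10 chromatin-state labels in the style of a ChromHMM segmentation.
STATE_LABELS = (
    "E1_TssActive",
    "E2_TssFlanking",
    "E3_Transcribed",
    "E4_WeakTranscribed",
    "E5_Enhancer",
    "E6_GenicEnhancer",
    "E7_ZnfRepeats",
    "E8_Heterochromatin",
    "E9_Bivalent",
    "E10_Quiescent",
)

# Child-stream indices of the master seed, one per output table.
_STREAMS = {
    "fragments": 1,
    "truth": 2,
    "probes": 3,
    "genes": 4,
    "states": 5,
    "dhs": 6,
    "coupling": 7,
    "expression": 8,
    "replication": 9,
    "massarray": 10,
}


class SimulationError(ValueError):
    """Raised when a configuration cannot be realized."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the discovery cohort being emulated: 26 samples
    (12 control vs 14 case), a majority-hypomethylated DMR mix (70%),
    fragment sizes averaging ~443 bp within the 200–2,000 bp HAF
    bounds, and a planted methylation effect of ~1.0 log2 units.
    """

    seed: int = 0
    # fragment map
    n_fragments: int = 10_000
    n_chroms: int = 2
    size_min: int = 200
    size_max: int = 2000
    size_scale: float = 245.0  # truncated-exponential scale -> mean size ~443 bp
    gap_mean: float = 600.0
    min_gap: int = 50
    genome_length: int | None = None  # per chromosome; derived when None
    n_random_probes: int = 500
    probes_per_fragment: int = 3
    # planted truth
    n_dmr: int = 500
    hypo_fraction: float = 0.7
    effect_mean: float = 1.0  # |delta| in log2 units
    effect_sd: float = 0.2
    failed_fraction: float = 0.02
    # groups and noise
    n_control: int = 12
    n_case: int = 14
    sample_sd: float = 0.5  # between-sample log2-ratio noise
    probe_sd: float = 0.2  # probe-level multiplicative noise, log2 units
    # methylation -> log-ratio link: E[log2(HpaII/MspI)] = baseline - slope * m
    baseline_log2: float = 2.0
    meth_slope: float = 4.0
    mspi_level: float = 1000.0  # mean MspI intensity, a.u.
    background_level: float = 50.0  # background median intensity, a.u.
    background_sd_log2: float = 0.5
    # annotation tracks
    gene_fraction: float = 0.5  # fraction of fragments covered by a gene model
    state_seg_mean: float = 2000.0
    state_seg_min: int = 500
    n_dhs: int = 300
    dhs_size_min: int = 150
    dhs_size_max: int = 500
    dhs_dmr_preference: float = 0.3
    # expression coupling
    coupled_fraction: float = 0.4  # DMR genes given an expression shift
    coupling_prob: float = 0.98  # probability the shift sign is concordant
    expr_effect: float = 1.5
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.0
    expr_noise_sd: float = 0.5
    # replication platform
    repl_concordance_prob: float = 0.98
    repl_effect: float = 5.0  # absolute methylation difference, percent
    repl_noise_sd: float = 1.0
    # absolute-methylation validation
    n_massarray_loci: int = 24

    def __post_init__(self) -> None:
        if self.seed < 0 or self.seed >= 2**31:
            raise SimulationError("seed must be in [0, 2^31)")
        for name in (
            "n_fragments", "n_chroms", "n_random_probes", "probes_per_fragment",
            "n_dmr", "n_control", "n_case", "n_dhs", "n_massarray_loci",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not 0.0 <= self.hypo_fraction <= 1.0:
            raise SimulationError("hypo_fraction must be in [0, 1]")
        if not 0.0 <= self.coupling_prob <= 1.0:
            raise SimulationError("coupling_prob must be in [0, 1]")
        if not (0 < self.size_min <= self.size_max):
            raise SimulationError("need 0 < size_min <= size_max")
        if self.n_dmr > self.n_fragments:
            raise SimulationError("n_dmr cannot exceed n_fragments")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for one named output table."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]])
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FragmentMap:
    """Disjoint, sorted HpaII-amplifiable fragments plus background probes."""

    fragments: pd.DataFrame  # fragment_id, chrom, start, end, size
    genome: pd.DataFrame  # chrom, length
    random_probe_ids: list[str]

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class SimTruth:
    """Planted ground truth of the synthetic experiment.

    ``fragments`` has one row per fragment: methylation fraction ``m``
    of the control group, the control mean log2(HpaII/MspI)
    ``control_mean``, the planted case shift ``delta`` (case − control,
    0 for null loci), ``direction`` in {hypo, hyper, null} and a
    ``failed`` flag.  ``coupled_genes`` maps DMR fragments to gene
    models with the sign of the coupled expression change; it is empty
    until :func:`couple_genes_to_dmrs` fills it.
    """

    fragments: pd.DataFrame
    coupled_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["fragment_id", "gene", "direction", "expr_sign"]
        )
    )


@dataclass
class AnnotationTracks:
    genes: pd.DataFrame  # refFlat-style
    states: pd.DataFrame  # chrom, start, end, state
    dhs: pd.DataFrame  # chrom, start, end, name


@dataclass
class SimData:
    """Everything one synthetic experiment produced."""

    config: SimConfig
    fragment_map: FragmentMap
    truth: SimTruth
    probes: pd.DataFrame
    tracks: AnnotationTracks
    groups: pd.DataFrame  # sample_id, group
    expression: pd.DataFrame  # genes x samples
    expression_truth: pd.DataFrame
    replication: pd.DataFrame
    massarray: pd.DataFrame


# ---------------------------------------------------------------------------
# fragment map
# ---------------------------------------------------------------------------

def _draw_sizes(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Fragment sizes: shifted exponential truncated to [size_min, size_max].

    With the default scale this gives a right-skewed distribution with
    mean ~443 bp, the average fragment size of the DMR set being
    emulated.
    """
    span = config.size_max - config.size_min
    if span == 0:
        return np.full(n, config.size_min)
    u = rng.random(n)
    # inverse CDF of Exp(scale) truncated at span
    scale = config.size_scale
    sizes = -scale * np.log1p(-u * (1.0 - np.exp(-span / scale)))
    return config.size_min + np.floor(sizes).astype(np.int64)


def generate_fragment_map(config: SimConfig) -> FragmentMap:
    """Place disjoint, sorted HAF intervals on a small synthetic genome.

    Fragments are laid out sequentially per chromosome with
    exponential gaps, which guarantees disjointness and sorted order.
    If ``genome_length`` is fixed and too small to hold the requested
    fragments, placement is retried a bounded number of times with
    fresh draws before failing.
    """
    rng = config.rng("fragments")
    per_chrom = np.full(config.n_chroms, config.n_fragments // max(config.n_chroms, 1))
    per_chrom[: config.n_fragments % max(config.n_chroms, 1)] += 1

    rows = []
    genome_rows = []
    frag_idx = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n = int(per_chrom[c])
        placed = None
        for _attempt in range(5):
            sizes = _draw_sizes(rng, n, config)
            gaps = config.min_gap + rng.exponential(config.gap_mean, n).astype(np.int64)
            starts = np.cumsum(gaps) + np.concatenate(([0], np.cumsum(sizes)[:-1]))
            ends = starts + sizes
            if config.genome_length is None or (n == 0) or ends[-1] + 100 <= config.genome_length:
                placed = (starts, ends)
                break
        if placed is None:
            raise SimulationError(
                f"could not place {n} fragments within genome_length="
                f"{config.genome_length} on {chrom}"
            )
        starts, ends = placed
        length = config.genome_length
        if length is None:
            length = int(ends[-1]) + 10_000 if n else 100_000
        genome_rows.append((chrom, int(length)))
        for s, e in zip(starts, ends):
            rows.append((f"HAF{frag_idx:06d}", chrom, int(s), int(e), int(e - s)))
            frag_idx += 1

    fragments = pd.DataFrame(
        rows, columns=["fragment_id", "chrom", "start", "end", "size"]
    )
    genome = pd.DataFrame(genome_rows, columns=["chrom", "length"])
    random_ids = [f"RAND{i:05d}" for i in range(config.n_random_probes)]
    return FragmentMap(fragments=fragments, genome=genome, random_probe_ids=random_ids)


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------

def simulate_methylation_truth(fragment_map: FragmentMap, config: SimConfig) -> SimTruth:
    """Plant DMRs: exactly ``n_dmr`` fragments get a nonzero case shift.

    Hypomethylation in cases means *less* methylation, hence a *higher*
    HpaII/MspI ratio: hypo direction corresponds to delta > 0 on the
    log2-ratio scale.  The hypo/hyper split equals ``hypo_fraction`` up
    to integer rounding.
    """
    if config.n_dmr > len(fragment_map):
        raise SimulationError("n_dmr exceeds number of fragments")
    rng = config.rng("truth")
    n = len(fragment_map)
    frag_ids = fragment_map.fragments["fragment_id"].to_numpy()

    m = rng.beta(2.0, 2.0, n)  # control methylation fraction per fragment
    control_mean = config.baseline_log2 - config.meth_slope * m

    delta = np.zeros(n)
    direction = np.full(n, "null", dtype=object)
    dmr_idx = rng.choice(n, size=config.n_dmr, replace=False)
    n_hypo = int(round(config.hypo_fraction * config.n_dmr))
    hypo_idx = dmr_idx[:n_hypo]
    hyper_idx = dmr_idx[n_hypo:]
    magnitudes = config.effect_mean + config.effect_sd * rng.standard_normal(config.n_dmr)
    magnitudes = np.abs(magnitudes)
    delta[hypo_idx] = magnitudes[:n_hypo]
    delta[hyper_idx] = -magnitudes[n_hypo:]
    direction[hypo_idx] = "hypo"
    direction[hyper_idx] = "hyper"

    failed = rng.random(n) < config.failed_fraction

    fragments = pd.DataFrame(
        {
            "fragment_id": frag_ids,
            "m": m,
            "control_mean": control_mean,
            "delta": delta,
            "direction": direction,
            "failed": failed,
        }
    )
    return SimTruth(fragments=fragments)


# ---------------------------------------------------------------------------
# probe intensities
# ---------------------------------------------------------------------------

def sample_ids(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: control then case samples, stable ids."""
    ids = [f"CTL{i + 1:02d}" for i in range(config.n_control)] + [
        f"CKD{i + 1:02d}" for i in range(config.n_case)
    ]
    groups = ["control"] * config.n_control + ["case"] * config.n_case
    return pd.DataFrame({"sample_id": ids, "group": groups})


def simulate_probe_intensities(
    truth: SimTruth, fragment_map: FragmentMap, config: SimConfig
) -> pd.DataFrame:
    """Long probe table: both channels for every probe of every sample.

    Non-failed fragments: MspI intensity is log-normal around
    ``mspi_level``; HpaII is MspI scaled by the fragment's per-sample
    log2 ratio (more methylation => lower HpaII).  Failed fragments and
    random probes draw *both* channels from the background
    distribution, mirroring loci that did not amplify by PCR.
    """
    tf = truth.fragments
    if not np.array_equal(
        tf["fragment_id"].to_numpy(), fragment_map.fragments["fragment_id"].to_numpy()
    ):
        raise SimulationError("truth and fragment map disagree on fragment ids")
    rng = config.rng("probes")
    samples = sample_ids(config)
    n_frag = len(tf)
    n_samp = len(samples)
    k = config.probes_per_fragment

    is_case = (samples["group"] == "case").to_numpy()
    # per-fragment, per-sample expected log2 ratio with biological noise
    lr = (
        tf["control_mean"].to_numpy()[:, None]
        + tf["delta"].to_numpy()[:, None] * is_case[None, :]
        + config.sample_sd * rng.standard_normal((n_frag, n_samp))
    )

    log2_mspi = np.log2(config.mspi_level)
    # probe-level log2 intensities, shape (n_frag, k, n_samp)
    noise_m = config.probe_sd * rng.standard_normal((n_frag, k, n_samp))
    noise_h = config.probe_sd * rng.standard_normal((n_frag, k, n_samp))
    mspi = 2.0 ** (log2_mspi + noise_m)
    hpaii = 2.0 ** (log2_mspi + lr[:, None, :] + noise_h)

    failed = tf["failed"].to_numpy()
    if failed.any():
        nf = int(failed.sum())
        bg_log2 = np.log2(config.background_level)
        mspi[failed] = 2.0 ** (
            bg_log2 + config.background_sd_log2 * rng.standard_normal((nf, k, n_samp))
        )
        hpaii[failed] = 2.0 ** (
            bg_log2 + config.background_sd_log2 * rng.standard_normal((nf, k, n_samp))
        )

    frag_ids = tf["fragment_id"].to_numpy()
    probe_ids = np.array(
        [f"{fid}_p{j}" for fid in frag_ids for j in range(k)], dtype=object
    )

    def _flatten(channel: str, arr: np.ndarray) -> pd.DataFrame:
        # (n_frag, k, n_samp) -> long rows ordered by fragment, probe, sample
        return pd.DataFrame(
            {
                "probe_id": np.repeat(probe_ids, n_samp),
                "fragment_id": np.repeat(frag_ids, k * n_samp),
                "sample_id": np.tile(samples["sample_id"].to_numpy(), n_frag * k),
                "group": np.tile(samples["group"].to_numpy(), n_frag * k),
                "channel": channel,
                "intensity": arr.reshape(-1),
            }
        )

    parts = [_flatten("HpaII", hpaii), _flatten("MspI", mspi)]

    # random (background) probes: both channels from the background
    n_rand = len(fragment_map.random_probe_ids)
    if n_rand:
        bg_log2 = np.log2(config.background_level)
        rand_ids = np.array(fragment_map.random_probe_ids, dtype=object)
        for channel in ("HpaII", "MspI"):
            vals = 2.0 ** (
                bg_log2
                + config.background_sd_log2 * rng.standard_normal((n_rand, n_samp))
            )
            parts.append(
                pd.DataFrame(
                    {
                        "probe_id": np.repeat(rand_ids, n_samp),
                        "fragment_id": "RANDOM",
                        "sample_id": np.tile(samples["sample_id"].to_numpy(), n_rand),
                        "group": np.tile(samples["group"].to_numpy(), n_rand),
                        "channel": channel,
                        "intensity": vals.reshape(-1),
                    }
                )
            )

    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------

def generate_annotation_tracks(
    fragment_map: FragmentMap, config: SimConfig, truth: SimTruth | None = None
) -> AnnotationTracks:
    """Gene models, a 10-state segmentation and DHS peaks.

    A ``gene_fraction`` subset of fragments each receive a covering
    gene model (refFlat-style, with exon and coding bounds).  State
    segments tile every chromosome with no gaps or overlaps.  DHS
    peaks are placed inside planted DMR fragments with probability
    ``dhs_dmr_preference`` (requires ``truth``), else uniformly.
    """
    frags = fragment_map.fragments
    genome = dict(zip(fragment_map.genome["chrom"], fragment_map.genome["length"]))

    # --- gene models -------------------------------------------------------
    rng = config.rng("genes")
    n_frag = len(frags)
    with_gene = rng.random(n_frag) < config.gene_fraction
    gene_rows = []
    for gi, (row, keep) in enumerate(zip(frags.itertuples(index=False), with_gene)):
        if not keep:
            continue
        chrom_len = genome[row.chrom]
        up = int(rng.integers(500, 5000))
        down = int(rng.integers(500, 5000))
        tx_start = max(0, row.start - up)
        tx_end = min(chrom_len, row.end + down)
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 6))
        if n_ex == 1:
            ex_starts, ex_ends = [tx_start], [tx_end]
        else:
            cuts = np.sort(rng.choice(
                np.arange(tx_start + 1, tx_end - 1), size=2 * (n_ex - 1), replace=False
            ))
            bounds = np.concatenate(([tx_start], cuts, [tx_end]))
            ex_starts = [int(bounds[2 * i]) for i in range(n_ex)]
            ex_ends = [int(bounds[2 * i + 1]) for i in range(n_ex)]
        margin = (tx_end - tx_start) // 10
        cds_start = tx_start + margin
        cds_end = tx_end - margin
        if cds_start >= cds_end:
            cds_start = cds_end = tx_start  # non-coding
        gene_rows.append(
            (
                f"GENE{gi:05d}",
                row.chrom,
                strand,
                int(tx_start),
                int(tx_end),
                ",".join(str(s) for s in ex_starts),
                ",".join(str(e) for e in ex_ends),
                int(cds_start),
                int(cds_end),
                row.fragment_id,  # provenance: the fragment this model covers
            )
        )
    genes = pd.DataFrame(
        gene_rows,
        columns=[
            "gene", "chrom", "strand", "txStart", "txEnd",
            "exonStarts", "exonEnds", "cdsStart", "cdsEnd", "fragment_id",
        ],
    )

    # --- chromatin-state segmentation -------------------------------------
    rng = config.rng("states")
    state_rows = []
    for chrom, length in genome.items():
        pos = 0
        while pos < length:
            seg = config.state_seg_min + int(rng.exponential(config.state_seg_mean))
            end = min(pos + seg, length)
            state = STATE_LABELS[int(rng.integers(0, len(STATE_LABELS)))]
            state_rows.append((chrom, pos, end, state))
            pos = end
    states = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "state"])

    # --- DHS peaks ---------------------------------------------------------
    rng = config.rng("dhs")
    dmr_frags = pd.DataFrame()
    if truth is not None:
        planted = truth.fragments.loc[truth.fragments["direction"] != "null", "fragment_id"]
        dmr_frags = frags[frags["fragment_id"].isin(planted)]
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    dhs_rows = []
    for i in range(config.n_dhs):
        size = int(rng.integers(config.dhs_size_min, config.dhs_size_max + 1))
        on_dmr = (
            len(dmr_frags) > 0
            and config.dhs_dmr_preference > 0
            and rng.random() < config.dhs_dmr_preference
        )
        if on_dmr:
            f = dmr_frags.iloc[int(rng.integers(0, len(dmr_frags)))]
            center = int(rng.integers(f["start"], f["end"]))
            chrom = f["chrom"]
        else:
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            center = int(rng.integers(0, genome[chrom]))
        start = max(0, center - size // 2)
        end = min(genome[chrom], start + size)
        dhs_rows.append((chrom, start, end, f"DHS{i:05d}"))
    dhs = pd.DataFrame(dhs_rows, columns=["chrom", "start", "end", "name"])
    dhs = dhs.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    return AnnotationTracks(genes=genes, states=states, dhs=dhs)


# ---------------------------------------------------------------------------
# methylation -> expression coupling
# ---------------------------------------------------------------------------

def _dmr_gene_map(
    truth: SimTruth, fragment_map: FragmentMap, tracks: AnnotationTracks
) -> pd.DataFrame:
    """Planted DMR fragments with their nearest gene (by TSS distance).

    Uses the same nearest-transcript rule the annotation stage
    applies, so the planted truth and the recovered mapping agree.
    """
    from . import annotate as _ann  # local import: annotate does not import simulate

    dmr = truth.fragments[truth.fragments["direction"] != "null"]
    merged = dmr.merge(
        fragment_map.fragments[["fragment_id", "chrom", "start", "end"]],
        on="fragment_id",
    )
    near = _ann.nearest_genes(
        merged[["chrom", "start", "end"]], tracks.genes
    )
    merged = merged.assign(gene=near["nearest_gene"].to_numpy())
    return merged.dropna(subset=["gene"])


def couple_genes_to_dmrs(
    truth: SimTruth,
    fragment_map: FragmentMap,
    tracks: AnnotationTracks,
    config: SimConfig,
) -> SimTruth:
    """Couple a fraction of DMR genes to expression changes.

    DMR fragments map to their nearest gene (TSS distance, the same
    rule the annotation stage uses).  Convention: hypomethylation in
    cases (delta > 0) paired with up-regulation in cases is the
    *concordant* coupling; the planted sign is concordant with
    probability ``coupling_prob``.
    """
    rng = config.rng("coupling")
    tf = truth.fragments
    if len(tracks.genes) == 0 or (tf["direction"] == "null").all():
        return SimTruth(fragments=tf, coupled_genes=truth.coupled_genes)
    merged = _dmr_gene_map(truth, fragment_map, tracks)
    merged = merged.drop_duplicates("gene", keep="first")
    keep = rng.random(len(merged)) < config.coupled_fraction
    merged = merged[keep]
    dir_sign = np.where(merged["direction"].to_numpy() == "hypo", 1, -1)
    concordant = rng.random(len(merged)) < config.coupling_prob
    expr_sign = np.where(concordant, dir_sign, -dir_sign)
    coupled = pd.DataFrame(
        {
            "fragment_id": merged["fragment_id"].to_numpy(),
            "gene": merged["gene"].to_numpy(),
            "direction": merged["direction"].to_numpy(),
            "expr_sign": expr_sign,
        }
    )
    return SimTruth(fragments=tf, coupled_genes=coupled.reset_index(drop=True))


def simulate_expression(
    truth: SimTruth, genes: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples) and its truth table.

    Coupled genes receive a case shift of ``expr_effect`` with the
    planted sign; every other gene is null.
    """
    rng = config.rng("expression")
    samples = sample_ids(config)
    gene_names = genes["gene"].to_numpy()
    n_g, n_s = len(gene_names), len(samples)
    is_case = (samples["group"] == "case").to_numpy()

    baseline = config.expr_baseline_mean + config.expr_baseline_sd * rng.standard_normal(n_g)
    shift = np.zeros(n_g)
    if len(truth.coupled_genes):
        coupled = truth.coupled_genes.set_index("gene")["expr_sign"]
        idx = pd.Index(gene_names).get_indexer(coupled.index)
        ok = idx >= 0
        if not ok.all():
            raise SimulationError("coupled gene missing from gene models")
        shift[idx[ok]] = config.expr_effect * coupled.to_numpy()[ok]

    values = (
        baseline[:, None]
        + shift[:, None] * is_case[None, :]
        + config.expr_noise_sd * rng.standard_normal((n_g, n_s))
    )
    expr = pd.DataFrame(values, index=pd.Index(gene_names, name="gene"),
                        columns=samples["sample_id"].to_numpy())
    expr_truth = pd.DataFrame(
        {"gene": gene_names, "expr_shift": shift, "is_de": shift != 0}
    )
    return expr, expr_truth


# ---------------------------------------------------------------------------
# replication and absolute-methylation tables
# ---------------------------------------------------------------------------

def simulate_replication_table(
    truth: SimTruth,
    fragment_map: FragmentMap,
    tracks: AnnotationTracks,
    config: SimConfig,
) -> pd.DataFrame:
    """Per-gene signed methylation differences on a replication platform.

    Emulates a bisulfite-array validation cohort restricted to the
    genes mapped from the planted DMRs (nearest-TSS rule): each gets
    an absolute (percent) case−control methylation difference whose
    sign matches the discovery direction with probability
    ``repl_concordance_prob`` (hypo => negative absolute difference),
    plus a small p-value.
    """
    rng = config.rng("replication")
    merged = _dmr_gene_map(truth, fragment_map, tracks).drop_duplicates("gene", keep="first")
    if merged.empty:
        return pd.DataFrame(columns=["gene", "difference", "p_value"])
    # discovery hypo (less methylation in cases) => negative absolute difference
    disc_sign = np.where(merged["direction"].to_numpy() == "hypo", -1.0, 1.0)
    concord = rng.random(len(merged)) < config.repl_concordance_prob
    sign = np.where(concord, disc_sign, -disc_sign)
    magnitude = np.abs(
        config.repl_effect + config.repl_noise_sd * rng.standard_normal(len(merged))
    )
    p = 10.0 ** (-rng.uniform(2.0, 6.0, len(merged)))
    return pd.DataFrame(
        {
            "gene": merged["gene"].to_numpy(),
            "difference": sign * magnitude,
            "p_value": p,
        }
    )


def simulate_massarray_table(
    truth: SimTruth, config: SimConfig
) -> pd.DataFrame:
    """Paired absolute (%) vs relative (log2 ratio) methylation table.

    Absolute methylation is the planted fraction with measurement
    noise; the relative value is the control-group log2(HpaII/MspI)
    with array noise, so the pairing is strongly negatively correlated
    by construction (more methylation => lower HpaII/MspI).
    """
    rng = config.rng("massarray")
    tf = truth.fragments[~truth.fragments["failed"]]
    n = min(config.n_massarray_loci, len(tf))
    take = tf.iloc[rng.choice(len(tf), size=n, replace=False)]
    absolute = np.clip(100.0 * take["m"].to_numpy() + 3.0 * rng.standard_normal(n), 0, 100)
    relative = take["control_mean"].to_numpy() + 0.15 * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "locus": take["fragment_id"].to_numpy(),
            "absolute_pct": absolute,
            "log2_ratio": relative,
        }
    )


# ---------------------------------------------------------------------------
# orchestration of the generator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimData:
    """Run every generator stage in order and bundle the outputs."""
    fragment_map = generate_fragment_map(config)
    truth = simulate_methylation_truth(fragment_map, config)
    tracks = generate_annotation_tracks(fragment_map, config, truth=truth)
    truth = couple_genes_to_dmrs(truth, fragment_map, tracks, config)
    probes = simulate_probe_intensities(truth, fragment_map, config)
    expression, expr_truth = simulate_expression(truth, tracks.genes, config)
    replication = simulate_replication_table(truth, fragment_map, tracks, config)
    massarray = simulate_massarray_table(truth, config)
    return SimData(
        config=config,
        fragment_map=fragment_map,
        truth=truth,
        probes=probes,
        tracks=tracks,
        groups=sample_ids(config),
        expression=expression,
        expression_truth=expr_truth,
        replication=replication,
        massarray=massarray,
    )


def write_dataset(data: SimData, out_dir: str | Path) -> dict[str, Path]:
    """Write every table to ``out_dir``; returns name -> path.

    Output is deterministic: the same :class:`SimConfig` produces
    byte-identical files.  Probe intensities are written with 6
    significant digits (arbitrary units); truth tables keep full float
    precision so they round-trip losslessly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _tsv(name: str, df: pd.DataFrame, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
        paths[name.split(".")[0]] = path

    _tsv("probes.tsv", data.probes, float_format="%.6g")
    _tsv(
        "fragments.bed",
        data.fragment_map.fragments[["chrom", "start", "end", "fragment_id"]],
        header=False,
    )
    _tsv("genome.tsv", data.fragment_map.genome)
    _tsv("groups.tsv", data.groups)
    _tsv("truth_fragments.tsv", data.truth.fragments)
    _tsv("truth_coupling.tsv", data.truth.coupled_genes)
    _tsv("genes.tsv", data.tracks.genes)
    _tsv("states.bed", data.tracks.states, header=False)
    _tsv("dhs.bed", data.tracks.dhs, header=False)
    _tsv("expression.tsv", data.expression, index=True, float_format="%.6g")
    _tsv("expression_truth.tsv", data.expression_truth)
    _tsv("replication.tsv", data.replication)
    _tsv("massarray.tsv", data.massarray)
    return paths
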