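import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import helpdmr as h

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> h.SimConfig:
    """A modest synthetic experiment shared by the unit tests."""
    return h.SimConfig(seed=11, n_fragments=400, n_dmr=40, n_random_probes=200)


@pytest.fixture(scope="session")
def small_data(small_config):
    return h.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_processed(small_data):
    """(signals, statuses, matrix) for the small dataset."""
    return h.process_probes(
        small_data.probes,
        small_data.fragment_map.fragments,
        small_data.groups,
        h.ProcessingParams(window_size=150),
    )


@pytest.fixture()
def toy_genes() -> pd.DataFrame:
    """Two genes on chr1: a 3-exon coding '+' gene and a 1-exon '-' gene."""
    return pd.DataFrame(
        {
            "gene": ["GA", "GB"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "txStart": [10_000, 40_000],
            "txEnd": [20_000, 45_000],
            "exonStarts": ["10000,13000,18000", "40000"],
            "exonEnds": ["11000,14000,20000", "45000"],
            "cdsStart": [10_500, 41_000],
            "cdsEnd": [19_000, 44_000],
        }
    )


def brute_force_pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Independent closed-form pooled two-sample t (b minus a)."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * tdist.sf(abs(t), n1 + n2 - 2)
    return float(t), float(p)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Textbook step-up adjustment, independent of statsmodels."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def brute_force_overlap(query: pd.DataFrame, subject: pd.DataFrame, min_overlap=1):
    """O(n*m) all-pairs interval intersection scan."""
    hits = []
    for q in query.itertuples(index=False):
        hit = False
        for s in subject.itertuples(index=False):
            if q.chrom != s.chrom:
                continue
            if min(q.end, s.end) - max(q.start, s.start) >= min_overlap:
                hit = True
                break
        hits.append(hit)
    return np.array(hits)
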