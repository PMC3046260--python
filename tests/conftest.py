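import numpy as np
import pytest
from scipy import stats as sps

from anchorprobe import (
    build_mappings,
    generate_expression_fixture,
    generate_transcript_fixture,
    load_anchor_gene_table,
    map_probes,
)


@pytest.fixture(scope="session")
def anchor_table():
    return load_anchor_gene_table()


@pytest.fixture(scope="session")
def expr_fixture():
    """Default planted-anchor expression fixture (seed 1)."""
    return generate_expression_fixture(seed=1)


@pytest.fixture(scope="session")
def noiseless_expr_fixture():
    return generate_expression_fixture(noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def tx_fixture():
    """Default transcript fixture with 5 planted probesets (seed 1)."""
    return generate_transcript_fixture(seed=1)


@pytest.fixture(scope="session")
def tx_mappings(tx_fixture):
    transcripts, probes, truth = tx_fixture
    hits = map_probes(probes, transcripts)
    return build_mappings(hits, truth.probeset_size)


# ---------------------------------------------------------------------------
# Independent oracles, coded straight from the textbook formulas and kept
# free of any package internals.

def welch_oracle(groups):
    """Welch heteroscedastic one-way ANOVA from the weighted-means formula."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    w = n / v
    grand = np.sum(w * m) / np.sum(w)
    lam = np.sum((1.0 - w / w.sum()) ** 2 / (n - 1.0))
    F = (np.sum(w * (m - grand) ** 2) / (k - 1.0)) / (
        1.0 + 2.0 * (k - 2.0) / (k**2 - 1.0) * lam
    )
    df1 = k - 1.0
    df2 = (k**2 - 1.0) / (3.0 * lam)
    return F, df1, df2, float(sps.f.sf(F, df1, df2))


def bh_oracle(pvals):
    """Step-up adjusted p-values q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(n)
    out[order] = q_sorted
    return out
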