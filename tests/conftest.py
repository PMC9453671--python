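import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly import CommunityTable


@pytest.fixture
def tiny_table():
    """3 taxa x 2 samples, counts [[1,2],[0,3],[5,0]]."""
    counts = pd.DataFrame(
        [[1, 2], [0, 3], [5, 0]], index=["A", "B", "C"], columns=["s1", "s2"]
    )
    return CommunityTable(counts, pd.Series({"s1": "g1", "s2": "g2"}))


@pytest.fixture
def small_tree():
    """((A:1,B:1):1,C:2); — D(A,B)=2, D(A,C)=D(B,C)=4."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


def planted_two_block_corr(n_taxa, n_samples, rho_within, seed):
    """Spearman matrix of two equal blocks of factor-correlated Gaussian
    latents (within-block correlation ``rho_within``, between-block 0 up
    to sampling noise) — the planted fixture for RMT threshold scans."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    half = n_taxa // 2
    x = np.empty((n_taxa, n_samples))
    for lo, hi in ((0, half), (half, n_taxa)):
        f = rng.normal(0, 1, n_samples)
        x[lo:hi] = np.sqrt(rho_within) * f + np.sqrt(1 - rho_within) * rng.normal(
            0, 1, (hi - lo, n_samples)
        )
    r = stats.spearmanr(x, axis=1).statistic
    np.fill_diagonal(r, 1.0)
    ids = [f"t{i}" for i in range(n_taxa)]
    labels = pd.Series([0] * half + [1] * (n_taxa - half), index=ids)
    return pd.DataFrame(r, index=ids, columns=ids), labels


def random_table(rng, n_taxa=20, n_samples=8, groups=None, depth=1000):
    """Random multinomial count table with optional group labels."""
    p = rng.dirichlet(np.ones(n_taxa))
    counts = np.column_stack([rng.multinomial(depth, p) for _ in range(n_samples)])
    samples = [f"s{i + 1}" for i in range(n_samples)]
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    if groups is None:
        groups = {s: "all" for s in samples}
    else:
        groups = {s: groups[i] for i, s in enumerate(samples)}
    return CommunityTable(
        pd.DataFrame(counts, index=taxa, columns=samples), pd.Series(groups)
    )
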