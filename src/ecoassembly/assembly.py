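"""Null-model quantification of community assembly processes.

For every pair of samples two standardized null-model statistics are
computed:

* **βNTI** — the standardized effect size of the (abundance-weighted) beta
  mean nearest taxon distance βMNTD against a null distribution generated
  by shuffling taxon labels across the tips of the phylogeny.  |βNTI| > 2
  marks deterministic (selection-driven) phylogenetic turnover:
  βNTI > 2 heterogeneous selection, βNTI < -2 homogeneous selection.
* **RCbray** — the Raup-Crick metric on Bray-Curtis dissimilarity: the
  rescaled percentile of the observed dissimilarity within a distribution
  of null communities assembled probabilistically from the regional
  species pool.  Given |βNTI| <= 2, RCbray > 0.95 marks dispersal
  limitation, RCbray < -0.95 homogenizing dispersal, and |RCbray| < 0.95
  drift (no single dominant process).

The fraction of sample pairs with |βNTI| < 2 is reported as the
*stochastic contribution rate* of a group.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from skbio import TreeNode

from .io import CommunityTable, ValidationError, cophenetic_matrix

__all__ = [
    "beta_mntd",
    "beta_nti",
    "rc_bray",
    "classify_assembly",
    "stochastic_contribution",
    "assembly_analysis",
    "summarize_assembly",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


def beta_mntd(
    abund_k, abund_m, dist: "pd.DataFrame | np.ndarray", weighted: bool = True
) -> float:
    """Beta mean nearest taxon distance between two communities.

    βMNTD = 0.5 * [ Σ_{i∈k} f_ik min_{j∈m} D_ij + Σ_{j∈m} f_jm min_{i∈k} D_ij ]

    where f are relative abundances when ``weighted`` (the default) or
    uniform 1/S otherwise, and the minima run over taxa present in the
    other community.
    """
    x = np.asarray(abund_k, dtype=float)
    y = np.asarray(abund_m, dtype=float)
    d = np.asarray(dist, dtype=float)
    pk, pm = x > 0, y > 0
    if not pk.any() or not pm.any():
        raise ValidationError("both samples must contain at least one taxon")
    sub = d[np.ix_(pk, pm)]
    min_k = sub.min(axis=1)  # nearest taxon in m for each taxon in k
    min_m = sub.min(axis=0)
    if weighted:
        fk = x[pk] / x[pk].sum()
        fm = y[pm] / y[pm].sum()
    else:
        fk = np.full(pk.sum(), 1.0 / pk.sum())
        fm = np.full(pm.sum(), 1.0 / pm.sum())
    return float(0.5 * (fk @ min_k + fm @ min_m))


def _beta_mntd_all_pairs(
    counts: np.ndarray, d: np.ndarray, pairs: list[tuple[int, int]], weighted: bool
) -> np.ndarray:
    """βMNTD for a list of sample-index pairs on one distance matrix."""
    return np.array(
        [beta_mntd(counts[:, i], counts[:, j], d, weighted) for i, j in pairs]
    )


def beta_nti(
    table: CommunityTable,
    tree: TreeNode | pd.DataFrame,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """βNTI for sample pairs of a table.

    The null randomizes taxon placement on the phylogeny: each replicate
    permutes the rows/columns of the cophenetic distance matrix (equivalent
    to shuffling tip labels across the whole tree, i.e. regional-pool
    randomization).  Each replicate's permutation is shared by all pairs,
    so results do not depend on pair evaluation order.

    Returns a DataFrame with columns sample_i, sample_j, beta_mntd,
    beta_nti.  A degenerate null (sd = 0) yields βNTI = 0 with a warning.
    """
    if n_null < 99:
        raise ValidationError(f"n_null must be >= 99, got {n_null}")
    dist = tree if isinstance(tree, pd.DataFrame) else cophenetic_matrix(tree)
    missing = [t for t in table.taxon_ids if t not in dist.index]
    if missing:
        raise ValidationError(f"taxa missing from tree/distances: {missing[:10]}")
    d = dist.loc[table.taxon_ids, table.taxon_ids].values
    counts = table.counts.values
    sample_ids = table.sample_ids
    if pairs is None:
        pairs = list(itertools.combinations(sample_ids, 2))
    index = {s: i for i, s in enumerate(sample_ids)}
    idx_pairs = [(index[a], index[b]) for a, b in pairs]

    obs = _beta_mntd_all_pairs(counts, d, idx_pairs, weighted)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6E74]))
    nulls = np.empty((n_null, len(idx_pairs)))
    n_taxa = counts.shape[0]
    for r in range(n_null):
        perm = rng.permutation(n_taxa)
        nulls[r] = _beta_mntd_all_pairs(counts, d[np.ix_(perm, perm)], idx_pairs, weighted)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    nti = np.zeros(len(idx_pairs))
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"degenerate null (sd=0) for {int(degenerate.sum())} pair(s); βNTI set to 0",
            stacklevel=2,
        )
    ok = ~degenerate
    nti[ok] = (obs[ok] - mean[ok]) / sd[ok]
    return pd.DataFrame(
        {
            "sample_i": [a for a, _ in pairs],
            "sample_j": [b for _, b in pairs],
            "beta_mntd": obs,
            "beta_nti": nti,
        }
    )


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis


def _null_community(
    rng: np.random.Generator,
    richness: int,
    depth: float,
    occ_prob: np.ndarray,
    abund_prob: np.ndarray,
) -> np.ndarray:
    """One null assembly: draw ``richness`` taxa from the pool weighted by
    occurrence frequency, then allocate ``depth`` individuals across them
    weighted by pool-wide relative abundance."""
    n_pool = len(occ_prob)
    chosen = rng.choice(n_pool, size=richness, replace=False, p=occ_prob)
    w = abund_prob[chosen]
    out = np.zeros(n_pool)
    out[chosen] = rng.multinomial(int(depth), w / w.sum())
    return out


def rc_bray(
    table: CommunityTable,
    pair: tuple[str, str],
    n_null: int = 999,
    seed: int = 0,
) -> float:
    """RCbray for one sample pair against a probabilistic regional-pool null.

    Null communities preserve each sample's observed richness and total
    abundance; taxa are drawn with probability proportional to their
    occurrence frequency across samples and filled with probability
    proportional to their pool-wide relative abundance.  With B_obs the
    observed Bray-Curtis and B_null the null draws,

        RCbray = 2 * ( [#(B_null < B_obs) + 0.5 #(B_null = B_obs)] / n_null - 0.5 )

    so RCbray ∈ [-1, 1].  Ties are counted with weight 0.5.  The RNG is
    seeded per pair from (seed, i, j) so results are independent of the
    order in which pairs are evaluated.
    """
    if n_null < 99:
        raise ValidationError(f"n_null must be >= 99, got {n_null}")
    counts = table.counts
    sa, sb = pair
    x, y = counts[sa].values, counts[sb].values
    occ = (counts.values > 0).sum(axis=1).astype(float)
    if occ.sum() == 0:
        raise ValidationError("empty table")
    occ_prob = occ / occ.sum()
    pool_abund = counts.values.sum(axis=1).astype(float)
    abund_prob = pool_abund / pool_abund.sum()
    rich_x, rich_y = int((x > 0).sum()), int((y > 0).sum())
    n_pool = int((occ > 0).sum())
    if rich_x > n_pool or rich_y > n_pool:
        raise ValidationError("sample richness exceeds regional pool size")

    ia, ib = table.sample_ids.index(sa), table.sample_ids.index(sb)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7263, ia, ib]))
    obs = braycurtis(x, y)
    below = ties = 0
    for _ in range(n_null):
        nx_ = _null_community(rng, rich_x, x.sum(), occ_prob, abund_prob)
        ny_ = _null_community(rng, rich_y, y.sum(), occ_prob, abund_prob)
        b = braycurtis(nx_, ny_)
        if b < obs - 1e-12:
            below += 1
        elif abs(b - obs) <= 1e-12:
            ties += 1
    rc_raw = (below + 0.5 * ties) / n_null
    return float(2 * (rc_raw - 0.5))


# ---------------------------------------------------------------------------
# classification and summaries


def classify_assembly(beta_nti_value: float, rc_bray_value: float) -> str:
    """Assign the assembly process for one sample pair.

    βNTI > 2: heterogeneous selection; βNTI < -2: homogeneous selection;
    otherwise (stochastic side, |βNTI| <= 2) by RCbray: > 0.95 dispersal
    limitation, < -0.95 homogenizing dispersal, else drift.  Boundary
    |βNTI| = 2 falls on the stochastic side.
    """
    if not -1 - 1e-9 <= rc_bray_value <= 1 + 1e-9:
        raise ValidationError(f"RCbray must be in [-1, 1], got {rc_bray_value}")
    if beta_nti_value > 2:
        return "heterogeneous_selection"
    if beta_nti_value < -2:
        return "homogeneous_selection"
    if rc_bray_value > 0.95:
        return "dispersal_limitation"
    if rc_bray_value < -0.95:
        return "homogenizing_dispersal"
    return "drift"


def stochastic_contribution(beta_nti_values) -> float:
    """Percent of pairs with |βNTI| < 2, to 2 decimals."""
    v = np.asarray(beta_nti_values, dtype=float)
    if v.size == 0:
        raise ValidationError("no pairs")
    return round(100.0 * float((np.abs(v) < 2).sum()) / v.size, 2)


def assembly_analysis(
    table: CommunityTable,
    tree: TreeNode | pd.DataFrame,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
    within_groups: bool = True,
) -> pd.DataFrame:
    """Per-pair βNTI, RCbray and assembly process.

    By default pairs are formed within groups only (e.g. the C(8,2) = 28
    pairs of an 8-replicate group), matching how per-group process
    fractions are reported; ``within_groups=False`` uses all pairs.
    """
    if within_groups:
        pairs, pair_group = [], []
        for g in dict.fromkeys(table.groups):
            samples = table.samples_in_group(g)
            for a, b in itertools.combinations(samples, 2):
                pairs.append((a, b))
                pair_group.append(g)
    else:
        pairs = list(itertools.combinations(table.sample_ids, 2))
        pair_group = [
            table.groups[a] if table.groups[a] == table.groups[b] else "between"
            for a, b in pairs
        ]
    nti = beta_nti(table, tree, n_null=n_null, seed=seed, weighted=weighted, pairs=pairs)
    rc = [rc_bray(table, p, n_null=n_null, seed=seed) for p in pairs]
    nti["group"] = pair_group
    nti["rc_bray"] = rc
    nti["process"] = [
        classify_assembly(b, r) for b, r in zip(nti["beta_nti"], nti["rc_bray"])
    ]
    return nti[["sample_i", "sample_j", "group", "beta_mntd", "beta_nti", "rc_bray", "process"]]


def summarize_assembly(results: pd.DataFrame) -> pd.DataFrame:
    """Per-group pair counts, process counts and stochastic contribution."""
    rows = {}
    for g, sub in results.groupby("group", sort=False):
        row = {"n_pairs": len(sub)}
        for p in PROCESSES:
            row[p] = int((sub["process"] == p).sum())
        row["stochastic_contribution"] = stochastic_contribution(sub["beta_nti"].values)
        rows[g] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out
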