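"""Alpha and beta diversity with group statistics.

Alpha diversity: observed richness (Sobs), Shannon entropy (nats by
default) and Faith's phylogenetic diversity (rooted).  Group contrasts use
one-way ANOVA followed by Fisher's LSD with a compact letter display, and
percent change versus a control group.  Beta diversity: Bray-Curtis
dissimilarity, principal coordinates analysis, and per-taxon
Kruskal-Wallis contrasts with significance stars.
"""

from __future__ import annotations

import itertools
import math
import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .io import CommunityTable, ValidationError

__all__ = [
    "sobs",
    "shannon",
    "faith_pd",
    "alpha_diversity_table",
    "percent_change",
    "group_compare",
    "bray_curtis",
    "pcoa",
    "kruskal_wallis_by_taxon",
]


def sobs(abundances) -> int:
    """Observed richness: number of taxa with abundance strictly > 0."""
    a = np.asarray(abundances, dtype=float)
    return int(np.count_nonzero(a > 0))


def shannon(abundances, base: float = math.e) -> float:
    """Shannon diversity H = -sum p_i log p_i over taxa with p_i > 0.

    Natural log by default (H in nats); pass ``base=2`` for bits.
    """
    a = np.asarray(abundances, dtype=float)
    if a.sum() <= 0:
        raise ValidationError("shannon undefined for an all-zero sample")
    p = a[a > 0] / a.sum()
    h = float(-(p * np.log(p)).sum())
    if base != math.e:
        h /= math.log(base)
    # clip the tiny negative that rounding can give for a single-taxon sample
    return max(h, 0.0)


def faith_pd(abundances, taxon_ids: list[str], tree: TreeNode) -> float:
    """Faith's phylogenetic diversity of the taxa present in a sample.

    Total branch length of the minimal subtree connecting the observed tips
    and the root (rooted PD, the convention of the mainstream
    implementations).  Computed as the union of root-to-tip edge sets, so
    multifurcating trees are handled directly.
    """
    a = np.asarray(abundances, dtype=float)
    present = {t for t, x in zip(taxon_ids, a) if x > 0}
    if not present:
        return 0.0
    tip_nodes = {t.name: t for t in tree.tips()}
    missing = [t for t in present if t not in tip_nodes]
    if missing:
        raise ValidationError(f"taxa not in tree: {sorted(missing)[:10]}")
    visited: set[int] = set()
    total = 0.0
    for name in present:
        node = tip_nodes[name]
        while node.parent is not None and id(node) not in visited:
            visited.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return float(total)


def alpha_diversity_table(table: CommunityTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample Sobs, Shannon and (if a tree is given) Faith PD."""
    rows = {}
    for s in table.sample_ids:
        v = table.counts[s].values
        row = {"group": table.groups[s], "sobs": sobs(v), "shannon": shannon(v)}
        if tree is not None:
            row["faith_pd"] = faith_pd(v, table.taxon_ids, tree)
        rows[s] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def percent_change(treatment_mean: float, control_mean: float) -> float:
    """100 * (treatment - control) / control, rounded half-up to 2 decimals."""
    if control_mean == 0:
        raise ValidationError("percent change undefined: control mean is 0")
    raw = 100.0 * (float(treatment_mean) - float(control_mean)) / float(control_mean)
    return float(Decimal(repr(raw)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# ANOVA + LSD compact letter display


def _lsd_pvalues(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Fisher's LSD p-values using the pooled ANOVA error term."""
    groups = list(values_by_group)
    ns = {g: len(values_by_group[g]) for g in groups}
    df_err = sum(ns.values()) - len(groups)
    mse = (
        sum((len(v) - 1) * np.var(v, ddof=1) for v in values_by_group.values()) / df_err
    )
    p = pd.DataFrame(1.0, index=groups, columns=groups)
    for g1, g2 in itertools.combinations(groups, 2):
        m1, m2 = np.mean(values_by_group[g1]), np.mean(values_by_group[g2])
        if mse == 0:
            pval = 1.0 if m1 == m2 else 0.0
        else:
            se = math.sqrt(mse * (1 / ns[g1] + 1 / ns[g2]))
            t = (m1 - m2) / se
            pval = 2 * stats.t.sf(abs(t), df_err)
        p.loc[g1, g2] = p.loc[g2, g1] = pval
    return p


def compact_letters(pvalues: pd.DataFrame, order: list[str], alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Guarantees: two groups share a letter iff their pairwise p-value is
    >= ``alpha``.  ``order`` fixes letter assignment (usually by descending
    mean, so 'a' marks the top group).
    """
    letter_sets: list[set[str]] = [set(order)]
    for g1, g2 in itertools.combinations(order, 2):
        if pvalues.loc[g1, g2] >= alpha:
            continue
        for s in list(letter_sets):
            if g1 in s and g2 in s:
                letter_sets.remove(s)
                for new in (s - {g1}, s - {g2}):
                    # absorb: only keep if not a subset of an existing set
                    if not any(new <= other for other in letter_sets):
                        letter_sets = [o for o in letter_sets if not o <= new]
                        letter_sets.append(new)
    # deterministic ordering of letters: by first member in `order`
    def set_key(s):
        return [order.index(g) for g in sorted(s, key=order.index)]

    letter_sets.sort(key=set_key)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for letter, s in zip(alphabet, letter_sets):
        for g in order:
            if g in s:
                letters[g] += letter
    return letters


def group_compare(
    values_by_group: dict[str, "np.ndarray | list[float]"], alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA with Fisher's LSD post hoc and a compact letter display.

    Returns one row per group: n, mean, standard error and letters, plus
    the global ANOVA F and p as DataFrame attrs.  Groups sharing a letter
    are not significantly different at ``alpha``.
    """
    if len(values_by_group) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValidationError(f"group {g!r} has < 2 values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant inputs warn inside f_oneway
        f_stat, p_global = stats.f_oneway(*arrays.values())
    if not np.isfinite(f_stat):  # all groups constant and equal
        f_stat, p_global = 0.0, 1.0
    order = sorted(arrays, key=lambda g: -np.mean(arrays[g]))
    letters = compact_letters(_lsd_pvalues(arrays), order, alpha)
    out = pd.DataFrame(
        {
            "n": {g: len(v) for g, v in arrays.items()},
            "mean": {g: float(np.mean(v)) for g, v in arrays.items()},
            "se": {g: float(stats.sem(v)) for g, v in arrays.items()},
            "letters": letters,
        }
    )
    out.index.name = "group"
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(p_global)
    return out


def format_group_summary(summary: pd.DataFrame, decimals: int = 2) -> pd.Series:
    """Render rows as ``mean ± se letters`` strings."""
    return pd.Series(
        {
            g: f"{row['mean']:.{decimals}f} ± {row['se']:.{decimals}f}{row['letters']}"
            for g, row in summary.iterrows()
        },
        name="summary",
    )


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(table: CommunityTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC(x, y) = 1 - 2 sum_i min(x_i, y_i) / sum_i (x_i + y_i).
    """
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero sample(s): {zero}")
    d = squareform(pdist(table.counts.values.T, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def pcoa(distances: pd.DataFrame) -> dict:
    """Principal coordinates analysis (classical MDS) of a distance matrix.

    Eigen-decomposes the Gower-centered matrix -D^2/2.  Axes are ordered by
    eigenvalue; explained proportions are eigenvalue / sum of *positive*
    eigenvalues, and axes with non-positive eigenvalues are dropped (no
    Lingoes/Cailliez correction).

    Returns a dict with ``coordinates`` (samples x axes DataFrame),
    ``eigenvalues`` and ``proportion_explained``.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be square and symmetric")
    ids = list(distances.index) if isinstance(distances, pd.DataFrame) else list(range(len(d)))
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh(g)
    idx = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]
    pos = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    denom = eigvals[pos].sum()
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(pos.sum())]
    return {
        "coordinates": pd.DataFrame(coords, index=ids, columns=axes),
        "eigenvalues": pd.Series(eigvals, index=[f"PC{i + 1}" for i in range(n)]),
        "proportion_explained": pd.Series(eigvals[pos] / denom, index=axes),
    }


# ---------------------------------------------------------------------------
# per-taxon group contrasts


def significance_stars(p: float) -> str:
    """Star annotation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _exact_kruskal_p(samples: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p-value for small samples: enumerate all ways the
    pooled values can be split into groups of the observed sizes."""
    pooled = np.concatenate(samples)
    sizes = [len(s) for s in samples]
    n = len(pooled)
    p_count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        groups, start = [], 0
        for k in sizes:
            groups.append(pooled[list(perm[start : start + k])])
            start += k
        h = _kruskal_h(groups)
        total += 1
        if h >= h_obs - 1e-12:
            p_count += 1
    return p_count / total


def _kruskal_h(samples: list[np.ndarray]) -> float:
    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    start, h = 0, 0.0
    for s in samples:
        r = ranks[start : start + len(s)]
        h += r.sum() ** 2 / len(s)
        start += len(s)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    # midrank tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis_by_taxon(
    table: CommunityTable,
    adjust: bool = False,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis H test across sample groups.

    Ranks use midranks with the tie correction.  ``method='exact'``
    enumerates all group assignments (feasible only for tiny samples).
    ``adjust=True`` adds Benjamini-Hochberg adjusted p-values; by default
    unadjusted p-values are starred, as is conventional for per-taxon
    relative-abundance panels.
    """
    group_labels = sorted(set(table.groups))
    if len(group_labels) < 2:
        raise ValidationError("need >= 2 groups")
    rows = {}
    for taxon in table.taxon_ids:
        v = table.counts.loc[taxon]
        samples = [
            v[[s for s in table.sample_ids if table.groups[s] == g]].values
            for g in group_labels
        ]
        if all((s == 0).all() for s in samples):
            warnings.warn(f"taxon {taxon!r} absent in all samples; skipped", stacklevel=2)
            continue
        if all(len(np.unique(np.concatenate(samples))) == 1 for _ in [0]):
            h, p = 0.0, 1.0
        elif method == "exact":
            h = _kruskal_h(samples)
            p = _exact_kruskal_p(samples, h)
        else:
            h, p = stats.kruskal(*samples)
        rows[taxon] = {"H": float(h), "p": float(p)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "taxon"
    if adjust:
        out["p_adj"] = _benjamini_hochberg(out["p"].values)
        out["stars"] = out["p_adj"].map(significance_stars)
    else:
        out["stars"] = out["p"].map(significance_stars)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
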