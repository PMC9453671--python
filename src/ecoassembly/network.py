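"""Random-matrix-theory co-occurrence networks and topological roles.

The chain mirrors molecular-ecological-network analysis (MENA): Spearman
correlations between log-transformed taxon abundances; a similarity
threshold chosen where the nearest-neighbor spacing distribution (NNSD) of
the thresholded matrix's unfolded eigenvalues transitions from
Wigner-Dyson (GOE, correlated noise) to Poisson statistics; an undirected
signed graph above the threshold; modularity-based module detection;
per-node within-module degree z-score (Zi) and among-module connectivity
(Pi) with the standard role thresholds Zi = 2.5 and Pi = 0.62.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .io import CommunityTable, ValidationError

__all__ = [
    "spearman_matrix",
    "nnsd_poisson_test",
    "rmt_threshold_scan",
    "ThresholdScanResult",
    "build_network",
    "topology_metrics",
    "zi_pi",
    "classify_role",
    "export_network",
]

#: Zi/Pi role thresholds from the topological-role literature.
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


def spearman_matrix(table: CommunityTable, transform: str = "log10p1") -> pd.DataFrame:
    """Pairwise Spearman correlation between taxa across samples.

    Abundances are log10(x + 1)-transformed by default (the pseudocount
    handles zeros; ranks, hence rho, are unchanged by the monotone
    transform but the transformed matrix is what the network stage and its
    exports operate on).  Ties use midranks.  Taxa constant across samples
    have undefined rho; their correlations are set to 0 with a warning.
    """
    if table.n_samples < 4:
        raise ValidationError("need >= 4 samples for correlations")
    if transform == "log10p1":
        x = np.log10(table.counts.values + 1.0)
    elif transform == "none":
        x = table.counts.values.astype(float)
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    constant = np.array([len(np.unique(row)) == 1 for row in x])
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa: correlations set to 0", stacklevel=2
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        r = float(rho) if np.isfinite(rho) else 0.0
        rho = np.array([[1.0, r], [r, 1.0]])
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=table.taxon_ids, columns=table.taxon_ids)


# ---------------------------------------------------------------------------
# NNSD / RMT thresholding


def _unfold(eigenvalues: np.ndarray, n_knots: int = 15) -> np.ndarray:
    """Unfold a spectrum: map eigenvalues through a smooth monotone fit of
    the cumulative spectral density so the mean spacing becomes 1.

    Duplicate eigenvalues (within 1e-8 relative tolerance) are collapsed
    first, as is standard before NNSD analysis of sparse matrices.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    scale = max(abs(ev[0]), abs(ev[-1]), 1.0)
    keep = np.concatenate([[True], np.diff(ev) > 1e-8 * scale])
    ev = ev[keep]
    n = len(ev)
    if n < 3:
        raise ValidationError("too few distinct eigenvalues to unfold")
    cdf = (np.arange(1, n + 1) - 0.5) / n
    k = min(n_knots, max(3, n // 5))
    knot_idx = np.unique(np.linspace(0, n - 1, k).round().astype(int))
    # PCHIP through a coarse subsample keeps the fit monotone and smooth
    fit = PchipInterpolator(ev[knot_idx], cdf[knot_idx], extrapolate=True)
    return n * fit(ev)


def nnsd_poisson_test(eigenvalues, n_bins: int = 20, n_knots: int = 15) -> float:
    """Chi-square goodness-of-fit p-value of the unfolded NNSD against the
    Poisson form P(s) = exp(-s).

    A high p (>= 0.05) means the spacings are consistent with independent
    (Poisson) statistics — the RMT signature of modular, non-random
    structure; a low p on a dense correlation matrix indicates GOE-like
    level repulsion.  Bins are equal-probability under Exp(1) so expected
    counts are uniform.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if len(ev) < 50:
        raise ValidationError(f"need >= 50 eigenvalues, got {len(ev)}")
    unfolded = _unfold(ev, n_knots=n_knots)
    s = np.diff(unfolded)
    s = s[s >= 0]
    if len(s) < 20:
        raise ValidationError("too few spacings after unfolding")
    s = s / s.mean()
    # equal-probability bin edges of Exp(1)
    qs = np.arange(1, n_bins) / n_bins
    edges = np.concatenate([[0.0], -np.log1p(-qs), [np.inf]])
    observed, _ = np.histogram(s, bins=edges)
    expected = np.full(n_bins, len(s) / n_bins)
    stat = ((observed - expected) ** 2 / expected).sum()
    # dof: n_bins - 1, minus 1 for the fitted mean (spacings normalized)
    return float(stats.chi2.sf(stat, n_bins - 2))


@dataclass
class ThresholdScanResult:
    """Outcome of an RMT threshold scan."""

    thresholds: np.ndarray
    p_values: np.ndarray  # NaN where the matrix was too small/degenerate to test
    chosen: float
    fallback: bool
    #: smallest scanned threshold with a Poisson-consistent, stable NNSD
    scan_table: pd.DataFrame = field(repr=False, default=None)


def rmt_threshold_scan(
    corr: pd.DataFrame,
    t_min: float = 0.30,
    t_max: float = 0.95,
    step: float = 0.01,
    alpha: float = 0.05,
    fallback: float = 0.6,
    min_eigenvalues: int = 50,
) -> ThresholdScanResult:
    """Scan correlation thresholds for the GOE -> Poisson NNSD transition.

    For each candidate t, entries with \\|rho\\| < t are zeroed (taxa left
    with no connections are dropped) and the NNSD of the remaining
    matrix's eigenvalues is tested against Poisson.  The chosen threshold
    is the smallest t whose fit is Poisson-consistent (p >= alpha) *and*
    remains so at the next step — one step of stability guards against
    isolated p-value spikes.  If no t qualifies the stated ``fallback``
    is returned with ``fallback=True``.
    """
    if not 0 < t_min < t_max <= 1:
        raise ValidationError(f"need 0 < t_min < t_max <= 1, got {t_min}, {t_max}")
    if corr.shape[0] < 2:
        raise ValidationError("empty correlation matrix")
    r = corr.values.copy()
    thresholds = np.round(np.arange(t_min, t_max + step / 2, step), 10)
    pvals = np.full(len(thresholds), np.nan)
    for i, t in enumerate(thresholds):
        m = np.where(np.abs(r) >= t, r, 0.0)
        np.fill_diagonal(m, 0.0)
        connected = (m != 0).any(axis=0)
        m = m[np.ix_(connected, connected)]
        if m.shape[0] < min_eigenvalues:
            continue
        np.fill_diagonal(m, 1.0)
        try:
            pvals[i] = nnsd_poisson_test(np.linalg.eigvalsh(m))
        except ValidationError:
            continue
    chosen, is_fallback = fallback, True
    for i in range(len(thresholds) - 1):
        if pvals[i] >= alpha and pvals[i + 1] >= alpha:
            chosen, is_fallback = float(thresholds[i]), False
            break
    if is_fallback:
        warnings.warn(
            f"no Poisson-consistent threshold found; falling back to {fallback}",
            stacklevel=2,
        )
    table = pd.DataFrame({"threshold": thresholds, "nnsd_p": pvals})
    return ThresholdScanResult(thresholds, pvals, chosen, is_fallback, table)


# ---------------------------------------------------------------------------
# graph construction and topology


def build_network(
    corr: pd.DataFrame,
    threshold: float,
    detect_modules: bool = True,
) -> nx.Graph:
    """Undirected signed graph with edges where \\|rho\\| >= threshold.

    Edge attributes: ``rho`` and ``sign`` ('+' or '-').  Isolated taxa are
    dropped.  Modules are assigned by greedy modularity maximization
    (deterministic agglomeration, ties broken by node order) and stored as
    the node attribute ``module``.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    r = corr.values
    ids = list(corr.index)
    g = nx.Graph()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(r[i, j]) >= threshold:
                g.add_edge(
                    ids[i],
                    ids[j],
                    rho=float(r[i, j]),
                    sign="+" if r[i, j] > 0 else "-",
                    weight=abs(float(r[i, j])),
                )
    if g.number_of_edges() == 0:
        raise ValidationError(f"empty network at threshold {threshold}")
    if detect_modules:
        communities = greedy_modularity_communities(g, weight=None)
        for module_id, members in enumerate(communities):
            for node in members:
                g.nodes[node]["module"] = module_id
    return g


def _modules(g: nx.Graph) -> dict[int, set]:
    out: dict[int, set] = {}
    for node, data in g.nodes(data=True):
        if "module" not in data:
            raise ValidationError(f"node {node!r} has no module assignment")
        out.setdefault(data["module"], set()).add(node)
    return out


def topology_metrics(g: nx.Graph) -> dict[str, float]:
    """avgCC, APD, GD and modularity M of the graph's stored partition.

    avgCC: mean local clustering coefficient; APD: mean shortest-path
    length over connected pairs (per component when disconnected, with a
    warning); GD: 2E / (N(N-1)); M: Newman modularity Q.
    """
    if g.number_of_nodes() < 2 or g.number_of_edges() < 1:
        raise ValidationError("need >= 2 nodes and >= 1 edge")
    avgcc = nx.average_clustering(g)
    gd = nx.density(g)
    if nx.is_connected(g):
        apd = nx.average_shortest_path_length(g)
    else:
        warnings.warn("graph disconnected; APD averaged over within-component pairs",
                      stacklevel=2)
        tot, n_pairs = 0.0, 0
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            k = sub.number_of_nodes()
            if k < 2:
                continue
            tot += nx.average_shortest_path_length(sub) * k * (k - 1) / 2
            n_pairs += k * (k - 1) // 2
        apd = tot / n_pairs
    q = nx.community.modularity(g, _modules(g).values(), weight=None)
    return {"avgCC": float(avgcc), "APD": float(apd), "GD": float(gd), "M": float(q)}


def zi_pi(g: nx.Graph) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and among-module connectivity (Pi).

    Zi = (κ_i - mean κ of i's module) / sd κ of i's module with κ the
    within-module degree (sd via population formula, 0-variance or
    singleton modules give Zi = 0).  Pi = 1 - Σ_s (k_is / k_i)^2 over
    modules s.  Role per :func:`classify_role`.
    """
    modules = _modules(g)
    within_degree = {}
    for mod, members in modules.items():
        sub = g.subgraph(members)
        for node in members:
            within_degree[node] = sub.degree(node)
    rows = {}
    for node in g.nodes:
        if g.degree(node) == 0:
            raise ValidationError(f"isolated node {node!r}")
        mod = g.nodes[node]["module"]
        kappa = np.array([within_degree[m] for m in modules[mod]], dtype=float)
        sd = kappa.std()
        zi = 0.0 if sd == 0 else (within_degree[node] - kappa.mean()) / sd
        k_i = g.degree(node)
        per_module: dict[int, int] = {}
        for nbr in g.neighbors(node):
            m = g.nodes[nbr]["module"]
            per_module[m] = per_module.get(m, 0) + 1
        pi = 1.0 - sum((k / k_i) ** 2 for k in per_module.values())
        rows[node] = {
            "module": mod,
            "degree": k_i,
            "Zi": float(zi),
            "Pi": float(pi),
            "role": classify_role(zi, pi),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "node"
    return out


def classify_role(zi: float, pi: float) -> str:
    """Four-way topological role from the Zi-Pi plane.

    peripherals (Zi < 2.5, Pi < 0.62); module hubs (Zi > 2.5, Pi < 0.62);
    connectors (Zi < 2.5, Pi > 0.62); network hubs (Zi > 2.5, Pi > 0.62).
    Boundary equality counts as the low side (non-hub / non-connector).
    """
    hub = zi > ZI_THRESHOLD
    connector = pi > PI_THRESHOLD
    if hub and connector:
        return "network_hub"
    if hub:
        return "module_hub"
    if connector:
        return "connector"
    return "peripheral"


def export_network(
    g: nx.Graph, path: str, format: str = "graphml", roles: pd.DataFrame | None = None
) -> None:
    """Write the network for external visualization (e.g. Gephi).

    ``graphml``: full graph with node attributes (module, Zi, Pi, role,
    degree, any annotations present) and edge attributes sign/rho.
    ``edge_list``: CSV with source, target, sign, rho.
    """
    if g.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    if format == "graphml":
        out = g.copy()
        if roles is not None:
            for node in out.nodes:
                for col in ("Zi", "Pi", "role", "degree"):
                    if node in roles.index:
                        val = roles.loc[node, col]
                        out.nodes[node][col] = (
                            float(val) if isinstance(val, (int, float, np.floating)) else str(val)
                        )
        nx.write_graphml(out, path)
    elif format == "edge_list":
        rows = [
            {"source": u, "target": v, "sign": d["sign"], "rho": d["rho"]}
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown format {format!r}")
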