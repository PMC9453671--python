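"""Ground-truth community simulators.

Generates phylogenies, group-structured ASV tables under known assembly
regimes, and module-structured correlated counts so that every pipeline
stage can be tested against a known generating process:

* ``selection`` — taxon niche optima evolve along the phylogeny by a
  mean-reverting (Ornstein-Uhlenbeck) walk, giving tunable phylogenetic
  niche conservatism; expected abundance in a sample follows a Gaussian
  niche response to the group's environment.  Groups with contrasting
  environments therefore experience heterogeneous selection.
* ``neutral`` — every sample is a multinomial draw from a single shared
  log-normal metacommunity: dispersal and drift only.
* ``dispersal_limited`` — each group draws from its own accessible subset
  of the metacommunity, with pool overlap controlled by a dispersal
  probability; within groups, sampling is neutral.
* module-structured counts — latent per-module factors induce block
  correlation for testing network inference.

Every generator is a pure function of its scenario and seed (bit
reproducible), and every simulated sample's counts sum exactly to the
sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import CommunityTable, ValidationError

__all__ = [
    "SimulationScenario",
    "simulate_tree",
    "evolve_optima",
    "simulate_selection_communities",
    "simulate_neutral_communities",
    "simulate_dispersal_limited",
    "simulate_module_network_counts",
    "default_group_labels",
]

#: study-style design: 5 vegetation groups x 8 replicate plots
DEFAULT_GROUPS = ("CK", "BL", "CF", "BF", "MF")


def default_group_labels(n_groups: int) -> tuple[str, ...]:
    if n_groups == len(DEFAULT_GROUPS):
        return DEFAULT_GROUPS
    return tuple(f"G{i + 1}" for i in range(n_groups))


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one synthetic assembly regime.

    selection_strength is the inverse squared niche width: expected
    abundance of taxon i in group g is proportional to
    exp(-(env_g - optimum_i)^2 * selection_strength).  Optima are on the
    scale of the environment axis (stationary sd 1), so strength 2
    (niche width 0.5) makes one environment unit strongly selective.
    niche_conservatism_rate is the OU mean-reversion rate per unit branch
    length: smaller = stronger phylogenetic signal in the optima.
    """

    regime: str = "neutral"  # selection | neutral | dispersal_limited
    n_taxa: int = 200
    n_samples: int = 8  # per group
    n_groups: int = 5
    selection_strength: float = 2.0
    env_values: tuple[float, ...] | None = None  # default: linspace(-2, 2)
    niche_conservatism_rate: float = 0.1
    dispersal: float = 1.0
    depth: int = 20_000
    metacommunity_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("selection", "neutral", "dispersal_limited"):
            raise ValidationError(f"unknown regime {self.regime!r}")
        if self.n_taxa < 2 or self.n_samples < 1 or self.n_groups < 1:
            raise ValidationError("n_taxa, n_samples, n_groups must be positive")
        if self.depth <= 0:
            raise ValidationError("sequencing depth must be positive")
        if not 0 <= self.dispersal <= 1:
            raise ValidationError(f"dispersal must be in [0,1], got {self.dispersal}")

    @property
    def envs(self) -> np.ndarray:
        if self.env_values is not None:
            e = np.asarray(self.env_values, dtype=float)
            if len(e) != self.n_groups or not np.isfinite(e).all():
                raise ValidationError("env_values must be finite, one per group")
            return e
        if self.n_groups == 1:
            return np.zeros(1)
        return np.linspace(-2.0, 2.0, self.n_groups)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# phylogeny


def simulate_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Ultrametric pure-birth (Yule) tree with tips t1..tN.

    Waiting times between speciations are exponential with rate equal to
    the current lineage count (unit speciation rate); tips are extended to
    the present, so the tree is ultrametric and cophenetic distances are
    triangle-compatible.
    """
    if n_taxa < 2:
        raise ValidationError(f"need n_taxa >= 2, got {n_taxa}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x74726565]))
    root = TreeNode()
    left, right = TreeNode(), TreeNode()
    root.extend([left, right])
    active = [(left, 0.0), (right, 0.0)]  # (node, birth time)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.length = t - birth
        children = (TreeNode(), TreeNode())
        node.extend(list(children))
        active.extend((c, t) for c in children)
    t_end = t + rng.exponential(1.0 / len(active))
    for node, birth in active:
        node.length = t_end - birth
    root.length = 0.0
    for k, tip in enumerate(root.tips()):
        tip.name = f"t{k + 1}"
    return root


def evolve_optima(tree: TreeNode, rate: float, seed: int = 0) -> pd.Series:
    """Evolve niche optima along the tree by a stationary OU process.

    Mean 0, stationary variance 1, mean-reversion ``rate`` per unit branch
    length.  Returns a Series indexed by tip name.  Smaller rates leave
    more phylogenetic signal in the optima (Brownian-like); large rates
    erase it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6F75]))
    values: dict[int, float] = {id(tree): float(rng.normal(0.0, 1.0))}
    for node in tree.preorder(include_self=False):
        decay = np.exp(-rate * (node.length or 0.0))
        sd = np.sqrt(max(1.0 - decay**2, 0.0))
        values[id(node)] = decay * values[id(node.parent)] + float(rng.normal(0.0, 1.0)) * sd
    return pd.Series(
        {tip.name: values[id(tip)] for tip in tree.tips()}, name="optimum"
    )


# ---------------------------------------------------------------------------
# community tables


def _sample_names(scenario: SimulationScenario) -> tuple[list[str], dict[str, str]]:
    labels = default_group_labels(scenario.n_groups)
    names, groups = [], {}
    for g in labels:
        for r in range(scenario.n_samples):
            name = f"{g}_{r + 1}"
            names.append(name)
            groups[name] = g
    return names, groups


def _table_from_probs(
    probs_per_sample: list[np.ndarray],
    scenario: SimulationScenario,
    rng: np.random.Generator,
    taxon_ids: list[str],
) -> CommunityTable:
    names, groups = _sample_names(scenario)
    counts = np.column_stack(
        [rng.multinomial(scenario.depth, p / p.sum()) for p in probs_per_sample]
    )
    df = pd.DataFrame(counts.astype(float), index=taxon_ids, columns=names)
    return CommunityTable(df, pd.Series(groups))


def simulate_selection_communities(
    scenario: SimulationScenario, tree: TreeNode | None = None
) -> tuple[CommunityTable, TreeNode]:
    """Communities under phylogenetically conserved environmental selection.

    Returns the table and the phylogeny it was simulated on (generated
    from the scenario seed when not supplied).
    """
    if scenario.regime != "selection":
        raise ValidationError("scenario.regime must be 'selection'")
    if tree is None:
        tree = simulate_tree(scenario.n_taxa, scenario.seed)
    tips = [t.name for t in tree.tips()]
    optima = evolve_optima(tree, scenario.niche_conservatism_rate, scenario.seed).loc[tips]
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 0x73656C]))
    probs = []
    for g, env in enumerate(scenario.envs):
        w = np.exp(-((env - optima.values) ** 2) * scenario.selection_strength)
        for _ in range(scenario.n_samples):
            probs.append(w)
    return _table_from_probs(probs, scenario, rng, tips), tree


def simulate_neutral_communities(scenario: SimulationScenario) -> CommunityTable:
    """All samples drawn multinomially from one shared log-normal
    metacommunity; no environmental term."""
    if scenario.regime != "neutral":
        raise ValidationError("scenario.regime must be 'neutral'")
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 0x6E7574]))
    meta = rng.lognormal(0.0, scenario.metacommunity_sigma, scenario.n_taxa)
    taxa = [f"t{i + 1}" for i in range(scenario.n_taxa)]
    probs = [meta] * (scenario.n_groups * scenario.n_samples)
    return _table_from_probs(probs, scenario, rng, taxa)


def simulate_dispersal_limited(scenario: SimulationScenario) -> CommunityTable:
    """Per-group accessible pools with overlap set by the dispersal rate.

    Each taxon has one home group; it is accessible to every other group
    independently with probability ``scenario.dispersal``.  dispersal = 1
    reduces to the neutral regime; dispersal = 0 gives disjoint pools.
    """
    if scenario.regime != "dispersal_limited":
        raise ValidationError("scenario.regime must be 'dispersal_limited'")
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 0x646973]))
    meta = rng.lognormal(0.0, scenario.metacommunity_sigma, scenario.n_taxa)
    home = rng.integers(scenario.n_groups, size=scenario.n_taxa)
    access = rng.random((scenario.n_groups, scenario.n_taxa)) < scenario.dispersal
    access[home, np.arange(scenario.n_taxa)] = True
    taxa = [f"t{i + 1}" for i in range(scenario.n_taxa)]
    probs = []
    for g in range(scenario.n_groups):
        w = meta * access[g]
        if w.sum() == 0:  # pathological tiny pools: keep the home taxa only
            w = meta * (home == g)
        for _ in range(scenario.n_samples):
            probs.append(w)
    return _table_from_probs(probs, scenario, rng, taxa)


def simulate_module_network_counts(
    n_taxa: int,
    n_modules: int,
    n_samples: int,
    within_corr: float = 0.9,
    depth: int = 20_000,
    latent_scale: float = 2.0,
    seed: int = 0,
) -> tuple[CommunityTable, pd.Series]:
    """Counts with planted module-structured correlation.

    One latent factor per module; taxon log-abundance loads on its
    module's factor plus independent noise.  The latent Pearson
    correlation is set to 2 sin(pi * within_corr / 6) — the Gaussian-copula
    inversion — so the latent *Spearman* correlation of same-module pairs
    equals ``within_corr``; between-module latent correlations are 0.
    ``latent_scale`` converts the unit-variance latent to log-abundance
    units large enough that count noise does not swamp the planted
    structure.  Note that closing each sample to the fixed depth
    (multinomial sampling) adds a compositional common mode: realized
    between-module correlations are negative rather than zero, and
    realized within-module correlations sit somewhat below the latent
    target, increasingly so for few modules.  Returns the table and the
    planted module label per taxon.
    """
    if n_modules < 1 or n_modules > n_taxa:
        raise ValidationError("need 1 <= n_modules <= n_taxa")
    if not 0 < within_corr < 1:
        raise ValidationError(f"within_corr must be in (0,1), got {within_corr}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6D6F64]))
    modules = np.arange(n_taxa) % n_modules
    base = rng.normal(0.0, 1.0, n_taxa)
    rho_latent = min(2.0 * np.sin(np.pi * within_corr / 6.0), 1.0 - 1e-12)
    loading = np.sqrt(rho_latent)
    noise_sd = np.sqrt(1.0 - rho_latent)
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    names = [f"S{j + 1}" for j in range(n_samples)]
    counts = np.empty((n_taxa, n_samples))
    for j in range(n_samples):
        factors = rng.normal(0.0, 1.0, n_modules)
        z = loading * factors[modules] + noise_sd * rng.normal(0.0, 1.0, n_taxa)
        p = np.exp(base + latent_scale * z)
        counts[:, j] = rng.multinomial(depth, p / p.sum())
    df = pd.DataFrame(counts, index=taxa, columns=names)
    groups = pd.Series("all", index=names)
    return CommunityTable(df, groups), pd.Series(modules, index=taxa, name="module")
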