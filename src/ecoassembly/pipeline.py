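"""End-to-end orchestration of the analysis chain.

Each ``run_*`` function is a thin driver over the library modules: it
reads validated inputs, executes one stage (diversity, assembly null
models, co-occurrence networks), writes deterministic TSV/JSON outputs
into the configured directory and returns the in-memory results.  Runs
with equal configs produce byte-identical analytic outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import assembly as asm
from . import diversity as dv
from . import network as net
from .io import (
    CommunityTable,
    ValidationError,
    filter_prevalence,
    read_asv_table,
    read_tree,
    write_asv_table,
    write_metadata,
)
from .simulate import (
    SimulationScenario,
    simulate_dispersal_limited,
    simulate_neutral_communities,
    simulate_selection_communities,
    simulate_tree,
)

logger = logging.getLogger("ecoassembly")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_EMPTY = 3


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    table: str | None = None
    tree: str | None = None
    metadata: str | None = None
    control: str = "CK"
    out_dir: str = "results"
    seed: int = 0
    n_null: int = 999
    t_min: float = 0.30
    t_max: float = 0.95
    step: float = 0.01
    threshold: float | None = None  # fixed network threshold; None = RMT scan
    transform: str = "log10p1"
    prevalence: float = 0.5
    weighted_bmntd: bool = True
    alpha: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _load(config: RunConfig) -> CommunityTable:
    if config.table is None:
        raise ValidationError("config.table is required")
    return read_asv_table(config.table, metadata=config.metadata)


def _write_summary(config: RunConfig, stage: str, extra: dict, t0: float) -> dict:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        **extra,
    }
    (out_dir / f"{stage}_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("stage=%s wall_time=%.2fs %s", stage, time.time() - t0,
                {k: v for k, v in extra.items() if isinstance(v, (int, float, str))})
    return summary


def run_simulate(config: RunConfig, scenario: SimulationScenario) -> dict:
    """Generate a synthetic dataset and write table/tree/metadata files."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree = None
    if scenario.regime == "selection":
        table, tree = simulate_selection_communities(scenario)
    elif scenario.regime == "neutral":
        table = simulate_neutral_communities(scenario)
        tree = simulate_tree(scenario.n_taxa, scenario.seed)
    else:
        table = simulate_dispersal_limited(scenario)
        tree = simulate_tree(scenario.n_taxa, scenario.seed)
    write_asv_table(table, out_dir / "asv_table.tsv")
    write_metadata(table, out_dir / "metadata.tsv")
    tree.write(str(out_dir / "tree.nwk"))
    (out_dir / "scenario.yaml").write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=True))
    return _write_summary(
        config, "simulate", {"n_taxa": table.n_taxa, "n_samples": table.n_samples,
                             "scenario": scenario.to_dict()}, t0
    )


def run_diversity(config: RunConfig) -> dict:
    """Alpha diversity + group letters + percent change, Bray-Curtis PCoA."""
    t0 = time.time()
    table = _load(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree = read_tree(config.tree) if config.tree else None

    alpha = dv.alpha_diversity_table(table, tree)
    alpha.to_csv(out_dir / "alpha_diversity.tsv", sep="\t")

    groups = sorted(set(table.groups))
    if config.control not in groups:
        raise ValidationError(f"control group {config.control!r} absent from metadata")
    metrics = [c for c in alpha.columns if c != "group"]
    summary_rows, change_rows = [], []
    for metric in metrics:
        by_group = {g: alpha.loc[alpha["group"] == g, metric].values for g in groups}
        summ = dv.group_compare(by_group, alpha=config.alpha)
        formatted = dv.format_group_summary(summ)
        for g in groups:
            summary_rows.append(
                {"metric": metric, "group": g, **summ.loc[g].to_dict(),
                 "formatted": formatted[g], "anova_F": summ.attrs["anova_F"],
                 "anova_p": summ.attrs["anova_p"]}
            )
            if g != config.control:
                change_rows.append(
                    {"metric": metric, "group": g,
                     "percent_change_vs_control": dv.percent_change(
                         summ.loc[g, "mean"], summ.loc[config.control, "mean"])}
                )
    pd.DataFrame(summary_rows).to_csv(out_dir / "alpha_group_summary.tsv", sep="\t", index=False)
    pd.DataFrame(change_rows).to_csv(out_dir / "alpha_percent_change.tsv", sep="\t", index=False)

    bc = dv.bray_curtis(table)
    ord_res = dv.pcoa(bc)
    coords = ord_res["coordinates"].copy()
    coords.insert(0, "group", [table.groups[s] for s in coords.index])
    coords.to_csv(out_dir / "pcoa_coordinates.tsv", sep="\t")
    ord_res["proportion_explained"].to_csv(out_dir / "pcoa_explained.tsv", sep="\t")

    explained = ord_res["proportion_explained"]
    extra = {
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
        "pcoa_axis1_pct": round(100 * float(explained.iloc[0]), 1) if len(explained) else None,
        "pcoa_axis2_pct": round(100 * float(explained.iloc[1]), 1) if len(explained) > 1 else None,
    }
    return _write_summary(config, "diversity", extra, t0)


def run_assembly(config: RunConfig) -> dict:
    """Per-pair βNTI/RCbray, process classification and per-group summary."""
    t0 = time.time()
    table = _load(config)
    if config.tree is None:
        raise ValidationError("assembly stage requires a phylogenetic tree")
    tree = read_tree(config.tree)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = asm.assembly_analysis(
        table, tree, n_null=config.n_null, seed=config.seed, weighted=config.weighted_bmntd
    )
    results.to_csv(out_dir / "assembly_pairs.tsv", sep="\t", index=False,
                   float_format="%.6f")
    summary = asm.summarize_assembly(results)
    summary.to_csv(out_dir / "assembly_groups.tsv", sep="\t")
    contributions = summary["stochastic_contribution"].to_dict()
    return _write_summary(
        config, "assembly",
        {"n_pairs": len(results), "n_null": config.n_null,
         "stochastic_contribution": contributions}, t0
    )


def run_network(config: RunConfig) -> dict:
    """Per-group RMT co-occurrence networks, topology metrics and roles."""
    t0 = time.time()
    table = _load(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics_rows, role_frames = [], []
    empty_groups, used_thresholds = [], {}
    for g in dict.fromkeys(table.groups):
        sub = table.subset_samples(table.samples_in_group(g))
        if sub.n_samples < 4:
            raise ValidationError(f"group {g!r} has < 4 samples")
        try:
            filtered = filter_prevalence(sub, config.prevalence)
            corr = net.spearman_matrix(filtered, transform=config.transform)
            if config.threshold is not None:
                thr, fallback = config.threshold, False
            else:
                scan = net.rmt_threshold_scan(
                    corr, t_min=config.t_min, t_max=config.t_max, step=config.step
                )
                thr, fallback = scan.chosen, scan.fallback
            g_net = net.build_network(corr, thr)
            roles = net.zi_pi(g_net)
            topo = net.topology_metrics(g_net)
        except ValidationError as exc:
            logger.warning("group %s: empty network (%s)", g, exc)
            empty_groups.append(g)
            continue
        used_thresholds[g] = {"threshold": thr, "fallback": fallback}
        metrics_rows.append(
            {"group": g, "nodes": g_net.number_of_nodes(), "edges": g_net.number_of_edges(),
             "threshold": thr, **topo}
        )
        roles = roles.copy()
        roles.insert(0, "group", g)
        role_frames.append(roles)
        net.export_network(g_net, str(out_dir / f"network_{g}.graphml"), roles=roles)
        net.export_network(g_net, str(out_dir / f"network_{g}_edges.csv"), format="edge_list")
    if metrics_rows:
        pd.DataFrame(metrics_rows).to_csv(out_dir / "network_metrics.tsv", sep="\t", index=False)
    if role_frames:
        pd.concat(role_frames).to_csv(out_dir / "network_roles.tsv", sep="\t")
    return _write_summary(
        config, "network",
        {"groups_analyzed": len(metrics_rows), "empty_groups": empty_groups,
         "thresholds": used_thresholds}, t0
    )


def run_all(config: RunConfig) -> dict:
    """The full chain: diversity, assembly and networks on one input set."""
    t0 = time.time()
    out = {
        "diversity": run_diversity(config),
        "assembly": run_assembly(config),
        "network": run_network(config),
    }
    return _write_summary(config, "all", {"stages": list(out)}, t0)
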