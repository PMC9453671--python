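"""Reading, validation and shared transforms for community data.

The central container is :class:`CommunityTable`, a taxa x samples count
matrix plus a sample -> group mapping.  All downstream stages (diversity,
assembly null models, co-occurrence networks) consume it.  Phylogenies are
handled as :class:`skbio.TreeNode` objects read from newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode


class ValidationError(ValueError):
    """Raised when an input table, tree or metadata file violates a contract."""


@dataclass(frozen=True)
class GroupDesign:
    """Ordered experimental groups with a designated control.

    Parameters
    ----------
    groups : tuple of str
        Group labels in presentation order (e.g. CK, BL, CF, BF, MF).
    control : str
        The label treated as the reference for percent-change reporting.
    """

    groups: tuple[str, ...]
    control: str

    def __post_init__(self):
        if len(set(self.groups)) != len(self.groups):
            raise ValidationError("duplicate group labels")
        if self.control not in self.groups:
            raise ValidationError(
                f"control group {self.control!r} not among groups {self.groups}"
            )


@dataclass
class CommunityTable:
    """Taxa x samples count matrix with per-sample group labels.

    ``counts`` is a pandas DataFrame indexed by taxon id with sample ids as
    columns; ``groups`` maps sample id -> group label.  Counts are
    non-negative reals (rarefied or otherwise normalised tables are
    accepted, not only integers).
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        self.counts = self.counts.astype(float)
        self.groups = pd.Series(self.groups)
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.counts.isna().any().any():
            raise ValidationError("counts contain missing values")
        if (self.counts.values < 0).any():
            bad = self.counts.index[(self.counts.values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative counts for taxa: {bad}")
        orphans = [s for s in self.counts.columns if s not in self.groups.index]
        if orphans:
            raise ValidationError(f"samples absent from metadata: {orphans}")
        self.groups = self.groups.loc[list(self.counts.columns)]

    # -- basic views -------------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_of(self, sample_id: str) -> str:
        return self.groups[sample_id]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def subset_samples(self, sample_ids: list[str]) -> "CommunityTable":
        return CommunityTable(self.counts[list(sample_ids)], self.groups.loc[list(sample_ids)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.groups.equals(other.groups)


# ---------------------------------------------------------------------------
# readers / writers


def read_metadata(path: str | Path) -> pd.Series:
    """Read a sample metadata TSV with columns ``sample_id`` and ``group``."""
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    return pd.Series(meta["group"].values, index=meta["sample_id"].values, name="group")


def read_asv_table(
    path: str | Path,
    metadata: str | Path | pd.Series | dict | None = None,
    format: str = "tsv",
) -> CommunityTable:
    """Read an ASV abundance table and attach sample groups.

    TSV dialect: tab-separated, UTF-8, first column taxon_id, header row of
    sample ids; lines starting with ``#`` are skipped.  When ``metadata`` is
    None every sample is assigned a single group ``"all"``.
    """
    if format not in ("tsv", "biom"):
        raise ValidationError(f"unsupported format {format!r}")
    if format == "biom":
        raise NotImplementedError(
            "BIOM input requires the biom-format package; export to TSV instead"
        )
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"empty or non-numeric cells in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric counts in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if metadata is None:
        groups = pd.Series("all", index=df.columns, name="group")
    elif isinstance(metadata, (str, Path)):
        groups = read_metadata(metadata)
    elif isinstance(metadata, dict):
        groups = pd.Series(metadata, name="group")
    else:
        groups = metadata
    return CommunityTable(df, groups)


def write_asv_table(table: CommunityTable, path: str | Path) -> None:
    """Write the counts matrix as TSV (first column ``taxon_id``).

    Deterministic: preserves the table's row and column order.
    """
    out = table.counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def write_metadata(table: CommunityTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": table.sample_ids, "group": [table.groups[s] for s in table.sample_ids]}
    ).to_csv(path, sep="\t", index=False)


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree; tips must be uniquely labeled.

    Missing branch lengths are set to 0 with a warning rather than raising,
    to tolerate tool-specific newick dialects.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises NewickFormatError with position info
        raise ValidationError(f"unparseable newick in {path}: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        seen, dups = set(), []
        for name in tips:
            if name in seen:
                dups.append(name)
            seen.add(name)
        raise ValidationError(f"duplicate tip labels: {sorted(set(dups))}")
    if tree.length is None:
        tree.length = 0.0  # the root conventionally carries no length
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif not np.isfinite(node.length) or node.length < 0:
            raise ValidationError(f"invalid branch length {node.length} at {node.name}")
    if n_missing:
        warnings.warn(f"{n_missing} branch length(s) missing; set to 0", stacklevel=2)
    return tree


def cophenetic_matrix(tree: TreeNode) -> pd.DataFrame:
    """Tip-to-tip (cophenetic) path distances as a symmetric DataFrame."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


# ---------------------------------------------------------------------------
# transforms


def filter_prevalence(table: CommunityTable, min_fraction: float = 0.5) -> CommunityTable:
    """Keep taxa detected (count > 0) in strictly more than ``min_fraction``
    of the samples.

    The default of 0.5 ("present in the majority of samples") is the usual
    pre-network filter of molecular-ecological-network pipelines.
    """
    if not 0 <= min_fraction <= 1:
        raise ValidationError(f"min_fraction must be in [0,1], got {min_fraction}")
    occupancy = (table.counts.values > 0).mean(axis=1)
    keep = occupancy > min_fraction
    if not keep.any():
        raise ValidationError(
            f"empty after filtering: no taxon present in > {min_fraction:.0%} of samples"
        )
    return CommunityTable(table.counts.loc[keep], table.groups)


def relative_abundance(table: CommunityTable) -> CommunityTable:
    """Per-sample proportions; every column sums to 1."""
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero sample(s): {zero}")
    return CommunityTable(table.counts / totals, table.groups)


def aggregate_by_rank(
    table: CommunityTable, taxonomy: pd.DataFrame | dict, rank: str
) -> CommunityTable:
    """Sum counts of taxa sharing the same label at ``rank``.

    ``taxonomy`` maps taxon_id -> rank labels, either a DataFrame indexed by
    taxon_id with rank columns (phylum, order, ...) or a dict of dicts.
    Taxa with no label at the rank are pooled into ``"unclassified"``.
    Sample totals are conserved exactly.
    """
    if isinstance(taxonomy, dict):
        taxonomy = pd.DataFrame.from_dict(taxonomy, orient="index")
    if rank not in taxonomy.columns:
        raise ValidationError(
            f"rank {rank!r} not in taxonomy schema {list(taxonomy.columns)}"
        )
    missing = [t for t in table.taxon_ids if t not in taxonomy.index]
    if missing:
        raise ValidationError(f"taxa without lineage entry: {missing[:10]}")
    labels = taxonomy.loc[table.taxon_ids, rank].fillna("unclassified")
    labels = labels.replace("", "unclassified")
    grouped = table.counts.groupby(labels.values, sort=False).sum()
    grouped.index.name = rank
    return CommunityTable(grouped, table.groups)
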