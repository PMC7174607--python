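"""Count tables, group mappings, newick trees and lineage tables.

The universal input of the pipeline is a taxa x sample table of non-negative
integer counts, optionally paired with a sample -> group mapping.  Trees are
held as :class:`skbio.TreeNode` objects throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CountTable",
    "read_count_table",
    "write_count_table",
    "read_groups",
    "filter_prevalence",
    "read_newick",
    "write_newick",
    "taxonomy_from_lineages",
    "read_lineages",
]

#: sentinel values treated as "missing rank" in lineage tables
MISSING_RANK = {"", "NA", "na", "none", None}


class CountTableError(ValueError):
    """Raised when a count table violates its invariants."""


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer counts with taxa as the index and samples as the columns.
    groups : pandas.Series, optional
        Group label per sample; its index must equal the sample set.
    """

    counts: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].tolist()
            raise CountTableError(f"duplicate taxa identifiers: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].tolist()
            raise CountTableError(f"duplicate sample identifiers: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise CountTableError("counts must be numeric")
        if np.any(arr < 0):
            t, s = np.argwhere(arr < 0)[0]
            raise CountTableError(
                f"negative count at taxon {c.index[t]!r}, sample {c.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            t, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise CountTableError(
                f"non-integer count {arr[t, s]!r} at taxon {c.index[t]!r}, "
                f"sample {c.columns[s]!r}"
            )
        self.counts = c.astype(np.int64)
        if self.groups is not None:
            g = pd.Series(self.groups)
            if set(g.index) != set(c.columns):
                raise CountTableError("groups must be defined for exactly the samples")
            self.groups = g.reindex(c.columns)

    @property
    def taxa_ids(self) -> list[str]:
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

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each taxon has a strictly positive count."""
        return (self.counts > 0).mean(axis=1)

    def with_groups(self, groups) -> "CountTable":
        return CountTable(self.counts.copy(), pd.Series(groups))


def read_count_table(path, orientation: str = "taxa_rows", sep: str | None = None) -> CountTable:
    """Read a delimited count table; the result is always taxa x samples.

    ``orientation="samples_rows"`` transposes the file on the way in.  The
    delimiter is sniffed from the extension (TSV default) unless given.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "samples_rows":
        df = df.T
    return CountTable(df)


def write_count_table(table: CountTable, path, sep: str = "\t") -> None:
    table.counts.to_csv(path, sep=sep)


def read_groups(path, sep: str = "\t") -> pd.Series:
    """Two-column sample -> group mapping (header optional ids in col 0)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.iloc[:, 0]


def filter_prevalence(table: CountTable, min_prevalence: float = 0.05) -> CountTable:
    """Keep taxa present (count > 0) in at least ``min_prevalence`` of samples.

    The comparison is inclusive (prevalence >= threshold) and the surviving
    taxa keep their original order.  Raises if nothing survives.
    """
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    keep = table.prevalence() >= min_prevalence
    if not keep.any():
        raise CountTableError(
            f"prevalence filter at {min_prevalence} removed every taxon"
        )
    return CountTable(table.counts.loc[keep], table.groups)


# ---------------------------------------------------------------------------
# newick


def read_newick(path_or_str) -> TreeNode:
    """Read a newick tree; duplicate leaf labels raise a parse error."""
    s = str(path_or_str)
    tree = TreeNode.read([s] if ";" in s else s)
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf labels in newick input: {dup}")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# taxonomy from lineages


def read_lineages(path, sep: str = "\t") -> pd.DataFrame:
    """Lineage table: taxon_id index, ordered rank columns (coarsest first)."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise ValueError("duplicate taxon identifiers in lineage table")
    return df


def taxonomy_from_lineages(lineages: pd.DataFrame) -> TreeNode:
    """Build a taxonomic tree from rank-ordered lineages.

    Internal nodes are shared rank prefixes; branch lengths equal the number
    of hierarchy levels spanned (1 per adjacent level, more when intermediate
    ranks are missing).  Leaves sit one level below the finest rank.
    """
    if lineages.index.has_duplicates:
        raise ValueError("duplicate taxon identifiers in lineage table")
    n_ranks = lineages.shape[1]
    root = TreeNode(name="root")
    # node registry keyed by the tuple of (level, rank-name) steps from the root
    nodes: dict[tuple, TreeNode] = {(): root}
    for taxon, row in lineages.iterrows():
        path = []
        for level, val in enumerate(row, start=1):
            if pd.isna(val) or val in MISSING_RANK:
                continue
            path.append((level, str(val)))
        path.append((n_ranks + 1, str(taxon)))
        prev_key: tuple = ()
        prev_level = 0
        for level, name in path:
            key = prev_key + ((level, name),)
            if key not in nodes:
                node = TreeNode(name=name, length=float(level - prev_level))
                nodes[prev_key].append(node)
                nodes[key] = node
            prev_key, prev_level = key, level
    return root
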