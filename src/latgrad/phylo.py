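"""Root distances and assemblage-level derivedness metrics.

The root distance (RD) of a species is the number of nodes separating its
tip from the root of a rooted phylogeny — a purely topological proxy for
how derived a lineage is: species that sit behind many splitting events
carry a higher RD than species on depauperate early-branching lineages.
Averaging RD over the species co-occurring in a grid cell gives the mean
root distance (MRD) of the local assemblage, the quantity whose
latitudinal gradient the rest of the pipeline models.

Convention: RD counts the internal nodes on the root-to-tip path,
including the root and excluding the tip, so both tips of ``(A,B);`` have
RD 1.  Equivalently RD is the edge depth of the tip.  Any fixed offset in
this convention cancels out of every downstream statistic (correlations,
smooth-model shapes, quartile membership), because MRD is shift-equivariant.
Branch lengths, when present in the input, are ignored: RD is defined for
trees without usable branch lengths.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd


class NewickFormatError(ValueError):
    """Raised for unparseable trees, multiple trees, or duplicate tips."""


def read_newick(path) -> dendropy.Tree:
    """Read one rooted tree from a Newick file.

    Polytomies are preserved; branch lengths are read but ignored by all
    RD computations.  Raises :class:`NewickFormatError` if the file holds
    no tree, more than one tree, or duplicate tip labels.
    """
    try:
        trees = dendropy.TreeList.get(
            path=str(path), schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise NewickFormatError(f"could not parse Newick file {path}: {exc}") from exc
    if len(trees) != 1:
        raise NewickFormatError(
            f"expected exactly one tree in {path}, found {len(trees)}"
        )
    tree = trees[0]
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if len(labels) != len(tree.leaf_nodes()):
        raise NewickFormatError("unlabelled tip(s) in tree")
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise NewickFormatError(f"duplicate tip labels: {sorted(dupes)}")
    return tree


def root_distances(tree: dendropy.Tree) -> pd.Series:
    """Per-tip root distance (node count from the tree base).

    RD(tip) = number of internal nodes on the path root → tip, counting
    the root and excluding the tip; this equals the tip's edge depth.
    Invariant under branch lengths.  Requires ≥ 2 tips.
    """
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("root distances require a tree with at least 2 tips")
    depth: dict[int, int] = {id(tree.seed_node): 0}
    rd = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + 1
        if node.is_leaf():
            rd[node.taxon.label] = depth[id(node)]
    return pd.Series(rd, name="rd", dtype=int).sort_index()


def normalize_name(name: str) -> str:
    """Case-fold and collapse space/underscore separators."""
    return re.sub(r"[\s_]+", "_", name.strip()).casefold()


@dataclass
class DropReport:
    """Species lost when joining occurrence data with the phylogeny."""

    matrix_only: list[str] = field(default_factory=list)
    tree_only: list[str] = field(default_factory=list)

    @property
    def n_matrix_only(self) -> int:
        return len(self.matrix_only)

    @property
    def n_tree_only(self) -> int:
        return len(self.tree_only)

    def summary(self) -> str:
        lines = [
            f"species in occurrence data without a tree placement: {self.n_matrix_only}",
            *(f"  - {s}" for s in self.matrix_only),
            f"species in tree without range data: {self.n_tree_only}",
            *(f"  - {s}" for s in self.tree_only),
        ]
        return "\n".join(lines)


def match_species(rd: pd.Series, matrix_species) -> tuple[pd.Series, DropReport]:
    """Restrict an RD table to the species of a presence matrix.

    Names are matched after normalization (case and space/underscore
    separators only — no fuzzy matching, so a real mismatch surfaces in
    the report instead of being silently paired).  The returned table is
    indexed by the *matrix* spelling of each name so downstream joins
    against occurrence columns need no further translation.
    """
    matrix_species = list(matrix_species)
    tree_norm = {normalize_name(s): s for s in rd.index}
    matched = {}
    matrix_only = []
    for sp in matrix_species:
        key = normalize_name(sp)
        if key in tree_norm:
            matched[sp] = int(rd[tree_norm[key]])
        else:
            matrix_only.append(sp)
    matched_norm = {normalize_name(s) for s in matched}
    tree_only = [orig for key, orig in tree_norm.items() if key not in matched_norm]
    out = pd.Series(matched, name="rd", dtype=int)
    return out, DropReport(matrix_only=sorted(matrix_only), tree_only=sorted(tree_only))


def mean_root_distance(pm, rd: pd.Series) -> np.ndarray:
    """Per-cell mean RD over the RD-matched species present in each cell.

    Cells containing no matched species get NaN and are excluded from all
    statistical stages downstream.
    """
    if len(rd) == 0:
        raise ValueError("empty RD table")
    idx = [pm.species.index(sp) for sp in rd.index]
    occ = pm.matrix[:, idx]
    counts = occ.sum(axis=1)
    sums = occ @ rd.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mrd = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mrd


def quartile_split(rd: pd.Series) -> tuple[set, set]:
    """Basal and derived species sets from the RD quartiles.

    Species are ranked from most basal (low RD) to most derived (high RD);
    the basal set is every species with RD ≤ Q1 and the derived set every
    species with RD ≥ Q3, where Q1/Q3 are linear-interpolation empirical
    quartiles (index h = p·(n−1) on the sorted sample).  Ties are included
    on both sides, so each set holds at least 25% of the species; with all
    RD values equal both sets contain every species.
    """
    if len(rd) < 4:
        raise ValueError("quartile split requires at least 4 species")
    values = rd.to_numpy(dtype=float)
    q1 = float(np.quantile(values, 0.25, method="linear"))
    q3 = float(np.quantile(values, 0.75, method="linear"))
    basal = set(rd.index[values <= q1])
    derived = set(rd.index[values >= q3])
    return basal, derived


def assemble_cell_metrics(pm, rd_matched: pd.Series) -> pd.DataFrame:
    """Per-cell table of richness, matched richness, MRD and quartile richness.

    Combines total richness, richness restricted to RD-matched species,
    MRD, and basal/derived richness (quartile subsets of the matched
    species) with the cell's geographic coordinates.
    """
    from .grid import richness  # local import to avoid a cycle

    basal, derived = quartile_split(rd_matched)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(pm.grid.n_cells),
            "x_m": pm.grid.x_m,
            "y_m": pm.grid.y_m,
            "latitude_deg": pm.grid.lat_deg,
            "longitude_deg": pm.grid.lon_deg,
            "richness": richness(pm),
            "matched_richness": richness(pm, set(rd_matched.index)),
            "mrd": mean_root_distance(pm, rd_matched),
            "basal_richness": richness(pm, basal),
            "derived_richness": richness(pm, derived),
        }
    )
    return df
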