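"""Canonical factor loadings and Euclidean-distance feature association.

A canonical factor loading (structure correlation coefficient) is the
Pearson correlation between an original feature and a canonical variable.
Placing, say, genes and geoclimatic variables in the same low-dimensional
loading space turns "which genes track this climate variable?" into a
nearest-neighbor query: under an assumed transitivity of correlation, two
features whose loading vectors are close are themselves correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cca import project
from .hierarchy import HCCAModel, HierarchyNode
from .io import OmicsMatrix

__all__ = [
    "LoadingTable",
    "factor_loadings",
    "path_loadings",
    "nearest_features",
    "export_gene_list",
]


@dataclass
class LoadingTable:
    """Feature x component structure correlations for one view at one node."""

    feature_ids: list[str]
    loadings: np.ndarray  # d x m, entries in [-1, 1]
    view: str = ""
    node_id: str = ""
    constant_mask: np.ndarray | None = None  # True where the feature was constant

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.ndim != 2 or self.loadings.shape[0] != len(self.feature_ids):
            raise ValueError("loading matrix shape does not match feature IDs")
        if np.any(np.abs(self.loadings) > 1 + 1e-9):
            raise ValueError("loadings must lie in [-1, 1]")
        if self.constant_mask is None:
            self.constant_mask = np.zeros(len(self.feature_ids), dtype=bool)

    def vector(self, feature_id: str, n_components: int | None = None) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature ID {feature_id!r}") from None
        m = n_components or self.loadings.shape[1]
        return self.loadings[i, :m]


def factor_loadings(X, U, n_components: int = 2, view: str = "", node_id: str = "") -> LoadingTable:
    """Pearson correlation of every feature of X with the first
    ``n_components`` canonical variables in U.

    Constant features (and degenerate canonical variables) get loading 0 and
    are flagged rather than propagating NaN.
    """
    feature_ids = (
        list(X.feature_ids)
        if isinstance(X, OmicsMatrix)
        else [f"f{i}" for i in range(np.asarray(X).shape[1])]
    )
    Xv = X.values if isinstance(X, OmicsMatrix) else np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    n = Xv.shape[0]
    if n < 3:
        raise ValueError("correlation needs at least 3 samples")
    if U.shape[0] != n:
        raise ValueError("sample count mismatch between X and U")
    if n_components > U.shape[1]:
        raise ValueError(
            f"asked for {n_components} components but U has {U.shape[1]}"
        )
    Uc = U[:, :n_components] - U[:, :n_components].mean(axis=0)
    Xc = Xv - Xv.mean(axis=0)
    xsd = np.sqrt((Xc**2).sum(axis=0))
    usd = np.sqrt((Uc**2).sum(axis=0))
    constant = xsd == 0
    denom = np.outer(np.where(constant, 1.0, xsd), np.where(usd == 0, 1.0, usd))
    load = (Xc.T @ Uc) / denom
    load[constant, :] = 0.0
    load[:, usd == 0] = 0.0
    load = np.clip(load, -1.0, 1.0)
    return LoadingTable(
        feature_ids=feature_ids,
        loadings=load,
        view=view or (X.name if isinstance(X, OmicsMatrix) else ""),
        node_id=node_id,
        constant_mask=constant,
    )


def _side_canonical_variables(node: HierarchyNode, view_index: int) -> np.ndarray:
    """The node's canonical variables on the side containing the view."""
    proj = node.projection
    if view_index in node.child_left.leaf_indices():
        child, W, mu = node.child_left, proj.w_left, proj.mean_left
    else:
        child, W, mu = node.child_right, proj.w_right, proj.mean_right
    return project(child.U, W, mu)


def path_loadings(
    model: HCCAModel,
    views: list[OmicsMatrix],
    view_index: int,
    level: int,
    n_components: int = 2,
) -> LoadingTable:
    """Loadings of a view's original features against the canonical
    variables of one merge node on that view's path to the root.

    ``level`` is the merge level (as recorded in ``merge_log``); it must
    index a node on the path from the view's leaf to the root.
    """
    path = model.nodes_on_path(view_index)
    levels = [int(node.node_id.removeprefix("merge")) for node in path]
    if level not in levels:
        raise ValueError(
            f"level {level} is not on view {view_index}'s root path; "
            f"valid levels: {levels}"
        )
    node = path[levels.index(level)]
    U_side = _side_canonical_variables(node, view_index)
    if n_components > U_side.shape[1]:
        raise ValueError(
            f"level {level} has only {U_side.shape[1]} canonical components"
        )
    return factor_loadings(
        views[view_index],
        U_side,
        n_components=n_components,
        view=model.view_names[view_index],
        node_id=node.node_id,
    )


def nearest_features(
    table_a: LoadingTable,
    table_b: LoadingTable,
    target_id: str,
    m: int = 100,
    n_components: int = 2,
) -> list[tuple[str, float]]:
    """The m features of table_b closest (Euclidean, over the first
    ``n_components`` loadings) to table_a's target feature, ascending.

    Both tables must come from the same hierarchy node: comparing loading
    spaces of different nodes is refused.  Ties break by feature ID.
    """
    if table_a.node_id != table_b.node_id:
        raise ValueError(
            f"loading tables come from different nodes "
            f"({table_a.node_id!r} vs {table_b.node_id!r}); recompute at one node"
        )
    target = table_a.vector(target_id, n_components)
    dists = np.sqrt(
        ((table_b.loadings[:, :n_components] - target) ** 2).sum(axis=1)
    )
    ranked = sorted(zip(table_b.feature_ids, dists), key=lambda t: (t[1], t[0]))
    return [(f, float(d)) for f, d in ranked[:m]]


def export_gene_list(ranked: list[tuple[str, float]], path) -> None:
    """Write a ranked (rank, feature_id, distance) TSV; byte-deterministic."""
    with open(path, "w") as fh:
        fh.write("rank\tfeature_id\tdistance\n")
        for rank, (fid, dist) in enumerate(ranked, start=1):
            fh.write(f"{rank}\t{fid}\t{dist!r}\n")
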