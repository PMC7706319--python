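"""Hierarchical CCA: recursive condition-number-guided merging of N views.

At each level the pair of remaining datasets whose cross-covariance has the
smallest condition number is merged by regularized CCA; the pair is replaced
by the concatenated coprojection (a pseudo-view of canonical variables) and
the process repeats until one joint representation remains.  Network
Laplacians apply only to original feature spaces: merged pseudo-views carry
no interaction graph, and their canonical-variable columns are not
re-standardized (they already have unit generalized norm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cca import CCAProjection, coproject_concat, fit_cca, project
from .condition import pair_table, select_pair
from .io import InteractionNetwork, OmicsMatrix, RunConfig

SERIAL_FORMAT = "hcca-model"
SERIAL_VERSION = 1

__all__ = [
    "HierarchyNode",
    "MergeRecord",
    "HCCAModel",
    "fit_hcca",
    "transform",
    "serialize",
    "deserialize",
]


@dataclass
class HierarchyNode:
    """A leaf (original view) or a merge (CCA coprojection) in the tree."""

    node_id: str
    kind: str  # "leaf" | "merge"
    view_index: int | None = None
    feature_ids: list[str] | None = None
    child_left: "HierarchyNode | None" = None
    child_right: "HierarchyNode | None" = None
    projection: CCAProjection | None = None
    U: OmicsMatrix | None = None  # joint representation at this node (training)

    def leaf_indices(self) -> list[int]:
        if self.kind == "leaf":
            return [self.view_index]
        return self.child_left.leaf_indices() + self.child_right.leaf_indices()


@dataclass(frozen=True)
class MergeRecord:
    level: int
    i: int  # indices into the level's current dataset list
    j: int
    kappa: float
    alpha_left: float
    alpha_right: float
    k: int


@dataclass
class HCCAModel:
    root: HierarchyNode
    merge_log: list[MergeRecord] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    view_names: list[str] = field(default_factory=list)

    @property
    def n_views(self) -> int:
        return len(self.view_names)

    def nodes_on_path(self, view_index: int) -> list[HierarchyNode]:
        """Merge nodes from the view's leaf up to the root, in merge order."""
        path: list[HierarchyNode] = []

        def walk(node: HierarchyNode) -> bool:
            if node.kind == "leaf":
                return node.view_index == view_index
            found = walk(node.child_left) or walk(node.child_right)
            if found:
                path.append(node)
            return found

        if not walk(self.root):
            raise ValueError(f"view index {view_index} not in the model")
        return path


def _as_laplacian(net, feature_ids: list[str]) -> np.ndarray:
    if isinstance(net, InteractionNetwork):
        return net.normalized_laplacian(feature_ids)
    L = np.asarray(net, dtype=float)
    if L.shape != (len(feature_ids), len(feature_ids)):
        raise ValueError("Laplacian dimension does not match the view")
    return L


def fit_hcca(
    views: list[OmicsMatrix],
    networks: dict[int, object] | None = None,
    config: RunConfig | None = None,
    fixed_first_pair: tuple[int, int] | None = None,
) -> HCCAModel:
    """Recursively merge views into one joint representation.

    Parameters
    ----------
    networks:
        Optional map from view index to an :class:`InteractionNetwork` (or a
        precomputed normalized Laplacian) on that view's features.  With a
        network present, that side of the CCA uses Laplacian-smoothed
        regularization; this requires ``config.c_target > 3``.
    fixed_first_pair:
        Force the level-1 merge (e.g. genes with geoclimate so their
        association can be read at every level); levels >= 2 revert to
        condition-number selection.
    """
    if not views:
        raise ValueError("empty view list")
    config = config or RunConfig()
    networks = networks or {}
    sample_ids = views[0].sample_ids
    for v in views[1:]:
        if v.sample_ids != sample_ids:
            raise ValueError("views are not sample-aligned; run align_samples first")
    for idx in networks:
        if not 0 <= idx < len(views):
            raise ValueError(f"network for unknown view index {idx}")

    view_names = [v.name or f"view{i}" for i, v in enumerate(views)]
    active: list[HierarchyNode] = []
    laplacians: list[np.ndarray | None] = []
    for i, v in enumerate(views):
        active.append(
            HierarchyNode(
                node_id=f"leaf:{view_names[i]}",
                kind="leaf",
                view_index=i,
                feature_ids=list(v.feature_ids),
                U=v,
            )
        )
        laplacians.append(
            _as_laplacian(networks[i], v.feature_ids) if i in networks else None
        )

    merge_log: list[MergeRecord] = []
    level = 0
    while len(active) > 1:
        level += 1
        mats = [node.U for node in active]
        table = pair_table(mats)
        if level == 1 and fixed_first_pair is not None:
            i, j = fixed_first_pair
            if not (0 <= i < len(active) and 0 <= j < len(active) and i != j):
                raise ValueError(
                    f"fixed_first_pair {fixed_first_pair} out of range for "
                    f"{len(active)} views"
                )
            i, j = min(i, j), max(i, j)
        else:
            i, j = select_pair(mats)
        kappa = next(s.kappa for s in table if (s.i, s.j) == (i, j))

        proj = fit_cca(
            mats[i],
            mats[j],
            Li=laplacians[i],
            Lj=laplacians[j],
            c=config.c_target,
            percent=config.variance_percent,
        )
        Ui = project(mats[i], proj.w_left, proj.mean_left)
        Uj = project(mats[j], proj.w_right, proj.mean_right)
        node_id = f"merge{level}"
        U = coproject_concat(Ui, Uj, sample_ids=sample_ids, node=node_id)
        merged = HierarchyNode(
            node_id=node_id,
            kind="merge",
            child_left=active[i],
            child_right=active[j],
            projection=proj,
            U=U,
        )
        merge_log.append(
            MergeRecord(level, i, j, kappa, proj.alpha_left, proj.alpha_right, proj.k)
        )
        # replace the pair by the merged pseudo-view (no network attached)
        for idx in sorted((i, j), reverse=True):
            del active[idx]
            del laplacians[idx]
        active.append(merged)
        laplacians.append(None)

    return HCCAModel(
        root=active[0],
        merge_log=merge_log,
        config=dict(config.__dict__),
        view_names=view_names,
    )


def _evaluate(node: HierarchyNode, views: list[OmicsMatrix], name: str) -> np.ndarray:
    if node.kind == "leaf":
        v = views[node.view_index]
        if list(v.feature_ids) != node.feature_ids:
            raise ValueError(
                f"feature IDs of view {node.view_index} ({v.name or 'unnamed'}) "
                "do not match the training view"
            )
        return v.values
    left = _evaluate(node.child_left, views, name)
    right = _evaluate(node.child_right, views, name)
    proj = node.projection
    Ui = (left - proj.mean_left) @ proj.w_left
    Uj = (right - proj.mean_right) @ proj.w_right
    return np.hstack([Ui, Uj])


def transform(model: HCCAModel, views: list[OmicsMatrix]) -> OmicsMatrix:
    """Replay the merge tree on (possibly new) samples using stored weights
    and centers."""
    if len(views) != model.n_views:
        raise ValueError(f"model expects {model.n_views} views, got {len(views)}")
    sample_ids = views[0].sample_ids
    for v in views[1:]:
        if v.sample_ids != sample_ids:
            raise ValueError("views are not sample-aligned; run align_samples first")
    values = _evaluate(model.root, views, model.root.node_id)
    return OmicsMatrix(
        sample_ids=list(sample_ids),
        feature_ids=list(model.root.U.feature_ids)
        if model.root.U is not None
        else [f"joint:{m}" for m in range(values.shape[1])],
        values=values,
        name="joint",
    )


# ---------------------------------------------------------------------------
# serialization (JSON; float repr round-trips exactly in Python)


def _arr(a: np.ndarray) -> list:
    return np.asarray(a, dtype=float).tolist()


def _node_to_dict(node: HierarchyNode) -> dict:
    d: dict = {"node_id": node.node_id, "kind": node.kind}
    if node.kind == "leaf":
        d["view_index"] = node.view_index
        d["feature_ids"] = node.feature_ids
    else:
        p = node.projection
        d["child_left"] = _node_to_dict(node.child_left)
        d["child_right"] = _node_to_dict(node.child_right)
        d["projection"] = {
            "w_left": _arr(p.w_left),
            "w_right": _arr(p.w_right),
            "correlations": _arr(p.correlations),
            "alpha_left": p.alpha_left,
            "alpha_right": p.alpha_right,
            "used_laplacian": list(p.used_laplacian),
            "mean_left": _arr(p.mean_left),
            "mean_right": _arr(p.mean_right),
            "spectrum": _arr(p.spectrum),
        }
        if node.U is not None:
            d["U_feature_ids"] = node.U.feature_ids
    return d


def _node_from_dict(d: dict) -> HierarchyNode:
    if d["kind"] == "leaf":
        return HierarchyNode(
            node_id=d["node_id"],
            kind="leaf",
            view_index=d["view_index"],
            feature_ids=list(d["feature_ids"]),
        )
    p = d["projection"]
    proj = CCAProjection(
        w_left=np.array(p["w_left"], dtype=float),
        w_right=np.array(p["w_right"], dtype=float),
        correlations=np.array(p["correlations"], dtype=float),
        alpha_left=p["alpha_left"],
        alpha_right=p["alpha_right"],
        used_laplacian=tuple(p["used_laplacian"]),
        mean_left=np.array(p["mean_left"], dtype=float),
        mean_right=np.array(p["mean_right"], dtype=float),
        spectrum=np.array(p["spectrum"], dtype=float),
    )
    node = HierarchyNode(
        node_id=d["node_id"],
        kind="merge",
        child_left=_node_from_dict(d["child_left"]),
        child_right=_node_from_dict(d["child_right"]),
        projection=proj,
    )
    if "U_feature_ids" in d:
        node.U = OmicsMatrix(
            sample_ids=[],
            feature_ids=[],
            values=np.zeros((0, 0)),
            name=d["node_id"],
        )
        # only the feature IDs are needed after deserialization
        node.U.feature_ids = list(d["U_feature_ids"])
        node.U.values = np.zeros((0, len(node.U.feature_ids)))
    return node


def serialize(model: HCCAModel, path) -> None:
    payload = {
        "format": SERIAL_FORMAT,
        "version": SERIAL_VERSION,
        "view_names": model.view_names,
        "config": model.config,
        "merge_log": [r.__dict__ for r in model.merge_log],
        "root": _node_to_dict(model.root),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def deserialize(path) -> HCCAModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupt or truncated model file ({exc})") from None
    if payload.get("format") != SERIAL_FORMAT:
        raise ValueError(f"{path}: not a {SERIAL_FORMAT} file")
    if payload.get("version") != SERIAL_VERSION:
        raise ValueError(
            f"{path}: model version {payload.get('version')} != {SERIAL_VERSION}"
        )
    return HCCAModel(
        root=_node_from_dict(payload["root"]),
        merge_log=[MergeRecord(**r) for r in payload["merge_log"]],
        config=payload["config"],
        view_names=list(payload["view_names"]),
    )
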