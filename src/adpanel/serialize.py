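"""JSON serialization of fitted trees and forests.

Schema (one node):
  {"posterior": [...], "weight": w, "node_risk": r,
   "feature": int, "threshold": t, "majority_left": bool,
   "risk_reduction": rr,
   "surrogates": [[feature, threshold, left_if_le, agreement], ...],
   "left": {...}, "right": {...}}
Leaves carry only posterior/weight/node_risk.  A forest document adds the
hyperparameters, class count, priors and (for boosting) stage weights.
"""

from __future__ import annotations

import json

import numpy as np

from .forest import Forest, ForestHyper
from .tree import FlatTree, TreeNode

__all__ = ["tree_to_dict", "tree_from_dict", "forest_to_json",
           "forest_from_json"]


def tree_to_dict(node: TreeNode) -> dict:
    out = {
        "posterior": [float(v) for v in node.posterior],
        "weight": node.weight,
        "node_risk": node.node_risk,
    }
    if not node.is_leaf:
        out.update(
            feature=int(node.feature),
            threshold=float(node.threshold),
            majority_left=bool(node.majority_left),
            risk_reduction=float(node.risk_reduction),
            surrogates=[[int(f), float(t), bool(d), float(a)]
                        for f, t, d, a in node.surrogates],
            left=tree_to_dict(node.left),
            right=tree_to_dict(node.right),
        )
    return out


def tree_from_dict(data: dict) -> TreeNode:
    node = TreeNode(
        posterior=np.asarray(data["posterior"], dtype=float),
        weight=float(data["weight"]),
        node_risk=float(data["node_risk"]),
    )
    if "feature" in data:
        node.feature = int(data["feature"])
        node.threshold = float(data["threshold"])
        node.majority_left = bool(data["majority_left"])
        node.risk_reduction = float(data["risk_reduction"])
        node.surrogates = [(int(f), float(t), bool(d), float(a))
                           for f, t, d, a in data["surrogates"]]
        node.left = tree_from_dict(data["left"])
        node.right = tree_from_dict(data["right"])
    return node


def forest_to_json(model: Forest, marker_names=None) -> str:
    doc = {
        "hyper": vars(model.hyper),
        "n_classes": model.n_classes,
        "n_features": model.n_features,
        "priors": [float(v) for v in model.priors],
        "alphas": None if model.alphas is None
        else [float(a) for a in model.alphas],
        "marker_names": list(marker_names) if marker_names else None,
        "trees": [tree_to_dict(t.root if isinstance(t, FlatTree) else t)
                  for t in model.trees],
    }
    return json.dumps(doc)


def forest_from_json(text: str) -> Forest:
    doc = json.loads(text)
    return Forest(
        trees=[tree_from_dict(t) for t in doc["trees"]],
        hyper=ForestHyper(**doc["hyper"]),
        n_classes=int(doc["n_classes"]),
        n_features=int(doc["n_features"]),
        alphas=None if doc["alphas"] is None else np.asarray(doc["alphas"]),
        priors=np.asarray(doc["priors"]),
    )
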