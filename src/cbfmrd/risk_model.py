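"""Two-feature prognostic risk stratification for t(8;21) AML.

The published rule stratifies patients by (1) whether the fusion
transcript fell by 3 logs or more at remission and (2) presence of the
KIT-D816 mutation at diagnosis:

* 3-log reduction achieved            -> low risk
* not achieved, KIT-D816 mutated      -> high risk
* not achieved, KIT-D816 wild-type    -> intermediate risk

:func:`induce_tree` is a minimal survival-tree inducer that re-derives
this structure from data: greedy recursive partitioning over binary
features, choosing at each node the split maximizing the two-group
log-rank statistic on overall survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .survival import TestResult, cif_estimate, curve_at, gray_test, km_estimate, logrank_test

logger = logging.getLogger(__name__)

__all__ = ["RiskGroup", "RiskTree", "TreeNode", "classify_patient", "induce_tree",
           "group_outcomes"]


class RiskGroup(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


def classify_patient(achieved_3log: bool, kit_d816: bool) -> RiskGroup:
    """Deterministic two-split risk rule (3-log reduction first, then KIT)."""
    if achieved_3log is None or kit_d816 is None:
        raise ValueError("both flags must be resolved")
    if achieved_3log:
        return RiskGroup.LOW
    return RiskGroup.HIGH if kit_d816 else RiskGroup.INTERMEDIATE


@dataclass
class TreeNode:
    feature: str | None = None       # None for a leaf
    statistic: float = 0.0
    n: int = 0
    # children keyed by the feature value (True / False)
    children: dict[bool, "TreeNode"] = field(default_factory=dict)
    leaf_label: str | None = None


@dataclass
class RiskTree:
    root: TreeNode
    max_depth: int
    min_node: int

    def split_order(self) -> list[str]:
        """Features in breadth-first split order (duplicates collapsed)."""
        order: list[str] = []
        queue = [self.root]
        while queue:
            node = queue.pop(0)
            if node.feature is not None:
                if node.feature not in order:
                    order.append(node.feature)
                queue.extend(node.children.values())
        return order

    def leaves(self) -> list[TreeNode]:
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            if node.feature is None:
                out.append(node)
            else:
                queue.extend(node.children.values())
        return out


def _best_split(features: dict[str, np.ndarray], times, events,
                idx: np.ndarray, min_node: int, feature_order: list[str]):
    """Feature maximizing the log-rank statistic on the subset ``idx``."""
    best = None
    for name in feature_order:  # declared order breaks ties deterministically
        f = features[name][idx]
        if f.all() or not f.any():
            continue
        if f.sum() < min_node or (~f).sum() < min_node:
            continue
        if events[idx].sum() == 0:
            continue
        try:
            res = logrank_test(times[idx], events[idx], f.astype(int))
        except ValueError:
            continue
        if best is None or res.statistic > best[1]:
            best = (name, res.statistic)
    if best is not None and best[1] <= 0:
        return None  # no split separates the hazards at all
    return best


def induce_tree(features: dict, times, events, max_depth: int = 2,
                min_node: int = 5) -> RiskTree:
    """Greedy log-rank survival tree over binary features (depth <= 2).

    At each node the binary split with the largest two-group log-rank
    statistic on overall survival is chosen, subject to both children
    holding at least ``min_node`` patients.  Ties are broken by the
    declared feature order.  If no admissible split exists at the root a
    single-leaf tree is returned with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    feature_order = list(features.keys())
    if len(feature_order) < 2:
        raise ValueError("need at least two candidate features")
    if events.sum() == 0:
        raise ValueError("need at least one event")
    features = {k: np.asarray(v, dtype=bool) for k, v in features.items()}

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(n=int(idx.sum()))
        if depth < max_depth:
            best = _best_split(features, times, events, idx, min_node, feature_order)
            if best is not None:
                node.feature, node.statistic = best
                f = features[node.feature]
                for value in (True, False):
                    node.children[value] = grow(idx & (f == value), depth + 1)
                return node
        node.leaf_label = f"leaf_{int(idx.sum())}"
        return node

    all_idx = np.ones(times.size, dtype=bool)
    root = grow(all_idx, 0)
    if root.feature is None:
        logger.warning("no admissible split at root; returning single-leaf tree")
    return RiskTree(root=root, max_depth=max_depth, min_node=min_node)


def group_outcomes(groups, os_times, os_events, relapse_times, event_type,
                   horizon_years: float = 2.0) -> dict:
    """Per-risk-group outcome table at a fixed horizon.

    For each group: Kaplan-Meier overall survival and Aalen-Johansen
    cumulative incidence of relapse at ``horizon_years``, with k-group
    log-rank (OS) and Gray (relapse) tests across groups.  With a single
    group the tests are flagged not applicable.
    """
    groups = np.asarray(groups)
    os_times = np.asarray(os_times, dtype=float)
    os_events = np.asarray(os_events, dtype=int)
    relapse_times = np.asarray(relapse_times, dtype=float)
    event_type = np.asarray(event_type, dtype=int)
    labels = [lab for lab in (RiskGroup.LOW, RiskGroup.INTERMEDIATE, RiskGroup.HIGH)
              if np.any(groups == lab)]
    if not labels:  # arbitrary group labels, keep their natural order
        labels = list(np.unique(groups))
    table = {}
    for lab in labels:
        m = groups == lab
        if m.sum() == 0:
            raise ValueError(f"empty group {lab}")
        km = km_estimate(os_times[m], os_events[m])
        os_h = curve_at(km, horizon_years)
        if np.any(event_type[m] == 1):
            cif = cif_estimate(relapse_times[m], event_type[m])
            cir_h = curve_at(cif, horizon_years, cause=1)
        else:
            cir_h = 0.0
        key = lab.value if isinstance(lab, RiskGroup) else str(lab)
        table[key] = {"n": int(m.sum()), "os": os_h, "cir": cir_h}

    tests: dict[str, TestResult | None] = {"os_logrank": None, "cir_gray": None}
    if len(labels) >= 2:
        if os_events.sum() > 0:
            tests["os_logrank"] = logrank_test(os_times, os_events, groups)
        if np.any(event_type == 1):
            tests["cir_gray"] = gray_test(relapse_times, event_type, groups)
    return {"groups": table, "tests": tests,
            "horizon_years": horizon_years,
            "tests_applicable": len(labels) >= 2}
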