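"""Independent brute-force Shapley oracle for boosted trees.

Computes, for one instance, the tree-path conditional expectation v(S) of
the model margin given only the features in subset S (unconditioned
splits are averaged over their children weighted by training cover), then
the exact Shapley value of each feature by enumerating all 2^M coalitions.
Written against the dumped tree structure only, independent of any
attribution code path it is used to check.
"""

from __future__ import annotations

import itertools
import json
from math import factorial

import numpy as np


def _parse_trees(booster):
    return [json.loads(s) for s in booster.get_dump(dump_format="json", with_stats=True)]


def _node_expectation(node, x, feat_idx, in_subset):
    if "leaf" in node:
        return node["leaf"]
    children = {c["nodeid"]: c for c in node["children"]}
    f = feat_idx[node["split"]]
    if in_subset[f]:
        val = x[f]
        if np.isnan(val):
            nxt = children[node["missing"]]
        elif val < node["split_condition"]:
            nxt = children[node["yes"]]
        else:
            nxt = children[node["no"]]
        return _node_expectation(nxt, x, feat_idx, in_subset)
    total = sum(c["cover"] for c in node["children"])
    return sum(
        (c["cover"] / total) * _node_expectation(c, x, feat_idx, in_subset)
        for c in node["children"]
    )


def margin_expectation(booster, x, subset, feature_names):
    """v(S): expected margin with only features in `subset` observed."""
    feat_idx = {name: i for i, name in enumerate(feature_names)}
    in_subset = np.zeros(len(feature_names), dtype=bool)
    in_subset[list(subset)] = True
    return sum(
        _node_expectation(t, np.asarray(x, dtype=float), feat_idx, in_subset)
        for t in _parse_trees(booster)
    )


def brute_force_shapley(booster, x, feature_names):
    """Exact Shapley values of every feature by coalition enumeration."""
    M = len(feature_names)
    values = {}
    for S in itertools.chain.from_iterable(
        itertools.combinations(range(M), k) for k in range(M + 1)
    ):
        values[frozenset(S)] = margin_expectation(booster, x, S, feature_names)
    phi = np.zeros(M)
    for i in range(M):
        rest = [j for j in range(M) if j != i]
        for k in range(M):
            w = factorial(k) * factorial(M - k - 1) / factorial(M)
            for S in itertools.combinations(rest, k):
                phi[i] += w * (
                    values[frozenset(S) | {i}] - values[frozenset(S)]
                )
    return phi
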