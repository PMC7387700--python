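"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately naive (double loops, exhaustive path
enumeration, pairwise counting) and shares no code with the implementation
under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_pair_table() -> dict[frozenset | tuple, int]:
    """Unordered amino-acid pairs with repetition, lexicographic order."""
    aas = sorted("ACDEFGHIKLMNPQRSTVWY")
    table = {}
    for k, (a, b) in enumerate(itertools.combinations_with_replacement(aas, 2)):
        table[(a, b)] = k
    return table


def brute_force_transform(d: float, kind: str, steepness: float = 2.0) -> float:
    if kind == "reciprocal":
        return 1.0 / max(d, 0.1)
    if kind == "reciprocal_squared":
        return 1.0 / max(d, 0.1) ** 2
    if kind == "sigmoid":
        return 1.0 / (1.0 + math.exp(steepness * (d - 5.0)))
    raise ValueError(kind)


def brute_force_featurize(record, kind: str, steepness: float = 2.0) -> np.ndarray:
    """Pure-python double-loop featurization of a StructureRecord."""
    table = brute_force_pair_table()
    values = [0.0] * 210
    for pep in record.peptide_residues:
        for hla in record.hla_residues:
            best = float("inf")
            for pa in pep.heavy_atoms:
                for ha in hla.heavy_atoms:
                    dist = math.dist(pa, ha)
                    if dist < best:
                        best = dist
            key = tuple(sorted((pep.aa, hla.aa)))
            values[table[key]] += brute_force_transform(best, kind, steepness)
    return np.asarray(values)


def mann_whitney_auc(labels, scores) -> float:
    """AUROC as the pairwise-comparison statistic, ties counted 0.5."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def enumerate_tree_decomposition(tree, x, positive: int):
    """(bias, contribs) of one sklearn tree by exhaustive path enumeration.

    All root-to-leaf paths are enumerated; the one consistent with x's
    split outcomes is selected and its value differences are accumulated.
    """
    t = tree.tree_
    values = t.value[:, 0, positive]

    paths = []

    def walk(node, path):
        if t.children_left[node] == -1:
            paths.append(path + [(node, None)])
            return
        walk(t.children_left[node], path + [(node, "L")])
        walk(t.children_right[node], path + [(node, "R")])

    walk(0, [])

    def follows(path):
        for node, branch in path[:-1]:
            go_left = x[t.feature[node]] <= t.threshold[node]
            if (branch == "L") != go_left:
                return False
        return True

    matching = [p for p in paths if follows(p)]
    assert len(matching) == 1
    path = matching[0]
    contribs = np.zeros(len(x))
    nodes = [n for n, _ in path]
    for parent, child in zip(nodes[:-1], nodes[1:]):
        contribs[t.feature[parent]] += values[child] - values[parent]
    return float(values[0]), contribs
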