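"""Distance-based clustering of promoter sequences: NJ with bootstrap.

Distances are p-distances over a fixed multiple alignment (pairwise
mismatch fraction over columns where neither sequence has a gap), with a
Jukes–Cantor correction available by flag.  Trees are built with
canonical Saitou–Nei neighbor joining (Q-criterion, standard branch-length
formulas).  Ties in the Q minimisation are broken on the lexicographically
lowest pair of cluster labels (a cluster is labelled by its smallest leaf
name), so the construction is fully deterministic.  Negative NJ branch
lengths are clamped to zero, the standard practice, and flagged on the
tree (``tree.negative_branch_clamped``).

Bootstrap support resamples alignment columns with replacement, rebuilds
the tree per replicate, and reports for each internal edge of the
reference tree the percentage of replicates containing the same leaf
bipartition.  Internal node names carry the support values in emitted
newick.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .formats_io import ValidationError

GAP_CHARS = frozenset("-.")


def _char_matrix(sequences: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(sequences)
    if len(labels) < 2:
        raise ValidationError("need at least 2 sequences")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValidationError("sequences must be aligned to equal length")
    if lengths == {0}:
        raise ValidationError("empty alignment")
    arr = np.array([list(sequences[lab].upper()) for lab in labels])
    return labels, arr


def p_distance(sequences: Mapping[str, str], model: str = "p") -> DistanceMatrix:
    """Pairwise distance matrix from an aligned set of sequences.

    ``model="p"`` gives the raw mismatch fraction (gapped columns excluded
    per pair); ``model="jc"`` applies the Jukes–Cantor correction
    d = -3/4 ln(1 - 4p/3).  A pair with no comparable columns is an error.
    """
    if model not in ("p", "jc"):
        raise ValidationError(f"unknown distance model {model!r}")
    labels, arr = _char_matrix(sequences)
    gap = np.isin(arr, list(GAP_CHARS))
    n = len(labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise ValidationError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}")
            p = float((arr[i, ok] != arr[j, ok]).sum()) / n_ok
            if model == "jc":
                if p >= 0.75:
                    raise ValidationError(
                        f"p-distance {p:.3f} between {labels[i]!r} and "
                        f"{labels[j]!r} is saturated for the JC correction")
                p = -0.75 * math.log(1 - 4 * p / 3)
            dm[i, j] = dm[j, i] = p
    return DistanceMatrix(dm, ids=labels)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou–Nei neighbor joining.

    Returns an unrooted tree represented with a trifurcating root.  The
    construction is deterministic: Q ties are broken on the smallest pair
    of cluster labels (lexicographic), and the attribute
    ``negative_branch_clamped`` records whether any negative branch length
    was clamped to zero.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    D: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[(a, b)] = D[(b, a)] = float(dm[a, b])

    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    active = sorted(labels)
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best = None
        best_pair = None
        for ia in range(n):
            for ib in range(ia + 1, n):
                a, b = active[ia], active[ib]
                q = (n - 2) * D[(a, b)] - r[a] - r[b]
                pair = tuple(sorted((a, b)))
                if best is None or q < best - 1e-12 or (
                        abs(q - best) <= 1e-12 and pair < best_pair):
                    best, best_pair = q, pair
        a, b = best_pair
        d_ab = D[(a, b)]
        va = 0.5 * d_ab + (r[a] - r[b]) / (2 * (n - 2))
        vb = d_ab - va
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length = clamp(va)
        child_b.length = clamp(vb)
        new_label = min(a, b)
        parent = TreeNode(children=[child_a, child_b])
        for c in active:
            if c in (a, b):
                continue
            d_new = 0.5 * (D[(a, c)] + D[(b, c)] - d_ab)
            D[(new_label, c)] = D[(c, new_label)] = d_new
        active = sorted([c for c in active if c not in (a, b)] + [new_label])
        nodes[new_label] = parent

    # resolve the final three clusters around an unrooted (trifurcating) root
    a, b, c = active
    va = clamp(0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)]))
    vb = clamp(0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)]))
    vc = clamp(0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)]))
    nodes[a].length, nodes[b].length, nodes[c].length = va, vb, vc
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    root.negative_branch_clamped = clamped
    return root


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each canonicalised to its smaller side."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        other = taxa - side
        out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap(sequences: Mapping[str, str], n_reps: int = 100,
              seed: int | None = None, model: str = "p") -> TreeNode:
    """NJ tree with bootstrap support (%) on internal nodes.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal edge of the reference tree is the percentage of replicate
    trees containing the same leaf bipartition.  Fully seeded.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    labels, arr = _char_matrix(sequences)
    taxa = frozenset(labels)
    reference = nj_tree(p_distance(sequences, model=model))

    rng = np.random.default_rng(seed)
    n_cols = arr.shape[1]
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = {lab: "".join(arr[i, cols]) for i, lab in enumerate(labels)}
        try:
            rep_tree = nj_tree(p_distance(resampled, model=model))
        except ValidationError:
            continue  # a replicate can lose all comparable columns for a pair
        for bp in _bipartitions(rep_tree, taxa):
            counts[bp] = counts.get(bp, 0) + 1

    for node in reference.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        key = min(side, taxa - side, key=lambda s: (len(s), sorted(s)))
        support = 100.0 * counts.get(key, 0) / n_reps
        node.name = f"{support:g}"
    return reference


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
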