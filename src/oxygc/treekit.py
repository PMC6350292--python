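"""Distances, identity, neighbour-joining and bootstrap from pre-aligned sequences.

Distances follow the p-distance model (proportion of differing nucleotides
among compared columns) with pairwise deletion: a column is compared for a
pair only when both sequences carry an unambiguous base there. Identity is
the mismatch-only complement of p-distance, on the percent scale — gap
columns are never penalised, which matters for fragmentary 16S sequences
whose alignment gaps reflect assembly incompleteness rather than indels.

Trees are :class:`dendropy.Tree` objects throughout the package; the NJ
implementation here is the classic Saitou–Nei agglomeration with a
deterministic, documented tie-break.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

UNAMBIGUOUS = frozenset("ACGT")


class UndefinedDistanceError(ValueError):
    """No comparable (both-unambiguous) columns between two sequences."""


class InsufficientTaxaError(ValueError):
    """Fewer taxa than an operation requires."""


def _comparable_mask(a: str, b: str) -> Tuple[int, int]:
    """(compared columns, mismatches) under pairwise deletion."""
    compared = mismatch = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
            compared += 1
            if x != y:
                mismatch += 1
    return compared, mismatch


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites among pairwise-comparable columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    compared, mismatch = _comparable_mask(seq_a, seq_b)
    if compared == 0:
        raise UndefinedDistanceError("no comparable columns between sequences")
    return mismatch / compared


def identity_percent(seq_a: str, seq_b: str) -> float:
    """100 × (1 − p-distance): mismatch-only identity, gaps excluded."""
    return 100.0 * (1.0 - p_distance(seq_a, seq_b))


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative labelled distance matrix."""

    labels: Sequence[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        la = list(self.labels)
        return float(self.d[la.index(a), la.index(b)])

    @classmethod
    def from_alignment(cls, alignment: Mapping[str, str]) -> "DistanceMatrix":
        """All-pairs p-distance matrix of an aligned sequence set."""
        labels = list(alignment)
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = p_distance(alignment[labels[i]], alignment[labels[j]])
        return cls(labels, d)

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.6f"
        )


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbour joining.

    Deterministic tie-break: among Q-minimal candidate pairs, join the pair
    whose (lexicographically smallest member label, other label) sorted pair
    sorts first. Negative branch lengths are clamped to 0 with the deficit
    transferred to the sister branch (the pair's total is preserved); each
    clamp is logged. Returns an unrooted tree (basal trifurcation).
    """
    n = len(dm)
    if n < 3:
        raise InsufficientTaxaError("neighbour joining requires at least 3 taxa")

    d = dm.d.astype(float).copy()
    # each active cluster: (sort key = smallest contained tip label, newick subtree)
    clusters: Dict[int, Tuple[str, str]] = {
        i: (lbl, _quote(lbl)) for i, lbl in enumerate(dm.labels)
    }
    active = list(range(n))
    next_id = n
    # grow matrix in-place by appending rows for joined nodes
    size = 2 * n - 2
    full = np.zeros((size, size))
    full[:n, :n] = d

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = full[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # all Q-minimal pairs (tolerate fp ties), pick deterministic one
        ties = np.argwhere(q <= qmin + 1e-12)
        best = min(
            ((i, j) for i, j in ties if i < j),
            key=lambda ij: tuple(sorted((clusters[idx[ij[0]]][0], clusters[idx[ij[1]]][0]))),
        )
        a, b = int(best[0]), int(best[1])
        ia, ib = int(idx[a]), int(idx[b])
        dab = sub[a, b]
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        # distances from new node u to every other active cluster
        u = next_id
        next_id += 1
        for k in active:
            if k in (ia, ib):
                continue
            duk = 0.5 * (full[ia, k] + full[ib, k] - dab)
            full[u, k] = full[k, u] = max(duk, 0.0)
        ka, sa = clusters.pop(ia)
        kb, sb = clusters.pop(ib)
        clusters[u] = (min(ka, kb), f"({sa}:{float(la)!r},{sb}:{float(lb)!r})")
        active = [k for k in active if k not in (ia, ib)] + [u]

    # terminal trifurcation: lengths from the three remaining clusters
    i, j, k = active
    li = 0.5 * (full[i, j] + full[i, k] - full[j, k])
    lj = 0.5 * (full[i, j] + full[j, k] - full[i, k])
    lk = 0.5 * (full[i, k] + full[j, k] - full[i, j])
    li, lj, lk = (max(float(x), 0.0) for x in (li, lj, lk))
    subtrees = sorted((clusters[i] + (li,), clusters[j] + (lj,), clusters[k] + (lk,)))
    newick = "(" + ",".join(f"{s}:{l!r}" for _, s, l in subtrees) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def _clamp_pair(la: float, lb: float) -> Tuple[float, float]:
    if la < 0:
        logger.info("negative NJ branch %.3g clamped; deficit moved to sister", la)
        lb += la
        la = 0.0
    if lb < 0:
        logger.info("negative NJ branch %.3g clamped; deficit moved to sister", lb)
        la = max(la + lb, 0.0)
        lb = 0.0
    return la, lb


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def induced_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length (patristic) distance matrix of a tree's tips."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _splits(tree: dendropy.Tree) -> set:
    """Non-trivial bipartitions as canonical frozensets of tip labels."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(all_labels)
    out = set()
    for node in tree.preorder_internal_node_iter():
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in below:
            below = all_labels - below
        if 2 <= len(below) <= len(all_labels) - 2:
            out.add(below)
    return out


def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int = 1000,
    seed: Optional[int] = None,
) -> dendropy.Tree:
    """NJ tree of the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    alignment is rebuilt into an NJ tree and every internal bipartition of
    the full-data tree is annotated with its replicate frequency as an
    integer percent (node labels).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = list(alignment)
    if len(labels) < 3:
        raise InsufficientTaxaError("bootstrap requires at least 3 sequences")
    ncol = len(next(iter(alignment.values())))
    if ncol < 1 or any(len(s) != ncol for s in alignment.values()):
        raise ValueError("alignment must be non-empty and rectangular")

    full_tree = nj_tree(DistanceMatrix.from_alignment(alignment))
    target = {s: 0 for s in _splits(full_tree)}

    rng = np.random.default_rng(seed)
    cols = [np.array([alignment[l][c] for l in labels]) for c in range(ncol)]
    done = 0
    for _ in range(n_reps):
        pick = rng.integers(0, ncol, size=ncol)
        reseq = {
            l: "".join(cols[c][i] for c in pick) for i, l in enumerate(labels)
        }
        try:
            rep_tree = nj_tree(DistanceMatrix.from_alignment(reseq))
        except (UndefinedDistanceError, ValueError):
            logger.warning("bootstrap replicate skipped (degenerate resample)")
            continue
        done += 1
        for s in _splits(rep_tree) & target.keys():
            target[s] += 1

    if done == 0:
        raise UndefinedDistanceError("all bootstrap replicates degenerate")
    all_labels = frozenset(labels)
    anchor = min(all_labels)
    for node in full_tree.preorder_internal_node_iter():
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = all_labels - below if anchor in below else below
        if key in target:
            node.label = str(round(100 * target[key] / done))
    return full_tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(source: str, rooted: Optional[bool] = None) -> dendropy.Tree:
    """Parse a Newick tree from a string or a file path."""
    kwargs = {"schema": "newick", "preserve_underscores": True}
    if rooted is not None:
        kwargs["rooting"] = "force-rooted" if rooted else "force-unrooted"
    if "(" in source:
        return dendropy.Tree.get(data=source, **kwargs)
    return dendropy.Tree.get(path=source, **kwargs)


def write_newick(tree: dendropy.Tree, path: Optional[str] = None) -> str:
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s
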