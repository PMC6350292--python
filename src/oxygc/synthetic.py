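"""Seeded synthetic worlds: trees, oxygen histories, GC-like traits, sequences.

Every generator is a pure function of its parameters plus a single integer
seed; named substreams derived from that seed keep the stages independently
re-simulable. The generators emulate the statistical structure the analysis
assumes — a Yule phylogeny, a small number of oxygen-requirement
transitions placed on edges (mirroring trees where whole clades share a
state), Brownian trait noise with tunable phylogenetic signal λ, coding
sequences with prescribed GC at the fourfold and second-position site
classes, and aligned 16S-like pairs with a prescribed mismatch identity.
They do not emulate realistic substitution processes, indels, rate
variation or selection.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .pgls import brownian_covariance, lambda_transform
from .seqcomp import classify_codon_position, FOURFOLD


def stream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible pseudo-random substream of a single integer seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class SimulationConfig:
    n_tips: int = 100
    birth_rate: float = 1.0
    n_transitions: int = 5
    slope_true: float = 0.0
    sigma2: float = 1.0
    lambda_true: float = 1.0
    intercept_true: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0 or self.sigma2 < 0:
            raise ValueError("rates must be positive, sigma2 non-negative")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Trees and state histories
# ---------------------------------------------------------------------------

def simulate_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Rooted ultrametric pure-birth (Yule) tree with ``n_tips`` tips.

    With k extant lineages the waiting time to the next split is
    Exponential(k · birth_rate); after the last split the tree is extended
    by one further waiting time, so the expected root-to-tip depth is
    Σ_{k=2..n} 1/(k · birth_rate). Tips are labelled t1..tn.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = stream(seed, "tree")
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    root = tree.seed_node
    tips: List[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        tips.append(child)
    k = 2
    while True:
        wait = rng.exponential(1.0 / (k * birth_rate))
        for t in tips:
            t.edge.length += wait
        if k == n_tips:
            break
        pick = int(rng.integers(0, k))
        node = tips.pop(pick)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            node.add_child(child)
            tips.append(child)
        k += 1
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = ns.new_taxon(label=f"t{i + 1}")
    return tree


def simulate_oxygen_states(
    tree: dendropy.Tree, n_transitions: int, seed: int = 0
) -> Dict[str, str]:
    """Tip oxygen states from exactly ``n_transitions`` flips on distinct edges.

    Edges (excluding the root edge) are chosen uniformly without
    replacement; states are inherited from an anaerobic root, flipping
    wherever a marked edge is crossed. Returns tip label → "aerobe" /
    "anaerobe".
    """
    edges = [
        nd for nd in tree.preorder_node_iter() if nd.parent_node is not None
    ]
    if not 0 <= n_transitions <= len(edges):
        raise ValueError(
            f"n_transitions must lie in [0, {len(edges)}], got {n_transitions}"
        )
    rng = stream(seed, "states")
    flipped = set(
        id(edges[i]) for i in rng.choice(len(edges), size=n_transitions, replace=False)
    )
    state: Dict[int, bool] = {id(tree.seed_node): False}  # False = anaerobe
    out: Dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        s = state[id(node.parent_node)] ^ (id(node) in flipped)
        state[id(node)] = s
        if node.is_leaf():
            out[node.taxon.label] = "aerobe" if s else "anaerobe"
    return out


def simulate_gc_trait(
    tree: dendropy.Tree,
    states: Mapping[str, str],
    config: SimulationConfig,
) -> Tuple[List[str], np.ndarray, np.ndarray, Dict[str, float]]:
    """GC-like tip trait: state mean shift plus Brownian noise with signal λ.

    y = intercept + slope · x + ε with x the 2/3 oxygen code (aerobe 3,
    anaerobe 2) and ε ~ MVN(0, σ² · C(λ)) for the tree's Brownian
    covariance C. Returns (labels, y, x, ground truth).
    """
    cov = brownian_covariance(tree)
    labels = list(cov.labels)
    missing = [l for l in labels if l not in states]
    if missing:
        raise ValueError(f"states missing for tips: {missing[:5]}")
    x = np.array([3.0 if states[l].startswith("aero") else 2.0 for l in labels])
    mean = config.intercept_true + config.slope_true * x
    V = config.sigma2 * lambda_transform(cov, config.lambda_true).C
    rng = stream(config.seed, "trait")
    if config.sigma2 == 0:
        y = mean
    else:
        L = np.linalg.cholesky(V + 1e-12 * np.eye(len(labels)))
        y = mean + L @ rng.standard_normal(len(labels))
    truth = {
        "slope_true": config.slope_true,
        "intercept_true": config.intercept_true,
        "sigma2": config.sigma2,
        "lambda_true": config.lambda_true,
    }
    return labels, y, x, truth


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

# fourfold-degenerate codon family prefixes under the bacterial code,
# split by their second base: AT-second vs GC-second
_AT2_PREFIXES = ("CT", "GT")            # Leu, Val
_GC2_PREFIXES = ("TC", "CC", "AC", "GC", "CG", "GG")  # Ser Pro Thr Ala Arg Gly


@dataclass(frozen=True)
class GeneratedCDS:
    """A synthetic coding sequence plus the generator's own site bookkeeping."""

    sequence: str
    gc_4fds: float
    gc_zrs: float
    n_4fds: int
    n_zrs: int


def generate_cds(
    n_codons: int,
    gc4_target: float,
    gczrs_target: float,
    table: int = 11,
    seed: int = 0,
) -> GeneratedCDS:
    """In-frame, stop-free CDS hitting prescribed 4FDS and ZRS GC fractions.

    Every codon is drawn from a fourfold-degenerate family, so all third
    positions are 4FDS and all second positions are ZRS; the realised
    fractions equal round(target · n)/n, within 1/n_codons of the targets.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    for t in (gc4_target, gczrs_target):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"target {t} outside [0, 1]")
    for p in _AT2_PREFIXES + _GC2_PREFIXES:
        if classify_codon_position(p + "A", 3, table) != FOURFOLD:
            raise ValueError(
                f"codon family {p}N is not fourfold under table {table}; "
                "only standard-degeneracy tables are supported"
            )
    rng = stream(seed, "cds")
    n_gc2 = round(gczrs_target * n_codons)
    n_gc4 = round(gc4_target * n_codons)
    prefixes = [
        str(rng.choice(_GC2_PREFIXES)) if i < n_gc2 else str(rng.choice(_AT2_PREFIXES))
        for i in range(n_codons)
    ]
    thirds = [
        str(rng.choice(("G", "C"))) if i < n_gc4 else str(rng.choice(("A", "T")))
        for i in range(n_codons)
    ]
    rng.shuffle(prefixes)
    rng.shuffle(thirds)
    seq = "".join(p + t for p, t in zip(prefixes, thirds))
    return GeneratedCDS(
        sequence=seq,
        gc_4fds=n_gc4 / n_codons,
        gc_zrs=n_gc2 / n_codons,
        n_4fds=n_codons,
        n_zrs=n_codons,
    )


def generate_16s_pair(
    length: int,
    identity_target: float,
    seed: int = 0,
    gap_columns: int = 0,
) -> Tuple[str, str]:
    """Aligned sequence pair with a prescribed mismatch-only identity.

    The second sequence differs from the first at round((1 − identity/100) ·
    length) positions. ``gap_columns`` extra columns carrying a gap in one
    of the two sequences are interleaved at random positions; they exercise
    (and must not change) the gap-excluding identity rule.
    """
    if not 0.0 <= identity_target <= 100.0:
        raise ValueError("identity_target must lie in [0, 100]")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = stream(seed, "16s")
    bases = np.array(list("ACGT"))
    a = rng.choice(bases, size=length)
    b = a.copy()
    k = round((1.0 - identity_target / 100.0) * length)
    if k:
        pos = rng.choice(length, size=k, replace=False)
        for p in pos:
            b[p] = rng.choice([x for x in "ACGT" if x != a[p]])
    cols = [(x, y) for x, y in zip(a, b)]
    for _ in range(gap_columns):
        at = int(rng.integers(0, len(cols) + 1))
        base = str(rng.choice(bases))
        cols.insert(at, (base, "-") if rng.random() < 0.5 else ("-", base))
    return "".join(c[0] for c in cols), "".join(c[1] for c in cols)
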