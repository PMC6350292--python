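"""Phylogenetically independent aerobe–anaerobe pairs.

An aerobe and an anaerobe flanking a single evolutionary change in oxygen
requirement form one pair; because no organism enters two pairs, the
within-pair GC differences are statistically independent and a paired test
on them is a phylogenetically controlled comparison.

The normative adjacency rule (the source literature defines it only by
example) is collapse-and-scan: maximal state-uniform clades of the rooted
tree are collapsed to single groups, and a bottom-up greedy scan creates
one state-contrast event per mixed node, pairing the largest available
aerobic group with the largest available anaerobic group. Groups left over
at a node where an event fired are discarded (conservative — preserves
independence); at single-state nodes the largest group propagates upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import dendropy

logger = logging.getLogger(__name__)

AEROBIC = "aerobic"
ANAEROBIC = "anaerobic"

#: raw oxygen-requirement categories → merged two-state coding
MERGE = {
    "aerobe": AEROBIC,
    "obligate aerobe": AEROBIC,
    "obligate_aerobe": AEROBIC,
    "anaerobe": ANAEROBIC,
    "obligate anaerobe": ANAEROBIC,
    "obligate_anaerobe": ANAEROBIC,
}

RANKS = ("species", "genus", "family", "order", "class")


class LabellingError(ValueError):
    """A tip lacks an oxygen-state label."""


def merge_state(state: str) -> str:
    """Collapse the four oxygen-requirement categories to aerobic/anaerobic."""
    key = state.strip().lower()
    if key in (AEROBIC, ANAEROBIC):
        return key
    try:
        return MERGE[key]
    except KeyError:
        raise LabellingError(f"unknown oxygen state: {state!r}") from None


@dataclass(frozen=True)
class OrganismRecord:
    organism_id: str
    oxygen_state: str
    taxonomy: Mapping[str, str] = field(default_factory=dict)
    annotation_count: Optional[int] = None

    @property
    def merged_state(self) -> str:
        return merge_state(self.oxygen_state)


@dataclass(frozen=True)
class StateChangeEvent:
    event_id: int
    aerobic_tips: FrozenSet[str]
    anaerobic_tips: FrozenSet[str]


@dataclass(frozen=True)
class PairRecord:
    event_id: int
    aerobic_tip: str
    anaerobic_tip: str
    mode: str
    identity_16s: Optional[float] = None


def taxonomic_prefilter(
    records: Sequence[OrganismRecord], ranks: Sequence[str] = RANKS
) -> List[Tuple[OrganismRecord, str]]:
    """Keep organisms in taxa containing both oxygen states, lowest rank first.

    Iterates ranks from species upward; at each rank, groups the records not
    claimed at a lower rank by their taxon name and keeps every group that
    contains both merged states. Returns (record, qualifying rank) tuples.
    """
    remaining = list(records)
    kept: List[Tuple[OrganismRecord, str]] = []
    for rank in ranks:
        groups: Dict[str, List[OrganismRecord]] = {}
        for rec in remaining:
            name = rec.taxonomy.get(rank)
            if name:
                groups.setdefault(name, []).append(rec)
        claimed = set()
        for name, members in groups.items():
            states = {m.merged_state for m in members}
            if AEROBIC in states and ANAEROBIC in states:
                kept.extend((m, rank) for m in members)
                claimed.update(id(m) for m in members)
        remaining = [r for r in remaining if id(r) not in claimed]
    return kept


# ---------------------------------------------------------------------------
# State-change events
# ---------------------------------------------------------------------------

def _merged_tip_states(
    tree: dendropy.Tree, states: Mapping[str, str]
) -> Dict[str, str]:
    out = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in states:
            raise LabellingError(f"tip {label!r} has no oxygen-state label")
        out[label] = merge_state(states[label])
    return out


def find_state_change_events(
    tree: dendropy.Tree, states: Mapping[str, str]
) -> List[StateChangeEvent]:
    """One event per oxygen-requirement contrast between adjacent uniform groups.

    ``states`` maps tip label → oxygen state (raw categories accepted; merged
    internally). Events are tip-disjoint by construction.
    """
    tip_state = _merged_tip_states(tree, states)
    events: List[Tuple[FrozenSet[str], FrozenSet[str]]] = []

    def group_key(g: FrozenSet[str]) -> Tuple[int, str]:
        return (-len(g), min(g))

    def visit(node) -> Dict[str, FrozenSet[str]]:
        """Return exposed (still pairable) groups, at most one per state."""
        if node.is_leaf():
            label = node.taxon.label
            return {tip_state[label]: frozenset([label])}
        child_groups: List[Tuple[str, FrozenSet[str]]] = []
        for child in node.child_nodes():
            for st, grp in visit(child).items():
                child_groups.append((st, grp))
        aer = sorted((g for s, g in child_groups if s == AEROBIC), key=group_key)
        ana = sorted((g for s, g in child_groups if s == ANAEROBIC), key=group_key)
        if aer and ana:
            events.append((aer[0], ana[0]))
            # leftovers at a mixed node are discarded: pairing any of them
            # higher up could straddle this event's branch
            return {}
        exposed: Dict[str, FrozenSet[str]] = {}
        if aer:
            # same-state sibling groups merge: together they form one
            # state-uniform clade of this node
            exposed[AEROBIC] = frozenset().union(*aer)
        if ana:
            exposed[ANAEROBIC] = frozenset().union(*ana)
        return exposed

    visit(tree.seed_node)
    events.sort(key=lambda ev: min(ev[0] | ev[1]))
    return [
        StateChangeEvent(i, aer, ana) for i, (aer, ana) in enumerate(events)
    ]


# ---------------------------------------------------------------------------
# Representatives and pairs
# ---------------------------------------------------------------------------

def _depths(tree: dendropy.Tree) -> Dict[int, float]:
    d = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        d[id(node)] = edge + (d[id(parent)] if parent is not None else 0.0)
    return d


def select_representative(
    group: FrozenSet[str],
    tree: dendropy.Tree,
    mode: str = "slow",
    annotation_counts: Optional[Mapping[str, int]] = None,
) -> str:
    """Pick the slowest- (or fastest-) evolving member of a tip group.

    Rate is the path length from the group's most recent common ancestor to
    the tip. Ties go to the genome with more annotated genes, then to the
    lexicographically smallest id.
    """
    if not group:
        raise ValueError("empty group")
    if mode not in ("slow", "fast"):
        raise ValueError(f"mode must be 'slow' or 'fast', got {mode!r}")
    if len(group) == 1:
        return next(iter(group))
    mrca = tree.mrca(taxon_labels=list(group))
    depths = _depths(tree)
    base = depths[id(mrca)]
    leaf_by_label = {
        lf.taxon.label: lf for lf in mrca.leaf_iter() if lf.taxon.label in group
    }
    counts = annotation_counts or {}

    def key(label: str):
        path = depths[id(leaf_by_label[label])] - base
        signed = path if mode == "slow" else -path
        return (round(signed, 12), -counts.get(label, 0), label)

    return min(group, key=key)


def extract_independent_pairs(
    tree: dendropy.Tree,
    states: Mapping[str, str],
    mode: str = "slow",
    annotation_counts: Optional[Mapping[str, int]] = None,
) -> List[PairRecord]:
    """One aerobe–anaerobe pair per state-change event (see module docstring)."""
    events = find_state_change_events(tree, states)
    pairs = []
    for ev in events:
        pairs.append(
            PairRecord(
                event_id=ev.event_id,
                aerobic_tip=select_representative(
                    ev.aerobic_tips, tree, mode, annotation_counts
                ),
                anaerobic_tip=select_representative(
                    ev.anaerobic_tips, tree, mode, annotation_counts
                ),
                mode=mode,
            )
        )
    return pairs


def attach_identities(
    pairs: Sequence[PairRecord], identities: Mapping[Tuple[str, str], float]
) -> List[PairRecord]:
    """Annotate pairs with 16S identity percentages (order-insensitive keys)."""
    out = []
    for p in pairs:
        ident = identities.get((p.aerobic_tip, p.anaerobic_tip))
        if ident is None:
            ident = identities.get((p.anaerobic_tip, p.aerobic_tip))
        out.append(replace(p, identity_16s=ident))
    return out


def filter_pairs_by_identity(
    pairs: Sequence[PairRecord], threshold: float
) -> List[PairRecord]:
    """Keep pairs whose 16S identity is at least ``threshold`` percent.

    Threshold 0 keeps everything. A positive threshold excludes pairs with
    no identity annotation, with a logged warning.
    """
    if threshold <= 0:
        return list(pairs)
    kept = []
    for p in pairs:
        if p.identity_16s is None:
            logger.warning(
                "pair (%s, %s) lacks 16S identity; excluded at threshold %s",
                p.aerobic_tip, p.anaerobic_tip, threshold,
            )
        elif p.identity_16s >= threshold:
            kept.append(p)
    return kept


def identity_threshold_sweep(
    pairs: Sequence[PairRecord], thresholds: Sequence[float]
) -> Dict[float, List[PairRecord]]:
    """One filtered pair subset per identity threshold (sensitivity analysis)."""
    return {t: filter_pairs_by_identity(pairs, t) for t in thresholds}
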