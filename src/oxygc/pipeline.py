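"""End-to-end orchestration: composition → pairing → tests, and PGLS tables.

Two entry points mirror the two phylogenetically controlled analyses:

``run_pairwise_analysis``
    per-organism GC at three site classes → independent aerobe–anaerobe
    pairs (slow- and fast-evolving representative datasets) → two-tailed
    Wilcoxon signed-rank test per site class per 16S-identity threshold,
    plus scatter data (points above the aerobe = anaerobe diagonal are
    pairs where the anaerobe has the higher GC).

``run_pgls_analysis``
    per-contrast ordinal coding (more oxygen-preferring = 3, less = 2) →
    PGLS of log GC on the code under a λ-scaled Brownian covariance, one
    row per contrast, one column block per site class.

Inputs are either file paths (Newick tree, TSV trait table, CDS FASTA) or
the built-in simulation preset with known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .pairing import (
    PairRecord,
    attach_identities,
    extract_independent_pairs,
    filter_pairs_by_identity,
    find_state_change_events,
)
from .pgls import (
    CONTRASTS,
    EmptyGroupError,
    brownian_covariance,
    encode_oxygen,
    log_transform_gc,
    pgls_fit,
)
from .seqcomp import CompositionRecord, composition_record
from .stats import wilcoxon_signed_rank
from .synthetic import (
    SimulationConfig,
    generate_16s_pair,
    generate_cds,
    simulate_gc_trait,
    simulate_oxygen_states,
    simulate_tree,
    stream,
)
from .treekit import identity_percent, read_newick, write_newick

logger = logging.getLogger(__name__)

MEASURES = ("gc_genome", "gc_4fds", "gc_zrs")


class InsufficientPairsError(ValueError):
    """Fewer than two independent pairs — no paired test possible."""


@dataclass
class RunConfig:
    """One end-to-end run: either file inputs or a simulation preset."""

    preset: Optional[str] = None
    tree_path: Optional[str] = None
    traits_path: Optional[str] = None
    cds_paths: Optional[Mapping[str, str]] = None  # organism id -> CDS FASTA
    identity_path: Optional[str] = None
    mode: str = "slow"
    contrasts: Sequence[str] = field(default_factory=lambda: list(CONTRASTS))
    identity_thresholds: Sequence[float] = (0.0,)
    lambda_mode: object = "ml"
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.tree_path is None):
            raise ValueError("set exactly one of preset / tree_path")


@dataclass
class World:
    """Resolved inputs for one run: tree, states, compositions, identities."""

    tree: dendropy.Tree
    states: Dict[str, str]                      # organism -> raw 4-way category
    compositions: Dict[str, CompositionRecord]
    annotation_counts: Dict[str, int]
    identities: Dict[Tuple[str, str], float] = field(default_factory=dict)
    truth: Dict[str, object] = field(default_factory=dict)
    cds: Dict[str, str] = field(default_factory=dict)  # organism -> CDS sequence


# ---------------------------------------------------------------------------
# Simulation preset
# ---------------------------------------------------------------------------

#: graded true 4FDS GC per oxygen category (fractions): the generating world
#: of the "table1" preset — strongest elevation in obligate aerobes,
#: weakest in obligate anaerobes, spanning the realistic prokaryote range
PRESET_GC4 = {
    "obligate anaerobe": 0.38,
    "anaerobe": 0.43,
    "aerobe": 0.50,
    "obligate aerobe": 0.58,
}
PRESET_N_TIPS = 80
PRESET_TRANSITIONS = 10
PRESET_BM_SD = 0.04        # Brownian sd of the GC fraction per unit depth
PRESET_N_CODONS = 300
PRESET_OBLIGATE_FRACTION = 0.5


def simulate_world(seed: int, n_tips: int = PRESET_N_TIPS,
                   n_transitions: int = PRESET_TRANSITIONS) -> World:
    """The "table1" preset: a synthetic world with graded oxygen/GC coupling."""
    tree = simulate_tree(n_tips, birth_rate=1.0, seed=seed)
    merged = simulate_oxygen_states(tree, n_transitions, seed=seed)
    rng = stream(seed, "world")

    states: Dict[str, str] = {}
    for label in sorted(merged):
        base = merged[label]
        obligate = rng.random() < PRESET_OBLIGATE_FRACTION
        states[label] = ("obligate " + base) if obligate else base

    cfg = SimulationConfig(
        n_tips=n_tips, sigma2=PRESET_BM_SD ** 2, lambda_true=1.0, seed=seed
    )
    labels, noise, _, _ = simulate_gc_trait(tree, merged, dataclasses.replace(cfg))

    compositions: Dict[str, CompositionRecord] = {}
    annotation_counts: Dict[str, int] = {}
    cds_by_organism: Dict[str, str] = {}
    gc4_true: Dict[str, float] = {}
    for label, eps in zip(labels, noise):
        gc4 = float(np.clip(PRESET_GC4[states[label]] + eps, 0.05, 0.95))
        gczrs = float(np.clip(0.30 + 0.4 * gc4, 0.05, 0.95))
        gc4_true[label] = gc4
        cds = generate_cds(
            PRESET_N_CODONS, gc4, gczrs, seed=int(stream(seed, "cds-" + label).integers(2**31))
        )
        compositions[label] = composition_record(
            label, genome=cds.sequence, cds_set=[cds.sequence]
        )
        annotation_counts[label] = int(rng.integers(1500, 4500))
        cds_by_organism[label] = cds.sequence

    world = World(
        tree=tree,
        states=states,
        compositions=compositions,
        annotation_counts=annotation_counts,
        truth={"gc4_by_state": PRESET_GC4, "gc4_true": gc4_true,
               "n_transitions": n_transitions},
        cds=cds_by_organism,
    )
    # one synthetic 16S divergence per state-change event, shared by every
    # aerobe-anaerobe combination within it (divergence time is a property
    # of the lineage split, not of the chosen representatives)
    for ev in find_state_change_events(tree, merged):
        target = float(rng.uniform(88.0, 100.0))
        a, b = generate_16s_pair(
            1000, target, seed=int(rng.integers(2**31)), gap_columns=20
        )
        ident = identity_percent(a, b)
        for at in sorted(ev.aerobic_tips):
            for nt in sorted(ev.anaerobic_tips):
                world.identities[(at, nt)] = ident
    return world


# ---------------------------------------------------------------------------
# File inputs
# ---------------------------------------------------------------------------

def load_world(config: RunConfig) -> World:
    if config.preset is not None:
        return simulate_world(config.seed)
    tree = read_newick(config.tree_path, rooted=True)
    traits = pd.read_csv(config.traits_path, sep="\t", dtype={"organism_id": str})
    states = dict(zip(traits["organism_id"], traits["oxygen_state"]))
    counts = (
        dict(zip(traits["organism_id"], traits["annotation_count"].fillna(0).astype(int)))
        if "annotation_count" in traits
        else {}
    )
    compositions: Dict[str, CompositionRecord] = {}
    if config.cds_paths:
        for oid, path in config.cds_paths.items():
            cds = [str(rec.seq) for rec in SeqIO.parse(path, "fasta")]
            compositions[oid] = composition_record(
                oid, genome="".join(cds), cds_set=cds
            )
    else:
        for _, row in traits.iterrows():
            compositions[row["organism_id"]] = CompositionRecord(
                row["organism_id"],
                row.get("gc_genome"), row.get("gc_4fds"), row.get("gc_zrs"),
                1, 1, 1,
            )
    identities: Dict[Tuple[str, str], float] = {}
    if config.identity_path:
        ident = pd.read_csv(config.identity_path, sep="\t")
        for _, row in ident.iterrows():
            identities[(str(row["organism_a"]), str(row["organism_b"]))] = float(
                row["identity_16s"]
            )
    return World(tree, states, compositions, counts, identities)


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------

def _merged(states: Mapping[str, str]) -> Dict[str, str]:
    from .pairing import merge_state

    return {k: merge_state(v) for k, v in states.items()}


def _pair_values(
    pairs: Sequence[PairRecord],
    compositions: Mapping[str, CompositionRecord],
    measure: str,
) -> Tuple[np.ndarray, np.ndarray]:
    aer, ana = [], []
    for p in pairs:
        va = getattr(compositions[p.aerobic_tip], measure)
        vn = getattr(compositions[p.anaerobic_tip], measure)
        if va is None or vn is None:
            logger.warning("pair (%s, %s) lacks %s; dropped",
                           p.aerobic_tip, p.anaerobic_tip, measure)
            continue
        aer.append(va)
        ana.append(vn)
    return np.array(aer), np.array(ana)


def run_pairwise_analysis(config: RunConfig, world: Optional[World] = None):
    """Independent-pair extraction and Wilcoxon tests; returns (report, scatter).

    One report row per (mode, site class, identity threshold): number of
    pairs, number where the aerobe has the higher GC, W+ and its two-tailed
    p. Scatter rows carry the per-pair aerobic and anaerobic values that
    Fig-style diagonal plots are drawn from.
    """
    world = world or load_world(config)
    merged = _merged(world.states)
    report_rows, scatter_rows = [], []
    for mode in ("slow", "fast"):
        pairs = extract_independent_pairs(
            world.tree, merged, mode, world.annotation_counts
        )
        pairs = attach_identities(pairs, world.identities)
        if len(pairs) < 2:
            raise InsufficientPairsError(
                f"only {len(pairs)} independent pair(s) extracted"
            )
        for thr in config.identity_thresholds:
            kept = filter_pairs_by_identity(pairs, thr)
            for measure in MEASURES:
                aer, ana = _pair_values(kept, world.compositions, measure)
                if len(aer) < 2:
                    logger.warning("skipping %s at threshold %s: <2 pairs", measure, thr)
                    continue
                diffs = aer - ana
                res = wilcoxon_signed_rank(diffs)
                report_rows.append({
                    "mode": mode, "measure": measure, "identity_threshold": thr,
                    "n_pairs": len(aer),
                    "n_aerobe_higher": int(np.sum(diffs > 0)),
                    "statistic_w_plus": res.statistic,
                    "p_two_tailed": res.p_two_tailed,
                    "method": res.method,
                })
        for p in pairs:
            row = {"mode": mode, "event_id": p.event_id,
                   "aerobic_tip": p.aerobic_tip, "anaerobic_tip": p.anaerobic_tip,
                   "identity_16s": p.identity_16s}
            for measure in MEASURES:
                row[f"aerobe_{measure}"] = getattr(
                    world.compositions[p.aerobic_tip], measure)
                row[f"anaerobe_{measure}"] = getattr(
                    world.compositions[p.anaerobic_tip], measure)
            scatter_rows.append(row)
    report = pd.DataFrame(report_rows)
    scatter = pd.DataFrame(scatter_rows)
    if config.out_dir:
        _write_outputs(config, {"pairwise_report.tsv": report,
                                "pairwise_scatter.tsv": scatter})
    return report, scatter


def run_pgls_analysis(config: RunConfig, world: Optional[World] = None) -> pd.DataFrame:
    """PGLS of log GC on the 2/3 oxygen code, per contrast and site class.

    Output is shaped like the source analysis' regression table: one row per
    contrast with n and, for each site class, λ̂, slope and two-tailed p.
    """
    world = world or load_world(config)
    tips = {lf.taxon.label for lf in world.tree.leaf_node_iter()}
    for oid in world.states:
        if oid not in tips:
            raise ValueError(f"organism {oid!r} missing from the tree")
    cov_full = brownian_covariance(world.tree)
    rows = []
    for contrast in config.contrasts:
        try:
            ids, codes = encode_oxygen(world.states, contrast)
        except EmptyGroupError:
            logger.warning("contrast %r skipped: empty group", contrast)
            continue
        row: Dict[str, object] = {"contrast": contrast}
        for measure in MEASURES:
            sel = [
                (i, c) for i, c in zip(ids, codes)
                if getattr(world.compositions[i], measure) is not None
            ]
            if len(sel) < 3 or len({c for _, c in sel}) < 2:
                logger.warning("contrast %r / %s skipped: n < 3", contrast, measure)
                continue
            sub_ids = [i for i, _ in sel]
            x = np.array([c for _, c in sel])
            y = np.array([
                log_transform_gc(getattr(world.compositions[i], measure))
                for i in sub_ids
            ])
            fit = pgls_fit(y, x, cov_full.subset(sub_ids), config.lambda_mode)
            row["n"] = fit.n
            row[f"{measure}_lambda"] = fit.lambda_hat
            row[f"{measure}_slope"] = fit.slope
            row[f"{measure}_p"] = fit.p_two_tailed
        if len(row) > 1:
            rows.append(row)
    table = pd.DataFrame(rows)
    if config.out_dir:
        _write_outputs(config, {"pgls_table.tsv": table})
    return table


def _write_outputs(config: RunConfig, frames: Mapping[str, pd.DataFrame]) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    for name, df in frames.items():
        df.to_csv(os.path.join(config.out_dir, name), sep="\t",
                  index=False, float_format="%.6g")
    manifest = {
        "oxygc_version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "mode": config.mode,
        "identity_thresholds": list(config.identity_thresholds),
        "contrasts": list(config.contrasts),
        "inputs": {
            "tree": config.tree_path,
            "traits": config.traits_path,
            "identities": config.identity_path,
        },
    }
    with open(os.path.join(config.out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def write_world(world: World, out_dir: str) -> None:
    """Dump a (typically simulated) world as FASTA / Newick / TSV / JSON files."""
    os.makedirs(out_dir, exist_ok=True)
    write_newick(world.tree, os.path.join(out_dir, "tree.nwk"))
    rows = []
    for oid in sorted(world.states):
        c = world.compositions[oid]
        rows.append({
            "organism_id": oid, "oxygen_state": world.states[oid],
            "annotation_count": world.annotation_counts.get(oid, ""),
            "gc_genome": c.gc_genome, "gc_4fds": c.gc_4fds, "gc_zrs": c.gc_zrs,
            "n_sites_genome": c.n_sites_genome, "n_sites_4fds": c.n_sites_4fds,
            "n_sites_zrs": c.n_sites_zrs,
        })
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "traits.tsv"), sep="\t", index=False,
        float_format="%.6f",
    )
    if world.identities:
        pd.DataFrame(
            [{"organism_a": a, "organism_b": b, "identity_16s": v}
             for (a, b), v in sorted(world.identities.items())]
        ).to_csv(os.path.join(out_dir, "identities.tsv"), sep="\t", index=False)
    if world.truth:
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            json.dump(world.truth, fh, indent=2, default=str)


def write_cds_fasta(world: World, path: str) -> None:
    """One CDS record per organism (synthetic worlds only)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for oid in sorted(world.cds):
            fh.write(f">{oid}\n")
            seq = world.cds[oid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
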