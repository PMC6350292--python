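"""Nucleotide composition at codon-degeneracy site classes.

GC content is computed for whole sequences, for fourfold degenerate sites
(4FDS: third codon positions where every base encodes the same amino acid;
the closest thing a prokaryotic genome offers to neutrally evolving sites),
and for zerofold redundant sites (ZRS), operationally defined here as the
second nucleotides of all non-stop codons — every substitution at such a
site is non-synonymous.

Also hosts the orthologue distance-ratio filter used to screen reciprocal
best-hit pairs against an outgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence, Tuple

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

BASES = "ACGT"

ZEROFOLD = "zerofold"
TWOFOLD = "twofold"
THREEFOLD = "threefold"
FOURFOLD = "fourfold"
OTHER = "other"


class UndefinedCompositionError(ValueError):
    """Raised when a GC fraction has an empty site set (0 unambiguous bases)."""


@dataclass(frozen=True)
class CompositionRecord:
    """GC fractions of one organism at the three site classes.

    A fraction is ``None`` exactly when its site count is 0 (no sites of
    that class were observed), never NaN.
    """

    organism_id: str
    gc_genome: Optional[float]
    gc_4fds: Optional[float]
    gc_zrs: Optional[float]
    n_sites_genome: int
    n_sites_4fds: int
    n_sites_zrs: int

    def __post_init__(self) -> None:
        for frac, count in (
            (self.gc_genome, self.n_sites_genome),
            (self.gc_4fds, self.n_sites_4fds),
            (self.gc_zrs, self.n_sites_zrs),
        ):
            if (frac is None) != (count == 0):
                raise ValueError("fraction undefined iff site count is 0")
            if frac is not None and not 0.0 <= frac <= 1.0:
                raise ValueError(f"GC fraction {frac} outside [0, 1]")


def gc_content(sequence: str) -> float:
    """GC fraction of ``sequence`` over its unambiguous A/C/G/T bases.

    Case-insensitive; any symbol outside {A, C, G, T} (N, gaps, IUPAC
    ambiguity codes ...) is excluded from numerator and denominator.
    """
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    total = gc + at
    if total == 0:
        raise UndefinedCompositionError("no unambiguous A/C/G/T bases in sequence")
    return gc / total


@lru_cache(maxsize=8)
def _codon_map(table: int) -> Tuple[dict, frozenset]:
    ct = CodonTable.unambiguous_dna_by_id[table]
    return dict(ct.forward_table), frozenset(ct.stop_codons)


def is_stop(codon: str, table: int = 11) -> bool:
    _, stops = _codon_map(table)
    return codon.upper() in stops


def classify_codon_position(codon: str, position: int, table: int = 11) -> str:
    """Degeneracy class of one position (1..3) of ``codon``.

    A position is *fourfold* iff all four substitutions there leave the
    encoded amino acid unchanged, *zerofold* iff none does, twofold /
    threefold in between. Stop codons are classified by the same
    substitution rule, with stop treated as its own "amino acid".
    Codons containing non-ACGT symbols classify as ``"other"``.
    """
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1, 2 or 3, got {position}")
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        return OTHER
    fwd, stops = _codon_map(table)

    def aa(c: str) -> str:
        return "*" if c in stops else fwd[c]

    ref = aa(codon)
    i = position - 1
    synonymous = sum(
        1
        for b in BASES
        if b != codon[i] and aa(codon[:i] + b + codon[i + 1:]) == ref
    )
    return {0: ZEROFOLD, 1: TWOFOLD, 2: THREEFOLD, 3: FOURFOLD}[synonymous]


def _iter_codons(cds_set: Iterable[str], table: int) -> Iterable[str]:
    """Yield codons from well-formed CDSs; skip malformed ones with a log line.

    A CDS is skipped when its length is not a multiple of 3 or it contains
    an internal stop codon (a trailing stop is fine and is yielded, flagged
    downstream). Codons containing ambiguity symbols are yielded as-is;
    site-class accumulators ignore them.
    """
    for idx, cds in enumerate(cds_set):
        s = cds.upper().replace("U", "T")
        if len(s) % 3 != 0:
            logger.warning("CDS %d skipped: length %d not divisible by 3", idx, len(s))
            continue
        codons = [s[j:j + 3] for j in range(0, len(s), 3)]
        if any(is_stop(c, table) for c in codons[:-1]):
            logger.warning("CDS %d skipped: internal stop codon", idx)
            continue
        yield from codons


def gc_at_4fds(cds_set: Sequence[str], table: int = 11) -> Tuple[float, int]:
    """Pooled GC fraction at fourfold degenerate third codon positions.

    Third positions of codons whose third position is fourfold are pooled
    across the entire CDS set; returns ``(gc_fraction, n_sites)``.
    """
    gc = n = 0
    for codon in _iter_codons(cds_set, table):
        if classify_codon_position(codon, 3, table) == FOURFOLD:
            n += 1
            if codon[2] in "GC":
                gc += 1
    if n == 0:
        raise UndefinedCompositionError("no fourfold degenerate sites in CDS set")
    return gc / n, n


def gc_at_zrs(
    cds_set: Sequence[str], table: int = 11, strict_zerofold: bool = False
) -> Tuple[float, int]:
    """Pooled GC fraction at zerofold redundant sites.

    Default (literal) definition: the second nucleotide of every non-stop
    codon. With ``strict_zerofold=True`` only second positions that
    classify zerofold by the substitution rule are pooled (sensitivity
    mode; Met/Trp-like codons are a subset of the literal definition).
    """
    gc = n = 0
    for codon in _iter_codons(cds_set, table):
        if is_stop(codon, table):
            continue
        cls = classify_codon_position(codon, 2, table)
        if cls == OTHER:
            continue  # ambiguous codon contributes no site
        if strict_zerofold and cls != ZEROFOLD:
            continue
        n += 1
        if codon[1] in "GC":
            gc += 1
    if n == 0:
        raise UndefinedCompositionError("no zerofold redundant sites in CDS set")
    return gc / n, n


def composition_record(
    organism_id: str,
    genome: Optional[str] = None,
    cds_set: Optional[Sequence[str]] = None,
    table: int = 11,
) -> CompositionRecord:
    """Build a :class:`CompositionRecord` from a genome sequence and/or CDS set."""
    gcg, ng = None, 0
    if genome is not None:
        s = genome.upper()
        gc = s.count("G") + s.count("C")
        ng = gc + s.count("A") + s.count("T")
        gcg = gc / ng if ng else None
    gc4, n4, gcz, nz = None, 0, None, 0
    if cds_set:
        try:
            gc4, n4 = gc_at_4fds(cds_set, table)
        except UndefinedCompositionError:
            pass
        try:
            gcz, nz = gc_at_zrs(cds_set, table)
        except UndefinedCompositionError:
            pass
    return CompositionRecord(organism_id, gcg, gc4, gcz, ng, n4, nz)


def ortholog_ratio_filter(
    d_in1_in2: float,
    d_in1_out: float,
    d_in2_out: float,
    threshold: float = 0.8,
) -> bool:
    """Screen a putative orthologue pair against an outgroup distance.

    ratio1 = d(in1, in2) / d(in1, out) and ratio2 = d(in1, in2) / d(in2, out);
    the pair is kept iff both ratios are ≤ ``threshold`` (boundary keeps).
    A pair whose ingroup members diverged nearly as much as either did from
    the outgroup is an unreliable orthologue call. Zero outgroup distance
    discards with a logged reason.
    """
    if min(d_in1_in2, d_in1_out, d_in2_out) < 0:
        raise ValueError("distances must be non-negative")
    if d_in1_out == 0 or d_in2_out == 0:
        logger.warning("orthologue pair discarded: zero outgroup distance")
        return False
    return d_in1_in2 / d_in1_out <= threshold and d_in1_in2 / d_in2_out <= threshold
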