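#!/usr/bin/env python
"""Compute site-class GC content for every simulated organism.

Reads the CDS FASTA produced by 01, computes whole-sequence GC, GC at
fourfold degenerate third positions (4FDS) and GC at second codon positions
(ZRS) for each organism, and writes results/composition.tsv. Prints the mean
of each measure per oxygen category — in the generating world these means
are graded from obligate anaerobes up to obligate aerobes.
"""

import os
import sys

import pandas as pd
from Bio import SeqIO

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from oxygc.seqcomp import composition_record  # noqa: E402

ROOT = os.path.join(os.path.dirname(__file__), "..")


def main() -> None:
    fasta = os.path.join(ROOT, "scratch", "simulated", "cds.fasta")
    traits = pd.read_csv(
        os.path.join(ROOT, "results", "simulated", "traits.tsv"), sep="\t"
    )
    rows = []
    for rec in SeqIO.parse(fasta, "fasta"):
        c = composition_record(rec.id, genome=str(rec.seq), cds_set=[str(rec.seq)])
        rows.append({
            "organism_id": c.organism_id, "gc_genome": c.gc_genome,
            "gc_4fds": c.gc_4fds, "gc_zrs": c.gc_zrs,
            "n_sites_genome": c.n_sites_genome, "n_sites_4fds": c.n_sites_4fds,
            "n_sites_zrs": c.n_sites_zrs,
        })
    comp = pd.DataFrame(rows)
    out = os.path.join(ROOT, "results", "composition.tsv")
    comp.to_csv(out, sep="\t", index=False, float_format="%.6f")

    merged = comp.merge(traits[["organism_id", "oxygen_state"]], on="organism_id")
    print(f"{len(comp)} organisms measured -> {os.path.relpath(out, ROOT)}")
    print("mean GC by oxygen category:")
    print(
        merged.groupby("oxygen_state")[["gc_genome", "gc_4fds", "gc_zrs"]]
        .mean()
        .round(4)
        .to_string()
    )


if __name__ == "__main__":
    main()
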