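#!/usr/bin/env python
"""Step 5: codon-level annotation of fixed variants; SAAC gene sets; NS/S.

Writes results/effects.tsv and results/saac.tsv, then tests whether the
non-synonymous/synonymous ratio is elevated inside the PASS regions, as the
study reports for its printed contingency table.
"""

from pathlib import Path

import pandas as pd
import pyfaidx

from passcan import effects as fx
from passcan.intervals import read_bed
from passcan.pipeline import effects_stage
from passcan.sweep_scan import PassRegion
from passcan.variants import read_site_classes

ROOT = Path(__file__).resolve().parents[1]
WORLD = ROOT / "results" / "world"
OUT = ROOT / "results"


def main() -> None:
    table = read_site_classes(OUT / "site_classes.tsv")
    fasta = pyfaidx.Fasta(str(WORLD / "reference.fa"))
    models = fx.load_gene_models(WORLD / "genes.gff3")
    effects_a, effects_b, saac = effects_stage(table, models, fasta)

    ea = fx.effects_frame(effects_a)
    ea.insert(0, "population", "A")
    eb = fx.effects_frame(effects_b)
    eb.insert(0, "population", "B")
    pd.concat([ea, eb]).to_csv(OUT / "effects.tsv", sep="\t", index=False)
    with open(OUT / "saac.tsv", "w") as fh:
        fh.write("gene\tpopulation\n")
        for g in sorted(saac.saac_a):
            fh.write(f"{g}\tA\n")
        for g in sorted(saac.saac_b):
            fh.write(f"{g}\tB\n")

    print(f"fixed-A variants annotated: {len(effects_a)}, "
          f"fixed-B: {len(effects_b)}")
    print(f"SAAC A (amino-acid changes exclusive to A): "
          f"{len(saac.saac_a)} genes")
    print(f"SAAC B: {len(saac.saac_b)} genes")

    regions = [PassRegion(c, s, e, 0, float("nan"))
               for c, s, e, _ in read_bed(OUT / "pass_regions.bed")]
    ns_in, s_in, ns_out, s_out = fx.ns_s_counts(effects_a, regions)
    if min(s_in, s_out) > 0:
        r_in, r_out, p = fx.ns_s_ratio_test(ns_in, s_in, ns_out, s_out)
        print(f"NS/S in PASS: {ns_in}/{s_in} = {r_in:.2f}; outside: "
              f"{ns_out}/{s_out} = {r_out:.2f}; Fisher p = {p:.3g}")
    else:
        print(f"NS/S strata too sparse for a ratio test "
              f"(in: {ns_in}/{s_in}, out: {ns_out}/{s_out})")


if __name__ == "__main__":
    main()
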