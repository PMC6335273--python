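#!/usr/bin/env python
"""Step 8: integrate SAAC, PASS overlap, DE and the marked-gene list into
the final candidate table (results/candidates.tsv).

A candidate must be marked, carry an A-exclusive amino-acid change, and be
supported by PASS-region overlap or differential expression at any stage.
"""

from pathlib import Path

import pandas as pd

from passcan.effects import load_gene_models
from passcan.expression import integrate_candidates
from passcan.intervals import read_bed
from passcan.pipeline import gene_locations
from passcan.sweep_scan import PassRegion

ROOT = Path(__file__).resolve().parents[1]
WORLD = ROOT / "results" / "world"
OUT = ROOT / "results"


def main() -> None:
    saac_table = pd.read_csv(OUT / "saac.tsv", sep="\t")
    saac_a = set(saac_table[saac_table.population == "A"].gene)
    regions = [PassRegion(c, s, e, 0, float("nan"))
               for c, s, e, _ in read_bed(OUT / "pass_regions.bed")]
    models = load_gene_models(WORLD / "genes.gff3")
    de = {g for g in (OUT / "de_genes.txt").read_text().split() if g}
    marked = {g for g in (WORLD / "marked_genes.txt").read_text().split() if g}

    cand = integrate_candidates(saac_a, regions, gene_locations(models),
                                de, marked)
    with open(OUT / "candidates.tsv", "w") as fh:
        fh.write("gene\tin_pass\tde\tmarked\n")
        for g in sorted(cand.candidates):
            fh.write(f"{g}\t{int(g in cand.pass_genes)}"
                     f"\t{int(g in cand.de_genes)}\t1\n")

    print(f"SAAC A: {len(saac_a)}, PASS-overlap genes: "
          f"{len(cand.pass_genes)}, DE genes: {len(de)}, "
          f"marked: {len(marked)}")
    print(f"candidates ({len(cand.candidates)}):")
    for g in sorted(cand.candidates):
        route = []
        if g in cand.pass_genes:
            route.append("PASS")
        if g in cand.de_genes:
            route.append("DE")
        print(f"  {g}  via {'+'.join(route)}")


if __name__ == "__main__":
    main()
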