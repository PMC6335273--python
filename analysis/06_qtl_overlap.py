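#!/usr/bin/env python
"""Step 6: overlap of PASS regions with the marked QTL intervals.

Writes results/qtl_overlap.tsv; the study's analogue reports 67% of the
PASS megabases falling inside trait QTLs.
"""

from pathlib import Path

from passcan import intervals as iv

ROOT = Path(__file__).resolve().parents[1]
WORLD = ROOT / "results" / "world"
OUT = ROOT / "results"


def main() -> None:
    pass_set = iv.read_bed(OUT / "pass_regions.bed")
    qtls = iv.merge(iv.read_bed(WORLD / "qtls.bed"))
    overlap_bp, frac, n_hit = iv.intersect_summary(pass_set, qtls)
    with open(OUT / "qtl_overlap.tsv", "w") as fh:
        fh.write("overlap_bp\tfrac_pass_covered\tn_qtls_hit\tn_qtls\n")
        fh.write(f"{overlap_bp}\t{frac:.6g}\t{n_hit}\t{len(qtls)}\n")
    print(f"PASS total: {pass_set.total_bp() / 1e6:.2f} Mb, "
          f"QTL total: {qtls.total_bp() / 1e6:.2f} Mb")
    print(f"overlap: {overlap_bp / 1e6:.2f} Mb = {100 * frac:.0f}% of PASS, "
          f"{n_hit}/{len(qtls)} QTLs hit")


if __name__ == "__main__":
    main()
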