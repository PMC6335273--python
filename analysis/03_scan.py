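#!/usr/bin/env python
"""Step 3: sliding-window homogeneity scan and PASS-region calling.

Reads results/site_classes.tsv, writes results/windows.tsv and
results/pass_regions.bed, and compares the called regions with the planted
sweep truth (Jaccard per planted interval).
"""

from pathlib import Path

from passcan import sweep_scan as sw
from passcan.intervals import read_bed
from passcan.variants import read_site_classes

ROOT = Path(__file__).resolve().parents[1]
WORLD = ROOT / "results" / "world"
OUT = ROOT / "results"


def jaccard(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def main() -> None:
    table = read_site_classes(OUT / "site_classes.tsv")
    sizes = sw.read_chrom_sizes(WORLD / "chrom_sizes.tsv")
    tests = sw.scan(table, sizes, window=50_000, step=10_000)
    regions = sw.call_pass(tests, alpha=0.05)
    sw.tests_to_frame(tests, 0.05).to_csv(OUT / "windows.tsv", sep="\t",
                                          index=False, float_format="%.6g")
    sw.regions_to_bed(regions, OUT / "pass_regions.bed")

    testable = sum(1 for t in tests if t.p_raw == t.p_raw)  # non-NaN
    print(f"{len(tests)} windows scanned, {testable} testable "
          f"(Bonferroni m={testable})")
    print(f"{len(regions)} PASS regions "
          f"({sum(r.end - r.start for r in regions) / 1e6:.2f} Mb):")
    for r in regions:
        print(f"  {r.chrom}:{r.start}-{r.end}  windows={r.n_windows}  "
              f"min_p_adj={r.min_p_adj:.3g}")
    truth = read_bed(WORLD / "sweeps_truth.bed")
    for chrom, s, e, _ in truth:
        hits = [r for r in regions
                if r.chrom == chrom and r.start < e and s < r.end]
        if hits:
            lo = min(r.start for r in hits)
            hi = max(r.end for r in hits)
            print(f"planted {chrom}:{s}-{e} recovered as {lo}-{hi} "
                  f"(Jaccard {jaccard((s, e), (lo, hi)):.3f})")
        else:
            print(f"planted {chrom}:{s}-{e} NOT recovered")


if __name__ == "__main__":
    main()
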