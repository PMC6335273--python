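"""Interval algebra: BED I/O, merge, intersect, and overlap summaries.

Coordinates are 0-based half-open throughout (BED convention). One-based
inclusive tables (RGD-style QTL dumps) can be converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class RegionSet:
    """A named list of (chrom, start, end, label) intervals."""

    regions: list[tuple[str, int, int, str]] = field(default_factory=list)
    merged: bool = False

    def __post_init__(self) -> None:
        for i, (chrom, start, end, _label) in enumerate(self.regions):
            if start >= end:
                raise ValueError(f"malformed interval at line {i + 1}: "
                                 f"{chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def total_bp(self) -> int:
        return sum(end - start for _, start, end, _ in self.regions)

    def sorted(self) -> "RegionSet":
        return RegionSet(sorted(self.regions, key=lambda r: (r[0], r[1], r[2])),
                         merged=self.merged)


def merge(regions: RegionSet, distance: int = 0) -> RegionSet:
    """Union intervals overlapping or within ``distance`` bp (0 = bookended).

    Matches bedtools-merge default semantics; labels of merged members are
    comma-concatenated.
    """
    out: list[tuple[str, int, int, str]] = []
    for chrom, start, end, label in regions.sorted():
        if out and out[-1][0] == chrom and start <= out[-1][2] + distance:
            pchrom, pstart, pend, plabel = out[-1]
            out[-1] = (pchrom, pstart, max(pend, end),
                       plabel + "," + label if label else plabel)
        else:
            out.append((chrom, start, end, label))
    return RegionSet(out, merged=True)


def intersect_summary(a: RegionSet, b: RegionSet) -> tuple[int, float, int]:
    """(overlap_bp, fraction of a covered, number of b intervals hit).

    Both inputs are expected merged (disjoint per chromosome); overlap_bp is
    exact regardless, n_b_hit counts b intervals with >= 1 bp of overlap.
    """
    by_chrom_a: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _ in a.sorted():
        by_chrom_a.setdefault(chrom, []).append((start, end))

    overlap_bp = 0
    n_b_hit = 0
    for chrom, bstart, bend, _ in b:
        hit = False
        for astart, aend in by_chrom_a.get(chrom, ()):
            lo, hi = max(astart, bstart), min(aend, bend)
            if lo < hi:
                overlap_bp += hi - lo
                hit = True
        n_b_hit += hit
    total_a = a.total_bp()
    frac = overlap_bp / total_a if total_a else 0.0
    return overlap_bp, frac, n_b_hit


def read_bed(path, one_based: bool = False) -> RegionSet:
    """Read BED3/BED6 (or a 1-based inclusive table with ``one_based``)."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: non-integer coordinate") from exc
            if one_based:
                start -= 1
            label = parts[3] if len(parts) > 3 else ""
            if start >= end:
                raise ValueError(f"{path}: line {ln}: empty/inverted interval")
            regions.append((chrom, start, end, label))
    return RegionSet(regions)


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in regions:
            if label:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")
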