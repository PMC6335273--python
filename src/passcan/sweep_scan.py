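"""Sliding-window scan for putative artificial selective sweep (PASS) regions.

For each 50-kb window (10-kb step) the scan forms the 2x2 table

    [[F_A, P_A],
     [F_B, P_B]]

of fixed differences (F) and polymorphic sites (P) per population and tests
homogeneity of the fixed/polymorphic ratio between populations (an HKA-style
contrast): under neutral divergence the two populations accumulate fixed
differences in proportion to their polymorphism, while a selective sweep in
population A inflates F_A without inflating P_A. Window p-values are
Bonferroni-corrected over the number of testable windows; significant windows
with an excess of fixation in A are merged (bedtools-style, bookended counts
as touching) into PASS regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import POLY_CLASSES_A, POLY_CLASSES_B, SiteClass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowCounts:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    P_A: int
    F_A: int
    P_B: int
    F_B: int

    def __post_init__(self) -> None:
        if min(self.P_A, self.F_A, self.P_B, self.F_B) < 0:
            raise ValueError("negative window counts")

    @property
    def table(self) -> list[list[int]]:
        return [[self.F_A, self.P_A], [self.F_B, self.P_B]]

    @property
    def total(self) -> int:
        return self.P_A + self.F_A + self.P_B + self.F_B


@dataclass(frozen=True)
class WindowTest:
    window: WindowCounts
    p_raw: float
    p_adj: float
    direction_a: bool


@dataclass(frozen=True)
class PassRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    min_p_adj: float


def make_windows(chrom_sizes: dict[str, int], window: int, step: int
                 ) -> list[tuple[str, int, int]]:
    """Tile each chromosome with [start, end) windows anchored at 0.

    A window at least as long as the chromosome yields the single truncated
    window [0, size); otherwise every start in range(0, size, step) is
    emitted with the end truncated at the chromosome end, so every base is
    covered. Zero-length chromosomes are skipped with a log entry.
    """
    if not (window >= step > 0):
        raise ValueError(f"need window >= step > 0, got window={window} step={step}")
    out: list[tuple[str, int, int]] = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            logger.warning("skipping zero-length chromosome %s", chrom)
            continue
        if window >= size:
            out.append((chrom, 0, size))
            continue
        for start in range(0, size, step):
            out.append((chrom, start, min(start + window, size)))
    return out


def count_windows(site_classes: pd.DataFrame,
                  windows: list[tuple[str, int, int]]) -> list[WindowCounts]:
    """Tally (P_A, F_A, P_B, F_B) per window from a classified-site table.

    A site at 1-based position p belongs to window [s, e) iff s < p <= e,
    i.e. its 0-based coordinate lies in the half-open window. Sites are
    binned with sorted-array bisection so overlapping windows stay cheap.
    """
    poly_a = {c.value for c in POLY_CLASSES_A}
    poly_b = {c.value for c in POLY_CLASSES_B}
    per_chrom: dict[str, dict[str, np.ndarray]] = {}
    for chrom, sub in site_classes.groupby("chrom", sort=False):
        cls = sub["site_class"]
        pos = sub["pos"].to_numpy()
        per_chrom[str(chrom)] = {
            "P_A": np.sort(pos[cls.isin(poly_a).to_numpy()]),
            "F_A": np.sort(pos[(cls == SiteClass.FIXED_A.value).to_numpy()]),
            "P_B": np.sort(pos[cls.isin(poly_b).to_numpy()]),
            "F_B": np.sort(pos[(cls == SiteClass.FIXED_B.value).to_numpy()]),
        }

    empty = np.empty(0, dtype=int)
    out = []
    for chrom, start, end in windows:
        arrays = per_chrom.get(chrom)

        def n_in(key: str) -> int:
            arr = arrays[key] if arrays else empty
            return int(np.searchsorted(arr, end, side="right")
                       - np.searchsorted(arr, start, side="right"))

        out.append(WindowCounts(chrom, start, end,
                                n_in("P_A"), n_in("F_A"), n_in("P_B"), n_in("F_B")))
    return out


def homogeneity_test(counts: WindowCounts, method: str = "fisher") -> float:
    """Two-sided p for homogeneity of F/P between populations.

    ``method`` is "fisher" (Fisher's exact, default — safe at the low
    per-window counts of polymorphism-poor inbred lines) or "chisq"
    (Pearson chi-square without continuity correction). Tables with a zero
    row or zero column carry no information about the ratio and return 1.
    """
    f_a, p_a, f_b, p_b = counts.F_A, counts.P_A, counts.F_B, counts.P_B
    if min(f_a, p_a, f_b, p_b) < 0:
        raise ValueError("negative counts")
    if (f_a + p_a == 0) or (f_b + p_b == 0) or (f_a + f_b == 0) or (p_a + p_b == 0):
        return 1.0
    table = [[f_a, p_a], [f_b, p_b]]
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    if method == "chisq":
        return float(stats.chi2_contingency(table, correction=False).pvalue)
    raise ValueError(f"unknown method {method!r}")


def bonferroni(p_values: list[float]) -> list[float]:
    """min(1, p * m) with m = number of p-values supplied."""
    m = len(p_values)
    out = []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, p * m))
    return out


def scan(site_classes: pd.DataFrame, chrom_sizes: dict[str, int],
         window: int = 50_000, step: int = 10_000, method: str = "fisher",
         min_f_ratio: float | None = None) -> list[WindowTest]:
    """Count, test and Bonferroni-correct every window of a genome scan.

    Windows with an all-zero table have no defined test and are excluded
    from the Bonferroni family m; their p_raw/p_adj are NaN.
    """
    windows = make_windows(chrom_sizes, window, step)
    counted = count_windows(site_classes, windows)
    testable = [w for w in counted if w.total > 0]
    p_raw = [homogeneity_test(w, method) for w in testable]
    p_adj = bonferroni(p_raw)
    adj_by_window = {id(w): (pr, pa) for w, pr, pa in zip(testable, p_raw, p_adj)}

    tests = []
    for w in counted:
        pr, pa = adj_by_window.get(id(w), (float("nan"), float("nan")))
        tests.append(WindowTest(w, pr, pa, _direction_a(w, min_f_ratio)))
    return tests


def _direction_a(w: WindowCounts, min_f_ratio: float | None = None) -> bool:
    """Excess of fixation in A: odds ratio toward A and F_A > F_B."""
    ok = (w.F_A * w.P_B > w.F_B * w.P_A) and (w.F_A > w.F_B)
    if ok and min_f_ratio is not None:
        ok = w.F_A > min_f_ratio * w.F_B
    return ok


def call_pass(tests: list[WindowTest], alpha: float = 0.05,
              min_f_ratio: float | None = None) -> list[PassRegion]:
    """Select significant, A-directed windows and merge them into regions.

    Selection is strict: p_adj < alpha (ties at alpha are not significant)
    and the direction rule holds. Overlapping or bookended selected windows
    on one chromosome merge into a single region carrying the member-window
    count and the smallest adjusted p.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha={alpha} outside (0, 1]")
    selected = []
    for t in tests:
        direction = t.direction_a
        if min_f_ratio is not None:
            direction = _direction_a(t.window, min_f_ratio)
        if np.isfinite(t.p_raw) and t.p_adj < alpha and direction:
            selected.append(t)
    selected.sort(key=lambda t: (t.window.chrom, t.window.start))

    regions: list[PassRegion] = []
    for t in selected:
        w = t.window
        if regions and regions[-1].chrom == w.chrom and w.start <= regions[-1].end:
            last = regions[-1]
            regions[-1] = PassRegion(last.chrom, last.start, max(last.end, w.end),
                                     last.n_windows + 1, min(last.min_p_adj, t.p_adj))
        else:
            regions.append(PassRegion(w.chrom, w.start, w.end, 1, t.p_adj))
    return regions


def tests_to_frame(tests: list[WindowTest], alpha: float = 0.05) -> pd.DataFrame:
    """Window-scan statistics as a tidy table (TSV-ready)."""
    rows = []
    for t in tests:
        w = t.window
        selected = bool(np.isfinite(t.p_raw) and t.p_adj < alpha and t.direction_a)
        rows.append((w.chrom, w.start, w.end, w.P_A, w.F_A, w.P_B, w.F_B,
                     t.p_raw, t.p_adj, selected))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "P_A", "F_A",
                                       "P_B", "F_B", "p_raw", "p_adj", "selected"])


def regions_to_bed(regions: list[PassRegion], path) -> None:
    """PASS regions as BED6; score = -log10(min p_adj), capped at 1000."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            if r.min_p_adj <= 0:
                score = 1000.0
            else:
                score = min(1000.0, -np.log10(r.min_p_adj))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tPASS_{i}\t{score:.4g}\t.\n")


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     dtype={"chrom": str})
    return dict(zip(df.chrom, df["size"].astype(int)))
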