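"""Per-window population-genetic statistics: Tajima's D, Fst, fixed density.

These back the descriptive comparison between the selected and control lines
in non-overlapping 10-kb windows: a selective sweep depresses Tajima's D
(excess of rare variants after the fixation of one haplotype), elevates
between-population differentiation (Fst), and concentrates fixed differences
of the selected line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import MISSING, GenotypeSite, SiteClass


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TajimaResult:
    window: tuple[str, int, int]
    S: int
    n: int  # haploid sample size used
    theta_pi: float
    theta_w: float
    D: float
    defined: bool
    reason: str = ""


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima (1989) for haploid sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d_from_counts(alt_counts: Sequence[int], n: int,
                          window: tuple[str, int, int] = ("", 0, 0)) -> TajimaResult:
    """Tajima's D from per-site minor/derived allele counts at fixed n.

    ``alt_counts`` holds, for each segregating site, the number of haploid
    chromosomes (of n) carrying the non-reference allele; counts of 0 or n
    are ignored as non-segregating. Unphased diploid data enters through the
    allele counts only — mean pairwise difference per site is
    k(n-k)/C(n,2), which does not require phase.
    """
    if n < 4:
        return TajimaResult(window, 0, n, 0.0, 0.0, float("nan"), False, "n < 4")
    seg = [k for k in alt_counts if 0 < k < n]
    S = len(seg)
    if S == 0:
        return TajimaResult(window, 0, n, 0.0, 0.0, float("nan"), False, "S = 0")
    pairs = n * (n - 1) / 2.0
    theta_pi = sum(k * (n - k) for k in seg) / pairs
    c = tajima_constants(n)
    theta_w = S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    D = (theta_pi - theta_w) / math.sqrt(var)
    return TajimaResult(window, S, n, theta_pi, theta_w, D, True)


def _called_alt_count(site: GenotypeSite, samples: Sequence[str]):
    """(called diploids, alt-carrying allele count) for biallelic use."""
    called = 0
    alt = 0
    for s in samples:
        gt = site.genotypes.get(s)
        if gt is None or MISSING in gt:
            continue
        called += 1
        alt += (gt[0] != 0) + (gt[1] != 0)
    return called, alt


def tajimas_d(sites: Sequence[GenotypeSite], samples: Sequence[str],
              window: tuple[str, int, int], min_called: int = 1) -> TajimaResult:
    """Tajima's D for one population over the sites of a window.

    Sites called in fewer than ``min_called`` samples are dropped; the
    haploid sample size is 2 x the minimum called-sample count across the
    retained sites, and per-site allele counts are rescaled onto that n by
    the observed allele frequency (sites share one n so the Tajima
    constants apply).
    """
    per_site = []
    for site in sites:
        called, alt = _called_alt_count(site, samples)
        if called >= min_called and called > 0:
            per_site.append((called, alt))
    if not per_site:
        return TajimaResult(window, 0, 0, 0.0, 0.0, float("nan"), False,
                            "no usable sites")
    n = 2 * min(called for called, _ in per_site)
    counts = []
    for called, alt in per_site:
        if called * 2 == n:
            counts.append(alt)
        else:
            # project the observed frequency onto the common n
            counts.append(round(alt / (2 * called) * n))
    return tajimas_d_from_counts(counts, n, window)


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FstResult:
    window: tuple[str, int, int]
    n_sites: int
    fst_weighted: float
    fst_mean: float
    defined: bool


def wc_site_components(n1: int, p1: float, h1: float,
                       n2: int, p2: float, h2: float) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) for one site.

    n_i: called diploid sample sizes; p_i: alternate-allele frequencies;
    h_i: observed heterozygote proportions. r = 2 populations.
    """
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _pop_freqs(site: GenotypeSite, samples: Sequence[str]):
    called = het = alt = 0
    for s in samples:
        gt = site.genotypes.get(s)
        if gt is None or MISSING in gt:
            continue
        called += 1
        a1 = gt[0] != 0
        a2 = gt[1] != 0
        alt += a1 + a2
        het += a1 != a2
    if called == 0:
        return 0, 0.0, 0.0
    return called, alt / (2 * called), het / called


def wc_fst(sites: Sequence[GenotypeSite], samples_a: Sequence[str],
           samples_b: Sequence[str], window: tuple[str, int, int]) -> FstResult:
    """Window Fst between two populations (Weir & Cockerham 1984).

    fst_weighted is the ratio of summed variance components Σa / Σ(a+b+c);
    fst_mean averages per-site a/(a+b+c) over sites with a nonzero
    denominator. Negative per-site estimates are retained unclamped. Sites
    monomorphic across the pooled sample contribute nothing; a window with
    no usable site is flagged undefined.
    """
    sum_a = sum_abc = 0.0
    per_site = []
    for site in sites:
        n1, p1, h1 = _pop_freqs(site, samples_a)
        n2, p2, h2 = _pop_freqs(site, samples_b)
        if n1 == 0 or n2 == 0:
            continue
        pooled = (n1 * p1 + n2 * p2) / (n1 + n2)
        if pooled == 0.0 or pooled == 1.0:
            continue  # not polymorphic across the pooled sample
        a, b, c = wc_site_components(n1, p1, h1, n2, p2, h2)
        sum_a += a
        sum_abc += a + b + c
        if a + b + c != 0:
            per_site.append(a / (a + b + c))
    if not per_site or sum_abc == 0:
        return FstResult(window, 0, float("nan"), float("nan"), False)
    return FstResult(window, len(per_site), sum_a / sum_abc,
                     float(np.mean(per_site)), True)


# ---------------------------------------------------------------------------
# Fixed-variant density
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityResult:
    window: tuple[str, int, int]
    fixed_count_a: int
    fixed_count_b: int
    density_a: float  # fixed variants per kb
    density_b: float


def fixed_density(site_classes: pd.DataFrame,
                  windows: list[tuple[str, int, int]]) -> list[DensityResult]:
    """Fixed variants per kb in non-overlapping windows, per population.

    Truncated terminal windows use their actual length in kb.
    """
    per_chrom: dict[str, dict[str, np.ndarray]] = {}
    for chrom, sub in site_classes.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        cls = sub["site_class"]
        per_chrom[str(chrom)] = {
            "a": np.sort(pos[(cls == SiteClass.FIXED_A.value).to_numpy()]),
            "b": np.sort(pos[(cls == SiteClass.FIXED_B.value).to_numpy()]),
        }
    empty = np.empty(0, dtype=int)
    out = []
    for chrom, start, end in windows:
        arrays = per_chrom.get(chrom)
        kb = (end - start) / 1000.0

        def n_in(key: str) -> int:
            arr = arrays[key] if arrays else empty
            return int(np.searchsorted(arr, end, side="right")
                       - np.searchsorted(arr, start, side="right"))

        ca, cb = n_in("a"), n_in("b")
        out.append(DensityResult((chrom, start, end), ca, cb, ca / kb, cb / kb))
    return out


# ---------------------------------------------------------------------------
# Tidy exports
# ---------------------------------------------------------------------------

def tajima_frame(results: list[TajimaResult]) -> pd.DataFrame:
    rows = [(r.window[0], r.window[1], r.window[2], r.S, r.n,
             r.theta_pi if r.defined else np.nan,
             r.theta_w if r.defined else np.nan,
             r.D if r.defined else np.nan) for r in results]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "S", "n",
                                       "theta_pi", "theta_w", "D"])


def fst_frame(results: list[FstResult]) -> pd.DataFrame:
    rows = [(r.window[0], r.window[1], r.window[2], r.n_sites,
             r.fst_weighted if r.defined else np.nan,
             r.fst_mean if r.defined else np.nan) for r in results]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                       "fst_weighted", "fst_mean"])


def density_frame(results: list[DensityResult]) -> pd.DataFrame:
    rows = [(r.window[0], r.window[1], r.window[2], r.fixed_count_a,
             r.fixed_count_b, r.density_a, r.density_b) for r in results]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fixed_a",
                                       "fixed_b", "density_a", "density_b"])
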