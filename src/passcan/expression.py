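"""Expression integration: TPM, Bayes-regularized paired t-test, candidates.

Raw counts are normalized to TPM (transcripts per kilobase of exon model per
million mapped reads). Differential expression between paired case/control
samples uses a Cyber-T-style regularized paired t-test: the per-gene variance
of the paired differences is shrunk toward a background variance estimated
from genes of similar mean expression (a running-window average of per-gene
SDs), which stabilizes the statistic at small replicate numbers. Gene-level
p-values are corrected by Benjamini–Hochberg FDR, and the final candidate set
intersects the marked SAAC genes with (sweep-region genes ∪ DE genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM-normalize a genes x samples count matrix given lengths in bp.

    Each sample column sums to 1e6 unless the sample has zero total counts
    (all-zero column, emitted with a warning).
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive and cover all genes")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero sample(s): {list(totals.index[zero])}")
        totals = totals.replace(0, np.nan)
    out = rate.div(totals, axis=1) * 1e6
    return out.fillna(0.0)


def running_background_sd(sd: pd.Series, mean_expr: pd.Series,
                          window: int = 101) -> pd.Series:
    """Background SD per gene: running mean of SDs over expression-ranked genes.

    Genes are ranked by mean expression; each gene's background is the mean
    per-gene SD within a centered window of ``window`` genes (truncated at
    the ends). This is the local-pooling step that lends degrees of freedom
    to low-replicate experiments.
    """
    order = mean_expr.sort_values(kind="mergesort").index
    sds = sd.reindex(order).to_numpy(dtype=float)
    n = len(sds)
    half = max(window // 2, 0)
    csum = np.concatenate([[0.0], np.cumsum(sds)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    bg = (csum[hi] - csum[lo]) / (hi - lo)
    return pd.Series(bg, index=order).reindex(sd.index)


@dataclass
class DEResult:
    table: pd.DataFrame  # gene-indexed: mean_diff, sd, sigma0, t_reg, df, p, q
    fdr: float = 0.05

    @property
    def de_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["q"] < self.fdr])


def cyber_t_paired(case: pd.DataFrame, control: pd.DataFrame,
                   v0: float = 10.0, window: int = 101,
                   fdr: float = 0.05) -> DEResult:
    """Regularized paired t-test per gene on aligned case/control matrices.

    Columns pair positionally (case_i with control_i). Per gene the paired
    differences d_i give mean m and SD s; the posterior SD blends s with the
    background sigma0 (running mean of s over expression-ranked genes) as

        sigma_p^2 = (v0*sigma0^2 + (n-1)*s^2) / (v0 + n - 2),
        t = m / (sigma_p / sqrt(n)),   df = v0 + n - 2,

    where v0 acts as prior pseudo-replicates. With v0 = 0 there is no prior
    information and the statistic degenerates to the classical paired t
    (sigma_p = s, df = n - 1).
    """
    if case.shape != control.shape:
        raise ValueError("case and control matrices differ in shape")
    n = case.shape[1]
    if n < 2:
        raise ValueError(f"need >= 2 pairs, got {n}")
    if v0 < 0:
        raise ValueError("v0 must be >= 0")
    diffs = case.to_numpy(dtype=float) - control.to_numpy(dtype=float)
    m = diffs.mean(axis=1)
    s = diffs.std(axis=1, ddof=1)
    mean_expr = pd.Series((case.to_numpy(dtype=float)
                           + control.to_numpy(dtype=float)).mean(axis=1) / 1.0,
                          index=case.index)
    sd = pd.Series(s, index=case.index)
    if v0 == 0:
        sigma0 = pd.Series(np.nan, index=case.index)
        sigma_p = s
        df = n - 1
    else:
        sigma0 = running_background_sd(sd, mean_expr, window)
        sigma_p = np.sqrt((v0 * sigma0.to_numpy() ** 2 + (n - 1) * s**2)
                          / (v0 + n - 2))
        df = v0 + n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sigma_p > 0, m / (sigma_p / np.sqrt(n)), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    table = pd.DataFrame({"mean_diff": m, "sd": s, "sigma0": sigma0,
                          "t_reg": t, "df": float(df), "p": p},
                         index=case.index)
    table["q"] = bh_fdr(list(p))
    return DEResult(table, fdr=fdr)


def bh_fdr(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in input order."""
    if len(p_values) == 0:
        return []
    arr = np.asarray(p_values, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return list(q)


@dataclass
class CandidateSet:
    saac_genes: frozenset[str]
    pass_genes: frozenset[str]
    de_genes: frozenset[str]
    marked_genes: frozenset[str]
    missing_location: frozenset[str] = field(default_factory=frozenset)

    @property
    def candidates(self) -> frozenset[str]:
        return self.marked_genes & self.saac_genes & (self.pass_genes | self.de_genes)


def integrate_candidates(saac: set[str], pass_regions, gene_locations,
                         de_genes: set[str], marked: set[str]) -> CandidateSet:
    """Final integration: marked ∩ SAAC ∩ (sweep-region genes ∪ DE genes).

    ``gene_locations`` is an intervals.RegionSet whose labels are gene ids;
    a SAAC gene overlaps a PASS region when their intervals share >= 1 bp.
    SAAC genes without a location are excluded from pass_genes only (warned).
    """
    region_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in pass_regions:
        region_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    loc: dict[str, tuple[str, int, int]] = {}
    for chrom, start, end, label in gene_locations:
        if label:
            loc[label] = (chrom, start, end)

    pass_genes = set()
    missing = set()
    for gene in saac:
        if gene not in loc:
            missing.add(gene)
            continue
        chrom, gstart, gend = loc[gene]
        if any(gstart < e and s < gend for s, e in region_by_chrom.get(chrom, ())):
            pass_genes.add(gene)
    if missing:
        warnings.warn(f"{len(missing)} SAAC gene(s) without location excluded "
                      "from PASS-gene overlap")
    return CandidateSet(frozenset(saac), frozenset(pass_genes),
                        frozenset(de_genes), frozenset(marked),
                        frozenset(missing))


def read_counts(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a counts TSV (gene, length, then sample columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = df["length"]
    counts = df.drop(columns=["length"])
    return counts, lengths
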