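"""End-to-end orchestration: classify -> scan -> popgen -> effects -> overlap
-> differential expression -> candidate integration.

Each stage writes its declared artifact under the output directory with a
fixed name, so runs are comparable and reproducible; ``manifest.json``
records parameters, input checksums and the package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import effects as fx
from . import expression as xp
from . import intervals as iv
from . import popgen as pg
from . import sweep_scan as sw
from .variants import (GenotypeSite, PopulationSpec, SiteClass, classify_all,
                       load_sites, write_site_classes, MISSING)


@dataclass
class ScanParams:
    window: int = 50_000
    step: int = 10_000
    stat_window: int = 10_000
    alpha: float = 0.05
    test: str = "fisher"
    min_f_ratio: float | None = None
    snv_only: bool = False


@dataclass
class ExprParams:
    v0: float = 10.0
    window: int = 101
    fdr: float = 0.05
    log_transform: bool = True


# ---------------------------------------------------------------------------
# Stages (in-memory, file-free)
# ---------------------------------------------------------------------------

def classify_stage(sites: Sequence[GenotypeSite], spec: PopulationSpec):
    return classify_all(sites, spec)


def scan_stage(site_classes: pd.DataFrame, chrom_sizes: dict[str, int],
               params: ScanParams):
    tests = sw.scan(site_classes, chrom_sizes, params.window, params.step,
                    params.test, params.min_f_ratio)
    regions = sw.call_pass(tests, params.alpha, params.min_f_ratio)
    return tests, regions


def _called(site: GenotypeSite, samples) -> int:
    return sum(1 for s in samples
               if (gt := site.genotypes.get(s)) and MISSING not in gt)


def popgen_stage(sites: Sequence[GenotypeSite], site_classes: pd.DataFrame,
                 spec: PopulationSpec, chrom_sizes: dict[str, int],
                 stat_window: int = 10_000):
    """Tajima's D (both populations), Fst and fixed density in tiled windows."""
    windows = sw.make_windows(chrom_sizes, stat_window, stat_window)
    by_window: dict[tuple[str, int, int], list[GenotypeSite]] = {w: [] for w in windows}
    # retention filter, then binning (tiled windows: direct index)
    for site in sites:
        if (_called(site, spec.samples_a) < spec.min_called_a
                or _called(site, spec.samples_b) < spec.min_called_b):
            continue
        size = chrom_sizes.get(site.chrom)
        if size is None:
            continue
        start = ((site.pos - 1) // stat_window) * stat_window
        key = (site.chrom, start, min(start + stat_window, size))
        if key in by_window:
            by_window[key].append(site)

    taj_a, taj_b, fst = [], [], []
    for w in windows:
        in_w = by_window[w]
        taj_a.append(pg.tajimas_d(in_w, spec.samples_a, w))
        taj_b.append(pg.tajimas_d(in_w, spec.samples_b, w))
        fst.append(pg.wc_fst(in_w, spec.samples_a, spec.samples_b, w))
    density = pg.fixed_density(site_classes, windows)

    ta = pg.tajima_frame(taj_a).rename(columns={"S": "S_a", "n": "n_a",
                                                "theta_pi": "theta_pi_a",
                                                "theta_w": "theta_w_a", "D": "D_a"})
    tb = pg.tajima_frame(taj_b)[["S", "n", "theta_pi", "theta_w", "D"]]
    tb.columns = ["S_b", "n_b", "theta_pi_b", "theta_w_b", "D_b"]
    tajima = pd.concat([ta, tb], axis=1)
    return tajima, pg.fst_frame(fst), pg.density_frame(density)


def effects_stage(site_classes: pd.DataFrame, models, reference):
    """Annotate per-population fixed variants; return (effects_a, effects_b, saac)."""
    fixed_a = site_classes[site_classes.site_class == SiteClass.FIXED_A.value]
    fixed_b = site_classes[site_classes.site_class == SiteClass.FIXED_B.value]
    effects_a = fx.annotate_fixed_sites(fixed_a[["chrom", "pos", "ref", "alt"]],
                                        models, reference)
    effects_b = fx.annotate_fixed_sites(fixed_b[["chrom", "pos", "ref", "alt"]],
                                        models, reference)
    return effects_a, effects_b, fx.saac_sets(effects_a, effects_b)


def de_stage(counts: pd.DataFrame, lengths: pd.Series, n_stages: int,
             params: ExprParams):
    """Per-stage regularized paired t-tests on (log2) TPM; DE at any stage."""
    from .synthetic import stage_pairs

    tpm = xp.tpm(counts, lengths)
    values = np.log2(tpm + 1.0) if params.log_transform else tpm
    per_stage = {}
    de_any: set[str] = set()
    for stage in range(1, n_stages + 1):
        case, control = stage_pairs(values, stage)
        if case.shape[1] == 0:
            continue
        res = xp.cyber_t_paired(case, control, params.v0, params.window,
                                params.fdr)
        per_stage[stage] = res
        de_any |= set(res.de_genes)
    return per_stage, frozenset(de_any)


def gene_locations(models) -> iv.RegionSet:
    return iv.RegionSet([(m.chrom, m.span[0], m.span[1], m.gene_id)
                         for m in models])


# ---------------------------------------------------------------------------
# File-level run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    tallies: dict[str, int]
    tests: list
    regions: list
    saac: fx.SaacSets
    qtl_summary: tuple[int, float, int]
    de_genes: frozenset[str]
    candidates: xp.CandidateSet
    outdir: Path


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(vcf: Path, populations: Path, reference: Path, gff: Path,
            qtl_bed: Path, counts_tsv: Path, marked_txt: Path, outdir: Path,
            scan_params: ScanParams | None = None,
            expr_params: ExprParams | None = None,
            name_a: str = "A", name_b: str = "B",
            min_called_a: int = 10, min_called_b: int = 9,
            n_stages: int = 3, seed: int = 0) -> RunResult:
    """Run the full analysis from files; write every fixed-name artifact."""
    import pyfaidx

    scan_params = scan_params or ScanParams()
    expr_params = expr_params or ExprParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    spec = PopulationSpec.from_tsv(populations, name_a, name_b,
                                   min_called_a, min_called_b)
    sites = list(load_sites(vcf, spec, snv_only=scan_params.snv_only))
    fasta = pyfaidx.Fasta(str(reference))
    chrom_sizes = {name: len(fasta[name]) for name in fasta.keys()}

    site_classes, tallies = classify_stage(sites, spec)
    write_site_classes(site_classes, outdir / "site_classes.tsv")

    tests, regions = scan_stage(site_classes, chrom_sizes, scan_params)
    sw.tests_to_frame(tests, scan_params.alpha).to_csv(
        outdir / "windows.tsv", sep="\t", index=False, float_format="%.6g")
    sw.regions_to_bed(regions, outdir / "pass_regions.bed")

    tajima, fst, density = popgen_stage(sites, site_classes, spec, chrom_sizes,
                                        scan_params.stat_window)
    tajima.to_csv(outdir / "tajima.tsv", sep="\t", index=False,
                  float_format="%.6g", na_rep="NA")
    fst.to_csv(outdir / "fst.tsv", sep="\t", index=False,
               float_format="%.6g", na_rep="NA")
    density.to_csv(outdir / "density.tsv", sep="\t", index=False,
                   float_format="%.6g")

    models = fx.load_gene_models(gff)
    effects_a, effects_b, saac = effects_stage(site_classes, models, fasta)
    ea = fx.effects_frame(effects_a)
    ea.insert(0, "population", name_a)
    eb = fx.effects_frame(effects_b)
    eb.insert(0, "population", name_b)
    pd.concat([ea, eb]).to_csv(outdir / "effects.tsv", sep="\t", index=False)
    with open(outdir / "saac.tsv", "w") as fh:
        fh.write("gene\tpopulation\n")
        for g in sorted(saac.saac_a):
            fh.write(f"{g}\t{name_a}\n")
        for g in sorted(saac.saac_b):
            fh.write(f"{g}\t{name_b}\n")

    pass_set = iv.RegionSet([(r.chrom, r.start, r.end, f"PASS_{i + 1}")
                             for i, r in enumerate(regions)])
    qtls = iv.merge(iv.read_bed(qtl_bed))
    qtl_summary = iv.intersect_summary(pass_set, qtls)
    with open(outdir / "qtl_overlap.tsv", "w") as fh:
        fh.write("overlap_bp\tfrac_pass_covered\tn_qtls_hit\tn_qtls\n")
        fh.write(f"{qtl_summary[0]}\t{qtl_summary[1]:.6g}\t{qtl_summary[2]}"
                 f"\t{len(qtls)}\n")

    counts, lengths = xp.read_counts(counts_tsv)
    per_stage, de_genes = de_stage(counts, lengths, n_stages, expr_params)
    de_frames = []
    for stage, res in per_stage.items():
        t = res.table.copy()
        t.insert(0, "stage", stage)
        de_frames.append(t)
    de_table = (pd.concat(de_frames) if de_frames else pd.DataFrame())
    de_table.to_csv(outdir / "de.tsv", sep="\t", float_format="%.6g",
                    na_rep="NA")

    marked = {line.strip() for line in Path(marked_txt).read_text().splitlines()
              if line.strip()}
    candidates = xp.integrate_candidates(set(saac.saac_a), regions,
                                         gene_locations(models), set(de_genes),
                                         marked)
    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write("gene\tin_pass\tde\tmarked\n")
        for g in sorted(candidates.candidates):
            fh.write(f"{g}\t{int(g in candidates.pass_genes)}"
                     f"\t{int(g in candidates.de_genes)}\t1\n")

    inputs = dict(vcf=vcf, populations=populations, reference=reference,
                  gff=gff, qtl_bed=qtl_bed, counts=counts_tsv,
                  marked=marked_txt)
    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": {
            "window": scan_params.window, "step": scan_params.step,
            "stat_window": scan_params.stat_window,
            "alpha": scan_params.alpha, "test": scan_params.test,
            "min_f_ratio": scan_params.min_f_ratio,
            "snv_only": scan_params.snv_only,
            "min_called_a": min_called_a, "min_called_b": min_called_b,
            "v0": expr_params.v0, "expr_window": expr_params.window,
            "fdr": expr_params.fdr, "log_transform": expr_params.log_transform,
            "n_stages": n_stages,
        },
        "inputs": {k: {"file": Path(v).name, "md5": _md5(Path(v))}
                   for k, v in inputs.items()},
        "class_tallies": tallies,
        "n_pass_regions": len(regions),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return RunResult(tallies, tests, regions, saac, qtl_summary, de_genes,
                     candidates, outdir)
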