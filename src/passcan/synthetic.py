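"""Seeded synthetic test worlds for the two-population sweep analysis.

The generator emulates the statistical structure the analysis assumes: two
diploid inbred populations (default 12 and 11 samples) derived from a shared
founder pool; founder variant sites scattered along a toy genome; planted
sweep intervals in population A where most sites are fixed for one alternate
allele (enriching A-fixed differences); neutral background elsewhere with
symmetric low fixation rates; residual per-sample heterozygosity and missing
calls layered on top (inbred lines are largely but not perfectly homozygous);
CDS gene models, some inside sweeps; QTL intervals covering the sweeps; and a
paired count matrix with planted differentially expressed genes.

Sites are simulated independently (no linkage): every implemented statistic
is count-based per window, so haplotype structure is unnecessary and the
generator stays desk-scale. Sweeps are modeled as an elevated per-site
fixation probability rather than a forward Wright–Fisher simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .effects import GeneModel, _COMPLEMENT
from .intervals import RegionSet
from .variants import GenotypeSite, PopulationSpec

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                if a + b + c not in STOPS]
AA_CHANGING_TRUTH = "aa_changing"


@dataclass
class SimConfig:
    """Knobs of the synthetic world; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_samples_a: int = 12
    n_samples_b: int = 11
    founder_site_density: float = 3.0     # founder sites per kb
    sweep_intervals: list[tuple[str, int, int]] | None = None  # None -> defaults
    sweep_fix_prob: float = 0.9
    background_fix_prob_a: float = 0.02
    background_fix_prob_b: float = 0.02
    het_residual_prob: float = 0.04       # residual per-sample heterozygosity
    missing_prob: float = 0.02
    indel_prob: float = 0.02
    n_genes: int = 200
    n_qtls: int = 8
    n_de_genes: int = 30
    de_log2fc: float = 2.0
    expr_dispersion: float = 0.1
    n_pairs_per_stage: int = 3
    n_stages: int = 3

    def __post_init__(self) -> None:
        for name in ("sweep_fix_prob", "background_fix_prob_a",
                     "background_fix_prob_b", "het_residual_prob",
                     "missing_prob", "indel_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sweep_intervals is None:
            self.sweep_intervals = self.default_sweeps()
        chroms = set(self.chrom_names())
        for chrom, start, end in self.sweep_intervals:
            if chrom not in chroms or not (0 <= start < end <= self.chrom_length):
                raise ValueError(f"sweep {chrom}:{start}-{end} outside genome")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def default_sweeps(self) -> list[tuple[str, int, int]]:
        """Two 200-kb sweeps (or fewer on a smaller genome)."""
        out = []
        length = min(200_000, self.chrom_length // 4)
        if self.n_chroms >= 1:
            start = self.chrom_length // 4
            out.append(("chr1", start, start + length))
        if self.n_chroms >= 2:
            start = self.chrom_length // 2
            out.append(("chr2", start, start + length))
        return out

    def population_spec(self, min_called_a: int = 10, min_called_b: int = 9
                        ) -> PopulationSpec:
        min_a = min(min_called_a, self.n_samples_a)
        min_b = min(min_called_b, self.n_samples_b)
        return PopulationSpec(
            "A", "B",
            tuple(f"A{i + 1}" for i in range(self.n_samples_a)),
            tuple(f"B{i + 1}" for i in range(self.n_samples_b)),
            min_a, min_b)


@dataclass
class SweepTruthSet:
    """Ground truth of one simulated world (pre-noise)."""

    seed: int
    sweep_intervals: list[tuple[str, int, int]]
    site_truth: pd.DataFrame  # chrom, pos, truth_class, ref, alt, aa_changing gene
    de_genes: list[str]
    saac_a: list[str]
    saac_b: list[str]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "sweep_intervals": [list(s) for s in self.sweep_intervals],
            "de_genes": self.de_genes,
            "saac_a": self.saac_a,
            "saac_b": self.saac_b,
            "class_tallies": self.site_truth["truth_class"].value_counts()
                                .sort_index().to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimWorld:
    config: SimConfig
    chrom_sizes: dict[str, int]
    reference: dict[str, str]
    genes: list[GeneModel]
    sites: list[GenotypeSite]
    truth: SweepTruthSet
    qtls: RegionSet
    counts: pd.DataFrame
    gene_lengths: pd.Series
    marked_genes: list[str]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, str], list[GeneModel], dict[str, int]]:
    """Random reference, CDS gene models (>= 1 per sweep), chromosome sizes."""
    rng = rng or np.random.default_rng(config.seed)
    sizes = {c: config.chrom_length for c in config.chrom_names()}
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    ref = {c: bytearray(lut[rng.integers(0, 4, size=n)].tobytes())
           for c, n in sizes.items()}

    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}

    def try_place(chrom: str, lo: int, hi: int, idx: int) -> bool:
        n_codons = int(rng.integers(100, 300))
        cds_len = 3 * n_codons
        n_ex = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_ex - 1,
                                 replace=False)) if n_ex > 1 else []
        chunk_lens = np.diff([0, *cuts, cds_len])
        introns = rng.integers(60, 200, size=n_ex - 1)
        span = cds_len + int(introns.sum())
        if hi - lo <= span + 2:
            return False
        for _ in range(40):
            start = int(rng.integers(lo, hi - span))
            end = start + span
            if all(end + 100 <= s or e + 100 <= start
                   for s, e in occupied[chrom]):
                break
        else:
            return False
        strand = "+" if rng.random() < 0.5 else "-"
        codon_idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
        cds = ("ATG" + "".join(SENSE_CODONS[i] for i in codon_idx)
               + str(rng.choice(["TAA", "TAG", "TGA"])))
        genomic = cds if strand == "+" else cds.translate(_COMPLEMENT)[::-1]
        segments = []
        g_off, cursor = 0, start
        for i, clen in enumerate(chunk_lens):
            clen = int(clen)
            segments.append((cursor, cursor + clen))
            ref[chrom][cursor:cursor + clen] = genomic[g_off:g_off + clen].encode()
            g_off += int(clen)
            cursor += int(clen)
            if i < n_ex - 1:
                cursor += int(introns[i])
        occupied[chrom].append((start, end))
        genes.append(GeneModel(f"gene{idx:04d}", f"tx{idx:04d}", chrom, strand,
                               segments))
        return True

    idx = 0
    for chrom, s_start, s_end in config.sweep_intervals or []:
        for _ in range(60):
            if try_place(chrom, s_start, s_end, idx):
                idx += 1
                break
        else:
            raise RuntimeError(f"could not place a gene inside sweep "
                               f"{chrom}:{s_start}-{s_end}")
    attempts = 0
    while idx < config.n_genes:
        chrom = str(rng.choice(list(sizes)))
        if try_place(chrom, 0, sizes[chrom], idx):
            idx += 1
        attempts += 1
        if attempts > config.n_genes * 50:
            raise RuntimeError("gene placement failed after bounded retries")

    reference = {c: arr.decode() for c, arr in ref.items()}
    genes.sort(key=lambda m: (m.chrom, m.span[0]))
    return reference, genes, sizes


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

_BACKGROUND_POLY = [("POLY_A_ONLY", 0.3), ("POLY_B_ONLY", 0.3),
                    ("POLY_BOTH", 0.2), ("SHARED_FIXED_ALT", 0.2)]


def _inbred_poly_genotypes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Homozygous 0/0 vs 1/1 genotypes segregating both alleles (n samples)."""
    q = rng.uniform(0.2, 0.8)
    hom_alt = rng.random(n) < q
    if hom_alt.all() or not hom_alt.any():
        hom_alt[int(rng.integers(n))] = not hom_alt[0]
    return np.stack([hom_alt, hom_alt], axis=1).astype(int)


def simulate_populations(config: SimConfig, reference: dict[str, str],
                         rng: np.random.Generator | None = None
                         ) -> tuple[list[GenotypeSite], pd.DataFrame]:
    """Plant founder sites with per-site truth classes; add het/missing noise.

    Returns the post-noise sites and the pre-noise truth table
    (chrom, pos, truth_class, ref, alt).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    spec = config.population_spec()
    samples = list(spec.samples_a) + list(spec.samples_b)
    n_a, n_b = len(spec.samples_a), len(spec.samples_b)
    sweeps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in config.sweep_intervals or []:
        sweeps_by_chrom.setdefault(chrom, []).append((s, e))

    sites: list[GenotypeSite] = []
    truth_rows = []
    for chrom, seq in reference.items():
        length = len(seq)
        n_sites = int(round(config.founder_site_density * length / 1000.0))
        # keep away from the last few bases so deletions stay in range
        positions = np.sort(rng.choice(np.arange(1, length - 5), size=n_sites,
                                       replace=False)) + 1  # 1-based
        for pos in positions:
            pos = int(pos)
            ref_base = seq[pos - 1]
            if rng.random() < config.indel_prob:
                if rng.random() < 0.5:  # insertion
                    ins = "".join(rng.choice(list(BASES),
                                             size=int(rng.integers(1, 4))))
                    ref_allele, alt_allele = ref_base, ref_base + ins
                else:  # deletion
                    k = int(rng.integers(1, 4))
                    ref_allele, alt_allele = seq[pos - 1: pos + k], ref_base
            else:
                alt = str(rng.choice([b for b in BASES if b != ref_base]))
                ref_allele, alt_allele = ref_base, alt

            in_sweep = any(s < pos <= e
                           for s, e in sweeps_by_chrom.get(chrom, ()))
            cls = _draw_truth_class(config, in_sweep, rng)
            gt = _genotypes_for_class(cls, n_a, n_b, rng)
            truth_rows.append((chrom, pos, cls, ref_allele, alt_allele))

            # residual heterozygosity, then missingness
            het = rng.random(n_a + n_b) < config.het_residual_prob
            gt[het, 0] = 0
            gt[het, 1] = 1
            miss = rng.random(n_a + n_b) < config.missing_prob
            gt[miss] = -1
            sites.append(GenotypeSite(
                chrom, pos, ref_allele, (alt_allele,),
                {s: (int(gt[i, 0]), int(gt[i, 1]))
                 for i, s in enumerate(samples)}))
    truth = pd.DataFrame(truth_rows,
                         columns=["chrom", "pos", "truth_class", "ref", "alt"])
    return sites, truth


def _draw_truth_class(config: SimConfig, in_sweep: bool,
                      rng: np.random.Generator) -> str:
    if in_sweep and rng.random() < config.sweep_fix_prob:
        return "FIXED_A"
    u = rng.random()
    if u < config.background_fix_prob_a:
        return "FIXED_A"
    if u < config.background_fix_prob_a + config.background_fix_prob_b:
        return "FIXED_B"
    v = rng.random()
    acc = 0.0
    for name, w in _BACKGROUND_POLY:
        acc += w
        if v < acc:
            return name
    return "MONOMORPHIC_REF"


def _genotypes_for_class(cls: str, n_a: int, n_b: int,
                         rng: np.random.Generator) -> np.ndarray:
    gt = np.zeros((n_a + n_b, 2), dtype=int)
    if cls == "FIXED_A":
        gt[:n_a] = 1
    elif cls == "FIXED_B":
        gt[n_a:] = 1
    elif cls == "SHARED_FIXED_ALT":
        gt[:] = 1
    elif cls == "POLY_A_ONLY":
        gt[:n_a] = _inbred_poly_genotypes(n_a, rng)
    elif cls == "POLY_B_ONLY":
        gt[n_a:] = _inbred_poly_genotypes(n_b, rng)
    elif cls == "POLY_BOTH":
        gt[:n_a] = _inbred_poly_genotypes(n_a, rng)
        gt[n_a:] = _inbred_poly_genotypes(n_b, rng)
    # MONOMORPHIC_REF: all zeros
    return gt


# ---------------------------------------------------------------------------
# Truth SAAC sets (whole-protein translate-and-diff, independent of effects)
# ---------------------------------------------------------------------------

def truth_aa_changing(reference: dict[str, str], genes: list[GeneModel],
                      truth: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Genes whose planted fixed variants change the protein, per population.

    SNVs are judged by mutating the genome, re-extracting the CDS and
    comparing full translations; indels touching the CDS change the protein
    by construction. This is a whole-protein oracle, independent of the
    codon-level annotator in :mod:`passcan.effects`.
    """
    from Bio.Seq import Seq

    changed = {"FIXED_A": set(), "FIXED_B": set()}
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in genes:
        by_chrom.setdefault(m.chrom, []).append(m)

    fixed = truth[truth.truth_class.isin(["FIXED_A", "FIXED_B"])]
    for row in fixed.itertuples(index=False):
        pos0 = int(row.pos) - 1
        for model in by_chrom.get(row.chrom, ()):
            lo, hi = model.span
            touched = range(pos0, pos0 + max(len(row.ref), 1))
            if not any(lo <= p < hi for p in touched):
                continue
            in_cds = any(any(s <= p < e for s, e in model.cds_segments)
                         for p in touched)
            if not in_cds:
                continue
            if len(row.ref) != 1 or len(row.alt) != 1:
                changed[row.truth_class].add(model.gene_id)
                continue
            seq = reference[row.chrom]
            mutated = {row.chrom: seq[:pos0] + row.alt + seq[pos0 + 1:]}
            prot_ref = str(Seq(model.cds_sequence(reference)).translate())
            prot_alt = str(Seq(model.cds_sequence(mutated)).translate())
            if prot_ref != prot_alt:
                changed[row.truth_class].add(model.gene_id)
    return changed["FIXED_A"], changed["FIXED_B"]


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimConfig, gene_ids: list[str],
                        gene_lengths: pd.Series,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Paired negative-binomial counts across stages; planted DE genes.

    Case samples of the planted DE genes are shifted by ``de_log2fc`` at
    every stage; per-sample depth factors vary so TPM normalization matters.
    Columns are named ``{A|B}_s{stage}_r{pair}``.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n_genes = len(gene_ids)
    n_de = min(config.n_de_genes, n_genes)
    de_genes = [gene_ids[i] for i in
                sorted(rng.choice(n_genes, size=n_de, replace=False))]
    de_mask = np.isin(gene_ids, de_genes)

    base_mu = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n_genes)
    disp = config.expr_dispersion
    nb_n = 1.0 / disp

    cols = {}
    for stage in range(1, config.n_stages + 1):
        for pair in range(1, config.n_pairs_per_stage + 1):
            for cond in ("A", "B"):
                depth = rng.uniform(0.8, 1.2)
                mu = base_mu * depth
                if cond == "A":
                    mu = np.where(de_mask, mu * 2.0**config.de_log2fc, mu)
                p = nb_n / (nb_n + mu)
                cols[f"{cond}_s{stage}_r{pair}"] = rng.negative_binomial(nb_n, p)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    return counts, de_genes


def stage_pairs(counts: pd.DataFrame, stage: int
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(case, control) column blocks for one stage, pair-aligned."""
    case = counts[[c for c in counts.columns
                   if c.startswith(f"A_s{stage}_")]]
    control = counts[[c for c in counts.columns
                      if c.startswith(f"B_s{stage}_")]]
    return case, control


# ---------------------------------------------------------------------------
# QTLs, marked genes, full world
# ---------------------------------------------------------------------------

def simulate_qtls(config: SimConfig, rng: np.random.Generator | None = None
                  ) -> RegionSet:
    """QTL intervals: one spanning each sweep (plus margin), the rest random."""
    rng = rng or np.random.default_rng(config.seed + 3)
    regions = []
    i = 1
    for chrom, s, e in config.sweep_intervals or []:
        lo = max(0, s - int(rng.integers(20_000, 100_000)))
        hi = min(config.chrom_length, e + int(rng.integers(20_000, 100_000)))
        regions.append((chrom, lo, hi, f"QTL{i}"))
        i += 1
    for _ in range(max(config.n_qtls - len(regions), 0)):
        chrom = str(rng.choice(config.chrom_names()))
        width = min(int(rng.integers(50_000, 300_000)),
                    max(config.chrom_length // 2, 1))
        start = int(rng.integers(0, config.chrom_length - width))
        regions.append((chrom, start, start + width, f"QTL{i}"))
        i += 1
    from .intervals import merge
    return merge(RegionSet(regions))


def simulate_world(config: SimConfig) -> SimWorld:
    """Generate a complete deterministic world from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    reference, genes, sizes = simulate_genome(config, rng)
    sites, truth_table = simulate_populations(config, reference, rng)
    gene_ids = [m.gene_id for m in genes]
    gene_lengths = pd.Series({m.gene_id: m.cds_length for m in genes},
                             name="length")
    counts, de_genes = simulate_expression(config, gene_ids, gene_lengths, rng)
    qtls = simulate_qtls(config, rng)

    changed_a, changed_b = truth_aa_changing(reference, genes, truth_table)
    saac_a = sorted(changed_a - changed_b)
    saac_b = sorted(changed_b - changed_a)

    sweep_genes = [m.gene_id for m in genes
                   if any(m.chrom == c and m.span[0] < e and s < m.span[1]
                          for c, s, e in config.sweep_intervals or [])]
    extra = [gene_ids[i] for i in
             sorted(rng.choice(len(gene_ids), size=min(10, len(gene_ids)),
                               replace=False))]
    marked = sorted(set(sweep_genes) | set(de_genes) | set(extra))

    truth = SweepTruthSet(config.seed, list(config.sweep_intervals or []),
                          truth_table, de_genes, saac_a, saac_b)
    return SimWorld(config, sizes, reference, genes, sites, truth, qtls,
                    counts, gene_lengths, marked)


# ---------------------------------------------------------------------------
# Writers (all plain text, deterministic)
# ---------------------------------------------------------------------------

def write_fasta(reference: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in reference:
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in genes:
            lo, hi = m.span
            fh.write(f"{m.chrom}\tpasscan\tgene\t{lo + 1}\t{hi}\t.\t{m.strand}"
                     f"\t.\tID={m.gene_id}\n")
            fh.write(f"{m.chrom}\tpasscan\tmRNA\t{lo + 1}\t{hi}\t.\t{m.strand}"
                     f"\t.\tID={m.transcript_id};Parent={m.gene_id}\n")
            # phase runs in transcript order; segments are written genomically
            tx_order = m.cds_segments if m.strand == "+" else m.cds_segments[::-1]
            phase_of = {}
            phase = 0
            for s, e in tx_order:
                phase_of[(s, e)] = phase
                phase = (3 - ((e - s) - phase) % 3) % 3
            for s, e in m.cds_segments:
                fh.write(f"{m.chrom}\tpasscan\tCDS\t{s + 1}\t{e}\t.\t{m.strand}"
                         f"\t{phase_of[(s, e)]}\tID=cds-{m.transcript_id};"
                         f"Parent={m.transcript_id}\n")


def write_vcf(sites: list[GenotypeSite], chrom_sizes: dict[str, int],
              samples: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=passcan-synthetic\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for site in sites:
            gts = []
            for s in samples:
                a1, a2 = site.genotypes.get(s, (-1, -1))
                gts.append(f"{'.' if a1 < 0 else a1}/{'.' if a2 < 0 else a2}")
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t"
                     f"{','.join(site.alts)}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_world(world: SimWorld, outdir) -> dict[str, Path]:
    """Emit every artifact of a world under one directory; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = world.config.population_spec()
    samples = list(spec.samples_a) + list(spec.samples_b)
    paths = {
        "fasta": out / "reference.fa",
        "gff": out / "genes.gff3",
        "vcf": out / "variants.vcf",
        "chrom_sizes": out / "chrom_sizes.tsv",
        "populations": out / "populations.tsv",
        "sweeps": out / "sweeps_truth.bed",
        "qtls": out / "qtls.bed",
        "counts": out / "counts.tsv",
        "marked": out / "marked_genes.txt",
        "truth": out / "truth.json",
    }
    write_fasta(world.reference, paths["fasta"])
    write_gff3(world.genes, paths["gff"])
    write_vcf(world.sites, world.chrom_sizes, samples, paths["vcf"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in world.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    with open(paths["populations"], "w") as fh:
        for s in spec.samples_a:
            fh.write(f"{s}\tA\n")
        for s in spec.samples_b:
            fh.write(f"{s}\tB\n")
    with open(paths["sweeps"], "w") as fh:
        for chrom, s, e in world.truth.sweep_intervals:
            fh.write(f"{chrom}\t{s}\t{e}\tsweep\n")
    from .intervals import write_bed
    write_bed(world.qtls, paths["qtls"])
    table = world.counts.copy()
    table.insert(0, "length", world.gene_lengths.reindex(table.index))
    table.to_csv(paths["counts"], sep="\t")
    Path(paths["marked"]).write_text("\n".join(world.marked_genes) + "\n")
    world.truth.to_json(paths["truth"])
    return paths
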