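"""Site classification: fixed vs polymorphic per population, against the reference.

Two inbred populations (A, the selected line; B, the control line) are compared
at each variant site. A site is a *fixed difference* for population A when every
called sample of A is homozygous for the same alternate allele while every
called sample of B is homozygous reference — i.e. A differs from both B and the
reference assembly. Sites segregating two or more alleles within a population's
called samples are *polymorphic* in that population. Sites where too few
samples carry a genotype call are dropped by a per-population retention filter
(defaults: 10 of 12 in A, 9 of 11 in B) so that population-level states are not
driven by missing calls.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

MISSING = -1


class SiteClass(enum.Enum):
    """Population-level state of one variant site."""

    FIXED_A = "FIXED_A"
    FIXED_B = "FIXED_B"
    POLY_A_ONLY = "POLY_A_ONLY"
    POLY_B_ONLY = "POLY_B_ONLY"
    POLY_BOTH = "POLY_BOTH"
    SHARED_FIXED_ALT = "SHARED_FIXED_ALT"
    MONOMORPHIC_REF = "MONOMORPHIC_REF"
    UNINFORMATIVE = "UNINFORMATIVE"


#: Classes counted as "polymorphic in A" / "in B" by the window scan.
POLY_CLASSES_A = frozenset({SiteClass.POLY_A_ONLY, SiteClass.POLY_BOTH})
POLY_CLASSES_B = frozenset({SiteClass.POLY_B_ONLY, SiteClass.POLY_BOTH})


@dataclass(frozen=True)
class PopulationSpec:
    """Sample-to-population assignment plus the call-count retention filter."""

    name_a: str
    name_b: str
    samples_a: tuple[str, ...]
    samples_b: tuple[str, ...]
    min_called_a: int = 10
    min_called_b: int = 9

    def __post_init__(self) -> None:
        if set(self.samples_a) & set(self.samples_b):
            raise ValueError("samples_a and samples_b overlap")
        if not (0 < self.min_called_a <= len(self.samples_a)):
            raise ValueError(
                f"min_called_a={self.min_called_a} outside (0, {len(self.samples_a)}]"
            )
        if not (0 < self.min_called_b <= len(self.samples_b)):
            raise ValueError(
                f"min_called_b={self.min_called_b} outside (0, {len(self.samples_b)}]"
            )

    def swapped(self) -> "PopulationSpec":
        """The same spec with populations A and B exchanged."""
        return PopulationSpec(
            self.name_b, self.name_a, self.samples_b, self.samples_a,
            self.min_called_b, self.min_called_a,
        )

    @classmethod
    def from_tsv(cls, path, name_a: str, name_b: str,
                 min_called_a: int = 10, min_called_b: int = 9) -> "PopulationSpec":
        """Read a two-column (sample, population) TSV."""
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                         dtype=str, comment="#")
        a = tuple(df.loc[df.population == name_a, "sample"])
        b = tuple(df.loc[df.population == name_b, "sample"])
        if not a or not b:
            raise ValueError(f"population map lacks samples for {name_a!r} or {name_b!r}")
        return cls(name_a, name_b, a, b, min_called_a, min_called_b)


@dataclass
class GenotypeSite:
    """One variant locus with per-sample diploid genotype calls.

    ``genotypes`` maps sample ID to a pair of allele indices into
    ``[ref] + alts``; ``MISSING`` (-1) marks an uncalled allele.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def allele(self, index: int) -> str:
        return ([self.ref] + list(self.alts))[index]


def load_sites(vcf_path, spec: PopulationSpec, snv_only: bool = False
               ) -> Iterator[GenotypeSite]:
    """Stream :class:`GenotypeSite` records from a multi-sample VCF.

    Records are yielded in file order (which must be coordinate-sorted per
    chromosome); multiallelic records come through once with all alternate
    alleles. ``snv_only`` drops any record with a non-length-1 allele.

    Raises ``ValueError`` if a spec sample is absent from the header, if the
    input is unsorted, or on a non-diploid genotype.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    header_samples = list(vcf.samples)
    wanted = list(spec.samples_a) + list(spec.samples_b)
    for sample in wanted:
        if sample not in header_samples:
            raise ValueError(f"sample {sample!r} missing from VCF header")
    col = {s: header_samples.index(s) for s in wanted}

    last: dict[str, int] = {}
    for rec in vcf:
        alts = tuple(rec.ALT)
        if snv_only and (len(rec.REF) != 1 or any(len(a) != 1 for a in alts)):
            continue
        chrom, pos = rec.CHROM, rec.POS
        if chrom in last and pos < last[chrom]:
            raise ValueError(
                f"unsorted VCF: {chrom}:{pos} after {chrom}:{last[chrom]}"
            )
        last[chrom] = pos
        gts = rec.genotypes  # [allele1, allele2, ..., phased] per sample
        genotypes: dict[str, tuple[int, int]] = {}
        for sample in wanted:
            g = gts[col[sample]]
            if len(g) != 3:  # alleles + phase flag for diploid
                raise ValueError(
                    f"non-diploid genotype for {sample} at {chrom}:{pos}"
                )
            a1 = g[0] if g[0] >= 0 else MISSING
            a2 = g[1] if g[1] >= 0 else MISSING
            genotypes[sample] = (a1, a2)
        yield GenotypeSite(chrom, pos, rec.REF, alts, genotypes)


def _population_state(site: GenotypeSite, samples: Sequence[str]):
    """(n_called, allele multiset) over the called samples of one population."""
    alleles: Counter[int] = Counter()
    n_called = 0
    for sample in samples:
        gt = site.genotypes.get(sample)
        if gt is None:
            continue
        a1, a2 = gt
        if a1 == MISSING or a2 == MISSING:
            continue
        n_called += 1
        alleles[a1] += 1
        alleles[a2] += 1
    return n_called, alleles


def classify_site(site: GenotypeSite, spec: PopulationSpec) -> SiteClass:
    """Assign the population-level :class:`SiteClass` for one site.

    The retention filter is applied first (UNINFORMATIVE when too few called
    samples in either population). A population fixed for an alternate allele
    while the other is also fixed for a *different* alternate does not meet
    the fixed-difference definition (the other population must match the
    reference) and folds into UNINFORMATIVE.
    """
    n_a, alleles_a = _population_state(site, spec.samples_a)
    n_b, alleles_b = _population_state(site, spec.samples_b)
    if n_a + n_b == 0 and not (set(spec.samples_a) | set(spec.samples_b)) & set(site.genotypes):
        raise ValueError(f"site {site.chrom}:{site.pos} covers no spec samples")
    if n_a < spec.min_called_a or n_b < spec.min_called_b:
        return SiteClass.UNINFORMATIVE

    poly_a = len(alleles_a) >= 2
    poly_b = len(alleles_b) >= 2
    if poly_a and poly_b:
        return SiteClass.POLY_BOTH
    if poly_a:
        return SiteClass.POLY_A_ONLY
    if poly_b:
        return SiteClass.POLY_B_ONLY

    (allele_a,) = alleles_a.keys()
    (allele_b,) = alleles_b.keys()
    if allele_a == 0 and allele_b == 0:
        return SiteClass.MONOMORPHIC_REF
    if allele_a == allele_b:
        return SiteClass.SHARED_FIXED_ALT
    if allele_a != 0 and allele_b == 0:
        return SiteClass.FIXED_A
    if allele_b != 0 and allele_a == 0:
        return SiteClass.FIXED_B
    # both fixed, for different alternate alleles
    return SiteClass.UNINFORMATIVE


def fixed_alt_allele(site: GenotypeSite, spec: PopulationSpec,
                     population: str = "a") -> str | None:
    """The alternate allele a population is fixed for, or None."""
    samples = spec.samples_a if population == "a" else spec.samples_b
    _, alleles = _population_state(site, samples)
    if len(alleles) != 1:
        return None
    (idx,) = alleles.keys()
    return site.allele(idx) if idx != 0 else None


def classify_all(sites: Iterable[GenotypeSite], spec: PopulationSpec,
                 keep_alt: bool = True) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify a sorted site stream; return (table, per-class tallies).

    The table has columns chrom, pos (1-based), site_class, and — when
    ``keep_alt`` — ref/alt columns for downstream effect annotation of fixed
    sites (alt is the fixed alternate allele for FIXED_* sites, else NA).
    """
    rows = []
    tallies: dict[str, int] = {c.value: 0 for c in SiteClass}
    for site in sites:
        cls = classify_site(site, spec)
        tallies[cls.value] += 1
        if keep_alt:
            if cls is SiteClass.FIXED_A:
                alt = fixed_alt_allele(site, spec, "a")
            elif cls is SiteClass.FIXED_B:
                alt = fixed_alt_allele(site, spec, "b")
            else:
                alt = None
            rows.append((site.chrom, site.pos, cls.value, site.ref, alt))
        else:
            rows.append((site.chrom, site.pos, cls.value))
    columns = ["chrom", "pos", "site_class"] + (["ref", "alt"] if keep_alt else [])
    table = pd.DataFrame(rows, columns=columns)
    return table, tallies


def write_site_classes(table: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "pos", "site_class", "ref", "alt")
            if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)


def read_site_classes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
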