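"""Codon-level effect annotation of fixed variants and SAAC gene sets.

A fixed variant of one population is annotated against a gene model: coding
SNVs are classified synonymous / non-synonymous / stopgain / stoploss by
substituting the alternate base into the reference codon (in transcript
orientation) and translating with the standard nuclear code; coding indels
are frameshift iff the length change is not a multiple of 3. Genes carrying
at least one amino-acid-altering fixed variant in exactly one population form
that population's SAAC (specific amino-acid-changed) gene set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq
from scipy import stats


class Effect(enum.Enum):
    SYNONYMOUS = "SYNONYMOUS"
    NONSYNONYMOUS = "NONSYNONYMOUS"
    STOPGAIN = "STOPGAIN"
    STOPLOSS = "STOPLOSS"
    FRAMESHIFT = "FRAMESHIFT"
    NONFRAMESHIFT_INDEL = "NONFRAMESHIFT_INDEL"
    NONCODING = "NONCODING"
    SPLICE_REGION = "SPLICE_REGION"


#: Effects that change the protein product ("amino acid changed" genes).
AA_CHANGING = frozenset({Effect.NONSYNONYMOUS, Effect.FRAMESHIFT,
                         Effect.NONFRAMESHIFT_INDEL, Effect.STOPGAIN,
                         Effect.STOPLOSS})
#: The deleterious subset as tallied alongside synonymous/non-synonymous.
DELETERIOUS = frozenset({Effect.FRAMESHIFT, Effect.NONFRAMESHIFT_INDEL,
                         Effect.STOPGAIN, Effect.STOPLOSS})

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class VariantEffect:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene_id: str
    transcript_id: str
    effect: Effect
    aa_change: str = ""


@dataclass
class GeneModel:
    """One transcript's CDS on the genome.

    ``cds_segments`` are 0-based half-open genomic intervals in genomic
    order; transcript orientation is derived from ``strand``. Models whose
    concatenated CDS length is not a multiple of 3 are flagged partial and
    skipped by the loader.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds_segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.cds_segments = sorted(self.cds_segments)
        prev_end = -1
        for start, end in self.cds_segments:
            if start >= end or start < prev_end:
                raise ValueError(f"{self.transcript_id}: bad CDS segments")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def cds_positions(self) -> list[int]:
        """Genomic 0-based positions of CDS bases, 5'->3' in transcript order."""
        pos = [p for s, e in self.cds_segments for p in range(s, e)]
        return pos[::-1] if self.strand == "-" else pos

    def cds_sequence(self, reference) -> str:
        parts = [_fetch(reference, self.chrom, s, e) for s, e in self.cds_segments]
        seq = "".join(parts)
        if self.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        return seq.upper()


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Slice [start, end) from a pyfaidx Fasta or a plain chrom->str mapping."""
    seq = reference[chrom][start:end]
    return str(getattr(seq, "seq", seq))


def load_gene_models(gff_path, longest_only: bool = True) -> list[GeneModel]:
    """Read CDS gene models from GFF3/GTF via an in-memory gffutils db.

    One transcript per gene is kept (the longest CDS) to give a single
    effect call per gene; models with partial terminal codons (CDS length
    not divisible by 3) are skipped.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    tx_to_gene: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        for tx in db.features_of_type(ftype):
            parents = tx.attributes.get("Parent", [tx.id])
            tx_to_gene[tx.id] = parents[0]

    by_tx: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        for parent in cds.attributes.get("Parent", [cds.id]):
            by_tx.setdefault(parent, []).append(cds)

    models = []
    for tx_id, features in by_tx.items():
        gene_id = tx_to_gene.get(tx_id, tx_id)
        segments = [(f.start - 1, f.end) for f in features]
        model = GeneModel(gene_id, tx_id, features[0].seqid, features[0].strand,
                          segments)
        if model.cds_length % 3 != 0:
            continue  # partial model
        models.append(model)

    if longest_only:
        best: dict[str, GeneModel] = {}
        for m in models:
            cur = best.get(m.gene_id)
            if cur is None or m.cds_length > cur.cds_length:
                best[m.gene_id] = m
        models = list(best.values())
    return sorted(models, key=lambda m: (m.chrom, m.span[0], m.gene_id))


def annotate_variant(chrom: str, pos: int, ref: str, alt: str,
                     model: GeneModel, reference) -> VariantEffect:
    """Effect of one variant (1-based ``pos``) on one gene model.

    Raises ``ValueError`` on a reference-allele mismatch against the FASTA.
    """
    pos0 = pos - 1
    observed = _fetch(reference, chrom, pos0, pos0 + len(ref)).upper()
    if observed != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: FASTA has {observed!r}, "
            f"variant says {ref!r}")
    if chrom != model.chrom:
        return VariantEffect(chrom, pos, ref, alt, model.gene_id,
                             model.transcript_id, Effect.NONCODING)

    if len(ref) == 1 and len(alt) == 1:
        return _annotate_snv(chrom, pos, ref, alt, model, reference)
    return _annotate_indel(chrom, pos, ref, alt, model)


def _in_cds(model: GeneModel, pos0: int) -> bool:
    return any(s <= pos0 < e for s, e in model.cds_segments)


def _near_splice(model: GeneModel, pos0: int, margin: int = 2) -> bool:
    for s, e in model.cds_segments:
        if s - margin <= pos0 < s or e <= pos0 < e + margin:
            return True
    return False


def _annotate_snv(chrom, pos, ref, alt, model: GeneModel, reference) -> VariantEffect:
    pos0 = pos - 1
    if not _in_cds(model, pos0):
        eff = Effect.SPLICE_REGION if _near_splice(model, pos0) else Effect.NONCODING
        return VariantEffect(chrom, pos, ref, alt, model.gene_id,
                             model.transcript_id, eff)
    positions = model.cds_positions()
    idx = positions.index(pos0)
    codon_i, offset = divmod(idx, 3)
    cds = model.cds_sequence(reference)
    codon = cds[codon_i * 3: codon_i * 3 + 3]
    sub = alt.upper() if model.strand == "+" else alt.upper().translate(_COMPLEMENT)
    new_codon = codon[:offset] + sub + codon[offset + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new_codon).translate())
    if aa_ref == aa_alt:
        eff = Effect.SYNONYMOUS
        change = ""
    elif aa_alt == "*":
        eff, change = Effect.STOPGAIN, f"{aa_ref}{codon_i + 1}*"
    elif aa_ref == "*":
        eff, change = Effect.STOPLOSS, f"*{codon_i + 1}{aa_alt}"
    else:
        eff, change = Effect.NONSYNONYMOUS, f"{aa_ref}{codon_i + 1}{aa_alt}"
    return VariantEffect(chrom, pos, ref, alt, model.gene_id,
                         model.transcript_id, eff, change)


def _annotate_indel(chrom, pos, ref, alt, model: GeneModel) -> VariantEffect:
    pos0 = pos - 1
    # bases touched: the replaced reference span (insertion anchors on pos0)
    touched = range(pos0, pos0 + max(len(ref), 1))
    if any(_in_cds(model, p) for p in touched):
        delta = abs(len(alt) - len(ref))
        eff = Effect.FRAMESHIFT if delta % 3 else Effect.NONFRAMESHIFT_INDEL
    elif any(_near_splice(model, p) for p in touched):
        eff = Effect.SPLICE_REGION
    else:
        eff = Effect.NONCODING
    return VariantEffect(chrom, pos, ref, alt, model.gene_id,
                         model.transcript_id, eff)


def annotate_fixed_sites(fixed: pd.DataFrame, models: Sequence[GeneModel],
                         reference) -> list[VariantEffect]:
    """Annotate a (chrom, pos, ref, alt) table of fixed variants.

    Each variant is annotated against every gene model whose CDS span
    (plus the 2-bp splice margin) it touches; variants hitting no model
    are reported once as NONCODING with an empty gene id.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)

    out: list[VariantEffect] = []
    for row in fixed.itertuples(index=False):
        chrom, pos, ref, alt = row.chrom, int(row.pos), row.ref, row.alt
        pos0 = pos - 1
        hits = []
        for m in by_chrom.get(chrom, ()):
            lo, hi = m.span
            if lo - 2 <= pos0 < hi + 2 + max(len(ref) - 1, 0):
                hits.append(annotate_variant(chrom, pos, ref, alt, m, reference))
        if hits:
            out.extend(hits)
        else:
            out.append(VariantEffect(chrom, pos, ref, alt, "", "",
                                     Effect.NONCODING))
    return out


@dataclass(frozen=True)
class SaacSets:
    amino_acid_changed_a: frozenset[str]
    amino_acid_changed_b: frozenset[str]

    @property
    def saac_a(self) -> frozenset[str]:
        return self.amino_acid_changed_a - self.amino_acid_changed_b

    @property
    def saac_b(self) -> frozenset[str]:
        return self.amino_acid_changed_b - self.amino_acid_changed_a


def saac_sets(effects_a: Iterable[VariantEffect],
              effects_b: Iterable[VariantEffect]) -> SaacSets:
    """SAAC gene sets from per-population fixed-variant effect lists."""
    changed_a = frozenset(e.gene_id for e in effects_a
                          if e.effect in AA_CHANGING and e.gene_id)
    changed_b = frozenset(e.gene_id for e in effects_b
                          if e.effect in AA_CHANGING and e.gene_id)
    return SaacSets(changed_a, changed_b)


def ns_s_ratio_test(ns_in: int, s_in: int, ns_out: int, s_out: int
                    ) -> tuple[float, float, float]:
    """(NS/S inside, NS/S outside, two-sided Fisher p) from stratum counts."""
    ratio_in = ns_in / s_in if s_in else float("nan")
    ratio_out = ns_out / s_out if s_out else float("nan")
    p = float(stats.fisher_exact([[ns_in, s_in], [ns_out, s_out]],
                                 alternative="two-sided").pvalue)
    return ratio_in, ratio_out, p


def ns_s_counts(effects: Iterable[VariantEffect],
                pass_regions) -> tuple[int, int, int, int]:
    """Split coding-SNV effects into (NS_in, S_in, NS_out, S_out) by PASS overlap."""
    region_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in pass_regions:
        region_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    ns_in = s_in = ns_out = s_out = 0
    for e in effects:
        if e.effect is Effect.NONSYNONYMOUS:
            is_ns = True
        elif e.effect is Effect.SYNONYMOUS:
            is_ns = False
        else:
            continue
        pos0 = e.pos - 1
        inside = any(s <= pos0 < t for s, t in region_by_chrom.get(e.chrom, ()))
        if inside:
            ns_in, s_in = ns_in + is_ns, s_in + (not is_ns)
        else:
            ns_out, s_out = ns_out + is_ns, s_out + (not is_ns)
    return ns_in, s_in, ns_out, s_out


def effects_frame(effects: Sequence[VariantEffect]) -> pd.DataFrame:
    rows = [(e.chrom, e.pos, e.ref, e.alt, e.gene_id, e.transcript_id,
             e.effect.value, e.aa_change) for e in effects]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                       "transcript", "effect", "aa_change"])
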