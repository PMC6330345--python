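"""Minimal variant-consequence annotation against toy gene models.

Classifies SNVs and indels into the consequence categories relevant for
flagging protein-disrupting somatic variants: stop gain/loss, start loss,
splice donor/acceptor (2 bp at each intron end), frameshift, missense,
synonymous, plus the non-coding categories (intron, UTR, intergenic).
Coding consequences are obtained by translating the strand-corrected CDS
with the standard genetic code and comparing proteins. Every category maps
to exactly one impact tier (HIGH / MODERATE / LOW / MODIFIER).

Gene models come from GFF3 (gene/mRNA/exon/CDS, 1-based inclusive) and the
genome from FASTA.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "VariantEffect",
    "IMPACT_BY_CATEGORY",
    "annotate_variant",
    "annotate_contrast_sites",
    "summarize_high_impact",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_gff3",
    "write_gff3",
]

IMPACT_BY_CATEGORY = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "splice_donor_variant": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "start_lost": "HIGH",
    "frameshift_variant": "HIGH",
    "missense_variant": "MODERATE",
    "synonymous_variant": "LOW",
    "intron_variant": "MODIFIER",
    "utr_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
}

SPLICE_WINDOW = 2  # bases at each intron end


def _check_intervals(intervals: Sequence[tuple[int, int]], label: str) -> tuple[tuple[int, int], ...]:
    ivs = tuple(sorted((int(a), int(b)) for a, b in intervals))
    for a, b in ivs:
        if a < 1 or b < a:
            raise ValueError(f"{label}: malformed interval ({a}, {b})")
    for (_, b1), (a2, _) in zip(ivs, ivs[1:]):
        if a2 <= b1:
            raise ValueError(f"{label}: overlapping intervals")
    return ivs


@dataclass(frozen=True)
class GeneModel:
    """One transcript model: sorted 1-based inclusive exon and CDS intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        object.__setattr__(self, "exons", _check_intervals(self.exons, f"{self.gene_id} exons"))
        object.__setattr__(self, "cds", _check_intervals(self.cds, f"{self.gene_id} CDS"))
        if self.cds:
            length = sum(b - a + 1 for a, b in self.cds)
            if length % 3 != 0:
                raise ValueError(f"{self.gene_id}: CDS length {length} not divisible by 3")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (b1 + 1, a2 - 1) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])
        )

    def cds_positions(self) -> list[int]:
        """Genomic positions of the coding sequence in 5'->3' order."""
        pos = [p for a, b in self.cds for p in range(a, b + 1)]
        return pos if self.strand == "+" else pos[::-1]


@dataclass(frozen=True)
class VariantEffect:
    category: str
    impact: str
    gene_id: str | None
    codon_change: str | None = None
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.category not in IMPACT_BY_CATEGORY:
            raise ValueError(f"unknown category {self.category!r}")
        if self.impact != IMPACT_BY_CATEGORY[self.category]:
            raise ValueError(f"{self.category} must have impact {IMPACT_BY_CATEGORY[self.category]}")


def _effect(category: str, gene_id: str | None, codon_change=None, aa_change=None) -> VariantEffect:
    return VariantEffect(category, IMPACT_BY_CATEGORY[category], gene_id, codon_change, aa_change)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _splice_category(model: GeneModel, positions: set[int]) -> str | None:
    for a, b in model.introns:
        if b - a + 1 < 2 * SPLICE_WINDOW:
            continue  # micro-introns: skip ambiguous windows
        left = set(range(a, a + SPLICE_WINDOW))
        right = set(range(b - SPLICE_WINDOW + 1, b + 1))
        donor, acceptor = (left, right) if model.strand == "+" else (right, left)
        if positions & donor:
            return "splice_donor_variant"
        if positions & acceptor:
            return "splice_acceptor_variant"
    return None


def _in_intervals(p: int, intervals) -> bool:
    return any(a <= p <= b for a, b in intervals)


def _annotate_snv(model: GeneModel, pos: int, ref: str, alt: str, genome: Mapping[str, str]) -> VariantEffect:
    splice = _splice_category(model, {pos})
    if splice:
        return _effect(splice, model.gene_id)
    if _in_intervals(pos, model.cds):
        coords = model.cds_positions()
        idx = coords.index(pos)
        seq = genome[model.chrom]
        cds_seq = "".join(seq[p - 1] for p in coords)
        base = alt
        if model.strand == "-":
            cds_seq = cds_seq.translate(_COMPLEMENT)
            base = alt.translate(_COMPLEMENT)
        cds_seq = cds_seq.upper()
        codon_i = idx // 3
        within = idx % 3
        ref_codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
        alt_codon = ref_codon[:within] + base.upper() + ref_codon[within + 1 :]
        aa_ref = str(Seq(ref_codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        codon_change = f"{ref_codon}>{alt_codon}"
        aa_change = f"{aa_ref}{codon_i + 1}{aa_alt}"
        if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
            return _effect("start_lost", model.gene_id, codon_change, aa_change)
        if aa_ref == aa_alt:
            return _effect("synonymous_variant", model.gene_id, codon_change, aa_change)
        if aa_alt == "*":
            return _effect("stop_gained", model.gene_id, codon_change, aa_change)
        if aa_ref == "*":
            return _effect("stop_lost", model.gene_id, codon_change, aa_change)
        return _effect("missense_variant", model.gene_id, codon_change, aa_change)
    if _in_intervals(pos, model.exons):
        return _effect("utr_variant", model.gene_id)
    return _effect("intron_variant", model.gene_id)


def _annotate_indel(model: GeneModel, pos: int, ref: str, alt: str) -> VariantEffect:
    # VCF left-anchored convention: the change affects pos+1 .. pos+len(ref)-1
    # for deletions, and the junction after pos for insertions.
    changed = set(range(pos + 1, pos + len(ref))) or {pos}
    splice = _splice_category(model, changed)
    if splice:
        return _effect(splice, model.gene_id)
    in_cds = any(_in_intervals(p, model.cds) for p in changed)
    if in_cds:
        shift = (len(alt) - len(ref)) % 3
        if shift != 0:
            return _effect("frameshift_variant", model.gene_id)
        return _effect("missense_variant", model.gene_id)  # in-frame coding indel
    if any(_in_intervals(p, model.exons) for p in changed):
        return _effect("utr_variant", model.gene_id)
    return _effect("intron_variant", model.gene_id)


def annotate_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    models: Iterable[GeneModel],
    genome: Mapping[str, str],
) -> list[VariantEffect]:
    """All consequences of one variant, one effect per overlapping model.

    ``pos`` is 1-based; ``ref`` must match the genome at that position.
    Variants overlapping no model yield a single intergenic effect.
    """
    if chrom not in genome:
        raise ValueError(f"unknown chromosome {chrom!r}")
    seq = genome[chrom]
    if pos < 1 or pos + len(ref) - 1 > len(seq):
        raise ValueError(f"{chrom}:{pos}: outside genome bounds")
    observed = seq[pos - 1 : pos - 1 + len(ref)].upper()
    if observed != ref.upper():
        raise ValueError(f"reference mismatch at {chrom}:{pos}: genome has {observed!r}, record says {ref!r}")

    span_positions = set(range(pos, pos + max(len(ref), 1)))
    effects = []
    for model in models:
        if model.chrom != chrom:
            continue
        lo, hi = model.span
        if span_positions & set(range(lo, hi + 1)):
            if len(ref) == 1 and len(alt) == 1:
                effects.append(_annotate_snv(model, pos, ref, alt, genome))
            else:
                effects.append(_annotate_indel(model, pos, ref, alt))
    if not effects:
        effects.append(_effect("intergenic_variant", None))
    return effects


def annotate_contrast_sites(
    contrast_sites: Iterable,
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> dict[str, list[VariantEffect]]:
    """Effects for every candidate site (keyed by site_id)."""
    return {
        s.site_id: annotate_variant(s.chrom, s.pos, s.ref_allele, s.alt_allele, models, genome)
        for s in contrast_sites
    }


def summarize_high_impact(
    effects_by_site: Mapping[str, list[VariantEffect]],
    contrast_sites: Iterable,
) -> pd.DataFrame:
    """Passing candidate sites carrying HIGH-impact consequences.

    One row per (site, gene, category); the affected clone is the
    heterozygous clone of the site.
    """
    rows = []
    for site in contrast_sites:
        if not site.passes:
            continue
        for eff in effects_by_site.get(site.site_id, []):
            if eff.impact != "HIGH":
                continue
            rows.append(
                {
                    "site_id": site.site_id,
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "affected_clone": ",".join(site.het_clones),
                    "gene_id": eff.gene_id,
                    "category": eff.category,
                    "impact": eff.impact,
                    "aa_change": eff.aa_change or "",
                }
            )
    cols = ["site_id", "chrom", "pos", "affected_clone", "gene_id", "category", "impact", "aa_change"]
    return pd.DataFrame(rows, columns=cols)


def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gff3(path) -> list[GeneModel]:
    """Gene models from GFF3 (gene/mRNA/exon/CDS), one model per mRNA."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons:
            exons = list(cds)
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write(
                f"{m.chrom}\tsomaclone\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            mrna_id = f"{m.gene_id}.t1"
            fh.write(
                f"{m.chrom}\tsomaclone\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={mrna_id};Parent={m.gene_id}\n"
            )
            for i, (a, b) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tsomaclone\texon\t{a}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, (a, b) in enumerate(m.cds, 1):
                fh.write(
                    f"{m.chrom}\tsomaclone\tCDS\t{a}\t{b}\t.\t{m.strand}\t0\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )
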