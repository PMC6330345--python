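"""Reading and writing per-sample allele-depth records as VCF 4.2.

The pipeline consumes variant-caller output (or simulator output) as VCF
with per-sample ``AD`` (ref,alt allele depths) and ``DP`` FORMAT fields,
sample names ``<clone>_<replicate>``, and the site QUAL column. Records are
flattened to one row per (site, alternate allele, sample); multi-allelic
sites are decomposed into one record per alternate allele. Records without
usable AD are dropped (absent data, never zero depth) with a logged count.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = ["read_vcf_allele_counts", "write_vcf", "filter_by_quality"]

RECORD_COLUMNS = [
    "site_id", "chrom", "pos", "ref_allele", "alt_allele",
    "site_quality", "clone", "replicate", "ref_depth", "alt_depth",
]


def read_vcf_allele_counts(
    path,
    sample_map: Mapping[str, tuple[str, int]],
) -> pd.DataFrame:
    """Flatten a VCF into one allele-count record per (site, ALT, sample).

    ``sample_map`` maps VCF sample names to (clone, replicate); every
    sample present in the file must be mapped. AD is interpreted as
    Number=R (ref depth first, one entry per alternate allele). Samples
    with missing AD at a site are excluded and counted in a log message.
    """
    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        unmapped = [s for s in vcf.header.samples if s not in sample_map]
        if unmapped:
            raise ValueError(f"samples absent from sample map: {unmapped}")
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            qual = float(rec.qual) if rec.qual is not None else 0.0
            site_id = rec.id if rec.id is not None else f"{rec.chrom}:{rec.pos}"
            for sample in rec.samples:
                clone, replicate = sample_map[sample]
                ad = rec.samples[sample].get("AD")
                if ad is None or any(x is None for x in ad) or len(ad) != 1 + len(alts):
                    skipped += 1
                    continue
                for i, alt in enumerate(alts):
                    rows.append(
                        (
                            site_id, rec.chrom, rec.pos, rec.ref, alt,
                            qual, clone, int(replicate), int(ad[0]), int(ad[i + 1]),
                        )
                    )
    if skipped:
        logger.warning("dropped %d sample-genotypes with missing AD", skipped)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_vcf(records: pd.DataFrame, path) -> None:
    """Write an allele-count record table as VCF 4.2.

    Records sharing (site_id, chrom, pos, ref, alt) become one biallelic
    VCF line with FORMAT AD (ref,alt) and DP per sample; sample names are
    ``<clone>_<replicate>``. Sites missing a sample's record get missing
    genotype fields.
    """
    header = pysam.VariantHeader()
    for chrom, grp in records.groupby("chrom", sort=True):
        header.contigs.add(str(chrom), length=int(grp["pos"].max()) + 1000)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", "1", "Integer", "Read depth")
    meta = records[["clone", "replicate"]].drop_duplicates().sort_values(["clone", "replicate"])
    sample_names = [f"{c}_{r}" for c, r in meta.itertuples(index=False, name=None)]
    for name in sample_names:
        header.add_sample(name)

    site_cols = ["site_id", "chrom", "pos", "ref_allele", "alt_allele", "site_quality"]
    sites = records[site_cols].drop_duplicates().sort_values(["chrom", "pos", "site_id"])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site_id, chrom, pos, ref, alt, qual in sites.itertuples(index=False, name=None):
            mask = (
                (records["site_id"] == site_id)
                & (records["chrom"] == chrom)
                & (records["pos"] == pos)
                & (records["alt_allele"] == alt)
            )
            rec = out.new_record(
                contig=str(chrom),
                start=int(pos) - 1,
                stop=int(pos) - 1 + len(str(ref)),
                alleles=(str(ref), str(alt)),
                id=str(site_id),
                qual=float(qual),
            )
            for row in records[mask].itertuples(index=False):
                name = f"{row.clone}_{row.replicate}"
                rec.samples[name]["AD"] = (int(row.ref_depth), int(row.alt_depth))
                rec.samples[name]["DP"] = int(row.ref_depth) + int(row.alt_depth)
            out.write(rec)


def filter_by_quality(records: pd.DataFrame, min_quality: float = 40.0) -> pd.DataFrame:
    """Retain records whose site quality strictly exceeds ``min_quality``.

    Idempotent and order-preserving; a site at exactly the threshold is
    removed.
    """
    return records.loc[records["site_quality"] > min_quality].copy()
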