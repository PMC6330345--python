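"""Rule-based heterozygous/homozygous genotype classification from allele depths.

Somatic polymorphisms between clones of a vegetatively propagated cultivar are
detected from replicated RNA-seq allele counts using deterministic depth and
allele-fraction rules rather than likelihood-based genotyping:

* a replicate is only assignable at a minimal depth (default 50 reads);
* it is heterozygous when the minor allele carries at least 30% of the reads;
* it is homozygous when the minor allele has at most one read and less than
  2% of the reads;
* everything else is left not-assigned;
* a clone-level status requires unanimity across its replicates;
* a candidate somatic site needs one (or more) heterozygous clone, all other
  clones homozygous, and — by default — at least one homozygous clone with
  zero minor-allele reads summed over its replicates.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

__all__ = [
    "Status",
    "Reason",
    "ClassificationThresholds",
    "GenotypeCall",
    "CloneContrastSite",
    "classify_replicate",
    "classify_clone",
    "classify_clone_counts",
    "classify_sites",
    "detect_contrast_sites",
    "contrast_sites_to_frame",
    "recover_planted_sites",
]


class Status(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    NOT_ASSIGNED = "not_assigned"


class Reason(str, Enum):
    LOW_DEPTH = "low_depth"
    AMBIGUOUS = "ambiguous"
    INCONSISTENT_REPLICATES = "inconsistent_replicates"


@dataclass(frozen=True)
class ClassificationThresholds:
    """Thresholds of the strict genotype-status rules.

    Parameters
    ----------
    min_depth
        Minimal read depth for a replicate (or for the pooled clone when
        ``pooled_depth`` is set) to be assignable. Reads.
    het_minor_fraction
        Minimal minor-allele read fraction for a heterozygous call
        (inclusive).
    hom_max_minor_reads
        Maximal number of minor-allele reads tolerated in a homozygous call
        (inclusive).
    hom_max_minor_fraction
        The minor-allele fraction of a homozygous call must be strictly
        below this proportion. Both homozygosity conditions must hold.
    require_zero_minor_clone
        Candidate somatic sites must have at least one homozygous clone with
        zero minor-allele reads summed across replicates.
    pooled_depth
        Apply ``min_depth`` to the clone's pooled depth instead of each
        replicate individually.
    """

    min_depth: int = 50
    het_minor_fraction: float = 0.30
    hom_max_minor_reads: int = 1
    hom_max_minor_fraction: float = 0.02
    require_zero_minor_clone: bool = True
    pooled_depth: bool = False

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 < self.hom_max_minor_fraction < self.het_minor_fraction <= 0.5:
            raise ValueError(
                "thresholds must satisfy 0 < hom_max_minor_fraction"
                " < het_minor_fraction <= 0.5"
            )
        if self.hom_max_minor_reads < 0:
            raise ValueError("hom_max_minor_reads must be >= 0")


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass(frozen=True)
class GenotypeCall:
    """Status of one replicate, or of one clone after aggregation."""

    status: Status
    minor_reads: int
    depth: int
    minor_fraction: float
    reason: Reason | None = None


def classify_replicate(
    major_reads: int,
    minor_reads: int,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> GenotypeCall:
    """Assign the het/hom/not-assigned status of a single replicate.

    The decision depends only on the smaller and larger of the two read
    counts, never on which allele (reference or alternate) is the minor one;
    arguments may be passed in either order.
    """
    if major_reads < 0 or minor_reads < 0:
        raise ValueError("read counts must be non-negative")
    minor = min(major_reads, minor_reads)
    depth = major_reads + minor_reads
    if depth < thresholds.min_depth:
        frac = minor / depth if depth > 0 else 0.0
        return GenotypeCall(Status.NOT_ASSIGNED, minor, depth, frac, Reason.LOW_DEPTH)
    frac = minor / depth
    if frac >= thresholds.het_minor_fraction:
        return GenotypeCall(Status.HETEROZYGOUS, minor, depth, frac)
    if minor <= thresholds.hom_max_minor_reads and frac < thresholds.hom_max_minor_fraction:
        return GenotypeCall(Status.HOMOZYGOUS, minor, depth, frac)
    return GenotypeCall(Status.NOT_ASSIGNED, minor, depth, frac, Reason.AMBIGUOUS)


def classify_clone(replicate_calls: Sequence[GenotypeCall]) -> GenotypeCall:
    """Aggregate replicate calls of one clone, demanding unanimity.

    All replicates must share the same assignable status; otherwise the
    clone is not assigned (``INCONSISTENT_REPLICATES``). Minor reads and
    depth are summed over replicates.
    """
    if not replicate_calls:
        raise ValueError("at least one replicate call is required")
    minor = sum(c.minor_reads for c in replicate_calls)
    depth = sum(c.depth for c in replicate_calls)
    frac = minor / depth if depth > 0 else 0.0
    statuses = {c.status for c in replicate_calls}
    if len(statuses) == 1 and Status.NOT_ASSIGNED not in statuses:
        return GenotypeCall(statuses.pop(), minor, depth, frac)
    if statuses == {Status.NOT_ASSIGNED}:
        reasons = {c.reason for c in replicate_calls}
        reason = reasons.pop() if len(reasons) == 1 else Reason.INCONSISTENT_REPLICATES
        return GenotypeCall(Status.NOT_ASSIGNED, minor, depth, frac, reason)
    return GenotypeCall(
        Status.NOT_ASSIGNED, minor, depth, frac, Reason.INCONSISTENT_REPLICATES
    )


def classify_clone_counts(
    replicate_counts: Sequence[tuple[int, int]],
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> GenotypeCall:
    """Classify a clone from its per-replicate (ref_reads, alt_reads) pairs.

    The clone's minor allele is the allele with fewer reads summed across
    replicates (exact ties resolve to the alternate allele; either choice
    yields a heterozygous fraction of 0.5). The aggregated ``minor_reads``
    counts that clone-level minor allele, which is what the zero-minor-read
    requirement of candidate-site detection inspects.
    """
    if not replicate_counts:
        raise ValueError("at least one replicate is required")
    total_ref = sum(r for r, _ in replicate_counts)
    total_alt = sum(a for _, a in replicate_counts)
    minor_is_alt = total_alt <= total_ref
    if thresholds.pooled_depth:
        pooled = classify_replicate(
            max(total_ref, total_alt),
            min(total_ref, total_alt),
            thresholds,
        )
        if pooled.status is Status.NOT_ASSIGNED and pooled.reason is Reason.LOW_DEPTH:
            return pooled
        # Replicate consistency is still demanded, without the depth gate.
        rep_thresholds = ClassificationThresholds(
            min_depth=1,
            het_minor_fraction=thresholds.het_minor_fraction,
            hom_max_minor_reads=thresholds.hom_max_minor_reads,
            hom_max_minor_fraction=thresholds.hom_max_minor_fraction,
            require_zero_minor_clone=thresholds.require_zero_minor_clone,
        )
        calls = [
            classify_replicate(r, a, rep_thresholds) for r, a in replicate_counts
        ]
    else:
        calls = [classify_replicate(r, a, thresholds) for r, a in replicate_counts]
    aggregated = classify_clone(calls)
    minor_total = total_alt if minor_is_alt else total_ref
    return GenotypeCall(
        aggregated.status,
        minor_total,
        aggregated.depth,
        minor_total / aggregated.depth if aggregated.depth else 0.0,
        aggregated.reason,
    )


@dataclass(frozen=True)
class CloneContrastSite:
    """A candidate somatic site with its per-clone statuses."""

    site_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    calls: Mapping[str, GenotypeCall] = field(repr=False)
    het_clones: tuple[str, ...] = ()
    hom_clones: tuple[str, ...] = ()
    zero_minor_clone_present: bool = False
    passes: bool = False


_SITE_COLS = ["site_id", "chrom", "pos", "ref_allele", "alt_allele"]


def classify_sites(
    records: pd.DataFrame,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> dict[tuple, dict[str, GenotypeCall]]:
    """Clone-level calls for every site in an allele-count record table.

    ``records`` needs the columns produced by the simulator or the VCF
    reader: site_id, chrom, pos, ref_allele, alt_allele, clone, replicate,
    ref_depth, alt_depth. Returns a mapping from the site key
    ``(site_id, chrom, pos, ref_allele, alt_allele)`` to per-clone calls.
    """
    out: dict[tuple, dict[str, GenotypeCall]] = {}
    for key, site_rows in records.groupby(_SITE_COLS, sort=False):
        clone_calls: dict[str, GenotypeCall] = {}
        for clone, rows in site_rows.groupby("clone", sort=False):
            rows = rows.sort_values("replicate")
            pairs = list(zip(rows["ref_depth"].astype(int), rows["alt_depth"].astype(int)))
            clone_calls[str(clone)] = classify_clone_counts(pairs, thresholds)
        out[key] = clone_calls
    return out


def detect_contrast_sites(
    site_calls: Mapping[tuple, Mapping[str, GenotypeCall]],
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> list[CloneContrastSite]:
    """Flag sites discriminating the clones (candidate somatic variants).

    A site passes when at least one clone is heterozygous, every remaining
    clone is homozygous (a single not-assigned clone disqualifies the site),
    and — when ``require_zero_minor_clone`` — at least one homozygous clone
    shows zero minor-allele reads summed across its replicates. The output
    is sorted by (chrom, pos, site_id).
    """
    sites: list[CloneContrastSite] = []
    for key, calls in site_calls.items():
        site_id, chrom, pos, ref, alt = key
        het = tuple(c for c, call in calls.items() if call.status is Status.HETEROZYGOUS)
        hom = tuple(c for c, call in calls.items() if call.status is Status.HOMOZYGOUS)
        zero_present = any(calls[c].minor_reads == 0 for c in hom)
        all_assigned = len(het) + len(hom) == len(calls)
        passes = bool(het) and all_assigned and (
            zero_present or not thresholds.require_zero_minor_clone
        )
        sites.append(
            CloneContrastSite(
                site_id=str(site_id),
                chrom=str(chrom),
                pos=int(pos),
                ref_allele=str(ref),
                alt_allele=str(alt),
                calls=dict(calls),
                het_clones=het,
                hom_clones=hom,
                zero_minor_clone_present=zero_present,
                passes=passes,
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.pos, s.site_id))
    return sites


def contrast_sites_to_frame(sites: Iterable[CloneContrastSite]) -> pd.DataFrame:
    """Flatten contrast sites into a report table (one row per site)."""
    rows = []
    for s in sites:
        row = {
            "site_id": s.site_id,
            "chrom": s.chrom,
            "pos": s.pos,
            "ref_allele": s.ref_allele,
            "alt_allele": s.alt_allele,
            "het_clones": ",".join(s.het_clones),
            "hom_clones": ",".join(s.hom_clones),
            "zero_minor_clone_present": s.zero_minor_clone_present,
            "passes": s.passes,
        }
        for clone, call in sorted(s.calls.items()):
            row[f"status_{clone}"] = call.status.value
            row[f"reason_{clone}"] = call.reason.value if call.reason else ""
        rows.append(row)
    return pd.DataFrame(rows)


def recover_planted_sites(
    contrast_sites: Iterable[CloneContrastSite],
    site_truth: Mapping[str, Mapping[str, str]],
) -> tuple[float, float]:
    """Precision and recall of passing sites against a truth manifest.

    ``site_truth`` maps site_id to per-clone true genotypes ("het" or
    "hom_ref"); a site is truly somatic when any clone is "het". Empty
    denominators yield 1.0.
    """
    planted = {s for s, clones in site_truth.items() if "het" in clones.values()}
    detected = {s.site_id for s in contrast_sites if s.passes}
    tp = len(detected & planted)
    precision = tp / len(detected) if detected else 1.0
    recall = tp / len(planted) if planted else 1.0
    return precision, recall
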