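"""Synthetic data with known ground truth for the clone-discrimination pipeline.

The generator emulates the study design the analysis assumes: a panel of
four clones of one cultivar (two with compact clusters, two with loose
clusters), three biological replicates each, sampled at two developmental
stages. It produces

* per-site, per-sample allele depths with planted clone-specific
  heterozygous sites over a homozygous background (negative-binomial depth,
  binomial allele sampling);
* gene-level count matrices per stage with planted clone-silent genes,
  clone effects constant over stages, and stage-specific effects
  (negative-binomial counts around log-normal baseline means);
* per-inflorescence flower and berry-class counts (Poisson flower numbers,
  multinomial per-flower outcomes);
* a truth manifest recording every planted site genotype and gene class.

All randomness flows from explicit integer seeds through independent
deterministic child streams, so identical parameters reproduce identical
tables byte for byte.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix

__all__ = [
    "ClonePanelSpec",
    "SomaticSiteSpec",
    "VariantSimParams",
    "ExpressionSimParams",
    "ReproductionParams",
    "TruthManifest",
    "default_panel",
    "simulate_allele_counts",
    "make_planted_sites",
    "simulate_reference_and_sites",
    "simulate_expression",
    "simulate_category_map",
    "simulate_phenotypes",
    "default_phenotype_params",
]

_BASES = np.array(["A", "C", "G", "T"])


def _rng(seed: int, *key: int) -> np.random.Generator:
    """A child generator deterministically derived from a master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


@dataclass(frozen=True)
class ClonePanelSpec:
    """The clone x replicate x stage layout of the study.

    Defaults mirror the design the pipeline targets: four clones of a
    single cultivar — two compact-cluster (C1, C2) and two loose-cluster
    (L1, L2) — with three biological replicates and two phenological
    stages (just before and at the end of flowering).
    """

    clone_ids: tuple[str, ...] = ("C1", "C2", "L1", "L2")
    group: Mapping[str, str] = field(
        default_factory=lambda: {"C1": "compact", "C2": "compact", "L1": "loose", "L2": "loose"}
    )
    n_replicates: int = 3
    stages: tuple[str, ...] = ("EL18-19", "EL26")

    def __post_init__(self) -> None:
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise ValueError("clone ids must be unique")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        missing = set(self.clone_ids) - set(self.group)
        if missing:
            raise ValueError(f"clones without a compactness group: {sorted(missing)}")
        bad = {g for g in self.group.values() if g not in ("compact", "loose")}
        if bad:
            raise ValueError(f"unknown compactness groups: {sorted(bad)}")

    @property
    def replicates(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_replicates + 1))

    def samples(self) -> list[tuple[str, int]]:
        return [(c, r) for c in self.clone_ids for r in self.replicates]

    def sample_names(self) -> list[str]:
        return [f"{c}_{r}" for c, r in self.samples()]

    def sample_map(self) -> dict[str, tuple[str, int]]:
        return {f"{c}_{r}": (c, r) for c, r in self.samples()}

    def clones_in_group(self, group: str) -> list[str]:
        return [c for c in self.clone_ids if self.group[c] == group]


def default_panel() -> ClonePanelSpec:
    return ClonePanelSpec()


@dataclass(frozen=True)
class SomaticSiteSpec:
    """One simulated polymorphic site.

    ``carrier_clone`` is heterozygous ref/alt; every other clone is
    homozygous for the reference allele. ``carrier_clone=None`` marks a
    background site where all clones are homozygous reference.
    """

    site_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    carrier_clone: str | None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.site_id}: ref and alt alleles are identical")
        if self.pos < 1:
            raise ValueError(f"{self.site_id}: positions are 1-based")


@dataclass(frozen=True)
class VariantSimParams:
    """Noise model for allele-depth simulation.

    ``mean_depth`` is the expected reads per site per sample;
    ``depth_dispersion`` the negative-binomial overdispersion of depth
    (0 gives a constant depth, the noiseless limit); ``error_rate`` the
    per-read probability that a homozygous sample shows the minor allele;
    ``het_alt_fraction`` the expected alternate fraction in heterozygotes
    (0.5 unless allele-specific expression skews it).
    """

    mean_depth: float = 100.0
    depth_dispersion: float = 0.1
    error_rate: float = 0.005
    het_alt_fraction: float = 0.5
    n_background_sites: int = 0
    site_quality: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.error_rate < self.het_alt_fraction <= 1.0:
            raise ValueError("need 0 <= error_rate < het_alt_fraction <= 1")
        if self.depth_dispersion < 0 or self.n_background_sites < 0:
            raise ValueError("dispersion and background count must be non-negative")


@dataclass
class TruthManifest:
    """Ground truth of a simulation run.

    ``site_truth``: site_id -> clone -> "het" | "hom_ref".
    ``gene_truth``: gene_id -> {"gene_class", "clone", "log2_effect", "stage"}
    with class in {absent_in_clone, constant_de, stage_de, null}.
    """

    site_truth: dict[str, dict[str, str]] = field(default_factory=dict)
    gene_truth: dict[str, dict] = field(default_factory=dict)

    def planted_het_sites(self) -> dict[str, str]:
        out = {}
        for site, clones in self.site_truth.items():
            for clone, status in clones.items():
                if status == "het":
                    out[site] = clone
        return out

    def genes_of_class(self, gene_class: str, clone: str | None = None) -> list[str]:
        return [
            g
            for g, info in self.gene_truth.items()
            if info["gene_class"] == gene_class
            and (clone is None or info.get("clone") == clone)
        ]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"site_truth": self.site_truth, "gene_truth": self.gene_truth},
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(site_truth=data["site_truth"], gene_truth=data["gene_truth"])

    def merge(self, other: "TruthManifest") -> "TruthManifest":
        return TruthManifest(
            site_truth={**self.site_truth, **other.site_truth},
            gene_truth={**self.gene_truth, **other.gene_truth},
        )


def make_planted_sites(
    panel: ClonePanelSpec,
    n_sites: int,
    chrom: str = "chr1",
    start_pos: int = 1000,
    spacing: int = 1000,
    seed: int = 0,
) -> list[SomaticSiteSpec]:
    """Planted heterozygous sites, carrier clones assigned round-robin."""
    rng = _rng(seed, 11)
    sites = []
    for i in range(n_sites):
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(
            SomaticSiteSpec(
                site_id=f"site_{i:04d}",
                chrom=chrom,
                pos=start_pos + i * spacing,
                ref_allele=str(_BASES[ref]),
                alt_allele=str(_BASES[alt]),
                carrier_clone=panel.clone_ids[i % len(panel.clone_ids)],
            )
        )
    return sites


def _draw_depths(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if dispersion <= 0:
        return np.full(size, int(round(mean)), dtype=int)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


def simulate_allele_counts(
    panel: ClonePanelSpec,
    sites: Sequence[SomaticSiteSpec],
    params: VariantSimParams,
    genome: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Per-site, per-sample allele depths with planted heterozygous clones.

    One record per site x clone x replicate. Depth is negative-binomial
    around ``mean_depth``; alternate reads are binomial with success
    probability ``het_alt_fraction`` in the carrier clone and
    ``error_rate`` elsewhere. ``params.n_background_sites`` extra
    all-homozygous sites are appended after the supplied ones; when a
    ``genome`` is given their reference alleles are taken from it.
    """
    if not panel.clone_ids:
        raise ValueError("empty clone panel: nothing to simulate")
    if not sites and params.n_background_sites == 0:
        raise ValueError("no sites requested: nothing to simulate")
    for site in sites:
        if site.carrier_clone is not None and site.carrier_clone not in panel.clone_ids:
            raise ValueError(f"{site.site_id}: carrier {site.carrier_clone!r} not in panel")

    rng = _rng(params.seed, 1)
    all_sites = list(sites)
    if params.n_background_sites:
        chrom = sites[0].chrom if sites else "chr1"
        last = max((s.pos for s in sites), default=0)
        for i in range(params.n_background_sites):
            pos = last + 1000 * (i + 1)
            if genome is not None and chrom in genome and pos <= len(genome[chrom]):
                ref = genome[chrom][pos - 1]
                choices = [b for b in "ACGT" if b != ref]
                alt = str(rng.choice(choices))
            else:
                ref_i, alt_i = rng.choice(4, size=2, replace=False)
                ref, alt = str(_BASES[ref_i]), str(_BASES[alt_i])
            all_sites.append(
                SomaticSiteSpec(
                    site_id=f"bg_{i:04d}",
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    carrier_clone=None,
                )
            )

    samples = panel.samples()
    n = len(samples)
    truth = TruthManifest()
    rows = []
    for site in all_sites:
        depths = _draw_depths(rng, params.mean_depth, params.depth_dispersion, n)
        truth.site_truth[site.site_id] = {
            c: ("het" if c == site.carrier_clone else "hom_ref") for c in panel.clone_ids
        }
        for (clone, rep), depth in zip(samples, depths):
            p = params.het_alt_fraction if clone == site.carrier_clone else params.error_rate
            alt_depth = int(rng.binomial(depth, p)) if depth > 0 else 0
            rows.append(
                (
                    site.site_id, site.chrom, site.pos, site.ref_allele,
                    site.alt_allele, params.site_quality, clone, rep,
                    int(depth) - alt_depth, alt_depth,
                )
            )
    records = pd.DataFrame(
        rows,
        columns=[
            "site_id", "chrom", "pos", "ref_allele", "alt_allele",
            "site_quality", "clone", "replicate", "ref_depth", "alt_depth",
        ],
    )
    return records, truth


_STOPS = {"TAA", "TAG", "TGA"}


def simulate_reference_and_sites(
    panel: ClonePanelSpec,
    n_sites: int,
    chrom: str = "chr1",
    n_codons: int = 50,
    spacing: int = 1000,
    margin: int = 2000,
    n_background_sites: int = 0,
    seed: int = 0,
):
    """A toy genome and gene models with one planted site inside each CDS.

    Each gene is a single-exon CDS of ``n_codons`` codons (ATG ... stop)
    tiled along one chromosome; each planted site falls in an internal
    codon, its reference allele matching the genome. Returns
    ``(genome, models, sites)`` ready for :func:`simulate_allele_counts`
    and downstream effect annotation.
    """
    from .effects import GeneModel  # local import to avoid a cycle at import time

    rng = _rng(seed, 7)
    length = 200 + n_sites * spacing + (n_background_sites + 2) * 1000 + margin
    seq = rng.choice(_BASES, size=length)
    models = []
    sites = []
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    sense = [c for c in codons if c not in _STOPS and c != "ATG"]
    for i in range(n_sites):
        start = 200 + i * spacing
        body = ["ATG"] + [str(rng.choice(sense)) for _ in range(n_codons - 2)] + ["TAA"]
        gene_seq = "".join(body)
        seq[start - 1 : start - 1 + len(gene_seq)] = list(gene_seq)
        end = start + len(gene_seq) - 1
        models.append(
            GeneModel(
                gene_id=f"gene_{i:04d}",
                chrom=chrom,
                strand="+",
                exons=((start, end),),
                cds=((start, end),),
            )
        )
        codon_i = int(rng.integers(1, n_codons - 1))
        offset = int(rng.integers(0, 3))
        pos = start + 3 * codon_i + offset
        ref = str(seq[pos - 1])
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        sites.append(
            SomaticSiteSpec(
                site_id=f"site_{i:04d}",
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                carrier_clone=panel.clone_ids[i % len(panel.clone_ids)],
            )
        )
    genome = {chrom: "".join(seq)}
    return genome, models, sites


@dataclass(frozen=True)
class ExpressionSimParams:
    """Negative-binomial expression model with planted gene classes.

    Baseline gene means are log-normal: log2 mean ~ Normal(loc, scale),
    emulating the spread of moderately to highly expressed genes after the
    usual pre-filtering of an RNA-seq count matrix. Per-sample library
    scaling factors are uniform on ``library_size_range``. Planted classes:

    ``planted_absent``
        clone -> gene ids silent in that clone (0-3 reads total per stage
        across its replicates; every other clone floored at
        ``expressed_floor`` reads per replicate).
    ``planted_constant_de``
        (clone, gene ids, log2 effect) applied identically at both stages.
    ``planted_stage_de``
        (clone, gene ids, log2 effect, stage) applied at that stage only.

    Planted sets must be disjoint.
    """

    n_genes: int = 1000
    library_size_range: tuple[float, float] = (0.85, 1.15)
    log2_mean_loc: float = 7.0
    log2_mean_scale: float = 1.5
    nb_dispersion: float = 0.05
    planted_absent: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    planted_constant_de: tuple[tuple[str, tuple[str, ...], float], ...] = ()
    planted_stage_de: tuple[tuple[str, tuple[str, ...], float, str], ...] = ()
    absent_total_max: int = 3
    expressed_floor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must be positive and ordered")
        seen: set[str] = set()
        for label, genes in self._planted_sets():
            gset = set(genes)
            overlap = seen & gset
            if overlap:
                raise ValueError(
                    f"genes planted in more than one class ({label}): {sorted(overlap)[:5]}"
                )
            seen |= gset
        for _, _, effect in self.planted_constant_de:
            if not np.isfinite(effect) or effect == 0:
                raise ValueError("planted log2 effects must be finite and nonzero")
        for _, _, effect, _ in self.planted_stage_de:
            if not np.isfinite(effect) or effect == 0:
                raise ValueError("planted log2 effects must be finite and nonzero")

    def _planted_sets(self):
        for clone, genes in self.planted_absent.items():
            yield f"absent:{clone}", tuple(genes)
        for clone, genes, _ in self.planted_constant_de:
            yield f"constant_de:{clone}", tuple(genes)
        for clone, genes, _, stage in self.planted_stage_de:
            yield f"stage_de:{clone}:{stage}", tuple(genes)


def gene_ids_for(params: ExpressionSimParams) -> list[str]:
    return [f"g{i:04d}" for i in range(params.n_genes)]


def simulate_expression(
    panel: ClonePanelSpec,
    params: ExpressionSimParams,
) -> tuple[dict[str, CountMatrix], TruthManifest]:
    """One count matrix per stage, plus the gene-class truth manifest."""
    gene_ids = gene_ids_for(params)
    known = set(gene_ids)
    for label, genes in params._planted_sets():
        stray = set(genes) - known
        if stray:
            raise ValueError(f"planted genes not in the simulated universe ({label}): {sorted(stray)[:5]}")

    rng = _rng(params.seed, 2)
    base_log2 = rng.normal(params.log2_mean_loc, params.log2_mean_scale, size=params.n_genes)
    base_mean = np.power(2.0, base_log2)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    truth = TruthManifest()
    for g in gene_ids:
        truth.gene_truth[g] = {"gene_class": "null", "clone": None, "log2_effect": 0.0, "stage": None}
    for clone, genes in params.planted_absent.items():
        for g in genes:
            truth.gene_truth[g] = {
                "gene_class": "absent_in_clone", "clone": clone, "log2_effect": None, "stage": None,
            }
    for clone, genes, effect in params.planted_constant_de:
        for g in genes:
            truth.gene_truth[g] = {
                "gene_class": "constant_de", "clone": clone, "log2_effect": float(effect), "stage": None,
            }
    for clone, genes, effect, stage in params.planted_stage_de:
        for g in genes:
            truth.gene_truth[g] = {
                "gene_class": "stage_de", "clone": clone, "log2_effect": float(effect), "stage": stage,
            }

    matrices: dict[str, CountMatrix] = {}
    lo, hi = params.library_size_range
    r = 1.0 / params.nb_dispersion if params.nb_dispersion > 0 else None
    for stage in panel.stages:
        cols = {}
        meta_rows = []
        for clone in panel.clone_ids:
            effect = np.zeros(params.n_genes)
            for c, genes, eff in params.planted_constant_de:
                if c == clone:
                    effect[[gene_index[g] for g in genes]] += eff
            for c, genes, eff, st in params.planted_stage_de:
                if c == clone and st == stage:
                    effect[[gene_index[g] for g in genes]] += eff
            clone_mean = base_mean * np.power(2.0, effect)
            for rep in panel.replicates:
                factor = rng.uniform(lo, hi)
                mean = clone_mean * factor
                if r is None:
                    counts = rng.poisson(mean)
                else:
                    counts = rng.negative_binomial(r, r / (r + mean))
                cols[f"{clone}_{rep}"] = counts.astype(int)
                meta_rows.append((f"{clone}_{rep}", clone, rep, stage))
        counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
        # enforce planted silence and the expression floor elsewhere
        for silent_clone, genes in params.planted_absent.items():
            idx = [g for g in genes]
            silent_cols = [f"{silent_clone}_{rep}" for rep in panel.replicates]
            other_cols = [c for c in counts.columns if c not in silent_cols]
            for g in idx:
                total = int(rng.integers(0, params.absent_total_max + 1))
                alloc = rng.multinomial(total, np.full(len(silent_cols), 1.0 / len(silent_cols)))
                counts.loc[g, silent_cols] = alloc
                counts.loc[g, other_cols] = counts.loc[g, other_cols].clip(
                    lower=params.expressed_floor
                )
        samples = pd.DataFrame(
            meta_rows, columns=["sample", "clone", "replicate", "stage"]
        ).set_index("sample")
        matrices[stage] = CountMatrix(counts, samples)
    return matrices, truth


def simulate_category_map(
    gene_ids: Sequence[str],
    truth: TruthManifest,
    n_categories: int = 15,
    planted_category: str = "CAT_planted",
    concentration: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """A toy functional-category map with planted genes concentrated.

    Null genes draw a category uniformly; planted (non-null) genes land in
    ``planted_category`` with probability ``concentration``, making
    enrichment of recovered gene lists detectable. Two-column frame
    (gene, category).
    """
    rng = _rng(seed, 3)
    cats = [f"CAT_{i:02d}" for i in range(n_categories)]
    rows = []
    for g in gene_ids:
        info = truth.gene_truth.get(g, {"gene_class": "null"})
        if info["gene_class"] != "null" and rng.uniform() < concentration:
            rows.append((g, planted_category))
        else:
            rows.append((g, str(rng.choice(cats))))
    return pd.DataFrame(rows, columns=["gene", "category"])


@dataclass(frozen=True)
class ReproductionParams:
    """Per-clone reproductive expectations.

    ``mean_flowers`` is the expected flower number per inflorescence; the
    probabilities give the fate of each flower (seeded berry, seedless
    berry, live green ovary, or abscised/desiccated — the remainder).
    """

    mean_flowers: float
    p_seeded: float
    p_seedless: float
    p_lgo: float

    def __post_init__(self) -> None:
        probs = (self.p_seeded, self.p_seedless, self.p_lgo)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("outcome probabilities must lie in [0, 1]")
        if sum(probs) > 1 + 1e-12:
            raise ValueError("outcome probabilities must sum to at most 1")
        if self.mean_flowers <= 0:
            raise ValueError("mean_flowers must be positive")

    @property
    def p_abscised(self) -> float:
        return max(0.0, 1.0 - self.p_seeded - self.p_seedless - self.p_lgo)


def default_phenotype_params(panel: ClonePanelSpec) -> dict[str, ReproductionParams]:
    """Reproductive expectations emulating a compact/loose clone panel.

    Compact clones: ~300 flowers, fruitset ~0.7. Loose clones differ by
    route — one with depressed fruitset at moderate flower number, one with
    many flowers but strong flower drop.
    """
    compact = ReproductionParams(300.0, 0.70, 0.013, 0.065)
    loose_a = ReproductionParams(380.0, 0.43, 0.017, 0.082)
    loose_b = ReproductionParams(500.0, 0.24, 0.043, 0.034)
    out = {}
    loose_seen = 0
    for clone in panel.clone_ids:
        if panel.group[clone] == "compact":
            out[clone] = compact
        else:
            out[clone] = loose_a if loose_seen == 0 else loose_b
            loose_seen += 1
    return out


def simulate_phenotypes(
    clone_params: Mapping[str, ReproductionParams],
    n_inflorescences: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-inflorescence flower and berry-class counts.

    Flowers per inflorescence are Poisson around the clone mean; each
    flower is assigned one outcome multinomially. Columns: clone,
    inflorescence, flowers, seeded, seedless, lgos.
    """
    if n_inflorescences < 1:
        raise ValueError("n_inflorescences must be >= 1")
    rng = _rng(seed, 4)
    rows = []
    for clone in clone_params:
        p = clone_params[clone]
        probs = [p.p_seeded, p.p_seedless, p.p_lgo, p.p_abscised]
        for i in range(1, n_inflorescences + 1):
            flowers = int(rng.poisson(p.mean_flowers))
            if flowers > 0:
                seeded, seedless, lgos, _ = rng.multinomial(flowers, probs)
            else:
                seeded = seedless = lgos = 0
            rows.append((clone, i, flowers, int(seeded), int(seedless), int(lgos)))
    return pd.DataFrame(
        rows, columns=["clone", "inflorescence", "flowers", "seeded", "seedless", "lgos"]
    )
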