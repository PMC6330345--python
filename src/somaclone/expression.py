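"""Expression-side filters for clone discrimination.

Operations on gene-level count matrices from a replicated multi-clone,
two-stage RNA-seq design:

* CPM normalisation and log2 transform (pseudo-count 1);
* differential-expression contrasts between clones (pairwise, and one loose
  clone against the pooled compact clones), significant at fold change > 2
  and Benjamini–Hochberg adjusted p < 0.05;
* genes never expressed (or only expressed) in one clone: at most 3 reads
  in the focal clone, an expression floor in every other clone, and a fold
  change of at least 8;
* genes with clone differences stable over both developmental stages;
* quality-threshold (QT) clustering of expression profiles with a pairwise
  diameter bound;
* hypergeometric functional-category enrichment.

The internal differential-expression test is a moderated two-sample test on
log2-CPM: per-gene variances are shrunk toward a common prior fitted
empirically across genes (scaled inverse-chi-square model), the standard
remedy for unstable variance estimates at three replicates per group.
Externally computed p-values (e.g. from a count-model DE package) may be
injected in its place.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "normalize_cpm",
    "log2_cpm",
    "bh_adjust",
    "de_test",
    "loose_vs_compact_contrast",
    "find_absence_presence",
    "find_constant_de",
    "count_de_summary",
    "qt_cluster",
    "clusters_from_labels",
    "mean_profiles",
    "hypergeom_enrichment",
]


@dataclass
class CountMatrix:
    """Gene-level integer counts with sample metadata.

    ``counts`` is genes x samples; ``samples`` is indexed by sample name
    with columns ``clone``, ``replicate`` and ``stage``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if set(self.counts.columns) != set(self.samples.index):
            raise ValueError("count columns and sample metadata disagree")
        required = {"clone", "replicate", "stage"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")
        if self.samples[sorted(required)].isna().any().any():
            raise ValueError("incomplete sample metadata")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        # align metadata to column order
        self.samples = self.samples.loc[self.counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def sample_names(self, clone: str | None = None, stage: str | None = None) -> list[str]:
        meta = self.samples
        if clone is not None:
            meta = meta[meta["clone"] == clone]
        if stage is not None:
            meta = meta[meta["stage"] == stage]
        return list(meta.index)

    def subset(self, sample_names: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_names)], self.samples.loc[list(sample_names)])

    def write_tsv(self, counts_path, samples_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        return cls(counts, samples)


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: counts x 1e6 / library size, per sample."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    return counts * 1e6 / lib


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1); an all-zero gene maps to 0."""
    return np.log2(normalize_cpm(counts) + 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of a scaled inverse-chi-square prior to gene variances.

    Returns (prior_df, prior_s2). Infinite prior_df means the observed
    spread of log variances is fully explained by chi-square sampling noise,
    in which case every gene shares the prior variance.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0 = float(np.exp(np.mean(e)))
        return d0, s0
    # invert trigamma(d0/2) = excess by Newton iteration
    y = max(excess, 1e-8)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0 = float(np.exp(np.mean(e) + special.digamma(x) - np.log(x)))
    return d0, s0


def _moderated_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided p-values of a moderated pooled-variance two-sample test.

    ``a`` and ``b`` are genes x replicates arrays of log2-CPM. Per-gene
    pooled variances are shrunk toward an empirical prior before forming
    the t statistic; degrees of freedom are residual + prior.
    """
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / df
    d0, s0 = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return np.clip(p, 0.0, 1.0)


def de_test(
    cm: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    p_values: Sequence[float] | None = None,
    contrast: str = "",
    stage: str = "",
) -> pd.DataFrame:
    """Differential expression between two sample groups.

    The log2 fold change is the ratio of group mean CPM with pseudo-count 1.
    P-values come from the internal moderated test unless ``p_values`` (one
    per gene, ordered like the matrix) injects an external test. A gene is
    significant when |fold change| > ``fc_threshold`` and the BH-adjusted
    p-value is below ``alpha``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("sample groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("at least two replicates per group are required")
    cpm = normalize_cpm(cm.counts)
    lfc = np.log2(
        (cpm[group_a].mean(axis=1) + 1.0) / (cpm[group_b].mean(axis=1) + 1.0)
    )
    if p_values is None:
        logcpm = np.log2(cpm + 1.0)
        p = _moderated_t(logcpm[group_a].to_numpy(), logcpm[group_b].to_numpy())
    else:
        p = np.asarray(p_values, dtype=float)
        if p.shape[0] != cm.counts.shape[0]:
            raise ValueError("injected p-values must match the gene count")
    adj = bh_adjust(p)
    significant = (np.abs(lfc.to_numpy()) > np.log2(fc_threshold)) & (adj < alpha)
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "contrast": contrast,
            "stage": stage,
            "log2_fold_change": lfc.to_numpy(),
            "p_value": p,
            "adjusted_p": adj,
            "significant": significant,
        }
    ).reset_index(drop=True)


def loose_vs_compact_contrast(
    cm: CountMatrix,
    loose_clone: str,
    compact_clones: Sequence[str],
    stage: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    p_values: Sequence[float] | None = None,
) -> pd.DataFrame:
    """One loose clone against the pooled compact clones at one stage."""
    compact_clones = list(compact_clones)
    if loose_clone in compact_clones:
        raise ValueError(f"{loose_clone!r} listed among the compact clones")
    if len(compact_clones) < 2:
        raise ValueError("at least two compact clones are required")
    group_a = cm.sample_names(clone=loose_clone, stage=stage)
    group_b: list[str] = []
    for clone in compact_clones:
        group_b.extend(cm.sample_names(clone=clone, stage=stage))
    return de_test(
        cm,
        group_a,
        group_b,
        fc_threshold=fc_threshold,
        alpha=alpha,
        p_values=p_values,
        contrast=f"{loose_clone}_vs_compact",
        stage=stage,
    )


def find_absence_presence(
    cm: CountMatrix,
    focal_clone: str,
    other_clones: Sequence[str],
    stage: str,
    max_reads: int = 3,
    min_fc: float = 8.0,
    expressed_floor: int = 5,
) -> pd.DataFrame:
    """Genes silent in the focal clone, or expressed only in it, at a stage.

    ``absent_in_clone``: at most ``max_reads`` reads summed over the focal
    clone's replicates, at least ``expressed_floor`` reads in every
    replicate of every other clone, and a CPM fold change (others over
    focal, pseudo-count 1) of at least ``min_fc``. ``only_expressed_in_clone``
    is the symmetric condition (every other clone silent).
    """
    other_clones = list(other_clones)
    if focal_clone in other_clones:
        raise ValueError("focal clone listed among the others")
    focal_cols = cm.sample_names(clone=focal_clone, stage=stage)
    other_cols_by_clone = {c: cm.sample_names(clone=c, stage=stage) for c in other_clones}
    other_cols = [s for cols in other_cols_by_clone.values() for s in cols]
    counts = cm.counts
    cpm = normalize_cpm(counts)
    focal_total = counts[focal_cols].sum(axis=1)
    focal_mean_cpm = cpm[focal_cols].mean(axis=1)
    other_mean_cpm = cpm[other_cols].mean(axis=1)

    others_floored = counts[other_cols].ge(expressed_floor).all(axis=1)
    fc_absent = (other_mean_cpm + 1.0) / (focal_mean_cpm + 1.0)
    absent = (focal_total <= max_reads) & others_floored & (fc_absent >= min_fc)

    focal_floored = counts[focal_cols].ge(expressed_floor).all(axis=1)
    others_silent = pd.Series(True, index=counts.index)
    for cols in other_cols_by_clone.values():
        others_silent &= counts[cols].sum(axis=1) <= max_reads
    fc_only = (focal_mean_cpm + 1.0) / (other_mean_cpm + 1.0)
    only = focal_floored & others_silent & (fc_only >= min_fc)

    rows = []
    for gene in counts.index[absent]:
        rows.append(
            {
                "gene_id": gene,
                "gene_class": "absent_in_clone",
                "clone": focal_clone,
                "stage": stage,
                "focal_total_reads": int(focal_total[gene]),
                "fold_change": float(fc_absent[gene]),
            }
        )
    for gene in counts.index[only]:
        rows.append(
            {
                "gene_id": gene,
                "gene_class": "only_expressed_in_clone",
                "clone": focal_clone,
                "stage": stage,
                "focal_total_reads": int(focal_total[gene]),
                "fold_change": float(fc_only[gene]),
            }
        )
    cols = ["gene_id", "gene_class", "clone", "stage", "focal_total_reads", "fold_change"]
    return pd.DataFrame(rows, columns=cols)


def find_constant_de(de_stage1: pd.DataFrame, de_stage2: pd.DataFrame) -> pd.DataFrame:
    """Genes significant in the same direction at both stages.

    Both inputs must come from the same contrast on the same gene universe.
    """
    g1 = de_stage1.set_index("gene_id")
    g2 = de_stage2.set_index("gene_id")
    if set(g1.index) != set(g2.index):
        raise ValueError("stage results cover different gene universes")
    g2 = g2.loc[g1.index]
    same_sign = np.sign(g1["log2_fold_change"]) == np.sign(g2["log2_fold_change"])
    stable = g1["significant"] & g2["significant"].to_numpy() & same_sign.to_numpy()
    out = pd.DataFrame(
        {
            "gene_id": g1.index[stable],
            "gene_class": "constant_de",
            "contrast": g1.loc[stable, "contrast"].to_numpy(),
            "direction": np.where(g1.loc[stable, "log2_fold_change"] > 0, "up", "down"),
            "log2_fc_stage1": g1.loc[stable, "log2_fold_change"].to_numpy(),
            "log2_fc_stage2": g2.loc[stable, "log2_fold_change"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def count_de_summary(de_results: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Significant gene counts per contrast, direction and stage.

    Also reports, per contrast, the number of genes significant with the
    same sign at both stages (each such gene counted once).
    """
    all_de = pd.concat(de_results, ignore_index=True)
    sig = all_de[all_de["significant"]].copy()
    sig["direction"] = np.where(sig["log2_fold_change"] > 0, "up", "down")
    rows = []
    for contrast, grp in all_de.groupby("contrast", sort=True):
        stages = sorted(grp["stage"].unique())
        row: dict = {"contrast": contrast}
        s = sig[sig["contrast"] == contrast]
        for stage in stages:
            for direction in ("up", "down"):
                n = int(((s["stage"] == stage) & (s["direction"] == direction)).sum())
                row[f"n_{direction}_{stage}"] = n
        if len(stages) == 2:
            a = s[s["stage"] == stages[0]].set_index("gene_id")["direction"]
            b = s[s["stage"] == stages[1]].set_index("gene_id")["direction"]
            shared = a.index.intersection(b.index)
            row["n_both_stages_same_sign"] = int((a[shared] == b[shared]).sum())
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)


def _distance_matrix(profiles: pd.DataFrame, metric) -> np.ndarray:
    x = profiles.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("profiles contain non-finite values")
    if callable(metric):
        n = x.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = metric(x[i], x[j])
        return d
    if metric == "correlation":
        sd = x.std(axis=1)
        if (sd == 0).any():
            raise ValueError("constant profiles have undefined correlation distance")
        d = 1.0 - np.corrcoef(x)
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 2.0)
    if metric == "euclidean":
        diff = x[:, None, :] - x[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    raise ValueError(f"unknown metric {metric!r}")


def qt_cluster(
    profiles: pd.DataFrame,
    max_diameter: float = 0.2,
    min_cluster_size: int = 2,
    metric: str | Callable = "correlation",
) -> pd.Series:
    """Quality-threshold clustering of expression profiles.

    Greedy QT: a candidate cluster is grown from every seed gene by
    repeatedly adding the gene that least increases the cluster diameter
    while keeping every pairwise distance at most ``max_diameter``; the
    largest candidate is emitted, its members removed, and the process
    repeats until no candidate reaches ``min_cluster_size``. Ties break
    toward the lowest gene index, making the output deterministic.

    Returns a Series indexed like ``profiles`` with integer cluster labels
    (0, 1, ... in order of emission; -1 marks unclustered genes).
    """
    if profiles.shape[0] == 0:
        raise ValueError("at least one profile is required")
    d = _distance_matrix(profiles, metric)
    n = d.shape[0]
    labels = np.full(n, -1, dtype=int)
    remaining = list(range(n))
    cluster_id = 0
    while remaining:
        best: list[int] | None = None
        for seed in remaining:
            cand = [seed]
            cand_set = {seed}
            diameter = 0.0
            # max distance from each outside point to the candidate
            while True:
                best_pt, best_diam = -1, np.inf
                for p in remaining:
                    if p in cand_set:
                        continue
                    new_diam = max(diameter, max(d[p, q] for q in cand))
                    if new_diam <= max_diameter and new_diam < best_diam:
                        best_pt, best_diam = p, new_diam
                if best_pt < 0:
                    break
                cand.append(best_pt)
                cand_set.add(best_pt)
                diameter = max(diameter, best_diam)
            if best is None or len(cand) > len(best):
                best = cand
        assert best is not None
        if len(best) < min_cluster_size:
            break
        for idx in best:
            labels[idx] = cluster_id
        cluster_id += 1
        remaining = [i for i in remaining if labels[i] == -1]
    return pd.Series(labels, index=profiles.index, name="cluster")


def clusters_from_labels(labels: pd.Series) -> list[list]:
    """Cluster membership lists, ordered by cluster label."""
    out = []
    for cid in sorted(labels[labels >= 0].unique()):
        out.append(list(labels.index[labels == cid]))
    return out


def mean_profiles(matrices: Mapping[str, CountMatrix], genes: Sequence | None = None) -> pd.DataFrame:
    """Mean log2-CPM per clone and stage: the profile matrix QT clusters.

    ``matrices`` maps stage label to its count matrix; columns of the result
    are ``<clone>@<stage>`` in sorted order.
    """
    cols = {}
    for stage in sorted(matrices):
        cm = matrices[stage]
        lcpm = log2_cpm(cm.counts)
        for clone in sorted(cm.samples["clone"].unique()):
            cols[f"{clone}@{stage}"] = lcpm[cm.sample_names(clone=clone, stage=stage)].mean(axis=1)
    out = pd.DataFrame(cols)
    if genes is not None:
        out = out.loc[list(genes)]
    return out


def hypergeom_enrichment(
    gene_list: Sequence,
    universe: Sequence,
    category_map: Mapping | pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric functional-category enrichment of a gene list.

    ``category_map`` is either a mapping gene -> category (or iterable of
    categories) or a two-column DataFrame (gene, category). For every
    category with members in the universe, the upper-tail (over-
    representation) and lower-tail (under-representation) hypergeometric
    p-values are reported, each BH-adjusted across categories; a result is
    significant when its adjusted p is below ``alpha``.
    """
    universe_set = set(universe)
    genes = set(gene_list)
    if not genes <= universe_set:
        raise ValueError("gene list is not a subset of the universe")
    if isinstance(category_map, pd.DataFrame):
        pairs = list(category_map.itertuples(index=False, name=None))
    else:
        pairs = []
        for gene, cats in category_map.items():
            if isinstance(cats, str):
                cats = [cats]
            pairs.extend((gene, c) for c in cats)
    members: dict[str, set] = {}
    for gene, cat in pairs:
        members.setdefault(cat, set()).add(gene)

    n_universe = len(universe_set)
    n_list = len(genes)
    rows = []
    for cat in sorted(members):
        in_universe = members[cat] & universe_set
        if not in_universe:
            warnings.warn(f"category {cat!r} has no genes in the universe; skipped")
            continue
        k_cat = len(in_universe)
        k = len(in_universe & genes)
        p_over = float(stats.hypergeom.sf(k - 1, n_universe, k_cat, n_list))
        p_under = float(stats.hypergeom.cdf(k, n_universe, k_cat, n_list))
        rows.append((cat, k, n_list, k_cat, n_universe, p_over, p_under))
    if not rows or n_list == 0:
        return pd.DataFrame(
            columns=[
                "category", "direction", "k", "n", "K", "N",
                "p_value", "adjusted_p", "significant",
            ]
        )
    base = pd.DataFrame(
        rows, columns=["category", "k", "n", "K", "N", "p_over", "p_under"]
    )
    out_frames = []
    for direction, col in (("over", "p_over"), ("under", "p_under")):
        part = base[["category", "k", "n", "K", "N"]].copy()
        part["direction"] = direction
        part["p_value"] = base[col].to_numpy()
        part["adjusted_p"] = bh_adjust(part["p_value"].to_numpy())
        part["significant"] = part["adjusted_p"] < alpha
        out_frames.append(part)
    out = pd.concat(out_frames, ignore_index=True)
    return out[
        ["category", "direction", "k", "n", "K", "N", "p_value", "adjusted_p", "significant"]
    ]
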