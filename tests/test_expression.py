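"""Expression filters: DE contrasts, presence/absence, QT clustering, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from somaclone.expression import (
    CountMatrix,
    bh_adjust,
    clusters_from_labels,
    count_de_summary,
    de_test,
    find_absence_presence,
    find_constant_de,
    hypergeom_enrichment,
    loose_vs_compact_contrast,
    mean_profiles,
    normalize_cpm,
    qt_cluster,
)
from somaclone.simulate import ExpressionSimParams, simulate_expression


def _matrix(counts: dict, clone_of: dict, stage="S1") -> CountMatrix:
    frame = pd.DataFrame(counts)
    frame.index = [f"g{i}" for i in range(len(frame))]
    samples = pd.DataFrame(
        {
            "clone": [clone_of[s] for s in frame.columns],
            "replicate": [int(s.split("_")[1]) for s in frame.columns],
            "stage": stage,
        },
        index=pd.Index(frame.columns, name="sample"),
    )
    return CountMatrix(frame, samples)


class TestCpm:
    def test_definition(self):
        counts = pd.DataFrame({"s": [10, 10**6 - 10]})
        assert normalize_cpm(counts).iloc[0, 0] == pytest.approx(10.0)

    def test_all_zero_gene_maps_to_zero_logcpm(self):
        counts = pd.DataFrame({"s1": [0, 100], "s2": [0, 50]})
        assert np.log2(normalize_cpm(counts) + 1).iloc[0].eq(0).all()

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [5, 10, 85]})
        doubled = counts * 2
        pd.testing.assert_frame_equal(normalize_cpm(counts), normalize_cpm(doubled))

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            normalize_cpm(pd.DataFrame({"s1": [0, 0]}))


class TestDeTest:
    def test_duplicated_data_gives_zero_fold_change(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=(50, 3))
        cm = _matrix(
            {f"a_{i+1}": base[:, i] for i in range(3)}
            | {f"b_{i+1}": base[:, i] for i in range(3)},
            {f"a_{i+1}": "A" for i in range(3)} | {f"b_{i+1}": "B" for i in range(3)},
        )
        res = de_test(cm, [f"a_{i+1}" for i in range(3)], [f"b_{i+1}" for i in range(3)])
        assert np.allclose(res["log2_fold_change"], 0.0)
        assert not res["significant"].any()

    def test_group_overlap_rejected(self):
        cm = _matrix(
            {"a_1": [1], "a_2": [2], "b_1": [3], "b_2": [4]},
            {"a_1": "A", "a_2": "A", "b_1": "B", "b_2": "B"},
        )
        with pytest.raises(ValueError):
            de_test(cm, ["a_1", "a_2"], ["a_2", "b_1"])

    def test_planted_effect_detected(self, panel):
        genes = tuple(f"g{i:04d}" for i in range(20))
        params = ExpressionSimParams(
            n_genes=400, planted_constant_de=(("L1", genes, 3.0),), seed=1
        )
        matrices, _ = simulate_expression(panel, params)
        cm = matrices[panel.stages[0]]
        res = de_test(
            cm,
            cm.sample_names(clone="L1", stage=panel.stages[0]),
            cm.sample_names(clone="C1", stage=panel.stages[0]),
        )
        hits = set(res.loc[res["significant"], "gene_id"])
        assert len(hits & set(genes)) >= 19
        assert res.set_index("gene_id").loc[list(genes), "log2_fold_change"].median() > 2

    def test_injected_pvalues_respected(self):
        cm = _matrix(
            {
                "a_1": [100, 100, 10000],
                "a_2": [110, 90, 10000],
                "b_1": [800, 100, 10000],
                "b_2": [820, 95, 10000],
            },
            {"a_1": "A", "a_2": "A", "b_1": "B", "b_2": "B"},
        )
        res = de_test(cm, ["a_1", "a_2"], ["b_1", "b_2"], p_values=[1e-6, 1.0, 1.0])
        assert res.loc[0, "significant"]  # big fold change and injected small p
        assert not res.loc[1, "significant"]  # injected p = 1 blocks the call
        assert not res.loc[2, "significant"]

    def test_gene_and_sample_order_invariance(self, panel):
        params = ExpressionSimParams(n_genes=100, seed=2)
        matrices, _ = simulate_expression(panel, params)
        cm = matrices[panel.stages[0]]
        a = cm.sample_names(clone="C1", stage=panel.stages[0])
        b = cm.sample_names(clone="L2", stage=panel.stages[0])
        res1 = de_test(cm, a, b)
        shuffled = CountMatrix(
            cm.counts.sample(frac=1.0, random_state=1), cm.samples
        )
        res2 = de_test(shuffled, list(reversed(a)), list(reversed(b)))
        merged = res1.set_index("gene_id").join(
            res2.set_index("gene_id"), rsuffix="_2"
        )
        assert np.allclose(merged["p_value"], merged["p_value_2"])


def test_loose_vs_compact_validations(panel):
    params = ExpressionSimParams(n_genes=20, seed=3)
    matrices, _ = simulate_expression(panel, params)
    cm = matrices[panel.stages[0]]
    with pytest.raises(ValueError):
        loose_vs_compact_contrast(cm, "L1", ["C1"], panel.stages[0])
    with pytest.raises(ValueError):
        loose_vs_compact_contrast(cm, "L1", ["C1", "L1"], panel.stages[0])


class TestAbsencePresence:
    def _cm(self, focal_counts, other_count=200):
        counts = {}
        clone_of = {}
        for clone in ("F", "X", "Y"):
            for rep in (1, 2, 3):
                name = f"{clone}_{rep}"
                clone_of[name] = clone
                if clone == "F":
                    counts[name] = [focal_counts[rep - 1], 500]
                else:
                    counts[name] = [other_count, 500]
        return _matrix(counts, clone_of)

    def test_three_reads_total_called_absent(self):
        cm = self._cm([0, 1, 2])
        calls = find_absence_presence(cm, "F", ["X", "Y"], "S1")
        absent = calls[calls["gene_class"] == "absent_in_clone"]
        assert list(absent["gene_id"]) == ["g0"]

    def test_four_reads_total_not_called(self):
        cm = self._cm([1, 1, 2])
        calls = find_absence_presence(cm, "F", ["X", "Y"], "S1")
        assert calls[calls["gene_class"] == "absent_in_clone"].empty

    def test_fold_change_floor_enforced(self):
        # focal silent but others barely expressed: fold change below 8
        cm = self._cm([0, 1, 2], other_count=6)
        calls = find_absence_presence(cm, "F", ["X", "Y"], "S1", expressed_floor=5)
        assert calls[calls["gene_class"] == "absent_in_clone"].empty

    def test_monotone_in_max_reads(self):
        cm = self._cm([1, 1, 2])
        strict = find_absence_presence(cm, "F", ["X", "Y"], "S1", max_reads=3)
        loose = find_absence_presence(cm, "F", ["X", "Y"], "S1", max_reads=4)
        strict_ids = set(strict.loc[strict["gene_class"] == "absent_in_clone", "gene_id"])
        loose_ids = set(loose.loc[loose["gene_class"] == "absent_in_clone", "gene_id"])
        assert strict_ids <= loose_ids

    def test_only_expressed_symmetric_condition(self):
        counts = {}
        clone_of = {}
        for clone in ("F", "X", "Y"):
            for rep in (1, 2, 3):
                name = f"{clone}_{rep}"
                clone_of[name] = clone
                counts[name] = [300 if clone == "F" else 1, 500]
        cm = _matrix(counts, clone_of)
        calls = find_absence_presence(cm, "F", ["X", "Y"], "S1")
        only = calls[calls["gene_class"] == "only_expressed_in_clone"]
        assert list(only["gene_id"]) == ["g0"]

    def test_focal_among_others_rejected(self):
        cm = self._cm([0, 0, 0])
        with pytest.raises(ValueError):
            find_absence_presence(cm, "F", ["F", "X"], "S1")


class TestConstantDe:
    def _de(self, sig, lfc, contrast="L1_vs_compact", stage="S1"):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(sig))],
                "contrast": contrast,
                "stage": stage,
                "log2_fold_change": lfc,
                "p_value": 0.001,
                "adjusted_p": 0.001,
                "significant": sig,
            }
        )

    def test_same_direction_both_stages_called(self):
        de1 = self._de([True, True, True], [2.0, 2.0, -2.0])
        de2 = self._de([True, False, True], [2.0, 2.0, -2.0], stage="S2")
        out = find_constant_de(de1, de2)
        assert set(out["gene_id"]) == {"g0", "g2"}
        assert set(out["direction"]) == {"up", "down"}

    def test_direction_flip_not_called(self):
        de1 = self._de([True], [2.0])
        de2 = self._de([True], [-2.0], stage="S2")
        assert find_constant_de(de1, de2).empty

    def test_mismatched_universe_rejected(self):
        de1 = self._de([True], [2.0])
        de2 = self._de([True, True], [2.0, 2.0], stage="S2")
        with pytest.raises(ValueError):
            find_constant_de(de1, de2)


def test_count_de_summary_partitions_and_overlap():
    frames = []
    for stage, sig_up, sig_down in (("S1", ["g0", "g1"], ["g2"]), ("S2", ["g0"], [])):
        rows = []
        for g in ["g0", "g1", "g2", "g3"]:
            lfc = 2.0 if g in sig_up else (-2.0 if g in sig_down else 0.0)
            rows.append((g, "A_vs_B", stage, lfc, 0.001, 0.001, g in sig_up or g in sig_down))
        frames.append(
            pd.DataFrame(
                rows,
                columns=[
                    "gene_id", "contrast", "stage", "log2_fold_change",
                    "p_value", "adjusted_p", "significant",
                ],
            )
        )
    summary = count_de_summary(frames)
    row = summary.iloc[0]
    assert row["n_up_S1"] == 2 and row["n_down_S1"] == 1
    assert row["n_up_S2"] == 1 and row["n_down_S2"] == 0
    assert row["n_both_stages_same_sign"] == 1  # g0, counted once


def qt_exhaustive(d: np.ndarray, max_diameter: float, min_size: int) -> list[list[int]]:
    """Oracle: repeatedly take the largest subset with diameter <= bound.

    Enumerates every subset of the remaining points (feasible for <= 10);
    ties break toward the lexicographically smallest index set.
    """
    remaining = list(range(d.shape[0]))
    clusters = []
    while remaining:
        best: tuple[int, list[int]] | None = None
        for r in range(len(remaining), 0, -1):
            for subset in itertools.combinations(remaining, r):
                diam = max(
                    (d[i, j] for i, j in itertools.combinations(subset, 2)),
                    default=0.0,
                )
                if diam <= max_diameter:
                    best = (r, list(subset))
                    break
            if best:
                break
        assert best is not None
        if best[0] < min_size:
            break
        clusters.append(best[1])
        remaining = [i for i in remaining if i not in best[1]]
    return clusters


def _bundle_profiles(rng, sizes, n_cond=8, noise=0.01):
    rows = []
    for size in sizes:
        base = rng.normal(0, 1, n_cond)
        for _ in range(size):
            rows.append(base + rng.normal(0, noise, n_cond))
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(sum(sizes))])


class TestQtClustering:
    def test_identical_profiles_form_one_cluster(self):
        profiles = pd.DataFrame([[1.0, 2.0, 3.0]] * 2, index=["a", "b"])
        labels = qt_cluster(profiles, max_diameter=0.2, metric="euclidean")
        assert clusters_from_labels(labels) == [["a", "b"]]

    def test_zero_diameter_with_distinct_profiles(self):
        rng = np.random.default_rng(1)
        profiles = pd.DataFrame(rng.normal(size=(5, 6)))
        labels = qt_cluster(profiles, max_diameter=0.0)
        assert (labels == -1).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_separated_bundles_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        profiles = _bundle_profiles(rng, sizes=(4, 3, 3))
        from somaclone.expression import _distance_matrix

        d = _distance_matrix(profiles, "correlation")
        labels = qt_cluster(profiles, max_diameter=0.2)
        got = [sorted(profiles.index.get_loc(g) for g in c) for c in clusters_from_labels(labels)]
        expected = [sorted(c) for c in qt_exhaustive(d, 0.2, 2)]
        assert sorted(map(tuple, got)) == sorted(map(tuple, expected))

    @pytest.mark.parametrize("seed", range(5))
    def test_emitted_clusters_respect_diameter_bound(self, seed):
        rng = np.random.default_rng(100 + seed)
        profiles = pd.DataFrame(rng.normal(size=(30, 8)))
        from somaclone.expression import _distance_matrix

        d = _distance_matrix(profiles, "correlation")
        labels = qt_cluster(profiles, max_diameter=0.6)
        for members in clusters_from_labels(labels):
            idx = [profiles.index.get_loc(g) for g in members]
            for i, j in itertools.combinations(idx, 2):
                assert d[i, j] <= 0.6 + 1e-12

    def test_nonfinite_profiles_rejected(self):
        profiles = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            qt_cluster(profiles)


def test_mean_profiles_shape(panel):
    params = ExpressionSimParams(n_genes=30, seed=4)
    matrices, _ = simulate_expression(panel, params)
    prof = mean_profiles(matrices)
    assert prof.shape == (30, 8)  # 4 clones x 2 stages
    assert all("@" in c for c in prof.columns)


class TestEnrichment:
    def test_closed_form_tail(self):
        universe = [f"u{i}" for i in range(20)]
        cmap = {g: ("A" if i < 5 else "B") for i, g in enumerate(universe)}
        res = hypergeom_enrichment(universe[:5], universe, cmap)
        p = res.loc[(res["category"] == "A") & (res["direction"] == "over"), "p_value"]
        assert float(p.iloc[0]) == pytest.approx(1.0 / comb(20, 5))

    def test_category_equal_to_universe_cannot_enrich(self):
        universe = [f"u{i}" for i in range(10)]
        res = hypergeom_enrichment(universe[:4], universe, {g: "ALL" for g in universe})
        p = res.loc[res["direction"] == "over", "p_value"]
        assert float(p.iloc[0]) == pytest.approx(1.0)

    def test_empty_gene_list_gives_no_over_representation(self):
        universe = [f"u{i}" for i in range(10)]
        res = hypergeom_enrichment([], universe, {g: "A" for g in universe})
        over = res[res["direction"] == "over"]
        assert over.empty or not over["significant"].any()

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["x"], ["a", "b"], {"a": "A"})

    def test_underrepresentation_reported(self):
        universe = [f"u{i}" for i in range(40)]
        cmap = {g: ("A" if i < 20 else "B") for i, g in enumerate(universe)}
        res = hypergeom_enrichment(universe[20:], universe, cmap)  # list avoids A entirely
        under = res[(res["category"] == "A") & (res["direction"] == "under")]
        assert float(under["p_value"].iloc[0]) < 1e-6


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_closed_form(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def test_null_positive_rate_close_to_alpha(panel):
    """Pre-adjustment p < 0.05 rate on pure-null simulations stays near 0.05."""
    rates = []
    for rep in range(10):
        params = ExpressionSimParams(n_genes=500, seed=2000 + rep)
        matrices, _ = simulate_expression(panel, params)
        cm = matrices[panel.stages[0]]
        res = de_test(
            cm,
            cm.sample_names(clone="C1", stage=panel.stages[0]),
            cm.sample_names(clone="L1", stage=panel.stages[0]),
        )
        rates.append((res["p_value"] < 0.05).mean())
    rate = float(np.mean(rates))
    sd = np.sqrt(0.05 * 0.95 / (10 * 500))
    assert abs(rate - 0.05) < 3 * sd
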