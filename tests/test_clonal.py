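import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromclone import (
    BarcodeCounts,
    CloneFunctionTable,
    correct_and_filter,
    correlate_function_with_tf,
    correlate_score_with_features,
    extract_barcodes,
    functional_perturbation_score,
    paired_clone_sizes,
)
from chromclone.synthdata import (
    DEFAULT_CONSTANT_POSITIONS,
    DEFAULT_FLANK5,
    DEFAULT_FLANK3,
    SimConfig,
    simulate_barcode_reads,
    simulate_clone_function,
)


def make_table(wt_rows, ko_rows, assays=None):
    clones = [f"clone_{i}" for i in range(len(wt_rows))]
    assays = assays or [f"a{j}" for j in range(len(wt_rows[0]))]
    idx = pd.MultiIndex.from_tuples(
        [(c, cond) for c in clones for cond in ("WT", "KO")],
        names=["clone", "condition"],
    )
    rows = []
    for w, k in zip(wt_rows, ko_rows):
        rows.extend([w, k])
    return CloneFunctionTable(pd.DataFrame(rows, index=idx, columns=assays))


class TestFunctionalPerturbationScore:
    def test_3_4_5_distance_on_prestandardized_columns(self):
        # columns standardised by construction across the 4 rows; WT->KO
        # displacement is (3 sd, 4 sd) for clone_0 and 0 for clone_1
        rng = np.random.default_rng(0)
        wt0 = np.array([0.0, 0.0])
        ko0 = np.array([3.0, 4.0])
        table = make_table([wt0, [1.0, -2.0]], [ko0, [1.0, -2.0]])
        V = table.values
        sd = V.std(ddof=1)
        fps = functional_perturbation_score(table)
        expect = np.sqrt((3 / sd["a0"]) ** 2 + (4 / sd["a1"]) ** 2)
        assert fps.scores["clone_0"] == pytest.approx(expect)
        assert fps.scores["clone_1"] == pytest.approx(0.0)

    def test_unit_variance_columns_give_exact_3_4_5(self):
        # craft columns whose pooled sample sd is exactly 1
        a0 = np.array([0.0, 3.0, 1.0, 1.0])
        a0 = (a0 - a0.mean()) / a0.std(ddof=1)
        table = make_table(
            [[0.0, 0.0], [1.0, 1.0]], [[3.0, 4.0], [1.0, 1.0]]
        )
        z = (table.values - table.values.mean()) / table.values.std(ddof=1)
        wt, ko = z.xs("WT", level=1), z.xs("KO", level=1)
        manual = np.sqrt(((wt - ko) ** 2).sum(axis=1))
        fps = functional_perturbation_score(table)
        assert np.allclose(fps.scores.to_numpy(), manual.to_numpy())

    def test_identical_wt_ko_scores_zero(self):
        table = make_table([[1.0, 2.0], [0.0, 5.0]], [[1.0, 2.0], [3.0, 1.0]])
        fps = functional_perturbation_score(table)
        assert fps.scores["clone_0"] == 0.0
        assert fps.scores["clone_1"] > 0

    def test_scores_equal_full_distance_matrix_restricted_to_pairs(self):
        rng = np.random.default_rng(1)
        n_clones, n_assays = 28, 8
        wt = rng.normal(size=(n_clones, n_assays))
        ko = rng.normal(size=(n_clones, n_assays))
        table = make_table(list(wt), list(ko))
        fps = functional_perturbation_score(table)
        # oracle: scipy full pairwise distance matrix on standardized rows
        from scipy.spatial.distance import squareform, pdist

        Z = (table.values - table.values.mean()) / table.values.std(ddof=1)
        D = squareform(pdist(Z.to_numpy()))
        rows = list(Z.index)
        for c in fps.scores.index:
            i, j = rows.index((c, "WT")), rows.index((c, "KO"))
            assert fps.scores[c] == pytest.approx(D[i, j], abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=-100.0, max_value=100.0),
        st.booleans(),
    )
    def test_affine_column_transform_invariance(self, a, b, negate):
        rng = np.random.default_rng(9)
        wt = rng.normal(size=(5, 3))
        ko = rng.normal(size=(5, 3))
        table = make_table(list(wt), list(ko))
        base = functional_perturbation_score(table).scores
        scaled = table.values.copy()
        scaled["a1"] = scaled["a1"] * (-a if negate else a) + b
        table2 = CloneFunctionTable(scaled)
        out = functional_perturbation_score(table2).scores
        assert np.allclose(base.to_numpy(), out.to_numpy(), atol=1e-10)

    def test_constant_column_dropped_with_warning(self):
        table = make_table([[1.0, 7.0], [2.0, 7.0]], [[3.0, 7.0], [4.0, 7.0]])
        with pytest.warns(UserWarning, match="constant"):
            fps = functional_perturbation_score(table)
        assert fps.dropped_assays == ["a1"]

    def test_pair_structure_enforced(self):
        idx = pd.MultiIndex.from_tuples(
            [("c0", "WT"), ("c0", "KO"), ("c1", "WT")], names=["clone", "condition"]
        )
        with pytest.raises(ValueError, match="exactly one WT and one KO"):
            CloneFunctionTable(pd.DataFrame(np.ones((3, 2)), index=idx))


class TestCloneCorrelations:
    def test_identical_and_anticorrelated_columns(self):
        clones = [f"c{i}" for i in range(5)]
        x = np.arange(5.0)
        assays = pd.DataFrame({"assay": x}, index=clones)
        tfz = pd.DataFrame({"tf_pos": x, "tf_neg": -x}, index=clones)
        out = correlate_function_with_tf(assays, tfz)
        assert out.loc["assay", "tf_pos"] == pytest.approx(1.0)
        assert out.loc["assay", "tf_neg"] == pytest.approx(-1.0)

    def test_matches_hand_pearson_to_1e12(self):
        rng = np.random.default_rng(2)
        clones = [f"c{i}" for i in range(10)]
        assays = pd.DataFrame(rng.normal(size=(10, 3)), index=clones, columns=list("xyz"))
        tfz = pd.DataFrame(rng.normal(size=(10, 2)), index=clones, columns=["t1", "t2"])
        out = correlate_function_with_tf(assays, tfz)
        for a in "xyz":
            for t in ["t1", "t2"]:
                hand = np.corrcoef(assays[a], tfz[t])[0, 1]
                assert out.loc[a, t] == pytest.approx(hand, abs=1e-12)

    def test_too_few_clones_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0]}, index=["c0", "c1"])
        with pytest.raises(ValueError, match=">= 3"):
            correlate_function_with_tf(df, df)

    def test_feature_equal_to_score_ranks_first(self):
        rng = np.random.default_rng(3)
        clones = [f"c{i}" for i in range(12)]
        wt = rng.normal(size=(12, 4))
        ko = wt + rng.normal(size=(12, 4))
        fps = functional_perturbation_score(make_table(list(wt), list(ko)))
        feats = pd.DataFrame(rng.normal(size=(12, 20)), index=fps.scores.index)
        feats["match"] = fps.scores.to_numpy()
        out = correlate_score_with_features(fps, feats)
        assert out.index[0] == "match"
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_permuted_scores_null_calibration(self):
        rng = np.random.default_rng(4)
        clones = [f"c{i}" for i in range(30)]
        wt = rng.normal(size=(30, 4))
        ko = wt + rng.normal(size=(30, 4))
        fps = functional_perturbation_score(make_table(list(wt), list(ko)))
        fps.scores[:] = rng.permutation(fps.scores.to_numpy())
        feats = pd.DataFrame(rng.normal(size=(30, 400)), index=fps.scores.index)
        out = correlate_score_with_features(fps, feats)
        frac = (out["p"] < 0.05).mean()
        assert 0.01 <= frac <= 0.10


class TestExtractBarcodes:
    def test_exact_read_counted_once(self):
        bc = "A" * 4 + "T" + "A" * 9 + "A" + "A" * 9 + "C" + "A" * 3
        assert len(bc) == 28
        read = "TTTT" + DEFAULT_FLANK5 + bc + DEFAULT_FLANK3 + "GGGG"
        out = extract_barcodes([read], DEFAULT_FLANK5, DEFAULT_FLANK3, DEFAULT_CONSTANT_POSITIONS)
        assert dict(out.counts) == {bc: 1}

    def test_constant_position_mismatch_discarded(self):
        bad = "A" * 28  # violates every constant position
        read = DEFAULT_FLANK5 + bad + DEFAULT_FLANK3
        out = extract_barcodes([read], DEFAULT_FLANK5, DEFAULT_FLANK3, DEFAULT_CONSTANT_POSITIONS)
        assert len(out.counts) == 0

    def test_missing_flank_unassigned(self):
        read = "ACGT" * 20
        out = extract_barcodes([read], DEFAULT_FLANK5, DEFAULT_FLANK3)
        assert out.n_reads_total == 1 and out.n_reads_assigned == 0

    def test_error_free_simulation_recovers_truth_exactly(self):
        reads, truth = simulate_barcode_reads(
            4, [10, 50, 200, 740], error_rate=0.0, seed=2
        )
        assert len(reads) == 1000
        out = extract_barcodes(
            reads, DEFAULT_FLANK5, DEFAULT_FLANK3, DEFAULT_CONSTANT_POSITIONS
        )
        assert dict(out.counts) == truth

    def test_never_emits_constant_violating_barcode(self):
        reads, _ = simulate_barcode_reads(3, [50, 50, 50], error_rate=0.05, seed=3)
        out = extract_barcodes(
            reads, DEFAULT_FLANK5, DEFAULT_FLANK3, DEFAULT_CONSTANT_POSITIONS
        )
        for bc in out.counts.index:
            assert all(bc[p] == b for p, b in DEFAULT_CONSTANT_POSITIONS.items())


class TestCorrectAndFilter:
    def _raw(self, d):
        return BarcodeCounts(counts=pd.Series(d), stage="raw")

    def test_variant_merged_into_centroid(self):
        center = "A" * 28
        variant = "C" + "A" * 27
        out = correct_and_filter(self._raw({center: 100, variant: 3}))
        assert dict(out.counts) == {center: 103}

    def test_low_count_barcode_removed(self):
        out = correct_and_filter(self._raw({"A" * 28: 9}))
        assert len(out.counts) == 0

    def test_count_conservation_before_min_count_cut(self):
        rng = np.random.default_rng(5)
        reads, truth = simulate_barcode_reads(3, [100, 500, 2000], error_rate=0.02, seed=6)
        raw = extract_barcodes(reads, DEFAULT_FLANK5, DEFAULT_FLANK3, DEFAULT_CONSTANT_POSITIONS)
        out = correct_and_filter(raw)
        assert out.n_reads_assigned == raw.counts.sum()

    def test_abundance_ratio_guard_prevents_merging_peers(self):
        a = "A" * 28
        b = "C" + "A" * 27  # distance 1 but similar abundance
        out = correct_and_filter(self._raw({a: 100, b: 60}))
        assert dict(out.counts) == {a: 100, b: 60}

    def test_simulation_at_1pct_error_recovers_within_5pct(self):
        reads, truth = simulate_barcode_reads(
            3, {0: 100, 1: 500, 2: 2000}, error_rate=0.01, seed=7
        )
        raw = extract_barcodes(reads, DEFAULT_FLANK5, DEFAULT_FLANK3, DEFAULT_CONSTANT_POSITIONS)
        out = correct_and_filter(raw)
        assert set(out.counts.index) == set(truth)
        for bc, n in truth.items():
            assert abs(out.counts[bc] - n) / n <= 0.05


class TestPairedCloneSizes:
    def _bc(self, d):
        return BarcodeCounts(counts=pd.Series(d), stage="filtered")

    def test_identical_samples_slope_one_intercept_zero(self):
        d = {"A" * 28: 100, "C" * 28: 300, "G" * 28: 600}
        table, slope, intercept = paired_clone_sizes(self._bc(d), self._bc(d))
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(table["residual"], 0.0)

    def test_disjoint_sets_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            paired_clone_sizes(
                self._bc({"A" * 28: 100}), self._bc({"C" * 28: 100})
            )

    def test_expanded_clones_sit_above_regression_line(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = dict(zip([f"BC{i}" for i in range(30)], rng.integers(50, 500, 30)))
            expanded = {k: v for k, v in base.items()}
            marked = list(base)[:3]
            for m in marked:
                expanded[m] = base[m] * 2
            table, slope, intercept = paired_clone_sizes(
                self._bc(base), self._bc(expanded)
            )
            if all(table.loc[m, "residual"] > 0 for m in marked):
                hits += 1
        assert hits >= 19


def test_simulated_clone_table_structure_and_null_case():
    cfg = SimConfig(n_clones=5, seed=3)
    table, pert = simulate_clone_function(cfg, perturbations=[0.0] * 5, noise_sd=0.0)
    assert len(table.values) == 10  # 2 rows per clone
    for c in table.clones:
        assert np.allclose(
            table.values.loc[(c, "WT")], table.values.loc[(c, "KO")]
        )
    assert (pert == 0).all()


def test_planted_perturbation_ranking_recovered():
    wins = 0
    for seed in range(40):
        cfg = SimConfig(n_clones=2, seed=seed)
        table, pert = simulate_clone_function(cfg, perturbations=[1.0, 5.0])
        fps = functional_perturbation_score(table)
        if fps.scores["clone_1"] > fps.scores["clone_0"]:
            wins += 1
    assert wins >= 38
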