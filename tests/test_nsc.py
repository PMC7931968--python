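"""Responsive-gene filter, NSC training, shrinkage path and cross-validation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import nsc_fields
from tgxddi import (
    ExpressionMatrix,
    FilterCriteria,
    NSCModel,
    compute_log2_ratios,
    cross_validate,
    filter_responsive_genes,
    shrinkage_path,
    simulate_reference_set,
    SimulationSpec,
    surviving_features,
    train_nsc,
)
from tgxddi.errors import (
    FoldError,
    InsufficientReplicatesError,
    PairingError,
    TrainingError,
    ValidationError,
)

CLASSES = ("DDI", "NONDDI")


def _profiles(n_conditions, shifted_conditions, shift, rng, n_genes=3, reps=4, noise=0.01):
    """Log2-scale replicate matrices; gene 0 is shifted in the named conditions."""
    out = {}
    genes = [f"G{i}" for i in range(n_genes)]
    for c in range(n_conditions):
        base = rng.normal(0, noise, size=(n_genes, reps))
        treated = base + rng.normal(0, noise, size=(n_genes, reps))
        if c in shifted_conditions:
            treated[0] += shift
        out[f"cond{c}"] = (
            pd.DataFrame(treated, index=genes),
            pd.DataFrame(rng.normal(0, noise, size=(n_genes, reps)), index=genes),
        )
    return out


class TestFilterResponsiveGenes:
    def test_null_gene_excluded(self, rng):
        profiles = _profiles(5, set(), 0.0, rng)
        assert "G0" not in filter_responsive_genes(profiles)

    def test_three_of_ten_conditions_included(self, rng):
        # 4-fold shift (2 log2 units) in exactly 3 of 10 conditions
        profiles = _profiles(10, {1, 4, 7}, 2.0, rng)
        selected = filter_responsive_genes(profiles, FilterCriteria(min_conditions=3))
        assert selected == ["G0"]

    def test_min_conditions_monotonicity(self, rng):
        profiles = _profiles(10, {1, 4, 7}, 2.0, rng)
        assert filter_responsive_genes(profiles, FilterCriteria(min_conditions=4)) == []

    def test_single_replicate_raises(self, rng):
        profiles = _profiles(3, set(), 0.0, rng)
        t, c = profiles["cond1"]
        profiles["cond1"] = (t.iloc[:, :1], c)
        with pytest.raises(InsufficientReplicatesError, match="cond1"):
            filter_responsive_genes(profiles)

    def test_matches_direct_welch_count(self, rng):
        """Selection agrees with a per-condition scalar t/fold-change recount."""
        profiles = {
            f"c{i}": (
                pd.DataFrame(rng.normal(0, 0.5, size=(6, 3)), index=list("ABCDEF")),
                pd.DataFrame(rng.normal(0, 0.5, size=(6, 3)), index=list("ABCDEF")),
            )
            for i in range(6)
        }
        crit = FilterCriteria(p_threshold=0.2, fc_threshold=1.2, min_conditions=2)
        expected = []
        for gi, gene in enumerate("ABCDEF"):
            hits = 0
            for t, c in profiles.values():
                tv, cv = t.iloc[gi].to_numpy(), c.iloc[gi].to_numpy()
                p = stats.ttest_ind(tv, cv, equal_var=False).pvalue
                fc = 2.0 ** (tv.mean() - cv.mean())
                if p < crit.p_threshold and (fc >= 1.2 or fc <= 1 / 1.2):
                    hits += 1
            if hits >= 2:
                expected.append(gene)
        assert filter_responsive_genes(profiles, crit) == expected


class TestComputeLog2Ratios:
    def test_identity_and_log2_of_four(self):
        genes = ["G1", "G2"]
        treated = ExpressionMatrix(genes, ["t1"], np.array([[4.0], [10.0]]))
        control = ExpressionMatrix(genes, ["c1"], np.array([[1.0], [10.0]]))
        out = compute_log2_ratios(treated, control, {"t1": "c1"})
        np.testing.assert_allclose(out.values[:, 0], [2.0, 0.0])

    def test_matches_scalar_loop(self, rng):
        genes = [f"G{i}" for i in range(7)]
        t_vals = rng.uniform(0.5, 20, size=(7, 3))
        c_vals = rng.uniform(0.5, 20, size=(7, 2))
        treated = ExpressionMatrix(genes, ["t1", "t2", "t3"], t_vals)
        control = ExpressionMatrix(genes, ["c1", "c2"], c_vals)
        pairing = {"t1": "c1", "t2": "c2", "t3": "c1"}
        out = compute_log2_ratios(treated, control, pairing)
        for j, (ts, cs) in enumerate([("t1", "c1"), ("t2", "c2"), ("t3", "c1")]):
            for i in range(7):
                expected = math.log2(t_vals[i, j] / c_vals[i, 0 if cs == "c1" else 1])
                assert out.values[i, j] == pytest.approx(expected, rel=1e-12)

    def test_unpaired_sample_raises(self):
        m = ExpressionMatrix(["G1"], ["t1"], np.array([[1.0]]))
        c = ExpressionMatrix(["G1"], ["c1"], np.array([[1.0]]))
        with pytest.raises(PairingError, match="t1"):
            compute_log2_ratios(m, c, {})

    def test_nonpositive_intensity_raises(self):
        m = ExpressionMatrix(["G1"], ["t1"], np.array([[0.0]]))
        c = ExpressionMatrix(["G1"], ["c1"], np.array([[1.0]]))
        with pytest.raises(ValidationError):
            compute_log2_ratios(m, c, {"t1": "c1"})


class TestTrainNSC:
    def test_hand_oracle_one_gene(self):
        """Class A {0,2}, class B {4,6}, delta 0.5: exact closed-form fields."""
        m = ExpressionMatrix(["G1"], list("abcd"), np.array([[0.0, 2.0, 4.0, 6.0]]))
        model = train_nsc(m, ["DDI", "DDI", "NONDDI", "NONDDI"], 0.5)
        assert model.class_centroids[0, 0] == pytest.approx(1.0)
        assert model.class_centroids[1, 0] == pytest.approx(5.0)
        assert model.overall_centroid[0] == pytest.approx(3.0)
        assert model.pooled_sd[0] == pytest.approx(math.sqrt(2))
        assert model.sd_offset == pytest.approx(math.sqrt(2))
        m_k = math.sqrt(1 / 2 + 1 / 4)
        d_expect = (1.0 - 3.0) / (m_k * 2 * math.sqrt(2))
        assert model.raw_diff[0, 0] == pytest.approx(d_expect)
        assert model.shrunken_diff[0, 0] == pytest.approx(math.copysign(abs(d_expect) - 0.5, d_expect))

    def test_zero_shrinkage_identity(self, small_matrix):
        m, labels = small_matrix
        model = train_nsc(m, labels, 0.0)
        np.testing.assert_allclose(model.shrunken_diff, model.raw_diff)
        np.testing.assert_allclose(model.shrunken_centroids(), model.class_centroids, atol=1e-12)

    def test_total_shrinkage(self, small_matrix):
        m, labels = small_matrix
        base = train_nsc(m, labels, 0.0)
        big = float(np.abs(base.raw_diff).max()) + 1.0
        model = train_nsc(m, labels, big)
        assert np.all(model.shrunken_diff == 0.0)
        for k in range(2):
            np.testing.assert_allclose(model.shrunken_centroids()[k], model.overall_centroid)

    def test_small_class_raises(self):
        m = ExpressionMatrix(["G1"], list("abc"), np.array([[0.0, 1.0, 2.0]]))
        with pytest.raises(TrainingError):
            train_nsc(m, ["DDI", "NONDDI", "NONDDI"], 0.0)

    def test_negative_delta_raises(self, small_matrix):
        m, labels = small_matrix
        with pytest.raises(ValidationError):
            train_nsc(m, labels, -0.1)

    def test_oracle_equivalence_random_instances(self, rng):
        """All fields match a loop-based recomputation on small instances."""
        for _ in range(20):
            J, per = int(rng.integers(1, 6)), int(rng.integers(2, 5))
            X = rng.normal(size=(J, 2 * per))
            labels = ["DDI"] * per + ["NONDDI"] * per
            delta = float(rng.uniform(0, 2))
            m = ExpressionMatrix([f"G{j}" for j in range(J)], [f"s{i}" for i in range(2 * per)], X)
            model = train_nsc(m, labels, delta)
            ora = nsc_fields(X, labels, delta)
            for k, name in enumerate(CLASSES):
                np.testing.assert_allclose(
                    model.class_centroids[k], ora["class_centroids"][name], rtol=1e-10
                )
                np.testing.assert_allclose(model.shrunken_diff[k], ora["d_shrunk"][name], rtol=1e-10, atol=1e-12)
                assert model.m_k[k] == pytest.approx(ora["m_k"][name], rel=1e-12)
                assert model.priors[k] == pytest.approx(ora["priors"][name], rel=1e-12)
            np.testing.assert_allclose(model.overall_centroid, ora["overall_centroid"], rtol=1e-10)
            np.testing.assert_allclose(model.pooled_sd, ora["pooled_sd"], rtol=1e-10)
            assert model.sd_offset == pytest.approx(ora["s0"], rel=1e-12)

    def test_soft_threshold_and_symmetry_properties(self, rng):
        """|d'| = max(|d|-delta, 0); equal class sizes give d_DDI = -d_nonDDI."""
        for _ in range(30):
            J, per = int(rng.integers(1, 8)), int(rng.integers(2, 5))
            X = rng.normal(size=(J, 2 * per))
            labels = ["DDI"] * per + ["NONDDI"] * per
            delta = float(rng.uniform(0, 3))
            m = ExpressionMatrix([f"G{j}" for j in range(J)], [f"s{i}" for i in range(2 * per)], X)
            model = train_nsc(m, labels, delta)
            d, ds = model.raw_diff, model.shrunken_diff
            np.testing.assert_allclose(np.abs(ds), np.maximum(np.abs(d) - delta, 0.0), atol=1e-12)
            assert np.all((np.sign(ds) == np.sign(d)) | (ds == 0))
            np.testing.assert_allclose(d[0], -d[1], rtol=1e-9, atol=1e-12)

    def test_json_round_trip(self, small_matrix):
        m, labels = small_matrix
        model = train_nsc(m, labels, 0.3)
        back = NSCModel.from_json(model.to_json())
        np.testing.assert_allclose(back.shrunken_diff, model.shrunken_diff)
        assert back.gene_ids == model.gene_ids
        assert back.delta == model.delta


def test_surviving_features_recovers_planted_genes(separated_reference):
    """At moderate shrinkage only the planted discriminative genes survive."""
    _, m, labels, informative = separated_reference
    model = train_nsc(m, labels, 4.0)
    assert sorted(surviving_features(model)) == sorted(informative)


def test_shrinkage_path_monotone(rng):
    for _ in range(10):
        X = rng.normal(size=(20, 12))
        m = ExpressionMatrix([f"G{j}" for j in range(20)], [f"s{i}" for i in range(12)], X)
        labels = ["DDI"] * 6 + ["NONDDI"] * 6
        table = shrinkage_path(m, labels, [0.0, 0.5, 1.0, 2.0, 50.0], k=3, seed=1)
        counts = table["n_surviving"].to_numpy()
        assert np.all(np.diff(counts) <= 0)
        assert counts[0] > 0 and counts[-1] == 0
        assert list(table["delta"]) == sorted(table["delta"])


class TestCrossValidate:
    def test_perfect_separation_is_100pct(self, separated_reference):
        _, m, labels, _ = separated_reference
        assert cross_validate(m, labels, 4.0, k=10, seed=42).accuracy == 1.0

    def test_same_seed_identical_folds(self, separated_reference):
        _, m, labels, _ = separated_reference
        a = cross_validate(m, labels, 4.0, k=10, seed=7)
        b = cross_validate(m, labels, 4.0, k=10, seed=7)
        assert a.folds == b.folds and a.predictions == b.predictions

    def test_permuted_labels_no_better_than_prior(self):
        """With labels shuffled the classifier has no real skill: pooled CV
        accuracy is not significantly above the larger-class prior (the best
        chance-level strategy), by a one-sided binomial test."""
        spec = SimulationSpec(8, 12, 100, 10, 2.0, 0.5, seed=3)
        m, labels, _ = simulate_reference_set(spec)
        prior = 12 / 20
        correct = trials = 0
        master = np.random.default_rng(99)
        for s in range(50):
            perm = master.permutation(len(labels))
            shuffled = [labels[i] for i in perm]
            cv = cross_validate(m, shuffled, 0.0, k=4, seed=s)
            correct += sum(cv.predictions[k] == cv.truths[k] for k in cv.predictions)
            trials += len(cv.predictions)
        p = stats.binomtest(correct, trials, prior, alternative="greater").pvalue
        assert p > 0.01

    def test_fold_error_for_tiny_class(self):
        X = np.random.default_rng(0).normal(size=(5, 6))
        m = ExpressionMatrix([f"G{j}" for j in range(5)], [f"s{i}" for i in range(6)], X)
        with pytest.raises(FoldError, match="smaller k"):
            cross_validate(m, ["DDI"] * 2 + ["NONDDI"] * 4, 0.0, k=2, seed=0)
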