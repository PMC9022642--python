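import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trussmorph as tm
from trussmorph.discriminant import (
    _wilks_tests,
    performance_band,
    roc_by_group,
    score_density,
)
from trussmorph.truss import TrussTable


def table_from(values, groups):
    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(len(values))],
        columns=[f"v{j}" for j in range(values.shape[1])],
    )
    return TrussTable(frame, list(groups))


@pytest.fixture(scope="module")
def cdfa_result(transformed_table):
    return tm.cdfa(transformed_table)


@pytest.fixture(scope="module")
def dapc_result(transformed_table):
    return tm.dapc(transformed_table, n_pcs=6)


class TestCdfa:
    def test_single_informative_variable_carries_all_variance(self):
        rng = np.random.default_rng(1)
        n = 40
        X = rng.normal(size=(n, 5))
        X[n // 2 :, 0] += 8.0
        groups = ["A"] * (n // 2) + ["B"] * (n // 2)
        result = tm.cdfa(table_from(X, groups))
        assert result.n_functions == 1
        assert result.percent_variance[0] == pytest.approx(100.0)

    def test_wilks_formula_on_known_eigenvalues(self):
        """lambda = {1, 1} gives Wilks 0.25 and canonical correlations
        sqrt(0.5); lambda all zero gives Wilks 1."""
        lam, chi2, df, p = _wilks_tests(np.array([1.0, 1.0]), n=50, p=4, g=3)
        assert lam[0] == pytest.approx(0.25)
        assert lam[1] == pytest.approx(0.5)
        canon = np.sqrt(np.array([1.0, 1.0]) / 2.0)
        assert np.allclose(canon, np.sqrt(0.5))
        lam0, *_ = _wilks_tests(np.array([0.0, 0.0]), n=50, p=4, g=3)
        assert np.allclose(lam0, 1.0)

    def test_function_count_bound(self, cdfa_result):
        # 7 groups, 35 variables -> at most 6 functions
        assert cdfa_result.n_functions == 6

    def test_percent_variance_sums_to_100(self, cdfa_result):
        assert cdfa_result.percent_variance.sum() == pytest.approx(100.0)

    def test_membership_rows_sum_to_one(self, cdfa_result):
        total = cdfa_result.membership_probabilities.sum(axis=1).to_numpy()
        assert np.allclose(total, 1.0, atol=1e-10)

    def test_canonical_correlation_identity(self, cdfa_result):
        lam = cdfa_result.eigenvalues
        assert np.allclose(
            cdfa_result.canonical_correlations, np.sqrt(lam / (1 + lam))
        )

    def test_scores_have_unit_within_group_variance(self, cdfa_result, transformed_table):
        labels = np.asarray(transformed_table.group_labels)
        S = cdfa_result.scores.to_numpy()
        n, g = len(labels), len(set(labels))
        pooled = sum(
            ((S[labels == grp] - S[labels == grp].mean(axis=0)) ** 2).sum(axis=0)
            for grp in set(labels)
        ) / (n - g)
        assert np.allclose(pooled, 1.0, atol=1e-8)

    def test_matches_sklearn_lda_assignments(self, transformed_table, cdfa_result):
        """Independent route: scikit-learn's LDA with proportional priors
        must assign every specimen to the same group."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        lda = LinearDiscriminantAnalysis()
        X = transformed_table.data.to_numpy()
        y = np.asarray(transformed_table.group_labels)
        pred = lda.fit(X, y).predict(X)
        assert (cdfa_result.assignment.to_numpy() == pred).mean() > 0.99

    def test_singular_within_covariance_advises_reduction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 20))  # more variables than specimens
        groups = ["A"] * 4 + ["B"] * 4
        with pytest.raises(ValueError, match="singular"):
            tm.cdfa(table_from(X, groups))


class TestDapc:
    def test_well_separated_groups_have_confident_posteriors(self):
        rng = np.random.default_rng(3)
        blocks, groups = [], []
        for k in range(3):
            b = rng.normal(size=(20, 4)) * 0.1
            b[:, k] += 50.0
            blocks.append(b)
            groups += [f"G{k}"] * 20
        result = tm.dapc(table_from(np.vstack(blocks), groups), n_pcs=4)
        own = np.array(
            [
                result.membership_probabilities.loc[spec, grp]
                for spec, grp in zip(result.membership_probabilities.index, groups)
            ]
        )
        assert (own > 0.999).all()

    def test_full_rank_dapc_reproduces_cdfa_assignment(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 5))
        X[20:40, 1] += 2.0
        X[40:, 2] -= 2.0
        groups = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
        table = table_from(X, groups)
        full = tm.dapc(table, n_pcs=5)
        ref = tm.cdfa(table)
        assert (full.assignment == ref.assignment).all()
        assert np.allclose(full.eigenvalues, ref.eigenvalues, rtol=1e-8)

    def test_function_count_bounded_by_npcs_and_groups(self, dapc_result):
        assert dapc_result.n_functions == 6  # min(6 PCs, 7 groups - 1)
        assert dapc_result.coefficients.shape == (6, 6)

    def test_variable_coefficients_back_projection(self, dapc_result, transformed_table):
        back = dapc_result.variable_coefficients
        assert back.shape == (35, 6)
        # back-projected coefficients reproduce the canonical scores
        X = transformed_table.data.to_numpy()
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        S = (Z - Z.mean(axis=0)) @ back.to_numpy()
        assert np.allclose(S, dapc_result.scores.to_numpy(), atol=1e-8)

    def test_invalid_npcs_rejected(self, transformed_table):
        with pytest.raises(ValueError, match="n_pcs"):
            tm.dapc(transformed_table, n_pcs=0)
        with pytest.raises(ValueError, match="n_pcs"):
            tm.dapc(transformed_table, n_pcs=100)


class TestRoc:
    def test_pair_counting_example(self):
        result = tm.roc_auc([2.0, 4.0, 1.0, 3.0], [True, True, False, False])
        assert result.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        result = tm.roc_auc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert result.auc == 1.0
        assert result.band == "outstanding"

    def test_all_ties(self):
        result = tm.roc_auc([5.0] * 10, [True] * 4 + [False] * 6)
        assert result.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            tm.roc_auc([1.0, 2.0], [True, True])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100)
        labels = rng.random(100) > 0.6
        curve = tm.roc_auc(scores, labels).curve
        assert curve.iloc[0].tolist() == [0.0, 0.0]
        assert curve.iloc[-1].tolist() == [1.0, 1.0]
        assert (curve.diff().dropna() >= 0).all().all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 200))
    def test_auc_equals_brute_force_pair_counting(self, seed, n):
        """The midrank AUC equals exhaustive concordant-pair counting
        with ties counted one half."""
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.random(n) > 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        pos, neg = scores[labels], scores[~labels]
        brute = (
            (pos[:, None] > neg[None, :]).sum()
            + 0.5 * (pos[:, None] == neg[None, :]).sum()
        ) / (len(pos) * len(neg))
        assert tm.roc_auc(scores, labels).auc == pytest.approx(brute, abs=1e-12)

    def test_band_boundaries(self):
        assert performance_band(0.95) == "outstanding"
        assert performance_band(0.90) == "outstanding"
        assert performance_band(0.85) == "excellent"
        assert performance_band(0.5) == "lower"

    def test_null_separation_auc_near_half(self):
        """Zero group separation: the mean one-vs-rest AUC over replicates
        stays near 0.5."""
        rng = np.random.default_rng(9)
        aucs = []
        for _ in range(50):
            scores = rng.normal(size=149)
            labels = np.zeros(149, dtype=bool)
            labels[rng.choice(149, 40, replace=False)] = True
            aucs.append(tm.roc_auc(scores, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestRocByGroup:
    def test_every_group_scored(self, dapc_result):
        rocs = roc_by_group(dapc_result)
        assert set(rocs) == set(dapc_result.groups)
        for r in rocs.values():
            assert 0.0 <= r.auc <= 1.0


class TestScoreDensity:
    def test_degenerate_group_concentrates_at_value(self):
        scores = pd.DataFrame({"F1": [2.0, 2.0, 2.0, 5.0, 6.0, 7.0]})
        result = type("R", (), {"scores": scores})()
        dens = score_density(result, 0, groups=["A"] * 3 + ["B"] * 3)
        assert dens.attrs["group_means"]["A"] == pytest.approx(2.0)
        assert dens["A"].idxmax() == pytest.approx(2.0, abs=0.05)

    def test_densities_integrate_to_one(self, dapc_result):
        dens = score_density(dapc_result, 0)
        grid = dens.index.to_numpy()
        for col in dens.columns:
            assert np.trapezoid(dens[col].to_numpy(), grid) == pytest.approx(
                1.0, abs=0.01
            )

    def test_disjoint_groups_have_zero_overlap(self):
        scores = pd.DataFrame({"F1": np.r_[np.linspace(0, 1, 30), np.linspace(100, 101, 30)]})
        result = type("R", (), {"scores": scores})()
        dens = score_density(result, 0, groups=["A"] * 30 + ["B"] * 30)
        overlap = np.trapezoid(
            np.minimum(dens["A"], dens["B"]), dens.index.to_numpy()
        )
        assert overlap == pytest.approx(0.0, abs=1e-6)
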