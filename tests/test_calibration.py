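"""Log-log OLS and phylogenetic GLS calibration fits."""

import json
import math

import numpy as np
import pytest
from scipy import stats

import hullmass as hm
from hullmass.errors import (
    InsufficientData,
    MissingTip,
    NonPositiveValue,
    UnknownTag,
)


def _noiseless_dataset(a=-2.0, b=0.9, n=8):
    x = np.linspace(4.5, 6.5, n)
    specimens = [
        hm.Specimen(
            species=f"sp{i}",
            common_name=f"sp{i}",
            mass_g=10.0 ** (a + b * xi),
            preparation="eviscerated",
            ch_vol_mm3=10.0**xi * 1.05,
            ch_vol_minus_feet_mm3=10.0**xi,
        )
        for i, xi in enumerate(x)
    ]
    return hm.CalibrationDataset(specimens, subset_tag="eviscerated")


class TestSubsets:
    def test_preparation_counts(self, pigeons):
        assert hm.subset_by_preparation(pigeons, "eviscerated").n == 13
        assert hm.subset_by_preparation(pigeons, "intact").n == 7
        assert hm.subset_by_preparation(pigeons, "combined").n == 20

    def test_unknown_tag(self, pigeons):
        with pytest.raises(UnknownTag):
            hm.subset_by_preparation(pigeons, "frozen")

    def test_fixture_values_and_typo_correction(self, pigeons):
        by_species = {s.species: s for s in pigeons.specimens}
        goura = by_species["Goura victoria"]
        assert goura.mass_g == 1951
        assert goura.ch_vol_mm3 == 1_487_180
        # the minus-feet volume printed with a shifted comma is ingested corrected
        assert by_species["Ptilinopus superbus"].ch_vol_minus_feet_mm3 == 74_691
        assert all(
            s.ch_vol_minus_feet_mm3 <= s.ch_vol_mm3 for s in pigeons.specimens
        )

    def test_empty_subset_fails_at_fit(self):
        data = _noiseless_dataset()
        intact = hm.subset_by_preparation(data, "intact")
        with pytest.raises(InsufficientData):
            hm.fit_loglog_ols(intact)


class TestOLS:
    def test_pigeon_eviscerated_minus_feet(self, eviscerated_model):
        m = eviscerated_model
        assert m.a == pytest.approx(-2.31, abs=0.01)
        assert m.b == pytest.approx(0.90, abs=0.01)
        assert m.r2 == pytest.approx(0.97, abs=0.01)
        assert m.n == 13

    def test_noiseless_line_recovered_exactly(self):
        m = hm.fit_loglog_ols(_noiseless_dataset())
        assert m.a == pytest.approx(-2.0, abs=1e-10)
        assert m.b == pytest.approx(0.9, abs=1e-12)
        assert m.r2 == 1.0
        assert m.mse == 0.0
        assert m.aic == float("-inf")
        ci_a, ci_b = hm.coefficient_ci(m)
        assert ci_a[0] == ci_a[1]
        assert ci_b[0] == ci_b[1]

    def test_matches_normal_equations_oracle(self, rng):
        data = hm.make_calibration_dataset(
            hm.SyntheticCalibrationSpec(n=6, sigma=0.1, seed=11)
        )
        x = np.log10(data.volumes())
        y = np.log10(data.masses())
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        m = hm.fit_loglog_ols(data)
        assert m.a == pytest.approx(beta[0], abs=1e-10)
        assert m.b == pytest.approx(beta[1], abs=1e-10)

    def test_matches_statsmodels(self, pigeons):
        import statsmodels.api as sm

        data = hm.subset_by_preparation(pigeons, "combined")
        x = np.log10(data.volumes())
        y = np.log10(data.masses())
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        m = hm.fit_loglog_ols(data)
        assert m.a == pytest.approx(ref.params[0], abs=1e-10)
        assert m.b == pytest.approx(ref.params[1], abs=1e-10)
        assert m.mse == pytest.approx(ref.mse_resid, abs=1e-12)
        assert m.r2 == pytest.approx(ref.rsquared, abs=1e-12)
        ci = ref.conf_int(alpha=0.05)
        assert m.ci_a == pytest.approx(tuple(ci[0]), abs=1e-8)
        assert m.ci_b == pytest.approx(tuple(ci[1]), abs=1e-8)

    def test_residual_orthogonality(self, pigeons):
        data = hm.subset_by_preparation(pigeons, "eviscerated")
        m = hm.fit_loglog_ols(data)
        x = np.log10(data.volumes())
        y = np.log10(data.masses())
        resid = y - (m.a + m.b * x)
        assert abs(resid.sum()) < 1e-8
        assert abs(resid @ x) < 1e-8

    def test_r2_three_ways_agree(self, pigeons):
        data = hm.subset_by_preparation(pigeons, "eviscerated")
        m = hm.fit_loglog_ols(data)
        x = np.log10(data.volumes())
        y = np.log10(data.masses())
        sxx = ((x - x.mean()) ** 2).sum()
        syy = ((y - y.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        assert m.r2 == pytest.approx(sxy**2 / (sxx * syy), abs=1e-10)
        assert m.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)

    def test_rejects_nonpositive_values(self):
        data = _noiseless_dataset()
        bad = hm.CalibrationDataset(
            data.specimens[:-1]
            + [
                hm.Specimen(
                    species="negative",
                    common_name="negative",
                    mass_g=1.0,
                    preparation="eviscerated",
                    ch_vol_mm3=1.0,
                    ch_vol_minus_feet_mm3=1.0,
                )
            ],
            subset_tag="eviscerated",
        )
        # masses/volumes validated at the Specimen level; fit also re-checks
        assert all(s.mass_g > 0 for s in bad.specimens)
        with pytest.raises(ValueError):
            hm.Specimen("x", "x", -1.0, "intact", 1.0, 1.0)
        with pytest.raises(NonPositiveValue):
            object.__setattr__(bad.specimens[-1], "mass_g", -5.0)
            hm.fit_loglog_ols(bad)


class TestCoefficientCI:
    def test_pigeon_slope_ci(self, eviscerated_model):
        _, ci_b = hm.coefficient_ci(eviscerated_model)
        assert ci_b[0] == pytest.approx(0.79, abs=0.01)
        assert ci_b[1] == pytest.approx(1.00, abs=0.01)

    def test_textbook_formula_oracle(self):
        data = hm.make_calibration_dataset(
            hm.SyntheticCalibrationSpec(n=9, sigma=0.08, seed=5)
        )
        m = hm.fit_loglog_ols(data)
        x = np.log10(data.volumes())
        n = len(x)
        sxx = ((x - x.mean()) ** 2).sum()
        tq = stats.t.ppf(0.975, n - 2)
        se_b = math.sqrt(m.mse / sxx)
        se_a = math.sqrt(m.mse * (1 / n + x.mean() ** 2 / sxx))
        assert m.ci_b == pytest.approx((m.b - tq * se_b, m.b + tq * se_b), abs=1e-10)
        assert m.ci_a == pytest.approx((m.a - tq * se_a, m.a + tq * se_a), abs=1e-10)

    def test_narrower_at_lower_level(self, eviscerated_model):
        ci90_a, ci90_b = hm.coefficient_ci(eviscerated_model, level=0.90)
        ci95_a, ci95_b = hm.coefficient_ci(eviscerated_model, level=0.95)
        assert ci90_b[1] - ci90_b[0] < ci95_b[1] - ci95_b[0]
        assert ci90_a[1] - ci90_a[0] < ci95_a[1] - ci95_a[0]


class TestBrownianCovariance:
    def test_star_tree_identity(self):
        tree = hm.read_newick("(A:1,B:1,C:1,D:1);")
        C = hm.brownian_covariance(tree, ["A", "B", "C", "D"])
        assert C == pytest.approx(np.eye(4))

    def test_nested_tree_by_construction(self):
        tree = hm.read_newick("((A:1,B:1):1,C:1);")
        C = hm.brownian_covariance(tree, ["A", "B", "C"])
        assert C == pytest.approx(np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 1.0]]))

    def test_missing_branch_lengths_default_to_one(self):
        tree = hm.read_newick("((A,B),C);")
        C = hm.brownian_covariance(tree, ["A", "B", "C"])
        assert C == pytest.approx(np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 1.0]]))

    def test_random_tree_vs_path_oracle(self, rng):
        # random binary tree over 8 tips with random branch lengths
        def grow(labels):
            if len(labels) == 1:
                return f"{labels[0]}:{rng.uniform(0.1, 2.0):.6f}"
            k = int(rng.integers(1, len(labels)))
            left, right = grow(labels[:k]), grow(labels[k:])
            return f"({left},{right}):{rng.uniform(0.1, 2.0):.6f}"

        labels = [f"t{i}" for i in range(8)]
        newick = grow(labels).rsplit(":", 1)[0] + ";"  # no length on the root
        tree = hm.read_newick(newick)
        C = hm.brownian_covariance(tree, labels)

        # oracle: shared depth from dendropy's own distance machinery,
        # cov(i, j) = (d(root, i) + d(root, j) - d(i, j)) / 2
        tree.calc_node_root_distances()
        root_dist = {
            leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()
        }
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, li in enumerate(labels):
            assert C[i, i] == pytest.approx(root_dist[li], abs=1e-9)
            for j, lj in enumerate(labels[i + 1 :], start=i + 1):
                patristic = pdm.patristic_distance(taxa[li], taxa[lj])
                expected = 0.5 * (root_dist[li] + root_dist[lj] - patristic)
                assert C[i, j] == pytest.approx(expected, abs=1e-9)

    def test_missing_tip(self):
        tree = hm.read_newick("(A:1,B:1,C:1);")
        with pytest.raises(MissingTip):
            hm.brownian_covariance(tree, ["A", "D"])


class TestPGLS:
    def test_identity_covariance_reproduces_ols(self):
        data = hm.make_calibration_dataset(hm.SyntheticCalibrationSpec(n=7, sigma=0.1, seed=2))
        star = hm.read_newick("(" + ",".join(f"{s}:1" for s in data.species) + ");")
        ols = hm.fit_loglog_ols(data)
        pgls = hm.fit_pgls(data, star)
        assert pgls.a == pytest.approx(ols.a, abs=1e-10)
        assert pgls.b == pytest.approx(ols.b, abs=1e-10)
        assert pgls.mse == pytest.approx(ols.mse, abs=1e-12)
        assert pgls.r2 == pytest.approx(ols.r2, abs=1e-10)
        assert pgls.covariance == "brownian"

    def test_matches_gls_oracle(self):
        tree = hm.read_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2);")
        data = hm.make_brownian_dataset(tree, a=-2.0, b=0.85, sigma2=0.01, seed=9)
        pgls = hm.fit_pgls(data, tree)
        C = hm.brownian_covariance(tree, data.species)
        x = np.log10(data.volumes())
        y = np.log10(data.masses())
        X = np.column_stack([np.ones(len(x)), x])
        Ci = np.linalg.inv(C)
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert pgls.a == pytest.approx(beta[0], abs=1e-10)
        assert pgls.b == pytest.approx(beta[1], abs=1e-10)

    def test_matches_statsmodels_gls(self):
        import statsmodels.api as sm

        tree = hm.read_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2);")
        data = hm.make_brownian_dataset(tree, a=-2.0, b=0.85, sigma2=0.02, seed=13)
        C = hm.brownian_covariance(tree, data.species)
        x = np.log10(data.volumes())
        y = np.log10(data.masses())
        ref = sm.GLS(y, sm.add_constant(x), sigma=C).fit()
        pgls = hm.fit_pgls(data, tree)
        assert pgls.a == pytest.approx(ref.params[0], abs=1e-10)
        assert pgls.b == pytest.approx(ref.params[1], abs=1e-10)

    def test_brownian_parameter_recovery(self):
        tree = hm.read_newick("(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")
        a_true, b_true, sigma2 = -2.31, 0.90, 0.004
        estimates = np.array(
            [
                [m.a, m.b]
                for m in (
                    hm.fit_pgls(hm.make_brownian_dataset(tree, a_true, b_true, sigma2, seed=s), tree)
                    for s in range(200)
                )
            ]
        )
        mean = estimates.mean(axis=0)
        mc_se = estimates.std(axis=0, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean[0] - a_true) < 4 * mc_se[0]
        assert abs(mean[1] - b_true) < 4 * mc_se[1]


class TestAIC:
    def test_lower_sse_means_lower_aic(self):
        tight = hm.fit_loglog_ols(
            hm.make_calibration_dataset(hm.SyntheticCalibrationSpec(n=13, sigma=0.02, seed=1))
        )
        loose = hm.fit_loglog_ols(
            hm.make_calibration_dataset(hm.SyntheticCalibrationSpec(n=13, sigma=0.2, seed=1))
        )
        assert tight.sse < loose.sse
        assert hm.aic(tight) < hm.aic(loose)

    def test_pigeon_aic_magnitude(self, eviscerated_model):
        # convention-dependent soft check against the published table value
        assert hm.aic(eviscerated_model) == pytest.approx(-29.4, abs=0.5)

    def test_loglik_oracle(self):
        data = hm.make_calibration_dataset(hm.SyntheticCalibrationSpec(n=10, sigma=0.1, seed=4))
        m = hm.fit_loglog_ols(data)
        n = m.n
        sigma2 = m.sse / n
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1)
        assert m.aic == pytest.approx(-2 * loglik + 6, abs=1e-10)


class TestModelSerialization:
    def test_json_round_trip_is_exact(self, eviscerated_model, tmp_path):
        path = tmp_path / "model.json"
        eviscerated_model.to_json(path)
        loaded = hm.CalibrationModel.from_json(path)
        assert loaded == eviscerated_model

    def test_json_has_prediction_fields(self, eviscerated_model):
        d = json.loads(eviscerated_model.to_json())
        for key in ("a", "b", "n", "mean_x", "sxx", "mse", "predictor_variant"):
            assert key in d


class TestParameterRecovery:
    def test_ols_bias_and_ci_coverage(self):
        """Slope recovery over replicated synthetic calibrations.

        Mirrors the extant calibration regime (n = 13, sigma = 0.07 on the
        log10 scale, predictor spanning 4.6-6.2): slope bias should be
        negligible and the 95% CI should cover the true slope at close to
        nominal rate.
        """
        b_true = 0.90
        slopes = []
        covered = 0
        n_rep = 500
        for seed in range(n_rep):
            data = hm.make_calibration_dataset(
                hm.SyntheticCalibrationSpec(
                    n=13, a=-2.31, b=b_true, sigma=0.07, x_range=(4.6, 6.2), seed=seed
                )
            )
            m = hm.fit_loglog_ols(data)
            slopes.append(m.b)
            if m.ci_b[0] <= b_true <= m.ci_b[1]:
                covered += 1
        assert abs(np.mean(slopes) - b_true) < 0.005
        assert 0.92 <= covered / n_rep <= 0.98
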