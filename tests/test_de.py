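import numpy as np
import pytest
from scipy import stats

from compenseq import (
    SimulationConfig,
    estimate_dispersions,
    filter_expressed,
    fit_nb_glm,
    qlf_test,
    select_degs,
    simulate_counts,
)
from compenseq.de import nb_deviance, squeeze_var


def nb_deviance_oracle(y, mu, phi):
    """Sum of NB unit deviances, written directly from the definition."""
    total = 0.0
    for yi, mi in zip(y, mu):
        if phi == 0:
            term = (yi * np.log(yi / mi) if yi > 0 else 0.0) - (yi - mi)
        else:
            term = (yi * np.log(yi / mi) if yi > 0 else 0.0) - (
                yi + 1 / phi
            ) * np.log((1 + phi * yi) / (1 + phi * mi))
        total += 2 * term
    return total


def golden_section_group_deviance(y, phi, tol=1e-12):
    """Best single-group NB deviance by 1-D golden-section search."""
    lo, hi = np.log(max(np.mean(y), 0.05) / 50), np.log(max(np.mean(y), 0.05) * 50)
    gr = (np.sqrt(5) - 1) / 2
    f = lambda logm: nb_deviance_oracle(y, np.full(len(y), np.exp(logm)), phi)
    c, d = hi - gr * (hi - lo), lo + gr * (hi - lo)
    while hi - lo > tol:
        if f(c) < f(d):
            hi, d = d, c
            c = hi - gr * (hi - lo)
        else:
            lo, c = c, d
            d = lo + gr * (hi - lo)
    return f((lo + hi) / 2)


class TestFilterExpressed:
    def test_all_zero_gene_excluded(self, simulated_dataset):
        counts, sheet, _ = simulated_dataset
        mask = filter_expressed(counts, sheet)
        zero = counts.counts.sum(axis=1) == 0
        assert not mask[zero].any()

    def test_high_cpm_gene_included(self, simulated_dataset):
        counts, sheet, _ = simulated_dataset
        cpm = counts.counts / counts.library_sizes()[None, :] * 1e6
        mask = filter_expressed(counts, sheet)
        assert mask[(cpm >= 100).all(axis=1)].all()

    def test_matches_direct_rule_evaluation(self, simulated_dataset):
        counts, sheet, _ = simulated_dataset
        mask = filter_expressed(counts, sheet, min_cpm=2.0, min_samples=3)
        cpm = counts.counts / counts.library_sizes()[None, :] * 1e6
        expected = np.array([(row >= 2.0).sum() >= 3 for row in cpm])
        np.testing.assert_array_equal(mask, expected)


class TestNbGlm:
    def test_constant_counts_poisson_closed_form(self):
        coef, mu, dev = fit_nb_glm(
            [10, 10, 10, 10], [0, 0, 1, 1], np.zeros(4), phi=0.0
        )
        np.testing.assert_allclose(mu, 10.0, atol=1e-8)
        assert abs(coef[1]) < 1e-10  # logFC 0
        assert dev < 1e-10

    def test_four_fold_difference_closed_form(self):
        coef, mu, _ = fit_nb_glm([5, 5, 20, 20], [0, 0, 1, 1], np.zeros(4), phi=0.1)
        assert abs(coef[1] - 2.0) < 1e-8  # log2(20/5)
        np.testing.assert_allclose(mu, [5, 5, 20, 20], rtol=1e-8)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.4])
    def test_deviance_matches_golden_section_oracle(self, phi):
        rng = np.random.default_rng(42)
        for _ in range(20):
            mu_a, mu_b = rng.uniform(3, 300, size=2)
            size = 1 / phi if phi > 0 else None
            ya = (
                rng.negative_binomial(size, size / (size + mu_a), 4)
                if size
                else rng.poisson(mu_a, 4)
            )
            yb = (
                rng.negative_binomial(size, size / (size + mu_b), 4)
                if size
                else rng.poisson(mu_b, 4)
            )
            y = np.concatenate([ya, yb])
            if y.sum() == 0:
                continue
            _, _, dev = fit_nb_glm(y, [0, 0, 0, 0, 1, 1, 1, 1], np.zeros(8), phi)
            oracle = golden_section_group_deviance(
                ya, phi
            ) + golden_section_group_deviance(yb, phi)
            assert abs(dev - oracle) < 1e-6


class TestDispersionEstimation:
    def test_identical_rows_get_identical_estimates(self):
        cfg = SimulationConfig(
            n_genes=300, lib_size_range=(500_000, 500_000), seed=21
        )
        counts, sheet, _ = simulate_counts(cfg)
        counts.counts[1] = counts.counts[0]
        disp = estimate_dispersions(counts, sheet, "W", "KM")
        assert disp.phi[0] == disp.phi[1]
        assert disp.squeezed_phi[0] == pytest.approx(disp.squeezed_phi[1], abs=1e-10)

    def test_recovers_constant_dispersion(self):
        cfg = SimulationConfig(
            n_genes=2000,
            lib_size_range=(1_000_000, 1_000_000),
            replicates={"W": 50, "KM": 50, "ZERO": 2},
            dispersion_params=(0.2, 0.0),
            de_fraction=0.0,
            seed=5,
        )
        counts, sheet, _ = simulate_counts(cfg)
        disp = estimate_dispersions(counts, sheet, "W", "KM")
        assert 0.16 <= np.median(disp.squeezed_phi) <= 0.24

    def test_poisson_data_gives_near_zero_dispersion(self):
        cfg = SimulationConfig(
            n_genes=1000,
            lib_size_range=(1_000_000, 1_000_000),
            replicates={"W": 20, "KM": 20, "ZERO": 2},
            dispersion_params=(0.0, 0.0),
            de_fraction=0.0,
            seed=6,
        )
        counts, sheet, _ = simulate_counts(cfg)
        disp = estimate_dispersions(counts, sheet, "W", "KM")
        assert np.median(disp.squeezed_phi) < 0.01

    def test_squeezed_lies_between_raw_and_trend(self, simulated_dataset):
        counts, sheet, _ = simulated_dataset
        disp = estimate_dispersions(counts, sheet, "W", "KM")
        lo = np.minimum(disp.phi, disp.trend_phi) - 1e-9
        hi = np.maximum(disp.phi, disp.trend_phi) + 1e-9
        assert ((disp.squeezed_phi >= lo) & (disp.squeezed_phi <= hi)).all()
        assert disp.prior_df > 0

    def test_single_replicate_group_rejected(self):
        cfg = SimulationConfig(n_genes=50, lib_size_range=(50_000, 50_000), seed=1)
        counts, sheet, _ = simulate_counts(cfg)
        sheet.assignments = {
            s: ("KM" if s == "KM_1" else "W") for s in counts.sample_ids
        }
        with pytest.raises(ValueError, match=">= 2 samples"):
            estimate_dispersions(counts, sheet, "W", "KM")


class TestQLFTest:
    def test_role_swap_negates_logfc_and_keeps_p(self, simulated_dataset):
        counts, sheet, _ = simulated_dataset
        fwd = qlf_test(counts, sheet, "W", "KM")
        rev = qlf_test(counts, sheet, "KM", "W")
        tested = fwd["tested"].to_numpy()
        np.testing.assert_allclose(
            fwd.loc[tested, "logFC"], -rev.loc[tested, "logFC"], atol=1e-10
        )
        np.testing.assert_allclose(
            fwd.loc[tested, "p"], rev.loc[tested, "p"], atol=1e-10
        )

    def test_bh_invariants(self, simulated_dataset):
        counts, sheet, _ = simulated_dataset
        res = qlf_test(counts, sheet, "W", "KM")
        t = res[res["tested"]].sort_values("p")
        assert (t["fdr"].to_numpy() >= t["p"].to_numpy() - 1e-15).all()
        # BH-adjusted values are monotone in p rank
        assert (np.diff(t["fdr"].to_numpy()) >= -1e-12).all()
        assert t["fdr"].min() >= t["p"].min() - 1e-15

    def test_untested_genes_carry_na_statistics(self, simulated_dataset):
        counts, sheet, _ = simulated_dataset
        res = qlf_test(counts, sheet, "W", "KM")
        skipped = res[~res["tested"]]
        if len(skipped):
            assert skipped[["logFC", "F", "p", "fdr"]].isna().all().all()

    def test_null_type_one_error_near_nominal(self):
        cfg = SimulationConfig(
            n_genes=2000,
            lib_size_range=(1_500_000, 2_200_000),
            replicates={"W": 4, "KM": 4, "ZERO": 2},
            de_fraction=0.0,
            seed=77,
        )
        counts, sheet, _ = simulate_counts(cfg)
        res = qlf_test(counts, sheet, "W", "KM")
        p = res.loc[res["tested"], "p"].to_numpy()
        for alpha in (0.01, 0.05, 0.10):
            se = np.sqrt(alpha * (1 - alpha) / len(p))
            assert abs(np.mean(p < alpha) - alpha) < 3 * se + 1e-9

    def test_global_depth_shift_in_offsets_changes_nothing(self):
        y = np.array([23, 14, 40, 31, 80, 95, 60, 71])
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        coef1, _, dev1 = fit_nb_glm(y, group, np.zeros(8), phi=0.1)
        offsets = np.full(8, np.log(3.7))
        coef2, _, dev2 = fit_nb_glm(y, group, offsets, phi=0.1)
        assert abs(coef1[1] - coef2[1]) < 1e-8
        assert abs(dev1 - dev2) < 1e-8


class TestSelectDegs:
    def test_threshold_arithmetic(self, simulated_dataset):
        import pandas as pd

        res = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "logFC": [0.3, -1.0],
                "p": [0.04, 0.04],
                "tested": [True, True],
            }
        )
        out = select_degs(res, p_threshold=0.05, min_fold=1.5)
        assert list(out["gene_id"]) == ["b"]
        assert list(out["direction"]) == ["down"]

    def test_matches_brute_force_filter(self, simulated_dataset):
        counts, sheet, _ = simulated_dataset
        res = qlf_test(counts, sheet, "W", "KM")
        out = select_degs(res, p_threshold=0.05, min_fold=1.5)
        expected = set()
        for _, row in res.iterrows():
            if (
                row["tested"]
                and row["p"] == row["p"]
                and row["p"] < 0.05
                and abs(row["logFC"]) > np.log2(1.5)
            ):
                expected.add(row["gene_id"])
        assert set(out["gene_id"]) == expected


class TestSqueezeVar:
    def test_chi_square_scale_recovered(self):
        rng = np.random.default_rng(11)
        df = 6.0
        s2 = rng.chisquare(df, size=4000) / df * 2.5
        post, d0, s0 = squeeze_var(s2, df)
        assert abs(np.mean(s0) - 2.5) < 0.15
        assert ((post >= np.minimum(s2, s0)) & (post <= np.maximum(s2, s0))).all()

    def test_extra_variability_yields_finite_prior_df(self):
        rng = np.random.default_rng(12)
        df = 6.0
        sigma2 = rng.lognormal(0.0, 0.8, size=3000)
        s2 = rng.chisquare(df, size=3000) / df * sigma2
        _, d0, _ = squeeze_var(s2, df)
        assert np.isfinite(d0) and d0 > 0
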