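"""Proxy-panel harmonization and binned polynomial bias correction."""

import numpy as np
import pandas as pd
import pytest

from ccfreq.bias import (
    apply_bias_correction,
    assign_bins,
    fit_bias_model,
    harmonize,
)
from ccfreq.evaluate import lins_ccc


def _gwas(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "effect_allele", "other_allele", "estimated_total_maf"]
    )


def _proxy(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "allele1", "allele2", "freq"])


class TestHarmonize:
    def test_matching_alleles_kept_without_flip(self):
        out = harmonize(
            _gwas([("1", 100, "A", "G", 0.21)]), _proxy([("1", 100, "A", "G", 0.2)])
        )
        assert len(out) == 1
        assert out.loc[0, "proxy_maf"] == pytest.approx(0.2)
        assert not out.loc[0, "flip_applied"]

    def test_opposing_anchor_flipped_then_folded(self):
        # proxy frequency 0.8 anchored to the GWAS other allele -> 0.2
        out = harmonize(
            _gwas([("1", 100, "G", "A", 0.21)]), _proxy([("1", 100, "A", "G", 0.8)])
        )
        assert out.loc[0, "proxy_maf"] == pytest.approx(0.2)
        assert out.loc[0, "flip_applied"]

    def test_allele_mismatch_removed(self):
        with pytest.raises(ValueError, match="allele harmonization"):
            harmonize(
                _gwas([("1", 100, "A", "T", 0.2)]), _proxy([("1", 100, "A", "G", 0.2)])
            )

    def test_chr_prefix_normalized_and_intersection_taken(self):
        out = harmonize(
            _gwas([("chr1", 100, "A", "G", 0.2), ("chr2", 5, "C", "T", 0.1)]),
            _proxy([("1", 100, "A", "G", 0.25), ("3", 7, "C", "T", 0.3)]),
        )
        assert len(out) == 1
        assert out.loc[0, "proxy_maf"] == pytest.approx(0.25)

    def test_duplicate_keys_rejected(self):
        dup = _gwas([("1", 100, "A", "G", 0.2), ("1", 100, "A", "G", 0.3)])
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(dup, _proxy([("1", 100, "A", "G", 0.2)]))

    def test_empty_overlap_is_an_error(self):
        with pytest.raises(ValueError, match="overlap"):
            harmonize(
                _gwas([("1", 100, "A", "G", 0.2)]), _proxy([("2", 100, "A", "G", 0.2)])
            )


def _pairs(proxy, est):
    return pd.DataFrame({"proxy_maf": proxy, "estimated_total_maf": est})


class TestFitBiasModel:
    def test_identity_data_gives_zero_bias(self, rng):
        proxy = rng.uniform(0.0, 0.5, 2000)
        model = fit_bias_model(_pairs(proxy, proxy))
        np.testing.assert_allclose(model.coefficients[:, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(model.coefficients[:, 1], 1.0, atol=1e-8)
        np.testing.assert_allclose(model.coefficients[:, 2], 0.0, atol=1e-8)
        np.testing.assert_allclose(model.bias(rng.uniform(0, 0.5, 100)), 0.0, atol=1e-8)

    def test_linear_shrinkage_recovered(self, rng):
        proxy = rng.uniform(0.2, 0.3, 500)  # single bin
        model = fit_bias_model(_pairs(proxy, 0.9 * proxy))
        x = np.linspace(0.21, 0.29, 9)
        np.testing.assert_allclose(model.bias(x), -0.1 * x, atol=1e-6)

    def test_quadratic_coefficient_recovered(self, rng):
        proxy = rng.uniform(0.0, 0.5, 5000)
        model = fit_bias_model(_pairs(proxy, proxy - 0.02 * proxy**2))
        np.testing.assert_allclose(model.coefficients[:, 2], -0.02, atol=1e-6)

    def test_matches_statsmodels_ols(self, rng):
        """Dual route: per-bin coefficients equal a statsmodels OLS fit."""
        import statsmodels.api as sm

        proxy = rng.uniform(0.1, 0.2, 200)
        est = 0.95 * proxy - 0.03 * proxy**2 + rng.normal(0, 0.005, proxy.size)
        model = fit_bias_model(_pairs(proxy, est))
        X = sm.add_constant(np.column_stack([proxy, proxy**2]))
        ref = sm.OLS(est, X).fit().params
        np.testing.assert_allclose(model.coefficients[1], ref, atol=1e-8)

    def test_underpopulated_bin_borrows_nearest(self, rng, caplog):
        proxy = np.concatenate([rng.uniform(0.0, 0.1, 200), rng.uniform(0.42, 0.5, 5)])
        with caplog.at_level("WARNING", logger="ccfreq.bias"):
            model = fit_bias_model(_pairs(proxy, 0.9 * proxy))
        assert model.fallback_from[4] == 0
        assert "borrowing" in caplog.text
        np.testing.assert_allclose(model.coefficients[4], model.coefficients[0])

    def test_all_bins_underpopulated_fails(self):
        with pytest.raises(ValueError, match="minimum fit count"):
            fit_bias_model(_pairs(np.array([0.1, 0.2]), np.array([0.1, 0.2])))


class TestApplyBiasCorrection:
    def _estimates(self, rng, n=200):
        total = rng.uniform(0.0, 0.5, n)
        return pd.DataFrame(
            {"maf_case": total * 0.98, "maf_control": np.minimum(total * 1.02, 0.5),
             "maf_total": total}
        )

    def test_identity_model_leaves_estimates_unchanged(self, rng):
        proxy = rng.uniform(0, 0.5, 1000)
        model = fit_bias_model(_pairs(proxy, proxy))
        est = self._estimates(rng)
        out = apply_bias_correction(est, model)
        for col in ("maf_case", "maf_control", "maf_total"):
            np.testing.assert_allclose(out[col + "_adj"], est[col], atol=1e-7)
            np.testing.assert_array_equal(out[col], est[col])  # originals kept

    def test_three_columns_appended_and_clamped(self, rng):
        proxy = rng.uniform(0, 0.5, 1000)
        model = fit_bias_model(_pairs(proxy, 0.8 * proxy))  # strong upward correction
        est = self._estimates(rng)
        out = apply_bias_correction(est, model)
        assert list(out.columns[-3:]) == ["maf_case_adj", "maf_control_adj", "maf_total_adj"]
        assert out["maf_case_adj"].max() <= 0.5
        assert out["maf_case_adj"].min() >= 0.0

    def test_out_of_range_estimate_rejected(self, rng):
        proxy = rng.uniform(0, 0.5, 1000)
        model = fit_bias_model(_pairs(proxy, proxy))
        bad = pd.DataFrame({"maf_case": [0.2], "maf_control": [0.2], "maf_total": [0.7]})
        with pytest.raises(ValueError, match="0, 0.5"):
            apply_bias_correction(bad, model)


def _shrunk_study(rng, n=5000, noise=0.005):
    """True MAFs with a monotone downward-biased estimate across the whole
    spectrum, as the SE route produces under covariate adjustment."""
    true = rng.uniform(0.01, 0.5, n)
    est = np.clip(0.85 * true - 0.2 * true**2 + rng.normal(0, noise, n), 0.0, 0.5)
    return true, est


class TestImprovementProperty:
    def test_correction_improves_ccc_and_bias_per_bin(self, rng):
        true, est = _shrunk_study(rng)
        model = fit_bias_model(_pairs(true, est))
        frame = pd.DataFrame({"maf_case": est, "maf_control": est, "maf_total": est})
        adj = apply_bias_correction(frame, model)["maf_total_adj"].to_numpy()

        assert lins_ccc(true, adj) > lins_ccc(true, est)
        assert np.mean(np.abs(adj - true)) < np.mean(np.abs(est - true))
        which = assign_bins(true)
        for k in range(5):
            mask = which == k
            if mask.sum() >= 30:
                assert np.mean(np.abs(adj[mask] - true[mask])) < np.mean(
                    np.abs(est[mask] - true[mask])
                )

    def test_ten_percent_subset_fit_suffices(self, rng):
        true, est = _shrunk_study(rng)
        subset = rng.random(true.size) < 0.1
        model = fit_bias_model(_pairs(true[subset], est[subset]))
        frame = pd.DataFrame({"maf_case": est, "maf_control": est, "maf_total": est})
        adj = apply_bias_correction(frame, model)["maf_total_adj"].to_numpy()
        assert lins_ccc(true, adj) > lins_ccc(true, est)
        assert np.mean(np.abs(adj - true)) < np.mean(np.abs(est - true))

    def test_identity_safety_under_symmetric_noise(self, rng):
        noise = 0.01
        true = rng.uniform(0.01, 0.49, 5000)
        est = np.clip(true + rng.normal(0, noise, true.size), 0, 0.5)
        model = fit_bias_model(_pairs(true, est))
        frame = pd.DataFrame({"maf_case": est, "maf_control": est, "maf_total": est})
        adj = apply_bias_correction(frame, model)["maf_total_adj"].to_numpy()
        assert np.mean(np.abs(adj - est)) < noise
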