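"""Generator contracts: determinism, moments, attenuation, scoring, I/O."""

import numpy as np
import pandas as pd
import pytest

import latentdiff as ld
from latentdiff.polychoric import bvn_cdf
from scipy.special import ndtr


def test_perfect_reliability_means_no_error():
    scen = ld.CTTScenario(delta_mu=1.0, var_tau=1.0, reliability=1.0)
    df = ld.generate_continuous_ctt(scen, n_per_group=500, seed=0)
    np.testing.assert_allclose(df["observed"], df["true"])


def test_observed_variance_inflated_by_error():
    """reliability 0.9 inflates observed variance to ~1.11 at large n."""
    scen = ld.CTTScenario(delta_mu=1.0, var_tau=1.0, reliability=0.9)
    df = ld.generate_continuous_ctt(scen, n_per_group=200_000, seed=5)
    for g in ("g1", "g2"):
        v = df.loc[df.group == g, "observed"].var(ddof=1)
        assert v == pytest.approx(1.0 / 0.9, rel=0.02)


def test_continuous_generator_seed_determinism():
    scen = ld.CTTScenario(delta_mu=0.5, var_tau=2.0, reliability=0.8)
    a = ld.generate_continuous_ctt(scen, 100, seed=9)
    b = ld.generate_continuous_ctt(scen, 100, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_scenario_validation():
    with pytest.raises(ValueError):
        ld.CTTScenario(delta_mu=1, var_tau=-1, reliability=0.9)
    with pytest.raises(ValueError):
        ld.CTTScenario(delta_mu=1, var_tau=1, reliability=0.0)
    scen = ld.CTTScenario(delta_mu=1, var_tau=1, reliability=0.5)
    with pytest.raises(ValueError):
        ld.generate_continuous_ctt(scen, n_per_group=1)


class TestOrdinalGenerator:
    def test_exchangeable_groups_have_equal_margins(self):
        cfg = ld.OrdinalFactorConfig.simple(
            n_items=4, group_sizes=(20_000, 20_000), latent_d=0.0, seed=11
        )
        data = ld.generate_ordinal_factor_data(cfg)
        for item in data.scale_def.items:
            p1 = (
                data.responses.loc[data.group_mask("g1"), item]
                .value_counts(normalize=True)
                .sort_index()
            )
            p2 = (
                data.responses.loc[data.group_mask("g2"), item]
                .value_counts(normalize=True)
                .sort_index()
            )
            assert np.abs(p1 - p2).max() < 0.02

    def test_fixed_seed_reproduces_dataset(self):
        cfg = ld.OrdinalFactorConfig.simple(n_items=3, group_sizes=(200, 200), seed=7)
        a = ld.generate_ordinal_factor_data(cfg)
        b = ld.generate_ordinal_factor_data(cfg)
        pd.testing.assert_frame_equal(a.responses, b.responses)
        pd.testing.assert_series_equal(a.group, b.group)

    def test_nonincreasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ld.OrdinalFactorConfig(
                loadings=(0.7, 0.7, 0.7),
                thresholds=((0.0, -0.5),) * 3,
                residual_variances=(0.51,) * 3,
                group_sizes=(100, 100),
            )

    def test_degenerate_item_raises(self):
        # thresholds so extreme that an item is constant in both groups
        with pytest.raises(ld.DegenerateItemError):
            cfg = ld.OrdinalFactorConfig(
                loadings=(0.7, 0.7, 0.7),
                thresholds=((8.0,), (-0.5, 0.5), (-0.5, 0.5)),
                residual_variances=(0.51,) * 3,
                group_sizes=(100, 100),
                seed=2,
            )
            ld.generate_ordinal_factor_data(cfg)

    def test_small_sample_warning(self):
        with pytest.warns(UserWarning, match="20 respondents per indicator"):
            ld.OrdinalFactorConfig.simple(n_items=6, group_sizes=(50, 50))

    def test_fine_categorization_approaches_continuous_attenuation(self):
        """With many narrow categories the sum-score d matches the
        continuous closed form true_d * sqrt(omega)."""
        thr = tuple(np.linspace(-4.0, 4.0, 40))
        cfg = ld.OrdinalFactorConfig(
            loadings=(0.7,) * 6,
            thresholds=(thr,) * 6,
            residual_variances=(0.51,) * 6,
            group_sizes=(100_000, 100_000),
            latent_d=0.5,
            seed=13,
        )
        data = ld.generate_ordinal_factor_data(cfg)
        omega = ld.implied_scale_reliability(cfg)
        d_y = ld.cohens_d_observed(data.scored(), np.asarray(data.group)).d
        assert d_y == pytest.approx(ld.attenuated_d(0.5, omega), abs=0.015)

    def test_sum_score_variance_matches_model_implied(self):
        """Generator moments agree with the exact ordinal model moments.

        The model-implied variance of the ordinal sum score is computed
        analytically from the bivariate cell probabilities of the latent
        responses — an independent route from the sampling code.
        """
        cfg = ld.OrdinalFactorConfig.simple(
            n_items=4, loading=0.6, group_sizes=(150_000, 150_000), seed=17
        )
        data = ld.generate_ordinal_factor_data(cfg)
        thr = np.asarray(cfg.thresholds[0])
        lam = 0.6

        # univariate category moments via the normal CDF at the thresholds
        p_gt = 1.0 - ndtr(thr)  # P(category > k), k = 0..3
        mean_item = p_gt.sum()  # E[c] = sum_k P(c > k)
        # E[c_i c_j] = sum_{k,l} P(c_i > k, c_j > l) via bivariate survival
        rho = lam * lam
        surv = (
            1.0
            - ndtr(thr)[:, None]
            - ndtr(thr)[None, :]
            + bvn_cdf(thr[:, None], thr[None, :], rho)
        )
        e_cc = surv.sum()
        e_c2 = sum((2 * k + 1) * p_gt[k] for k in range(len(thr)))
        var_item = e_c2 - mean_item**2
        cov_item = e_cc - mean_item**2
        m = cfg.n_items
        var_sum = m * var_item + m * (m - 1) * cov_item

        g1 = data.responses.loc[data.group_mask("g1")].sum(axis=1)
        assert g1.var(ddof=1) == pytest.approx(var_sum, rel=0.02)


class TestReliability:
    def test_homogeneous_scale_closed_form(self):
        cfg = ld.OrdinalFactorConfig.simple(n_items=6, loading=0.7, group_sizes=(200, 200))
        assert ld.implied_scale_reliability(cfg) == pytest.approx(17.64 / 20.70, rel=1e-9)

    def test_error_free_items_reach_one(self):
        cfg = ld.OrdinalFactorConfig(
            loadings=(1.0, 1.0, 1.0),
            thresholds=((-0.5, 0.5),) * 3,
            residual_variances=(1e-12,) * 3,
            group_sizes=(100, 100),
        )
        assert ld.implied_scale_reliability(cfg) == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_items_give_zero(self):
        cfg = ld.OrdinalFactorConfig(
            loadings=(0.0, 0.0, 0.0),
            thresholds=((-0.5, 0.5),) * 3,
            residual_variances=(1.0,) * 3,
            group_sizes=(100, 100),
        )
        assert ld.implied_scale_reliability(cfg) == 0.0


class TestScoringAndIO:
    def _tiny_data(self):
        cfg = ld.OrdinalFactorConfig.simple(n_items=3, group_sizes=(120, 120), seed=3)
        return ld.generate_ordinal_factor_data(cfg)

    def test_reverse_keying_flips_categories(self):
        data = self._tiny_data()
        rev = ld.ItemResponseData(
            responses=data.responses,
            group=data.group,
            scale_def=ld.ScaleDefinition(
                items=data.scale_def.items,
                reverse_keyed=data.scale_def.items,
                scoring="sum",
                n_categories=5,
            ),
        )
        expected = 3 * 4 - data.scored()
        np.testing.assert_allclose(rev.scored(), expected)

    def test_mean_scoring_is_sum_over_items(self):
        data = self._tiny_data()
        mean_def = ld.ScaleDefinition(
            items=data.scale_def.items, scoring="mean", n_categories=5
        )
        mdata = ld.ItemResponseData(
            responses=data.responses, group=data.group, scale_def=mean_def
        )
        np.testing.assert_allclose(mdata.scored(), data.scored() / 3)

    def test_csv_and_yaml_round_trip(self, tmp_path):
        data = self._tiny_data()
        ld.write_item_csv(data, tmp_path / "items.csv")
        data.scale_def.to_yaml(tmp_path / "scale.yaml")
        sdef = ld.ScaleDefinition.from_yaml(tmp_path / "scale.yaml")
        back = ld.read_item_csv(tmp_path / "items.csv", sdef)
        pd.testing.assert_frame_equal(back.responses, data.responses)
        assert sdef == data.scale_def
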