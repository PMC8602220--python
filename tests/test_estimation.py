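import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ppmopkpd import (
    Dataset,
    ErrorModel,
    FitSettings,
    Observation,
    PKPDParams,
    PlasmaPKParams,
    compute_rse,
    fit_plasma,
    fit_tissue_pd,
    generate_study,
    obs_loglik,
    study_designs,
    predict_dataset,
    total_negloglik,
)
from ppmopkpd.estimation import (
    DEFAULT_ERROR_MODELS,
    EstimationError,
    NonIdentifiableError,
    _loglik_terms,
)


def make_obs(value, censored=False, loq=None):
    return Observation(animal="a1", group="g", time_day=1.0, dvid="cp",
                       value=value, censored=censored, loq=loq)


class TestObsLoglik:
    def test_censored_far_above_loq_vanishes(self):
        # prediction sits ~99 sigma above the LOQ: P(Y < LOQ) underflows
        em = ErrorModel("proportional", b=0.01)
        ll = obs_loglik(make_obs(10.0, censored=True, loq=10.0), pred=1000.0,
                        em=em)
        assert ll <= math.log(1e-250)

    def test_censored_well_inside_interval_is_near_certain(self):
        # pred = loq/2 with sigma = loq/10: P(0 < Y < loq) = Phi(5) - Phi(-5)
        em = ErrorModel("combined", a=1.0, b=1e-9)  # sigma ~ a = loq/10
        ll = obs_loglik(make_obs(10.0, censored=True, loq=10.0), pred=5.0,
                        em=em, truncate=False)
        assert ll == pytest.approx(math.log(norm.cdf(5) - norm.cdf(-5)),
                                   abs=1e-12)

    def test_zero_residual_attains_maximal_density(self):
        em = ErrorModel("proportional", b=0.2)
        pred = 50.0
        sigma = 0.2 * pred
        expected = -math.log(sigma * math.sqrt(2 * math.pi)) \
            - math.log(norm.cdf(pred / sigma))
        assert obs_loglik(make_obs(50.0), pred=pred, em=em) \
            == pytest.approx(expected, abs=1e-12)

    def test_truncation_normalizer_only_matters_near_zero(self):
        em = ErrorModel("proportional", b=0.5)
        plain = obs_loglik(make_obs(1.0), pred=1.0, em=em, truncate=False)
        cond = obs_loglik(make_obs(1.0), pred=1.0, em=em, truncate=True)
        assert cond > plain  # dividing by P(Y>0) < 1 raises the density
        assert cond - plain == pytest.approx(-math.log(norm.cdf(2.0)))


class TestTotalNegloglik:
    def test_empty_dataset_is_zero(self, ref):
        empty = Dataset(pd.DataFrame(columns=[
            "id", "group", "study", "time_day", "dvid", "dv", "cens", "loq",
            "dose_mgkg", "evid", "amt_ng"]))
        assert total_negloglik(empty, ref) == 0.0

    def test_duplication_doubles_the_value(self, ref, plasma_ds):
        nll = total_negloglik(plasma_ds, ref)
        obs = plasma_ds.df[plasma_ds.df["evid"] == 0]
        doubled = Dataset(pd.concat([plasma_ds.df, obs], ignore_index=True))
        assert total_negloglik(doubled, ref) == pytest.approx(2 * nll, rel=1e-12)

    def test_agrees_with_unvectorized_reference_loop(self, ref, plasma_ds):
        nll = total_negloglik(plasma_ds, ref)
        pred = predict_dataset(plasma_ds.subset(dvids=["cp"]), ref.plasma)
        obs = plasma_ds.observations.reset_index(drop=True)
        total = 0.0
        for i, row in obs.iterrows():
            sigma = max(0.2 * pred[i], 1e-10)
            if row.cens:
                p = norm.cdf((row.loq - pred[i]) / sigma) \
                    - norm.cdf(-pred[i] / sigma)
                p /= norm.cdf(pred[i] / sigma)
                total += math.log(max(p, 1e-300))
            else:
                total += norm.logpdf(row.dv, pred[i], sigma) \
                    - norm.logcdf(pred[i] / sigma)
        assert nll == pytest.approx(-total, rel=1e-10)

    def test_unit_rescaling_shifts_by_data_constant(self, ref, plasma_ds):
        """Under pure proportional error, expressing cp in ug/mL instead of
        ng/mL shifts the log-likelihood of each *quantified* observation by
        log(1000) (the Jacobian of the density); censored terms are pure
        probabilities and do not shift. The argmax is unchanged up to the Vc
        rescaling."""
        scale = 1e-3
        df = plasma_ds.df.copy()
        obs_rows = df["evid"] == 0
        df.loc[obs_rows, ["dv", "loq"]] *= scale
        scaled = Dataset(df)

        def rescaled(params: PKPDParams) -> PKPDParams:
            flat = params.to_dict()
            flat["Vc"] = flat["Vc"] / scale
            return PKPDParams.from_dict(flat)

        n_unc = int((plasma_ds.observations["cens"] == 0).sum())
        shift = n_unc * math.log(scale)
        for factor in (1.0, 1.3):
            flat = ref.to_dict()
            flat["kel"] *= factor
            p = PKPDParams.from_dict(flat)
            nll_orig = total_negloglik(plasma_ds, p)
            nll_scaled = total_negloglik(scaled, rescaled(p))
            assert nll_scaled - nll_orig == pytest.approx(shift, rel=1e-9)

    def test_censoring_rule_vanishes_as_loq_shrinks(self, ref, plasma_ds):
        # re-censor the same draws at a tiny LOQ: nothing falls below it, and
        # the likelihood equals the fully uncensored one
        df = plasma_ds.df.copy()
        obs = df["evid"] == 0
        assert df.loc[obs, "cens"].sum() > 0  # design censors the 24 h samples
        uncensored = df.copy()
        uncensored.loc[obs, "cens"] = 0
        drop = (df["evid"] == 0) & (df["cens"] == 1)
        remaining = Dataset(uncensored[~drop])
        tiny = uncensored.copy()
        tiny.loc[tiny["evid"] == 0, "loq"] = 1e-12
        assert total_negloglik(Dataset(tiny[~drop]), ref) == pytest.approx(
            total_negloglik(remaining, ref), rel=1e-12)


class TestLoglikVector:
    def test_sigma_floor_guards_zero_prediction(self):
        em = ErrorModel("proportional", b=0.2)
        sigma = em.sigma(np.array([0.0]))
        assert sigma[0] == 1e-10
        ll = _loglik_terms(np.array([0.5]), np.array([0.0]),
                           np.array([False]), np.array([np.nan]), sigma)
        assert np.isfinite(ll[0])


class TestFitPlasma:
    def test_noise_free_data_recovers_generating_values(self, ref, designs):
        ds = generate_study(designs["plasma_single"], ref,
                            ems={"cp": ErrorModel("proportional", b=1e-6)},
                            seed=1)
        init = PlasmaPKParams(vc=5.86 * 1.3, kel=102.72 / 1.3,
                              k12=21.53 * 1.2, k21=30.24 / 1.2)
        fit = fit_plasma(ds, init, FitSettings(n_starts=1), fix_b=1e-3)
        for name, truth in (("Vc", 5.86), ("kel", 102.72),
                            ("k12", 21.53), ("k21", 30.24)):
            assert fit.estimates[name] == pytest.approx(truth, rel=1e-3)

    def test_optimum_not_worse_than_any_start(self, ref, plasma_ds, plasma_fit):
        nll_init = total_negloglik(plasma_ds.subset(dvids=["cp"]), ref)
        assert plasma_fit.neg2ll / 2 <= nll_init + 1e-9

    def test_all_censored_dataset_is_rejected(self, ref, plasma_ds):
        df = plasma_ds.df.copy()
        obs = df["evid"] == 0
        df.loc[obs, "cens"] = 1
        df.loc[obs, "dv"] = df.loc[obs, "loq"]
        with pytest.raises(EstimationError):
            fit_plasma(Dataset(df), ref.plasma)


class TestFitTissue:
    def test_missing_transcript_block_is_structural(self, ref, tissue_ds):
        no_sk = tissue_ds.subset(dvids=["ct", "dys"])
        with pytest.raises(NonIdentifiableError):
            fit_tissue_pd(no_sk, ref.plasma, ref)

    def test_baselines_are_fixed_not_estimated(self, ref, tissue_ds):
        fit = fit_tissue_pd(tissue_ds, ref.plasma, ref,
                            FitSettings(n_starts=1, maxiter=5),
                            fixed={"Vt": 0.21, "a_sk": 0.1})
        assert fit.fixed["skmRNA0"] == 1.3
        assert fit.fixed["Dys0"] == 0.10
        assert "skmRNA0" not in fit.estimates
        assert "Vt" not in fit.estimates


class TestRSE:
    def test_plasma_rse_reasonable_and_excludes_fixed(self, plasma_fit,
                                                      plasma_ds):
        rse = compute_rse(plasma_fit, plasma_ds)
        assert set(rse) == {"Vc", "kel", "k12", "k21", "b_cp"}
        assert all(0 < v < 100 for v in rse.values())

    def test_known_information_content_oracle(self, ref, designs):
        """With tiny residual error the information on log-parameters scales
        like n/b^2; RSE from the numerical Hessian must match the analytic
        single-parameter oracle for Vc within a factor set by correlation."""
        b = 0.05
        ds = generate_study(designs["plasma_single"], ref,
                            ems={"cp": ErrorModel("proportional", b=b)}, seed=9)
        fit = fit_plasma(ds, ref.plasma, FitSettings(n_starts=1), b_init=b)
        rse = compute_rse(fit, ds)
        n_unc = int((ds.observations["cens"] == 0).sum())
        floor = 100.0 * b / math.sqrt(n_unc)  # uncorrelated lower bound
        assert rse["Vc"] >= floor * 0.5
        assert rse["Vc"] < 40 * floor
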