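"""The control-panel fit and its oracle: brute-force least squares.

The oracle solves the normal equations directly on the linear intensity
scale and applies the same log-ratio/median-centring definition; it is
independent of the lstsq/QR path used by the implementation.
"""

import numpy as np
import pandas as pd
import pytest

from methylcnv import (
    SampleIntensitySet, ValidationError, combined_intensity, filter_probes,
    fit_reference, log_intensity, probe_log2_ratios,
)


def oracle_fit(query, controls):
    """Normal-equations least squares + log2 ratio + median centring."""
    C = np.asarray(controls, float)
    q = np.asarray(query, float)
    beta = np.linalg.solve(C.T @ C, C.T @ q)
    r = np.log2(q / (C @ beta))
    return beta, r - np.median(r)


def _toy_controls(n_probes=200, n_controls=3, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.lognormal(7.5, 0.6, n_probes)
    return base[:, None] * rng.lognormal(0, 0.1, (n_probes, n_controls)) * \
        np.exp2(rng.normal(0, 0.1, (n_probes, n_controls)))


class TestPointwiseOps:
    def test_combined_intensity_is_channel_sum(self):
        assert combined_intensity(100, 50) == 150
        assert combined_intensity(0, 0) == 0
        assert combined_intensity(1023, 0) == 1023
        with pytest.raises(ValidationError):
            combined_intensity(-1, 5)

    def test_log_intensity_pseudocount(self):
        assert log_intensity(0) == 0.0
        assert log_intensity(1023) == 10.0
        assert log_intensity(3) == 2.0
        with pytest.raises(ValidationError):
            log_intensity(-0.5)


class TestFilterProbes:
    def _iset(self, combined, roles):
        meth = pd.DataFrame(combined / 2, index=[f"cg{i}" for i in
                                                 range(len(combined))],
                            columns=list(roles))
        return SampleIntensitySet(meth, meth.copy(), roles)

    def test_bright_probes_all_retained_at_zero_threshold(self):
        combined = np.full((5, 4), 500.0)
        iset = self._iset(combined, {"q": "query", "c1": "control",
                                     "c2": "control", "c3": "control"})
        assert filter_probes(iset, min_combined=0).all()

    def test_probe_missing_in_one_sample_excluded_everywhere(self):
        combined = np.full((5, 3), 500.0)
        iset = self._iset(combined, {"q": "query", "c1": "control",
                                     "c2": "control"})
        iset.meth.iloc[2, 0] = np.nan  # missing in the query only
        mask = filter_probes(iset, min_combined=0)
        assert not mask.iloc[2] and mask.sum() == 4

    def test_dim_probes_excluded_by_control_median(self):
        combined = np.full((4, 3), 500.0)
        combined[1, 1:] = 10.0  # dim across controls
        combined[0, 0] = 10.0   # dim in the query only: retained
        iset = self._iset(combined, {"q": "query", "c1": "control",
                                     "c2": "control"})
        mask = filter_probes(iset, min_combined=100)
        assert list(mask) == [True, False, True, True]

    def test_all_probes_excluded_is_fatal(self):
        combined = np.full((3, 3), 5.0)
        iset = self._iset(combined, {"q": "query", "c1": "control",
                                     "c2": "control"})
        with pytest.raises(ValidationError, match="excluded all"):
            filter_probes(iset, min_combined=1e6)


class TestFitReference:
    def test_self_fit_recovers_indicator_coefficients(self):
        C = _toy_controls()
        beta, r = fit_reference(C[:, 0], C)
        assert beta == pytest.approx([1.0, 0.0, 0.0], abs=1e-8)
        assert np.abs(r).max() < 1e-8

    def test_constant_log_shift_absorbed(self):
        C = _toy_controls(n_controls=2)
        query = C[:, 0] * 2 ** 0.3  # +0.3 on the log2 scale
        beta, r = fit_reference(query, C)
        oracle_beta, oracle_r = oracle_fit(query, C)
        assert np.abs(r).max() < 1e-8
        np.testing.assert_allclose(beta, oracle_beta, atol=1e-8)

    def test_localized_shift_recovered_elsewhere_flat(self):
        C = _toy_controls(n_controls=2, seed=4)
        query = C[:, 0].copy()
        query[10:21] *= 2 ** 0.5
        _, r = fit_reference(query, C)
        _, oracle_r = oracle_fit(query, C)
        np.testing.assert_allclose(r, oracle_r, atol=1e-8)
        assert np.median(r[10:21]) == pytest.approx(0.5, abs=0.05)
        outside = np.r_[r[:10], r[21:]]
        assert np.abs(np.median(outside)) < 0.05

    def test_matches_bruteforce_oracle_on_random_toys(self):
        rng = np.random.default_rng(12)
        for trial in range(25):
            C = _toy_controls(n_probes=60, n_controls=3, seed=100 + trial)
            query = C @ rng.lognormal(0, 0.3, 3) * np.exp2(rng.normal(0, 0.2, 60))
            beta, r = fit_reference(query, C)
            oracle_beta, oracle_r = oracle_fit(query, C)
            np.testing.assert_allclose(beta, oracle_beta, atol=1e-8)
            np.testing.assert_allclose(r, oracle_r, atol=1e-8)

    def test_collinear_control_dropped_with_warning(self, caplog):
        C = _toy_controls(n_controls=2, seed=5)
        C3 = np.c_[C, C[:, 0] * 2.0]  # third column collinear with first
        with caplog.at_level("WARNING"):
            beta, r = fit_reference(C3[:, 1], C3)
        assert "collinear" in caplog.text
        assert np.abs(r).max() < 1e-8

    def test_fewer_than_two_independent_controls_fatal(self):
        c = _toy_controls(n_controls=1, seed=6)[:, 0]
        C = np.c_[c, 3 * c]
        with pytest.raises(ValidationError, match="independent control"):
            fit_reference(c * 1.1, C)

    def test_input_contract(self):
        C = _toy_controls(n_probes=5)
        with pytest.raises(ValidationError, match="retained probes"):
            fit_reference(C[:, 0], C)  # < 10 probes
        with pytest.raises(ValidationError, match="control"):
            fit_reference(C[:, 0], C[:, :1])


class TestProbeLogRatios:
    def test_per_sample_median_exactly_zero(self, small_cohort):
        _, _, cohort = small_cohort
        ratios = probe_log2_ratios(cohort.intensities)
        med = np.nanmedian(ratios.values.to_numpy(), axis=0)
        np.testing.assert_allclose(med, 0.0, atol=1e-9)

    def test_matches_per_sample_fit_reference(self, small_cohort):
        _, _, cohort = small_cohort
        iset = cohort.intensities
        ratios = probe_log2_ratios(iset)
        kept = ratios.mask.to_numpy()
        combined = (iset.meth + iset.unmeth).to_numpy()
        ctrl_idx = [iset.sample_ids.index(s) for s in iset.control_samples]
        q = iset.query_samples[0]
        beta, r = fit_reference(combined[kept, iset.sample_ids.index(q)],
                                combined[np.ix_(kept, ctrl_idx)])
        np.testing.assert_allclose(ratios.values[q].to_numpy()[kept], r,
                                   atol=1e-10)
        np.testing.assert_allclose(ratios.coefficients[q].to_numpy(), beta,
                                   atol=1e-10)

    def test_control_passed_as_query_is_flat(self, small_cohort):
        # a panel member offered as a query sample is fitted by itself exactly
        _, _, cohort = small_cohort
        iset = cohort.intensities
        twin = iset.control_samples[0]
        meth = iset.meth.assign(twin_q=iset.meth[twin])
        unmeth = iset.unmeth.assign(twin_q=iset.unmeth[twin])
        roles = dict(iset.roles) | {"twin_q": "query"}
        ratios = probe_log2_ratios(SampleIntensitySet(meth, unmeth, roles))
        r = ratios.values["twin_q"].to_numpy()
        assert np.nanmax(np.abs(r)) < 1e-8

    def test_scale_invariance_of_one_query(self, small_cohort):
        _, _, cohort = small_cohort
        iset = cohort.intensities
        q = iset.query_samples[0]
        meth, unmeth = iset.meth.copy(), iset.unmeth.copy()
        meth[q] *= 3.7
        unmeth[q] *= 3.7
        scaled = SampleIntensitySet(meth, unmeth, iset.roles)
        r0 = probe_log2_ratios(iset).values[q].to_numpy()
        r1 = probe_log2_ratios(scaled).values[q].to_numpy()
        np.testing.assert_allclose(r1, r0, atol=1e-6)

    def test_control_permutation_stability(self, small_cohort):
        _, _, cohort = small_cohort
        iset = cohort.intensities
        order = iset.query_samples + iset.control_samples[::-1]
        permuted = iset.subset(order)
        r0 = probe_log2_ratios(iset).values.to_numpy()
        r1 = probe_log2_ratios(permuted).values.to_numpy()
        np.testing.assert_allclose(r1, r0, atol=1e-9)

    def test_excluded_probes_nan_for_all_samples(self, small_cohort):
        _, _, cohort = small_cohort
        iset = cohort.intensities
        meth = iset.meth.copy()
        meth.iloc[5, 0] = np.nan
        ratios = probe_log2_ratios(SampleIntensitySet(meth, iset.unmeth,
                                                      iset.roles))
        assert not ratios.mask.iloc[5]
        assert ratios.values.iloc[5].isna().all()
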