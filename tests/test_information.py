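"""Closed-form information quantities, the small-noise formula and the numeric oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from accinfo import information as info
from accinfo.information import (
    Channel,
    InfoResult,
    ProfileSet,
    acc_info_direct,
    acc_info_two_tier,
    benefit_condition,
    info_phi,
    info_small_noise,
    linear_profile,
    mi_numeric,
    raw_info_direct,
    raw_info_two_tier,
    zigzag_info,
    zigzag_profile,
)

SQRT_2PIE = math.sqrt(2 * math.pi * math.e)


def tiled_linear_mi(phi, seed=0, n_mc=20_000, k_scale=400.0):
    """Numeric MI of a linear Gaussian channel, on a K-fold tiled domain.

    Tiling measures the bulk information rate (total MI minus ln K), pushing
    the O(1/phi) domain-edge term below ~1.8/(K*phi); the estimate remains a
    full quadrature+MC mutual information with no small-noise assumption.
    """
    k = max(1, math.ceil(k_scale / phi))
    profile = linear_profile(k * phi, 1.0, length=float(k))
    n_grid = int(min(max(512, 2.0 * k * phi), 12_000))
    res = mi_numeric(profile, n_grid=n_grid, n_mc=n_mc, seed=seed)
    return InfoResult(value=res.value - math.log(k), method="numeric", mc_stderr=res.mc_stderr)


class TestInfoPhi:
    def test_reference_values(self):
        assert info_phi(SQRT_2PIE).value == pytest.approx(0.0, abs=1e-12)
        assert info_phi(math.e * SQRT_2PIE).value == pytest.approx(1.0, abs=1e-12)

    def test_bits_conversion(self):
        r = info_phi(100.0)
        assert r.value_bits == pytest.approx(r.value / math.log(2))

    def test_rejects_non_positive_phi(self):
        for phi in (0.0, -1.0):
            with pytest.raises(ValueError):
                info_phi(phi)

    def test_matches_numeric_oracle(self):
        est = tiled_linear_mi(100.0, seed=1)
        assert abs(est.value - info_phi(100.0).value) < 0.02


class TestClosedForms:
    def test_raw_direct_reduces_to_bare_gradient_at_neff_one(self):
        assert raw_info_direct(5.0, 0.1, 1.0).value == pytest.approx(info_phi(50.0).value)

    def test_doubling_neff_adds_half_ln2(self):
        a = raw_info_direct(1.0, 0.1, 4.0).value
        b = raw_info_direct(1.0, 0.1, 8.0).value
        assert b - a == pytest.approx(0.5 * math.log(2))

    def test_gain_cancels_in_raw_two_tier(self):
        vals = [raw_info_two_tier(1.0, 0.1, 0.05, 4.0, lam).value for lam in (1, 2, 4, 8)]
        assert max(vals) - min(vals) == 0.0

    def test_raw_two_tier_below_raw_direct_iff_eta_positive(self):
        base = raw_info_direct(1.0, 0.1, 4.0).value
        assert raw_info_two_tier(1.0, 0.1, 0.0, 4.0).value == pytest.approx(base)
        assert raw_info_two_tier(1.0, 0.1, 0.05, 4.0).value < base

    def test_acc_direct_limits(self):
        assert acc_info_direct(1.0, 0.1, 0.0, 4.0).value == pytest.approx(
            raw_info_direct(1.0, 0.1, 4.0).value
        )
        # n_eff -> infinity leaves only the readout noise
        assert acc_info_direct(1.0, 0.1, 0.02, 1e12).value == pytest.approx(
            info_phi(1.0 / 0.02).value, abs=1e-6
        )

    def test_acc_two_tier_limits_and_monotonicity_in_gain(self):
        big_gain = acc_info_two_tier(1.0, 0.1, 0.05, 4.0, 1e9).value
        assert big_gain == pytest.approx(raw_info_two_tier(1.0, 0.1, 0.05, 4.0).value, abs=1e-9)
        vals = [acc_info_two_tier(1.0, 0.1, 0.05, 4.0, lam).value for lam in (1, 2, 4, 8, 16)]
        assert np.all(np.diff(vals) > 0)
        # with no averaging and no amplification the second access only hurts
        assert acc_info_two_tier(1.0, 0.1, 0.05, 1.0, 1.0).value < acc_info_direct(
            1.0, 0.1, 0.05, 1.0
        ).value

    def test_benefit_condition_reference_cases(self):
        ok, margin = benefit_condition(1.0, 1.0, 8.0)
        assert not ok and margin == pytest.approx(-1.0 / 64)
        ok, margin = benefit_condition(1.0, 4.0, 2.0)
        assert ok and margin == pytest.approx(0.5)
        assert acc_info_two_tier(1.0, 1.0, 1.0, 4.0, 2.0).value > acc_info_direct(
            1.0, 1.0, 1.0, 4.0
        ).value
        assert not benefit_condition(0.5, 1.0, 4.0)[0]   # no averaging
        assert not benefit_condition(0.5, 4.0, 1.0)[0]   # no amplification

    def test_zigzag_info_subtracts_ln_gain(self):
        base = info_phi(100.0)
        assert zigzag_info(base, 1).value == base.value
        assert zigzag_info(base, 3).value == pytest.approx(base.value - math.log(3))
        with pytest.raises(ValueError):
            zigzag_info(base, 2.5)


@given(
    eta0=st.floats(0.001, 3.0),
    n_eff=st.floats(1.0, 64.0),
    gain=st.floats(1.0, 32.0),
    sigma0=st.floats(0.01, 3.0),
)
def test_benefit_margin_sign_identity(eta0, n_eff, gain, sigma0):
    """sign(margin) == sign(acc_two_tier - acc_direct) everywhere in the domain."""
    _, margin = benefit_condition(eta0, n_eff, gain)
    delta = (
        acc_info_two_tier(1.0, sigma0, eta0, n_eff, gain).value
        - acc_info_direct(1.0, sigma0, eta0, n_eff).value
    )
    if abs(margin) < 1e-12:
        assert abs(delta) < 1e-9
    else:
        assert math.copysign(1, margin) == math.copysign(1, delta)


class TestSmallNoise:
    def test_linear_channel_reproduces_info_phi_exactly(self):
        assert info_small_noise(linear_profile(100.0, 1.0)).value == pytest.approx(
            info_phi(100.0).value, abs=1e-10
        )

    def test_fisher_additivity_for_two_identical_channels(self):
        one = linear_profile(100.0, 1.0)
        two = ProfileSet(channels=one.channels * 2, domain=one.domain)
        assert info_small_noise(two).value == pytest.approx(
            info_phi(100.0 * math.sqrt(2)).value, abs=1e-10
        )

    def test_accessibility_bound(self):
        p = linear_profile(50.0, 1.0)
        base = info_small_noise(p, extra_noise=0.0).value
        prev = base
        for eta in (0.1, 0.5, 1.0, 3.0):
            v = info_small_noise(p, extra_noise=eta).value
            assert v < prev
            prev = v

    def test_scale_invariance(self):
        p = linear_profile(80.0, 1.0)
        a = info_small_noise(p, extra_noise=0.5).value
        b = info_small_noise(p.scaled(7.0), extra_noise=3.5).value
        assert a == pytest.approx(b, abs=1e-9)

    def test_zero_variance_channel_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            info_small_noise(linear_profile(10.0, 0.0))

    def test_flat_profile_rejected(self):
        flat = ProfileSet(
            channels=(
                Channel(
                    name="flat",
                    mean=lambda x: np.ones_like(np.asarray(x, float)),
                    sd=lambda x: np.full_like(np.asarray(x, float), 0.1),
                    dmean=lambda x: np.zeros_like(np.asarray(x, float)),
                ),
            ),
            domain=(0.0, 1.0),
        )
        with pytest.raises(ValueError, match="Fisher"):
            info_small_noise(flat)

    def test_matches_numeric_for_multichannel_embryo_profiles(self):
        # noise scaled down so max sigma_x << ROI length, where the
        # small-noise expression is supposed to hold
        from accinfo.synthetic_data import default_embryo_spec

        spec = default_embryo_spec(gap_sd=0.015, stripe_sd=0.03)
        channels = tuple(
            Channel(
                name=g,
                mean=spec.mean_function(g),
                sd=spec.sd_function(g),
                dmean=spec.slope_function(g),
            )
            for g in spec.gene_names
        )
        roi = ProfileSet(channels=channels, domain=spec.roi)
        small = info_small_noise(roi)
        est = mi_numeric(roi, n_grid=2048, n_mc=20_000, seed=5)
        assert abs(small.value - est.value) < 0.05


class TestMiNumeric:
    def test_two_noisy_copies_equal_one_channel_with_reduced_noise(self):
        base = linear_profile(60.0, 1.0)
        double = ProfileSet(channels=base.channels * 2, domain=base.domain)
        combined = linear_profile(60.0, 1.0 / math.sqrt(2))
        a = mi_numeric(double, n_grid=1024, n_mc=15_000, seed=2)
        b = mi_numeric(combined, n_grid=1024, n_mc=15_000, seed=3)
        assert abs(a.value - b.value) < 3 * (a.mc_stderr + b.mc_stderr) + 0.01

    def test_extra_noise_only_reduces_information(self):
        p = linear_profile(60.0, 1.0)
        a = mi_numeric(p, extra_noise=0.0, n_grid=1024, n_mc=10_000, seed=4)
        b = mi_numeric(p, extra_noise=1.0, n_grid=1024, n_mc=10_000, seed=4)
        assert b.value < a.value

    def test_tier_output_bounded_by_neff_input_copies(self):
        # data-processing: averaging n_eff noisy readouts of the input cannot
        # beat n_eff independent copies of the input itself
        c_max, sigma0, eta0, n_eff, lam = 1.0, 1 / 60, 1 / 80, 4, 3.0
        xi = lam * math.sqrt((sigma0**2 + eta0**2) / n_eff)
        tier = linear_profile(lam * c_max, xi)
        copies = ProfileSet(
            channels=linear_profile(c_max, sigma0).channels * n_eff, domain=(0.0, 1.0)
        )
        a = mi_numeric(tier, n_grid=1024, n_mc=10_000, seed=6)
        b = mi_numeric(copies, n_grid=1024, n_mc=10_000, seed=7)
        assert a.value < b.value + 3 * (a.mc_stderr + b.mc_stderr)

    def test_zero_variance_rejected_and_stderr_positive(self):
        with pytest.raises(ValueError, match="zero total variance"):
            mi_numeric(linear_profile(10.0, 0.0), n_grid=64, n_mc=200, seed=0)
        r = mi_numeric(linear_profile(10.0, 1.0), n_grid=256, n_mc=2000, seed=0)
        assert r.mc_stderr > 0
        assert r.method == "numeric"

    def test_zigzag_profile_loses_ln_gain(self):
        # small-noise regime: fold regions carry vanishing weight
        xi = 5e-4
        zz = zigzag_profile(1.0, 3, xi)
        lin = linear_profile(3.0, xi)
        a = mi_numeric(zz, n_grid=12_000, n_mc=15_000, seed=8)
        b = mi_numeric(lin, n_grid=12_000, n_mc=15_000, seed=9)
        assert (b.value - a.value) == pytest.approx(
            math.log(3), abs=3 * math.hypot(a.mc_stderr, b.mc_stderr)
        )


class TestInfoResult:
    def test_validation_and_serialization(self):
        r = InfoResult(value=1.0, method="closed_form")
        assert r.to_dict()["value_bits"] == pytest.approx(1 / math.log(2))
        with pytest.raises(ValueError):
            InfoResult(value=1.0, method="guesswork")
        with pytest.raises(ValueError):
            InfoResult(value=1.0, method="numeric", mc_stderr=-0.1)
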