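"""Generator contracts: determinism, noiseless fidelity, known ground truth."""

import numpy as np
import pytest

from myelinquant import (
    compute_fa,
    fisher_exact_2x2,
    fit_tensor_volume,
    make_scheme,
    simulate_dwi,
    simulate_ihc_image,
    simulate_mbp_development,
    simulate_plate,
    simulate_teeth,
)
from myelinquant.mbp import four_param_logistic, inverse_four_param_logistic
from myelinquant.synthetic import default_phantom_spec, mbp_mean_curve


class TestScheme:
    def test_study_acquisition_layout(self):
        scheme = make_scheme(30, 970.0, 1, seed=0)
        assert scheme.n_volumes == 31
        assert np.sum(scheme.b_values == 970.0) == 30
        assert scheme.n_b0 == 1

    def test_unit_norm_directions(self):
        scheme = make_scheme(30, 970.0, 1, seed=5)
        norms = np.linalg.norm(scheme.directions[scheme.b_values > 0], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_deterministic_given_seed(self):
        a = make_scheme(30, 970.0, 1, seed=3)
        b = make_scheme(30, 970.0, 1, seed=3)
        c = make_scheme(30, 970.0, 1, seed=4)
        np.testing.assert_array_equal(a.directions, b.directions)
        assert not np.allclose(a.directions, c.directions)


class TestSimulateDwi:
    def test_isotropic_voxel_closed_form(self):
        # g^T (d I) g = d for any unit direction -> S = S0 exp(-b d)
        scheme = make_scheme(12, 1000.0, 1, seed=0)
        spec = default_phantom_spec(
            n_per_group=1, snr=np.inf, seed=0, grid_shape=(6, 6, 5)
        )
        spec = type(spec)(
            **{**spec.__dict__, "partial_volume": 0.0, "tract_regions": ()}
        )
        volumes, _ = simulate_dwi(spec, scheme)
        dwi = next(iter(volumes.values()))
        expected = 1000.0 * np.exp(-scheme.b_values * spec.background_diffusivity)
        np.testing.assert_allclose(dwi[3, 3, 2], expected, rtol=1e-12)

    def test_noiseless_round_trip_matches_ground_truth(self, noiseless_study, scheme31):
        spec, volumes, truth = noiseless_study
        for subject, dwi in volumes.items():
            grp = truth.group_assignment[subject]
            fit = fit_tensor_volume(dwi, scheme31)
            D_true = truth.tensor_field[grp]
            rel = np.abs(fit.D - D_true).max() / np.abs(D_true).max()
            assert rel < 1e-10

    def test_ground_truth_fa_matches_closed_form(self, noiseless_study):
        spec, _, truth = noiseless_study
        for grp, rd in spec.tract_radial_diffusivity.items():
            lam = np.array([spec.tract_axial_diffusivity, rd, rd])
            region = spec.tract_regions[0]
            tract_fa = truth.fa_field[grp][region.slices]
            np.testing.assert_allclose(tract_fa, compute_fa(lam), atol=1e-12)

    def test_seed_contract(self):
        scheme = make_scheme(8, 970.0, 1, seed=0)
        spec_a = default_phantom_spec(n_per_group=1, snr=20.0, seed=7, grid_shape=(8, 8, 6))
        va, _ = simulate_dwi(spec_a, scheme)
        vb, _ = simulate_dwi(spec_a, scheme)
        spec_c = default_phantom_spec(n_per_group=1, snr=20.0, seed=8, grid_shape=(8, 8, 6))
        vc, _ = simulate_dwi(spec_c, scheme)
        for key in va:
            np.testing.assert_array_equal(va[key], vb[key])
            assert not np.array_equal(va[key], vc[key])

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError, match="snr"):
            default_phantom_spec(snr=-1.0)


class TestMbpDevelopment:
    def test_null_effect_no_noise_equal_means(self):
        table = simulate_mbp_development(
            ages=[3, 7, 11], effect=0.0, noise_cv=0.0, n_per_cell=3, seed=0
        )
        means = table.groupby(["pnd", "group"]).mbp_ng_ml.mean().unstack()
        np.testing.assert_allclose(means["T4"], means["vehicle"])

    def test_treated_mean_dominates(self):
        table = simulate_mbp_development(
            ages=range(3, 12), effect=2.0, noise_cv=0.0, n_per_cell=2, seed=0
        )
        means = table.groupby(["pnd", "group"]).mbp_ng_ml.mean().unstack()
        assert (means["T4"] >= means["vehicle"]).all()
        # strictly greater in the rising phase between the two midpoints
        rising = means.loc[6:9]
        assert (rising["T4"] > rising["vehicle"]).all()

    def test_curve_is_logistic_in_age(self):
        ages = np.arange(3, 12)
        vals = mbp_mean_curve(ages, "vehicle", effect=2.0)
        assert np.all(np.diff(vals) > 0)
        table = simulate_mbp_development(ages=ages, effect=2.0, noise_cv=0.0, seed=0)
        vehicle = table[table.group == "vehicle"].groupby("pnd").mbp_ng_ml.mean()
        np.testing.assert_allclose(vehicle.to_numpy(), vals, rtol=1e-12)

    def test_age_range_validated(self):
        with pytest.raises(ValueError, match="ages"):
            simulate_mbp_development(ages=[2], seed=0)


class TestPlate:
    def test_serial_dilution_layout(self):
        plate = simulate_plate(standard_top=100.0, n_serial=7, dilution_factor=2.0, seed=0)
        std = plate[plate.kind == "standard"]
        assert std.nominal_ng_ml.min() == pytest.approx(1.5625)
        assert len(plate[plate.kind == "blank"]) == 1

    def test_noiseless_inversion_round_trip(self):
        params = (0.05, 2.0, 10.0, 1.0)
        plate = simulate_plate(curve_params=params, noise_cv=0.0, seed=0)
        std = plate[plate.kind == "standard"]
        back = inverse_four_param_logistic(std.signal.to_numpy(), *params)
        np.testing.assert_allclose(back, std.nominal_ng_ml.to_numpy(), rtol=1e-8)

    def test_sample_dilution_arithmetic(self):
        params = (0.05, 2.0, 10.0, 1.0)
        plate = simulate_plate(
            curve_params=params, noise_cv=0.0, samples=[("s", 80.0, 4.0)], seed=0
        )
        sig = float(plate[plate.kind == "sample"].signal.iloc[0])
        assert sig == pytest.approx(float(four_param_logistic(20.0, *params)))


class TestIhcImage:
    @pytest.mark.parametrize("fraction", [0.0, 0.25])
    def test_exact_constructed_fraction(self, fraction):
        _, mask, realized = simulate_ihc_image(
            (100, 100), positive_fraction=fraction, noise_sd=0.0, seed=0
        )
        n_mask = int(mask.sum())
        assert realized == round(fraction * n_mask) / n_mask

    def test_intensity_ordering_required(self):
        with pytest.raises(ValueError, match="intensity"):
            simulate_ihc_image((10, 10), 0.2, fg_intensity=10, bg_intensity=50)


class TestTeeth:
    def test_deterministic_extremes(self):
        table = simulate_teeth(7, (1.0, 0.0), seed=0)
        np.testing.assert_array_equal(table, [[7, 0], [0, 7]])

    def test_binomial_expectation(self):
        totals = np.zeros(2)
        reps = 1000
        for s in range(reps):
            totals += simulate_teeth(11, (0.8, 0.1), seed=s)[:, 0]
        np.testing.assert_allclose(totals / reps, [8.8, 1.1], atol=0.15)

    def test_type_i_error_of_downstream_fisher(self):
        # equal eruption probabilities: Fisher rejects at most ~alpha
        hits = sum(
            fisher_exact_2x2(simulate_teeth(11, (0.5, 0.5), seed=s)) <= 0.05
            for s in range(500)
        )
        assert hits / 500 <= 0.07
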