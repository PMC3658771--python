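import numpy as np
import pytest

from mpcontour import (
    AlgoParams,
    DegenerateRegionError,
    ParameterError,
    Termination,
    evolve_pass,
    gradient_flow,
    init_level_set,
    region_means,
    total_energy,
)
from mpcontour.preprocessing import edge_indicator
from mpcontour.singlepass import sharp_region_means

from _oracles import disk_sdf, naive_total_energy


class TestAlgoParams:
    def test_defaults_satisfy_stability(self):
        p = AlgoParams()
        assert p.tau * p.alpha < 0.25

    def test_stability_condition_enforced(self):
        with pytest.raises(ParameterError, match="1/4"):
            AlgoParams(tau=1.0, alpha=0.3)
        with pytest.raises(ParameterError, match="1/4"):
            AlgoParams(tau=2.0, alpha=0.2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda1": -1.0},
            {"tau": 0.0},
            {"eps": -1.5},
            {"mu": -0.1},
            {"mean_weighting": "fuzzy"},
            {"stationary_window": 0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            AlgoParams(**kwargs)


class TestInitLevelSet:
    def test_darkest_pixels_seed_the_outside(self):
        img = np.full((5, 5), 50.0)
        img[2, 3] = 10.0
        phi = init_level_set(img, np.ones((5, 5), bool), rho=6.0, kappa=1.0)
        assert phi[2, 3] == 6.0
        assert (phi == -6.0).sum() == 24
        assert set(np.unique(phi)) == {-6.0, 6.0}

    def test_constant_image_degenerates_to_all_outside(self):
        """Every pixel satisfies I < min + kappa, so phi0 is +rho everywhere."""
        phi = init_level_set(np.full((6, 6), 128.0), np.ones((6, 6), bool), 6.0, 1.0)
        assert (phi == 6.0).all()

    def test_masked_region_with_its_own_minimum(self):
        img = np.full((8, 8), 20.0)
        square = np.zeros((8, 8), bool)
        square[2:6, 2:6] = True
        img[square] = 200.0
        img[3, 3] = 150.0  # darkest pixel of the masked region
        phi = init_level_set(img, square, rho=6.0, kappa=1.0)
        assert (phi[~square] == 6.0).all()  # outside the mask
        assert phi[3, 3] == 6.0  # regional minimum
        inner = square.copy()
        inner[3, 3] = False
        assert (phi[inner] == -6.0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateRegionError):
            init_level_set(np.zeros((4, 4)), np.zeros((4, 4), bool))

    @pytest.mark.parametrize("kwargs", [{"rho": 0.0}, {"kappa": -1.0}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            init_level_set(np.zeros((4, 4)), np.ones((4, 4), bool), **kwargs)


class TestRegionMeans:
    def test_uniform_phi_gives_global_mean_on_both_sides(self):
        """With phi constant the weights are spatially uniform on each side."""
        img = np.array([[10.0, 20.0], [30.0, 40.0]])
        c1, c2 = region_means(img, np.full((2, 2), -6.0), np.ones((2, 2), bool), min_area=0.1)
        assert c1 == pytest.approx(25.0, abs=1e-9)
        assert c2 == pytest.approx(25.0, abs=1e-9)

    def test_smoothed_means_mix_the_tails(self):
        """Frozen hand computation: c1 = 100 H(6)/(H(6)+H(-6)) = 92.202."""
        img = np.array([[0.0, 0.0], [100.0, 100.0]])
        phi = np.array([[6.0, 6.0], [-6.0, -6.0]])
        c1, c2 = region_means(img, phi, np.ones((2, 2), bool), eps=1.5, min_area=0.1)
        assert c1 == pytest.approx(92.2021, abs=1e-3)
        assert c2 == pytest.approx(7.7979, abs=1e-3)

    def test_sharp_means_are_the_binary_limit(self):
        img = np.array([[0.0, 0.0], [100.0, 100.0]])
        phi = np.array([[6.0, 6.0], [-6.0, -6.0]])
        assert sharp_region_means(img, phi, np.ones((2, 2), bool)) == (100.0, 0.0)

    def test_mask_restriction_zeroes_excluded_rows(self):
        img = np.array([[0.0, 0.0], [100.0, 100.0]])
        phi = np.array([[-6.0, 6.0], [-6.0, 6.0]])
        mask = np.array([[True, True], [False, False]])
        c1, c2 = region_means(img, phi, mask, min_area=0.1)
        assert c1 == 0.0
        assert c2 == 0.0

    def test_degeneracy_threshold_triggers(self):
        """Half a pixel-equivalent of weighted area counts as empty."""
        img = np.array([[10.0, 20.0], [30.0, 40.0]])
        with pytest.raises(DegenerateRegionError) as exc:
            region_means(img, np.full((2, 2), -6.0), np.ones((2, 2), bool))
        assert exc.value.side == "outer"

    def test_sharp_means_degenerate_on_one_sided_phi(self):
        with pytest.raises(DegenerateRegionError):
            sharp_region_means(np.zeros((3, 3)), np.full((3, 3), 6.0), np.ones((3, 3), bool))


class TestTotalEnergy:
    def test_penalty_closed_form(self):
        """phi = 2i has |grad phi| = 2 except on the last row: E_P ~ alpha N/2."""
        i, _ = np.mgrid[0:32, 0:32].astype(float)
        phi = 2.0 * i
        img = np.full((32, 32), 100.0)
        g = edge_indicator(img)
        params = AlgoParams(mu=0.0, v=0.0)
        e = total_energy(phi, img, g, np.ones((32, 32), bool), 100.0, 100.0, params)
        assert e == pytest.approx(params.alpha * 32 * 32 / 2.0, rel=1e-4)

    def test_sdf_with_matching_means_leaves_only_length_term(self):
        phi = disk_sdf((32, 32), (15.5, 15.5), 8.0)
        img = np.full((32, 32), 80.0)
        g = edge_indicator(img)
        p_len = AlgoParams(alpha=1e-9, v=0.0)
        e = total_energy(phi, img, g, np.ones((32, 32), bool), 80.0, 80.0, p_len)
        # data terms vanish identically; remaining energy ~ mu * contour length
        assert e > 0
        assert e == pytest.approx(p_len.mu * 2 * np.pi * 8.0, rel=0.25)

    def test_nonnegative_and_finite(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (16, 16))
        phi = rng.normal(0, 5, (16, 16))
        e = total_energy(phi, img, edge_indicator(img), np.ones((16, 16), bool), 50.0, 150.0, AlgoParams())
        assert np.isfinite(e)
        assert e >= 0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        params = AlgoParams()
        for _ in range(5):
            img = rng.uniform(0, 255, (16, 16))
            phi = rng.normal(0, 4, (16, 16))
            mask = rng.random((16, 16)) > 0.3
            g = edge_indicator(img)
            c1, c2 = rng.uniform(0, 255, 2)
            vectorized = total_energy(phi, img, g, mask, c1, c2, params)
            looped = naive_total_energy(phi, img, g, mask, c1, c2, params)
            assert vectorized == pytest.approx(looped, rel=1e-12)


class TestGradientFlow:
    def test_near_zero_on_sdf_with_constant_image(self):
        """Every term has a zero: data (c1=c2=I), penalty (|grad|=1), area (v=0)."""
        phi = disk_sdf((48, 48), (23.5, 23.5), 12.0)
        img = np.full((48, 48), 120.0)
        g = edge_indicator(img)
        q = gradient_flow(phi, img, g, np.ones((48, 48), bool), 120.0, 120.0, AlgoParams())
        rr, cc = np.mgrid[0:48, 0:48]
        d = np.sqrt((rr - 23.5) ** 2 + (cc - 23.5) ** 2)
        away_from_kink = (d > 3) & (rr > 4) & (rr < 43) & (cc > 4) & (cc < 43)
        assert np.abs(q[away_from_kink]).max() < 0.05

    def test_penalty_drives_gradient_toward_unity(self):
        """|grad phi| = 2 gives a positive diffusion rate (1 - 1/2) > 0."""
        phi = 2.0 * disk_sdf((48, 48), (23.5, 23.5), 12.0)
        img = np.full((48, 48), 120.0)
        g = edge_indicator(img)
        q = gradient_flow(phi, img, g, np.ones((48, 48), bool), 120.0, 120.0, AlgoParams())
        rr, cc = np.mgrid[0:48, 0:48]
        d = np.sqrt((rr - 23.5) ** 2 + (cc - 23.5) ** 2)
        ring = np.abs(d - 8.0) < 1.0
        assert (q[ring] > 0).all()

    def test_data_term_pushes_matching_pixels_inward(self):
        """A pixel matching c1 better than c2 must get a negative update."""
        img = np.full((9, 9), 60.0)
        img[4, 4] = 200.0
        phi = np.full((9, 9), 6.0)
        g = edge_indicator(img)
        q = gradient_flow(phi, img, g, np.ones((9, 9), bool), 200.0, 60.0, AlgoParams())
        assert q[4, 4] < 0

    def test_matches_energy_finite_difference(self, bright_square):
        """-Q equals the variation of the discrete energy at fixed c1, c2."""
        img, _ = bright_square
        g = edge_indicator(img)
        mask = np.ones(img.shape, bool)
        params = AlgoParams()
        result = evolve_pass(img, g, mask, params)
        phi, c1, c2 = result.phi_final, result.c1, result.c2
        q = gradient_flow(phi, img, g, mask, c1, c2, params)
        rng = np.random.default_rng(17)
        h = 1e-3
        for _ in range(5):
            i = int(rng.integers(2, img.shape[0] - 2))
            j = int(rng.integers(2, img.shape[1] - 2))
            plus, minus = phi.copy(), phi.copy()
            plus[i, j] += h
            minus[i, j] -= h
            de = (
                total_energy(plus, img, g, mask, c1, c2, params)
                - total_energy(minus, img, g, mask, c1, c2, params)
            ) / (2 * h)
            denom = max(abs(de), abs(q[i, j]), 1e-12)
            assert abs(de + q[i, j]) / denom < 1e-3


class TestEvolvePass:
    def test_recovers_bright_square(self, bright_square):
        img, truth = bright_square
        g = edge_indicator(img)
        result = evolve_pass(img, g, np.ones(img.shape, bool), AlgoParams())
        agreement = (result.inner_mask == truth).mean()
        assert agreement >= 0.95
        assert result.c1 == pytest.approx(200.0, abs=5.0)
        assert result.c2 == pytest.approx(50.0, abs=5.0)

    def test_constant_image_degenerates_immediately(self):
        img = np.full((16, 16), 77.0)
        result = evolve_pass(img, edge_indicator(img), np.ones((16, 16), bool), AlgoParams())
        assert result.terminated_by == Termination.DEGENERATE_EMPTY_INNER
        assert result.n_iters == 0
        assert not result.inner_mask.any()
        assert result.outer_mask.all()

    def test_partition_is_exact(self, bright_square):
        img, _ = bright_square
        g = edge_indicator(img)
        mask = np.zeros(img.shape, bool)
        mask[10:54, 10:54] = True
        result = evolve_pass(img, g, mask, AlgoParams())
        assert not (result.inner_mask & result.outer_mask).any()
        assert ((result.inner_mask | result.outer_mask) == mask).all()

    def test_deterministic_rerun_is_bit_identical(self, bright_square):
        img, _ = bright_square
        g = edge_indicator(img)
        mask = np.ones(img.shape, bool)
        a = evolve_pass(img, g, mask, AlgoParams())
        b = evolve_pass(img, g, mask, AlgoParams())
        assert np.array_equal(a.phi_final, b.phi_final)
        assert np.array_equal(a.inner_mask, b.inner_mask)
        assert a.energy_trace == b.energy_trace
        assert a.n_iters == b.n_iters

    def test_energy_descends_on_clean_phantom(self, bright_square):
        img, _ = bright_square
        g = edge_indicator(img)
        result = evolve_pass(img, g, np.ones(img.shape, bool), AlgoParams())
        trace = np.asarray(result.energy_trace)
        assert len(trace) > 1
        increases = np.diff(trace)
        assert increases.max() <= 0.01 * trace[0]
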