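import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itwater import (
    GridDensity,
    MixtureDensity,
    QuadratureConvergenceError,
    QuadratureSpec,
    evaluate,
    gradient,
    integrate,
    momentum_conjugate,
    read_cube,
    shannon_entropy,
    write_cube,
)

GAUSS_S = 1.5 * math.log(2 * math.pi * math.e)  # 4.256816...


def dilated(mix: MixtureDensity, lam: float) -> MixtureDensity:
    return MixtureDensity.from_parts(
        mix.centers * lam, mix.sigmas * lam, mix.weights, space=mix.space
    )


class TestEvaluate:
    def test_peak_value_of_unit_gaussian(self, unit_gaussian):
        assert evaluate(unit_gaussian, [0.0, 0.0, 0.0]) == pytest.approx(
            (2 * math.pi) ** -1.5, rel=1e-12
        )

    def test_far_field_is_zero(self, unit_gaussian):
        assert evaluate(unit_gaussian, [50.0, 0.0, 0.0]) == pytest.approx(0.0, abs=1e-30)

    def test_mixture_is_sum_of_components(self):
        mix = MixtureDensity.from_parts([[0, 0, 0], [2, 0, 0]], [1.0, 0.5], [0.6, 0.4])
        a = MixtureDensity.from_parts([[0, 0, 0]], [1.0], [1.0])
        b = MixtureDensity.from_parts([[2, 0, 0]], [0.5], [1.0])
        p = [1.0, 0.3, -0.2]
        expected = 0.6 * evaluate(a, p) + 0.4 * evaluate(b, p)
        assert evaluate(mix, p) == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_points_rejected(self, unit_gaussian):
        with pytest.raises(ValueError):
            evaluate(unit_gaussian, [np.nan, 0, 0])

    def test_weights_must_normalize(self):
        with pytest.raises(ValueError):
            MixtureDensity(
                components=(
                    # hand-built component with weight 0.5 only
                    __import__("itwater").GaussianComponent((0, 0, 0), 1.0, 0.5),
                )
            )


class TestGradient:
    def test_zero_at_center_by_symmetry(self, unit_gaussian):
        g = gradient(unit_gaussian, [0.0, 0.0, 0.0])
        assert np.allclose(g, 0.0, atol=1e-15)

    def test_analytic_direction_and_magnitude(self):
        # Gaussian at (1,0,0): grad at origin points toward the center
        mix = MixtureDensity.from_parts([[1, 0, 0]], [1.0], [1.0])
        g = gradient(mix, [0.0, 0.0, 0.0])
        rho = evaluate(mix, [0.0, 0.0, 0.0])
        assert g[0] == pytest.approx(rho * 1.0, rel=1e-12)  # -(x-c)/sigma^2 * rho
        assert g[1] == pytest.approx(0.0, abs=1e-15)

    def test_grid_gradient_matches_analytic(self, rng):
        mix = MixtureDensity.from_parts([[0, 0, 0], [1.5, 0, 0]], [1.0, 0.8], [0.6, 0.4])
        ax = np.linspace(-6, 6, 81)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        vals = evaluate(mix, np.stack([X.ravel(), Y.ravel(), Z.ravel()], 1)).reshape(X.shape)
        grid = GridDensity(origin=[-6, -6, -6], spacing=[ax[1] - ax[0]] * 3, values=vals)
        pts = rng.uniform(-3, 3, size=(50, 3))
        dev = np.max(np.abs(gradient(mix, pts) - gradient(grid, pts)))
        # documented FD tolerance: second-order central differences at h=0.15
        assert dev < 1e-3


class TestMomentumConjugate:
    def test_width_conjugation_rule(self):
        mix = MixtureDensity.from_parts([[1, 2, 3]], [0.5], [1.0])
        gamma = momentum_conjugate(mix)
        assert gamma.space == "momentum"
        assert gamma.components[0].sigma == pytest.approx(1.0, rel=1e-15)
        assert gamma.components[0].center == (0.0, 0.0, 0.0)

    def test_weights_preserved_componentwise(self):
        mix = MixtureDensity.from_parts(
            [[0, 0, 0], [3, 0, 0], [0, 3, 0]], [0.4, 0.6, 1.1], [0.5, 0.3, 0.2]
        )
        gamma = momentum_conjugate(mix)
        assert np.allclose(gamma.weights, mix.weights)

    def test_conjugate_normalization_conserved(self):
        mix = MixtureDensity.from_parts([[0, 0, 0], [4, 1, 0]], [0.5, 1.2], [0.7, 0.3])
        mass = integrate("density", momentum_conjugate(mix)).value
        assert mass == pytest.approx(1.0, rel=1e-8)

    def test_momentum_input_rejected(self):
        mix = MixtureDensity.from_parts([[0, 0, 0]], [1.0], [1.0], space="momentum")
        with pytest.raises(ValueError):
            momentum_conjugate(mix)

    @pytest.mark.parametrize("sigma", [0.3, 1.0, 2.7])
    def test_conjugate_entropy_identity(self, sigma):
        """S_r + S_p = 3(1 + ln pi) for any single-Gaussian conjugate pair."""
        mix = MixtureDensity.from_parts([[0.5, -1, 2]], [sigma], [1.0])
        total = shannon_entropy(mix) + shannon_entropy(momentum_conjugate(mix))
        assert total == pytest.approx(3 * (1 + math.log(math.pi)), rel=1e-4)


class TestIntegrate:
    def test_unit_mass(self):
        mix = MixtureDensity.from_parts(
            [[0, 0, 0], [2, 1, 0], [-1, 0, 3]], [0.5, 1.0, 1.5], [0.2, 0.5, 0.3]
        )
        assert integrate("density", mix).value == pytest.approx(1.0, rel=1e-8)

    def test_density_squared_closed_form(self, unit_gaussian):
        res = integrate("density^2", unit_gaussian)
        assert res.value == pytest.approx((4 * math.pi) ** -1.5, rel=1e-6)

    def test_refinement_improves_entropy_vs_fine_oracle(self):
        mix = MixtureDensity.from_parts(
            [[0, 0, 0], [2.5, 0, 0], [0, 2.5, 0]], [0.6, 0.9, 1.2], [0.3, 0.3, 0.4]
        )
        oracle = integrate(
            "density*log(density)", mix, QuadratureSpec(base_points_per_axis=160)
        ).value
        coarse = integrate(
            "density*log(density)",
            mix,
            QuadratureSpec(base_points_per_axis=16, refinement_levels=1, tolerance=1.0),
        )
        fine = integrate(
            "density*log(density)",
            mix,
            QuadratureSpec(base_points_per_axis=32, refinement_levels=1, tolerance=1.0),
        )
        assert abs(fine.value - oracle) < abs(coarse.value - oracle) / 2

    def test_nonconvergence_raises_with_estimates(self, unit_gaussian):
        quad = QuadratureSpec(base_points_per_axis=16, refinement_levels=1, tolerance=1e-16)
        with pytest.raises(QuadratureConvergenceError) as exc:
            integrate("density*log(density)", unit_gaussian, quad)
        assert len(exc.value.estimates) == 2

    def test_custom_functional_callable(self, unit_gaussian):
        res = integrate(lambda rho: rho * rho, unit_gaussian)
        assert res.value == pytest.approx((4 * math.pi) ** -1.5, rel=1e-6)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(lam=st.floats(0.5, 3.0))
    def test_entropy_scaling_law(self, lam):
        """Dilating a mixture by lambda shifts S by exactly 3 ln(lambda)."""
        mix = MixtureDensity.from_parts([[0, 0, 0], [2, 0, 0]], [0.7, 1.1], [0.5, 0.5])
        s0 = shannon_entropy(mix)
        s1 = shannon_entropy(dilated(mix, lam))
        assert s1 - s0 == pytest.approx(3 * math.log(lam), abs=1e-5)


class TestCubeIO:
    @staticmethod
    def _gaussian_grid(n=61, half=6.0):
        ax = np.linspace(-half, half, n)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        vals = (2 * np.pi) ** -1.5 * np.exp(-0.5 * (X**2 + Y**2 + Z**2))
        return GridDensity(
            origin=[-half] * 3, spacing=[ax[1] - ax[0]] * 3, values=vals
        ).normalized()

    def test_roundtrip_identical_values(self, tmp_path):
        grid = self._gaussian_grid(n=31)
        path = tmp_path / "g.cube"
        write_cube(grid, path)
        back = read_cube(path)
        assert np.array_equal(back.values, grid.values)
        assert np.allclose(back.origin, grid.origin)
        assert np.allclose(back.spacing, grid.spacing)

    def test_gaussian_cube_entropy_within_one_percent(self, tmp_path):
        path = tmp_path / "g.cube"
        write_cube(self._gaussian_grid(), path)
        s = shannon_entropy(read_cube(path))
        assert abs(s - GAUSS_S) / GAUSS_S < 0.01

    def test_angstrom_sign_convention(self, tmp_path):
        # negative voxel count flags angstrom axis vectors per the CUBE spec
        grid = self._gaussian_grid(n=21)
        path = tmp_path / "ang.cube"
        bohr_per_ang = __import__("itwater.units", fromlist=["BOHR_PER_ANGSTROM"]).BOHR_PER_ANGSTROM
        with path.open("w") as fh:
            fh.write("comment\ncomment\n")
            fh.write(f"0 {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}\n")
            for d in range(3):
                step_ang = grid.spacing[d] / bohr_per_ang
                axis = [0.0, 0.0, 0.0]
                axis[d] = step_ang
                fh.write(f"-{grid.shape[d]} {axis[0]} {axis[1]} {axis[2]}\n")
            for v in grid.values.ravel():
                fh.write(f"{v:.16E}\n")
        back = read_cube(path)
        assert np.allclose(back.spacing, grid.spacing, rtol=1e-12)
        assert np.array_equal(back.values, grid.values)

    def test_negative_voxels_clamped_and_renormalized(self, tmp_path):
        grid = self._gaussian_grid(n=21)
        vals = grid.values.copy()
        vals[0, 0, 0] = -0.5
        path = tmp_path / "neg.cube"
        write_cube(GridDensity(grid.origin, grid.spacing, np.abs(vals)), path)
        # flip the first voxel on the first data line negative, keep the rest
        text = path.read_text().splitlines()
        body_start = 6
        tokens = text[body_start].split()
        tokens[0] = f"{-0.5:.16E}"
        text[body_start] = " ".join(tokens)
        path.write_text("\n".join(text) + "\n")
        back = read_cube(path)
        assert np.all(back.values >= 0)
        assert back.total_mass() == pytest.approx(1.0)

    def test_malformed_header_reports_line(self, tmp_path):
        path = tmp_path / "bad.cube"
        path.write_text("c\nc\nnot_a_number 0 0 0\n1 1 0 0\n1 0 1 0\n1 0 0 1\n")
        with pytest.raises(ValueError, match=":3:"):
            read_cube(path)
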