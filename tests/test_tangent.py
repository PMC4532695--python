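import numpy as np
import pytest

from lileychaos import (
    augmented_dimension,
    augmented_rhs,
    benettin_spectrum,
    compute_spectrum,
    diagonal_linear,
    lorenz63,
)
from lileychaos.tangent import pack_augmented, unpack_augmented


class TestAugmentedSystem:
    @pytest.mark.parametrize("n,k,expected", [(10, 3, 43), (10, 10, 120), (3, 2, 11)])
    def test_dimension_identity(self, n, k, expected):
        assert augmented_dimension(n, k) == expected

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            augmented_dimension(10, 11)
        with pytest.raises(ValueError):
            augmented_dimension(10, 0)

    def test_pack_unpack_round_trip(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(10)
        E, _ = np.linalg.qr(rng.standard_normal((10, 3)))
        nu = rng.standard_normal(3)
        z = pack_augmented(y, E, nu)
        assert len(z) == 43
        y2, E2, nu2 = unpack_augmented(z, 10, 3)
        assert np.array_equal(y, y2) and np.array_equal(E, E2) and np.array_equal(nu, nu2)

    def test_diagonal_system_accumulator_rates_exact(self):
        # standard basis vectors are invariant for a diagonal Jacobian, so
        # the accumulator derivatives are exactly the diagonal rates
        rates = np.array([-1.0, -2.0, -3.0])
        sysd = diagonal_linear(rates)
        y = np.array([0.5, -0.2, 0.1])
        E = np.eye(3)
        z = pack_augmented(y, E, np.zeros(3))
        dz = augmented_rhs(z, sysd, k=3)
        _, dE, dnu = unpack_augmented(dz, 3, 3)
        assert np.allclose(dnu, rates)
        assert np.allclose(dE, 0.0)

    def test_rejects_non_orthonormal_frame(self):
        sysd = diagonal_linear([-1.0, -2.0, -3.0])
        E = np.eye(3)
        E[0, 1] = 0.1  # deliberate drift far beyond tolerance
        z = pack_augmented(np.ones(3), E, np.zeros(3))
        with pytest.raises(ValueError, match="orthonormal"):
            augmented_rhs(z, sysd, k=3)

    def test_first_order_orthonormality_preservation(self):
        # d/dt of the Gram matrix vanishes when the frame is orthonormal
        sysl = lorenz63()
        rng = np.random.default_rng(1)
        E, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        z = pack_augmented(np.array([1.0, 2.0, 15.0]), E, np.zeros(3))
        dz = augmented_rhs(z, sysl, k=3)
        _, dE, _ = unpack_augmented(dz, 3, 3)
        gram_dot = dE.T @ E + E.T @ dE
        assert np.max(np.abs(gram_dot)) < 1e-10


class TestSpectraOnBenchmarks:
    @pytest.mark.parametrize("method", ["continuous", "discrete"])
    def test_diagonal_spectrum_recovery(self, method):
        sysd = diagonal_linear([-1.0, -2.0, -3.0])
        res = compute_spectrum(sysd, k=3, t_transient=0.0, t_run=2000.0,
                               seed=1, method=method, dt_renorm=1.0)
        assert np.allclose(res.exponents, [-1000.0, -2000.0, -3000.0], rtol=1e-3)
        assert res.method == method

    def test_partial_spectrum_picks_largest_rates(self):
        rng = np.random.default_rng(9)
        rates = -rng.uniform(0.05, 3.0, size=10)
        sysd = diagonal_linear(rates)
        res = compute_spectrum(sysd, k=3, t_transient=0.0, t_run=5000.0,
                               seed=2, method="continuous", dt_renorm=1.0)
        top3 = np.sort(rates)[::-1][:3] * 1000.0
        assert np.allclose(res.exponents, top3, rtol=0.01, atol=0.5)

    def test_exponents_sorted_descending_and_unit_conversion(self):
        sysd = diagonal_linear([-3.0, -1.0, -2.0])  # unsorted input rates
        res = compute_spectrum(sysd, k=3, t_transient=0.0, t_run=1000.0,
                               seed=0, method="discrete", dt_renorm=1.0)
        assert np.all(np.diff(res.exponents) <= 0)
        assert res.exponents[0] == pytest.approx(-1000.0, rel=1e-3)

    def test_cross_method_agreement_on_lorenz(self):
        sysl = lorenz63()
        kw = dict(k=3, t_transient=50.0, t_run=2000.0, seed=3, dt_renorm=0.5)
        rc = compute_spectrum(sysl, method="continuous", **kw)
        rd = compute_spectrum(sysl, method="discrete", **kw)
        for a, b in zip(rc.exponents, rd.exponents):
            if abs(b) > 1.0:
                assert a == pytest.approx(b, rel=0.02)
            else:
                assert a == pytest.approx(b, abs=0.5)

    def test_full_spectrum_sum_matches_jacobian_trace(self):
        # Lorenz has constant trace -(sigma+1+beta); the identity holds for
        # the time-averaged trace along the same trajectory within 1%
        sysl = lorenz63()
        res = benettin_spectrum(sysl, k=3, t_transient=50.0, t_run=2000.0,
                                dt_renorm=0.5, seed=4)
        assert res.mean_trace_per_s == pytest.approx(-(10.0 + 1.0 + 8.0 / 3.0) * 1000.0,
                                                     rel=1e-6)
        assert res.exponents.sum() == pytest.approx(res.mean_trace_per_s, rel=0.01)

    def test_orthonormality_maintained_at_checkpoints(self):
        sysl = lorenz63()
        res = compute_spectrum(sysl, k=3, t_transient=50.0, t_run=500.0,
                               seed=5, method="continuous", dt_renorm=0.5)
        assert res.max_ortho_drift < 1e-6


class TestContractsAndDeterminism:
    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrum(diagonal_linear([-1.0, -2.0]), k=3)

    def test_bad_method_rejected(self, standard_params):
        with pytest.raises(ValueError):
            compute_spectrum(standard_params, method="magic")

    def test_zero_exponent_on_liley_limit_cycle(self, standard_params):
        # any bounded non-equilibrium attractor of an autonomous flow has a
        # zero exponent along the flow direction
        res = compute_spectrum(standard_params, k=2, t_transient=10_000.0,
                               t_run=30_000.0, seed=6, method="continuous")
        assert not res.diverged
        assert np.min(np.abs(res.exponents)) < 0.5

    def test_seed_determinism_bitwise(self, standard_params):
        kw = dict(k=3, t_transient=1000.0, t_run=3000.0, seed=7, method="discrete")
        r1 = compute_spectrum(standard_params, **kw)
        r2 = compute_spectrum(standard_params, **kw)
        assert np.array_equal(r1.exponents, r2.exponents)
        assert np.array_equal(r1.history_lambdas, r2.history_lambdas)

    def test_result_json_round_trip_fields(self, tmp_path):
        res = compute_spectrum(diagonal_linear([-1.0, -2.0, -3.0]), k=2,
                               t_transient=0.0, t_run=100.0, seed=8,
                               method="discrete", dt_renorm=1.0)
        import json

        doc = json.loads(res.to_json(tmp_path / "lyap.json"))
        assert doc["k"] == 2
        assert doc["method"] == "discrete"
        assert len(doc["exponents_per_s"]) == 2
        assert doc["history"][0].keys() == {"t_ms", "lambdas"}

    def test_divergence_flagged(self):
        sysd = diagonal_linear([0.05, -1.0])  # unstable direction blows up
        res = compute_spectrum(sysd, k=2, t_transient=0.0, t_run=2000.0,
                               seed=9, method="discrete", dt_renorm=1.0,
                               divergence_bound=1e3)
        assert res.diverged
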