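import numpy as np
import pytest

from vffr import ParameterError, SobolSpec, run_vffr_sensitivity, sobol_indices
from vffr.errors import DegenerateOutputError
from vffr.sensitivity import saltelli_sample, steady_vffr_model


def unit_spec(k=3, n=256, seed=0):
    return SobolSpec(
        ranges={f"x{i}": (0.0, 1.0) for i in range(k)}, n_base=n, seed=seed
    )


def evaluate(design, f):
    f_ab = np.stack([f(design.AB[i]) for i in range(design.AB.shape[0])])
    return f(design.A), f(design.B), f_ab


class TestSaltelliDesign:
    def test_row_count_identity(self):
        spec = SobolSpec(
            ranges={"a": (0, 1), "b": (0, 1), "c": (0, 1), "d": (0, 1)},
            n_base=256,
        )
        design = saltelli_sample(spec)
        assert design.all_rows().shape == (256 * 6, 4)

    def test_seeded_determinism(self):
        d1 = saltelli_sample(unit_spec(seed=9))
        d2 = saltelli_sample(unit_spec(seed=9))
        assert np.array_equal(d1.A, d2.A) and np.array_equal(d1.B, d2.B)
        assert np.array_equal(d1.AB, d2.AB)

    def test_degenerate_ranges_collapse_rows(self):
        spec = SobolSpec(ranges={"a": (2.0, 2.0), "b": (5.0, 5.0)}, n_base=64)
        design = saltelli_sample(spec)
        assert np.allclose(design.all_rows(), [2.0, 5.0])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            SobolSpec(ranges={"a": (0, 1)}, n_base=100)  # not a power of two
        with pytest.raises(ParameterError):
            SobolSpec(ranges={"a": (1, 0)})


class TestIndexEstimators:
    def test_single_input_model(self):
        spec = unit_spec(k=3, n=1024)
        design = saltelli_sample(spec)
        f = lambda x: x[:, 0]
        res = sobol_indices(spec.names, *evaluate(design, f))
        assert res.s_main[0] == pytest.approx(1.0, abs=0.05)
        assert res.s_total[0] == pytest.approx(1.0, abs=0.05)
        assert np.all(np.abs(res.s_main[1:]) < 0.05)
        assert np.all(np.abs(res.s_total[1:]) < 0.05)

    def test_additive_model_analytic_fractions(self):
        # variance fractions c_i^2 / sum c_j^2 for Y = x1 + 2 x2 + 3 x3
        spec = unit_spec(k=3, n=1024, seed=3)
        design = saltelli_sample(spec)
        f = lambda x: x[:, 0] + 2 * x[:, 1] + 3 * x[:, 2]
        res = sobol_indices(spec.names, *evaluate(design, f))
        expected = np.array([1.0, 4.0, 9.0]) / 14.0
        assert np.max(np.abs(res.s_main - expected)) < 0.03
        assert np.max(np.abs(res.s_total - expected)) < 0.03

    def test_zero_variance_raises(self):
        spec = unit_spec(k=2, n=64)
        design = saltelli_sample(spec)
        f = lambda x: np.ones(x.shape[0])
        with pytest.raises(DegenerateOutputError):
            sobol_indices(spec.names, *evaluate(design, f))

    def test_total_dominates_main_within_bootstrap_error(self):
        spec = unit_spec(k=3, n=1024, seed=11)
        design = saltelli_sample(spec)
        f = lambda x: x[:, 0] * x[:, 1] + x[:, 2]  # interacting model
        res = sobol_indices(spec.names, *evaluate(design, f))
        sd_main = (res.s_main_ci[:, 1] - res.s_main_ci[:, 0]) / (2 * 1.96)
        assert np.all(res.s_total >= res.s_main - 3 * sd_main)
        assert res.s_main.sum() <= 1 + 3 * sd_main.sum()

    def test_estimate_converges_with_n(self):
        # S_ref for Y = x1 + x1 * x2 on U(0,1)^2 via large double-loop MC
        rng = np.random.default_rng(0)
        M = 1000
        x1 = rng.uniform(size=M)
        inner = rng.uniform(size=(M, M))
        y_cond = x1[:, None] * (1 + inner)  # E[Y | x1] = 1.5 x1
        v_total = (rng.uniform(size=10**6) * (1 + rng.uniform(size=10**6))).var()
        s_ref = y_cond.mean(axis=1).var() / v_total
        errs = []
        for n in (256, 4096):
            spec = SobolSpec(ranges={"x1": (0, 1), "x2": (0, 1)}, n_base=n, seed=2)
            design = saltelli_sample(spec)
            f = lambda x: x[:, 0] * (1 + x[:, 1])
            res = sobol_indices(spec.names, *evaluate(design, f))
            errs.append(abs(res.s_main[0] - s_ref))
        assert errs[1] < errs[0] + 0.01


class TestVffrSensitivity:
    def test_default_ranges_ranking_and_pa_insensitivity(self):
        res = run_vffr_sensitivity(SobolSpec(n_base=1024, seed=4))
        assert res.ranking[0] == "R_cmv"
        assert res.s_main[-1] < 0.05  # pa_mean
        assert res.s_total[-1] < 0.05
        assert 0 <= res.total_interaction_fraction < 0.2

    def test_degenerate_lesion_ranges_raise(self):
        spec = SobolSpec(
            ranges={"R_cmv": (5, 40), "z1": (0, 0), "z2": (0, 0),
                    "pa_mean": (70, 110)},
            n_base=64,
        )
        with pytest.raises(DegenerateOutputError):
            run_vffr_sensitivity(spec)

    def test_degenerate_resistance_has_no_main_effect(self):
        spec = SobolSpec(
            ranges={"R_cmv": (20, 20), "z1": (0, 5), "z2": (0, 2),
                    "pa_mean": (70, 110)},
            n_base=1024,
        )
        res = run_vffr_sensitivity(spec)
        assert abs(res.s_main[0]) < 0.05

    def test_vectorized_model_matches_scalar_solver(self, rng):
        from vffr import LesionCharacteristic, steady_vffr

        x = np.column_stack([
            rng.uniform(5, 40, 20), rng.uniform(0, 5, 20),
            rng.uniform(0, 2, 20), rng.uniform(70, 110, 20),
        ])
        vec = steady_vffr_model(x)
        for row, v in zip(x, vec):
            ref = steady_vffr(row[3], LesionCharacteristic(row[1], row[2]), row[0])
            assert v == pytest.approx(ref.vffr, rel=1e-12)
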