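import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nirchem as nc
from nirchem.spectra_io import SpectraSet, make_meta
from nirchem.preprocess import PipelineSpec, Step, _APPROACHES


def spectra_from(X, w=None, replicates=True):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if w is None:
        w = np.arange(p, dtype=float) + 4000.0
    meta = make_meta(
        [f"s{i}" for i in range(n)], ["sp"] * n,
        replicates=[1] * n if replicates else None,
    )
    return SpectraSet(wavenumbers=w, absorbance=X, meta=meta)


# ---------------------------------------------------------------- cut_region

def test_cut_above_max_is_identity(rng):
    s = spectra_from(rng.normal(size=(2, 10)))
    out = nc.cut_region(s, 1e6)
    np.testing.assert_array_equal(out.absorbance, s.absorbance)


def test_cut_default_grid_9000_keeps_2480_points():
    grid = nc.make_grid(nc.default_truffle_config())
    expected = int(np.sum(grid <= 9000.0))  # direct enumeration
    s = spectra_from(np.zeros((1, grid.size)), w=grid)
    assert nc.cut_region(s, 9000.0).n_points == expected == 2480


def test_cut_6000_keeps_only_low_wavenumbers():
    grid = nc.make_grid(nc.default_truffle_config())
    s = spectra_from(np.zeros((1, grid.size)), w=grid)
    out = nc.cut_region(s, 6000.0)
    assert out.wavenumbers.max() <= 6000.0
    assert out.n_points == int(np.sum(grid <= 6000.0))


def test_cut_below_axis_min_errors(rng):
    s = spectra_from(rng.normal(size=(1, 5)))
    with pytest.raises(ValueError, match="nothing retained"):
        nc.cut_region(s, 100.0)


# ------------------------------------------------------------------ smoothing

def test_smooth_truncated_window_means():
    s = spectra_from([[1, 2, 3, 4, 5, 6, 7]])
    out = nc.smooth_moving_average(s, span=5)
    np.testing.assert_allclose(out.absorbance[0], [2, 2.5, 3, 4, 5, 5.5, 6])


def test_smooth_constant_invariance(rng):
    s = spectra_from(np.full((3, 11), 2.5))
    out = nc.smooth_moving_average(s, span=5)
    np.testing.assert_allclose(out.absorbance, s.absorbance)


def test_smooth_preserves_linear_trend_interior():
    s = spectra_from([np.arange(20.0)])
    out = nc.smooth_moving_average(s, span=5)
    np.testing.assert_allclose(out.absorbance[0][2:-2], np.arange(20.0)[2:-2])


def test_smooth_even_span_rejected(rng):
    s = spectra_from(rng.normal(size=(1, 10)))
    with pytest.raises(ValueError, match="odd"):
        nc.smooth_moving_average(s, span=4)


# ------------------------------------------------------------------------ MSC

def test_msc_identity_when_rows_equal_reference(rng):
    r = rng.normal(1.0, 0.3, size=40)
    s = spectra_from(np.tile(r, (3, 1)))
    out, fit = nc.msc(s)
    np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-10)
    np.testing.assert_allclose(fit.intercepts, 0, atol=1e-10)
    np.testing.assert_allclose(fit.slopes, 1, atol=1e-10)


def test_msc_inverts_affine_rows_exactly(rng):
    r = rng.normal(1.0, 0.3, size=50)
    s = spectra_from([3.0 + 2.0 * r])
    out, fit = nc.msc(s, reference=r)
    np.testing.assert_allclose(out.absorbance[0], r, atol=1e-10)
    assert fit.intercepts[0] == pytest.approx(3.0, abs=1e-10)
    assert fit.slopes[0] == pytest.approx(2.0, abs=1e-10)


def test_msc_matches_normal_equations_oracle(rng):
    X = rng.normal(0.5, 0.2, size=(3, 50))
    r = X.mean(axis=0)
    out, fit = nc.msc(spectra_from(X))
    # independent oracle: per-row normal equations
    design = np.column_stack([np.ones_like(r), r])
    for i in range(3):
        a, b = np.linalg.solve(design.T @ design, design.T @ X[i])
        assert fit.intercepts[i] == pytest.approx(a, abs=1e-10)
        assert fit.slopes[i] == pytest.approx(b, abs=1e-10)
        np.testing.assert_allclose(out.absorbance[i], (X[i] - a) / b, atol=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    a=st.floats(-5, 5),
    b=st.floats(-4, 4).filter(lambda v: abs(v) > 1e-3),
    seed=st.integers(0, 1000),
)
def test_msc_exactness_property(a, b, seed):
    """Any affine transform a + b*r of the reference is restored to r."""
    r = np.random.default_rng(seed).normal(0.5, 0.2, size=30)
    out, _ = nc.msc(spectra_from([a + b * r]), reference=r)
    np.testing.assert_allclose(out.absorbance[0], r, atol=1e-8)


def test_msc_degenerate_reference_errors():
    with pytest.raises(ValueError, match="degenerate"):
        nc.msc(spectra_from(np.ones((2, 10))), reference=np.full(10, 3.0))


# ------------------------------------------------------------------------ SNV

def test_snv_rows_centred_and_scaled(rng):
    out = nc.snv(spectra_from(rng.normal(2.0, 3.0, size=(4, 30))))
    np.testing.assert_allclose(out.absorbance.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(out.absorbance.std(axis=1), 1, atol=1e-12)


def test_snv_affine_invariance(rng):
    x = rng.normal(size=30)
    out = nc.snv(spectra_from([x, 4.0 - 2.5 * x]))
    np.testing.assert_allclose(out.absorbance[0], -out.absorbance[1], atol=1e-10)


def test_snv_matches_direct_formula(rng):
    X = rng.normal(size=(4, 30))
    out = nc.snv(spectra_from(X))
    expected = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
    np.testing.assert_allclose(out.absorbance, expected, atol=1e-12)


def test_snv_zero_variance_row_errors():
    with pytest.raises(ValueError, match="zero-variance"):
        nc.snv(spectra_from(np.ones((1, 10))))


# ----------------------------------------------------------------- derivative

def test_derivative_of_constant_is_zero():
    out = nc.derivative(spectra_from(np.full((2, 10), 3.3)), order=1)
    np.testing.assert_allclose(out.absorbance, 0, atol=1e-12)


def test_second_derivative_of_line_is_zero():
    w = np.arange(10, dtype=float)
    out = nc.derivative(spectra_from([2 * w + 1], w=w), order=2)
    np.testing.assert_allclose(out.absorbance, 0, atol=1e-10)


def test_derivative_quadratic_matches_analytic():
    w = np.arange(4000.0, 4030.0)  # unit spacing
    s = spectra_from([w**2], w=w)
    d1 = nc.derivative(s, order=1).absorbance[0]
    np.testing.assert_allclose(d1[1:-1], 2 * w[1:-1], rtol=1e-12)
    d2 = nc.derivative(s, order=2).absorbance[0]
    np.testing.assert_allclose(d2, 2.0, rtol=1e-9)


def test_derivative_unequal_spacing_rejected(rng):
    w = np.array([1.0, 2.0, 4.0, 8.0])
    with pytest.raises(ValueError, match="equally spaced"):
        nc.derivative(spectra_from(rng.normal(size=(1, 4)), w=w), order=1)


def test_savitzky_golay_derivative_close_to_plain_on_smooth_signal():
    w = np.arange(4000.0, 4100.0)
    x = np.sin(w / 30.0)
    s = spectra_from([x], w=w)
    plain = nc.derivative(s, order=1).absorbance[0]
    sg = nc.derivative(s, order=1, savitzky_golay=True).absorbance[0]
    np.testing.assert_allclose(sg[5:-5], plain[5:-5], atol=2e-4)


# -------------------------------------------------------------------- detrend

def test_detrend_annihilates_line():
    w = np.linspace(4000, 5000, 30)
    out = nc.detrend(spectra_from([0.002 * w - 3.0], w=w), poly_order=1)
    np.testing.assert_allclose(out.absorbance, 0, atol=1e-10)


def test_detrend_residual_orthogonal_to_basis(rng):
    w = np.linspace(4000, 5000, 40)
    out = nc.detrend(spectra_from(rng.normal(size=(3, 40)), w=w), poly_order=1)
    design = np.column_stack([np.ones_like(w), w])
    coef, *_ = np.linalg.lstsq(design, out.absorbance.T, rcond=None)
    np.testing.assert_allclose(coef, 0, atol=1e-10)


def test_detrend_quadratic_matches_least_squares_oracle():
    w = np.linspace(0.0, 1.0, 25) + 4000.0
    x = (w - 4000.0) ** 2
    out = nc.detrend(spectra_from([x], w=w), poly_order=1)
    design = np.column_stack([np.ones_like(w), w])
    beta = np.linalg.solve(design.T @ design, design.T @ x)
    np.testing.assert_allclose(out.absorbance[0], x - design @ beta, atol=1e-8)


def test_detrend_idempotent(rng):
    w = np.linspace(4000, 9000, 50)
    s = spectra_from(rng.normal(size=(2, 50)), w=w)
    once = nc.detrend(s, poly_order=1)
    twice = nc.detrend(once, poly_order=1)
    np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-10)


def test_detrend_order_too_high_errors(rng):
    with pytest.raises(ValueError):
        nc.detrend(spectra_from(rng.normal(size=(1, 4))), poly_order=4)


# ------------------------------------------------------------------- bin_mean

def test_bin_block_means():
    out = nc.bin_mean(spectra_from([np.arange(1.0, 21.0)]), width=10)
    np.testing.assert_allclose(out.absorbance[0], [5.5, 15.5])


def test_bin_drops_trailing_block_and_preserves_mean_when_divisible(rng):
    X = rng.normal(size=(2, 40))
    out = nc.bin_mean(spectra_from(X), width=10)
    assert out.n_points == 4
    np.testing.assert_allclose(out.absorbance.mean(), X.mean(), atol=1e-12)
    out2 = nc.bin_mean(spectra_from(rng.normal(size=(1, 43))), width=10)
    assert out2.n_points == 4  # trailing 3 columns dropped


def test_bin_default_grid_gives_248_variables():
    grid = nc.make_grid(nc.default_truffle_config())
    s = spectra_from(np.zeros((1, grid.size)), w=grid)
    assert nc.bin_mean(nc.cut_region(s, 9000.0), width=10).n_points == 248


def test_bin_width_exceeding_columns_errors(rng):
    with pytest.raises(ValueError):
        nc.bin_mean(spectra_from(rng.normal(size=(1, 5))), width=6)


# --------------------------------------------------------- average_replicates

def test_average_replicates_mean_and_collapse(small_set):
    X = np.zeros((6, 20))
    X[0], X[1], X[2] = 0.0, 3.0, 6.0
    s = small_set.with_absorbance(X)
    out = nc.average_replicates(s)
    assert out.n_spectra == 2
    np.testing.assert_allclose(out.absorbance[0], 3.0)
    assert "replicate" not in out.meta.columns


def test_average_replicates_idempotent_on_identical_rows(small_set):
    X = np.tile(small_set.absorbance[0], (6, 1))
    out = nc.average_replicates(small_set.with_absorbance(X))
    np.testing.assert_allclose(out.absorbance[0], small_set.absorbance[0])


def test_average_replicates_inconsistent_species_errors(small_set):
    meta = small_set.meta.copy()
    meta.loc[1, "species"] = "other"
    s = SpectraSet(small_set.wavenumbers, small_set.absorbance, meta)
    with pytest.raises(ValueError, match="inconsistent species"):
        nc.average_replicates(s)


def test_average_replicates_75_samples(truffle_data):
    s, _ = truffle_data
    out = nc.average_replicates(s)
    assert out.n_spectra == 75


# ------------------------------------------------- pipelines / make_approach

def test_pipeline_msc_before_cut_rejected():
    with pytest.raises(ValueError, match="msc before cut"):
        PipelineSpec([Step("msc"), Step("cut", {"threshold": 9000.0})])
    # explicit override allows studying the wrong order
    PipelineSpec([Step("msc"), Step("cut", {"threshold": 9000.0})],
                 allow_unsafe_order=True)


def test_pipeline_terminal_steps_enforced():
    with pytest.raises(ValueError, match="terminal"):
        PipelineSpec([Step("bin", {"width": 10}), Step("msc")])
    with pytest.raises(ValueError, match="terminal"):
        PipelineSpec([Step("average_replicates"), Step("bin", {"width": 10})])


def test_pipeline_repeated_step_rejected():
    with pytest.raises(ValueError, match="repeated"):
        PipelineSpec([Step("snv"), Step("snv")])


@pytest.mark.parametrize(
    "approach, kinds",
    [
        ("i", ["cut", "msc"]),
        ("ii", ["cut", "msc", "derivative"]),
        ("iii", ["cut", "msc", "derivative"]),
        ("iv", ["cut", "msc", "detrend"]),
        ("v", ["cut", "smooth", "msc", "derivative"]),
        ("vi", ["cut", "smooth", "msc", "derivative"]),
        ("vii", ["cut", "smooth", "msc", "detrend"]),
    ],
)
def test_make_approach_step_order(approach, kinds):
    spec = nc.make_approach(approach)
    assert [s.kind for s in spec.steps] == kinds + ["bin", "average_replicates"]
    assert spec.steps[-2].params == {"width": 10}


def test_make_approach_parameters_match_design():
    assert nc.make_approach("ii").steps[2].params == {"order": 1}
    assert nc.make_approach("iii").steps[2].params == {"order": 2}
    assert nc.make_approach("iv").steps[2].params == {"poly_order": 1}
    assert nc.make_approach("vi").steps[0].params == {"threshold": 6000.0}
    for a in ("i", "ii", "iii", "iv", "v", "vii"):
        assert nc.make_approach(a).steps[0].params == {"threshold": 9000.0}
    for a in ("v", "vi", "vii"):
        assert nc.make_approach(a).steps[1].params == {"span": 5}


def test_make_approach_unknown_id_errors():
    with pytest.raises(ValueError, match="unknown approach"):
        nc.make_approach("viii")


def test_apply_pipeline_provenance_and_shapes(truffle_data):
    s, _ = truffle_data
    out = nc.apply_pipeline(s, nc.make_approach("i"))
    assert out.absorbance.shape == (75, 248)
    steps = [e["step"] for e in out.provenance]
    assert steps == ["cut", "msc", "bin", "average_replicates"]
    assert out.provenance[-1]["shape"] == [75, 248]


def test_operators_deterministic(truffle_data):
    s, _ = truffle_data
    a = nc.apply_pipeline(s, nc.make_approach("vii"))
    b = nc.apply_pipeline(s, nc.make_approach("vii"))
    np.testing.assert_array_equal(a.absorbance, b.absorbance)


def test_cut_then_msc_beats_msc_then_cut(truffle_data):
    """High-wavenumber offsets leak through MSC if the cut comes second."""
    s, _ = truffle_data
    good = nc.msc(nc.cut_region(s, 9000.0))[0]
    bad_full = nc.msc(s)[0]
    bad = nc.cut_region(bad_full, 9000.0)
    assert good.absorbance.var(axis=0).sum() < bad.absorbance.var(axis=0).sum()
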