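import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegtopo import (
    PipelineConfig,
    amplitude,
    assemble_features,
    betti_curve,
    heat_kernel,
    landscape,
    make_grid,
    persistence_entropy,
)
from eegtopo.vectorize import DiagramFeaturizer, feature_names


class TestLandscape:
    def test_single_tent_peak_and_feet(self, make_diagram):
        pd_obj = make_diagram([(0.0, 2.0, 1)])
        grid = np.linspace(0.0, 2.0, 101)  # contains t = 1 exactly
        layers = landscape(pd_obj, dim=1, n_layers=2, grid=grid)
        assert layers[0, 50] == pytest.approx(1.0)  # peak (d - b)/2 at (b + d)/2
        assert layers[0, 0] == 0.0 and layers[0, -1] == 0.0
        np.testing.assert_array_equal(layers[1], 0.0)

    def test_duplicate_pairs_fill_second_layer(self, make_diagram):
        pd_obj = make_diagram([(0.0, 2.0, 1), (0.0, 2.0, 1)])
        grid = np.linspace(0.0, 2.0, 50)
        layers = landscape(pd_obj, dim=1, n_layers=2, grid=grid)
        np.testing.assert_array_equal(layers[0], layers[1])

    def test_nested_tents_second_max(self, make_diagram):
        pd_obj = make_diagram([(0.0, 4.0, 1), (1.0, 3.0, 1)])
        grid = np.linspace(0.0, 4.0, 101)  # contains t = 2
        layers = landscape(pd_obj, dim=1, n_layers=2, grid=grid)
        at_two = np.argmin(np.abs(grid - 2.0))
        assert layers[0, at_two] == pytest.approx(2.0)
        assert layers[1, at_two] == pytest.approx(1.0)


class TestBettiCurve:
    def test_interval_counts(self, make_diagram):
        pd_obj = make_diagram([(0.0, 2.0, 0), (1.0, 3.0, 0)])
        grid = np.array([1.5, 2.5])
        np.testing.assert_array_equal(betti_curve(pd_obj, 0, grid), [2.0, 1.0])

    def test_empty_diagram_all_zero(self, make_diagram):
        pd_obj = make_diagram([(0.0, np.inf, 0)])
        grid = np.linspace(0, 1, 10)
        np.testing.assert_array_equal(betti_curve(pd_obj, 0, grid), 0.0)

    def test_matches_interval_stabbing_oracle(self, rng, make_diagram):
        b = rng.uniform(0, 1, 10)
        d = b + rng.uniform(0.01, 1, 10)
        pd_obj = make_diagram([(bi, di, 1) for bi, di in zip(b, d)], n_nodes=1)
        grid = make_grid(pd_obj, 100)
        curve = betti_curve(pd_obj, 1, grid)
        oracle = [sum(1 for bi, di in zip(b, d) if bi <= t < di) for t in grid]
        np.testing.assert_array_equal(curve, oracle)


class TestHeatKernel:
    def test_empty_diagram_zero_raster(self, make_diagram):
        pd_obj = make_diagram([(0.0, np.inf, 0)])
        raster = heat_kernel(pd_obj, 0, sigma=1.6, grid=np.linspace(0, 1, 20))
        np.testing.assert_array_equal(raster, 0.0)

    def test_sign_structure_and_antisymmetry(self, make_diagram):
        pd_obj = make_diagram([(0.2, 0.8, 1)], n_nodes=1)
        grid = np.linspace(0.0, 1.0, 50)
        raster = heat_kernel(pd_obj, 1, sigma=1.6, grid=grid)
        i = np.argmin(np.abs(grid - 0.2))
        j = np.argmin(np.abs(grid - 0.8))
        assert raster[i, j] > 0 and raster[j, i] < 0
        assert raster[i, j] == pytest.approx(-raster[j, i])
        assert np.abs(raster + raster.T).max() < 1e-9
        assert abs(raster.sum()) < 1e-9


class TestPersistenceEntropy:
    def test_equal_lifetimes_give_log_n(self, make_diagram):
        pd_obj = make_diagram([(0.0, 1.0, 1), (2.0, 3.0, 1)], n_nodes=1)
        assert persistence_entropy(pd_obj, 1) == pytest.approx(np.log(2))

    def test_single_pair_zero_entropy(self, make_diagram):
        assert persistence_entropy(make_diagram([(0.0, 5.0, 1)], n_nodes=1), 1) == 0.0

    def test_lifetimes_one_and_three(self, make_diagram):
        pd_obj = make_diagram([(0.0, 1.0, 1), (0.0, 3.0, 1)], n_nodes=1)
        expected = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        assert persistence_entropy(pd_obj, 1) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.5623, abs=1e-4)

    @given(c=st.sampled_from([0.1, 0.5, 1.0, 2.0, 10.0]), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, c, seed):
        from conftest import diagram as make_diagram

        rng = np.random.default_rng(seed)
        b = rng.uniform(0, 1, 6)
        d = b + rng.uniform(0.01, 1, 6)
        base = make_diagram([(bi, di, 1) for bi, di in zip(b, d)], n_nodes=1)
        scaled = make_diagram([(c * bi, c * di, 1) for bi, di in zip(b, d)], n_nodes=1)
        assert persistence_entropy(scaled, 1) == pytest.approx(
            persistence_entropy(base, 1), rel=1e-10
        )

    def test_upper_bound_log_npairs(self, rng, make_diagram):
        b = rng.uniform(0, 1, 7)
        d = b + rng.uniform(0.01, 1, 7)
        pd_obj = make_diagram([(bi, di, 1) for bi, di in zip(b, d)], n_nodes=1)
        assert persistence_entropy(pd_obj, 1) <= np.log(7) + 1e-12


class TestAmplitude:
    def test_zero_curve(self):
        grid = np.linspace(0, 1, 100)
        assert amplitude(np.zeros(100), 1, grid) == 0.0

    def test_constant_curve_riemann_sum(self):
        grid = np.linspace(0.0, 2.0, 100)
        values = np.full(100, 3.0)
        # L1 norm of a constant c over range R is c*R, up to one bin width
        assert amplitude(values, 1, grid) == pytest.approx(6.0, rel=0.02)

    def test_tent_area_closed_form(self, make_diagram):
        pd_obj = make_diagram([(0.0, 2.0, 1)], n_nodes=1)
        grid = make_grid(pd_obj, 100)
        layer = landscape(pd_obj, 1, 1, grid)
        # area of the tent over (0, 2) is (d - b)^2 / 4 = 1
        assert amplitude(layer, 1, grid) == pytest.approx(1.0, rel=0.02)

    def test_betti_amplitude_monotone_under_insertion(self, rng, make_diagram):
        b = rng.uniform(0, 1, 5)
        d = b + rng.uniform(0.05, 1, 5)
        pairs = [(bi, di, 1) for bi, di in zip(b, d)]
        small = make_diagram(pairs, n_nodes=1)
        grown = make_diagram(pairs + [(0.2, 0.9, 1)], n_nodes=1)
        grid = make_grid(small, 100)
        assert amplitude(betti_curve(grown, 1, grid), 1, grid) >= amplitude(
            betti_curve(small, 1, grid), 1, grid
        )


class TestAssembleFeatures:
    def test_canonical_layout_has_22_amplitudes(self, make_diagram):
        names = feature_names()
        assert len(names) == 22
        assert names[0] == "PL_p1_layers1_H0" and names[-1] == "PE_H1"
        pd_obj = make_diagram([(0, 1, 0), (0.2, 0.8, 1), (0, np.inf, 0)])
        vec = assemble_features(pd_obj, band_index=3)
        assert vec.shape == (23,)
        assert vec[-1] == 3.0
        assert np.isfinite(vec).all()

    def test_empty_diagram_all_zero(self, make_diagram):
        pd_obj = make_diagram([(0.0, np.inf, 0)])
        vec = assemble_features(pd_obj, band_index=1)
        np.testing.assert_array_equal(vec[:-1], 0.0)

    def test_h1_empty_diagram_zeroes_h1_slots(self, make_diagram):
        pd_obj = make_diagram([(0, 1, 0), (0, 2, 0), (0, np.inf, 0)])
        vec = assemble_features(pd_obj, band_index=1)
        names = feature_names()
        h1_slots = [i for i, n in enumerate(names) if n.endswith("H1")]
        h0_slots = [i for i, n in enumerate(names) if n.endswith("H0")]
        np.testing.assert_array_equal(vec[h1_slots], 0.0)
        assert np.any(vec[h0_slots] != 0.0)

    def test_featurizer_transform_shape(self, make_diagram):
        diagrams = [
            (make_diagram([(0, 1, 0), (0.1, 0.9, 1)]), b) for b in (1, 2, 3)
        ]
        X = DiagramFeaturizer().fit().transform(diagrams)
        assert X.shape == (3, 23)
        np.testing.assert_array_equal(X[:, -1], [1, 2, 3])


@given(seed=st.integers(0, 1000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_landscape_layer_ordering(seed):
    from conftest import diagram  # reuse the builder directly

    rng = np.random.default_rng(seed)
    b = rng.uniform(0, 1, 8)
    d = b + rng.uniform(0.01, 1, 8)
    pd_obj = diagram([(bi, di, 1) for bi, di in zip(b, d)], n_nodes=1)
    grid = make_grid(pd_obj, 80)
    layers = landscape(pd_obj, 1, 4, grid)
    assert np.all(layers[:-1] >= layers[1:] - 1e-12)
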