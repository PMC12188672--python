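"""Truncated-cone volume, radii, height, error propagation, distance matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentgeo import (
    ConeConfig,
    ConeModel,
    TimeSeries,
    assemble_distance_matrix,
    cone_height,
    cone_height_error,
    estimate_pair,
    interaction_volume,
    radius_fallback,
    radius_from_te_series,
)
from latentgeo.cone import ZERO_DERIVATIVE_TOL
from latentgeo.exceptions import (
    GeometryError,
    InsufficientDataError,
    ValidationError,
)
from latentgeo.fixtures import (
    SPECIES,
    load_fixture,
)
from latentgeo.infoflow import TEChunkSeries
from latentgeo.timeseries import SplineCurve


class TestInteractionVolume:
    def test_one_significant_direction(self):
        V, interacting = interaction_volume(0.05, 0.2, 0.01, 0.5)
        assert V == pytest.approx(0.05)
        assert interacting

    def test_both_significant_sum_not_net(self):
        V, interacting = interaction_volume(0.03, 0.04, 0.01, 0.02)
        assert V == pytest.approx(0.07)
        assert interacting

    def test_both_null(self):
        V, interacting = interaction_volume(0.1, 0.2, 0.5, 0.9)
        assert V == 0.0
        assert not interacting

    def test_alpha_is_inclusive(self):
        V, _ = interaction_volume(0.1, 0.0, 0.10, 1.0)
        assert V == pytest.approx(0.1)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            interaction_volume(0.1, 0.1, 1.5, 0.5)


class TestRadii:
    def test_constant_profile_zero(self):
        chunks = TEChunkSeries([0.0, 1.0, 2.0, 3.0], [0.2] * 4, 10)
        assert radius_from_te_series(chunks) == 0.0

    def test_linear_profile_slope(self):
        t = np.arange(5.0)
        chunks = TEChunkSeries(t, 0.4 * t + 0.1, 10)
        assert radius_from_te_series(chunks) == pytest.approx(0.4)

    def test_alternating_profile(self):
        chunks = TEChunkSeries([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 0.0, 1.0], 10)
        assert radius_from_te_series(chunks) == pytest.approx(1.0)

    def test_single_chunk_rejected(self):
        with pytest.raises(InsufficientDataError):
            radius_from_te_series(TEChunkSeries([0.0], [0.1], 10))

    def test_central_scheme(self):
        t = np.arange(5.0)
        chunks = TEChunkSeries(t, -0.3 * t, 10)
        assert radius_from_te_series(chunks, scheme="central") == pytest.approx(0.3)

    def test_fallback_positive_slope(self):
        t = np.linspace(0, 10, 30)
        assert radius_fallback(TimeSeries("a", t, 2 * t + 1)) == pytest.approx(2.0)

    def test_fallback_negative_slope_absolute(self):
        t = np.linspace(0, 10, 30)
        assert radius_fallback(TimeSeries("a", t, -3 * t + 40)) == pytest.approx(3.0)

    def test_fallback_noisy_line(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 10, 100)
        y = 1.5 * t + rng.normal(0, 0.01, 100)
        # closed-form OLS oracle
        tc = t - t.mean()
        expected = abs((tc * y).sum() / (tc**2).sum())
        got = radius_fallback(TimeSeries("n", t, y))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(1.5, abs=0.01)


class TestConeHeight:
    @pytest.mark.parametrize(
        "V,rx,ry,expected",
        [
            (0.0711, 20.21159, 0.00818, 0.000166),  # case-study row AS-ASL
            (0.05968, 5.19208, 5.27732, 0.000693),  # ASpOH-ASoOH
            (0.00933, 0.14796, 3.21513, 0.000822),  # ASL-ASpOH
            (np.pi, 1.0, 1.0, 1.0),
        ],
    )
    def test_height_values(self, V, rx, ry, expected):
        assert cone_height(V, rx, ry) == pytest.approx(expected, abs=5e-7)

    def test_both_radii_zero(self):
        with pytest.raises(GeometryError):
            cone_height(0.1, 0.0, 0.0)

    def test_all_fixture_rows_map_to_printed_heights(self):
        # every interacting pair of all three individuals, except the one
        # row whose printed height is inconsistent with its cone table
        for ind in (1, 2, 3):
            cones = load_fixture(f"cone_individual_{ind}")
            heights = load_fixture(f"heights_individual_{ind}")
            merged = cones.merge(heights, on=["X", "Y"])
            for row in merged.itertuples(index=False):
                if row.V == 0 or "inconsistent" in row.flag:
                    continue
                calc = cone_height(row.V, row.r_x, row.r_y)
                assert calc == pytest.approx(
                    row.h, abs=5e-7, rel=5e-4
                ), f"individual {ind}, pair {row.X}-{row.Y}"


class TestConeHeightError:
    def test_case_study_row(self):
        dh = cone_height_error(0.0711, 0.00315, 20.21159, 2.24584, 0.00818, 0.00442)
        assert dh == pytest.approx(3.7e-05, abs=5e-7)

    def test_zero_uncertainty(self):
        assert cone_height_error(0.1, 0, 1.0, 0, 2.0, 0) == 0.0

    def test_volume_only_term(self):
        V, dV, rx, ry = 0.2, 0.01, 1.3, 0.4
        q = rx**2 + rx * ry + ry**2
        expected = 3 * dV / (np.pi * q**2)
        assert cone_height_error(V, dV, rx, 0, ry, 0) == pytest.approx(expected)

    def test_homogeneous_variant_scales_dv(self):
        V, dV, rx, ry = 0.2, 0.01, 1.3, 0.4
        q = rx**2 + rx * ry + ry**2
        printed = cone_height_error(V, dV, rx, 0, ry, 0)
        homog = cone_height_error(V, dV, rx, 0, ry, 0, variant="homogeneous")
        assert homog == pytest.approx(printed * q)

    @pytest.mark.parametrize("bump", ["dV", "dr_x", "dr_y"])
    def test_monotone_in_each_uncertainty(self, bump):
        base = dict(V=0.1, dV=0.01, r_x=0.8, dr_x=0.05, r_y=0.3, dr_y=0.02)
        lo = cone_height_error(**base)
        hi_args = dict(base)
        hi_args[bump] *= 2
        assert cone_height_error(**hi_args) >= lo


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    V=st.floats(min_value=1e-6, max_value=10),
    rx=st.floats(min_value=1e-3, max_value=50),
    ry=st.floats(min_value=1e-3, max_value=50),
    c=st.floats(min_value=1e-3, max_value=100),
)
def test_height_scaling_properties(V, rx, ry, c):
    """h is linear in V and scales as 1/c^2 under radius scaling."""
    h = cone_height(V, rx, ry)
    assert cone_height(c * V, rx, ry) == pytest.approx(c * h, rel=1e-9)
    assert cone_height(V, c * rx, c * ry) == pytest.approx(h / c**2, rel=1e-9)


def _curve(label, values, t=None, errors=None):
    t = np.arange(len(values), dtype=float) if t is None else t
    return SplineCurve(
        label=label,
        knot_times=t,
        knot_values=np.asarray(values, dtype=float),
        dense_times=t,
        dense_values=np.asarray(values, dtype=float),
        dense_errors=None if errors is None else np.asarray(errors, dtype=float),
    )


class TestEstimatePair:
    def test_zero_error_band_gives_zero_uncertainties(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=100)
        x = np.roll(y, 1) + 0.05 * rng.normal(size=100)
        cx = _curve("x", x + 10, errors=np.zeros(100))
        cy = _curve("y", y + 10, errors=np.zeros(100))
        model = estimate_pair(cx, cy, config=ConeConfig(seed=0, n_rep=20))
        assert model.interacting
        # identical replicates; only float-mean rounding can remain
        assert model.dV == pytest.approx(0.0, abs=1e-12)
        assert model.dr_x == pytest.approx(0.0, abs=1e-12)
        assert model.dr_y == pytest.approx(0.0, abs=1e-12)
        assert model.dh == pytest.approx(0.0, abs=1e-9)
        assert not model.high_se

    def test_coupled_pair_interacting_with_positive_height(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=100)
        x = np.roll(y, 1) + 0.05 * rng.normal(size=100)
        model = estimate_pair(
            _curve("x", x + 10), _curve("y", y + 10),
            config=ConeConfig(seed=1),
        )
        assert model.interacting
        assert model.h > 0

    def test_independent_pair_not_interacting(self):
        rng = np.random.default_rng(2)
        model = estimate_pair(
            _curve("x", rng.normal(size=100) + 10),
            _curve("y", rng.normal(size=100) + 10),
            config=ConeConfig(seed=2),
        )
        assert not model.interacting
        assert model.V == 0.0
        assert model.h == 0.0

    def test_flat_te_profile_falls_back_to_trajectory_slope(self):
        # linear trajectories: the direction whose chunked TE profile is
        # flat gets its radius from the concentration slope instead
        t = np.linspace(0, 24, 100)
        model = estimate_pair(
            _curve("x", 2 * t + 1, t=t),
            _curve("y", 30 - t, t=t),
            config=ConeConfig(seed=3),
        )
        assert model.fallback_used
        assert model.r_y == pytest.approx(1.0)  # |slope| of the y line

    def test_uncertainty_from_error_band(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=100)
        x = np.roll(y, 1) + 0.05 * rng.normal(size=100)
        err = np.full(100, 0.2)
        model = estimate_pair(
            _curve("x", x + 10, errors=err),
            _curve("y", y + 10, errors=err),
            config=ConeConfig(seed=4, n_rep=30),
        )
        assert model.interacting
        assert model.dV > 0
        assert model.dh > 0
        assert model.high_se == (model.dh > model.h)


class TestAssembleDistanceMatrix:
    def test_individual1_zeros_at_non_interacting_pairs(self, individual1_matrix):
        dm = individual1_matrix
        assert dm.entry("AS", "ASoOH") == 0.0
        assert dm.entry("AS", "ASLpOH") == 0.0
        i, j = dm.index("AS"), dm.index("ASoOH")
        assert dm.no_interaction[i, j]
        assert dm.entry("AS", "ASL") == pytest.approx(0.000166)
        k, l = dm.index("ASL"), dm.index("ASLpOH")
        assert dm.high_se[k, l]

    def test_symmetry_and_zero_diagonal(self, individual1_matrix):
        dm = individual1_matrix
        np.testing.assert_array_equal(dm.D, dm.D.T)
        np.testing.assert_array_equal(np.diag(dm.D), np.zeros(6))

    def test_empty_model_list(self):
        dm = assemble_distance_matrix([], ["a", "b", "c"])
        np.testing.assert_array_equal(dm.D, np.zeros((3, 3)))
        assert dm.no_interaction[0, 1]

    def test_duplicate_pair_rejected(self):
        m = ConeModel(pair=("a", "b"), V=0.1, h=1.0, interacting=True)
        m2 = ConeModel(pair=("b", "a"), V=0.2, h=2.0, interacting=True)
        with pytest.raises(ValidationError):
            assemble_distance_matrix([m, m2], ["a", "b"])

    def test_unknown_label_rejected(self):
        m = ConeModel(pair=("a", "z"), V=0.1, h=1.0, interacting=True)
        with pytest.raises(ValidationError):
            assemble_distance_matrix([m], ["a", "b"])

    def test_augmented_adds_errors(self, individual1_matrix):
        dm = individual1_matrix
        aug = dm.augmented()
        i, j = dm.index("AS"), dm.index("ASL")
        assert aug.D[i, j] == pytest.approx(0.000166 + 3.7e-05)

    def test_species_order(self, individual1_matrix):
        assert individual1_matrix.labels == SPECIES


def test_zero_derivative_tolerance_is_tiny():
    # flat really means flat: numerical zeros, not small values
    assert ZERO_DERIVATIVE_TOL <= 1e-9
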