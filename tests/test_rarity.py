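"""Rarity metrics LA/RA/GR, independence weights, RI and quartile classes."""

import numpy as np
import pandas as pd
import pytest

from netnight.io import AbundanceMatrix, build_matrix
from netnight.rarity import (
    classify_quartiles,
    geographic_range,
    independence_weights,
    local_abundance,
    rarity_index,
    rarity_profiles,
    regional_abundance,
)
from .conftest import make_record


def matrix_from(counts, sites_nights, species):
    index = pd.MultiIndex.from_tuples(sites_nights, names=["site", "night"])
    return AbundanceMatrix(pd.DataFrame(counts, index=index, columns=species))


class TestLocalAbundance:
    def test_absent_species_is_zero(self):
        m = matrix_from([[2, 0], [3, 0]], [("s1", "n1"), ("s1", "n2")], ["a", "b"])
        assert local_abundance(m)["b"] == 0.0

    def test_single_site_hand_value(self):
        # counts {2, 0} over 2 nights, site total 10 -> mean/night 1, /10 = 0.1
        m = matrix_from(
            [[2, 5], [0, 3]], [("s1", "n1"), ("s1", "n2")], ["a", "other"]
        )
        assert local_abundance(m)["a"] == pytest.approx(0.1)

    def test_median_of_two_sites(self):
        # site1 value 0.1 (as above); site2: {3,3} over 2 nights, total 10 -> 0.3
        m = matrix_from(
            [[2, 5], [0, 3], [3, 2], [3, 2]],
            [("s1", "n1"), ("s1", "n2"), ("s2", "n1"), ("s2", "n2")],
            ["a", "other"],
        )
        assert local_abundance(m)["a"] == pytest.approx(0.2)


class TestRegionalAbundance:
    def test_hand_values(self):
        m = matrix_from(
            [[4, 1, 0], [4, 0, 0], [4, 0, 0]],
            [("s1", "n1"), ("s2", "n1"), ("s3", "n1")],
            ["a", "b", "c"],
        )
        ra = regional_abundance(m)
        assert ra["a"] == pytest.approx(4.0)  # 12 records over 3 sites
        assert ra["b"] == pytest.approx(1.0)  # 1 record, 1 site
        assert ra["c"] == 0.0  # zero records, flagged downstream


class TestGeographicRange:
    def test_two_sites_degenerate_hull(self):
        assert geographic_range(np.array([0.0, 1.0]), np.array([0.0, 0.0])) == 0.0

    def test_equatorial_degree_square_area(self):
        """1x1 degree square at the equator: ~111.32 km per degree."""
        lon = np.array([0.0, 1.0, 1.0, 0.0])
        lat = np.array([0.0, 0.0, 1.0, 1.0])
        area = geographic_range(lon, lat)
        assert area == pytest.approx(111.32**2, rel=0.01)

    def test_interior_site_leaves_hull_area_unchanged(self):
        lon = np.array([0.0, 1.0, 1.0, 0.0])
        lat = np.array([0.0, 0.0, 1.0, 1.0])
        area = geographic_range(lon, lat)
        area2 = geographic_range(np.append(lon, 0.5), np.append(lat, 0.5))
        assert area2 == pytest.approx(area, rel=1e-6)

    def test_collinear_sites_have_zero_area(self):
        assert geographic_range(np.array([0.0, 0.5, 1.0]), np.zeros(3)) == 0.0

    def test_missing_coordinates_error(self):
        with pytest.raises(ValueError, match="missing"):
            geographic_range(np.array([0.0, np.nan]), np.array([0.0, 1.0]))


class TestIndependenceWeights:
    def test_plug_in_values(self):
        # uncorrelated -> 1.5; perfectly correlated -> 0.5
        a = np.array([0.0, 1.0, 0.0, 1.0])
        assert independence_weights(a, np.array([0, 0, 1, 1.0]), np.array([1, 1, 0, 0.0]))[0] == pytest.approx(1.5)
        b = np.array([0.0, 0.5, 0.25, 1.0])
        w_la, _, _ = independence_weights(b, b, b)
        assert w_la == pytest.approx(0.5)

    def test_mixed_correlations_arithmetic(self):
        """r_LARA = 0.5 and r_LAGR = 0.3 give omega_LA = 1.1 under the
        default 1/2 + sum((1-|r|)/2) rule."""
        rng = np.random.default_rng(0)
        # construct vectors with the required Pearson correlations exactly
        n = 2000
        x = rng.standard_normal(n)
        e1, e2 = rng.standard_normal((2, n))
        y = 0.5 * x + np.sqrt(1 - 0.25) * e1
        z = 0.3 * x + np.sqrt(1 - 0.09) * e2
        w_la, _, _ = independence_weights(x, y, z)
        r1 = abs(np.corrcoef(x, y)[0, 1])
        r2 = abs(np.corrcoef(x, z)[0, 1])
        assert w_la == pytest.approx(0.5 + (1 - r1) / 2 + (1 - r2) / 2)
        assert w_la == pytest.approx(1.1, abs=0.05)

    def test_squared_variant(self):
        a = np.array([0.0, 1.0, 0.0, 1.0])
        w = independence_weights(a, a, a, variant="half_sum_sq")
        assert w[0] == pytest.approx(0.0)  # (1/2)((1-1)+(1-1))

    def test_zero_variance_metric_warns(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            w = independence_weights(
                np.ones(4), np.array([0, 1, 2, 3.0]), np.array([3, 1, 2, 0.0])
            )
        assert w[0] == pytest.approx(1.5)


class TestRarityIndex:
    def test_extremes_map_to_zero_and_one(self):
        la = np.array([0.0, 0.1, 0.5])
        ra = np.array([0.0, 2.0, 9.0])
        gr = np.array([0.0, 10.0, 400.0])
        ri, _, _ = rarity_index(la, ra, gr)
        assert ri[0] == pytest.approx(0.0)
        assert ri[2] == pytest.approx(1.0)

    def test_weighted_mean_arithmetic(self):
        std = np.array([0.2, 0.6, 1.0])
        w = (1.0, 1.0, 2.0)
        ri = (std * w).sum() / sum(w)
        assert ri == pytest.approx(0.7)

    def test_single_species_errors(self):
        with pytest.raises(ValueError):
            rarity_index(np.array([1.0]), np.array([1.0]), np.array([1.0]))

    def test_invariant_to_affine_rescaling_of_raw_metric(self):
        """Min-max standardisation absorbs any common positive rescaling
        applied after the log transform."""
        rng = np.random.default_rng(3)
        la, ra, gr = rng.gamma(2.0, 2.0, size=(3, 12))
        ri1, _, _ = rarity_index(la, ra, gr)
        scaled = np.expm1(np.log1p(gr) * 3.0 + 1.0)  # affine on the log scale
        ri2, _, _ = rarity_index(la, ra, scaled)
        np.testing.assert_allclose(ri1, ri2, atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        la, ra, gr = rng.gamma(2.0, 2.0, size=(3, 10))
        perm = rng.permutation(10)
        ri, _, _ = rarity_index(la, ra, gr)
        ri_p, _, _ = rarity_index(la[perm], ra[perm], gr[perm])
        np.testing.assert_allclose(ri[perm], ri_p, atol=1e-12)


class TestClassifyQuartiles:
    def test_eight_species_two_per_tail(self):
        classes = classify_quartiles(np.arange(1, 9) / 8)
        assert list(classes[:2]) == ["R", "R"]
        assert list(classes[-2:]) == ["C", "C"]
        assert list(classes[2:6]) == ["U"] * 4

    def test_four_species(self):
        classes = classify_quartiles(np.array([0.1, 0.4, 0.6, 0.9]))
        assert list(classes) == ["R", "U", "U", "C"]

    def test_all_equal_collapses_to_common(self):
        with pytest.warns(UserWarning, match="degenerate"):
            classes = classify_quartiles(np.full(6, 0.5))
        assert set(classes) == {"C"}

    def test_too_few_species_all_uncommon(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            classes = classify_quartiles(np.array([0.2, 0.8]))
        assert list(classes) == ["U", "U"]


def test_profiles_table_dominant_species_attains_max_ri():
    """A species that is maximal in occupancy, counts and spread must get
    the top rarity index (i.e. be the most common)."""
    rng = np.random.default_rng(5)
    sites = pd.DataFrame(
        {"site": [f"s{i}" for i in range(5)],
         "lon": [-48, -47, -46.5, -47.5, -46],
         "lat": [-3, -2, -2.5, -1.5, -1.0]}
    )
    records = []
    for si, site in enumerate(sites["site"]):
        for night in ("n1", "n2"):
            for _ in range(6):  # dominant species everywhere, abundant
                records.append(make_record(site=site, night=night, species="dom"))
            if si < 2:  # others patchy and sparse
                records.append(make_record(site=site, night=night, species=f"sp{si}"))
                records.append(make_record(site=site, night=night, species="sp9"))
    m = build_matrix(records, sorted({r.species_id for r in records}))
    table = rarity_profiles(m, sites)
    top = table.loc[table["RI"].idxmax(), "species"]
    assert top == "dom"
    assert table.loc[table["species"] == "dom", "rarity_class"].item() == "C"
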