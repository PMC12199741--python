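"""Tallies, region aggregation, drift-time and covariate statistics."""

import numpy as np
import pandas as pd
import pytest

import driftsource as ds
from driftsource.errors import ValidationError
from driftsource.landings import (DEFAULT_REGIONS, RegionBox, aggregate_regions,
                                  covariate_association, density_cloud,
                                  drift_time_summary, region_of_cells,
                                  round_half_up, season_of, tally_landings)

TOTAL = 584_300


def _records(cell_counts, start="2001-06-15"):
    rows = []
    pid = 0
    for cell, n in cell_counts.items():
        for _ in range(n):
            rows.append({"particle_id": pid, "release_date": start,
                         "landing_date": start, "drift_days": 0,
                         "cell_id": cell, "lon": 0.0, "lat": 0.0})
            pid += 1
    return pd.DataFrame(rows)


class TestRounding:
    @pytest.mark.parametrize("x,expect", [
        (7.5878, 7.6), (7.4016, 7.4), (5.4994, 5.5),
        (0.05, 0.1), (0.15, 0.2), (0.25, 0.3),  # half-up, not banker's
        (98.9717, 99.0),
    ])
    def test_half_up_one_decimal(self, x, expect):
        assert round_half_up(x, 1) == expect


class TestTally:
    def test_printed_counts_reproduce_printed_percentages(self):
        """The study's six headline polygons: counts over the schedule total."""
        tab = tally_landings(_records({1: 0}).iloc[0:0], TOTAL)
        assert tab.empty
        counts = {"cape_inubo": 44_336, "johnston_w": 43_248, "galapagos_nw": 32_133}
        expect = {"cape_inubo": 7.6, "johnston_w": 7.4, "galapagos_nw": 5.5}
        for name, n in counts.items():
            pct = round_half_up(100.0 * n / TOTAL, 1)
            assert pct == expect[name]

    def test_tally_counts_and_percent(self):
        rec = _records({10: 3, 20: 1})
        tab = tally_landings(rec, 8)
        assert list(tab["cell_id"]) == [10, 20]
        assert list(tab["count"]) == [3, 1]
        assert tab["percent"].iloc[0] == pytest.approx(37.5)
        assert tab["percent"].sum() <= 100.0 + 1e-12

    def test_total_smaller_than_landings_rejected(self):
        with pytest.raises(ValidationError):
            tally_landings(_records({1: 5}), 3)


class TestRegions:
    def test_default_regions_are_disjoint(self):
        for i, a in enumerate(DEFAULT_REGIONS):
            for b in DEFAULT_REGIONS[i + 1:]:
                assert not a.overlaps(b)

    def test_centroid_in_box_aggregation(self):
        cells = {1: (140.0, 35.0),   # Japan box
                 2: (190.0, 10.0),   # central Pacific box
                 3: (260.0, 5.0),    # ETP box
                 4: (300.0, 5.0)}    # none
        tab = tally_landings(_records({1: 4, 2: 3, 3: 2, 4: 1}), 20)
        out = aggregate_regions(tab, cells, DEFAULT_REGIONS, 20)
        got = dict(zip(out["region"], out["count"]))
        assert got == {"Japan": 4, "central Pacific": 3, "ETP": 2, "other": 1}
        assert out["count"].sum() == 10  # region counts + residue = landings

    def test_single_box_covering_all(self):
        cells = {1: (5.0, 5.0), 2: (6.0, 6.0)}
        tab = tally_landings(_records({1: 2, 2: 2}), 10)
        box = RegionBox("all", lat=(0, 10), lon=(0, 10))
        out = aggregate_regions(tab, cells, [box], 10)
        assert dict(zip(out["region"], out["percent"]))["all"] == pytest.approx(40.0)

    def test_lower_bound_inclusive_upper_exclusive(self):
        box = RegionBox("b", lat=(29.0, 43.5), lon=(135.0, 150.0))
        assert box.contains(135.0, 29.0)
        assert not box.contains(150.0, 29.0)
        assert not box.contains(135.0, 43.5)

    def test_wrap_aware_box(self):
        box = RegionBox("seam", lat=(0, 10), lon=(350.0, 10.0))
        assert box.contains(355.0, 5.0)
        assert box.contains(5.0, 5.0)
        assert not box.contains(180.0, 5.0)

    def test_overlapping_boxes_rejected(self):
        a = RegionBox("a", lat=(0, 10), lon=(0, 10))
        b = RegionBox("b", lat=(5, 15), lon=(5, 15))
        tab = tally_landings(_records({1: 1}), 5)
        with pytest.raises(ValidationError):
            aggregate_regions(tab, {1: (1.0, 1.0)}, [a, b], 5)


class TestDriftTime:
    def test_exact_p_and_bonferroni(self):
        rec = pd.concat([
            _records({1: 3}).assign(drift_days=[1, 2, 3]),
            _records({2: 3}).assign(drift_days=[4, 5, 6],
                                    particle_id=[10, 11, 12]),
        ])
        summary, reports = drift_time_summary(rec, {1: "A", 2: "B"})
        assert set(summary["region"]) == {"A", "B"}
        assert summary.set_index("region").loc["A", "mean_days"] == 2.0
        assert len(reports) == 1
        assert reports[0].p_raw == pytest.approx(0.1)
        assert reports[0].p_adjusted == pytest.approx(0.1)  # one comparison

    def test_identical_groups_adjusted_one(self):
        rec = pd.concat([
            _records({1: 3}).assign(drift_days=[5, 6, 7]),
            _records({2: 3}).assign(drift_days=[5, 6, 7], particle_id=[8, 9, 10]),
        ])
        _, reports = drift_time_summary(rec, {1: "A", 2: "B"})
        assert reports[0].p_adjusted == 1.0


class TestDensity:
    def test_single_stationary_particle(self):
        traj = pd.DataFrame({"particle_id": [0] * 5, "time": range(5),
                             "lon": [10.2] * 5, "lat": [3.7] * 5})
        H, _, _ = density_cloud(traj, 1.0, lon_range=(0, 20), lat_range=(0, 10))
        assert H.max() == pytest.approx(1.0)
        assert (H > 0).sum() == 1

    def test_normalisation(self):
        rng = np.random.default_rng(0)
        traj = pd.DataFrame({"particle_id": np.arange(500), "time": 0,
                             "lon": rng.uniform(0, 20, 500),
                             "lat": rng.uniform(0, 10, 500)})
        H, _, _ = density_cloud(traj, 1.0, lon_range=(0, 20), lat_range=(0, 10))
        assert H.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_positions_multinomial_bound(self):
        rng = np.random.default_rng(1)
        n, npix = 20_000, 200
        traj = pd.DataFrame({"particle_id": np.arange(n), "time": 0,
                             "lon": rng.uniform(0, 20, n),
                             "lat": rng.uniform(0, 10, n)})
        H, _, _ = density_cloud(traj, 1.0, lon_range=(0, 20), lat_range=(0, 10))
        p = 1.0 / npix
        sd = np.sqrt(p * (1 - p) / n)
        # every pixel within ~4 sigma of uniform expectation (200 pixels)
        assert np.all(np.abs(H - p) < 4.5 * sd)


class TestCovariates:
    def test_season_definition(self):
        assert season_of(12) == "DJF"
        assert season_of(9) == "SON"
        assert season_of(3) == "MAM"
        assert season_of(6) == "JJA"

    def test_unlabeled_month_rejected(self):
        enso = ds.synth.make_enso("2001-01", "2001-06", (0, 0, 1), seed=0)
        rec = _records({1: 2}, start="2001-09-10")
        with pytest.raises(ValidationError):
            covariate_association(rec, enso, {1: "A"})

    def test_doubled_neutral_rate_detected(self):
        """Landing rate doubled in Neutral months -> both pairwise tests
        significant at 100 months."""
        rng = np.random.default_rng(7)
        enso = ds.synth.make_enso("2000-01", "2008-04", (0.3, 0.3, 0.4), seed=7)
        assert len(enso) == 100
        rows = []
        pid = 0
        for per, phase in enso.items():
            lam = 10.0 if phase == "Neutral" else 5.0
            for _ in range(rng.poisson(lam)):
                rows.append({"particle_id": pid, "release_date": "2000-01-01",
                             "landing_date": str(per.to_timestamp().date()),
                             "drift_days": 1, "cell_id": 1, "lon": 140.0,
                             "lat": 35.0})
                pid += 1
        rec = pd.DataFrame(rows)
        monthly, reports = covariate_association(rec, enso, {1: "Japan"},
                                                 by="phase")
        fam = {(r.group_a, r.group_b): r.p_adjusted for r in reports["Japan"]}
        for pair, p in fam.items():
            if "Neutral" in pair:
                assert p < 0.05
        # months with no landings count as zero rows
        assert len(monthly) == 100

    def test_permuted_labels_match_exhaustive_oracle(self):
        """12-month toy: the rank-sum family agrees with a brute-force
        permutation oracle."""
        from tests.test_stats import brute_force_p
        rng = np.random.default_rng(3)
        enso = ds.synth.make_enso("2001-01", "2001-12", (0.5, 0.5, 0.0), seed=11)
        rows = []
        pid = 0
        for per in enso.index:
            for _ in range(rng.integers(0, 5)):
                rows.append({"particle_id": pid, "release_date": "2001-01-01",
                             "landing_date": str(per.to_timestamp().date()),
                             "drift_days": 1, "cell_id": 1, "lon": 140.0,
                             "lat": 35.0})
                pid += 1
        rec = pd.DataFrame(rows)
        monthly, reports = covariate_association(rec, enso, {1: "Japan"},
                                                 by="phase")
        tab = monthly[monthly["region"] == "Japan"]
        groups = {k: v["count"].to_numpy(float) for k, v in tab.groupby("phase")}
        for r in reports["Japan"]:
            assert r.p_raw == pytest.approx(
                brute_force_p(groups[r.group_a], groups[r.group_b]), abs=1e-12)
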