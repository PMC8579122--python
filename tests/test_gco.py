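"""Sniff-panel scoring: block centring, NIF/IS/OI, region clustering, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aromastat import gco
from aromastat.datasets import SAMPLES, gco_long
from conftest import make_events


# ---------------------------------------------------------------------------
# block centring


class TestBlockCentre:
    def test_hand_example(self):
        # panellist A scores {2, 4} (mean 3); B scores {1, 2} (mean 1.5);
        # grand mean 2.25 -> A shifted by -0.75, B by +0.75
        events = make_events(
            [("A", "S1", 1000, 2), ("A", "S1", 1100, 4), ("B", "S1", 1000, 1), ("B", "S1", 1100, 2)]
        )
        centred = gco.block_centre(events)
        a = centred[centred["panellist"] == "A"]["intensity_centred"].tolist()
        b = centred[centred["panellist"] == "B"]["intensity_centred"].tolist()
        assert a == [1.25, 3.25]
        assert b == [1.75, 2.75]

    def test_two_panellist_shift(self):
        # one panellist with {2, 4}: assessor mean 3; second assessor {2, 2}
        # makes the grand mean 2.5, so the centred scores become {1.5, 3.5}
        events = make_events(
            [("A", "S1", 1000, 2), ("A", "S1", 1100, 4), ("B", "S1", 1000, 2), ("B", "S1", 1100, 2)]
        )
        centred = gco.block_centre(events)
        assert centred[centred["panellist"] == "A"]["intensity_centred"].tolist() == [1.5, 3.5]

    def test_identity_when_all_panellists_share_mean(self):
        events = make_events(
            [("A", "S1", 1000, 2), ("A", "S1", 1100, 4), ("B", "S1", 1000, 4), ("B", "S1", 1100, 2)]
        )
        centred = gco.block_centre(events)
        assert (centred["intensity_centred"] == centred["intensity"]).all()

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 8), st.integers(1, 5)),
            min_size=2,
            max_size=60,
        )
    )
    def test_grand_mean_conserved(self, raw):
        events = make_events(
            [(f"J{p}", "S1", 1000 + 5 * k, i) for k, (p, i) in enumerate(raw)]
        )
        centred = gco.block_centre(events)
        assert centred["intensity_centred"].mean() == pytest.approx(
            events["intensity"].mean(), abs=1e-12
        )


# ---------------------------------------------------------------------------
# scalar scores


class TestNif:
    @pytest.mark.parametrize(
        "detected,panel,expected", [(9, 9, 100), (8, 9, 89), (4, 9, 44), (0, 9, 0), (5, 9, 56)]
    )
    def test_printed_grid(self, detected, panel, expected):
        assert gco.nif(detected, panel) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gco.nif(10, 9)
        with pytest.raises(ValueError):
            gco.nif(1, 0)


class TestIntensityScore:
    def test_full_panel_maximum_scale(self):
        assert gco.intensity_score([5] * 9, panel_size=9) == pytest.approx(100.0)

    def test_nondetectors_count_as_zero_in_default_mode(self):
        # 3 detectors at centred 5 among 9 panellists: mean 15/9, IS = 33.3%
        assert gco.intensity_score([5, 5, 5], panel_size=9) == pytest.approx(100 * 15 / 9 / 5)
        assert gco.intensity_score([5, 5, 5], mode="detectors_only") == pytest.approx(100.0)

    def test_no_detections_give_zero(self):
        assert gco.intensity_score([], panel_size=9) == 0.0

    def test_negative_average_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            assert gco.intensity_score([-1.0, -2.0], panel_size=9) == 0.0

    def test_centred_average_3_75_gives_75(self):
        # a 9-panellist set with block-centred panel mean 3.75 -> IS 75
        vals = [3.75] * 9
        assert gco.intensity_score(vals, panel_size=9) == pytest.approx(75.0)


class TestOdourImportance:
    @pytest.mark.parametrize(
        "nif,is_,expected",
        [(89, 75, 82), (33, 20, 26), (89, 46, 64), (89, 72, 80), (89, 68, 78), (0, 0, 0)],
    )
    def test_printed_cells(self, nif, is_, expected):
        assert gco.odour_importance(nif, is_) == expected

    @given(st.integers(0, 100))
    def test_idempotent_when_equal(self, x):
        assert gco.odour_importance(x, x) == x

    def test_geometric_mean_bound(self, gco_table):
        long = gco_long(gco_table)
        both = long[(long["nif"] > 0) & (long["intensity_score"] > 0)]
        lo = np.minimum(both["nif"], both["intensity_score"])
        hi = np.maximum(both["nif"], both["intensity_score"])
        oi = np.sqrt(both["nif"] * both["intensity_score"])
        assert ((lo <= oi + 1e-9) & (oi <= hi + 1e-9)).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gco.odour_importance(-1, 10)


# ---------------------------------------------------------------------------
# clustering


def brute_force_single_linkage(onsets, tolerance):
    """O(n^2) oracle: connected components of the <=tolerance graph."""
    n = len(onsets)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(onsets[i] - onsets[j]) <= tolerance:
                parent[find(i)] = find(j)
    labels = [find(i) for i in range(n)]
    # canonical: order components by their minimum onset
    comp_min = {}
    for lab, x in zip(labels, onsets):
        comp_min[lab] = min(comp_min.get(lab, np.inf), x)
    ranks = {lab: r for r, lab in enumerate(sorted(comp_min, key=comp_min.get))}
    return [ranks[lab] for lab in labels]


class TestClusterEvents:
    def test_tight_cluster_single_region(self):
        events = make_events([("A", "S1", 1459, 3), ("B", "S1", 1461, 2), ("C", "S1", 1458, 4)])
        out = gco.cluster_events(events, tolerance=5)
        assert out["region_id"].nunique() == 1
        assert out["consensus_ri"].iloc[0] == pytest.approx(1459)

    def test_distant_events_split(self):
        events = make_events([("A", "S1", 1000, 3), ("B", "S1", 1100, 3)])
        out = gco.cluster_events(events, tolerance=5)
        assert out["region_id"].nunique() == 2

    def test_panellist_contributes_once_per_region_and_sample(self):
        events = make_events(
            [("A", "S1", 1000, 2), ("A", "S1", 1001, 5), ("A", "S2", 1000, 3), ("B", "S1", 1002, 1)]
        )
        out = gco.cluster_events(events, tolerance=5)
        assert out["region_id"].nunique() == 1
        kept = out[(out["panellist"] == "A") & (out["sample"] == "S1")]
        assert len(kept) == 1 and kept["intensity"].iloc[0] == 5  # highest intensity wins

    def test_wide_cluster_split_at_largest_gap(self):
        # chain with gaps <= tol but span > 3*tol must break at the widest gap
        onsets = [1000, 1004, 1008, 1012, 1020, 1024, 1028, 1032]
        events = make_events([(f"J{k}", "S1", x, 3) for k, x in enumerate(onsets)])
        out = gco.cluster_events(events, tolerance=5).sort_values("onset_ri")
        regions = out["region_id"].tolist()
        assert regions[:4] == [regions[0]] * 4
        assert regions[4:] == [regions[4]] * 4
        assert regions[0] != regions[4]

    def test_matches_brute_force_linkage(self, rng):
        for _ in range(25):
            centres = np.sort(rng.uniform(800, 2200, size=rng.integers(2, 8)))
            onsets = np.concatenate(
                [c + rng.normal(0, 1.0, size=rng.integers(1, 6)) for c in centres]
            )
            events = make_events(
                [(f"J{k}", "S1", x, int(rng.integers(1, 6))) for k, x in enumerate(onsets)]
            )
            out = gco.cluster_events(events, tolerance=5).sort_values("onset_ri")
            got = pd.factorize(out["region_id"])[0].tolist()
            expected = brute_force_single_linkage(np.sort(onsets), 5)
            spans = out.groupby("region_id")["onset_ri"].agg(lambda s: s.max() - s.min())
            if (spans <= 15).all():
                assert got == expected

    def test_empty_input(self):
        out = gco.cluster_events(make_events([]).reindex(columns=gco.EVENT_COLUMNS), tolerance=5)
        assert out.empty

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            gco.cluster_events(make_events([("A", "S1", 1000, 3)]), tolerance=0)


# ---------------------------------------------------------------------------
# selection rules on the bundled region table


class TestSelectionRules:
    def test_odour_active_needs_more_than_three_detections(self):
        regions = pd.DataFrame(
            {
                "region_id": ["r1", "r2", "r3"],
                "det_A": [4, 3, 0],
                "det_B": [0, 3, 0],
                "det_C": [0, 3, 0],
                "det_D": [0, 3, 0],
            }
        )
        kept = gco.filter_odour_active(regions, min_detections=4)
        assert kept["region_id"].tolist() == ["r1"]

    def test_kept_region_reports_all_samples(self, gco_table):
        kept = gco.filter_odour_active(gco_table)
        assert {f"nif_{s}" for s in SAMPLES} <= set(kept.columns)

    def test_threshold_is_strict(self):
        regions = pd.DataFrame({"oi_A": [64.0, 65.0, 66.0], "compound": ["x", "y", "z"]})
        sel = gco.select_important(regions, oi_threshold=65)
        assert sel["compound"].tolist() == ["z"]

    def test_ranked_by_descending_mean_oi(self, gco_table, important_table):
        sel = gco.select_important(gco_table, oi_threshold=65)
        assert sel["mean_oi"].is_monotonic_decreasing
        # the printed shortlist appears in printed order at the top ranks
        printed = important_table["compound"].tolist()
        got = [c for c in sel["compound"] if c in printed]
        assert got == printed


# ---------------------------------------------------------------------------
# relative peak areas


class TestRelativePeakArea:
    def test_unity_and_zero(self):
        assert gco.relative_peak_area(2.5, 2.5) == 1.0
        assert gco.relative_peak_area(0.0, 2.5) == 0.0

    def test_zero_internal_standard_rejected(self):
        with pytest.raises(ValueError):
            gco.relative_peak_area(1.0, 0.0)

    def test_random_areas_against_hand_division(self, rng):
        areas = rng.uniform(0.1, 10, size=50)
        is_areas = rng.uniform(0.5, 5, size=50)
        for a, b in zip(areas, is_areas):
            assert gco.relative_peak_area(a, b) == pytest.approx(a / b, rel=1e-12)

    def test_mean_sd_over_extraction_replicates(self):
        peaks = pd.DataFrame(
            {
                "peak_id": ["x", "x", "is", "is"],
                "sample": ["S1"] * 4,
                "replicate": [1, 2, 1, 2],
                "area": [2.0, 4.0, 2.0, 2.0],
                "is_internal_standard": [False, False, True, True],
            }
        )
        out = gco.relative_peak_areas(peaks)
        assert out["rpa_mean"].iloc[0] == pytest.approx(1.5)
        assert out["rpa_sd"].iloc[0] == pytest.approx(np.std([1.0, 2.0], ddof=1))

    def test_run_without_internal_standard_rejected(self):
        peaks = pd.DataFrame(
            {
                "peak_id": ["x"],
                "sample": ["S1"],
                "replicate": [1],
                "area": [2.0],
                "is_internal_standard": [False],
            }
        )
        with pytest.raises(ValueError, match="internal-standard"):
            gco.relative_peak_areas(peaks)


# ---------------------------------------------------------------------------
# region scoring end to end


class TestScoreRegions:
    def test_certain_detection_gives_nif_100(self):
        events = make_events([(f"J{k}", "S1", 1200, 3) for k in range(9)])
        regions = gco.score_regions(gco.cluster_events(gco.block_centre(events)), panel_size=9)
        assert regions["nif_S1"].iloc[0] == 100

    def test_uniform_max_intensity_gives_is_100(self):
        events = make_events([(f"J{k}", "S1", 1200, 5) for k in range(9)])
        regions = gco.score_regions(gco.cluster_events(gco.block_centre(events)), panel_size=9)
        assert regions["is_S1"].iloc[0] == 100
        assert regions["oi_S1"].iloc[0] == 100
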