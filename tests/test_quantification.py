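"""Integrated-intensity measurement, binning, and clustering readouts."""

import numpy as np
import pytest

from chromoquant import (
    bin_three_ranges,
    clustering_summary,
    integrated_intensity,
    measure_foci,
    measure_nuclei,
    tertile_edges,
)
from chromoquant.quantification import FocusRecord, NucleusRecord
from chromoquant.segmentation import LabelMap


class TestIntegratedIntensity:
    def test_zero_image_sums_to_zero(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True
        assert integrated_intensity(mask, np.zeros((8, 8))) == 0.0

    def test_three_pixel_arithmetic(self):
        img = np.zeros((4, 4))
        img[0, 0], img[1, 1], img[2, 2] = 1.0, 2.0, 3.0
        assert integrated_intensity(([0, 1, 2], [0, 1, 2]), img) == 6.0

    def test_matches_explicit_accumulation_loop(self, rng):
        img = rng.random((32, 32)) * 100
        rows = rng.integers(0, 32, size=200)
        cols = rng.integers(0, 32, size=200)
        expected = 0.0
        for r, c in zip(rows, cols):  # independent brute-force oracle
            expected += img[r, c]
        assert integrated_intensity((rows, cols), img) == pytest.approx(
            expected, rel=1e-12
        )

    def test_empty_region_is_zero(self, rng):
        assert integrated_intensity(([], []), rng.random((4, 4))) == 0.0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            integrated_intensity(([5], [0]), np.zeros((4, 4)))


class TestMeasureNuclei:
    def test_constant_mark_area_and_sum(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[0, :10] = 1  # 10 pixels
        recs = measure_nuclei(LabelMap(labels, 1), np.full((10, 10), 4.0))
        assert len(recs) == 1
        assert recs[0].area_px == 10
        assert recs[0].integrated_intensity == 40.0

    def test_equivalent_radius_formula(self):
        # a 314-pixel object: sqrt(314 / pi) ~ 9.997
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[0] = 0
        flat = labels.ravel()
        flat[:314] = 1
        recs = measure_nuclei(LabelMap(flat.reshape(40, 40), 1), np.ones((40, 40)))
        assert recs[0].area_px == 314
        assert recs[0].equivalent_radius_px == pytest.approx(9.9974, abs=1e-3)

    def test_sums_match_truth_mask_brute_force(self, segmented_field):
        _, _, _, _, mark, nuclei, _ = segmented_field
        recs = measure_nuclei(nuclei, mark)
        img = mark.pixels.astype(float)
        for rec in recs:
            mask = nuclei.labels == rec.nucleus_id
            brute = float(img[mask].sum())  # direct mask summation oracle
            assert rec.integrated_intensity == pytest.approx(brute, rel=1e-9)
            assert rec.area_px == int(mask.sum())

    def test_compartment_mapping_applied(self):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[1:3, 1:3] = 1
        labels[4:6, 4:6] = 2
        recs = measure_nuclei(
            LabelMap(labels, 2), np.ones((6, 6)), {1: "positive"}
        )
        assert recs[0].compartment == "positive"
        assert recs[1].compartment == "unassigned"


class TestMeasureFoci:
    def test_no_foci_counts_zero(self):
        foci = LabelMap(np.zeros((8, 8), dtype=np.int32), 0, owners={})
        recs, counts = measure_foci(foci, np.ones((8, 8)), nucleus_ids=[1, 2])
        assert recs == []
        assert counts == {1: 0, 2: 0}

    def test_two_foci_per_nucleus_counted_and_summed(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[1:3, 1:3] = 1  # area 4
        labels[6:8, 6:9] = 2  # area 6
        img = np.full((10, 10), 2.0)
        foci = LabelMap(labels, 2, owners={1: 5, 2: 5})
        recs, counts = measure_foci(foci, img)
        assert counts == {5: 2}
        assert {r.focus_id: r.integrated_intensity for r in recs} == {1: 8.0, 2: 12.0}

    def test_orphan_focus_rejected(self):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[2:4, 2:4] = 1
        foci = LabelMap(labels, 1, owners={})
        with pytest.raises(ValueError, match="no owning nucleus"):
            measure_foci(foci, np.ones((6, 6)))


class TestBinThreeRanges:
    def test_one_value_per_bin(self):
        dist = bin_three_ranges([1, 5, 9], (4, 8))
        assert dist.fractions == pytest.approx((1 / 3, 1 / 3, 1 / 3))
        assert dist.n == 3

    def test_all_below_first_edge(self):
        assert bin_three_ranges([1, 2, 3], (4, 8)).fractions == (1.0, 0.0, 0.0)

    def test_boundary_values_go_to_upper_range(self):
        # intervals are [min, e1), [e1, e2), [e2, inf)
        dist = bin_three_ranges([4.0, 8.0], (4, 8))
        assert dist.fractions == (0.0, 0.5, 0.5)

    def test_uniform_values_at_tertile_edges(self, rng):
        vals = rng.random(1000)
        edges = tertile_edges(vals)
        dist = bin_three_ranges(vals, edges)
        # direct counting oracle
        expected = (
            np.mean(vals < edges[0]),
            np.mean((vals >= edges[0]) & (vals < edges[1])),
            np.mean(vals >= edges[1]),
        )
        assert dist.fractions == pytest.approx(expected, abs=1e-12)
        assert all(abs(f - 1 / 3) < 0.05 for f in dist.fractions)

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            bin_three_ranges([], (1, 2))

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_three_ranges([1, 2], (5, 5))


def _nucleus(nid, comp, intensity):
    return NucleusRecord(nid, comp, 50, intensity, (0.0, 0.0), 3.99)


def _focus(fid, nid, intensity):
    return FocusRecord(fid, nid, 5, intensity)


class TestClusteringSummary:
    def test_single_group_single_focus(self):
        nrecs = [_nucleus(1, "positive", 200.0)]
        frecs = [_focus(1, 1, 40.0)]
        out = clustering_summary(nrecs, frecs, {1: 1})
        assert list(out) == ["positive"]
        assert out["positive"]["focus_intensity"].tolist() == [40.0]
        assert out["positive"]["focus_count"].tolist() == [1]
        assert out["positive"]["nucleus_intensity"].tolist() == [200.0]

    def test_empty_group_gives_empty_vectors(self):
        nrecs = [_nucleus(1, "positive", 10.0), _nucleus(2, "negative", 10.0)]
        out = clustering_summary(nrecs, [], {1: 0, 2: 0})
        assert out["negative"]["focus_intensity"].size == 0
        assert out["negative"]["focus_count"].tolist() == [0]

    def test_unknown_group_key_rejected(self):
        with pytest.raises(KeyError):
            clustering_summary([], [], {}, group_by="genotype")

    def test_coalesced_group_has_brighter_fewer_foci(self):
        """Two compartments with equal truth totals: the coalesced one has
        a larger mean individual-focus intensity and a smaller mean count."""
        nrecs, frecs, counts = [], [], {}
        fid = 1
        for nid in range(1, 11):  # dispersed: 4 foci of 100
            nrecs.append(_nucleus(nid, "negative", 400.0))
            counts[nid] = 4
            for _ in range(4):
                frecs.append(_focus(fid, nid, 100.0))
                fid += 1
        for nid in range(11, 21):  # coalesced: 2 foci of 200
            nrecs.append(_nucleus(nid, "positive", 400.0))
            counts[nid] = 2
            for _ in range(2):
                frecs.append(_focus(fid, nid, 200.0))
                fid += 1
        out = clustering_summary(nrecs, frecs, counts)
        assert (
            out["positive"]["focus_intensity"].mean()
            > out["negative"]["focus_intensity"].mean()
        )
        assert (
            out["positive"]["focus_count"].mean()
            < out["negative"]["focus_count"].mean()
        )
        assert out["positive"]["nucleus_intensity"].mean() == pytest.approx(
            out["negative"]["nucleus_intensity"].mean()
        )


class TestInvariants:
    def test_foci_sum_bounded_by_nucleus_sum(self, segmented_field):
        """Foci pixels are a subset of nucleus pixels with non-negative
        intensities, so per-nucleus focus totals never exceed the nucleus
        total."""
        _, _, _, _, mark, nuclei, foci = segmented_field
        nrecs = measure_nuclei(nuclei, mark)
        frecs, _ = measure_foci(foci, mark)
        totals = {r.nucleus_id: r.integrated_intensity for r in nrecs}
        per_nucleus = {}
        for f in frecs:
            per_nucleus[f.nucleus_id] = (
                per_nucleus.get(f.nucleus_id, 0.0) + f.integrated_intensity
            )
        for nid, fsum in per_nucleus.items():
            assert fsum <= totals[nid] + 1e-6

    def test_scaling_mark_scales_intensities_only(self, segmented_field):
        _, _, _, _, mark, nuclei, foci = segmented_field
        c = 3.0
        scaled = mark.pixels.astype(np.float64) * c
        n1 = measure_nuclei(nuclei, mark.pixels)
        n2 = measure_nuclei(nuclei, scaled)
        for a, b in zip(n1, n2):
            assert b.integrated_intensity == pytest.approx(
                c * a.integrated_intensity, rel=1e-12
            )
            assert b.area_px == a.area_px
        f1, c1 = measure_foci(foci, mark.pixels)
        f2, c2 = measure_foci(foci, scaled)
        assert c1 == c2
        for a, b in zip(f1, f2):
            assert b.integrated_intensity == pytest.approx(
                c * a.integrated_intensity, rel=1e-12
            )

    def test_relabeling_permutes_but_preserves_values(self, segmented_field):
        _, _, _, _, mark, nuclei, _ = segmented_field
        n = nuclei.n_objects
        perm = np.concatenate([[0], np.roll(np.arange(1, n + 1), 1)])
        relabeled = LabelMap(perm[nuclei.labels], n)
        orig = measure_nuclei(nuclei, mark)
        new = measure_nuclei(relabeled, mark)
        orig_vals = sorted(round(r.integrated_intensity, 6) for r in orig)
        new_vals = sorted(round(r.integrated_intensity, 6) for r in new)
        assert orig_vals == new_vals
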