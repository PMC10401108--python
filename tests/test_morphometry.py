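"""Vesicle morphometry: labelling vs flood-fill oracle, counting rules,
summary statistics and the power-law cargo scaling."""

from collections import deque

import numpy as np
import pytest

from ossify import (CellRecord, LabelVolume, StackSummary, VesicleRecord,
                    allometric_fit, build_cell_records, build_vesicle_records,
                    label_components, pooled_stats, stack_summary, vesicle_density)

# Table-style reference inputs for the three imaged stacks:
# (n_vesicles, mean vesicle volume µm³, mean filling factor)
STACKS = [(122, 0.60, 0.094), (270, 0.74, 0.085), (40, 0.26, 0.101)]


def _offsets(connectivity):
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                manhattan = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                out.append((dz, dy, dx))
    return out


def flood_fill_partition(mask, connectivity):
    """Independent BFS connected-component partition (set of voxel frozensets)."""
    offsets = _offsets(connectivity)
    seen = np.zeros_like(mask, dtype=bool)
    parts = set()
    shape = mask.shape
    for idx in zip(*np.nonzero(mask)):
        if seen[idx]:
            continue
        comp = []
        queue = deque([idx])
        seen[idx] = True
        while queue:
            z, y, x = queue.popleft()
            comp.append((z, y, x))
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(n, shape)) \
                        and mask[n] and not seen[n]:
                    seen[n] = True
                    queue.append(n)
        parts.add(frozenset(comp))
    return parts


def _partition_from_labels(labels):
    parts = set()
    for lab in np.unique(labels[labels > 0]):
        parts.add(frozenset(zip(*np.nonzero(labels == lab))))
    return parts


class TestLabelComponents:
    def test_single_sphere_one_label(self):
        z, y, x = np.ogrid[:16, :16, :16]
        mask = (z - 8) ** 2 + (y - 8) ** 2 + (x - 8) ** 2 <= 25
        assert label_components(mask).n_labels == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_two_separated_spheres_two_labels(self, connectivity):
        mask = np.zeros((8, 8, 20), dtype=bool)
        mask[3:6, 3:6, 2:5] = True
        mask[3:6, 3:6, 10:13] = True
        assert label_components(mask, connectivity).n_labels == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(200):
            mask = rng.random((6, 6, 6)) < 0.4
            ours = _partition_from_labels(
                label_components(mask, connectivity).labels)
            assert ours == flood_fill_partition(mask, connectivity)

    def test_labels_in_scan_order(self):
        mask = np.zeros((3, 3, 9), dtype=bool)
        mask[1, 1, 6] = True
        mask[1, 1, 0] = True
        labels = label_components(mask).labels
        assert labels[1, 1, 0] == 1 and labels[1, 1, 6] == 2


def _labels(arr, name, vs=0.2):
    return LabelVolume(np.asarray(arr, dtype=np.int32), name, vs)


class TestBuildVesicleRecords:
    def test_phantom_truth_recovered_exactly(self, small_phantom):
        records, qc = build_vesicle_records(small_phantom.truth["vesicle"],
                                            small_phantom.truth["precursor"],
                                            small_phantom.truth["cell"])
        truth = {r.vesicle_id: r for r in small_phantom.truth_table}
        assert {r.vesicle_id for r in records} == set(truth)
        for rec in records:
            t = truth[rec.vesicle_id]
            assert rec.vesicle_volume == t.vesicle_volume
            assert rec.precursor_volume == t.precursor_volume
            assert rec.filling_factor == t.filling_factor
            assert rec.cell_id == t.cell_id
            assert np.allclose(rec.centroid, t.centroid,
                               atol=small_phantom.params.voxel_size)
        assert qc.orphan_precursor_voxels == 0

    def test_vesicle_without_precursor_excluded(self):
        ves = np.zeros((4, 4, 10), dtype=np.int32)
        ves[1:3, 1:3, 1:3] = 1
        ves[1:3, 1:3, 6:8] = 2
        prec = np.zeros_like(ves)
        prec[1, 1, 1] = 1  # cargo only in vesicle 1
        cells = np.ones_like(ves)
        records, qc = build_vesicle_records(_labels(ves, "vesicle"),
                                            _labels(prec, "precursor"),
                                            _labels(cells, "cell"), min_volume=0)
        assert [r.vesicle_id for r in records] == [1]
        assert qc.n_excluded_no_precursor == 1

    def test_filling_factor_is_voxel_ratio(self):
        # 1000 vesicle voxels with 90 precursor voxels -> factor 0.090
        ves = np.zeros((10, 10, 10), dtype=np.int32)
        ves.ravel()[:1000] = 1
        prec = np.zeros_like(ves)
        prec.ravel()[:90] = 1
        cells = np.ones_like(ves)
        records, _ = build_vesicle_records(_labels(ves, "v", 0.008),
                                           _labels(prec, "p", 0.008),
                                           _labels(cells, "c", 0.008),
                                           min_volume=0)
        assert records[0].filling_factor == pytest.approx(0.09)

    def test_orphan_precursor_counted(self):
        ves = np.zeros((4, 4, 4), dtype=np.int32)
        ves[1, 1, 1] = 1
        prec = np.zeros_like(ves)
        prec[1, 1, 1] = 1
        prec[3, 3, 3] = 2  # entirely outside any vesicle
        records, qc = build_vesicle_records(_labels(ves, "v"), _labels(prec, "p"),
                                            _labels(np.ones_like(ves), "c"),
                                            min_volume=0)
        assert qc.orphan_precursor_voxels == 1
        assert len(records) == 1

    def test_split_precursor_assigned_by_majority(self):
        ves = np.zeros((3, 3, 8), dtype=np.int32)
        ves[1, 1, 0:3] = 1
        ves[1, 1, 3:8] = 2
        prec = np.zeros_like(ves)
        prec[1, 1, 2:6] = 1  # 1 voxel in vesicle 1, 3 voxels in vesicle 2
        records, _ = build_vesicle_records(_labels(ves, "v"), _labels(prec, "p"),
                                           _labels(np.ones_like(ves), "c"),
                                           min_volume=0)
        by_id = {r.vesicle_id: r for r in records}
        assert set(by_id) == {2}  # vesicle 1 keeps no cargo
        assert by_id[2].precursor_volume == pytest.approx(4 * 0.2**3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_vesicle_records(_labels(np.zeros((3, 3, 3)), "v"),
                                  _labels(np.zeros((3, 3, 4)), "p"),
                                  _labels(np.zeros((3, 3, 3)), "c"))

    def test_boundary_flag_exactness(self, small_phantom):
        records, _ = build_vesicle_records(small_phantom.truth["vesicle"],
                                           small_phantom.truth["precursor"],
                                           small_phantom.truth["cell"])
        flagged = [r for r in records if r.touches_boundary]
        interior = [r for r in records if not r.touches_boundary]
        assert len(flagged) + len(interior) == len(records)


def _records_with(n, mean_volume, filling, rng=None):
    recs = []
    for i in range(n):
        v, f = mean_volume, filling
        recs.append(VesicleRecord(i + 1, 1, v, v * f, f, (0.0, 0.0, 0.0), False))
    return recs


class TestSummaries:
    def test_stack1_precursor_per_vesicle(self):
        records = _records_with(122, 0.60, 0.094)
        s = stack_summary(records, [CellRecord(1, 1000.0, 122, 0.122)] * 6,
                          10471.33, 2734.51, stack_id="stack1")
        assert s.precursor_per_vesicle == pytest.approx(0.056, abs=1e-3)
        assert s.n_vesicles == 122 and s.n_cells == 6

    def test_single_vesicle_identities(self):
        s = stack_summary([VesicleRecord(1, 1, 2.0, 0.2, 0.1, (0, 0, 0), False)],
                          [CellRecord(1, 10.0, 1, 0.1)], 100.0, 10.0)
        assert (s.mean_vesicle_volume, s.filling_factor) == (2.0, 0.1)
        assert s.precursor_per_vesicle == pytest.approx(0.2)

    def test_stack3_product_identity_flags_rounding(self):
        # recomputing from the rounded per-stack means gives 0.026, not the
        # printed 0.024 — the product identity itself holds to float precision
        s = stack_summary(_records_with(40, 0.26, 0.101),
                          [CellRecord(1, 100.0, 40, 0.4)] * 7, 1563.27, 767.87)
        assert s.precursor_per_vesicle == pytest.approx(0.26 * 0.101, rel=1e-12)
        assert s.precursor_per_vesicle == pytest.approx(0.026, abs=0.0005)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            stack_summary([], [], 1.0, 1.0)

    def test_mean_and_total_ratio_both_reported(self):
        recs = [VesicleRecord(1, 1, 1.0, 0.10, 0.10, (0, 0, 0), False),
                VesicleRecord(2, 1, 3.0, 0.15, 0.05, (0, 0, 0), False)]
        s = stack_summary(recs, [CellRecord(1, 10.0, 2, 0.2)], 10.0, 1.0)
        assert s.filling_factor == pytest.approx(0.075)          # mean of ratios
        assert s.filling_factor_total == pytest.approx(0.25 / 4)  # ratio of totals


class TestPooledStats:
    def _summaries(self):
        return [stack_summary(_records_with(n, v, f),
                              [CellRecord(1, 100.0, n, n / 100)], 1.0, 1.0,
                              stack_id=f"stack{i + 1}")
                for i, (n, v, f) in enumerate(STACKS)]

    def test_count_weighted_pooling_reproduces_study_means(self):
        pooled_v, pooled_f, pooled_p = pooled_stats(self._summaries())
        assert pooled_v == pytest.approx(0.656, abs=0.001)
        assert pooled_f == pytest.approx(0.089, abs=0.0005)
        assert pooled_p == pytest.approx(pooled_v * pooled_f, rel=1e-12)

    def test_single_stack_identity(self):
        s = self._summaries()[:1]
        pooled_v, pooled_f, _ = pooled_stats(s)
        assert (pooled_v, pooled_f) == (s[0].mean_vesicle_volume,
                                        s[0].filling_factor)

    def test_equal_stacks_pool_to_common_value(self):
        s = stack_summary(_records_with(10, 0.5, 0.09),
                          [CellRecord(1, 10.0, 10, 1.0)], 1.0, 1.0)
        pooled_v, pooled_f, _ = pooled_stats([s, s, s])
        assert (pooled_v, pooled_f) == pytest.approx((0.5, 0.09))

    def test_zero_total_count_rejected(self):
        s = StackSummary("s", 1, 1, 1, 0, 0.5, 0.1, 0.05)
        with pytest.raises(ValueError):
            pooled_stats([s])


class TestAllometricFit:
    def test_exact_proportionality_gives_unit_exponent(self):
        rng = np.random.default_rng(0)
        recs = [VesicleRecord(i, 1, v, 0.09 * v, 0.09, (0, 0, 0), False)
                for i, v in enumerate(rng.uniform(0.05, 2.8, 50), 1)]
        fit = allometric_fit(recs)
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)
        assert fit.log_prefactor == pytest.approx(np.log10(0.09), abs=1e-9)

    def test_constant_filling_with_noise_exponent_near_one(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(np.log(0.65) - 0.405, 0.9, 400)
        recs = [VesicleRecord(i + 1, 1, float(vi),
                              float(0.09 * vi * np.exp(rng.normal(0, 0.2))),
                              0.09, (0, 0, 0), False) for i, vi in enumerate(v)]
        fit = allometric_fit(recs)
        assert fit.exponent == pytest.approx(1.0, abs=0.05)
        assert fit.n == 400

    def test_three_collinear_points_slope_two(self):
        recs = [VesicleRecord(i, 1, 10.0**i, 10.0 ** (2 * i), 1, (0, 0, 0), False)
                for i in (1, 2, 3)]
        fit = allometric_fit(recs)
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)
        assert fit.exponent_se == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        same = [VesicleRecord(i, 1, 1.0, 0.1, 0.1, (0, 0, 0), False)
                for i in range(5)]
        with pytest.raises(ValueError):
            allometric_fit(same)
        with pytest.raises(ValueError):
            allometric_fit(same[:2])


class TestVesicleDensity:
    def test_37_vesicles_per_1000_um3(self):
        pooled, per_cell = vesicle_density([CellRecord(1, 1000.0, 37, 0.037)])
        assert pooled == pytest.approx(0.037)
        assert per_cell == [pytest.approx(0.037)]

    def test_pooled_is_ratio_of_totals(self):
        cells = [CellRecord(1, 200.0, 10, 0.05), CellRecord(2, 400.0, 20, 0.05)]
        pooled, _ = vesicle_density(cells)
        assert pooled == pytest.approx(0.05)

    def test_no_vesicles_zero_density(self):
        pooled, _ = vesicle_density([CellRecord(1, 100.0, 0, 0.0)])
        assert pooled == 0.0

    def test_cell_records_from_phantom(self, small_phantom):
        records, _ = build_vesicle_records(small_phantom.truth["vesicle"],
                                           small_phantom.truth["precursor"],
                                           small_phantom.truth["cell"])
        cells = build_cell_records(small_phantom.truth["cell"], records)
        truth = small_phantom.cell_table
        assert [c.n_vesicles for c in cells] == [c.n_vesicles for c in truth]
        assert [c.imaged_cell_volume for c in cells] == pytest.approx(
            [c.imaged_cell_volume for c in truth])
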