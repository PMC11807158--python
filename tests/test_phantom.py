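"""Phantom generator: geometry, rendering, lesion semantics, cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathaware.phantom import (CohortSpec, FovealDip, LesionSpec, Noise,
                               PhantomSpec, Undulation, column_thicknesses,
                               generate_boundaries, inject_lesion,
                               make_bscan, plan_cohort, render_bscan)
from pathaware.types import SUBLAYER_IDS


class TestBoundaries:
    def test_flat_spec_gives_horizontal_lines(self, flat_spec):
        b = generate_boundaries(flat_spec)
        assert np.allclose(b, np.array(flat_spec.base_depths)[:, None])

    def test_same_seed_reproduces_curves(self, small_spec):
        assert np.array_equal(generate_boundaries(small_spec),
                              generate_boundaries(small_spec))

    def test_different_seed_changes_curves(self, small_spec):
        other = PhantomSpec(width=small_spec.width, height=small_spec.height,
                            seed=small_spec.seed + 1)
        assert not np.array_equal(generate_boundaries(small_spec),
                                  generate_boundaries(other))

    def test_foveal_dip_depth_at_center(self):
        # dip displaces the inner surface by its full depth at the center
        spec = PhantomSpec(width=320, height=160,
                           base_depths=(40, 70, 90, 100, 110, 120),
                           undulation=Undulation(amplitude=0.0,
                                                 thickness_amplitude=0.0),
                           foveal_dip=FovealDip(depth=40.0))
        b = generate_boundaries(spec)
        off_center = b[0, 0]          # Gaussian tail ~exp(-8.7), negligible
        assert b[0, 160] - off_center == pytest.approx(40.0, abs=0.5)

    def test_ordering_always_strict(self, small_spec):
        b = generate_boundaries(small_spec)
        assert (np.diff(b, axis=0) > 0).all()

    def test_unorderable_spec_rejected(self):
        spec = PhantomSpec(width=64, height=160,
                           base_depths=(40, 44, 48, 52, 56, 60),
                           foveal_dip=FovealDip(depth=60.0))
        with pytest.raises(ValueError, match="unordered"):
            generate_boundaries(spec)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), severity=st.floats(0.0, 1.0))
    def test_ordering_property_across_seeds_and_severity(self, seed, severity):
        spec = PhantomSpec(width=128, height=160, seed=seed,
                           severity=severity)
        b = generate_boundaries(spec)
        assert (np.diff(b, axis=0) > 0).all()
        assert b.min() >= 0 and b.max() <= 160


class TestRendering:
    def test_noise_free_image_is_piecewise_constant(self, clean_spec):
        b = generate_boundaries(clean_spec)
        image, sub, _ = render_bscan(b, clean_spec)
        expected = np.asarray(clean_spec.layer_intensities)[sub.labels]
        assert np.array_equal(image, expected)

    def test_total_mask_partitions_sublayers(self, small_spec):
        b = generate_boundaries(small_spec)
        _, sub, total = render_bscan(b, small_spec)
        assert (total.labels > 0).sum() == sum(
            (sub.labels == k).sum() for k in SUBLAYER_IDS)
        assert np.array_equal(total.labels > 0, sub.labels > 0)

    def test_flat_band_pixel_counts_match_thickness(self, flat_spec):
        b = generate_boundaries(flat_spec)
        _, sub, _ = render_bscan(b, flat_spec)
        depths = flat_spec.base_depths
        for k in SUBLAYER_IDS:
            t_k = depths[k] - depths[k - 1]
            assert (sub.labels == k).sum() == t_k * flat_spec.width

    def test_lesion_free_columns_are_class_ordered(self, small_spec):
        _, sub, _, _ = make_bscan(small_spec)
        for c in range(0, small_spec.width, 17):
            col = sub.labels[:, c]
            runs = col[col > 0]
            assert np.array_equal(np.unique(runs), SUBLAYER_IDS)
            # contiguous and ordered 1..5 top to bottom
            assert (np.diff(runs) >= 0).all()

    def test_same_seed_bit_identical_scan(self, small_spec):
        a = make_bscan(small_spec)
        b = make_bscan(small_spec)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1].labels, b[1].labels)


class TestLesion:
    def test_zero_severity_is_identity(self, healthy_scan, small_spec):
        image, sub, total = healthy_scan
        lesion = LesionSpec(column_spans=((50, 90),), severity=0.0)
        img2, sub2, tot2, box = inject_lesion(image, sub, total, lesion,
                                              small_spec)
        assert box is None
        assert np.array_equal(img2, image)
        assert np.array_equal(sub2.labels, sub.labels)

    def test_full_severity_box_covers_span_exactly(self, healthy_scan,
                                                   small_spec):
        image, sub, total = healthy_scan
        lesion = LesionSpec(column_spans=((100, 180),),
                            absent_layers=("PR-IS",), severity=1.0)
        _, sub2, _, box = inject_lesion(image, sub, total, lesion, small_spec)
        assert (box.x_start, box.x_end) == (100, 180)
        thick = column_thicknesses(sub2.labels)
        affected = (thick == 0).any(axis=0)
        assert np.flatnonzero(affected).min() == 100
        assert np.flatnonzero(affected).max() == 179
        # outside the box every sublayer is present
        outside = np.ones(small_spec.width, bool)
        outside[100:180] = False
        assert (thick[:, outside] > 0).all()

    def test_disjoint_spans_merge_into_single_box(self, healthy_scan,
                                                  small_spec):
        image, sub, total = healthy_scan
        lesion = LesionSpec(column_spans=((30, 50), (250, 270)),
                            absent_layers=("PR-OS",), severity=1.0)
        _, _, _, box = inject_lesion(image, sub, total, lesion, small_spec)
        assert (box.x_start, box.x_end) == (30, 270)

    def test_partial_severity_thins_without_box(self, healthy_scan,
                                                small_spec):
        image, sub, total = healthy_scan
        lesion = LesionSpec(column_spans=((100, 180),),
                            absent_layers=("PR-OS",), severity=0.5)
        _, sub2, _, box = inject_lesion(image, sub, total, lesion, small_spec)
        assert box is None
        before = column_thicknesses(sub.labels)[3, 100:180]
        after = column_thicknesses(sub2.labels)[3, 100:180]
        assert (after < before).all() and (after > 0).all()

    def test_total_band_stays_single_connected_run(self, diseased_scan):
        _, _, total, box = diseased_scan
        assert box is not None
        for c in range(total.labels.shape[1]):
            col = total.labels[:, c]
            on = np.flatnonzero(col)
            if on.size:
                assert on.max() - on.min() + 1 == on.size  # contiguous

    def test_total_mask_still_partitions_sublayers(self, diseased_scan):
        _, sub, total, _ = diseased_scan
        assert np.array_equal(total.labels > 0, sub.labels > 0)


class TestCohort:
    def test_full_progstar_scale_bookkeeping(self):
        from pathaware.study import BOOKKEEPING_SITES

        spec = CohortSpec(sites=BOOKKEEPING_SITES, visits=5,
                          eyes=("OD", "OS"), slices_per_volume=49, seed=0)
        manifest = plan_cohort(spec)
        volumes = manifest.groupby(["patient_id", "visit", "eye"]).ngroups
        assert sum(BOOKKEEPING_SITES.values()) == 259
        assert volumes == 2_590
        assert len(manifest) == 126_910

    def test_single_volume_manifest(self):
        spec = CohortSpec(sites={"s": 1}, visits=1, eyes=("OD",),
                          slices_per_volume=49, seed=0)
        assert len(plan_cohort(spec)) == 49

    def test_severity_monotone_across_visits(self):
        spec = CohortSpec(sites={"s": 5}, visits=5, seed=3)
        manifest = plan_cohort(spec)
        per = manifest.groupby(["patient_id", "eye", "slice_index"])
        for _, rows in per:
            sev = rows.sort_values("visit")["severity"].to_numpy()
            assert (np.diff(sev) >= -1e-12).all()

    def test_healthy_cohort_severity_zero(self):
        spec = CohortSpec(sites={"s": 3}, diseased=False, seed=3)
        assert (plan_cohort(spec)["severity"] == 0).all()

    def test_manifest_deterministic(self):
        spec = CohortSpec(sites={"a": 3, "b": 2}, seed=9)
        assert plan_cohort(spec).equals(plan_cohort(spec))
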