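"""The dust-cleanup sweep: radius rule, control flow, conservation, audit."""

import math

import numpy as np
import pytest

import atlasdust as ad
from atlasdust.cleanup import summarize_changes, replay_changes


class TestDilationRadius:
    @pytest.mark.parametrize("s,r", [(2, 1), (3, 1), (5, 2), (33, 2), (34, 3)])
    def test_sphere_volume_radius_examples(self, s, r):
        assert ad.dilation_radius(s) == r

    def test_single_voxel_size_rejected(self):
        with pytest.raises(ValueError):
            ad.dilation_radius(1)

    def test_monotone_non_decreasing(self):
        radii = [ad.dilation_radius(s) for s in range(2, 200)]
        assert all(a <= b for a, b in zip(radii, radii[1:]))
        assert radii[0] >= 1


def _constant_intensity(shape, value=100.0):
    return [ad.IntensityVolume(np.full(shape, value), modality_name="T1w")]


class TestCleanupControlFlow:
    def test_single_voxel_island_absorbed_by_surrounding_label(self):
        arr = np.full((3, 3, 3), 7, dtype=np.uint32)
        arr[1, 1, 1] = 999
        v = ad.LabelVolume(arr)
        cfg = ad.CleanupConfig(max_island_voxel_count=1, use_dilation=False)
        out, log = ad.cleanup_dust(v, _constant_intensity((3, 3, 3)), cfg)
        assert out.voxels[1, 1, 1] == 7
        moved = [r for r in log.records if r.moved]
        assert len(moved) == 1
        assert moved[0].distance == pytest.approx(0.0)

    def test_self_similar_island_skipped_without_force(self):
        # island of 7 diagonal to a 7 body; intensities make 7 its best match
        arr = np.zeros((4, 4, 1), dtype=np.uint32)
        arr[0, 0, 0] = 7
        arr[1:, 1:, 0] = 7
        arr[1, 1, 0] = 7
        v = ad.LabelVolume(arr)
        t1 = np.zeros((4, 4, 1))
        t1[arr == 7] = 200.0
        ivs = [ad.IntensityVolume(t1, modality_name="T1w")]
        cfg = ad.CleanupConfig(max_island_voxel_count=1, use_dilation=False,
                               connectivity=ad.Connectivity.FACE,
                               labels_to_review=(7,), force_relabel=False)
        out, log = ad.cleanup_dust(v, ivs, cfg)
        assert out.voxels[0, 0, 0] == 7  # unchanged
        assert any(r.note == "self-skip" for r in log.records)
        # with force on, the island must move to the best non-self label
        cfg_f = ad.CleanupConfig(max_island_voxel_count=1, use_dilation=False,
                                 connectivity=ad.Connectivity.FACE,
                                 labels_to_review=(7,), force_relabel=True)
        out_f, log_f = ad.cleanup_dust(v, ivs, cfg_f)
        assert out_f.voxels[0, 0, 0] == 0

    def test_excluded_labels_not_reviewed_but_can_receive(self):
        arr = np.full((3, 3, 3), 7, dtype=np.uint32)
        arr[1, 1, 1] = 999
        arr[0, 0, 0] = 8
        v = ad.LabelVolume(arr)
        t1 = np.full((3, 3, 3), 50.0)
        t1[0, 0, 0] = 50.0
        ivs = [ad.IntensityVolume(t1, modality_name="T1w")]
        cfg = ad.CleanupConfig(max_island_voxel_count=1, use_dilation=False,
                               labels_to_exclude=(8,), force_relabel=True)
        out, log = ad.cleanup_dust(v, ivs, cfg)
        assert all(r.old_label != 8 for r in log.records)

    def test_stage2_eradicates_suspicious_dust_of_size_up_to_six(self, defect_phantom):
        spec, (lab, ivs, post, truth) = defect_phantom
        cfg = ad.CleanupConfig(max_island_voxel_count=6,
                               connectivity=ad.Connectivity.FACE,
                               use_dilation=False, force_relabel=True,
                               labels_to_review=(spec.suspicious_label_id,))
        out, log = ad.cleanup_dust(lab, list(ivs), cfg)
        remaining = ad.find_islands(out, spec.suspicious_label_id,
                                    ad.Connectivity.FACE)
        assert all(r.size > 6 for r in remaining)

    def test_dilation_merges_nearby_pairs_and_skips_them(self):
        """Hand-traced 7x7x1 example.

        Two size-1 islands one voxel apart are both removed at s=1 (no
        dilation at s=1). The same geometry with two size-2 islands and a
        small gap merges under the s=2 dilation (r=1) into one dilated
        component of masked size 4, so both are skipped at s=2.
        """
        shape = (7, 7, 1)
        host = np.zeros(shape, dtype=np.uint32)
        t1 = np.zeros(shape)
        ivs = [ad.IntensityVolume(t1, modality_name="T1w")]

        singles = host.copy()
        singles[2, 3, 0] = 5
        singles[4, 3, 0] = 5
        v1 = ad.LabelVolume(singles)
        cfg = ad.CleanupConfig(max_island_voxel_count=2, use_dilation=True,
                               connectivity=ad.Connectivity.FACE,
                               labels_to_review=(5,), force_relabel=True)
        out1, _ = ad.cleanup_dust(v1, ivs, cfg)
        assert ad.find_islands(out1, 5, ad.Connectivity.FACE) == []

        pairs = host.copy()
        pairs[1, 3, 0] = pairs[2, 3, 0] = 5   # island A, size 2
        pairs[4, 3, 0] = pairs[5, 3, 0] = 5   # island B, size 2, gap 1
        v2 = ad.LabelVolume(pairs)
        out2, log2 = ad.cleanup_dust(v2, ivs, cfg)
        # dilated masks touch → one component of masked size 4 ≠ 2 → skipped
        assert [r.size for r in ad.find_islands(out2, 5, ad.Connectivity.FACE)] == [2, 2]
        assert all(not r.moved for r in log2.records)

    def test_isolated_pair_is_removed_with_dilation(self):
        shape = (9, 9, 1)
        arr = np.zeros(shape, dtype=np.uint32)
        arr[4, 4, 0] = arr[4, 5, 0] = 5
        v = ad.LabelVolume(arr)
        cfg = ad.CleanupConfig(max_island_voxel_count=2, use_dilation=True,
                               connectivity=ad.Connectivity.FACE,
                               labels_to_review=(5,), force_relabel=True)
        out, _ = ad.cleanup_dust(v, _constant_intensity(shape), cfg)
        assert ad.find_islands(out, 5, ad.Connectivity.FACE) == []

    def test_requires_intensities_and_coregistration(self):
        v = ad.LabelVolume(np.zeros((3, 3, 3), dtype=np.uint32))
        cfg = ad.CleanupConfig(max_island_voxel_count=1)
        with pytest.raises(ValueError):
            ad.cleanup_dust(v, [], cfg)
        bad = [ad.IntensityVolume(np.zeros((3, 3, 2)), modality_name="T1w")]
        with pytest.raises(ad.GeometryMismatchError):
            ad.cleanup_dust(v, bad, cfg)


@pytest.fixture(scope="module")
def cleanup_run(defect_phantom):
    spec, (lab, ivs, post, truth) = defect_phantom
    cfg = ad.CleanupConfig(max_island_voxel_count=6,
                           connectivity=ad.Connectivity.FACE,
                           use_dilation=False, force_relabel=True,
                           labels_to_review=(spec.suspicious_label_id,))
    out, log = ad.cleanup_dust(lab, list(ivs), cfg)
    return lab, out, log


class TestConservationAndAudit:
    def test_shape_and_total_count_conserved(self, cleanup_run):
        lab, out, log = cleanup_run
        assert out.voxels.shape == lab.voxels.shape
        assert sum(log.output_counts.values()) == lab.voxels.size

    def test_no_new_labels(self, cleanup_run):
        lab, out, _ = cleanup_run
        assert set(out.label_ids) <= set(lab.label_ids)

    def test_per_label_counts_reconcile_with_log(self, cleanup_run):
        lab, out, log = cleanup_run
        lost: dict[int, int] = {}
        gained: dict[int, int] = {}
        for r in log.records:
            if r.moved:
                lost[r.old_label] = lost.get(r.old_label, 0) + r.island.size
                gained[r.new_label] = gained.get(r.new_label, 0) + r.island.size
        for l in set(log.input_counts) | set(log.output_counts):
            expect = (log.input_counts.get(l, 0)
                      - lost.get(l, 0) + gained.get(l, 0))
            assert log.output_counts.get(l, 0) == expect

    def test_replaying_log_reproduces_output_exactly(self, cleanup_run):
        lab, out, log = cleanup_run
        replayed = replay_changes(lab, log)
        np.testing.assert_array_equal(replayed.voxels, out.voxels)

    def test_untouched_labels_bit_identical(self, cleanup_run):
        lab, out, log = cleanup_run
        touched = {r.old_label for r in log.records if r.moved}
        touched |= {r.new_label for r in log.records if r.moved}
        keep = ~np.isin(lab.voxels, sorted(touched))
        np.testing.assert_array_equal(lab.voxels[keep], out.voxels[keep])

    def test_summary_reconciles_with_volume_diff(self, cleanup_run):
        lab, out, log = cleanup_run
        summary = summarize_changes(log)
        n_diff = int((lab.voxels != out.voxels).sum())
        assert summary["total_voxels_moved"] == n_diff

    def test_empty_log_gives_zero_summary(self):
        summary = summarize_changes(ad.ChangeLog())
        assert summary["total_voxels_moved"] == 0
        assert summary["islands_moved"] == {}


def test_planted_islands_recovered_to_generating_label(defect_phantom):
    """Dust drawn from a neighbor's intensity distribution goes back to it."""
    spec, (lab, ivs, post, truth) = defect_phantom
    cfg = ad.CleanupConfig(max_island_voxel_count=6,
                           connectivity=ad.Connectivity.FACE,
                           use_dilation=False, force_relabel=True,
                           labels_to_review=(spec.suspicious_label_id,))
    out, _ = ad.cleanup_dust(lab, list(ivs), cfg)
    hits = sum(
        all(out.voxels[c] == p.true_label for c in p.coords)
        for p in truth.planted
    )
    assert hits / len(truth.planted) >= 0.95
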