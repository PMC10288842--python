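"""Tests for liver-referenced thresholding and lesion extraction."""

import numpy as np
import pytest

from netmtv import (
    PetVolume,
    ReferenceStats,
    generate_phantom,
    largest_lesion_metrics,
    segment_mtv,
    segmentation_threshold,
)
from netmtv.mtvseg import EmptySegmentationError, Lesion, SegmentationResult


def brute_force_components(binary: np.ndarray) -> list[set]:
    """Flood-fill reference labeling (26-neighborhood), for small grids."""
    todo = {tuple(i) for i in np.argwhere(binary)}
    comps = []
    while todo:
        stack = [todo.pop()]
        comp = set(stack)
        while stack:
            x, y, z = stack.pop()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        nb = (x + dx, y + dy, z + dz)
                        if nb in todo:
                            todo.remove(nb)
                            comp.add(nb)
                            stack.append(nb)
        comps.append(comp)
    return comps


class TestThreshold:
    @pytest.mark.parametrize(
        "mean, sd, expected",
        [(4.41, 1.14, 8.895), (0.0, 0.0, 0.0), (2.0, 0.0, 3.0)],
    )
    def test_formula(self, mean, sd, expected):
        assert segmentation_threshold(suv_mean=mean, suv_sd=sd) == pytest.approx(expected)

    def test_accepts_reference_stats(self):
        st = ReferenceStats(suv_mean=4.41, suv_max=6.0, suv_sd=1.14, n_voxels=600)
        assert segmentation_threshold(st) == pytest.approx(8.895)

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            segmentation_threshold(suv_mean=-1.0, suv_sd=0.5)


class TestSegmentMtv:
    def test_all_background(self):
        vol = PetVolume(np.full((20, 20, 20), 2.0), spacing=(2, 2, 2))
        seg = segment_mtv(vol, threshold=8.895)
        assert seg.total_mtv_ml == 0.0
        assert seg.lesions == ()

    def test_sphere_volume_within_shell_bound(self, lesion_phantom):
        cfg, vol, excl, truth = lesion_phantom
        seg = segment_mtv(vol, 8.895, exclusion_mask=excl, min_lesion_ml=0.5)
        assert len(seg.lesions) == 1
        true_ml = truth.lesion_volumes_ml[0]
        # surface shell: 4 pi r^2 * spacing of voxels may go either way
        shell_ml = 4 * np.pi * 25.0**2 * 2.0 / 1000.0
        assert abs(seg.total_mtv_ml - true_ml) < shell_ml
        assert abs(seg.total_mtv_ml - true_ml) / true_ml < 0.10

    def test_physiological_sphere_excluded_not_counted_as_mtv(self, lesion_phantom):
        cfg, vol, excl, truth = lesion_phantom
        seg = segment_mtv(vol, 8.895, exclusion_mask=excl, min_lesion_ml=0.5)
        seg_no_mask = segment_mtv(vol, 8.895, min_lesion_ml=0.5)
        assert seg.excluded_component_count == 1
        assert len(seg_no_mask.lesions) == 2
        assert seg_no_mask.total_mtv_ml > seg.total_mtv_ml

    def test_exclusion_mask_disjoint_from_lesions_is_noop(self, two_sphere_config):
        vol, _, _ = generate_phantom(two_sphere_config)
        mask = np.zeros(vol.shape, dtype=bool)
        mask[:3, :3, :3] = True  # corner far from both lesions
        a = segment_mtv(vol, 8.895)
        b = segment_mtv(vol, 8.895, exclusion_mask=mask)
        assert a.total_mtv_ml == b.total_mtv_ml
        assert len(a.lesions) == len(b.lesions)

    def test_threshold_monotonicity(self, lesion_phantom):
        _, vol, excl, _ = lesion_phantom
        mtvs = [segment_mtv(vol, thr, exclusion_mask=excl).total_mtv_ml
                for thr in (6.0, 8.0, 8.895, 10.0, 11.9)]
        assert all(a >= b for a, b in zip(mtvs, mtvs[1:]))

    def test_two_sphere_additivity(self, two_sphere_config):
        from dataclasses import replace

        both = two_sphere_config
        only_a = replace(both, lesions=both.lesions[:1])
        only_b = replace(both, lesions=both.lesions[1:])
        mtv = {}
        for name, cfg in [("both", both), ("a", only_a), ("b", only_b)]:
            vol, _, _ = generate_phantom(cfg)
            mtv[name] = segment_mtv(vol, 8.895).total_mtv_ml
        assert mtv["both"] == pytest.approx(mtv["a"] + mtv["b"], abs=1e-9)

    def test_strict_inequality_at_threshold(self):
        vox = np.full((10, 10, 10), 1.0)
        vox[4:6, 4:6, 4:6] = 8.895  # exactly at threshold -> background
        vol = PetVolume(vox, spacing=(2, 2, 2))
        assert segment_mtv(vol, 8.895).total_mtv_ml == 0.0

    def test_grid_mismatch_raises(self):
        vol = PetVolume(np.ones((10, 10, 10)), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="shape"):
            segment_mtv(vol, 5.0, exclusion_mask=np.zeros((5, 5, 5), dtype=bool))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_labeling_agrees_with_flood_fill(self, seed):
        rng = np.random.default_rng(seed)
        vox = rng.uniform(0, 12, (15, 15, 15))
        vol = PetVolume(vox, spacing=(2, 2, 2))
        seg = segment_mtv(vol, 8.0)
        mine = {frozenset((int(a), int(b), int(c)) for a, b, c in L.voxel_indices)
                for L in seg.lesions}
        ref = {frozenset(c) for c in brute_force_components(vox > 8.0)}
        assert mine == ref

    def test_min_lesion_ml_drops_small_components(self):
        vox = np.full((20, 20, 20), 1.0)
        vox[2, 2, 2] = 12.0  # single voxel = 0.008 ml
        vox[10:14, 10:14, 10:14] = 12.0  # 64 voxels = 0.512 ml
        vol = PetVolume(vox, spacing=(2, 2, 2))
        seg = segment_mtv(vol, 8.895, min_lesion_ml=0.1)
        assert len(seg.lesions) == 1
        assert seg.lesions[0].n_voxels == 64


class TestLargestLesion:
    def _lesion(self, n_vox, suv_max, suv_mean, anchor=(0, 0, 0)):
        idx = np.array([(anchor[0] + i, anchor[1], anchor[2]) for i in range(n_vox)])
        return Lesion(voxel_indices=idx, volume_ml=n_vox * 0.008,
                      suv_max=suv_max, suv_mean=suv_mean)

    def _seg(self, lesions):
        lesions = sorted(lesions, key=lambda L: (-L.volume_ml, -L.suv_max, L.seed_index))
        return SegmentationResult(
            lesions=tuple(lesions), threshold=8.895,
            total_mtv_ml=sum(L.volume_ml for L in lesions), excluded_component_count=0,
        )

    def test_largest_by_volume_wins(self):
        small = self._lesion(10, suv_max=20.0, suv_mean=15.0)
        big = self._lesion(50, suv_max=15.0, suv_mean=11.0, anchor=(5, 5, 5))
        assert largest_lesion_metrics(self._seg([small, big])) == (15.0, 11.0)

    def test_volume_tie_broken_by_suv_max(self):
        a = self._lesion(10, suv_max=18.0, suv_mean=12.0)
        b = self._lesion(10, suv_max=25.0, suv_mean=13.0, anchor=(5, 5, 5))
        assert largest_lesion_metrics(self._seg([a, b]))[0] == 25.0

    def test_empty_segmentation_raises(self):
        with pytest.raises(EmptySegmentationError):
            largest_lesion_metrics(self._seg([]))
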