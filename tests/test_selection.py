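"""t-test patch selection: statistic correctness, decision rules, and
the null behavior of the retention threshold."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cxrcad import (
    Patch,
    PatchConfig,
    PhantomSpec,
    SelectionConfig,
    extract_patches,
    generate_phantom,
    score_patch,
    select_patches,
    threshold_select,
    two_sample_t,
)
from cxrcad.errors import InsufficientDataError
from cxrcad.patching import resize_to_working
from cxrcad.selection import DISCARD, FORCED_DISCARD, FORCED_RETAIN, RETAIN


def _patch(pixels, box=None, parent="p", label="unknown"):
    pixels = np.asarray(pixels, dtype=float)
    if box is None:
        box = (0, 0, pixels.shape[0], pixels.shape[1])
    return Patch(parent_id=parent, box=box, pixels=pixels, lung_fraction=0.0, label=label)


class TestTwoSampleT:
    def test_textbook_example(self):
        t, dof, p = two_sample_t([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
        assert t == pytest.approx(-2.0)
        assert dof == pytest.approx(8.0)
        assert p == pytest.approx(0.0805, abs=2e-4)

    @pytest.mark.parametrize("flavor", ["welch", "pooled"])
    def test_matches_scipy_on_random_groups(self, flavor, rng):
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(2, 40))
            b = rng.normal(rng.normal(), 2, rng.integers(2, 40))
            t, dof, p = two_sample_t(a, b, flavor)
            ref = stats.ttest_ind(a, b, equal_var=(flavor == "pooled"))
            assert t == pytest.approx(ref.statistic, rel=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_equal_means(self):
        t, _, p = two_sample_t([0.4, 0.4, 0.4], [0.4, 0.4, 0.4])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_unequal_means(self):
        t, _, p = two_sample_t([0.2] * 50, [0.8] * 50)
        assert np.isinf(t) and t < 0 and p == 0.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            two_sample_t([1.0], [1, 2, 3])

    def test_welch_equals_pooled_for_balanced_equal_variance(self, rng):
        a = rng.normal(0, 1, 30)
        b = a[::-1] + 0.5  # same sample variance, same n
        tw, dw, _ = two_sample_t(a, b, "welch")
        tp, dp, _ = two_sample_t(a, b, "pooled")
        assert tw == pytest.approx(tp)
        assert dw == pytest.approx(dp)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        a=st.lists(st.floats(0, 1, width=32), min_size=2, max_size=30),
        b=st.lists(st.floats(0, 1, width=32), min_size=2, max_size=30),
        flavor=st.sampled_from(["welch", "pooled"]),
    )
    def test_properties_hold_for_arbitrary_groups(self, a, b, flavor):
        """p in [0,1]; swapping groups flips t and keeps p; agreement
        with the reference implementation away from degeneracy."""
        t1, dof1, p1 = two_sample_t(a, b, flavor)
        t2, _, p2 = two_sample_t(b, a, flavor)
        assert 0.0 <= p1 <= 1.0
        assert t1 == pytest.approx(-t2, abs=1e-9) or (np.isinf(t1) and np.isinf(t2))
        assert p1 == pytest.approx(p2, abs=1e-12)
        if np.ptp(a) > 1e-6 or np.ptp(b) > 1e-6:
            ref = stats.ttest_ind(a, b, equal_var=(flavor == "pooled"))
            assert p1 == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)

    def test_two_sided_p_symmetric_under_group_swap(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(1, 2, 25)
        t1, _, p1 = two_sample_t(a, b)
        t2, _, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestScorePatch:
    def test_fully_nonlung_forced_discard(self):
        mask = np.zeros((32, 32), dtype=np.uint8)
        st = score_patch(_patch(np.random.rand(32, 32)), mask, SelectionConfig())
        assert st.decision == FORCED_DISCARD
        assert st.n_lung == 0 and st.n_nonlung == 32 * 32

    def test_fully_lung_forced_retain(self):
        mask = np.ones((32, 32), dtype=np.uint8)
        st = score_patch(_patch(np.random.rand(32, 32)), mask, SelectionConfig())
        assert st.decision == FORCED_RETAIN

    def test_boundary_patch_with_contrast_retained(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[:, :16] = 1
        pixels = np.where(mask == 1, 0.3, 0.7) + rng.normal(0, 0.02, (32, 32))
        st = score_patch(_patch(pixels), mask, SelectionConfig())
        assert st.decision == RETAIN
        assert st.p_value < 1e-10
        # oracle: same test on the two extracted pixel groups
        t, _, p = two_sample_t(pixels[mask == 1], pixels[mask == 0])
        assert st.t_statistic == pytest.approx(t)
        assert st.p_value == pytest.approx(p)

    def test_null_rejection_rate_near_alpha(self):
        """Constant image across the lung boundary: retention should be a
        type-I error occurring at roughly the 0.003 threshold rate."""
        rng = np.random.default_rng(42)
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[:, :8] = 1
        config = SelectionConfig()
        n, rejections = 2000, 0
        for _ in range(n):
            pixels = 0.5 + rng.normal(0, 0.02, (16, 16))
            if score_patch(_patch(pixels), mask, config).decision == RETAIN:
                rejections += 1
        assert rejections / n == pytest.approx(0.003, abs=0.004)

    def test_group_sizes_partition_patch(self, rng):
        mask = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        st = score_patch(_patch(rng.random((32, 32))), mask, SelectionConfig())
        assert st.n_lung + st.n_nonlung == 32 * 32


class TestSelectPatches:
    def test_empty_input(self):
        retained, all_stats = select_patches([], lambda _i: None)
        assert retained == [] and all_stats == []

    def test_equals_per_patch_brute_force(self, nodule_phantom):
        config = PatchConfig(n_patches=11, patch_size=64, working_resolution=256)
        working = resize_to_working(nodule_phantom, 256)
        patches = extract_patches(nodule_phantom, config)
        sel_config = SelectionConfig()
        retained, all_stats = select_patches(patches, lambda _i: working.mask, sel_config)
        oracle = [
            p for p in patches
            if score_patch(p, working.mask, sel_config).decision in (RETAIN, FORCED_RETAIN)
        ]
        assert [p.box for p in retained] == [p.box for p in oracle]
        assert len(all_stats) == len(patches)

    def test_raising_threshold_never_shrinks_retention(self, nodule_phantom, rng):
        config = PatchConfig(n_patches=11, patch_size=64, working_resolution=256)
        working = resize_to_working(nodule_phantom, 256)
        # add jitter so p-values spread over a range
        patches = extract_patches(nodule_phantom, config)
        for p in patches:
            p.pixels = np.clip(p.pixels + rng.normal(0, 0.2, p.pixels.shape), 0, 1)
        kept = []
        for thr in (1e-12, 1e-6, 0.003, 0.5):
            retained, _ = select_patches(
                patches, lambda _i: working.mask, SelectionConfig(p_threshold=thr)
            )
            kept.append({id(p) for p in retained})
        for small, big in zip(kept, kept[1:]):
            assert small <= big


class TestThresholdSelect:
    def test_uniform_bright_patch_discarded(self):
        assert threshold_select([_patch(np.full((16, 16), 0.9))]) == []

    def test_bimodal_patch_retained(self):
        pixels = np.concatenate(
            [np.full(128, 0.2), np.full(128, 0.8)]
        ).reshape(16, 16)
        retained = threshold_select([_patch(pixels)], min_dark_fraction=0.3)
        assert len(retained) == 1  # Otsu splits between modes; dark fraction 0.5

    def test_explicit_cutoff(self):
        dark = _patch(np.full((8, 8), 0.1))
        bright = _patch(np.full((8, 8), 0.9))
        retained = threshold_select([dark, bright], dark_cutoff=0.5, min_dark_fraction=0.3)
        assert retained == [dark]

    def test_empty_input(self):
        assert threshold_select([]) == []
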