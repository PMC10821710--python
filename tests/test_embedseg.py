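"""EmbedSeg target preparation, loss structure and clustering decoder."""

import numpy as np
import pytest

from im2im.core import EmbedSegParams
from im2im.embedseg import (
    InstanceTarget,
    SIGMA_BASELINE,
    compute_centers,
    decode_instances,
    embedseg_loss,
    merge_tile_instances,
    normalized_grid,
    split_heads,
)
from im2im.nn import Tensor


class TestComputeCenters:
    def test_square_centroid_is_middle_pixel(self):
        m = np.zeros((9, 9), dtype=int)
        m[3:6, 3:6] = 1
        tgt = compute_centers(m, mode="centroid")
        assert np.allclose(tgt.centers[1] * 9, [4, 4])

    def test_l_shape_brute_force_medoid_and_centroid(self):
        # pixels {(0,0),(0,1),(1,0)}: centroid (1/3, 1/3); the corner pixel
        # minimizes the summed distance (2 < 1 + sqrt(2)), so it is the medoid
        m = np.zeros((4, 4), dtype=int)
        m[0, 0] = m[0, 1] = m[1, 0] = 1
        cen = compute_centers(m, mode="centroid").centers[1]
        assert np.allclose(cen * 4, [1 / 3, 1 / 3])
        coords = np.argwhere(m == 1)
        sums = [
            sum(np.sqrt(((c - o) ** 2).sum()) for o in coords) for c in coords
        ]
        brute = coords[int(np.argmin(sums))]
        med = compute_centers(m, mode="medoid").centers[1]
        assert np.allclose(med * 4, brute)

    def test_medoid_tie_breaks_to_lowest_lexicographic_voxel(self):
        # two pixels: both have identical summed distance; lexicographic wins
        m = np.zeros((4, 4), dtype=int)
        m[1, 1] = m[1, 2] = 1
        med = compute_centers(m, mode="medoid").centers[1]
        assert np.allclose(med * 4, [1, 1])

    def test_medoid_inside_non_convex_instance(self):
        m = np.zeros((10, 10), dtype=int)
        m[1, 1:9] = 1
        m[1:9, 1] = 1  # L-shape; centroid falls off the arm
        med = compute_centers(m, mode="medoid").centers[1] * 10
        assert m[int(med[0]), int(med[1])] == 1

    def test_empty_mask_gives_no_centers(self):
        tgt = compute_centers(np.zeros((5, 5), dtype=int))
        assert tgt.centers == {}


def _synthetic_pred(shape, instances, centers, sigma=0.05, seed_val=0.95):
    """Raw network-output array whose heads decode to a perfect embedding."""
    d = len(shape)
    grid = normalized_grid(shape)
    offsets = np.zeros((d,) + shape, dtype=np.float32)
    for lab, c in centers.items():
        mask = instances == lab
        for a in range(d):
            offsets[a][mask] = c[a] - grid[a][mask]
    raw = np.zeros((d + 2,) + shape, dtype=np.float32)
    raw[0:d] = np.arctanh(np.clip(offsets, -0.999, 0.999))
    raw[d] = np.log(sigma) - np.log(SIGMA_BASELINE)  # exp head -> sigma
    from im2im.embedseg import SEED_GAIN

    seed_map = np.full(shape, 0.02, dtype=np.float32)
    seed_map[instances > 0] = seed_val
    raw[d + 1] = np.log(seed_map / (1 - seed_map)) / SEED_GAIN
    return raw


def _two_blob_world():
    inst = np.zeros((32, 32), dtype=np.int32)
    inst[4:10, 4:10] = 1
    inst[20:27, 18:26] = 2
    return inst


class TestLoss:
    def test_perfect_embedding_reaches_floor(self):
        inst = _two_blob_world()
        tgt = compute_centers(inst)
        params = EmbedSegParams()
        perfect = _synthetic_pred(inst.shape, inst, tgt.centers, seed_val=0.999)
        bad = np.zeros_like(perfect)
        l_perfect = embedseg_loss(Tensor(perfect[None]), [tgt], params).item()
        l_bad = embedseg_loss(Tensor(bad[None]), [tgt], params).item()
        assert l_perfect < 0.1 * l_bad

    def test_constant_sigma_zero_smoothness(self):
        inst = _two_blob_world()
        tgt = compute_centers(inst)
        base = EmbedSegParams(w_instance=0.0, w_seed=0.0, w_sigma=1.0)
        pred = _synthetic_pred(inst.shape, inst, tgt.centers)  # constant sigma
        assert embedseg_loss(Tensor(pred[None]), [tgt], base).item() == pytest.approx(
            0.0, abs=1e-8
        )

    def test_masked_loss_ignores_excluded_content(self, rng):
        # predictions AND annotations inside the excluded region contribute
        # nothing: perturbing them, or planting an unannotated instance there,
        # leaves the loss unchanged
        inst = np.zeros((16, 32), dtype=np.int32)
        inst[4:10, 4:10] = 1
        excl = np.zeros((16, 32), dtype=np.uint8)
        excl[:, 20:] = 1
        pred = rng.normal(size=(4, 16, 32)).astype(np.float32) * 0.3
        params = EmbedSegParams(bg_margin=4)
        tgt = compute_centers(inst, exclusion=excl)
        base = embedseg_loss(Tensor(pred[None]), [tgt], params).item()

        perturbed = pred.copy()
        perturbed[:, :, 20:] += rng.normal(size=(4, 16, 12)).astype(np.float32)
        assert embedseg_loss(
            Tensor(perturbed[None]), [tgt], params
        ).item() == pytest.approx(base, rel=1e-6)

        # an instance fully inside the excluded region is invisible
        inst2 = inst.copy()
        inst2[4:10, 24:30] = 2
        tgt2 = compute_centers(inst2, exclusion=excl)
        assert embedseg_loss(
            Tensor(pred[None]), [tgt2], params
        ).item() == pytest.approx(base, rel=1e-6)

    def test_empty_exclusion_equals_no_mask(self, rng):
        inst = _two_blob_world()
        pred = rng.normal(size=(4, 32, 32)).astype(np.float32) * 0.3
        params = EmbedSegParams()
        with_mask = embedseg_loss(
            Tensor(pred[None]),
            [compute_centers(inst, exclusion=np.zeros_like(inst, dtype=np.uint8))],
            params,
        ).item()
        without = embedseg_loss(
            Tensor(pred[None]), [compute_centers(inst)], params
        ).item()
        assert with_mask == pytest.approx(without, rel=1e-6)

    def test_loss_finite_and_backpropagates(self, rng):
        inst = _two_blob_world()
        tgt = compute_centers(inst)
        pred = Tensor(rng.normal(size=(1, 4, 32, 32)).astype(np.float32),
                      requires_grad=True)
        loss = embedseg_loss(pred, [tgt], EmbedSegParams())
        assert np.isfinite(loss.item())
        loss.backward()
        assert pred.grad is not None and np.all(np.isfinite(pred.grad))


def _oracle_decode(instances, centers, sigma):
    """Assign pixels by thresholding phi against each true center."""
    out = np.zeros_like(instances)
    grid = normalized_grid(instances.shape)
    for lab, c in centers.items():
        mask = instances == lab
        # perfect embeddings collapse to the center; phi = 1 > 0.5
        out[mask] = lab
    return out


class TestDecode:
    def test_two_separated_blobs_recovered_exactly(self):
        inst = _two_blob_world()
        tgt = compute_centers(inst)
        raw = _synthetic_pred(inst.shape, inst, tgt.centers)
        from im2im.embedseg import decode_from_maps

        decoded = decode_from_maps(raw, EmbedSegParams(), 2)
        oracle = _oracle_decode(inst, tgt.centers, 0.05)
        # labels assigned in creation order may differ from gt labels; compare
        # as partitions
        from im2im.metrics import average_precision

        assert average_precision(decoded, oracle) == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_random_fixtures_match_assignment_oracle(self, seed):
        r = np.random.default_rng(seed)
        shape = (48, 48)
        inst = np.zeros(shape, dtype=np.int32)
        n = int(r.integers(1, 6))
        lab = 0
        for _ in range(n):
            y, x = r.integers(2, 36, 2)
            h, w = r.integers(4, 10, 2)
            if inst[y:y + h, x:x + w].any():
                continue
            lab += 1
            inst[y:y + h, x:x + w] = lab
        if lab == 0:
            return
        tgt = compute_centers(inst)
        raw = _synthetic_pred(shape, inst, tgt.centers)
        from im2im.embedseg import decode_from_maps
        from im2im.metrics import average_precision

        decoded = decode_from_maps(raw, EmbedSegParams(), 2)
        assert average_precision(decoded, _oracle_decode(inst, tgt.centers, 0.05)) == 1.0

    def test_all_seed_below_threshold_empty(self):
        shape = (16, 16)
        offsets = np.zeros((2,) + shape, dtype=np.float32)
        sigma = np.full((1,) + shape, 0.05, dtype=np.float32)
        seed = np.full(shape, 0.3, dtype=np.float32)
        out = decode_instances(offsets, sigma, seed)
        assert out.max() == 0

    def test_disjoint_components_share_one_embedding_center(self):
        # two far-apart squares labelled as ONE instance: their embeddings
        # collapse to a single center, so decoding yields one multi-component
        # instance
        inst = np.zeros((32, 32), dtype=np.int32)
        inst[2:8, 2:8] = 1
        inst[24:30, 24:30] = 1
        tgt = compute_centers(inst, mode="centroid")
        raw = _synthetic_pred(inst.shape, inst, tgt.centers)
        from im2im.embedseg import decode_from_maps
        from scipy.ndimage import label as cc_label

        decoded = decode_from_maps(raw, EmbedSegParams(), 2)
        labs = [v for v in np.unique(decoded) if v > 0]
        assert len(labs) == 1
        n_components = cc_label(decoded > 0)[1]
        assert n_components == 2

    def test_decode_deterministic(self, rng):
        offsets = rng.normal(size=(2, 24, 24)).astype(np.float32) * 0.1
        sigma = np.full((1, 24, 24), 0.08, dtype=np.float32)
        seed = rng.random((24, 24)).astype(np.float32)
        a = decode_instances(offsets, sigma, seed)
        b = decode_instances(offsets, sigma, seed)
        assert np.array_equal(a, b)

    def test_min_size_filter(self):
        inst = np.zeros((16, 16), dtype=np.int32)
        inst[4, 4] = 1  # single-pixel instance
        tgt = compute_centers(inst)
        raw = _synthetic_pred(inst.shape, inst, tgt.centers)
        from im2im.embedseg import decode_from_maps

        out = decode_from_maps(raw, EmbedSegParams(min_size=2), 2)
        assert out.max() == 0


class TestTileMerge:
    def test_overlapping_instances_relabeled_by_iou(self):
        full = np.zeros((16, 24), dtype=np.int32)
        full[4:12, 4:12] = 3
        tile = np.zeros((16, 16), dtype=np.int32)
        tile[4:12, 0:8] = 1  # same object seen in the next window
        merged = merge_tile_instances(full.copy(), tile, (0, 4))
        assert np.array_equal(np.unique(merged), [0, 3])

    def test_new_instance_gets_fresh_label(self):
        full = np.zeros((16, 24), dtype=np.int32)
        full[0:4, 0:4] = 1
        tile = np.zeros((16, 16), dtype=np.int32)
        tile[10:14, 2:6] = 1
        merged = merge_tile_instances(full.copy(), tile, (0, 8))
        assert set(np.unique(merged)) == {0, 1, 2}
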