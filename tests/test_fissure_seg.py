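"""Hessian sheet filter, similarity model and orientation components."""

import numpy as np
import pytest

from lobereg.core_image import Volume
from lobereg.fissure_seg import (
    FissureFilterParams,
    FissureMap,
    HessianEigen,
    fissure_detection_scores,
    fissure_similarity,
    filter_components,
    hessian_eigens,
    orientation_connected_components,
    segment_fissures,
    threshold_candidates,
)
from lobereg.lung_seg import LungMask


def _eigen_from_values(lam2, lam3):
    shape = (1, 1, 1)
    return HessianEigen(
        lam1=np.zeros(shape),
        lam2=np.full(shape, float(lam2)),
        lam3=np.full(shape, float(lam3)),
        e3=np.zeros((3,) + shape),
    )


class TestHessianEigens:
    def test_quadratic_closed_form(self):
        """f = a x^2 has constant Hessian diag(2a, 0, 0)."""
        n, a = 32, 2.0
        x = np.arange(n, dtype=float) - n / 2
        v = Volume(np.broadcast_to((a * x**2)[:, None, None], (n, n, n)).copy())
        h = hessian_eigens(v, sigma=1.0)
        c = (n // 2, n // 2, n // 2)
        assert h.lam3[c] == pytest.approx(2 * a, rel=0.05)
        assert abs(h.lam1[c]) < 0.05 * 2 * a and abs(h.lam2[c]) < 0.05 * 2 * a
        assert abs(h.e3[0][c]) == pytest.approx(1.0, abs=1e-6)

    def test_constant_image_zero(self):
        h = hessian_eigens(Volume(np.full((16, 16, 16), 7.0)), sigma=1.0)
        # truncated discrete derivative kernels leave ~1e-4 residue
        np.testing.assert_allclose(h.lam3, 0.0, atol=1e-2)

    def test_gaussian_sheet_closed_form(self):
        """Bright Gaussian sheet across z: lam3 = -A s / (s^2+sigma^2)^{3/2},
        normal along z."""
        n, A, s, sigma = 33, 100.0, 1.5, 1.0
        z = np.arange(n, dtype=float) - n // 2
        profile = A * np.exp(-(z**2) / (2 * s**2))
        v = Volume(np.broadcast_to(profile[None, None, :], (n, n, n)).copy())
        h = hessian_eigens(v, sigma=sigma)
        c = (n // 2, n // 2, n // 2)
        expected = -A * s / (s**2 + sigma**2) ** 1.5
        assert h.lam3[c] == pytest.approx(expected, rel=0.05)
        assert abs(h.e3[2][c]) == pytest.approx(1.0, abs=1e-6)

    def test_ordering_and_unit_normals(self, rng):
        v = Volume(rng.normal(0, 100, (16, 16, 16)))
        h = hessian_eigens(v, sigma=1.0)
        assert np.all(np.abs(h.lam1) <= np.abs(h.lam2) + 1e-9)
        assert np.all(np.abs(h.lam2) <= np.abs(h.lam3) + 1e-9)
        np.testing.assert_allclose(np.linalg.norm(h.e3, axis=0), 1.0, atol=1e-6)

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            hessian_eigens(Volume(np.zeros((8, 8, 8))), sigma=0.0)


class TestSimilarityModel:
    @pytest.mark.parametrize(
        "lam3,lam2,expected",
        [
            (-50.0, 0.0, 1.0),  # both exponents vanish
            (-85.0, 0.0, np.exp(-1.0)),  # (85-50)^6/35^6 = 1
            (-50.0, 25.0, np.exp(-1.0)),  # 25^6/25^6 = 1
            (10.0, 0.0, 0.0),  # Theta gate: lam3 >= 0
            (0.0, 0.0, 0.0),
        ],
    )
    def test_calibration_points(self, lam3, lam2, expected):
        fm = fissure_similarity(_eigen_from_values(lam2, lam3))
        assert fm.s[0, 0, 0] == pytest.approx(expected, abs=1e-9)

    def test_s_in_unit_interval_and_gated(self, rng):
        lam2 = rng.normal(0, 60, (10, 10, 10))
        lam3 = rng.normal(0, 60, (10, 10, 10))
        h = HessianEigen(np.zeros_like(lam2), lam2, lam3, np.zeros((3, 10, 10, 10)))
        fm = fissure_similarity(h)
        assert np.all(fm.s >= 0) and np.all(fm.s <= 1)
        assert np.all(fm.s[lam3 >= 0] == 0)

    def test_literal_form_is_negligible(self):
        p = FissureFilterParams(literal_structure_term=True)
        fm = fissure_similarity(_eigen_from_values(0.0, -50.0), p)
        assert fm.s[0, 0, 0] < 1e-9

    def test_threshold_strict(self):
        normals = np.zeros((3, 1, 1, 3))
        s = np.array([[[0.1, 0.100001, 0.0]]])
        p = FissureFilterParams()
        mask = threshold_candidates(FissureMap(s=s, normals=normals), p)
        assert mask.tolist() == [[[False, True, False]]]


def _components_from_normals(positions, normals, shape=(4, 4, 4), p=None):
    cand = np.zeros(shape, dtype=bool)
    field = np.zeros((3,) + shape)
    for pos, nrm in zip(positions, normals):
        cand[pos] = True
        field[(slice(None),) + pos] = nrm
    return orientation_connected_components(cand, field, p)


class TestOrientationComponents:
    def test_sign_flip_merges(self):
        c = _components_from_normals(
            [(1, 1, 1), (1, 1, 2)], [(0, 0, 1), (0, 0, -1)]
        )
        assert c.counts.tolist() == [2]

    def test_orthogonal_split(self):
        c = _components_from_normals(
            [(1, 1, 1), (1, 1, 2)], [(0, 0, 1), (1, 0, 0)]
        )
        assert sorted(c.counts.tolist()) == [1, 1]

    @pytest.mark.parametrize("deg,merged", [(15.0, True), (20.0, False)])
    def test_cutoff_around_cos(self, deg, merged):
        a = np.deg2rad(deg)
        c = _components_from_normals(
            [(1, 1, 1), (1, 1, 2)], [(0, 0, 1), (0, np.sin(a), np.cos(a))]
        )
        assert (len(c.counts) == 1) == merged

    def test_signed_mode_keeps_flipped_apart(self):
        p = FissureFilterParams(signed_dot=True)
        c = _components_from_normals(
            [(1, 1, 1), (1, 1, 2)], [(0, 0, 1), (0, 0, -1)], p=p
        )
        assert sorted(c.counts.tolist()) == [1, 1]

    def test_partition_covers_candidates(self, rng):
        cand = rng.random((8, 8, 8)) > 0.6
        normals = rng.normal(size=(3, 8, 8, 8))
        normals /= np.linalg.norm(normals, axis=0, keepdims=True)
        c = orientation_connected_components(cand, normals)
        np.testing.assert_array_equal(c.labels > 0, cand)
        assert c.counts.sum() == cand.sum()

    def test_matches_bfs_oracle(self, rng):
        """Union-find components equal a brute-force BFS labeling."""
        from collections import deque

        p = FissureFilterParams(dot_threshold=0.8)
        for trial in range(5):
            cand = rng.random((10, 10, 10)) > 0.5
            normals = rng.normal(size=(3, 10, 10, 10))
            normals /= np.linalg.norm(normals, axis=0, keepdims=True)
            got = orientation_connected_components(cand, normals, p)

            # oracle: BFS over the same adjacency rule
            labels = np.zeros(cand.shape, dtype=int)
            nxt = 0
            offsets = [
                (i, j, k)
                for i in (-1, 0, 1)
                for j in (-1, 0, 1)
                for k in (-1, 0, 1)
                if (i, j, k) != (0, 0, 0)
            ]
            for start in map(tuple, np.argwhere(cand)):
                if labels[start]:
                    continue
                nxt += 1
                q = deque([start])
                labels[start] = nxt
                while q:
                    cur = q.popleft()
                    for off in offsets:
                        nb = tuple(np.add(cur, off))
                        if any(c < 0 or c >= 10 for c in nb):
                            continue
                        if not cand[nb] or labels[nb]:
                            continue
                        dot = abs(
                            float(np.dot(normals[(slice(None),) + cur], normals[(slice(None),) + nb]))
                        )
                        if dot >= p.dot_threshold:
                            labels[nb] = nxt
                            q.append(nb)

            # same partition up to label permutation
            for lab in range(1, nxt + 1):
                sel = labels == lab
                got_ids = np.unique(got.labels[sel])
                assert len(got_ids) == 1
                assert (got.labels == got_ids[0]).sum() == sel.sum()


class TestFilterComponents:
    def test_size_rule(self):
        from lobereg.fissure_seg import FissureComponents

        labels = np.zeros((10, 10, 10), dtype=int)
        labels.ravel()[:5] = 1
        labels.ravel()[5:125] = 2
        labels.ravel()[125:425] = 3
        c = FissureComponents(labels=labels, counts=np.array([5, 120, 300]))
        mask = filter_components(c, min_size=100)
        assert mask.sum() == 420
        assert filter_components(c, min_size=0).sum() == 425

    def test_all_removed_warns(self):
        from lobereg.fissure_seg import FissureComponents

        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0, 0, 0] = 1
        c = FissureComponents(labels=labels, counts=np.array([1]))
        with pytest.warns(UserWarning, match="removed"):
            mask = filter_components(c, min_size=10)
        assert not mask.any()


class TestSegmentFissures:
    def test_phantom_recall_precision(self, clean_atlas):
        mask, _ = segment_fissures(clean_atlas.ct, clean_atlas.lungs)
        recall, precision = fissure_detection_scores(mask, clean_atlas.fissure)
        assert recall >= 0.7
        assert precision >= 0.7

    def test_each_true_fissure_survives(self, clean_atlas):
        mask, _ = segment_fissures(clean_atlas.ct, clean_atlas.lungs)
        # left oblique, right oblique, right horizontal all intersected
        for lung, side in ((clean_atlas.lungs.left, "left"), (clean_atlas.lungs.right, "right")):
            truth = clean_atlas.fissure & lung
            assert (mask & truth).sum() > 0.3 * truth.sum(), side

    def test_vessel_tubes_rejected(self):
        """A bright tube has large |lam2|, so F_sheet suppresses it."""
        from lobereg.phantom import PhantomSpec, make_atlas_phantom

        plain = make_atlas_phantom(PhantomSpec(shape=(48, 48, 48), noise_sd=0))
        with_v = make_atlas_phantom(PhantomSpec(shape=(48, 48, 48), noise_sd=0, vessel_count=4))
        vessel_vox = with_v.ct.data != plain.ct.data
        mask, _ = segment_fissures(with_v.ct, with_v.lungs)
        recall, precision = fissure_detection_scores(mask, with_v.fissure)
        assert recall >= 0.7 and precision >= 0.7
        # vessel cores never survive into the fissure mask
        from scipy import ndimage

        core = ndimage.binary_erosion(vessel_vox)
        assert (mask & core).sum() <= 0.02 * max(core.sum(), 1)

    def test_noise_only_lung_negative_control(self, rng):
        """Featureless noisy parenchyma yields an empty fissure mask."""
        n = 48
        x, y, z = np.meshgrid(*(np.arange(n, dtype=float),) * 3, indexing="ij")
        lung = ((x - 24) / 10) ** 2 + ((y - 24) / 14) ** 2 + ((z - 24) / 18) ** 2 <= 1
        data = np.where(lung, -900.0, 40.0) + rng.normal(0, 15, (n, n, n))
        lungs = LungMask(left=lung, right=np.zeros_like(lung))
        mask, _ = segment_fissures(Volume(data), lungs)
        assert not mask.any()

    def test_rotation_equivariance(self, clean_atlas_small):
        """Rotating the scan 90 degrees about z rotates the detection."""
        rot = lambda a: np.rot90(a, k=1, axes=(0, 1)).copy()
        v_rot = Volume(rot(clean_atlas_small.ct.data))
        lungs = clean_atlas_small.lungs
        lungs_rot = LungMask(left=rot(lungs.left), right=rot(lungs.right))
        mask, _ = segment_fissures(clean_atlas_small.ct, lungs)
        mask_rot, _ = segment_fissures(v_rot, lungs_rot)
        np.testing.assert_array_equal(mask_rot, rot(mask))
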