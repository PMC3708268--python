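"""Candidate extraction, blob features, codebook quantization."""

import numpy as np
import pytest

from oracles import perimeter_edges_brute
from lungcad.features import (Codebook, build_codebook, compute_features,
                              discretize, extract_candidates)
from lungcad.phantom import PhantomConfig, generate_slice


def render_disk(radius, size=None):
    size = size or (2 * radius + 3)
    rr, cc = np.mgrid[0:size, 0:size]
    c0 = size // 2
    return (rr - c0) ** 2 + (cc - c0) ** 2 <= radius ** 2


class TestExtractCandidates:
    def test_finds_all_phantom_nodules(self, clean_phantom):
        _, image, gt = clean_phantom
        cands = extract_candidates(image, gt.lung_mask, min_area=5,
                                   intensity_quantile=0.95)
        assert len(cands) == len(gt.nodule_centers) == 3
        truth = sorted((r, c) for r, c, _rad, _m in gt.nodule_centers)
        for cand, (r, c) in zip(cands, truth):
            assert abs(cand.centroid[0] - r) <= 1 and abs(cand.centroid[1] - c) <= 1

    def test_no_nodules_empty_list(self):
        image, gt = generate_slice(PhantomConfig(n_nodules=0, seed=4))
        assert extract_candidates(image, gt.lung_mask) == []

    def test_min_area_filter_dominates(self, clean_phantom):
        _, image, gt = clean_phantom
        assert extract_candidates(image, gt.lung_mask, min_area=10 ** 5) == []

    def test_ordering_is_deterministic(self, clean_phantom):
        _, image, gt = clean_phantom
        c1 = extract_candidates(image, gt.lung_mask)
        c2 = extract_candidates(image, gt.lung_mask)
        assert [c.centroid for c in c1] == [c.centroid for c in c2]
        rows = [c.centroid[0] for c in c1]
        assert rows == sorted(rows)


class TestComputeFeatures:
    def test_single_pixel_closed_form(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        f = compute_features(mask, np.full((5, 5), 0.4))
        area, perim, circ, mean, std, _ecc = f
        assert area == 1 and perim == 4
        assert circ == pytest.approx(4 * np.pi / 16)
        assert mean == pytest.approx(0.4) and std == 0.0

    def test_disk_matches_brute_force_boundary_count(self):
        mask = render_disk(8)
        f = compute_features(mask, mask.astype(float))
        assert f[0] == mask.sum()
        assert f[1] == perimeter_edges_brute(mask)
        # digitized disk with edge-count perimeter: 4πA/P² = 4π·197/68²
        assert f[2] == pytest.approx(4 * np.pi * 197 / 68 ** 2)

    def test_circularity_ranks_round_above_elongated(self):
        disk = render_disk(6, size=40)
        bar = np.zeros((40, 40), dtype=bool)
        bar[19:21, 2:38]   = True
        img = np.ones((40, 40))
        assert compute_features(disk, img)[2] > compute_features(bar, img)[2]
        # eccentricity orders the other way
        assert compute_features(disk, img)[5] < compute_features(bar, img)[5]

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            compute_features(np.zeros((4, 4), dtype=bool), np.zeros((4, 4)))


class TestCodebook:
    def test_single_centroid_is_normalized_mean(self, rng):
        v = rng.normal(size=(20, 3))
        cb = build_codebook(v, M=1, seed=0)
        assert np.allclose(cb.centroids, 0.0, atol=1e-12)

    def test_two_separated_clusters_recovered(self, rng):
        a = rng.normal([0, 0], 0.05, (50, 2))
        b = rng.normal([5, 5], 0.05, (50, 2))
        cb = build_codebook(np.vstack([a, b]), M=2, seed=0)
        za = cb.transform(np.array([0.0, 0.0])).ravel()
        zb = cb.transform(np.array([5.0, 5.0])).ravel()
        d = [min(np.linalg.norm(c - z) for c in cb.centroids) for z in (za, zb)]
        assert max(d) < 0.1

    def test_deterministic_given_seed(self, rng):
        v = rng.normal(size=(40, 4))
        cb1 = build_codebook(v, M=3, seed=9)
        cb2 = build_codebook(v, M=3, seed=9)
        assert np.array_equal(cb1.centroids, cb2.centroids)

    def test_insufficient_distinct_vectors_rejected(self):
        v = np.tile([1.0, 2.0], (10, 1))
        with pytest.raises(ValueError):
            build_codebook(v, M=2, seed=0)

    def test_json_roundtrip(self, rng):
        cb = build_codebook(rng.normal(size=(20, 3)), M=2, seed=0)
        cb2 = Codebook.from_json(cb.to_json())
        assert np.allclose(cb.centroids, cb2.centroids)


class TestDiscretize:
    def test_single_symbol_codebook(self, rng):
        v = rng.normal(size=(10, 2))
        cb = build_codebook(v, M=1, seed=0)
        assert list(discretize(v[:3], cb)) == [0, 0, 0]

    def test_vector_at_centroid_maps_to_it(self, rng):
        v = rng.normal(size=(30, 2))
        cb = build_codebook(v, M=3, seed=0)
        raw = cb.centroids * cb.scale + cb.mean  # invert normalization
        assert list(discretize(raw, cb)) == [0, 1, 2]

    def test_matches_exhaustive_nearest_centroid(self, rng):
        v = rng.normal(size=(50, 4))
        cb = build_codebook(v, M=5, seed=1)
        got = discretize(v, cb)
        z = cb.transform(v)
        for i in range(len(v)):
            dists = [np.linalg.norm(z[i] - c) for c in cb.centroids]
            assert got[i] == int(np.argmin(dists))

    def test_idempotent(self, rng):
        v = rng.normal(size=(20, 3))
        cb = build_codebook(v, M=4, seed=2)
        assert np.array_equal(discretize(v, cb), discretize(v, cb))

    def test_empty_input_empty_sequence(self, rng):
        cb = build_codebook(rng.normal(size=(10, 2)), M=2, seed=0)
        assert len(discretize([], cb)) == 0


class TestClassSeparation:
    def test_benign_and_malignant_symbols_disjoint(self):
        """Small round vs large irregular nodules occupy disjoint symbol sets."""
        n_disjoint = 0
        n_seeds = 10
        for seed in range(n_seeds):
            img_b, gt_b = generate_slice(PhantomConfig(
                n_nodules=2, nodule_radius_range=(2.0, 3.5), seed=seed))
            img_m, gt_m = generate_slice(PhantomConfig(
                n_nodules=2, nodule_radius_range=(4.5, 6.5), malignant=True,
                seed=seed + 50))
            # quantile 0.90: the larger malignant blobs exceed 5% of the
            # lung area, so a 0.95 quantile would sit inside the nodules
            fb = [c.features for c in extract_candidates(
                img_b, gt_b.lung_mask, intensity_quantile=0.90)]
            fm = [c.features for c in extract_candidates(
                img_m, gt_m.lung_mask, intensity_quantile=0.90)]
            if not fb or not fm:
                continue
            cb = build_codebook(np.vstack(fb + fm), M=2, seed=seed)
            sb = set(discretize(np.vstack(fb), cb).tolist())
            sm = set(discretize(np.vstack(fm), cb).tolist())
            n_disjoint += int(not (sb & sm))
        assert n_disjoint >= 0.95 * n_seeds - 1  # >= 9 of 10 seeds
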