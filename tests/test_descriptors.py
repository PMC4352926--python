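"""HOG / LBP descriptors checked against independent brute-force oracles.

The oracles re-derive every step with explicit per-pixel loops and scalar
arithmetic from the documented contract (centered [-1,0,1] masks with
replicate-edge padding, unsigned orientations folded into [0,180) with
half-open 20-degree bins, 5-cell / 9-half-overlapping-block geometry,
neighbor >= center LBP codes), so they share no code with the implementation.
"""

import math

import numpy as np
import pytest

from vosshog.descriptors import (
    DescriptorError,
    HOGConfig,
    HOGTransformer,
    LBPTransformer,
    block_normalize,
    compute_gradients,
    hog_descriptor,
    lbp_descriptor,
    orientation_binning,
)
from vosshog.encoding import voss_encode
from conftest import random_sequence


# ---------------------------------------------------------------------------
# brute-force oracles


def _pixel(img, i, j):
    """Replicate-edge lookup."""
    i = min(max(i, 0), img.shape[0] - 1)
    j = min(max(j, 0), img.shape[1] - 1)
    return float(img[i, j])


def brute_gradients(img):
    rows, cols = img.shape
    ix = np.zeros((rows, cols))
    iy = np.zeros((rows, cols))
    for i in range(rows):
        for j in range(cols):
            ix[i, j] = _pixel(img, i, j + 1) - _pixel(img, i, j - 1)
            iy[i, j] = _pixel(img, i + 1, j) - _pixel(img, i - 1, j)
    return ix, iy


def brute_hog(img, n_bins=9, n_cells=5, eps=1e-5):
    rows, cols = img.shape
    ix, iy = brute_gradients(img)
    # half-span boundaries: 5 cells (remainder to the last), each halved
    base = cols // n_cells
    cell_widths = [base] * (n_cells - 1) + [cols - base * (n_cells - 1)]
    edges = [0]
    for w in cell_widths:
        edges.append(edges[-1] + w // 2)
        edges.append(edges[-1] + w - w // 2)
    span_hists = []
    for s in range(len(edges) - 1):
        hist = [0.0] * n_bins
        for i in range(rows):
            for j in range(edges[s], edges[s + 1]):
                g = math.hypot(ix[i, j], iy[i, j])
                if g == 0.0:
                    continue
                theta = math.degrees(math.atan2(iy[i, j], ix[i, j])) % 180.0
                hist[int(theta // 20.0) % n_bins] += g
        span_hists.append(hist)
    out = []
    for b in range(2 * n_cells - 1):
        block = [span_hists[b][k] + span_hists[b + 1][k] for k in range(n_bins)]
        norm = math.sqrt(sum(v * v for v in block) + eps**2)
        out.extend(v / norm for v in block)
    return np.array(out)


def brute_lbp(img):
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    hist = np.zeros(256)
    for i in range(1, img.shape[0] - 1):
        for j in range(1, img.shape[1] - 1):
            code = 0
            for bit, (dr, dc) in enumerate(offsets):
                if img[i + dr, j + dc] >= img[i, j]:
                    code += 2**bit
            hist[code] += 1
    return hist


def random_matrices(rng, count, min_w=10, max_w=40):
    for _ in range(count):
        yield rng.integers(0, 2, size=(4, int(rng.integers(min_w, max_w + 1)))).astype(float)


# ---------------------------------------------------------------------------


class TestGradients:
    def test_constant_image_has_zero_magnitude(self):
        field = compute_gradients(np.full((4, 12), 3.0))
        assert np.all(field.G == 0)

    def test_centered_difference_hand_value(self):
        field = compute_gradients(np.array([[0.0, 0.0, 1.0, 1.0]]))
        assert field.I_x[0, 2] == 1.0

    def test_magnitude_is_euclidean(self):
        field = compute_gradients(np.random.default_rng(0).random((4, 20)))
        assert np.allclose(field.G, np.sqrt(field.I_x**2 + field.I_y**2))

    def test_matches_loop_oracle(self, rng):
        img = rng.random((4, 17))
        ix, iy = brute_gradients(img)
        field = compute_gradients(img)
        assert np.allclose(field.I_x, ix) and np.allclose(field.I_y, iy)

    def test_too_narrow_rejected(self):
        with pytest.raises(DescriptorError):
            compute_gradients(np.zeros((4, 2)))

    def test_theta_range(self, rng):
        field = compute_gradients(rng.random((4, 30)))
        assert np.all((field.theta >= 0) & (field.theta < 180))


class TestOrientationBinning:
    def test_default_bin_count_is_nine(self):
        cfg = HOGConfig()
        assert cfg.angular_range / cfg.bin_width == cfg.n_bins == 9

    def test_zero_magnitude_window_votes_nothing(self):
        field = compute_gradients(np.ones((4, 12)))
        hist = orientation_binning(field, (0, 4, 0, 12))
        assert np.all(hist == 0)

    def test_mass_conservation(self, rng):
        field = compute_gradients(rng.random((4, 25)))
        hist = orientation_binning(field, (0, 4, 3, 14))
        assert np.isclose(hist.sum(), field.G[0:4, 3:14].sum())

    def test_known_angle_votes_into_first_bin(self):
        field = compute_gradients(np.zeros((3, 5)))
        field.theta[:] = 10.0
        field.G[:] = 2.0
        hist = orientation_binning(field, (0, 1, 0, 5))
        assert hist[0] == 10.0 and np.all(hist[1:] == 0)

    def test_empty_window_rejected(self):
        field = compute_gradients(np.ones((4, 12)))
        with pytest.raises(DescriptorError):
            orientation_binning(field, (0, 4, 5, 5))


class TestBlockNormalize:
    def test_l2_pythagorean(self):
        assert np.allclose(block_normalize([3, 4], "L2", epsilon=0), [0.6, 0.8])

    def test_zero_vector_fixed_point(self):
        for scheme in ("L2", "L1", "L1-sqrt"):
            assert np.all(block_normalize(np.zeros(9), scheme, 1e-5) == 0)

    def test_l1_proportion(self):
        assert np.allclose(block_normalize([1, 3], "L1", epsilon=0), [0.25, 0.75])

    def test_l1_sqrt_formula(self):
        v = np.array([1.0, 3.0])
        assert np.allclose(block_normalize(v, "L1-sqrt", 1e-5),
                           np.sqrt(v / (4.0 + 1e-5)))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(DescriptorError):
            block_normalize([1.0], "L3")


class TestHOGDescriptor:
    @pytest.mark.parametrize("length", [10, 23, 57, 120, 567])
    def test_length_invariance(self, rng, length):
        vec = hog_descriptor(voss_encode(random_sequence(rng, length)))
        assert vec.shape == (81,)

    def test_homopolymer_mass_is_purely_vertical(self):
        """A homopolymer image has constant rows: no horizontal derivative
        anywhere, so every vote lands in the 90-degree (vertical) bin."""
        m = voss_encode("A" * 40)
        assert np.all(compute_gradients(m).I_x == 0)
        vec = hog_descriptor(m).reshape(9, 9)
        # bin [80,100) holds all block mass (1.0 up to the norm's epsilon)
        assert np.allclose(vec[:, 4], 1.0, atol=1e-6)
        mask = np.ones(9, dtype=bool)
        mask[4] = False
        assert np.all(vec[:, mask] == 0)

    def test_matches_brute_force(self, rng):
        for img in random_matrices(rng, 120):
            assert np.max(np.abs(hog_descriptor(img) - brute_hog(img))) < 1e-12

    def test_too_short_names_minimum(self):
        with pytest.raises(DescriptorError, match="minimum 10"):
            hog_descriptor(voss_encode("ACGTACGTA"))

    def test_l2_block_subnorms_bounded(self, rng):
        for img in random_matrices(rng, 20):
            vec = hog_descriptor(img)
            for b in range(9):
                assert np.linalg.norm(vec[9 * b : 9 * (b + 1)]) <= 1.0 + 1e-12

    def test_purity(self, rng):
        img = next(random_matrices(rng, 1))
        assert np.array_equal(hog_descriptor(img), hog_descriptor(img))


class TestLBPDescriptor:
    def test_constant_image_single_code(self):
        hist = lbp_descriptor(np.ones((4, 10)))
        assert hist[255] == 16 and hist.sum() == 16

    def test_matches_brute_force(self, rng):
        for img in random_matrices(rng, 120, min_w=3, max_w=25):
            assert np.array_equal(lbp_descriptor(img), brute_lbp(img))

    def test_histogram_sums_to_interior_count(self, rng):
        img = rng.integers(0, 2, size=(4, 33)).astype(float)
        assert lbp_descriptor(img).sum() == 2 * 31

    def test_normalized_sums_to_one(self, rng):
        img = rng.integers(0, 2, size=(4, 33)).astype(float)
        assert np.isclose(lbp_descriptor(img, normalize=True).sum(), 1.0)

    def test_too_small_rejected(self):
        with pytest.raises(DescriptorError):
            lbp_descriptor(np.zeros((2, 10)))


class TestTransformers:
    def test_hog_rows(self, small_corpus):
        X = HOGTransformer().fit_transform(small_corpus.samples[:5])
        assert X.shape == (5, 81)

    def test_lbp_rows(self, small_corpus):
        X = LBPTransformer().fit_transform(small_corpus.samples[:5])
        assert X.shape == (5, 256)

    def test_class_prototypes_distinct(self, small_corpus):
        """Each class's first sample yields a distinct HOG descriptor."""
        first = {}
        for seq, label in zip(small_corpus.samples, small_corpus.labels):
            first.setdefault(label, seq)
        vecs = HOGTransformer().fit_transform(list(first.values()))
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                assert not np.allclose(vecs[i], vecs[j])
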