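"""HOG and basic LBP descriptors for Voss-encoded genomic images.

The 4 x N binary indicator matrix is treated as a grayscale image.  The HOG
descriptor uses centered 1-D derivative masks, unsigned orientations over
[0, 180) binned at 20 degrees (180/20 = 9 channels), and nine half-overlapping
block windows along the sequence axis, giving a fixed 9 x 9 = 81-dimensional
vector for any sequence length above the minimum — this length invariance is
what makes variable-length genes comparable.

Block geometry: the full 4-row height is a single cell row; the width is
partitioned into 5 equal-width cells (remainder to the last), each cell split
into two half-spans; the 9 blocks are the consecutive pairs of the resulting
10 half-spans (2*5 - 1 = 9, adjacent blocks overlapping by half a block).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .encoding import NucleotideSequence, voss_encode

#: Shortest sequence the default 5-cell layout supports (each half-span >= 1 px).
MIN_SEQUENCE_LENGTH = 10

_NORM_SCHEMES = ("L2", "L1", "L1-sqrt")


class DescriptorError(ValueError):
    """Input incompatible with the descriptor geometry."""


@dataclass
class HOGConfig:
    """Descriptor geometry and normalization settings.

    n_bins x n_blocks is the descriptor length (81 by default).  ``epsilon``
    is the small constant of the block-normalization denominators; its value
    does not influence the result materially.
    """

    n_bins: int = 9
    angular_range: int = 180
    n_cells: int = 5
    norm: str = "L2"
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise DescriptorError("n_bins must be >= 1")
        if self.angular_range not in (180, 360):
            raise DescriptorError("angular_range must be 180 or 360")
        if self.norm not in _NORM_SCHEMES:
            raise DescriptorError(
                f"unknown norm {self.norm!r}; choose one of {_NORM_SCHEMES}"
            )
        if self.epsilon <= 0:
            raise DescriptorError("epsilon must be > 0")

    @property
    def n_blocks(self) -> int:
        return 2 * self.n_cells - 1

    @property
    def bin_width(self) -> float:
        return self.angular_range / self.n_bins

    @property
    def descriptor_length(self) -> int:
        return self.n_blocks * self.n_bins

    @property
    def min_width(self) -> int:
        # every half-span needs >= 1 column and the base cell width >= 2
        return 2 * self.n_cells


@dataclass
class GradientField:
    """Derivatives, magnitude, and folded orientation of an image."""

    I_x: np.ndarray
    I_y: np.ndarray
    G: np.ndarray
    theta: np.ndarray


def compute_gradients(image: np.ndarray, angular_range: int = 180) -> GradientField:
    """Centered-difference gradients with replicate-edge padding.

    I_x and I_y are the correlations of the image with the 1-D mask
    [-1, 0, 1] along columns and rows respectively; G = sqrt(I_x^2 + I_y^2);
    theta = atan2(I_y, I_x) in degrees folded into [0, angular_range).
    Zero-gradient pixels get theta = 0 (they carry no vote anyway).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DescriptorError(f"expected a 2-D image, got ndim={img.ndim}")
    if img.shape[1] < 3:
        raise DescriptorError(
            f"image width {img.shape[1]} is narrower than the 3-tap mask"
        )
    padded = np.pad(img, 1, mode="edge")
    I_x = padded[1:-1, 2:] - padded[1:-1, :-2]
    I_y = padded[2:, 1:-1] - padded[:-2, 1:-1]
    G = np.hypot(I_x, I_y)
    theta = np.degrees(np.arctan2(I_y, I_x)) % angular_range
    theta[G == 0] = 0.0
    return GradientField(I_x=I_x, I_y=I_y, G=G, theta=theta)


def orientation_binning(field: GradientField, window: tuple[int, int, int, int],
                        cfg: HOGConfig | None = None) -> np.ndarray:
    """Magnitude-weighted orientation histogram over a pixel window.

    ``window`` is (row_start, row_stop, col_start, col_stop).  Each pixel
    casts its full magnitude into the single half-open 20-degree bin
    containing its orientation (no interpolation); an orientation of exactly
    ``angular_range`` wraps to bin 0.
    """
    cfg = cfg or HOGConfig()
    r0, r1, c0, c1 = window
    if r1 <= r0 or c1 <= c0:
        raise DescriptorError(f"empty window {window}")
    g = field.G[r0:r1, c0:c1].ravel()
    t = field.theta[r0:r1, c0:c1].ravel()
    bins = (t // cfg.bin_width).astype(int) % cfg.n_bins
    hist = np.zeros(cfg.n_bins)
    np.add.at(hist, bins, g)
    return hist


def block_normalize(v: np.ndarray, norm: str = "L2", epsilon: float = 1e-5) -> np.ndarray:
    """Normalize one block histogram (L2, L1, or L1-sqrt scheme)."""
    v = np.asarray(v, dtype=float)
    if norm == "L2":
        return v / np.sqrt(np.sum(v * v) + epsilon**2)
    if norm == "L1":
        return v / (np.sum(np.abs(v)) + epsilon)
    if norm == "L1-sqrt":
        return np.sqrt(v / (np.sum(np.abs(v)) + epsilon))
    raise DescriptorError(f"unknown norm {norm!r}; choose one of {_NORM_SCHEMES}")


def _half_span_edges(width: int, n_cells: int) -> list[int]:
    """Column boundaries of the 2*n_cells half-spans (remainder to last cell)."""
    base = width // n_cells
    cell_widths = [base] * (n_cells - 1) + [width - base * (n_cells - 1)]
    edges = [0]
    for w in cell_widths:
        edges.append(edges[-1] + w // 2)
        edges.append(edges[-1] + (w - w // 2))
    return edges


def hog_descriptor(matrix: np.ndarray, cfg: HOGConfig | None = None) -> np.ndarray:
    """HOG vector of an encoded sequence (length n_blocks * n_bins; 81 default)."""
    cfg = cfg or HOGConfig()
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise DescriptorError("expected a 2-D matrix")
    width = m.shape[1]
    if width < cfg.min_width:
        raise DescriptorError(
            f"sequence length {width} is below the minimum {cfg.min_width} "
            f"required by the {cfg.n_cells}-cell block layout"
        )
    field = compute_gradients(m, cfg.angular_range)
    edges = _half_span_edges(width, cfg.n_cells)
    span_hists = [
        orientation_binning(field, (0, m.shape[0], edges[i], edges[i + 1]), cfg)
        for i in range(len(edges) - 1)
    ]
    blocks = [
        block_normalize(span_hists[i] + span_hists[i + 1], cfg.norm, cfg.epsilon)
        for i in range(cfg.n_blocks)
    ]
    return np.concatenate(blocks)


# LBP neighbor offsets, clockwise from the top-left pixel; bit i has weight 2**i.
_LBP_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def lbp_descriptor(matrix: np.ndarray, normalize: bool = False) -> np.ndarray:
    """Basic 8-neighbor LBP code histogram (256 bins) over interior pixels.

    A neighbor scores 1 when its intensity is >= the center's.  Raw counts by
    default, so the histogram sums to (rows-2)*(cols-2); ``normalize=True``
    divides by that count.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 3:
        raise DescriptorError(
            f"LBP needs a matrix of at least 3 x 3, got {m.shape}"
        )
    center = m[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for bit, (dr, dc) in enumerate(_LBP_OFFSETS):
        neighbor = m[1 + dr : m.shape[0] - 1 + dr, 1 + dc : m.shape[1] - 1 + dc]
        codes += (neighbor >= center).astype(np.int64) << bit
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    if normalize:
        hist /= codes.size
    return hist


# ---------------------------------------------------------------------------
# sklearn transformers


class _SequenceTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer over sequences / Voss matrices -> feature rows."""

    def fit(self, X, y=None):
        return self

    def _to_matrix(self, item) -> np.ndarray:
        if isinstance(item, (NucleotideSequence, str)):
            return voss_encode(item)
        return np.asarray(item)

    def transform(self, X) -> np.ndarray:
        return np.vstack([self._row(self._to_matrix(item)) for item in X])


class HOGTransformer(_SequenceTransformer):
    """Map sequences (or 4 x N matrices) to fixed-length HOG feature rows."""

    def __init__(self, n_bins: int = 9, n_cells: int = 5, norm: str = "L2",
                 epsilon: float = 1e-5, angular_range: int = 180):
        self.n_bins = n_bins
        self.n_cells = n_cells
        self.norm = norm
        self.epsilon = epsilon
        self.angular_range = angular_range

    @property
    def _config(self) -> HOGConfig:
        return HOGConfig(n_bins=self.n_bins, angular_range=self.angular_range,
                         n_cells=self.n_cells, norm=self.norm, epsilon=self.epsilon)

    def _row(self, matrix: np.ndarray) -> np.ndarray:
        return hog_descriptor(matrix, self._config)


class LBPTransformer(_SequenceTransformer):
    """Map sequences (or matrices) to 256-bin basic-LBP histogram rows."""

    def __init__(self, normalize: bool = False):
        self.normalize = normalize

    def _row(self, matrix: np.ndarray) -> np.ndarray:
        return lbp_descriptor(matrix, normalize=self.normalize)
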