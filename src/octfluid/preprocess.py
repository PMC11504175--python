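"""B-scan enhancement chain and edge-map generation.

The chain standardizes intensities against a reference scan (histogram
matching), removes impulsive speckle (median filter), boosts local
contrast (CLAHE with a relative clip limit, default 1.37), applies gamma
correction (default exponent 1.7), crops to the entropy-selected region
of interest, and derives an edge map from an antisymmetric
derivative-of-Gaussian filter pair at scale tau (default 1.8).

The edge operator is the first-order term of a local Taylor expansion of
the image intensity smoothed at scale tau: a pair of exactly antisymmetric
kernels (horizontal and vertical), combined by gradient magnitude and
rescaled to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.exposure import match_histograms as _sk_match_histograms

from .errors import ConfigError, ShapeError

logger = logging.getLogger("octfluid")


# ------------------------------------------------------------ domain types

@dataclass(frozen=True)
class BScan:
    """One 2-D grayscale OCT slice with intensities in [0, 1]."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ShapeError("BScan requires a non-empty 2-D grid")
        if not np.isfinite(px).all():
            raise ConfigError("BScan contains non-finite values")
        if px.min() < 0 or px.max() > 1:
            raise ConfigError("BScan intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class EdgeMap:
    """Magnitude response of the antisymmetric edge filter, in [0, 1]."""

    response: np.ndarray
    tau: float

    @property
    def height(self) -> int:
        return self.response.shape[0]

    @property
    def width(self) -> int:
        return self.response.shape[1]


@dataclass(frozen=True)
class PreprocessParams:
    clip_limit: float = 1.37        # CLAHE clip, multiple of the uniform bin height
    gamma: float = 1.7
    tau: float = 1.8                # edge-filter scale, px
    median_kernel: int = 3
    clahe_tiles: tuple = (8, 8)
    clahe_bins: int = 256
    entropy_window: int = 9
    entropy_threshold: float = 0.5  # bits
    roi_margin: int = 8

    def __post_init__(self):
        if self.clip_limit <= 0 or self.gamma <= 0 or self.tau <= 0:
            raise ConfigError("clip_limit, gamma and tau must be positive")
        for name in ("median_kernel", "entropy_window"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ConfigError(f"{name} must be odd and >= 3, got {v}")
        if self.roi_margin < 0:
            raise ConfigError("roi_margin must be >= 0")


@dataclass(frozen=True)
class RoiBox:
    """Half-open [start, end) crop box, 0-based row-major."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self):
        if not (0 <= self.row_start < self.row_end
                and 0 <= self.col_start < self.col_end):
            raise ConfigError(f"degenerate RoiBox {self}")

    @property
    def shape(self):
        return (self.row_end - self.row_start, self.col_end - self.col_start)


# -------------------------------------------------------------- operations

def match_histogram(image: BScan, reference: BScan) -> BScan:
    """Map the image's intensity distribution onto the reference's."""
    ref = reference.pixels
    if np.ptp(ref) == 0:
        raise ConfigError("constant reference image: inverse CDF undefined")
    out = _sk_match_histograms(image.pixels, ref)
    return BScan(np.clip(out, 0.0, 1.0), source_id=image.source_id)


def median_denoise(image: BScan, kernel: int = 3) -> BScan:
    """Median filter with edge-replicated borders."""
    if kernel < 3 or kernel % 2 == 0:
        raise ConfigError(f"median kernel must be odd and >= 3, got {kernel}")
    out = ndimage.median_filter(image.pixels, size=kernel, mode="nearest")
    return BScan(out, source_id=image.source_id)


def clahe(image: BScan, params: PreprocessParams = PreprocessParams()) -> BScan:
    """Contrast-limited adaptive histogram equalization.

    Per-tile histograms are clipped at ``clip_limit`` times the uniform bin
    height and the excess is redistributed uniformly; per-pixel output is
    bilinearly blended between the four surrounding tile mappings.
    """
    img = image.pixels
    h, w = img.shape
    tr, tc = params.clahe_tiles
    tr, tc = min(tr, h), min(tc, w)
    nbins = params.clahe_bins
    bins = np.minimum((img * nbins).astype(int), nbins - 1)

    row_edges = np.linspace(0, h, tr + 1).astype(int)
    col_edges = np.linspace(0, w, tc + 1).astype(int)
    luts = np.empty((tr, tc, nbins))
    for i in range(tr):
        for j in range(tc):
            tile = bins[row_edges[i]:row_edges[i + 1],
                        col_edges[j]:col_edges[j + 1]]
            n = tile.size
            hist = np.bincount(tile.ravel(), minlength=nbins).astype(float)
            clip_at = params.clip_limit * n / nbins
            excess = np.maximum(hist - clip_at, 0.0).sum()
            occupied = hist > 0
            clipped = np.minimum(hist, clip_at)
            # redistribute the excess over the histogram's support so a
            # narrow (low-contrast) tile is still equalized across it
            clipped[occupied] += excess / occupied.sum()
            luts[i, j] = clipped.cumsum() / n

    # bilinear blending between tile centres
    centres_r = (row_edges[:-1] + row_edges[1:]) / 2.0
    centres_c = (col_edges[:-1] + col_edges[1:]) / 2.0
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    fi = np.interp(rr, centres_r, np.arange(tr))
    fj = np.interp(cc, centres_c, np.arange(tc))
    i0 = np.floor(fi).astype(int)
    j0 = np.floor(fj).astype(int)
    i1 = np.minimum(i0 + 1, tr - 1)
    j1 = np.minimum(j0 + 1, tc - 1)
    wi = fi - i0
    wj = fj - j0

    i0b, i1b = np.broadcast_to(i0, (h, w)), np.broadcast_to(i1, (h, w))
    j0b, j1b = np.broadcast_to(j0, (h, w)), np.broadcast_to(j1, (h, w))
    v00 = luts[i0b, j0b, bins]
    v01 = luts[i0b, j1b, bins]
    v10 = luts[i1b, j0b, bins]
    v11 = luts[i1b, j1b, bins]
    out = ((1 - wi) * ((1 - wj) * v00 + wj * v01)
           + wi * ((1 - wj) * v10 + wj * v11))
    return BScan(np.clip(out, 0.0, 1.0), source_id=image.source_id)


def gamma_correct(image: BScan, gamma: float = 1.7) -> BScan:
    """Elementwise power-law correction out = in ** gamma."""
    if gamma <= 0:
        raise ConfigError(f"gamma must be positive, got {gamma}")
    return BScan(image.pixels ** gamma, source_id=image.source_id)


def local_entropy(image: BScan, window: int = 9, nbins: int = 256) -> np.ndarray:
    """Base-2 Shannon entropy of the intensity histogram in each
    window x window neighbourhood (edge-replicated borders)."""
    img = image.pixels
    bins = np.minimum((img * nbins).astype(int), nbins - 1)
    present = np.unique(bins)
    area = window * window
    ent = np.zeros(img.shape)
    for b in present:
        p = ndimage.uniform_filter((bins == b).astype(float), size=window,
                                   mode="nearest")
        nz = p > 0
        ent[nz] -= p[nz] * np.log2(p[nz])
    del area
    return ent


def extract_roi(image: BScan,
                params: PreprocessParams = PreprocessParams()) -> tuple:
    """Crop to the minimal row band whose mean local entropy exceeds the
    threshold, expanded by ``roi_margin``; full image if nothing passes."""
    ent = local_entropy(image, params.entropy_window, params.clahe_bins)
    row_mean = ent.mean(axis=1)
    above = np.nonzero(row_mean > params.entropy_threshold)[0]
    h, w = image.pixels.shape
    if above.size == 0:
        logger.warning("no row exceeds the entropy threshold; "
                       "falling back to the full image")
        box = RoiBox(0, h, 0, w)
    else:
        r0 = max(0, int(above[0]) - params.roi_margin)
        r1 = min(h, int(above[-1]) + 1 + params.roi_margin)
        box = RoiBox(r0, r1, 0, w)
    cropped = BScan(image.pixels[box.row_start:box.row_end,
                                 box.col_start:box.col_end],
                    source_id=image.source_id)
    return cropped, box


def _dog_kernels(tau: float):
    """Antisymmetric derivative-of-Gaussian pair at scale tau."""
    radius = int(np.ceil(3 * tau))
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (x / tau) ** 2)
    g /= g.sum()
    dg = -x / tau ** 2 * g          # exactly antisymmetric: dg[-x] == -dg[x]
    kx = np.outer(g, dg)            # horizontal derivative
    ky = np.outer(dg, g)            # vertical derivative
    return kx, ky


def edge_responses(image: BScan, tau: float = 1.8) -> tuple:
    """Signed horizontal/vertical responses of the psi filter (no rescale)."""
    if tau <= 0:
        raise ConfigError(f"tau must be positive, got {tau}")
    kx, ky = _dog_kernels(tau)
    rx = ndimage.convolve(image.pixels, kx, mode="reflect")
    ry = ndimage.convolve(image.pixels, ky, mode="reflect")
    return rx, ry


def edge_map(image: BScan, tau: float = 1.8) -> EdgeMap:
    """Gradient-magnitude edge map rescaled to [0, 1]."""
    rx, ry = edge_responses(image, tau)
    mag = np.hypot(rx, ry)
    peak = mag.max()
    # a constant image leaves only summation dust; don't rescale that to 1
    if peak > 1e-9:
        mag = mag / peak
    else:
        mag = np.zeros_like(mag)
    return EdgeMap(response=mag, tau=tau)


def preprocess_pipeline(image: BScan, reference: BScan | None,
                        params: PreprocessParams = PreprocessParams()
                        ) -> tuple:
    """Full chain: match -> median -> CLAHE -> gamma -> ROI; edge map from
    the enhanced, cropped image so the dual network inputs stay registered.

    Pass ``reference=None`` to skip histogram matching.
    Returns (enhanced BScan, EdgeMap, RoiBox).
    """
    x = image if reference is None else match_histogram(image, reference)
    x = median_denoise(x, params.median_kernel)
    x = clahe(x, params)
    x = gamma_correct(x, params.gamma)
    x, box = extract_roi(x, params)
    edges = edge_map(x, params.tau)
    return x, edges, box
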