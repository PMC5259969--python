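"""Order-statistic-gradient segmentation of a bright object on a darker field.

The pre-processing chain isolates one region of interest (ROI) from an RGB
raster of a skull silhouette photographed against a darker background:

    RGB -> grayscale -> morphological gradient (order-statistic max - min
    over a 10x10 domain) -> binarize -> fill holes -> clear border ->
    remove small particles -> largest component.

The gradient stage marks an edge band roughly half the filter domain wide
on each side of the true object outline, so the filled binary mask is the
object dilated by the (reflected) filter window. ``extract_roi`` therefore
finishes with a matched erosion that undoes this thickening exactly for
digitally convex silhouettes (dilation followed by its adjoint erosion is
the identity on convex sets) and nearly so for concave ones; it can be
switched off via :class:`SegmentationConfig`.

Zero padding is used at image borders, matching the order-statistic
filter's convention; it inflates the gradient along the frame, which is
harmless because border-touching components are discarded anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "SegmentationConfig",
    "NoObjectError",
    "DegenerateHistogramError",
    "read_image",
    "to_grayscale",
    "order_statistic_filter",
    "morphological_gradient",
    "binarize",
    "otsu_threshold",
    "fill_holes",
    "clear_border",
    "remove_small_objects",
    "extract_roi",
]

# Luma weights of the standard RGB -> grayscale conversion.
_LUMA = np.array([0.2989, 0.5870, 0.1140])

_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = np.ones((3, 3), dtype=bool)


class NoObjectError(RuntimeError):
    """No foreground survived; ``stage`` names the step that emptied the mask."""

    def __init__(self, stage: str):
        super().__init__(f"no object found (mask empty after stage: {stage})")
        self.stage = stage


class DegenerateHistogramError(ValueError):
    """Otsu thresholding was asked to split a constant image."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation chain.

    domain_height, domain_width
        Order-statistic filter domain in pixels (default 10x10).
    threshold_method
        ``"fixed_0.5"`` (midpoint of the dynamic range) or ``"otsu"``.
    min_object_area_frac
        Particle-removal threshold as a fraction of image area, so the
        same config behaves alike on thumbnails and full-resolution
        photographs.
    hole_connectivity / object_connectivity
        4-connected holes against 8-connected objects (complementary
        duality).
    compensate_gradient_band
        Apply the matched final erosion (see module docstring).
    """

    domain_height: int = 10
    domain_width: int = 10
    threshold_method: str = "fixed_0.5"
    min_object_area_frac: float = 1e-4
    hole_connectivity: int = 4
    object_connectivity: int = 8
    compensate_gradient_band: bool = True

    def __post_init__(self) -> None:
        if self.domain_height < 1 or self.domain_width < 1:
            raise ValueError("filter domain dimensions must be >= 1")
        if not (0.0 < self.min_object_area_frac < 1.0):
            raise ValueError("min_object_area_frac must lie in (0, 1)")
        if self.threshold_method not in ("fixed_0.5", "otsu"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.hole_connectivity not in (4, 8) or self.object_connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def domain(self) -> tuple[int, int]:
        return (self.domain_height, self.domain_width)


def _structure(connectivity: int) -> np.ndarray:
    return _STRUCT4 if connectivity == 4 else _STRUCT8


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit TIFF or PNG as an (H, W, 3) array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luma conversion 0.2989 R + 0.5870 G + 0.1140 B, rescaled to [0, 1].

    The rescaling divides by the weight sum (0.9999) so that pure white
    maps to exactly 1.0.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {img.shape}")
    arr = img.astype(float)
    if np.issubdtype(img.dtype, np.integer):
        arr = arr / np.iinfo(img.dtype).max
    return (arr @ _LUMA) / _LUMA.sum()


def order_statistic_filter(
    img: np.ndarray, order_index: int, domain: tuple[int, int] = (10, 10)
) -> np.ndarray:
    """k-th smallest value in the sliding h x w neighborhood of each pixel.

    ``order_index`` is 1-based: 1 is the minimum (erosion), h*w the maximum
    (dilation). Borders are zero padded.
    """
    h, w = domain
    n = h * w
    if not (1 <= order_index <= n):
        raise ValueError(f"order_index must be in 1..{n}, got {order_index}")
    return ndimage.rank_filter(
        np.asarray(img, dtype=float), rank=order_index - 1, size=domain,
        mode="constant", cval=0.0,
    )


def morphological_gradient(img: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Last-order minus first-order filter: the edge-highlighting gradient."""
    n = cfg.domain_height * cfg.domain_width
    hi = order_statistic_filter(img, n, cfg.domain)
    lo = order_statistic_filter(img, 1, cfg.domain)
    return hi - lo


def otsu_threshold(img: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance-maximizing threshold over a histogram.

    Returns the bin-center threshold; foreground is strictly above it.
    """
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise DegenerateHistogramError("constant image has a degenerate histogram")
    counts, edges = np.histogram(img, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m = np.cumsum(counts * centers)
    # class means below/above each cut; guard empty classes
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    mu0 = np.where(w0[:-1] > 0, m[:-1] / np.maximum(w0[:-1], 1), 0.0)
    mu1 = np.where(w1[:-1] > 0, (m[-1] - m[:-1]) / np.maximum(w1[:-1], 1), 0.0)
    sigma_b = w0[:-1] * w1[:-1] * (mu0 - mu1) ** 2
    sigma_b[~valid] = -np.inf
    k = int(np.argmax(sigma_b))
    return float(centers[k])


def binarize(img: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Threshold a gray image to a boolean mask (True = foreground)."""
    img = np.asarray(img, dtype=float)
    if cfg.threshold_method == "otsu":
        thr = otsu_threshold(img)
    else:
        lo, hi = float(img.min()), float(img.max())
        thr = lo + 0.5 * (hi - lo)
    return img > thr


def fill_holes(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Turn background not reachable from the border into foreground."""
    return ndimage.binary_fill_holes(
        np.asarray(mask, dtype=bool), structure=_structure(cfg.hole_connectivity)
    )


def clear_border(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Remove every component that touches the first/last row or column."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_structure(cfg.object_connectivity))
    if n == 0:
        return mask.copy()
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    doomed = np.unique(labels[border & mask])
    out = mask.copy()
    out[np.isin(labels, doomed[doomed > 0])] = False
    return out


def remove_small_objects(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Delete components with area < min_object_area_frac * H * W.

    A component exactly at the threshold is kept (>= comparison).
    """
    mask = np.asarray(mask, dtype=bool)
    # small tolerance so a component exactly at a fraction-derived threshold
    # is kept despite float round-off
    thr = cfg.min_object_area_frac * mask.shape[0] * mask.shape[1] - 1e-9
    labels, n = ndimage.label(mask, structure=_structure(cfg.object_connectivity))
    if n == 0:
        return mask.copy()
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= thr) + 1
    return np.isin(labels, keep)


def _matched_erosion(mask: np.ndarray, domain: tuple[int, int]) -> np.ndarray:
    """Erosion adjoint to the rank-filter dilation (reflected window).

    The rank filter's window at pixel p spans offsets -(d//2) .. d-d//2-1
    per axis; the adjoint erosion uses the reflected offsets, which for
    even domains differ by one pixel. Implemented directly so the pairing
    is exact.
    """
    dh, dw = domain
    pad = ((dh - 1 - dh // 2, dh // 2), (dw - 1 - dw // 2, dw // 2))
    padded = np.pad(np.asarray(mask, dtype=bool), pad, constant_values=False)
    windows = sliding_window_view(padded, (dh, dw))
    return windows.all(axis=(-2, -1))


def _largest_component(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_structure(cfg.object_connectivity))
    if n == 0:
        raise ValueError("empty mask")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def extract_roi(
    img: np.ndarray,
    cfg: SegmentationConfig | None = None,
    debug_dir: str | Path | None = None,
) -> np.ndarray:
    """Run the full chain on an RGB raster and return the ROI mask.

    Raises :class:`NoObjectError` naming the stage that emptied the mask.
    With ``debug_dir`` set, each intermediate mask is written as a PNG.
    """
    cfg = cfg or SegmentationConfig()
    gray = to_grayscale(img)
    if gray.shape[0] < cfg.domain_height or gray.shape[1] < cfg.domain_width:
        raise ValueError("image smaller than the filter domain")
    grad = morphological_gradient(gray, cfg)

    stages: list[tuple[str, np.ndarray]] = []
    mask = binarize(grad, cfg)
    stages.append(("binarize", mask))
    mask = fill_holes(mask, cfg)
    stages.append(("fill_holes", mask))
    mask = clear_border(mask, cfg)
    stages.append(("clear_border", mask))
    mask = remove_small_objects(mask, cfg)
    stages.append(("remove_small_objects", mask))
    for stage, m in stages:
        if not m.any():
            _write_debug(debug_dir, stages)
            raise NoObjectError(stage)
    mask = _largest_component(mask, cfg)
    if cfg.compensate_gradient_band:
        mask = _matched_erosion(mask, cfg.domain)
        if not mask.any():
            _write_debug(debug_dir, stages)
            raise NoObjectError("gradient_band_compensation")
        mask = _largest_component(mask, cfg)
        stages.append(("gradient_band_compensation", mask))
    _write_debug(debug_dir, stages)
    return mask


def _write_debug(debug_dir: str | Path | None, stages: list[tuple[str, np.ndarray]]) -> None:
    if debug_dir is None:
        return
    from PIL import Image

    out = Path(debug_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (stage, m) in enumerate(stages):
        Image.fromarray((m.astype(np.uint8) * 255)).save(out / f"{i}_{stage}.png")
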