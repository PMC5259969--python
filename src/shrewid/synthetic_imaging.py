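"""Synthetic skull-silhouette scenes with ground-truth masks and labels.

The study corpus is photographs of shrew skulls in three views (dorsal,
lateral, jaw), each belonging to one of four population-sex classes
(NM, NF, SM, SF: northern/southern x male/female). Those photographs are
not redistributable, so this module generates labeled stand-ins that keep
the statistical structure the pipeline assumes: a single bright silhouette
on a darker field, a linear illumination ramp, sensor noise, small clutter
particles, and optionally a component touching the image border.

Archetype geometry is invented; only its topology matters downstream:

* dorsal - a rounded teardrop (two fused ellipses; braincase + rostrum),
* lateral - a tapered wedge,
* jaw - an open crescent, whose concavity guarantees convex_area > area.

Class differences are injected as per-class scale factors on the semi-axes
and taper, so the separation between classes (in units of the within-class
axis jitter) is an explicit knob. The generator is fully deterministic:
equal seeds give byte-identical images.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .shape_features import FEATURE_NAMES, extract_features

__all__ = [
    "VIEWS",
    "CLASSES",
    "ShapeParams",
    "SceneSpec",
    "LabeledImage",
    "ClassOffsets",
    "Manifest",
    "offsets_for_separation",
    "rasterize",
    "render_silhouette",
    "generate_dataset",
    "generate_feature_table",
    "derive_image_seed",
]

VIEWS = ("dorsal", "lateral", "jaw")
CLASSES = ("NM", "NF", "SM", "SF")

#: Base silhouette geometry per view on the default 512x384 canvas:
#: (semi_axis_a, semi_axis_b, taper).
BASE_GEOMETRY = {
    "dorsal": (80.0, 48.0, 0.0),
    "lateral": (90.0, 36.0, 0.35),
    "jaw": (70.0, 46.0, 0.0),
}


@dataclass(frozen=True)
class ShapeParams:
    """Full parameterization of one silhouette."""

    view: str
    klass: str
    semi_axis_a: float
    semi_axis_b: float
    taper: float = 0.0
    roughness_amp: float = 0.0
    rotation: float = 0.0
    center: tuple[float, float] | None = None  # (row, col); None = canvas center

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.klass not in CLASSES:
            raise ValueError(f"klass must be one of {CLASSES}, got {self.klass!r}")
        if not (self.semi_axis_a >= self.semi_axis_b > 0):
            raise ValueError("require semi_axis_a >= semi_axis_b > 0")
        if not (0.0 <= self.taper <= 1.0):
            raise ValueError("taper must lie in [0, 1]")
        if self.roughness_amp < 0:
            raise ValueError("roughness_amp must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    """Canvas, photometry and nuisance parameters of one rendered scene."""

    height: int = 384
    width: int = 512
    background_level: float = 0.15
    foreground_level: float = 0.85
    illum_gradient: float = 0.0
    noise_sd: float = 0.02
    n_clutter: int = 0
    clutter_max_area: float = 80.0
    touch_border: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.foreground_level <= self.background_level:
            raise ValueError("foreground_level must exceed background_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_clutter < 0 or self.clutter_max_area <= 0:
            raise ValueError("invalid clutter parameters")


@dataclass(frozen=True)
class LabeledImage:
    """A rendered scene with its ground truth."""

    pixels: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) bool
    view: str
    region: str  # "N" or "S"
    sex: str  # "M" or "F"
    shape_params: ShapeParams

    @property
    def klass(self) -> str:
        return self.region + self.sex


@dataclass(frozen=True)
class ClassOffsets:
    """Per-class scale factors applied to the base geometry."""

    a_scale: float = 1.0
    b_scale: float = 1.0
    taper_delta: float = 0.0


def offsets_for_separation(
    separation_sd: float, axis_jitter: float = 0.02
) -> dict[str, ClassOffsets]:
    """Class offsets giving adjacent classes a mean semi_axis_a difference of
    ``separation_sd`` within-class standard deviations.

    Within-class jitter multiplies each axis by ``1 + N(0, axis_jitter)``,
    so an offset of ``separation_sd * axis_jitter`` on the a-scale yields
    the requested separation. The b-axis and taper get smaller per-class
    shifts so classes differ in elongation as well as size.
    """
    out = {}
    for i, k in enumerate(CLASSES):
        step = i * separation_sd * axis_jitter
        out[k] = ClassOffsets(
            a_scale=1.0 + step, b_scale=1.0 + 0.6 * step, taper_delta=0.3 * step
        )
    return out


def _roughness_profile(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # low-order random Fourier coefficients of the boundary modulation
    ks = np.arange(2, 6)
    c = rng.normal(0.0, 1.0 / np.sqrt(ks))
    d = rng.normal(0.0, 1.0 / np.sqrt(ks))
    norm = math.sqrt(float(c @ c + d @ d)) or 1.0
    return c / norm, d / norm


def _inside(view: str, x: np.ndarray, y: np.ndarray, a: float, b: float, taper: float) -> np.ndarray:
    """Archetype membership in the canonical (unrotated) frame.

    ``x`` runs along the long axis, ``y`` across it.
    """
    if view == "dorsal":
        e1 = ((x + 0.15 * a) / (0.85 * a)) ** 2 + (y / b) ** 2 <= 1.0
        e2 = ((x - 0.45 * a) / (0.55 * a)) ** 2 + (y / (0.6 * b)) ** 2 <= 1.0
        return e1 | e2
    if view == "lateral":
        w = np.clip(1.0 - taper * (x + a) / (2.0 * a), 0.2, None)
        return (x / a) ** 2 + (y / (b * w)) ** 2 <= 1.0
    if view == "jaw":
        outer = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        inner = (x / (0.72 * a)) ** 2 + ((y - 0.45 * b) / (0.8 * b)) ** 2 <= 1.0
        return outer & ~inner
    raise ValueError(f"unknown view {view!r}")


def rasterize(params: ShapeParams, spec: SceneSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Rasterize the silhouette on the scene canvas (pixel-center sampling).

    ``rng`` drives the boundary-roughness profile; when omitted a generator
    seeded from ``spec.seed`` is used, so identical inputs give identical
    masks. Raises ``ValueError`` if the silhouette leaves the canvas or
    breaks into several components.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cr, cc = params.center if params.center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    # evaluate only a window certain to contain the shape; the roughness
    # modulation g has unit-norm Fourier coefficients so |g| <= sqrt(8),
    # bounding the radial scale well below the hard 1.5 cap
    s_max = min(1.5, 1.0 + math.sqrt(8.0) * params.roughness_amp
                / min(params.semi_axis_a, params.semi_axis_b))
    reach = s_max * params.semi_axis_a + 3.0
    r0 = max(int(np.floor(cr - reach)), 0)
    r1 = min(int(np.ceil(cr + reach)) + 1, h)
    c0 = max(int(np.floor(cc - reach)), 0)
    c1 = min(int(np.ceil(cc + reach)) + 1, w)
    rr, ccg = np.meshgrid(np.arange(r0, r1, dtype=float),
                          np.arange(c0, c1, dtype=float), indexing="ij")
    yv = rr - cr
    xv = ccg - cc
    th = math.radians(params.rotation)
    xr = math.cos(th) * xv + math.sin(th) * yv
    yr = -math.sin(th) * xv + math.cos(th) * yv
    if params.roughness_amp > 0:
        c, d = _roughness_profile(rng)
        theta = np.arctan2(yr, xr)
        ks = np.arange(2, 6)
        g = np.zeros_like(theta)
        for j, k in enumerate(ks):
            g += c[j] * np.cos(k * theta) + d[j] * np.sin(k * theta)
        s = 1.0 + (params.roughness_amp / min(params.semi_axis_a, params.semi_axis_b)) * g
        s = np.clip(s, 0.5, 1.5)
        xr = xr / s
        yr = yr / s
    window = _inside(params.view, xr, yr, params.semi_axis_a, params.semi_axis_b, params.taper)
    mask = np.zeros((h, w), dtype=bool)
    mask[r0:r1, c0:c1] = window
    if not mask.any():
        raise ValueError("silhouette rasterized to an empty mask")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("silhouette extends beyond image bounds; reduce its size")
    from scipy import ndimage

    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n != 1:
        # roughness can pinch off sub-pixel satellites at sharp tips; a
        # negligible satellite (< 0.5% of the area) is discarded, anything
        # bigger is a genuine split and an error
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        main = int(np.argmax(sizes)) + 1
        if sizes.sum() - sizes[main - 1] > 0.005 * sizes.sum():
            raise ValueError(f"silhouette broke into {n} components; reduce roughness")
        mask = labels == main
    return mask


def _paint_disc(canvas: np.ndarray, center: tuple[float, float], radius: float) -> None:
    h, w = canvas.shape
    r0 = max(int(center[0] - radius - 1), 0)
    r1 = min(int(center[0] + radius + 2), h)
    c0 = max(int(center[1] - radius - 1), 0)
    c1 = min(int(center[1] + radius + 2), w)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    disc = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    canvas[r0:r1, c0:c1] |= disc


def render_silhouette(params: ShapeParams, spec: SceneSpec) -> LabeledImage:
    """Render one labeled scene.

    The truth mask is the rasterized archetype alone; clutter particles and
    the optional border-touching component appear only in the pixels. All
    randomness (roughness, clutter placement, noise) flows from
    ``spec.seed``, so identical inputs give byte-identical images.
    """
    rng = np.random.default_rng(spec.seed)
    mask = rasterize(params, spec, rng=rng)
    h, w = spec.height, spec.width

    img = np.where(mask, spec.foreground_level, spec.background_level)
    cols = np.arange(w, dtype=float)[None, :]
    img = img + spec.illum_gradient * (cols - (w - 1) / 2.0)

    from scipy import ndimage

    # keep clutter clear of the object: gradient bands of object and clutter
    # must not merge downstream, so the margin exceeds one filter domain
    keepout = ndimage.binary_dilation(mask, iterations=12)
    clutter = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_clutter):
        for _attempt in range(50):
            area = rng.uniform(4.0, spec.clutter_max_area)
            radius = math.sqrt(area / math.pi)
            center = (rng.uniform(radius + 2, h - radius - 3),
                      rng.uniform(radius + 2, w - radius - 3))
            trial = np.zeros((h, w), dtype=bool)
            _paint_disc(trial, center, radius)
            if not (trial & keepout).any():
                clutter |= trial
                break
    if spec.touch_border:
        radius = rng.uniform(6.0, 12.0)
        edge = rng.integers(4)
        pos = rng.uniform(0.2, 0.8)
        centers = {
            0: (0.0, pos * w),
            1: (h - 1.0, pos * w),
            2: (pos * h, 0.0),
            3: (pos * h, w - 1.0),
        }
        _paint_disc(clutter, centers[int(edge)], radius)
    img[clutter & ~mask] = spec.foreground_level

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    pixels = np.repeat((np.round(img * 255.0).astype(np.uint8))[:, :, None], 3, axis=2)
    return LabeledImage(
        pixels=pixels,
        truth_mask=mask,
        view=params.view,
        region=params.klass[0],
        sex=params.klass[1],
        shape_params=params,
    )


@dataclass(frozen=True)
class Manifest:
    """Index of a generated dataset: one row per image."""

    table: pd.DataFrame  # columns: path, view, region, sex, seed

    COLUMNS = ("path", "view", "region", "sex", "seed")

    def __post_init__(self) -> None:
        t = self.table
        if tuple(t.columns) != self.COLUMNS:
            raise ValueError(f"manifest columns must be {self.COLUMNS}")
        if t["path"].duplicated().any():
            raise ValueError("manifest paths must be unique")
        if not t["view"].isin(VIEWS).all():
            raise ValueError("unknown view label in manifest")
        if not (t["region"].isin(("N", "S")).all() and t["sex"].isin(("M", "F")).all()):
            raise ValueError("unknown region/sex label in manifest")

    @property
    def records(self) -> list[tuple]:
        return list(self.table.itertuples(index=False, name=None))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Manifest":
        return cls(pd.read_csv(path, dtype={"path": str, "view": str, "region": str, "sex": str}))


def derive_image_seed(master_seed: int, view: str, klass: str, index: int) -> int:
    """Stable per-image seed: hash of (master seed, view, class, index)."""
    key = f"{master_seed}:{view}:{klass}:{index}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def _sample_params(
    view: str,
    klass: str,
    offsets: ClassOffsets,
    rng: np.random.Generator,
    canvas: tuple[int, int],
    axis_jitter: float,
    roughness_amp: float = 1.5,
) -> ShapeParams:
    a0, b0, taper0 = BASE_GEOMETRY[view]
    a = a0 * offsets.a_scale * (1.0 + rng.normal(0.0, axis_jitter))
    b = b0 * offsets.b_scale * (1.0 + rng.normal(0.0, axis_jitter))
    b = min(b, 0.98 * a)  # keep a >= b under jitter
    taper = float(np.clip(taper0 + offsets.taper_delta, 0.0, 0.9))
    h, w = canvas
    center = (
        (h - 1) / 2.0 + rng.uniform(-8.0, 8.0),
        (w - 1) / 2.0 + rng.uniform(-8.0, 8.0),
    )
    return ShapeParams(
        view=view,
        klass=klass,
        semi_axis_a=a,
        semi_axis_b=b,
        taper=taper,
        roughness_amp=roughness_amp,
        rotation=float(rng.uniform(-5.0, 5.0)),
        center=center,
    )


def generate_dataset(
    n_per_class: int,
    class_offsets: dict[str, ClassOffsets] | None = None,
    spec: SceneSpec | None = None,
    out_dir: str | Path = ".",
    axis_jitter: float = 0.02,
    image_format: str = "png",
) -> Manifest:
    """Write ``3 * 4 * n_per_class`` labeled images plus ``manifest.csv``.

    Images land under ``<out_dir>/<view>/<region>/<sex>/``; per-image seeds
    derive deterministically from ``spec.seed`` so the dataset is
    reproducible and extensible (adding images never reshuffles old ones).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if image_format not in ("png", "tif"):
        raise ValueError("image_format must be 'png' or 'tif'")
    spec = spec or SceneSpec()
    class_offsets = class_offsets or offsets_for_separation(4.0, axis_jitter)
    out_dir = Path(out_dir)
    rows = []
    for view in VIEWS:
        for klass in CLASSES:
            region, sex = klass[0], klass[1]
            subdir = out_dir / view / region / sex
            subdir.mkdir(parents=True, exist_ok=True)
            for i in range(n_per_class):
                img_seed = derive_image_seed(spec.seed, view, klass, i)
                shape_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=img_seed, spawn_key=(1,))
                )
                params = _sample_params(
                    view, klass, class_offsets[klass], shape_rng,
                    (spec.height, spec.width), axis_jitter,
                )
                labeled = render_silhouette(params, replace(spec, seed=img_seed))
                rel = Path(view) / region / sex / f"{view}_{klass}_{i:03d}.{image_format}"
                _write_image(out_dir / rel, labeled.pixels)
                rows.append((str(rel), view, region, sex, img_seed))
    manifest = Manifest(pd.DataFrame(rows, columns=list(Manifest.COLUMNS)))
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def _write_image(path: Path, pixels: np.ndarray) -> None:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, pixels)
    else:
        from PIL import Image

        Image.fromarray(pixels).save(path)


def generate_feature_table(
    n_per_class: int,
    class_offsets: dict[str, ClassOffsets] | None = None,
    spec: SceneSpec | None = None,
    views: tuple[str, ...] = VIEWS,
    axis_jitter: float = 0.02,
) -> pd.DataFrame:
    """Descriptor table from truth masks alone (no files, no segmentation).

    Renders each silhouette's ground-truth mask and measures the seven
    descriptors directly — the fast path for classifier-level experiments
    where the segmentation stage is not under study. Seeding matches
    :func:`generate_dataset`, so the same (seed, view, class, index) yields
    the same silhouette in both.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    spec = spec or SceneSpec()
    class_offsets = class_offsets or offsets_for_separation(4.0, axis_jitter)
    rows = []
    for view in views:
        for klass in CLASSES:
            for i in range(n_per_class):
                img_seed = derive_image_seed(spec.seed, view, klass, i)
                shape_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=img_seed, spawn_key=(1,))
                )
                params = _sample_params(
                    view, klass, class_offsets[klass], shape_rng,
                    (spec.height, spec.width), axis_jitter,
                )
                mask = rasterize(params, replace(spec, seed=img_seed))
                fv = extract_features(mask)
                rows.append((view, klass[0], klass[1], klass, *fv.as_array()))
    return pd.DataFrame(
        rows, columns=["view", "region", "sex", "klass", *FEATURE_NAMES]
    )
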