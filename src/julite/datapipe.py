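"""Data pipeline: augmentation, corpus expansion, leak-free splits, image
folder I/O and a procedural synthetic defect-image generator.

The six-class vocabulary covers the visually distinct surface conditions of
dried jujube fruit: deformation (warped outline), wrinkles (ridged skin),
normal fruit, cracks (dark linear fissures), mold (low-contrast gray-green
patches) and bird pecks (small punctures).  The synthetic generator renders
each class's signature procedurally on an ellipsoidal red-brown fruit over a
textured background, so the whole training/evaluation stack can be exercised
end-to-end without the photographic corpus; it is a pure function of
(label, seed, config).

Training augmentation follows the recipe the model family is trained with:
random resized crop (area 70-100%, aspect 0.8-1.25, bicubic), independent
horizontal/vertical flips (p=0.5 each), rotation within +/-15 deg and shear
within 10 deg, +/-20% brightness/contrast/saturation jitter, and a random
rectangular occlusion covering 2-20% of the image filled with a preset
value.  Evaluation resizes the shorter side to 256 and center-crops 224.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageEnhance, ImageFilter

__all__ = [
    "CLASSES", "AugmentConfig", "FolderDataset", "ImageRecord",
    "SyntheticConfig", "TransformParams", "apply_params", "augment_corpus",
    "draw_params", "eval_transform", "generate_dataset",
    "generate_synthetic_image", "identity_params", "load_manifest",
    "random_occlusion", "split_dataset", "train_transform",
    "variant_transform", "VARIANT_KINDS",
]

CLASSES = ("deformed", "wrinkled", "normal", "cracked", "mold", "bird_pecked")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

SPLITS = ("train", "test", "validation")
DEFAULT_RATIOS = (0.7, 0.2, 0.1)

#: preset fill for occlusion rectangles and affine borders
FILL_VALUE = (128, 128, 128)


@dataclass(frozen=True)
class ImageRecord:
    path: str
    label: str
    split: str = "train"
    seed: int | None = None      # augmentation stream seed; None = original
    base_id: str | None = None   # shared by all variants of one base image

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation ranges plus the corpus-expansion factor.

    `multiplicity` is the static expansion applied to the training split:
    each base image contributes itself plus multiplicity-1 augmented
    variants with stored seeds (12,000 base images -> a 48,000-image corpus
    at the default 4)."""

    crop_scale: tuple[float, float] = (0.70, 1.00)
    crop_aspect: tuple[float, float] = (0.8, 1.25)
    flip_prob: float = 0.5
    rotation_deg: float = 15.0
    shear_deg: float = 10.0
    occlusion_area: tuple[float, float] = (0.02, 0.20)
    occlusion_fill: tuple[int, int, int] = FILL_VALUE
    color_jitter: float = 0.20
    output_size: int = 224
    multiplicity: int = 4
    mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    std: tuple[float, float, float] = (0.25, 0.25, 0.25)


@dataclass(frozen=True)
class TransformParams:
    """Concrete draws of every random element of the training transform."""

    crop_box: tuple[int, int, int, int] | None  # left, top, right, bottom
    hflip: bool
    vflip: bool
    angle_deg: float
    shear_deg: float
    brightness: float
    contrast: float
    saturation: float
    occlusion: tuple[int, int, int, int] | None  # x0, y0, x1, y1 in output px


def identity_params() -> TransformParams:
    """All transform elements at their identity values."""
    return TransformParams(crop_box=None, hflip=False, vflip=False,
                           angle_deg=0.0, shear_deg=0.0, brightness=1.0,
                           contrast=1.0, saturation=1.0, occlusion=None)


def _check_image(image: Image.Image) -> Image.Image:
    if not isinstance(image, Image.Image):
        raise TypeError("expected a PIL image")
    if image.mode != "RGB":
        raise ValueError(f"expected an RGB image, got mode {image.mode!r}")
    if min(image.size) < 64:
        raise ValueError(f"image too small: {image.size} (min dimension 64)")
    return image


def _draw_crop(rng: np.random.Generator, w: int, h: int,
               cfg: AugmentConfig) -> tuple[int, int, int, int]:
    area = w * h
    for _ in range(10):
        frac = rng.uniform(*cfg.crop_scale)
        log_aspect = rng.uniform(math.log(cfg.crop_aspect[0]),
                                 math.log(cfg.crop_aspect[1]))
        aspect = math.exp(log_aspect)
        cw = int(round(math.sqrt(area * frac * aspect)))
        ch = int(round(math.sqrt(area * frac / aspect)))
        if 0 < cw <= w and 0 < ch <= h:
            left = int(rng.integers(0, w - cw + 1))
            top = int(rng.integers(0, h - ch + 1))
            return left, top, left + cw, top + ch
    side = min(w, h)
    return (w - side) // 2, (h - side) // 2, (w + side) // 2, (h + side) // 2


def draw_params(rng: np.random.Generator, image_size: tuple[int, int],
                cfg: AugmentConfig) -> TransformParams:
    w, h = image_size
    j = cfg.color_jitter
    s = cfg.output_size
    crop = _draw_crop(rng, w, h, cfg)
    hflip = rng.random() < cfg.flip_prob
    vflip = rng.random() < cfg.flip_prob
    angle = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    shear = float(rng.uniform(-cfg.shear_deg, cfg.shear_deg))
    bright, contrast, sat = (float(rng.uniform(1 - j, 1 + j)) for _ in range(3))
    occ = _draw_occlusion_box(rng, s, s, cfg.occlusion_area)
    return TransformParams(crop, hflip, vflip, angle, shear, bright,
                           contrast, sat, occ)


def _draw_occlusion_box(rng: np.random.Generator, w: int, h: int,
                        area_range: tuple[float, float]) -> tuple[int, int, int, int]:
    frac = rng.uniform(*area_range)
    target = frac * w * h
    aspect = math.exp(rng.uniform(math.log(0.5), math.log(2.0)))
    rh = max(1, min(h, int(round(math.sqrt(target / aspect)))))
    rw = max(1, min(w, int(round(target / rh))))
    x0 = int(rng.integers(0, w - rw + 1))
    y0 = int(rng.integers(0, h - rh + 1))
    return x0, y0, x0 + rw, y0 + rh


def apply_params(image: Image.Image, params: TransformParams,
                 cfg: AugmentConfig) -> np.ndarray:
    """Apply concrete transform draws; returns a standardized (3, S, S) array."""
    img = _check_image(image)
    if params.crop_box is not None:
        img = img.crop(params.crop_box)
    s = cfg.output_size
    img = img.resize((s, s), Image.BICUBIC)
    if params.hflip:
        img = img.transpose(Image.FLIP_LEFT_RIGHT)
    if params.vflip:
        img = img.transpose(Image.FLIP_TOP_BOTTOM)
    if params.angle_deg or params.shear_deg:
        img = _affine(img, params.angle_deg, params.shear_deg, cfg.occlusion_fill)
    if params.brightness != 1.0:
        img = ImageEnhance.Brightness(img).enhance(params.brightness)
    if params.contrast != 1.0:
        img = ImageEnhance.Contrast(img).enhance(params.contrast)
    if params.saturation != 1.0:
        img = ImageEnhance.Color(img).enhance(params.saturation)
    arr = np.asarray(img, dtype=np.float64)
    if params.occlusion is not None:
        x0, y0, x1, y1 = params.occlusion
        arr[y0:y1, x0:x1] = np.asarray(cfg.occlusion_fill, dtype=np.float64)
    return _standardize(arr, cfg.mean, cfg.std)


def _affine(img: Image.Image, angle_deg: float, shear_deg: float,
            fill) -> Image.Image:
    """Rotation + x-shear about the image center, bicubic, fixed fill."""
    w, h = img.size
    cx, cy = w / 2.0, h / 2.0
    a = math.radians(angle_deg)
    sh = math.tan(math.radians(shear_deg))
    # output->input map M = R(a) @ Shear(sh) about the image center
    m00, m01 = math.cos(a), -math.sin(a)
    m10, m11 = math.sin(a), math.cos(a)
    s00, s01, s10, s11 = 1.0, sh, 0.0, 1.0
    t00 = m00 * s00 + m01 * s10
    t01 = m00 * s01 + m01 * s11
    t10 = m10 * s00 + m11 * s10
    t11 = m10 * s01 + m11 * s11
    c0 = cx - t00 * cx - t01 * cy
    c1 = cy - t10 * cx - t11 * cy
    return img.transform((w, h), Image.AFFINE, (t00, t01, c0, t10, t11, c1),
                         resample=Image.BICUBIC, fillcolor=tuple(fill))


def _standardize(arr_hwc_255: np.ndarray, mean, std) -> np.ndarray:
    x = arr_hwc_255 / 255.0
    x = (x - np.asarray(mean)) / np.asarray(std)
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def train_transform(image: Image.Image, rng: np.random.Generator,
                    cfg: AugmentConfig | None = None) -> np.ndarray:
    """Full stochastic training transform -> standardized (3, S, S) array."""
    cfg = cfg or AugmentConfig()
    img = _check_image(image)
    params = draw_params(rng, img.size, cfg)
    return apply_params(img, params, cfg)


#: the three corpus-expansion strategies, cycled over a base image's variants
VARIANT_KINDS = ("crop", "flip", "comprehensive")


def variant_transform(image: Image.Image, rng: np.random.Generator,
                      cfg: AugmentConfig, kind: str) -> np.ndarray:
    """One corpus-expansion variant.

    Each augmented copy of a base image applies a single expansion strategy:
    `crop` (random resized crop), `flip` (random horizontal/vertical flips),
    or `comprehensive` (rotation + shear, random occlusion and color jitter
    combined).
    """
    img = _check_image(image)
    full = draw_params(rng, img.size, cfg)
    ident = identity_params()
    if kind == "crop":
        params = replace(ident, crop_box=full.crop_box)
    elif kind == "flip":
        hflip, vflip = full.hflip, full.vflip
        if not (hflip or vflip):  # a flip variant must flip something
            hflip = True
        params = replace(ident, hflip=hflip, vflip=vflip)
    elif kind == "comprehensive":
        params = replace(full, crop_box=None, hflip=False, vflip=False)
    else:
        raise ValueError(f"unknown variant kind {kind!r}")
    return apply_params(img, params, cfg)


def eval_transform(image: Image.Image, cfg: AugmentConfig | None = None,
                   resize_short: int = 256) -> np.ndarray:
    """Deterministic evaluation transform: resize shorter side, center crop."""
    cfg = cfg or AugmentConfig()
    img = image
    if not isinstance(img, Image.Image):
        raise TypeError("expected a PIL image")
    if img.mode != "RGB":
        raise ValueError(f"expected an RGB image, got mode {img.mode!r}")
    w, h = img.size
    scale = resize_short / min(w, h)
    img = img.resize((max(1, round(w * scale)), max(1, round(h * scale))),
                     Image.BICUBIC)
    s = cfg.output_size
    w, h = img.size
    left, top = (w - s) // 2, (h - s) // 2
    img = img.crop((left, top, left + s, top + s))
    return _standardize(np.asarray(img, dtype=np.float64), cfg.mean, cfg.std)


def random_occlusion(image: np.ndarray | Image.Image, rng: np.random.Generator,
                     area_range: tuple[float, float] = (0.02, 0.20),
                     fill=FILL_VALUE) -> np.ndarray:
    """Fill one random axis-aligned rectangle (area fraction in `area_range`,
    fully inside the image) with `fill`.  Returns an HWC uint8 array."""
    arr = np.array(image, dtype=np.uint8, copy=True)
    if arr.ndim != 3 or arr.shape[0] < 10 or arr.shape[1] < 10:
        raise ValueError("image must be at least 10x10 RGB")
    h, w = arr.shape[:2]
    x0, y0, x1, y1 = _draw_occlusion_box(rng, w, h, area_range)
    arr[y0:y1, x0:x1] = np.asarray(fill, dtype=np.uint8)
    return arr


# -- corpus bookkeeping ----------------------------------------------------

def augment_corpus(records: list[ImageRecord], multiplicity: int) -> list[ImageRecord]:
    """Expand each base record into `multiplicity` records: the original plus
    multiplicity-1 augmented variants, each with its own stored seed."""
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    out = []
    for i, rec in enumerate(records):
        base_id = rec.base_id or rec.path
        out.append(replace(rec, base_id=base_id, seed=None))
        for k in range(1, multiplicity):
            out.append(replace(rec, base_id=base_id, seed=i * multiplicity + k))
    return out


def split_dataset(records: list[ImageRecord],
                  ratios: tuple[float, float, float] = DEFAULT_RATIOS,
                  seed: int = 0) -> tuple[list[ImageRecord], ...]:
    """Stratified train/test/validation split keeping all variants of one
    base image in a single split (no augmentation leakage)."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    by_class_base: dict[str, dict[str, list[ImageRecord]]] = {}
    for rec in records:
        base = rec.base_id or rec.path
        by_class_base.setdefault(rec.label, {}).setdefault(base, []).append(rec)
    buckets: tuple[list[ImageRecord], ...] = ([], [], [])
    for label in sorted(by_class_base):
        bases = sorted(by_class_base[label])
        order = rng.permutation(len(bases))
        n = len(bases)
        counts = _apportion(n, ratios)
        idx = 0
        for which, cnt in enumerate(counts):
            for j in order[idx:idx + cnt]:
                for rec in by_class_base[label][bases[j]]:
                    buckets[which].append(replace(rec, split=SPLITS[which]))
            idx += cnt
    return buckets


def _apportion(n: int, ratios) -> list[int]:
    """Integer counts summing to n, matching ratios (largest remainder)."""
    raw = [n * r for r in ratios]
    counts = [int(math.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: raw[i] - counts[i],
                   reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


# -- synthetic image generation -------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """The synthetic corpus emulates the composition of the photographic
    study corpus: six classes, `n_per_class` images each (2000/class at full
    scale, i.e. 12,000 base images)."""

    image_size: int = 224
    n_per_class: int = 2000
    seed: int = 0
    difficulty: str = "easy"

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.difficulty not in ("easy", "hard"):
            raise ValueError("difficulty must be 'easy' or 'hard'")


def _fruit_boundary(theta: np.ndarray, deform: float, deform_k: int,
                    deform_phase: float, rng_base: np.random.Generator):
    """Radius profile of the fruit outline; `deform` > 0 adds the strong
    lobed warp that defines the deformed class."""
    base = 1.0 + 0.04 * np.sin(theta * rng_base.integers(3, 6)
                               + rng_base.uniform(0, 2 * np.pi)) * rng_base.uniform(0.3, 1.0)
    if deform > 0:
        base = base + deform * np.sin(deform_k * theta + deform_phase)
    return base


def generate_synthetic_image(label: str, seed: int,
                             cfg: SyntheticConfig | None = None) -> Image.Image:
    """Render one synthetic fruit image; pure function of (label, seed, cfg)."""
    cfg = cfg or SyntheticConfig()
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASSES}")
    s = cfg.image_size
    easy = cfg.difficulty == "easy"
    # base appearance is label-independent: same seed -> same fruit/background
    rng_base = np.random.default_rng(np.random.SeedSequence([cfg.seed, seed]))
    rng_defect = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, seed, CLASS_INDEX[label] + 1]))

    # background: soft vertical gradient + grain
    grad = np.linspace(185, 215, s)[:, None]
    bg = np.repeat(grad, s, axis=1)[..., None] * np.array([1.0, 0.98, 0.95])
    bg += rng_base.normal(0, 4.0, (s, s, 3))
    canvas = np.clip(bg, 0, 255)

    # fruit geometry
    cx = s / 2 + rng_base.uniform(-0.03, 0.03) * s
    cy = s / 2 + rng_base.uniform(-0.03, 0.03) * s
    rx = rng_base.uniform(0.30, 0.36) * s
    ry = rx * rng_base.uniform(0.78, 0.95)
    tilt = rng_base.uniform(0, np.pi)
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    deform_amp = (0.22 if easy else 0.09) if label == "deformed" else 0.0
    deform_k = int(rng_defect.integers(3, 6))
    deform_phase = rng_defect.uniform(0, 2 * np.pi)
    radius = _fruit_boundary(theta, deform_amp, deform_k, deform_phase, rng_base)
    bx = np.cos(theta) * radius * rx
    by = np.sin(theta) * radius * ry
    xs = cx + bx * np.cos(tilt) - by * np.sin(tilt)
    ys = cy + bx * np.sin(tilt) + by * np.cos(tilt)

    mask_img = Image.new("L", (s, s), 0)
    ImageDraw.Draw(mask_img).polygon(list(zip(xs.tolist(), ys.tolist())), fill=255)
    mask = np.asarray(mask_img, dtype=np.float64) / 255.0

    # fruit shading: red-brown with radial darkening and a specular patch
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    d2 = (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    shade = np.clip(1.15 - 0.45 * d2, 0.45, 1.15)
    if deform_amp > 0:
        # dents cast internal shadows: shading follows the boundary lobes
        ux = (xx - cx) * np.cos(tilt) + (yy - cy) * np.sin(tilt)
        uy = -(xx - cx) * np.sin(tilt) + (yy - cy) * np.cos(tilt)
        ang = np.arctan2(uy / ry, ux / rx)
        shade = shade * (1 + 0.9 * deform_amp
                         * np.sin(deform_k * ang + deform_phase))
    base_col = np.array([rng_base.uniform(140, 175),
                         rng_base.uniform(45, 70),
                         rng_base.uniform(38, 60)])
    hx = cx - 0.35 * rx
    hy = cy - 0.35 * ry
    highlight = np.exp(-(((xx - hx) / (0.35 * rx)) ** 2
                         + ((yy - hy) / (0.35 * ry)) ** 2))
    fruit = base_col[None, None, :] * shade[..., None] + 55 * highlight[..., None]
    fruit += rng_base.normal(0, 3.0, (s, s, 3))

    fruit = _apply_defect(fruit, label, mask, (cx, cy, rx, ry, tilt), s,
                          easy, rng_defect)

    out = canvas * (1 - mask[..., None]) + fruit * mask[..., None]
    return Image.fromarray(np.clip(out, 0, 255).astype(np.uint8), "RGB")


def _apply_defect(fruit: np.ndarray, label: str, mask: np.ndarray,
                  geom, s: int, easy: bool,
                  rng: np.random.Generator) -> np.ndarray:
    cx, cy, rx, ry, tilt = geom
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    if label == "cracked":
        overlay = Image.new("L", (s, s), 0)
        draw = ImageDraw.Draw(overlay)
        width = max(3, s // 24) if easy else max(1, s // 80)
        for _ in range(int(rng.integers(2, 4)) if easy else int(rng.integers(1, 4))):
            ang = tilt + rng.uniform(-0.5, 0.5)
            x, y = cx + rng.uniform(-0.3, 0.3) * rx, cy + rng.uniform(-0.3, 0.3) * ry
            pts = [(x, y)]
            step = s / 18
            for _ in range(int(rng.integers(5, 10))):
                ang += rng.uniform(-0.4, 0.4)
                x += step * math.cos(ang)
                y += step * math.sin(ang)
                pts.append((x, y))
            draw.line(pts, fill=255, width=width)
        alpha = (np.asarray(overlay, dtype=np.float64) / 255.0) * mask
        depth = 0.82 if easy else 0.5
        fruit = fruit * (1 - depth * alpha[..., None])
    elif label == "mold":
        overlay = Image.new("L", (s, s), 0)
        draw = ImageDraw.Draw(overlay)
        for _ in range(int(rng.integers(2, 5)) + (1 if easy else 0)):
            bx = cx + rng.uniform(-0.45, 0.45) * rx
            by = cy + rng.uniform(-0.45, 0.45) * ry
            br = rng.uniform(0.3, 0.5) * rx * (1.0 if easy else 0.55)
            draw.ellipse((bx - br, by - br, bx + br, by + br), fill=255)
        overlay = overlay.filter(ImageFilter.GaussianBlur(radius=s / 40))
        alpha = (np.asarray(overlay, dtype=np.float64) / 255.0) * mask
        alpha *= 0.95 if easy else 0.4
        mold_col = np.array([118.0, 150.0, 92.0])
        fruit = fruit * (1 - alpha[..., None]) + mold_col[None, None, :] * alpha[..., None]
    elif label == "bird_pecked":
        # punctures expose pale flesh inside a dark bruised rim
        core = Image.new("L", (s, s), 0)
        rim = Image.new("L", (s, s), 0)
        core_draw = ImageDraw.Draw(core)
        rim_draw = ImageDraw.Draw(rim)
        r_peck = (s / 13 if easy else s / 45)
        count = int(rng.integers(2, 5)) if easy else int(rng.integers(1, 6))
        for _ in range(count):
            px = cx + rng.uniform(-0.4, 0.4) * rx
            py = cy + rng.uniform(-0.4, 0.4) * ry
            rr = r_peck * rng.uniform(0.9, 1.2)
            rim_draw.ellipse((px - 1.35 * rr, py - 1.35 * rr,
                              px + 1.35 * rr, py + 1.35 * rr), fill=255)
            core_draw.ellipse((px - rr, py - rr, px + rr, py + rr), fill=255)
        core_a = (np.asarray(core, dtype=np.float64) / 255.0) * mask
        rim_a = np.clip(np.asarray(rim, dtype=np.float64) / 255.0 - core_a, 0, 1) * mask
        depth = 0.6 if easy else 0.5
        fruit = fruit * (1 - depth * rim_a[..., None])
        flesh = np.array([228.0, 190.0, 150.0]) * (0.9 if easy else 0.75)
        fruit = fruit * (1 - core_a[..., None]) + flesh[None, None, :] * core_a[..., None]
    elif label == "wrinkled":
        direction = rng.uniform(0, np.pi)
        u = (xx - cx) * math.cos(direction) + (yy - cy) * math.sin(direction)
        freq = rng.uniform(5, 8) / (2 * rx)
        amp = 0.38 if easy else 0.13
        ridges = 1.0 + amp * np.sin(2 * np.pi * freq * u + rng.uniform(0, 2 * np.pi))
        fruit = fruit * (1 + (ridges - 1) * mask)[..., None]
    # "deformed" is handled by the boundary warp; "normal" adds nothing
    return fruit


# -- dataset materialization ----------------------------------------------

def generate_dataset(cfg: SyntheticConfig, outdir: str | Path,
                     ratios: tuple[float, float, float] = DEFAULT_RATIOS) -> Path:
    """Write a class-subdirectory PNG image folder plus a CSV manifest
    (`path,label,split,seed`) with corpus standardization constants in the
    manifest header.  Returns the manifest path."""
    outdir = Path(outdir)
    records = []
    for label in CLASSES:
        (outdir / label).mkdir(parents=True, exist_ok=True)
        for i in range(cfg.n_per_class):
            img_seed = CLASS_INDEX[label] * cfg.n_per_class + i
            name = f"{label}_{img_seed:06d}.png"
            rel = f"{label}/{name}"
            path = outdir / rel
            try:
                if not path.exists():
                    generate_synthetic_image(label, img_seed, cfg).save(path)
            except OSError as exc:
                raise OSError(f"failed writing {path}: {exc}") from exc
            records.append(ImageRecord(rel, label, seed=img_seed, base_id=rel))
    splits = split_dataset(records, ratios, seed=cfg.seed)
    mean, std = _corpus_stats(outdir, splits[0])
    manifest = outdir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write(f"# mean={','.join(f'{v:.6f}' for v in mean)}\n")
        fh.write(f"# std={','.join(f'{v:.6f}' for v in std)}\n")
        fh.write("path,label,split,seed\n")
        for bucket in splits:
            for rec in sorted(bucket, key=lambda r: r.path):
                fh.write(f"{rec.path},{rec.label},{rec.split},{rec.seed}\n")
    return manifest


def _corpus_stats(root: Path, train_records, sample_cap: int = 512):
    """Per-channel mean/std over (a deterministic subsample of) the training
    split, on the [0, 1] scale."""
    recs = sorted(train_records, key=lambda r: r.path)
    if len(recs) > sample_cap:
        idx = np.linspace(0, len(recs) - 1, sample_cap).astype(int)
        recs = [recs[i] for i in idx]
    acc = np.zeros(3)
    acc2 = np.zeros(3)
    n = 0
    for rec in recs:
        arr = np.asarray(Image.open(root / rec.path).convert("RGB"),
                         dtype=np.float64) / 255.0
        acc += arr.mean(axis=(0, 1))
        acc2 += (arr ** 2).mean(axis=(0, 1))
        n += 1
    mean = acc / n
    std = np.sqrt(np.maximum(acc2 / n - mean ** 2, 1e-8))
    return mean, std


def load_manifest(manifest: str | Path):
    """Read a manifest written by :func:`generate_dataset`.

    Returns (records, mean, std); mean/std are None if the header lacks them.
    """
    manifest = Path(manifest)
    records = []
    mean = std = None
    with open(manifest) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "mean":
                    mean = tuple(float(v) for v in val.split(","))
                elif key.strip() == "std":
                    std = tuple(float(v) for v in val.split(","))
                continue
            if not header_seen:
                if line != "path,label,split,seed":
                    raise ValueError(f"unexpected manifest header: {line}")
                header_seen = True
                continue
            path, label, split, seed = line.split(",")
            records.append(ImageRecord(
                path, label, split,
                seed=None if seed in ("", "None") else int(seed),
                base_id=path))
    return records, mean, std


class FolderDataset:
    """Image-folder dataset over a manifest split; yields (array, class index).

    Training mode statically expands the split via :func:`augment_corpus`
    (each base image plus `multiplicity - 1` fixed-seed augmented variants),
    so every record is a deterministic array; evaluation mode applies the
    deterministic center-crop transform.  Because records are pure functions
    of the manifest, small corpora are cached in memory after first access.
    """

    _CACHE_BUDGET_BYTES = 512 * 1024 * 1024

    def __init__(self, root: str | Path, split: str,
                 augment: AugmentConfig | None = None, train: bool = False,
                 cache: bool | None = None):
        self.root = Path(root)
        records, mean, std = load_manifest(self.root / "manifest.csv")
        self.records = [r for r in records if r.split == split]
        if not self.records:
            raise ValueError(f"split {split!r} is empty")
        cfg = augment or AugmentConfig()
        if mean is not None and std is not None:
            cfg = replace(cfg, mean=tuple(mean), std=tuple(std))
        self.cfg = cfg
        self.train = train
        if train and cfg.multiplicity > 1:
            self.records = augment_corpus(self.records, cfg.multiplicity)
        if cache is None:
            need = len(self.records) * 3 * cfg.output_size**2 * 8
            cache = need <= self._CACHE_BUDGET_BYTES
        self._cache: dict[int, np.ndarray] | None = {} if cache else None

    def __len__(self):
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.label] = out.get(r.label, 0) + 1
        return out

    def get(self, index: int, epoch: int = 0) -> tuple[np.ndarray, int]:
        rec = self.records[index]
        if self._cache is not None and index in self._cache:
            return self._cache[index], CLASS_INDEX[rec.label]
        path = self.root / rec.path
        if not path.exists():
            raise FileNotFoundError(f"missing image file: {path}")
        img = Image.open(path).convert("RGB")
        if self.train:
            if rec.seed is None:  # the original: clean standardized resize
                arr = apply_params(img, identity_params(), self.cfg)
            else:
                rng = np.random.default_rng(np.random.SeedSequence([rec.seed]))
                kind = VARIANT_KINDS[rec.seed % len(VARIANT_KINDS)]
                arr = variant_transform(img, rng, self.cfg, kind)
        else:
            arr = eval_transform(img, self.cfg,
                                 resize_short=round(self.cfg.output_size * 256 / 224))
        if self._cache is not None:
            self._cache[index] = arr
        return arr, CLASS_INDEX[rec.label]
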