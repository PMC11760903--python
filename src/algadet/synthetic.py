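"""Synthetic microalgae microscope scenes with exact ground truth.

Real annotated microalgae micrographs are scarce, so this module renders
controllable stand-ins: bright-field-like scenes (bright textured
background, darker cells) populated with parametric caricatures of seven
morphology classes —

======================  =======================================
class                   rendered morphology
======================  =======================================
*Chaetoceros*           chain of beads
*Chlorella*             small disc
*Chrysophyta*           lobed rosette
*Prorocentrum lima*     ovoid (egg-shaped)
*Karenia*               ellipse with a thin flagellum
*Dunaliella*            teardrop
*Phaeodactylum*         thin spindle
======================  =======================================

The shapes are caricatures for controllable difficulty, not renderings of
the real taxa.  Each instance's recorded box is the exact tight bounding
box of its rendered pixel mask.  Boxes are stored normalized, center
format, on a 0-based pixel grid with pixel centers at half-integer
coordinates: a mask spanning pixel columns ``x0..x1`` has normalized width
``(x1 - x0 + 1) / W`` and center ``(x0 + x1 + 1) / 2 / W``.

Augmentation mirrors the standard pipeline for small microscopy corpora:
salt-and-pepper impulse noise and random scaling.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .boxes import Box
from .losses import iou as box_iou

__all__ = [
    "CLASS_NAMES",
    "SceneSpec",
    "SceneAnnotation",
    "YoloParseError",
    "generate_scene",
    "salt_pepper",
    "random_scale",
    "write_yolo_labels",
    "read_yolo_labels",
    "build_dataset",
    "save_image",
    "load_image",
]

#: default seven morphology classes, index = class id in label files
CLASS_NAMES = (
    "Chaetoceros",
    "Chlorella",
    "Chrysophyta",
    "Prorocentrum lima",
    "Karenia",
    "Dunaliella",
    "Phaeodactylum",
)


class YoloParseError(ValueError):
    """Raised for malformed YOLO label lines (message includes line number)."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``instances_per_image`` is an inclusive count range; ``overlap_max``
    bounds the pairwise IoU of placed instance boxes; ``background`` is
    (mean intensity, texture amplitude) on the [0, 1] intensity scale;
    ``instance_size`` is the instance extent range as a fraction of the
    short image side; ``species`` restricts a scene to a single class
    (single-culture captures), ``None`` mixes classes uniformly.
    """

    width: int = 640
    height: int = 640
    classes: tuple[str, ...] = CLASS_NAMES
    instances_per_image: tuple[int, int] = (3, 8)
    overlap_max: float = 0.2
    background: tuple[float, float] = (0.85, 0.04)
    instance_size: tuple[float, float] = (0.08, 0.18)
    pixel_noise: float = 0.01
    species: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.width < 16 or self.height < 16:
            raise ValueError("image must be at least 16x16")
        if len(self.classes) < 1:
            raise ValueError("at least one class required")
        lo, hi = self.instances_per_image
        if lo < 0 or hi < lo:
            raise ValueError("invalid instance count range")

    @classmethod
    def easy(cls, size: int = 128, species: int | None = None, seed: int = 0) -> "SceneSpec":
        """A low-difficulty preset: few, large, well-separated, high-contrast
        cells — the regime of a clean single-culture capture."""
        return cls(
            width=size,
            height=size,
            instances_per_image=(2, 4),
            overlap_max=0.0,
            background=(0.88, 0.02),
            instance_size=(0.20, 0.30),
            pixel_noise=0.005,
            species=species,
            seed=seed,
        )


@dataclass
class SceneAnnotation:
    """A rendered scene plus its ground truth (normalized center boxes).

    ``masks`` holds the per-instance boolean pixel masks when the scene was
    generated with ``keep_masks=True`` (diagnostics; empty otherwise).
    """

    image: np.ndarray
    records: list[tuple[int, Box]] = field(default_factory=list)
    masks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        for cid, b in self.records:
            for val in (b.cx, b.cy, b.w, b.h):
                if not 0.0 <= val <= 1.0:
                    raise ValueError("normalized box coordinates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# rendering


def _shape_mask(kind: int, h: int, w: int, cx: float, cy: float, size: float,
                angle: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean pixel mask of one instance; `size` is the major extent in px."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64) + 0.5
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    a = size / 2.0
    kind = kind % 7
    if kind == 0:  # chain of beads
        n_beads = int(rng.integers(3, 6))
        r = a / (1.0 + 0.8 * (n_beads - 1))
        centers = (np.arange(n_beads) - (n_beads - 1) / 2.0) * 1.6 * r
        mask = np.zeros((h, w), dtype=bool)
        for uc in centers:
            mask |= (u - uc) ** 2 + v**2 <= r**2
        return mask
    if kind == 1:  # small disc
        r = a * 0.6
        return u**2 + v**2 <= r**2
    if kind == 2:  # lobed rosette
        r_pix = np.hypot(u, v)
        theta = np.arctan2(v, u)
        phase = rng.uniform(0, 2 * np.pi)
        return r_pix <= a * (0.78 + 0.22 * np.sin(6 * theta + phase))
    if kind == 3:  # ovoid / egg
        b = a * 0.72
        b_eff = b * (1.0 + 0.2 * np.clip(u / a, -1, 1))
        return (u / a) ** 2 + (v / np.maximum(b_eff, 1e-6)) ** 2 <= 1
    if kind == 4:  # ellipse with flagellum
        b = a * 0.62
        body = (u / a) ** 2 + (v / b) ** 2 <= 1
        flagellum = (u >= 0) & (u <= 1.5 * a) & (np.abs(v) <= 0.9)
        return body | flagellum
    if kind == 5:  # teardrop
        t = u / a
        width = a * 0.55 * (1.0 - t) * np.sqrt(np.clip((1.0 + t) / 2.0, 0, 1))
        return (np.abs(t) <= 1) & (np.abs(v) <= width)
    # kind == 6: thin spindle
    t = u / a
    return (np.abs(t) <= 1) & (np.abs(v) <= a * 0.16 * (1.0 - t**2))


def _tight_box(mask: np.ndarray, w: int, h: int) -> Box:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    y0, y1 = rows[0], rows[-1]
    x0, x1 = cols[0], cols[-1]
    return Box(
        cx=(x0 + x1 + 1) / 2.0 / w,
        cy=(y0 + y1 + 1) / 2.0 / h,
        w=(x1 - x0 + 1) / w,
        h=(y1 - y0 + 1) / h,
    )


def _class_intensity(class_id: int, n_classes: int, rng: np.random.Generator) -> float:
    # distinct optical densities per taxon, jittered per instance
    base = 0.14 + 0.48 * (class_id / max(n_classes - 1, 1))
    return float(np.clip(base + rng.normal(0, 0.02), 0.05, 0.75))


def generate_scene(spec: SceneSpec, seed: int | None = None,
                   keep_masks: bool = False) -> SceneAnnotation:
    """Render one scene; deterministic for a fixed spec and seed.

    Instances that cannot be placed within the overlap/bounds constraints
    after bounded retries are skipped with a warning, so a scene may hold
    fewer instances than drawn.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    h, w = spec.height, spec.width
    mean_bg, tex = spec.background
    texture = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=max(h, w) / 24)
    if texture.std() > 0:
        texture = texture / texture.std()
    image = np.clip(mean_bg + tex * texture, 0, 1)

    n_instances = int(rng.integers(spec.instances_per_image[0], spec.instances_per_image[1] + 1))
    records: list[tuple[int, Box]] = []
    boxes_px: list[Box] = []
    masks: list[np.ndarray] = []
    short = min(h, w)
    for _ in range(n_instances):
        class_id = spec.species if spec.species is not None else int(rng.integers(len(spec.classes)))
        placed = False
        for _attempt in range(30):
            size = rng.uniform(*spec.instance_size) * short
            margin = size * 0.9 + 2
            if 2 * margin >= min(h, w):
                size = short * 0.3
                margin = size * 0.9 + 2
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            angle = rng.uniform(0, np.pi)
            mask = _shape_mask(class_id, h, w, cx, cy, size, angle, rng)
            if not mask.any():
                continue
            rows = np.flatnonzero(mask.any(axis=1))
            cols = np.flatnonzero(mask.any(axis=0))
            if rows[0] == 0 or cols[0] == 0 or rows[-1] == h - 1 or cols[-1] == w - 1:
                continue  # touches the border; retry
            box_n = _tight_box(mask, w, h)
            box_px = Box(box_n.cx * w, box_n.cy * h, box_n.w * w, box_n.h * h)
            if any(box_iou(box_px, prev) > spec.overlap_max for prev in boxes_px):
                continue
            intensity = _class_intensity(class_id, len(spec.classes), rng)
            image[mask] = np.clip(intensity + rng.normal(0, 0.01, int(mask.sum())), 0, 1)
            records.append((class_id, box_n))
            boxes_px.append(box_px)
            if keep_masks:
                masks.append(mask)
            placed = True
            break
        if not placed:
            warnings.warn("could not place an instance within constraints; scene holds fewer", stacklevel=2)
    if spec.pixel_noise > 0:
        image = np.clip(image + rng.normal(0, spec.pixel_noise, (h, w)), 0, 1)
    return SceneAnnotation(image=image, records=records, masks=masks)


# ---------------------------------------------------------------------------
# augmentation


def _intensity_extremes(image: np.ndarray) -> tuple[float, float]:
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return float(info.min), float(info.max)
    return 0.0, 1.0


def salt_pepper(image: np.ndarray, fraction: float, seed: int = 0) -> np.ndarray:
    """Impulse noise: exactly ``round(fraction * n_pixels)`` pixels replaced,
    half with the minimum intensity and half with the maximum (an odd count
    assigns the extra pixel by a seeded coin flip).  Untouched pixels are
    bit-identical to the input."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"noise fraction must lie in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    out = image.copy()
    n = int(round(fraction * image.size))
    if n == 0:
        return out
    lo, hi = _intensity_extremes(image)
    idx = rng.choice(image.size, size=n, replace=False)
    n_lo = n // 2
    if n % 2 == 1 and rng.integers(2) == 1:
        n_lo += 1
    flat = out.reshape(-1)
    flat[idx[:n_lo]] = lo
    flat[idx[n_lo:]] = hi
    return out


def random_scale(scene: SceneAnnotation, scale_range: tuple[float, float] = (0.8, 1.2),
                 seed: int = 0, mode: str = "resize", min_visible: float = 0.25) -> SceneAnnotation:
    """Rescale a scene by a seeded factor.

    ``mode="resize"`` rescales the whole image; normalized boxes are
    unchanged.  ``mode="crop_pad"`` rescales and then center-crops (factor
    > 1) or center-pads (factor < 1) back to the original size; boxes are
    remapped and clipped, and instances whose visible area falls below
    ``min_visible`` of their full area are dropped.
    """
    if mode not in ("resize", "crop_pad"):
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = scale_range
    if not (lo > 0 and hi >= lo):
        raise ValueError("scale bounds must be positive with hi >= lo")
    rng = np.random.default_rng(seed)
    factor = float(rng.uniform(lo, hi))
    if factor == 1.0:
        return SceneAnnotation(image=scene.image.copy(), records=list(scene.records))
    h, w = scene.image.shape[:2]
    nh, nw = max(1, round(h * factor)), max(1, round(w * factor))
    scaled = ndimage.zoom(scene.image, (nh / h, nw / w), order=1)
    if mode == "resize":
        return SceneAnnotation(image=scaled, records=list(scene.records))

    off_y, off_x = (nh - h) / 2.0, (nw - w) / 2.0
    canvas = np.full((h, w), float(np.median(scene.image)), dtype=scene.image.dtype)
    src_y0, src_x0 = max(0, int(round(off_y))), max(0, int(round(off_x)))
    dst_y0, dst_x0 = max(0, -int(round(off_y))), max(0, -int(round(off_x)))
    span_y = min(nh - src_y0, h - dst_y0)
    span_x = min(nw - src_x0, w - dst_x0)
    canvas[dst_y0 : dst_y0 + span_y, dst_x0 : dst_x0 + span_x] = scaled[
        src_y0 : src_y0 + span_y, src_x0 : src_x0 + span_x
    ]
    records: list[tuple[int, Box]] = []
    for cid, b in scene.records:
        # pixel corners in the scaled frame, then into the canvas frame
        x1 = (b.cx - b.w / 2) * nw - off_x
        x2 = (b.cx + b.w / 2) * nw - off_x
        y1 = (b.cy - b.h / 2) * nh - off_y
        y2 = (b.cy + b.h / 2) * nh - off_y
        full_area = (x2 - x1) * (y2 - y1)
        cx1, cx2 = max(x1, 0.0), min(x2, float(w))
        cy1, cy2 = max(y1, 0.0), min(y2, float(h))
        if cx2 <= cx1 or cy2 <= cy1:
            continue
        if (cx2 - cx1) * (cy2 - cy1) < min_visible * full_area:
            continue
        records.append(
            (cid, Box((cx1 + cx2) / 2 / w, (cy1 + cy2) / 2 / h, (cx2 - cx1) / w, (cy2 - cy1) / h))
        )
    return SceneAnnotation(image=canvas, records=records)


# ---------------------------------------------------------------------------
# YOLO text-label IO


def write_yolo_labels(records, path) -> None:
    """Write records as YOLO label lines ``class cx cy w h`` (6 decimals).

    A record is ``(class_id, Box)`` or ``(class_id, Box, score)``; the score
    is appended as a sixth column (prediction files).
    """
    lines = []
    for rec in records:
        cid, box = rec[0], rec[1]
        line = f"{int(cid)} {box.cx:.6f} {box.cy:.6f} {box.w:.6f} {box.h:.6f}"
        if len(rec) > 2:
            line += f" {rec[2]:.6f}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path, with_scores: bool = False):
    """Parse a YOLO label file back into records.

    Returns ``(class_id, Box)`` tuples, or ``(class_id, Box, score)`` when
    ``with_scores`` is set (missing score column defaults to 1.0).
    """
    records = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise YoloParseError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        try:
            cid = int(parts[0])
            vals = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise YoloParseError(f"{path}:{lineno}: {exc}") from exc
        box = Box(*vals[:4])
        if with_scores:
            records.append((cid, box, vals[4] if len(vals) > 4 else 1.0))
        else:
            records.append((cid, box))
    return records


def save_image(image: np.ndarray, path) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image), 0, 1)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)


def load_image(path) -> np.ndarray:
    """Read a grayscale PNG back to a [0, 1] float array."""
    return np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0


# ---------------------------------------------------------------------------
# dataset builder


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _split_counts(m: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder allocation of m items to the three splits."""
    raw = [m * r for r in ratios]
    counts = [int(np.floor(x)) for x in raw]
    rema = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(m - sum(counts)):
        counts[rema[i % 3]] += 1
    return tuple(counts)


def build_dataset(spec: SceneSpec, n_images: int, out_dir,
                  split: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0, noise_fraction: float = 0.0,
                  scale_range: tuple[float, float] | None = None) -> dict:
    """Build a class-balanced dataset on disk and return its manifest.

    Each image is a single-species scene (the capture regime of cultured
    samples); image counts are balanced across classes, with any remainder
    going to the lowest class ids.  Splits are applied per class with
    largest-remainder rounding, so e.g. 10 images per class at 8:1:1 give
    8/1/1.  With ``noise_fraction`` > 0 or a ``scale_range``, training
    images are augmented in place (salt-and-pepper noise, random whole-image
    rescale) while validation and test images stay clean.

    Fully deterministic for a fixed spec and seed; the manifest records the
    spec, every per-file SHA-256 hash and the per-split counts.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    out = Path(out_dir)
    n_classes = len(spec.classes)
    per_class = [n_images // n_classes] * n_classes
    for i in range(n_images - sum(per_class)):
        per_class[i] += 1
    if n_images % n_classes:
        warnings.warn(
            f"{n_images} images across {n_classes} classes: using nearest balanced "
            f"allocation {per_class}", stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    manifest: dict = {
        "seed": int(seed),
        "n_images": int(n_images),
        "split_ratios": list(split),
        "class_names": list(spec.classes),
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()},
        "noise_fraction": noise_fraction,
        "scale_range": list(scale_range) if scale_range else None,
        "splits": {"train": [], "val": [], "test": []},
    }
    for name in ("train", "val", "test"):
        (out / "images" / name).mkdir(parents=True, exist_ok=True)
        (out / "labels" / name).mkdir(parents=True, exist_ok=True)

    counter = 0
    for class_id, m in enumerate(per_class):
        n_tr, n_va, n_te = _split_counts(m, split)
        assignments = ["train"] * n_tr + ["val"] * n_va + ["test"] * n_te
        for k, split_name in enumerate(assignments):
            scene_seed = int(rng.integers(0, 2**31 - 1))
            scene = generate_scene(
                SceneSpec(**{**asdict(spec), "species": class_id, "seed": scene_seed})
            )
            if split_name == "train":
                if scale_range is not None:
                    scene = random_scale(scene, scale_range, seed=scene_seed + 1, mode="resize")
                if noise_fraction > 0:
                    scene = SceneAnnotation(
                        image=salt_pepper(scene.image, noise_fraction, seed=scene_seed + 2),
                        records=scene.records,
                    )
            stem = f"img_{counter:05d}"
            counter += 1
            img_path = out / "images" / split_name / f"{stem}.png"
            lbl_path = out / "labels" / split_name / f"{stem}.txt"
            save_image(scene.image, img_path)
            write_yolo_labels(scene.records, lbl_path)
            manifest["splits"][split_name].append(
                {
                    "image": str(img_path.relative_to(out)),
                    "label": str(lbl_path.relative_to(out)),
                    "class_id": class_id,
                    "scene_seed": scene_seed,
                    "sha256_image": _file_sha256(img_path),
                    "sha256_label": _file_sha256(lbl_path),
                }
            )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
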