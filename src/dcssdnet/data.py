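"""Frame I/O, preprocessing, augmentation, splits, and synthetic data.

Covers the data side of the detector: the ROI center-crop that strips
the black periphery of capsule-endoscopy frames, the four geometric
augmentations with exact box transforms, Pascal-VOC XML reading/writing
in the LabelImg dialect, deterministic dataset splitting and k-fold
partitioning, and a seeded generator of endoscopy-like synthetic frames
with exact ground-truth boxes.

Box convention: internal boxes are 0-based half-open pixel coordinates
``(xmin, ymin, xmax, ymax)``; VOC XML on disk is 1-based inclusive, so
the reader subtracts 1 from the minima and the writer adds it back.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "AnnotatedFrame",
    "SyntheticSceneSpec",
    "roi_center_crop",
    "transform_sample",
    "read_voc_annotation",
    "write_voc_annotation",
    "split_dataset",
    "kfold",
    "generate_synthetic_dataset",
    "write_manifest",
    "read_manifest",
    "load_frame",
]

#: border rows/cols with mean 8-bit intensity below this are "black"
BLACKNESS_THRESHOLD = 10.0


@dataclass
class AnnotatedFrame:
    """An RGB frame with its ground-truth boxes.

    image: (H, W, 3) uint8; boxes: (M, 4) float, 0-based half-open
    pixels; labels: one class name per box (always "polyp" here).
    """

    image: np.ndarray
    boxes: np.ndarray
    labels: list[str] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 4)
        h, w = self.image.shape[:2]
        if len(self.boxes):
            if (self.boxes[:, [0, 1]].min() < 0
                    or self.boxes[:, 2].max() > w
                    or self.boxes[:, 3].max() > h):
                raise ValueError("box outside image bounds")


def roi_center_crop(image: np.ndarray,
                    threshold: float = BLACKNESS_THRESHOLD,
                    ) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop to the largest centered square with a non-black border.

    Returns ``(cropped, (x_offset, y_offset))`` so that a box
    ``(xmin, ymin, xmax, ymax)`` in the original frame becomes
    ``(xmin - x_offset, ...)`` in the crop.  An image with no black
    periphery comes back unchanged with offset (0, 0); a fully black
    frame raises ``ValueError``.
    """
    h, w = image.shape[:2]
    gray = np.asarray(image, dtype=float)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    side = min(h, w)
    y0, x0 = (h - side) // 2, (w - side) // 2
    sq = gray[y0:y0 + side, x0:x0 + side]
    for t in range(side // 2):
        s = side - 2 * t
        top = sq[t, t:t + s].mean()
        bottom = sq[t + s - 1, t:t + s].mean()
        left = sq[t:t + s, t].mean()
        right = sq[t:t + s, t + s - 1].mean()
        if min(top, bottom, left, right) > threshold:
            crop = image[y0 + t:y0 + t + s, x0 + t:x0 + t + s]
            return crop, (x0 + t, y0 + t)
    raise ValueError("image is entirely black: no ROI found")


_AUG_OPS = ("hflip", "vflip", "hvflip", "rot270")


def transform_sample(frame: AnnotatedFrame, op: str) -> AnnotatedFrame:
    """Apply one geometric augmentation to image and boxes consistently.

    hflip / vflip mirror across the vertical / horizontal axis, hvflip
    does both, rot270 rotates a square frame by 270 degrees about its
    center (point map (x, y) -> (y, H - x)).
    """
    if op not in _AUG_OPS:
        raise ValueError(f"unknown op {op!r}; choose from {_AUG_OPS}")
    img = frame.image
    h, w = img.shape[:2]
    b = frame.boxes.copy()
    if op == "hflip":
        new_img = img[:, ::-1].copy()
        nb = np.stack([w - b[:, 2], b[:, 1], w - b[:, 0], b[:, 3]], axis=1) \
            if len(b) else b
    elif op == "vflip":
        new_img = img[::-1].copy()
        nb = np.stack([b[:, 0], h - b[:, 3], b[:, 2], h - b[:, 1]], axis=1) \
            if len(b) else b
    elif op == "hvflip":
        new_img = img[::-1, ::-1].copy()
        nb = np.stack([w - b[:, 2], h - b[:, 3], w - b[:, 0], h - b[:, 1]],
                      axis=1) if len(b) else b
    else:  # rot270
        if h != w:
            raise ValueError("rot270 requires a square frame; crop first")
        new_img = np.rot90(img, k=1).copy()
        nb = np.stack([b[:, 1], h - b[:, 2], b[:, 3], h - b[:, 0]], axis=1) \
            if len(b) else b
    return AnnotatedFrame(new_img, nb, list(frame.labels),
                          f"{frame.source_id}:{op}")


# ---------------------------------------------------------------------------
# Pascal-VOC XML (LabelImg dialect)


def _req(parent: etree._Element, tag: str, path: str | Path):
    el = parent.find(tag)
    if el is None or el.text is None:
        raise ValueError(f"{path}: missing element {parent.tag}/{tag}")
    return el.text


def read_voc_annotation(path: str | Path) -> dict:
    """Parse a LabelImg VOC XML file.

    Returns ``{"source_id", "width", "height", "boxes", "labels"}`` with
    boxes converted to internal 0-based half-open coordinates.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed VOC XML in {path}: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise ValueError(f"{path}: missing element annotation/size")
    width = int(_req(size, "width", path))
    height = int(_req(size, "height", path))
    boxes, labels = [], []
    for obj in root.findall("object"):
        name = _req(obj, "name", path)
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"{path}: missing element object/bndbox")
        xmin = float(_req(bnd, "xmin", path))
        ymin = float(_req(bnd, "ymin", path))
        xmax = float(_req(bnd, "xmax", path))
        ymax = float(_req(bnd, "ymax", path))
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(
                f"{path}: object/bndbox has xmax <= xmin or ymax <= ymin")
        boxes.append((xmin - 1, ymin - 1, xmax, ymax))
        labels.append(name)
    filename = root.findtext("filename", default=path.stem)
    return {"source_id": filename, "width": width, "height": height,
            "boxes": np.array(boxes, dtype=float).reshape(-1, 4),
            "labels": labels}


def write_voc_annotation(frame: AnnotatedFrame, path: str | Path,
                         image_path: str | Path | None = None) -> None:
    """Write a frame's annotation as LabelImg-dialect VOC XML."""
    h, w = frame.image.shape[:2]
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = frame.source_id or Path(path).stem
    if image_path is not None:
        etree.SubElement(root, "path").text = str(image_path)
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(w)
    etree.SubElement(size, "height").text = str(h)
    etree.SubElement(size, "depth").text = str(frame.image.shape[2])
    etree.SubElement(root, "segmented").text = "0"
    for box, label in zip(frame.boxes, frame.labels):
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(round(box[0])) + 1)
        etree.SubElement(bnd, "ymin").text = str(int(round(box[1])) + 1)
        etree.SubElement(bnd, "xmax").text = str(int(round(box[2])))
        etree.SubElement(bnd, "ymax").text = str(int(round(box[3])))
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# splits


def split_dataset(ids: list, fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                  seed: int = 0) -> tuple[list, list, list]:
    """Deterministic disjoint train/val/test split by largest remainder."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    ids = list(ids)
    n = len(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    raw = [f * n for f in fractions]
    sizes = [int(x) for x in raw]
    for _ in range(n - sum(sizes)):  # distribute remainder
        rema = [r - s for r, s in zip(raw, sizes)]
        sizes[int(np.argmax(rema))] += 1
    out, start = [], 0
    for s in sizes:
        out.append([ids[i] for i in order[start:start + s]])
        start += s
    return tuple(out)


def kfold(ids: list, k: int = 5, seed: int = 0) -> list[list]:
    """Deterministic k folds; sizes differ by at most one."""
    ids = list(ids)
    if len(ids) < k:
        raise ValueError(f"cannot make {k} folds from {len(ids)} items")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(order, k)]


# ---------------------------------------------------------------------------
# synthetic endoscopy frames


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of the synthetic endoscopy-frame renderer.

    Frames emulate capsule-endoscopy imagery: a vignetted, mucosa-
    textured disc with one or more elliptical polyp blobs (textured
    interior, darker boundary rim) plus optional bubble and specular-
    highlight distractors and a black circular border.  Rendering is a
    pure function of ``seed``.
    """

    image_size: int = 299
    n_polyps: tuple[int, int] = (1, 2)
    polyp_radius: tuple[int, int] | None = None  # default ~(7%, 17%) of size
    contrast: tuple[float, float] = (0.25, 0.55)
    artifacts: frozenset = frozenset({"bubbles", "specular", "black_border"})
    seed: int = 0

    def radius_range(self) -> tuple[int, int]:
        if self.polyp_radius is not None:
            lo, hi = self.polyp_radius
        else:
            lo = max(4, round(0.07 * self.image_size))
            hi = round(0.17 * self.image_size)
        if hi >= self.image_size // 2:
            raise ValueError("polyp radius exceeds image half-size")
        return int(lo), int(hi)


def _render_frame(spec: SyntheticSceneSpec, rng: np.random.Generator,
                  index: int) -> AnnotatedFrame:
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    cx = cy = (s - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy) / (s / 2.0)

    # mucosa base: warm tint + two scales of smoothed noise + vignette
    base = np.array([0.72, 0.42, 0.36])
    tex_coarse = gaussian_filter(rng.normal(0, 1, (s, s)), s * 0.04)
    tex_fine = gaussian_filter(rng.normal(0, 1, (s, s)), max(1.0, s * 0.008))
    lum = 1.0 + 0.25 * tex_coarse / (np.abs(tex_coarse).max() + 1e-9) \
        + 0.08 * tex_fine / (np.abs(tex_fine).max() + 1e-9)
    vignette = 1.0 - 0.45 * np.clip(r, 0, 1) ** 2
    img = base[None, None, :] * (lum * vignette)[:, :, None]

    # polyps: elliptical blobs with textured interior and darker rim
    lo, hi = spec.radius_range()
    n_polyps = int(rng.integers(spec.n_polyps[0], spec.n_polyps[1] + 1))
    boxes, labels = [], []
    for _ in range(n_polyps):
        for _attempt in range(50):
            a = rng.uniform(lo, hi)
            b = rng.uniform(0.6, 1.0) * a
            theta = rng.uniform(0, np.pi)
            max_ext = max(a, b)
            rad = rng.uniform(0, 0.55) * (s / 2.0 - max_ext - 2)
            ang = rng.uniform(0, 2 * np.pi)
            pcx = cx + rad * np.cos(ang)
            pcy = cy + rad * np.sin(ang)
            ct, st = np.cos(theta), np.sin(theta)
            xr = (xx - pcx) * ct + (yy - pcy) * st
            yr = -(xx - pcx) * st + (yy - pcy) * ct
            e = (xr / a) ** 2 + (yr / b) ** 2
            mask = e <= 1.0
            if mask.any():
                break
        contrast = rng.uniform(*spec.contrast)
        profile = np.clip(1.0 - e, 0.0, 1.0) ** 0.6
        bump = gaussian_filter(rng.normal(0, 1, (s, s)), max(1.0, s * 0.01))
        bump = 0.12 * bump / (np.abs(bump).max() + 1e-9)
        tint = np.array([1.0 + contrast, 1.0 + 0.35 * contrast, 1.0])
        gain = 1.0 + (contrast + bump) * profile
        img = np.where(mask[:, :, None],
                       img * gain[:, :, None] * tint[None, None, :] / tint.mean(),
                       img)
        rim = (e > 0.75) & (e <= 1.05)
        img[rim] *= 0.72
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        boxes.append((cols[0], rows[0], cols[-1] + 1, rows[-1] + 1))
        labels.append("polyp")

    if "bubbles" in spec.artifacts:
        for _ in range(int(rng.integers(0, 5))):
            br = rng.uniform(0.015, 0.04) * s
            bx = rng.uniform(0.2, 0.8) * s
            by = rng.uniform(0.2, 0.8) * s
            d = np.hypot(xx - bx, yy - by)
            ring = (d > br * 0.7) & (d <= br)
            img[ring] = img[ring] * 0.6 + 0.35
            inner = d <= br * 0.7
            img[inner] = img[inner] * 0.9 + 0.05

    if "specular" in spec.artifacts:
        for _ in range(int(rng.integers(1, 6))):
            sx = rng.uniform(0.15, 0.85) * s
            sy = rng.uniform(0.15, 0.85) * s
            sr = rng.uniform(0.004, 0.012) * s
            d = np.hypot(xx - sx, yy - sy)
            glow = np.exp(-(d / (sr + 1e-9)) ** 2)
            img = img + glow[:, :, None] * 0.9

    if "black_border" in spec.artifacts:
        border = np.clip((1.02 - r) / 0.04, 0, 1)
        img *= border[:, :, None]

    img = np.clip(img, 0.0, 1.0)
    image = (img * 255).round().astype(np.uint8)
    return AnnotatedFrame(image, np.array(boxes, dtype=float).reshape(-1, 4),
                          labels, source_id=f"synthetic_{spec.seed}_{index:04d}")


def generate_synthetic_dataset(spec: SyntheticSceneSpec, n_frames: int,
                               out_dir: str | Path | None = None,
                               ) -> list[AnnotatedFrame]:
    """Render ``n_frames`` deterministic synthetic frames.

    With ``out_dir`` set, also writes PNG images, VOC XML annotations,
    and a ``manifest.csv`` (id, image path, xml path).
    """
    rng = np.random.default_rng(spec.seed)
    frames = [_render_frame(spec, rng, i) for i in range(n_frames)]
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "annotations").mkdir(parents=True, exist_ok=True)
        rows = []
        for fr in frames:
            img_path = out / "images" / f"{fr.source_id}.png"
            xml_path = out / "annotations" / f"{fr.source_id}.xml"
            Image.fromarray(fr.image).save(img_path)
            write_voc_annotation(fr, xml_path, image_path=img_path)
            rows.append((fr.source_id, str(img_path), str(xml_path)))
        write_manifest(rows, out / "manifest.csv")
    return frames


def write_manifest(rows: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image", "annotation"])
        writer.writerows(rows)


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def load_frame(image_path: str | Path, xml_path: str | Path) -> AnnotatedFrame:
    """Load an image + VOC annotation pair into an AnnotatedFrame."""
    image = np.asarray(Image.open(image_path).convert("RGB"))
    meta = read_voc_annotation(xml_path)
    return AnnotatedFrame(image, meta["boxes"], meta["labels"],
                          source_id=meta["source_id"])
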