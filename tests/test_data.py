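"""Preprocessing, augmentation, VOC I/O, splits, and the synthetic generator."""

import numpy as np
import pytest

from dcssdnet import (AnnotatedFrame, SyntheticSceneSpec,
                      generate_synthetic_dataset, kfold, read_voc_annotation,
                      roi_center_crop, split_dataset, transform_sample,
                      write_voc_annotation)
from dcssdnet.data import load_frame


def _frame(image, boxes, labels=None):
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    if labels is None:
        labels = ["polyp"] * len(boxes)
    return AnnotatedFrame(image, boxes, labels, "test")


# -- ROI crop ---------------------------------------------------------------

def test_roi_crop_leaves_clean_image_unchanged():
    img = np.full((64, 64, 3), 120, dtype=np.uint8)
    out, offset = roi_center_crop(img)
    assert offset == (0, 0)
    np.testing.assert_array_equal(out, img)


def test_roi_crop_strips_black_frame():
    img = np.zeros((256, 256, 3), dtype=np.uint8)
    img[28:228, 28:228] = 180  # centered 200x200 bright square
    out, offset = roi_center_crop(img)
    assert out.shape == (200, 200, 3)
    assert offset == (28, 28)


def test_roi_crop_fully_black_raises():
    with pytest.raises(ValueError, match="black"):
        roi_center_crop(np.zeros((64, 64, 3), dtype=np.uint8))


def test_roi_crop_box_remap_preserves_overlap():
    img = np.zeros((120, 120, 3), dtype=np.uint8)
    img[20:100, 20:100] = 200
    box = np.array([30.0, 40.0, 60.0, 70.0])
    out, (ox, oy) = roi_center_crop(img)
    remapped = box - [ox, oy, ox, oy]
    # same pixels covered before and after the translation
    w0 = img[int(box[1]):int(box[3]), int(box[0]):int(box[2])]
    w1 = out[int(remapped[1]):int(remapped[3]), int(remapped[0]):int(remapped[2])]
    np.testing.assert_array_equal(w0, w1)


# -- geometric augmentation -------------------------------------------------

def _mask_bbox_oracle(frame, op):
    """Transform a rasterized box mask with the image and re-extract bbox."""
    out_boxes = []
    for b in frame.boxes:
        mask = np.zeros(frame.image.shape[:2], dtype=np.uint8)
        mask[int(b[1]):int(b[3]), int(b[0]):int(b[2])] = 1
        m = transform_sample(_frame(mask[:, :, None].repeat(3, axis=2),
                                    np.zeros((0, 4))), op).image[:, :, 0]
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        out_boxes.append((cols[0], rows[0], cols[-1] + 1, rows[-1] + 1))
    return np.array(out_boxes, dtype=float)


@pytest.mark.parametrize("op", ["hflip", "vflip", "hvflip", "rot270"])
def test_box_transform_matches_mask_oracle(op):
    rng = np.random.default_rng(11)
    img = rng.integers(0, 255, (100, 100, 3), dtype=np.uint8)
    boxes = [(10, 20, 30, 40), (55, 5, 95, 60)]
    frame = _frame(img, boxes)
    out = transform_sample(frame, op)
    np.testing.assert_array_equal(out.boxes, _mask_bbox_oracle(frame, op))


def test_hflip_reference_box():
    img = np.zeros((100, 100, 3), dtype=np.uint8)
    out = transform_sample(_frame(img, [(10, 20, 30, 40)]), "hflip")
    np.testing.assert_array_equal(out.boxes[0], [70, 20, 90, 40])


def test_flips_are_involutions_and_rot270_has_order_4():
    rng = np.random.default_rng(12)
    img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
    frame = _frame(img, [(5, 10, 20, 30)])
    for op in ("hflip", "vflip", "hvflip"):
        twice = transform_sample(transform_sample(frame, op), op)
        np.testing.assert_array_equal(twice.image, frame.image)
        np.testing.assert_array_equal(twice.boxes, frame.boxes)
    r = frame
    for _ in range(4):
        r = transform_sample(r, "rot270")
    np.testing.assert_array_equal(r.image, frame.image)
    np.testing.assert_array_equal(r.boxes, frame.boxes)


def test_flips_preserve_box_areas():
    rng = np.random.default_rng(13)
    img = rng.integers(0, 255, (80, 80, 3), dtype=np.uint8)
    frame = _frame(img, [(3, 7, 33, 19), (40, 41, 77, 79)])
    area = lambda b: (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    for op in ("hflip", "vflip", "hvflip", "rot270"):
        out = transform_sample(frame, op)
        np.testing.assert_array_equal(area(out.boxes), area(frame.boxes))


def test_rot270_rejects_non_square():
    img = np.zeros((50, 60, 3), dtype=np.uint8)
    with pytest.raises(ValueError, match="square"):
        transform_sample(_frame(img, np.zeros((0, 4))), "rot270")


def test_unknown_op_rejected():
    img = np.zeros((10, 10, 3), dtype=np.uint8)
    with pytest.raises(ValueError):
        transform_sample(_frame(img, np.zeros((0, 4))), "transpose")


# -- VOC XML ----------------------------------------------------------------

def test_voc_reader_converts_to_zero_based_half_open(tmp_path):
    xml = """<annotation><filename>f.png</filename>
    <size><width>50</width><height>40</height><depth>3</depth></size>
    <object><name>polyp</name>
      <bndbox><xmin>1</xmin><ymin>1</ymin><xmax>10</xmax><ymax>10</ymax></bndbox>
    </object></annotation>"""
    p = tmp_path / "f.xml"
    p.write_text(xml)
    meta = read_voc_annotation(p)
    np.testing.assert_array_equal(meta["boxes"][0], [0, 0, 10, 10])
    assert meta["labels"] == ["polyp"]


def test_voc_round_trip_identity_randomized(tmp_path):
    rng = np.random.default_rng(21)
    for trial in range(100):
        h, w = int(rng.integers(40, 200)), int(rng.integers(40, 200))
        n = int(rng.integers(0, 4))
        boxes = []
        for _ in range(n):
            x0, y0 = rng.integers(0, w - 10), rng.integers(0, h - 10)
            boxes.append((x0, y0, x0 + int(rng.integers(2, w - x0)),
                          y0 + int(rng.integers(2, h - y0))))
        frame = _frame(np.zeros((h, w, 3), dtype=np.uint8), boxes)
        p = tmp_path / f"t{trial}.xml"
        write_voc_annotation(frame, p)
        meta = read_voc_annotation(p)
        np.testing.assert_array_equal(meta["boxes"], frame.boxes)
        # write what was read -> byte-identical second read
        frame2 = _frame(np.zeros((h, w, 3), dtype=np.uint8), meta["boxes"])
        p2 = tmp_path / f"t{trial}b.xml"
        write_voc_annotation(frame2, p2)
        assert p.read_bytes() == p2.read_bytes()


def test_voc_reader_errors_name_the_file(tmp_path):
    bad = tmp_path / "bad.xml"
    bad.write_text("<annotation><size></size")
    with pytest.raises(ValueError, match="bad.xml"):
        read_voc_annotation(bad)
    inverted = tmp_path / "inverted.xml"
    inverted.write_text(
        "<annotation><size><width>10</width><height>10</height>"
        "<depth>3</depth></size><object><name>polyp</name><bndbox>"
        "<xmin>5</xmin><ymin>1</ymin><xmax>5</xmax><ymax>9</ymax>"
        "</bndbox></object></annotation>")
    with pytest.raises(ValueError, match="bndbox"):
        read_voc_annotation(inverted)


# -- splits -----------------------------------------------------------------

def test_split_sizes_70_10_20():
    train, val, test = split_dataset(list(range(100)), (0.7, 0.1, 0.2), seed=0)
    assert (len(train), len(val), len(test)) == (70, 10, 20)
    assert sorted(train + val + test) == list(range(100))


def test_split_is_deterministic_and_fraction_checked():
    a = split_dataset(list(range(37)), seed=5)
    b = split_dataset(list(range(37)), seed=5)
    assert a == b
    with pytest.raises(ValueError):
        split_dataset(list(range(10)), (0.5, 0.2, 0.2))


def test_kfold_partition_properties():
    ids = [f"id{i}" for i in range(23)]
    folds = kfold(ids, k=5, seed=3)
    sizes = [len(f) for f in folds]
    assert max(sizes) - min(sizes) <= 1
    flat = [x for f in folds for x in f]
    assert sorted(flat) == sorted(ids)
    assert kfold(ids, k=5, seed=3) == folds
    with pytest.raises(ValueError):
        kfold(ids[:3], k=5)


# -- synthetic generator ----------------------------------------------------

def test_synthetic_dataset_is_deterministic_and_in_bounds(tmp_path):
    spec = SyntheticSceneSpec(image_size=128, seed=7)
    frames_a = generate_synthetic_dataset(spec, 10, tmp_path / "a")
    frames_b = generate_synthetic_dataset(spec, 10)
    assert len(frames_a) == 10
    for fa, fb in zip(frames_a, frames_b):
        np.testing.assert_array_equal(fa.image, fb.image)
        np.testing.assert_array_equal(fa.boxes, fb.boxes)
    assert len(list((tmp_path / "a" / "images").glob("*.png"))) == 10
    assert len(list((tmp_path / "a" / "annotations").glob("*.xml"))) == 10
    for f in frames_a:
        assert f.image.shape == (128, 128, 3)
        if len(f.boxes):
            assert f.boxes[:, :2].min() >= 0
            assert f.boxes[:, 2:].max() <= 128


def test_synthetic_annotations_round_trip_from_disk(tmp_path):
    spec = SyntheticSceneSpec(image_size=96, seed=3)
    frames = generate_synthetic_dataset(spec, 3, tmp_path)
    for f in frames:
        loaded = load_frame(tmp_path / "images" / f"{f.source_id}.png",
                            tmp_path / "annotations" / f"{f.source_id}.xml")
        np.testing.assert_array_equal(loaded.image, f.image)
        np.testing.assert_array_equal(loaded.boxes, f.boxes)


def test_synthetic_zero_polyps_yields_empty_valid_annotation(tmp_path):
    spec = SyntheticSceneSpec(image_size=96, n_polyps=(0, 0), seed=1)
    frames = generate_synthetic_dataset(spec, 2, tmp_path)
    for f in frames:
        assert len(f.boxes) == 0
        meta = read_voc_annotation(
            tmp_path / "annotations" / f"{f.source_id}.xml")
        assert len(meta["boxes"]) == 0


def test_synthetic_radius_exceeding_image_rejected():
    spec = SyntheticSceneSpec(image_size=64, polyp_radius=(40, 64), seed=0)
    with pytest.raises(ValueError, match="radius"):
        generate_synthetic_dataset(spec, 1)


def test_boxes_outside_image_rejected_by_frame_invariant():
    img = np.zeros((32, 32, 3), dtype=np.uint8)
    with pytest.raises(ValueError, match="bounds"):
        AnnotatedFrame(img, np.array([[0, 0, 40, 10.0]]), ["polyp"])
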