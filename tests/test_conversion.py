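import json

import numpy as np
import pytest

from fastcat import (
    AnnotationSet,
    BoxAnnotation,
    DSVConfig,
    VideoMeta,
    from_dsv,
    to_coco,
    to_dsv,
    to_voc_xml,
    to_yolo,
)

VIDEO = VideoMeta(path="v", fps=30.0, frame_count=500, width=100, height=100)


def make_set(boxes):
    return AnnotationSet(stage="final", video=VIDEO, boxes=boxes)


def random_boxes(rng, n, width=100, height=100):
    out = []
    for i in range(n):
        w = int(rng.integers(1, width // 2))
        h = int(rng.integers(1, height // 2))
        out.append(
            BoxAnnotation(
                frame=int(rng.integers(0, 500)),
                x=int(rng.integers(0, width - w)),
                y=int(rng.integers(0, height - h)),
                w=w, h=h,
                label=str(rng.choice(["polyp", "paris-Is"])),
                provenance=str(rng.choice(["expert", "ai", "tracker"])),
            )
        )
    return out


class TestDSV:
    def test_one_row_per_box_plus_header(self, tmp_path):
        s = make_set([
            BoxAnnotation(frame=i, x=1, y=2, w=3, h=4, label="polyp",
                          provenance="ai") for i in range(3)
        ])
        path = tmp_path / "b.dsv"
        to_dsv(s, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 4

    def test_empty_set_header_only(self, tmp_path):
        path = tmp_path / "b.dsv"
        to_dsv(make_set([]), path)
        assert len(path.read_text().strip().splitlines()) == 1

    def test_yolo_norm_coordinates(self, tmp_path):
        # box (10,10,20,20) on 100x100 -> cx=cy=0.20, w=h=0.20
        s = make_set([BoxAnnotation(frame=0, x=10, y=10, w=20, h=20,
                                    label="polyp", provenance="expert")])
        cfg = DSVConfig(coordinate_style="yolo_norm")
        path = tmp_path / "b.dsv"
        to_dsv(s, path, cfg)
        row = path.read_text().strip().splitlines()[1].split(",")
        geom = dict(zip(cfg.columns, row))
        assert float(geom["cx"]) == pytest.approx(0.20)
        assert float(geom["cy"]) == pytest.approx(0.20)
        assert float(geom["wn"]) == pytest.approx(0.20)
        assert float(geom["hn"]) == pytest.approx(0.20)

    def test_yolo_without_dimensions_config_error(self, tmp_path):
        s = AnnotationSet(boxes=[BoxAnnotation(frame=0, x=1, y=1, w=2, h=2,
                                               label="p", provenance="ai")])
        with pytest.raises(ValueError, match="dimensions"):
            to_dsv(s, tmp_path / "b.dsv", DSVConfig(coordinate_style="yolo_norm"))

    @pytest.mark.parametrize("style", ["xywh_abs", "xyxy_abs"])
    @pytest.mark.parametrize("delimiter", [",", "\t", ";"])
    def test_absolute_round_trip_exact(self, tmp_path, style, delimiter):
        rng = np.random.default_rng(7)
        s = make_set(random_boxes(rng, 50))
        cfg = DSVConfig(delimiter=delimiter, coordinate_style=style)
        path = tmp_path / "b.dsv"
        to_dsv(s, path, cfg)
        back = from_dsv(path, cfg, video=VIDEO)
        assert [(b.frame, b.x, b.y, b.w, b.h, b.label, b.provenance)
                for b in back.boxes] == [
            (b.frame, b.x, b.y, b.w, b.h, b.label, b.provenance) for b in s.boxes
        ]

    def test_yolo_norm_round_trip_within_one_px(self, tmp_path):
        rng = np.random.default_rng(8)
        video = VideoMeta(path="v", fps=30.0, frame_count=500, width=384, height=288)
        s = AnnotationSet(stage="final", video=video,
                          boxes=random_boxes(rng, 50, 384, 288))
        cfg = DSVConfig(coordinate_style="yolo_norm")
        path = tmp_path / "b.dsv"
        to_dsv(s, path, cfg)
        back = from_dsv(path, cfg, video=video)
        for orig, rt in zip(s.boxes, back.boxes):
            assert abs(orig.x - rt.x) <= 1 and abs(orig.y - rt.y) <= 1
            assert abs(orig.w - rt.w) <= 1 and abs(orig.h - rt.h) <= 1

    def test_provenance_and_label_preserved(self, tmp_path):
        s = make_set([BoxAnnotation(frame=1, x=1, y=1, w=2, h=2,
                                    label="paris-IIa", provenance="duplicated")])
        path = tmp_path / "b.dsv"
        to_dsv(s, path)
        b = from_dsv(path).boxes[0]
        assert (b.label, b.provenance) == ("paris-IIa", "duplicated")

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "b.dsv"
        cfg = DSVConfig()
        path.write_text(
            ",".join(cfg.columns) + "\n"
            + "0,polyp,1,2,3,4,ai,\n"
            + "1,polyp,oops\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            from_dsv(path, cfg)

    def test_config_file_round_trip(self, tmp_path):
        cfg_path = tmp_path / "conv.json"
        cfg_path.write_text(json.dumps(
            {"delimiter": ";", "coordinate_style": "xyxy_abs", "header": False}
        ))
        cfg = DSVConfig.from_file(cfg_path)
        assert cfg.delimiter == ";" and not cfg.header
        assert cfg.columns[:2] == ["frame", "label"]


class TestDetectionFormats:
    def test_yolo_txt_per_frame(self, tmp_path):
        s = make_set([
            BoxAnnotation(frame=0, x=10, y=10, w=20, h=20, label="polyp",
                          provenance="ai"),
            BoxAnnotation(frame=2, x=0, y=0, w=50, h=50, label="polyp",
                          provenance="expert"),
        ])
        cmap = to_yolo(s, tmp_path / "yolo")
        assert cmap == {"polyp": 0}
        line = (tmp_path / "yolo" / "000000.txt").read_text().strip()
        assert line == "0 0.200000 0.200000 0.200000 0.200000"
        assert (tmp_path / "yolo" / "classes.txt").read_text() == "polyp\n"

    def test_voc_xml_boxes(self, tmp_path):
        s = make_set([BoxAnnotation(frame=3, x=10, y=20, w=30, h=40,
                                    label="polyp", provenance="ai")])
        to_voc_xml(s, tmp_path / "voc")
        import xml.etree.ElementTree as ET

        root = ET.parse(tmp_path / "voc" / "000003.xml").getroot()
        bb = root.find("object/bndbox")
        assert [int(bb.find(k).text) for k in ("xmin", "ymin", "xmax", "ymax")] == [
            10, 20, 40, 60
        ]

    def test_coco_counts(self, tmp_path):
        rng = np.random.default_rng(9)
        s = make_set(random_boxes(rng, 10))
        to_coco(s, tmp_path / "coco.json")
        doc = json.loads((tmp_path / "coco.json").read_text())
        assert len(doc["annotations"]) == 10
        assert len(doc["images"]) == len({b.frame for b in s.boxes})
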