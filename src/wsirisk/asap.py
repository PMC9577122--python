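"""ASAP-dialect annotation XML I/O.

Reads Annotations/Annotation/Coordinates/Coordinate polygons, converts
each polygon to a 0-based half-open bounding box (floor of the minimum
corner, ceil of the maximum), and takes the class from PartOfGroup.
"""

from __future__ import annotations

import math
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Sequence

from wsirisk.synthetic import CLASSES, AnnotationRegion

__all__ = ["read_asap_annotations", "write_asap_annotations", "AnnotationParseError"]

_GROUP_COLORS = {
    "punlmp": "#64FE2E",
    "low_grade": "#F4FA58",
    "high_grade": "#FE9A2E",
    "invasive": "#FE2E2E",
}


class AnnotationParseError(ValueError):
    pass


def read_asap_annotations(xml_path) -> list[AnnotationRegion]:
    """Parse an ASAP annotation file into bounding-box regions.

    Annotations whose PartOfGroup is not a known class are skipped with
    a warning; malformed XML raises AnnotationParseError carrying the
    parser's line/column position.
    """
    xml_path = Path(xml_path)
    try:
        tree = ET.parse(xml_path)
    except ET.ParseError as exc:
        raise AnnotationParseError(
            f"{xml_path}: malformed XML at line {exc.position[0]}, "
            f"column {exc.position[1]}: {exc}"
        ) from exc
    regions = []
    for annotation in tree.getroot().iter("Annotation"):
        group = annotation.get("PartOfGroup", "")
        if group not in CLASSES:
            warnings.warn(
                f"{xml_path.name}: skipping annotation in unknown group {group!r}"
            )
            continue
        xs, ys = [], []
        for coord in annotation.iter("Coordinate"):
            try:
                xs.append(float(coord.get("X")))
                ys.append(float(coord.get("Y")))
            except (TypeError, ValueError) as exc:
                raise AnnotationParseError(
                    f"{xml_path}: coordinate missing numeric X/Y"
                ) from exc
        if not xs:
            warnings.warn(f"{xml_path.name}: skipping empty annotation")
            continue
        box = (
            math.floor(min(xs)),
            math.floor(min(ys)),
            math.ceil(max(xs)),
            math.ceil(max(ys)),
        )
        regions.append(AnnotationRegion(box=box, class_label=group))
    return regions


def write_asap_annotations(xml_path, regions: Sequence[AnnotationRegion]) -> None:
    """Write regions as 4-corner polygon annotations in the ASAP dialect."""
    root = ET.Element("ASAP_Annotations")
    annotations = ET.SubElement(root, "Annotations")
    for i, region in enumerate(regions):
        x0, y0, x1, y1 = region.box
        annotation = ET.SubElement(
            annotations,
            "Annotation",
            Name=f"Annotation {i}",
            Type="Polygon",
            PartOfGroup=region.class_label,
            Color=_GROUP_COLORS.get(region.class_label, "#000000"),
        )
        coords = ET.SubElement(annotation, "Coordinates")
        corners = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
        for order, (x, y) in enumerate(corners):
            ET.SubElement(
                coords, "Coordinate", Order=str(order), X=str(x), Y=str(y)
            )
    groups = ET.SubElement(root, "AnnotationGroups")
    for cls in sorted({r.class_label for r in regions}):
        ET.SubElement(
            groups,
            "Group",
            Name=cls,
            PartOfGroup="None",
            Color=_GROUP_COLORS.get(cls, "#000000"),
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(xml_path, encoding="unicode", xml_declaration=True)
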