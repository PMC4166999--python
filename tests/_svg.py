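"""SVG-parsing helpers for tests: recover glyph coordinates independently of
the renderer by walking the XML tree."""

import io
from xml.etree import ElementTree as ET

from betascope.viz import write_svg

SVG_NS = "http://www.w3.org/2000/svg"


def to_text(document) -> str:
    buf = io.StringIO()
    write_svg(document, buf)
    return buf.getvalue()


def parse(document_or_text):
    if isinstance(document_or_text, str):
        return ET.fromstring(document_or_text)
    return ET.fromstring(to_text(document_or_text))


def strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def by_class(root, cls: str):
    return [
        el
        for el in root.iter()
        if cls in (el.get("class") or "").split()
    ]


def circle_centers(root, cls: str = "data-point"):
    return [
        (float(el.get("cx")), float(el.get("cy")))
        for el in by_class(root, cls)
    ]


def polyline_points(el):
    return [
        tuple(float(v) for v in pair.split(","))
        for pair in el.get("points").split()
    ]
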