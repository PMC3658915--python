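"""Network export: XGMML (with read-back) and Pajek .net.

XGMML carries the full metadata of a network as typed ``att`` children
(string/integer/real, inferred from the Python value), which is what lets a
viewer like Cytoscape color a variation network by its ``tna_reason`` tags.
Pajek's .net format stores only the topology: a ``*Vertices`` block with
1-based indices (assigned in lexicographic id order) and an ``*Arcs`` block
of directed edges; metadata is not representable and is dropped (documented
loss).  Both writers emit deterministic, LF-terminated output.
"""

from __future__ import annotations

import os

from lxml import etree

from .errors import FormatError, ValidationError
from .network import METABOLITE, REACTION, MetabolicNetwork

__all__ = ["write_xgmml", "read_xgmml", "write_pajek"]

_XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def _att_type(value) -> tuple[str, str]:
    if isinstance(value, bool):
        return "string", str(value).lower()
    if isinstance(value, int):
        return "integer", str(value)
    if isinstance(value, float):
        return "real", repr(value)
    return "string", str(value)


def _append_atts(parent, metadata: dict) -> None:
    for key in sorted(metadata):
        att_type, text = _att_type(metadata[key])
        etree.SubElement(
            parent, "att", name=key, type=att_type, value=text
        )


def write_xgmml(net: MetabolicNetwork, path: str | os.PathLike) -> None:
    """Write the network as an XGMML document (UTF-8, deterministic order)."""
    root = etree.Element(
        "graph",
        label=net.provenance or "metnet",
        directed="1",
        nsmap={None: _XGMML_NS},
    )
    root.set("representation", net.representation)
    for vid in net.vertices():
        node = etree.SubElement(root, "node", id=vid, label=vid)
        node.set("vtype", net.vertex_type(vid))
        _append_atts(node, net.vertex_metadata(vid))
    for edge in net.edges():
        el = etree.SubElement(root, "edge", source=edge.source, target=edge.target)
        if edge.set_label is not None:
            el.set("set", edge.set_label)
        _append_atts(el, edge.meta)
    tree = etree.ElementTree(root)
    tree.write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _parse_att(el) -> tuple[str, "str | int | float"]:
    name = el.get("name")
    att_type = el.get("type", "string")
    raw = el.get("value", "")
    if att_type == "integer":
        return name, int(raw)
    if att_type == "real":
        return name, float(raw)
    return name, raw


def read_xgmml(path: str | os.PathLike) -> MetabolicNetwork:
    """Read a network written by :func:`write_xgmml` (or structurally equal).

    Raises :class:`ValidationError` when an edge references an undeclared
    node id.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(str(exc)) from None
    root = tree.getroot()
    ns = {"x": _XGMML_NS} if root.tag.startswith("{") else None
    tag = (lambda t: f"x:{t}") if ns else (lambda t: t)
    representation = root.get("representation", "RC")
    net = MetabolicNetwork(representation, provenance=root.get("label", ""))
    for node in root.findall(tag("node"), ns):
        metadata = dict(_parse_att(a) for a in node.findall(tag("att"), ns))
        vtype = node.get("vtype") or metadata.pop("vtype", METABOLITE)
        net.add_vertex(node.get("id"), vtype, metadata)
    for el in root.findall(tag("edge"), ns):
        src, dst = el.get("source"), el.get("target")
        for vid in (src, dst):
            if not net.has_vertex(vid):
                raise ValidationError(
                    f"edge references undeclared node id {vid!r}"
                )
        metadata = dict(_parse_att(a) for a in el.findall(tag("att"), ns))
        net.add_edge(src, dst, el.get("set"), metadata)
    return net


def write_pajek(net: MetabolicNetwork, path: str | os.PathLike) -> None:
    """Write the network topology as a Pajek .net file.

    Vertices get 1-based consecutive indices in lexicographic id order;
    every edge becomes a directed arc ``src dst 1``.  Labels containing
    double quotes are backslash-escaped.  Metadata is not representable in
    this format and is dropped.
    """
    ids = net.vertices()
    index = {vid: i for i, vid in enumerate(ids, start=1)}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"*Vertices {len(ids)}\n")
        for vid in ids:
            label = vid.replace("\\", "\\\\").replace('"', '\\"')
            fh.write(f'{index[vid]} "{label}"\n')
        fh.write("*Arcs\n")
        for edge in net.edges():
            fh.write(f"{index[edge.source]} {index[edge.target]} 1\n")
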