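"""Standard-format persistence: PNML net exchange and config files.

PNML (ISO/IEC 15909-2) is the Petri net interchange format.  We emit a
single-page Place/Transition net that any PNML tool can read; everything
the core grammar cannot express — real-valued markings, rate constants,
inhibitory arcs, transition kinds, role tags — travels in a namespaced
``toolspecific`` block that foreign tools are required to ignore.  The
standard ``initialMarking`` element carries the rounded integer marking
for those tools; our reader prefers the exact real value.

Trajectory/report CSV export lives on the Trajectory and SummaryTable
objects themselves; config files are plain YAML maps of place/transition
ids to token levels or rate constants.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import yaml
from lxml import etree

from .core import Arc, PetriNet, Place, Transition, require_valid
from .errors import ConfigError, PnmlError

__all__ = ["write_pnml", "read_pnml", "load_config"]

log = logging.getLogger(__name__)

PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"
PTNET_TYPE = "http://www.pnml.org/version-2009/grammar/ptnet"
TOOL = "oglcnet"
TOOL_VERSION = "0.1"


def _q(tag: str) -> str:
    return f"{{{PNML_NS}}}{tag}"


def _text_child(parent, tag: str, text: str):
    el = etree.SubElement(parent, _q(tag))
    sub = etree.SubElement(el, _q("text"))
    sub.text = text
    return el


def _toolspecific(parent, **entries: str):
    tool = etree.SubElement(
        parent, _q("toolspecific"), tool=TOOL, version=TOOL_VERSION
    )
    for key, value in entries.items():
        etree.SubElement(tool, _q(key)).text = value
    return tool


def write_pnml(net: PetriNet, destination) -> None:
    """Serialise a validating net to a PNML file or file-like object."""
    require_valid(net)
    root = etree.Element(_q("pnml"), nsmap={None: PNML_NS})
    net_el = etree.SubElement(root, _q("net"), id=net.name or "net", type=PTNET_TYPE)
    _text_child(net_el, "name", net.name)
    page = etree.SubElement(net_el, _q("page"), id="page0")

    for p in net.places:
        el = etree.SubElement(page, _q("place"), id=p.id)
        _text_child(el, "name", p.name)
        _text_child(el, "initialMarking", str(int(round(p.initial_tokens))))
        extras = {"realMarking": repr(p.initial_tokens)}
        if p.role_tag is not None:
            extras["roleTag"] = p.role_tag
        _toolspecific(el, **extras)

    for t in net.transitions:
        el = etree.SubElement(page, _q("transition"), id=t.id)
        _text_child(el, "name", t.name)
        _toolspecific(el, rateConstant=repr(t.rate_constant), kind=t.kind)

    for i, a in enumerate(net.arcs):
        el = etree.SubElement(
            page, _q("arc"), id=f"a{i}", source=a.source, target=a.target
        )
        if a.weight != 1:
            _text_child(el, "inscription", repr(a.weight))
        if a.arc_type != "standard":
            _toolspecific(el, arcType=a.arc_type)

    tree = etree.ElementTree(root)
    if hasattr(destination, "write"):
        destination.write(
            etree.tostring(tree, xml_declaration=True, encoding="UTF-8",
                           pretty_print=True)
        )
    else:
        tree.write(str(destination), xml_declaration=True, encoding="UTF-8",
                   pretty_print=True)


def _tool_entries(el) -> dict[str, str]:
    out = {}
    for tool in el.findall(_q("toolspecific")):
        if tool.get("tool") != TOOL:
            log.warning("ignoring toolspecific block of unknown tool %r",
                        tool.get("tool"))
            continue
        for child in tool:
            tag = etree.QName(child).localname
            out[tag] = (child.text or "").strip()
    return out


def _inner_text(el, tag: str) -> str | None:
    child = el.find(_q(tag))
    if child is None:
        return None
    text_el = child.find(_q("text"))
    return (text_el.text or "").strip() if text_el is not None else (child.text or "").strip()


def read_pnml(source) -> PetriNet:
    """Parse a PNML document into a validating net.

    Foreign ``toolspecific`` blocks are ignored with a logged warning;
    absent rate constants default to 1; malformed XML, dangling arc
    references, non-bipartite arcs and duplicate ids raise
    :class:`PnmlError` naming the offending element.
    """
    try:
        tree = etree.parse(str(source) if isinstance(source, Path) else source)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise PnmlError(f"cannot parse PNML: {exc}") from exc
    root = tree.getroot()
    net_el = root.find(_q("net"))
    if net_el is None:
        raise PnmlError("document has no <net> element")
    name = _inner_text(net_el, "name") or net_el.get("id") or "net"

    places, transitions, arcs = [], [], []
    for el in net_el.iter(_q("place")):
        pid = el.get("id")
        if pid is None:
            raise PnmlError("place without id")
        entries = _tool_entries(el)
        if "realMarking" in entries:
            tokens = float(entries["realMarking"])
        else:
            tokens = float(_inner_text(el, "initialMarking") or 0.0)
        places.append(
            Place(
                id=pid,
                name=_inner_text(el, "name") or pid,
                initial_tokens=tokens,
                role_tag=entries.get("roleTag"),
            )
        )
    for el in net_el.iter(_q("transition")):
        tid = el.get("id")
        if tid is None:
            raise PnmlError("transition without id")
        entries = _tool_entries(el)
        transitions.append(
            Transition(
                id=tid,
                name=_inner_text(el, "name") or tid,
                rate_constant=float(entries.get("rateConstant", 1.0)),
                kind=entries.get("kind", "internal"),
            )
        )
    ids = {p.id for p in places} | {t.id for t in transitions}
    for el in net_el.iter(_q("arc")):
        src, dst = el.get("source"), el.get("target")
        for endpoint in (src, dst):
            if endpoint not in ids:
                raise PnmlError(
                    f"arc {el.get('id')!r} references missing element {endpoint!r}"
                )
        weight = float(_inner_text(el, "inscription") or 1.0)
        arc_type = _tool_entries(el).get("arcType", "standard")
        arcs.append(Arc(source=src, target=dst, weight=weight, arc_type=arc_type))

    net = PetriNet(places=tuple(places), transitions=tuple(transitions),
                   arcs=tuple(arcs), name=name)
    from .core import validate_net

    violations = validate_net(net)
    if violations:
        raise PnmlError(f"PNML net is structurally invalid: {violations[0]}")
    return net


def load_config(source) -> dict:
    """Load a YAML override map of markings, rates and doses.

    Accepts either a flat ``{id: number}`` map or the nested
    ``{places: ..., rates: ..., doses: ...}`` form.  Type errors name the
    offending key; id resolution against a concrete variant happens in
    :func:`oglcnet.models.build_model`, which lists the valid ids.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config must be a mapping, got {type(data).__name__}")
    def check_numbers(mapping, context):
        for key, value in mapping.items():
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(
                    f"value for {context}{key!r} must be a number, "
                    f"got {value!r}"
                )
    nested = set(data) <= {"places", "rates", "doses"}
    if nested:
        for section in data:
            if not isinstance(data[section], dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            check_numbers(data[section], f"{section}.")
        return {k: dict(v) for k, v in data.items()}
    check_numbers(data, "")
    return dict(data)
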