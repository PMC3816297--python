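"""Versioned XML storage for accounts and the per-project registry.

One XML document per workflow execution.  Every save re-checks the
structural rules (structurally invalid graphs are never persisted),
increments the account version and stamps the version date; temporal and
functional violations do not block saving — an experiment whose payloads
have moved is still worth recording — but are written into the document as
``<recorded-violations>`` metadata.

Alongside the account files, a small JSON registry lists the name,
location, version and version date of every execution file saved for a
project, so a project directory is self-describing.

The dialect (see ``docs/account.xsd``)::

    <account id=".." name=".." version=".." version_date=".." ...>
      <project-ref id=".." name=".."/>
      <agents>     <agent id=".." .../>     </agents>
      <activities> <activity id=".." .../>  </activities>
      <entities>   <entity id=".." [size=".."] .../> </entities>
      <relations>  <relation id=".." kind=".." source=".." target=".."
                             auto_derived="..">  </relations>
      <annotations/>
      <recorded-violations/>
    </account>

Collections are serialised as entities carrying a ``size`` attribute
greater than 1.  Node lists, relations, groups and violation records are
emitted in sorted order, so save -> load -> save is byte-identical apart
from the version and version-date stamps.
"""

from __future__ import annotations

import json
import shutil
import subprocess
from dataclasses import asdict, dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional

from lxml import etree

from .errors import ProvenanceError, SchemaError, StructuralError
from .model import (
    Account,
    ActivityFields,
    AgentFields,
    Annotation,
    CollectionFields,
    DerivationType,
    EntityFields,
    Node,
    NodeKind,
    ProvenanceProject,
    RelationEdge,
    RelationKind,
)
from .validation import (
    PayloadResolver,
    Violation,
    check_functional,
    check_structural,
    check_temporal,
)
from .views import ViewOptions, to_dot

__all__ = [
    "RegistryEntry",
    "save_account",
    "load_account",
    "load_registry",
    "save_registry",
    "save_project_meta",
    "load_project_meta",
    "load_project",
    "export_graph_image",
]

REGISTRY_NAME = "registry.json"
PROJECT_META_NAME = "project.json"

_TS = "%Y-%m-%dT%H:%M:%S"


def _fmt_ts(value: Optional[datetime]) -> str:
    return value.isoformat() if value is not None else ""


def _parse_ts(text: Optional[str]) -> Optional[datetime]:
    if not text:
        return None
    try:
        return datetime.fromisoformat(text)
    except ValueError as exc:
        raise SchemaError(f"unparseable timestamp {text!r}: {exc}") from None


@dataclass
class RegistryEntry:
    """One saved execution file of a project."""

    account_name: str
    file_location: str
    version: int
    version_date: str


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def load_registry(path: Path | str) -> list[RegistryEntry]:
    path = Path(path)
    if not path.exists():
        return []
    data = json.loads(path.read_text(encoding="utf-8"))
    return [RegistryEntry(**entry) for entry in data.get("entries", [])]


def save_registry(path: Path | str, entries: list[RegistryEntry]) -> None:
    path = Path(path)
    payload = {"entries": [asdict(e) for e in sorted(entries, key=lambda e: e.file_location)]}
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# project metadata sidecar
# ---------------------------------------------------------------------------


def save_project_meta(
    project: ProvenanceProject,
    directory: Path | str,
    payload_base: Optional[str] = None,
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "id": project.id,
        "name": project.name,
        "description": project.description,
        "funding_institutions": project.funding_institutions,
        "partner_institutions": project.partner_institutions,
        "coordinator": project.coordinator,
        "start_date": _fmt_ts(project.start_date),
        "end_date": _fmt_ts(project.end_date),
    }
    if payload_base is not None:
        meta["payload_base"] = payload_base
    path = directory / PROJECT_META_NAME
    path.write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    return path


def load_project_meta(directory: Path | str) -> ProvenanceProject:
    path = Path(directory) / PROJECT_META_NAME
    if not path.exists():
        raise ProvenanceError(f"no project metadata at {path}")
    meta = json.loads(path.read_text(encoding="utf-8"))
    return ProvenanceProject(
        id=meta["id"],
        name=meta["name"],
        description=meta.get("description", ""),
        funding_institutions=meta.get("funding_institutions", []),
        partner_institutions=meta.get("partner_institutions", []),
        coordinator=meta.get("coordinator", ""),
        start_date=_parse_ts(meta.get("start_date")),
        end_date=_parse_ts(meta.get("end_date")),
    )


def project_payload_base(directory: Path | str) -> Optional[Path]:
    """The project's configured payload directory, if any (resolved)."""
    path = Path(directory) / PROJECT_META_NAME
    if not path.exists():
        return None
    base = json.loads(path.read_text(encoding="utf-8")).get("payload_base")
    if base is None:
        return None
    base = Path(base)
    return base if base.is_absolute() else Path(directory) / base


def load_project(directory: Path | str) -> ProvenanceProject:
    """Project metadata plus every account listed in the registry."""
    directory = Path(directory)
    project = load_project_meta(directory)
    for entry in load_registry(directory / REGISTRY_NAME):
        location = Path(entry.file_location)
        if not location.is_absolute():
            location = directory / location
        project.accounts.append(load_account(location))
    return project


# ---------------------------------------------------------------------------
# account XML
# ---------------------------------------------------------------------------


def _append_annotations(parent: etree._Element, annotations: list[Annotation]) -> None:
    for ann in annotations:
        el = etree.SubElement(parent, "annotation", key=ann.key)
        el.text = ann.text


def _append_groups(parent: etree._Element, groups: set[str]) -> None:
    for group in sorted(groups):
        el = etree.SubElement(parent, "group")
        el.text = group


def _node_element(parent: etree._Element, node: Node) -> None:
    f = node.fields
    if node.kind is NodeKind.AGENT:
        el = etree.SubElement(
            parent,
            "agent",
            id=node.id,
            name=f.name,
            institution=f.institution,
            position=f.position,
            function=f.function,
            notes=f.notes,
        )
    elif node.kind is NodeKind.ACTIVITY:
        el = etree.SubElement(
            parent,
            "activity",
            id=node.id,
            name=f.name,
            program=f.program,
            program_version=f.program_version,
            command_line=f.command_line,
            function=f.function,
            start_time=_fmt_ts(f.start_time),
            end_time=_fmt_ts(f.end_time),
            environment=f.environment,
            notes=f.notes,
        )
    else:
        el = etree.SubElement(
            parent,
            "entity",
            id=node.id,
            name=f.name,
            description=f.description,
            location=f.location,
            notes=f.notes,
        )
        if node.kind is NodeKind.COLLECTION:
            el.set("size", str(f.size))
    _append_groups(el, node.groups)
    _append_annotations(el, node.annotations)


def account_to_xml(account: Account, recorded: list[Violation] = ()) -> bytes:
    """Serialise an account to the XML dialect (deterministic byte output)."""
    root = etree.Element(
        "account",
        id=account.id,
        name=account.name,
        description=account.description,
        location=account.location,
        execution_date=_fmt_ts(account.execution_date),
        version=str(account.version),
        version_date=_fmt_ts(account.version_date),
        start_time=_fmt_ts(account.start_time),
        end_time=_fmt_ts(account.end_time),
        notes=account.notes,
    )
    ref = getattr(account, "project_ref", None)
    if ref is not None:
        etree.SubElement(root, "project-ref", id=ref[0], name=ref[1])

    agents = etree.SubElement(root, "agents")
    activities = etree.SubElement(root, "activities")
    entities = etree.SubElement(root, "entities")
    parent_of = {
        NodeKind.AGENT: agents,
        NodeKind.ACTIVITY: activities,
        NodeKind.ENTITY: entities,
        NodeKind.COLLECTION: entities,
    }
    for nid in sorted(account.nodes):
        node = account.nodes[nid]
        _node_element(parent_of[node.kind], node)

    relations = etree.SubElement(root, "relations")
    for eid in sorted(account.edges):
        e = account.edges[eid]
        el = etree.SubElement(
            relations,
            "relation",
            id=e.id,
            kind=e.kind.value,
            source=e.source,
            target=e.target,
        )
        if e.role is not None:
            el.set("role", e.role)
        if e.derivation_type is not None:
            el.set("derivation_type", e.derivation_type.value)
        el.set("auto_derived", "true" if e.auto_derived else "false")
        _append_annotations(el, e.annotations)

    anns = etree.SubElement(root, "annotations")
    _append_annotations(anns, account.annotations)

    recorded_el = etree.SubElement(root, "recorded-violations")
    for v in recorded:
        vel = etree.SubElement(recorded_el, "violation", axis=v.axis, rule=v.rule)
        vel.set("message", v.message)
        for element in v.elements:
            eel = etree.SubElement(vel, "element")
            eel.text = element

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def save_account(
    project: Optional[ProvenanceProject],
    account: Account,
    path: Path | str,
    resolver: Optional[PayloadResolver] = None,
    registry_path: Optional[Path | str] = None,
    now: Optional[datetime] = None,
) -> RegistryEntry:
    """Persist an account, bump its version, and update the registry.

    Raises :class:`StructuralError` (listing the violations) rather than
    writing a structurally invalid graph.  Temporal violations — and
    functional ones, when a resolver is supplied — are recorded inside the
    document instead of blocking the save.
    """
    structural = check_structural(account)
    if structural:
        raise StructuralError(
            "refusing to persist a structurally invalid account: "
            + "; ".join(v.message for v in structural),
            violations=structural,
        )
    path = Path(path)
    if project is not None:
        account.project_ref = (project.id, project.name)
    account.version += 1
    account.version_date = now if now is not None else datetime.now().replace(microsecond=0)
    recorded = list(check_temporal(account))
    if resolver is not None:
        recorded += check_functional(account, resolver)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(account_to_xml(account, recorded))

    registry_path = Path(registry_path) if registry_path else path.parent / REGISTRY_NAME
    entries = load_registry(registry_path)
    entry = RegistryEntry(
        account_name=account.name,
        file_location=path.name if path.parent == registry_path.parent else str(path),
        version=account.version,
        version_date=_fmt_ts(account.version_date),
    )
    entries = [e for e in entries if e.file_location != entry.file_location] + [entry]
    save_registry(registry_path, entries)
    return entry


def _parse_node(el: etree._Element) -> Node:
    tag = el.tag
    get = el.get
    if tag == "agent":
        kind = NodeKind.AGENT
        fields = AgentFields(
            name=get("name", ""),
            institution=get("institution", ""),
            position=get("position", ""),
            function=get("function", ""),
            notes=get("notes", ""),
        )
    elif tag == "activity":
        kind = NodeKind.ACTIVITY
        fields = ActivityFields(
            name=get("name", ""),
            program=get("program", ""),
            program_version=get("program_version", ""),
            command_line=get("command_line", ""),
            function=get("function", ""),
            start_time=_parse_ts(get("start_time")),
            end_time=_parse_ts(get("end_time")),
            environment=get("environment", ""),
            notes=get("notes", ""),
        )
    elif tag == "entity":
        size = get("size")
        if size is not None:
            kind = NodeKind.COLLECTION
            fields = CollectionFields(
                name=get("name", ""),
                size=int(size),
                description=get("description", ""),
                location=get("location", ""),
                notes=get("notes", ""),
            )
        else:
            kind = NodeKind.ENTITY
            fields = EntityFields(
                name=get("name", ""),
                description=get("description", ""),
                location=get("location", ""),
                notes=get("notes", ""),
            )
    else:
        raise SchemaError(f"unknown node element <{tag}>")
    node = Node(id=get("id", ""), kind=kind, fields=fields)
    if not node.id:
        raise SchemaError(f"<{tag}> element without an id attribute")
    for child in el:
        if child.tag == "group":
            node.groups.add(child.text or "")
        elif child.tag == "annotation":
            node.annotations.append(Annotation(child.get("key", ""), child.text or ""))
        else:
            raise SchemaError(f"unknown child <{child.tag}> of <{tag}>")
    return node


def load_account(path: Path | str) -> Account:
    """Reconstruct an account from its XML document.

    Round-trips losslessly with :func:`save_account`.  The graph is loaded
    without re-running creation-time checks, so documents edited or
    corrupted outside this library load successfully and their faults are
    reported by the validation checkers instead.
    """
    path = Path(path)
    tree = etree.parse(str(path))  # XMLSyntaxError carries line info
    root = tree.getroot()
    if root.tag != "account":
        raise SchemaError(f"expected <account> document, found <{root.tag}>")
    get = root.get
    account = Account(id=get("id") or "", name=get("name", ""))
    account.description = get("description", "")
    account.location = get("location", "")
    account.execution_date = _parse_ts(get("execution_date"))
    account.version = int(get("version", "1"))
    account.version_date = _parse_ts(get("version_date"))
    # bypass the creation-time window check: corrupt windows load and are
    # then reported by check_temporal
    account.start_time = _parse_ts(get("start_time"))
    account.end_time = _parse_ts(get("end_time"))
    account.notes = get("notes", "")

    for section in root:
        if section.tag == "project-ref":
            account.project_ref = (section.get("id", ""), section.get("name", ""))
        elif section.tag in ("agents", "activities", "entities"):
            for el in section:
                node = _parse_node(el)
                account.nodes[node.id] = node
        elif section.tag == "relations":
            for el in section:
                if el.tag != "relation":
                    raise SchemaError(f"unknown child <{el.tag}> of <relations>")
                kind_text = el.get("kind", "")
                try:
                    kind = RelationKind(kind_text)
                except ValueError:
                    raise SchemaError(
                        f"unknown relation kind {kind_text!r}"
                    ) from None
                dtype_text = el.get("derivation_type")
                edge = RelationEdge(
                    id=el.get("id", ""),
                    kind=kind,
                    source=el.get("source", ""),
                    target=el.get("target", ""),
                    role=el.get("role"),
                    derivation_type=DerivationType(dtype_text) if dtype_text else None,
                    auto_derived=el.get("auto_derived") == "true",
                )
                for child in el:
                    if child.tag != "annotation":
                        raise SchemaError(
                            f"unknown child <{child.tag}> of <relation>"
                        )
                    edge.annotations.append(
                        Annotation(child.get("key", ""), child.text or "")
                    )
                account.edges[edge.id] = edge
        elif section.tag == "annotations":
            for child in section:
                account.annotations.append(
                    Annotation(child.get("key", ""), child.text or "")
                )
        elif section.tag == "recorded-violations":
            pass  # informational snapshot; validity is always recomputed
        else:
            raise SchemaError(f"unknown section <{section.tag}> in <account>")
    return account


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def export_graph_image(
    account: Account,
    path: Path | str,
    options: Optional[ViewOptions] = None,
    fmt: Optional[str] = None,
) -> Path:
    """Render the account's DOT through Graphviz into an image file.

    The format defaults to the output suffix (gif, png or svg).  DOT
    emission itself never needs the renderer — use
    :func:`provgraph.views.to_dot` for that.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower() or "gif"
    dot = shutil.which("dot")
    if dot is None:
        raise ProvenanceError(
            "Graphviz 'dot' renderer not found on PATH; install graphviz or "
            "export DOT text with provgraph.views.to_dot instead"
        )
    dot_text = to_dot(account, options)
    path.parent.mkdir(parents=True, exist_ok=True)
    subprocess.run(
        [dot, f"-T{fmt}", "-o", str(path)],
        input=dot_text.encode("utf-8"),
        check=True,
    )
    return path
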