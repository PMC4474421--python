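"""Reading and writing curated signed-interaction tables.

Curated molecular-interaction databases export edge lists in two common
dialects:

* a headered TSV with columns ``source  effect  target  [provenance]``,
  where *effect* is a keyword such as ``activation`` or ``inhibition``;
* the Cytoscape SIF format, headerless ``source  relation  target...``
  lines (one source may list several targets).

Every entity appearing in an edge file must be annotated with a role —
``compound``, ``regulator`` or ``enzyme`` — in a companion roles TSV
(header ``id  name  role``).  Effects map to integer signs: +1 for
activation, -1 for inhibition, 0 for an interaction with no stated
direction.  Unknown effect keywords are hard parse errors rather than
silent sign-0 coercions, because a silently wrong sign would corrupt
sign composition downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from .errors import ArgumentError, ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .network import SignedNetwork

ROLES = ("compound", "regulator", "enzyme")

#: Case-insensitive effect keyword -> sign mapping.
EFFECT_KEYWORDS = {
    "activation": +1,
    "activates": +1,
    "up": +1,
    "inhibition": -1,
    "inhibits": -1,
    "down": -1,
    "unknown": 0,
    "unspecified": 0,
}

#: Canonical keyword written for each sign.
SIGN_TO_KEYWORD = {+1: "activates", -1: "inhibits", 0: "unknown"}

VALID_SIGNS = frozenset({+1, -1, 0})


@dataclass(frozen=True)
class Entity:
    """A network node: a compound, a CYP regulator, or a CYP enzyme."""

    id: str
    name: str
    role: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("entity id must be non-empty")
        if self.role not in ROLES:
            raise ValidationError(
                f"entity {self.id!r}: role must be one of {ROLES}, got {self.role!r}"
            )


@dataclass(frozen=True)
class InteractionRecord:
    """One curated signed edge.

    ``multiplicity`` counts how many identical input rows collapsed into
    this record; degree computations downstream count distinct edges, not
    multiplicity.
    """

    source_id: str
    target_id: str
    sign: int
    provenance: str = ""
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.source_id == self.target_id:
            raise ValidationError(
                f"self-loop {self.source_id!r} -> {self.target_id!r} is not allowed"
            )
        if self.sign not in VALID_SIGNS:
            raise ValidationError(
                f"edge {self.source_id!r}->{self.target_id!r}: sign must be "
                f"+1, -1 or 0, got {self.sign!r}"
            )


@dataclass
class InteractionTable:
    """A validated collection of entities and deduplicated signed edges."""

    entities: dict[str, Entity] = field(default_factory=dict)
    records: list[InteractionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for rec in self.records:
            for eid in (rec.source_id, rec.target_id):
                if eid not in self.entities:
                    raise ValidationError(
                        f"record references unknown entity {eid!r}"
                    )
            key = (rec.source_id, rec.target_id, rec.sign)
            if key in seen:
                raise ValidationError(f"duplicate record {key} after collapse")
            seen.add(key)

    def role(self, entity_id: str) -> str:
        return self.entities[entity_id].role

    @property
    def n_records(self) -> int:
        return len(self.records)


def _map_effect(keyword: str, line_number: int) -> int:
    try:
        return EFFECT_KEYWORDS[keyword.strip().lower()]
    except KeyError:
        raise ParseError(
            f"unmappable effect keyword {keyword!r} "
            f"(expected one of {sorted(EFFECT_KEYWORDS)})",
            line_number=line_number,
        ) from None


def read_roles(path: str | Path) -> dict[str, Entity]:
    """Read a roles TSV (header ``id  name  role``) into an entity map."""
    path = Path(path)
    entities: dict[str, Entity] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty roles file (expected header)") from None
        if [h.strip().lower() for h in header[:3]] != ["id", "name", "role"]:
            raise ParseError(
                f"{path}: roles header must be 'id\\tname\\trole', got {header!r}",
                line_number=1,
            )
        for i, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ParseError(
                    f"{path}: expected 3 columns, got {len(row)}", line_number=i
                )
            eid, name, role = row[0].strip(), row[1].strip(), row[2].strip().lower()
            if eid in entities:
                raise ValidationError(f"{path}: duplicate entity id {eid!r}")
            entities[eid] = Entity(id=eid, name=name or eid, role=role)
    return entities


def _iter_tsv_edges(path: Path) -> Iterable[tuple[int, str, str, int, str]]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty edge file (expected header)") from None
        cols = [h.strip().lower() for h in header]
        if cols[:3] != ["source", "effect", "target"]:
            raise ParseError(
                f"{path}: edge header must start 'source\\teffect\\ttarget', "
                f"got {header!r}",
                line_number=1,
            )
        for i, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ParseError(
                    f"{path}: expected >=3 columns, got {len(row)}", line_number=i
                )
            source, effect, target = (c.strip() for c in row[:3])
            provenance = row[3].strip() if len(row) > 3 else ""
            yield i, source, target, _map_effect(effect, i), provenance


def _iter_sif_edges(path: Path) -> Iterable[tuple[int, str, str, int, str]]:
    # SIF: headerless, `source<TAB>relation<TAB>target1[<TAB>target2 ...]`
    with path.open(newline="", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: SIF line needs source, relation and >=1 target",
                    line_number=i,
                )
            source = parts[0].strip()
            sign = _map_effect(parts[1], i)
            for target in parts[2:]:
                yield i, source, target.strip(), sign, ""


def read_interactions(
    path: str | Path,
    dialect: str = "tsv",
    roles_path: str | Path | None = None,
    entities: dict[str, Entity] | None = None,
) -> InteractionTable:
    """Read an edge file plus role annotations into an ``InteractionTable``.

    Parameters
    ----------
    path:
        Edge file in the chosen dialect.
    dialect:
        ``"tsv"`` (headered) or ``"sif"`` (Cytoscape simple interaction
        format, headerless).
    roles_path:
        Roles TSV mapping every entity id in the edge file to a role.
        Alternatively pass a pre-built ``entities`` map.

    Exact duplicate rows (same source, target and sign) collapse into one
    record whose ``multiplicity`` counts the input rows.  Rows for the same
    ordered pair with *different* signs are retained as separate records;
    resolving the conflict is deferred to network construction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge file not found: {path}")
    if dialect not in ("tsv", "sif"):
        raise ArgumentError(f"unsupported dialect {dialect!r} (use 'tsv' or 'sif')")
    if entities is None:
        if roles_path is None:
            raise ArgumentError("either roles_path or entities must be given")
        entities = read_roles(roles_path)

    iterator = _iter_tsv_edges(path) if dialect == "tsv" else _iter_sif_edges(path)

    order: list[tuple[str, str, int]] = []
    collected: dict[tuple[str, str, int], InteractionRecord] = {}
    missing: set[str] = set()
    for line_no, source, target, sign, prov in iterator:
        if source == target:
            raise ValidationError(
                f"{path}: line {line_no}: self-loop on {source!r} is not allowed"
            )
        for eid in (source, target):
            if eid not in entities:
                missing.add(eid)
        key = (source, target, sign)
        if key in collected:
            old = collected[key]
            collected[key] = replace(
                old,
                multiplicity=old.multiplicity + 1,
                provenance=old.provenance or prov,
            )
        else:
            order.append(key)
            collected[key] = InteractionRecord(
                source_id=source, target_id=target, sign=sign, provenance=prov
            )
    if missing:
        raise ValidationError(
            "entities without role annotation: " + ", ".join(sorted(missing))
        )

    used = {eid for k in order for eid in k[:2]}
    table_entities = {eid: ent for eid, ent in entities.items() if eid in used}
    return InteractionTable(
        entities=table_entities, records=[collected[k] for k in order]
    )


def write_roles(entities: Iterable[Entity], path: str | Path) -> None:
    """Write a roles TSV (header ``id  name  role``)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write("id\tname\trole\n")
        for ent in sorted(entities, key=lambda e: e.id):
            fh.write(f"{ent.id}\t{ent.name}\t{ent.role}\n")


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    """Write an ``InteractionTable`` in the headered TSV edge dialect."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write("source\teffect\ttarget\tprovenance\n")
        for rec in table.records:
            fh.write(
                f"{rec.source_id}\t{SIGN_TO_KEYWORD[rec.sign]}\t"
                f"{rec.target_id}\t{rec.provenance}\n"
            )


def write_network(net: "SignedNetwork", path: str | Path, dialect: str = "sif") -> None:
    """Write a signed network as SIF or headered TSV.

    SIF writes one ``source<TAB>relation<TAB>target`` line per edge with
    relation in {activates, inhibits, unknown}; reading the file back
    reproduces the edge set and signs exactly.
    """
    if dialect not in ("tsv", "sif"):
        raise ArgumentError(f"unsupported dialect {dialect!r} (use 'tsv' or 'sif')")
    path = Path(path)
    edges = sorted(net.edges())
    with path.open("w", newline="", encoding="utf-8") as fh:
        if dialect == "tsv":
            fh.write("source\teffect\ttarget\n")
        for source, target, sign in edges:
            fh.write(f"{source}\t{SIGN_TO_KEYWORD[sign]}\t{target}\n")
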