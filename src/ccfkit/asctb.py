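"""ASCT+B-style tables and ontology crosswalks.

An ASCT+B table records, per row, one anatomical-structure *partonomy
path* (body > organ > ... > most specific structure), the cell types
located in that structure, and the biomarkers that characterize those cell
types, typed as one of five categories: genes, proteins, metabolites,
proteoforms and lipids.

The CSV dialect here is deliberately flat: column families ``AS/1``,
``AS/1/ID``, ``AS/2``, ... for the path, ``CT/n`` (+ ``/ID``) for cell
types and ``BG/BP/BM/BF/BL`` families for the five biomarker categories,
one fully-specified row per combination. Terms without an ontology id get
a deterministic temporary id ``ASCTB-TEMP:<slug>``.

Crosswalks map tool-assigned labels to ontology terms with a skos-style
confidence (``exactMatch`` or ``narrowMatch``).
"""

from __future__ import annotations

import io
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import (
    DuplicateIdError,
    PartonomyCycleError,
    TableFormatError,
    UnknownStructureError,
)

__all__ = [
    "BIOMARKER_CATEGORIES",
    "AsctbRow",
    "AsctbTable",
    "Crosswalk",
    "Finding",
    "Term",
    "ValidationReport",
    "apply_crosswalk",
    "asctb_temp_id",
    "cells_in_structure",
    "normalize_curie",
    "parse_asctb_table",
    "parse_crosswalk",
    "partonomy_closure",
    "serialize_asctb_table",
    "validate_table",
]

# The five biomarker categories and their column-family codes.
BIOMARKER_CATEGORIES = ("gene", "protein", "metabolite", "proteoform", "lipid")
_CATEGORY_TO_CODE = {"gene": "BG", "protein": "BP", "metabolite": "BM", "proteoform": "BF", "lipid": "BL"}
_CODE_TO_CATEGORY = {v: k for k, v in _CATEGORY_TO_CODE.items()}

_CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9.]*:\S+$")
_UNDERSCORE_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9.]*)_(\S+)$")
_COLUMN_RE = re.compile(r"^(AS|CT|BG|BP|BM|BF|BL)/(\d+)(/ID)?$")


@dataclass(frozen=True)
class Term:
    label: str
    id: str


@dataclass(frozen=True)
class BiomarkerTerm:
    label: str
    id: str
    category: str


@dataclass
class AsctbRow:
    as_path: list[Term]
    cell_types: list[Term] = field(default_factory=list)
    biomarkers: list[BiomarkerTerm] = field(default_factory=list)


@dataclass
class AsctbTable:
    rows: list[AsctbRow]

    def anatomical_structures(self) -> dict[str, str]:
        """Map as_id -> label over every path entry, first occurrence wins."""
        out: dict[str, str] = {}
        for row in self.rows:
            for term in row.as_path:
                out.setdefault(term.id, term.label)
        return out

    def cell_types(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for row in self.rows:
            for term in row.cell_types:
                out.setdefault(term.id, term.label)
        return out

    def biomarkers(self) -> dict[str, BiomarkerTerm]:
        out: dict[str, BiomarkerTerm] = {}
        for row in self.rows:
            for term in row.biomarkers:
                out.setdefault(term.id, term)
        return out


def _slug(label: str) -> str:
    slug = re.sub(r"[^a-z0-9]+", "-", label.casefold()).strip("-")
    return slug or "term"


def asctb_temp_id(label: str) -> str:
    """Deterministic temporary ontology id for an unmapped term."""
    return f"ASCTB-TEMP:{_slug(label)}"


class _TempIdAssigner:
    """Assigns ASCTB-TEMP ids, disambiguating slug collisions within a table."""

    def __init__(self):
        self._by_label: dict[str, str] = {}
        self._used: set[str] = set()

    def __call__(self, label: str) -> str:
        key = " ".join(label.split()).casefold()
        if key in self._by_label:
            return self._by_label[key]
        base = asctb_temp_id(label)
        candidate, i = base, 2
        while candidate in self._used:
            candidate = f"{base}-{i}"
            i += 1
        self._by_label[key] = candidate
        self._used.add(candidate)
        return candidate


def normalize_curie(curie: str) -> tuple[str, bool]:
    """Canonicalize a CURIE to ``PREFIX:LOCALID`` colon form.

    Accepts the underscore dialect (``CL_0000540``) and returns
    ``(canonical, changed)``.
    """
    curie = curie.strip()
    if _CURIE_RE.match(curie):
        return curie, False
    m = _UNDERSCORE_CURIE_RE.match(curie)
    if m:
        return f"{m.group(1)}:{m.group(2)}", True
    return curie, False


def _family_columns(columns, family: str):
    """Ordered (label_col, id_col_or_None) pairs for one column family."""
    slots: dict[int, dict[str, str]] = {}
    for col in columns:
        m = _COLUMN_RE.match(str(col).strip())
        if m and m.group(1) == family:
            slot = slots.setdefault(int(m.group(2)), {})
            slots[int(m.group(2))]["id" if m.group(3) else "label"] = col
    return [
        (slots[i].get("label"), slots[i].get("id"))
        for i in sorted(slots)
        if slots[i].get("label") is not None
    ]


def parse_asctb_table(source) -> AsctbTable:
    """Parse the flat ASCT+B CSV dialect into an :class:`AsctbTable`.

    ``source`` may be CSV text, a path, or a DataFrame. Requires at least
    the ``AS/n`` and ``CT/n`` column families in the header; biomarker
    families are optional. Terms with an empty id column receive a
    deterministic ``ASCTB-TEMP:<slug>`` id, collision-checked per table.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".csv")):
        df = pd.read_csv(source, dtype=str).fillna("")
    else:
        df = pd.read_csv(io.StringIO(str(source)), dtype=str).fillna("")
    df = df.fillna("")

    as_cols = _family_columns(df.columns, "AS")
    ct_cols = _family_columns(df.columns, "CT")
    if not as_cols:
        raise TableFormatError("header must contain an AS/n column family")
    if not ct_cols:
        raise TableFormatError("header must contain a CT/n column family")
    bio_cols = {
        code: _family_columns(df.columns, code) for code in _CODE_TO_CATEGORY
    }

    temp_id = _TempIdAssigner()

    def term(label: str, raw_id: str) -> Term | None:
        label = " ".join(str(label).split())
        raw_id = str(raw_id).strip()
        if not label and not raw_id:
            return None
        if not raw_id:
            raw_id = temp_id(label)
        return Term(label=label, id=raw_id)

    rows: list[AsctbRow] = []
    for _, rec in df.iterrows():
        as_path = [
            t for lab, idc in as_cols
            if (t := term(rec[lab], rec[idc] if idc else "")) is not None
        ]
        if not as_path:
            continue
        cts = [
            t for lab, idc in ct_cols
            if (t := term(rec[lab], rec[idc] if idc else "")) is not None
        ]
        bios: list[BiomarkerTerm] = []
        for code, cols in bio_cols.items():
            for lab, idc in cols:
                t = term(rec[lab], rec[idc] if idc else "")
                if t is not None:
                    bios.append(BiomarkerTerm(t.label, t.id, _CODE_TO_CATEGORY[code]))
        rows.append(AsctbRow(as_path=as_path, cell_types=cts, biomarkers=bios))
    return AsctbTable(rows=rows)


def serialize_asctb_table(table: AsctbTable) -> str:
    """Serialize to the flat CSV dialect; ``parse(serialize(t))`` is a fixpoint."""
    n_as = max((len(r.as_path) for r in table.rows), default=1)
    n_ct = max((len(r.cell_types) for r in table.rows), default=1)
    n_bio = {
        code: max(
            (sum(1 for b in r.biomarkers if b.category == cat) for r in table.rows),
            default=0,
        )
        for code, cat in _CODE_TO_CATEGORY.items()
    }
    columns: list[str] = []
    for i in range(1, n_as + 1):
        columns += [f"AS/{i}", f"AS/{i}/ID"]
    for i in range(1, max(n_ct, 1) + 1):
        columns += [f"CT/{i}", f"CT/{i}/ID"]
    for code in _CODE_TO_CATEGORY:
        for i in range(1, n_bio[code] + 1):
            columns += [f"{code}/{i}", f"{code}/{i}/ID"]

    records = []
    for row in table.rows:
        rec = dict.fromkeys(columns, "")
        for i, t in enumerate(row.as_path, 1):
            rec[f"AS/{i}"], rec[f"AS/{i}/ID"] = t.label, t.id
        for i, t in enumerate(row.cell_types, 1):
            rec[f"CT/{i}"], rec[f"CT/{i}/ID"] = t.label, t.id
        slot = Counter()
        for b in row.biomarkers:
            code = _CATEGORY_TO_CODE[b.category]
            slot[code] += 1
            rec[f"{code}/{slot[code]}"], rec[f"{code}/{slot[code]}/ID"] = b.label, b.id
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=columns).to_csv(index=False)


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning" | "info"
    row: int | None
    message: str


@dataclass
class ValidationReport:
    n_rows: int
    n_anatomical_structures: int
    n_cell_types: int
    n_biomarkers_per_category: dict[str, int]
    n_asctb_temp_ids: int
    n_malformed_ids: int
    findings: list[Finding]

    @property
    def n_errors(self) -> int:
        return sum(1 for f in self.findings if f.severity == "error")

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": {
                    "rows": self.n_rows,
                    "anatomical_structures": self.n_anatomical_structures,
                    "cell_types": self.n_cell_types,
                    "biomarkers_per_category": self.n_biomarkers_per_category,
                    "asctb_temp_ids": self.n_asctb_temp_ids,
                    "malformed_ids": self.n_malformed_ids,
                },
                "findings": [
                    {"severity": f.severity, "row": f.row, "message": f.message}
                    for f in self.findings
                ],
            },
            indent=2,
            sort_keys=True,
        )

    def __str__(self) -> str:
        lines = [
            f"rows: {self.n_rows}",
            f"anatomical structures: {self.n_anatomical_structures}",
            f"cell types: {self.n_cell_types}",
        ]
        for cat in BIOMARKER_CATEGORIES:
            lines.append(f"{cat} biomarkers: {self.n_biomarkers_per_category.get(cat, 0)}")
        lines.append(f"ASCTB-TEMP ids: {self.n_asctb_temp_ids}")
        lines.append(f"malformed ids: {self.n_malformed_ids}")
        for f in self.findings:
            loc = f"row {f.row}" if f.row is not None else "table"
            lines.append(f"[{f.severity}] {loc}: {f.message}")
        return "\n".join(lines)


def validate_table(table: AsctbTable) -> ValidationReport:
    """Structural validation: id syntax, biomarker categories, duplicates.

    Returns findings rather than raising; never mutates the table.
    Underscore-dialect CURIEs (``CL_0000540``) yield an info finding with
    the colon-form normalization.
    """
    findings: list[Finding] = []
    temp_ids: set[str] = set()
    malformed: set[str] = set()

    def check_id(term_id: str, row_idx: int, what: str):
        if term_id.startswith("ASCTB-TEMP:"):
            temp_ids.add(term_id)
            return
        canonical, changed = normalize_curie(term_id)
        if changed:
            findings.append(
                Finding("info", row_idx, f"{what} id {term_id!r} normalized to {canonical!r}")
            )
        elif not _CURIE_RE.match(term_id):
            malformed.add(term_id)
            findings.append(
                Finding("error", row_idx, f"{what} id {term_id!r} is not a valid CURIE")
            )

    seen_rows: dict[tuple, int] = {}
    for idx, row in enumerate(table.rows):
        for t in row.as_path:
            check_id(t.id, idx, "anatomical structure")
        for t in row.cell_types:
            check_id(t.id, idx, "cell type")
        for b in row.biomarkers:
            check_id(b.id, idx, "biomarker")
            if b.category not in BIOMARKER_CATEGORIES:
                findings.append(
                    Finding(
                        "error",
                        idx,
                        f"biomarker category {b.category!r} not one of {BIOMARKER_CATEGORIES}",
                    )
                )
        key = (
            tuple((t.label, t.id) for t in row.as_path),
            tuple((t.label, t.id) for t in row.cell_types),
            tuple((b.label, b.id, b.category) for b in row.biomarkers),
        )
        if key in seen_rows:
            findings.append(
                Finding("warning", idx, f"duplicate of row {seen_rows[key]}")
            )
        else:
            seen_rows[key] = idx

    per_cat = {cat: 0 for cat in BIOMARKER_CATEGORIES}
    for b in table.biomarkers().values():
        if b.category in per_cat:
            per_cat[b.category] += 1
    return ValidationReport(
        n_rows=len(table.rows),
        n_anatomical_structures=len(table.anatomical_structures()),
        n_cell_types=len(table.cell_types()),
        n_biomarkers_per_category=per_cat,
        n_asctb_temp_ids=len(temp_ids),
        n_malformed_ids=len(malformed),
        findings=findings,
    )


def _partonomy_graph(table: AsctbTable) -> nx.DiGraph:
    g = nx.DiGraph()
    for row in table.rows:
        ids = [t.id for t in row.as_path]
        g.add_nodes_from(ids)
        for parent, child in zip(ids, ids[1:]):
            if parent != child:
                g.add_edge(parent, child)
    return g


def partonomy_closure(table: AsctbTable) -> set[tuple[str, str]]:
    """Transitive closure of the part_of hierarchy as (ancestor, descendant) pairs."""
    g = _partonomy_graph(table)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        nodes = [e[0] for e in cycle] + [cycle[-1][1]]
        raise PartonomyCycleError(nodes)
    closure = set()
    for node in g.nodes:
        for desc in nx.descendants(g, node):
            closure.add((node, desc))
    return closure


def cells_in_structure(
    table: AsctbTable, as_id: str, include_descendants: bool = False
) -> set[str]:
    """Cell types located in a structure (a row's cell types are located in
    the most specific structure of its path), optionally unioned over all
    partonomy descendants."""
    known = set(table.anatomical_structures())
    if as_id not in known:
        raise UnknownStructureError(f"anatomical structure {as_id!r} not in table")
    targets = {as_id}
    if include_descendants:
        targets |= {d for a, d in partonomy_closure(table) if a == as_id}
    out: set[str] = set()
    for row in table.rows:
        if row.as_path and row.as_path[-1].id in targets:
            out |= {t.id for t in row.cell_types}
    return out


@dataclass(frozen=True)
class CrosswalkEntry:
    source_label: str
    target_id: str
    target_label: str
    match: str  # "exactMatch" | "narrowMatch"


@dataclass
class Crosswalk:
    entries: list[CrosswalkEntry]

    def __post_init__(self):
        keys = [_normalize_label(e.source_label) for e in self.entries]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise DuplicateIdError(f"duplicate source labels in crosswalk: {sorted(dupes)}")
        self._index = dict(zip(keys, self.entries))

    def lookup(self, label: str) -> CrosswalkEntry | None:
        return self._index.get(_normalize_label(label))


def _normalize_label(label: str) -> str:
    return " ".join(str(label).split()).casefold()


def parse_crosswalk(source) -> Crosswalk:
    """Read a crosswalk CSV (source_label, target_id, target_label, match)."""
    if isinstance(source, pd.DataFrame):
        df = source
    elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        df = pd.read_csv(source, dtype=str).fillna("")
    else:
        df = pd.read_csv(io.StringIO(str(source)), dtype=str).fillna("")
    required = {"source_label", "target_id", "target_label", "match"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"crosswalk CSV missing columns: {sorted(missing)}")
    entries = [
        CrosswalkEntry(
            source_label=r["source_label"],
            target_id=normalize_curie(r["target_id"])[0],
            target_label=r["target_label"],
            match=r["match"],
        )
        for _, r in df.iterrows()
    ]
    return Crosswalk(entries=entries)


def apply_crosswalk(
    labels: list[str], crosswalk: Crosswalk
) -> list[tuple[str, str, str]]:
    """Map tool-assigned labels to ontology terms.

    Matching is exact after case-folding and whitespace collapse. Unmapped
    labels receive an ``ASCTB-TEMP:<slug>`` id and the match ``"unmapped"``.
    Returns (label, target_id, match) triples in input order.
    """
    out = []
    for label in labels:
        entry = crosswalk.lookup(label)
        if entry is None:
            out.append((label, asctb_temp_id(label), "unmapped"))
        else:
            out.append((label, entry.target_id, entry.match))
    return out
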