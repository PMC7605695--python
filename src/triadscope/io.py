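"""Readers and writers for rosters, ordinal contact matrices and binary networks.

On-disk conventions
-------------------
* Roster CSV: columns ``id, gender, age, classroom, setting, audit_1..audit_10``.
* Matrix CSV: first row and first column are actor ids, body is integer.
* UCINET DL: the ``format=fullmatrix`` and ``format=edgelist1`` variants with
  an optional ``labels:`` section; all other DL variants are rejected.
* Edge list CSV: ``source,target`` (optional ``weight``) with a header row.

Ids are matched case-sensitively after whitespace trimming.  Roster readers
key records by id, so reader output is invariant to row order; matrix readers
preserve the file's declared actor order exactly.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ShapeError, UsageError, ValidationError
from .model import (
    MISSING,
    Actor,
    AuditResponse,
    BinaryNetwork,
    ContactMatrix,
    normalize_gender,
    validate_age,
)

ROSTER_COLUMNS = ["id", "gender", "age", "classroom", "setting"] + [
    f"audit_{k}" for k in range(1, 11)
]


# ---------------------------------------------------------------------------
# roster
# ---------------------------------------------------------------------------

def read_roster(
    path: str | Path,
    age_window: tuple[int, int] = (10, 25),
) -> tuple[list[Actor], list[AuditResponse]]:
    """Read a roster CSV into validated actors and AUDIT responses.

    Raises :class:`SchemaError` naming any missing column, and
    :class:`ValidationError` naming the actor and item for out-of-range
    values.  Duplicate ids are rejected.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"roster {path}: missing required column(s) {missing}")

    actors: list[Actor] = []
    audits: list[AuditResponse] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        actor_id = str(row["id"]).strip()
        if actor_id in seen:
            raise ValidationError(f"roster {path}: duplicate actor id {actor_id!r}")
        seen.add(actor_id)
        actor = Actor(
            id=actor_id,
            gender=normalize_gender(row["gender"]),
            age=validate_age(row["age"], actor_id, age_window),
            classroom=str(row["classroom"]).strip(),
            setting=str(row["setting"]).strip().lower(),
        )
        items = tuple(int(row[f"audit_{k}"]) for k in range(1, 11))
        actors.append(actor)
        audits.append(AuditResponse(actor_id=actor_id, items=items))

    by_class: dict[str, str] = {}
    for a in actors:
        if by_class.setdefault(a.classroom, a.setting) != a.setting:
            raise ValidationError(
                f"roster {path}: classroom {a.classroom!r} mixes rural and urban actors"
            )
    return actors, audits


def write_roster(
    actors: Sequence[Actor],
    audits: Sequence[AuditResponse],
    path: str | Path,
) -> None:
    by_id = {r.actor_id: r for r in audits}
    rows = []
    for a in actors:
        row = {
            "id": a.id, "gender": a.gender, "age": a.age,
            "classroom": a.classroom, "setting": a.setting,
        }
        row.update({f"audit_{k}": v for k, v in enumerate(by_id[a.id].items, start=1)})
        rows.append(row)
    pd.DataFrame(rows, columns=ROSTER_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# matrix CSV helpers
# ---------------------------------------------------------------------------

def _read_labelled_matrix_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    labels = [str(x).strip() for x in df.index]
    col_labels = [str(x).strip() for x in df.columns]
    if labels != col_labels:
        raise ShapeError(f"matrix {path}: row labels differ from column labels")
    values = df.to_numpy()
    if values.shape[0] != values.shape[1]:
        raise ShapeError(f"matrix {path}: not square ({values.shape})")
    return labels, values.astype(int)


def _write_labelled_matrix_csv(
    labels: Sequence[str], values: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(path)


# ---------------------------------------------------------------------------
# UCINET DL dialect (fullmatrix and edgelist1 only)
# ---------------------------------------------------------------------------

_DL_HEADER = re.compile(r"^dl\b", re.IGNORECASE)


def _parse_dl(text: str) -> tuple[list[str], np.ndarray]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not _DL_HEADER.match(lines[0]):
        raise SchemaError("DL file must start with a 'dl' header line")
    header = lines[0].lower().replace(",", " ")
    n_match = re.search(r"n\s*=\s*(\d+)", header)
    if not n_match:
        raise SchemaError("DL header missing n=<count>")
    n = int(n_match.group(1))
    fmt_match = re.search(r"format\s*=\s*(\S+)", header)
    fmt = fmt_match.group(1) if fmt_match else "fullmatrix"
    if fmt not in ("fullmatrix", "edgelist1"):
        raise SchemaError(
            f"unsupported DL format {fmt!r}: only 'fullmatrix' and 'edgelist1' are supported"
        )

    labels = [str(k) for k in range(1, n + 1)]
    body = lines[1:]
    i = 0
    while i < len(body):
        key = body[i].lower().rstrip(":")
        if key == "labels":
            raw: list[str] = []
            i += 1
            while i < len(body) and body[i].lower().rstrip(":") != "data":
                raw.extend(s.strip().strip('"') for s in re.split(r"[,\s]+", body[i]) if s.strip())
                i += 1
            if len(raw) != n:
                raise SchemaError(f"DL labels section has {len(raw)} labels, expected {n}")
            labels = raw
        elif key == "data":
            data_lines = body[i + 1:]
            break
        else:
            raise SchemaError(f"unsupported DL section {body[i]!r}")
    else:
        raise SchemaError("DL file has no data: section")

    values = np.zeros((n, n), dtype=int)
    if fmt == "fullmatrix":
        rows = [re.split(r"[,\s]+", ln.strip()) for ln in data_lines]
        if len(rows) != n:
            raise ShapeError(f"DL fullmatrix data has {len(rows)} rows, expected {n}")
        for r, toks in enumerate(rows):
            if len(toks) != n:
                raise ShapeError(f"DL fullmatrix row {r + 1} has {len(toks)} entries, expected {n}")
            values[r] = [int(float(t)) for t in toks]
    else:  # edgelist1: "source target [weight]" using labels or 1-based indices
        index = {lab: k for k, lab in enumerate(labels)}
        for ln in data_lines:
            toks = re.split(r"[,\s]+", ln.strip())
            if len(toks) not in (2, 3):
                raise SchemaError(f"DL edgelist1 line {ln!r} is not 'source target [weight]'")
            src, dst = toks[0].strip('"'), toks[1].strip('"')
            w = int(float(toks[2])) if len(toks) == 3 else 1
            try:
                si, di = index[src], index[dst]
            except KeyError:
                si, di = int(src) - 1, int(dst) - 1  # numeric 1-based fallback
            values[si, di] = w
    return labels, values


def _format_dl(labels: Sequence[str], values: np.ndarray, fmt: str) -> str:
    n = len(labels)
    out = [f"dl n={n} format={fmt}", "labels:", ",".join(labels), "data:"]
    if fmt == "fullmatrix":
        out += [" ".join(str(int(v)) for v in row) for row in values]
    else:
        out += [f"{labels[i]} {labels[j]}" for i, j in zip(*np.nonzero(values))]
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def read_contact_matrix(
    path: str | Path,
    classroom: str | None = None,
    dialect: str = "csv",
    missing_action: str = "as_never",
) -> ContactMatrix:
    """Read an ordinal contact matrix (CSV or UCINET DL full matrix).

    ``missing_action`` controls the :data:`~triadscope.model.MISSING` sentinel
    (0): ``"as_never"`` keeps it (downstream it behaves like rating 1);
    ``"drop"`` removes any actor with a missing outgoing row.
    """
    path = Path(path)
    if dialect == "csv":
        labels, values = _read_labelled_matrix_csv(path)
    elif dialect == "ucinet_dl":
        labels, values = _parse_dl(path.read_text())
    else:
        raise UsageError(f"unknown contact-matrix dialect {dialect!r}")

    if missing_action == "drop":
        off = ~np.eye(len(labels), dtype=bool)
        keep = ~((values == MISSING) & off).any(axis=1)
        labels = [lab for lab, k in zip(labels, keep) if k]
        values = values[np.ix_(keep, keep)]
    elif missing_action != "as_never":
        raise UsageError(f"unknown missing_action {missing_action!r}")

    return ContactMatrix(
        classroom=classroom or path.stem, actor_order=labels, values=values
    )


def write_contact_matrix(
    matrix: ContactMatrix, path: str | Path, dialect: str = "csv"
) -> None:
    path = Path(path)
    if dialect == "csv":
        _write_labelled_matrix_csv(matrix.actor_order, matrix.values, path)
    elif dialect == "ucinet_dl":
        path.write_text(_format_dl(matrix.actor_order, matrix.values, "fullmatrix"))
    else:
        raise UsageError(f"unknown contact-matrix dialect {dialect!r}")


# ---------------------------------------------------------------------------
# binary networks
# ---------------------------------------------------------------------------

def read_network(
    path: str | Path,
    classroom: str | None = None,
    dialect: str = "csv",
    layer: str = "unknown",
    actor_order: Sequence[str] | None = None,
) -> BinaryNetwork:
    """Read a binary network from CSV matrix, UCINET DL, or edge list.

    Edge lists do not carry isolates; pass ``actor_order`` to recover them
    (otherwise the order is the sorted set of labels seen in edges).
    """
    path = Path(path)
    if dialect == "csv":
        labels, values = _read_labelled_matrix_csv(path)
    elif dialect == "ucinet_dl":
        labels, values = _parse_dl(path.read_text())
    elif dialect == "edge_list":
        df = pd.read_csv(path, dtype=str)
        need = {"source", "target"}
        if not need <= set(df.columns):
            raise SchemaError(f"edge list {path}: needs columns {sorted(need)}")
        edges = [(s.strip(), t.strip()) for s, t in zip(df["source"], df["target"])]
        if actor_order is None:
            labels = sorted({x for e in edges for x in e})
        else:
            labels = [str(x).strip() for x in actor_order]
        index = {lab: k for k, lab in enumerate(labels)}
        values = np.zeros((len(labels), len(labels)), dtype=int)
        for s, t in edges:
            values[index[s], index[t]] = 1
    else:
        raise UsageError(f"unknown network dialect {dialect!r}")

    values = (np.asarray(values) != 0).astype(int)
    return BinaryNetwork(
        classroom=classroom or path.stem, actor_order=list(labels),
        adjacency=values, layer=layer,
    )


def write_network(net: BinaryNetwork, path: str | Path, dialect: str = "csv") -> None:
    """Write a binary network; the file re-reads to an identical network."""
    path = Path(path)
    if dialect == "csv":
        _write_labelled_matrix_csv(net.actor_order, net.adjacency, path)
    elif dialect == "ucinet_dl":
        path.write_text(_format_dl(net.actor_order, net.adjacency, "edgelist1"))
    elif dialect == "edge_list":
        pd.DataFrame(net.edges(), columns=["source", "target"]).to_csv(path, index=False)
    else:
        raise UsageError(f"unknown network dialect {dialect!r}")
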