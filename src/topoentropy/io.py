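"""Readers and writers for edge lists, partitions, and structure files.

Formats:

* **Edge list** — one edge per line, two vertex tokens separated by
  whitespace or a comma; ``#`` starts a comment.  Duplicate and reversed
  duplicate pairs are rejected.
* **Partition** — JSON object mapping ``"d_lo,d_hi"`` to an edge count, or
  a two-column CSV (pair, count).
* **Structure file (SDF/MOL)** — optional, requires rdkit: heavy-atom
  connectivity only, hydrogens suppressed, bond orders ignored.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .graph import DegreePair, EdgePartition, MolecularGraph, PartitionError

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_partition",
    "write_partition",
    "read_structure_file",
]


def read_edge_list(path: str | Path) -> MolecularGraph:
    """Load a molecular graph from a plain-text edge list."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = [t for t in line.replace(",", " ").split() if t]
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two vertex tokens, got {line!r}"
                )
            edges.append((tokens[0], tokens[1]))
    return MolecularGraph(edges)


def write_edge_list(graph: MolecularGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted((str(u), str(v)) for u, v in graph.edges):
            fh.write(f"{u}\t{v}\n")


def _parse_pair_token(token: str) -> DegreePair:
    parts = token.strip().strip("()").replace(" ", "").split(",")
    if len(parts) != 2:
        raise PartitionError(f"cannot parse degree pair {token!r}")
    return DegreePair(int(parts[0]), int(parts[1]))


def read_partition(path: str | Path) -> EdgePartition:
    """Load an edge partition from JSON or two-column CSV (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, dict):
            raise PartitionError(f"{path}: expected a JSON object of pair -> count")
        return EdgePartition({_parse_pair_token(k): v for k, v in data.items()})
    counts: dict[DegreePair, int] = {}
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if row[0].strip().lower() in {"pair", "degree_pair"}:
                continue  # header
            if len(row) == 3:  # "a, b, count" (pair split by the csv comma)
                pair, count = _parse_pair_token(f"{row[0]},{row[1]}"), int(row[2])
            elif len(row) == 2:
                pair, count = _parse_pair_token(row[0]), int(row[1])
            else:
                raise PartitionError(f"{path}: cannot parse row {row!r}")
            counts[pair] = counts.get(pair, 0) + count
    return EdgePartition(counts)


def write_partition(partition: EdgePartition, path: str | Path) -> None:
    """Write a partition as JSON ("d_lo,d_hi" -> count) or CSV, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {f"{p.d_lo},{p.d_hi}": c for p, c in partition.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pair", "count"])
            for p, c in partition.items():
                writer.writerow([f"({p.d_lo},{p.d_hi})", c])


def read_structure_file(path: str | Path) -> MolecularGraph:
    """Heavy-atom graph from an SDF/MOL file (first molecule); needs rdkit."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "structure-file ingestion requires the optional rdkit dependency"
        ) from exc
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=False)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise ValueError(f"{path}: no parsable molecule found")
    edges = [
        (f"a{b.GetBeginAtomIdx()}", f"a{b.GetEndAtomIdx()}") for b in mol.GetBonds()
    ]
    return MolecularGraph(edges)
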