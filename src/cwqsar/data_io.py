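"""Compound tables, split files, deduplication, identity percentages.

Datasets are ordered lists of ``Compound`` records (id, SMILES, endpoint).
Splits assign each compound one of four roles: active training (A),
passive training (P), calibration (C), validation (V).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataFormatError

__all__ = [
    "ROLES",
    "Compound",
    "Dataset",
    "SplitAssignment",
    "read_dataset",
    "write_dataset",
    "deduplicate",
    "read_split",
    "write_split",
    "identity_percentage",
]

ROLES = ("A", "P", "C", "V")


@dataclass(frozen=True)
class Compound:
    id: str
    smiles: str
    endpoint: float

    def __post_init__(self):
        if not self.smiles:
            raise DataFormatError(f"compound {self.id!r}: empty SMILES")
        if not math.isfinite(self.endpoint):
            raise DataFormatError(f"compound {self.id!r}: non-finite endpoint")


@dataclass
class Dataset:
    compounds: list[Compound] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for c in self.compounds:
            if c.id in seen:
                raise DataFormatError(f"duplicate compound id {c.id!r}")
            seen.add(c.id)

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def by_id(self, cid: str) -> Compound:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.compounds],
                "smiles": [c.smiles for c in self.compounds],
                "endpoint": [c.endpoint for c in self.compounds],
            }
        )


@dataclass
class SplitAssignment:
    """Map compound id -> role letter; all four roles must be present."""

    role: dict[str, str]

    def __post_init__(self):
        for cid, r in self.role.items():
            if r not in ROLES:
                raise DataFormatError(f"unknown role {r!r} for id {cid!r}")
        missing = [r for r in ROLES if r not in set(self.role.values())]
        if missing:
            raise DataFormatError(f"split is missing role(s): {missing}")

    def ids_with_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise DataFormatError(f"unknown role {role!r}")
        return [cid for cid, r in self.role.items() if r == role]

    def sizes(self) -> dict[str, int]:
        out = {r: 0 for r in ROLES}
        for r in self.role.values():
            out[r] += 1
        return out

    def fingerprint(self) -> str:
        import hashlib

        text = ";".join(f"{cid}={r}" for cid, r in sorted(self.role.items()))
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def read_dataset(
    path: str | Path,
    fmt: str | None = None,
    id_col: str = "id",
    smiles_col: str = "smiles",
    endpoint_col: str = "endpoint",
) -> Dataset:
    """Read a compound table from CSV/TSV (with header) or SMI.

    SMI lines are whitespace-separated ``SMILES [id [endpoint]]``; a missing
    id defaults to the 1-based line number, a missing endpoint to 0.0.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".smi": "smi"}.get(path.suffix.lower(), "csv")
    if fmt == "smi":
        compounds = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            smiles = fields[0]
            cid = fields[1] if len(fields) > 1 else str(lineno)
            try:
                endpoint = float(fields[2]) if len(fields) > 2 else 0.0
            except ValueError:
                raise DataFormatError(
                    f"{path}: non-numeric endpoint {fields[2]!r} on line {lineno}"
                )
            compounds.append(Compound(cid, smiles, endpoint))
        return Dataset(compounds)
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (id_col, smiles_col, endpoint_col):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing column {col!r}")
    compounds = []
    rows = zip(df[id_col], df[smiles_col], df[endpoint_col])
    for row_number, (cid, smiles, raw) in enumerate(rows, start=1):
        try:
            endpoint = float(raw)
        except (TypeError, ValueError):
            raise DataFormatError(
                f"{path}: non-numeric endpoint {raw!r} on row {row_number}"
            )
        compounds.append(Compound(str(cid), str(smiles), endpoint))
    try:
        return Dataset(compounds)
    except DataFormatError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_dataset(ds: Dataset, path: str | Path) -> None:
    ds.to_frame().to_csv(path, index=False)


def deduplicate(ds: Dataset) -> tuple[Dataset, list[tuple[str, str]]]:
    """Drop compounds whose whitespace-stripped SMILES was seen before.

    Returns the reduced dataset and a list of (removed id, kept id) pairs.
    The first occurrence is always kept, and retained records are unchanged.
    """
    seen: dict[str, str] = {}
    kept: list[Compound] = []
    removed: list[tuple[str, str]] = []
    for c in ds:
        key = c.smiles.strip()
        if key in seen:
            removed.append((c.id, seen[key]))
        else:
            seen[key] = c.id
            kept.append(c)
    return Dataset(kept), removed


def write_split(split: SplitAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"id": list(split.role.keys()), "role": list(split.role.values())}
    ).to_csv(path, index=False)


def read_split(path: str | Path) -> SplitAssignment:
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "role"):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing column {col!r}")
    return SplitAssignment(dict(zip(df["id"], df["role"])))


def identity_percentage(s1: SplitAssignment, s2: SplitAssignment, role: str) -> float:
    """Percent of s1's ``role`` compounds also holding ``role`` in s2.

    The denominator is the size of the role set in the FIRST split (the
    rows of an identity matrix), which makes the matrix asymmetric.
    """
    if set(s1.role) != set(s2.role):
        raise DataFormatError("splits cover different compound id sets")
    set1 = set(s1.ids_with_role(role))
    set2 = set(s2.ids_with_role(role))
    if not set1 or not set2:
        raise DataFormatError(f"role {role!r} is empty in one of the splits")
    return 100.0 * len(set1 & set2) / len(set1)


def identity_matrix(
    splits: Mapping[str, SplitAssignment] | Iterable[SplitAssignment], role: str
) -> pd.DataFrame:
    """Pairwise identity-percentage matrix for one role across splits."""
    if isinstance(splits, Mapping):
        names = list(splits.keys())
        items = list(splits.values())
    else:
        items = list(splits)
        names = [str(i + 1) for i in range(len(items))]
    data = [
        [round(identity_percentage(a, b, role), 1) for b in items] for a in items
    ]
    return pd.DataFrame(data, index=names, columns=names)
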