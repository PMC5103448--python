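"""Readers and writers for the plain-text formats used throughout the package.

Sequences travel as FASTA, tabular data (hit tables, reports, cluster maps,
truth tables) as TSV with fixed column orders, and the diagnostic-motif
catalog as YAML.  Internal coordinates are 0-based half-open; anything
written for humans is 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
import yaml

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}

Alphabet = Literal["nt", "aa"]

#: Column order for external evidence-hit tables.
HIT_TABLE_COLUMNS = ["query_id", "source_name", "subject_id", "e_value", "bit_score"]


class FormatError(ValueError):
    """Raised for malformed sequence files, tables, or catalogs."""


@dataclass
class SeqRecord:
    """A named sequence over a declared alphabet.

    ``residues`` is stored uppercase.  In amino-acid mode a single ``*`` is
    tolerated as a terminal stop and nowhere else.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id must be a non-empty token, got {self.id!r}")
        if not self.residues:
            raise FormatError(f"record {self.id!r} has an empty sequence")


def _validate_residues(rec_id: str, residues: str, alphabet: Alphabet) -> None:
    allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    for pos, ch in enumerate(residues):
        if ch in allowed:
            continue
        if alphabet == "aa" and ch == "*" and pos == len(residues) - 1:
            continue
        raise FormatError(
            f"record {rec_id!r}: residue {ch!r} at position {pos + 1} "
            f"not in {alphabet} alphabet"
        )


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[SeqRecord]:
    """Read a FASTA file, validating ids and residues.

    Residues are uppercased.  Duplicate ids and out-of-alphabet residues are
    hard errors; an empty file yields an empty list with a warning.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        parts = header.split(maxsplit=1)
        rec_id = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        if rec_id in seen:
            raise FormatError(f"duplicate sequence id {rec_id!r} in {path}")
        seen.add(rec_id)
        residues = "".join(chunks).upper()
        if not residues:
            raise FormatError(f"record {rec_id!r} in {path} has no sequence lines")
        _validate_residues(rec_id, residues, alphabet)
        records.append(SeqRecord(id=rec_id, residues=residues, description=desc))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
        _flush()
    if not records:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with lines wrapped at ``width`` columns.

    Byte output is a deterministic function of the input records.
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    records = list(records)
    if not records:
        warnings.warn(f"{path}: writing empty FASTA file", stacklevel=2)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read an external evidence-hit TSV (query_id, source_name, subject_id,
    e_value, bit_score)."""
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "source_name": str, "subject_id": str})
    missing = [c for c in HIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: hit table missing columns {missing}")
    df = df[HIT_TABLE_COLUMNS]
    if (df["e_value"] < 0).any():
        bad = df.loc[df["e_value"] < 0].iloc[0]
        raise FormatError(f"{path}: negative e-value for query {bad['query_id']!r}")
    return df


def write_hit_table(df: pd.DataFrame, path: str | Path) -> None:
    df[HIT_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write any report table as TSV (fixed column order = DataFrame order)."""
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Motif catalog I/O.  The catalog data model itself lives in hoxminer.catalog;
# this module owns (de)serialisation and structural validation.
# ---------------------------------------------------------------------------

_CATALOG_KEYS = {"groups"}
_GROUP_KEYS = {"name", "class", "features"}
_FEATURE_KEYS = {
    "region",
    "positions",
    "offset",
    "window",
    "pattern",
    "predicates",
    "weight",
    "required",
    "scope",
    "note",
}


def read_catalog(path: str | Path):
    """Load a diagnostic-motif catalog from YAML and validate it.

    Unknown keys, unknown region types, and homeodomain positions outside
    1..60 are rejected.
    """
    from .catalog import DiagnosticFeature, MotifCatalog, REGIONS

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or not set(doc) <= _CATALOG_KEYS:
        raise FormatError(f"{path}: catalog must be a mapping with key 'groups'")
    groups: dict[str, str] = {}
    features: list[DiagnosticFeature] = []
    for g in doc.get("groups", []):
        extra = set(g) - _GROUP_KEYS
        if extra:
            raise FormatError(f"{path}: unknown group keys {sorted(extra)}")
        name = g["name"]
        cls = g["class"]
        if cls not in ("hox", "parahox"):
            raise FormatError(f"{path}: group {name!r} has unknown class {cls!r}")
        if name in groups:
            raise FormatError(f"{path}: duplicate group {name!r}")
        groups[name] = cls
        for f in g.get("features", []):
            extra = set(f) - _FEATURE_KEYS
            if extra:
                raise FormatError(f"{path}: unknown feature keys {sorted(extra)} in group {name!r}")
            region = f.get("region")
            if region not in REGIONS:
                raise FormatError(f"{path}: unknown region type {region!r} in group {name!r}")
            feat = DiagnosticFeature(
                group=name,
                region=region,
                positions=tuple(f.get("positions", ())),
                offset=f.get("offset"),
                window=tuple(f["window"]) if f.get("window") else None,
                pattern=f.get("pattern", ""),
                predicates=tuple(f.get("predicates", ())),
                weight=float(f.get("weight", 1.0)),
                required=bool(f.get("required", False)),
                scope=f.get("scope", "bilaterian"),
                note=f.get("note", ""),
            )
            features.append(feat)
    return MotifCatalog(classes=groups, features=tuple(features))


def write_catalog(catalog, path: str | Path) -> None:
    """Serialise a catalog back to the YAML layout ``read_catalog`` accepts."""
    doc: dict = {"groups": []}
    for name in catalog.labels:
        entry: dict = {"name": name, "class": catalog.classes[name], "features": []}
        for feat in catalog.features_of(name):
            f: dict = {"region": feat.region}
            if feat.positions:
                f["positions"] = list(feat.positions)
            if feat.offset is not None:
                f["offset"] = feat.offset
            if feat.window is not None:
                f["window"] = list(feat.window)
            f["pattern"] = feat.pattern
            if feat.predicates:
                f["predicates"] = list(feat.predicates)
            f["weight"] = feat.weight
            if feat.required:
                f["required"] = True
            f["scope"] = feat.scope
            if feat.note:
                f["note"] = feat.note
            entry["features"].append(f)
        doc["groups"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
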