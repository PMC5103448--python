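"""Diagnostic-feature catalog for Hox/ParaHox paralog-group classification.

The ancestral lophotrochozoan complement — 11 Hox paralog groups (Hox1,
Hox2, Hox3, Hox4, Hox5, Lox5, Antp, Lox4, Lox2, Post2, Post1) and 3 ParaHox
genes (Gsx, Xlox, Cdx) — is the label set.  Each label carries diagnostic
features anchored to the canonical homeodomain coordinate frame: positions
1-60 inside the domain, negative offsets for the N-terminal flank (-1 is the
residue immediately before position 1) and positive offsets for the
C-terminal flank (+1 is the residue immediately after position 60).

A feature is one of:

* an exact motif (``pattern``) at a fixed set of homeodomain positions, at a
  fixed flank offset, or searched within a flank window;
* a per-position residue-class predicate (e.g. ``non-basic`` = not K/R/H);
* a placeholder: the literature localises a signature (e.g. the Hox1 motif at
  positions 6-8) without printing its residues.  Placeholders have an empty
  pattern and weight 0 and are excluded from scoring until a user fills them
  in, e.g. from :mod:`hoxminer.discovery` output on their own alignment.

``X`` never matches any pattern or predicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Optional

REGIONS = ("HD_POS", "N_FLANK", "C_FLANK")

BASIC_RESIDUES = frozenset("KRH")

#: Residue-class predicates usable in catalog files.
PREDICATES: dict[str, Callable[[str], bool]] = {
    "basic": lambda aa: aa in BASIC_RESIDUES,
    "non-basic": lambda aa: aa not in BASIC_RESIDUES and aa != "X",
    "any": lambda aa: aa != "X",
}


class CatalogError(ValueError):
    """Raised for structurally invalid catalogs."""


@dataclass(frozen=True)
class DiagnosticFeature:
    group: str
    region: str  # HD_POS | N_FLANK | C_FLANK
    positions: tuple[int, ...] = ()  # HD positions 1..60 (HD_POS only)
    offset: Optional[int] = None  # exact flank offset (+/-, flank regions)
    window: Optional[tuple[int, int]] = None  # inclusive flank offset window
    pattern: str = ""  # exact motif; empty => placeholder unless predicates set
    predicates: tuple[str, ...] = ()  # per-position predicate names
    weight: float = 1.0
    required: bool = False
    scope: str = "bilaterian"  # bilaterian | lophotrochozoan | molluscan
    note: str = ""

    @property
    def is_placeholder(self) -> bool:
        return not self.pattern and not self.predicates

    @property
    def length(self) -> int:
        if self.pattern:
            return len(self.pattern)
        if self.predicates:
            return len(self.predicates)
        return len(self.positions)

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise CatalogError(f"unknown region {self.region!r}")
        if self.region == "HD_POS":
            for p in self.positions:
                if not 1 <= p <= 60:
                    raise CatalogError(
                        f"group {self.group}: homeodomain position {p} outside 1..60"
                    )
            if self.pattern and len(self.pattern) != len(self.positions):
                raise CatalogError(
                    f"group {self.group}: pattern length {len(self.pattern)} "
                    f"!= number of positions {len(self.positions)}"
                )
            if self.predicates and len(self.predicates) != len(self.positions):
                raise CatalogError(
                    f"group {self.group}: predicate count mismatch at {self.positions}"
                )
        else:
            if self.offset is None and self.window is None and not self.is_placeholder:
                raise CatalogError(
                    f"group {self.group}: flank feature needs offset or window"
                )
            if self.offset is not None and self.offset == 0:
                raise CatalogError(f"group {self.group}: flank offset 0 is undefined")
            if self.window is not None and self.window[0] > self.window[1]:
                raise CatalogError(f"group {self.group}: empty flank window {self.window}")
        for name in self.predicates:
            if name not in PREDICATES:
                raise CatalogError(f"group {self.group}: unknown predicate {name!r}")
        if self.weight < 0:
            raise CatalogError(f"group {self.group}: negative weight")
        if self.is_placeholder and self.weight != 0:
            raise CatalogError(
                f"group {self.group}: placeholder features must carry weight 0"
            )


@dataclass(frozen=True)
class MotifCatalog:
    """Label set (with hox/parahox class) plus the features of every label."""

    classes: dict[str, str]  # label -> "hox" | "parahox"
    features: tuple[DiagnosticFeature, ...]

    def __post_init__(self) -> None:
        for feat in self.features:
            if feat.group not in self.classes:
                raise CatalogError(f"feature references unknown group {feat.group!r}")
            feat.validate()
        # two exact patterns pinned to the same spot in one group conflict
        seen: set[tuple] = set()
        for feat in self.features:
            if feat.is_placeholder:
                continue
            key = (feat.group, feat.region, feat.positions, feat.offset)
            if feat.offset is None and feat.region != "HD_POS":
                continue  # windowed features may coexist
            if key in seen:
                raise CatalogError(f"group {feat.group}: conflicting features at {key}")
            seen.add(key)

    @property
    def labels(self) -> list[str]:
        return list(self.classes)

    @property
    def hox_labels(self) -> list[str]:
        return [g for g, c in self.classes.items() if c == "hox"]

    @property
    def parahox_labels(self) -> list[str]:
        return [g for g, c in self.classes.items() if c == "parahox"]

    def features_of(self, group: str) -> list[DiagnosticFeature]:
        return [f for f in self.features if f.group == group]

    def scored_features_of(self, group: str) -> list[DiagnosticFeature]:
        return [f for f in self.features_of(group) if not f.is_placeholder]

    def diagnostic_hd_positions(self, group: str) -> set[int]:
        """Homeodomain positions any feature of ``group`` declares (used by the
        simulator to protect them from mutation)."""
        out: set[int] = set()
        for f in self.features_of(group):
            if f.region == "HD_POS":
                out.update(f.positions)
        return out


def default_catalog() -> MotifCatalog:
    """The packaged catalog of printed Hox/ParaHox diagnostic signatures.

    Exact content: Hox4/Hox5 share the hexapeptide "YPWM" in the N-terminal
    flank; Hox4 carries "LPNTK" in the C-terminal flank; Hox5 carries the
    molluscan "HIAKNM" immediately after homeodomain position 60; Hox3 has
    the lophotrochozoan "AL" at positions 36-37; Hox1 has non-basic residues
    at positions 2-3; Hox2 and Hox3 have a non-basic DNA-contacting residue
    at position 4 between basic residues at 3 and 5; Gsx has the
    lophotrochozoan pentapeptide "LRTCD" in the C-terminal arm.  Signatures
    the literature localises without printing residues ship as inert
    placeholders.
    """
    from .formats import read_catalog

    with resources.as_file(
        resources.files("hoxminer.data") / "default_catalog.yaml"
    ) as path:
        return read_catalog(path)
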