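"""Paralog-group assignment from diagnostic residues and motifs.

A peptide is classified only after a homeodomain hit anchors the 1-60
coordinate frame.  Every non-placeholder catalog feature of every group is
tested against the peptide; a group's score is the weight sum of its
matched features, a missing *required* feature zeroes the group, and the
argmax wins provided it clears ``min_score`` and leads the runner-up by at
least ``min_margin``.  Tied or sub-threshold peptides come back AMBIGUOUS
with the candidate set (groups 4 and 5, for example, cannot be separated by
the shared YPWM hexapeptide alone); peptides without a homeodomain are
UNCLASSIFIED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .catalog import PREDICATES, DiagnosticFeature, MotifCatalog
from .hdscan import HD_WIDTH, HomeodomainHit, HomeodomainProfile, scan

ASSIGNED = "ASSIGNED"
AMBIGUOUS = "AMBIGUOUS"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class FeatureMatch:
    feature: DiagnosticFeature
    start_aa: int  # 0-based peptide offset of the first matched residue
    matched_text: str


@dataclass
class ClassifyParams:
    min_score: float = 1.0
    min_margin: float = 1.0

    def __post_init__(self) -> None:
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")
        if self.min_margin < 0:
            raise ValueError("min_margin must be >= 0")


@dataclass
class ClassificationResult:
    protein_id: str
    status: str  # ASSIGNED | AMBIGUOUS | UNCLASSIFIED
    label: Optional[str] = None
    candidates: tuple[str, ...] = ()
    scores: dict[str, float] = field(default_factory=dict)
    matches: list[FeatureMatch] = field(default_factory=list)
    hd_hit: Optional[HomeodomainHit] = None
    unassignable_groups: tuple[str, ...] = ()  # all-placeholder groups


def match_feature(
    peptide: str, hd_hit: HomeodomainHit, feature: DiagnosticFeature
) -> Optional[FeatureMatch]:
    """Test one feature against a homeodomain-anchored peptide.

    HD_POS features read residues at position_map(p); exact-offset flank
    features read at a fixed offset from the domain edge; windowed flank
    features slide the pattern across the window and report the first match.
    A window running past either peptide end is a no-match, not an error.
    X never matches anything.
    """
    if feature.is_placeholder:
        return None
    L = len(peptide)

    if feature.region == "HD_POS":
        idxs = [hd_hit.position_map(p) for p in feature.positions]
        if any(i < 0 or i >= L for i in idxs):
            return None
        text = "".join(peptide[i] for i in idxs)
        if feature.pattern:
            if text != feature.pattern:
                return None
        else:
            for ch, pred in zip(text, feature.predicates):
                if not PREDICATES[pred](ch):
                    return None
        return FeatureMatch(feature=feature, start_aa=idxs[0], matched_text=text)

    # flanks: translate an offset into a 0-based peptide index of the first
    # pattern residue
    def index_of(offset: int) -> int:
        if offset < 0:  # N_FLANK: -1 is the residue before position 1
            return hd_hit.hd_start + offset
        return hd_hit.hd_start + HD_WIDTH + offset - 1  # C_FLANK: +1 follows pos 60

    pattern = feature.pattern
    if not pattern:  # predicate flanks are not part of the catalog grammar
        return None
    plen = len(pattern)

    if feature.offset is not None:
        offsets = [feature.offset]
    else:
        lo, hi = feature.window
        if feature.region == "N_FLANK":
            hi = min(hi, -plen)  # pattern must fit before the domain
        offsets = list(range(lo, hi + 1))

    for off in offsets:
        start = index_of(off)
        if start < 0 or start + plen > L:
            continue
        if feature.region == "N_FLANK" and start + plen > hd_hit.hd_start:
            continue
        if peptide[start : start + plen] == pattern:
            return FeatureMatch(feature=feature, start_aa=start, matched_text=pattern)
    return None


def score_groups(
    peptide: str, hd_hit: HomeodomainHit, catalog: MotifCatalog
) -> tuple[dict[str, float], list[FeatureMatch]]:
    scores: dict[str, float] = {}
    matches: list[FeatureMatch] = []
    for group in catalog.labels:
        total = 0.0
        group_matches: list[FeatureMatch] = []
        zeroed = False
        for feat in catalog.scored_features_of(group):
            m = match_feature(peptide, hd_hit, feat)
            if m is not None:
                total += feat.weight
                group_matches.append(m)
            elif feat.required:
                zeroed = True
        scores[group] = 0.0 if zeroed else total
        if not zeroed:
            matches.extend(group_matches)
    return scores, matches


def classify(
    peptide: str | "object",
    profile: HomeodomainProfile,
    catalog: MotifCatalog,
    params: ClassifyParams | None = None,
    scan_threshold: float | None = None,
    protein_id: str = "",
) -> ClassificationResult:
    """Assign a Hox/ParaHox label to one peptide (see module docstring)."""
    from .hdscan import calibrate_threshold

    params = params or ClassifyParams()
    if hasattr(peptide, "residues"):
        protein_id = protein_id or peptide.id
        peptide = peptide.residues
    if scan_threshold is None:
        scan_threshold = calibrate_threshold(profile)
    unassignable = tuple(
        g for g in catalog.labels if not catalog.scored_features_of(g)
    )

    hits = scan(peptide, profile, scan_threshold, protein_id=protein_id)
    if not hits:
        return ClassificationResult(
            protein_id=protein_id,
            status=UNCLASSIFIED,
            unassignable_groups=unassignable,
        )
    hd_hit = hits[0]
    scores, matches = score_groups(peptide, hd_hit, catalog)
    top = max(scores.values())
    top_groups = tuple(sorted(g for g, s in scores.items() if s == top))

    result = ClassificationResult(
        protein_id=protein_id,
        status=AMBIGUOUS,
        scores=scores,
        matches=matches,
        hd_hit=hd_hit,
        unassignable_groups=unassignable,
    )
    if top < params.min_score:
        result.candidates = top_groups if top > 0 else ()
        return result
    if len(top_groups) > 1:
        result.candidates = top_groups
        return result
    runner_up = max((s for g, s in scores.items() if g != top_groups[0]), default=0.0)
    if top - runner_up < params.min_margin:
        within = tuple(
            sorted(g for g, s in scores.items() if top - s < params.min_margin)
        )
        result.candidates = within
        return result
    result.status = ASSIGNED
    result.label = top_groups[0]
    result.candidates = top_groups
    result.matches = [m for m in matches if m.feature.group == result.label]
    return result


def results_to_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Report table (1-based coordinates for matched features)."""
    rows = []
    for r in results:
        rows.append(
            {
                "protein_id": r.protein_id,
                "status": r.status,
                "label": r.label or "",
                "candidates": ";".join(r.candidates),
                "score": r.scores.get(r.label, 0.0) if r.label else (
                    max(r.scores.values()) if r.scores else 0.0
                ),
                "hd_start_1based": (r.hd_hit.hd_start + 1) if r.hd_hit else 0,
                "hd_score_bits": round(r.hd_hit.score, 3) if r.hd_hit else 0.0,
                "matched_features": ";".join(
                    f"{m.feature.region}:{m.matched_text}@{m.start_aa + 1}"
                    for m in r.matches
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "status",
            "label",
            "candidates",
            "score",
            "hd_start_1based",
            "hd_score_bits",
            "matched_features",
        ],
    )
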