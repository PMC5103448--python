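"""Protein redundancy removal by 100 %-identity clustering.

Identity between two peptides is the number of matches in their global
alignment divided by the number of alignment columns (gap columns
included), with match = 1, mismatch = 0, and a unit gap penalty.  Two modes
are offered because "100 % identity" is ambiguous for substrings:

* ``exact`` (default): only string-equal peptides cluster together;
* ``containment``: a peptide that is a contiguous substring of a longer
  member additionally joins that member's cluster (identity 1.0 over its
  own aligned columns).

The representative of a cluster is its longest member, ties broken by
lexicographic id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner

from .formats import SeqRecord

Mode = Literal["exact", "containment"]


@dataclass(frozen=True)
class Cluster:
    representative_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.representative_id in self.member_ids


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the optimal global alignment of
    ``a`` and ``b`` (unit gap penalty; columns include gap columns)."""
    if not a or not b:
        raise ValueError("pairwise identity of an empty sequence is undefined")
    aligner = _global_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_exact(proteins: Sequence[SeqRecord], mode: Mode = "exact") -> list[Cluster]:
    """Cluster peptides at 100 % identity.

    Clusters partition the input id set.  In containment mode substrings are
    absorbed greedily into the longest compatible representative.
    """
    if mode not in ("exact", "containment"):
        raise ValueError(f"mode must be 'exact' or 'containment', got {mode!r}")

    def represent(ids: list[str]) -> str:
        lengths = {i: seq_of[i] for i in ids}
        return min(ids, key=lambda i: (-len(lengths[i]), i))

    seq_of = {rec.id: rec.residues for rec in proteins}
    if len(seq_of) != len(proteins):
        raise ValueError("duplicate protein ids in input")

    by_seq: dict[str, list[str]] = {}
    for rec in proteins:
        by_seq.setdefault(rec.residues, []).append(rec.id)

    if mode == "exact":
        return [
            Cluster(representative_id=represent(ids), member_ids=tuple(ids))
            for ids in by_seq.values()
        ]

    # containment: longest-first; each distinct string joins the first
    # already-kept representative string that contains it
    distinct = sorted(by_seq, key=lambda s: (-len(s), s))
    rep_strings: list[str] = []
    assignment: dict[str, str] = {}  # distinct string -> representative string
    for s in distinct:
        host = next((r for r in rep_strings if s in r), None)
        if host is None:
            rep_strings.append(s)
            assignment[s] = s
        else:
            assignment[s] = host
    groups: dict[str, list[str]] = {}
    for s, host in assignment.items():
        groups.setdefault(host, []).extend(by_seq[s])
    return [
        Cluster(representative_id=represent(ids), member_ids=tuple(ids))
        for ids in groups.values()
    ]


def clusters_to_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """TSV-ready member -> representative map."""
    rows = [
        {"member_id": m, "representative_id": c.representative_id}
        for c in clusters
        for m in c.member_ids
    ]
    return pd.DataFrame(rows, columns=["member_id", "representative_id"])


def representatives(
    proteins: Sequence[SeqRecord], clusters: Sequence[Cluster]
) -> list[SeqRecord]:
    seq_of = {rec.id: rec for rec in proteins}
    return [seq_of[c.representative_id] for c in clusters]
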