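"""Single-copy marker recovery: a simplified completeness assessment.

Each marker peptide is aligned locally (Smith-Waterman, BLOSUM62 by
default) against every protein in the set under evaluation and classified:

* ``complete``   — exactly one protein covers >= ``cov_complete`` of the
  marker at identity >= ``id_min``;
* ``duplicated`` — more than one such protein;
* ``fragmented`` — the best qualifying hit covers at least ``cov_fragment``
  but less than ``cov_complete`` of the marker;
* ``missing``    — anything less.

``completeness_pct`` is 100 x complete / total markers, matching the C/D/F/M
category semantics of ortholog-completeness benchmarks (the thresholds here
are this package's own, documented defaults rather than a trained model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .formats import SeqRecord

COMPLETE = "complete"
DUPLICATED = "duplicated"
FRAGMENTED = "fragmented"
MISSING = "missing"


def _local_aligner(matrix: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def align_marker(
    marker_peptide: str, protein_peptide: str, matrix: str = "BLOSUM62"
) -> tuple[float, float, float]:
    """Best local alignment of marker vs protein.

    Returns ``(score, marker_coverage, identity)`` where marker_coverage is
    the fraction of marker residues inside the aligned region and identity
    is identical columns over alignment columns (gaps included).
    """
    if not marker_peptide or not protein_peptide:
        raise ValueError("cannot align empty peptides")
    aligner = _local_aligner(matrix)
    alignments = aligner.align(marker_peptide, protein_peptide)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0, 0.0, 0.0
    aln = alignments[0]
    aligned_marker = sum(int(e - s) for s, e in aln.aligned[0])
    counts = aln.counts()
    coverage = aligned_marker / len(marker_peptide)
    identity = counts.identities / aln.length if aln.length else 0.0
    return float(aln.score), coverage, identity


@dataclass
class MarkerRecoveryReport:
    statuses: dict[str, str]  # marker id -> category
    best_hits: pd.DataFrame  # marker, status, best_protein, coverage, identity

    @property
    def completeness_pct(self) -> float:
        n = len(self.statuses)
        complete = sum(1 for s in self.statuses.values() if s == COMPLETE)
        return 100.0 * complete / n

    def count(self, status: str) -> int:
        return sum(1 for s in self.statuses.values() if s == status)


def assess(
    markers: Sequence[SeqRecord],
    proteome: Sequence[SeqRecord],
    cov_complete: float = 0.9,
    cov_fragment: float = 0.3,
    id_min: float = 0.4,
    matrix: str = "BLOSUM62",
) -> MarkerRecoveryReport:
    """Classify every marker against the proteome (see module docstring)."""
    if not markers:
        raise ValueError("marker set is empty")
    if not 0 < cov_fragment < cov_complete <= 1:
        raise ValueError("thresholds must satisfy 0 < cov_fragment < cov_complete <= 1")
    statuses: dict[str, str] = {}
    rows = []
    for marker in markers:
        qualifying = 0
        best = ("", 0.0, 0.0, 0.0)  # protein_id, score, coverage, identity
        for prot in proteome:
            score, cov, ident = align_marker(marker.residues, prot.residues, matrix)
            if ident >= id_min and cov >= cov_complete:
                qualifying += 1
            if ident >= id_min and (cov, score) > (best[2], best[1]):
                best = (prot.id, score, cov, ident)
        if qualifying == 1:
            status = COMPLETE
        elif qualifying > 1:
            status = DUPLICATED
        elif best[2] >= cov_fragment:
            status = FRAGMENTED
        else:
            status = MISSING
        statuses[marker.id] = status
        rows.append(
            {
                "marker": marker.id,
                "status": status,
                "best_protein": best[0],
                "coverage": round(best[2], 4),
                "identity": round(best[3], 4),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["marker", "status", "best_protein", "coverage", "identity"]
    )
    return MarkerRecoveryReport(statuses=statuses, best_hits=frame)
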