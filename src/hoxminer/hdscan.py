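"""Position-specific scoring profile over the 60-column homeodomain and a
sliding-window scanner that localises the domain in query peptides.

The profile establishes the canonical homeodomain coordinate frame: hit
position 1 is the first domain residue, 60 the last; flank offsets -1/+1
are the residues immediately before/after.  Scores are log-odds in bits,

    score(col, aa) = log2( ((count + c) / (N_col + 20 c)) / q_aa )

with Laplace pseudocount ``c`` (default 1), per-column gap-excluded depth
``N_col``, and background ``q_aa`` (default uniform 0.05).  A window score is
the sum of its 60 per-position scores.  Residues outside the 20-letter
alphabet (X) score like an unobserved residue (count 0).

The default acceptance threshold is calibrated empirically as a high
quantile of the window-score null distribution over seeded random peptides —
the offline analogue of an e-value gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}
HD_WIDTH = 60


@dataclass(frozen=True)
class HomeodomainProfile:
    """60 x 20 log-odds matrix (bits) plus the unseen-residue score per
    column (used for X and other non-standard letters)."""

    scores: np.ndarray  # shape (60, 20)
    unseen: np.ndarray  # shape (60,)
    pseudocount: float
    background: np.ndarray  # shape (20,)

    def __post_init__(self) -> None:
        assert self.scores.shape == (HD_WIDTH, 20)
        assert np.isfinite(self.scores).all()

    def score_matrix_for(self, peptide: str) -> np.ndarray:
        """Per-(column, peptide-position) scores, shape (60, len(peptide))."""
        codes = np.array([_AA_INDEX.get(ch, 20) for ch in peptide], dtype=np.int64)
        padded = np.concatenate([self.scores, self.unseen[:, None]], axis=1)
        return padded[:, codes]


@dataclass(frozen=True)
class HomeodomainHit:
    protein_id: str
    hd_start: int  # 0-based peptide offset of homeodomain position 1
    score: float  # bits

    def position_map(self, hd_position: int) -> int:
        """Absolute 0-based peptide offset of homeodomain position 1..60."""
        if not 1 <= hd_position <= HD_WIDTH:
            raise ValueError(f"homeodomain position {hd_position} outside 1..60")
        return self.hd_start + hd_position - 1


def build_profile(
    aligned_seqs: list[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> HomeodomainProfile:
    """Profile from gap-column-stripped aligned homeodomains.

    Columns that are gap in every sequence are removed; the result must be
    exactly 60 columns wide.  A gap in a column excludes that sequence from
    the column's counts (the denominator uses per-column depth).
    """
    if not aligned_seqs:
        raise ValueError("cannot build a profile from an empty alignment")
    widths = {len(s) for s in aligned_seqs}
    if len(widths) != 1:
        raise ValueError(f"aligned sequences have unequal lengths {sorted(widths)}")
    ncol = widths.pop()
    keep = [
        j for j in range(ncol) if any(s[j] != "-" for s in aligned_seqs)
    ]
    if len(keep) != HD_WIDTH:
        raise ValueError(
            f"alignment is {len(keep)} informative columns wide; homeodomain "
            f"profiles require exactly {HD_WIDTH}"
        )
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not np.isclose(background.sum(), 1.0):
        raise ValueError("background must be a 20-vector summing to 1")

    scores = np.empty((HD_WIDTH, 20))
    unseen = np.empty(HD_WIDTH)
    for out_j, j in enumerate(keep):
        counts = np.zeros(20)
        for s in aligned_seqs:
            ch = s[j]
            if ch == "-":
                continue
            if ch not in _AA_INDEX:
                raise ValueError(f"non-standard residue {ch!r} in profile training data")
            counts[_AA_INDEX[ch]] += 1
        n = counts.sum()
        freqs = (counts + pseudocount) / (n + 20 * pseudocount)
        scores[out_j] = np.log2(freqs / background)
        # X and other non-standard letters score like an unobserved residue
        # under the mean background frequency
        unseen[out_j] = np.log2(
            (pseudocount / (n + 20 * pseudocount)) / background.mean()
        )
    return HomeodomainProfile(
        scores=scores, unseen=unseen, pseudocount=pseudocount, background=background
    )


def window_scores(peptide: str, profile: HomeodomainProfile) -> np.ndarray:
    """Score of every width-60 window, index = window start offset."""
    L = len(peptide)
    n_win = L - HD_WIDTH + 1
    if n_win <= 0:
        return np.empty(0)
    per_pos = profile.score_matrix_for(peptide)  # (60, L)
    out = np.zeros(n_win)
    for i in range(HD_WIDTH):
        out += per_pos[i, i : i + n_win]
    return out


def scan(
    peptide: str | "object",
    profile: HomeodomainProfile,
    threshold_bits: float,
    protein_id: str = "",
) -> list[HomeodomainHit]:
    """All windows scoring at or above the threshold, best score first (ties
    by start offset).  Overlapping hits are allowed.  Peptides shorter than
    60 residues yield an empty list with a warning."""
    if hasattr(peptide, "residues"):
        protein_id = protein_id or peptide.id
        peptide = peptide.residues
    if len(peptide) < HD_WIDTH:
        warnings.warn(
            f"peptide {protein_id or '<anonymous>'} shorter than {HD_WIDTH} aa; "
            "no homeodomain hit possible",
            stacklevel=2,
        )
        return []
    ws = window_scores(peptide, profile)
    hits = [
        HomeodomainHit(protein_id=protein_id, hd_start=int(i), score=float(s))
        for i, s in enumerate(ws)
        if s >= threshold_bits
    ]
    hits.sort(key=lambda h: (-h.score, h.hd_start))
    return hits


def calibrate_threshold(
    profile: HomeodomainProfile,
    n_peptides: int = 1000,
    peptide_length: int = 200,
    quantile: float = 0.999,
    seed: int = 2016,
) -> float:
    """Empirical null threshold: the ``quantile`` of the per-peptide *best*
    window score over seeded random peptides drawn uniformly from the
    20-letter alphabet.  Calibrating on the per-peptide maximum controls the
    probability that a random peptide yields any hit at all (a familywise
    null), which is what an e-value-gated search controls."""
    rng = np.random.default_rng(seed)
    best = np.empty(n_peptides)
    for i in range(n_peptides):
        pep = "".join(AA20[j] for j in rng.integers(0, 20, size=peptide_length))
        best[i] = window_scores(pep, profile).max()
    return float(np.quantile(best, quantile))


def default_profile() -> HomeodomainProfile:
    """Profile trained on the packaged consensus homeodomain alignment."""
    from .synthetic import consensus_alignment

    return build_profile([r.residues for r in consensus_alignment()])
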