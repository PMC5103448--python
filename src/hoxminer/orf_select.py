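"""Coding-sequence identification: six-frame ORF enumeration and evidence-vote
CDS selection.

The protocol mirrors empirical homology-based CDS prediction for de novo
transcriptomes: every start-to-stop open reading frame longer than 50 amino
acids is translated, each candidate is scored positive/negative by a set of
independent evidence sources, and per transcript the unique candidate with
the highest number of positive evidences is selected.

Conventions
-----------
* ">50 aa" is strict: a 50-residue peptide is rejected, a 51-residue one kept.
* Peptide length counts the initial Met and excludes the stop codon; the
  nucleotide span of a candidate *includes* its stop codon, so
  ``aa_length == (nt_end - nt_start) / 3 - 1``.
* Per frame, only the longest ORF per stop codon is emitted (the first ATG
  after the previous in-frame stop); nested starts are not re-emitted.
* An ORF must end at a stop codon; open ends at the transcript boundary are
  not emitted as partial CDS.
* Coordinates are 0-based half-open on the forward strand for all six
  frames.  Frame +k reads the forward strand from offset k-1; frame -k reads
  the reverse complement from offset k-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import pandas as pd

from .formats import SeqRecord

_CODON_TABLE = {}  # filled below from the standard genetic code
_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

FRAME_ORDER = (1, 2, 3, -1, -2, -3)


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)


_build_codon_table()

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing N (or other ambiguity)
    becomes X.  Stop codons are the caller's business."""
    return _CODON_TABLE.get(codon, "X")


def translate_frame(seq: str, offset: int = 0) -> str:
    """Translate ``seq`` from ``offset`` to the last whole codon; stops as '*'."""
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("*" if codon in _STOP_CODONS else translate_codon(codon))
    return "".join(out)


@dataclass(frozen=True)
class OrfCandidate:
    """A maximal start-to-stop ORF.  ``nt_start``/``nt_end`` are forward-strand
    coordinates spanning ATG..stop inclusive."""

    transcript_id: str
    index: int  # enumeration order within the transcript
    frame: int  # +1..+3 forward, -1..-3 reverse
    nt_start: int
    nt_end: int
    peptide: str  # no stop; begins with M

    @property
    def aa_length(self) -> int:
        return len(self.peptide)

    @property
    def candidate_id(self) -> str:
        return f"{self.transcript_id}.orf{self.index}"

    def __post_init__(self) -> None:
        assert (self.nt_end - self.nt_start) % 3 == 0
        assert self.aa_length == (self.nt_end - self.nt_start) // 3 - 1
        assert self.peptide.startswith("M")


def enumerate_orfs(
    transcript: SeqRecord | tuple[str, str],
    min_len_exclusive: int = 50,
) -> list[OrfCandidate]:
    """All six-frame ATG-to-stop ORFs with more than ``min_len_exclusive``
    residues, longest-per-stop within each frame.

    Accepts a :class:`SeqRecord` or an ``(id, sequence)`` pair.  Codons
    containing N translate to X; stop detection is unaffected.
    """
    if isinstance(transcript, SeqRecord):
        tid, seq = transcript.id, transcript.residues
    else:
        tid, seq = transcript
    seq = seq.upper()
    L = len(seq)
    found: list[tuple[int, int, int, str]] = []  # (frame, fwd_start, fwd_end, peptide)

    for strand, s in ((1, seq), (-1, reverse_complement(seq))):
        for off in range(3):
            frame = strand * (off + 1)
            atg: int | None = None  # position (in s) of the first ATG of the open ORF
            for i in range(off, L - 2, 3):
                codon = s[i : i + 3]
                if codon in _STOP_CODONS:
                    if atg is not None:
                        aa_len = (i - atg) // 3
                        if aa_len > min_len_exclusive:
                            pep = "".join(
                                translate_codon(s[j : j + 3]) for j in range(atg, i, 3)
                            )
                            if strand == 1:
                                fwd = (atg, i + 3)
                            else:
                                fwd = (L - (i + 3), L - atg)
                            found.append((frame, fwd[0], fwd[1], pep))
                        atg = None
                elif atg is None and codon == "ATG":
                    atg = i

    frame_rank = {f: r for r, f in enumerate(FRAME_ORDER)}
    found.sort(key=lambda t: (frame_rank[t[0]], t[1]))
    return [
        OrfCandidate(transcript_id=tid, index=k, frame=f, nt_start=a, nt_end=b, peptide=p)
        for k, (f, a, b, p) in enumerate(found)
    ]


# ---------------------------------------------------------------------------
# Evidence sources and the vote
# ---------------------------------------------------------------------------


class EvidenceSource(Protocol):
    """A pluggable yes/no oracle over candidate peptides, standing in for one
    reference-library similarity search."""

    name: str

    def is_positive(self, candidate: OrfCandidate) -> bool: ...


class ProfileEvidenceSource:
    """Positive iff the homeodomain profile scan yields a hit at or above the
    threshold."""

    def __init__(self, profile, threshold_bits: float, name: str = "hd_profile"):
        self.name = name
        self.profile = profile
        self.threshold_bits = threshold_bits

    def is_positive(self, candidate: OrfCandidate) -> bool:
        from .hdscan import scan

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return bool(scan(candidate.peptide, self.profile, self.threshold_bits))


class KmerEvidenceSource:
    """Positive iff the candidate shares at least ``min_shared`` distinct
    k-mers with a reference peptide set."""

    def __init__(
        self,
        reference_peptides: Iterable[str],
        k: int = 5,
        min_shared: int = 5,
        name: str = "ref_kmer",
    ):
        self.name = name
        self.k = k
        self.min_shared = min_shared
        self._kmers: set[str] = set()
        for pep in reference_peptides:
            for i in range(len(pep) - k + 1):
                self._kmers.add(pep[i : i + k])

    def is_positive(self, candidate: OrfCandidate) -> bool:
        pep = candidate.peptide
        shared = {
            pep[i : i + self.k]
            for i in range(len(pep) - self.k + 1)
            if pep[i : i + self.k] in self._kmers
        }
        return len(shared) >= self.min_shared


class ExternalHitsSource:
    """Positive iff an external hit table row for the candidate id has
    e-value at or below the cutoff (default 1e-06, the conventional
    similarity-search gate)."""

    def __init__(self, hits: pd.DataFrame, evalue_max: float = 1e-6, name: str = "external"):
        self.name = name
        self.evalue_max = evalue_max
        self._positive: set[str] = set(
            hits.loc[hits["e_value"] <= evalue_max, "query_id"].astype(str)
        )
        self._all_ids: set[str] = set(hits["query_id"].astype(str))

    def warn_unknown(self, candidates: Sequence[OrfCandidate]) -> None:
        known = {c.candidate_id for c in candidates}
        unknown = self._all_ids - known
        if unknown:
            warnings.warn(
                f"external hit table references {len(unknown)} unknown candidate "
                f"id(s), e.g. {sorted(unknown)[:3]}; rows ignored",
                stacklevel=2,
            )

    def is_positive(self, candidate: OrfCandidate) -> bool:
        return candidate.candidate_id in self._positive


def collect_evidence(
    candidates: Sequence[OrfCandidate], sources: Sequence[EvidenceSource]
) -> pd.DataFrame:
    """One row per candidate with a boolean column per source and the total
    ``evidence_count`` (number of positive sources)."""
    for src in sources:
        if isinstance(src, ExternalHitsSource):
            src.warn_unknown(candidates)
    rows = []
    for cand in candidates:
        row: dict = {
            "transcript_id": cand.transcript_id,
            "orf_index": cand.index,
            "candidate_id": cand.candidate_id,
        }
        count = 0
        for src in sources:
            pos = bool(src.is_positive(cand))
            row[src.name] = pos
            count += pos
        row["evidence_count"] = count
        rows.append(row)
    cols = ["transcript_id", "orf_index", "candidate_id"] + [s.name for s in sources] + [
        "evidence_count"
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class SelectedCds:
    candidate: OrfCandidate
    evidence_count: int
    zero_evidence: bool = False  # kept only under the keep_longest policy


def select_cds(
    candidates: Sequence[OrfCandidate],
    evidence: pd.DataFrame,
    keep_longest: bool = False,
) -> list[SelectedCds]:
    """Per transcript, the unique CDS with the most evidence.

    Ties break by longer peptide, then 5'-most forward-strand start, then
    frame order +1, +2, +3, -1, -2, -3.  Transcripts whose best count is zero
    are dropped unless ``keep_longest`` is set, in which case the longest ORF
    is kept and flagged.
    """
    counts = dict(zip(evidence["candidate_id"], evidence["evidence_count"]))
    missing = [c.candidate_id for c in candidates if c.candidate_id not in counts]
    if missing:
        raise ValueError(f"evidence table does not cover candidates {missing[:3]}")
    frame_rank = {f: r for r, f in enumerate(FRAME_ORDER)}
    by_transcript: dict[str, list[OrfCandidate]] = {}
    for cand in candidates:
        by_transcript.setdefault(cand.transcript_id, []).append(cand)

    out: list[SelectedCds] = []
    for tid in by_transcript:
        cands = by_transcript[tid]
        best = min(
            cands,
            key=lambda c: (
                -counts[c.candidate_id],
                -c.aa_length,
                c.nt_start,
                frame_rank[c.frame],
            ),
        )
        n = int(counts[best.candidate_id])
        if n > 0:
            out.append(SelectedCds(best, n))
        elif keep_longest:
            longest = min(
                cands, key=lambda c: (-c.aa_length, c.nt_start, frame_rank[c.frame])
            )
            out.append(SelectedCds(longest, 0, zero_evidence=True))
    return out


def selected_to_frame(selected: Sequence[SelectedCds]) -> pd.DataFrame:
    """Report table for selected CDS (1-based inclusive coordinates)."""
    rows = [
        {
            "transcript_id": s.candidate.transcript_id,
            "candidate_id": s.candidate.candidate_id,
            "frame": s.candidate.frame,
            "nt_start_1based": s.candidate.nt_start + 1,
            "nt_end_1based": s.candidate.nt_end,
            "aa_length": s.candidate.aa_length,
            "evidence_count": s.evidence_count,
            "zero_evidence": s.zero_evidence,
        }
        for s in selected
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "candidate_id",
            "frame",
            "nt_start_1based",
            "nt_end_1based",
            "aa_length",
            "evidence_count",
            "zero_evidence",
        ],
    )
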