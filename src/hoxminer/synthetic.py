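"""Synthetic transcriptomes with planted Hox/ParaHox genes and a truth table.

The simulator emulates an assembled mixed-stage transcriptome at the level
the mining pipeline consumes: each non-decoy transcript carries a single
true CDS (5' UTR + ATG..stop + 3' UTR on a uniformly chosen strand/frame)
whose peptide is a random N-terminal flank, a group-specific 60-residue
homeodomain, and a random C-terminal flank, with every diagnostic feature
the catalog declares for the group planted at its declared region/offset.
Decoy transcripts are random nucleotide sequences rejection-sampled to
contain no ATG-initiated ORF longer than 50 aa; duplicate transcripts carry
an exact copy of an already-emitted CDS under a new id; frameshifted
transcripts carry single-nucleotide indels (the homopolymer-type errors of
pyrosequencing reads) at recorded coordinates.

Group consensus homeodomains are fixed synthetic 60-mers built from a
shared Antp-like backbone with group-specific residues exactly at
catalog-diagnostic positions, so label recovery is well-posed by
construction.  Hox4, Hox5, and Antp intentionally share the backbone
unchanged: those groups are distinguished by flanking motifs (or not at
all), never by homeodomain residues.

Everything is a pure function of (spec, catalog, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import PREDICATES, DiagnosticFeature, MotifCatalog, default_catalog
from .formats import SeqRecord
from .orf_select import enumerate_orfs, reverse_complement, translate_frame

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Antp-like 60-residue backbone.  Positions 2-3 are basic and position 5 is
# non-basic so that the backbone alone satisfies no catalog predicate.
_BASE_HD = "RKRGQQTYTRYQTLELEKEFHFNRYLTRRRRIEIAHALCLTERQIKIWFQNRRMKWKKEN"

# Group-specific residues, keyed by 1-based homeodomain position.  Every
# override sits at a position some catalog feature declares (scored or
# placeholder) except the Post-1/Post-2/central-class tags, whose positions
# the catalog deliberately leaves open.
_HD_OVERRIDES: dict[str, dict[int, str]] = {
    "Hox1": {2: "S", 3: "S", 6: "M", 7: "S", 8: "W", 29: "M", 56: "T"},
    "Hox2": {2: "T", 4: "N", 5: "K", 24: "S", 58: "G", 59: "A"},
    "Hox3": {4: "T", 5: "R", 14: "W", 36: "A", 37: "L"},
    "Hox4": {},
    "Hox5": {},
    "Lox5": {45: "S"},
    "Antp": {},
    "Lox4": {46: "A"},
    "Lox2": {47: "V"},
    "Post2": {50: "W"},
    "Post1": {50: "M"},
    "Gsx": {53: "S"},
    "Xlox": {54: "S"},
    "Cdx": {57: "A"},
}

DECOY = "DECOY"


def consensus_homeodomains() -> dict[str, str]:
    """The fixed 60-mer consensus homeodomain of every default label."""
    assert len(_BASE_HD) == 60
    out = {}
    for group, overrides in _HD_OVERRIDES.items():
        hd = list(_BASE_HD)
        for pos, aa in overrides.items():
            hd[pos - 1] = aa
        out[group] = "".join(hd)
    return out


def consensus_alignment() -> list[SeqRecord]:
    """Labeled, gap-free 60-column alignment of the consensus homeodomains —
    the packaged training set for profile building and signature discovery."""
    return [SeqRecord(id=g, residues=hd) for g, hd in consensus_homeodomains().items()]


@dataclass
class GeneratorSpec:
    """Conditions under which a synthetic transcriptome is generated.

    ``group_mix`` gives the exact number of planted transcripts per label.
    Duplicates add ``round(duplicate_rate * planted)`` exact peptide copies;
    decoys add ``round(decoy_rate * n_transcripts)`` random transcripts;
    ``round(frameshift_rate * planted)`` planted transcripts receive one
    single-nucleotide indel inside the CDS.
    """

    n_transcripts: int = 0
    group_mix: dict[str, int] = field(default_factory=dict)
    decoy_rate: float = 0.0
    duplicate_rate: float = 0.0
    hd_mut_rate: float = 0.0
    frameshift_rate: float = 0.0
    utr_len_range: tuple[int, int] = (30, 150)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("decoy_rate", "duplicate_rate", "hd_mut_rate", "frameshift_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(c < 0 for c in self.group_mix.values()):
            raise ValueError("group_mix counts must be non-negative")
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be non-negative")


@dataclass
class TruthRecord:
    transcript_id: str
    planted_group: str  # label or DECOY
    cds_start: int = -1  # 0-based half-open nt span including the stop codon
    cds_end: int = -1
    frame: int = 0
    hd_start_aa: int = -1  # 0-based peptide offset of homeodomain position 1
    peptide: str = ""
    duplicate_of: Optional[str] = None
    frameshift_positions: tuple[int, ...] = ()


TRUTH_COLUMNS = [
    "transcript_id",
    "planted_group",
    "cds_start",
    "cds_end",
    "frame",
    "hd_start_aa",
    "peptide",
    "duplicate_of",
    "frameshift_positions",
]


def truth_to_frame(records: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "planted_group": r.planted_group,
                "cds_start": r.cds_start,
                "cds_end": r.cds_end,
                "frame": r.frame,
                "hd_start_aa": r.hd_start_aa,
                "peptide": r.peptide,
                "duplicate_of": r.duplicate_of if r.duplicate_of else "",
                "frameshift_positions": ",".join(map(str, r.frameshift_positions)),
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


def _exact_patterns(catalog: MotifCatalog) -> list[str]:
    return [f.pattern for f in catalog.features if f.pattern]


def _contains_foreign_pattern(flank: str, patterns: list[str], planted: list[tuple[int, str]]) -> bool:
    """True if the flank contains a catalog pattern anywhere other than a
    planted span."""
    planted_spans = {(start, start + len(p)) for start, p in planted}
    for pat in patterns:
        start = flank.find(pat)
        while start != -1:
            if (start, start + len(pat)) not in planted_spans:
                return True
            start = flank.find(pat, start + 1)
    return False


def generate_protein(
    group: str,
    catalog: MotifCatalog,
    spec: GeneratorSpec,
    seed: int,
) -> tuple[str, TruthRecord]:
    """A peptide for ``group``: M + random N-flank + consensus homeodomain
    (substituted at ``hd_mut_rate`` outside the group's catalog-diagnostic
    positions) + random C-flank, with every non-placeholder feature of the
    group planted at its declared region/offset.

    Flanks are rejection-sampled so no catalog motif occurs outside its
    planted location.  Deterministic for fixed (group, catalog, spec, seed).
    """
    if group not in catalog.classes:
        raise KeyError(f"unknown group {group!r}")
    if group not in _HD_OVERRIDES:
        raise KeyError(f"no consensus homeodomain for group {group!r}")
    rng = np.random.default_rng(seed)
    consensus = consensus_homeodomains()[group]
    protected = {p - 1 for p in catalog.diagnostic_hd_positions(group)}

    hd = list(consensus)
    if spec.hd_mut_rate > 0:
        for i in range(60):
            if i in protected:
                continue
            if rng.random() < spec.hd_mut_rate:
                choices = AA20.replace(hd[i], "")
                hd[i] = choices[rng.integers(0, len(choices))]
    hd_str = "".join(hd)

    n_len = int(rng.integers(20, 61))
    c_len = int(rng.integers(15, 41))
    patterns = _exact_patterns(catalog)
    features = catalog.scored_features_of(group)
    # conflicting exact-offset plantings within one group are a hard error
    offsets_seen: set[tuple[str, int]] = set()
    for f in features:
        if f.pattern and f.offset is not None:
            key = (f.region, f.offset)
            if key in offsets_seen:
                raise ValueError(f"group {group}: two exact patterns at offset {f.offset}")
            offsets_seen.add(key)

    for _attempt in range(200):
        n_flank = list("M" + _random_peptide(rng, n_len - 1))
        c_flank = list(_random_peptide(rng, c_len))
        planted_n: list[tuple[int, str]] = []
        planted_c: list[tuple[int, str]] = []
        ok = True
        for feat in features:
            if not feat.pattern or feat.region == "HD_POS":
                continue
            plen = len(feat.pattern)
            if feat.region == "N_FLANK":
                # offset o < 0: first pattern residue sits |o| before HD pos 1
                if feat.offset is not None:
                    start = n_len + feat.offset
                else:
                    lo, hi = feat.window
                    hi = min(hi, -plen)  # pattern must end before the domain
                    lo = max(lo, -(n_len - 1))  # keep the initial Met intact
                    if lo > hi:
                        ok = False
                        break
                    start = n_len + int(rng.integers(lo, hi + 1))
                if start < 1 or start + plen > n_len:
                    ok = False
                    break
                n_flank[start : start + plen] = feat.pattern
                planted_n.append((start, feat.pattern))
            else:  # C_FLANK, offset o >= 1: first residue sits o after pos 60
                if feat.offset is not None:
                    start = feat.offset - 1
                else:
                    lo, hi = feat.window
                    hi = min(hi, c_len - plen + 1)
                    if lo > hi:
                        ok = False
                        break
                    start = int(rng.integers(lo, hi + 1)) - 1
                if start < 0 or start + plen > c_len:
                    ok = False
                    break
                c_flank[start : start + plen] = feat.pattern
                planted_c.append((start, feat.pattern))
        if not ok:
            continue
        n_str = "".join(n_flank)
        c_str = "".join(c_flank)
        if _contains_foreign_pattern(n_str, patterns, planted_n):
            continue
        if _contains_foreign_pattern(c_str, patterns, planted_c):
            continue
        break
    else:
        raise RuntimeError(f"could not place features for group {group}")

    # HD_POS features must hold on the (unmutated-at-diagnostic) consensus
    for feat in features:
        if feat.region != "HD_POS":
            continue
        if feat.pattern:
            for pos, aa in zip(feat.positions, feat.pattern):
                if hd_str[pos - 1] != aa:
                    raise ValueError(
                        f"group {group}: consensus violates pattern {feat.pattern!r} "
                        f"at homeodomain position {pos}"
                    )
        for pos, pred in zip(feat.positions, feat.predicates):
            if not PREDICATES[pred](hd_str[pos - 1]):
                raise ValueError(
                    f"group {group}: consensus violates predicate {pred!r} at "
                    f"homeodomain position {pos}"
                )

    peptide = n_str + hd_str + c_str
    truth = TruthRecord(
        transcript_id="", planted_group=group, hd_start_aa=n_len, peptide=peptide
    )
    return peptide, truth


_SYNONYMS: dict[str, list[str]] = {}


def _synonyms() -> dict[str, list[str]]:
    if not _SYNONYMS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _SYNONYMS.setdefault(aa, []).append(codon)
        for aa in _SYNONYMS:
            _SYNONYMS[aa].sort()
    return _SYNONYMS


_STOPS = ("TAA", "TAG", "TGA")


def reverse_translate(peptide: str, seed: int) -> str:
    """A standard-code CDS for ``peptide``: ATG-initiated, one stop codon,
    codons drawn uniformly among synonyms.  If the peptide does not start
    with M, a Met codon is prepended (so the output always translates to
    'M' + peptide.lstrip-nothing … i.e. M is added, not substituted)."""
    rng = np.random.default_rng(seed)
    syn = _synonyms()
    if not peptide.startswith("M"):
        peptide = "M" + peptide
    codons = []
    for aa in peptide:
        if aa not in syn:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        options = syn[aa]
        codons.append(options[rng.integers(0, len(options))])
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


NT = "ACGT"


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, size=length))


def _make_decoy(rng: np.random.Generator, length: int, min_len: int = 50) -> str:
    """Random nucleotide sequence with no ATG-initiated ORF > ``min_len`` aa
    in any of the six frames (rejection-sampled)."""
    for _ in range(1000):
        seq = _random_nt(rng, length)
        if not enumerate_orfs(("decoy", seq), min_len):
            return seq
    raise RuntimeError("decoy rejection sampling failed")


def _frame_of(cds_start: int, cds_end: int, L: int, strand: int) -> int:
    if strand == 1:
        return (cds_start % 3) + 1
    return -(((L - cds_end) % 3) + 1)


def generate_transcriptome(
    spec: GeneratorSpec, catalog: MotifCatalog | None = None
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Transcripts plus their truth table.

    Planted transcripts (per ``group_mix``) are 5' UTR + CDS + 3' UTR on a
    uniform strand; the last UTR codon before the CDS is forced to an
    in-frame stop so the planted ATG starts the maximal ORF of its frame.
    See :class:`GeneratorSpec` for how duplicate, decoy, and frameshift
    counts derive from the rates.
    """
    catalog = catalog or default_catalog()
    for g in spec.group_mix:
        if g not in catalog.classes:
            raise KeyError(f"group_mix references unknown label {g!r}")
    rng = np.random.default_rng(spec.seed)
    records: list[SeqRecord] = []
    truths: list[TruthRecord] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"tr{counter:05d}"

    def emit_planted(group: str, peptide: str, truth: TruthRecord,
                     duplicate_of: Optional[str] = None) -> None:
        tid = next_id()
        cds = reverse_translate(peptide, seed=int(rng.integers(0, 2**31)))
        lo, hi = spec.utr_len_range
        utr5 = _random_nt(rng, int(rng.integers(lo, hi + 1)))
        utr3 = _random_nt(rng, int(rng.integers(lo, hi + 1)))
        if len(utr5) >= 3:
            utr5 = utr5[:-3] + "TAA"  # in-frame stop right before the ATG
        fwd = utr5 + cds + utr3
        strand = 1 if rng.random() < 0.5 else -1
        L = len(fwd)
        cds_start, cds_end = len(utr5), len(utr5) + len(cds)
        if strand == -1:
            seq = reverse_complement(fwd)
            cds_start, cds_end = L - cds_end, L - cds_start
        else:
            seq = fwd
        truth.transcript_id = tid
        truth.cds_start, truth.cds_end = cds_start, cds_end
        truth.frame = _frame_of(cds_start, cds_end, L, strand)
        truth.duplicate_of = duplicate_of
        records.append(SeqRecord(id=tid, residues=seq))
        truths.append(truth)

    for group in spec.group_mix:
        for _ in range(spec.group_mix[group]):
            peptide, truth = generate_protein(
                group, catalog, spec, seed=int(rng.integers(0, 2**31))
            )
            emit_planted(group, peptide, truth)

    planted = list(truths)
    n_dup = round(spec.duplicate_rate * len(planted))
    if n_dup and not planted:
        raise ValueError("duplicate_rate > 0 requires a non-empty group_mix")
    for _ in range(n_dup):
        src = planted[int(rng.integers(0, len(planted)))]
        truth = TruthRecord(
            transcript_id="",
            planted_group=src.planted_group,
            hd_start_aa=src.hd_start_aa,
            peptide=src.peptide,
        )
        emit_planted(src.planted_group, src.peptide, truth, duplicate_of=src.transcript_id)

    n_fs = round(spec.frameshift_rate * len(planted))
    fs_targets = rng.choice(len(planted), size=n_fs, replace=False) if n_fs else []
    for idx in fs_targets:
        truth = truths[idx]
        rec = records[idx]
        pos = int(rng.integers(truth.cds_start + 3, truth.cds_end - 3))
        seq = rec.residues
        if rng.random() < 0.5:  # homopolymer-style single-nt insertion
            seq = seq[:pos] + NT[rng.integers(0, 4)] + seq[pos:]
        else:  # deletion
            seq = seq[:pos] + seq[pos + 1 :]
        records[idx] = SeqRecord(id=rec.id, residues=seq)
        truth.frameshift_positions = (pos,)

    n_decoy = round(spec.decoy_rate * spec.n_transcripts)
    for _ in range(n_decoy):
        tid = next_id()
        length = int(rng.integers(300, 601))
        seq = _make_decoy(rng, length)
        records.append(SeqRecord(id=tid, residues=seq))
        truths.append(TruthRecord(transcript_id=tid, planted_group=DECOY))

    return records, truth_to_frame(truths)


def check_truth_consistency(records: list[SeqRecord], truth: pd.DataFrame) -> None:
    """Verify that translating each recorded CDS span in its recorded frame
    reproduces the recorded peptide (frameshift-free rows only)."""
    seqs = {r.id: r.residues for r in records}
    for _, row in truth.iterrows():
        if row["planted_group"] == DECOY or row["frameshift_positions"]:
            continue
        seq = seqs[row["transcript_id"]]
        s, e, frame = int(row["cds_start"]), int(row["cds_end"]), int(row["frame"])
        if frame > 0:
            sub = seq[s:e]
        else:
            L = len(seq)
            sub = reverse_complement(seq)[L - e : L - s]
        aa = translate_frame(sub)
        if aa != row["peptide"] + "*":
            raise AssertionError(
                f"{row['transcript_id']}: CDS span does not translate to the "
                f"recorded peptide"
            )
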