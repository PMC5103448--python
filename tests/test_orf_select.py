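"""ORF enumeration against a brute-force oracle, the strict >50 aa filter,
and the evidence-vote selection rules."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_orfs
from conftest import random_transcript
from hoxminer import GeneratorSpec, enumerate_orfs, generate_transcriptome, select_cds
from hoxminer.formats import SeqRecord
from hoxminer.orf_select import (
    ExternalHitsSource,
    OrfCandidate,
    collect_evidence,
    reverse_complement,
)
from hoxminer.synthetic import reverse_translate


def _cds_for(aa_len: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    pep = "M" + "".join("ACDEFGHIKLNQSTVWY"[i] for i in rng.integers(0, 17, aa_len - 1))
    return reverse_translate(pep, seed=seed)


def test_planted_cds_recovered_with_truth_coordinates(catalog):
    spec = GeneratorSpec(
        n_transcripts=6,
        group_mix={"Hox1": 2, "Hox4": 2, "Gsx": 2},
        utr_len_range=(30, 60),
        seed=21,
    )
    records, truth = generate_transcriptome(spec, catalog)
    by_id = dict(zip(truth["transcript_id"], truth.to_dict("records")))
    for rec in records:
        cands = enumerate_orfs(rec, 50)
        row = by_id[rec.id]
        hits = [
            c
            for c in cands
            if (c.nt_start, c.nt_end, c.frame)
            == (row["cds_start"], row["cds_end"], row["frame"])
        ]
        assert len(hits) == 1
        assert hits[0].peptide == row["peptide"]


def test_filter_boundary_is_strictly_greater_than_50():
    # two ORFs planted in one transcript: exactly 50 aa and exactly 51 aa;
    # the spacer carries stop codons in all six frames so nothing reads through
    spacer = "TTAATTAATTAATTAATTAA"
    seq = spacer + _cds_for(50, 1) + spacer + _cds_for(51, 2) + spacer
    lengths = sorted(c.aa_length for c in enumerate_orfs(("t", seq), 50))
    assert 50 not in lengths
    assert 51 in lengths


def test_nested_atg_not_reemitted():
    # peptide with internal Met: only the outermost ORF of that stop appears
    pep = "M" + "A" * 30 + "M" + "A" * 40
    seq = reverse_translate(pep, seed=3)
    cands = enumerate_orfs(("t", seq), 50)
    assert len(cands) == 1
    assert cands[0].aa_length == len(pep)


def test_n_codons_translate_to_x_without_breaking_stops():
    pep = "M" + "K" * 60
    cds = reverse_translate(pep, seed=4)
    seq = cds[:9] + "N" + cds[10:]  # corrupt codon 4
    (cand,) = enumerate_orfs(("t", seq), 50)
    assert cand.peptide[3] == "X"
    assert cand.aa_length == 61


def test_short_sequence_yields_empty_list():
    assert enumerate_orfs(("t", "ATGTAA"), 50) == []


@pytest.mark.parametrize("seed", range(100))
def test_enumeration_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    seq = random_transcript(rng, length=2000, with_n=(seed % 5 == 0))
    got = {
        (c.frame, c.nt_start, c.nt_end, c.peptide) for c in enumerate_orfs(("t", seq), 50)
    }
    assert got == brute_force_orfs(seq, 50)


def test_aa_nt_coordinate_round_trip():
    rng = np.random.default_rng(6)
    seq = random_transcript(rng, length=1500)
    for cand in enumerate_orfs(("t", seq), 50):
        # residue p of the peptide maps to one codon on the forward strand
        for p in (0, cand.aa_length - 1):
            if cand.frame > 0:
                codon = seq[cand.nt_start + 3 * p : cand.nt_start + 3 * p + 3]
            else:
                rc = reverse_complement(seq)
                s = len(seq) - cand.nt_end
                codon = rc[s + 3 * p : s + 3 * p + 3]
            from hoxminer.orf_select import translate_codon

            assert translate_codon(codon) == cand.peptide[p]


class _FixedSource:
    def __init__(self, name, positives):
        self.name = name
        self._positives = positives

    def is_positive(self, candidate):
        return candidate.candidate_id in self._positives


def _candidate(tid, index, aa_len, nt_start=0, frame=1):
    pep = "M" + "A" * (aa_len - 1)
    return OrfCandidate(
        transcript_id=tid,
        index=index,
        frame=frame,
        nt_start=nt_start,
        nt_end=nt_start + 3 * (aa_len + 1),
        peptide=pep,
    )


def test_highest_evidence_count_wins():
    cands = [_candidate("t1", i, 60 + i, nt_start=100 * i) for i in range(3)]
    sources = [
        _FixedSource("s1", {"t1.orf0"}),
        _FixedSource("s2", {"t1.orf0", "t1.orf1"}),
        _FixedSource("s3", {"t1.orf0"}),
    ]
    ev = collect_evidence(cands, sources)
    assert list(ev["evidence_count"]) == [3, 1, 0]
    (sel,) = select_cds(cands, ev)
    assert sel.candidate.candidate_id == "t1.orf0"
    assert sel.evidence_count == 3


def test_tie_breaks_by_length_then_position_then_frame():
    a = _candidate("t1", 0, 80, nt_start=500)
    b = _candidate("t1", 1, 120, nt_start=900)
    ev = collect_evidence([a, b], [_FixedSource("s", {"t1.orf0", "t1.orf1"})])
    (sel,) = select_cds([a, b], ev)
    assert sel.candidate.aa_length == 120
    # equal lengths: 5'-most start wins
    c = _candidate("t2", 0, 80, nt_start=900)
    d = _candidate("t2", 1, 80, nt_start=300)
    ev = collect_evidence([c, d], [_FixedSource("s", {"t2.orf0", "t2.orf1"})])
    (sel,) = select_cds([c, d], ev)
    assert sel.candidate.nt_start == 300
    # equal length and start: forward frame order wins
    e = _candidate("t3", 0, 80, nt_start=60, frame=-2)
    f = _candidate("t3", 1, 80, nt_start=60, frame=2)
    ev = collect_evidence([e, f], [_FixedSource("s", set())])
    assert select_cds([e, f], ev) == []
    sel = select_cds([e, f], ev, keep_longest=True)[0]
    assert sel.candidate.frame == 2 and sel.zero_evidence


def test_zero_evidence_transcripts_dropped_by_default():
    cands = [_candidate("t1", 0, 70), _candidate("t2", 0, 90)]
    ev = collect_evidence(cands, [_FixedSource("s", {"t1.orf0"})])
    selected = select_cds(cands, ev)
    assert [s.candidate.transcript_id for s in selected] == ["t1"]
    kept = select_cds(cands, ev, keep_longest=True)
    assert len(kept) == 2
    flags = {s.candidate.transcript_id: s.zero_evidence for s in kept}
    assert flags == {"t1": False, "t2": True}


def test_at_most_one_cds_per_transcript(catalog):
    spec = GeneratorSpec(
        n_transcripts=8, group_mix={"Hox1": 4, "Cdx": 4}, utr_len_range=(60, 200), seed=30
    )
    records, _ = generate_transcriptome(spec, catalog)
    cands = [c for rec in records for c in enumerate_orfs(rec, 50)]
    ev = collect_evidence(cands, [_FixedSource("s", {c.candidate_id for c in cands})])
    selected = select_cds(cands, ev)
    tids = [s.candidate.transcript_id for s in selected]
    assert len(tids) == len(set(tids))


def test_external_evalue_gate_at_1e_06():
    cands = [_candidate("t1", 0, 70), _candidate("t2", 0, 70)]
    hits = pd.DataFrame(
        {
            "query_id": ["t1.orf0", "t2.orf0"],
            "source_name": ["blastp", "blastp"],
            "subject_id": ["ref1", "ref2"],
            "e_value": [1e-7, 1e-5],  # only the first passes the 1e-06 cutoff
            "bit_score": [55.0, 30.0],
        }
    )
    src = ExternalHitsSource(hits)
    ev = collect_evidence(cands, [src])
    gate = dict(zip(ev["candidate_id"], ev["evidence_count"]))
    assert gate == {"t1.orf0": 1, "t2.orf0": 0}


def test_external_unknown_ids_warn_and_are_ignored():
    cands = [_candidate("t1", 0, 70)]
    hits = pd.DataFrame(
        {
            "query_id": ["ghost.orf0"],
            "source_name": ["blastp"],
            "subject_id": ["r"],
            "e_value": [1e-9],
            "bit_score": [99.0],
        }
    )
    src = ExternalHitsSource(hits)
    with pytest.warns(UserWarning, match="unknown candidate"):
        ev = collect_evidence(cands, [src])
    assert list(ev["evidence_count"]) == [0]
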