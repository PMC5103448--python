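"""Independent brute-force reference implementations used to pin down the
behaviour of the production code.  Each oracle deliberately uses a different
algorithm from the module it checks."""

from __future__ import annotations

import numpy as np

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")

_CODON = {}


def _codon_table():
    if not _CODON:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON.update(standard_dna_table.forward_table)
    return _CODON


def brute_force_orfs(seq: str, min_len_exclusive: int = 50):
    """Every (frame, ATG, next-stop) triple, reduced to longest-per-stop.

    Returns a set of (frame, fwd_start, fwd_end, peptide) tuples on the
    forward strand, comparable with enumerate_orfs output.
    """
    table = _codon_table()
    seq = seq.upper()
    L = len(seq)
    out = set()
    for strand in (1, -1):
        s = seq if strand == 1 else seq.translate(_COMP)[::-1]
        for off in range(3):
            frame = strand * (off + 1)
            codon_starts = list(range(off, L - 2, 3))
            stops = [i for i in codon_starts if s[i : i + 3] in _STOPS]
            atgs = [i for i in codon_starts if s[i : i + 3] == "ATG"]
            # next stop strictly after each ATG
            best_atg_for_stop = {}
            for a in atgs:
                nxt = next((t for t in stops if t > a), None)
                if nxt is None:
                    continue
                if nxt not in best_atg_for_stop or a < best_atg_for_stop[nxt]:
                    best_atg_for_stop[nxt] = a
            for stop, a in best_atg_for_stop.items():
                aa_len = (stop - a) // 3
                if aa_len <= min_len_exclusive:
                    continue
                pep = "".join(
                    "X"
                    if s[j : j + 3] not in table
                    else table[s[j : j + 3]]
                    for j in range(a, stop, 3)
                )
                if strand == 1:
                    out.add((frame, a, stop + 3, pep))
                else:
                    out.add((frame, L - (stop + 3), L - a, pep))
    return out


def window_score_oracle(peptide: str, profile) -> list[float]:
    """Plain per-window, per-position summation of profile scores."""
    from hoxminer.hdscan import _AA_INDEX

    out = []
    for start in range(len(peptide) - 60 + 1):
        total = 0.0
        for i in range(60):
            ch = peptide[start + i]
            if ch in _AA_INDEX:
                total += profile.scores[i, _AA_INDEX[ch]]
            else:
                total += profile.unseen[i]
        out.append(total)
    return out


def global_alignment_score_oracle(a: str, b: str) -> int:
    """Needleman-Wunsch score with match=1, mismatch=0, gap=-1."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    dp[:, 0] = -np.arange(n + 1)
    dp[0, :] = -np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = dp[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
            dp[i, j] = max(match, dp[i - 1, j] - 1, dp[i, j - 1] - 1)
    return int(dp[n, m])


def local_affine_score_oracle(a: str, b: str, matrix, open_gap=-11, extend_gap=-1):
    """Smith-Waterman-Gotoh best score under an affine gap model.

    ``open_gap`` is the score of a gap of length 1 (as in the production
    aligner), ``extend_gap`` each additional gapped column.
    """
    n, m = len(a), len(b)
    NEG = -10**9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG, dtype=float)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG, dtype=float)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + open_gap, E[i, j - 1] + extend_gap)
            F[i, j] = max(H[i - 1, j] + open_gap, F[i - 1, j] + extend_gap)
            sub = matrix[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def column_signature_oracle(sequences, labels, tau_in, tau_out):
    """Direct per-column frequency tabulation of diagnostic calls.

    Returns a set of (column, label, residue) triples.
    """
    width = len(sequences[0])
    label_set = sorted(set(labels))
    out = set()
    for j in range(width):
        for g in label_set:
            col = [s[j] for s, lb in zip(sequences, labels) if lb == g]
            ungapped = [c for c in col if c != "-"]
            if len(ungapped) < 2 or len(ungapped) * 2 <= len(col):
                continue
            for residue in set(ungapped):
                if residue == "X":
                    continue
                f_in = ungapped.count(residue) / len(ungapped)
                if f_in < tau_in:
                    continue
                worst = 0.0
                for other in label_set:
                    if other == g:
                        continue
                    ocol = [
                        s[j]
                        for s, lb in zip(sequences, labels)
                        if lb == other and s[j] != "-"
                    ]
                    if ocol:
                        worst = max(worst, ocol.count(residue) / len(ocol))
                if worst <= tau_out:
                    out.add((j, g, residue))
    return out
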