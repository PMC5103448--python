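"""Signature-residue discovery from a labeled multiple alignment.

A signature residue is one shared at a position by the orthologs of one
paralog group and rare or absent in all other groups.  Operationally,
column j is diagnostic for label g with residue a iff the gap-excluded
frequency of a within g is at least ``tau_in`` and its frequency in every
other label is at most ``tau_out``.  Columns with a gap majority (or fewer
than two ungapped residues) in g are uncallable for g.  Maximal runs of
adjacent calls for one label merge into exact motifs, closing the loop to
the classifier: the emitted features are catalog-ready and can fill the
placeholder slots the default catalog leaves open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .catalog import DiagnosticFeature


@dataclass(frozen=True)
class LabeledMsa:
    """Equal-length aligned sequences ('-' gaps) with one label each."""

    sequences: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError("one label per sequence required")
        widths = {len(s) for s in self.sequences}
        if len(widths) > 1:
            raise ValueError(f"aligned sequences have unequal lengths {sorted(widths)}")
        if len(set(self.labels)) < 2:
            raise ValueError("signature discovery needs at least two labels")

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    @property
    def label_set(self) -> list[str]:
        seen: list[str] = []
        for lb in self.labels:
            if lb not in seen:
                seen.append(lb)
        return seen

    def column(self, j: int, label: str) -> list[str]:
        return [
            s[j] for s, lb in zip(self.sequences, self.labels) if lb == label
        ]


@dataclass(frozen=True)
class SignatureCall:
    column: int  # 0-based alignment column
    label: str
    residue: str
    freq_in: float
    max_freq_out: float


def column_signatures(
    msa: LabeledMsa, tau_in: float = 0.9, tau_out: float = 0.1
) -> list[SignatureCall]:
    """All (column, label, residue) diagnostic calls (see module docstring).

    ``tau_in`` must exceed 0.5 and ``tau_out`` must stay below 0.5 so a call
    is unambiguous within its label and rare outside it.
    """
    if not 0.5 < tau_in <= 1.0:
        raise ValueError(f"tau_in must be in (0.5, 1], got {tau_in}")
    if not 0.0 <= tau_out < 0.5:
        raise ValueError(f"tau_out must be in [0, 0.5), got {tau_out}")
    labels = msa.label_set
    calls: list[SignatureCall] = []
    for j in range(msa.width):
        freq: dict[str, dict[str, float]] = {}
        callable_for: dict[str, bool] = {}
        for lb in labels:
            col = msa.column(j, lb)
            ungapped = [c for c in col if c != "-"]
            callable_for[lb] = len(ungapped) >= 2 and len(ungapped) * 2 > len(col)
            n = len(ungapped)
            counts: dict[str, float] = {}
            for c in ungapped:
                counts[c] = counts.get(c, 0) + 1
            freq[lb] = {c: k / n for c, k in counts.items()} if n else {}
        for lb in labels:
            if not callable_for[lb]:
                continue
            for residue, f_in in freq[lb].items():
                if residue == "X" or f_in < tau_in:
                    continue
                f_out = max(
                    (freq[other].get(residue, 0.0) for other in labels if other != lb),
                    default=0.0,
                )
                if f_out <= tau_out:
                    calls.append(
                        SignatureCall(
                            column=j,
                            label=lb,
                            residue=residue,
                            freq_in=f_in,
                            max_freq_out=f_out,
                        )
                    )
    calls.sort(key=lambda c: (c.column, c.label))
    return calls


def merge_motifs(calls: Sequence[SignatureCall]) -> list[DiagnosticFeature]:
    """Merge maximal runs of adjacent same-label calls into exact-pattern
    features; singletons become length-1 features.

    Positions are 1-based alignment columns; when the alignment is a
    homeodomain-anchored 60-column block they coincide with homeodomain
    positions 1-60 and the features drop straight into a catalog.
    """
    by_label: dict[str, list[SignatureCall]] = {}
    for c in calls:
        by_label.setdefault(c.label, []).append(c)
    features: list[DiagnosticFeature] = []
    for label in sorted(by_label):
        run: list[SignatureCall] = []
        ordered = sorted(by_label[label], key=lambda c: c.column)

        def flush() -> None:
            if not run:
                return
            features.append(
                DiagnosticFeature(
                    group=label,
                    region="HD_POS",
                    positions=tuple(c.column + 1 for c in run),
                    pattern="".join(c.residue for c in run),
                    weight=1.0,
                    scope="lophotrochozoan",
                    note="discovered signature",
                )
            )
            run.clear()

        for c in ordered:
            if run and c.column == run[-1].column + 1:
                run.append(c)
            elif run and c.column == run[-1].column:
                # two residues called at one column cannot share a motif
                flush()
                run.append(c)
            else:
                flush()
                run.append(c)
        flush()
    return features
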