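# Methods

## The mining protocol

`hoxminer` re-implements, as a tested library, the in-silico protocol used to
mine Hox and ParaHox homeobox genes out of de novo transcriptome assemblies
of non-model animals (the motivating use case is molluscan mixed-stage
transcriptomes). The stages, in order:

1. **ORF enumeration** — every start-to-stop open reading frame in all six
   frames, under the standard genetic code, strictly longer than 50 amino
   acids. The bound is exclusive on purpose: a 50-residue peptide fails, a
   51-residue one passes. Within a frame only the longest ORF per stop codon
   is emitted (the first ATG after the previous in-frame stop); an ORF must
   end at a stop codon, so open-ended partial CDS at transcript boundaries
   are not emitted. Codons containing N translate to X and never count as
   stops. Peptide length includes the initial Met and excludes the stop;
   the nucleotide span of a candidate includes the stop codon.
2. **Evidence vote** — each candidate is scored positive/negative by
   independent evidence sources and the unique candidate per transcript
   with the highest number of positives is selected. Ties break by longer
   peptide, then 5'-most forward-strand start, then frame order
   +1, +2, +3, -1, -2, -3. Transcripts with zero positive evidence are
   dropped by default (`keep_longest` retains and flags the longest ORF
   instead). Three sources are built in: a homeodomain-profile scan, a
   shared-k-mer test against the packaged consensus homeodomain set
   (k = 5, ≥ 5 distinct shared k-mers), and an external hit table gated at
   e-value ≤ 1e-06 — the last lets users plug in real blastp/hmmsearch/
   rps-blast output, which this package deliberately does not run.
3. **Redundancy removal** — proteins are clustered at 100 % identity,
   where identity is matches divided by alignment columns (gap columns
   included) on the optimal global alignment with match = 1, mismatch = 0
   and unit gap penalty. Because that definition is ambiguous for
   substrings, two modes are exposed: `exact` (default; string equality)
   and `containment` (a peptide that is a contiguous substring of a longer
   member joins its cluster). Representative = longest member, ties by
   lexicographic id.
4. **Homeodomain localisation** — a 60-column position-specific scoring
   profile scanned over every window of each non-redundant protein.
5. **Paralog classification** — diagnostic residues and motifs, anchored
   to homeodomain coordinates, vote per label.
6. **Reporting** — per-stage counts (transcripts, candidate ORFs, selected
   CDS, non-redundant proteins, homeodomain hits, classified /
   ambiguous / unclassified), plus a per-transcript truth evaluation when
   a simulator truth table is supplied.

Coordinates are 0-based half-open internally and 1-based inclusive in every
written report. Homeodomain positions are numbered 1–60; flank offsets
count away from the domain (-1 immediately before position 1, +1
immediately after position 60).

## Profile scoring and threshold calibration

With Laplace pseudocount `c` (default 1), per-column gap-excluded depth
`N_j`, and background `q_a` (default uniform 0.05):

    score_j(a) = log2( ((count_j(a) + c) / (N_j + 20 c)) / q_a )   [bits]

A window score is the sum of its 60 per-position scores; X and other
non-standard letters take the unobserved-residue score of the column under
the mean background. The default acceptance threshold is the 99.9th
percentile of the *per-peptide maximum* window score over 1,000 seeded
random 200-aa peptides. Calibrating on the per-peptide maximum rather than
on pooled window scores controls the probability that a random peptide
produces any hit at all — the offline analogue of the e-value gate an
online similarity search would provide — and makes a random 200-residue
peptide hit-free in ≥ 99.9 % of trials by construction. Planted consensus
domains score ≈ 160–190 bits against the packaged profile versus a null
around -10 bits, so the margin is enormous and the threshold is not
delicate.

## The diagnostic catalog and the classifier

The label set is the ancestral lophotrochozoan toolkit: 11 Hox paralog
groups (Hox1, Hox2, Hox3, Hox4, Hox5, Lox5, Antp, Lox4, Lox2, Post2,
Post1) and 3 ParaHox genes (Gsx, Xlox, Cdx). The default catalog contains
exactly the signatures whose residues are printed in the literature this
protocol operationalises:

| group | feature |
|---|---|
| Hox1 | non-basic residues (not K/R/H) at homeodomain positions 2–3 |
| Hox2, Hox3 | non-basic DNA-contacting residue at position 4 between basic residues at 3 and 5 |
| Hox3 | lophotrochozoan "AL" at positions 36–37 (**required**, see below) |
| Hox4, Hox5 | hexapeptide "YPWM" in the N-terminal flank (window -60..-1) |
| Hox4 | "LPNTK" in the C-terminal flank (window +1..+30) |
| Hox5 | molluscan "HIAKNM" anchored at offset +1 |
| Gsx | lophotrochozoan "LRTCD" in the C-terminal flank |

Signatures that are *localised* but not printed (e.g. the Hox1 motif at
positions 6–8, the Hox2 singles at 2/24/58–59, the Lox5/Ubd-A
parapeptides, the Antp Hox-PBC region, Post-1/Post-2 residues, Xlox/Cdx
peptides) ship as inert placeholders: empty pattern, weight 0, excluded
from scoring until the user fills them — typically from
`hoxminer discover` output on their own reference alignment. This is a
deliberate anti-fabrication stance: the package never invents residues.

Scoring: each matched feature contributes its weight (default 1.0); a
missing *required* feature zeroes the group; the argmax is assigned if it
reaches `min_score` (default 1.0) and leads the runner-up by `min_margin`
(default 1.0); ties and sub-threshold peptides return AMBIGUOUS with the
candidate set; peptides without a homeodomain hit are UNCLASSIFIED.

One feature is marked required: the Hox3 "AL" motif. Hox2 and Hox3 share
their only other scored feature (the position-4 predicate), so without a
required AL a genuine Hox2 peptide would always tie Hox2/Hox3. Treating
the lophotrochozoan AL as obligatory for Hox3 — within a classifier whose
whole label set is the lophotrochozoan toolkit — separates the two groups
in both directions while leaving the deliberate Hox4/Hox5 ambiguity under
YPWM-alone untouched.

## The synthetic transcriptome generator

The generator exists so every downstream stage is testable without
external data; it emulates exactly the structure the pipeline assumes.
Per planted gene: peptide = Met + random N-flank (20–60 aa) +
group-consensus homeodomain + random C-flank (15–40 aa), with every
non-placeholder catalog feature planted at its declared region/offset and
flanks rejection-sampled so no catalog motif appears anywhere else.
Homeodomain substitutions are applied per position at `hd_mut_rate`, never
at the group's catalog-declared positions. The CDS is a uniform-synonym
reverse translation; the transcript is 5' UTR + CDS + 3' UTR (UTR lengths
uniform in 30–150 nt) on a uniformly chosen strand, with the UTR codon
immediately before the ATG forced to an in-frame stop so the planted ATG
heads the maximal ORF of its frame. Decoys are random nucleotide
sequences (300–600 nt) rejection-sampled to contain no ORF > 50 aa;
duplicates are exact peptide copies under new transcript ids and fresh
UTRs; frameshifted transcripts carry one single-nucleotide indel inside
the CDS at a recorded coordinate, modelling the homopolymer errors of
pyrosequencing. Counts: planted = Σ group_mix; duplicates =
round(duplicate_rate × planted); decoys = round(decoy_rate ×
n_transcripts); frameshifts = round(frameshift_rate × planted). The
generator is a pure function of (spec, catalog, seed).

Group consensus homeodomains are fixed synthetic 60-mers: a shared
Antp-like backbone with group-specific residues exactly at
catalog-declared positions (Hox4, Hox5 and Antp keep the backbone
unchanged — those groups genuinely carry no homeodomain-internal
signature and are separated by flanking motifs or not at all). The
backbone has basic residues at positions 2–3 and a non-basic position 5,
so it satisfies no catalog predicate by accident.

What the generator does *not* emulate — and therefore what passing tests
do not establish about real data: sequencing noise and coverage variation,
chimeric and fragmented assemblies beyond single indels, alternative
isoforms, real homeodomain divergence structure (real paralog groups
differ at many more positions, with correlated substitutions), UTR
composition bias, and genuinely novel lineage-specific motifs. Recovery
rates measured here characterise the pipeline's mechanics, not its
sensitivity on real transcriptomes.

## Signature discovery

Column j of a labeled alignment is diagnostic for label g with residue a
iff the gap-excluded frequency of a within g is ≥ `tau_in` (default 0.9)
and its frequency in every other label is ≤ `tau_out` (default 0.1);
columns with a gap majority or fewer than two ungapped residues in g are
uncallable for g. Whether outgroup absence should be strict
(`tau_out = 0`) is exposed as a parameter rather than decided. Maximal
runs of adjacent same-label calls merge into exact motifs; positions are
1-based alignment columns and coincide with homeodomain positions on a
60-column domain-anchored block, so the output drops straight into a
catalog. Raising `tau_in` or lowering `tau_out` never adds a call.

## Marker recovery (completeness)

Each marker is Smith-Waterman-aligned (BLOSUM62, gap open -11 / extend -1)
against every protein; coverage is the fraction of marker residues inside
the aligned region and identity is identical columns over alignment
columns. A marker is *complete* if exactly one protein reaches coverage
≥ 0.9 at identity ≥ 0.4, *duplicated* if more than one does, *fragmented*
if the best qualifying hit covers ≥ 0.3 but < 0.9, else *missing*;
completeness % = 100 × complete / total. The category semantics follow
the C/D/F/M convention of single-copy-ortholog benchmarks; the numeric
thresholds are this package's own documented defaults (the benchmark
tools' trained, per-family cutoffs are out of scope), and all three are
configurable.

## Numerical and degenerate-input choices

- Tie-breaks are total and documented everywhere a ranking exists
  (selection, cluster representatives, hit ordering), so every report is
  byte-deterministic for fixed inputs and config.
- Empty FASTA files read as empty lists with a warning; duplicate ids and
  out-of-alphabet residues are hard errors naming the offender.
- Peptides shorter than 60 aa scan to an empty hit list with a warning,
  not an error; feature windows running past a peptide end are no-matches.
- `*` is accepted only as a terminal stop in amino-acid FASTA; X matches
  no pattern or predicate and takes the unseen-residue profile score.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit spec/CLI seeds.

## Problem sizes used by the test and acceptance suites

Oracle equivalences run on 100 random 2-kb transcripts (ORF enumeration),
20 random 140-aa peptides (window scoring), 20–25 random peptide pairs
(global and local alignment DP), and 10–20 random labeled MSAs
(discovery). Recovery is measured noise-free on one transcriptome with
all 14 labels and at `hd_mut_rate = 0.10` on 500 seeded proteins. The
empirical nulls use 1,000 random peptides/pairs. The whole suite runs in
well under a minute on one CPU; `scripts/acceptance.py` recomputes its
quantities in a few seconds.

## Known limitations

- Partial CDS at transcript edges (no stop codon) are never emitted, so
  genuinely truncated assemblies lose their genes at stage 1; the
  protocol's source material is silent on this and the strict reading was
  chosen.
- Frameshifted transcripts are expected to fail selection or classify
  poorly; no frameshift correction is attempted.
- Eight of the fourteen labels have placeholder-only catalogs by design
  and can never be assigned until the user supplies residues; they
  surface as AMBIGUOUS with an explicit `unassignable_groups` note.
- The homeodomain boundary convention (exactly 60 columns, positions
  1–60) is an assumption of this package, as is the per-peptide-maximum
  null calibration of the scan threshold.
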