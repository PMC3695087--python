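# Methods

## Model and assumptions

The screen assumes that serum-antibody selection enriches a phage-display
repertoire for peptides mimicking epitopes, and that *linear* epitopes —
and only those — leave a sequence-level footprint: families of abundant
7-mers locally similar to one stretch of the antigen. Two statistics
separate real antigens from the sea of chance matches:

- **initial score** = distinct matching peptides / protein length
  (stringent step), and
- **final score** = summed best-hit bit scores / protein length
  (exhaustive step),

both normalizing by length because the expected number of chance matches
to a protein is proportional to its length. Conformational and non-protein
epitopes are invisible to this screen by construction: a serum whose
response is purely conformational yields no shortlisted candidate, which
is the correct negative result rather than a failure mode.

## Alignment and statistics

Short peptides are aligned by an exhaustive ungapped local aligner: for
each peptide × protein pair, a per-diagonal maximum-subarray scan finds
the best-scoring window under the substitution matrix, which for a 7-mer
query is exactly the best ungapped HSP. No word seeding or other BLAST
heuristics are used — at 7 residues they save nothing and make results
depend on seeding internals. Ties are broken by smallest protein start,
then longest alignment, so output is deterministic.

Raw scores are converted with the ungapped Karlin–Altschul parameters of
the chosen matrix (BLOSUM62 default: λ = 0.3176, K = 0.134, H = 0.4012;
PAM30 selectable: λ = 0.3400, K = 0.2830, H = 1.7536). λ and H are
re-derived in the test suite by solving Σᵢⱼ pᵢpⱼ·exp(λsᵢⱼ) = 1 over the
Robinson–Robinson composition; K is taken from NCBI's tabulation (it has
no closed form). The two-sequence expectation uses edge-corrected
effective lengths, E = K·m′·n′·e^(−λS) with m′ = max(m − ℓ, 1),
n′ = max(n − ℓ, 1), ℓ = ln(K·m·n)/H.

A gapped mode (Biopython PairwiseAligner, open/extend penalties) exists
for completeness; the statistics constants then no longer strictly apply
and the defaults remain ungapped.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_step2` / `n_step1` | 500 / 120 | selected private peptides used in step 2 / step 1 |
| `step1_bit_threshold` | 18.5 bits | stringent per-hit cutoff for shortlisting (≈ a 5-residue identical stretch) |
| `min_matches` | 2 | distinct peptides required to shortlist a protein |
| `top_candidates` | 100 | shortlist size carried into step 2 |
| `step2_evalue_cutoff` | 10 | permissive inclusion cutoff for step-2 best hits |
| matrix | BLOSUM62 | PAM30 available for short-query-style scoring |

The 18.5-bit threshold is interpreted as a *bit* score (the scale on which
alignment viewers report "max score"); it is configurable, as is every
other threshold. Step-2 sums use bit scores, unweighted by peptide
abundance: each distinct peptide contributes its single best HSP once.

Display conventions of the report tables: initial scores are truncated at
4 decimals, final scores rendered to 7 significant figures; full precision
is kept internally and the identities final·length = Σ scores and
initial·length = matches hold exactly before display.

## Read processing

Reads are demultiplexed by exact match of the leading 4-base barcode (no
error correction), the 21-nt insert is cut at 1-based positions 29–49
(configurable, since the absolute offset depends on primer design),
identical DNA inserts are collapsed first, and unique inserts are
translated in frame 1 with TAG read as Q (heptapeptide libraries are
propagated in amber-suppressor hosts; a flag restores TAG-as-stop).
TAA/TGA or any ambiguous base inside the insert rejects the read: a 7-mer
identity pipeline cannot tolerate guessed residues. Quality scores are
ignored by default; an optional mean-Phred filter over the insert is
provided.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the screen relies on:
a shared heavy-tailed background (Zipf-distributed counts, shape 2.0,
1000 peptides) present in case and control; 50 sample-private background
peptides per sample; and a spiked family of 40 draws of mutated 7-mer
windows (per-residue mutation rate 0.1) of a planted epitope, private to
the case sample, with upper-tail counts so they survive top-N selection.
The proteome is 200 decoys drawn i.i.d. from Robinson–Robinson
frequencies, sanitized so no decoy contains any 5-mer of a planted
epitope — making rank-1 recovery a test of the method rather than an
accident of random homology — plus one 400-aa target.

Two generator defaults deserve their rationale:

- **The planted epitope is a fixed detectable sequence (NFTLPSWA), not a
  random 8-mer.** Detectability under this method is a property of the
  epitope itself: a 7-mer window must self-score ≥ ~34 raw (18.5 bits) to
  pass step 1, which windows composed of common low-scoring residues
  cannot do regardless of enrichment. A random epitope therefore sometimes
  builds an antigen the screen is *defined* not to see (the real-world
  analogue: sera whose epitopes are conformational produce no candidates).
  The default plants a canonically detectable linear epitope; setting
  `epitope_sequences=None` reverts to the random target's own residues to
  study exactly that failure mode.
- **Decoy lengths (350–450 aa) bracket the 400-aa target.** With an
  exhaustive aligner and the permissive step-2 E ≤ 10 cutoff, essentially
  every selected peptide contributes its best chance hit to every
  candidate, giving each protein a chance floor ≈ N·b(n)/n bits per
  residue that *grows as proteins get shorter* (b(n), the typical best-hit
  bit score, grows only logarithmically with n). Very short proteins can
  thus out-rank a genuine target on chance alone — visibly so in real
  screens, where short proteins with epitope-homologous stretches top the
  final table and the major-epitope score is needed to tell them apart.
  Recovery benchmarks are therefore run among length-comparable decoys,
  which isolates the spike signal from the length artifact.

Not modelled: phage amplification bias, panning-round kinetics, sequencing
error (reads are error-free so the FASTQ round trip is exact), codon-usage
bias beyond NNK-compatibility, and real-proteome homology structure
(decoys are i.i.d.). Passing the recovery tests therefore demonstrates the
ranking machinery, not performance against a real proteome's paralog
families.

## Numerical and design choices

- Single-linkage site clustering requires interval *overlap* (≥ 1 shared
  residue); adjacency does not merge. Each peptide's single best hit
  belongs to exactly one site, so site scores partition the candidate's
  summed score.
- Position profiles spread each hit's bits uniformly over its aligned
  residues, conserving total mass; this is one reasonable construction of
  a per-residue density, chosen for its conservation property.
- Tie-breaks everywhere are deterministic: descending score then ascending
  accession (candidates), descending count then lexicographic peptide
  (selection), smallest start then longest (alignments).
- "Shared with a control" means presence at any count — no abundance-ratio
  test — and isoforms are ranked independently, with no gene-level
  collapsing.
- Every generator stage draws from its own seed stream derived from the
  master seed, so each artifact is reproducible independently of call
  order; same seed ⇒ byte-identical FASTA/TSV/FASTQ outputs.

## Problem sizes

Default test and benchmark sizes — 200 decoys, ~70–90 selected peptides,
10 recovery seeds — run the full pipeline in seconds per seed; they are
chosen as the smallest sizes at which the selection, shortlist and
rescoring steps all operate non-trivially.

## Known limitations

- E-values use ideal ungapped constants, not composition-adjusted ones, so
  they differ from modern BLAST output in the second digit.
- The exhaustive aligner is more sensitive than heuristic bl2seq: it never
  misses a weak HSP, so step-2 sums include low-scoring chance hits that a
  seeded search would drop. Thresholds are calibrated on this package's own
  statistics and should not be transplanted from BLAST runs.
- No significance model for final scores is provided; ranking is ordinal,
  and the major-epitope score is the intended tie-breaker against
  short-protein chance inflation.
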