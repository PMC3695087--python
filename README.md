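# antigenscreen

Identify candidate protein antigens — and localize their linear epitopes —
from next-generation sequencing of random-heptapeptide phage-display
libraries panned on serum antibodies.

## The problem

Biopanning a random 7-mer phage library on the IgG of a serum sample and
sequencing the selected phage yields a *peptide profile* of the antibody
repertoire: tens of thousands of 7-mers, each with a read count. Peptides
mimicking a **linear epitope** of a protein antigen show up as families of
abundant, mutually similar sequences — but any single short peptide aligns
by chance to hundreds of proteins, so naive BLAST lookup cannot name the
antigen. The screen exploits two facts: a real antigen collects matches
from **many distinct** selected peptides, and chance matches accrue in
proportion to protein **length**.

## The method

For a sample of interest and designated controls (other immunogens, naive
animals, healthy donors):

1. **Select** the *N*₂ (default 500) most abundant peptides not present in
   any control sample; the head of that list (*N*₁ = 120) is the stringent
   subset.
2. **Step 1 — shortlist.** Align the 120 peptides against the protein
   database (ungapped Smith–Waterman with BLOSUM62 and Karlin–Altschul
   statistics, an exhaustive stand-in for blastp). Keep proteins matched by
   ≥ 2 distinct peptides at ≥ 18.5 bits and rank by the
   **initial score** = (distinct matching peptides) / (protein length),
   keeping the top 100.
3. **Step 2 — final ranking.** Align all 500 peptides against each
   shortlisted protein (the bl2seq surrogate); include each peptide's best
   hit when its two-sequence E-value ≤ 10, and rank by the
   **final score** = Σ(bit scores) / (protein length).
4. **Epitope localization.** Cluster the included hits on each candidate by
   interval overlap (single linkage). The **major-epitope score** is the
   summed bit scores at the strongest site; per-position profiles spread
   each hit's bits over its aligned residues.

Bit scores and E-values follow the standard ungapped Karlin–Altschul
formulas, bits = (λS − ln K)/ln 2 and E = K·m′·n′·e^(−λS), with NCBI's
constants for BLOSUM62 (λ = 0.3176, K = 0.134, H = 0.4012); PAM30 is
selectable.

A seeded synthetic-data generator (`antigenscreen.synthdata`) produces
decoy proteomes, epitope-spiked case/control repertoires, and the FASTQ
reads encoding them (4-base barcode, fixed flanks, insert at bases 29–49,
NNK codons, amber TAG→Q), with ground truth for every planted quantity.

## Worked example

```bash
python examples/simulate_and_rank.py
```

```
planted epitope NFTLPSWA at (220, 227) on TARGET_1; 22 distinct spiked peptides

rank  accession  length  matches  sum_scores  final_score  major_site
   1  TARGET_1      400       72       916.2     2.290597  [218,227]
```

The screen was run on a simulated serum: 200 decoy proteins plus one
400-aa target carrying the epitope NFTLPSWA at residues 220–227, with 40
spiked (epitope-derived, possibly mutated) peptides among the case
sample's private repertoire. The target is the only candidate surviving
the stringent step-1 shortlist; 72 of the selected peptides match it for a
summed 916.2 bits, a final score of 2.29 bits per residue, and the major
epitope site [218, 227] recovers the planted interval.

The same workflow is available from the shell:

```bash
sas simulate --seed 42 --out sim/
sas process  --reads sim/reads.fastq.gz --barcodes barcodes.tsv --out counts/
sas select   --sample counts/case.tsv --control counts/control.tsv --out selected.tsv
sas rank     --peptides selected.tsv --db sim/proteins.fasta --out candidates.tsv
```

See `examples/score_arithmetic.py` for the score formulas on report-style
inputs and `examples/epitope_mapping.py` for site clustering and position
profiles.

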