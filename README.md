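# dysbiota

Automated pathogenic-content estimation for gut-microbiome 16S data.

Typical metagenomic analyses summarize a microbiome's health through
α-diversity or the Firmicutes/Bacteroidetes ratio, then rely on manual
inspection of the bacteria whose abundances changed. `dysbiota` adds a
quantitative, automated layer on top: it annotates each differentially
abundant genus as *harmful* (explicitly disease-associated) or *harmless*
(conservatively, everything else) from a curated pathogen Genus–Species
table, cumulates the signed abundance variations into eubiotic and dysbiotic
frequencies, and tests whether one condition drives the microbiome towards a
more harmless composition than another. It is aimed at microbiome
bioinformaticians comparing disease states or treatments (e.g. arms of a
clinical study) from genus-level differential-abundance results.

## Method

Input is a table of differential genera with signed abundance variations
Δg = g₁ − g₂ (genus abundance in a condition minus its abundance in the
baseline); computing Δg — normalization and differential fitting — is the
user's task and deliberately out of scope. The stages are:

1. **Species-level classification** (optional). Query 16S sequences are
   classified against any reference FASTA + taxonomy with a Wang-style
   naive-Bayes k-mer classifier: sequences are decomposed into 8-mers counted
   present/absent per sequence, word probabilities are smoothed as
   (m(w)+0.5)/(M+1), queries are scored by the summed log probabilities over
   both orientations, and per-rank bootstrap confidences come from 100
   resamples of ⌊W/8⌋ words (default cutoff 80).
2. **Annotation.** With observed species available, a pathogen-listed genus
   is *harmful* iff at least one observed species is listed, *harmless* if
   species were observed but none is listed, and *discarded* when none of its
   species was observed; unlisted genera are conservatively harmless. Without
   species information, table membership of the genus decides.
3. **Impact cumulation.** Each genus contributes |Δg| to one quadrant of a
   Cartesian plane (harmless/harmful × increase/decrease). Eubiotic frequency
   = harmless increases + harmful decreases (quadrants 1+3); dysbiotic =
   the converse (2+4). Per condition pair this yields a Condition × Impact
   contingency table of frequency counts.
4. **Statistics.** Fisher's exact test on pairs of contingency rows, computed
   from log-space hypergeometric probabilities (accurate down to p ≈ 1e-300):
   one-sided ("the row condition is more associated with a harmless
   composition than the column condition") or two-sided against a control.

Companion measures: Shannon and inverse Simpson α-diversity, per-arm
Firmicutes/Bacteroidetes ratios (mean ± s.e.m.), and the low-abundance genus
filter (drop genera with >1 zero-count sample in a group or group sum < 5).

A fully seeded synthetic module generates reference sequences, reads,
pathogen tables and Δg tables with known ground truth, so the entire pipeline
is testable without external downloads.

## Worked example

Simulate a ground-truth dataset and run the full pipeline on it:

```bash
dysbiota simulate --n-genera 6 --sequence-length 800 \
    --reads-per-species 10 --seed 7 --outdir sim
dysbiota all --reference sim/reference.fasta --taxonomy sim/taxonomy.tsv \
    --queries sim/queries.fasta --delta-table sim/delta_table.tsv \
    --pathogen-table sim/pathogen_table.tsv --seed 7 --outdir out
```

which prints the cumulated Condition × Impact table:

```
              eubiotic  dysbiotic
case-control       102         88
```

meaning that, summed over the six genera, 102 units of |Δg| moved the
community in the eubiotic direction (harmless genera up, harmful genera
down) and 88 in the dysbiotic direction. This matches
`sim/expected_contingency.csv`, the generator's planted truth. `out/` also
contains per-read classifications with bootstrap confidences
(`assignments.tsv`), genus annotations, quadrant-level plot data and a PNG of
the Cartesian impact plane.

Fisher tests on a contingency table — here the published treatment-arm rows
of a rheumatoid-arthritis study (methotrexate, prednisone, untreated new
onset/chronic, vs healthy baseline):

```bash
dysbiota test --contingency study.csv --outdir test_out
```

```
                NORA-HLT  UCRA-HLT  MTX-HLT  Prednisone-HLT
NORA-HLT               1  1.09e-10        1          0.0491
UCRA-HLT               1         1        1               1
MTX-HLT        8.51e-185  3.95e-40        1         2.7e-88
Prednisone-HLT     0.962  2.99e-09        1               1
```

Entry (row, column) is the one-sided p-value that the row condition leads to
a more harmless-composed microbiome than the column condition: both
treatments are strongly more eubiotic than untreated chronic disease
(MTX vs UCRA p = 3.95e-40, Prednisone vs UCRA p = 2.99e-09).

The same stages are available as library functions
(`dysbiota.classify_batch`, `annotate_genera`, `cumulate_impact`,
`pairwise_condition_tests`, …); see the module docstrings and
`docs/methods.md`.

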