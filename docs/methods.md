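# Methods

## Model and assumptions

`dysbiota` treats a microbiome comparison as a two-step reduction. First,
every differentially abundant genus is given a binary functional label —
*harmful* if explicitly disease-associated in a curated pathogen
Genus–Species table, *harmless* otherwise. The harmless default is
deliberately conservative: absence of evidence of pathogenicity is treated as
harmlessness, not benefit, which biases the method against calling dysbiosis
rather than towards it. Second, the signed abundance variations Δg = g₁ − g₂
are folded, by label and sign, into two cumulated frequencies per condition
pair:

    eubiotic  = Σ Δg   over harmless genera with Δg > 0
              + Σ |Δg| over harmful genera with Δg < 0
    dysbiotic = Σ Δg   over harmful genera with Δg > 0
              + Σ |Δg| over harmless genera with Δg < 0

These form a Condition × Impact contingency table whose rows are compared
with Fisher's exact test. The underlying assumption is that |Δg| counts
(reads or normalized counts) are exchangeable units of "movement" of the
community, so their cumulated frequencies can be treated as counts in a 2×2
exact test. That is a modelling convenience, not a sampling model: p-values
should be read as a ranking of association strength, not literal error
probabilities, and the package accordingly applies no multiple-testing
correction by default (a Bonferroni helper is provided).

## Pathogen table

Pathogenicity knowledge enters only through the Genus–Species table
(tab-separated, `Genus<TAB>Species`). The bundled table is a small, curated
set of well-known human bacterial pathogens intended as a usable default and
test fixture; real analyses should supply a project-specific table via
`--pathogen-table`. Lookup is case-insensitive, whitespace-normalized, and
truncates names to the binomial, so strain decorations in reference
taxonomies do not break matching. Rows whose species does not begin with its
genus are rejected with a warning rather than silently re-homed — a curation
error should be visible. Inclusion is binary: frequency/pathogenicity grades
found in some source catalogues are not encoded because the downstream
statistic has no use for them.

## Classifier

The species-level classifier is a Wang-style naive Bayes over k-mer words,
chosen because it is fast, has no alignment step, and its bootstrap
confidence gives a principled per-rank acceptance rule.

* words: overlapping k-mers, k = 8 (configurable), counted present/absent per
  sequence; words containing ambiguous bases are skipped;
* conditional word probability for taxon t with M(t) training sequences:
  P(w|t) = (m(w,t) + 0.5) / (M(t) + 1), where m(w,t) is the number of t's
  sequences containing w;
* score: Σ log P(w|t) over the query's distinct words, maximized over
  species-level taxa; ties break to the lexicographically smallest species
  name for reproducibility;
* orientation: both strands are scored and the better one kept, since
  amplicon orientation is not guaranteed;
* bootstrap: 100 trials, each resampling ⌊W/8⌋ of the query's W distinct
  words with replacement; the confidence at a rank is the percentage of
  trials whose assignment agrees with the full-word assignment on the whole
  lineage prefix down to that rank. Prefix agreement (rather than
  name-at-rank agreement) guarantees confidences are non-increasing from
  domain to species even when a taxonomy reuses names across parents;
* cutoff: ranks below 80 are reported unclassified; species entering the
  genus → observed-species map must reach the cutoff at species rank.

Smoothing constants, bootstrap depth and subsample fraction follow the
classifier's de-facto conventions; all are configurable. A query with no
usable words (e.g. all-N) is unclassified at every rank with confidence 0.

## Annotation rules

In species mode (observed-species map available):

| genus in pathogen table | observed species       | label     |
|-------------------------|------------------------|-----------|
| yes                     | ≥1 listed species      | harmful   |
| yes                     | none listed            | harmless  |
| yes                     | no species observed    | discarded |
| no                      | any / none             | harmless  |

The last row is a design choice: the discard rule exists because a
pathogen-listed genus's harmfulness hinges on which species are present, so
without species evidence it cannot be decided; a genus with no listed
pathogens is harmless by definition regardless of species resolution.
`strict_discard=True` switches to the stricter alternative (discard every
genus without observed species). In genus-only mode nothing is discarded and
table membership of the genus decides. Genera resolvable only to higher-order
taxonomy should be excluded before annotation
(`collapse_otus_to_genus` flags them).

## Numerical choices

* **Fisher exact test.** The conditional null of a 2×2 table given its
  margins is hypergeometric; log probabilities are computed from a cached
  log-factorial table (log-gamma) and summed with log-sum-exp, so one-sided
  p-values are accurate to ~1e-13 relative down to the double-precision
  floor. Two-sided p-values sum all tables whose probability is at most the
  observed one times (1 + 1e-7); the tolerance absorbs log-space rounding of
  exact pmf ties (the convention R and scipy use). p-values below ~1e-323
  are reported as 0 with a log note. Degenerate tables (a zero row or column
  margin) have a single attainable outcome and return p = 1 with a warning.
* **Rounding.** Δg may be fractional (normalized abundances) but Fisher
  testing needs integer counts. Rounding eubiotic and dysbiotic sums
  independently could make them disagree with the rounded total (e.g.
  1.5 + 1.5), so the eubiotic entry is rounded half-up and the dysbiotic
  entry is defined as round(total) − round(eubiotic). Half-up is monotone,
  so the dysbiotic entry is never negative, and conservation
  (eubiotic + dysbiotic = rounded Σ|Δg| over non-discarded genera) holds
  exactly by construction.
* **Zero-variation genera** carry no impact and are dropped at input with a
  log line; condition pairs whose genera are all discarded produce a zero
  row and a warning rather than an error.
* **Diversity.** Shannon entropy is reported in nats (natural log), the
  common ecology convention, with a `base` option; inverse Simpson is
  1/Σp². Both delegate to scikit-bio after validating that the vector is
  nonnegative with positive total (an all-zero sample has no defined
  diversity). The low-abundance filter interprets "null abundance in more
  than 1 sample" strictly as ≥2 zero-count samples within the group being
  analyzed, and is applied per comparison group by default (both thresholds
  and the grouping are arguments).

## Synthetic data

The generators emulate the shape of a 16S study, not its biology:

* genera are copies of one random ancestor mutated at the inter-genus
  divergence (default 10%), species are copies of their genus root at the
  intra-genus divergence (default 2%), sequences are 1200 bp — roughly
  full-length 16S;
* reads are full-length i.i.d.-substitution copies (default 1%) with an
  optional reverse-complement fraction; no indels, chimeras, quality
  profiles or length variation (an indel-free model is sufficient to
  exercise k-mer classification, which is what the tests need);
* Δg tables plant signed effects per genus (uniform ±[5, 50] by default, or
  caller-specified), and the expected contingency is computed inline from
  the planted labels and signs, independent of the impact module, so it can
  serve as that module's oracle;
* phylum count matrices plant per-arm Firmicutes/Bacteroidetes ratios with
  log-normal scatter (sdlog 0.1) and multinomial sampling at fixed depth.

Consequently, passing tests demonstrate correctness of the bookkeeping,
classification and statistics under clean, well-separated conditions; they
say nothing about classifier accuracy on real amplicon data, where reference
gaps, chimeras and within-genus ambiguity dominate. Default problem sizes
(10 genera × 2 species, 500 reads, 1000-table conservation sweeps,
exhaustive Fisher enumeration to N = 60) were chosen to exercise every code
path at desk scale.

## Known limitations

* Δg computation (normalization, differential fitting) is out of scope by
  design; the statistic inherits whatever biases the upstream pipeline has.
* The Fisher test ignores the per-genus structure of the cumulated counts; a
  single large-|Δg| genus can dominate a row.
* A genus may legitimately carry different labels in different condition
  pairs of one run when the observed species differ per arm; the package
  annotates per pair and warns when labels diverge.
* The bundled pathogen table is a minimal default, not an authoritative
  clinical resource.
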