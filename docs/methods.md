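# Methods

## Scope and model

`xenosift` re-implements the analysis core of a paired primary-tumor / PDX /
matched-normal whole-exome study as a tested library plus thin CLI. The
package does not run an external aligner or variant caller: it consumes
alignment records (SAM) or pileup tables, and re-implements the species
classification, somatic filtering, mutation-revisiting, spectrum, tiering
and purity logic on top of them. A built-in synthetic-data generator stands
in for the (inaccessible) patient exomes and provides ground truth for every
stage.

## Synthetic-data generator

**References.** A toy "human" chromosome (`hs_chrT`) is drawn uniformly over
A/C/G/T; the "mouse" homolog (`mm_chrT`) is derived by i.i.d. substitution
at an expected `species_divergence` fraction of sites (default 0.15; each
substituted site is forced to a different base). Divergence is substitution
only — no inter-species indels — so every read's true locus has a
coordinate-identical homolog in the other species. That is sufficient to
exercise score-based species classification; it deliberately omits
structural divergence, repeats and paralogy.

**Reads.** Single-end reads (default 100 bp, mean depth configurable) are
sampled uniformly; a PDX read is of mouse origin with probability
`contamination_fraction`. Human tumor reads carry each overlapping somatic
mutation independently with probability `purity × m / 2` (`m` = 1 het,
2 hom), and per-base errors at `error_rate`. Alignment records against both
contigs are produced by a documented ungapped scorer (+1 match / −1
mismatch at the read's shared coordinate), so tests need no third-party
aligner; the classifier consumes standard SAM with `AS` tags, so real
aligner output works identically. Paired-end input is supported at the
classification layer (per-mate best scores are summed); the simulator
itself emits single-end reads only.

**Pileups.** The count-model path draws per-site depth as
Poisson(mean depth) and the alt count as Binomial(depth, purity × m / 2) —
total copy number fixed at two, clonal mutations only. This is the simplest
model consistent with interpreting VAF clusters at 0.25/0.5 as purity
0.5/1.0 het and clusters at 0.4/1.0 as purity 0.4/1.0 hom. Artifact classes
are realized with their defining signatures at a 0.30 alt fraction (high
enough that the *filter*, not the detection threshold, must reject them):
germline leakage (alt at 0.5 in the matched normal too), strand bias (alt
reads on one strand only), low base quality (alt BQ 12 vs 36), low mapping
quality (alt MQ 5 vs 60), and 1-bp deletions inside homopolymer runs of 8
that are planted into the reference before the mouse copy is derived.

**What passing tests do not show.** The generator has no sequencing-error
spectrum, no CNV or subclonal structure, no mappability variation, no indel
errors outside the homopolymer class, and artifact classes are pure
(one mechanism per site). Truth recovery on this benchmark demonstrates the
*logic* of each stage, not real-exome operating characteristics.

## Species classification

Classification unit is the read (read pair when mates exist: mate best
scores are summed, matching paired-end aligner behavior). The call is the
species holding the strictly best total alignment score; exact ties are
`ambiguous` and discarded — the conservative reading of keeping reads of
human *but not* mouse origin. Scores come from the `AS` tag when present,
else `aligned_length − 2·NM`. Mapping quality is never used for the species
decision: it is reference-relative and collapses exactly when a read maps
well to both genomes. Secondary/supplementary records compete for the
per-species best score but are never double-counted. Because the paper-level
mapping-rate bookkeeping is convention-dependent, the summary reports both:
`mapped_fraction_strict` (unambiguous species placement) and
`mapped_fraction_lenient` (mapped anywhere, ambiguous included).

## Somatic filtering

The putative detector emits every site/allele with ≥ `min_alt_reads`
(default 4) tumor alt reads and tumor VAF ≥ `min_vaf` (default 0.05); these
defaults are declared, standard values, not inferred from any published
caller's internals. The four SNV criteria, all configurable:

- **Germline contingency** (`alpha` = 0.05): pass outright when the normal
  carries zero alt reads; otherwise a two-sided Fisher exact test on
  `[tumor alt, tumor ref; normal alt, normal ref]`. The variant is kept
  only when the table is significant *and* the tumor VAF exceeds the normal
  VAF — a table significant because the normal is enriched is still
  rejected. Zero coverage in either sample makes the criterion
  not-assessable and the variant is rejected with an explicit reason.
- **Strand bias**: fail only when (a) all alt reads sit on one strand and
  (b) the Fisher test on `[alt fwd, alt rev; ref fwd, ref rev]` is
  significant. Condition (a) keeps well-supported balanced sites immune to
  ref-strand skew.
- **Base quality** (`delta_bq` = 10): fail when the alt-read median BQ sits
  more than `delta_bq` below the ref-read median *and* a one-sided
  Mann-Whitney rank test is significant. Fewer than two alt observations →
  pass with a `review` flag (insufficient evidence).
- **Mapping quality** (`min_mean_mq` = 20): fail when the mean MQ of
  alt-carrying reads is below threshold.

Fisher tests use `scipy.stats.fisher_exact`; the test suite verifies every
emitted p-value against an independent brute-force hypergeometric
enumeration over exact rationals (agreement to 1e-10 on a dense table grid
plus random tables with margins ≤ 60).

Indels are left-aligned (standard shift-left normalization against the
reference) and rejected inside homopolymer runs longer than
`max_homopolymer` (default 6) or within `germline_window` (default 25 bp)
of an indel observed in the normal. This is a context screen, not a
re-alignment engine — no local assembly is attempted.

No multiple-testing correction is applied across sites: the criteria are
per-site screens applied to an already-thresholded candidate list, not a
genome-wide discovery scan. Manual review of ambiguous calls is replaced by
a machine-readable `review` flag on variants that pass with a
not-assessable sub-check. Output is VCF 4.2 with per-criterion FILTER tags
(PASS, GERMLINE, STRAND, BQBIAS, LOWMQ, INDEL_RLN).

## Mutation revisiting and sharing

All unique mutations from either tumor's kept calls are re-examined in both
samples' pileups. VAF = alt/coverage when coverage > 0 and is *undefined*
(not zero) at zero coverage, so absence of coverage is never mistaken for
absence of mutation. "Presence" for sharing classification is
≥ `presence_min_alt_reads` (default 2) alt reads — the literature defines
presence only implicitly, so the threshold is explicit and configurable.
Sites under 20X in either sample carry `low_coverage`; low-coverage
"unique" labels additionally carry `uncertain=true`.

## Spectra, tiering

Spectra are six-class, pyrimidine-collapsed (purine-reference substitutions
map to their reverse complement), indels excluded; no trinucleotide context
and no signature decomposition — group-level class fractions plus cosine
similarity between groups are the analysis unit. Tiering uses frozen
in-repo knowledge fixtures (a small ClinVar/COSMIC-style catalogue of
(gene, protein-change) pairs, a Cancer Gene Census subset and a
bladder-cancer recurrent-gene list); live database queries are
version-unstable and out of scope. Protein-effect parsing covers the short
notation only (`E542K`, `Q524*`, `F253fs`, `E3_splice`, `K145del`…), not
full HGVS.

## Purity model

`E[VAF] = purity × m / 2` at total copy number 2. Cluster centers are
density modes of the VAF histogram (grid 0.01, Gaussian smoothing bandwidth
0.03, both configurable) rather than k-means — robust to a secondary
homozygous cluster. A mode's *mass* is the fraction of points within ±0.05;
mass below the dominance threshold (0.05) is reported as "no clear
cluster". `infer_purity` returns `2 × center` clamped to [0, 1]; because
binomial noise can push a genuinely pure sample's het mode slightly above
0.5, centers in (0.5, 0.5 + tol] (tol default 0.02) clamp to 1.0, while
larger centers raise an error — they indicate a homozygous cluster or copy
number change, not a het cluster. Copy-number-aware purity estimation is an
explicit non-goal.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` seeded from the
  config; identical config ⇒ byte-identical outputs (tested).
- Coordinates are 1-based throughout; indels use a compact left-aligned
  `+SEQ`/`-SEQ` internal notation and VCF-style anchoring on output.
- Detection ordering is deterministic by (contig, position, alt); verdicts
  are order-independent (tested by shuffling).
- Degenerate inputs are soft where a run should continue (a site beyond the
  contig end yields a per-site error record; an empty sharing group yields
  an empty spectrum row) and hard where silence would corrupt results
  (mismatched tumor/normal loci, conflicting ref alleles at one site,
  unknown config keys, contigs with no species prefix).
- Problem sizes in the test and acceptance runs (toy genome 20 kb, depth
  200 pileups, 500–600 het / 200–300 hom sites, 10–12 k reads per sample in
  the read-level contamination experiment) were chosen so that binomial
  standard errors sit comfortably inside the assertion tolerances while a
  full suite run stays interactive.

## Known limitations

Two-species only; no alignment-free (k-mer) classification; no CNV,
subclonality or phasing; the simulator's artifact classes are idealized;
the sharing percentages of any real tumor pair depend on its biology and
sequencing depth and are not reproducible quantities — on synthetic data
they are checked against the generator's ledger instead.
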