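# Methods

This note documents the models implemented in `te-exchange`, the defaults
and why they were chosen, what the simulator does and does not emulate, and
the numerical conventions.

## The transfer test

For a TE family and a species pair, the evidence for horizontal exchange is
the family's synonymous divergence relative to host genes of the same pair:

- d<sub>S</sub> < genic 2.5% quantile (strict) → **strong**;
- 2.5% quantile ≤ d<sub>S</sub> ≤ median → **potential**;
- d<sub>S</sub> > median → **none**;
- saturated or unavailable d<sub>S</sub> → **undefined**.

Quantiles use linear interpolation (type 7, numpy's default); the
convention is configurable. Boundary ties resolve toward the weaker
category ("below" is read as strict). Genic sets smaller than 40 values
trigger a warning because the 2.5% quantile is then dominated by one or two
order statistics. Saturated genic values are dropped with a count retained.

Low d<sub>S</sub> can also reflect selection on codon usage. The
confirmation rule conditions on the effective number of codons: among genic
loci whose N<sub>c</sub> lies within ±2.5 units of the TE's N<sub>c</sub>
(a 5-unit window, sliding per TE rather than binned), the TE must fall more
than k = 2 sample standard deviations below the mean genic d<sub>S</sub>.
Fewer than 5 genic points in the window yields "insufficient window" rather
than a verdict. This implements the published decision rule directly; it is
not a full codon-usage likelihood model, and a hook is left where a
likelihood-based confirmation could be substituted.

Exchange between non-sister species is corroborated by tree discordance: a
neighbor-joining tree (scikit-bio, negative branch lengths clamped to zero)
built from the family's pairwise distance matrix is compared with the
species tree by the unrooted Robinson–Foulds distance; RF > 0 flags
discordance. NJ + RF was chosen over likelihood phylogenetics because the
discordance call is qualitative and this route is deterministic and
oracle-checkable.

## Divergence estimation (NG86)

d<sub>S</sub>/d<sub>N</sub> use Nei–Gojobori (1986) counting:

- per-codon site counts: at each position, the synonymous fraction is the
  number of amino-acid-preserving single-nucleotide changes divided by the
  number of changes not creating a stop codon (stop neighbours are excluded
  from the denominator, so s + n = 3 exactly per codon);
- per-codon-pair differences: synonymous/nonsynonymous steps averaged over
  all orderings of the differing positions, discarding pathways through
  stop codons; pairs whose every pathway is blocked are excluded and
  counted;
- codon pairs containing gaps, ambiguity characters or stop codons are
  excluded pairwise (cleandata-style);
- Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is reported as
  saturated (NaN) rather than raised.

Counting replaces the maximum-likelihood estimator used in the original
analysis because the downstream logic needs only pairwise d<sub>S</sub>
values comparable between TEs and genes, and counting is fully specified
and testable against an exhaustive enumeration oracle (the suite checks
agreement to 1e-9 on random codon pairs).

ENC is Wright's N<sub>c</sub> = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with the
unbiased homozygosity F̂ = (nΣp² − 1)/(n − 1) per amino acid, amino acids
observed fewer than twice excluded, and N<sub>c</sub> capped to [20, 61].
If a redundancy class has no usable amino acid (short TE ORFs can lack
3-fold or 6-fold classes entirely) the estimate is reported undefined with
a reason code instead of imputing the missing class mean — imputation would
silently bias exactly the short sequences the test cares about.

Consensus building takes the most frequent base per column (N and gaps do
not vote), drops columns with a strict gap majority, and breaks ties by the
lexicographically smallest base — deterministic and seed-free.

## Polymorphism

Tajima's D follows the 1989 constants exactly, with n = the number of
copies (the "copy number as sample size" convention) and columns containing
gaps or N excluded listwise. D is undefined for S = 0 or n < 4.

Significance comes from a neutral null: Kingman genealogies (pairwise
coalescence rate 1) with Poisson mutations at locus rate θ/2 per unit
branch length, so E[S] = θ·a₁(n) — the ms-style simulation, re-implemented
so that the identical machinery can also emit copy *sequences*. Replicates
with S = 0 are recorded as undefined and excluded from quantiles with a
logged count rather than scored as D = 0. The p-value is one-sided
lower-tail with add-one correction, p = (1 + #{D ≤ observed})/(1 + R),
since the question is whether D is significantly below zero (a
post-transfer expansion signature). The null is cross-checked against an
independent msprime simulation in the test suite.

Shared polymorphism between two species' copy sets of one family counts a
site as shared iff it is polymorphic in both species and the segregating
allele sets intersect in ≥ 2 alleles; the denominator is the union of
polymorphic sites (a "sum" denominator is available, as the verbal
definition "out of total polymorphic sites" admits both readings).

## Annotation rules

The candidate decision tree reproduces the published filtering logic: one
TE database hit (e ≤ 1e−8) → known family; several hits all in one
superfamily → novel within that superfamily; one order but several
superfamilies → novel within the order; no TE hits and the primary
(lowest-e-value, ties by identity then subject id) nr hit is a gene →
discarded; anything else retained as unknown. The class is independent of
row order.

Family clustering is single linkage at strictly > 90% gap-excluded
identity, with the longest ungapped member as representative (linkage was
unstated in the source workflow; single linkage matches the transitive
"grouped by similar matches" description).

Copy number is median TE depth / median depth of a single-copy reference
chromosome; for LTR elements the terminus (inflated by solo-LTRs) and body
are estimated separately and averaged. The support filters: keep a family
with ≥ 25 repeat-mask hits in ≥ 1 species, and keep iff ≥ 80% of consensus
positions have depth ≥ 2× the baseline (both boundaries inclusive). The
original description of the coverage filter is grammatically ambiguous;
this reading is implemented with `fold` and `min_frac` configurable. Note
the rule as written would discard a genuine single-copy family in a
homozygous line (~1× relative coverage); it is implemented as stated.
Insertion calls require frequency ≥ 50%.

TE density is computed per 1-Mb window with 100-kb step as
te_bases / (window span − N bases in the window); insertion density
analogously per midpoint count, scaled to events per Mb. N bases are
counted per window (the two printed formulas in the source say "chromosome"
once and "window" once; the per-window reading is used consistently).
Terminal windows keep their actual span; all-N windows are undefined.

## Small RNAs

Reads of 21–23 nt are siRNAs, 24–29 nt piRNAs (inclusive). The ping-pong
statistic is defined at the 5′-end level: for a (+,−) read pair the overlap
is (5′ of the − read) − (5′ of the + read) + 1, counted over offsets 1–25.
All pairs are enumerated via position-histogram correlation (cost linear in
TE length). z₁₀ compares the offset-10 count with the mean/SD of the other
24 offsets; the background set is configurable. Positional composition is
reported per strand class in read orientation, with U written as T.
Ingest assumes reads pre-filtered against miRNA/snoRNA/viral databases.

## The simulator

The synthetic-data module defines the study conditions:

- **Species tree**: ((((pseudoobscura, persimilis), miranda), lowei),
  affinis), ultrametric, with the pseudoobscura–persimilis path anchored at
  0.018 substitutions per synonymous site (the pair's average genic
  synonymous divergence) and deeper nodes at 3×, 6× and 12× the sister-node
  depth. Absolute divergence times are not published for this group; the
  deeper depths are round placeholders and only relative depths matter for
  the classifier tests.
- **Sequence evolution**: JC69 by default (K2P with κ optional) on a random
  stop-free ORF, 300 codons by default. JC69 was chosen as the simplest
  model with closed-form calibration checks; the original study needed no
  sequence-level simulator, so this is a package design choice. A per-locus
  lognormal rate multiplier (σ = 0.3 in the pipeline) models among-locus
  rate variation so the genic d<sub>S</sub> distribution has realistic
  spread.
- **Horizontal transfer**: the recipient lineage is re-grafted onto the
  donor lineage at a fractional depth (0 = present), so expected
  donor–recipient divergence is 2 × fraction × depth. No generative
  transfer model exists in the literature for this; re-grafting is the
  minimal mechanism producing the dS signature.
- **Copies**: Kingman coalescent, mutations Poisson on branches, uniform
  site placement (finite sites; infinite sites approximated at low θ,
  default θ/site = 0.01). The expansion flag multiplies external branch
  lengths (default ×10), loading the spectrum with singletons and driving
  D negative.
- **Coverage**: lognormal multiplicative depth noise at a given CV (default
  0.1, typical for Illumina depth after GC effects), mean = copies ×
  baseline (default 30×). Depth noise was not characterised in the source.
- **Ping-pong reads**: initiator 5′ sites chosen among consensus positions
  with/without T so that P(1U) = u1_freq (default 0.75, a typical germline
  piRNA U1 fraction) while every read stays an exact consensus substring;
  responders are exact reverse complements placed at the 10-nt offset, so
  the 10A bias is emergent, never coded. Default background fraction 0.2.
- **Genome mosaics and hit tables** provide fixtures for the density and
  decision-tree stages with exact ground truth.

With the seed fixed, every generator output is byte-identical across runs.

What the simulator does **not** emulate: indels and alignment error,
nested/fragmented insertions, GC-content and mappability structure in
coverage, sequencing error in reads, piRNA cluster structure, and selection
within families. Passing tests therefore demonstrate correctness of the
inference chain under the stated generative assumptions, not robustness to
every artefact of real genome data.

## Pipeline scale and defaults

The orchestrated run (`te-exchange run`) defaults to 120 genes, 20
vertical + 5 transferred families at 300 codons, transfers at 5% of tree
depth between sympatric non-sister species (the allopatric outgroup does
not exchange TEs, and sister-pair exchange is observationally confounded
with hybridisation), 10 copies per species for the polymorphism stage and
2000 ping-pong pairs. These sizes give stable classifier behaviour
(pipeline determinism is byte-exact per seed) while a full run completes in
seconds; all sizes are configuration fields. The calibration suite sizes
(10,000 null draws; 200 power replicates; 1000-replicate nulls) were chosen
so that Monte-Carlo error is well below each decision margin.

## Known limitations

- NG86 understates d<sub>S</sub> at high divergence relative to ML
  estimators with transition/transversion and codon-frequency parameters;
  comparisons across methods should recompute genic and TE values with the
  same estimator (the package always does).
- The ENC-conditioned confirmation is a decision rule, not the full
  codon-usage likelihood analysis; at small genic sample sizes the window
  SD is noisy.
- Donor/recipient direction and transfer dating are out of scope.
- The coverage-based copy-number route assumes a mappable, single-copy
  baseline chromosome.
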