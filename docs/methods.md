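# Methods

This note documents the models, rules and numerical choices implemented in
dmrkit, the assumptions behind the synthetic-data generator, and what the
validation results do and do not demonstrate about real data.

## Data model

Per-cytosine methylation evidence is held strand-resolved: each cytosine on
each strand is an independent record (chrom, position, strand, methylated
count, unmethylated count, context ∈ {CG, CHG, CHH}). Symmetric CG
dinucleotides are **not** collapsed across strands; the standard per-cytosine
mapper output is strand-resolved and collapsing is an analysis choice we do
not impose (a pooling step can emulate it if wanted). Zero-coverage sites are
retained on read — they carry information for the ectopic-CHG eligibility
rule — but never contribute to weighted levels. Internally all coordinates
are 0-based half-open; 1-based report and GFF3 coordinates are converted at
the boundary, which makes interval arithmetic and BED export uniform.

The **weighted methylation level** of any site set is Σ methylated / Σ total
reads over sites with coverage ≥ `min_cov` (default 4 reads, the conventional
WGBS floor). We use count-weighted pooling rather than the mean of per-site
fractions because it is robust to uneven coverage and is the standard
definition.

## DMR calling

The caller composes four stages, each independently testable:

1. **Binning** — fixed 100-bp tiles anchored at position 0 of each
   chromosome (terminal short bin kept). A bin's level is the weighted level
   of its covered cytosines of one context; undefined with zero covered
   sites.
2. **Per-site calls (DMCs)** — one call per site covered ≥ `min_cov` in
   *both* samples; a site is differential when |level difference| meets the
   context threshold. The per-site threshold reuses the bin-level threshold
   (0.40 CG / 0.35 CHG; 0.15 for ectopic CHG): one threshold per context is
   the most parsimonious rule and avoids importing an unstated test
   statistic. Both the bin screen and the per-site rule are applied.
3. **Bin screening** — a candidate bin needs (i) defined levels in both
   samples, (ii) a signed level difference of the requested direction with
   magnitude ≥ `min_diff`, and (iii) ≥ `min_dmc` DMCs *of matching
   direction* inside the bin (4 CG, 5 CHG, 3 ectopic-CHG). Requiring
   direction agreement prevents antagonistic sites from qualifying a bin.
4. **Merging** — single-linkage: candidates whose edge-to-edge gap is
   ≤ 200 bp merge (so two 100-bp bins separated by up to two empty bins
   join); clusters of a single bin are discarded — an isolated candidate bin
   is never a DMR. Merging is per (context, direction); opposite-direction
   candidates never join. A DMR's `mean_delta` is the unweighted mean of its
   member-bin deltas, matching the per-bin screening semantics; count-pooled
   interval levels are computed separately for heatmaps.

**Ectopic CHG** calls additionally require the control bin to be essentially
unmethylated: weighted CHG level ≤ 0.02 *and* no single site with ≥ 2
methylated reads. Strict zero would be brittle under bisulfite
conversion error; the tolerance admits isolated single-read artifacts and is
configurable.

Replicated controls are pooled at the count level before comparison; treated
lines are single libraries (bulked seedlings), so a replicate-aware test is
not possible and pooling maximises control coverage. No FDR control is
applied across bins — the rule-based definition has no per-bin p-value — and
CHH DMRs are out of scope (the caller is context-generic but CHH thresholds
are deliberately not defaulted).

## Annotation and overlap statistics

DMRs are classified by largest base-pair overlap against gene and
transposable-element intervals (ties break gene > TE, a fixed and documented
arbitrary choice; zero overlap ⇒ intergenic). Gene proximity uses the gap
between closest interval ends, 0 when overlapping, strand ignored; the
default window is 1 kb.

The multi-set intersection test computes the exact null distribution of
|S₁ ∩ … ∩ S_k| for independent uniform draws without replacement from a
universe of n elements. Conditioning on the running intersection gives an
iterated hypergeometric convolution: X₂ ~ Hypergeom(n, |S₁|, |S₂|) and
X_j | X_{j−1}=m ~ Hypergeom(n, m, |S_j|). The 2-set case uses the
closed-form hypergeometric survival function; the k-set recursion is checked
in the tests against exhaustive subset enumeration (machine precision) and
Monte-Carlo. The p-value is the upper tail P(X ≥ observed); expected size is
n·Π(|S_i|/n). For bin-overlap tests the recommended universe is the set of
bins with defined levels in *every* compared sample — bins uncovered in any
sample could never be called, and counting them inflates significance. The
universe choice is exposed because results are sensitive to it.

## Profiles

Gene-body metaplots use fixed 100-bp absolute intervals anchored at each
gene's 5′ and 3′ ends in strand-aware orientation (flank 2 kb, body window
1.5 kb by default; both configurable — the display extents are a
presentation choice, not a statistic). A gene contributes a given interval
only where it has a covered site, and body intervals that would cross the
gene midpoint are skipped so the two anchored walks never overlap within a
short gene. The profile value is the unweighted mean over contributing genes
of each gene's interval weighted level.

Chromosome-scale ratio tracks divide 100-kb weighted levels of one sample by
another; the ratio is undefined where the denominator level is below a 0.01
floor (division-by-near-zero guard). DMR × sample matrices pool counts over
each DMR interval per sample.

## Restoration and segregation

For each DMR with control, eM2 and eM3 levels (count-pooled over the DMR
interval), the restoration fraction is the linear interpolation

    r = clip((m_eM3 − m_eM2) / (m_control − m_eM2), 0, 1),

the unique linear form with r = 0 at the progenitor's level and r = 1 at the
control's. A DMR is *restored* at r ≥ 0.8, *unrestored* below 0.2, *partial*
between. The fraction is undefined when |m_control − m_eM2| < 0.2: called
DMRs always lose ≥ 0.4 at bin level, but re-pooled interval levels can fall
lower, hence the explicit gate. Two sibling lines *segregate* at a DMR when
exactly one of them is restored. Per-DMR pooled interval levels (not per-bin
levels) are used for these statistics; the alternative site-level definition
of a "restored locus" is out of scope.

## The synthetic-data generator

The generator emulates the structure of a chemically epimutagenized study:
an untreated control and a solvent control with two replicates each, treated
lines with strong regional CG loss, non-suppressor lines with near-control
methylation (planted-event probability 0.005), and eM3 siblings with
independent partial restoration.

* **Genome/annotation**: i.i.d. nucleotides at 36% GC; genes (1.5–4 kb, 10
  per 100 kb) and TEs (0.5–3 kb, 5 per 100 kb) placed uniformly without
  overlap. Cytosine contexts follow from the sequence on both strands.
* **True methylome**: per-site probability drawn from a Beta distribution
  around the context × compartment mean (concentration 100, degenerate at 0
  and 1, so a configured mean of 0 stays exactly 0). Default means: CG
  0.80/0.90/0.70 (gene/TE/intergenic), CHG 0.05/0.40/0.05, CHH
  0.02/0.10/0.02. Baseline CG is deliberately high in every compartment:
  the generator emulates the *methylated fraction* of a plant genome — where
  regional losses are observable and DMRs arise — rather than genome-wide
  averages, so that a planted additive loss of −0.6 (clipped at 0) produces
  a level difference of the same magnitude anywhere.
* **Epimutagenesis**: the genome is tiled into 1-kb regions; each is
  independently affected with probability 0.1, adding −0.6 to CG
  probabilities inside (region-level events, because regional signal is what
  bin-merging callers detect and what contiguous hypomethylated blocks in
  real data look like). The registry of affected regions is the ground
  truth for recall/precision. Positive deltas on CHG plant ectopic-gain
  scenarios.
* **Restoration**: each planted region independently reverts to control
  probabilities with probability 0.35 (the observed scale of third-generation
  recovery); independent draws per sibling line are the sole segregation
  mechanism.
* **Read counts**: coverage ~ Poisson(20) per site (a config hook exists
  for overdispersion, not enabled by default), methylated count ~
  Binomial(coverage, p·(1 − 0.005)); conversion error thins methylated reads
  only, mirroring the dominant bisulfite error mode.

What the simulator does **not** model: read-level artifacts (FASTQ,
sequencing error, PCR duplicates, mapping bias), context-dependent coverage,
correlated methylation beyond the planted tiles, partial/heterogeneous
demethylation within a region, cell-type mixtures, or any dose–response
calibration to chemical concentration (dose is exposed only as the
probability/effect-size pair). Passing the recovery checks therefore shows
the rules and arithmetic are implemented correctly and that the caller
detects clean regional signal at realistic coverage; it does not certify
sensitivity on real libraries, where boundary effects, partial losses and
mapping artifacts make recovery strictly harder.

## Validation problem sizes and tolerances

The acceptance script and test suite use: a 200-kb instance for exact
equivalence with a brute-force reference implementation of the caller rules;
a 3-Mb, 20× study for planted-region recovery (recall/precision ≥ 0.90),
null behaviour (20 resampled self-comparisons), ectopic-CHG recovery, and
the transgenerational statistics (planting probability raised to 0.35 to
obtain ≥ 1,000 regions for restoration-parameter recovery, 0.17 for ≈ 500
sibling-segregation regions — scenario sizing, not caller tuning); and a
1-Mb uniform methylome (~100 genes) for metaplot flatness, so each interval
averages enough genes for a ±0.02 band. Stochastic recovery checks use
3-standard-error bands around the planted parameter. Exactness checks
(2-set hypergeometric tail, k-set pmf vs enumeration) are at 10⁻¹⁰ or
machine precision. All randomness flows from explicit integer seeds; every
simulation stage derives an operation-specific generator so stages are
independently reproducible.

## Degenerate inputs and tie-breaks

Empty tables, empty candidate sets and empty DMR lists propagate as empty
outputs, not errors. Duplicate site keys and duplicate feature IDs are
errors (surfacing upstream corruption) rather than being silently merged.
Bins with no covered site are undefined and excluded from bedGraph export.
A ratio bin is undefined if either level is undefined or the denominator is
below the floor. Feature-class ties break gene > TE. The terminal short bin
of each chromosome is analysed like any other. Config validation reports
every violation at once and normalisation is idempotent.
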