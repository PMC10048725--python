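# Methods

## Data model and coordinates

Chromosomes are read from FASTA or GenBank flat files into a uniform record
(id, species, uppercased sequence, gap spans, feature intervals). All
coordinates are 0-based half-open; GenBank's 1-based inclusive locations are
converted on read and `join(...)` locations expanded to exon intervals; BED is
consumed natively. Gap spans cover every `N` plus any annotated
`gap`/`assembly_gap` feature. Softmasked (lowercase) bases are ordinary
sequence: the analysis operates on whole chromosomes, so repeat masking is
irrelevant to it. Chromosomes shorter than `min_length` (default 10 kb) are
excluded from cross-chromosome statistics with a logged warning — binomial
approximations and correlations over 16-dimensional content vectors are
unstable on very short records.

## Counting

Dinucleotides are counted in overlapping windows at offsets 0..L−2 on the
given (plus) strand only; windows containing a non-ACGT character are skipped
and excluded from the valid-window count `W` (so `W = L − 1` exactly on
gap-free sequences). Reverse-complement relationships are handled analytically
(Chargaff null, pair reporting), never by counting both strands: a dimer and
its reverse complement are distinct contents whose relationship is itself part
of the analysis.

## Null models and normalization

Two nulls predict each dimer count from base composition:

* **binomial**: `p_XY = p_X p_Y` with `p_X = n_X / Σn` over valid bases;
* **chargaff**: the binomial probabilities averaged with the
  reverse-complement dimer's, enforcing intra-strand parity.

Expectation and variance are binomial with sample size `n = W`. (The window
count, not the sequence length, is the correct trial count for overlapping
dimer windows; on gap-free sequences this is the conventional `L − 1`.)
Overlapping windows are not independent trials, but the binomial variance is
used only as a per-chromosome quality annotation — all inference is
Monte-Carlo (below), which needs no independence assumption.

The normalized content is the residual `C′ = C − E`. For cross-chromosome
correlation the residual is divided by `W` (`per_window` scale, the default):
raw residuals grow with chromosome length, and length would otherwise dominate
correlations across chromosomes spanning orders of magnitude in size. Raw
residuals and z-scores `(C − E)/σ` are available via `normalization.scale`.
The binomial ±σ is reported alongside the residual but never subtracted from
it.

## Monte-Carlo significance

Replicate null datasets draw one count per (replicate, chromosome, dimer) from
`Binomial(W, p_XY)` under the configured model. Each replicate dataset is
normalized exactly like the empirical data and all 120 unordered dimer-pair
Pearson correlations computed; the significance of a pair is

    σ = (r_empirical − mean_R(r_null)) / std_R(r_null)

with the sample standard deviation (denominator R−1, hence the requirement
R ≥ 2; default R = 10). |σ| > 1 is the significance rule throughout the
package; no multiple-testing correction is applied, matching the design of
the analysis this pipeline implements. The RNG stream is keyed on
(seed, replicate, chromosome id), so adding chromosomes to a dataset never
reshuffles earlier draws. Chromosomes with undefined values (zero variance)
are dropped pairwise, not globally.

## Annotation attributes and the explained-pair filter

Gene content and coding content are coverage fractions of the gap-corrected
length, `c = n / (L − n_gaps)`, with `n` the merged (union) base count of gene
spans and of mRNA ∪ CDS spans respectively. Introns inside annotated mRNAs
count as coding by default because many assemblies annotate mRNA but not CDS;
`include_mrna=False` restricts to CDS spans proper. Enhancer counts are
z-scored within each genome (sample std), which deliberately discards
between-genome level differences: enhancer annotation depth reflects research
effort far more than biology. Genomes with one chromosome or zero spread are
excluded from the enhancer attribute.

Each dimer's content is tested against each attribute with the same replicate
machinery (attribute vs null-sampled dimer contents). Dimers are then
classified by length-vs-genic opposition: significant positive correlation
with length and/or anticorrelation with gene/CDS content puts a dimer in the
length class, the reverse pattern in the genic class; no signal — or
conflicting signals, such as a dimer correlated with both length and coding
content — leaves it unclassified. A significant pair correlation is
*explained* when both dimers are classified and the sign pattern follows from
the classes (same class ∧ correlated, or different classes ∧ anticorrelated);
only unexplained significant pairs proceed to the moderation stage. This
filtering is conservative: it removes couplings that could plausibly arise
from codon usage or other constraints on genic sequence, at the cost of
discarding some genuine structure-driven couplings.

## Replacement model for property influence

A property model assigns one value `M_XY` per dimer (DiProDB-style TSV: id,
name, 16 dimer columns in AA, AC, ..., TT order). The chromosomal mean is the
fraction-weighted value `V_E = Σ M_ij c_ij` with `c_ij = C_ij / W`. Fractions,
not raw counts, keep `V_E` comparable across chromosomes of different lengths,
which the cross-chromosome aggregation requires. The influence of dimer XY is
estimated by replacing its occurrences with dimers drawn from the chromosome's
own null model:

    Δ_XY = V_E − (V_E − M_XY c_XY + c_XY Σ M_ij p_ij) = c_XY (M_XY − Σ M_ij p_ij)

Because `Σc = Σp = 1`, Δ is exactly invariant under `M → M + k` and scales
linearly under `M → aM`; the four-term and closed forms are both implemented
and checked against each other. Across chromosomes, `mean(Δ)/std(Δ)` (std with
denominator n−1, ≥3 chromosomes required) is the influence significance and
`|mean Δ| / |mean V_E|` the relative change; entries significant at >1σ with
relative change ≥ 10% (boundary included) form the large-influence table. The
relative-change filter is applied at the aggregate level — one mean Δ and one
mean V_E per (property, dimer) over all chromosomes — with per-chromosome
ratios exported for inspection. Zero spread with nonzero mean yields a signed
unbounded-significance sentinel (spread below 1e-12 of the mean counts as
zero, absorbing float noise in degenerate cases).

## Moderating pairs

For every unexplained significant pair and every property where both dimers
appear in the large-influence table, a moderation event is emitted when the
signs match the rule: correlation significance > +1 with opposite influence
signs (`correlated_opposite`), or < −1 with equal signs
(`anticorrelated_same`). Events are counted per (pair, property) combination;
the same pair may moderate several properties. Pairs derivable via
reverse-complement partners are reported separately, not deduplicated. The
stage accepts hand-entered TSV tables in place of computed ones, and the
package bundles published reference tables (pair-correlation significances and
per-property sign lists from a 2478-chromosome, 155-species survey) for
reproduction runs. Applying the strict rule to those tables yields 8
correlated-opposite events and 20 anticorrelated-same events; the source
tables' own summary lists 19 of the latter (AG–TA on the Roll_shift model,
id 57, satisfies the stated rule but is absent from the printed list). No
special case is added for it.

## Synthetic data generator

Chromosomes are first-order Markov chains, not i.i.d. bases, so dimer content
is controllable independently of base content — precisely the excess the
binomial null must detect. The baseline transition matrix `T0[x, y] = p_y`
reproduces i.i.d. composition. A planted dimer-probability shift ε on XY adds
`ε / p_X` to `T[X, Y]`, renormalizing the rest of row X proportionally;
generation fails up front if any entry leaves (0, 1). A coupling
(XY, ZV, ρ) draws per chromosome a latent Gaussian pair with correlation
exactly ρ (`z2 = ρ z1 + √(1−ρ²) w`) and shifts the two dimer probabilities by
`δ·z1` and `δ·z2`. The exact-correlation construction (rather than a shared
single latent with a sign flip) honours intermediate |ρ| values. With
`chargaff_parity` enabled, every planted shift is mirrored onto the reverse
complement dimer, emulating the intra-strand parity of real genomes (needed
for reverse-complement-consistency checks; off by default).

Defaults are the reference recovery conditions: 1 genome × 40 chromosomes ×
50 kb, base composition A/C/G/T = 0.3/0.2/0.2/0.3 (a typical ~40% GC
eukaryotic value), coupling amplitude δ = 0.01 in absolute dimer-probability
units. Gene/mRNA/CDS intervals (mean gene 2 kb, CDS a contiguous
`cds_fraction` of each gene), enhancer intervals and N-gap runs are placed
uniformly at random; CDS intervals can be regenerated with GC-dimer-enriched
transitions (`cds_gc_dimer_bias`) to exercise the explained-pair filter.
Sequence generation is a per-base loop over precomputed cumulative rows
(~20 ms per 50 kb chromosome).

What the generator does *not* emulate: realistic gene structure
(introns/exons beyond interval placement), isochores or large-scale
composition heterogeneity within a chromosome, phylogenetic correlation
between genomes, and any dependence of annotation placement on sequence.
Passing recovery tests therefore shows the statistics detect planted
couplings of the stated size under idealized noise, not that real-genome
couplings of any particular size will be detected.

## Calibration and problem sizes

The test suite and the acceptance script calibrate the machinery on data
sampled from the null itself (200 synthetic chromosome compositions, R = 10):
the mean pair significance is compatible with zero within Monte-Carlo error,
and under the Chargaff model mirrored pairs behave symmetrically. The
Monte-Carlo standard error of the mean significance is estimated as
`std/√120` over the 120 pairs; pair significances are not fully independent
(they share replicate datasets), so this is an approximation, held
deterministic by fixed seeds. Planted-coupling recovery runs the default
conditions (ρ = −0.8, δ = 0.01, 40 × 50 kb) over 20 seeds and requires
significant anticorrelation in at least 19. These sizes keep a full suite run
under a minute while leaving all statistical margins wide.

## Pipeline

Stages communicate through TSV files (composition → normalized contents →
pair correlations → attributes/classification → unexplained pairs → property
influences → coupled pairs), so each is independently runnable and published
tables can be injected mid-pipeline. A run writes a JSON manifest (package
version, full config, chromosome count, outputs); outputs are pure functions
of (inputs, config), and a rerun with the same config is byte-identical. On
any stage failure the partial outputs of that run are removed.

## Known limitations

* The ±1σ Monte-Carlo rule is lenient by design (no multiple-testing
  control); at R = 10 the null std itself is noisy, so significances near 1
  are fragile.
* W-based binomial variance ignores window overlap; it is annotation only.
* The explained-pair filter is binary (length vs genic); attributes beyond
  the built-in four require code, not config.
* Enhancer handling assumes counts are only comparable within a genome.
* Property models are consumed as given; no uncertainty in the model values
  is propagated.
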