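# Methods

## Coordinate conventions and annotation model

All coordinates are 0-based, half-open internally; VCF, GFF3 and GenBank I/O
convert at the boundary. The chromosome is circular by default: a gene
wrapping the replication origin is stored unwrapped (`end > length`) and all
interval arithmetic is taken modulo the genome length.

A position is assigned to exactly one region. CDS membership always wins.
Otherwise, if the position lies within the promoter window (default 200 bp)
upstream of a CDS start *on that CDS's strand*, it is a promoter position of
that gene; when two windows overlap, the nearer CDS start wins and remaining
ties go to the lexicographically lower locus tag, so assignment is
deterministic. There is deliberately no downstream (terminator-side) window.
Everything else is intergenic.

Coding effects are computed codon-wise under NCBI translation table 11.
Minus-strand CDSs have variant alleles complemented onto the coding strand.
Start-codon variants are classified by plain codon translation (no start-loss
logic), and a stop-loss substitution is reported as nonsynonymous. Small
InDels are recorded as `small_indel` without frameshift sub-typing. A variant
whose reference allele disagrees with the genome raises immediately rather
than being re-anchored — in practice this catches 0/1-based coordinate bugs
at the first variant, not after a silent mis-annotation campaign.

The six substitution classes collapse the twelve directed single-base changes
onto strand-symmetric pairs (G→A and C→T are both G:C→A:T). Transitions are
purine↔purine or pyrimidine↔pyrimidine.

Cohort filters follow the campaign logic: alternate-read frequencies below
0.50 are discarded (the boundary value 0.50 is kept) and synonymous SNPs are
dropped by default. Filtering preserves order and is idempotent.

Coverage anomaly flagging compares each base's depth to the genome median:
maximal runs of at least `min_window` (default 500 bp) at ≤ `low_fold`
(0.25×) flag putative deletions, at ≥ `high_fold` (1.75×) putative
duplications. The median is robust to the anomalies themselves as long as
they cover well under half the genome; an all-zero profile is an error, not
an empty result.

## Hotspot statistics

The gene–mutation matrix counts, per strain and gene, mutations whose effect
is in a configurable class set (default nonsynonymous + nonsense, matching a
ranking by nonsynonymous counts; a wider set is available because the 10%
threshold is stated over "carried mutations" generally). Genes with zero
counts are retained so enrichment denominators are correct.

A hotspot gene is one mutated in at least `min_fraction` (default 10%) of
strains; the boundary is inclusive. Ordering is by number of mutated strains,
then total mutations, then locus tag; ranks are dense. Raising the threshold
can only remove genes (tested as a monotonicity property).

Length enrichment spreads the matrix total over gene lengths:
`expected_g = total · length_g / Σ lengths`, `fold_g = observed_g /
expected_g`. The default background is the summed annotated gene length; a
genome-length background is a switch, since both definitions are defensible
and they differ exactly by the coding fraction. No significance testing is
attached — the campaign logic is threshold counting, and dN/dS-style tests
are explicitly out of scope.

Candidate SNP ranking is lexicographic: fewer *other* mutated hotspot genes
in the same strain (hotspot-abundance criterion), then higher titer
improvement, then the smaller biomass reduction; strains lacking screen data
keep their candidates but rank last. Expert metabolic judgement is a
pass-through `user_flag`, never computed.

## Screen decision model

"Exceeding the 90% confidence interval" is implemented as exceeding the upper
bound of the two-sided Student-t interval of the same-plate control mean —
the natural reading when neither distribution nor sidedness is specified.
Stage 1 (no replicates) additionally requires a ≥ 1 mM absolute gain over the
control mean. Stage 2 (triplicates) requires clearing the control CI, a
relative gain of ≥ +10% (10.0% passes) and biomass change no worse than
−35%. Percent improvements are `100·(variant/control − 1)`; displayed values
round half-away-from-zero, but decisions always use unrounded values, because
rounded percentages are not reliable inputs (printed percent columns in
screening reports are routinely inconsistent with their own titers).
Cross-plate comparisons raise: plate-to-plate environmental variation is the
reason controls are replicated on every plate in the first place.

The two-sample titer comparison is a pooled-variance Student t-test (Welch
optional). Zero-variance degenerate samples report (0, 1) for equal means and
a flagged 0-limit otherwise.

## Monod batch model and fitting

States: biomass X (g CDW L⁻¹), glucose S (g L⁻¹), product P (mM).
The default structure is Monod growth plus a Herbert–Pirt substrate balance
and substrate-saturated production:

    µ    = µ_max S/(K_S+S)
    q_P  = q_P,max S/(K_S+S)      (or q_P,max·µ/µ_max with growth_coupled)
    dX/dt = µX
    dS/dt = −(µ/Y_XS)X − q_P X M_His/(1000·Y_PS)
    dP/dt = q_P X

Both production structures are "classical"; the choice is a visible switch,
not a hidden assumption. Maintenance is omitted by default. `Y_PS` (g product
per g glucose routed to product) is a fixed stoichiometric constant, default
155.15/180.16 (one histidine per glucose); it is not fitted because batch
data cannot separate it from `q_P,max`. The implied maximum glucose uptake
`q_S,max` (mmol g⁻¹ h⁻¹) is derived, not fitted. Glucose is floored at zero:
once depleted, all rates vanish and X and P plateau. Integration is LSODA
(`rtol 1e-8` for simulation, `1e-7` inside the fit loop); trajectories are
deterministic for fixed tolerances.

**Loss.** Residuals are per-point relative: `(model−data)/max(|data|, 5% of
the observable's cohort scale)`. This is the maximum-likelihood weighting
under multiplicative observation noise — which is also the generator's noise
model — and it is what makes `K_S` identifiable at all: the information about
the Monod constant lives in the few low-substrate points near depletion, and
a cohort-mean scaling drowns them (with it, `K_S` errors of 10–20% at 1%
noise are typical; per-point weighting brings all parameters within a few
percent). The 5% floor keeps depleted (zero) observations at finite weight.

**Multi-batch scoping.** Each of `µ_max, K_S, Y_XS, q_P,max` is declared
global (one shared value) or local (one value per batch); the default scope
shares the Monod constant and biomass yield, the rates stay local. Parameters
are optimized in log space (positivity built in) by Levenberg–Marquardt with
data-driven initial guesses and seeded multi-start (default 3 starts;
occasional `K_S → 0` local minima at single-start are rescued by the extra
starts). Function evaluations are capped (500) so a pathological start
terminates instead of grinding.

**Bootstrap.** Parametric: per-observable relative residual SDs are estimated
from the fit, new datasets are simulated from the fitted trajectories with
that noise, each is refitted starting from the point estimate, and 2.5/97.5
percentiles taken per parameter (asymmetric about the estimate by
construction). Bounds are anchored to include the point estimate, preserving
`low ≤ estimate ≤ high` even when refit scatter is at solver precision.
`n_boot < 10` is refused; with ~50 replicates the percentile interval is
expected to under-cover slightly relative to its nominal 95% — coverage is
measured, not assumed (see below).

**KPIs.** With M_His = 155.15 and M_glc = 180.16 g mol⁻¹ and six carbons in
both molecules, titer (g L⁻¹) = mM·M_His/1000, molar yield = mM /
(1000·g_glc/M_glc), and the C-mol yield equals the molar yield exactly for
this C6→C6 conversion (asserted). Yields are reported per glucose supplied,
appropriate for fully depleting batches. Volumetric productivity divides the
final titer by the run duration.

## Synthetic study conditions

The generator's defaults are the campaign conditions the package is validated
under:

- **Mutation load**: negative-binomial per strain, mean 180, dispersion 5,
  clamped to [47, 470] — the overdispersion reproduces the wide spread of
  mutation counts across independently mutagenized cultures; a Poisson at
  mean 180 could not.
- **Spectrum**: a fraction `gc_to_at_fraction = 0.9` of SNPs are G:C→A:T
  transitions (the alkylating-mutagen signature; the bias is strong but no
  exact figure is established, so 0.9 is an explicit, documented choice), the
  rest uniform over the remaining five classes subject to the reference base.
- **Read frequencies**: true mutations uniform on [0.5, 1.0]; a 10% decoy
  fraction gets frequencies below 0.5 so the frequency filter has real work.
- **InDels**: off by default (none were observed in such campaigns under
  short cultivation intervals); an option enables them for robustness tests.
- **Planted hotspots**: listed genes receive one extra nonsynonymous SNP per
  strain with the configured probability (default tests use 0.20 against a
  ~0.02 background).
- **Calibration genome**: 2 Mb with 300 genes, chosen so the per-gene
  background hit probability under a 180-mutation load (~0.023) sits well
  below the 10% hotspot threshold — the same regime as a multi-megabase
  chromosome. Smaller toy genomes make every gene a trivial hotspot and the
  calibration meaningless.
- **Plate screens**: 48-well plates with control triplicates (mean 11.5 mM,
  between-plate SD 0.3 mM, OD600 18.4), 5% multiplicative measurement noise,
  variant triplicates at `control·(1+effect)`.
- **Fermentations**: initial (0.25 g L⁻¹ CDW, 40 g L⁻¹ glucose, 0 mM),
  sampled hourly to 48 h, 1% multiplicative noise. Recovery tests use
  K_S = 1.0 g L⁻¹ and Y_XS = 0.30 g g⁻¹ shared across three batches with
  per-batch µ_max (0.15, 0.10, 0.08 h⁻¹) and q_P,max (0.13, 0.14,
  0.17 mmol g⁻¹ h⁻¹), the rate scale of engineered histidine producers.

Every generator is a pure function of (config, seed): identical seeds give
byte-identical FASTA/GFF/VCF/CSV output, and every emitted variant appears in
the ground-truth table.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: sequencing error and alignment artefacts (sites are
drawn uniformly; real coverage and callability vary), linkage between
mutations, fitness effects coupling genotype to load, selection during
outgrowth, plate position effects beyond a per-plate control shift, and any
dose–mortality relationship of the mutagen (dose is not a model input).

## Validation design

The acceptance suite (and `scripts/acceptance.py`, which recomputes the same
quantities from scratch at a user seed) checks:

1. worked-example arithmetic against measured campaign end points
   (e.g. 20.9 vs 11.5 mM → +82%; 29.1 mM from 40 g L⁻¹ → 0.13 C-mol C-mol⁻¹,
   4.5 g L⁻¹, 0.11 g g⁻¹);
2. codon-wise effect calls against an independent whole-CDS retranslation
   oracle on 500 random SNPs (100% agreement required);
3. strand invariance: annotating the reverse-complemented, coordinate-
   remapped genome leaves every effect class and protein change unchanged;
4. hotspot null calibration (observed hotspot count inside the 95% band of a
   plug-in binomial null) and planted recovery (3 genes at p = 0.20 outrank
   every unplanted gene in ≥ 95% of 20 seeded cohorts of 100 strains);
5. generator spectrum control (G:C→A:T share 0.90 ± 0.03 over ~18,000 SNPs);
6. screen calibration: null plates yield improved-calls at ≤ the nominal 5%
   implied by the one-sided reading of the 90% CI plus the +10% margin
   (1,000 plates; the margin makes the empirical rate nearly zero), and
   +20% planted effects at 5% noise are recovered ≥ 90% of the time;
7. Monod recovery within 5% for all global and local parameters at 1% noise,
   and bootstrap coverage — the fraction of (experiment, parameter) pairs
   whose 95% interval brackets the generating value over 20 seeded
   experiments at n_boot = 50 — of at least 0.90. Percentile intervals at 50
   replicates under-cover their nominal 95% somewhat, so measured coverage
   lands in the high 0.8s to low 0.9s depending on the seed.

Problem sizes (300 SNPs per oracle batch, 20-seed replications, n_boot = 50,
hourly sampling to 48 h) are the package's chosen validation scale; they keep
the full suite in the tens of minutes on a single CPU while leaving each
check statistically meaningful.

## Known limitations

- One chromosome per reference; plasmids and multi-record FASTA are rejected.
- No frameshift typing, no tRNA/rRNA annotation, no effect prediction beyond
  codon logic.
- Hotspot calling is threshold counting; no significance testing.
- `K_S` is structurally weakly identified in batch data when S ≫ K_S for most
  of the run; the per-point relative loss mitigates but cannot remove this —
  fits of real data should treat small fitted Monod constants as "below the
  resolution of the experiment".
- The bootstrap assumes the fitted noise model (independent multiplicative
  Gaussian); autocorrelated sensor noise would make its bounds optimistic.
- Selection criterion III (metabolic judgement) is a user-supplied flag only.
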