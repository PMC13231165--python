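# Methods

## The assay and its statistic

HUH-seq reads out the substrate specificity of a Rep (HUH-endonuclease) by
depletion.  The substrate pool is a 97-nt ssDNA oligo whose seven bases
immediately 5′ of the cleavage site (substrate positions −7…−1) are
randomized; the +1/+2 positions are fixed to `AC`, completing the
circovirus-type origin context.  Cleaved molecules cannot be amplified, so
for each of the 4⁷ = 16,384 k-mers the cleavage efficiency is estimated as

    reduction = (f_ref − f_treat) / f_ref

where f are k-mer frequencies, each the **mean of per-replicate
frequencies** (not pooled counts) over the replicates retained by QC.
Reduction is stored as a fraction in (−∞, 1]: 1 is complete depletion, 0 no
effect, negative values are relative enrichment of uncleaved k-mers
(unavoidable under renormalization when much of the pool is consumed), and
NA marks k-mers absent from the reference.  Values are rendered as
percentages only at the presentation layer.

Processing order matches the assay: demultiplex by 5′ sample barcode
(exact match by default; one-substitution tolerance is opt-in and the
barcode set must satisfy pairwise Hamming distance > 2·max_mismatch, which
is checked before any compute) → extract the randomized 7-mer (exact match
of both constant flanks, with a fixed-coordinate fallback for reads of
exactly design length whose anchors are mutated) → count all 16,384 k-mers
including zero-count entries → replicate QC → reduction → histograms and
logos.  All stages are deterministic and invariant to read order.

## Replicate QC

Replicate agreement is scored by pairwise Pearson correlation of raw
per-k-mer counts.  Exclusion is *greedy worst-first*: while any retained
replicate has mean r against the other retained replicates below the
threshold (default 0.8), the worst offender is dropped and correlations
re-evaluated.  The one-shot version of the rule ("exclude every replicate
whose mean r is below threshold") would discard intact replicates whenever
a single corrupted sibling drags every mean down; the greedy form removes
only the replicate that actually disagrees, which is the behaviour wanted
when one replicate of three has failed.  A condition is never reduced below
two replicates; if the survivors still disagree the condition is flagged
unusable, which the CLI reports as a fatal QC state (exit code 3).  Every
exclusion is logged with the correlation values.

Two correlation axes are emitted and labelled explicitly: replicate QC uses
Pearson on raw counts; between-condition comparison uses Pearson on
per-k-mer reductions with NA dropped pairwise (entries with fewer than 3
shared finite k-mers are NA).

## Specificity logos

The logo over positions −7…−1 includes k-mers whose reduction meets a
threshold (default 0.5, i.e. ≥ 50% depletion).  Two weighting schemes are
provided because the choice is a genuine free parameter of the method:
`reduction_weighted` (default) weights each included k-mer by its
reduction, so a base's column weight is the summed reduction of included
k-mers carrying it; `unweighted` counts each included k-mer once.  Columns
are probability-normalized unless raw mode is requested; the scheme, the
threshold and the included-k-mer count are recorded in the logo metadata.
Logos are always emitted as numeric position × base matrices (TSV); no
plotting library is required to use or test them.

## Synthetic HUH-seq runs

The generator writes a pooled multiplexed FASTQ (constant high-quality
placeholder qualities — the method never uses them), a sample sheet, a
manifest, and a truth table with every condition's per-k-mer cleavage
probability and expected reduction.  All randomness flows from the manifest
seed; an identical manifest reproduces byte-identical files.  Reads carry
their sample and intended k-mer in the FASTQ title, so demultiplexing and
extraction can be validated against generator truth.  The error model is
substitution-only (rate 0.001/base by default): the analysis extracts
fixed-coordinate k-mers, so indels would only lower the assignment rate,
not move the statistic.

**Reference pool.**  `uniform` is available as the idealized pool, but the
canonical study scenario uses `synthesis_bias`: mild per-position base bias
(relative weights 1 : 0.90 : 0.78 : 0.68, rotated across positions)
compounded over the 7 positions, plus 160 "spike" k-mers carrying 15% of
the pool — the composition heterogeneity real synthesized randomized pools
show.  The lot is fixed by an internal seed independent of the sampling
seed, as a library's composition is a property of the synthesis, not of
the sequencing run.  This skew is what makes count-based replicate QC
meaningful: at 10⁵ reads over 16,384 k-mers a perfectly uniform pool gives
Poisson-dominated counts whose between-replicate correlation is ≈ 0
regardless of data quality.  Under the default scenario intact replicates
correlate at r ≈ 0.93 and the deliberately corrupted replicate (its k-mer
identities permuted before sampling, emulating a failed library) at
r ≈ 0.

**Cleavage models.**  Three parameterizations:

* `position_weight` — P(cleave|kmer) = extent · Π_j w[j, base_j], with w a
  7×4 matrix of per-position per-base propensities in [0, 1]; convenient
  for one-hot single-target constructions used in tests.
* `survival_weight` — the weights are per-base *survival* factors:
  P = extent · (1 − Π_j w[j, base_j]).  Survival multiplies across
  positions, so cleavage spans the full (0, 1) range over the k-mer space.
  The default "promiscuous" enzyme (a broadly reactive, high-Mn engineered
  variant: motif survival 0.22, other bases 1.0/0.78/0.52 per position)
  uses this form; its reduction histogram is strongly right-shifted, as
  observed for relaxed-specificity variants, while still preferring the
  canonical TATTATT motif at every position.
* `mismatch_logistic` — logistic in the Hamming distance to the motif; the
  default "specific" enzyme (wild-type-like, low Mn: extent 0.95, midpoint
  1, scale 0.5) cleaves essentially only the motif and its one-mismatch
  neighbours.

Treatment samples draw k-mer i with weight ∝ p_ref(i)·(1 − P_cleave(i));
the recorded truth reduction is 1 − (1 − P_cleave(i))/Σ_j p_ref(j)(1 −
P_cleave(j)), i.e. exactly what an infinite-depth pipeline would estimate.
Under the default scenario at 10⁵ reads/sample × 3 replicates the pipeline
recovers truth reductions with Spearman ρ ≈ 0.93.

**What the generator does not emulate:** PCR amplification bias,
Illumina-realistic quality/error profiles, indels, chimeras, or the
phosphorothioate/PhiX details of the wet protocol (flow-cell chemistry
only).  Passing the recovery tests therefore demonstrates correctness of
the analysis given reads of the assumed architecture, not robustness to
every real-world artifact.

## Selection-round simulation and enrichment

The naive library draws residues per mutagenized position with NNK codon
multiplicities (Leu 3/32, Met 1/32, stop 1/32, …).  Each sorting round
resamples reads with probability proportional to variant fitness — the
product of per-position per-residue fitness factors — so designated winner
residues converge monotonically in expectation.  Reads are the constant 5′
flank plus the coding region; each amino-acid variant is written with a
deterministic codon choice (the lexicographically smallest compatible
codon).  Selection acts on protein variants and the analysis decodes to
amino acids, so codon-level synonymy is deliberately not modelled.

Enrichment between rounds is score = log2((f_post + p)/(f_pre + p)) with
additive pseudocount p defaulting to 1/(assigned reads of the smaller
round); the scheme and p are recorded in output metadata.  The score is
antisymmetric under round exchange at matched p.  Stop-containing variants
are tallied separately and excluded from residue logos by default
(`include_stop=True` adds `*` as a 21st symbol); whether stop-containing
reads should enter enrichment at all is not settled by the protocol, so
both behaviours are exposed.  Consensus is the per-position argmax of the
frequency logo with exact ties broken toward the parent residue (logged);
the reference round for enrichment must always be named explicitly.

The default sDBM parent sequence is a synthetic stand-in: only the residues
the engineering narrative pins down (wild-type H81 and K86; round-2 fixes
R79/W81/P84) are meaningful, the rest are placeholders.  Residue numbering
is 1-based full-length PCV2 numbering with a stored offset, so the coding
amplicon can start anywhere.

## Curve fits

* **Polarization** from intensities is the anisotropy-form ratio
  (Ipar − Iper)/(Ipar + 2·Iper), undefined only when both intensities are
  zero.
* **Quadratic binding**: nonlinear least squares of the ligand-depletion
  isotherm with [Dt] fixed at the known probe concentration.
  Initialization is Amin = min(y), Amax = max(y), K_D = the concentration
  nearest half-signal; K_D is bounded positive.  Requires ≥ 6 distinct
  concentrations.  Two modes: `replicate_mean` (default — fit each
  replicate day separately, report the mean K_D, matching how dissociation
  constants are averaged over independent reactions) and `pooled`.  The
  model reduces to the Langmuir isotherm as [Dt] → 0 (verified numerically
  at [Dt] = 10⁻⁶·K_D) and K_D is invariant to affine rescaling of the
  signal axis.
* **Beacon rates** are reported as relative initial rates (signal·s⁻¹):
  the OLS slope over the initial window (default 60 s after dead time,
  ≥ 5 points) with R² as a linearity diagnostic; a single-exponential fit
  is available for curves that saturate in-run.  Rates are never converted
  to k_cat — for RNA substrates the assay runs below binding saturation,
  so absolute turnover is not identifiable.  Saturated-at-start curves are
  flagged too-fast-to-measure only when the caller supplies the detector's
  saturation level, since a flat low trace (no cleavage) is otherwise
  indistinguishable from a flat high one.
* **Metal activation** uses single-site hyperbolic saturation (Hill
  coefficient optional, fixed at 1 by default — no evidence warrants more
  structure).  If the data never reach 2·K_app the result carries a
  wide-confidence flag.
* **DSF T_m**: Savitzky–Golay smoothing (polynomial order 3, default
  window 11 grid points — at the assay's 0.5 °C ramp resolution this
  keeps single-seed scatter near 0.3 °C on a width-2 °C transition while
  leaving the symmetric peak position unbiased), numerical dF/dT, and the
  interior derivative maximum with the first/last 2 °C excluded against
  edge artifacts.  The peak is refined by parabolic interpolation through
  its three points.  Peaks are accepted at ≥ 5% prominence of the
  derivative range, so a linear or flat trace yields a no-transition NA
  rather than a spurious T_m; multiple peaks within 50% prominence of the
  largest are all reported with the largest flagged primary.

All fits are deterministic given identical inputs; non-convergence yields
a flagged result with NaN parameters, never a dropped series.

## Problem sizes and defaults

The canonical simulated study uses 10⁵ reads per sample, 3 replicates per
condition, one untreated reference condition plus one promiscuous and one
specific enzyme condition, substitution rate 0.001, QC threshold r = 0.8,
logo threshold 0.5 — a desk-scale rendering of the assay that preserves
its statistical structure (per-k-mer expected counts of ~6 per replicate).
Parameter-recovery studies for the fits use 20 seeds per scenario with the
published titration designs: 12-point 1:2 dilution from 1 µM with 10 nM
probe and 2%-of-range noise for binding; 8 points over 10–1000 µM with 5%
noise for Mn²⁺ activation; a 0.5 °C grid over 20–95 °C with 1% amplitude
noise for melts.

## Known limitations

* Percent reduction is a relative, renormalized statistic: when most of
  the pool is cleaved, uncleaved k-mers show negative reductions, and
  absolute cleavage extents are not identifiable without spike-ins.
* Replicate QC on raw counts has no power against an unbiased uniform
  library; it measures consistency of pool structure, not accuracy.
* The selection simulator models selection as per-position multiplicative
  fitness with no epistasis, and sequencing as error-prone but unbiased.
* Anchor matching is exact by design (determinism first); heavily
  error-laden reads are dropped rather than rescued.
* No paired-end merging, adapter trimming or quality filtering: the
  amplicon architecture is fixed and qualities are unused.
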