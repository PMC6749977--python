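# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic-data generators do and do not emulate, and the
numerical choices that affect results.

## Count model and ΔTE

Each gene's RNA-seq and ribosome-footprint counts are modelled jointly with a
negative-binomial GLM (log link, variance μ + αμ²):

    log μ_gj = log s_j + Patient_j + Time_j + Assay_j + (Time:Assay)_j

* `s_j` — median-of-ratios size factors computed on the combined RNA + RPF
  matrix, rescaled to geometric mean 1. Computing them jointly means the
  assay main effect absorbs the systematic depth difference between library
  types; genes with a zero in any sample are excluded from the reference set.
* Reference levels: unstimulated time point; RNA assay. The interaction
  coefficients therefore read directly as ΔTE per stimulated time point:
  positive ΔTE = more ribosome occupancy than the RNA change explains.
* All reported fold changes are log2, raw MLE, no shrinkage — this keeps the
  identity ΔRPF = ΔRNA + ΔTE exact (the three are linear contrasts of one
  fitted coefficient vector). A gene with all-zero counts in one
  (time, assay) cell therefore has a divergent MLE for the affected
  contrasts; the expression filter upstream removes most such genes, and the
  remainder are visible as extreme fold changes with large standard errors
  rather than silently clipped.

Fitting is Fisher-scoring IRLS (convergence max |Δβ| < 1e-8, ≤ 100
iterations, η clipped at ±30). The unit tests verify the IRLS optimum
against direct numerical maximization of the same likelihood to 1e-4.

## Dispersion

One dispersion per gene, shared by both assays, estimated on the full design
by Cox–Reid-adjusted profile maximum likelihood (`α ∈ [1e-8, 10]`, Brent
search on log α). Three modes:

* `genewise` — the CR-adjusted MLE as is.
* `trend` — genes take the fitted parametric trend α(μ) = a₀ + a₁/μ
  (least squares over genewise estimates with iterative outlier trimming).
* `moderated` (default) — empirical-Bayes MAP toward the trend: a log-normal
  prior centered on the trend whose variance is the excess of the observed
  residual spread of log genewise estimates (MAD-based) over their expected
  sampling variance, approximated by trigamma((m − p)/2) for m libraries and
  p design columns; floored at 0.25². With 40 libraries and 13 columns the
  sampling noise of log α̂ is substantial (SD ≈ 0.28), and plugging noisy
  dispersions into the tests visibly inflates them; moderation removes most
  of that inflation without flattening genuine dispersion differences.

## Tests and their references

* **Wald per time point** — z = c′β̂ / se(c′β̂) with the expected-information
  covariance, referred to a **t distribution with m − p degrees of freedom**.
  With 13 parameters estimated from 40 libraries the normal reference is
  accurate near the center but anticonservative in the far tail — exactly
  where BH discoveries live — which inflated the realized false discovery
  rate several-fold in null simulations even with the true dispersion
  plugged in. The t reference (the same small-sample correction
  quasi-likelihood F-tests use) restores tail calibration.
* **LRT across time points** — 2(ℓ_full − ℓ_reduced) where the reduced model
  drops the interaction block (df = number of interaction columns, 4 for the
  five-time-point design). With *known* dispersion the chi-square reference
  is well calibrated; with a plug-in estimate the statistic scales roughly
  multiplicatively with the dispersion error for well-expressed genes, so
  the null is referred to a **lognormal-scale mixture of chi-square** whose
  log-variance is the estimator's posterior variance (sampling variance
  combined with the moderation prior), evaluated by 32-node Gauss–Hermite
  quadrature. When dispersions are supplied externally the reference reduces
  to the plain chi-square.
* **BH correction** — per contrast per time point across genes; the LRT in
  its own family. NaN p-values propagate without affecting the number of
  tests.
* **DTEG flag** — default rule is the *intersection*: ΔTE Wald adjusted
  p < α at ≥ 1 time point AND LRT adjusted p < α. A union over the five BH
  families approximately sums their false discoveries and exceeded any
  sensible gene-level FDR in simulation (≈ 0.2 at nominal 0.05); requiring
  both tests keeps the gene-level FDR near nominal while losing little
  power for sustained effects. `union`, `wald` and `lrt` rules remain
  available, and all constituent adjusted p-values are reported so any rule
  can be applied downstream. The DTG flag is ΔRNA-significance at any time
  point.

## Expression filter

Genes need mean TPM ≥ 1 (CDS-length TPM, unweighted mean across all samples
of an assay) in *both* assays; the boundary is inclusive because the removal
rule is strictly "< 1". The mean is global rather than per-condition — the
simplest reading of "across all conditions" — and the filter is idempotent.

## Regulatory classes

Per gene and measure, significance = Wald adjusted p < 0.05 at any time
point (ΔTE additionally accepts the across-time LRT); direction = sign of
the fold change at the time point with the smallest adjusted p. The decision
table:

| ΔRNA | ΔRPF | ΔTE | signs | class |
|------|------|-----|-------|-------|
| sig | sig | n.s. | — | forwarded (direction from ΔRNA) |
| n.s. | sig | sig | — | exclusive (direction from ΔTE) |
| sig | sig | sig | opposite | buffered |
| sig | n.s. | sig | opposite | buffered_complete |
| sig | any | sig | same | intensified |

The 8-group view folds `buffered_complete` into `buffered` and splits each
class by direction. Note that "buffered down" means the *translational*
direction is down (translation works against an RNA increase).

## Temporal clustering

Within each class, genes are clustered on their concatenated per-time-point
log2 fold-change vectors — (ΔRPF, ΔRNA) for forwarded genes, (ΔRPF, ΔTE) for
the translationally regulated classes. The linkage is ward.D: the
Lance–Williams Ward recurrence applied to *unsquared* Euclidean distances,
reproducing R `hclust(method="ward.D")` merge-for-merge (verified against a
frozen reference run). scipy's `ward` implements the D2 variant and is not
interchangeable.

Cluster labels come from a deterministic top-down cut: a cluster splits into
its two subtrees when both hold ≥ `min_cluster_size` genes (default 20) and
the join is tall relative to its children (max child merge height ≤ 0.5 ×
join height). The height guard separates genuine structure from the smooth
height growth of homogeneous noise: in simulation, noise joins show
child/parent ratios of 0.45–0.85 while planted separations sit below 0.01,
so the 0.5 default has a wide margin on both sides. Clusters under 50 genes
are flagged non-displayable. Classes smaller than the minimum cluster size
form a single unlabelled cluster (label 0).

## Footprint QC

P-site = footprint 5′ end + 12 nt, strand-aware, for all read lengths (the
generator's default read length is 29 nt). The pipeline works in transcript
coordinates — footprints arrive pre-assigned to per-transcript contigs —
because genome alignment is upstream of this package and the QC arithmetic
is coordinate-frame independent. Coordinates are 0-based half-open
internally; BED is honored as 0-based, GTF converted from 1-based inclusive.
Periodicity counts only CDS-internal P-sites. The stop drop-off profile is
P-site density over ±window around the stop codon, upstream mean normalized
to 1; the ratio is post-stop (offset ≥ +3) over pre-stop mean density, which
equals the read-through fraction when termination is leaky.

## Enrichment

eCLIP filter: signalValue ≥ 8 (inclusive — the stated rule is a fold
threshold) and peak p < 1e-5 (strict). A gene is a target when ≥ 1 surviving
peak overlaps its annotated span on the matching strand; region-restricted
(3′UTR/CDS) assignment is not implemented. Pre-filtered target lists (e.g.
POSTAR-style) can be passed directly as gene sets. The permutation null
draws same-size gene sets uniformly without replacement from the background
(DTG ∪ DTEG); draws are shared across RBPs within a group, which makes 1e5
draws tractable for hundreds of RBPs. Empirical p uses the +1 correction
(never zero), z = (obs − null mean)/null SD, BH across all (RBP, group)
pairs, overrepresented at adjusted p < 0.05. A degenerate null (SD 0, e.g.
targets ⊇ background) flags z as undefined.

## Cohort network

TE per patient = TPM_RPF / TPM_mRNA, defined only where both TPMs are
positive; pairs need ≥ 5 complete patients. Spearman ρ via average ranks
with the t-approximation p; a pair is "correlated" at nominal p < 0.05
(configurable — the threshold before permutation is not a printed constant
anywhere authoritative). Hubs: per RBP, the observed number of correlated
candidate pairs is compared to target sets of the same size redrawn from the
analyzed genes (patient labels intact; redrawing targets rather than
permuting patients matches the "random set" construction), 10,000 draws, +1
empirical p, BH across RBPs, hub at adjusted p < 0.05. The |ρ| ≥ 0.45 edge
filter is visualization-only and never feeds back into hub calls. Severity:
complete-linkage hierarchical clustering (the R `hclust` default) of
patients on log10 marker TPM, cut into 4 groups, ordered by mean marker
expression into severity 1–4; the low-vs-high comparison is an
equal-variance two-sample t test on log10 TPM. Marker genes are a required
user input (fibrosis panels vary by cohort; ACTA2, COL1A1 and POSTN are
typical members); the synthetic cohort plants its own five-marker panel.

## Synthetic-data generators

`generate_counts` emulates the study design: 4 patients × 5 time points
(0, 45 min, 2 h, 6 h, 24 h) × 2 assays, one library each, ~2e6 expected
counts per library. Per gene: log-normal baseline abundance (log10 SD 0.8,
a realistic bulk TPM spread), NB dispersion uniform in (0.01, 0.1) — the
low-biological-CV regime of cultured cells, matching the package's reference
dispersions of 0.05–0.1 — patient batch effects as gene-independent
log-normal multipliers shared between the RNA and RPF libraries of a patient
(log2 SD 0.5), and per-library depth jitter (log2 SD 0.1) so size factors
have work to do. Regulatory classes are planted as constraints on the
(ΔRNA, ΔTE) pair (effect magnitude 2 log2 by default, sustained across all
stimulated time points unless a transient fraction is requested); ΔRPF is
always derived as the sum, never sampled. The truth channel carries exact
planted effects, so ΔTE = ΔRPF − ΔRNA holds identically.

`generate_footprints` places P-sites on codon positions with P(frame 0) =
f + (1 − f)/3, converts to strand-aware 5′ ends, and optionally adds
stop-codon read-through at a given relative density. `generate_cohort`
plants hub RBPs whose across-patient footprint abundance drives target
log10 TE with a monotone linear link plus Gaussian noise (SD 0.15 log10 by
default), decoy RBPs with random targets, and marker genes whose expression
increases with the planted severity level (extremes separated by 2 log10).
`generate_peaks` writes narrowPeak records over target-gene spans with
exactly `round(fraction × n)` records passing the 8-fold/1e-5 filters.

What the generators do **not** emulate: raw reads, alignment and multimapping
artifacts, UTR/isoform structure, gene–gene correlation, library-preparation
biases, count outliers of the Cook's-distance kind, or nonlinear
RBP–target dose responses. Passing tests therefore demonstrate that the
statistics are implemented correctly and calibrated under the stated model,
not that the model captures every feature of real libraries.

## Problem sizes

The test-suite and acceptance script use 2,000 genes for calibration and
recovery runs, 1,200 for classification, 9e4 reads for periodicity, 1e5
enrichment permutations, 1e4 hub permutations and a 30-patient cohort — the
sizes at which the target properties (calibration bands, ≥ 90% recovery)
are statistically meaningful — and a 300-gene end-to-end run for the
byte-determinism check, where gene count is irrelevant.

## Known limitations

* No independent filtering, outlier replacement or lfc shrinkage; genes with
  empty count cells yield extreme MLE fold changes (flagged by their
  standard errors, removed in practice by the TPM filter).
* The scale-mixture LRT reference is first-order in the dispersion error and
  slightly conservative (null rejection ≈ 4.3–4.7% at nominal 5%).
* Whole-gene peak overlap only; no per-read-length P-site offsets.
* Severity stratification assumes the marker panel moves monotonically with
  severity; discordant markers would blur the extreme groups.
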