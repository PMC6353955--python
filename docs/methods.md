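# Methods

`chrombind` re-implements, as a tested library, the quantification
machinery used to relate a transcription factor's (TF) binding to mitotic
chromosomes with its interphase mobility, single-molecule binding
kinetics, genome occupancy statistics and sequence features.  This note
records the models, the conventions and defaults chosen where the design
was open, what the synthetic generators do and do not emulate, and the
known limitations.

## Mitotic bound fraction (MBF)

A metaphase cell is modelled as two compartments: the condensed
chromosome plate and the cytoplasm.  With mean fluorescence signals
`S_chrom`, `S_cyto` and volume fractions `V_chrom = 0.16`,
`V_cyto = 0.84` (the chromosome volume fraction measured once by confocal
3D segmentation and consumed here as a constant),

    MBF = S_chrom·V_chrom / (S_cyto·V_cyto + S_chrom·V_chrom).

The denominator is the total signal (sum of the two volume-weighted
compartment signals), so MBF is a proper fraction: equal compartment
intensities give `MBF = V_chrom = 0.16`, and TFs are binned as depleted
(< 0.165), intermediate ([0.165, 0.23], closed on both sides — boundary
membership is otherwise undefined) or enriched (> 0.23).

**Segmentation.** The chromosome plate is the largest 8-connected
component of the Otsu-thresholded DNA channel (≥ `min_area_px`, default
50 px).  The plate is dilated by 5 px (disk element) and excluded from
the cytoplasmic mask to keep out-of-focus chromosomal signal out of the
cytoplasmic mean.  The cell footprint is thresholded on the TF channel
against a robust background estimate (image median + 5 MAD-σ): a plain
Otsu cut fails whenever the plate is much brighter or dimmer than the
cytoplasm, because the strongest intensity gap is then between cytoplasm
and plate rather than at the background.  This assumes the cell occupies
a minority of the field, which holds for single-cell crops.  The
cytoplasmic region is the 21-px dilation of the cell footprint minus the
dilated plate, clipped by default to the cell footprint
(`restrict_to_cell=True`): without the clip, background pixels in the
dilation ring dilute the cytoplasmic mean by tens of percent and make the
MBF estimate grossly biased; the unclipped variant remains available.

**Statistics.** Per-TF summaries use the mean and `SD(n−1)/√n` SEM;
a single cell has SEM 0 by convention.

## FRAP

Three circular ROIs are recorded: bleached spot (ROI1), non-bleached
control (ROI2) and background.  After frame-wise background subtraction
the trace is double-normalized,

    I(t) = (mean_pre ROI2′ / ROI2′(t)) · (ROI1′(t) / mean_pre ROI1′),

which pins the pre-bleach level at 1 and cancels exactly any
multiplicative drift (acquisition bleaching) common to both ROIs.  Only
post-bleach frames enter the fit of `I(t) = I0 − a·e^{−βt}`, with time
rebased to the first post-bleach frame.  Derived measures:
`t_1/2 = ln 2 / β` and the immobile fraction
`Imof = 1 − a / (1 − (I0 − a))` (recovered amplitude over bleached
depth).  Cells are fitted individually and summarized afterwards, not
pooled.

**Numerics.** Nonlinear least squares (`scipy.optimize.curve_fit`,
parameters bounded positive) restarted from five deterministic
initializations: β from a log-linear regression of `log(Î0 − I)` against
time (Î0 = mean of the last 10% of frames) plus a geometric grid spanning
the recording; lowest RSS wins.  A flat post-bleach trace raises "no
recovery signal".  Confidence intervals come from a residual bootstrap
(resampled residuals re-added to the fitted curve, percentile intervals).

## Single-molecule kinetics

Two illumination schemes: (i) continuous 50-ms frames; (ii) 50-ms TF
snapshots every 1.2 s (interlaced with Hoechst snapshots).  Spots are
local maxima above `background + min_snr·σ` (σ from the MAD), refined by
a 7×7 2D-Gaussian least-squares fit; positions are in nm, y down.
Frame-to-frame linking is nearest-neighbour within a 500-nm gate.

**Bound events.** A molecule is chromatin-bound when consecutive-frame
localizations stay confined to a 160-nm-diameter region for ≥ 2 frames.
The confinement test grows the event window while every member stays
within 80 nm of the running window centroid — i.e. the window fits a
160-nm-diameter disc wherever the detections place it, so two
localizations up to 160 nm apart form a minimal event.  Anchoring the
disc on the first localization instead (stricter at the stated radius) is
available via `anchor="first"`.  A missed detection (frame gap) ends the
event.  Event durations follow the scheme timing: n frames of continuous
50-ms exposure mean ≥ n·50 ms bound (minimal event 100 ms); n snapshots
1.2 s apart mean ≥ (n−1)·1.2 s bound (minimal event 1.2 s).

**Rates.** With `N_b` bound events in Hoechst class a (bright /
intermediate / dark, from two thresholds on the preceding DNA snapshot,
assignment at the event's first localization), class area `A_a`, total
detected molecules `N_tot` and recording time `T`:

    ψon = N_b / (A_a · N_tot · T)        [µm⁻² s⁻¹]
    τ_res = (1/N_tot) Σ_j t_b,j          [s]

`N_tot` is global (not per class) and molecules without bound events
contribute zero bound time; dividing by bound molecules only is exposed
as an option.  A molecule with several disjoint events contributes each
event to `N_b` and their summed duration to its bound time.

## Sequence features and stability selection

Features per TF: seven category fractions (positively charged R/K/H,
aromatic F/W/Y/H, polar N/Q/S/T/C/H/D/E/R/K, hydrophobic aliphatic
A/V/L/I/M, tiny A/G/S/C, small tiny+N/D/T/P/V, bulky F/W/Y/R/K/I/L/M/H —
the table ships as an editable mapping; tests pin the shipped defaults,
not biology), the 20 single-residue composition fractions, the summed
Kyte–Doolittle hydropathy (GRAVY sum), residues in same-charge runs of
length ≥ 2 (positive R/K, negative D/E, neutral rest; run-count and
longest-run conventions exposed), disorder content from an external
per-residue mask (domains are runs of **more than 5** disordered
residues; sum and fraction), the DBD net charge (#basic − #acidic over
the union of DBD intervals, 0-based half-open; per-DBD mean exposed), the
dispersion of positive charges (population variance / mean of R+K counts
in all 5-residue windows; 0/0 → 0), and one-hot DBD-family flags for
families present in more than 10 cohort records.  Histidine is excluded
from charge counts by default.  Records with any missing feature are
dropped; unbounded columns are min-max normalized over the cohort.

**Model.** log(MBF) is regressed on the feature matrix with the lasso.
One run: draw a train/holdout split (defaults 401/100, redrawn every run;
fixed-split mode available), standardize predictors on the training rows,
select the penalty by 10-fold CV, record nonzero coefficients (original
scale) and holdout predictions.  Features with nonzero coefficients in
≥ 90% of 500 runs are stably selected; "nonzero" rather than "positive"
because negatively associated features are genuine findings, with signs
reported through the run-averaged coefficients.

**Penalty rule.** The CV-minimum penalty systematically over-selects
here: the cohort is fixed and runs differ only by the split, so a null
feature spuriously correlated with the response in the full sample stays
correlated in every 401-row subsample and is retained run after run.  The
default is therefore the one-standard-error rule (sparsest penalty within
1 SE of the CV minimum), the standard choice when the goal is support
recovery; `penalty_rule="min"` is available and appropriate when pure
prediction is the aim.

**Identifiability.** Exact support recovery by the lasso requires the
planted support not to be strongly correlated with null features
(irrepresentable condition).  Category fractions are exact linear
combinations of the single-residue fractions, and some feature pairs
(disorder sum / fraction; DBD net charge / K-R content) are correlated at
0.4–0.8 in realistic cohorts; supports planted on such features cannot be
recovered exactly with high probability by any penalty rule.  The
simulation study therefore plants its three effects on weakly-correlated
features (charge dispersion and two DBD-family flags, echoing the kinds
of features that are genuinely predictive of mitotic retention), with the
signal-to-noise ratio fixed at 5.

## Co-localization

Per nucleus: (1) pixel-wise Pearson correlation of the Hoechst and TF
channels over the nuclear mask; (2) per-density-class TF signal
fractions.  The nuclear mask thresholds the DNA channel with a 4-class
multi-Otsu (background + three chromatin densities, lowest threshold; a
2-class Otsu can cut inside the nucleus), fills holes and keeps the
largest component.  The density partition is 1-D k-means (k = 3) on the
nuclear Hoechst intensities: a deterministic quantile-seeded run competes
with 50 k-means++ restarts and the lower inertia wins — the quantile seed
alone can land in a local optimum when one density class dominates —
then clusters are relabeled high/medium/low by descending mean.
Fractions are TF-signal sums per class over the nuclear total and sum to
1 by construction.

## Association statistics

Pearson correlation for linear-scale panels, Spearman (average ranks on
ties) for log-scale ones, the two-sided Wilcoxon rank-sum test for group
comparisons, and the fraction of occupied motifs
FOM = (peaks containing the top motif) / (genomic occurrences of it).
For n ≤ 8 correlation p-values are exact permutation enumerations (all
n! rearrangements, two-sided on |r|); the rank-sum test is exact for
tie-free samples with min(n) ≤ 20 and a continuity-corrected normal
approximation otherwise.  Replicates are averaged by the caller before
correlating.

## Synthetic data

All generators are deterministic given (seed, parameters), carry both in
a `GroundTruth` record, and have truths recomputable in closed form.
Images are single-precision grayscale with 0.05 µm/px default pixel size;
noise is additive Gaussian (optional Poisson for the metaphase images).

- **Metaphase cells**: ellipse cell + plate; DNA channel bright only on
  the plate; TF channel carries the planted compartment intensities; the
  true MBF follows the two-compartment formula.
- **FRAP traces**: pre-bleach frames at 1, post-bleach from the
  single-exponential model, both ROIs multiplied by an acquisition-bleach
  decay (cancelled exactly by the normalization), constant background;
  default timing 5 pre-bleach frames, 0.38-s intervals, 74 s recovery.
- **Single-molecule datasets**: a disc nucleus with three concentric
  Hoechst classes of specified areas; per-class molecule counts are
  deterministic (area-proportional) so planted-rate standard errors are
  closed-form binomial.  Bound molecules sit at a fixed point from frame
  0 with Exp(τ) dwell (or forever), localized every frame with Gaussian
  jitter; after unbinding they diffuse.  Free molecules random-walk with
  `D_free` (default 5 µm²/s) and are localized with probability 0.1 per
  frame — fast diffusers are motion-blurred under 50-ms exposures, so
  their detection efficiency is far below that of bound molecules.  The
  planted ψon and τ_res are finite-sum expressions under the scheme's
  frame timing; they neglect confinement-criterion breakage by
  localization jitter (negligible for the 10-nm default against the 80-nm
  radius) and the rare spurious events of free molecules.  Not emulated:
  photophysics (blinking, dye bleaching), 3D PSF and defocus, rebinding.
- **Interphase nuclei**: disc nucleus with three concentric density
  regions (specified area fractions, strictly decreasing Hoechst levels);
  the TF channel is `base · enrichment` per region, so true signal
  fractions are normalized enrichment-area products.
- **Protein cohorts**: sequences drawn with per-protein Dirichlet residue
  compositions (length 200–600), random disorder masks and one or two
  random DBD intervals with families from a 15-member pool (yielding a
  ~50-column design matrix under the >10-record family rule);
  `log MBF = intercept + X·β + N(0, σ²)` on the normalized matrix, with
  σ set directly or via a target SNR.  Real cohorts differ in ways the
  generator does not capture — phylogenetic relatedness, composition–
  disorder coupling, family-specific DBD charge — so passing recovery
  tests demonstrates correctness of the machinery under the stated model,
  not performance guarantees on real proteomes.

## Problem sizes

The verification suite and the reproduction script size their simulations
to run comfortably on a single CPU: MBF recovery uses 45 cells over a
9-point MBF grid; FRAP uses 200 traces with 60 bootstrap resamples each;
event-calling equivalence uses 100 random tracks of up to 500
localizations; the stability-selection study keeps the full cohort
(n = 501, 50 features, SNR 5, 20 replicate cohorts plus 20 null cohorts)
and uses 120–150 splits per replicate instead of 500 — the retention
standard error at 150 runs is ~2%, small against the observed gap between
planted (≈100%) and null (≤75%) retention frequencies.

## Known limitations

- The cell-footprint threshold assumes background-dominated crops.
- Event calling allows no gap frames; blinking fluorophores fragment long
  events (as in the original criterion).
- ψon/τ_res inherit the global-`N_tot` convention; comparisons across
  datasets require comparable detection efficiencies.
- The lasso's averaged coefficients are penalized (shrunk) estimates;
  they order and sign effects but do not unbiasedly size them.
- Exact statistics are enumerative and deliberately limited to small n.
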