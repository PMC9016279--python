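# Methods

## Pipeline overview

The pipeline consumes five regional source series (cM1, iM1, cpMC, ipMC,
SMA; 128 Hz, 60 s per subject per session) and proceeds: IAF estimation →
band definition → epoching → per-epoch MVAR fit → DC and gPDC band averages
→ per-epoch IAAFT surrogate detection → ICW grading → group statistics.
All randomness derives from one master seed through `numpy.random.SeedSequence`
entropy tuples (subject, session, epoch, channel), so a rerun with an
identical configuration reproduces every numeric output byte-for-byte.

## MVAR estimation

Each 10 s epoch (N = 1,280 samples, mean-centered per channel; no detrending
or tapering) is fit by ordinary least squares on the lag-stacked regression
at fixed order p = 8. OLS is the standard estimator for short EEG epochs and
is unbiased under a correctly specified order; the residual covariance uses
denominator N − p, the effective sample count after lag truncation. BIC
order selection (functional form `ln det Σ̂_p + p·M²·ln N_eff / N_eff`,
epoch-averaged, ties toward parsimony) is available as a diagnostic; on
order-2 test systems it recovers the truth in ≥ 90% of 1,280-sample epochs.
The batched surrogate path solves the same normal equations in float32 for
throughput; the observed statistic is computed through that identical
routine (see *Surrogate testing*), so no precision asymmetry enters the
test.

## Spectral measures

Spectra are evaluated on 513 uniform frequencies on [0, 64] Hz (Δf =
0.125 Hz); band averages are arithmetic means over bins whose center lies in
the closed band interval. Two conventions deserve note:

* **gPDC numerator.** The squared-modulus gPDC is implemented as
  σ_i⁻²|Ā_ij|² / Σ_m σ_m⁻²|Ā_mj|² (receiver-variance numerator, the
  standard generalized-PDC form). A source-variance numerator σ_j⁻¹ breaks
  the defining property that the squared outflows of a source sum to 1;
  with the receiver form both normalization identities hold to 1e−10 on
  every model we construct or fit.
* **Squared moduli.** All connectivity values, band averages and statistics
  operate on squared moduli, the scale on which the 0–1 normalizations hold.

Band edges are subject-specific: α = [IAF−2, IAF+2] Hz, β = [IAF+2.5,
IAF+20] Hz, with the IAF estimated from the T0 recording (Welch PSD, 4 s
Hann segments, 50% overlap, segments zero-padded twofold so the PSD grid is
0.125 Hz; per-channel discrete argmax in 7.5–12.5 Hz averaged over the five
channels). No parabolic interpolation is used.

## Surrogate testing

The null hypothesis is the absence of cross-channel coupling. Per epoch,
every channel is independently resampled by IAAFT (distinct sub-seeds per
channel), each of the 100 replicates is refit and band-averaged exactly like
the original epoch, and a directed connection is declared present when its
observed band gPDC strictly exceeds the surrogate threshold.

* **Threshold convention.** The threshold is the surrogate order statistic
  of rank ⌈(1−α)(n+1)⌉ — the exact Monte-Carlo test: under exchangeability
  the observed value exceeds it with probability ⌊α(n+1)⌋/(n+1) (1/101 ≈
  0.0099 for n = 100 at α = 0.01). The naive "(1−α)·n-th of n" rank (99th of
  100) doubles the realized level to 2/101 ≈ 0.0198; with the exact
  convention the measured false-positive rate on fully uncoupled white noise
  is binomially compatible with α over thousands of connection-epochs.
* **IAAFT stopping.** The standalone surrogate generator iterates to the
  rank-permutation fixed point (cap 200). The pipeline default caps
  iterations at 10: on band-limited oscillatory series the surrogate's
  relative spectral error plateaus near 1% within ~10 iterations, while the
  exact fixed point needs a median of ~60 more iterations without further
  spectral gain; the cap keeps a full population run (21,600 surrogate
  refits) tractable. The final step is always the rank-ordered amplitude
  adjustment, so the surrogate's value multiset equals the original's
  exactly at any cap.
* **Per-epoch thresholds.** Surrogates are generated and thresholded per
  epoch (not pooled across epochs), because the ICW counts per-epoch
  detections; this is a documented choice where the procedure could
  plausibly pool.
* Replicates whose refit fails are dropped with a warning; more than 10%
  dropped aborts the epoch.

## Group statistics

* **Power transfer (DC).** Subject-level band DC = mean over the six epochs
  of the band-averaged |DC|²; one-tailed paired Wilcoxon signed-rank per
  directed connection (default alternative: T1 > T0), BH-FDR over the 20
  connections within each band. For ≤ 12 nonzero paired differences the
  p-value is computed by exhaustive sign-assignment enumeration on midranks
  (exact under ties); larger samples defer to scipy.
* **Topography (ICW/McNemar).** Paired binary unit = subject × epoch
  (18 × 6 = 108 pairs). With b/c the discordant counts (present at T0 only /
  T1 only), p = min(1, 2·P(Bin(b+c, ½) ≤ min(b, c))); BH-FDR within band.
  The subject×epoch pairing is a documented choice — the proportions being
  compared are ICW-weighted, and the epoch is the resolution at which ICW is
  defined.
* **Clinical correlation.** Spearman rho (tie-corrected) between per-subject
  Δ%ICW and ΔFMA / ΔFAC, computed for all 20 connections × 2 scores × 2
  bands and FDR-corrected jointly; constant inputs yield a missing rho.

## The synthetic population

No generative description of real ROI source series exists to copy, so the
generator is designed, not estimated; its defaults are the package's study
conditions. Each node carries an AR(2) α oscillator; premotor nodes add a
β oscillator at IAF + 10 Hz (pole radius 0.8). Per subject, IAF ~
Normal(9.07, 0.99²) Hz (clipped to 7.8–12.2 Hz). The α pole angle is placed
by a short fixed-point correction so each node's composite AR spectrum peaks
exactly at the subject's IAF (the raw AR(2) peak sits below the pole angle,
and the β factor tilts the peak upward).

Couplings are single lag-1 off-diagonal coefficients. The default graph is
acyclic — stability then reduces to the per-node AR poles regardless of
coupling strengths — and every source carrying a longitudinal change keeps
stable outflow in both sessions, because a source column with no outflow
makes the gPDC column denominator collapse to the tiny |Ā_jj(f)|² at
resonance, turning estimation noise into spurious detections. Defaults:
stable ipMC→SMA and SMA→cM1 (0.30); planted changes ipMC→iM1 and cpMC→cM1
(0 → 0.35) and cpMC→SMA (0.35 → 0); a clinically coupled cpMC→ipMC whose T1
strength is graded 0 → 0.25 across subjects. ΔFMA = round(80 × graded
strength) + bounded integer noise, clipped to 0–66 (only rank structure
matters for the Spearman stage); ΔFAC is constructed analogously on its 0–5
scale with coarser steps.

**Alpha bandwidth and its consequences.** The default α pole radius is 0.90,
giving the ~2 Hz-wide alpha peaks typical of resting EEG. Two measured
consequences: (i) surrogate detection stays calibrated — with radius ≥ 0.95
the rhythm's phase coherence persists across a whole 10 s epoch and
same-frequency oscillators acquire large spurious cross-coefficients
relative to the phase-randomized null, producing dozens of McNemar false
positives; (ii) the per-subject IAF argmax jitters by up to ~0.5 Hz, a small
fraction of the ±2 Hz α band, so band placement is barely affected. The
IAF-recovery validation therefore uses spectrally cleaner oscillators
(radius 0.97 via the `alpha_pole_radius` field), where the peak is
identifiable to within one 0.25 Hz Welch bin; with the realistic default
bandwidth the estimator is unbiased but one-bin precision is not attainable
from 60 s of data.

What the generator does **not** emulate: 1/f background activity, volume
conduction or source-leakage mixing, non-stationarity within and across
epochs, artifacts, lesion-dependent spectra, and inter-subject variability
beyond the IAF and the graded coupling. Passing tests therefore demonstrate
the pipeline's correctness and calibration on band-limited linear dynamics,
not robustness to those real-data features.

## Numerical notes and limitations

* Constructed and simulated models are rejected unless the companion
  spectral radius is < 1; simulation discards a 1,000-sample burn-in.
* Epoch-level detection rates of *true but unchanged* connections can shift
  between sessions when a neighbour's coupling changes (the gPDC column
  normalization couples a source's outflows; detectability of a fixed
  coupling depends on context). The default population keeps stable
  couplings strong enough to saturate detection at both sessions, which is
  why the McNemar stage isolates the planted changes; with borderline
  coupling strengths that guarantee disappears — a property of the method,
  not of the implementation.
* The DC/Wilcoxon branch reflects *total* (direct + mediated) flow: planting
  a new path changes the DC of many ordered pairs downstream, and estimated
  inflow toward isolated nodes is noise-dominated; its results are reported
  unthresholded by design alongside the FDR-corrected topographic branch.
* All tabular outputs are plain text (TSV/CSV/JSON) and round-trip
  losslessly at full float precision.
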