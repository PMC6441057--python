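# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package. Nothing here states an empirical result that the
test suite does not itself compute.

## Time and unit conventions

Seconds from recording start; bin `k` covers `[k·bin_s, (k+1)·bin_s)`;
sample `i` covers time `i/fs`. Signals are in microvolts, never rescaled.
The internal HDF5 container stores samples at their native dtype, so
write→read round-trips are bit-exact; EDF is read-only interoperability
(16-bit physical scaling is lossy) via a minimal built-in parser, since no
EDF library is available in the supported environment. Power is the squared
analytic (Hilbert) envelope of a band-passed trace — `A²` for a tone of
amplitude `A`; all coupling measures use ratios, so the convention cancels.

Zero-phase filtering uses symmetric (linear-phase) FIR kernels applied by
FFT convolution with "same" alignment, which is exact zero-phase filtering
at a fraction of filtfilt's cost on long traces. Kernels span ~3 periods of
the band's low edge, except narrow phase-amplitude-coupling bands, where the
kernel is sized for a transition width of half the bandwidth (a 3-cycle
kernel has a ~6 Hz transition band and cannot separate 2-Hz-wide phase
bands).

## Sleep staging

Per 2-s bin, rectified-EMG maximum and screw-channel band powers from 1-s
Hamming windows with 50 % overlap. Rules, precedence MOVE > REM > NREM > WI:

- MOVE: `emg_max > 2 × SD(emg_max over all bins)`. The study adjusted this
  threshold per animal against video; the package exposes a fixed-µV
  override instead (`StagingThresholds.emg_threshold_uv`). The SD is taken
  over bin-wise maxima of the *rectified* EMG (the raw-vs-rectified choice
  is unstated in the source description; rectified is the robust reading).
- REM: theta/delta ratio > 2 × its recording-level mean.
- NREM: alpha/gamma ratio > its recording-level mean.
- REM wins when both ratio criteria fire — it is the stricter criterion.
  This tie-break is a package decision; it is configurable in effect via
  the threshold factors.

Band edges: delta 1–4 and theta 5–9 Hz match the connectivity bands; alpha
10–15 and gamma 30–48 Hz are package choices (gamma stops below the 50-Hz
line). The merge passes relabel a single non-moving gap bin flanked by REM
(threshold 1 × mean theta/delta) or NREM (threshold 0.5 × mean alpha/gamma)
and iterate to a fixed point, so merging is idempotent. Epoch selection
takes, per REM bout of ≥ 10 bins, the first 10 REM bins and the 10 NREM
bins preceding a 10-bin excluded transition gap; the gap's own labels are
unconstrained (the exclusion is about the transition, not its content).

## Spectra, coherence, statistics

Welch estimates use 2-s Hamming windows with 50 % overlap (0.5-Hz grid,
19 segments per 20-s epoch), density-normalized so the PSD integrates to
the signal variance. Line noise (50 Hz ± 1 Hz) is masked out of band
averages and test families rather than filtered. Coherence is the standard
magnitude-squared form `|P_xy|²/(P_xx·P_yy)`; the unsquared variant is not
bounded by 1 and is not offered. With 19 half-overlapping segments the
independent-noise bias floor is ~1/13 (effective segments); with
non-overlapping segments it is the classic 1/K. Band connectivity is the
unweighted mean of coherence over in-band unmasked bins, computed per 20-s
epoch, averaged within animal before any group statistic (the animal is the
experimental unit).

t-tests are two-sided and pooled-variance by default (Welch by flag); a
degenerate zero-variance comparison with equal means returns p = 1.
Permutation tests permute group labels; all `C(n, n_a)` assignments are
enumerated when they fit the permutation budget (then the p-value is exact
and seed-independent), otherwise Monte Carlo with the add-one correction.
FDR control is Benjamini–Hochberg, one family per spectrum panel
(channel × state) and one per state × band set for connectivity. BH controls
the false discovery rate, not family-wise error: isolated null-bin
rejections at the α level are expected behavior, and the tests assert
rates, not absence.

## Phase–amplitude coupling

Tort-style KL modulation index: mean fast-band envelope in 18 phase bins of
the slow band's analytic phase, normalized to a distribution, MI =
KL(P‖uniform)/log 18 ∈ [0, 1]. Multiple REM segments are filtered
separately and pooled at the histogram stage, avoiding concatenation edge
artifacts. Comodulogram grid: phase 2–12 Hz step 1 (bandwidth 2), amplitude
20–120 Hz step 5 (bandwidth 10); summary = mean MI over cells with centers
in phase 7–8 × amplitude 60–90 Hz. The MI variant and grid are package
choices (the source names only "modulation index"); MI is invariant to
overall amplitude and drops to the null level under FFT phase
randomization.

## Ripple detection

Pipeline: band-pass 150–250 Hz → square → 10-ms boxcar → z-score against
all NREM + waking-immobility samples (movement excluded; EMG contaminates
the band). Candidates are runs ≥ 2 SD with sub-20-ms gaps merged, kept if
50–100 ms long and, in the default "band" mode, peaked within [2, 5] SD —
reading "2 to 5 SD" as an acceptance band that rejects large artifacts.
The FMAToolbox convention (boundaries 2 SD, peak must exceed 5 SD) is mode
`"fma"`. The study's manual screening against spiking activity is replaced
by an automatic veto: an event is rejected if its 500–1000 Hz power z-score
(own baseline) exceeds its ripple-band peak z. Intraripple frequency is the
median instantaneous frequency (analytic-phase derivative) inside the
event. Envelope smoothing (10 ms) and merge gap (20 ms) follow common
toolbox defaults; baselines are session-wide, not per-epoch.

## The synthetic world

The generator emulates what the analysis chain assumes: scheduled
MOVE/WI/NREM/REM bouts (defaults 60/60/240/120 s cycles, 2 kHz); a shared
1/f^α background across channels (giving band-structured nonzero coherence)
plus per-channel colored and white noise; NREM frontal delta (2 Hz, 40 µV),
continuous 10–15 Hz sigma background (10 µV), Poisson spindle bursts
(6/min, 0.7 s, 30 µV, shared across cortical/thalamic channels); REM theta
(7.5 Hz, 50 µV) on frontal/retrosplenial/hippocampal channels with
hippocampal 60–90 Hz gamma whose envelope is `(1 + κ·cos θ-phase)`,
κ ∈ [0, 1]; EMG bursts (100 µV) during movement against a 10-µV rest tone;
CA1 ripples (160 Hz, 60 ms) during NREM and, at 0.4 × the rate, waking
immobility; and an optional ripple-locked mFC spindle burst (gain × 10 µV
at ripple peak + lag) implementing the ripple→spindle coupling contrast.
Cohorts draw per-animal seeds from one master seed plus a lognormal global
gain (sd 0.2) per animal — the electrode-position/impedance variability
that dominates between-animal differences in absolute power in real data.
Ratio- and z-score-based measures are invariant to it by construction.

Three generator choices deserve explanation because naive alternatives make
the ripple-detection targets incoherent:

- **Spectral slope α = 2** (not α ≈ 1). Published LFP/EEG spectra fall off
  roughly as 1/f² above ~10 Hz. With α = 1 the Gaussian 150–250 Hz floor is
  within ~3× (amplitude) of a 3-SD ripple packet, and the packet–noise
  interference cross term swings the power envelope by ±70 % along the
  packet, fragmenting the detector's above-threshold run — no packet can
  then satisfy the 50–100 ms duration filter with a ≤ 5 SD peak.
- **Sharp-transient artifacts on CA1** (population-spike/twitch surrogate:
  biphasic 2-ms, 150 µV, 20/min). In purely Gaussian noise the smoothed
  ripple-band envelope has SD ≈ mean, so "2–5 SD above baseline" is barely
  above the noise floor. Real pyramidal-layer LFP contains millisecond
  transients far larger than the ripple band's Gaussian floor; they inflate
  the baseline SD so that genuine ripples sit at a modest 2–5 SD and
  artifacts far above 5 SD — precisely the regime the detection band (and
  the original manual spike screening) presupposes. The artifacts are
  themselves rejected by the duration filter and the spike veto.
- **Per-event calibration.** Ripple packets are sinusoids under a
  plateau-plus-cosine-ramp envelope. For each event the amplitude is solved
  (bisection on the quadratic envelope response) so the detector's peak
  z-score on the realized local background equals `amp_sd`, and the plateau
  length is iterated so the contiguous above-2-SD span equals `dur_ms`;
  events at uncalibratable locations (e.g. an artifact inside the packet
  window, ~5–25 % depending on rates) are skipped and never logged in
  ground truth. This makes recall, duration-fidelity and amplitude targets
  well-defined event by event rather than only on average. Ground-truth
  `start/end` record the calibrated detectable span.

What a green test on this world establishes: that the chain recovers states,
events, coupling strengths and group contrasts it is designed to measure,
at realistic SNR, with exact bookkeeping. What it does not establish:
performance on real mice — the generator has no volume conduction, no
biophysical oscillator dynamics, no state-transition ambiguity (bouts are
clean by construction), stationary within-state statistics, and only one
channel per region.

## Pipeline

`run_pipeline` executes stage → epoch pairs → {PSD, coherence, PAC} →
ripples → coupling → statistics over a cohort (synthetic or loaded from
files), writing one tidy CSV per stage plus mean ± SEM report tables and a
JSON-lines run log. Intermediates are plain CSVs, so any stage can be
recomputed from saved outputs (e.g. coupling from a stored ripple event
table); no content-addressed cache layer is used — at cohort scale the full
run is minutes, and plain files keep the determinism contract trivial
(fixed master seed → byte-identical outputs; the run log is excluded from
that contract because it records wall-clock timings). In the cohort
pipeline the PAC stage evaluates only the 7–8 × 60–90 Hz summary region
(the full comodulogram is available in the library); event caps, bands,
channels, α, permutation count and FDR families are configuration.

Scaled-down simulation sizes in the acceptance tests (shorter sessions,
50–100 events per animal instead of 585, 1 kHz for coupling cohorts) are
stated in the test docstrings; they preserve test power because the
simulated coupling effect is large relative to between-animal variance.

## Known limitations

- The EDF reader handles the common equal-rate, 16-bit case only.
- Staging thresholds are recording-global; drifting EMG baselines would
  need the per-animal override.
- The ripple detector assumes a usable NREM/WI baseline; sessions without
  immobility raise an error rather than guessing.
- Exhaustive permutation enumeration is limited to label assignments that
  fit in the permutation budget; beyond that p-values are Monte Carlo.
- The coupling analysis uses power ratios, not spindle event detection; a
  spindle detector is out of scope.
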