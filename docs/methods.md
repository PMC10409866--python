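# Methods

## The kinetic model

Decoding of one A-site codon by the ternary complex EF-Tu·GTP·aa-tRNA
(TC) is modelled as a continuous-time Markov chain over mechanistic
states:

```
UNBOUND <-> IB <-> CR -> POST_GTP -> ACCOMMODATED_CLASSICAL <-> HYBRID_APstar
             \______/        \-> DROPPED
```

- `UNBOUND -> IB` at the pseudo-first-order association rate `k1_app`
  (= k₁·[TC] at the working concentration; no bimolecular bookkeeping).
- `IB -> UNBOUND` at `k_rev1` (k₋₁), `IB -> CR` at `k2`.
- `CR -> UNBOUND` at `k_rev2` (k₋₂). In the FRET observable the codon
  reading decay is a loss of FRET, i.e. full dissociation; the sub-frame
  passage back through IB is not resolvable at 30.3 frames/s, so the
  chain takes CR directly back to UNBOUND.
- `CR -> POST_GTP` at `k_gtp`, lumping GTPase activation and GTP
  hydrolysis — only their composite is kinetically constrained here.
- `POST_GTP -> ACCOMMODATED` via the series composite of `k4` (Pi
  release / rearrangement) and `k5` (accommodation), collapsed to one
  exponential with the same mean (optionally kept as two sequential
  states, or extended by a parallel slow route `k_slow`/`k5b`, which
  produces visibly biphasic product formation as seen with
  heterogeneously modified tRNAs).
- `POST_GTP -> DROPPED` at `k7` (proofreading drop-off; absorbing).
- `ACCOMMODATED <-> HYBRID` at `k_hyb_fwd`/`k_hyb_rev` (the classical
  A/A, A/P to hybrid A/P* fluctuations of the peptidyl-tRNA).

Protocols: `wildtype` is the full scheme; `H84A` (GTPase-deficient
EF-Tu) sets `k_gtp = 0`, so nothing beyond CR is reachable and the CR
decay reports codon–anticodon stability; `hybrid_only` restricts the
chain to the two post-decoding states.

All rates are apparent first-order rates in s⁻¹; times are seconds.

Analytic machinery: hitting probabilities and conditional mean
first-passage times (MFPT) are linear solves over the transient block of
the generator; the conditional form E[T·1{hit}]/P(hit) is used because
drop-off makes unconditional means infinite. Occupancy time courses are
matrix exponentials. `chain_cycles` concatenates cycles by identifying
each cycle's accommodated state with the next cycle's unbound state;
without drop-off the MFPT through the chain is exactly the sum of the
per-cycle MFPTs (strong Markov property), which reproduces the
position-dependent delay of a modified codon placed later in the open
reading frame.

### Reference rate sets

`REFERENCE_RATES` carries one rate set per codon ("AAA", "m6AAA"). The
dissociation rates (k₋₁ = 8.1/15 s⁻¹, k₋₂ = 0.34/1.1 s⁻¹) and the
fluctuation rates (2.9/4.4 and 2.8/4.2 s⁻¹) are the single-molecule
measurements for these codons. The remaining forward constants (k₂,
k_gtp, k₄, k₅, k₇, k_pep) are *nominal* defaults chosen on the measured
apparent-rate scale (e.g. k₂ = 30 s⁻¹, consistent with the ~33 s⁻¹
apparent codon-recognition rate; k_gtp scaled ~8-fold lower for the
methylated codon, matching the observed τ_GTP ratio); they are not
measured elemental values and analyses must not treat them as such.
`k1_app` defaults to 0.7 s⁻¹, i.e. k₁ ≈ 1.4×10⁸ M⁻¹s⁻¹ at the 5 nM TC
concentration of the single-molecule delivery experiment; binding is
then concentrated early in the observation window, which is also the
regime assumed by the finite-window rate correction below.

## Forward model of the synthetic traces

State trajectories are drawn by exact stochastic simulation (Gillespie);
per-trajectory random streams derive from a single master seed through
`numpy` `SeedSequence` spawning, so datasets are reproducible to the
byte.

Rendering maps a trajectory to two per-frame channels. Frame i
integrates (i·Δt, (i+1)·Δt] at Δt = 1/30.3 s; the true frame FRET
efficiency is the occupancy-time-weighted mean of the state efficiencies
(UNBOUND 0, IB/CR/POST_GTP 0.9, classical 0.8, hybrid 0.6 by default).
Donor = I·(1−E), acceptor = I·E, each plus i.i.d. Gaussian read noise;
bleed-through is then *added* to the observed acceptor as β·donor
(β = 0.13), which makes the analysis-side subtraction an exact inverse.
Channel noise defaults to the value that gives a high-FRET state an
apparent width of ≈0.05 in E (the first-order propagation
sd(E) ≈ (σ/I)·√(E² + (1−E)²) is inverted by
`channel_noise_for_fret_sd`); state widths in the trace therefore come
from channel noise, not from an extra per-state jitter, and a noiseless
render reproduces the state means exactly.

Photobleaching is a single exponential event at 0.03 s⁻¹ per trace, in
acceptor mode (FRET drops to zero — indistinguishable from dissociation)
or donor mode (both channels die — detectable as a total-intensity step)
with equal probability. Blinking is not simulated (the analysis truncates
such events in real data). No spot PSFs or EMCCD gain statistics — this
generator emulates extracted per-molecule intensity tables, not movies.
Ground truth recorded per trace: the trajectory, bleach time and mode,
and the mechanistic class over the observable window (truncated at
either bleach event; binding episodes shorter than two frames are
treated as unobservable, because no frame-based analysis can see them).

What passing recovery tests does and does not show: the generator shares
the analysis' own structural assumptions (exponential dwells, Gaussian
noise, single-step bleaching), so recovery demonstrates correctness and
calibration of the estimators under the stated acquisition physics — not
robustness to un-modelled features of real data (blinking, baseline
drift, heterogeneous intensities, non-Markovian dynamics).

## The trace-analysis chain

1. **Quality selection.** Bleach steps are downward steps in the
   smoothed total intensity larger than 45% of the initial level; more
   than one step (an aggregate) rejects the trace, and the first step
   sets the truncation index. Channels must anticorrelate: the Pearson
   correlation of frame-to-frame differences over the pre-truncation
   region must be ≤ −0.05. These thresholds are declared defaults; the
   original semi-automated selection did not publish its values.
2. **Corrections.** acceptor′ = acceptor − 0.13·donor, then
   E = acceptor′/(donor+acceptor′). Frames after truncation or with
   near-zero total intensity (below 25% of the 75th percentile — both
   dyes dark, ratio undefined) are masked.
3. **Idealization.** Gaussian-emission HMMs with 1..4 states are fitted
   by EM from a deterministic quantile initialization (no RNG), the
   state count chosen by BIC, and the Viterbi path cut into dwells.
   The variance floor (min_covar 5×10⁻⁵) sits well below real state
   widths but rules out zero-variance spike states. Traces with fewer
   than 10 valid frames are skipped.
4. **Transition filter.** Adjacent dwells whose mean difference is
   smaller than the larger of the two state s.d.s are merged
   (duration-weighted), repeated to a fixed point — such steps cannot be
   distinguished from noise.
5. **Level collapse.** For dwell analysis, each fitted state maps to its
   nearest named level (dark 0, high 0.9, classical 0.8, hybrid 0.6) and
   consecutive same-level dwells merge, so HMM sub-states and
   boundary-blur states do not chop dwells. Each analysis passes the
   level set actually present in its experiment (a GTPase-deficient
   recording has only dark/high; blur frames must not map onto
   post-decoding levels that cannot occur).
6. **Dwell extraction.** A dwell of class src→dst is the residence time
   at the src level ending in a transition to the dst level. The final
   dwell of every trace is right-censored (window end or truncation) —
   counted, but excluded from the decay fit. For fast binding events on
   a dark background, durations can instead be measured by signal area
   (sum of frame efficiencies across the event, one frame of margin,
   divided by the reference level): camera blur makes frame counting
   systematically wrong for events only a few frames long, while the
   integrated signal is conserved.
7. **Decay fit.** The dwell histogram (integer frame grid, bin width two
   frames by default, widened for slow decays; bins starting before the
   two-frame resolvability floor excluded) normalized by its maximum is
   fitted by y = y₀ + A·e^(−t/τ); k_observed = 1/τ. The fit maximizes
   the binned Poisson likelihood — ordinary least squares on sparse
   exponential bins is strongly biased — and the offset is bounded to
   ±10% of the peak (the normalized histogram decays to zero; y₀ is a
   baseline nuisance). A geometric (frame-discrete) maximum-likelihood
   estimate is stored as a cross-check, and a Poisson χ² flags misfits
   (e.g. bimodal dwell mixtures). Fits are refused below 20 dwells.
8. **Rate corrections.** k_corrected = k_observed − k_photobleach − 1/T
   with k_photobleach = 0.03 s⁻¹ and T = 33 s. Under the forward model
   this is exact to first order: acceptor-mode bleach terminates dwells
   (adding its hazard to the decay), donor-mode bleach and the window
   end censor dwells whose exclusion adds the censor hazard to the
   fitted slope (≈1/T when dwell starts are spread early in the window).
   Negative corrected rates are flagged, not clamped. Reported values
   pool the dwells of all replicates (n is the total transition count);
   per-replicate fits provide the scatter.
9. **Missed-event correction** (reversible pairs only). Partner visits
   shorter than the camera dead time D (one frame) are not resolved and
   concatenate dwells; the observed dwell is a geometric sum of true
   dwells plus the hidden gap durations. Mean matching gives
   1/k_true = p·(1/k_obs − m·g) with p = e^(−k_partner·D),
   m = (1−p)/p and g = E[partner dwell | < D], solved for both
   directions by fixed-point iteration. Applied to the
   classical↔hybrid pair, where both dwell times are within an order of
   magnitude of the frame interval.
10. **Classification.** From the filtered idealization: traces already
    at a classical/hybrid level at the start of recording are
    `post_decoding`; traces that become visible later and reach a
    classical/hybrid level are `decoding`; visible-then-dark without
    such a visit is `rejected`; a bound phase persisting to the end of
    the valid window is `stalled`; no resolvable event is `dark`
    (excluded, counted). Detection requires E ≥ 0.125 for ≥2 consecutive
    frames. Ties break toward the earlier-listed class in
    (post_decoding, decoding, rejected, stalled). Per-replicate class
    percentages are compared across conditions by two-tailed Welch
    t-tests without multiplicity adjustment.
11. **State distributions.** Frames of a selected phase (boundary frames
    trimmed — they integrate two states) are pooled and fitted by a sum
    of Gaussians (EM, quantile-initialized, k-means restarts on
    non-convergence); component means are reported per replicate as
    mean ± s.d.
12. **Contours.** Traces are post-synchronized to their first detected
    binding transition and pooled on a fixed (time × E) grid with the
    trace count.

## Ensemble fitting

Relative fluorescence divides by the t = 0 value; product signals are
rescaled to [0, 1] per replicate (fitted rates are invariant to affine
rescaling). One- or two-phase exponentials (rising
y₀ + ΣAᵢ(1−e^(−kᵢt)) or decaying form, direction inferred from the
data unless forced) are fitted by variable projection — a log-spaced
grid over rates with the offset/amplitudes solved linearly, then a
bounded least-squares polish — which removes the local-optimum fragility
of weak second phases. Stopped-flow records are fitted on the average of
the technical replicates (the convention for displayed stopped-flow
curves); quench-flow reaction times are fitted per replicate and
aggregated as mean ± SEM across replicates. Phases are ordered by their
developed amplitude |Aᵢ(1−e^(−kᵢT))| within the record, i.e. by their
share of the observed signal change; a second phase with a developed
share < 5% or a rate ratio < 3 is treated as unidentifiable and the fit
falls back to one phase with a note. τ = 1/k_app per phase; delays
between constructs are differences of major-phase τ. Group comparisons
use two-tailed unpaired Student's or Welch's t-tests.

## Validation studies (`ribodecode.benchmarks`)

Each benchmark simulates data with a published value as ground truth and
recovers it through the full chain (problem sizes chosen to keep every
study at desk scale, a few minutes in total):

- codon-reading decay k₋₂ under the GTPase-deficient protocol, 3
  replicates × 200 traces per codon (0.34 and 1.1 s⁻¹; their ratio is
  the ~3.2-fold destabilization by the methylated codon);
- initial-binding dissociation k₋₁ = 15 s⁻¹ from 3 × 100 traces of
  rejected-type events (area-based durations — mean dwell is only two
  frames);
- classical↔hybrid rates 2.9/4.4 s⁻¹ from 3 × 150 post-decoding traces;
- post-decoding state means 0.79/0.58 and the codon-reading mean 0.96
  (width 0.03) by Gaussian-sum fits;
- stopped-flow apparent rates 70 s⁻¹ (record 0–100 ms) and 33 s⁻¹
  (record 0–0.5 s — the window must develop the 5×-slower minor phase,
  which a 100 ms record does not) at 1% noise, 5 replicates, two-phase
  fits with an 80% major phase;
- product-formation reaction times τ = 3.3 s (2nd-codon position) and
  the 16 s delay at the 4th-codon position (τ 18 vs 2 s), 2% noise,
  3 replicates.

`scripts/acceptance.py` runs all of these from one master seed.

## Known limitations

- Dwell rates close to or above the frame rate (>~30 s⁻¹) are not
  recoverable; the pipeline flags fast appearances rather than fitting
  them.
- The missed-event correction assumes a sharp dead time of one frame;
  the real detection probability rises smoothly over 1–3 frames, leaving
  a residual few-percent underestimate of fast fluctuation rates.
- The −1/T window correction assumes dwell starts early/spread in the
  window; generators with very slow binding would need the censoring
  treated explicitly.
- Class fractions depend on the nominal forward rates of the generator,
  which are not individually measured; classification is validated by
  agreement with ground-truth labels, not by reproducing published
  percentages.
- IB and CR share one FRET level, so "rejected" and "decoding" differ by
  progression, not by level — as in the underlying experiment.
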