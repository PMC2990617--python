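# Methods

## The exchange model and its assumptions

The observable in a hyperpolarised ¹³C experiment is longitudinal
magnetisation, not concentration: the injected substrate carries a large
non-equilibrium polarisation that decays with T₁ and is partially consumed
by every readout pulse.  Label flux between the substrate and product
pools (pyruvate↔lactate via LDH, fumarate→malate via fumarase) is modelled
as first-order exchange, giving the linear system

    d/dt [M_s, M_p] = [[-(k_fwd + r1_sub), k_rev], [k_fwd, -(k_rev + r1_prod)]] · [M_s, M_p].

Assumptions: the substrate appears instantaneously at t = 0 (direct
injection into a cell suspension; the in-vivo bolus shape is deliberately
out of scope), exchange is first-order over the observation window, and
relaxation is mono-exponential per pool.  Transverse magnetisation, B1
inhomogeneity, slice profiles and perfusion are not modelled.

The closed-form solution uses the degenerate-safe 2×2 matrix exponential
`e^{At} = e^{μt}[cosh(qt)I + sinh(qt)/q · (A − μI)]` with
`q² = ((a₁₁−a₂₂)/2)² + k_fwd·k_rev ≥ 0`.  Both eigenvalues `μ ± q` are
non-positive for non-negative rates, so the implementation works with
`e^{(μ±q)t}` directly (no overflow anywhere an optimiser may wander) and
switches to the series limit of `sinh(qt)/q` when `q → 0` (repeated
eigenvalue), so degenerate parameter combinations evaluate exactly rather
than failing.

### Pulsed readout

Each pulse records `sin θ · M_z` and leaves `cos θ · M_z`.  Because the
cos-loss is a scalar common to both pools it commutes with the linear
evolution, so the signal at pulse *i* is `sin θ · cosⁱθ · M(tᵢ)` with `M`
the continuous solution — evaluated vectorised, and verified in the tests
against per-millisecond brute-force stepping with explicit discrete pulse
events.  RF losses are kept discrete by default because that is what a
transient-by-transient acquisition does physically; an `effective_decay`
mode that folds them into `r1_eff = r1 − ln(cos θ)/TR` is provided for
comparison (on a uniform train the two differ only by a constant factor).

Acquisition presets: cell suspensions 6°/1 s/240 transients; tumours
5°/1 s/128 transients with every sixteenth transient excluded from fits
(acquired from the whole coil volume rather than the tumour slice — the
pulses still occur, so they are simulated and then masked).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `r1_sub`, `r1_prod` | 1/30 | s⁻¹ | polarisation lifetime ~30 s in vivo; fixed, not fitted — over one ≤240 s bolus, k and r1 are strongly collinear, so floating both is not identifiable. Configurable. |
| `t_first` | one repetition time | s | delay from substrate appearance to the first pulse |
| fit mode | unidirectional | — | the reported constants are *apparent* rate constants; a bidirectional mode (free `k_rev`, or `k_rev` tied to `k_rev_ratio·k_fwd` for a fixed-pool-ratio convention) is provided, and whichever mode is chosen should be used consistently across cohorts |
| multi-start | 5 log-spaced k₀ in [10⁻⁴, 0.5] | s⁻¹ | a single start is prone to the k ≈ 0 basin when product signal is weak |
| loss | OLS, both channels, product weight 1 | — | noise is additive and channel-independent in these spectra, so unweighted OLS is the maximum-likelihood choice; alternative weighting exposed |
| `m0_prod` | 0 | a.u. | the product pool starts unlabelled (75 mM *unlabelled* lactate in the cell experiments carries no ¹³C signal) |

The rate constant and initial magnetisation are log-parameterised, so
negative-rate solutions cannot occur; standard errors come back to the
natural scale by the delta method, with the residual variance estimated
from the fit (`σ² = SSR/dof`).

## Spectrum synthesis and quantification

Spectra are sums of Lorentzian lines (area = amplitude) plus i.i.d.
Gaussian noise, on a ppm axis from the spectral width and carrier
frequency (32 kHz at 100 MHz by default).  Default carboxyl shifts (ppm):
pyruvate 171.0, lactate 183.2, pyruvate hydrate 179.5, alanine 176.5,
fumarate 175.4, malate C1 181.8, malate C4 180.6 — literature values,
configurable; with the in-vivo 60 Hz linewidth these proximities reproduce
the real masking of malate by lactate/pyruvate-hydrate.  Cell-suspension
linewidth defaults to 20 Hz.

Quantification is two-regime by design:

* **Isolated peaks** — trapezoidal integration over `centre ± window`,
  minus the median intensity of peak-free regions (≥20 linewidths from any
  declared peak: Lorentzian tails are heavy, and including near-tail
  regions makes the median converge to the mean residual tail under noise,
  a small but real bias), divided by the analytic capture fraction
  `(2/π)·atan(window/hwhm)` — an uncorrected ±20-linewidth window still
  misses ~1.6% of a Lorentzian's area.
* **Overlapped peaks** — when another declared peak lies within
  `window + 5 linewidths`, windowed integration is biased by construction
  (for the in-vivo malate doublet, 1.2 ppm apart at 0.6 ppm FWHM plus the
  fumarate tail, the bias is ~20% on the malate/fumarate ratio, and worse
  at low malate).  The area is instead taken from a joint linear
  least-squares decomposition onto Lorentzians of known shift and
  linewidth plus a constant offset — the standard spectroscopic treatment
  of overlap — and the event is recorded in the run log.  Only positions
  and widths are assumed known (instrument knowledge); amplitudes are
  always estimated.

The two inequivalent malate resonances are summed into one intensity
(slightly negative noise areas clipped to zero, logged), and the
malate/fumarate ratio is that sum over the fumarate area.  The dynamic
fits consume peak areas, not raw spectra; the spectral path exists to
exercise the quantification end to end.

## The synthetic cohort generator

The generator is the study-conditions oracle: its defaults encode the
treatment effects the experiments reported, and everything downstream is
tested against it.

* **Cell schedule** (baseline k_P = 0.05 s⁻¹, a plausible suspension value;
  the printed results constrain only the *relative* changes): k_P scales
  1 → 0.52 (72 h) → 0.28 (96 h); k_F = 0 until necrosis appears, then
  2.8×10⁻⁴ and 6.1×10⁻⁴ s⁻¹; NADH autofluorescence scales 1 → 0.23 → 0.11.
  Apoptotic/necrotic fractions (0.05/0.03, 0.40/0.18, 0.30/0.38) follow
  the reported time-course shape — apoptosis peaks at 72 h then declines,
  necrosis keeps rising — and keep k_F ≈ 1.6×10⁻³·necrotic_frac, the
  linear link the correlation analysis assumes.
* **Tumour schedule**: baseline k_P = 0.075 s⁻¹ scaling by 0.038/0.075 at
  24 h and 0.020/0.075 at 48 h; no dynamic k_F (in vivo the malate signal
  supports only the 20-s snapshot ratio).
* **Variation**: per-sample rate constants are mean-preserving log-normal
  draws with CV 10% (a declared assumption — the printed s.d. constrain
  only group-level spread); polarisation uniform in 18–25%; cell count
  uniform in 2–6×10⁷; observation noise additive Gaussian with sd = 2% of
  each trajectory's initial substrate signal.
* **Cytometry**: three log-normal populations in the annexin × sytox
  plane (viable double-negative, apoptotic annexin⁺, necrotic
  double-positive), mixing weights from the schedule, 20 000 events per
  sample; NADH log-normal with median scaled by `nadh_scale` (the
  log-normal mean scales identically, so the percent change in the mean
  equals the schedule effect up to sampling error).  Default gates sit at
  the geometric midpoints between the negative and positive population
  medians — the valley between the generated modes.

What the generator does **not** emulate: bolus pharmacokinetics, baseline
drift and phase errors in real spectra, scatter gating/compensation/doublet
exclusion in cytometry, tumour growth, and any correlation structure
between a sample's kinetic and cytometric readouts beyond the schedule
point they share.  Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to every
artefact of scanner data.

## Statistics

Group comparisons use the two-sided Mann–Whitney U test.  For pooled
n ≤ 12 (every group size in these experiments) the permutation
distribution of U is enumerated in full over all C(n, n_a) assignments of
the pooled mid-ranks — exact under ties, unlike the common closed-form
tables — with the two-sided p from the distribution's symmetry about
n_a·n_b/2; larger samples use the tie-corrected normal approximation with
continuity correction.  All-tied input gives p = 1.  Significance is
declared at p < 0.05 with no multiple-testing correction (none was applied
in the source analyses; stated here deliberately).

Percent change is reported as `100·(baseline − followup)/baseline`
(positive = decrease, rounded to integer percent for display; raw floats
kept in JSON), fold change as `followup/baseline`, and the necrosis–k_F
association as the squared Pearson correlation.  Note two conventions in
the source worth flagging: a ratio pair (0.017 → 0.090) is quoted as
"5.4-fold" where the computed ratio of printed means is 5.29 (rounding of
unprinted means), and one "55%" increase equals the change as a fraction
of the *final* value; the package always reports the conventional
definitions and leaves reconciliation to the reader.

## Numerical choices and limitations

* Trajectory fits need ≥10 usable transients; fewer is rejected up front.
* The multi-start search stops early only when a start reproduces the data
  to a relative residual of 10⁻⁹ (noiseless round trips); noisy fits
  always run all starts.
* k_F-scale fits (~3×10⁻⁴ s⁻¹) leave a product signal peaking near 0.3% of
  the initial substrate signal, so at the default 2% observation noise a
  single fit carries ~60% relative error (Cramér–Rao-level, not an
  estimator defect).  Group averaging is essential at that scale — the
  tests read the necrosis–k_F linearity from 16-replicate means — and this
  is precisely the regime in which dynamic malate measurements stop being
  feasible in vivo.
* Reported percent effects from small cohorts (n = 4/group at CV 10%)
  carry ~4-point sampling scatter; the acceptance script averages 10
  replicate cohorts to estimate the population effect, while the test
  suite pins one fixed-seed cohort.
* Trapezoid integration needs a few points per half-width to avoid
  discretisation bias; the default 8192 points over 320 ppm give ~4 points
  per cell-linewidth HWHM (≈0.3% bias), and tests that probe unbiasedness
  use finer grids.
* Problem sizes throughout (240/128-transient trajectories, 10–16 samples
  per condition, 100-replicate calibrations, 20 000-event cytometry) were
  chosen so the full suite exercises every path at full fidelity in well
  under a minute of fitting time.
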