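# Methods

`ssvepkit` implements training-free frequency decoding for steady-state
visual evoked potential (SSVEP) brain-computer interfaces driven by
*hybrid* visual stimuli: a conventional flicker (FS) or pattern-reversal
(PRS) driver combined with a periodic size modulation (none / square /
triangular / sine). This note records the models, the parameter choices,
and the places where the design was genuinely open.

## Stimulus model

A stimulus is defined by its base kind, motion waveform, nominal
frequency `f`, refresh rate (60 Hz default), and modulation ratio
`r = 0.33`. The nominal frequency counts full on-off cycles per second
for FS and pattern reversals per second for PRS; the size modulation
therefore runs at `f` for FS and `f/2` for PRS, which is what makes PRS
hybrids drive a *subharmonic* EEG response at `f/2`. All size profiles
span `[1 - r, 1 + r]` with period `1/f_m`. Phase conventions the
underlying physiology does not pin down were fixed for reproducibility:
sine motion starts at the base size and grows; triangular motion starts
at the minimum; square motion starts enlarged, aligned with the flicker
"on" state; the frame state uses the left-closed rule
`state(k) = parity(floor(rate * k / refresh))`. The 6.67 Hz stimulus is
treated as the nominal value 6.67 everywhere (frame tables, references,
simulator) rather than the monitor-exact 20/3: internal consistency
between the EEG model and the decoder matters more than monitor
arithmetic.

## Preprocessing

Raw recordings are decimated to 256 Hz by polyphase resampling
(integer factors only), bandpassed 2-54 Hz with a design-order-6
Butterworth filter applied forward-backward (zero phase; effective
12th-order magnitude — the common reading of "sixth-order zero-phase";
the design order is configurable for the other reading), and cut into
epochs starting `0.135 s` after each stimulus onset — a literature
value for visual-pathway latency, exposed as an overridable constant.
Epoch indices are 0-based half-open: start `round((onset_s + 0.135) fs)`,
length `round(w fs)`. Epochs that would run past the recording raise an
error; nothing is silently padded.

## Decoders

**CCA.** For each candidate frequency `f` a reference matrix holds
sin/cos pairs at harmonics `h f`, `h = 1..N_h` (`N_h = 5`), on the time
grid `n = 1/fs ... N_s/fs`. The decision statistic is the largest
canonical correlation between the mean-centered epoch and the reference.
It is computed by rank-revealing pivoted QR of both centered row spaces
followed by an SVD of the cross-projection (relative rank tolerance
1e-10), which is numerically stable, handles rank-deficient epochs
(e.g. noiseless simulations with proportional channels), and is exactly
invariant to invertible channel mixing. The predicted frequency is the
argmax; ties break toward the lowest frequency.

**FBCCA.** The epoch is filtered into `N_m = 5` sub-bands (4-52, 8-52,
12-52, 16-52, 20-52 Hz; zero-phase Butterworth, design order 6 — the
family/order of the original filter bank is unstated, so the
preprocessing family is reused and both are configurable) and the score
is `sum_m w(m) rho_m^2` with `w(m) = m^-a + b`, `a = 1.25`, `b = 0.25`.

**sFBCCA.** Adds one term for PRS hybrids: the epoch filtered to
1-52 Hz is scored against the reference extended with a sin/cos pair at
`f/2`, weighted by `w_sub = m_sub^-a + b` with `m_sub = 0.5`, so
`w_sub ≈ 2.63` exceeds every sub-band weight. The five ordinary
sub-band terms keep the plain reference; only the subharmonic term uses
the extended one. This preserves an exact, bit-identical reduction to
FBCCA when `w_sub = 0` (exposed as `w_sub_override`). The alternative
reading — extended references in every term — is available via
`extended_reference_in_subbands`. An `m_sub` sweep driver explores the
weight's effect on accuracy.

## ITR

The Wolpaw information transfer rate per decision, scaled to bits/min
by the window length `T`:
`ITR = (60/T) [log2 N + p log2 p + (1-p) log2((1-p)/(N-1))]`, with
`0 log 0 = 0`. Below chance (`p < 1/N`) the formula is returned as
computed rather than clipped; sweep consumers should treat that regime
qualitatively.

## Synthetic sessions

The simulator emulates the layout of a four-class experiment: targets
at 6, 6.67, 7.5 and 10 Hz, 5 s stimulation trials separated by 3 s cue
gaps, 5 trials per class per session (all configurable), 8 channels
with a posterior gain gradient peaking at the Oz-equivalent channel.
Each trial adds, from 0.135 s after onset, sinusoids at the harmonics
`h f` (h = 1..5) with per-trial random phases, plus — in PRS-hybrid
mode — a subharmonic at `f/2`.

Component amplitudes are free parameters of the model (no deposited
recordings exist to calibrate against) and were fixed once:
fundamental 1.0, harmonics 0.6 / 0.3 / 0.15 / 0.1, and subharmonic 1.0
in PRS-hybrid mode. The subharmonic equals the fundamental because the
half-rate size modulation is a motion stimulus in its own right — PRS
hybrids have two *main* stimulation frequencies (SSVEP at `f`, motion
response at `f/2`), not a weak sideband.

Background noise is `1/f^alpha` (alpha = 1) Gaussian noise with a 0.6
common-mode fraction: a shared pink component plus independent
per-channel residuals, each channel unit-variance, scaled by `sigma`
(default 2.5). The spatial correlation matters: with fully independent
noise, 8-channel CCA averages the background away and classification
only degrades at noise levels so high that the component peaks the
simulator is supposed to reproduce would be invisible in a 5 s
spectrum. Under the defaults, the subharmonic peak stands about 3x
above the neighbouring noise floor in a 5 s Oz spectrum and FBCCA
decodes 1 s windows at roughly 90% — the operating regime the method
comparisons are meaningful in. An `snr_db` knob replaces `sigma` with
the value that sets component power over 1-54 Hz noise power at the
Oz-equivalent channel to a requested ratio.

What the simulator does *not* model: eye blinks and EMG artifacts,
alpha-band rhythms, inter-subject amplitude/latency variability,
non-stationarity within a session, and realistic volume-conduction
topographies (all components share one spatial pattern). Passing tests
therefore demonstrate correctness and the qualitative behaviour of the
decoders under a controlled signal model, not human-subject performance
levels.

## Numerical choices and degenerate inputs

- CCA rank tolerance 1e-10 (relative); all-zero epochs raise a
  degenerate-input error rather than returning 0.
- Amplitude estimation uses the single-bin DFT magnitude `2|X_k|/N` at
  the nearest bin and warns when a component misses the grid by more
  than a quarter bin.
- Epochs shorter than `fs/2` samples trigger a warning (filter-bank
  transients dominate) but are still scored; the standard windows
  (1-3.5 s) are unaffected.
- Sweeps are bit-reproducible given (seed, config); per-trial phases
  and noise all derive from one seeded generator.

## Problem sizes used in the checks

End-to-end comparisons run on 200-trial sessions (50 per class) for
noise sweeps and 4 x 52-trial sessions for the FBCCA/sFBCCA
comparison, at 1 s windows — large enough for stable proportions while
keeping the full suite fast on a single CPU.
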