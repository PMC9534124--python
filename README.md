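# ssvepkit

Training-free frequency decoding for SSVEP/SSMVEP brain-computer
interfaces, built around hybrid visual stimuli that combine a flicker
(FS) or pattern-reversal (PRS) driver with a periodic size modulation.

A user gazing at one of several stimuli flickering at distinct
frequencies produces occipital EEG with power at that frequency and its
harmonics. The decoder's job is to recover the attended frequency from
a short multichannel epoch, with no training data. `ssvepkit` provides
the standard tools and one extension:

- **CCA** — score an epoch `X` against sin/cos templates
  `Y_f = [sin(2πfn); cos(2πfn); …; sin(2πN_h fn); cos(2πN_h fn)]`
  by the largest canonical correlation
  `ρ_f = max_{w_x,w_y} corr(w_xᵀX, w_yᵀY_f)`; pick `argmax_f ρ_f`.
- **FBCCA** — decompose the epoch into `N_m = 5` sub-bands (4–52 …
  20–52 Hz) and combine `ρ_f = Σ_m w(m)·(ρ_f^m)²` with
  `w(m) = m^{-a} + b` (`a = 1.25`, `b = 0.25`).
- **sFBCCA** — for PRS hybrids, whose size modulation at `f/2` evokes a
  subharmonic response, add a term from the 1–52 Hz band scored against
  a template extended with a sin/cos pair at `f/2`:
  `ρ_f = Σ_m w(m)·(ρ_f^m)² + w_sub·(ρ_f^sub)²`,
  `w_sub = m_sub^{-a} + b` with `m_sub = 0.5`.

Around the decoders: the eight hybrid-stimulus temporal profiles
(frame-quantized at the monitor refresh), the preprocessing chain
(decimate to 256 Hz → zero-phase 2–54 Hz Butterworth → latency-shifted
epochs), Wolpaw ITR metrics and sweep drivers, and a fully seeded
synthetic EEG simulator so everything is testable without recordings.
See `docs/methods.md` for the models and parameter rationale.

## Worked example

```python
import ssvepkit as sk

cfg = sk.SimulationConfig(seed=8, include_subharmonic=True, n_trials_per_class=5)
session = sk.generate_session(cfg)           # 20 trials, 4 classes
rec = sk.bandpass(session.recording)         # zero-phase 2-54 Hz

for method in ("cca", "fbcca", "sfbcca"):
    preds, truths = sk.classify_session(rec, 1.0, sk.ScoringConfig(method=method))
    acc = sk.accuracy(preds, truths)
    print(f"{method:7s} accuracy {acc:.2f}  ITR {sk.itr(acc, 4, 1.0):6.1f} bits/min")
```

prints

```
cca     accuracy 0.70  ITR   38.6 bits/min
fbcca   accuracy 0.70  ITR   38.6 bits/min
sfbcca  accuracy 0.80  ITR   57.7 bits/min
```

One simulated PRS-hybrid session at the default (moderate) noise level,
decoded from 1 s windows: plain CCA and FBCCA recover 14 of 20 trials;
the subharmonic term lifts sFBCCA to 16 of 20, worth ~19 bits/min of
information transfer rate at this window length. Accuracies vary with
the session seed; directional comparisons should pool hundreds of
trials (see `ssvepkit.window_sweep` and the test suite).

## Command line

```bash
ssvepkit stimgen --frequency 6 --out frames/          # 8 frame tables (CSV)
ssvepkit simulate --seed 1 --mode prs-hybrid --out rec # fixture recording
ssvepkit classify --recording rec --method sfbcca --window 1 --out preds.csv
ssvepkit sweep --recording rec --out sweep.csv         # windows x methods
ssvepkit msub-sweep --recording rec --out msub.csv     # subharmonic weight grid
```

Recordings use a plain-text fixture format (`<stem>.csv` matrix +
`<stem>.json` sidecar with sampling rate, channel names and the event
table); EDF/BDF files are read via MNE.

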