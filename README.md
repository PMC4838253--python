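# tempasym

Temporal asymmetry in hearing: ramped and damped sinusoids are carrier
tones multiplied by a periodically rising or decaying exponential
envelope.  The two members of a pair are time-mirror images with
*identical* long-term spectra, yet they sound different — ramped trains
are heard as continuous tones with a salient pitch, damped trains as a
drumming sound with weaker pitch, with the perceptual gap largest at an
envelope half-life of about 4 ms.  Any model built on a fixed, long
analysis window cannot tell the two apart; the difference is evidence
for *stimulus-dependent* windows of temporal integration in the auditory
system, and it leaves a measurable trace in the N100m deflection of the
auditory evoked field.

`tempasym` is a Python toolkit for studying this phenomenon end to end.
It is aimed at auditory modellers and MEG researchers and provides:

* **stimuli** — ramped/damped train synthesis (1 kHz carrier, 50 ms
  cycles, half-lives 0.5–32 ms, √T½ level normalisation), WAV I/O, and
  the temporal asymmetry index `AI = (x_r − x_d)/(x_r + x_d)`;
* **periphery** — a gammatone/ERB filterbank plus functional hair-cell
  transduction producing auditory-nerve spike probabilities `p(t, k)`;
* **gpm** — a hierarchical generative pitch model: a coincidence layer
  `A₁(t, l) = Σₖ p(t,k) p(t−l,k)` over cochlear delay lines, two leaky
  integration stages with effective windows `Eₙ = τₙ/(1 + ωλ)`, and a
  top-down controller that shrinks the windows on pitch
  prediction/expectation mismatch — plus the static-window
  autocorrelation control and an N100m-predicting read-out;
* **aim** — a simplified auditory image model: adaptive-threshold strobe
  detection, strobed temporal integration into a stabilised auditory
  image (30 ms buffer decay), and carrier-ridge salience;
* **psychophysics** — paired-comparison schedules and Bradley–Terry–Luce
  maximum-likelihood scaling of tonal salience;
* **aef** — evoked-field quantification: baseline/drift correction,
  N100m amplitude and latency, sustained-field depth, pooled Wilcoxon
  rank-sum statistics, hemispheric contrasts, and a cross-validated
  linear map from the model derivative to the field;
* **synthetic** — a seeded generator of subject-level source waveforms
  and paired-comparison choices with the study's statistical structure,
  so the whole pipeline is testable without any recordings.

## Worked example

Run the two critical 4 ms stimuli through both models:

```python
import tempasym as ta
from tempasym import aim, gpm, periphery
from tempasym.stimuli import asymmetry_index

readout = {}
for etype in ("ramped", "damped"):
    w = ta.make_stimulus(4.0, etype)                  # 1 s, 48 kHz, RMS-normalised
    nap = periphery.waveform_to_nap(w)                # 100-channel NAP at 8 kHz
    cascade = gpm.run_cascade(nap)                    # adaptive-window pitch model
    sai = aim.build_sai(nap, aim.detect_strobes(nap)) # strobed auditory image
    readout[etype] = (
        cascade.peak_lag_ms(),
        cascade.track.settled_salience(),
        sai.summary_peak_interval_ms(),
        aim.carrier_salience(sai, 1000.0),
    )
    print(f"{etype:>6}: pitch lag {readout[etype][0]:.3f} ms, "
          f"GPM salience {readout[etype][1]:.4f}, "
          f"SAI peak at {readout[etype][2]:.3f} ms, "
          f"SAI salience {readout[etype][3]:.4f}")

print("AI (GPM):", round(asymmetry_index(readout['ramped'][1], readout['damped'][1]), 4))
print("AI (SAI):", round(asymmetry_index(readout['ramped'][3], readout['damped'][3]), 4))
```

prints

```
ramped: pitch lag 1.000 ms, GPM salience 0.1267, SAI peak at -1.000 ms, SAI salience 0.3591
damped: pitch lag 1.000 ms, GPM salience 0.1139, SAI peak at -1.000 ms, SAI salience 0.1600
AI (GPM): 0.0534
AI (SAI): 0.3835
```

Both models place the pitch at the 1 ms carrier lag (1 kHz) for both
stimuli — the percept has the same pitch *value* — while the salience
read-outs are larger for the ramped train, and the strobed-integration
image amplifies the asymmetry far beyond its size at the level of the
simulated auditory nerve.  Across the full half-life set the salience of
both models grows with T½ and the asymmetry index peaks at 4 ms,
mirroring the psychophysics and the N100m amplitudes.

A command-line interface mirrors the modules
(`tempasym synth|periphery|gpm|aim|btl|simulate|aef`), e.g.

```sh
tempasym synth --halflife 4 --type ramped --out stim/
tempasym simulate --seed 7 --out data/
```

## Caveats

The periphery is a functional approximation (gammatone + rectification,
compression, saturation, phase-locking low-pass, weak adaptation), not a
transmission-line cochlea; the top-down controller approximates a
mechanism whose exact dynamics are not public; and the synthetic data
encode the target pattern by construction — see `docs/methods.md` for
the model equations, parameter defaults, and what the tests do and do
not establish about real recordings.
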