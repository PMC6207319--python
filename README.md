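# blinksim

Generative models of human spontaneous blinking, and the distribution
analysis that characterises their inter-blink intervals (IBIs).

Humans blink 20–30 times a minute — far more than eye lubrication
requires — and the intervals between spontaneous blinks form strikingly
different distributions across people and tasks: positively skewed,
approximately normal, widespread peak-less, and bimodal.  `blinksim`
implements two first-passage-time models of the blink generator for
researchers studying blink timing and its cognitive correlates:

* **OSD** — a one-dimensional stochastic diffusion model.  The
  generator's potential follows an Ornstein–Uhlenbeck process
  `dX = (−βX + μ)dt + φ dW` with decay rate β, mean input μ and noise
  φ; a blink is the first passage to a constant threshold, after which
  X resets.  This classic model produces skewed, normal and peak-less
  interval distributions, but never bimodal ones.
* **LIF with an oscillating threshold** — a leaky integrate-and-fire
  generator `dV/dt = −cV + I + ξ` whose input arrives binomially
  (amplitude b with probability p per step) and whose firing threshold
  fluctuates sinusoidally, `θ(t) = a + k·sin(2πt/τ)`, standing for slow
  physiological modulation of blink excitability.  The oscillation lets
  the model additionally produce bimodal and trimodal interval
  distributions: bursts of short intervals when the threshold trough
  traps the potential, prolonged intervals between troughs.

The analysis half estimates the IBI density with a Gaussian KDE over
the 0–20 s range (plug-in bandwidth), finds peaks by derivative sign
changes with absolute (> 0.1) and relative (quarter-spread) admission
rules, classifies modality, runs parameter-grid sweeps, and searches
for LIF parameters whose bimodal peak pair matches classic
experimentally observed distributions (bundled reference table) within
±0.025 s.

## Worked example

Simulate the oscillating-threshold model in its bimodal regime — trough
`a − k = 0.15`, period `τ = 9 s`, decay `c = 0.7` — and classify the
resulting interval distribution:

```python
from blinksim import LIFParams, SimulationClock, simulate_lif, IBIDensityClassifier

params = LIFParams(c=0.7, k=0.85, a=1.0, tau=9.0)          # sigma = 0, b = 1, p = 1/2
sample = simulate_lif(params, SimulationClock(seed=42))     # dt 1 ms, 3000 s
clf = IBIDensityClassifier().fit(sample)
print(len(sample), clf.modality_, clf.peaks_, round(clf.bandwidth_, 3))
```

```
1665 bimodal [0.49  6.985] 0.624
```

The run produced 1665 intervals whose kernel density (bandwidth
0.62 s) has two admitted peaks: a burst peak at 0.49 s — the regrowth
time from reset to the threshold trough — and a prolonged-interval peak
at 6.99 s, trailing the 9 s threshold period (peak spacing is always
below τ).  This is the peak pair of a classic experimentally observed
bimodal blink distribution; `blinksim.match_reference` automates the
search over decay values for each bundled reference case.

The same estimator is a regular scikit-learn estimator
(`get_params`/`set_params`, fitted attributes), and module functions
(`estimate_density`, `find_peaks`, `classify`, `match_peaks`) expose
each step separately.

A command-line interface mirrors the library:

```sh
blinksim simulate-lif --c 0.7 --k 0.85 --tau 9 --seed 42 --out ibis.txt
blinksim classify --in ibis.txt --out report.json
blinksim sweep --model lif --stride 8 --seed 1 --out sweep_out/
blinksim match --case 6 --seed 1 --out matches.tsv
```

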