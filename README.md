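# polyburst

Quantitative machinery for studying how the Polycomb system (PRC1 /
H2AK119ub1) represses transcription by sustaining a long-lived deep
promoter OFF state. The package covers three experimental modalities of
live-cell single-gene biology, each backed by a synthetic-data module
with known ground truth:

1. **Live-cell nascent-transcription trajectories** (MS2/MCP-type
   imaging, 8-h movies at 4-min frames): spot following, photobleaching
   correction, single pre-mRNA intensity calibration, and an
   inflection-point caller that extracts transcription **ON periods**
   (duration, amplitude in transcripts, polymerase re-initiation rate)
   and groups them into **permissive periods** (ON periods recurring
   within 60 min).
2. **Three-state stochastic gene-expression model**: each allele exits
   the deep OFF state into a permissive period with probability
   *P*<sub>O>P</sub> at cell-cycle-onset draws; permissive alleles fire
   a Poisson number of ON periods with empirically sampled spacing and
   mixed negative-binomial/Poisson amplitudes; transcripts dilute at
   division and decay with age. Simulated transcripts-per-cell
   histograms are fitted to smRNA-FISH-like targets by grid search on
   *P*<sub>O>P</sub>, including an acute-derepression protocol that
   tests fold-changes in *P*<sub>O>P</sub>.
3. **Single-particle tracking (SPT) kinetics**: nearest-neighbour track
   linking, bi-exponential survival fits of bound-molecule track
   lengths, H2B-based photobleaching correction
   τ<sub>bound</sub> = τ<sub>H2B</sub>·τ<sub>dwell</sub>/(τ<sub>H2B</sub>−τ<sub>dwell</sub>),
   lag-1 MSD diffusion coefficients and two-Gaussian log₁₀(*D*)
   mobility mixtures.

The model core in standard notation: for a cell with *n* alleles each
independently permissive with probability *q*, the zero-class fraction
is *f*₀ = (1−*q*)ⁿ, inverted as *q* = 1 − *f*₀^(1/*n*) to recover
per-allele statistics from cells that never fire during a movie. The
survival of bound molecules is modelled as
*y*(t) = A·e^(−t/τ₁)/e^(−t₁/τ₁) + (1−A)·e^(−t/τ₂)/e^(−t₁/τ₂).

## Worked example

```python
import numpy as np
import polyburst as pb

# allele occupancy: 18% of cells show zero permissive alleles
q = pb.invert_zero_class(0.18, n_alleles=3)
print(f"per-allele permissive probability q = {q:.4f}")
# per-allele permissive probability q = 0.4354

# call ON periods on a noise-free trajectory (transcript units x 330 a.u.)
traj = pb.FluorescenceTrajectory(
    "cell1", 4.0, np.array([0, 0, 1, 2, 3, 3, 2, 1, 0]) * 330.0,
    bleach_corrected=True)
(on,) = pb.call_on_periods(traj, pb.UnitaryIntensity(330.0, 0.0))
print(on.min_frame, on.max_frame, on.amplitude_transcripts, on.duration_min)
# 1 4 3.0 12.0   -> a 12-min ON period of 3 transcripts

# fit P_O>P to a simulated smRNA-FISH target
target = pb.simulate_population(pb.ThreeStateParams(p_op=0.1), 2000, seed=11)
p_star, profile = pb.fit_p_op(
    target, pb.ThreeStateParams(), [0.05, 0.075, 0.1, 0.125, 0.15],
    n_cells=2000, n_rep=5, seed=5)
print(p_star)
# 0.1   -> the generating transition probability is recovered
```

The ON-period caller output means: the burst rose from the quiescent
frame 1 to its peak at frame 4 (12 min), gaining 3 transcripts' worth
of calibrated fluorescence; amplitudes above 2.5 transcripts addition-
ally carry a re-initiation rate from a linear fit of the rising flank.

A shell interface mirrors the library
(`polyburst simulate-traj | call-on | permissive | fraction-permissive |
infer-lambda | simulate-fish | fit-pop | fit-halflife | spt-tracks |
spt-dwell | spt-mobility`), each subcommand taking `--config`, `--seed`
and `--out`.

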