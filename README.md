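# mugrid

**Surface-EMG electrode-grid design and motor-unit identification.**

High-density surface electromyography (HD-EMG) records muscle activity with
grids of closely spaced electrodes; blind-source-separation decomposition of
these multichannel signals recovers the discharge times of individual motor
units — the only neural cells whose activity can be read out noninvasively.
How many units a grid can reveal depends on its **area** and its
**interelectrode distance (IED)**: a unit is recoverable only if its
multichannel action potential (MUAP) is distinguishable from every other
active unit's.  `mugrid` implements the complete computational pipeline for
studying this question:

* an anatomical **motor-unit pool** in a layered cylindrical muscle
  (farthest-point territory placement, exponential innervation numbers
  15–1500 at 20 fibers/mm²);
* a line-source **volume conductor** producing each unit's MUAP on any
  electrode montage;
* the **theoretical identifiability** statistic: unit *i* is identifiable
  when, for every *j ≠ i*, the time-aligned normalized mean-square
  difference of their multichannel MUAPs is ≥ 5% —
  `NMSD = (E_i + E_j − 2 C(lag*)) / max(E_i, E_j)` — an upper bound on the
  yield of *any* decomposition algorithm, swept over grid sizes
  (14.4–36 cm²) and IEDs (2–36 mm);
* **ground-truth EMG synthesis** (recruitment per the tibialis-anterior
  threshold law `Fth(j) = 0.50(58.12 j + 120 j^1.83)` %MVC, linear rate
  coding, trapezoidal force profiles, band-limited noise at a set SNR);
* **convolutive blind-source separation**: channel extension to ~1000
  observations, spatial whitening, log-cosh fixed-point source extraction
  with deflation, CoV-driven refinement, a 28-dB pulse-to-noise-ratio gate,
  and cross-correlation duplicate removal — including quadrant-wise
  decomposition of composite 256-electrode montages;
* **post-hoc metrics**: spike-triggered averaging, early/late recruitment
  classification, adjacent-electrode correlation, per-subject count
  normalization, weighted logarithmic trend fits, and rate-of-agreement
  scoring against ground truth.

The package is a library: import it from Python, or run the narrative
scripts in `examples/`.

## Worked example

Simulate a pool, ask how many of its 200 units a grid could theoretically
discriminate, then decompose a synthetic recording and check the result
against ground truth:

```python
import mugrid as mg
from mugrid.discriminability import sweep_shared_master

pool = mg.build_pool(count=200, seed=1)
df = sweep_shared_master(pool, lengths_cm=[4, 7, 10], ieds_mm=[2, 8, 36],
                         fiber_subsample=100, seed=2)
print(df.pivot_table(index="ied_mm", columns="length_cm",
                     values="pct_identifiable"))
```

```
length_cm  4.0   7.0   10.0
ied_mm
2.0        63.5  70.0  75.0
8.0        64.0  69.0  73.0
36.0       54.0  55.0  69.5
```

Each entry is the percentage of the 200 simulated units whose multichannel
MUAP differs from every other unit's by at least 5% NMSD: larger grids (left
to right) and denser grids (bottom to top) discriminate more units, i.e.
they raise the ceiling on what any decomposition algorithm could identify.

Decomposition against ground truth (`examples/03_decompose_synthetic_emg.py`):

```
recording: 64 channels, 30 s, 10 active units, SNR 20 dB
accepted pulse trains: 8
 train  truth_unit   roa  n_spikes  pnr_db
     0           9 1.000       112  35.763
     1           6 1.000       269  38.285
     2           4 1.000       378  40.435
     3           0 0.994       534  32.471
     4           2 1.000       469  31.468
     5           8 0.994       162  33.342
     6           1 1.000       513  35.244
     7           5 1.000       327  33.250
```

Every pulse train passing the 28-dB PNR gate reproduces a distinct
ground-truth unit's discharge times with a rate of agreement ≥ 0.99.

The other example scripts cover pool anatomy and MUAP amplitudes (`01`),
the experimental montage reconstructions and spatial interpolation (`04`),
and spike-triggered averaging with recruitment and trend analyses (`05`).

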