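# pcfscan

Pair-correlation-function (pCF) analysis of confocal line-scan
fluorescence carpets, with a Brownian-dynamics simulator of
nucleocytoplasmic transport so the entire method can be exercised and
validated end to end without microscope data.

## The problem and who this is for

Fluorescence correlation spectroscopy (FCS) infers diffusion and
concentration from intensity fluctuations in a diffraction-limited focal
volume.  Scanning the beam rapidly along a line turns one focal volume
into 32–64 of them: the acquisition becomes a *carpet* — a matrix whose
columns are positions along the line and whose rows are successive scan
lines in time.  The pair correlation function cross-correlates the
intensity at two positions a distance δr apart,

    G(τ; δr) = ⟨δF(0, t) · δF(δr, t + τ)⟩ / (⟨F(0)⟩⟨F(δr)⟩),

and its maximum over τ marks the average time the *same* molecule needs
to travel δr.  Because only the molecule itself can carry correlation
from one spot to the other, the pCF reports single-molecule transport in
the presence of many identical molecules — and a barrier between the two
positions (for example the nuclear envelope with its pore complexes)
shows up as a dramatic lengthening of that peak delay, while an
impenetrable boundary (the gap between adjacent cells) suppresses the
maximum entirely.

The package is aimed at quantitative fluorescence microscopists and
methods developers: it provides the carpet data model and I/O,
stationarity quality control, multi-tau auto/pair correlators with an
exhaustive-summation oracle, closed-form diffusion models with fitting
and PSF calibration, transit-delay maps with connectivity classification,
and a particle-level simulator of two-compartment transport (passive
semi-permeable barrier plus an optional directional capture-and-release
channel emulating carrier-mediated nuclear import).

## A worked example

Simulate a nucleus-like compartment (D = 12.5 µm²/s, 32-pixel line,
100 nm pixels, 6.3 µs dwell, 0.473 ms line period), then recover D from
the averaged per-column autocorrelation and read the intracompartment
pCF(4) transit delay:

```python
import pcfscan as p
from pcfscan import workflows as wf

fit, sim = wf.compartment_d_experiment(d_true=12.5, n_lines=60_000, seed=1)
print(f"D = {fit.d:.2f} um^2/s, N = {fit.n_molecules:.2f} per focal volume")

peak = wf.intra_pcf_delay(sim, delta_pixels=4)
print(f"pCF(4) peak delay = {peak.tau_peak_s * 1e3:.2f} ms")
```

Output from the run above:

```
D = 12.84 um^2/s, N = 1.65 per focal volume
pCF(4) peak delay = 2.39 ms
```

The fitted D agrees with the simulated ground truth of 12.5 µm²/s to a
few percent, and the 0.4 µm pair-correlation delay of ~2.4 ms matches
the closed-form expectation (δr² − w0²)/4D ≈ 1.95 ms to within a lag
bin.  A two-compartment experiment with the barrier calibrated to a
250 ms mean crossing time (`workflows.passive_barrier_experiment`, which
pools several independent ~30 s records before the peak readout)
lengthens the cross-barrier pCF delay into the hundreds of milliseconds,
and enabling the directional import channel produces a fast
cytoplasm→nucleus component that vanishes again when the channel is
switched off — the simulated analogs of passive shuttling, active
import, and energy depletion.

The same workflows are scriptable from the shell:

```bash
pcfscan simulate --preset paper-scan --seed 1 -o out/run1
pcfscan correlate out/run1.tif --delta 4 -o out/pcf4.csv
pcfscan fit out/pcf4.csv --w0 0.25 --baseline -o out/fit.json
pcfscan analyze out/run1.tif --delta 14 --barrier-col 15.5 --direction both -o out/map
```

## Layout

| module                | contents |
|-----------------------|----------|
| `pcfscan.carpet`      | `LineScanCarpet`, TIFF/CSV/raw I/O with JSON sidecar, segment selection, stationarity QC, Keq |
| `pcfscan.correlate`   | multi-tau and direct correlators, pCF carpets, block averaging, detrending |
| `pcfscan.models`      | closed-form ACF/pCF diffusion models, fitting, PSF calibration, analytic peak times |
| `pcfscan.simulate`    | Brownian-dynamics scanner, barrier/active transport, first-passage oracles, permeability calibration |
| `pcfscan.transport`   | peak detection, transit maps, barrier index, direction-resolved analysis |
| `pcfscan.workflows`   | end-to-end experiment recipes |
| `pcfscan.cli`         | `pcfscan simulate | correlate | fit | analyze | report` |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
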