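# slowsync

Analysis toolkit for studying how suppressing activity in one cortical node
reshapes interareal coupling: from raw extracellular recordings and BOLD
series to band-power modulation indices, interareal coherence, spike–field
phase locking, and seed-based connectivity maps. A synthetic-data package
generates every input with known ground truth, so each estimator is testable
against the parameters that produced its data.

## Modules

| Module | Purpose |
| --- | --- |
| `slowsync.synthgen` | Coupled sinusoid+noise LFPs, von Mises phase-locked spike trains (locked-only vs mixed scenarios), wideband extracellular mixtures, and 4D BOLD datasets with controllable region coupling |
| `slowsync.ephys` | Two-step zero-phase LFP extraction (1–250 Hz at 1 kHz), 400–3000 Hz MUA band, median-based spike detection (4·median(\|x\|)/0.6745, 1 ms refractory), firing rates with baseline normalization, autocorrelation independence lag |
| `slowsync.spectral` | Kaiser-window spectrograms (6 s windows, 50 % overlap, 0.15 Hz grid), 30 s × 1 Hz median smoothing, band power, the (post−base)/(post+base) modulation index, multitaper spectra of Gaussian-smoothed spike trains |
| `slowsync.coupling` | Welch magnitude-squared coherence (2 s segments), γ-envelope ultra-slow (0.02–0.5 Hz) coherence with 1/f correction, Hilbert instantaneous phase, LFP–LFP PLV with circular-shift surrogate significance (PLV > surrogate 95th percentile **and** PLV > 0.1), preferred phase differences, spike-phase locking |
| `slowsync.fmri` | BOLD preprocessing (volume dropping, motion + ventricle nuisance regression, 0.01–0.1 Hz band-pass, optional smoothing), seed correlation maps, antero-posterior seed profiles, k-means partitioning of connectivity profiles, Fisher-z two-sample t contrast maps with optional permutation cluster correction |
| `slowsync.pipeline` | Epoch binning around the injection event, Wilcoxon rank-sum + Benjamini–Hochberg FDR, the locked-vs-mixed spike-locking simulation, coherence-vs-connectivity regression, and the end-to-end "virtual DREADD" scenario |

## Command line

```bash
slowsync synth lfp   --spec lfp.yaml --out DIR --seed 1   # coupled LFPs
slowsync synth sim   --out DIR --seed 1                   # spike scenarios
slowsync synth bold  --spec bold.yaml --out DIR --seed 1  # BOLD dataset
slowsync ephys       --in DIR/raw --out DIR \
    --windows baseline=0:900,transition=900:1800,active=1800:3900
slowsync spectral    --lfp DIR/lfp --out spec.h5
slowsync couple      --lfp DIR/lfp --pairs 0:1,0:2,1:2 --out couple.csv
slowsync fmri seedmap --in DIR/bold --out map.nii
slowsync run         --out DIR --seed 1                   # full scenario
```

File formats: flat little-endian float32 binary + JSON sidecar for
multichannel signals, CSV for spike times, NIfTI-1 for BOLD and maps, HDF5
for spectrograms, YAML for generator specs.

## Notes

- All randomness flows through per-call integer seeds; identical specs and
  seeds give byte-identical outputs.
- The "virtual DREADD" harness (`slowsync.pipeline.run_virtual_dreadd`)
  builds a three-node control vs manipulated comparison where manipulation
  removes off-preferred-phase spikes, suppresses local γ, and raises shared
  slow/δ components; the expected sign pattern (γ power down, slow/δ power
  and coherence up, spike PLV up, seed connectivity up) is verified across
  seeds in the test suite.
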