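# firmap

Fast model-based iterative reconstruction of quantitative **T1 maps** from
undersampled **golden-angle radial inversion-recovery Look-Locker (IR-LL)**
MRI k-space.

A single-shot IR-LL scan acquires one radial spoke per repetition while the
longitudinal magnetisation recovers from inversion, so each time frame holds
exactly one spoke — far too little to reconstruct frames independently.
`firmap` reconstructs the parameter maps directly: every pixel is modelled by
the driven recovery

```
M(t) = M0* − (M0 + M0*) · exp(−t / T1*),        T1 = T1* · M0 / M0*
```

and the reconstruction alternates between this parametric model and a
k-space data-consistency step that reinserts the measured spokes at their
acquired grid nodes.  The fit is split in two steps per iteration: a
pixel-vectorised nonlinear three-parameter fit on the phase-sensitively
combined coil data, then a closed-form linear refit of one complex amplitude
per coil — which also absorbs the coil sensitivities, so no separate
sensitivity measurement is needed.  Three initial models are provided (OFM,
IFM, MFM), iterations can run on every n-th projection only, and a
synthetic multi-coil phantom generator with exact ground truth makes the
whole pipeline testable without scanner data.

Intended users: researchers working on quantitative MRI reconstruction who
want a compact, fully inspectable reference implementation of the
model-based IR-LL approach with an end-to-end synthetic test bench.

## Worked example

```python
import firmap as fm

# brain-like phantom: WM/GM/CSF at T1 = 700/1400/4000 ms, 4 coils,
# 600 golden-angle projections, TR 6 ms, flip 7 deg, noiseless
spec = fm.default_brain_spec()
gt, times, radial, gridded = fm.simulate_dataset(spec)

cfg = fm.ReconConfig(initial_model="mfm", max_iters=50, tol=0.0)
maps, log = fm.reconstruct(gridded, times, cfg)

print(fm.roi_stats(maps.t1_ms, gt.roi_masks))
print(f"consistency metric: {log.metric[0]:.0f} -> {log.metric[-1]:.0f}")
```

prints

```
   roi         mean         std  mean_over_std
0   WM   724.737820   69.660148      10.403909
1   GM  1353.711204   90.129951      15.019549
2  CSF  3718.816504  621.123557       5.987241
consistency metric: 16606 -> 943
```

ROI-mean T1 is recovered within 3.5% (WM), 3.3% (GM) and 7.1% (CSF) of the
ground truth after 50 iterations from the mean first model (MFM), and the
k-space consistency metric has dropped by a factor ~18.  Starting from the
interpolated first model (IFM) instead reaches sub-percent ROI errors in 30
iterations.  Longer MFM runs keep improving (≤2.4% everywhere at 150
iterations).

The same pipeline is scriptable from the shell:

```sh
firmap simulate --out data.h5
firmap recon --data data.h5 --model mfm --iters 50 --out maps/
firmap roi --maps maps/ --masks data.masks.h5 --out stats.csv
```

Parameter maps are written as single-slice NIfTI volumes, ROI tables as CSV.

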