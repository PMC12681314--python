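# smsradial

Calibration-less **simultaneous multislice (SMS) radial real-time MRI**:
golden-angle acquisition with CAIPIRINHA phase cycling, a digital
dynamic-phantom simulator, and a compressed-sensing reconstruction
pipeline — built for researchers who want to study or prototype SMS rtMRI
reconstruction (e.g., for speech and swallowing imaging of the oral cavity)
without scanner access.

## The method

A multiband RF pulse excites `NSli` slices at once. At excitation `n` the
pulse imposes CAIPIRINHA phase `i·φₙ` on slice `i`, with

    φₙ = mod(2π n / NSli, 2π),

so that over one period the slice phases form a discrete Fourier basis and
the slices can be separated computationally. Sampling is radial: the spoke
angle advances by the golden angle `180°/GR ≈ 111.25°` (GA), or by
`180°/(GR·NSli)` (SMS-GA) so that the phase-cycle states interleave evenly
within each frame. Spokes are binned retrospectively into frames of any
length (25 spokes × TR 2.5 ms = 62.5 ms temporal resolution; 10 spokes =
25 ms).

Reconstruction solves, per slice stack `x = (x₁ … x_NSli)`,

    x̂ = argmin_x  ½ Σᵢ ‖φᵢ F Sᵢ xᵢ − y‖₂² + λ ‖T x‖₁

where `F` is the NUFFT onto the spoke coordinates, `Sᵢ` the coil
sensitivities of slice `i`, `φᵢ` the CAIPIRINHA phases, and `T` the
temporal finite-difference transform (λ = 4×10⁻² by default). The problem
is solved by ADMM with automated penalty adaptation; CG-SENSE (15
iterations, no regularization) is the baseline, and a width-3 temporal
median filter suppresses residual undersampling artifacts. The
sensitivities are estimated **from the data itself**: PCA coil compression,
conjugate-phase demodulation to motion-averaged per-slice k-space, adjoint
NUFFT, and ESPIRiT on the central 24×24 Cartesian block — no prescan.

The simulator generates the ground truth the pipeline is tested against: a
moving "tongue" ellipse inside a static head with per-slice distinct
markers and texture, smooth complex coil maps, and the exact forward model
above plus complex Gaussian noise.

## Worked example

```python
from smsradial import RunConfig, run_simulation
from smsradial.experiments import run_reconstruction, slice_recovery, centroid_error

cfg = RunConfig(max_iterations=30)  # 64x64 grid, 3 slices, 8 coils, 40 frames of 25 spokes
run = run_simulation(cfg)    # phantom + coil maps + noisy multiband k-space
result, maps = run_reconstruction(run.kspace, cfg)   # ESPIRiT + ADMM + median
rec = slice_recovery(result.videos, run.phantom)
print("per-slice correlation:", rec["own_correlation"].round(3))
print("leakage margin:       ", rec["leakage_margin"].round(3))
print("centroid error (px):  ", round(centroid_error(result.videos, run.phantom), 2))
```

Output (seed 0, 30 ADMM iterations):

```
per-slice correlation: [0.981 0.977 0.983]
leakage margin:        [0.56  0.598 0.53 ]
centroid error (px):   1.1
```

The correlation row says each reconstructed slice matches its own ground
truth to better than 0.97; the margin row says it matches its own slice by
at least 0.53 more than it matches either of the other two simultaneously
excited slices (i.e., slice separation succeeded); and the tracked centroid
of the moving ellipse is recovered to about one pixel.

The same pipeline is scriptable from the shell:

```bash
smsradial simulate run.h5 --seed 1
smsradial recon run.h5 --method admm
smsradial metrics run.h5
smsradial export-video run.h5 frames/
```

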