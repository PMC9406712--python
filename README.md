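# flowdht

In-flow digital holographic tomography (DHT) of rolling cells: a complete,
instrument-free computational pipeline from off-axis holograms to 3D
refractive-index (RI) tomograms and single-cell morphometrics.

## The problem

A holographic flow cytometer records off-axis interference frames of single
cells rolling along a microfluidic channel tilted 45° against the camera
axes.  As the cell translates it also rotates, so the frame sequence samples
the cell from a few tens of viewing angles — enough, with the right
reconstruction, to recover the cell's 3D refractive-index map n(x, y, z)
label-free.  The computational chain has four stages:

1. **Hologram processing** — each frame H is apodized (Tukey window), the +1
   diffraction order is isolated in the Fourier spectrum and re-centred, the
   complex amplitude U(x, y; z) is refocused by angular-spectrum propagation
   to the plane z̄ minimizing the Tamura coefficient
   TC(z) = σ(|U_z|) / μ(|U_z|), aberrations are cancelled by dividing by an
   identically processed cell-free reference, and the phase is unwrapped and
   windowed-Fourier denoised, giving quantitative phase maps (QPMs).
2. **Rolling-angle recovery** — the frame completing a full turn is the one
   minimizing the Tamura Similarity Index against the first frame; assuming
   rotation proportional to translation, frame k gets the projection angle
   θ_k = 360 · l_k / L360, where l_k = √(x_k² + y_k²) is the centroid
   displacement from frame 1 and L360 the displacement at the full-turn
   frame.
3. **Tomographic reconstruction** — QPMs are de-tilted, cropped, converted
   to line integrals of the RI contrast Δn = n − n0, and inverted slice by
   slice: by filtered back projection (FBP), or by high-order total
   variation (HOTV) with polynomial-annihilation (PA) regularization,

       min_x  μ/2 ‖A x − b‖₂² + ‖PA_k x‖₁,   x ≥ 0,

   solved by a split-Bregman scheme with 30 inner (conjugate-gradient) and
   30 outer (Bregman) iterations.  PA_k is the k-th finite difference along
   each in-slice axis; k = 1 is classical TV, k ≥ 2 admits
   piecewise-polynomial interiors that match smooth cellular RI textures.
4. **Morphometrics** — from the segmented tomogram: average RI, biovolume V,
   equivalent diameter (6V/π)^{1/3}, and dry mass (1/α)·∫Δn dV with
   α = 0.2 mL/g.

A seeded numerical phantom generator (random Gaussian RI texture in
[1.334, 1.410] inside a spherical support) and an optical forward simulator
(phase projection, off-axis fringe synthesis, rolling-sequence assembly)
close the loop, so the whole chain is testable without any instrument data.

## Worked example

```python
import flowdht as fd

spec   = fd.PhantomSpec(grid_size=48, voxel_size=0.2, cell_radius=4.0,
                        correlation_length=0.8, seed=7, edge_voxels=2)
flow   = fd.FlowSpec(noise_sigma=0.08, n_frames=40, seed=0)
optics = fd.OpticalConfig()            # 0.488 um, 55x, NA 0.5, 30 fps

sim  = fd.simulate_rolling_sequence(spec, flow, optics, fov_pixels=256)
qpms = fd.process_sequence(sim.holograms, sim.reference_hologram,
                           optics.wavelength, carrier=sim.carrier)
k360  = fd.find_full_rotation(qpms, min_lag=10)
track = fd.track_centroids(qpms)
seq   = fd.assign_angles(track.with_full_rotation(k360))
sino  = fd.build_sinogram([qpms[k] for k in seq.frames], seq,
                          tilt=45.0, crop_size=12.8,
                          wavelength=optics.wavelength)
rec, log = fd.hotv_reconstruct(sino)   # HOTV-2, DF = 48, 30/30 iterations

mask = fd.segment_cell(rec, 0.33 * rec.contrast.max())
print("k360:", k360)
print(fd.compute_features(rec, mask))
```

prints (seed-7 phantom, one simulated acquisition):

```
k360: 36
FeatureRecord(average_ri=1.36597915708418, biovolume=214.53600000000006,
              equivalent_diameter=7.427349358875165,
              dry_mass=34.30340222105794, segmentation_threshold=nan,
              alpha=0.2)
```

The full rotation is found at frame 36 (the simulated cell turns 10° per
frame, so the true full turn is at frame 36); the reconstructed cell
averages n = 1.366, occupies a biovolume of ~215 µm³ (equivalent diameter
7.4 µm, consistent with the 8 µm phantom), and carries ~34 pg of dry mass —
the scale expected for a monocyte-sized cell at these refractive-index
contrasts.

The same pipeline is scriptable from the shell:

```
flowdht simulate   --config run.yaml --out holo.tiff
flowdht process    --holograms holo.tiff --reference holo_reference.tiff --out qpm.tiff
flowdht angles     --qpms qpm.tiff --out angles.csv
flowdht reconstruct --qpms qpm.tiff --angles angles.csv --solver hotv-2 --out tomo.tiff
flowdht features   --tomogram tomo.tiff --out features.csv
flowdht benchmark  --seeds 10 --out ssim.csv
```

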