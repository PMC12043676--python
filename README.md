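# tens-depth

Computational dosimetry for surface electrical nerve stimulation (TENS) on a
layered forearm phantom: how does stimulus pulse width trade off against
threshold current, and how deep does activation reach?

The pipeline chains five stages:

1. **`tens_depth.phantom`** — a voxelized concentric-cylinder forearm
   surrogate (skin / SAT / muscle / cortical bone / cancellous bone / marrow,
   IT'IS low-frequency conductivities), two gel-backed disc electrodes
   (radius 3 mm, thickness 2 mm, 2 cm apart) and straight nerve trajectories
   at configurable depths below the skin (median 5.5 mm, radial 13.1 mm,
   ulnar 14.9 mm by default).
2. **`tens_depth.solver`** — the Ohmic quasi-static problem ∇·σ∇φ = 0 with
   Dirichlet electrode voltages and insulating outer boundaries, discretized
   with 7-point finite differences and harmonic-mean face conductivities and
   solved by Jacobi-preconditioned conjugate gradients. One unit solve per
   montage is rescaled to any electrode current by linearity.
3. **`tens_depth.axon`** — the McIntyre–Richardson–Grill double-cable
   myelinated axon (node / MYSA / FLUT / 6×STIN compartments, published
   geometry sets for 5.7–16 µm fibers, nodal fast Na⁺ / persistent Na⁺ /
   slow K⁺ / leak channels at 36 °C), driven by extracellular potentials
   sampled along a nerve trajectory and advanced with a banded
   backward-Euler scheme (dt 0.0025 ms, 3.5 ms windows).
4. **`tens_depth.protocol`** — charge-balanced biphasic pulses
   (widths 30/88/146/262/495 µs, 0.1 ms interphase), titration of the
   threshold factor T (doubling bracket + bisection to 1%; threshold current
   I_T = T × baseline), strength-duration curves and Weiss / Lapicque
   rheobase-chronaxie fits.
5. **`tens_depth.af_vta`** — activating function as the largest absolute
   Hessian eigenvalue of φ per voxel, an AF isosurface threshold calibrated
   along the titrated axon at its threshold current, and the volume of
   tissue activated (VTA), activation depth and VTA-vs-pulse-width linear
   fit at a common evaluation current (mean of the shortest- and
   longest-pulse thresholds).

`tens_depth.pipeline` orchestrates everything from one YAML config;
`tens_depth.config` validates it (unknown keys rejected).

## CLI

```sh
tens-depth run config.yaml --out results/ [--vtk]   # full pipeline
tens-depth solve --config config.yaml --out fields.vtk
tens-depth titrate --config config.yaml --pw 30 --nerve median
tens-depth sdcurve --config config.yaml --out sd.csv
```

A minimal `config.yaml` is just `{}` (all defaults); any section can be
overridden, e.g.

```yaml
phantom: {radius: 40.0, length: 120.0, spacing: 1.0}
electrodes: {separation: 20.0, radius: 3.0, thickness: 2.0}
nerves:
  - {name: median, depth: 5.5}
  - {name: ulnar, depth: 14.9}
pulse: {widths_us: [30, 88, 146, 262, 495], interphase_ms: 0.1}
axon: {diameter: 5.7, n_nodes: 101, variant: sensory}
titration: {tol: 0.01, baseline_mA: 5.0}
```

Outputs: `sd.csv` (pulse_width_us, threshold_mA), `vta.csv` (per pulse
width: threshold current, AF threshold, VTA mm³, max activation depth mm),
`report.json` (config hash, electrode currents, fits, timings) and
optionally ASCII legacy-VTK field files.

The default desk-scale run (1 mm grid, 101-node axon, five pulse widths)
completes in about a minute on one CPU.

## Notes and limitations

- The phantom is a deliberately simple layered cylinder, not an anatomical
  arm model: absolute thresholds, field magnitudes and VTA volumes are
  geometry-dependent and only the qualitative pulse-width relationships are
  expected to transfer.
- The `sensory` axon variant currently uses the published MRG nodal
  constants (identical to `motor`); fiber-type specific conductances can be
  supplied via `build_axon(channel_overrides=...)`.
- Air voxels are excluded from the linear system; the quasi-static
  approximation ignores tissue capacitance and dispersion.
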