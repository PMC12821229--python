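# mammosim

Patient-specific prone-to-supine breast deformation modelling, implemented as
a tested Python pipeline exercised on synthetic phantoms:

- **geometry_io** — STL (binary/ASCII) and Slicer markups (`.mrk.json`) I/O,
  skin-shell extrusion (prism → 3 tets with a deterministic diagonal rule),
  triangle-mesh geodesics, and barycentric interpolation of volumetric
  displacement fields.
- **phantom** — parametric prone breast phantom (half-ellipsoid body +
  1.5 mm extruded skin + spherical tumor inclusion + planar chest wall +
  apex nipple + labeled boundary node sets), a bilateral chest surface for
  alignment tests, and a forward-simulated "supine" ground truth with known
  material parameters.
- **alignment** — intermammary flat-patch detection, geodesic-radius
  boundary transfer, trimmed-ICP rigid registration (Kabsch inner step) and
  cranial-caudal nipple leveling.
- **constitutive** — neo-Hookean energy/stress
  (`Psi = mu0/2 (I1_bar - 3) + K0/2 (J - 1)^2`), single- or multi-term
  Prony stress relaxation via an exact piecewise-linear internal-variable
  recurrence, and the skin scaling rule `mu_S = f mu_B`.
- **solver** — total-Lagrangian explicit central-difference dynamics on
  4-node tets with nodal-volume-averaged dilatation (F-bar type) against
  volumetric locking, lumped mass, gravity inversion, symmetry Dirichlet
  sets, rigid chest-wall contact (small-sliding penalty + Coulomb friction,
  or fixed tie), an energy ledger, and the nipple closest-approach stopping
  criterion. A numba fast path accelerates the element kernel (numpy
  fallback is the reference implementation).
- **calibration** — nipple-distance objective, piecewise viscous-modulus
  rule (g = 0.8 / 0.5 / 0.1 over [160,230) / [230,300) / [300,inf) Pa),
  bounded hybrid simulated annealing over `mu_B` in [160, 300] Pa with
  golden-section refinement, and an exhaustive skin-factor search over
  f in {4, 6, 8, 10, 12}.
- **evaluation** — tumor centroid distance and tumor-skin projection
  distance (closest point on the deformed surface), JSON reports.
- **cli** — `mammosim` entry point wiring the stages.

Internal units are SI (m, kg, s, Pa); STL/markups files are interpreted as
millimetres by default.

## CLI

```bash
mammosim phantom   --seed 1 --out phantom_out          # STL + .mrk.json + model.yaml
mammosim simulate  --config run.yaml --out traj.h5     # trajectory + summary JSON
mammosim align     --prone p.stl --supine s.stl --markups p.mrk.json \
                   --supine-markups s.mrk.json --out transform.json
mammosim calibrate --config run.yaml --target supine_nipple.mrk.json --out calib.json
mammosim all       --config run.yaml --seed 1 --out run_out   # closed-loop experiment
```

The YAML config has `phantom`, `material`, `simulation`, `contact`,
`calibration` and `truth` blocks; all defaults follow the modelled protocol
(gravity 9.8 m/s^2 inverted along y, rho = 1000 kg/m^3, tau = 0.01 s,
friction 0.5, 0.3 s maximum simulation time, 5 mm clinical-scale stop
threshold — 2 mm at phantom scale).

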