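# emdasim

Voxel volume-conductor dosimetry for **Electromotive Drug Administration
(EMDA)** — intravesical chemotherapy (mitomycin C) driven by a ~20 mA
direct current between a helical catheter electrode inside the bladder
and two dispersive 5 × 7 cm patch electrodes on the lower abdominal skin.

The package answers a mechanism question: *are the fields produced inside
the bladder wall strong enough for electroporation, or is the treatment
operating in the iontophoresis regime?*  It is written for researchers in
tissue-scale bioelectromagnetics and for anyone who wants a small,
self-contained, fully testable current-injection field solver on
segmented anatomy.

## What it computes

1. **Phantom** — a synthetic segmented pelvis (analytic primitives: body
   ellipsoid with subcutaneous fat, bone, intestines, spherical-shell
   bladder with saline lumen and a superior air pocket, prostate) with
   the EMDA hardware voxelized into it: the 20-turn helical wire
   electrode (0.4 mm wire, 1.25 mm major radius, 1.6 mm pitch → 32 mm
   long), an insulating 12 mm catheter balloon at the bladder neck, and
   two anterior skin patches.  A user-supplied NIfTI label volume with a
   JSON legend can be used instead.
2. **Solver** — the steady-state conduction problem
   ∇·(σ∇V) = 0 on the voxel grid, 7-point finite volumes with
   harmonic-mean face conductances, insulating outer boundaries,
   equipotential current-source terminals (unit-Dirichlet solve + exact
   linear rescaling to the injected current I), and a thin resistive
   contact layer g (S/m²) on the patch–skin faces.  Fields follow as
   E = −∇V and J = σE.
3. **Dosimetry** — per-tissue max/mean/SD of |E| and |J| (population SD,
   with the max voxel location and a top-0.1 %-winsorized max to audit
   single-voxel extrema) and anterior/posterior bladder-wall splits.
4. **Mechanism assessment** — Schwan's steady-state induced transmembrane
   voltage ITV_max = 1.5·E·R for a spherical cell of radius R (bladder
   superficial "umbrella" cells are up to 250 µm across, R = 125 µm),
   the fraction of voxels exceeding the electroporation thresholds
   (40 000 V/m conventional; 10 000 V/m for 100 ms exposures), and the
   fraction inside the iontophoresis window 1–5 A/m²
   (= 0.1–0.5 mA/cm²).

## Worked example

```bash
emda run --out demo            # generate → solve → report, all defaults
```

On the default phantom (2 mm voxels, ~0.69 M unknowns, seed 0) this
finishes in well under a minute and prints, among other lines:

```
INFO emdasim: solve done: 591 iterations, terminal voltage 3.128 V
bladder_wall: E_max 20.4 V/m | >40k: 0.0% | >10k: 0.0% | in 1-5 A/m^2: 49.5%
              | ITV_max [bladder_superficial: 3.83 mV]
              | electroporation_excluded+iontophoresis_plausible
```

and writes `tissue_stats.csv`, whose bladder-wall row reads

| tissue | n_voxels | E_max | E_mean | E_sd | J_max | J_mean | J_sd |
|---|---|---|---|---|---|---|---|
| bladder_wall | 5204 | 20.4 | 6.4 | 3.5 | 4.09 | 1.28 | 0.71 |

Reading: at 20 mA the peak bladder-wall field is ~20 V/m — three orders
of magnitude below any electroporation threshold, inducing at most a few
mV across even the largest urothelial cells — while about half of the
wall sits inside the 1–5 A/m² iontophoresis window.  The strongest field
overall (~340 V/m) appears in the subcutaneous fat directly under the
skin patches, and the anterior bladder wall carries markedly more current
than the posterior wall because both patches sit on the anterior abdomen.

The same steps from Python:

```python
import emdasim as em

labels = em.generate_pelvis_phantom(em.PhantomParams())
sol, system = em.solve_emda(labels, current_A=0.020)
print(em.tissue_stats(sol, labels, "bladder_wall"))
print(em.report_text(em.classify_regimes(sol, labels)))
```

`emda generate / solve / report` run the stages separately;
`--config run.yaml` overrides any default (phantom geometry, conductivity
table, injected current, solver tolerance, thresholds), and
`--resolution-mm` / `--current-mA` / `--seed` are quick overrides.

## Layout

- `src/emdasim/phantom.py` — phantom generator, electrode voxelizers,
  conductivity table
- `src/emdasim/solver.py` — finite-volume assembly, CG solve, field
  derivation, conservation audit
- `src/emdasim/dosimetry.py` — per-tissue statistics and regional maps
- `src/emdasim/biophysics.py` — ITV, unit conversions, regime
  classification
- `src/emdasim/{config,io,cli}.py` — YAML config, NIfTI/JSON/CSV I/O,
  command line
- `docs/methods.md` — model assumptions, parameter provenance, numerical
  choices, limitations
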