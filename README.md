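# glycodiff

Analysis tools for translational diffusion, solvation and aggregation of
carbohydrates in aqueous solution, built around an empirical
hydration-number model that predicts a sugar's hydrodynamic radius — and
hence its diffusion coefficient — from its radius of gyration and a count
of its polar atoms.

It is aimed at people who study or design glycomaterials (mono- to
oligosaccharides and their derivatives) and want to connect MD-style
trajectory observables (mean squared displacement, radial distribution
functions, aggregate statistics, R_g) to measurable transport properties
(DOSY-NMR diffusion coefficients, hydrodynamic radii) without running long
simulations for every candidate.

## The model

Stokes–Einstein links the diffusion coefficient of a solute to the radius
of the hydrodynamically equivalent sphere:

    D = k_B T / (6 π η R_H)

The hydrodynamic sphere contains the bare solute *plus* its tightly
entrained waters. Treating the bare solute as a sphere of radius R_g (its
radius of gyration) and dividing the volume difference by the volume of
one water molecule (V_w = 30 Å³) counts those waters:

    N_W = (4/3) π (R_H³ − R_g³) / V_w

For small carbohydrates N_W tracks the experimentally inferred hydration
number n_H, and both come out at roughly 1.1 waters per polar (oxygen)
atom, N_PA. Inverting the volume relation turns this into a predictor that
needs only R_g (which converges in very short simulations) and a count of
oxygens (carboxylate, amide and ester groups count as two polar atoms):

    R_H = ( 3 V_w N / 4π + R_g³ )^(1/3),   N = 1.1 · N_PA

followed by Stokes–Einstein with the viscosity of real water
(η = 0.00089 kg m⁻¹ s⁻¹ at 298 K). Over 18 carbohydrates from xylose to
maltoheptaose this predictor matches DOSY NMR with a mean absolute error
of 0.02 × 10⁻⁹ m²/s — as good as or better than full MD estimates with
the TIP5P or OPC water models (0.05 and 0.04 respectively).

Around the model, the package implements the standard trajectory
estimators it was validated against: multi-origin MSD → D by linear
regression (slope/6, with an optional periodic-box finite-size
correction), center-to-water-oxygen RDFs with first-shell statistics and
the coordination number N1, Gaussian-weighted water occupancy grids, and
contact-graph aggregation kinetics (2.85 Å any-atom cutoff, ≥2-frame
persistence). A synthetic-data module generates Brownian, ideal-solvent
and constructed-aggregate trajectories with exactly known ground truth, so
every estimator is tested against closed forms.

## Worked example

Predict xylose's diffusion coefficient from its simulated radius of
gyration (2.34 Å) and its five oxygens:

```sh
$ glycodiff predict --rg 2.34 --npa 5
R_H = 3.73 A
D = 0.66 x 1e-9 m^2/s
```

The measured DOSY value is 0.71 × 10⁻⁹ m²/s; the prediction is within
0.05. The same numbers are available from Python:

```python
>>> from glycodiff import predict_rh, predict_d, entrained_waters
>>> round(predict_d(2.64, 6), 2)        # glucose: R_g = 2.64 A, 6 oxygens
0.61
>>> round(entrained_waters(3.93, 2.64), 1)   # glucose N_W from R_H, R_g
5.9
```

A full synthetic diffusion run, end to end:

```sh
glycodiff synth brownian --d-true 0.62 --n-frames 2000 --seed 7 --out run.xyz
glycodiff msd run.xyz --groups run.groups --unwrap --max-lag 5000 --out msd.tsv
glycodiff fitd msd.tsv --out d.tsv
```

which prints `D = 0.62… x 1e-9 m^2/s` (the generator's ground truth,
recovered within a few percent).

## Layout

- `src/glycodiff/core.py` — domain types, units, periodic-box geometry
- `src/glycodiff/io.py` — extended-XYZ/PDB, grouping files, cube/DX grids,
  packaged reference tables (checksummed)
- `src/glycodiff/synthetic.py` — ground-truth generators
- `src/glycodiff/diffusion.py` — MSD, D fitting, Stokes–Einstein, Welch's t
- `src/glycodiff/solvation.py` — RDF, N1, occupancy maps
- `src/glycodiff/aggregation.py` — contacts, clusters, lifetimes
- `src/glycodiff/hydration.py` — the empirical model and table scoring
- `src/glycodiff/cli.py` — the `glycodiff` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
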