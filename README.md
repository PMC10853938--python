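# gbsolv

Solvation free energies from molecular geometry alone: electronegativity-
equalization atomic charges, generalized-Born and surface descriptors, and
a small dense neural network.

`gbsolv` implements a fast implicit-solvent pipeline. Given only element
symbols, Cartesian coordinates, and the total charge of a solute, it

1. assigns **atomic partial charges** by electronegativity equalization
   (EE): a single linear solve with element- and coordination-number-
   dependent electronegativity/hardness parameters and a screened-Coulomb
   coupling;
2. computes **geometric descriptors** — per-atom exposed van der Waals
   surface areas and volumes from pairwise spherical-cap overlap;
3. computes **generalized-Born (GB) electrostatic descriptors** — element-
   grouped self and pair energies built on the Still pair function, scaled
   by the Born dielectric factor (1 − 1/ε);
4. reduces the descriptor vector (z-score → PCA → drop the 9 smallest
   components → whiten): 58 → 49 features for water, 61 → 52 for other
   solvents (three solvent descriptors added: ε, boiling point, heavy-atom
   count);
5. regresses ΔG°solv (kcal/mol) with a dense ReLU network — (49, 16, 8, 1)
   for water (945 parameters) or (52, 14, 7, 1) for nonaqueous solvents
   (855 parameters) — trained with Nadam on weighted MSE with an L2 weight
   penalty.

Everything — charge solver, cap geometry, GB terms, PCA reduction, network
forward/backward pass, Nadam, early stopping — is implemented on numpy and
validated against independent oracles (symbolic elimination, Monte-Carlo
integration, ordinary least squares) in the test suite. Two data-
augmentation operators for scarce ionic data are included: dielectric
extrapolation of ionic records to new solvents and boiling-point
replication.

## Quick start (CLI)

Generate a synthetic training set, train an aqueous model, and predict:

```sh
$ gbsolv synth --n 1500 --seed 7 --out-dir data
data/train.csv

$ gbsolv train data/train.csv --out model.json
# trained on 1500 records (aqueous), 945 parameters -> model.json
train      MSE -0.063  MAE 0.346  RMSE 0.463  slope 0.987  intercept -0.126  R2 0.991
validation MSE -0.059  MAE 0.532  RMSE 0.768  slope 0.971  intercept -0.204  R2 0.968
```

(`MSE` is the *mean signed error*; `slope`/`intercept`/`R2` are from the
predicted-vs-reference regression line. The synthetic labels carry 0.5
kcal/mol of Gaussian noise, so a validation RMSE approaching that value is
near the attainable floor.)

Predict the hydration free energy of a molecule from an XYZ file (the
total charge rides in the comment line as `charge=<int>`):

```sh
$ gbsolv predict acetamide.xyz --model model.json -v
# acetamide.xyz in water (eps=78.36)
# charges: [-0.0445  0.0669 -0.1192 -0.1578  0.0419  0.0366  0.0366  0.0752  0.0643]
# S_tot = 14.272 A^2, V_tot = 45.514 A^3
dG_solv = -2.979 kcal/mol
```

Inspect intermediate stages:

```sh
$ gbsolv charges acetamide.xyz      # EE charges and coordination numbers
$ gbsolv surface acetamide.xyz      # per-atom exposed areas/volumes
$ gbsolv features acetamide.xyz     # the raw 58-entry descriptor vector (CSV)
$ gbsolv fit-ee targets.csv --out params.txt   # refit EE parameters
```

All commands accept `--json` where machine-readable output makes sense and
exit nonzero with a message on stderr for malformed input, unsupported
elements, or unknown solvents.

## Quick start (Python)

```python
import numpy as np
from gbsolv import Molecule, solve_charges, featurize, lookup_solvent

mol = Molecule(("O", "H", "H"),
               np.array([[0.000, 0.000, 0.000],
                         [0.957, 0.000, 0.000],
                         [-0.240, 0.927, 0.000]]))

sol = solve_charges(mol)
print(np.round(sol.charges, 4), round(sol.chi, 4))
# [-0.1317  0.0659  0.0659] 2.428

vec = featurize(mol, lookup_solvent("water"))
print(vec.shape, np.round(vec[:4], 3))
# (58,) [ 3.     0.    18.003 29.603]
```

Charges always sum to the molecular charge exactly (the conservation
constraint is a row of the linear system, plus a round-off projection).

Training from arrays instead of the CLI:

```python
from gbsolv import make_dataset, train_model

ds = make_dataset(2000, seed=0)          # synthetic records, declared labels
model = train_model(ds.X_raw, ds.y, ds.schema, strata=ds.strata, seed=0)
model.save("model.json")
```

`make_dataset` labels its records with a *declared* linear function of the
reduced features plus Gaussian noise, so learning experiments have an
exactly known ground truth; `ds.coef`, `ds.intercept`, and
`ds.noise_sigma` expose it.

## Supported chemistry

Elements H, C, N, O, F, Si, P, S, Cl, Br, I (charge solver); the element-
resolved descriptors cover the nine organic elements H, C, N, O, F, S, Cl,
Br, I. The solvent registry (`gbsolv/data/solvents.txt`, a user-editable
text table) ships water and ~70 common organic solvents, each described by
dielectric constant, boiling point, and heavy-atom count. Parameter tables
(EE parameters, Bondi and covalent radii, the retained element-pair list)
are plain text under `src/gbsolv/data/` and can be swapped via file
arguments.

## Layout

```
src/gbsolv/
  molecule.py   geometries, XYZ I/O, radii, coordination numbers, solvents
  charges.py    EE linear system, solver, simplex refitting
  surface.py    spherical-cap exposed areas and volumes
  features.py   Still pair function, GB terms, descriptor assembly
  model.py      PCA reduction, dense network, Nadam training, persistence
  datasets.py   ionic augmentation operators, synthetic record generator
  cli.py        click command-line interface
  data/         plain-text parameter tables
tests/          oracle-based unit/property tests + acceptance suite
scripts/        acceptance.py (headline-number reproduction)
docs/           methods.md (modeling conventions, numerics, limitations)
```

## License and scope

Research code for method exploration on synthetic and user-supplied data.
The shipped parameter tables reproduce standard literature values; no
trained model weights are bundled — train on your own reference data.
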