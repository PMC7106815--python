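# cavqsar

QSAR modelling of flavonoid activity on osteoblastic voltage-gated calcium
(CaV) channels.

Flavonoids — kaempferol, quercetin, scutellarein and their relatives — can
activate or inhibit the L-type CaV channel of bone-forming osteoblasts, and
ranking them by that activity is one route to screening phytochemicals for
osteogenic potential. This package implements the full modelling stack for
that problem as a tested library:

- **Molecular graphs and topological descriptors.** Structures (SMILES or
  MOL/SDF V2000, parsed with RDKit) become heavy-atom graphs, from which the
  package computes the second-order kappa alpha shape index

  &nbsp;&nbsp;²κα = (A + α − 1)(A + α − 2)² / (P + α)²,

  with A the heavy-atom count, P the number of two-bond paths and α the
  Kier covalent-radius correction, and the total/mean information content
  on the distance equality

  &nbsp;&nbsp;Id = K·log₂K − Σ_g f_g·log₂f_g, IdwAverage = −Σ_g (f_g/K)·log₂(f_g/K),

  where the K = A(A−1)/2 pairwise graph distances fall into equality
  classes of sizes f_g. A geometric descriptor (moment of inertia about the
  y-axis) is computed from conformer coordinates; quantum-chemical
  descriptors (Most+vePotential, DeltaEpsilonC) are accepted as supplied
  table columns.

- **Principal-components regression (PCR) with GA descriptor selection.**
  The response pIC₅₀ = −log₁₀ IC₅₀(μM) is regressed on the leading
  principal components of the standardized descriptor matrix (X = TPᵀ);
  the retained component count p′ is chosen to maximize adjusted r², and a
  seeded genetic algorithm searches descriptor subsets. Fitted models
  back-transform to plain linear equations β₀ + Σ βⱼxⱼ.

- **The validation-metric suite.** r², adjusted r², F, standard error of
  estimate, leave-one-out PRESS/SDEP/q², Roy's r_m² family, external
  r²_pred and RMSEP, and k-fold external validation.

- **Published data tables as audited fixtures.** The 24-compound
  activation table and 23-compound inhibition table (observed/predicted
  pIC₅₀ and residuals), the compound roster with PubChem CIDs and the
  20/4 train/test split, the training-set descriptor ranking table, and
  the patch-clamp time constants (metadata only) ship as checksummed CSVs.
  The recomputable summary statistics of the activation model are
  reproduced from them; summary values that independent recomputation
  contradicts are carried as `printed_unreproduced` metadata and never
  asserted.

## Worked example

```sh
$ cavqsar reproduce
training r2       0.3183
external r2_pred  0.9579
std error (N-p)   0.0933
test RMSEP        0.01785
```

The activation model explains ~32% of training variance (r² = 0.3183 over
the 20 training compounds), predicts the 4 held-out compounds well
(r²_pred ≈ 0.958 against the training observed mean, RMSEP ≈ 0.018
pIC₅₀ units), with a standard error of estimate of 0.0933 at df = N − p.

```sh
$ cavqsar rank --model A --subset train
rank  name           predicted  observed  split
1     Myricetin      0.630      0.556     train
2     Isorhamnetin   0.611      0.732     train
3     Tamarixetin    0.602      0.663     train
...
```

Ranking is by predicted activation pIC₅₀, ties alphabetical.

From Python:

```python
from cavqsar import read_structure, compute_descriptors, fit_pcr
from cavqsar.synthetic_data import SyntheticSpec, gen_qsar_dataset

g = read_structure("O=c1cc(-c2ccc(O)cc2)oc2cc(O)c(O)c(O)c12")  # scutellarein
compute_descriptors(g)   # {'k2alpha': ..., 'Id': ..., 'IdwAverage': ..., ...}

df = gen_qsar_dataset(SyntheticSpec(seed=1))          # 24 synthetic compounds
model = fit_pcr(df[[c for c in df if c.startswith("d")]], df["activity"])
model.linear_model.coefficients
```

Other CLI subcommands: `descriptors` (SDF or SMILES-CSV in, descriptor CSV
out), `fit` (PCR with `--ga` subset selection), `validate` (`--loo`,
`--kfold 6x4`).

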