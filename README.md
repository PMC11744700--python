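# pofp — photophysics-oriented fingerprints for organic luminophores

`pofp` implements a compact, interpretable molecular fingerprint for
aggregate-state photophysics — the regime of aggregation-induced emission
(AIE), aggregation-caused quenching (ACQ), delayed fluorescence (TADF/AIDF)
and room-temperature phosphorescence (RTP) — together with the analysis
stack that makes the fingerprint useful:

* **fingerprints** — SMILES → 46-digit POFP vectors by SMARTS substructure
  matching (RDKit);
* **data** — reading, validating and cleaning database-style photophysics
  tables, and the wavelength/energy conversion `E ≈ 1240/λ`;
* **synthetic** — a fragment-assembly generator producing donor–acceptor
  chromophore datasets from a *stated* ground-truth function of the
  fingerprint, so every downstream method can be tested against a known
  answer without external data;
* **models** — the standard small-data QSPR zoo (linear, SVM, kNN, trees,
  random forest, gradient boosting) plus a four-layer ReLU neural network,
  with seeded 5-fold cross-validation and the R²/MAE/MSE and
  accuracy/weighted-F1/confusion metric suite;
* **interpret** — integrated-gradient attribution of trained models,
  normalized/unnormalized/fraction-of-total variants, baseline sweeps;
* **cvae** — a conditional variational autoencoder over POFP(num)
  conditioned on emission energy, whose decoder yields *mean fingerprint
  profiles* at target wavelengths.

It is written for photophysics and materials-informatics researchers who
want structure–property models whose inputs they can read: every digit of
the fingerprint names a donor, acceptor, ESIPT pattern, conjugation breaker
or the aromatic-atom count, so a model attribution is directly a statement
about chemistry.

## The fingerprint

A POFP is a vector `s = (s1, …, s46)`:

| digits | block | examples |
|--------|-------|----------|
| 1–15   | electron donors & ESIPT patterns | dialkylamino, triphenylamine, enol-imide |
| 16–38  | electron acceptors | cyano, C=N, BF₂ bridge, aromatic N |
| 39–45  | conjugation breakers | *t*-butyl, saturated aromatic bridges |
| 46     | aromatic-atom count | the conjugation-scale proxy |

Digits 1–45 are counts of **distinct matched atom sets** of 45 SMARTS
patterns (`num` mode) or presence bits (`bit` mode); digit 46 counts atoms
flagged aromatic under RDKit's default aromaticity model. The canonical
worked example is tetraphenylethylene (TPE): one C=C double bond and four
phenyl rings, hence exactly two active digits, `s10 = 1` and `s46 = 24`.

A property model is then a map `p = F(s1, …, s46)`. Attribution of a
prediction to digit *i* uses integrated gradients along the straight path
`s(α) = s̄ + α(s − s̄)` from a baseline fingerprint s̄:

```
IG_i = (s_i − s̄_i) ∫₀¹ ∂F/∂s_i (s(α)) dα
```

approximated by a 100-point trapezoidal rule. The normalized attributions
satisfy completeness (they sum to `F(s) − F(s̄)`), and a fraction-of-total
variant rescales them to sum to exactly 1.

## Worked example

```python
import numpy as np
from pofp import compute_pofp, fingerprint_table, wavelength_to_energy
from pofp.synthetic import generate_dataset
from pofp.models import ModelSpec, build_fcnn, cross_validate, fit
from pofp.interpret import classify_and_attribute, attribution_report

TPE = "C(=C(c1ccccc1)c1ccccc1)(c1ccccc1)c1ccccc1"
fp = compute_pofp(TPE, mode="num")
print({f"s{i+1}": int(v) for i, v in enumerate(fp.values) if v})
# {'s10': 1, 's46': 24}

# a 700-record synthetic study with a known generative rule
ds = generate_dataset(700, seed=42).to_frame()
X, kept, _ = fingerprint_table(ds["smiles"].tolist(), "num")
y = np.array([wavelength_to_energy(l) for l in ds["lambda_solid_nm"]])

cv = cross_validate(ModelSpec("fcnn", "regression", seed=42), X, y,
                    folds=5, seed=42)
print({k: round(v, 4) for k, v in cv["mean"].items()})
# {'r2': 0.866, 'mae': 0.0892, 'mse': 0.0167}

clf = fit(build_fcnn(task="classification", seed=42),
          X.astype(float), ds["feature_class"].to_numpy())
predicted, result = classify_and_attribute(clf, TPE)
print(predicted)                       # ACQ
print(attribution_report(result, min_abs=1e-9).to_string(index=False))
# feature                      name  attribution
#     s10 carbon–carbon double bond    -0.054664
#     s46       aromatic atom count     0.093517
```

Reading the output: the cross-validated R² of 0.866 approaches the noise
ceiling of the synthetic ground truth (≈0.98 at σ = 0.05 eV), the MAE is in
eV. The classifier — trained on *synthetic* labels in which flexibility
(2·s10 + 2·s17 + breakers + ESIPT digits) must beat rigidity (s46/6) for
AIE — places TPE in ACQ, exactly what that rule says for s10 = 1, s46 = 24;
a database-trained model would see TPE as the AIE archetype. The two signed
attributions sum to `F(x) − F(baseline)` (0.0389) as completeness requires.

The same pipeline is scriptable from the shell:

```bash
pofp simulate --n 700 --seed 42 --out data.csv
pofp fingerprint --in data.csv --mode num --out fp.csv
pofp cv --in data.csv --task regression --model fcnn --folds 5 --seed 42 --out cv.json
pofp train --in data.csv --task classification --model fcnn --seed 42 --out clf.joblib
pofp interpret --model clf.joblib --smiles "$TPE" --out ig.csv
pofp sweep --model clf.joblib --feature 46 --values 12,18,24,30 \
     --template s10=1 --baseline s10=0.5,s46=6 --target AIE --out sweep.csv
pofp cvae-train --in data.csv --seed 0 --out cvae.npz
pofp cvae-generate --model cvae.npz --out profiles.csv
```

Every output file gets a `.provenance.json` sidecar with the package
version, the seed and a configuration hash.

## Scope

The package consumes exported tables; it contains no web client for any
database. General-purpose fingerprints (MACCS, Morgan, AP, TT) are
benchmark baselines to be taken from RDKit, not re-implemented. The CVAE
decodes mean fingerprints, not chemical structures: one-directional
encoders cannot be inverted into complete molecules.
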