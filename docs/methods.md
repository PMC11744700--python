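# Methods

## The fingerprint and its matching semantics

The POFP assigns one digit per curated substructure: 15 donor/ESIPT
patterns, 23 acceptors, 7 conjugation breakers, plus the aromatic-atom
count. The pattern table is compiled into `pofp.features` and audited at
import: every SMARTS must parse, and the category blocks must partition as
15/23/7.

**Match counting.** A digit in `num` mode is the number of *distinct
matched atom sets*: two matches that map the same atoms in a different
order (the two orientations of the symmetric `[C]=[C]` across one double
bond) count once. This is RDKit's `GetSubstructMatches(uniquify=True)`
semantics, and it is what makes the tetraphenylethylene reference value
s10 = 1 come out. `bit` mode is the indicator `count ≥ 1`; no fuzzy
matching. The test suite checks every pattern against an independent
brute-force subgraph-isomorphism enumeration on a 20-molecule panel.

**Aromaticity.** Digit 46 counts atoms flagged aromatic under RDKit's
default aromaticity perception. The model name (`rdkit-default`) is stored
in every `POFPVector` so counts remain reproducible if a different
perception scheme is ever added. Molecules are matched on the implicit-H
representation; explicit-H counts inside patterns (e.g. `[O;H]`) rely on
RDKit's H-count queries, and molecules are not hydrogen-expanded first.

**Pattern repairs and oddities.** One published-style pattern (row 12,
naphthalene) is syntactically incomplete — it opens a ring closure it never
closes — and is repaired to a fused-naphthalene SMARTS; the repair lives in
an auditable one-entry table (`SMARTS_REPAIRS`) next to the raw rows.
Rows 8/9 (thiophene/furan) demand explicit *single* ring-closure bonds and
therefore never match the aromatic forms of those rings under the default
model; they are kept as defined rather than silently "fixed", since the
fingerprint's definition table is the contract. Rows 42/43 are named "BF4/
PF6 cation" although the patterns depict anions; the names are kept, the
discrepancy noted here. Kekulization failures on exotic aromatic systems
downgrade to partial sanitization with a warning instead of rejection, so
borderline database entries survive cleaning.

**Element support.** The fingerprint can represent H, B, C, N, O, F, Si,
P, S, Cl, Se, Br, I plus the five heavy metals of feature 38 (Au, Bi, Ir,
Ru, Eu) — those five are included precisely because a pattern references
them. Anything else (e.g. Fe, transition-metal complexes) is flagged
`disallowed_element` during cleaning or fingerprinting, never silently
zeroed.

## Wavelength–energy conversion

`E = 1240 / λ` with the constant exactly 1240 (not 1239.84): the relation
is the spectroscopist's rule of thumb and is used as such throughout. It is
strictly decreasing and an involution under λ↔E exchange, both property-
tested. Regression targets are energies in eV, converted from wavelengths
before fitting.

## The synthetic study

The generator exists so that regression, classification, attribution and
the CVAE can be validated against known answers; it emulates the *shape* of
curated photophysics databases (fragment-assembled donor–acceptor
chromophores, solid-state emission 320–1130 nm, class labels AIE/ACQ/TADF/
AIDF/RTP, mechanism labels ICT_TICT/ESIPT/NA/CL) without attempting to
reproduce any real distribution.

**Assembly.** A core (benzene, biphenyl, stilbene, naphthalene or pyridine
template) receives 0–3 donors, 0–3 acceptors and 0–2 breakers drawn from
categorical distributions, bonded via single bonds; substituents beyond a
core's slot count are dropped and empty slots hydrogen-capped. Core
templates use ring-closure digits 7–8 so fragment snippets (ring digits
1–2) can never collide with an open core ring — the failure mode that
produces crossed-ring monsters. Each fragment family provably activates its
digit block (tested). Every assembled SMILES parses, canonicalizes and
fingerprints without rejection.

**Ground-truth energy.** With D = Σ s1..15, A = Σ s16..38:

```
E = 3.6 − 0.12·D − 0.10·A − 0.20·min(D, A) − 0.010·s46 + ε,
ε ~ N(0, 0.05²) eV, clipped to [1.1, 3.9] eV
```

The functional form and coefficients are this package's invention; they
encode the field's qualitative rules (donors, acceptors and conjugation
red-shift; donor–acceptor co-presence is synergistic) at magnitudes that
put ~700-record studies in a realistic signal-to-noise regime (noise
ceiling R² ≈ 0.98).

**Ground-truth labels.** Flexibility X = 2·s10 + 2·s17 + Σ breakers +
Σ ESIPT digits competes with rigidity Y = s46/6. X > Y gives AIE;
X < Y − 1, or X exactly at either boundary, gives ACQ; strictly inside the
band the delayed classes TADF/AIDF/RTP are drawn uniformly. (The boundary
convention is a deliberate resolution of an ambiguous tie rule: it keeps the
two anchor cases — benzene → ACQ, TPE → not AIE — and still lets delayed
classes occur through non-multiple-of-six aromatic counts.) Mechanisms are
deterministic in the digits: ESIPT if any of s13–15, else CL for aromatic-
free heteroatom donors, else ICT_TICT when both D > 0 and A > 0, else NA.
This mirrors how mechanism labels track representative functional groups.

What passing tests on this generator do **not** show: performance on real
measurements (instrument noise, polymorphism, solvent effects, label noise
and class imbalance are all absent), or the sign structure of real
attribution studies — the synthetic classifier legitimately calls TPE ACQ
because the generative rule says so, whereas database-trained models treat
TPE as the AIE archetype.

## Models

Classical learners are scikit-learn estimators with ecosystem-default
hyperparameters, exposed through `ModelSpec.hyperparameters`; every
stochastic family takes the threaded seed. The FCNN is an `MLPRegressor`/
`MLPClassifier` with hidden layers (128, 64, 32), ReLU, Adam at 1e-3,
batch 32, at most 500 epochs with early stopping on a 10% validation split
(patience 25) — sized for the ~700-row regime. Fingerprint columns are
standardized *on the training fold only*; the scaler is stored with the
model so prediction and gradients include the chain rule through it.

The FCNN's input gradient is computed analytically from the fitted weights
(ReLU masks on the forward pre-activations; softmax or logistic Jacobian
for classification probabilities; a logit mode is available). It matches
central finite differences to <1e-4 relative error in tests. Tree and
kernel families do not expose gradients and say so with a typed error.

Cross-validation uses seeded shuffled K-fold, stratified for
classification; a class rarer than the fold count relaxes stratification
with a warning rather than failing. Reported metrics are means over folds
with per-fold values retained. Quantum-yield and lifetime targets are
regressed untransformed.

## Integrated gradients

The path integral over the straight line from baseline to input is
approximated by a trapezoidal rule over `n_steps = 100` points including
both endpoints. For ReLU networks the integrand (the gradient along the
path) is piecewise *constant*, so the quadrature error at the kinks is
O(1/n); at n = 100 this is of order a few percent of the largest
attribution, and the implementation is convergence-tested against a
10,000-step oracle (errors shrink by ~an order of magnitude per 10×
steps). Completeness — normalized attributions summing to
`F(x) − F(baseline)` — holds exactly for linear models and within 1e-2 for
trained FCNNs at n = 100.

Three variants: `unnormalized_eq4` (bare path-averaged gradient; smooth
sweep curves), `normalized_eq3` (multiplied by `s_i − s̄_i`; complete),
and `fraction_of_total` (normalized attributions divided by their sum, so
contributions sum to exactly 1; guarded against a zero denominator). For
classification the attributed output is the softmax probability of the
target class. Baselines are arbitrary finite vectors; the near-indifferent
hypothetical baseline s10 = 0.5, s46 = 6 ships as `baseline_s10_s46()`,
and fractional fingerprints are deliberately legal model inputs for sweeps.

## The conditional VAE

Encoder (46-digit fingerprint ⊕ standardized energy) → two ReLU layers
(64, 32) → latent mean and log-variance; decoder (latent ⊕ standardized
energy) → (32, 64) → 46 linear outputs. The latent dimension defaults to 2
so the decoder input is 3-dimensional. Loss: reconstruction MSE summed over
digits plus `kl_weight` (default 1.0) times KL(N(μ,σ²)‖N(0,I)), optimized
with the reparameterization trick and Adam (manual NumPy backprop; no deep-
learning framework is used). Training, shuffling and sampling all draw from
one seeded generator, so runs are bit-reproducible.

Generation decodes z = 0 under the target energy — "μ = 0, σ = 0" read as
decoding the latent prior mean with no sampling noise. Outputs are clipped
at zero only at report time so training gradients are unaffected. An
`identity` activation option turns the model into an analytically
tractable linear CVAE: with the latent collapsed by a strong KL weight the
decoder is a linear regression of fingerprint on energy, which must pass
through the (mean energy, mean fingerprint) point — used as a closed-form
sanity check in the tests. Exact encoder widths, KL weighting and schedule
for database-scale studies are not fixed by any reference; the defaults
here were chosen for the 700-record synthetic study and are all exposed in
`CVAEConfig`.

## Numerical and design notes

* Degenerate inputs: zero-variance regression targets are fitable but
  flagged (R² undefined → NaN with a warning); x = baseline gives all-zero
  attributions and a guarded error only for the fraction-of-total variant;
  empty fingerprint batches return 0×46 matrices.
* The CSV reader treats only empty cells as missing — the mechanism label
  "NA" is data, not NaN.
* Duplicate SMILES are retained by default (polymorph entries are
  legitimate); `clean_records(..., dedup=True)` keeps first occurrences.
* Problem sizes in the default test run: 700-record synthetic study for
  model/CVAE claims, 2,000 rows for the Gaussian-MAE-floor identity,
  1,000 assemblies for generator validity, a 20-molecule panel for the
  brute-force matcher equivalence.

## Known limitations

* The fingerprint ignores stereochemistry, morphology and thermodynamic
  history; identical fingerprints can belong to photophysically different
  polymorphs.
* Digit 46 depends on the aromaticity model; exotic ring systems surviving
  via partial sanitization may count differently in other toolkits.
* The SMARTS table is closed-world: chemistry outside its 45 motifs is
  invisible except through the aromatic count.
* Synthetic benchmarks bound optimism, not real-world accuracy.
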