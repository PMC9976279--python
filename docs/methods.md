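# Methods

This note records the models, conventions and numerical choices behind
`solqspr`, in the order data flows through the pipeline.

## Curation

Input rows are `(id, smiles, logS, source)` with log(S) in log10 molar
units at 298 K (intrinsic solubility: the neutral form of the solute).

* **Standardization.** SMILES are parsed with RDKit; unparseable strings
  are rejected. Multi-component SMILES are treated as salts only when every
  component except the heaviest is on a fixed counterion whitelist (Na⁺,
  K⁺, Li⁺, Ca²⁺, Mg²⁺, halides, sulfate/bisulfate, nitrate, acetate,
  ammonium); the lighter components are then stripped (the
  lowest-molecular-weight-component rule) and the surviving parent's
  formal charges neutralized by adding/removing protons where chemically
  possible. Any other multi-component entry is rejected as a
  solvate/mixture. Precedence had to be chosen here: the whitelist decides
  *whether* the entry is a salt, the MW rule decides *what* is removed.
* **Tautomers** are preserved as written — literature sources are assumed
  to have recorded an appropriate tautomeric form, and tautomer
  canonicalization would silently change the identity of some compounds.
* **Zwitterions.** Formal charges on single-component molecules are left
  untouched (neutralization only follows counterion stripping); such
  records are counted in the curation report (`retained_with_formal_charge`).
* **Deduplication** uses standard InChI at default settings; the first
  occurrence in input order wins. Averaging duplicate measurements was
  deliberately avoided: it would mix sources with different (unknown)
  error models.
* **Filters.** Rejection is by strict inequality — heavy atoms < 4,
  MW > 1400, rotatable bonds > 20 — so boundary molecules (n-butane,
  exactly 20 rotatable bonds) are retained. Rotatable bonds use the RDKit
  default definition (non-ring single bonds between non-terminal heavy
  atoms, amide C–N excluded). The first matching reason in the order
  small → large → flexible is tallied, and the report satisfies
  `input = retained + rejections + duplicates` by construction.

## Descriptors and scaling

The default panel (`rdkit2d`) is the full RDKit 2D descriptor list
(~210 columns; Crippen logP/MR, Lipinski counts, VSA/EState surface terms,
topological indices, QED, fragment counts). Cleanup removes, in order:

1. columns whose name contains `solubility`, `logs` or `esol`
   (case-insensitive) — a descriptor must not smuggle in the target;
2. columns returning Boolean or string values for any molecule;
3. columns that are missing, non-finite, or raise for **any** molecule —
   dropped for *all* molecules so every row shares one valid column set.

Exact retained counts are toolkit-version-dependent; they are logged in the
matrix's drop record, never asserted. The panel registry accepts custom
panels, which is also how the cleanup rules are unit-tested with
deliberately misbehaving descriptors.

Scaling is classic standardization (subtract mean, divide by SD) with the
**population (divide-by-N) SD**, fit on training rows only; zero-variance
columns are dropped at fit time and recorded. In the validation protocol
the scaler is refit inside every inner fold and outer training portion, so
no test or validation information leaks into the transform.

Fingerprints are Morgan, radius 2, 2048 bits, fixed per run.

## Models

* **Random Forest** (scikit-learn): hyperparameters exposed are
  `n_trees`, `max_depth`, `min_samples_leaf`, `max_features`, and
  `bootstrap` (default on; turning it off makes a full-depth forest an
  exact memorizer, which several oracle tests exploit). Gini importances
  are the mean impurity decrease, normalized to sum to 1.
* **Dense network** (scikit-learn MLP): three hidden layers with strictly
  decreasing widths (default 256/128/64), ReLU activations, Adam, MSE loss
  (the differentiable counterpart of tuning to RMSE), batch size 32,
  epoch budget 200 with early stopping on a 10% validation split
  (patience 20). Features are standardized via the scaler above, which is
  stored inside the fitted model so prediction accepts raw matrices.
* Default grids (config-overridable): RF `n_trees ∈ {100, 500}` ×
  `max_features ∈ {sqrt, 1/3, all}` × `min_samples_leaf ∈ {1, 3}`;
  NN widths `{(256,128,64), (128,64,32)}` × learning rate `{1e-3, 1e-4}`.

Both families are deterministic given `(seed, data)`; predictions on
refit-with-different-seed models agree only stochastically and are never
asserted bit-exact.

## Validation protocol

`nested_cv(records, features, family, grid, n_resamples=50, test_frac=0.30,
inner_k=5, seed)`:

1. the master seed spawns one child seed per resample (NumPy
   `SeedSequence`), making resamples independent but bit-reproducible;
2. each resample draws a random (unstratified) 70/30 split;
3. an inner 5-fold CV on the training portion — folds fixed per resample,
   shared across grid points — scores each grid point by mean fold RMSE;
   the minimum wins, ties broken by grid order;
4. the winner is refit on the full training portion and scored on the
   held-out 30%;
5. the report stores every per-resample statistic and aggregates
   mean ± SD (sample SD, ddof = 1).

A single best hyperparameter set is carried to the final 100% refit: the
modal choice across resamples (ties again by grid order). The final model
records the SHA-256 of the validation report it came from.

On synthetic data the protocol is calibrated: as the library grows, the
validation RMSE approaches the generator's noise SD from above (the
irreducible-error floor). The shipped check uses n = 2000, σ = 0.62, three
resamples, a 200-tree forest on the generator's own count features, and
lands within 15% of σ (~0.65–0.66 observed); count features rather than the
full panel isolate protocol calibration from featurization error, and
these sizes keep the default suite fast while leaving the sampling error
of the check well below its tolerance.

## Error statistics

For predictions y_calc against experiment y_exp (both log10 molar), with
error e = y_calc − y_exp:

* bias (mean displacement) M = mean(e) — positive means solubility is
  overpredicted;
* SDEP = population SD of e;
* RMSE = √(mean e²), so **RMSE² = SDEP² + M² exactly** under the
  divide-by-N convention — the identity is asserted (tolerance 1e-9) on
  every statistics object ever constructed;
* R² = 1 − SS_res/SS_tot about the experimental mean; it may be negative,
  and is reported as undefined when the experimental values have zero
  variance. Note that a predictor equal to the experimental mean scores
  R² = 0 exactly — "worse than the null model" therefore means RMSE
  greater than the experimental SD (strict), which is the flag exposed;
* % ± 0.5 log uses an inclusive boundary (|e| ≤ 0.5).

Range restriction for cross-test-set comparison keeps molecules with
lower < y_exp < upper, both bounds strict, matching the printed convention
of the solubility-challenge range (−6.79, −1.18); an empty result is valid
and left to the caller to flag.

## Chemical-space audit

Tanimoto similarity is |A∩B|/|A∪B| over fingerprint bit sets, defined as 0
when both are empty. Set-to-set distributions score all |A|·|B| pairs
(within-set: unordered pairs) and summarize with mean/median/max plus a
fixed 0.05-bin histogram on [0, 1]. Bemis–Murcko scaffolds (rings plus
linkers, side chains removed) are counted per set with pairwise overlaps;
acyclic molecules share a single "empty scaffold" bucket, counted once and
flagged separately, since leaving them out would silently shrink set
counts. The similarity graph connects molecules at Tanimoto ≥ threshold
(default 0.5, *inclusive*), weights edges by the similarity, and computes a
Fruchterman–Reingold layout with the weight as spring strength; coordinates
are seeded, advisory output — tests only ever assert their finiteness.

## Counterfactual attribution

Mutation operates on an atom-level SMILES tokenization: each candidate
applies 1–3 random substitutions/insertions/deletions of atom tokens drawn
from the vocabulary observed in the input library (keeping mutants roughly
in-distribution), and any string that fails to parse or standardize is
discarded within a bounded attempt budget (default 100 × the requested
candidate count; exhaustion yields an empty list, logged by the caller).
Surviving mutants are deduplicated by InChI and never include the original.

Candidates whose predicted log(S) shifts by ≥ 1 log unit (inclusive) are
counterfactuals. They are clustered by fingerprint similarity (RDKit
Butina, threshold Tanimoto 0.7, config-overridable) and each cluster is
represented by its largest-|Δ| member — the most informative exemplar.
Original/counterfactual pairs differing in **exactly one** RDKit
fragment-count descriptor attribute the shift to that fragment. Per
fragment, with the descriptor direction normalized (aligned shift =
direction × Δpred), f_increase and f_decrease are the fractions of pairs
with positive and negative aligned shift (exact ties count toward
neither), and effect = f_increase − f_decrease ∈ [−1, 1]; negating all
predicted shifts negates every effect. Attribution uses the final trained
model, not per-resample models: the question answered is what the
deployed model has learned.

## Synthetic libraries

The generator exists so that every stage has a ground truth. Molecules are
assembled by decorating one of five scaffolds (benzene, pyridine,
piperidine, cyclohexane, biphenyl) with 0–4 substituents (C1–C4 alkyl,
hydroxyl, primary amine, carboxyl, F/Cl/Br, methoxy) at ring-carbon sites —
a grammar that guarantees chemical validity without repair loops, at the
cost of limited scaffold diversity (a handful of Murcko frameworks, far
fewer than a real literature set).

The noiseless truth is linear in five structural counts with defaults

| term | coefficient | rationale |
|---|---|---|
| aromatic rings | −1.1 | each ring adds ~2 logP-equivalents of hydrophobicity |
| aliphatic carbons | −0.5 | the dominant lipophilicity-like term (largest variance share) |
| H-bond donors | +0.7 | donors promote hydration |
| H-bond acceptors | +0.4 | weaker than donors |
| halogens | −0.6 | hydrophobic, mildly polarizable |
| intercept | −0.8 | centers the library in the 0 to −5 log range |

Counts use RDKit definitions throughout, so an ordinary linear regression
on the count features recovers the coefficients exactly on noiseless data.
The dominance of the aliphatic-carbon term is what makes calculated-logP
descriptors carry the top Gini importance when a forest is trained on the
full 2D panel — though on the panel the importance is shared with the
binned lipophilicity/refractivity surface descriptors (SlogP_VSA/SMR_VSA),
so only membership of that family, not an exact winner, is a stable
property.

Observations add i.i.d. Gaussian noise in log10 units; presets σ = 0.17
("tight", low inter-laboratory variance) and σ = 0.62 ("loose"). The
default target range for the noiseless truth is (−7.0, −0.5), placing the
bulk of the library between 0 and −5 log units; molecules outside the
range are resampled, and an unreachable range raises an error naming the
constraint. Noise tests use n = 4000 draws (SD sampling error ≈ 1.1%,
comfortably inside the 2% assertion band).

What the generator does **not** emulate: real scaffold diversity,
correlated/heteroscedastic measurement error across sources, tautomeric
and ionization ambiguity, stereochemistry, and any nonlinearity in the
structure–solubility map. Passing tests on synthetic data therefore
demonstrate the *machinery* (protocol calibration, leakage-freedom,
attribution correctness), not predictive accuracy on real chemistry.

Scaffold-disjoint splitting assigns whole Murcko-scaffold groups to the
test side via subset-sum (groups are indivisible), realizing the requested
fraction to within 2% of the library size or failing with the list of
achievable fractions.

## Known limitations

* Only the RDKit 2D panel ships; larger panels plug in through the
  registry but are not bundled.
* Graph neural networks are out of scope; the published graph-model
  results enter only through the error-decomposition identity.
* The solubility-descriptor blocklist is a substring heuristic
  (`solubility`/`logs`/`esol`); a descriptor encoding solubility under
  another name would pass it.
* Scaffold and similarity statistics computed against published data are
  sensitive to fingerprint/InChI versions of the underlying toolkit.
* The counterfactual procedure attributes *model* behaviour; agreement
  with chemical intuition on synthetic truth does not certify the model's
  chemistry on real data.
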