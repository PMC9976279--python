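"""Counterfactual fragment attribution for solubility models.

The procedure explains what a trained regressor has learned by perturbing
molecules rather than inspecting weights: each molecule is mutated a small
number of times (1-3 random token edits on an atom-level SMILES
tokenization; edits that do not decode to a valid, standardizable molecule
are discarded within a bounded attempt budget), mutants whose predicted
log(S) shifts by at least one log unit are kept as counterfactuals (one
representative per fingerprint-similarity cluster), and original/mutant
pairs that differ in exactly one fragment-count descriptor attribute the
prediction shift to that chemical fragment.  For each fragment the
statistic reported is f_increase - f_decrease: the net fraction of pairs
in which adding the fragment raised the predicted solubility.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from rdkit.Chem import Fragments
from rdkit.ML.Cluster import Butina

from . import features as _features
from . import models as _models
from .curation import MoleculeRecord, standardize
from .features import morgan_fp
from .chemspace import tanimoto

__all__ = [
    "CounterfactualCandidate",
    "CounterfactualPair",
    "FragmentEffect",
    "mutate",
    "select",
    "make_pairs",
    "fragment_effects",
    "fragment_counts",
]

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d\d|[BCNOPSFIbcnops]|\d|\(|\)|=|#|\+|-|/|\\|\.)"
)
_ATOM_RE = re.compile(r"^(\[[^\]]+\]|Br|Cl|[BCNOPSFIbcnops])$")

#: Default mutation alphabet: atom tokens of common organic chemistry.
DEFAULT_ALPHABET = ("C", "c", "N", "n", "O", "o", "F", "Cl", "Br", "S")

#: Minimum predicted log(S) shift for a counterfactual (log10 units).
MIN_DELTA = 1.0


def tokenize(smiles: str) -> list[str]:
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"cannot tokenize SMILES {smiles!r}")
    return tokens


def alphabet_from_library(records: Sequence[MoleculeRecord]) -> tuple[str, ...]:
    """Atom-token vocabulary observed in a library, keeping mutants in-distribution."""
    seen: set[str] = set()
    for r in records:
        seen.update(t for t in tokenize(r.smiles) if _ATOM_RE.match(t))
    return tuple(sorted(seen)) or DEFAULT_ALPHABET


@dataclass(frozen=True)
class CounterfactualCandidate:
    record: MoleculeRecord
    delta_pred: float  # predicted log(S), counterfactual minus original


@dataclass(frozen=True)
class CounterfactualPair:
    """An original/counterfactual pair differing in one fragment descriptor."""

    original: MoleculeRecord
    counterfactual: MoleculeRecord
    delta_pred: float
    descriptor: str
    direction: int  # +1 fragment count increased in the counterfactual, -1 decreased

    def __post_init__(self) -> None:
        if abs(self.delta_pred) < MIN_DELTA:
            raise ValueError(
                f"counterfactual pairs require |delta_pred| >= {MIN_DELTA}, got {self.delta_pred}"
            )
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass(frozen=True)
class FragmentEffect:
    descriptor: str
    n_pairs: int
    f_increase: float
    f_decrease: float
    effect: float  # f_increase - f_decrease, in [-1, 1]

    def __post_init__(self) -> None:
        if not -1.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [-1, 1]")
        if self.f_increase + self.f_decrease > 1.0 + 1e-12:
            raise ValueError("fractions exceed 1")


def _edit(tokens: list[str], rng: np.random.Generator, alphabet: Sequence[str]) -> list[str]:
    tokens = list(tokens)
    op = rng.integers(3)
    atom_pos = [i for i, t in enumerate(tokens) if _ATOM_RE.match(t)]
    if op == 0 and atom_pos:            # substitute an atom token
        i = int(atom_pos[rng.integers(len(atom_pos))])
        tokens[i] = alphabet[rng.integers(len(alphabet))]
    elif op == 1:                        # insert an atom token
        i = int(rng.integers(len(tokens) + 1))
        tokens.insert(i, alphabet[rng.integers(len(alphabet))])
    elif atom_pos:                       # delete an atom token
        i = int(atom_pos[rng.integers(len(atom_pos))])
        del tokens[i]
    return tokens


def mutate(
    record: MoleculeRecord,
    max_mutations: int = 3,
    n_candidates: int = 20,
    seed: int = 0,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    attempt_budget: Optional[int] = None,
) -> list[MoleculeRecord]:
    """Generate valid mutant molecules of one record.

    Each candidate applies 1..max_mutations random token substitutions,
    insertions or deletions to the SMILES token sequence; strings that do
    not parse, fail standardization, or reproduce the original molecule
    are discarded.  Deterministic for a fixed seed; returns up to
    ``n_candidates`` distinct molecules (an empty list when the attempt
    budget is exhausted, or when ``max_mutations`` is 0).
    """
    if max_mutations <= 0:
        return []
    rng = np.random.default_rng(seed)
    budget = attempt_budget if attempt_budget is not None else 100 * n_candidates
    base = tokenize(record.smiles)
    out: list[MoleculeRecord] = []
    seen_inchi = {record.inchi}
    for _ in range(budget):
        if len(out) >= n_candidates:
            break
        toks = list(base)
        for _ in range(int(rng.integers(1, max_mutations + 1))):
            toks = _edit(toks, rng, alphabet)
        smi = "".join(toks)
        res = standardize(smi, id=f"{record.id}-mut{len(out):03d}")
        if not isinstance(res, MoleculeRecord):
            continue
        if res.inchi in seen_inchi:
            continue
        seen_inchi.add(res.inchi)
        out.append(res)
    return out


def select(
    model: _models.FittedModel,
    original: MoleculeRecord,
    candidates: Sequence[MoleculeRecord],
    featurizer: Optional[Callable[[Sequence[MoleculeRecord]], "_features.FeatureMatrix"]] = None,
    delta: float = MIN_DELTA,
    cluster_threshold: float = 0.7,
) -> list[CounterfactualCandidate]:
    """Keep candidates whose predicted log(S) shifts by at least ``delta``.

    The shift is inclusive ("at least").  Survivors are clustered by
    fingerprint Tanimoto similarity (single-linkage at
    ``cluster_threshold``) and the candidate with the largest absolute
    shift represents each cluster.  ``featurizer`` maps records to a
    feature matrix covering the model's training columns; the default
    computes the model's descriptor columns directly and silently drops
    candidates with non-finite descriptor values.
    """
    if not candidates:
        return []

    if featurizer is None:
        def featurizer(recs):
            m, _skipped = _features.descriptor_matrix_for(recs, model.columns if model.scaler is None else model.scaler.names)
            return m

    all_recs = [original, *candidates]
    X = featurizer(all_recs)
    kept_ids = set(X.ids)
    if original.id not in kept_ids:
        raise ValueError("original molecule could not be featurized")
    preds = dict(zip(X.ids, _models.predict(model, X)))
    base = preds[original.id]

    shifted = [
        CounterfactualCandidate(record=c, delta_pred=float(preds[c.id] - base))
        for c in candidates
        if c.id in preds and abs(preds[c.id] - base) >= delta
    ]
    if len(shifted) <= 1:
        return shifted

    fps = [morgan_fp(c.record) for c in shifted]
    dists = []
    for i in range(1, len(fps)):
        for j in range(i):
            dists.append(1.0 - tanimoto(fps[i], fps[j]))
    clusters = Butina.ClusterData(
        dists, len(fps), 1.0 - cluster_threshold, isDistData=True
    )
    reps = [
        max((shifted[i] for i in cluster), key=lambda c: abs(c.delta_pred))
        for cluster in clusters
    ]
    reps.sort(key=lambda c: c.record.id)
    return reps


def fragment_counts(record: MoleculeRecord) -> dict[str, int]:
    """Integer fragment-count descriptor vector (fr_* fragment panel)."""
    mol = record.mol()
    return {name: int(fn(mol)) for name, fn in _FRAGMENT_FNS}


_FRAGMENT_FNS = sorted(
    (name, getattr(Fragments, name))
    for name in dir(Fragments)
    if name.startswith("fr_") and callable(getattr(Fragments, name))
)


def make_pairs(
    original: MoleculeRecord,
    selected: Sequence[CounterfactualCandidate],
) -> list[CounterfactualPair]:
    """Pair the original with counterfactuals differing in exactly one
    fragment descriptor."""
    base = fragment_counts(original)
    pairs: list[CounterfactualPair] = []
    for cand in selected:
        cc = fragment_counts(cand.record)
        diff = [k for k in base if cc[k] != base[k]]
        if len(diff) != 1:
            continue
        k = diff[0]
        pairs.append(
            CounterfactualPair(
                original=original,
                counterfactual=cand.record,
                delta_pred=cand.delta_pred,
                descriptor=k,
                direction=1 if cc[k] > base[k] else -1,
            )
        )
    return pairs


def fragment_effects(pairs: Sequence[CounterfactualPair]) -> list[FragmentEffect]:
    """Per-fragment increase/decrease fractions and their difference.

    The descriptor direction is normalized so that ``effect > 0`` means
    adding the fragment raises the predicted solubility: for each pair the
    aligned shift is ``direction * delta_pred``; f_increase is the fraction
    of pairs with positive aligned shift, f_decrease with negative (exact
    ties count toward neither).  Descriptors with zero pairs are omitted.
    """
    by_desc: dict[str, list[float]] = {}
    for p in pairs:
        by_desc.setdefault(p.descriptor, []).append(p.direction * p.delta_pred)
    out = []
    for desc in sorted(by_desc):
        aligned = np.asarray(by_desc[desc])
        n = aligned.size
        f_inc = float(np.sum(aligned > 0) / n)
        f_dec = float(np.sum(aligned < 0) / n)
        out.append(
            FragmentEffect(
                descriptor=desc, n_pairs=n,
                f_increase=f_inc, f_decrease=f_dec, effect=f_inc - f_dec,
            )
        )
    return out
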