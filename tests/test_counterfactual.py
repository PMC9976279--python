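"""Counterfactual attribution: mutation validity, selection, fragment effects."""

import numpy as np
import pytest

from solqspr.counterfactual import (
    CounterfactualPair,
    FragmentEffect,
    alphabet_from_library,
    fragment_counts,
    fragment_effects,
    make_pairs,
    mutate,
    select,
)
from solqspr.curation import MoleculeRecord, standardize
from solqspr.models import ModelSpec, fit
from solqspr.synthetic import count_features


@pytest.fixture(scope="module")
def molecule():
    return standardize("CCc1ccccc1O", id="mol")


@pytest.fixture(scope="module")
def count_model(tight_library=None):
    from solqspr.synthetic import SyntheticSpec, generate_library

    lib = generate_library(SyntheticSpec(n_molecules=250, seed=77, noise_sigma=0.17))
    model = fit(ModelSpec("rf", {"n_trees": 300}, 0), count_features(lib.records), lib.truth)
    return model, lib


class TestMutate:
    def test_zero_mutations_empty(self, molecule):
        assert mutate(molecule, max_mutations=0) == []

    def test_deterministic(self, molecule):
        a = mutate(molecule, seed=5, n_candidates=10)
        b = mutate(molecule, seed=5, n_candidates=10)
        assert [r.smiles for r in a] == [r.smiles for r in b]

    def test_candidates_valid_and_standardized(self, molecule):
        cands = mutate(molecule, seed=1, n_candidates=15)
        assert cands
        for c in cands:
            again = standardize(c.smiles)
            assert isinstance(again, MoleculeRecord)
            assert again.smiles == c.smiles
            assert c.inchi != molecule.inchi  # original removed

    def test_candidates_distinct(self, molecule):
        cands = mutate(molecule, seed=2, n_candidates=20)
        inchis = [c.inchi for c in cands]
        assert len(set(inchis)) == len(inchis)

    def test_exhausted_budget_gives_empty_list(self, molecule):
        assert mutate(molecule, seed=0, n_candidates=5, attempt_budget=0) == []

    def test_alphabet_from_library(self, records):
        alpha = alphabet_from_library(records)
        assert "C" in alpha and all(isinstance(t, str) for t in alpha)


class TestSelect:
    def test_delta_filter_inclusive(self, count_model):
        model, lib = count_model
        rec = lib.records[0]
        cands = mutate(rec, seed=3, n_candidates=20, alphabet=alphabet_from_library(lib.records))
        chosen = select(model, rec, cands, featurizer=count_features, delta=1.0)
        for c in chosen:
            assert abs(c.delta_pred) >= 1.0

    def test_identical_candidate_excluded(self, count_model):
        model, lib = count_model
        rec = lib.records[0]
        twin = MoleculeRecord(id="twin", smiles=rec.smiles, inchi=rec.inchi)
        assert select(model, rec, [twin], featurizer=count_features) == []

    def test_near_identical_candidates_one_representative(self, count_model):
        """Two candidates above the cluster threshold collapse to the one
        with the larger predicted shift."""
        model, _ = count_model
        orig = standardize("c1ccccc1", id="orig")
        # two long alkyl-substituted benzenes: highly similar fingerprints
        c1 = standardize("CCCCCCCCc1ccccc1", id="c1")
        c2 = standardize("CCCCCCCCCc1ccccc1", id="c2")
        from solqspr.chemspace import tanimoto
        from solqspr.features import morgan_fp

        assert tanimoto(morgan_fp(c1), morgan_fp(c2)) > 0.7
        chosen = select(model, orig, [c1, c2], featurizer=count_features, delta=1.0)
        assert len(chosen) == 1
        deltas = {c.record.id: abs(c.delta_pred) for c in
                  select(model, orig, [c1, c2], featurizer=count_features, delta=1.0, cluster_threshold=1.0)}
        if len(deltas) == 2:  # both pass the filter individually
            assert abs(chosen[0].delta_pred) == max(deltas.values())


def pair(desc, delta, direction=1):
    o = standardize("c1ccccc1", id="o")
    c = standardize("Cc1ccccc1", id="c")
    return CounterfactualPair(original=o, counterfactual=c, delta_pred=delta,
                              descriptor=desc, direction=direction)


class TestFragmentEffects:
    def test_hand_example_three_donor_pairs(self):
        """Three pairs adding one H-bond-donor fragment with shifts
        +1.2, +1.1, -1.0 give f_inc=2/3, f_dec=1/3, effect=+1/3."""
        pairs = [pair("fr_NH2", d) for d in (1.2, 1.1, -1.0)]
        (eff,) = fragment_effects(pairs)
        assert eff.f_increase == pytest.approx(2 / 3)
        assert eff.f_decrease == pytest.approx(1 / 3)
        assert eff.effect == pytest.approx(1 / 3)
        assert eff.n_pairs == 3

    def test_all_increase_boundary(self):
        pairs = [pair("fr_NH2", d) for d in (1.5, 2.0)]
        (eff,) = fragment_effects(pairs)
        assert eff.effect == 1.0

    def test_direction_normalization(self):
        # removing a fragment (direction -1) while prediction rises counts
        # as the fragment decreasing solubility
        (eff,) = fragment_effects([pair("fr_unbrch_alkane", 1.5, direction=-1)])
        assert eff.effect == -1.0

    def test_antisymmetry_under_delta_negation(self):
        pairs = [pair("fr_NH2", d) for d in (1.2, 1.1, -1.0)] + [
            pair("fr_halogen", d, direction=-1) for d in (1.3, -1.6)
        ]
        neg = [
            CounterfactualPair(
                original=p.original, counterfactual=p.counterfactual,
                delta_pred=-p.delta_pred, descriptor=p.descriptor, direction=p.direction,
            )
            for p in pairs
        ]
        for a, b in zip(fragment_effects(pairs), fragment_effects(neg)):
            assert a.descriptor == b.descriptor
            assert b.effect == pytest.approx(-a.effect)

    def test_counts_conserved(self):
        pairs = [pair("fr_NH2", 1.2), pair("fr_NH2", -1.4), pair("fr_ether", 1.1)]
        effs = {e.descriptor: e for e in fragment_effects(pairs)}
        assert sum(e.n_pairs for e in effs.values()) == 3
        assert effs["fr_ether"].n_pairs == 1

    def test_small_delta_pair_rejected(self):
        with pytest.raises(ValueError, match="delta_pred"):
            pair("fr_NH2", 0.5)

    def test_effect_bounds_enforced(self):
        with pytest.raises(ValueError):
            FragmentEffect(descriptor="x", n_pairs=1, f_increase=1.0, f_decrease=0.5, effect=0.5)


class TestEndToEnd:
    def test_donor_fragments_raise_solubility_on_synthetic_truth(self, count_model):
        """With a ground truth where H-bond donors raise log(S), the
        attribution recovers positive donor-fragment effects."""
        model, lib = count_model
        alpha = alphabet_from_library(lib.records)
        all_pairs = []
        for i, rec in enumerate(lib.records[:30]):
            cands = mutate(rec, n_candidates=15, seed=100 + i, alphabet=alpha)
            chosen = select(model, rec, cands, featurizer=count_features, delta=1.0)
            all_pairs.extend(make_pairs(rec, chosen))
        assert all_pairs, "no single-fragment counterfactual pairs found"
        effects = {e.descriptor: e.effect for e in fragment_effects(all_pairs)}
        donors = [v for k, v in effects.items() if k in ("fr_NH2", "fr_NH1", "fr_Al_OH", "fr_Ar_OH")]
        assert donors and np.mean(donors) > 0

    def test_pairs_differ_in_exactly_one_fragment(self, count_model):
        model, lib = count_model
        rec = lib.records[1]
        cands = mutate(rec, n_candidates=15, seed=200, alphabet=alphabet_from_library(lib.records))
        chosen = select(model, rec, cands, featurizer=count_features, delta=1.0)
        for p in make_pairs(rec, chosen):
            base, cc = fragment_counts(p.original), fragment_counts(p.counterfactual)
            diffs = [k for k in base if base[k] != cc[k]]
            assert diffs == [p.descriptor]
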