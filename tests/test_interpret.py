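import json

import numpy as np
import pytest

from dilipred import featurize as ft
from dilipred import interpret as it
from dilipred.models import AttentionNetwork, fit_baseline


class FeatureZeroModel:
    """Scores = feature 0; provably ignores every other feature."""

    def predict_proba(self, X):
        p = np.clip(np.asarray(X)[:, 0], 0, 1)
        return np.column_stack([1 - p, p])


class RecordingModel(FeatureZeroModel):
    def __init__(self):
        self.seen = []

    def predict_proba(self, X):
        self.seen.append(np.asarray(X).copy())
        return super().predict_proba(X)


def perfect_data(n=60, d=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, d))
    y = (X[:, 0] > 0.5).astype(int)
    return X, y


class TestPermutationImportance:
    def test_unused_feature_exactly_zero(self):
        X, y = perfect_data()
        table = it.permutation_importance(FeatureZeroModel(), X, y, repeats=10, seed=1)
        np.testing.assert_array_equal(table.replicates[1:], 0.0)

    def test_perfect_feature_mean_near_half(self):
        # shuffling the only informative column of a perfect separator
        # drives AUROC to ~0.5, so the drop averages ~0.5
        X, y = perfect_data(n=200)
        table = it.permutation_importance(FeatureZeroModel(), X, y, repeats=50, seed=2)
        assert table.baseline == 1.0
        se = table.sds[0] / np.sqrt(table.repeats)
        assert abs(table.means[0] - 0.5) < 3 * max(se, 0.01)

    def test_default_repeats_is_fifty(self):
        X, y = perfect_data(n=30, d=2)
        table = it.permutation_importance(FeatureZeroModel(), X, y, seed=0)
        assert table.replicates.shape == (2, 50)

    def test_shuffle_preserves_marginal(self):
        # the permuted column is an exact rearrangement of the original
        X, y = perfect_data(n=25, d=3)
        model = RecordingModel()
        it.permutation_importance(model, X, y, repeats=4, seed=3)
        n = len(y)
        for stacked in model.seen[1:]:  # [0] is the baseline call
            for r in range(stacked.shape[0] // n):
                block = stacked[r * n : (r + 1) * n]
                for j in range(X.shape[1]):
                    np.testing.assert_allclose(np.sort(block[:, j]), np.sort(X[:, j]))

    def test_matches_sklearn_implementation(self):
        # independent oracle: sklearn's permutation_importance on the
        # same model agrees on the ranking of the informative feature
        from sklearn.inspection import permutation_importance as sk_pi

        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 5))
        y = (X[:, 2] > 0).astype(int)
        m = fit_baseline("lr", X, y, seed=0)
        ours = it.permutation_importance(m, X, y, repeats=20, seed=5)
        theirs = sk_pi(m.model, X, y, scoring="roc_auc", n_repeats=20, random_state=5)
        assert np.argmax(ours.means) == np.argmax(theirs.importances_mean) == 2

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        X, y = perfect_data(n=30, d=2)
        table = it.permutation_importance(FeatureZeroModel(), X, y, repeats=5, seed=0)
        path = tmp_path / "imp.csv"
        table.to_csv(path)
        back = pd.read_csv(path)
        reps = np.array([json.loads(r) for r in back["replicates"]])
        np.testing.assert_allclose(reps, table.replicates)

    def test_plot_writes_figure(self, tmp_path):
        X, y = perfect_data(n=30, d=3)
        table = it.permutation_importance(FeatureZeroModel(), X, y, repeats=5, seed=0)
        path = tmp_path / "imp.png"
        table.plot(path, k=3)
        assert path.stat().st_size > 0


class TestCoefficientImportance:
    def test_informative_feature_ranks_first_with_positive_sign(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 4))
        y = (X[:, 1] > 0).astype(int)
        m = fit_baseline("lr", X, y, seed=0)
        df = it.coefficient_importance(m, feature_names=["a", "b", "c", "d"])
        assert df.iloc[0]["name"] == "b"
        assert df.iloc[0]["coefficient"] > 0

    def test_zero_coefficient_ranks_last(self):
        class Fake:
            coef_ = np.array([[1.5, 0.0, -0.7]])

        df = it.coefficient_importance(Fake())
        assert df.iloc[-1]["coefficient"] == 0.0

    def test_unfitted_rejected(self):
        with pytest.raises(ValueError, match="fitted"):
            it.coefficient_importance(object())


@pytest.fixture(scope="module")
def explained_compound():
    smiles = "CC(=O)Nc1ccc(O)cc1"
    bits, bitmap = ft.compute_structural(smiles)
    desc = ft.compute_descriptors(smiles)
    x_raw = ft.assemble(bits, desc)
    net = AttentionNetwork(1032, hidden=(16,), seed=0)
    return smiles, x_raw, bitmap, net


class TestExplainCompound:
    def test_default_k_three_fragments(self, explained_compound):
        _, x_raw, bitmap, net = explained_compound
        exp = it.explain_compound(net, x_raw, bitmap, compound_id="a")
        assert len(exp.top_fragments) == 3
        weights = [f["weight"] for f in exp.top_fragments]
        assert weights == sorted(weights, reverse=True)

    def test_k_larger_than_set_bits_truncates(self, explained_compound):
        _, x_raw, bitmap, net = explained_compound
        n_set = int(x_raw[:1024].sum())
        exp = it.explain_compound(net, x_raw, bitmap, k=5000)
        assert len(exp.top_fragments) == n_set

    def test_weights_are_raw_forward_pass_values(self, explained_compound):
        _, x_raw, bitmap, net = explained_compound
        exp = it.explain_compound(net, x_raw, bitmap)
        s = net.attention(x_raw[None, :]).ravel()
        np.testing.assert_allclose(exp.attention, s, atol=1e-15)
        for frag in exp.top_fragments:
            assert frag["weight"] == pytest.approx(s[frag["feature"]])
        assert exp.attention.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fragments_only_from_set_bits(self, explained_compound):
        _, x_raw, bitmap, net = explained_compound
        exp = it.explain_compound(net, x_raw, bitmap, k=10)
        for frag in exp.top_fragments:
            assert x_raw[frag["feature"]] == 1
            assert frag["environments"], "collisions must be surfaced, not hidden"

    def test_descriptors_reported_separately(self, explained_compound):
        _, x_raw, bitmap, net = explained_compound
        exp = it.explain_compound(net, x_raw, bitmap)
        assert [d["name"] for d in exp.descriptor_attributions] == list(ft.DESCRIPTOR_NAMES)
        desc_features = {f["feature"] for f in exp.top_fragments}
        assert all(f < 1024 for f in desc_features)

    def test_invalid_k(self, explained_compound):
        _, x_raw, bitmap, net = explained_compound
        with pytest.raises(ValueError, match="k"):
            it.explain_compound(net, x_raw, bitmap, k=0)

    def test_probability_flag(self, explained_compound):
        _, x_raw, bitmap, net = explained_compound
        exp = it.explain_compound(net, x_raw, bitmap, min_prob=0.0)
        assert exp.high_confidence  # any p >= 0.0


class TestRenderHighlights:
    def test_sidecar_atoms_within_molecule(self, explained_compound, tmp_path):
        from rdkit import Chem

        smiles, x_raw, bitmap, net = explained_compound
        exp = it.explain_compound(net, x_raw, bitmap)
        svg = tmp_path / "mol.svg"
        sidecar = it.render_highlights(exp, smiles, svg_path=svg)
        n_atoms = Chem.MolFromSmiles(smiles).GetNumAtoms()
        assert sidecar["highlights"]
        for h in sidecar["highlights"]:
            for atom_set in h["atom_sets"]:
                assert all(0 <= a < n_atoms for a in atom_set)
        assert svg.read_text().lstrip().startswith("<?xml")

    def test_radius_zero_single_atom_highlight(self):
        bits, bitmap = ft.compute_structural("C")
        desc = ft.compute_descriptors("C")
        net = AttentionNetwork(1032, hidden=(8,), seed=1)
        exp = it.explain_compound(net, ft.assemble(bits, desc), bitmap, k=1)
        sidecar = it.render_highlights(exp, "C")
        assert sidecar["highlights"][0]["atom_sets"] == [[0]]
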