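"""Model interpretation: dataset-level feature importance and per-compound
attention attribution mapped back to molecular substructures.

Two complementary layers:

* permutation feature importance — model-agnostic; one feature column of
  the held-out evaluation matrix is shuffled at a time and the drop in
  AUROC (baseline minus permuted) is recorded over repeated shuffles.
  For logistic regression, signed coefficients give a second, cheaper
  ranking.
* attention attribution — for a single compound, the attention weights
  of the network are read off the forward pass; the top-k weights among
  *set* fingerprint bits are mapped to every atom environment hashed to
  those bits (hash collisions are surfaced, not hidden) and can be
  rendered as an atom-highlighted depiction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import auroc, predict_proba_1d
from .featurize import DESCRIPTOR_NAMES, BitEnvironmentMap, feature_names as default_feature_names


@dataclass
class ImportanceTable:
    """Per-feature replicate AUROC decreases with summary statistics."""

    feature_names: list[str]
    replicates: np.ndarray  # (n_features, repeats), baseline - permuted
    baseline: float
    metric: str = "auroc"
    repeats: int = 50

    @property
    def means(self) -> np.ndarray:
        return self.replicates.mean(axis=1)

    @property
    def sds(self) -> np.ndarray:
        return self.replicates.std(axis=1, ddof=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": np.arange(len(self.feature_names)),
                "name": self.feature_names,
                "mean": self.means,
                "sd": self.sds,
                "replicates": [json.dumps(r.tolist()) for r in self.replicates],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def top(self, k: int = 10) -> pd.DataFrame:
        df = self.to_frame().drop(columns="replicates")
        return df.sort_values(["mean", "feature"], ascending=[False, True]).head(k)

    def plot(self, path, k: int = 10) -> None:
        """Box plot of replicate AUROC decreases for the k top features."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order = np.argsort(-self.means)[:k][::-1]
        fig, ax = plt.subplots(figsize=(6, 0.5 * k + 1.5))
        ax.boxplot(
            [self.replicates[i] for i in order],
            orientation="horizontal",
            tick_labels=[self.feature_names[i] for i in order],
        )
        ax.set_xlabel(f"decrease in {self.metric.upper()}")
        ax.set_title("Permutation feature importance")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def permutation_importance(
    model,
    X: np.ndarray,
    y,
    repeats: int = 50,
    seed: int = 0,
    feature_names: list[str] | None = None,
    metric=auroc,
) -> ImportanceTable:
    """Permutation feature importance on an evaluation matrix.

    For each feature, each replicate shuffles only that column (the
    permuted column is an exact rearrangement of the original), rescores
    the model, and records baseline minus permuted metric; larger means
    more important. Shuffles for all repeats of one feature are scored in
    a single stacked ``predict_proba`` call, which keeps tree ensembles
    tractable at 1032 features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    n, d = X.shape
    if feature_names is None:
        feature_names = (
            default_feature_names(d - len(DESCRIPTOR_NAMES))
            if d > len(DESCRIPTOR_NAMES)
            else [f"f{i}" for i in range(d)]
        )
    baseline = metric(y, predict_proba_1d(model, X))
    rng = np.random.default_rng(seed)
    stacked = np.tile(X, (repeats, 1))
    replicates = np.empty((d, repeats))
    for j in range(d):
        original = stacked[:, j].copy()
        for r in range(repeats):
            stacked[r * n : (r + 1) * n, j] = X[rng.permutation(n), j]
        probs = predict_proba_1d(model, stacked)
        for r in range(repeats):
            replicates[j, r] = baseline - metric(y, probs[r * n : (r + 1) * n])
        stacked[:, j] = original
    return ImportanceTable(
        feature_names=list(feature_names),
        replicates=replicates,
        baseline=float(baseline),
        repeats=repeats,
    )


def coefficient_importance(lr_model, feature_names: list[str] | None = None) -> pd.DataFrame:
    """Signed logistic-regression coefficients ranked by magnitude.

    Positive coefficients push toward a DILI-positive prediction.
    """
    est = getattr(lr_model, "model", lr_model)  # unwrap FittedBaseline/DiliModel
    est = getattr(est, "model", est)
    if not hasattr(est, "coef_"):
        raise ValueError("model is not a fitted logistic regression")
    coefs = np.asarray(est.coef_).ravel()
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(len(coefs))]
    df = pd.DataFrame(
        {"feature": np.arange(len(coefs)), "name": feature_names, "coefficient": coefs}
    )
    df["abs"] = df["coefficient"].abs()
    df = df.sort_values(["abs", "feature"], ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="abs")


@dataclass
class AttentionExplanation:
    """Per-compound attention attribution.

    ``top_fragments`` holds the k highest-attention *set* structural
    bits, each with every environment hashed to it; descriptor features
    are reported separately and never mapped to fragments. Weights are
    the raw forward-pass attention values (no renormalization after
    truncation); ``high_confidence`` flags p >= the configured cutoff.
    """

    compound_id: str
    probability: float
    high_confidence: bool
    attention: np.ndarray  # full W_att (length = feature dim)
    weighted: np.ndarray  # v = W_att * inp
    top_fragments: list[dict] = field(default_factory=list)
    descriptor_attributions: list[dict] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "id": self.compound_id,
            "probability": self.probability,
            "high_confidence": self.high_confidence,
            "top_fragments": self.top_fragments,
            "descriptor_attributions": self.descriptor_attributions,
            "attention": [round(float(w), 10) for w in self.attention],
            "weighted": [round(float(w), 10) for w in self.weighted],
        }


def explain_compound(
    model,
    x_raw: np.ndarray,
    bitmap: BitEnvironmentMap,
    compound_id: str = "",
    k: int = 3,
    min_prob: float = 0.8,
) -> AttentionExplanation:
    """Attention-based substructure attribution for one compound.

    ``model`` is a :class:`~dilipred.models.DiliModel` of kind ``attn``
    (or a bare :class:`~dilipred.models.AttentionNetwork`); ``x_raw`` the
    compound's raw feature vector; ``bitmap`` its bit-environment map.
    Among structural bits set to 1, the k highest attention weights are
    selected (ties broken toward the lower feature index) and mapped to
    all their environments.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x_raw = np.asarray(x_raw, dtype=float).ravel()
    if hasattr(model, "transform"):
        x = model.transform(x_raw[None, :])
        net = model.model
        n_bits = model.n_bits
    else:
        x = x_raw[None, :]
        net = model
        n_bits = x_raw.size - len(DESCRIPTOR_NAMES)
    cache = net.forward(x, training=False)
    w_att = cache["s"].ravel()
    v = cache["v"].ravel()
    p = float(cache["p"].ravel()[0])

    set_bits = np.flatnonzero(x_raw[:n_bits] != 0)
    order = sorted(set_bits, key=lambda j: (-w_att[j], j))
    top = []
    for j in order[: min(k, len(order))]:
        envs = bitmap.entries.get(int(j), [])
        top.append(
            {
                "feature": int(j),
                "weight": float(w_att[j]),
                "environments": [
                    {"center": e.center, "radius": e.radius, "fragment": e.fragment,
                     "atoms": list(e.atoms)}
                    for e in envs
                ],
            }
        )
    desc = [
        {"name": name, "weight": float(w_att[n_bits + i]), "value": float(x_raw[n_bits + i])}
        for i, name in enumerate(DESCRIPTOR_NAMES)
    ]
    return AttentionExplanation(
        compound_id=compound_id,
        probability=p,
        high_confidence=p >= min_prob,
        attention=w_att,
        weighted=v,
        top_fragments=top,
        descriptor_attributions=desc,
    )


def render_highlights(
    explanation: AttentionExplanation,
    smiles: str,
    svg_path=None,
) -> dict:
    """Depict the molecule with top-fragment atoms highlighted.

    Returns the JSON-able sidecar mapping each top feature to its atom
    index sets; writes an SVG when ``svg_path`` is given. If rendering
    fails, the sidecar is still returned with a warning.
    """
    from .featurize import mol_from_smiles

    mol = mol_from_smiles(smiles)
    n_atoms = mol.GetNumAtoms()
    sidecar = {
        "id": explanation.compound_id,
        "highlights": [
            {
                "feature": frag["feature"],
                "weight": frag["weight"],
                "atom_sets": [
                    [a for a in env["atoms"] if a < n_atoms] for env in frag["environments"]
                ],
            }
            for frag in explanation.top_fragments
        ],
    }
    if svg_path is not None:
        try:
            from rdkit.Chem.Draw import rdMolDraw2D

            atoms = sorted(
                {a for h in sidecar["highlights"] for s in h["atom_sets"] for a in s}
            )
            drawer = rdMolDraw2D.MolDraw2DSVG(400, 350)
            rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol, highlightAtoms=atoms)
            drawer.FinishDrawing()
            with open(svg_path, "w") as fh:
                fh.write(drawer.GetDrawingText())
        except Exception as e:  # pragma: no cover - depends on rdkit drawing
            warnings.warn(f"could not render molecule {explanation.compound_id}: {e}",
                          stacklevel=2)
    return sidecar
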