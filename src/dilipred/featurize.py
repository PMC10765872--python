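"""SMILES featurization: ECFP6 structural bits plus physicochemical descriptors.

Each molecule is represented by the concatenation of a 1024-bit
extended-connectivity fingerprint of radius 3 (binary presence semantics)
and eight physicochemical descriptors in the fixed order MW, ALOGP, HBD,
HBA, PSA, ROTB, AROM, ALERT, giving 1032 features. Fingerprinting keeps a
per-molecule map from every set bit back to the atom environments hashed
to it, so predictions can later be attributed to substructures; hash
collisions (several environments on one bit) are preserved, not hidden.

Descriptors are standardized to zero mean and unit variance with
statistics estimated on the training partition only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

DESCRIPTOR_NAMES = ("MW", "ALOGP", "HBD", "HBA", "PSA", "ROTB", "AROM", "ALERT")
N_DESCRIPTORS = len(DESCRIPTOR_NAMES)
DEFAULT_RADIUS = 3
DEFAULT_N_BITS = 1024

# Default structural-alert queries for the ALERT descriptor: a small set of
# hepatotoxicity-linked motifs (hydrazine/hydrazide, aniline-forming amines,
# nitroaromatics, thiophene, quinone, aliphatic halide, Michael acceptor,
# aromatic N-oxide). Fully configurable; ALERT counts matched queries.
DEFAULT_ALERT_SMARTS: tuple[tuple[str, str], ...] = (
    ("hydrazine", "[NX3][NX3]"),
    ("acylhydrazide", "[CX3](=O)[NX3][NX3]"),
    ("aniline", "[NX3;H2,H1][c]"),
    ("nitroaromatic", "[c][N+](=O)[O-]"),
    ("thiophene", "c1ccsc1"),
    ("quinone", "O=C1C=CC(=O)C=C1"),
    ("alkyl_halide", "[CX4][Cl,Br,I]"),
    ("michael_acceptor", "[CX3]=[CX3][CX3]=[OX1]"),
    ("aromatic_n_oxide", "[c][n+][O-]"),
)


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


@dataclass(frozen=True)
class BitEnvironment:
    """One atom environment hashed to a fingerprint bit."""

    center: int
    radius: int
    fragment: str  # canonical SMILES of the environment subgraph
    atoms: tuple[int, ...]  # atom indices of the environment in the molecule


@dataclass
class BitEnvironmentMap:
    """Map from set bit index to all environments hashed to that bit."""

    entries: dict[int, list[BitEnvironment]] = field(default_factory=dict)

    def fragments(self, bit: int) -> list[str]:
        return [e.fragment for e in self.entries.get(bit, [])]

    def to_jsonable(self) -> dict:
        return {
            str(bit): [
                {
                    "center": e.center,
                    "radius": e.radius,
                    "fragment": e.fragment,
                    "atoms": list(e.atoms),
                }
                for e in envs
            ]
            for bit, envs in sorted(self.entries.items())
        }


def _environment_fragment(mol: Chem.Mol, center: int, radius: int) -> tuple[str, tuple[int, ...]]:
    """Canonical SMILES and atom set of one circular environment."""
    if radius == 0:
        frag = Chem.MolFragmentToSmiles(mol, atomsToUse=[center], canonical=True)
        return frag, (center,)
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    atoms = {center}
    for b in bond_ids:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    frag = Chem.MolFragmentToSmiles(
        mol, atomsToUse=sorted(atoms), bondsToUse=list(bond_ids), canonical=True
    )
    return frag, tuple(sorted(atoms))


def compute_structural(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> tuple[np.ndarray, BitEnvironmentMap]:
    """Binary circular fingerprint plus its bit-to-substructure provenance.

    Returns a 0/1 vector of length ``n_bits`` (1 = substructure present)
    and the map from each set bit to every (center, radius, fragment)
    environment hashed there. Chirality is ignored for reproducibility.
    """
    mol = mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    bv = gen.GetFingerprint(mol, additionalOutput=ao)
    bits = np.zeros(n_bits, dtype=np.int8)
    bits[list(bv.GetOnBits())] = 1
    bit_map = BitEnvironmentMap()
    for bit, envs in ao.GetBitInfoMap().items():
        entries = []
        for center, r in envs:
            frag, atoms = _environment_fragment(mol, center, r)
            entries.append(BitEnvironment(center=center, radius=r, fragment=frag, atoms=atoms))
        bit_map.entries[int(bit)] = entries
    return bits, bit_map


def compile_alerts(patterns=DEFAULT_ALERT_SMARTS) -> list[tuple[str, Chem.Mol]]:
    """Compile (name, SMARTS) pairs into substructure queries."""
    compiled = []
    for name, smarts in patterns:
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise ValueError(f"invalid alert SMARTS {smarts!r} ({name})")
        compiled.append((name, q))
    return compiled


def compute_descriptors(smiles: str, alert_patterns=None) -> np.ndarray:
    """Eight physicochemical descriptors in the fixed block order.

    MW molecular weight (g/mol); ALOGP Crippen log P; HBD / HBA hydrogen
    bond donor / acceptor counts; PSA topological polar surface area
    (A^2); ROTB rotatable bonds; AROM aromatic rings; ALERT number of
    matched structural-alert queries.
    """
    mol = mol_from_smiles(smiles)
    if alert_patterns is None:
        alert_patterns = compile_alerts()
    alert = sum(1 for _, q in alert_patterns if mol.HasSubstructMatch(q))
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcNumHBD(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            rdMolDescriptors.CalcTPSA(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            rdMolDescriptors.CalcNumAromaticRings(mol),
            alert,
        ],
        dtype=float,
    )


@dataclass
class ScalerState:
    """Per-descriptor mean and (population) standard deviation."""

    mean: np.ndarray
    sd: np.ndarray

    def to_jsonable(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_jsonable(cls, d: dict) -> "ScalerState":
        return cls(mean=np.asarray(d["mean"], float), sd=np.asarray(d["sd"], float))


def fit_scaler(descriptors: np.ndarray) -> ScalerState:
    """Estimate standardization statistics on the fitting (training) set.

    Zero-variance columns are flagged with a warning and will map to all
    zeros under :func:`apply_scaler`.
    """
    X = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("scaler requires >= 2 rows to estimate variance")
    sk = StandardScaler().fit(X)
    sd = np.sqrt(sk.var_)
    for j in np.flatnonzero(sd == 0):
        logger.warning(
            "descriptor column %d (%s) has zero variance; scaled to zeros",
            j,
            DESCRIPTOR_NAMES[j] if j < N_DESCRIPTORS else str(j),
        )
    return ScalerState(mean=sk.mean_.copy(), sd=sd)


def apply_scaler(state: ScalerState, descriptors: np.ndarray) -> np.ndarray:
    """Standardize descriptors using stored fitting-set statistics."""
    X = np.asarray(descriptors, dtype=float)
    safe_sd = np.where(state.sd == 0, 1.0, state.sd)
    return (X - state.mean) / safe_sd


def assemble(structural: np.ndarray, scaled_descriptors: np.ndarray) -> np.ndarray:
    """Concatenate structural bits (first) and scaled descriptors (last 8)."""
    s = np.asarray(structural, dtype=float).ravel()
    d = np.asarray(scaled_descriptors, dtype=float).ravel()
    if d.shape[0] != N_DESCRIPTORS:
        raise ValueError(f"descriptor block must have {N_DESCRIPTORS} values")
    return np.concatenate([s, d])


def feature_names(n_bits: int = DEFAULT_N_BITS) -> list[str]:
    return [f"bit_{i}" for i in range(n_bits)] + list(DESCRIPTOR_NAMES)


def featurize_frame(
    df: pd.DataFrame,
    smiles_column: str = "smiles",
    id_column: str = "id",
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    alert_patterns=None,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, BitEnvironmentMap], np.ndarray]:
    """Featurize a table of compounds, skipping unparseable SMILES.

    Returns the surviving rows, the raw (unscaled) feature matrix with
    structural bits first, per-compound bit-environment maps keyed by id,
    and the raw descriptor block (needed to fit/apply a scaler later).
    Invalid SMILES are logged and dropped rather than aborting the batch.
    """
    if smiles_column not in df.columns:
        raise KeyError(f"missing SMILES column {smiles_column!r}")
    if alert_patterns is None:
        alert_patterns = compile_alerts()
    kept_rows, bit_rows, desc_rows = [], [], []
    bitmaps: dict[str, BitEnvironmentMap] = {}
    for _, row in df.iterrows():
        smiles = row[smiles_column]
        try:
            bits, bmap = compute_structural(smiles, radius=radius, n_bits=n_bits)
            desc = compute_descriptors(smiles, alert_patterns)
        except SmilesError as e:
            logger.warning("skipping record %s: %s", row.get(id_column, "?"), e)
            continue
        kept_rows.append(row)
        bit_rows.append(bits)
        desc_rows.append(desc)
        bitmaps[str(row.get(id_column, len(kept_rows) - 1))] = bmap
    if not kept_rows:
        return df.iloc[0:0], np.zeros((0, n_bits + N_DESCRIPTORS)), {}, np.zeros((0, N_DESCRIPTORS))
    kept = pd.DataFrame(kept_rows).reset_index(drop=True)
    bits_mat = np.vstack(bit_rows).astype(float)
    desc_mat = np.vstack(desc_rows)
    X_raw = np.hstack([bits_mat, desc_mat])
    return kept, X_raw, bitmaps, desc_mat


def write_feature_csv(path, ids, X: np.ndarray, n_bits: int = DEFAULT_N_BITS) -> None:
    cols = feature_names(n_bits)
    out = pd.DataFrame(X, columns=cols)
    out.insert(0, "id", list(ids))
    out.to_csv(path, index=False)


def write_bitmap_json(path, bitmaps: dict[str, BitEnvironmentMap]) -> None:
    with open(path, "w") as fh:
        json.dump(
            {cid: bm.to_jsonable() for cid, bm in sorted(bitmaps.items())},
            fh,
            indent=None,
            sort_keys=True,
        )
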