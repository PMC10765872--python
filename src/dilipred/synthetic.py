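"""Synthetic SMILES libraries with planted structural-alert signal.

Builds random drug-like-ish molecules from a fixed scaffold list, plants
known alert motifs (hydrazide- and aniline-type fragments) by bonded
attachment, and draws binary toxicity labels from a logistic model

    logit P(y=1) = base + beta_motif * (#planted motifs) + beta_desc * (logP - 2)

followed by independent label flips at a configurable noise rate. The
point is statistical structure, not medicinal-chemistry realism: labels
are driven by recoverable substructures plus a lipophilicity term, which
is exactly the signal the interpretation layers are supposed to surface.

Ground truth (which motifs were planted, their atom indices in the
emitted canonical SMILES, and the fingerprint bits attributable to each
planted motif) is emitted alongside, so recovery tests need no
re-matching logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen

from .datasets import SourceRecord
from .featurize import DEFAULT_N_BITS, DEFAULT_RADIUS, compute_structural, mol_from_smiles

# ~20 simple scaffolds; attachment happens at any carbon with a free H.
SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",          # benzene
    "C1CCCCC1",          # cyclohexane
    "c1ccncc1",          # pyridine
    "c1ccc2ccccc2c1",    # naphthalene
    "C1CCNCC1",          # piperidine
    "C1CCOC1",           # tetrahydrofuran
    "c1ccoc1",           # furan
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccc2ncccc2c1",    # quinoline
    "C1CCCC1",           # cyclopentane
    "c1cncnc1",          # pyrimidine
    "C1COCCN1",          # morpholine
    "C1CCNC1",           # pyrrolidine
    "c1ccc2occc2c1",     # benzofuran
    "c1ccc(-c2ccccc2)cc1",  # biphenyl
    "C1CCC2CCCCC2C1",    # decalin
    "c1ccsc1",           # thiophene-free? (thiophene is an alert; keep anyway, label ignores it)
    "C1CC2CCC1CC2",      # bicyclooctane
    "c1cc2ccccc2[nH]1",  # indole isomer
    "C1CCCCCC1",         # cycloheptane
)

DECORATIONS: tuple[str, ...] = ("C", "CC", "O", "Cl", "F", "OC", "C(C)C")

# (name, fragment SMILES, attachment atom index within the fragment).
# Attachment atoms are chosen so the fragment still matches as a
# substructure query after substitution.
DEFAULT_MOTIFS: tuple[tuple[str, str, int], ...] = (
    ("acylhydrazide", "CC(=O)NN", 0),  # attach at the methyl carbon
    ("aniline", "Nc1ccccc1", 4),       # attach para to the amine
)


@dataclass
class GeneratorConfig:
    n: int = 1000
    motifs: tuple[tuple[str, str, int], ...] = DEFAULT_MOTIFS
    motif_prob: float = 0.25
    beta_motif: float = 6.0
    beta_desc: float = 0.5
    base_rate: float = -2.0
    label_noise: float = 0.02
    n_decorations_max: int = 2
    seed: int = 0
    radius: int = DEFAULT_RADIUS
    n_bits: int = DEFAULT_N_BITS

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if not (0 <= self.motif_prob <= 1):
            raise ValueError("motif_prob must be in [0, 1]")
        for name, smi, attach in self.motifs:
            frag = Chem.MolFromSmiles(smi)
            if frag is None:
                raise ValueError(f"invalid motif SMILES {smi!r} ({name})")
            if not (0 <= attach < frag.GetNumAtoms()):
                raise ValueError(f"motif {name}: attachment index {attach} out of range")


@dataclass
class GroundTruth:
    compound_id: str
    smiles: str
    motifs: list[dict] = field(default_factory=list)  # name, atoms, bits
    logit: float = 0.0
    probability: float = 0.0
    label: int = 0
    flipped: bool = False

    def to_jsonable(self) -> dict:
        return {
            "id": self.compound_id,
            "smiles": self.smiles,
            "motifs": self.motifs,
            "logit": self.logit,
            "probability": self.probability,
            "label": self.label,
            "flipped": self.flipped,
        }


def _free_carbons(mol: Chem.Mol, limit: int | None = None) -> list[int]:
    """Carbon atoms with at least one hydrogen available for substitution."""
    idxs = []
    for atom in mol.GetAtoms():
        if limit is not None and atom.GetIdx() >= limit:
            continue
        if atom.GetAtomicNum() == 6 and atom.GetTotalNumHs() > 0:
            idxs.append(atom.GetIdx())
    return idxs


def _attach(base: Chem.Mol, frag: Chem.Mol, base_idx: int, frag_idx: int) -> tuple[Chem.Mol, int]:
    """Single-bond the fragment onto the base; returns (mol, fragment offset)."""
    offset = base.GetNumAtoms()
    rw = Chem.RWMol(Chem.CombineMols(base, frag))
    rw.AddBond(base_idx, offset + frag_idx, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol, offset


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def generate(config: GeneratorConfig) -> tuple[list[SourceRecord], list[GroundTruth]]:
    """Generate a labeled synthetic library with ground-truth sidecar.

    Fully reproducible for a fixed seed. Every emitted SMILES parses, and
    every planted motif is recoverable by substructure match.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scaffold_mols = [mol_from_smiles(s) for s in SCAFFOLDS]
    motif_mols = [(name, mol_from_smiles(smi), smi, attach) for name, smi, attach in config.motifs]

    records: list[SourceRecord] = []
    truths: list[GroundTruth] = []
    i = 0
    while len(records) < config.n:
        i += 1
        mol = Chem.Mol(scaffold_mols[rng.integers(len(scaffold_mols))])
        scaffold_size = mol.GetNumAtoms()
        planted: list[tuple[str, list[int]]] = []  # (name, atom indices)
        try:
            for name, frag, _smi, attach in motif_mols:
                if rng.random() >= config.motif_prob:
                    continue
                sites = _free_carbons(mol, limit=scaffold_size)
                if not sites:
                    continue
                site = int(sites[rng.integers(len(sites))])
                mol, offset = _attach(mol, frag, site, attach)
                planted.append((name, list(range(offset, offset + frag.GetNumAtoms()))))
            n_dec = int(rng.integers(0, config.n_decorations_max + 1))
            for _ in range(n_dec):
                sites = _free_carbons(mol, limit=scaffold_size)
                if not sites:
                    break
                dec = mol_from_smiles(DECORATIONS[rng.integers(len(DECORATIONS))])
                site = int(sites[rng.integers(len(sites))])
                mol, _ = _attach(mol, dec, site, 0)
        except Chem.rdchem.MolSanitizeException:  # pragma: no cover - rare bad valence
            continue

        smiles = Chem.MolToSmiles(mol)
        # remap atom indices into the canonical output order, which is the
        # parse order of the emitted SMILES
        order = list(map(int, mol.GetProp("_smilesAtomOutputOrder").strip("[]").split(","))) if mol.HasProp("_smilesAtomOutputOrder") else list(range(mol.GetNumAtoms()))
        old_to_new = {old: new for new, old in enumerate(order)}
        planted = [(name, sorted(old_to_new[a] for a in atoms)) for name, atoms in planted]

        logp = Crippen.MolLogP(mol_from_smiles(smiles))
        logit = config.base_rate + config.beta_motif * len(planted) + config.beta_desc * (logp - 2.0)
        p = _sigmoid(logit)
        label = int(rng.random() < p)
        flipped = bool(rng.random() < config.label_noise)
        if flipped:
            label = 1 - label

        cid = f"SYN{len(records):05d}"
        records.append(
            SourceRecord(
                compound_id=cid,
                smiles=smiles,
                source="synthetic",
                raw_class="DILI positive" if label == 1 else "DILI negative",
            )
        )
        gt = GroundTruth(cid, smiles, logit=logit, probability=p, label=label, flipped=flipped)
        for name, atoms in planted:
            gt.motifs.append(
                {
                    "name": name,
                    "atoms": atoms,
                    "bits": sorted(
                        attributable_bits(smiles, atoms, radius=config.radius, n_bits=config.n_bits)
                    ),
                }
            )
        truths.append(gt)
    return records, truths


def attributable_bits(
    smiles: str,
    atom_indices: list[int],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> set[int]:
    """Fingerprint bits whose environments lie entirely within the atom set.

    These are the bits a planted fragment contributes to the molecule's
    fingerprint, usable as ground truth for importance-recovery checks.
    """
    _, bitmap = compute_structural(smiles, radius=radius, n_bits=n_bits)
    atoms = set(atom_indices)
    out = set()
    for bit, envs in bitmap.entries.items():
        if any(set(e.atoms) <= atoms for e in envs):
            out.add(bit)
    return out


def consensus_motif_bits(truths: list[GroundTruth], min_fraction: float = 0.5) -> dict[str, set[int]]:
    """Bits attributable to each motif in at least ``min_fraction`` of its carriers.

    Environments that cross the attachment point vary from molecule to
    molecule; the consensus keeps the context-independent interior bits.
    """
    counts: dict[str, dict[int, int]] = {}
    carriers: dict[str, int] = {}
    for gt in truths:
        for m in gt.motifs:
            carriers[m["name"]] = carriers.get(m["name"], 0) + 1
            bits = counts.setdefault(m["name"], {})
            for b in m["bits"]:
                bits[b] = bits.get(b, 0) + 1
    return {
        name: {b for b, c in bits.items() if c >= min_fraction * carriers[name]}
        for name, bits in counts.items()
    }


def write_ground_truth(path, truths: list[GroundTruth]) -> None:
    with open(path, "w") as fh:
        json.dump([gt.to_jsonable() for gt in truths], fh, sort_keys=True)


def records_to_frame(records: list[SourceRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"id": r.compound_id, "smiles": r.smiles, "source": r.source, "raw_class": r.raw_class}
            for r in records
        ]
    )
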