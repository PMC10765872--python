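"""Multi-source DILI label harmonization.

Merges compound tables from heterogeneous hepatotoxicity corpora (NCTR
drug labeling, Greene et al., Xu et al., Liew et al., DILIrank, plus
synthetic libraries) into a single binary-labeled dataset:

* per-source class maps to {positive, negative, excluded} — only
  compounds clearly associated (or clearly not associated) with liver
  injury are retained;
* deduplication on canonical SMILES with a source-priority rule for
  label conflicts (DILIrank > NCTR > Greene > Xu > Liew, the two curated
  regulatory lists winning over literature sets);
* hold-out assignment: DILIrank records form the test partition, all
  other sources the training partition.

Every dropped record carries a machine-readable reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

from rdkit import Chem

from .featurize import SmilesError, mol_from_smiles

logger = logging.getLogger(__name__)

EXCLUDED = "EXCLUDED"

# (source -> raw class -> 1 / 0 / EXCLUDED). Classes of intermediate or
# ambiguous concern are excluded outright rather than guessed.
CLASS_MAPS: dict[str, dict[str, object]] = {
    "NCTR": {
        "most-DILI-concern": 1,
        "no-DILI-concern": 0,
        "less-DILI-concern": EXCLUDED,
    },
    "Greene": {"HH": 1, "NE": 0, "WE": EXCLUDED, "AH": EXCLUDED},
    "Xu": {"DILI positive": 1, "DILI negative": 0},
    "Liew": {"DILI positive": 1, "DILI negative": 0},
    "DILIrank": {
        "Most-DILI-concern": 1,
        "No-DILI-concern": 0,
        "Less-DILI-concern": EXCLUDED,
        "Ambiguous-DILI-concern": EXCLUDED,
    },
    "synthetic": {"DILI positive": 1, "DILI negative": 0},
}

# Conflict-resolution priority, highest first. The relative order of the
# literature sets (Greene > Xu > Liew) is a package choice, configurable.
DEFAULT_PRIORITY: tuple[str, ...] = ("DILIrank", "NCTR", "Greene", "Xu", "Liew", "synthetic")

TEST_SOURCES: frozenset[str] = frozenset({"DILIrank"})


@dataclass(frozen=True)
class SourceRecord:
    compound_id: str
    smiles: str
    source: str
    raw_class: str


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    canonical_smiles: str
    label: int
    source: str
    partition: str = ""


def harmonize(record: SourceRecord) -> int | str:
    """Map a source-specific class string to 1, 0, or ``EXCLUDED``."""
    try:
        table = CLASS_MAPS[record.source]
    except KeyError:
        raise ValueError(f"unknown source {record.source!r}") from None
    try:
        return table[record.raw_class]
    except KeyError:
        raise ValueError(
            f"unknown class {record.raw_class!r} for source {record.source!r}"
        ) from None


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def deduplicate_and_resolve(
    records: list[tuple[SourceRecord, int]],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    drop_log: list[dict] | None = None,
) -> list[CompoundRecord]:
    """Collapse duplicates on canonical SMILES, resolving label conflicts.

    ``records`` are (record, binary label) pairs with excluded classes
    already removed. On conflict the label of the highest-priority source
    wins; an internal conflict within the winning source, or one compound
    id mapping to several structures, is dropped with a logged reason.
    The result is sorted by canonical SMILES, so it is independent of
    input order and the operation is idempotent.
    """
    if drop_log is None:
        drop_log = []
    rank = {src: i for i, src in enumerate(priority)}

    canon: list[tuple[str, SourceRecord, int]] = []
    for rec, label in records:
        try:
            cs = canonical_smiles(rec.smiles)
        except SmilesError:
            logger.warning("dropping %s: unclear structural format", rec.compound_id)
            drop_log.append({"id": rec.compound_id, "reason": "unparseable_smiles"})
            continue
        canon.append((cs, rec, label))

    # one compound id must not name two different structures
    id_to_smiles: dict[str, set[str]] = {}
    for cs, rec, _ in canon:
        id_to_smiles.setdefault(rec.compound_id, set()).add(cs)
    bad_ids = {cid for cid, ss in id_to_smiles.items() if len(ss) > 1}
    for cid in sorted(bad_ids):
        drop_log.append({"id": cid, "reason": "conflicting_structures_for_id"})
        logger.warning("dropping id %s: maps to multiple structures", cid)
    canon = [t for t in canon if t[1].compound_id not in bad_ids]

    groups: dict[str, list[tuple[SourceRecord, int]]] = {}
    for cs, rec, label in canon:
        groups.setdefault(cs, []).append((rec, label))

    out: list[CompoundRecord] = []
    for cs in sorted(groups):
        members = groups[cs]
        best_rank = min(rank.get(r.source, len(priority)) for r, _ in members)
        winners = [(r, l) for r, l in members if rank.get(r.source, len(priority)) == best_rank]
        labels = {l for _, l in winners}
        if len(labels) > 1:
            for r, _ in winners:
                drop_log.append({"id": r.compound_id, "reason": "intra_source_label_conflict"})
            logger.warning("dropping %s: conflicting labels within top-priority source", cs)
            continue
        rec, label = min(winners, key=lambda t: t[0].compound_id)
        out.append(
            CompoundRecord(
                compound_id=rec.compound_id,
                canonical_smiles=cs,
                label=int(label),
                source=rec.source,
            )
        )
    return out


def split(records: list[CompoundRecord]) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Assign partitions: DILIrank records to test, all others to train."""
    train, test = [], []
    for r in records:
        part = "test" if r.source in TEST_SOURCES else "train"
        (test if part == "test" else train).append(
            CompoundRecord(r.compound_id, r.canonical_smiles, r.label, r.source, part)
        )
    if not train:
        logger.warning("training partition is empty")
    if not test:
        logger.warning("test partition is empty")
    return train, test


def prepare(
    records: list[SourceRecord],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> tuple[list[CompoundRecord], list[dict]]:
    """Full harmonization pipeline: map classes, drop excluded, dedup, split."""
    drop_log: list[dict] = []
    labeled: list[tuple[SourceRecord, int]] = []
    for rec in records:
        label = harmonize(rec)
        if label == EXCLUDED:
            drop_log.append({"id": rec.compound_id, "reason": f"excluded_class:{rec.raw_class}"})
            continue
        labeled.append((rec, int(label)))
    dedup = deduplicate_and_resolve(labeled, priority, drop_log)
    train, test = split(dedup)
    return train + test, drop_log


def records_from_frame(df) -> list[SourceRecord]:
    """Read SourceRecords from a DataFrame with id/smiles/source/raw_class."""
    required = {"id", "smiles", "source", "raw_class"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"missing columns: {sorted(missing)}")
    return [
        SourceRecord(str(r["id"]), str(r["smiles"]), str(r["source"]), str(r["raw_class"]))
        for _, r in df.iterrows()
    ]


def records_to_frame(records: list[CompoundRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id": r.compound_id,
                "canonical_smiles": r.canonical_smiles,
                "label": r.label,
                "source": r.source,
                "partition": r.partition,
            }
            for r in records
        ]
    )


def write_drop_log(path, drop_log: list[dict]) -> None:
    with open(path, "w") as fh:
        for entry in drop_log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
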