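"""Compound curation and dataset assembly.

Raw activity records come from two kinds of sources:

* *database* records (PubChem/BindingDB/ChEMBL-style exports) carrying either
  a quantitative binding value (IC50/Ki/Kd) or a qualitative activity call;
* *qHTS* records carrying separate agonist-assay and antagonist-assay
  outcomes ("OPRM agonist outcome" / "OPRM antagonist outcome" columns).

Curation canonicalizes SMILES, applies the source-specific labeling rule,
deduplicates on canonical SMILES (dropping label conflicts entirely), and
assembles a training/external split in which a configurable number of qHTS
non-binders is transferred into the training set after overlap removal.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

log = logging.getLogger(__name__)

# RDKit is chatty about odd-but-recoverable SMILES; parse failures are
# reported through SmilesParseError instead.
RDLogger.DisableLog("rdApp.error")


class Label(str, enum.Enum):
    BINDER = "binder"
    NONBINDER = "nonbinder"
    EXCLUDED = "excluded"


class SourceKind(str, enum.Enum):
    DATABASE = "database"
    QHTS = "qhts"


#: qualitative annotations mapped to the binary activity classes
_QUALITATIVE_BINDER = {"active", "positive"}
_QUALITATIVE_NONBINDER = {"inactive", "negative"}
_QUALITATIVE_EXCLUDED = {"not determined", "inconclusive"}


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed; carries the offending source id."""

    def __init__(self, smiles: str, source_id: str = "") -> None:
        self.smiles = smiles
        self.source_id = source_id
        super().__init__(f"unparsable SMILES {smiles!r} (source_id={source_id!r})")


@dataclass(frozen=True)
class RawRecord:
    """One activity record as read from a source table."""

    source_id: str
    smiles: str
    source_kind: SourceKind
    quantitative_activity: bool = False
    qualitative_label: str | None = None
    agonist_outcome: str | None = None
    antagonist_outcome: str | None = None


@dataclass(frozen=True)
class CuratedCompound:
    canonical_smiles: str
    label: Label
    source_kind: SourceKind


@dataclass
class DatasetBundle:
    """Training/external compound split with transfer bookkeeping."""

    training: list[CuratedCompound]
    external: list[CuratedCompound]
    transfer_count: int
    seed: int

    def counts(self) -> dict[str, int]:
        def tally(items: Sequence[CuratedCompound]) -> tuple[int, int]:
            b = sum(1 for c in items if c.label is Label.BINDER)
            return b, len(items) - b

        tb, tn = tally(self.training)
        eb, en = tally(self.external)
        return {
            "training_binders": tb,
            "training_nonbinders": tn,
            "external_binders": eb,
            "external_nonbinders": en,
        }

    def manifest(self) -> str:
        return json.dumps(
            {**self.counts(), "transfer_count": self.transfer_count, "seed": self.seed},
            sort_keys=True,
        )


def canonicalize_smiles(smiles: str, source_id: str = "") -> str:
    """Return the canonical SMILES for *smiles*.

    Deterministic and idempotent: structurally identical inputs map to the
    same output. Raises :class:`SmilesParseError` for unparsable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, source_id)
    return Chem.MolToSmiles(mol)


def label_database_record(rec: RawRecord) -> Label:
    """Labeling rule for database-style records.

    A quantitative binding value (IC50/Ki/Kd present) marks a binder
    regardless of any qualitative annotation. Otherwise the qualitative
    field decides: active/positive -> binder, inactive/negative ->
    non-binder, not determined/inconclusive/absent/unrecognized -> excluded.
    """
    if rec.source_kind is not SourceKind.DATABASE:
        raise ValueError("label_database_record requires a database record")
    if rec.quantitative_activity:
        return Label.BINDER
    q = rec.qualitative_label.strip().lower() if rec.qualitative_label else None
    if q in _QUALITATIVE_BINDER:
        return Label.BINDER
    if q in _QUALITATIVE_NONBINDER:
        return Label.NONBINDER
    if q is not None and q not in _QUALITATIVE_EXCLUDED:
        log.warning("unrecognized qualitative label %r (id=%s): excluded", q, rec.source_id)
    return Label.EXCLUDED


def label_qhts_record(rec: RawRecord) -> Label:
    """Labeling rule for qHTS records.

    Inactive in both the agonist and the antagonist assay -> non-binder;
    active in at least one -> binder; a missing outcome excludes the record.
    """
    if rec.source_kind is not SourceKind.QHTS:
        raise ValueError("label_qhts_record requires a qHTS record")
    ago, anta = rec.agonist_outcome, rec.antagonist_outcome
    if ago is None or anta is None:
        log.warning("qHTS record %s missing an assay outcome: excluded", rec.source_id)
        return Label.EXCLUDED
    ago, anta = ago.strip().lower(), anta.strip().lower()
    for val in (ago, anta):
        if val not in ("active", "inactive"):
            log.warning("qHTS record %s has outcome %r: excluded", rec.source_id, val)
            return Label.EXCLUDED
    if ago == "inactive" and anta == "inactive":
        return Label.NONBINDER
    return Label.BINDER


def curate_records(records: Iterable[RawRecord]) -> tuple[list[CuratedCompound], list[RawRecord]]:
    """Canonicalize, label and deduplicate raw records of one source kind.

    Returns the curated compounds and the list of rejected records
    (unparsable SMILES or excluded labels). Parse failures are record-level:
    logged and skipped, never fatal.
    """
    labeled: list[tuple[str, Label, SourceKind]] = []
    rejected: list[RawRecord] = []
    for rec in records:
        try:
            smi = canonicalize_smiles(rec.smiles, rec.source_id)
        except SmilesParseError as exc:
            log.warning("skipping record: %s", exc)
            rejected.append(rec)
            continue
        lab = (
            label_database_record(rec)
            if rec.source_kind is SourceKind.DATABASE
            else label_qhts_record(rec)
        )
        if lab is Label.EXCLUDED:
            rejected.append(rec)
            continue
        labeled.append((smi, lab, rec.source_kind))
    return deduplicate(labeled), rejected


def deduplicate(
    compounds: Sequence[tuple[str, Label] | tuple[str, Label, SourceKind]],
) -> list[CuratedCompound]:
    """Collapse duplicate canonical SMILES; drop label conflicts entirely.

    Groups sharing a canonical SMILES and a single label keep the first
    occurrence; groups with conflicting labels contribute no survivors.
    Output preserves the input order of survivors.
    """
    labels_seen: dict[str, set[Label]] = {}
    for item in compounds:
        smi, lab = item[0], item[1]
        labels_seen.setdefault(smi, set()).add(lab)

    out: list[CuratedCompound] = []
    emitted: set[str] = set()
    for item in compounds:
        smi, lab = item[0], item[1]
        kind = item[2] if len(item) > 2 else SourceKind.DATABASE
        if len(labels_seen[smi]) > 1:
            continue  # conflicting classes: every member dropped
        if smi in emitted:
            continue
        emitted.add(smi)
        out.append(CuratedCompound(smi, lab, kind))
    return out


def assemble_datasets(
    db: Sequence[CuratedCompound],
    qhts: Sequence[CuratedCompound],
    transfer_count: int,
    seed: int,
) -> DatasetBundle:
    """Build the training/external split.

    qHTS compounds whose canonical SMILES already occurs in the database set
    are removed first (overlap removal); then ``transfer_count`` qHTS
    non-binders are sampled without replacement (seeded) and appended to the
    training set. Training = database + transferred non-binders; external =
    the remaining qHTS compounds.
    """
    db_smiles = {c.canonical_smiles for c in db}
    qhts_kept = [c for c in qhts if c.canonical_smiles not in db_smiles]
    nonbinder_idx = [i for i, c in enumerate(qhts_kept) if c.label is Label.NONBINDER]
    if transfer_count > len(nonbinder_idx):
        raise ValueError(
            f"transfer_count={transfer_count} exceeds the {len(nonbinder_idx)} "
            "qHTS non-binders available after overlap removal"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(nonbinder_idx, size=transfer_count, replace=False).tolist()) if transfer_count else set()
    transferred = [c for i, c in enumerate(qhts_kept) if i in chosen]
    external = [c for i, c in enumerate(qhts_kept) if i not in chosen]
    return DatasetBundle(
        training=list(db) + transferred,
        external=external,
        transfer_count=transfer_count,
        seed=seed,
    )
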