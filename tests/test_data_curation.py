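"""Curation rules: canonicalization, labeling, deduplication, assembly."""

import numpy as np
import pytest

from morqsar.data_curation import (CuratedCompound, Label, RawRecord,
                                   SmilesParseError, SourceKind,
                                   assemble_datasets, canonicalize_smiles,
                                   curate_records, deduplicate,
                                   label_database_record, label_qhts_record)
from morqsar.synthetic_data import toy_smiles_fixture

DB = SourceKind.DATABASE
QHTS = SourceKind.QHTS


def _compounds(n, label, prefix):
    return [CuratedCompound(f"{prefix}{i}", label, DB) for i in range(n)]


class TestCanonicalization:
    def test_structural_identity(self):
        assert canonicalize_smiles("OCC") == canonicalize_smiles("CCO")

    @pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1", "C1=CC=CC=C1", "CC(=O)O"])
    def test_idempotence(self, smiles):
        once = canonicalize_smiles(smiles)
        assert canonicalize_smiles(once) == once

    def test_unparsable_raises_with_source_id(self):
        with pytest.raises(SmilesParseError) as err:
            canonicalize_smiles("not_a_smiles", source_id="rec42")
        assert err.value.source_id == "rec42"


class TestDatabaseLabeling:
    @pytest.mark.parametrize("rec, expected", [
        (RawRecord("a", "C", DB, quantitative_activity=True), Label.BINDER),
        (RawRecord("b", "C", DB, qualitative_label="active"), Label.BINDER),
        (RawRecord("c", "C", DB, qualitative_label="positive"), Label.BINDER),
        (RawRecord("d", "C", DB, qualitative_label="inactive"), Label.NONBINDER),
        (RawRecord("e", "C", DB, qualitative_label="negative"), Label.NONBINDER),
        (RawRecord("f", "C", DB, qualitative_label="inconclusive"), Label.EXCLUDED),
        (RawRecord("g", "C", DB, qualitative_label="not determined"), Label.EXCLUDED),
        (RawRecord("h", "C", DB), Label.EXCLUDED),
        (RawRecord("i", "C", DB, qualitative_label="weird"), Label.EXCLUDED),
    ])
    def test_rules(self, rec, expected):
        assert label_database_record(rec) is expected

    def test_quantitative_dominates_conflicting_qualitative(self):
        rec = RawRecord("j", "C", DB, quantitative_activity=True,
                        qualitative_label="inactive")
        assert label_database_record(rec) is Label.BINDER

    def test_rejects_qhts_record(self):
        with pytest.raises(ValueError):
            label_database_record(RawRecord("k", "C", QHTS))


class TestQhtsLabeling:
    def test_enumeration_of_outcome_pairs(self):
        """Of the four outcome pairs exactly one (inactive, inactive) is a
        non-binder; every pair with at least one active call is a binder."""
        results = {}
        for ago in ("active", "inactive"):
            for anta in ("active", "inactive"):
                rec = RawRecord("q", "C", QHTS, agonist_outcome=ago,
                                antagonist_outcome=anta)
                results[(ago, anta)] = label_qhts_record(rec)
        assert results[("inactive", "inactive")] is Label.NONBINDER
        nonbinders = [k for k, v in results.items() if v is Label.NONBINDER]
        assert nonbinders == [("inactive", "inactive")]
        assert all(v is Label.BINDER for k, v in results.items()
                   if k != ("inactive", "inactive"))

    @pytest.mark.parametrize("ago, anta", [(None, "inactive"), ("active", None),
                                           ("maybe", "inactive")])
    def test_missing_or_bad_outcome_excluded(self, ago, anta):
        rec = RawRecord("q", "C", QHTS, agonist_outcome=ago, antagonist_outcome=anta)
        assert label_qhts_record(rec) is Label.EXCLUDED


class TestDeduplicate:
    def test_same_label_collapses_to_first(self):
        out = deduplicate([("s1", Label.BINDER), ("s1", Label.BINDER),
                           ("s2", Label.NONBINDER)])
        assert [(c.canonical_smiles, c.label) for c in out] == [
            ("s1", Label.BINDER), ("s2", Label.NONBINDER)]

    def test_conflicting_labels_drop_all_members(self):
        assert deduplicate([("s1", Label.BINDER), ("s1", Label.NONBINDER)]) == []

    def test_empty(self):
        assert deduplicate([]) == []

    def test_survivor_order_is_input_order(self):
        out = deduplicate([("b", Label.BINDER), ("a", Label.BINDER),
                           ("b", Label.BINDER), ("c", Label.NONBINDER)])
        assert [c.canonical_smiles for c in out] == ["b", "a", "c"]


class TestAssembleDatasets:
    def test_printed_dataset_arithmetic(self):
        """Reference-scale counting: 9,958 B + 191 N database compounds and
        509 B + 2,018 N qHTS compounds with 192 overlapping non-binders,
        transferring 1,727, must yield 9,958/1,918 training and 509/99
        external compounds."""
        db = _compounds(9958, Label.BINDER, "b") + _compounds(191, Label.NONBINDER, "n")
        # 192 qHTS non-binders share SMILES with database non-binders/binders
        overlap = [CuratedCompound(f"b{i}", Label.NONBINDER, QHTS) for i in range(192)]
        qhts = ([CuratedCompound(f"qb{i}", Label.BINDER, QHTS) for i in range(509)]
                + [CuratedCompound(f"qn{i}", Label.NONBINDER, QHTS) for i in range(2018 - 192)]
                + overlap)
        bundle = assemble_datasets(db, qhts, transfer_count=1727, seed=0)
        c = bundle.counts()
        assert c == {"training_binders": 9958, "training_nonbinders": 1918,
                     "external_binders": 509, "external_nonbinders": 99}
        train_smiles = {x.canonical_smiles for x in bundle.training}
        ext_smiles = {x.canonical_smiles for x in bundle.external}
        assert not train_smiles & ext_smiles

    def test_no_transfer_no_overlap_is_identity(self):
        db = _compounds(3, Label.BINDER, "d")
        qhts = [CuratedCompound(f"q{i}", Label.BINDER, QHTS) for i in range(2)]
        bundle = assemble_datasets(db, qhts, transfer_count=0, seed=5)
        assert bundle.training == db
        assert bundle.external == qhts

    def test_toy_counts_and_sample_enumeration(self):
        db = _compounds(3, Label.BINDER, "db_b") + _compounds(1, Label.NONBINDER, "db_n")
        qhts = ([CuratedCompound(f"qb{i}", Label.BINDER, QHTS) for i in range(2)]
                + [CuratedCompound(f"qn{i}", Label.NONBINDER, QHTS) for i in range(5)]
                + [CuratedCompound("db_n0", Label.NONBINDER, QHTS)])  # 1 N overlaps
        bundle = assemble_datasets(db, qhts, transfer_count=4, seed=3)
        c = bundle.counts()
        assert c["external_binders"] == 2 and c["external_nonbinders"] == 1  # 6-1-4
        transferred = {x.canonical_smiles for x in bundle.training} - {
            x.canonical_smiles for x in db}
        external_n = {x.canonical_smiles for x in bundle.external
                      if x.label is Label.NONBINDER}
        assert transferred | external_n == {f"qn{i}" for i in range(5)}
        assert not transferred & external_n

    def test_conservation_and_determinism(self):
        db = _compounds(10, Label.BINDER, "d")
        qhts = [CuratedCompound(f"q{i}", Label.NONBINDER, QHTS) for i in range(20)]
        b1 = assemble_datasets(db, qhts, 7, seed=11)
        b2 = assemble_datasets(db, qhts, 7, seed=11)
        assert len(db) + len(qhts) == len(b1.training) + len(b1.external)
        assert b1.manifest() == b2.manifest()
        assert [c.canonical_smiles for c in b1.external] == [
            c.canonical_smiles for c in b2.external]

    def test_transfer_exceeding_pool_is_fatal(self):
        with pytest.raises(ValueError, match="transfer_count"):
            assemble_datasets(_compounds(2, Label.BINDER, "d"),
                              [CuratedCompound("q0", Label.NONBINDER, QHTS)],
                              transfer_count=2, seed=0)


class TestCurateRecords:
    def test_toy_fixture_branches(self):
        records = toy_smiles_fixture()
        db_curated, db_rejected = curate_records(
            [r for r in records if r.source_kind is DB])
        by_label = {c.canonical_smiles: c.label for c in db_curated}
        # ethanol duplicate collapses; benzene conflict pair fully dropped
        assert by_label == {"CCO": Label.BINDER, "CC(=O)O": Label.NONBINDER,
                            "CCC": Label.BINDER}
        assert {r.source_id for r in db_rejected} == {"db6", "db7", "db8"}

        qhts_curated, qhts_rejected = curate_records(
            [r for r in records if r.source_kind is QHTS])
        labels = {c.label for c in qhts_curated}
        assert sum(1 for c in qhts_curated if c.label is Label.NONBINDER) == 1
        assert sum(1 for c in qhts_curated if c.label is Label.BINDER) == 3
        assert {r.source_id for r in qhts_rejected} == {"q5"}
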