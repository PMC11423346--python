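import numpy as np
import pandas as pd
import pytest

from komet import curation
from komet.curation import (
    BioactivityRecord,
    Label,
    SplitSpec,
    balance_negatives,
    filter_structures,
    label_dti,
    make_splits,
)
from komet.io import InteractionSet, MoleculeRecord, ProteinRecord, Registry


def rec(mol="m1", prot="p1", mt="Kd", value=1e-8, smiles="CCO",
        org="Homo sapiens", src="A", mw=300.0):
    return {
        "source_db": src, "mol_id": mol, "smiles": smiles, "prot_id": prot,
        "organism": org, "measure_type": mt, "value_molar": value,
        "mol_weight": mw,
    }


def bio(mol="m1", prot="p1", mt="Kd", value=1e-8):
    return BioactivityRecord("A", mol, "CCO", prot, "Homo sapiens", mt, value)


class TestLabeling:
    def test_single_strong_binder_positive(self):
        assert label_dti([bio(value=5e-8)]).label is Label.POSITIVE

    def test_single_weak_binder_negative(self):
        assert label_dti([bio(mt="IC50", value=2e-4)]).label is Label.NEGATIVE

    def test_concordant_pair_mean_in_window_nonconclusive(self):
        # ratio 8 <= 10, mean 2.25e-7 M sits between 100 nM and 100 uM
        out = label_dti([bio(value=5e-8), bio(value=4e-7)])
        assert out.label is Label.NONCONCLUSIVE

    def test_measure_type_precedence_kd_over_ic50(self):
        out = label_dti([bio(mt="Kd", value=5e-8), bio(mt="IC50", value=2e-3)])
        assert out.label is Label.POSITIVE
        assert all(r.measure_type == "Kd" for r in out.provenance)

    def test_discordant_all_low_positive(self):
        # ratio 90 > one log unit, but every value is below 100 nM
        out = label_dti([bio(value=1e-9), bio(value=9e-8)])
        assert out.label is Label.POSITIVE

    def test_discordant_mixed_nonconclusive(self):
        out = label_dti([bio(value=1e-8), bio(value=1e-3)])
        assert out.label is Label.NONCONCLUSIVE

    def test_boundary_value_is_nonconclusive(self):
        # thresholds are strict: exactly 100 nM is not a positive
        assert label_dti([bio(value=1e-7)]).label is Label.NONCONCLUSIVE
        assert label_dti([bio(value=1e-4)]).label is Label.NONCONCLUSIVE

    def test_permutation_invariance(self):
        records = [bio(value=5e-8), bio(value=4e-7), bio(mt="IC50", value=1e-3)]
        a = label_dti(records)
        b = label_dti(records[::-1])
        assert a.label is b.label


class TestStructureFilter:
    def test_consistent_smiles_kept_inconsistent_dropped(self):
        df = pd.DataFrame([
            rec(mol="ok", src="A"), rec(mol="ok", src="B"),
            rec(mol="bad", src="A"), rec(mol="bad", src="B", smiles="OCC"),
        ])
        out = filter_structures(df)
        assert set(out["mol_id"]) == {"ok"}

    def test_mw_bounds_inclusive(self):
        df = pd.DataFrame([
            rec(mol="low", mw=99.9), rec(mol="edge", mw=100.0),
            rec(mol="high", mw=900.0), rec(mol="over", mw=900.1),
        ])
        out = filter_structures(df)
        assert set(out["mol_id"]) == {"edge", "high"}

    def test_molecule_without_human_target_dropped(self):
        df = pd.DataFrame([
            rec(mol="mouse_only", org="Mus musculus"),
            rec(mol="both", prot="p1", org="Mus musculus"),
            rec(mol="both", prot="p2", org="homo SAPIENS"),
        ])
        out = filter_structures(df)
        assert set(out["mol_id"]) == {"both"}

    def test_idempotent(self):
        df = pd.DataFrame([
            rec(mol="a"), rec(mol="b", mw=50.0), rec(mol="c", org="Rattus"),
        ])
        once = filter_structures(df)
        twice = filter_structures(once)
        pd.testing.assert_frame_equal(once, twice)


def positives_2x2():
    mols = Registry(
        [MoleculeRecord(f"d{i}", fingerprint=np.eye(4, dtype=np.uint8)[i]) for i in range(2)]
    )
    prots = Registry([ProteinRecord(f"p{j}", "ACDK") for j in range(2)])
    return InteractionSet(mols, prots, np.array([0, 1]), np.array([0, 1]), np.array([1, 1]))


class TestBalanceNegatives:
    def test_unique_feasible_completion(self):
        res = balance_negatives(positives_2x2(), seed=0)
        assert set(res.sampled_negatives) == {(0, 1), (1, 0)}
        assert res.max_deficit == 0

    def test_complete_bipartite_graph_reports_deficits(self):
        mols = Registry(
            [MoleculeRecord(f"d{i}", fingerprint=np.eye(4, dtype=np.uint8)[i]) for i in range(2)]
        )
        prots = Registry([ProteinRecord(f"p{j}", "ACDK") for j in range(2)])
        full = InteractionSet(
            mols, prots, np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]), np.ones(4, dtype=int)
        )
        res = balance_negatives(full, seed=0)
        assert res.sampled_negatives == []
        assert len(res.molecule_deficits) == 2 and len(res.protein_deficits) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_balance_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n_M, n_P = 100, 20
        mols = Registry(
            MoleculeRecord(f"d{i}", fingerprint=np.array([1], dtype=np.uint8))
            for i in range(n_M)
        )
        prots = Registry(ProteinRecord(f"p{j}", "ACDK") for j in range(n_P))
        flat = rng.choice(n_M * n_P, size=300, replace=False)
        pos = InteractionSet(
            mols, prots, flat // n_P, flat % n_P, np.ones(300, dtype=int)
        )
        res = balance_negatives(pos, seed=seed)
        ds = res.dataset
        for idx_arr, n_ent in ((ds.mol_idx, n_M), (ds.prot_idx, n_P)):
            pos_deg = np.bincount(idx_arr[ds.labels == 1], minlength=n_ent)
            neg_deg = np.bincount(idx_arr[ds.labels == -1], minlength=n_ent)
            assert np.abs(pos_deg - neg_deg).max() <= 1
        negs = set(zip(ds.mol_idx[ds.labels == -1].tolist(), ds.prot_idx[ds.labels == -1].tolist()))
        poss = set(zip(ds.mol_idx[ds.labels == 1].tolist(), ds.prot_idx[ds.labels == 1].tolist()))
        assert not negs & poss

    def test_forbidden_pairs_never_sampled(self):
        forbidden = {(0, 1)}
        res = balance_negatives(positives_2x2(), forbidden=forbidden, seed=0)
        assert (0, 1) not in set(res.sampled_negatives)

    def test_deterministic_under_seed(self):
        a = balance_negatives(positives_2x2(), seed=3)
        b = balance_negatives(positives_2x2(), seed=3)
        assert a.sampled_negatives == b.sampled_negatives


def random_dataset(rng, n_M=40, n_P=12, n_Z=200):
    mols = Registry(
        MoleculeRecord(f"d{i}", fingerprint=np.array([1], dtype=np.uint8))
        for i in range(n_M)
    )
    prots = Registry(ProteinRecord(f"p{j}", "ACDK") for j in range(n_P))
    flat = rng.choice(n_M * n_P, size=n_Z, replace=False)
    labels = rng.choice([-1, 1], size=n_Z)
    return InteractionSet(mols, prots, flat // n_P, flat % n_P, labels)


class TestSplits:
    def test_random_split_partitions_pairs_exactly(self, rng):
        ds = random_dataset(rng)
        folds = make_splits(ds, SplitSpec("random", 5, seed=1))
        all_test = [p for _, test in folds for p in test.pairs()]
        assert len(all_test) == ds.n_Z
        assert set(all_test) == ds.pairs()
        for train, test in folds:
            assert train.n_Z + test.n_Z == ds.n_Z
            assert not train.pairs() & test.pairs()

    def test_unseen_drugs_molecule_disjointness(self, rng):
        ds = random_dataset(rng)
        for train, test in make_splits(ds, SplitSpec("unseen_drugs", 4, seed=2)):
            assert not set(train.mol_idx) & set(test.mol_idx)

    def test_unseen_targets_protein_disjointness(self, rng):
        ds = random_dataset(rng)
        for train, test in make_splits(ds, SplitSpec("unseen_targets", 4, seed=2)):
            assert not set(train.prot_idx) & set(test.prot_idx)

    def test_orphan_double_disjointness_and_shrinkage(self, rng):
        ds = random_dataset(rng)
        folds = make_splits(ds, SplitSpec("orphan", 5, seed=3))
        kept = sum(train.n_Z + test.n_Z for train, test in folds) / len(folds)
        assert kept < ds.n_Z  # mismatched-fold pairs are dropped
        for train, test in folds:
            assert not set(train.mol_idx) & set(test.mol_idx)
            assert not set(train.prot_idx) & set(test.prot_idx)

    def test_deterministic_under_seed(self, rng):
        ds = random_dataset(rng)
        f1 = make_splits(ds, SplitSpec("orphan", 3, seed=7))
        f2 = make_splits(ds, SplitSpec("orphan", 3, seed=7))
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a.mol_idx, c.mol_idx)
            np.testing.assert_array_equal(b.mol_idx, d.mol_idx)

    def test_too_many_folds_rejected(self, rng):
        ds = random_dataset(rng, n_P=3, n_Z=30)
        with pytest.raises(ValueError):
            make_splits(ds, SplitSpec("unseen_targets", 5, seed=0))


class TestCurate:
    def test_end_to_end_counts(self):
        df = pd.DataFrame([
            rec(mol="a", prot="p1", value=1e-8),             # positive
            rec(mol="b", prot="p1", value=5e-4),             # negative
            rec(mol="c", prot="p1", value=1e-6),             # nonconclusive
            rec(mol="d", prot="p1", src="A"),                # smiles conflict ->
            rec(mol="d", prot="p1", src="B", smiles="XX"),   # dropped
        ])
        labeled, report = curation.curate(df)
        assert report.n_records_in == 5
        assert report.n_records_structure == 3
        assert report.n_pairs_measured == 3
        assert (report.n_positive, report.n_negative, report.n_nonconclusive) == (1, 1, 1)


class TestTestSetCompletion:
    def test_topped_up_to_half_prevalence(self, rng):
        ds = random_dataset(rng, n_M=30, n_P=10, n_Z=100)
        pos_only = ds.subset(ds.labels == 1)
        out = curation.complete_test_negatives(pos_only, train_pairs=set(), seed=0)
        n_pos = int((out.labels == 1).sum())
        n_neg = int((out.labels == -1).sum())
        assert n_neg == n_pos
        assert not set(zip(out.mol_idx[out.labels == -1].tolist(),
                           out.prot_idx[out.labels == -1].tolist())) & pos_only.pairs()

    def test_train_pairs_never_reused(self, rng):
        ds = random_dataset(rng, n_M=20, n_P=8, n_Z=60)
        pos_only = ds.subset(ds.labels == 1)
        train_pairs = {(i, j) for i in range(20) for j in range(4)}
        out = curation.complete_test_negatives(pos_only, train_pairs=train_pairs, seed=1)
        negs = set(zip(out.mol_idx[out.labels == -1].tolist(),
                       out.prot_idx[out.labels == -1].tolist()))
        assert not negs & train_pairs
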