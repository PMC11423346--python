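"""Bioactivity curation, binary labeling, balanced negatives, and splits.

The curation path reproduces the construction of a large-scale DTI training
set from a multi-source bioactivity table:

1. *structure filter* — keep molecules whose reported SMILES agrees across
   all contributing sources, whose molecular weight lies in [100, 900] g/mol
   (drug-likeness), and that hit at least one human protein;
2. *bioactivity filter* — keep (molecule, protein) pairs with at least one
   Kd, Ki or IC50 measurement;
3. *concordance* — when several sources report the selected measurement
   type, values must agree within one log unit (max/min <= 10), otherwise
   the pair is labeled only if all values fall on the same side;
4. *binary labeling* — mean value < 100 nM is a positive interaction,
   > 100 uM a negative one, the window in between is nonconclusive.

Negative completion then samples unlabeled pairs so each entity has as many
negative as positive interactions (a greedy deficit-driven procedure), and
four train/test split scenarios (random, unseen_drugs, unseen_targets,
orphan) control whether test molecules/proteins were seen in training.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from enum import Enum

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SchemaError
from .io import InteractionSet

POSITIVE_THRESHOLD_M = 1e-7  # 100 nM
NEGATIVE_THRESHOLD_M = 1e-4  # 100 uM
MW_MIN = 100.0
MW_MAX = 900.0
MEASURE_PRECEDENCE = ("Kd", "Ki", "IC50")

BIOACTIVITY_COLUMNS = [
    "source_db", "mol_id", "smiles", "prot_id", "organism",
    "measure_type", "value_molar",
]


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONCONCLUSIVE = "nonconclusive"


@dataclasses.dataclass
class BioactivityRecord:
    source_db: str
    mol_id: str
    smiles: str
    prot_id: str
    organism: str
    measure_type: str
    value_molar: float

    def __post_init__(self) -> None:
        if self.measure_type not in MEASURE_PRECEDENCE:
            raise ValueError(
                f"measure_type must be one of {MEASURE_PRECEDENCE}, "
                f"got {self.measure_type!r}"
            )
        if not self.value_molar > 0:
            raise ValueError("bioactivity value must be positive (molar units)")


@dataclasses.dataclass
class LabeledDTI:
    mol_id: str
    prot_id: str
    label: Label
    provenance: list


@dataclasses.dataclass
class SplitSpec:
    scenario: str = "random"
    n_folds: int = 5
    seed: int = 0

    SCENARIOS = ("random", "unseen_drugs", "unseen_targets", "orphan")

    def __post_init__(self) -> None:
        if self.scenario not in self.SCENARIOS:
            raise ValueError(f"scenario must be one of {self.SCENARIOS}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def read_bioactivities(path, fmt: str = "tsv") -> pd.DataFrame:
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for c in BIOACTIVITY_COLUMNS:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")
    df["value_molar"] = df["value_molar"].astype(float)
    if "mol_weight" in df.columns:
        df["mol_weight"] = pd.to_numeric(df["mol_weight"], errors="coerce")
    return df


# ---------------------------------------------------------------------------
# filters


def filter_structures(
    records: pd.DataFrame,
    mw_backend: str = "column",
) -> pd.DataFrame:
    """Structure-quality filter on a bioactivity table.

    Keeps a molecule's records only if (i) the SMILES string reported by
    every contributing source is identical, (ii) the molecular weight is
    within [100, 900] g/mol inclusive, and (iii) the molecule has at least
    one record against a human protein ("Homo sapiens", case-insensitive).
    Canonicalization is assumed upstream: disagreement is plain string
    inequality.  ``mw_backend`` is ``"column"`` (a mol_weight column) or
    ``"rdkit"`` (compute from SMILES).
    """
    if records.empty:
        return records.copy()
    df = records.copy()

    smiles_per_mol = df.groupby("mol_id")["smiles"].nunique()
    consistent = set(smiles_per_mol.index[smiles_per_mol == 1])

    if mw_backend == "column":
        if "mol_weight" not in df.columns:
            raise ConfigurationError(
                "mw_backend='column' requires a mol_weight column; "
                "use mw_backend='rdkit' to compute from SMILES"
            )
        mw = df.groupby("mol_id")["mol_weight"].first()
    elif mw_backend == "rdkit":
        from .io import molecular_weight

        mw = df.groupby("mol_id")["smiles"].first().map(molecular_weight)
    else:
        raise ConfigurationError(f"unknown mw_backend {mw_backend!r}")
    in_range = set(mw.index[(mw >= MW_MIN) & (mw <= MW_MAX)])

    human = df["organism"].str.strip().str.lower() == "homo sapiens"
    has_human = set(df.loc[human, "mol_id"])

    keep = consistent & in_range & has_human
    return df[df["mol_id"].isin(keep)].reset_index(drop=True)


def label_dti(records, mean: str = "arithmetic") -> LabeledDTI:
    """Binary-label one (molecule, protein) pair from its measurements.

    Uses only the highest-precedence measurement type present (Kd, else Ki,
    else IC50).  When the selected values agree within one log unit
    (max/min <= 10) the label follows their mean; otherwise the pair is
    positive only if *all* values are below 100 nM, negative only if all
    are above 100 uM, and nonconclusive in every other case.
    """
    recs = list(records)
    if not recs:
        raise ValueError("need at least one record")
    mol_id, prot_id = recs[0].mol_id, recs[0].prot_id
    if any(r.mol_id != mol_id or r.prot_id != prot_id for r in recs):
        raise ValueError("all records must concern the same (molecule, protein) pair")

    chosen: list[BioactivityRecord] = []
    for mt in MEASURE_PRECEDENCE:
        chosen = [r for r in recs if r.measure_type == mt]
        if chosen:
            break
    values = np.array(sorted(r.value_molar for r in chosen))

    if values.max() / values.min() <= 10.0:  # within one log unit
        if mean == "arithmetic":
            center = float(values.mean())
        elif mean == "geometric":
            center = float(math.exp(np.log(values).mean()))
        else:
            raise ValueError("mean must be 'arithmetic' or 'geometric'")
        if center < POSITIVE_THRESHOLD_M:
            lab = Label.POSITIVE
        elif center > NEGATIVE_THRESHOLD_M:
            lab = Label.NEGATIVE
        else:
            lab = Label.NONCONCLUSIVE
    else:
        if (values < POSITIVE_THRESHOLD_M).all():
            lab = Label.POSITIVE
        elif (values > NEGATIVE_THRESHOLD_M).all():
            lab = Label.NEGATIVE
        else:
            lab = Label.NONCONCLUSIVE
    return LabeledDTI(mol_id, prot_id, lab, chosen)


@dataclasses.dataclass
class CurationReport:
    """Survivor counts after each curation stage."""

    n_records_in: int
    n_records_structure: int
    n_pairs_measured: int
    n_pairs_concordant: int
    n_positive: int
    n_negative: int
    n_nonconclusive: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def curate(
    records: pd.DataFrame,
    mw_backend: str = "column",
    mean: str = "arithmetic",
) -> tuple[list[LabeledDTI], CurationReport]:
    """Run the full curation path on a bioactivity table.

    Returns the labeled pairs (positives, negatives, nonconclusives) plus a
    per-stage survivor report.
    """
    n_in = len(records)
    df = filter_structures(records, mw_backend=mw_backend)
    n_struct = len(df)

    pairs: dict[tuple[str, str], list[BioactivityRecord]] = defaultdict(list)
    for row in df.itertuples(index=False):
        pairs[(row.mol_id, row.prot_id)].append(
            BioactivityRecord(
                source_db=row.source_db,
                mol_id=row.mol_id,
                smiles=row.smiles,
                prot_id=row.prot_id,
                organism=row.organism,
                measure_type=row.measure_type,
                value_molar=row.value_molar,
            )
        )
    n_measured = len(pairs)

    labeled = [label_dti(v, mean=mean) for v in pairs.values()]
    # "concordant" = pairs whose selected values sit within one log unit
    n_concord = 0
    for dti in labeled:
        vals = [r.value_molar for r in dti.provenance]
        if max(vals) / min(vals) <= 10.0:
            n_concord += 1

    counts = {lab: 0 for lab in Label}
    for dti in labeled:
        counts[dti.label] += 1
    report = CurationReport(
        n_records_in=n_in,
        n_records_structure=n_struct,
        n_pairs_measured=n_measured,
        n_pairs_concordant=n_concord,
        n_positive=counts[Label.POSITIVE],
        n_negative=counts[Label.NEGATIVE],
        n_nonconclusive=counts[Label.NONCONCLUSIVE],
    )
    return labeled, report


# ---------------------------------------------------------------------------
# balanced negative completion


@dataclasses.dataclass
class BalanceResult:
    dataset: InteractionSet  # positives + known negatives + sampled negatives
    sampled_negatives: list[tuple[int, int]]
    molecule_deficits: dict[str, int]
    protein_deficits: dict[str, int]

    @property
    def max_deficit(self) -> int:
        vals = list(self.molecule_deficits.values()) + list(self.protein_deficits.values())
        return max((abs(v) for v in vals), default=0)


def balance_negatives(
    positives: InteractionSet,
    known_negatives: list[tuple[int, int]] | None = None,
    forbidden: set[tuple[int, int]] | None = None,
    seed: int = 0,
) -> BalanceResult:
    """Greedy degree-balanced negative completion.

    Samples unlabeled (molecule, protein) pairs as presumed negatives so
    that each entity's negative degree matches its positive degree as
    closely as feasible, counteracting database bias toward heavily studied
    entities.  Repeatedly takes the entity with the largest remaining
    deficit and pairs it with a uniformly random partner that also has a
    deficit (falling back to a zero-deficit partner, which leaves that
    partner at a surplus of one); pairs that are positive, known-negative,
    nonconclusive, or already chosen are never used.  When exact balance is
    infeasible the result carries the residual per-entity deficits rather
    than silently dropping the constraint.
    """
    rng = np.random.default_rng(seed)
    known_negatives = [tuple(p) for p in (known_negatives or [])]
    forbidden = set(forbidden or set())
    pos_pairs = positives.pairs()
    blocked = pos_pairs | forbidden | set(known_negatives)

    n_M, n_P = positives.n_M, positives.n_P
    mol_def = np.zeros(n_M, dtype=np.int64)
    prot_def = np.zeros(n_P, dtype=np.int64)
    for i, j, y in zip(positives.mol_idx, positives.prot_idx, positives.labels):
        if y == 1:
            mol_def[i] += 1
            prot_def[j] += 1
    for i, j in known_negatives:
        mol_def[i] -= 1
        prot_def[j] -= 1

    sampled: list[tuple[int, int]] = []
    # entities that proved unmatchable are retired to guarantee termination
    stuck_m: set[int] = set()
    stuck_p: set[int] = set()
    while True:
        mm = np.where(mol_def > 0)[0]
        mm = mm[~np.isin(mm, list(stuck_m))] if stuck_m else mm
        pp = np.where(prot_def > 0)[0]
        pp = pp[~np.isin(pp, list(stuck_p))] if stuck_p else pp
        best_m = mm[np.argmax(mol_def[mm])] if len(mm) else None
        best_p = pp[np.argmax(prot_def[pp])] if len(pp) else None
        if best_m is None and best_p is None:
            break
        use_mol = best_p is None or (
            best_m is not None and mol_def[best_m] >= prot_def[best_p]
        )
        if use_mol:
            i = int(best_m)
            cands = [
                j for j in range(n_P)
                if prot_def[j] > 0 and (i, j) not in blocked
            ]
            if not cands:
                cands = [
                    j for j in range(n_P)
                    if prot_def[j] == 0 and (i, j) not in blocked
                ]
            if not cands:
                stuck_m.add(i)
                continue
            j = int(rng.choice(cands))
        else:
            j = int(best_p)
            cands = [
                i for i in range(n_M)
                if mol_def[i] > 0 and (i, j) not in blocked
            ]
            if not cands:
                cands = [
                    i for i in range(n_M)
                    if mol_def[i] == 0 and (i, j) not in blocked
                ]
            if not cands:
                stuck_p.add(j)
                continue
            i = int(rng.choice(cands))
        sampled.append((i, j))
        blocked.add((i, j))
        mol_def[i] -= 1
        prot_def[j] -= 1

    neg_pairs = known_negatives + sampled
    mol_idx = np.concatenate([positives.mol_idx, [p[0] for p in neg_pairs]]).astype(np.int64)
    prot_idx = np.concatenate([positives.prot_idx, [p[1] for p in neg_pairs]]).astype(np.int64)
    labels = np.concatenate(
        [positives.labels, -np.ones(len(neg_pairs), dtype=np.int64)]
    ).astype(np.int64)
    dataset = InteractionSet(positives.molecules, positives.proteins, mol_idx, prot_idx, labels)
    mol_ids = positives.molecules.ids
    prot_ids = positives.proteins.ids
    return BalanceResult(
        dataset=dataset,
        sampled_negatives=sampled,
        molecule_deficits={mol_ids[i]: int(mol_def[i]) for i in range(n_M) if mol_def[i] != 0},
        protein_deficits={prot_ids[j]: int(prot_def[j]) for j in range(n_P) if prot_def[j] != 0},
    )


def complete_test_negatives(
    test_set: InteractionSet,
    train_pairs: set[tuple[int, int]],
    forbidden: set[tuple[int, int]] | None = None,
    seed: int = 0,
) -> InteractionSet:
    """Top up a test fold with uniformly sampled unlabeled pairs as negatives
    until prevalence is 50% (true negatives are kept first)."""
    rng = np.random.default_rng(seed)
    forbidden = set(forbidden or set())
    n_pos = int((test_set.labels == 1).sum())
    n_neg = int((test_set.labels == -1).sum())
    need = n_pos - n_neg
    if need <= 0:
        return test_set
    used = test_set.pairs() | train_pairs | forbidden
    mols = np.unique(test_set.mol_idx)
    prots = np.unique(test_set.prot_idx)
    extra: list[tuple[int, int]] = []
    budget = 50 * need + 1000
    while len(extra) < need and budget > 0:
        i = int(rng.choice(mols))
        j = int(rng.choice(prots))
        budget -= 1
        if (i, j) in used:
            continue
        used.add((i, j))
        extra.append((i, j))
    mol_idx = np.concatenate([test_set.mol_idx, [p[0] for p in extra]]).astype(np.int64)
    prot_idx = np.concatenate([test_set.prot_idx, [p[1] for p in extra]]).astype(np.int64)
    labels = np.concatenate([test_set.labels, -np.ones(len(extra), dtype=np.int64)])
    return InteractionSet(test_set.molecules, test_set.proteins, mol_idx, prot_idx, labels)


# ---------------------------------------------------------------------------
# split scenarios


def _fold_assignment(n: int, n_folds: int, rng) -> np.ndarray:
    """Balanced random assignment of n items to folds."""
    folds = np.repeat(np.arange(n_folds), -(-n // n_folds))[:n]
    rng.shuffle(folds)
    return folds


def make_splits(
    dataset: InteractionSet, spec: SplitSpec
) -> list[tuple[InteractionSet, InteractionSet]]:
    """Train/test folds under one of the four scenarios.

    random         pairs are partitioned across folds;
    unseen_drugs   molecules are partitioned and each pair follows its
                   molecule's fold, so test molecules never occur in train;
    unseen_targets the symmetric scenario on proteins;
    orphan         molecules and proteins are partitioned independently and
                   a pair is kept only when both folds coincide, so both
                   test-entity sets are disjoint from training (this drops
                   pairs, shrinking the dataset).
    """
    if dataset.n_Z == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(spec.seed)
    k = spec.n_folds
    out = []
    if spec.scenario == "random":
        pf = _fold_assignment(dataset.n_Z, k, rng)
        for f in range(k):
            out.append((dataset.subset(pf != f), dataset.subset(pf == f)))
        return out
    if spec.scenario in ("unseen_drugs", "unseen_targets"):
        if spec.scenario == "unseen_drugs":
            n_ent, ent_idx = dataset.n_M, dataset.mol_idx
        else:
            n_ent, ent_idx = dataset.n_P, dataset.prot_idx
        if k > n_ent:
            raise ValueError(f"n_folds={k} exceeds the number of entities {n_ent}")
        ef = _fold_assignment(n_ent, k, rng)
        pf = ef[ent_idx]
        for f in range(k):
            out.append((dataset.subset(pf != f), dataset.subset(pf == f)))
        return out
    # orphan
    if k > dataset.n_M or k > dataset.n_P:
        raise ValueError("n_folds exceeds the molecule or protein count")
    mf = _fold_assignment(dataset.n_M, k, rng)
    pfold = _fold_assignment(dataset.n_P, k, rng)
    pair_m = mf[dataset.mol_idx]
    pair_p = pfold[dataset.prot_idx]
    kept = pair_m == pair_p
    for f in range(k):
        out.append(
            (dataset.subset(kept & (pair_m != f)), dataset.subset(kept & (pair_m == f)))
        )
    return out
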