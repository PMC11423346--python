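"""Evaluation protocols: AUPR, cross-validated lambda selection, and the
scaffold-hopping ranking benchmark.

DTI prediction is evaluated as binary classification with the area under
the precision-recall curve (average precision).  The regularization weight
``lambda`` — the model's only hyperparameter — is chosen over the grid
``{1e-11, 1e-10, ..., 10, 100}`` by 5-fold cross-validation with a fresh
landmark draw and full feature refit in every fold.

The scaffold-hopping protocol trains a model with one ligand of an
active pair forced positive for the query protein (every other interaction
of that protein removed), then ranks the hidden second active among decoy
molecules; summaries are the cumulative histogram curve (CHC: fraction of
cases solved at or below each rank), its normalized AUC, and the fraction
of cases retrieved in the top 1% / 5%.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from . import svm
from .curation import SplitSpec, make_splits
from .exceptions import CaseError, EvaluationError, MetricError
from .io import InteractionSet, fingerprint_matrix
from .pipeline import PipelineConfig, fit_features, train_pipeline

logger = logging.getLogger(__name__)

#: lambda grid searched by cross-validation.
DEFAULT_LAMBDA_GRID = tuple(10.0 ** k for k in range(-11, 3))


# ---------------------------------------------------------------------------
# AUPR


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve as average precision.

    Candidates are ranked by descending score; ties keep the stable input
    order (so equal-score items are credited in the order supplied).  The
    value is the mean over positives of the precision at each positive's
    rank — a step-interpolated area, matching average precision; a random
    scorer scores about the positive prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels).tolist()) != {-1, 1}:
        raise MetricError("AUPR needs both classes present")
    order = np.argsort(-scores, kind="stable")
    y = labels[order] == 1
    tp = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    precision = tp / ranks
    return float(precision[y].mean())


# ---------------------------------------------------------------------------
# cross-validated lambda selection


@dataclasses.dataclass
class CVResult:
    fold_auprs: list[float]  # at the chosen lambda
    chosen_lambda: float
    grid: dict[float, list[float]]  # lambda -> per-fold AUPRs
    # test triples per used fold and their scores at each lambda, so callers
    # can re-score folds against e.g. planted ground-truth labels
    fold_tests: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = dataclasses.field(
        default_factory=list
    )
    fold_scores: dict[float, list[np.ndarray]] = dataclasses.field(default_factory=dict)

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_auprs))

    @property
    def std_aupr(self) -> float:
        return float(np.std(self.fold_auprs))

    def aupr_against(self, label_fn) -> float:
        """Mean fold AUPR at the chosen lambda, re-labeling test pairs with
        ``label_fn(mol_idx, prot_idx) -> +1/-1`` (planted-truth recovery)."""
        vals = []
        for (mi, pj, _y), s in zip(self.fold_tests, self.fold_scores[self.chosen_lambda]):
            vals.append(aupr(s, label_fn(mi, pj)))
        return float(np.mean(vals))


def cross_validate(
    dataset: InteractionSet,
    cfg: PipelineConfig | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    split: SplitSpec | None = None,
    seed: int = 0,
) -> CVResult:
    """K-fold cross-validation over the lambda grid.

    Each fold refits the whole feature pipeline (fresh landmark draw,
    eigenbasis, centering mean and Platt parameters on training data only);
    the lambda path within a fold reuses that fold's features.  Folds whose
    test labels are single-class are skipped with a warning.
    """
    cfg = cfg or PipelineConfig()
    split = split or SplitSpec(scenario="random", n_folds=5, seed=seed)
    folds = make_splits(dataset, split)
    fingerprints = fingerprint_matrix(dataset.molecules, cfg.n_bits, cfg.radius)
    sequences = [p.sequence for p in dataset.proteins]

    grid = {lam: [] for lam in lambda_grid}
    fold_scores = {lam: [] for lam in lambda_grid}
    fold_tests = []
    rng = np.random.default_rng(seed)
    n_used = 0
    for f, (train, test) in enumerate(folds):
        if len(set(test.labels.tolist())) < 2 or train.n_Z == 0:
            logger.warning("fold %d skipped: single-class or empty", f)
            continue
        n_used += 1
        fold_seed = int(rng.integers(2**31))
        _, _, M_feat, P_feat = fit_features(
            train, cfg, fold_seed, fingerprints, sequences
        )
        train_problem = svm.TrainingProblem(
            M_feat, P_feat, train.mol_idx, train.prot_idx, train.labels
        )
        test_problem = svm.TrainingProblem(
            M_feat, P_feat, test.mol_idx, test.prot_idx, test.labels
        )
        fold_tests.append((test.mol_idx, test.prot_idx, test.labels))
        for lam in lambda_grid:
            model = svm.fit(train_problem, lam=lam, max_iter=cfg.max_iter, tol=cfg.tol)
            scores = svm.scores_implicit(model.W, model.b, test_problem)
            grid[lam].append(aupr(scores, test.labels))
            fold_scores[lam].append(scores)
    if n_used == 0:
        raise EvaluationError("every fold was skipped; cannot cross-validate")
    means = {lam: float(np.mean(v)) for lam, v in grid.items()}
    best = max(means, key=lambda lam: (means[lam], -lam))
    return CVResult(
        fold_auprs=grid[best], chosen_lambda=best, grid=grid,
        fold_tests=fold_tests, fold_scores=fold_scores,
    )


# ---------------------------------------------------------------------------
# scaffold hopping


@dataclasses.dataclass
class HopCase:
    """One scaffold-hopping case: find the hidden active among decoys."""

    case_id: str
    query_prot: int  # protein index in the registry
    known_active: int  # molecule index
    unknown_active: int  # molecule index
    decoys: list[int]  # molecule indices, unknown_active excluded

    def __post_init__(self) -> None:
        if self.unknown_active in self.decoys:
            raise CaseError(f"case {self.case_id}: unknown active among the decoys")
        cands = [self.unknown_active] + list(self.decoys)
        if len(set(cands)) != len(cands):
            raise CaseError(f"case {self.case_id}: duplicate candidates")


def rank_with_ties(scores: np.ndarray, target_index: int) -> int:
    """1-based rank of one candidate: 1 + #strictly-greater + ceil(ties/2)."""
    s = np.asarray(scores, dtype=float)
    t = s[target_index]
    greater = int((s > t).sum())
    ties = int((s == t).sum()) - 1  # excluding the target itself
    return 1 + greater + math.ceil(ties / 2)


def run_hop_case(
    case: HopCase,
    dataset: InteractionSet,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> int:
    """Train for one hop case and rank the unknown active.

    The training set is the dataset with every pair involving the query
    protein removed, plus the (known active, query) pair forced positive.
    All candidates (unknown active first, then decoys) are scored against
    the query protein and the 1-based tie-aware rank of the unknown active
    is returned.
    """
    cfg = cfg or PipelineConfig()
    keep = dataset.prot_idx != case.query_prot
    mol_idx = np.concatenate([dataset.mol_idx[keep], [case.known_active]])
    prot_idx = np.concatenate([dataset.prot_idx[keep], [case.query_prot]])
    labels = np.concatenate([dataset.labels[keep], [1]])
    train = InteractionSet(dataset.molecules, dataset.proteins, mol_idx, prot_idx, labels)

    fitted = train_pipeline(train, cfg, seed=seed)
    candidates = [case.unknown_active] + list(case.decoys)
    table = fitted.score_pairs(
        np.asarray(candidates), np.full(len(candidates), case.query_prot)
    )
    return rank_with_ties(np.asarray(table.scores), 0)


@dataclasses.dataclass
class HopSummary:
    chc: np.ndarray  # chc[r-1] = fraction of cases with rank <= r
    auc: float  # mean of the CHC over ranks, in [0, 1]
    top1pct: float
    top5pct: float


def hop_summary(ranks, n_candidates: int = 500) -> HopSummary:
    """Cumulative histogram curve and its summaries over hop-case ranks."""
    ranks = np.asarray(ranks, dtype=int)
    if len(ranks) == 0:
        raise MetricError("no hop-case ranks supplied")
    if ranks.min() < 1 or ranks.max() > n_candidates:
        raise MetricError(f"ranks must lie in [1, {n_candidates}]")
    grid = np.arange(1, n_candidates + 1)
    chc = (ranks[None, :] <= grid[:, None]).mean(axis=1)
    r1 = int(0.01 * n_candidates)
    r5 = int(0.05 * n_candidates)
    return HopSummary(
        chc=chc,
        auc=float(chc.mean()),
        top1pct=float(chc[r1 - 1]) if r1 >= 1 else 0.0,
        top5pct=float(chc[r5 - 1]) if r5 >= 1 else 0.0,
    )
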