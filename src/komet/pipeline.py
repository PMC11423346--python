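"""End-to-end training pipeline: registries -> features -> fitted model.

Fits the molecule and protein feature maps on the *training* entities only
(landmarks, eigenbasis and centering mean all come from training data, so
no information leaks from test folds), trains the pair-space SVM, and
optionally Platt-calibrates it.  The fitted :class:`PipelineModel` can then
score any (molecule, protein) pair over the shared entity registries.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import svm
from .features import FeatureMap, fit_feature_map
from .io import InteractionSet, PredictionTable, fingerprint_matrix
from .kernels import LAKernelParams, LocalAlignmentKernel, TanimotoKernel

#: defaults for large datasets; both are clipped to the training-set size.
DEFAULT_M_M = 3000
DEFAULT_D_M = 1000


@dataclasses.dataclass
class PipelineConfig:
    """Tunables of the full pipeline (all sizes clip to the data)."""

    n_bits: int = 1024
    radius: int = 2
    m_M: int = DEFAULT_M_M  # molecule landmarks
    d_M: int = DEFAULT_D_M  # molecule feature dimension
    m_P: int | None = None  # protein landmarks; None = all (exact map)
    d_P: int | None = None  # protein feature dimension; None = rank
    la_params: LAKernelParams | None = None
    center_molecules: bool = True
    center_proteins: bool = True
    normalize: bool = True
    lam: float = 1e-6
    max_iter: int = 200
    tol: float = 1e-6
    calibrate: bool = True
    _prot_kernel: LocalAlignmentKernel | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    def la(self) -> LAKernelParams:
        return self.la_params or LAKernelParams()

    def prot_kernel(self) -> LocalAlignmentKernel:
        """Shared LA-kernel instance (its pair cache spans folds and cases)."""
        if self._prot_kernel is None:
            self._prot_kernel = LocalAlignmentKernel(self.la())
        return self._prot_kernel


@dataclasses.dataclass
class PipelineModel:
    """Fitted feature maps + SVM over a fixed pair of entity registries."""

    mol_map: FeatureMap
    prot_map: FeatureMap
    model: svm.KometModel
    M_feat: np.ndarray  # features of every registry molecule
    P_feat: np.ndarray  # features of every registry protein
    mol_ids: list[str]
    prot_ids: list[str]

    def score_pairs(self, mol_idx, prot_idx) -> PredictionTable:
        return svm.predict(
            self.model, self.M_feat, self.P_feat,
            np.asarray(mol_idx), np.asarray(prot_idx),
            self.mol_ids, self.prot_ids,
        )

    def score_interactions(self, dataset: InteractionSet) -> PredictionTable:
        return self.score_pairs(dataset.mol_idx, dataset.prot_idx)


def fit_features(
    train: InteractionSet,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    fingerprints: np.ndarray | None = None,
    sequences: list[str] | None = None,
) -> tuple[FeatureMap, FeatureMap, np.ndarray, np.ndarray]:
    """Fit both feature maps on training entities; extrapolate to all.

    Returns ``(mol_map, prot_map, M_feat, P_feat)`` where the feature
    matrices cover every entity in the registries (training-fitted maps are
    simply evaluated on unseen entities).
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    if fingerprints is None:
        fingerprints = fingerprint_matrix(train.molecules, cfg.n_bits, cfg.radius)
    if sequences is None:
        sequences = [p.sequence for p in train.proteins]

    train_mols = np.unique(train.mol_idx)
    train_prots = np.unique(train.prot_idx)

    mol_kernel = TanimotoKernel()
    m_M = min(cfg.m_M, len(train_mols))
    d_M = min(cfg.d_M, m_M)
    mol_map = fit_feature_map(
        [fingerprints[i] for i in train_mols],
        mol_kernel,
        n_landmarks=m_M,
        dim=d_M,
        seed=int(rng.integers(2**31)),
        center=cfg.center_molecules,
        normalize=cfg.normalize,
        ids=[train.molecules[i].mol_id for i in train_mols],
    )

    prot_kernel = cfg.prot_kernel()
    n_tp = len(train_prots)
    m_P = n_tp if cfg.m_P is None else min(cfg.m_P, n_tp)
    d_P = None if cfg.d_P is None else min(cfg.d_P, m_P)
    prot_map = fit_feature_map(
        [sequences[j] for j in train_prots],
        prot_kernel,
        n_landmarks=m_P,
        dim=d_P,
        seed=int(rng.integers(2**31)),
        center=cfg.center_proteins,
        normalize=cfg.normalize,
        ids=[train.proteins[j].prot_id for j in train_prots],
    )

    M_feat = mol_map.transform_batch(list(fingerprints))
    P_feat = prot_map.transform_batch(sequences)
    return mol_map, prot_map, M_feat, P_feat


def train_pipeline(
    train: InteractionSet,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    fingerprints: np.ndarray | None = None,
    sequences: list[str] | None = None,
) -> PipelineModel:
    """Fit feature maps and the SVM on a training interaction set.

    ``fingerprints``/``sequences`` may be precomputed for the *full*
    registries (rows in registry order); otherwise they are derived from the
    records.  Only entities that occur in training triples inform the
    feature maps; features are then extrapolated to every registry entity.
    """
    cfg = cfg or PipelineConfig()
    mol_map, prot_map, M_feat, P_feat = fit_features(
        train, cfg, seed, fingerprints, sequences
    )
    problem = svm.TrainingProblem(
        M_feat, P_feat, train.mol_idx, train.prot_idx, train.labels
    )
    model = svm.fit(problem, lam=cfg.lam, max_iter=cfg.max_iter, tol=cfg.tol)
    if cfg.calibrate and len(set(train.labels.tolist())) == 2:
        svm.calibrate(model, problem)
    return PipelineModel(
        mol_map=mol_map,
        prot_map=prot_map,
        model=model,
        M_feat=M_feat,
        P_feat=P_feat,
        mol_ids=train.molecules.ids,
        prot_ids=train.proteins.ids,
    )
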