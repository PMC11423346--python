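"""Explicit kernel feature maps via the Nystrom approximation.

A :class:`FeatureMap` turns an entity (a molecule fingerprint or a protein
sequence) into a real vector whose dot products approximate the kernel.  It
is fitted on ``m`` randomly chosen landmark entities: the landmark Gram
``K_mm`` is eigendecomposed, eigenvalues below a clipping threshold are
dropped (the log-transformed local-alignment kernel need not be positive
semidefinite), and the extrapolation matrix

    E = U_d diag(sigma_d)^(-1/2)

maps the kernel evaluations of any entity against the landmarks to its
``d``-dimensional feature vector ``psi(x) = E^T [k(x, l_1), ..., k(x, l_m)]``.
With ``m = d = n`` (all entities as landmarks) the construction is exact:
feature dot products reproduce the (clipped) Gram matrix.

Features are then mean-centered with the training-set mean ``mu`` and
l2-normalized: ``psi~(x) = (psi(x) - mu) / ||psi(x) - mu||``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .exceptions import DimensionError
from .kernels import LAKernelParams, LocalAlignmentKernel, TanimotoKernel

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1
EIG_CLIP = 1e-10


def _as_matrix_kernel(kernel):
    if hasattr(kernel, "matrix"):
        return kernel

    class _Wrapped:
        def __init__(self, k):
            self._k = k

        def __call__(self, a, b):
            return self._k(a, b)

        def matrix(self, A, B):
            return np.array([[self._k(a, b) for b in B] for a in A], dtype=float)

    return _Wrapped(kernel)


@dataclasses.dataclass
class FeatureMap:
    """Fitted Nystrom feature map: landmarks + extrapolation + centering."""

    landmark_ids: list[str]
    landmarks: list  # raw landmark entities, in landmark order
    kernel: Callable
    E: np.ndarray  # m x d
    center: np.ndarray  # length d mean vector mu (zeros if centered=False)
    centered: bool = True
    normalized: bool = True
    eigenvalues: np.ndarray | None = None  # kept spectrum, descending

    @property
    def n_landmarks(self) -> int:
        return self.E.shape[0]

    @property
    def dim(self) -> int:
        return self.E.shape[1]

    # -- transforms ---------------------------------------------------------

    def transform_raw(self, entity) -> np.ndarray:
        """Uncentered, unnormalized feature psi(x) = E^T k(x, landmarks)."""
        k = _as_matrix_kernel(self.kernel)
        A = entity[None, :] if isinstance(entity, np.ndarray) else [entity]
        kvec = np.asarray(k.matrix(A, self._landmark_block()), dtype=float)
        return (kvec @ self.E)[0]

    def transform(self, entity) -> np.ndarray:
        """Feature vector of one entity, centered/normalized per the flags."""
        psi = self.transform_raw(entity)
        if self.centered:
            psi = psi - self.center
        if self.normalized:
            nrm = np.linalg.norm(psi)
            if nrm == 0.0:
                warnings.warn(
                    "entity feature equals the center exactly; returning the "
                    "zero vector (norm undefined)",
                    RuntimeWarning,
                )
                return psi
            psi = psi / nrm
        return psi

    def transform_batch(self, entities: Sequence) -> np.ndarray:
        """Row-wise transform; bit-identical to looping :meth:`transform`."""
        if len(entities) == 0:
            return np.empty((0, self.dim))
        return np.stack([self.transform(e) for e in entities])

    def _landmark_block(self):
        if len(self.landmarks) and isinstance(self.landmarks[0], np.ndarray):
            return np.asarray(self.landmarks)
        return self.landmarks

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Single-archive serialization (npz with a JSON config entry)."""
        kcfg = _kernel_config(self.kernel)
        lm = self._landmark_block()
        lm_arr = np.asarray(lm) if isinstance(lm, np.ndarray) else np.array(lm, dtype="U")
        np.savez(
            path,
            format_version=FORMAT_VERSION,
            landmark_ids=np.array(self.landmark_ids, dtype="U"),
            landmarks=lm_arr,
            E=np.asfortranarray(self.E),
            center=self.center,
            centered=self.centered,
            normalized=self.normalized,
            kernel_config=json.dumps(kcfg),
        )

    @classmethod
    def load(cls, path) -> "FeatureMap":
        with np.load(path, allow_pickle=False) as z:
            kcfg = json.loads(str(z["kernel_config"]))
            lm = z["landmarks"]
            if lm.dtype.kind in ("U", "S"):
                landmarks = [str(s) for s in lm]
            else:
                landmarks = [np.asarray(r) for r in lm]
            return cls(
                landmark_ids=[str(s) for s in z["landmark_ids"]],
                landmarks=landmarks,
                kernel=_kernel_from_config(kcfg),
                E=np.ascontiguousarray(z["E"]),
                center=z["center"],
                centered=bool(z["centered"]),
                normalized=bool(z["normalized"]),
            )


def _kernel_config(kernel) -> dict:
    if isinstance(kernel, TanimotoKernel):
        return {"type": "tanimoto"}
    if isinstance(kernel, LocalAlignmentKernel):
        p = kernel.params
        return {
            "type": "local_alignment",
            "beta": p.beta,
            "gap_open": p.gap_open,
            "gap_extend": p.gap_extend,
            "substitution": "BLOSUM62",
            "log_transform": p.log_transform,
            "unknown_score": p.unknown_score,
        }
    raise ValueError("only built-in kernels are serializable")


def _kernel_from_config(cfg: dict):
    if cfg["type"] == "tanimoto":
        return TanimotoKernel()
    if cfg["type"] == "local_alignment":
        return LocalAlignmentKernel(
            LAKernelParams(
                beta=cfg["beta"],
                gap_open=cfg["gap_open"],
                gap_extend=cfg["gap_extend"],
                substitution=cfg["substitution"],
                log_transform=cfg["log_transform"],
                unknown_score=cfg["unknown_score"],
            )
        )
    raise ValueError(f"unknown kernel type {cfg['type']!r}")


def fit_feature_map(
    entities: Sequence,
    kernel: Callable,
    n_landmarks: int | None = None,
    dim: int | None = None,
    seed: int = 0,
    center: bool = True,
    normalize: bool = True,
    ids: Sequence[str] | None = None,
    center_on: str = "train_set",
    strict_dim: bool = False,
) -> FeatureMap:
    """Fit a Nystrom feature map on a training entity set.

    Parameters
    ----------
    entities : raw entities (fingerprint rows or sequences), training order.
    kernel : element kernel, ideally exposing a vectorized ``matrix(A, B)``.
    n_landmarks : m, drawn uniformly without replacement (default: all).
    dim : d <= m, number of leading eigen-directions kept (default: the
        numerical rank after eigenvalue clipping at 1e-10).
    seed : RNG seed for the landmark draw.
    center_on : compute the centering mean over ``"train_set"`` (all
        entities, the default) or over ``"landmarks"`` only.
    strict_dim : raise :class:`DimensionError` when ``dim`` exceeds the
        achievable rank instead of silently reducing it.
    """
    n = len(entities)
    if n < 1:
        raise ValueError("need at least one entity")
    m = n if n_landmarks is None else int(n_landmarks)
    if m > n:
        raise ValueError(f"n_landmarks={m} exceeds the number of entities n={n}")
    if m < 1:
        raise ValueError("need at least one landmark")
    if dim is not None and dim > m:
        raise ValueError(f"dim={dim} exceeds n_landmarks={m}")
    if center_on not in ("train_set", "landmarks"):
        raise ValueError("center_on must be 'train_set' or 'landmarks'")

    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    rng = np.random.default_rng(seed)
    if m == n:
        lidx = np.arange(n)
    else:
        lidx = np.sort(rng.choice(n, size=m, replace=False))
    is_arr = isinstance(entities[0], np.ndarray)
    landmarks = (
        [np.asarray(entities[i]) for i in lidx] if is_arr else [entities[i] for i in lidx]
    )
    lm_block = np.asarray(landmarks) if is_arr else landmarks

    k = _as_matrix_kernel(kernel)
    K_mm = np.asarray(k.matrix(lm_block, lm_block), dtype=float)
    K_mm = 0.5 * (K_mm + K_mm.T)
    evals, evecs = scipy.linalg.eigh(K_mm)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > EIG_CLIP))
    if rank == 0:
        raise DimensionError("landmark Gram has no eigenvalue above the clip 1e-10")
    d = rank if dim is None else int(dim)
    if d > rank:
        if strict_dim:
            raise DimensionError(
                f"requested dim={d} but only {rank} eigenvalues exceed the "
                f"1e-10 clip; achievable rank is {rank}"
            )
        logger.info("reducing feature dim from %d to achievable rank %d", d, rank)
        d = rank
    kept = evals[:d]
    E = evecs[:, :d] / np.sqrt(kept)[None, :]

    fmap = FeatureMap(
        landmark_ids=[ids[i] for i in lidx],
        landmarks=landmarks,
        kernel=kernel,
        E=E,
        center=np.zeros(d),
        centered=center,
        normalized=normalize,
        eigenvalues=kept,
    )
    if center:
        base = landmarks if center_on == "landmarks" else entities
        raw = np.stack([fmap.transform_raw(e) for e in base])
        fmap.center = raw.mean(axis=0)
    return fmap
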