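"""Linear SVM in the implicit Kronecker pair space.

A (molecule, protein) pair with features ``m`` (length d_M) and ``p``
(length d_P) has pair feature ``z = m (x) p`` (tensor product, dimension
d_Z = d_M * d_P).  The classifier is ``sign(<w, z> + b)`` with ``w``
viewed as the matrix ``W`` of shape d_M x d_P, and is trained by
minimizing the penalized empirical hinge risk

    f(W, b) = (1/n_Z) sum_k max(0, 1 - y_k (<m_ik, W p_jk> + b))
              + (lambda/2) ||W||_F^2

with full-batch limited-memory BFGS.  The central trick is that the
pair-space scores never require materializing the Kronecker features:

    <m_ik (x) p_jk, w> = <m_ik, W p_jk> = <m_ik, q_jk>,   q_j := W p_j

so all scores cost O(n_P * d_M * d_P + n_Z * d_M) instead of O(n_Z * d_Z),
and the gradient factorizes the same way.  Platt scaling then maps raw
margins ``<z, w>`` to probabilities ``sigma(s * f + t)``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.optimize
import scipy.sparse

from .exceptions import (
    CalibrationError,
    DivergenceError,
    ShapeError,
    TrainingDataError,
)
from .io import PredictionTable

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200


@dataclasses.dataclass
class TrainingProblem:
    """Entity feature matrices plus indexed labeled pairs."""

    M: np.ndarray  # n_M x d_M molecule features
    P: np.ndarray  # n_P x d_P protein features
    mol_idx: np.ndarray  # length n_Z
    prot_idx: np.ndarray  # length n_Z
    labels: np.ndarray  # +1/-1, length n_Z

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        self.P = np.asarray(self.P, dtype=np.float64)
        self.mol_idx = np.asarray(self.mol_idx, dtype=np.int64)
        self.prot_idx = np.asarray(self.prot_idx, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.M.ndim != 2 or self.P.ndim != 2:
            raise ShapeError("feature matrices must be 2-D")
        if not (len(self.mol_idx) == len(self.prot_idx) == len(self.labels)):
            raise ShapeError("triple arrays must share a length")
        if len(self.mol_idx):
            if self.mol_idx.max() >= self.M.shape[0] or self.mol_idx.min() < 0:
                raise ShapeError("molecule index out of bounds of M")
            if self.prot_idx.max() >= self.P.shape[0] or self.prot_idx.min() < 0:
                raise ShapeError("protein index out of bounds of P")
        if not np.isin(self.labels, (-1.0, 1.0)).all():
            raise TrainingDataError("labels must be +1/-1")

    @property
    def n_Z(self) -> int:
        return len(self.labels)

    @property
    def d_M(self) -> int:
        return self.M.shape[1]

    @property
    def d_P(self) -> int:
        return self.P.shape[1]


@dataclasses.dataclass
class KometModel:
    """Fitted pair-space linear classifier.

    ``W`` is the d_M x d_P matrix view of the pair-space weight vector;
    ``platt_s``/``platt_t`` are present only after calibration.
    """

    W: np.ndarray
    b: float
    lam: float
    platt_s: float | None = None
    platt_t: float | None = None
    n_iter: int | None = None
    final_objective: float | None = None

    @property
    def is_calibrated(self) -> bool:
        return self.platt_s is not None

    def decision_function(self, problem: TrainingProblem) -> np.ndarray:
        return scores_implicit(self.W, self.b, problem)

    def save(self, path) -> None:
        np.savez(
            path,
            format_version=1,
            W=self.W,
            b=self.b,
            lam=self.lam,
            platt=np.array(
                [self.platt_s, self.platt_t] if self.is_calibrated else [np.nan, np.nan]
            ),
        )

    @classmethod
    def load(cls, path) -> "KometModel":
        with np.load(path) as z:
            s, t = z["platt"]
            return cls(
                W=z["W"],
                b=float(z["b"]),
                lam=float(z["lam"]),
                platt_s=None if np.isnan(s) else float(s),
                platt_t=None if np.isnan(t) else float(t),
            )


def scores_implicit(W: np.ndarray, b: float, problem: TrainingProblem) -> np.ndarray:
    """Pair scores ``<m_ik, W p_jk> + b`` without forming pair features.

    Computes ``q_j = W p_j`` for every protein (n_P * d_M * d_P work), then
    one dot product per triple (n_Z * d_M work).
    """
    W = np.asarray(W, dtype=np.float64)
    if W.shape != (problem.d_M, problem.d_P):
        raise ShapeError(
            f"W has shape {W.shape}, expected ({problem.d_M}, {problem.d_P})"
        )
    Q = problem.P @ W.T  # n_P x d_M
    return np.einsum(
        "kd,kd->k", problem.M[problem.mol_idx], Q[problem.prot_idx]
    ) + float(b)


def objective_and_gradient(
    W: np.ndarray, b: float, problem: TrainingProblem, lam: float
) -> tuple[float, np.ndarray, float]:
    """Hinge risk and its (sub)gradient, assembled in factorized form.

    Returns ``(f, grad_W, grad_b)`` where ``f`` is the mean hinge loss plus
    ``(lam/2) ||W||_F^2``.  At the hinge kink (margin exactly 1) the
    subgradient 0 is used.  The gradient groups active triples by protein:
    ``a_j = sum_{k: j_k = j} g_k m_{i_k}`` and ``grad_W = (1/n_Z) sum_j
    a_j p_j^T + lam W``, never materializing pair features.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if problem.n_Z == 0:
        raise TrainingDataError("cannot evaluate the objective on zero triples")
    W = np.asarray(W, dtype=np.float64)
    y = problem.labels
    scores = scores_implicit(W, b, problem)
    margins = y * scores
    hinge = np.maximum(0.0, 1.0 - margins)
    f = hinge.mean() + 0.5 * lam * float(np.sum(W * W))

    active = margins < 1.0  # strict: zero subgradient exactly at the kink
    g = np.where(active, -y, 0.0)
    n_Z = problem.n_Z
    nz = np.flatnonzero(g)
    if len(nz):
        # A[j] = sum over active triples with protein j of g_k * m_{i_k}
        agg = scipy.sparse.csr_matrix(
            (g[nz], (problem.prot_idx[nz], np.arange(len(nz)))),
            shape=(problem.P.shape[0], len(nz)),
        )
        A = agg @ problem.M[problem.mol_idx[nz]]  # n_P x d_M
        grad_W = (A.T @ problem.P) / n_Z + lam * W
    else:
        grad_W = lam * W.copy()
    grad_b = float(g.sum()) / n_Z
    return float(f), grad_W, grad_b


def _smoothed_objective(x, problem, lam, mu, d_M, d_P):
    """Softplus-smoothed hinge: mu*softplus((1-m)/mu) -> hinge as mu -> 0."""
    W = x[:-1].reshape(d_M, d_P)
    y = problem.labels
    s = scores_implicit(W, x[-1], problem)
    u = (1.0 - y * s) / mu
    f = mu * np.logaddexp(0.0, u).mean() + 0.5 * lam * float(np.sum(W * W))
    sig = 1.0 / (1.0 + np.exp(-np.clip(u, -500, 500)))
    g = -y * sig
    agg = scipy.sparse.csr_matrix(
        (g, (problem.prot_idx, np.arange(len(g)))),
        shape=(problem.P.shape[0], len(g)),
    )
    gW = (agg @ problem.M[problem.mol_idx]).T @ problem.P / len(g) + lam * W
    return f, np.concatenate([gW.ravel(), [g.mean()]])


def fit(
    problem: TrainingProblem,
    lam: float = 1e-6,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> KometModel:
    """Train by full-batch L-BFGS from ``W = 0, b = 0``.

    The hinge objective is nonsmooth, and quasi-Newton line searches can
    stall a fraction of a percent above the optimum at a kink; after the
    main exact-hinge run the solution is therefore polished through a short
    smoothing homotopy (softplus-smoothed hinge at decreasing temperature,
    warm-started) followed by a final exact-hinge run, keeping whichever
    iterate achieves the lowest exact objective.  The bias is unpenalized
    and optimized jointly.  ``seed`` is accepted for interface uniformity;
    the optimization itself is deterministic.
    """
    if problem.n_Z == 0:
        raise TrainingDataError("no training triples")
    d_M, d_P = problem.d_M, problem.d_P

    def fun(x):
        W = x[:-1].reshape(d_M, d_P)
        f, gW, gb = objective_and_gradient(W, x[-1], problem, lam)
        if not np.isfinite(f):
            raise DivergenceError(
                "objective became non-finite; consider a larger lambda"
            )
        return f, np.concatenate([gW.ravel(), [gb]])

    opts = {"maxiter": max_iter, "gtol": tol, "ftol": 1e-15, "maxcor": 20}
    x0 = np.zeros(d_M * d_P + 1)
    res = scipy.optimize.minimize(fun, x0, jac=True, method="L-BFGS-B", options=opts)
    best_x, best_f, n_iter = res.x, float(res.fun), int(res.nit)

    x = res.x
    for mu in (1e-2, 1e-4, 1e-6):
        sres = scipy.optimize.minimize(
            _smoothed_objective, x, args=(problem, lam, mu, d_M, d_P),
            jac=True, method="L-BFGS-B", options=opts,
        )
        x = sres.x
        n_iter += int(sres.nit)
    pres = scipy.optimize.minimize(fun, x, jac=True, method="L-BFGS-B", options=opts)
    n_iter += int(pres.nit)
    if float(pres.fun) < best_f:
        best_x, best_f = pres.x, float(pres.fun)

    W = best_x[:-1].reshape(d_M, d_P)
    return KometModel(
        W=W,
        b=float(best_x[-1]),
        lam=lam,
        n_iter=n_iter,
        final_objective=best_f,
    )


def _softplus(u: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, u)


def fit_platt(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Platt calibration: minimize sum_k softplus(-y_k (s f_k + t)).

    Returns ``(s, t)`` such that ``sigma(s f + t)`` estimates P(y = +1 | f).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if len(set(labels.tolist())) < 2:
        raise CalibrationError("Platt calibration needs both classes present")

    def fun(x):
        u = -labels * (x[0] * scores + x[1])
        f = _softplus(u).mean()
        sig = 1.0 / (1.0 + np.exp(-np.clip(u, -500, 500)))
        common = -labels * sig
        return f, np.array([(common * scores).mean(), common.mean()])

    res = scipy.optimize.minimize(
        fun, np.array([1.0, 0.0]), jac=True, method="L-BFGS-B",
        options={"gtol": 1e-10, "ftol": 1e-15, "maxiter": 500},
    )
    return float(res.x[0]), float(res.x[1])


def calibrate(model: KometModel, problem: TrainingProblem) -> KometModel:
    """Fit Platt parameters on raw margins ``<z, w>`` (bias excluded)."""
    raw = scores_implicit(model.W, 0.0, problem)
    s, t = fit_platt(raw, problem.labels)
    model.platt_s, model.platt_t = s, t
    return model


def predict(
    model: KometModel,
    mol_features: np.ndarray,
    prot_features: np.ndarray,
    mol_idx: np.ndarray,
    prot_idx: np.ndarray,
    mol_ids: list[str] | None = None,
    prot_ids: list[str] | None = None,
) -> PredictionTable:
    """Score (molecule, protein) pairs; probabilities iff calibrated."""
    mol_idx = np.asarray(mol_idx, dtype=np.int64)
    prot_idx = np.asarray(prot_idx, dtype=np.int64)
    problem = TrainingProblem(
        mol_features, prot_features, mol_idx, prot_idx,
        np.ones(len(mol_idx)),
    )
    scores = scores_implicit(model.W, model.b, problem)
    probs = None
    if model.is_calibrated:
        raw = scores_implicit(model.W, 0.0, problem)
        u = model.platt_s * raw + model.platt_t
        probs = 1.0 / (1.0 + np.exp(-np.clip(u, -500, 500)))
    if mol_ids is None:
        mol_ids = [str(i) for i in mol_idx]
    else:
        mol_ids = [mol_ids[i] for i in mol_idx]
    if prot_ids is None:
        prot_ids = [str(j) for j in prot_idx]
    else:
        prot_ids = [prot_ids[j] for j in prot_idx]
    return PredictionTable(mol_ids, prot_ids, scores, probs)
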