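"""Base similarity functions: Tanimoto and Local Alignment kernels.

The Tanimoto (Jaccard) kernel compares molecules through the substructures
their fingerprints share and is positive semidefinite.  The Local Alignment
(LA) kernel compares protein sequences by summing ``exp(beta * score)`` over
*all* gapped local alignments — a soft Smith–Waterman that detects remote
homology; as ``beta`` grows its log-transform converges to the best local
alignment score.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import numpy as np

from .exceptions import AlphabetError, DegenerateInputError

_OVERFLOW_LIMIT = 1e280  # switch the summation DP to log-space beyond this


# ---------------------------------------------------------------------------
# Tanimoto


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |a AND b| / |a OR b| of two binary fingerprints."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    inter = float(np.dot(a, b))
    union = float(a.sum() + b.sum()) - inter
    if union == 0.0:
        raise DegenerateInputError(
            "Tanimoto undefined for two all-zero fingerprints; filter empty "
            "fingerprints upstream"
        )
    return inter / union


class TanimotoKernel:
    """Tanimoto kernel over 0/1 fingerprint vectors, with vectorized Gram."""

    def __call__(self, a: np.ndarray, b: np.ndarray) -> float:
        return tanimoto(a, b)

    def matrix(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Kernel values between the rows of A and the rows of B."""
        A = np.asarray(A, dtype=np.float64)
        B = np.asarray(B, dtype=np.float64)
        pa = A.sum(axis=1)
        pb = B.sum(axis=1)
        if (pa == 0).any() or (pb == 0).any():
            raise DegenerateInputError("all-zero fingerprint in Tanimoto Gram input")
        inter = A @ B.T
        union = pa[:, None] + pb[None, :] - inter
        return inter / union


# ---------------------------------------------------------------------------
# Local alignment kernel


def load_substitution_matrix(name_or_path: str = "BLOSUM62"):
    """Load a substitution matrix by name, or from an NCBI-format file."""
    from Bio.Align import substitution_matrices

    if name_or_path in substitution_matrices.load():
        return substitution_matrices.load(name_or_path)
    return substitution_matrices.read(name_or_path)


@dataclasses.dataclass
class LAKernelParams:
    """Hyperparameters of the local alignment kernel.

    beta            alignment-sharpness (>0); small beta sums many alignments
                    softly, large beta approaches Smith–Waterman.
    gap_open        affine gap opening penalty d (subtracted from the score).
    gap_extend      affine gap extension penalty e; a gap of length g costs
                    d + e*(g-1).
    substitution    residue-pair score table; by name ("BLOSUM62"), path to an
                    NCBI-format matrix file, or an explicit mapping
                    {(x, y): score}.
    log_transform   return ln(K)/beta instead of K.
    unknown_score   score for an extended-alphabet letter (B/Z/X/U/O) absent
                    from the matrix.
    """

    beta: float = 0.5
    gap_open: float = 11.0
    gap_extend: float = 1.0
    substitution: object = "BLOSUM62"
    log_transform: bool = True
    unknown_score: float = -4.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (math.isfinite(self.gap_open) and math.isfinite(self.gap_extend)):
            raise ValueError("gap penalties must be finite")
        if isinstance(self.substitution, str):
            self.substitution = load_substitution_matrix(self.substitution)

    def score(self, x: str, y: str) -> float:
        sub = self.substitution
        if isinstance(sub, Mapping) and not hasattr(sub, "alphabet"):
            try:
                return float(sub[(x, y)])
            except KeyError:
                try:
                    return float(sub[(y, x)])
                except KeyError:
                    return self._fallback(x, y, set(a for pair in sub for a in pair))
        alphabet = set(sub.alphabet)
        if x in alphabet and y in alphabet:
            return float(sub[x, y])
        return self._fallback(x, y, alphabet)

    def _fallback(self, x: str, y: str, alphabet: set) -> float:
        # only the ambiguity/rare codes may fall back to the constant score;
        # a standard residue absent from the matrix is a real error
        for letter in (x, y):
            if letter not in alphabet and letter not in "BZXUO":
                raise AlphabetError(
                    f"letter {letter!r} missing from the substitution matrix"
                )
        return float(self.unknown_score)


def _la_kernel_float_py(ex: np.ndarray, gd: float, ge: float) -> float:
    """Plain-float summation DP over the exp(beta*s) table ``ex``.

    Recursions (affine gaps, gap-in-x runs always precede gap-in-y runs
    between two aligned pairs, so every alignment is counted exactly once):

        M[i,j]  = ex[i,j] * (1 + M[i-1,j-1] + X[i-1,j-1] + Y[i-1,j-1])
        X[i,j]  = gd*M[i-1,j] + ge*X[i-1,j]
        Y[i,j]  = gd*(M[i,j-1] + X[i,j-1]) + ge*Y[i,j-1]
        X2[i,j] = M[i-1,j] + X2[i-1,j]
        Y2[i,j] = M[i,j-1] + X2[i,j-1] + Y2[i,j-1]
        K       = 1 + X2[n,m] + Y2[n,m] + M[n,m]
    """
    n, m = ex.shape
    zeros = [0.0] * (m + 1)
    Mp, Xp, Yp, X2p, Y2p = zeros[:], zeros[:], zeros[:], zeros[:], zeros[:]
    exl = ex.tolist()
    for i in range(1, n + 1):
        row = exl[i - 1]
        Mc = [0.0] * (m + 1)
        Xc = [0.0] * (m + 1)
        Yc = [0.0] * (m + 1)
        X2c = [0.0] * (m + 1)
        Y2c = [0.0] * (m + 1)
        for j in range(1, m + 1):
            Mc[j] = row[j - 1] * (1.0 + Mp[j - 1] + Xp[j - 1] + Yp[j - 1])
            Xc[j] = gd * Mp[j] + ge * Xp[j]
            Yc[j] = gd * (Mc[j - 1] + Xc[j - 1]) + ge * Yc[j - 1]
            X2c[j] = Mp[j] + X2p[j]
            Y2c[j] = Mc[j - 1] + X2c[j - 1] + Y2c[j - 1]
        Mp, Xp, Yp, X2p, Y2p = Mc, Xc, Yc, X2c, Y2c
    return 1.0 + X2p[m] + Y2p[m] + Mp[m]


def _make_numba_dp():
    """Compile the float DP with numba when available (identical recursions)."""
    try:
        import numba
    except ImportError:  # pragma: no cover - environment dependent
        return None

    @numba.njit(cache=False, fastmath=False)
    def _dp(ex, gd, ge):  # pragma: no cover - exercised via la_kernel
        n, m = ex.shape
        Mp = np.zeros(m + 1)
        Xp = np.zeros(m + 1)
        Yp = np.zeros(m + 1)
        X2p = np.zeros(m + 1)
        Y2p = np.zeros(m + 1)
        Mc = np.zeros(m + 1)
        Xc = np.zeros(m + 1)
        Yc = np.zeros(m + 1)
        X2c = np.zeros(m + 1)
        Y2c = np.zeros(m + 1)
        for i in range(1, n + 1):
            Mc[0] = 0.0
            Xc[0] = 0.0
            Yc[0] = 0.0
            X2c[0] = 0.0
            Y2c[0] = 0.0
            for j in range(1, m + 1):
                Mc[j] = ex[i - 1, j - 1] * (1.0 + Mp[j - 1] + Xp[j - 1] + Yp[j - 1])
                Xc[j] = gd * Mp[j] + ge * Xp[j]
                Yc[j] = gd * (Mc[j - 1] + Xc[j - 1]) + ge * Yc[j - 1]
                X2c[j] = Mp[j] + X2p[j]
                Y2c[j] = Mc[j - 1] + X2c[j - 1] + Y2c[j - 1]
            Mp, Mc = Mc, Mp
            Xp, Xc = Xc, Xp
            Yp, Yc = Yc, Yp
            X2p, X2c = X2c, X2p
            Y2p, Y2c = Y2c, Y2p
        return 1.0 + X2p[m] + Y2p[m] + Mp[m]

    return _dp


_NUMBA_DP = None
_NUMBA_TRIED = False


def _la_kernel_float(ex: np.ndarray, gd: float, ge: float) -> float:
    global _NUMBA_DP, _NUMBA_TRIED
    if not _NUMBA_TRIED:
        _NUMBA_TRIED = True
        _NUMBA_DP = _make_numba_dp()
    if _NUMBA_DP is not None:
        return float(_NUMBA_DP(np.ascontiguousarray(ex), gd, ge))
    return _la_kernel_float_py(ex, gd, ge)


def _la_kernel_log(bs: np.ndarray, lgd: float, lge: float) -> float:
    """Same DP carried in log-space (values are log-weights)."""
    n, m = bs.shape
    NEG = -np.inf
    Mp = np.full(m + 1, NEG)
    Xp = np.full(m + 1, NEG)
    Yp = np.full(m + 1, NEG)
    X2p = np.full(m + 1, NEG)
    Y2p = np.full(m + 1, NEG)
    lse = np.logaddexp
    for i in range(1, n + 1):
        Mc = np.full(m + 1, NEG)
        Xc = np.full(m + 1, NEG)
        Yc = np.full(m + 1, NEG)
        X2c = np.full(m + 1, NEG)
        Y2c = np.full(m + 1, NEG)
        for j in range(1, m + 1):
            prev = lse(lse(0.0, Mp[j - 1]), lse(Xp[j - 1], Yp[j - 1]))
            Mc[j] = bs[i - 1, j - 1] + prev
            Xc[j] = lse(lgd + Mp[j], lge + Xp[j])
            Yc[j] = lse(lgd + lse(Mc[j - 1], Xc[j - 1]), lge + Yc[j - 1])
            X2c[j] = lse(Mp[j], X2p[j])
            Y2c[j] = lse(Mc[j - 1], lse(X2c[j - 1], Y2c[j - 1]))
        Mp, Xp, Yp, X2p, Y2p = Mc, Xc, Yc, X2c, Y2c
    return float(lse(lse(0.0, X2p[m]), lse(Y2p[m], Mp[m])))


def la_kernel(x: str, y: str, params: LAKernelParams | None = None) -> float:
    """Local alignment kernel between two sequences.

    Sums ``exp(beta * score(pi))`` over every gapped local alignment ``pi``
    (the empty alignment contributes 1, so K >= 1), then optionally returns
    ``ln(K)/beta``.  Symmetric in (x, y).  Falls back to a log-space DP when
    intermediates overflow double precision.
    """
    params = params or LAKernelParams()
    if len(x) == 0 or len(y) == 0:
        return 0.0 if params.log_transform else 1.0
    beta = params.beta
    S = np.array(
        [[params.score(cx, cy) for cy in y] for cx in x], dtype=np.float64
    )
    bs = beta * S
    gd = math.exp(-beta * params.gap_open)
    ge = math.exp(-beta * params.gap_extend)
    K = np.inf
    if bs.max() * min(len(x), len(y)) < math.log(_OVERFLOW_LIMIT):
        K = _la_kernel_float(np.exp(bs), gd, ge)
    if not math.isfinite(K) or K > _OVERFLOW_LIMIT:
        lK = _la_kernel_log(bs, -beta * params.gap_open, -beta * params.gap_extend)
        return lK / beta if params.log_transform else math.exp(lK)
    return math.log(K) / beta if params.log_transform else K


class LocalAlignmentKernel:
    """LA kernel as a callable over sequences, with pairwise matrix helper.

    Evaluations are memoized per instance (the kernel is symmetric, so pairs
    are cached under a canonical order); repeated Gram/transform calls over
    the same sequence universe — e.g. across cross-validation folds — pay
    for each distinct pair once.
    """

    def __init__(self, params: LAKernelParams | None = None):
        self.params = params or LAKernelParams()
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        v = self._cache.get(key)
        if v is None:
            v = la_kernel(x, y, self.params)
            self._cache[key] = v
        return v

    def matrix(self, A: Sequence[str], B: Sequence[str]) -> np.ndarray:
        out = np.empty((len(A), len(B)))
        for i, a in enumerate(A):
            for j, b in enumerate(B):
                out[i, j] = self(a, b)
        return out


# ---------------------------------------------------------------------------
# Gram assembly


@dataclasses.dataclass
class GramMatrix:
    """Symmetric kernel matrix with its row/column entity ids."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("Gram matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("id list length must match matrix size")
        if v.size and np.abs(v - v.T).max() > 1e-10:
            raise ValueError("Gram matrix not symmetric to 1e-10")
        self.values = v


def gram(
    entities: Sequence,
    kernel: Callable,
    ids: Sequence[str] | None = None,
    block_size: int = 256,
) -> GramMatrix:
    """Exact symmetric Gram matrix of a pairwise kernel, assembled blockwise.

    ``kernel`` is either an element-wise callable or an object with a
    ``matrix(A, B)`` method (used per block, so peak extra memory is
    O(block_size**2) beyond the output).
    """
    n = len(entities)
    if n < 1:
        raise ValueError("need at least one entity")
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    out = np.empty((n, n))
    has_matrix = hasattr(kernel, "matrix")
    for bi in range(0, n, block_size):
        for bj in range(bi, n, block_size):
            ai = entities[bi : bi + block_size]
            aj = entities[bj : bj + block_size]
            if has_matrix:
                block = kernel.matrix(
                    np.asarray(ai) if isinstance(ai[0], np.ndarray) else ai,
                    np.asarray(aj) if isinstance(aj[0], np.ndarray) else aj,
                )
            else:
                block = np.empty((len(ai), len(aj)))
                for i, a in enumerate(ai):
                    for j, b in enumerate(aj):
                        try:
                            block[i, j] = kernel(a, b)
                        except Exception as exc:
                            raise type(exc)(
                                f"kernel failed at entities ({bi + i}, {bj + j}): {exc}"
                            ) from exc
            out[bi : bi + block.shape[0], bj : bj + block.shape[1]] = block
            if bj > bi:
                out[bj : bj + block.shape[1], bi : bi + block.shape[0]] = block.T
    out = 0.5 * (out + out.T)  # kill last-ulp asymmetry from float kernels
    return GramMatrix(out, ids)
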