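"""Non-negative PARAFAC (CP) decomposition of EEM data cubes.

An EEM study stacks into a three-way tensor X (sample x excitation x emission)
that is intrinsically trilinear: X_ijk ~ sum_f a_if b_jf c_kf, where each
component f is one fluorophore with excitation loading b_f, emission loading
c_f, and per-sample relative concentration a_if. All three modes are
constrained non-negative (intensities and spectra are physical), fitted by
alternating least squares with exact per-row NNLS subproblems, multi-start
initialization, and the scale indeterminacy resolved by unit-norm spectral
loadings with magnitudes absorbed into the scores.

Rank selection follows standard EEM practice: the core consistency diagnostic
(CORCONDIA) collapses when over-factored, and split-half analysis checks that
components refit on random sample halves agree (Tucker congruence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import nnls

from .core import EEMDataset

__all__ = [
    "ParafacModel",
    "RankSelection",
    "fit_parafac",
    "core_consistency",
    "split_half",
    "select_rank",
    "project_scores",
    "tucker_congruence",
    "match_components",
    "decimate_emission",
]

_RIDGE = 1e-12


@dataclass
class ParafacModel:
    """Fitted CP model: X_ijk ~ sum_f scores_if ex_jf em_kf.

    ``ex_loadings`` and ``em_loadings`` columns are unit-norm; all magnitude
    lives in ``sample_scores``. ``fit_error`` is the residual sum of squares
    divided by the total sum of squares (in [0, 1]).
    """

    n_components: int
    sample_scores: np.ndarray
    ex_loadings: np.ndarray
    em_loadings: np.ndarray
    fit_error: float
    n_iterations: int
    converged: bool
    fit_error_history: list[float] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return np.einsum(
            "if,jf,kf->ijk", self.sample_scores, self.ex_loadings, self.em_loadings
        )


def _nnls_rows(G: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve min_{a>=0} a G a^T - 2 a w^T per row of W via Gram-Cholesky NNLS."""
    F = G.shape[0]
    L = np.linalg.cholesky(G + _RIDGE * np.trace(G) * np.eye(F) / F)
    A = np.empty_like(W)
    At = L.T.copy()
    for i in range(W.shape[0]):
        b = solve_triangular(L, W[i], lower=True)
        A[i], _ = nnls(At, b)
    return A


def _mode_products(X, A, B, C):
    """W matrices X_(n) * khatri-rao of the other two factors, per mode."""
    WA = np.einsum("ijk,jf,kf->if", X, B, C, optimize=True)
    WB = np.einsum("ijk,if,kf->jf", X, A, C, optimize=True)
    WC = np.einsum("ijk,if,jf->kf", X, A, B, optimize=True)
    return WA, WB, WC


def _normalize(A, B, C):
    """Push factor magnitudes into the score mode A; B, C unit-norm columns."""
    nb = np.linalg.norm(B, axis=0)
    nc = np.linalg.norm(C, axis=0)
    nb[nb == 0] = 1.0
    nc[nc == 0] = 1.0
    return A * (nb * nc)[None, :], B / nb[None, :], C / nc[None, :]


def _als(X, F, rng, max_iter, tol, init=None):
    n, p, q = X.shape
    normX2 = float((X**2).sum())
    if init is None:
        A = rng.uniform(0.1, 1.0, (n, F))
        B = rng.uniform(0.1, 1.0, (p, F))
        C = rng.uniform(0.1, 1.0, (q, F))
    else:
        A, B, C = (m.copy() for m in init)
    history = []
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = np.einsum("ijk,jf,kf->if", X, B, C, optimize=True)
        A = _nnls_rows((B.T @ B) * (C.T @ C), W)
        W = np.einsum("ijk,if,kf->jf", X, A, C, optimize=True)
        B = _nnls_rows((A.T @ A) * (C.T @ C), W)
        W = np.einsum("ijk,if,jf->kf", X, A, B, optimize=True)
        C = _nnls_rows((A.T @ A) * (B.T @ B), W)
        # residual via Gram identity: ||X - Xhat||^2 = ||X||^2 - 2<X,Xhat> + ||Xhat||^2,
        # where <X,Xhat> = sum(W * C) because C was just solved against W.
        cross = float((W * C).sum())
        model2 = float(((A.T @ A) * (B.T @ B) * (C.T @ C)).sum())
        err = max(normX2 - 2.0 * cross + model2, 0.0) / max(normX2, _RIDGE)
        history.append(err)
        if prev - err < tol * max(prev, _RIDGE) and np.isfinite(prev):
            converged = True
            break
        prev = err
    return A, B, C, history, it, converged


def _hosvd_init(X, F):
    """Non-negative HOSVD-style starting point: |leading singular vectors|."""
    factors = []
    for mode in range(3):
        M = np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)
        k = min(F, min(M.shape))
        U, _, _ = np.linalg.svd(M, full_matrices=False)
        Fm = np.abs(U[:, :k]) + 1e-3
        if k < F:  # pad with uniform columns when the mode is rank-deficient
            Fm = np.hstack([Fm, np.full((M.shape[0], F - k), 1e-1)])
        factors.append(Fm)
    return tuple(factors)


def fit_parafac(
    tensor: np.ndarray,
    n_components: int,
    *,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    restart_iter: int = 60,
    seed: int = 0,
) -> ParafacModel:
    """Fit a non-negative CP model by multi-start alternating least squares.

    The first candidate starts from a non-negative HOSVD initialization
    (absolute leading singular vectors per mode); the remaining
    ``n_restarts - 1`` candidates are random. Each is screened for
    ``restart_iter`` iterations; the two best by screened fit error are
    refined until the relative fit-error change drops below ``tol`` or
    ``max_iter`` is reached, and the better refined solution is returned
    (screening rank is not a reliable predictor near degenerate basins).
    Deterministic given ``seed``.
    """
    X = np.asarray(tensor, dtype=float)
    if X.ndim != 3:
        raise ValueError(f"expected a 3-way tensor, got ndim={X.ndim}")
    if not np.all(np.isfinite(X)):
        raise ValueError("tensor contains non-finite values; preprocess first")
    F = int(n_components)
    if F < 1:
        raise ValueError("n_components must be >= 1")
    if F > min(X.shape):
        raise ValueError(
            f"n_components={F} exceeds the smallest tensor dimension {min(X.shape)}"
        )
    rng = np.random.default_rng(seed)
    cands = [_als(X, F, rng, restart_iter, tol, init=_hosvd_init(X, F))]
    for _ in range(max(1, n_restarts) - 1):
        cands.append(_als(X, F, rng, restart_iter, tol))
    cands.sort(key=lambda c: c[3][-1])
    refined = []
    for A, B, C, hist0, it0, _ in cands[:2]:
        A, B, C, hist1, it1, conv1 = _als(X, F, rng, max_iter, tol, init=(A, B, C))
        refined.append((A, B, C, hist0 + hist1, it0 + it1, conv1))
    A, B, C, history, n_iter, converged = min(refined, key=lambda c: c[3][-1])
    A, B, C = _normalize(A, B, C)
    return ParafacModel(
        n_components=F,
        sample_scores=A,
        ex_loadings=B,
        em_loadings=C,
        fit_error=history[-1],
        n_iterations=n_iter,
        converged=converged,
        fit_error_history=history,
    )


def core_consistency(model: ParafacModel, tensor: np.ndarray) -> float:
    """CORCONDIA: 100 * (1 - ||G - T||^2 / ||T||^2) for the LS Tucker core G.

    T is the superdiagonal identity core. Near 100 when the trilinear model is
    appropriate; collapses (possibly below 0) when over-factored. For F = 1 the
    core has a single element and the diagnostic is 100 by definition.
    Degenerate (rank-deficient) loadings yield NaN (failure flag) rather than
    an exception.
    """
    F = model.n_components
    if F == 1:
        return 100.0
    X = np.asarray(tensor, dtype=float)
    A, B, C = model.sample_scores, model.ex_loadings, model.em_loadings
    conds = [np.linalg.cond(M) for M in (A, B, C)]
    if not all(np.isfinite(c) and c < 1e10 for c in conds):
        warnings.warn("degenerate loadings: core consistency not defined", RuntimeWarning)
        return float("nan")
    Ap, Bp, Cp = (np.linalg.pinv(M) for M in (A, B, C))
    G = np.einsum("fi,gj,hk,ijk->fgh", Ap, Bp, Cp, X, optimize=True)
    T = np.zeros((F, F, F))
    T[np.arange(F), np.arange(F), np.arange(F)] = 1.0
    return float(100.0 * (1.0 - ((G - T) ** 2).sum() / F))


def tucker_congruence(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity between two loading vectors (1 = identical shape)."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def match_components(
    loadings_a: np.ndarray, loadings_b: np.ndarray
) -> tuple[list[tuple[int, int]], list[float]]:
    """Greedy one-to-one matching of components by Tucker congruence.

    ``loadings_a``/``loadings_b`` are (length x F) matrices (e.g. concatenated
    excitation+emission loadings). Returns matched index pairs and their
    congruences, best matches first.
    """
    Fa, Fb = loadings_a.shape[1], loadings_b.shape[1]
    sim = np.array(
        [[tucker_congruence(loadings_a[:, i], loadings_b[:, j]) for j in range(Fb)] for i in range(Fa)]
    )
    pairs, congs = [], []
    avail_a, avail_b = set(range(Fa)), set(range(Fb))
    for _ in range(min(Fa, Fb)):
        best = max(((sim[i, j], i, j) for i in avail_a for j in avail_b))
        congs.append(float(best[0]))
        pairs.append((best[1], best[2]))
        avail_a.discard(best[1])
        avail_b.discard(best[2])
    return pairs, congs


def _spectral_loadings(model: ParafacModel) -> np.ndarray:
    return np.vstack([model.ex_loadings, model.em_loadings])


def split_half(
    tensor: np.ndarray,
    n_components: int,
    *,
    n_splits: int = 3,
    seed: int = 0,
    n_restarts: int = 8,
    max_iter: int = 500,
    tol: float = 1e-8,
    restart_iter: int = 80,
) -> float:
    """Split-half similarity (%) of the spectral loadings at a given rank.

    Samples are split into random halves; a model is fit on each half; matched
    Tucker congruences on the concatenated ex+em loadings are averaged. The
    worst (minimum) similarity over ``n_splits`` random splits is returned, as
    a percentage. Deterministic given ``seed``.
    """
    X = np.asarray(tensor, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("split-half analysis needs at least 4 samples")
    rng = np.random.default_rng(seed)
    worst = np.inf
    for s in range(n_splits):
        perm = rng.permutation(n)
        halves = (perm[: n // 2], perm[n // 2 :])
        models = [
            fit_parafac(
                X[idx],
                n_components,
                n_restarts=n_restarts,
                max_iter=max_iter,
                tol=tol,
                restart_iter=restart_iter,
                seed=int(rng.integers(2**31 - 1)),
            )
            for idx in halves
        ]
        _, congs = match_components(_spectral_loadings(models[0]), _spectral_loadings(models[1]))
        worst = min(worst, 100.0 * float(np.mean(congs)))
    return worst


@dataclass
class RankSelection:
    chosen: int
    diagnostics: pd.DataFrame
    warning: bool = False


def select_rank(
    tensor: np.ndarray,
    candidates,
    *,
    split_half_min: float = 95.0,
    core_consistency_min: float = 60.0,
    seed: int = 0,
    n_splits: int = 3,
    n_restarts: int = 8,
    max_iter: int = 500,
    restart_iter: int = 80,
) -> RankSelection:
    """Rank selection over candidate component counts.

    For each candidate F the fit error, core consistency and split-half
    similarity are computed; the chosen rank is the largest F whose split-half
    similarity and core consistency both clear their thresholds. If no
    candidate qualifies, the smallest candidate is returned with a warning
    flag set.
    """
    candidates = sorted(int(f) for f in candidates)
    if not candidates:
        raise ValueError("empty candidate range")
    X = np.asarray(tensor, dtype=float)
    rows = []
    for F in candidates:
        model = fit_parafac(
            X, F, n_restarts=n_restarts, max_iter=max_iter, restart_iter=restart_iter, seed=seed + F
        )
        cc = core_consistency(model, X)
        sh = split_half(
            X,
            F,
            n_splits=n_splits,
            seed=seed + 1000 + F,
            n_restarts=n_restarts,
            max_iter=max_iter,
            restart_iter=restart_iter,
        )
        rows.append(
            {
                "n_components": F,
                "fit_error": model.fit_error,
                "core_consistency": cc,
                "split_half_similarity": sh,
            }
        )
    diag = pd.DataFrame(rows)
    ok = diag[
        (diag["split_half_similarity"] >= split_half_min)
        & (diag["core_consistency"] >= core_consistency_min)
    ]
    if len(ok):
        return RankSelection(int(ok["n_components"].max()), diag, warning=False)
    warnings.warn("no candidate rank met both diagnostics; returning the smallest", RuntimeWarning)
    return RankSelection(candidates[0], diag, warning=True)


def project_scores(model: ParafacModel, samples) -> np.ndarray:
    """Score new samples against fixed spectral loadings (non-negative LS).

    ``samples`` is an (m, n_ex, n_em) array, a single EEM matrix, or an
    :class:`~eemstress.core.EEMDataset` on the model's grid.
    """
    if isinstance(samples, EEMDataset):
        X = samples.to_tensor()
    else:
        X = np.asarray(samples, dtype=float)
        if X.ndim == 2:
            X = X[None]
    B, C = model.ex_loadings, model.em_loadings
    if X.shape[1:] != (B.shape[0], C.shape[0]):
        raise ValueError(
            f"sample shape {X.shape[1:]} does not match model grid {(B.shape[0], C.shape[0])}"
        )
    W = np.einsum("ijk,jf,kf->if", X, B, C, optimize=True)
    return _nnls_rows((B.T @ B) * (C.T @ C), W)


def decimate_emission(tensor_or_dataset, factor: int):
    """Keep every ``factor``-th emission point (desk-scale speedup for ALS)."""
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if isinstance(tensor_or_dataset, EEMDataset):
        return tensor_or_dataset.to_tensor()[:, :, ::factor]
    return np.asarray(tensor_or_dataset)[..., ::factor]
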