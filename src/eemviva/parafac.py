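"""Non-negative trilinear PARAFAC by alternating least squares.

The model approximates a 3-way array (samples x emission x excitation) as a
sum of F rank-1 trilinear components::

    x_ijk ~ sum_f a_if * b_jf * c_kf

with all factors constrained non-negative.  Under trilinearity the
decomposition is unique up to permutation and scaling, so the loading
columns estimate the pure excitation/emission spectra of the underlying
fluorophores and the scores their relative concentrations.

Each ALS step solves an exact non-negative least-squares (NNLS) problem for
one factor matrix with the other two fixed, via an active-set solver on the
Gram system (fast NNLS).  Exact per-block minimization makes the residual
sum of squares non-increasing over iterations.

Canonical form: loading columns have unit Euclidean norm, all magnitude is
carried by the scores, and components are ordered by decreasing score
energy (ties broken lexicographically on the emission loading).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Non-negative least squares
# ---------------------------------------------------------------------------

def _fnnls(ZtZ: np.ndarray, Ztx: np.ndarray, tol: float | None = None) -> np.ndarray:
    """Exact NNLS on the normal-equation (Gram) system, active-set method.

    Solves ``min_d ||Z d - x||^2  s.t. d >= 0`` given ``ZtZ = Z'Z`` and
    ``Ztx = Z'x``.  Lawson-Hanson active-set logic expressed on the Gram
    matrices; exact at termination (KKT conditions hold), not a clipped
    unconstrained solution.
    """
    n = ZtZ.shape[0]
    if tol is None:
        tol = 10 * np.finfo(float).eps * np.abs(ZtZ).max() * n
    passive = np.zeros(n, dtype=bool)
    d = np.zeros(n)
    w = Ztx - ZtZ @ d
    it, max_outer = 0, 30 * n
    while (~passive).any() and w[~passive].max(initial=-np.inf) > tol and it < max_outer:
        it += 1
        j = int(np.argmax(np.where(passive, -np.inf, w)))
        passive[j] = True
        s = np.zeros(n)
        s[passive] = _solve_spd(ZtZ[np.ix_(passive, passive)], Ztx[passive])
        while (s[passive] <= tol).any():
            neg = passive & (s <= tol)
            alpha = np.min(d[neg] / (d[neg] - s[neg]))
            d = d + alpha * (s - d)
            passive = passive & (d > tol)
            s = np.zeros(n)
            if passive.any():
                s[passive] = _solve_spd(ZtZ[np.ix_(passive, passive)], Ztx[passive])
            else:
                break
        d = s.copy()
        d[~passive] = 0.0
        w = Ztx - ZtZ @ d
    return np.maximum(d, 0.0)


def _solve_spd(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve a small symmetric positive (semi)definite system, lstsq fallback."""
    try:
        return np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(G, b, rcond=None)[0]


def nnls_solve(design: np.ndarray, targets: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Non-negative least squares for one or many right-hand sides.

    Parameters
    ----------
    design : (m, n) matrix.
    targets : (m,) vector or (m, p) matrix; each column solved independently.
    ridge : optional Tikhonov term added to the Gram matrix when the design
        is rank deficient; 0 disables the fallback.

    Returns
    -------
    (n,) or (n, p) array of non-negative coefficients, each column the exact
    minimizer of ``||design @ beta - target||^2`` over ``beta >= 0``.
    """
    design = np.asarray(design, dtype=float)
    targets = np.asarray(targets, dtype=float)
    G = design.T @ design
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    elif np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; enable the ridge fallback"
        )
    single = targets.ndim == 1
    T = targets[:, None] if single else targets
    Zt = design.T @ T
    out = np.column_stack([_fnnls(G, Zt[:, i]) for i in range(Zt.shape[1])])
    return out[:, 0] if single else out


def _nn_rows(gram: np.ndarray, mttkrp: np.ndarray, mode_name: str) -> np.ndarray:
    """Row-wise NNLS update for one ALS block.

    ``gram`` is the F x F Hadamard product of the other two factor Gram
    matrices; ``mttkrp`` the matricized-tensor-times-Khatri-Rao product
    (n_rows x F).  Rows whose unconstrained solution is already non-negative
    are accepted directly (identical to the active-set answer); the rest go
    through the exact active-set solver.
    """
    F = gram.shape[0]
    try:
        sol = np.linalg.solve(gram, mttkrp.T).T
    except np.linalg.LinAlgError:
        # expected in over-factored fits where a component collapses to zero
        logger.debug("singular Gram matrix in %s-mode update; ridge fallback", mode_name)
        sol = np.linalg.solve(gram + 1e-12 * np.trace(gram) / F * np.eye(F), mttkrp.T).T
    bad = (sol < 0).any(axis=1)
    if bad.any():
        for i in np.nonzero(bad)[0]:
            sol[i] = _fnnls(gram, mttkrp[i])
    return np.maximum(sol, 0.0)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class ParafacModel:
    """Fitted PARAFAC factors in canonical form.

    scores : (I, F) relative concentrations a_if (carry all magnitude).
    em_loadings : (J, F) unit-norm emission profiles b_jf.
    ex_loadings : (K, F) unit-norm excitation profiles c_kf.
    em_wavelengths / ex_wavelengths : optional axes for peak reporting.
    """

    F: int
    scores: np.ndarray
    em_loadings: np.ndarray
    ex_loadings: np.ndarray
    em_wavelengths: np.ndarray | None = None
    ex_wavelengths: np.ndarray | None = None

    def reconstruct(self) -> np.ndarray:
        return np.einsum("if,jf,kf->ijk", self.scores, self.em_loadings, self.ex_loadings)

    def emission_peak(self, f: int) -> float:
        """Wavelength of the emission-loading maximum of component ``f``."""
        if self.em_wavelengths is None:
            raise ValueError("model carries no emission axis")
        return float(self.em_wavelengths[int(np.argmax(self.em_loadings[:, f]))])

    def excitation_peak(self, f: int) -> float:
        if self.ex_wavelengths is None:
            raise ValueError("model carries no excitation axis")
        return float(self.ex_wavelengths[int(np.argmax(self.ex_loadings[:, f]))])

    def emission_local_maxima(self, f: int, min_rel_height: float = 0.0) -> list[float]:
        """Wavelengths of strict local maxima of an emission loading.

        ``min_rel_height`` drops maxima below that fraction of the loading's
        global maximum (filters noise ripples on flat regions).
        """
        if self.em_wavelengths is None:
            raise ValueError("model carries no emission axis")
        return local_maxima(self.em_loadings[:, f], self.em_wavelengths, min_rel_height)


@dataclass
class FitDiagnostics:
    """Fit-quality record for one PARAFAC model."""

    explained_variance_pct: float
    sse: float
    sse_trace: np.ndarray
    n_iterations: int
    converged: bool
    core_consistency_pct: float
    core: np.ndarray = field(repr=False, default=None)
    n_starts: int = 1
    start_sses: np.ndarray | None = None


def local_maxima(y: np.ndarray, x: np.ndarray, min_rel_height: float = 0.0) -> list[float]:
    """Strict local maxima of a sampled curve, endpoints included when they dominate."""
    y = np.asarray(y, dtype=float)
    floor = min_rel_height * y.max() if y.size else 0.0
    peaks = []
    for i in range(len(y)):
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < len(y) - 1 else -np.inf
        if y[i] > left and y[i] > right and y[i] >= floor:
            peaks.append(float(x[i]))
    return peaks


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _tensor_of(cube) -> np.ndarray:
    X = cube.data if hasattr(cube, "data") else np.asarray(cube, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("PARAFAC input must be a 3-way array")
    if not np.isfinite(X).all():
        raise ValueError("PARAFAC input contains non-finite values; preprocess the cube first")
    return X


def _mttkrp(X: np.ndarray, mats: tuple[np.ndarray, np.ndarray], mode: int) -> np.ndarray:
    if mode == 0:
        return np.einsum("ijk,jf,kf->if", X, *mats, optimize=True)
    if mode == 1:
        return np.einsum("ijk,if,kf->jf", X, *mats, optimize=True)
    return np.einsum("ijk,if,jf->kf", X, *mats, optimize=True)


def _als_single(X: np.ndarray, F: int, B0: np.ndarray, C0: np.ndarray,
                tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, bool]:
    ss_total = float((X ** 2).sum())
    B, C = B0.copy(), C0.copy()
    A = None
    sse_trace: list[float] = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        A = _nn_rows((B.T @ B) * (C.T @ C), _mttkrp(X, (B, C), 0), "sample")
        B = _nn_rows((A.T @ A) * (C.T @ C), _mttkrp(X, (A, C), 1), "emission")
        MC = _mttkrp(X, (A, B), 2)
        C = _nn_rows((A.T @ A) * (B.T @ B), MC, "excitation")
        # SSE via Gram identity: ||X - Xhat||^2 = ||X||^2 - 2<Xhat,X> + ||Xhat||^2
        cross = float((MC * C).sum())
        model_ss = float((((A.T @ A) * (B.T @ B)) * (C.T @ C)).sum())
        sse = max(ss_total - 2.0 * cross + model_ss, 0.0)
        sse_trace.append(sse)
        if sse <= 1e-14 * ss_total:
            converged = True
            break
        if np.isfinite(prev) and abs(prev - sse) <= tol * max(prev, np.finfo(float).tiny):
            converged = True
            break
        prev = sse
    return A, B, C, sse_trace, converged


def _svd_init(X: np.ndarray, F: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic first start: magnitudes of leading singular vectors of
    the emission and excitation unfoldings (abs to satisfy non-negativity);
    random-padded if F exceeds the unfolding rank."""
    I, J, K = X.shape

    def lead(unf: np.ndarray, n_rows: int) -> np.ndarray:
        U = np.linalg.svd(unf, full_matrices=False)[0]
        r = min(F, U.shape[1])
        M = np.abs(U[:, :r])
        if r < F:
            M = np.hstack([M, 0.1 + rng.random((n_rows, F - r))])
        return M + 1e-9  # avoid exactly-zero columns

    B = lead(X.transpose(1, 0, 2).reshape(J, I * K), J)
    C = lead(X.transpose(2, 0, 1).reshape(K, I * J), K)
    return B, C


def canonicalize(scores: np.ndarray, em: np.ndarray, ex: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-norm loadings, magnitude in scores, components by score energy."""
    A, B, C = scores.copy(), em.copy(), ex.copy()
    nb = np.linalg.norm(B, axis=0)
    nc = np.linalg.norm(C, axis=0)
    nb[nb == 0] = 1.0
    nc[nc == 0] = 1.0
    B /= nb
    C /= nc
    A *= nb * nc
    energy = (A ** 2).sum(axis=0)
    # stable ordering; break exact ties lexicographically on the emission loading
    order = sorted(range(A.shape[1]),
                   key=lambda f: (-energy[f], tuple(B[:, f])))
    return A[:, order], B[:, order], C[:, order]


def fit_parafac(cube, F: int, n_starts: int = 10, seed: int | None = 0,
                tol: float = 1e-8, max_iter: int = 2000
                ) -> tuple[ParafacModel, FitDiagnostics]:
    """Fit a non-negative F-component PARAFAC model by multi-start ALS.

    One SVD-informed start plus ``n_starts - 1`` seeded random non-negative
    starts; the lowest-SSE solution is returned in canonical form.  ALS stops
    when the relative SSE change drops below ``tol`` or after ``max_iter``
    sweeps.  Output is deterministic given (cube, F, seed, n_starts).
    """
    X = _tensor_of(cube)
    if F < 1:
        raise ValueError("F must be >= 1")
    I, J, K = X.shape
    rng = np.random.default_rng(seed)
    best = None
    start_sses = []
    for s in range(max(1, n_starts)):
        if s == 0:
            B0, C0 = _svd_init(X, F, rng)
        else:
            B0 = 0.1 + rng.random((J, F))
            C0 = 0.1 + rng.random((K, F))
        A, B, C, trace, conv = _als_single(X, F, B0, C0, tol, max_iter)
        start_sses.append(trace[-1])
        if best is None or trace[-1] < best[3][-1]:
            best = (A, B, C, trace, conv)
    A, B, C, trace, conv = best
    if not conv:
        logger.warning("PARAFAC ALS did not converge in %d iterations (F=%d)", max_iter, F)
    A, B, C = canonicalize(A, B, C)
    model = ParafacModel(
        F=F, scores=A, em_loadings=B, ex_loadings=C,
        em_wavelengths=getattr(getattr(cube, "grid", None), "em_wavelengths", None),
        ex_wavelengths=getattr(getattr(cube, "grid", None), "ex_wavelengths", None),
    )
    ev = explained_variance(model, X)
    cc, core = _corcondia_core(A, B, C, X)
    diag = FitDiagnostics(
        explained_variance_pct=ev,
        sse=trace[-1],
        sse_trace=np.asarray(trace),
        n_iterations=len(trace),
        converged=conv,
        core_consistency_pct=cc,
        core=core,
        n_starts=max(1, n_starts),
        start_sses=np.asarray(start_sses),
    )
    return model, diag


def explained_variance(model: ParafacModel, cube) -> float:
    """Percent of the raw (uncentered) total sum of squares captured by the model."""
    X = _tensor_of(cube)
    ss_total = float((X ** 2).sum())
    if ss_total == 0:
        raise ValueError("explained variance undefined for an all-zero cube")
    resid = X - model.reconstruct()
    return 100.0 * (1.0 - float((resid ** 2).sum()) / ss_total)


def _corcondia_core(A, B, C, X) -> tuple[float, np.ndarray]:
    """Least-squares Tucker core for fixed loadings, and the CORCONDIA value.

    The LS core given fixed factor matrices is the tensor contracted with
    their Moore-Penrose pseudo-inverses; CORCONDIA measures its closeness to
    the F x F x F superidentity.
    """
    Ap, Bp, Cp = (np.linalg.pinv(M) for M in (A, B, C))
    G = np.einsum("fi,gj,hk,ijk->fgh", Ap, Bp, Cp, X, optimize=True)
    F = A.shape[1]
    T = np.zeros((F, F, F))
    idx = np.arange(F)
    T[idx, idx, idx] = 1.0
    denom = float((T ** 2).sum())
    val = 100.0 * (1.0 - float(((G - T) ** 2).sum()) / denom)
    return val, G


def corcondia(model: ParafacModel, cube) -> float:
    """Core consistency diagnostic (percent) of a fitted model on a cube."""
    X = _tensor_of(cube)
    return _corcondia_core(model.scores, model.em_loadings, model.ex_loadings, X)[0]


# ---------------------------------------------------------------------------
# Component matching
# ---------------------------------------------------------------------------

def tucker_congruence(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two loading vectors (in [0,1] for non-negative ones)."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def congruence_matrix(Ma: np.ndarray, Mb: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(Ma, axis=0)
    nb = np.linalg.norm(Mb, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (Ma / na).T @ (Mb / nb)


def match_components(model_a: ParafacModel, model_b: ParafacModel,
                     mode: str = "both") -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one component matching by Tucker congruence.

    Returns ``(perm, congruences)`` where component ``f`` of ``model_a``
    is paired with component ``perm[f]`` of ``model_b``.  The assignment
    maximizes the summed congruence exactly (Hungarian algorithm, never
    greedy).  ``mode`` selects the emission loadings, excitation loadings,
    or their elementwise product ("both").
    """
    if model_a.F != model_b.F:
        raise ValueError("component counts differ; cannot match")
    Cem = congruence_matrix(model_a.em_loadings, model_b.em_loadings)
    Cex = congruence_matrix(model_a.ex_loadings, model_b.ex_loadings)
    sim = {"em": Cem, "ex": Cex, "both": Cem * Cex}[mode]
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(model_a.F, dtype=int)
    perm[rows] = cols
    return perm, sim[rows, cols][np.argsort(rows)]
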