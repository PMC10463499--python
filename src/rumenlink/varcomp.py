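"""REML variance components: heritability, microbiability and joint models.

The three linear mixed models fitted here share the form

    y = X b + u_1 + ... + u_K + e,     u_k ~ N(0, sigma2_k K_k),
    e ~ N(0, sigma2_e I)

with K_k a genetic (GRM) and/or microbial (MRM) relationship matrix:

* model 1 — GRM only: heritability h2 = sigma2_a / sigma2_p;
* model 2 — MRM only: microbiability m2 = sigma2_m / sigma2_p;
* model 3 — GRM + MRM jointly;

with sigma2_p the sum of all components.  Estimation is restricted maximum
likelihood: EM steps for the first iterations (stability far from the
optimum), then average-information (AI) Newton updates with step halving.
Components proposed negative are truncated at a small floor and, if they
stay there, fixed and flagged.  A single-kernel fast path maximizes the
profiled restricted likelihood over the variance ratio on the eigenbasis of
the kernel; it is algebraically the same optimum as the AI path.

Significance of a component is a likelihood-ratio test against the nested
model without it, with the 50:50 chi2_0/chi2_1 boundary mixture (the p-value
is half the chi2_1 tail).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .containers import RelationshipMatrix

logger = logging.getLogger("rumenlink")

LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------- design aid

def build_design(covariates: pd.DataFrame | None = None,
                 pcs: np.ndarray | None = None,
                 n: int | None = None) -> np.ndarray:
    """Fixed-effects design: intercept, one-hot factors (first level as
    reference) and continuous PC columns."""
    blocks = []
    if covariates is not None:
        n = len(covariates)
        for col in covariates.columns:
            d = pd.get_dummies(covariates[col].astype("category"), drop_first=True)
            if d.shape[1]:
                blocks.append(d.to_numpy(dtype=float))
    if pcs is not None:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        if pcs.shape[0] != (n or pcs.shape[0]):
            pcs = pcs.T
        n = pcs.shape[0]
        blocks.append(pcs)
    if n is None:
        raise ValueError("cannot infer sample size for the design matrix")
    X = np.column_stack([np.ones(n)] + blocks) if blocks else np.ones((n, 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")
    return X


# ------------------------------------------------------------------ results

@dataclass
class VarCompResult:
    """REML estimates for one model fit."""

    sigma2: dict                      # term name (+ "residual") -> estimate
    se: dict                          # approximate SEs from the AI matrix
    ratios: dict                      # term name -> sigma2 / sigma2_p
    ratio_se: dict
    logL: float
    converged: bool
    n_iter: int
    n: int
    fixed_at_zero: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    @property
    def sigma2_p(self) -> float:
        return float(sum(self.sigma2.values()))


@dataclass
class LrtResult:
    stat: float
    p_value: float


# ------------------------------------------------- restricted log-likelihood

def restricted_loglik(y: np.ndarray, X: np.ndarray, kernels: list,
                      sigma2: list) -> float:
    """Direct evaluation of the REML log-likelihood

        -0.5 [ (n-p) log 2pi + log|V| + log|X' V^-1 X| + y' P y ]

    with V = sum_k sigma2_k K_k + sigma2_e I (residual variance is the last
    element of ``sigma2``).  Serves as the independent check of the fitters.
    """
    n, p = X.shape
    V = sigma2[-1] * np.eye(n)
    for s2, K in zip(sigma2[:-1], kernels):
        V = V + s2 * K
    c = cho_factor(V, lower=True)
    logdetV = 2.0 * np.log(np.diag(c[0])).sum()
    Vi_y = cho_solve(c, y)
    Vi_X = cho_solve(c, X)
    XtViX = X.T @ Vi_X
    _, logdetXVX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return -0.5 * ((n - p) * LOG2PI + logdetV + logdetXVX + yPy)


def reml_null(y: np.ndarray, X: np.ndarray) -> VarCompResult:
    """Closed-form REML of the fixed-effects-only model y = Xb + e."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    s2 = rss / (n - p)
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    logL = -0.5 * ((n - p) * (LOG2PI + 1.0 + np.log(s2)) + logdetXtX)
    return VarCompResult(
        sigma2={"residual": s2}, se={"residual": s2 * np.sqrt(2.0 / (n - p))},
        ratios={}, ratio_se={}, logL=float(logL), converged=True, n_iter=0, n=n,
    )


# ------------------------------------------------------------------ AI-REML

def _ai_quantities(y, X, kernels_full, sigma2):
    """P, Py, per-term gradients and the AI matrix at the current point."""
    n, p = X.shape
    V = np.zeros((n, n))
    for s2, K in zip(sigma2, kernels_full):
        V += s2 * K
    c = cho_factor(V, lower=True)
    Vi = cho_solve(c, np.eye(n))
    Vi_X = Vi @ X
    XtViX = X.T @ Vi_X
    P = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
    Py = P @ y
    m = len(kernels_full)
    KPy = [K @ Py for K in kernels_full]
    grad = np.array(
        [-0.5 * (np.sum(P * K) - Py @ KPy_k) for K, KPy_k in zip(kernels_full, KPy)]
    )
    PKPy = [P @ v for v in KPy]
    AI = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            AI[i, j] = AI[j, i] = 0.5 * (KPy[i] @ PKPy[j])
    logdetV = 2.0 * np.log(np.diag(c[0])).sum()
    _, logdetXVX = np.linalg.slogdet(XtViX)
    logL = -0.5 * ((n - p) * LOG2PI + logdetV + logdetXVX + float(y @ Py))
    return grad, AI, logL, float(y @ Py), Py, KPy, P


def reml_fit(y: np.ndarray, X: np.ndarray, kernels: list,
             names: list | None = None, max_iter: int = 100,
             tol_logl: float = 1e-8, tol_param: float = 1e-6,
             n_em: int = 3, method: str = "auto",
             init: list | None = None) -> VarCompResult:
    """Fit the multi-kernel REML model.

    ``kernels`` is a list of n x n PSD matrices (or RelationshipMatrix);
    the residual identity term is implicit.  ``method`` is ``"ai"`` (general
    EM-warm-started average-information iterations), ``"eigen"`` (single
    kernel only: profiled likelihood on the kernel eigenbasis) or ``"auto"``
    (eigen when there is one kernel).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    kmats = [k.values if isinstance(k, RelationshipMatrix) else np.asarray(k, float)
             for k in kernels]
    for K in kmats:
        if K.shape != (len(y), len(y)):
            raise ValueError("kernel dimensions do not match the phenotype")
    names = names or [f"k{i}" for i in range(len(kmats))]
    if len(names) != len(kmats):
        raise ValueError("names/kernels length mismatch")
    n, p = X.shape
    if n <= p + len(kmats):
        raise ValueError("too few observations for the requested model")
    if method == "auto":
        method = "eigen" if len(kmats) == 1 else "ai"
    if method == "eigen":
        if len(kmats) != 1:
            raise ValueError("eigen path requires exactly one kernel")
        return _reml_fit_eigen(y, X, kmats[0], names[0])
    return _reml_fit_ai(y, X, kmats, names, max_iter, tol_logl, tol_param, n_em, init)


def _finalize(y, X, kernels, names, sigma2, logL, converged, n_iter,
              fixed_mask, floor):
    m = len(kernels)
    full = kernels + [np.eye(len(y))]
    grad, AI, logL_f, *_ = _ai_quantities(y, X, full, list(sigma2))
    se = np.full(m + 1, np.nan)
    active = [i for i in range(m + 1) if not (i < m and fixed_mask[i])]
    try:
        cov = np.linalg.inv(AI[np.ix_(active, active)])
        for pos, i in enumerate(active):
            se[i] = np.sqrt(max(cov[pos, pos], 0.0))
    except np.linalg.LinAlgError:
        cov = None
    s2p = float(np.sum(sigma2))
    sigma2_rep = [0.0 if (i < m and fixed_mask[i]) or sigma2[i] <= 1.5 * floor
                  else float(sigma2[i]) for i in range(m + 1)]
    # residual never reported as hard zero
    sigma2_rep[-1] = float(sigma2[-1])
    s2p_rep = float(np.sum(sigma2_rep))
    ratios = {names[i]: sigma2_rep[i] / s2p_rep for i in range(m)}
    ratio_se = {}
    for i in range(m):
        if cov is not None and i in active:
            # delta method for sigma2_i / sigma2_p
            gvec = np.full(len(active), -sigma2[i] / s2p**2)
            gvec[active.index(i)] += 1.0 / s2p
            ratio_se[names[i]] = float(np.sqrt(max(gvec @ cov @ gvec, 0.0)))
        else:
            ratio_se[names[i]] = np.nan
    notes = []
    for i, K in enumerate(kernels):
        scale = np.mean(np.diag(K))
        if scale > 0 and np.max(np.abs(K - scale * np.eye(len(y)))) < 1e-10:
            notes.append(f"term {names[i]} proportional to identity: non-identifiable")
    return VarCompResult(
        sigma2={**{names[i]: sigma2_rep[i] for i in range(m)},
                "residual": sigma2_rep[-1]},
        se={**{names[i]: float(se[i]) for i in range(m)}, "residual": float(se[-1])},
        ratios=ratios, ratio_se=ratio_se, logL=float(logL_f),
        converged=converged, n_iter=n_iter, n=len(y),
        fixed_at_zero=[names[i] for i in range(m) if fixed_mask[i]],
        notes=notes,
    )


def _try_loglik(y, X, kernels, sigma2):
    """Restricted logL, or -inf when V is not positive definite (possible for
    indefinite kernels such as the Yang GRM at small n)."""
    try:
        return restricted_loglik(y, X, kernels, sigma2)
    except np.linalg.LinAlgError:
        return -np.inf


def _reml_fit_ai(y, X, kernels, names, max_iter, tol_logl, tol_param, n_em, init):
    n, p = X.shape
    m = len(kernels)
    vy = float(np.var(y, ddof=1))
    floor = 1e-6 * vy
    full = kernels + [np.eye(n)]
    sigma2 = np.array(init, dtype=float) if init is not None else np.full(
        m + 1, vy / (m + 1)
    )
    sigma2 = np.maximum(sigma2, floor)
    fixed = np.zeros(m, dtype=bool)
    clamp_count = np.zeros(m, dtype=int)
    logL_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, AI, logL, yPy, Py, KPy, P = _ai_quantities(y, X, full, list(sigma2))
        if it > 1 and abs(logL - logL_prev) < tol_logl:
            converged = True
            break
        old = sigma2.copy()
        if it <= n_em:
            # EM update: sigma2_k' = sigma2_k + sigma2_k^2 (y'PKPy - tr(PK))/n
            cand = sigma2.copy()
            for i in range(m + 1):
                if i < m and fixed[i]:
                    continue
                tr_pk = np.sum(P * full[i])
                cand[i] = sigma2[i] + sigma2[i] ** 2 * ((Py @ KPy[i]) - tr_pk) / n
            cand = np.maximum(cand, floor)
            for _ in range(12):  # back off toward the old point if V loses PD
                if np.isfinite(_try_loglik(y, X, kernels, list(cand))):
                    sigma2 = cand
                    break
                cand = 0.5 * (cand + old)
        else:
            active = [i for i in range(m + 1) if not (i < m and fixed[i])]
            ai_a = AI[np.ix_(active, active)]
            try:
                delta = np.linalg.solve(ai_a, grad[active])
            except np.linalg.LinAlgError:
                delta = grad[active] / max(np.trace(ai_a) / len(active), 1e-12)
            step = 1.0
            for _ in range(12):
                cand = sigma2.copy()
                for pos, i in enumerate(active):
                    cand[i] = sigma2[i] + step * delta[pos]
                cand = np.maximum(cand, floor)
                cand_logL = _try_loglik(y, X, kernels, list(cand))
                if cand_logL >= logL - 1e-10:
                    sigma2 = cand
                    break
                step *= 0.5
        sigma2 = np.maximum(sigma2, floor)
        for i in range(m):
            if sigma2[i] <= floor * 1.0000001:
                clamp_count[i] += 1
                if clamp_count[i] >= 2:
                    fixed[i] = True
            else:
                clamp_count[i] = 0
        logL_prev = logL
        if np.max(np.abs(sigma2 - old)) < tol_param * max(vy, 1e-12):
            converged = True
            break
    if not converged:
        logger.warning("AI-REML did not converge in %d iterations", max_iter)
    return _finalize(y, X, kernels, names, sigma2, logL_prev, converged, it,
                     fixed, floor)


# ------------------------------------------------------------- eigen path

def _reml_fit_eigen(y, X, K, name, evals=None, evecs=None):
    """Single-kernel REML by profiling the restricted likelihood over the
    variance ratio h2 = sigma2_k / (sigma2_k + sigma2_e) on the eigenbasis
    of K."""
    n, p = X.shape
    if evals is None:
        evals, evecs = np.linalg.eigh(K)
    ystar = evecs.T @ y
    Xstar = evecs.T @ X
    d = evals
    # keep V = h2*K + (1-h2)*I positive definite: the kernel may be
    # indefinite (the Yang GRM at small n), which caps the feasible ratio
    d_min = float(d.min())
    h2_hi = 1.0 - 1e-9
    if d_min < 1.0:
        h2_hi = min(h2_hi, (1.0 - 1e-6) / (1.0 - d_min))

    def profiled(h2):
        w = h2 * d + (1.0 - h2)
        w = np.maximum(w, 1e-12)
        Xw = Xstar / w[:, None]
        XtWX = Xstar.T @ Xw
        XtWy = Xw.T @ ystar
        beta = np.linalg.solve(XtWX, XtWy)
        yPy = float(ystar @ (ystar / w) - XtWy @ beta)
        _, logdetXWX = np.linalg.slogdet(XtWX)
        s2 = yPy / (n - p)
        logL = -0.5 * (
            (n - p) * (LOG2PI + 1.0 + np.log(s2))
            + np.log(w).sum()
            + logdetXWX
        )
        return logL, s2

    res = optimize.minimize_scalar(
        lambda h: -profiled(h)[0], bounds=(0.0, h2_hi), method="bounded",
        options={"xatol": 1e-10},
    )
    candidates = [0.0, float(res.x)]
    best_h2 = max(candidates, key=lambda h: profiled(h)[0])
    logL, s2p = profiled(best_h2)
    sigma2 = np.array([best_h2 * s2p, (1.0 - best_h2) * s2p])
    floor = 1e-6 * float(np.var(y, ddof=1))
    fixed = np.array([best_h2 <= 1e-8])
    return _finalize(y, X, [K], [name], sigma2, logL, True, int(res.nfev),
                     fixed, floor)


# ----------------------------------------------------------------- wrappers

def estimate_h2(y, X, G, method: str = "auto", **kwargs) -> VarCompResult:
    """Model 1: y = Xb + a + e with a ~ N(0, G sigma2_a)."""
    return reml_fit(y, X, [G], names=["genetic"], method=method, **kwargs)


def estimate_m2(y, X, M, method: str = "auto", **kwargs) -> VarCompResult:
    """Model 2: y = Xb + m + e with m ~ N(0, M sigma2_m)."""
    return reml_fit(y, X, [M], names=["microbial"], method=method, **kwargs)


def estimate_joint(y, X, G, M, **kwargs) -> VarCompResult:
    """Model 3: y = Xb + a + m + e with both relationship matrices."""
    return reml_fit(y, X, [G, M], names=["genetic", "microbial"],
                    method="ai", **kwargs)


def lrt(full: VarCompResult, reduced: VarCompResult) -> LrtResult:
    """Boundary-corrected LRT of one variance component.

    stat = max(0, 2 (logL_full - logL_reduced)); p = 0.5 P(chi2_1 >= stat),
    the 50:50 mixture appropriate for a parameter tested on the boundary.
    """
    diff = full.logL - reduced.logL
    if diff < -1e-6:
        raise RuntimeError(
            f"full-model logL ({full.logL:.6f}) below reduced ({reduced.logL:.6f}); "
            "optimization failure"
        )
    stat = max(0.0, 2.0 * diff)
    p = 0.5 * float(stats.chi2.sf(stat, df=1))
    if stat == 0.0:
        p = 0.5
    return LrtResult(stat=stat, p_value=min(max(p, np.nextafter(0, 1)), 1.0))


# -------------------------------------------------------------- trait scans

def feature_h2_scan(features, X, G, alpha: float = 0.05) -> pd.DataFrame:
    """Model-1 REML per microbial feature against the GRM.

    ``features`` is a MicrobialFeatureSet (or anything with
    ``trait_columns()``).  Binary traits are analysed on the observed 0/1
    scale.  Constant features are skipped with a warning.  The kernel is
    eigendecomposed once and reused across features.
    """
    G_vals = G.values if isinstance(G, RelationshipMatrix) else np.asarray(G, float)
    evals, evecs = np.linalg.eigh(G_vals)
    rows = []
    for name, cls, vec in features.trait_columns():
        vec = np.asarray(vec, dtype=float)
        ok = np.isfinite(vec)
        if vec[ok].std() == 0 or ok.sum() < X.shape[1] + 3:
            logger.warning("feature %s constant or too sparse; skipped", name)
            continue
        if not ok.all():
            yv, Xv = vec[ok], X[ok]
            fit = reml_fit(yv, Xv, [G_vals[np.ix_(ok.nonzero()[0], ok.nonzero()[0])]],
                           names=["genetic"], method="eigen")
            null = reml_null(yv, Xv)
        else:
            fit = _reml_fit_eigen(vec, X, G_vals, "genetic", evals=evals, evecs=evecs)
            null = reml_null(vec, X)
        test = lrt(fit, null)
        rows.append(
            {
                "feature": name,
                "class": cls,
                "h2": fit.ratios["genetic"],
                "se": fit.ratio_se["genetic"],
                "logL": fit.logL,
                "lrt_stat": test.stat,
                "lrt_p": test.p_value,
                "heritable": test.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)
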