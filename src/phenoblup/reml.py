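"""Multi-kernel linear mixed models: REML estimation and BLUP.

The engine behind every model in the package: pedigree/genomic/spectral
hybrid prediction (an intercept plus GCA and SCA random effects, each
with its own relationship kernel), the per-wavelength spatial
adjustment of spectra, and the bivariate across-trial polygenic model
used for the heritability decomposition.

The model is

    y = X beta + sum_k Z_k u_k + e,
    u_k ~ N(0, C_k sigma2_k),   e ~ N(0, I sigma2_e),

with C_k an arbitrary (PSD) covariance over the levels of effect k.
Variance components are estimated by average-information REML with
EM-like fallback steps and step halving, so the restricted
log-likelihood never decreases over accepted iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .errors import ConfigurationError, ConvergenceError, KeyedError, StructuralError
from .kernels import KernelMatrix


@dataclass
class RandomEffect:
    """One random term: an observation->level map plus a covariance.

    ``levels`` gives, per observation, the level id of this effect
    (e.g. the dent parent of each hybrid).  ``kernel`` is the
    relationship matrix over levels; ``None`` means i.i.d. levels
    (identity covariance), as used for field rows and columns.
    """

    name: str
    levels: list
    kernel: KernelMatrix | None = None

    def level_ids(self) -> list:
        return list(dict.fromkeys(self.levels))

    def obs_covariance(self) -> np.ndarray:
        """G_k = Z C Z' over the observations."""
        if self.kernel is None:
            lev = np.asarray(self.levels, dtype=object)
            return (lev[:, None] == lev[None, :]).astype(float)
        return self.kernel.submatrix(list(self.levels))


@dataclass
class FittedModel:
    """REML solution: variance components, fixed effects, and BLUPs."""

    beta: np.ndarray
    varcomp: dict[str, float]
    blup: dict[str, dict]
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)
    # internals needed for out-of-sample prediction
    effects: list[RandomEffect] = field(default_factory=list)
    X: np.ndarray | None = None
    Py: np.ndarray | None = None

    @property
    def mu(self) -> float:
        """GLS intercept (first fixed-effect coefficient)."""
        return float(self.beta[0])

    @property
    def sigma2_e(self) -> float:
        return self.varcomp["residual"]


def _reml_pieces(y, X, V):
    """(loglik, P, Py) for a given covariance V."""
    c = cho_factor(V, lower=True)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    Vi = cho_solve(c, np.eye(len(y)))
    ViX = Vi @ X
    XtViX = X.T @ ViX
    cx = cho_factor((XtViX + XtViX.T) / 2.0, lower=True)
    logdetX = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
    P = Vi - ViX @ cho_solve(cx, ViX.T)
    P = (P + P.T) / 2.0
    Py = P @ y
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return ll, P, Py


def restricted_loglik(
    y: np.ndarray,
    effects: list[RandomEffect],
    sigma2: dict[str, float],
    X: np.ndarray | None = None,
) -> float:
    """Restricted log-likelihood at given variance components.

    Exposed so callers (and tests) can profile the likelihood surface
    independently of the optimizer.
    """
    y = np.asarray(y, float)
    X = np.ones((len(y), 1)) if X is None else np.asarray(X, float)
    V = np.eye(len(y)) * sigma2["residual"]
    for eff in effects:
        V = V + sigma2[eff.name] * eff.obs_covariance()
    ll, _, _ = _reml_pieces(y, X, V)
    return ll


def fit_reml(
    y,
    effects: list[RandomEffect],
    X: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> FittedModel:
    """Estimate variance components by AI-REML and return BLUPs.

    Observations with missing ``y`` are dropped row-wise.  The fixed
    part defaults to an intercept.  Convergence requires both
    ``|delta logREML| < tol`` and a relative parameter change below
    1e-6; the accepted iterate sequence is monotone in the restricted
    likelihood (AI steps are halved toward an EM-like update whenever
    they would decrease it or leave the admissible region).
    """
    y = np.asarray(y, dtype=float)
    names = [e.name for e in effects]
    if len(set(names)) != len(names):
        raise StructuralError(f"duplicate effect names: {names}")
    for e in effects:
        if len(e.levels) != len(y):
            raise StructuralError(
                f"effect {e.name!r} maps {len(e.levels)} observations, "
                f"expected {len(y)}"
            )

    keep = ~np.isnan(y)
    if not keep.all():
        y = y[keep]
        effects = [
            RandomEffect(e.name, [l for l, k in zip(e.levels, keep) if k], e.kernel)
            for e in effects
        ]
        if X is not None:
            X = np.asarray(X, float)[keep]
    n = len(y)
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if n < X.shape[1] + 2:
        raise ConfigurationError(
            f"n = {n} observations cannot support {X.shape[1]} fixed "
            "parameters plus variance estimation"
        )

    G = [e.obs_covariance() for e in effects]
    K = len(G)
    vary = float(np.var(y, ddof=1)) if n > 1 else 0.0

    # degenerate data: nothing to decompose
    if vary < 1e-14:
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        vc = {nm: 0.0 for nm in names}
        vc["residual"] = 0.0
        blup = {e.name: {lev: 0.0 for lev in e.level_ids()} for e in effects}
        return FittedModel(
            beta, vc, blup, loglik=np.inf, converged=True, n_iter=0,
            effects=effects, X=X, Py=np.zeros(n),
        )

    floor = max(1e-10 * vary, 1e-12)
    theta = np.full(K + 1, vary / (K + 1.0))  # [..effects.., residual]

    def build_V(th):
        V = np.eye(n) * th[-1]
        for k in range(K):
            V = V + th[k] * G[k]
        return V

    def loglik(th):
        try:
            ll, P, Py = _reml_pieces(y, X, build_V(th))
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        return ll, P, Py

    ll, P, Py = loglik(theta)
    if not np.isfinite(ll):
        raise ConvergenceError("restricted likelihood undefined at start", trace=[])

    trace = [(0, ll, theta.copy())]
    converged = False
    it = 0
    stall = 0  # consecutive iterations with sub-tolerance loglik change
    for it in range(1, max_iter + 1):
        # score and average-information matrix
        W = [G[k] @ Py for k in range(K)] + [Py]
        score = np.empty(K + 1)
        for k in range(K + 1):
            Gk = G[k] if k < K else np.eye(n)
            score[k] = -0.5 * (float(np.sum(P * Gk)) - float(Py @ W[k]))
        PW = [P @ w for w in W]
        AI = 0.5 * np.array(
            [[float(W[a] @ PW[b]) for b in range(K + 1)] for a in range(K + 1)]
        )

        # EM-like fallback direction (always admissible after flooring)
        em = theta + theta**2 * np.array(
            [(float(Py @ W[k]) - float(np.sum(P * (G[k] if k < K else np.eye(n)))))
             for k in range(K + 1)]
        ) / n

        # active set: components pinned at the floor whose score pushes
        # them further down stay fixed; they otherwise poison the AI step
        free = ~((theta <= floor * 1.5) & (score < 0))
        delta = np.zeros(K + 1)
        if free.any():
            try:
                AIf = AI[np.ix_(free, free)]
                ridge = 1e-8 * max(np.trace(AIf) / free.sum(), 1.0)
                delta[free] = np.linalg.solve(
                    AIf + ridge * np.eye(int(free.sum())), score[free]
                )
            except np.linalg.LinAlgError:
                delta = em - theta
        else:
            delta = em - theta

        new = None
        for direction in (delta, em - theta):
            step = 1.0
            for _ in range(12):
                cand = np.maximum(theta + step * direction, floor)
                ll_c, P_c, Py_c = loglik(cand)
                if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                    new = (cand, ll_c, P_c, Py_c)
                    break
                step *= 0.5
            if new is not None:
                break
        if new is None:
            # no admissible improvement in any direction: treat as stationary
            converged = True
            break

        cand, ll_new, P, Py = new
        rel = float(np.max(np.abs(cand - theta) / np.maximum(theta, floor)))
        d_ll = ll_new - ll
        theta, ll = cand, ll_new
        trace.append((it, ll, theta.copy()))
        stall = stall + 1 if abs(d_ll) < tol else 0
        # a flat likelihood ridge can leave parameters drifting while the
        # criterion is numerically maximized; three stalled steps suffice
        if abs(d_ll) < tol and (rel < 1e-6 or stall >= 3):
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations "
            f"(last |delta logREML| = {abs(d_ll):.3e})",
            trace=trace,
        )

    # GLS fixed effects and BLUPs at the solution
    V = build_V(theta)
    c = cho_factor(V, lower=True)
    ViX = cho_solve(c, X)
    XtViX = X.T @ ViX
    beta = np.linalg.solve((XtViX + XtViX.T) / 2.0, ViX.T @ y)
    resid_proj = cho_solve(c, y - X @ beta)  # V^{-1}(y - X beta) == Py

    varcomp = {nm: float(theta[k]) for k, nm in enumerate(names)}
    varcomp["residual"] = float(theta[-1])
    blup = {}
    for k, e in enumerate(effects):
        lev = e.level_ids()
        if e.kernel is None:
            lev_arr = np.asarray(e.levels, dtype=object)
            Zt = (np.asarray(lev, dtype=object)[:, None] == lev_arr[None, :]).astype(float)
            u = theta[k] * Zt @ resid_proj
        else:
            u = theta[k] * e.kernel.submatrix(lev, list(e.levels)) @ resid_proj
        blup[e.name] = dict(zip(lev, u.astype(float)))

    return FittedModel(
        beta=beta,
        varcomp=varcomp,
        blup=blup,
        loglik=float(ll),
        converged=True,
        n_iter=it,
        trace=trace,
        effects=effects,
        X=X,
        Py=resid_proj,
    )


def predict(
    fm: FittedModel,
    new_levels: dict[str, list],
    X_new: np.ndarray | None = None,
) -> np.ndarray:
    """BLUP prediction for new observations.

    ``new_levels`` maps each effect name to the level id of every new
    observation (effects omitted contribute nothing, i.e. their new
    levels are assumed unrelated to training).  The prediction is

        yhat = X_new beta + sum_k sigma2_k C_k(new, train) Z_k' Vinv r,

    with r the training residual y - X beta.
    """
    sizes = {len(v) for v in new_levels.values()}
    if len(sizes) != 1:
        raise StructuralError("new_levels entries have inconsistent lengths")
    m = sizes.pop()
    X_new = np.ones((m, 1)) if X_new is None else np.asarray(X_new, float)
    pred = X_new @ fm.beta
    known = {e.name: e for e in fm.effects}
    for name, levels in new_levels.items():
        if name not in known:
            raise KeyedError(f"model has no effect named {name!r}", keys=[name])
        e = known[name]
        s2 = fm.varcomp[name]
        if e.kernel is None:
            train = np.asarray(e.levels, dtype=object)
            C = (np.asarray(levels, dtype=object)[:, None] == train[None, :]).astype(float)
        else:
            C = e.kernel.submatrix(list(levels), list(e.levels))
        pred = pred + s2 * C @ fm.Py
    return np.asarray(pred, float)


# ---------------------------------------------------------------------------
# Bivariate across-trial polygenic model
# ---------------------------------------------------------------------------

@dataclass
class BivariateComponents:
    """Variance components of the two-trial polygenic model.

    var(u) = [[s2_u1, s_u12], [s_u12, s2_u2]] (x) K  (PSD by
    construction), var(e) = diag(s2_e1, s2_e2) (x) I.
    """

    sigma2_u1: float
    sigma2_u2: float
    sigma_u12: float
    sigma2_e1: float
    sigma2_e2: float
    loglik: float = np.nan
    converged: bool = True

    def genetic_matrix(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_u1, self.sigma_u12], [self.sigma_u12, self.sigma2_u2]]
        )


def _sigma_from_params(p):
    l11, l21, l22 = np.exp(p[0]), p[1], np.exp(p[2])
    e1, e2 = np.exp(p[3]), np.exp(p[4])
    return l11 * l11, l11 * l21, l21 * l21 + l22 * l22, e1, e2


def _bivariate_negloglik_eig(p, y1t, y2t, ones1t, ones2t, d):
    """Balanced-design restricted likelihood via the eigenbasis of K.

    With both trials observing the same genotypes, rotating each trial
    by the eigenvectors of K block-diagonalizes V into 2x2 blocks per
    eigenvalue, making every likelihood evaluation O(n).
    """
    s11, s12, s22, e1, e2 = _sigma_from_params(p)
    a = s11 * d + e1  # V11 per eigen-index
    b = s22 * d + e2
    c = s12 * d
    det = a * b - c * c
    if np.any(det <= 0) or np.any(a <= 0):
        return 1e12
    logdetV = float(np.sum(np.log(det)))
    # V^{-1} blocks: [b, -c; -c, a] / det
    ia, ib, ic = b / det, a / det, -c / det
    # X columns in the rotated basis: (ones1t, 0) and (0, ones2t)
    xtvx11 = float(np.sum(ia * ones1t**2))
    xtvx22 = float(np.sum(ib * ones2t**2))
    xtvx12 = float(np.sum(ic * ones1t * ones2t))
    detx = xtvx11 * xtvx22 - xtvx12**2
    if detx <= 0:
        return 1e12
    viy1 = ia * y1t + ic * y2t
    viy2 = ic * y1t + ib * y2t
    xtvy1 = float(np.sum(ones1t * viy1))
    xtvy2 = float(np.sum(ones2t * viy2))
    beta1 = (xtvx22 * xtvy1 - xtvx12 * xtvy2) / detx
    beta2 = (xtvx11 * xtvy2 - xtvx12 * xtvy1) / detx
    r1 = y1t - beta1 * ones1t
    r2 = y2t - beta2 * ones2t
    quad = float(np.sum(r1 * (ia * r1 + ic * r2) + r2 * (ic * r1 + ib * r2)))
    return 0.5 * (logdetV + np.log(detx) + quad)


def _bivariate_negloglik(p, y, X, K11, K22, K12, n1):
    s11, s12, s22, e1, e2 = _sigma_from_params(p)
    n = len(y)
    V = np.empty((n, n))
    V[:n1, :n1] = s11 * K11 + e1 * np.eye(n1)
    V[n1:, n1:] = s22 * K22 + e2 * np.eye(n - n1)
    V[:n1, n1:] = s12 * K12
    V[n1:, :n1] = s12 * K12.T
    try:
        ll, _, _ = _reml_pieces(y, X, V)
    except np.linalg.LinAlgError:
        return 1e12
    if not np.isfinite(ll):
        return 1e12
    return -ll


def fit_bivariate(
    y1,
    y2,
    genotypes1,
    genotypes2,
    K: KernelMatrix,
    tol: float = 1e-9,
) -> BivariateComponents:
    """REML fit of the bivariate (two-trial) polygenic model.

    ``y1``/``y2`` are per-trial phenotypes (e.g. absorbance at one
    wavelength) for genotypes ``genotypes1``/``genotypes2``, all present
    in ``K``.  Fixed effects are the trial means.  The 2x2 genetic
    covariance is parameterized by its Cholesky factor, so the estimate
    is PSD by construction; per-trial residual variances are
    log-parameterized.  Optimization is a deterministic Nelder-Mead
    start-ed from moment estimates.
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    if len(y1) == 0 or len(y2) == 0:
        raise ConfigurationError(
            "one trial has no observations; fit the univariate model instead"
        )
    g1, g2 = list(genotypes1), list(genotypes2)
    if not set(g1) & set(g2):
        raise StructuralError(
            "trials share no genotype; the genetic covariance is not estimable"
        )
    balanced = g1 == g2
    if balanced:
        K11 = K.submatrix(g1)
        d, U = np.linalg.eigh(K11)
        d = np.clip(d, 0.0, None)
        args = (U.T @ y1, U.T @ y2, U.T @ np.ones(len(y1)), U.T @ np.ones(len(y2)), d)
        negloglik, extra = _bivariate_negloglik_eig, args
    else:
        K11 = K.submatrix(g1)
        K22 = K.submatrix(g2)
        K12 = K.submatrix(g1, g2)
        n1 = len(y1)
        y = np.concatenate([y1, y2])
        X = np.zeros((len(y), 2))
        X[:n1, 0] = 1.0
        X[n1:, 1] = 1.0
        negloglik, extra = _bivariate_negloglik, (y, X, K11, K22, K12, n1)

    v1 = max(float(np.var(y1, ddof=1)), 1e-12)
    v2 = max(float(np.var(y2, ddof=1)), 1e-12)
    l11 = np.sqrt(v1 / 2.0)
    l22 = np.sqrt(v2 / 2.0)
    starts = [
        np.array([np.log(l11), 0.0, np.log(l22), np.log(v1 / 2), np.log(v2 / 2)]),
        np.array(
            [np.log(l11), 0.8 * l22, np.log(0.6 * l22), np.log(v1 / 2), np.log(v2 / 2)]
        ),
    ]
    best = None
    for p0 in starts:
        res = optimize.minimize(
            negloglik,
            p0,
            args=extra,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": tol, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    p = best.x
    l11, l21, l22 = np.exp(p[0]), p[1], np.exp(p[2])
    comp = BivariateComponents(
        sigma2_u1=float(l11 * l11),
        sigma2_u2=float(l21 * l21 + l22 * l22),
        sigma_u12=float(l11 * l21),
        sigma2_e1=float(np.exp(p[3])),
        sigma2_e2=float(np.exp(p[4])),
        loglik=-float(best.fun),
        converged=bool(best.success and np.isfinite(best.fun)),
    )
    return comp


def yamada_decomposition(b: BivariateComponents) -> dict[str, float]:
    """Across-trial genetic / GxE / residual variances (Yamada).

    sigma2_G = sigma_u12;  sigma2_GxE = (sigma2_u1 + sigma2_u2)/2 -
    sigma_u12;  sigma2_e = (sigma2_e1 + sigma2_e2)/2.  Proportions of
    their total are included; a negative genetic covariance yields a
    negative sigma2_G, reported as-is (proportions are then clipped to
    [0, 1] only for reporting).
    """
    s_g = b.sigma_u12
    s_gxe = 0.5 * (b.sigma2_u1 + b.sigma2_u2) - b.sigma_u12
    s_e = 0.5 * (b.sigma2_e1 + b.sigma2_e2)
    total = s_g + s_gxe + s_e
    out = {"sigma2_G": s_g, "sigma2_GxE": s_gxe, "sigma2_e": s_e}
    if total > 0:
        for key, val in list(out.items()):
            out["prop" + key[6:]] = val / total
    else:  # degenerate: no variance at all
        for key in list(out.items()):
            out["prop" + key[0][6:]] = np.nan
    return out
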