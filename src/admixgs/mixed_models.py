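"""Animal-model machinery: BLUP via Henderson's equations and REML
variance components.

The working model is the standard animal model

    y = X b + Z a + e,    a ~ N(0, G sigma_g^2),   e ~ N(0, I sigma_e^2),

where G is *any* additive relationship matrix (pedigree A, genomic,
linkage-IBD or single-step H) — the matrix is the only thing that differs
between the evaluation models compared here. ``solve_mme`` returns BLUE
fixed effects and BLUP breeding values for every individual in the
relationship matrix, phenotyped or not. ``reml`` estimates variance
components by restricted maximum likelihood using average-information
steps with step-halving (the log-likelihood never decreases across
accepted iterations); a bivariate version with genetic covariance
structure A (x) G0 and trait-specific residuals covers the two-test
analysis, and ``lrt`` performs boundary-corrected likelihood-ratio tests
for variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla, stats

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "MMEResult",
    "REMLResult",
    "solve_mme",
    "reml",
    "reml_bivariate",
    "lrt",
    "build_design",
]


@dataclass
class ModelSpec:
    """What to fit: response column, fixed-effect columns, options.

    Fixed-effect columns with non-float dtype are treated as factors
    (dummy-coded); float columns enter as covariates. ``family_effect``
    adds a random common-environment effect of full-sib family.
    """

    response: str
    fixed_effects: list = field(default_factory=list)
    family_effect: bool = False


@dataclass
class VarianceComponents:
    """Univariate or bivariate variance components.

    Univariate: sigma_g2 / sigma_e2 (+ h2). Bivariate: G0 (2x2 genetic
    covariance, PSD), residual variances per trait with zero residual
    covariance, genetic correlation.
    """

    sigma_g2: float | None = None
    sigma_e2: float | None = None
    sigma_f2: float | None = None          # common-environment family variance
    G0: np.ndarray | None = None
    resid: np.ndarray | None = None
    se: dict = field(default_factory=dict)

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2 + (self.sigma_f2 or 0.0)
        return self.sigma_g2 / tot

    @property
    def genetic_correlation(self) -> float:
        g = self.G0
        return g[0, 1] / np.sqrt(g[0, 0] * g[1, 1])


@dataclass
class MMEResult:
    beta: np.ndarray
    beta_names: list
    ebv: pd.DataFrame      # id, ebv
    method: str
    model_tag: str = ""


@dataclass
class REMLResult:
    vc: VarianceComponents
    loglik: float
    converged: bool
    n_iter: int
    trajectory: list
    components: tuple = ()
    boundary: bool = False


# ---------------------------------------------------------------------------
# design matrices


def build_design(table: pd.DataFrame, spec: ModelSpec):
    """Design matrix for the fixed effects: intercept + dummy-coded factors
    (first level dropped) + float covariates."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    for f in spec.fixed_effects:
        col = table[f]
        if pd.api.types.is_float_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(f)
        else:
            levels = pd.unique(col)
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{f}[{lev}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"fixed effects are confounded (rank {rank} < {X.shape[1]}); a "
            "minimum-norm generalized inverse is used and only estimable "
            "functions of the fixed effects are meaningful")
    return X, names


def _records(table: pd.DataFrame, spec: ModelSpec, ids):
    """Rows with a phenotype and a relationship-matrix entry, plus Z."""
    id_set = set(np.asarray(ids).tolist())
    sub = table[table[spec.response].notna() & table["id"].isin(id_set)]
    if len(sub) == 0:
        raise ValueError("no usable records")
    lookup = pd.Series(np.arange(len(ids)), index=ids)
    z_ix = lookup.loc[sub["id"]].to_numpy()
    return sub.reset_index(drop=True), z_ix


# ---------------------------------------------------------------------------
# BLUP


def solve_mme(spec: ModelSpec, table: pd.DataFrame, relmat,
              vc: VarianceComponents, method: str = "auto",
              model_tag: str = "") -> MMEResult:
    """Henderson's mixed-model equations at fixed variance components.

    EBVs are returned for every individual in the relationship matrix,
    including those without phenotypes. ``method`` is 'mme' (needs an
    invertible G), 'gls' (the equivalent V-based route that never inverts
    G), or 'auto' (mme with gls fallback).
    """
    if vc.sigma_g2 is None or vc.sigma_e2 is None or vc.sigma_e2 <= 0:
        raise ValueError("univariate variance components required")
    sub, z_ix = _records(table, spec, relmat.ids)
    y = sub[spec.response].to_numpy(dtype=float)
    X, names = build_design(sub, spec)
    G = relmat.values
    n_ind = relmat.n
    sg2, se2 = float(vc.sigma_g2), float(vc.sigma_e2)

    if sg2 <= 0:  # complete shrinkage limit
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        ebv = np.zeros(n_ind)
        return MMEResult(beta, names, pd.DataFrame({"id": relmat.ids, "ebv": ebv}),
                         "shrinkage-limit", model_tag)

    def _gls():
        Gzz = G[np.ix_(z_ix, z_ix)]
        V = sg2 * Gzz + se2 * np.eye(len(y))
        cf = sla.cho_factor(V, check_finite=False)
        ViX = sla.cho_solve(cf, X, check_finite=False)
        Viy = sla.cho_solve(cf, y, check_finite=False)
        beta = np.linalg.pinv(X.T @ ViX) @ (X.T @ Viy)
        resid = Viy - ViX @ beta
        ebv = sg2 * (G[:, z_ix] @ resid)
        return beta, ebv, "gls"

    def _mme():
        lam = se2 / sg2
        # Cholesky guards against a silently near-singular G (e.g. a GRM
        # built from fewer markers than individuals)
        np.linalg.cholesky(G)
        Gi = np.linalg.inv(G)
        nz = len(y)
        Z = np.zeros((nz, n_ind))
        Z[np.arange(nz), z_ix] = 1.0
        top = np.hstack([X.T @ X, X.T @ Z])
        bot = np.hstack([Z.T @ X, Z.T @ Z + lam * Gi])
        lhs = np.vstack([top, bot])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
        return sol[:X.shape[1]], sol[X.shape[1]:], "mme"

    if method == "gls":
        beta, ebv, used = _gls()
    elif method == "mme":
        beta, ebv, used = _mme()
    else:
        try:
            beta, ebv, used = _mme()
        except np.linalg.LinAlgError:
            beta, ebv, used = _gls()
    if not np.all(np.isfinite(ebv)):
        raise ValueError("non-finite EBVs; check the relationship matrix")
    return MMEResult(beta, names,
                     pd.DataFrame({"id": relmat.ids, "ebv": ebv}), used, model_tag)


# ---------------------------------------------------------------------------
# REML: general dense AI engine


def _profile(y, X, V):
    """REML log-likelihood pieces for a given V: (loglik, P, Py)."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    C = XtVi @ X
    sign, logdet_c = np.linalg.slogdet(C)
    Ci = np.linalg.pinv(C)
    P = Vi - XtVi.T @ Ci @ XtVi
    Py = P @ y
    sign_v, logdet_v = np.linalg.slogdet(V)
    ll = -0.5 * (logdet_v + logdet_c + y @ Py)
    return ll, P, Py


def _reml_ai_dense(y, X, Ks, names, start, lower, tol=1e-8, max_iter=200,
                   psd_group=None):
    """AI-REML over V = sum_k theta_k K_k with monotone step-halving.

    ``lower`` gives per-parameter floors (-inf for covariances);
    ``psd_group`` optionally names indices (i11, i12, i22) kept jointly PSD
    by eigenvalue clipping. Returns (theta, loglik, AI, trajectory,
    converged, n_iter, boundary_flag).
    """
    theta = np.asarray(start, dtype=float)
    lower = np.asarray(lower, dtype=float)
    k = len(Ks)

    def _V(th):
        V = th[0] * Ks[0]
        for j in range(1, k):
            V = V + th[j] * Ks[j]
        return V

    def _project(th):
        th = np.maximum(th, lower)
        if psd_group is not None:
            i11, i12, i22 = psd_group
            G0 = np.array([[th[i11], th[i12]], [th[i12], th[i22]]])
            w, Q = np.linalg.eigh(G0)
            if w.min() < 0:
                G0 = Q @ np.diag(np.maximum(w, 1e-8 * max(w.max(), 1e-12))) @ Q.T
                th[i11], th[i12], th[i22] = G0[0, 0], G0[0, 1], G0[1, 1]
        return th

    theta = _project(theta)
    ll, P, Py = _profile(y, X, _V(theta))
    traj = [(theta.copy(), ll)]
    converged = False
    AI = np.eye(k)
    it = 0
    for it in range(1, max_iter + 1):
        score = np.empty(k)
        q = []
        for j in range(k):
            KPy = Ks[j] @ Py
            q.append(KPy)
            score[j] = -0.5 * (np.sum(P * Ks[j]) - Py @ KPy)
        AI = np.empty((k, k))
        Pq = [P @ qj for qj in q]
        for a_ in range(k):
            for b_ in range(a_, k):
                AI[a_, b_] = AI[b_, a_] = 0.5 * (q[a_] @ Pq[b_])
        try:
            step = np.linalg.solve(AI + 1e-12 * np.eye(k), score)
        except np.linalg.LinAlgError:
            step = score / max(np.abs(np.diag(AI)).max(), 1.0)

        accepted = False
        for _ in range(30):
            cand = _project(theta + step)
            try:
                ll_new, P_new, Py_new = _profile(y, X, _V(cand))
            except np.linalg.LinAlgError:
                ll_new = -np.inf
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        delta = np.max(np.abs(cand - theta) / (np.abs(theta) + 1.0))
        theta, ll, P, Py = cand, ll_new, P_new, Py_new
        traj.append((theta.copy(), ll))
        if delta < tol:
            converged = True
            break
    boundary = bool(np.any(np.isclose(theta, lower, atol=1e-12) & np.isfinite(lower)))
    return theta, ll, AI, traj, converged, it, boundary


def _reml_eigen(y, X, K, tol=1e-8, max_iter=200):
    """Fast univariate AI-REML via eigen-rotation of K = Z G Z'.

    One O(n^3) decomposition, then O(n) per iteration. Same contract as
    the dense engine for V = sg2 K + se2 I.
    """
    n = len(y)
    S, U = np.linalg.eigh(K)
    S = np.maximum(S, 0.0)
    yt, Xt = U.T @ y, U.T @ X
    vy = y.var()
    floor = 1e-10 * vy
    theta = np.array([0.5 * vy, 0.5 * vy])

    def pieces(th):
        v = th[0] * S + th[1]
        if v.min() <= 0:
            raise np.linalg.LinAlgError
        vi = 1.0 / v
        XtVi = Xt.T * vi
        C = XtVi @ Xt
        Ci = np.linalg.pinv(C)
        _, logdet_c = np.linalg.slogdet(C)
        beta = Ci @ (XtVi @ yt)
        r = yt - Xt @ beta
        Py = vi * r
        ll = -0.5 * (np.log(v).sum() + logdet_c + yt @ Py)
        return ll, vi, Py, Xt.T * vi, Ci

    def P_dot(vec, vi, XtVi, Ci):
        return vi * vec - XtVi.T @ (Ci @ (XtVi @ vec))

    ll, vi, Py, XtVi, Ci = pieces(theta)
    traj = [(theta.copy(), ll)]
    converged = False
    AI = np.eye(2)
    it = 0
    for it in range(1, max_iter + 1):
        q = [S * Py, Py]
        # tr(P K) = tr(V^-1 K) - tr(C^-1 X'V^-1 K V^-1 X), K diagonal here
        M = XtVi @ XtVi.T          # X'V^-2 X
        Ms = (XtVi * S) @ XtVi.T   # X'V^-1 diag(S) V^-1 X
        trPK = [float(vi @ S) - float(np.sum(Ms * Ci.T)),
                float(vi.sum()) - float(np.sum(M * Ci.T))]
        score = np.array([-0.5 * (trPK[j] - Py @ q[j]) for j in range(2)])
        Pq = [P_dot(qj, vi, XtVi, Ci) for qj in q]
        AI = 0.5 * np.array([[q[a] @ Pq[b] for b in range(2)] for a in range(2)])
        try:
            step = np.linalg.solve(AI + 1e-12 * np.eye(2), score)
        except np.linalg.LinAlgError:
            step = score / max(abs(AI[0, 0]), 1.0)
        accepted = False
        for _ in range(30):
            cand = np.maximum(theta + step, [floor, floor])
            try:
                out = pieces(cand)
            except np.linalg.LinAlgError:
                out = None
            if out is not None and out[0] >= ll - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        delta = np.max(np.abs(cand - theta) / (np.abs(theta) + 1.0))
        theta = cand
        ll, vi, Py, XtVi, Ci = out
        traj.append((theta.copy(), ll))
        if delta < tol:
            converged = True
            break
    boundary = bool(np.any(theta <= floor * (1 + 1e-6)))
    return theta, ll, AI, traj, converged, it, boundary


def _family_incidence(sub: pd.DataFrame, pedigree: pd.DataFrame):
    ped = pedigree.set_index("id")
    fams = [(ped.loc[i, "sire"], ped.loc[i, "dam"]) for i in sub["id"]]
    codes = pd.Series(fams).astype("category").cat.codes.to_numpy()
    W = np.zeros((len(sub), codes.max() + 1))
    W[np.arange(len(sub)), codes] = 1.0
    return W


def reml(spec: ModelSpec, table: pd.DataFrame, relmat,
         pedigree: pd.DataFrame | None = None, tol: float = 1e-8,
         max_iter: int = 200) -> REMLResult:
    """Univariate REML for the animal model.

    Uses the eigen-rotation fast path for the plain model; adding a
    common-environment family effect (``spec.family_effect``, requires
    ``pedigree``) switches to the dense multi-component engine. Variances
    are floored at 1e-10 x phenotypic variance; hitting the floor is
    flagged as a boundary estimate. Standard errors come from the inverse
    average-information matrix.
    """
    sub, z_ix = _records(table, spec, relmat.ids)
    y = sub[spec.response].to_numpy(dtype=float)
    n = len(y)
    X, _ = build_design(sub, spec)
    if n <= X.shape[1] + 1:
        raise ValueError("too few records for the fixed effects")
    K = relmat.values[np.ix_(z_ix, z_ix)]

    if spec.family_effect:
        if pedigree is None:
            raise ValueError("family_effect requires the pedigree")
        W = _family_incidence(sub, pedigree)
        vy = y.var()
        Ks = [K, W @ W.T, np.eye(n)]
        theta, ll, AI, traj, conv, it, boundary = _reml_ai_dense(
            y, X, Ks, ("g", "fam", "e"),
            start=[vy / 3] * 3, lower=[1e-10 * vy] * 3,
            tol=tol, max_iter=max_iter)
        sg2, sf2, se2 = theta
        comps = ("genetic", "family", "residual")
    else:
        theta, ll, AI, traj, conv, it, boundary = _reml_eigen(
            y, X, K, tol=tol, max_iter=max_iter)
        sg2, se2 = theta
        sf2 = None
        comps = ("genetic", "residual")

    try:
        cov = np.linalg.inv(AI)
        se = {c: float(np.sqrt(max(cov[i, i], 0.0)))
              for i, c in enumerate(comps)}
        # delta-method SE of h2 (plain model only)
        if sf2 is None:
            tot = sg2 + se2
            grad = np.array([se2, -sg2]) / tot**2
            se["h2"] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se = {}
    if not conv:
        warnings.warn(f"REML did not converge in {it} iterations; "
                      "see trajectory")
    vc = VarianceComponents(sigma_g2=float(sg2), sigma_e2=float(se2),
                            sigma_f2=None if sf2 is None else float(sf2),
                            se=se)
    return REMLResult(vc, float(ll), conv, it, traj, comps, boundary)


def reml_bivariate(spec1: ModelSpec, spec2: ModelSpec, table: pd.DataFrame,
                   relmat, tol: float = 1e-8, max_iter: int = 200) -> REMLResult:
    """Bivariate animal model with genetic covariance A (x) G0 and
    trait-specific residual variances (zero residual covariance).

    The two responses may live on disjoint individuals (the two-test
    design) or overlap. If one trait has no records the fit degenerates to
    the univariate model for the other; the cross-components are NaN.
    """
    sub1, z1 = _records(table, spec1, relmat.ids)
    try:
        sub2, z2 = _records(table, spec2, relmat.ids)
    except ValueError:
        sub2, z2 = None, None
    if sub2 is None or len(sub2) == 0:
        uni = reml(spec1, table, relmat, tol=tol, max_iter=max_iter)
        G0 = np.array([[uni.vc.sigma_g2, np.nan], [np.nan, np.nan]])
        vc = VarianceComponents(G0=G0, resid=np.array([uni.vc.sigma_e2, np.nan]))
        return REMLResult(vc, uni.loglik, uni.converged, uni.n_iter,
                          uni.trajectory, ("G0_11", "e1"), uni.boundary)

    y = np.concatenate([sub1[spec1.response].to_numpy(dtype=float),
                        sub2[spec2.response].to_numpy(dtype=float)])
    X1, _ = build_design(sub1, spec1)
    X2, _ = build_design(sub2, spec2)
    n1, n2 = len(sub1), len(sub2)
    X = np.zeros((n1 + n2, X1.shape[1] + X2.shape[1]))
    X[:n1, :X1.shape[1]] = X1
    X[n1:, X1.shape[1]:] = X2

    A = relmat.values
    A11 = A[np.ix_(z1, z1)]
    A12 = A[np.ix_(z1, z2)]
    A22 = A[np.ix_(z2, z2)]
    n = n1 + n2
    K11 = np.zeros((n, n)); K11[:n1, :n1] = A11
    K22 = np.zeros((n, n)); K22[n1:, n1:] = A22
    K12 = np.zeros((n, n)); K12[:n1, n1:] = A12; K12[n1:, :n1] = A12.T
    D1 = np.zeros((n, n)); D1[:n1, :n1] = np.eye(n1)
    D2 = np.zeros((n, n)); D2[n1:, n1:] = np.eye(n2)

    v1 = sub1[spec1.response].var()
    v2 = sub2[spec2.response].var()
    start = [0.4 * v1, 0.0, 0.4 * v2, 0.6 * v1, 0.6 * v2]
    lower = [1e-10 * v1, -np.inf, 1e-10 * v2, 1e-10 * v1, 1e-10 * v2]
    theta, ll, AI, traj, conv, it, boundary = _reml_ai_dense(
        y, X, [K11, K12, K22, D1, D2], ("g11", "g12", "g22", "e1", "e2"),
        start=start, lower=lower, tol=tol, max_iter=max_iter,
        psd_group=(0, 1, 2))
    comps = ("G0_11", "G0_12", "G0_22", "e1", "e2")
    try:
        cov = np.linalg.inv(AI)
        se = {c: float(np.sqrt(max(cov[i, i], 0.0))) for i, c in enumerate(comps)}
        # delta-method SE of the genetic correlation
        g11, g12, g22 = theta[0], theta[1], theta[2]
        r = g12 / np.sqrt(g11 * g22)
        grad = np.array([-0.5 * r / g11, 1.0 / np.sqrt(g11 * g22),
                         -0.5 * r / g22, 0.0, 0.0])
        se["rg"] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se = {}
    if not conv:
        warnings.warn(f"bivariate REML did not converge in {it} iterations")
    vc = VarianceComponents(
        G0=np.array([[theta[0], theta[1]], [theta[1], theta[2]]]),
        resid=np.array([theta[3], theta[4]]), se=se)
    return REMLResult(vc, float(ll), conv, it, traj, comps, boundary)


def lrt(full: REMLResult, reduced: REMLResult, df: int = 1,
        boundary: bool = True):
    """Likelihood-ratio test of nested REML fits.

    For a single variance component tested on its boundary the reference
    distribution is the 50:50 mixture of chi-square(0) and chi-square(df);
    otherwise a plain chi-square(df). Returns (statistic, p-value).
    """
    if not set(reduced.components) < set(full.components):
        raise ValueError("models are not nested (component sets)")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if stat == 0.0:
        return 0.0, 1.0
    p = stats.chi2.sf(stat, df)
    if boundary:
        p = 0.5 * p
    return float(stat), float(min(p, 1.0))
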