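"""Multivariate multilevel random-effects meta-regression with BLUPs.

The second stage treats each region's 4-vector of cumulative curve
coefficients as a noisy observation of a mean structure driven by
region-level meta-predictors (mean temperature, temperature IQR, share of
population aged 80+), with its known first-stage sampling covariance S_i,
a country-level random effect shared by all regions of a country, and an
optional region-level random effect:

    eta_i ~ N(X_i beta,  S_i + Psi_region + Psi_country(shared in country))

Variance components are estimated by REML.  The country structure makes
the marginal covariance block-diagonal by country, which the likelihood
exploits.  The unstructured 4x4 covariances are parameterized through the
log-Cholesky factorization (positive definite by construction) and
optimized by BFGS; the fixed effects follow by generalized least squares.

Best linear unbiased predictions (BLUPs) shrink each region's first-stage
curve toward the meta-regression prediction in proportion to its sampling
uncertainty, via the exact conditional-normal formula within each country
block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_solve, solve_triangular

from .first_stage import ReducedAssoc

__all__ = [
    "MetaModel",
    "Blup",
    "MetaData",
    "fit_meta",
    "fit_meta_core",
    "blup",
    "blups_to_frame",
    "frame_to_blups",
    "wald_test",
    "heterogeneity_stats",
]

PREDICTOR_COLUMNS = ("temp_mean", "temp_iqr", "pct_80plus")


# ---------------------------------------------------------------------------
# data marshalling


@dataclass
class MetaData:
    """Stacked inputs of one meta-regression (one stratum)."""

    y: np.ndarray  # (n, k) outcomes
    S: np.ndarray  # (n, k, k) within-region covariances
    X: np.ndarray  # (n, q) predictor design incl. intercept, original scale
    groups: np.ndarray  # (n,) country labels
    region_ids: list[str]
    predictor_names: tuple[str, ...]


def build_meta_data(
    reduced: list[ReducedAssoc],
    regions: pd.DataFrame,
    predictors: tuple[str, ...] = PREDICTOR_COLUMNS,
) -> MetaData:
    meta = regions.set_index("region_id")
    y, S, X, groups, ids = [], [], [], [], []
    for r in reduced:
        if r.region_id not in meta.index:
            raise KeyError(f"region {r.region_id} has no predictor row")
        row = meta.loc[r.region_id]
        y.append(r.eta)
        S.append(r.sigma)
        X.append([1.0, *[float(row[p]) for p in predictors]])
        groups.append(row["country_id"])
        ids.append(r.region_id)
    return MetaData(
        y=np.asarray(y),
        S=np.asarray(S),
        X=np.asarray(X),
        groups=np.asarray(groups),
        region_ids=ids,
        predictor_names=predictors,
    )


# ---------------------------------------------------------------------------
# log-Cholesky parameterization


def _ltri_size(k: int) -> int:
    return k * (k + 1) // 2


def _theta_to_psi(theta: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[idx]) if i == j else theta[idx]
            idx += 1
    return L @ L.T


def _psi_to_theta(psi: np.ndarray) -> np.ndarray:
    k = psi.shape[0]
    L = np.linalg.cholesky(psi + 1e-10 * np.eye(k))
    out = []
    for i in range(k):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# REML machinery (country-blockwise)


def _country_blocks(data: MetaData) -> list[dict]:
    """Precompute per-country index sets and stacked designs (theta-free)."""
    k = data.y.shape[1]
    out = []
    for g in pd.unique(data.groups):
        idx = np.flatnonzero(data.groups == g)
        out.append(
            {
                "idx": idx,
                "Xb": np.kron(data.X[idx], np.eye(k)),
                "yb": data.y[idx].ravel(),
                "S": data.S[idx],
            }
        )
    return out


def _group_blocks(blocks: list[dict]) -> list[dict]:
    """Batch country blocks of equal size for vectorized linear algebra."""
    by_m: dict[int, list[dict]] = {}
    for b in blocks:
        by_m.setdefault(b["idx"].size, []).append(b)
    groups = []
    for m, bs in by_m.items():
        groups.append(
            {
                "m": m,
                "Xb": np.stack([b["Xb"] for b in bs]),  # (B, m*k, q*k)
                "yb": np.stack([b["yb"] for b in bs]),  # (B, m*k)
                "S": np.stack([b["S"] for b in bs]),  # (B, m, k, k)
            }
        )
    return groups


def _fast_reml_pieces(
    groups: list[dict], psi_c: np.ndarray, psi_r: np.ndarray, k: int
):
    """Batched computation of (A, rhs, logdetV, cache) over country groups.

    ``cache`` holds per-group (Xb, yb, Zx, Zy) with Z = V^-1 [Xb | yb] so
    the residual quadratic form can be evaluated after the GLS solve
    without another factorization (and without cancellation-prone
    algebraic shortcuts).
    """
    qk = groups[0]["Xb"].shape[2]
    A = np.zeros((qk, qk))
    rhs = np.zeros(qk)
    logdetV = 0.0
    cache = []
    for g in groups:
        B, m = g["Xb"].shape[0], g["m"]
        V = np.tile(psi_c[None, :, :], (B, m, m))  # (B, m*k, m*k)
        Sd = g["S"] + psi_r  # (B, m, k, k)
        for a in range(m):
            V[:, a * k : (a + 1) * k, a * k : (a + 1) * k] += Sd[:, a]
        L = np.linalg.cholesky(V)  # raises LinAlgError if not PD
        logdetV += float(2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum())
        rhs_all = np.concatenate([g["Xb"], g["yb"][:, :, None]], axis=2)
        Z = np.linalg.solve(V, rhs_all)  # (B, mk, qk+1)
        Zx, Zy = Z[:, :, :-1], Z[:, :, -1]
        A += np.einsum("bij,bik->jk", g["Xb"], Zx)
        rhs += np.einsum("bij,bi->j", g["Xb"], Zy)
        cache.append((g["Xb"], g["yb"], Zx, Zy))
    return A, rhs, logdetV, cache


def _rss_from_cache(cache: list, bhat: np.ndarray) -> float:
    """r' V^-1 r summed over blocks, using Z = V^-1 [Xb | yb]."""
    rss = 0.0
    for Xb, yb, Zx, Zy in cache:
        r = yb - np.einsum("bij,j->bi", Xb, bhat)
        Vinv_r = Zy - np.einsum("bij,j->bi", Zx, bhat)
        rss += float(np.einsum("bi,bi->", r, Vinv_r))
    return rss


def _block_cov(block: dict, psi_c: np.ndarray, psi_r: np.ndarray, k: int) -> np.ndarray:
    m = block["idx"].size
    V = np.tile(psi_c, (m, m))
    for a in range(m):
        V[a * k : (a + 1) * k, a * k : (a + 1) * k] += block["S"][a] + psi_r
    return V


def _gls_pieces(
    data: MetaData,
    psi_c: np.ndarray,
    psi_r: np.ndarray,
    blocks: list[dict],
):
    """Blockwise GLS: returns (bhat, vcov_b, logdetV, rss, logdetA, solves).

    ``solves`` caches per-block Cholesky pieces for reuse in BLUPs.
    """
    k = data.y.shape[1]
    q = data.X.shape[1]
    A = np.zeros((q * k, q * k))
    rhs = np.zeros(q * k)
    logdetV = 0.0
    chols = []
    for block in blocks:
        V = _block_cov(block, psi_c, psi_r, k)
        try:
            C = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular marginal covariance block") from exc
        logdetV += 2.0 * np.log(np.diag(C)).sum()
        CiX = solve_triangular(C, block["Xb"], lower=True, check_finite=False)
        Ciy = solve_triangular(C, block["yb"], lower=True, check_finite=False)
        A += CiX.T @ CiX
        rhs += CiX.T @ Ciy
        chols.append((block, C))
    bhat = np.linalg.solve(A, rhs)
    sign, logdetA = np.linalg.slogdet(A)
    rss = 0.0
    solves = []
    for block, C in chols:
        r = block["yb"] - block["Xb"] @ bhat
        Vinv_r = cho_solve((C, True), r, check_finite=False)
        rss += float(r @ Vinv_r)
        solves.append((block, C, r, Vinv_r))
    return bhat, np.linalg.inv(A), logdetV, rss, logdetA, solves


def _reml_nll(
    theta: np.ndarray,
    data: MetaData,
    groups: list[dict],
    k: int,
    use_region_level: bool,
) -> float:
    t = _ltri_size(k)
    psi_c = _theta_to_psi(theta[:t], k)
    psi_r = _theta_to_psi(theta[t : 2 * t], k) if use_region_level else np.zeros((k, k))
    try:
        A, rhs, logdetV, cache = _fast_reml_pieces(groups, psi_c, psi_r, k)
        bhat = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return 1e12
    sign, logdetA = np.linalg.slogdet(A)
    rss = _rss_from_cache(cache, bhat)
    n_eff = data.y.size - data.X.shape[1] * k
    return 0.5 * (n_eff * np.log(2 * np.pi) + logdetV + logdetA + rss)


@dataclass
class MetaModel:
    """Fitted multilevel meta-regression for one stratum."""

    beta: np.ndarray  # (q, k) fixed effects, original predictor scale
    vcov_beta: np.ndarray  # (q*k, q*k) covariance of vec(beta) (row-major)
    psi_country: np.ndarray
    psi_region: np.ndarray
    reml_loglik: float
    predictor_names: tuple[str, ...]
    standardization: tuple[np.ndarray, np.ndarray]  # (means, sds) of predictors
    data: MetaData
    fit_meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.beta.shape[1]

    def predict(self, x_row: np.ndarray) -> np.ndarray:
        """Fixed-effect prediction for one predictor row (with intercept)."""
        return np.asarray(x_row) @ self.beta


def fit_meta_core(
    data: MetaData,
    use_region_level: bool = False,
    fix_psi: np.ndarray | None = None,
    max_iter: int = 500,
    gtol: float = 1e-5,
) -> MetaModel:
    """REML fit on already-standardized (or raw) stacked inputs.

    ``fix_psi`` skips optimization and evaluates at the given country-level
    covariance (used for degenerate/oracle checks).
    """
    n, k = data.y.shape
    q = data.X.shape[1]
    if len(pd.unique(data.groups)) < 2 and fix_psi is None:
        raise ValueError("need at least two countries to estimate country effects")
    if np.linalg.matrix_rank(data.X) < q:
        raise ValueError("meta-predictor design is rank deficient")
    blocks = _country_blocks(data)
    t = _ltri_size(k)

    if fix_psi is not None:
        psi_c = np.asarray(fix_psi, dtype=float)
        psi_r = np.zeros((k, k))
        bhat, vcov_b, logdetV, rss, logdetA, _ = _gls_pieces(data, psi_c, psi_r, blocks)
        n_eff = data.y.size - q * k
        ll = -0.5 * (n_eff * np.log(2 * np.pi) + logdetV + logdetA + rss)
        return MetaModel(
            beta=bhat.reshape(q, k),
            vcov_beta=vcov_b,
            psi_country=psi_c,
            psi_region=psi_r,
            reml_loglik=ll,
            predictor_names=data.predictor_names,
            standardization=(np.zeros(q - 1), np.ones(q - 1)),
            data=data,
            fit_meta={"fixed": True},
        )

    # start at a fraction of the marginal residual covariance
    Sbar = data.S.mean(axis=0)
    resid = data.y - data.X @ np.linalg.lstsq(data.X, data.y, rcond=None)[0]
    start_cov = np.cov(resid.T) if n > k else np.eye(k)
    start_cov = 0.5 * start_cov + 0.1 * Sbar + 1e-6 * np.eye(k)
    theta0 = _psi_to_theta(start_cov)
    if use_region_level:
        theta0 = np.concatenate([theta0, _psi_to_theta(0.5 * start_cov)])

    trace: list[float] = []
    groups = _group_blocks(blocks)

    def obj(th: np.ndarray) -> float:
        return _reml_nll(th, data, groups, k, use_region_level)

    # bounds keep the log-Cholesky diagonal finite: the lower bound is a
    # numerically-zero variance, i.e. the PSD boundary of the parameter space
    bounds = []
    for block in range(2 if use_region_level else 1):
        for i in range(k):
            for j in range(i + 1):
                bounds.append((-12.0, 4.0) if i == j else (-10.0, 10.0))
    res = optimize.minimize(
        obj,
        theta0,
        method="L-BFGS-B",
        jac="3-point",
        bounds=bounds,
        options={"maxiter": max_iter, "maxfun": 200_000, "gtol": gtol, "ftol": 1e-12},
        callback=lambda xk: trace.append(obj(xk)),
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    at_bound = any(
        np.isclose(x, b[0]) or np.isclose(x, b[1]) for x, b in zip(res.x, bounds)
    )
    polished = False
    if not res.success and not at_bound and grad_norm > 100 * gtol:
        # line searches stall once finite-difference gradient noise dominates;
        # a derivative-free polish settles the remaining distance
        nm = optimize.minimize(
            obj, res.x, method="Nelder-Mead",
            options={"maxiter": 400 * res.x.size, "fatol": 1e-10, "xatol": 1e-8},
        )
        if nm.fun <= res.fun + 1e-8:
            res = nm
            polished = True
        else:
            raise RuntimeError(
                f"meta-regression REML did not converge: {res.message} "
                f"(last gradient max-norm {grad_norm:.2e})"
            )
    psi_c = _theta_to_psi(res.x[:t], k)
    psi_r = _theta_to_psi(res.x[t : 2 * t], k) if use_region_level else np.zeros((k, k))
    bhat, vcov_b, *_ = _gls_pieces(data, psi_c, psi_r, blocks)
    return MetaModel(
        beta=bhat.reshape(q, k),
        vcov_beta=vcov_b,
        psi_country=psi_c,
        psi_region=psi_r,
        reml_loglik=-float(res.fun),
        predictor_names=data.predictor_names,
        standardization=(np.zeros(q - 1), np.ones(q - 1)),
        data=data,
        fit_meta={
            "n_iter": int(res.nit),
            "grad_norm": grad_norm,
            "objective_trace": trace,
            "polished": polished,
            "success": bool(res.success) or polished or grad_norm <= 50 * gtol,
        },
    )


def fit_meta(
    reduced: list[ReducedAssoc],
    regions: pd.DataFrame,
    predictors: tuple[str, ...] = PREDICTOR_COLUMNS,
    use_region_level: bool = False,
    standardize: bool = True,
    **kwargs,
) -> MetaModel:
    """Pool reduced associations; predictors are z-scored internally for
    conditioning and the fixed effects reported on the original scale."""
    data = build_meta_data(reduced, regions, predictors)
    q = data.X.shape[1]
    k = data.y.shape[1]
    if standardize:
        means = data.X[:, 1:].mean(axis=0)
        sds = data.X[:, 1:].std(axis=0)
        sds[sds == 0] = 1.0
    else:
        means, sds = np.zeros(q - 1), np.ones(q - 1)
    Xs = data.X.copy()
    Xs[:, 1:] = (Xs[:, 1:] - means) / sds
    sdata = MetaData(
        y=data.y, S=data.S, X=Xs, groups=data.groups,
        region_ids=data.region_ids, predictor_names=data.predictor_names,
    )
    model = fit_meta_core(sdata, use_region_level=use_region_level, **kwargs)

    # back-transform beta and its covariance to the original predictor scale:
    # design rows satisfy [1, x] = [1, z] @ Binv with B below, so beta_orig = B beta_std
    B = np.eye(q)
    B[0, 1:] = -means / sds
    for j in range(1, q):
        B[j, j] = 1.0 / sds[j - 1]
    T = np.kron(B, np.eye(k))
    beta_orig = B @ model.beta
    vcov_orig = T @ model.vcov_beta @ T.T
    return MetaModel(
        beta=beta_orig,
        vcov_beta=vcov_orig,
        psi_country=model.psi_country,
        psi_region=model.psi_region,
        reml_loglik=model.reml_loglik,
        predictor_names=predictors,
        standardization=(means, sds),
        data=data,
        fit_meta=model.fit_meta,
    )


# ---------------------------------------------------------------------------
# BLUPs


@dataclass
class Blup:
    region_id: str
    stratum: str
    coef: np.ndarray
    vcov: np.ndarray


def blup(model: MetaModel, stratum: str = "total") -> list[Blup]:
    """Per-region shrunken curves via the conditional-normal formula.

    coef_i = X_i beta + Cov(u_c + v_i, y_c) V_c^{-1} (y_c - X_c beta); the
    covariance adds the conditional variance of the random effects and the
    fixed-effect uncertainty.
    """
    data = model.data
    k = model.k
    psi_c, psi_r = model.psi_country, model.psi_region
    blocks = _country_blocks(data)
    bvec = model.beta.ravel()
    from scipy.linalg import cho_factor

    out: dict[int, Blup] = {}
    for block in blocks:
        idx = block["idx"]
        m = idx.size
        V = _block_cov(block, psi_c, psi_r, k)
        cf = cho_factor(V, lower=True)
        r = block["yb"] - block["Xb"] @ bvec
        Vinv_r = cho_solve(cf, r)
        for a_pos, i in enumerate(idx):
            Ci = np.tile(psi_c, (1, m)).copy()
            Ci[:, a_pos * k : (a_pos + 1) * k] += psi_r
            coef = data.X[i] @ model.beta + Ci @ Vinv_r
            cond_var = (psi_c + psi_r) - Ci @ cho_solve(cf, Ci.T)
            Xi = np.kron(data.X[i][None, :], np.eye(k))
            vcov = cond_var + Xi @ model.vcov_beta @ Xi.T
            vcov = 0.5 * (vcov + vcov.T)
            out[i] = Blup(region_id=data.region_ids[i], stratum=stratum, coef=coef, vcov=vcov)
    return [out[i] for i in range(len(data.region_ids))]


def blups_to_frame(blups: list[Blup]) -> pd.DataFrame:
    """Flatten BLUPs to a table (vcov as its upper triangle)."""
    iu = np.triu_indices(4)
    rows = []
    for b in blups:
        row = {"region_id": b.region_id, "stratum": b.stratum}
        row.update({f"coef{j + 1}": b.coef[j] for j in range(4)})
        row.update({f"vcov_{a + 1}{c + 1}": b.vcov[a, c] for a, c in zip(*iu)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_blups(df: pd.DataFrame) -> list[Blup]:
    """Inverse of :func:`blups_to_frame` (CSV round trip)."""
    iu = np.triu_indices(4)
    out = []
    for _, row in df.iterrows():
        vcov = np.zeros((4, 4))
        for a, c in zip(*iu):
            vcov[a, c] = vcov[c, a] = row[f"vcov_{a + 1}{c + 1}"]
        out.append(
            Blup(
                region_id=str(row["region_id"]),
                stratum=str(row["stratum"]),
                coef=np.array([row[f"coef{j + 1}"] for j in range(4)]),
                vcov=vcov,
            )
        )
    return out


# ---------------------------------------------------------------------------
# inference on the pooled model


def wald_test(model: MetaModel, which_predictors: tuple[str, ...]) -> tuple[float, int, float]:
    """Wald chi-square test that the named meta-predictor rows are zero."""
    if len(which_predictors) == 0:
        raise ValueError("empty predictor selection")
    names = ("intercept",) + tuple(model.predictor_names)
    rows = []
    for p in which_predictors:
        if p not in names:
            raise KeyError(f"unknown predictor {p!r}; have {names}")
        rows.append(names.index(p))
    k = model.k
    sel = np.concatenate([np.arange(r * k, (r + 1) * k) for r in rows])
    b = model.beta.ravel()[sel]
    V = model.vcov_beta[np.ix_(sel, sel)]
    stat = float(b @ np.linalg.solve(V, b))
    dof = sel.size
    return stat, dof, float(stats.chi2.sf(stat, dof))


def heterogeneity_stats(model: MetaModel) -> tuple[float, int, float]:
    """Multivariate Cochran Q and I-squared at the fixed-effects (Psi = 0) fit.

    Q = sum_i (eta_i - X_i beta0)' S_i^{-1} (eta_i - X_i beta0) with beta0 the
    GLS fit at zero heterogeneity; I2 = max(0, (Q - dof) / Q).
    """
    data = model.data
    k = model.k
    fe = fit_meta_core(data, fix_psi=np.zeros((k, k)))
    Q = 0.0
    for i in range(data.y.shape[0]):
        r = data.y[i] - data.X[i] @ fe.beta
        try:
            Q += float(r @ np.linalg.solve(data.S[i], r))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular S for region {data.region_ids[i]}") from exc
    dof = data.y.size - data.X.shape[1] * k
    i2 = max(0.0, (Q - dof) / Q) if Q > 0 else 0.0
    return Q, dof, i2
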