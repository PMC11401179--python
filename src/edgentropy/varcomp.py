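"""Multivariate variance-component ("morphometricity"-style) model.

The model for an N x P behavioral table Y with similarity matrix R is

    Y = XB + C + E,   Vec(C) ~ N(0, Sigma_c (x) R),  Vec(E) ~ N(0, Sigma_e (x) I)

Covariates are removed by projecting onto the orthogonal complement of the
column space of [1 X] (dimension N - rank), giving an equivalent model with
no fixed effects. Sigma_c and Sigma_e are then estimated in closed form by
moment matching,

    Sigma_c = (1/nu) Y' (R - tau I) Y,    Sigma_e = (1/nu) Y' (kappa I - tau R) Y,

with tau = Tr(R)/N, kappa = Tr(R^2)/N and nu = N (kappa - tau^2). The
overall variance explained is M = Tr(Sigma_c) / (Tr(Sigma_c) + Tr(Sigma_e))
and per-measure fractions are the corresponding diagonal ratios.

Inference: a one-sided Wald test of M > 0 with a delta-method standard
error computed from the Gaussian covariance of the two quadratic forms, and
a permutation test that permutes the rows and columns of R jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space
from sklearn.base import BaseEstimator

__all__ = [
    "quantile_normalize", "impute", "project_out_covariates",
    "VarianceComponentModel", "fit_moment_matching", "univariate_fit",
    "permutation_p", "bootstrap_contrast", "jackknife_contrast",
    "edgewise_variance",
]


# ---------------------------------------------------------------------------
# behavioral preprocessing

def quantile_normalize(raw: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Rank-based inverse-normal transform, column-wise.

    Ranks (ties averaged) are mapped through Phi^{-1}((rank - 0.5) / N), so
    any monotone transform of a column yields identical output and each
    column is marginally Gaussian.
    """
    is_df = isinstance(raw, pd.DataFrame)
    X = np.asarray(raw, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N = X.shape[0]
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.unique(col).size < 3:
            raise ValueError(f"column {j} has fewer than 3 distinct values")
        ranks = stats.rankdata(col, method="average")
        out[:, j] = stats.norm.ppf((ranks - 0.5) / N)
    if is_df:
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out if np.asarray(raw).ndim > 1 else out[:, 0]


def impute(behavior: pd.DataFrame, covariates: pd.DataFrame,
           dose_col: str = "dose") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-impute behavioral scores; missing medication dose -> 0."""
    beh = behavior.copy()
    for col in beh.columns:
        frac = beh[col].isna().mean()
        if frac >= 0.10:
            raise ValueError(f"behavior column {col!r} has {frac:.0%} missing")
        beh[col] = beh[col].fillna(beh[col].median())
    cov = covariates.copy()
    if dose_col in cov.columns:
        cov[dose_col] = cov[dose_col].fillna(0.0)
    for col in cov.columns:
        if cov[col].isna().any():
            cov[col] = cov[col].fillna(cov[col].median())
    return beh, cov


# ---------------------------------------------------------------------------
# covariate projection

def project_out_covariates(Y: np.ndarray, X: np.ndarray | None,
                           R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transform (Y, R) to the orthogonal complement of span([1 X]).

    Returns (Y_t, R_t) of dimension N - rank([1 X]); the transformed model
    has no fixed effects, so any XB added to Y leaves the fit unchanged.
    """
    Y = np.asarray(Y, float)
    N = Y.shape[0]
    ones = np.ones((N, 1))
    D = ones if X is None else np.column_stack([ones, np.asarray(X, float)])
    rank = np.linalg.matrix_rank(D)
    if X is not None and rank < D.shape[1]:
        # identify collinear columns by rank increments
        bad = []
        cur = np.linalg.matrix_rank(ones)
        M = ones
        for j in range(np.asarray(X).shape[1]):
            M2 = np.column_stack([M, np.asarray(X, float)[:, [j]]])
            r2 = np.linalg.matrix_rank(M2)
            if r2 == cur:
                bad.append(j)
            else:
                M, cur = M2, r2
        raise ValueError(f"covariate matrix is rank deficient; collinear "
                         f"columns (0-based): {bad}")
    U = null_space(D.T)  # N x (N - rank), orthonormal
    Y_t = U.T @ Y
    R_t = U.T @ np.asarray(R, float) @ U
    return Y_t, R_t


# ---------------------------------------------------------------------------
# moment matching core

def _kernel_moments(R: np.ndarray) -> tuple[float, float, float]:
    N = R.shape[0]
    tau = float(np.trace(R)) / N
    kappa = float(np.trace(R @ R)) / N
    nu = N * (kappa - tau ** 2)
    return tau, kappa, nu


def _quadratic_cov(A: np.ndarray, B: np.ndarray, R: np.ndarray,
                   Sc: np.ndarray, Se: np.ndarray) -> float:
    """Cov(Tr(Y'AY), Tr(Y'BY)) for Vec(Y) ~ N(0, Sc (x) R + Se (x) I)."""
    AR, BR = A @ R, B @ R
    t_rr = float(np.trace(AR @ BR))
    t_r = float(np.trace(AR @ B))
    t_i = float(np.trace(A @ B))
    c_cc = float(np.trace(Sc @ Sc))
    c_ce = float(np.trace(Sc @ Se))
    c_ee = float(np.trace(Se @ Se))
    return 2.0 * (c_cc * t_rr + 2.0 * c_ce * t_r + c_ee * t_i)


@dataclass
class VarCompResult:
    """Closed-form moment-matching fit on the projected model."""

    sigma_c: np.ndarray
    sigma_e: np.ndarray
    tau: float
    kappa: float
    nu: float
    m_raw: float
    m_overall: float
    m_per_measure: np.ndarray
    m_per_measure_raw: np.ndarray
    se_overall: float
    se_per_measure: np.ndarray
    p_wald: float
    p_wald_per_measure: np.ndarray


def _fit_projected(Y_t: np.ndarray, R_t: np.ndarray) -> VarCompResult:
    Y_t = np.asarray(Y_t, float)
    if Y_t.ndim == 1:
        Y_t = Y_t[:, None]
    N = Y_t.shape[0]
    tau, kappa, nu = _kernel_moments(R_t)
    if abs(nu) <= 1e-8:
        raise ValueError(
            "model unidentifiable: nu(R) ~ 0 (similarity matrix is close to "
            "a multiple of the identity)"
        )
    A_c = (R_t - tau * np.eye(N)) / nu
    A_e = (kappa * np.eye(N) - tau * R_t) / nu
    Sc = Y_t.T @ A_c @ Y_t
    Se = Y_t.T @ A_e @ Y_t
    Sc = (Sc + Sc.T) / 2
    Se = (Se + Se.T) / 2
    tc, te = float(np.trace(Sc)), float(np.trace(Se))
    tot = tc + te
    m_raw = tc / tot if tot != 0 else 0.0
    mi_raw = np.array([
        Sc[p, p] / (Sc[p, p] + Se[p, p]) if (Sc[p, p] + Se[p, p]) != 0 else 0.0
        for p in range(Sc.shape[0])
    ])
    # Two delta-method SEs from the Gaussian covariance of the quadratic
    # forms. The *test* SE evaluates the covariance at the null
    # configuration (Sigma_c = 0, Sigma_e = empirical total covariance):
    # consistent under the null, so the one-sided Wald test is calibrated
    # and tracks the permutation distribution. The *reporting* SE (error
    # bars, recovery intervals) evaluates it at the PSD-clipped estimates,
    # which is the plug-in that tracks the sampling spread under signal.
    Se0 = Y_t.T @ Y_t / Y_t.shape[0]
    Sc0 = np.zeros_like(Se0)
    Sc_pos = _nearest_psd(Sc)
    Se_pos = _nearest_psd(Se, floor=1e-12)
    A_t = A_c + A_e

    def _overall_se(Sc_in, Se_in):
        var_c = _quadratic_cov(A_c, A_c, R_t, Sc_in, Se_in)
        var_t = _quadratic_cov(A_t, A_t, R_t, Sc_in, Se_in)
        cov_ct = _quadratic_cov(A_c, A_t, R_t, Sc_in, Se_in)
        return _ratio_se(tc, tot, var_c, var_t, cov_ct)

    se_score = _overall_se(Sc0, Se0)
    se = _overall_se(Sc_pos, Se_pos)
    se_i = np.empty(Sc.shape[0])
    p_i = np.empty(Sc.shape[0])
    for p in range(Sc.shape[0]):
        tot_p = Sc[p, p] + Se[p, p]

        def _measure_se(sc_val, se_val):
            sc_p = np.array([[sc_val]])
            se_p = np.array([[max(se_val, 1e-12)]])
            v_c = _quadratic_cov(A_c, A_c, R_t, sc_p, se_p)
            v_t = _quadratic_cov(A_t, A_t, R_t, sc_p, se_p)
            c_ct = _quadratic_cov(A_c, A_t, R_t, sc_p, se_p)
            return _ratio_se(Sc[p, p], tot_p, v_c, v_t, c_ct)

        se_i[p] = _measure_se(max(Sc[p, p], 0.0), max(Se[p, p], 1e-12))
        p_i[p] = _wald_pvalue(mi_raw[p], _measure_se(0.0, Se0[p, p]))
    return VarCompResult(
        sigma_c=Sc, sigma_e=Se, tau=tau, kappa=kappa, nu=nu,
        m_raw=m_raw, m_overall=float(np.clip(m_raw, 0.0, 1.0)),
        m_per_measure=np.clip(mi_raw, 0.0, 1.0),
        m_per_measure_raw=mi_raw,
        se_overall=se, se_per_measure=se_i,
        p_wald=_wald_pvalue(m_raw, se_score), p_wald_per_measure=p_i,
    )


def _nearest_psd(S: np.ndarray, floor: float = 0.0) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    return (V * np.clip(w, floor, None)) @ V.T


def _ratio_se(num: float, den: float, var_num: float, var_den: float,
              cov_nd: float) -> float:
    if den == 0:
        return float("nan")
    m = num / den
    var = (var_num - 2 * m * cov_nd + m ** 2 * var_den) / den ** 2
    return float(np.sqrt(max(var, 0.0)))


def _wald_pvalue(m: float, se: float) -> float:
    if not np.isfinite(se) or se == 0:
        raise ValueError("Wald test undefined: zero or non-finite SE")
    return float(stats.norm.sf(m / se))


# ---------------------------------------------------------------------------
# estimator class

class VarianceComponentModel(BaseEstimator):
    """Moment-matching variance-component model with Wald and permutation
    inference.

    Parameters
    ----------
    n_perm : int
        Permutations for the row/column permutation test of R (0 disables).
    random_state : int
        Seed for the permutation test.

    Attributes (after ``fit``)
    --------------------------
    sigma_c_, sigma_e_ : (P, P) moment-matching estimates (projected model).
    tau_, kappa_, nu_ : kernel moments of the projected R.
    m_overall_, m_per_measure_ : variance fractions, clipped to [0, 1].
    m_raw_, m_per_measure_raw_ : unclipped trace/diagonal ratios.
    se_overall_, se_per_measure_ : delta-method standard errors.
    p_wald_, p_perm_ : one-sided significance of M > 0.
    """

    def __init__(self, n_perm: int = 1000, random_state: int = 0):
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, Y: np.ndarray, R: np.ndarray,
            X: np.ndarray | None = None) -> "VarianceComponentModel":
        Y = np.asarray(Y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        Y_t, R_t = project_out_covariates(Y, X, np.asarray(R, float))
        res = _fit_projected(Y_t, R_t)
        self.Y_t_, self.R_t_ = Y_t, R_t
        self.sigma_c_, self.sigma_e_ = res.sigma_c, res.sigma_e
        self.tau_, self.kappa_, self.nu_ = res.tau, res.kappa, res.nu
        self.m_raw_, self.m_overall_ = res.m_raw, res.m_overall
        self.m_per_measure_ = res.m_per_measure
        self.m_per_measure_raw_ = res.m_per_measure_raw
        self.se_overall_ = res.se_overall
        self.se_per_measure_ = res.se_per_measure
        self.p_wald_ = res.p_wald
        self.p_wald_per_measure_ = res.p_wald_per_measure
        if self.n_perm:
            self.p_perm_ = permutation_p(
                Y_t, R_t, n_perm=self.n_perm, seed=self.random_state,
                observed=res.m_raw)
        return self

    def mean_variance_explained(self) -> float:
        """Mean of the per-measure (clipped) variance fractions."""
        return float(np.mean(self.m_per_measure_))


def fit_moment_matching(Y_t: np.ndarray, R_t: np.ndarray) -> VarCompResult:
    """Closed-form fit on an already-projected model (no fixed effects)."""
    return _fit_projected(Y_t, R_t)


def univariate_fit(y: np.ndarray, X: np.ndarray | None, R: np.ndarray,
                   n_perm: int = 0, seed: int = 0) -> VarianceComponentModel:
    """Single-outcome version (P = 1), e.g. for PANSS scales."""
    y = np.asarray(y, float).reshape(-1, 1)
    return VarianceComponentModel(n_perm=n_perm, random_state=seed).fit(y, R, X)


# ---------------------------------------------------------------------------
# permutation test

def permutation_p(Y_t: np.ndarray, R_t: np.ndarray, n_perm: int = 1000,
                  seed: int = 0, observed: float | None = None) -> float:
    """Permute rows and columns of R jointly; p = (1 + #{M_perm >= M})/(n+1).

    The kernel moments tau, kappa, nu are invariant under a joint row and
    column permutation, so each permutation only needs the quadratic form
    q = Tr(Y' R_perm Y); the trace estimates are then
    Tr(Sigma_c) = (q - tau T0)/nu and Tr(Sigma_e) = (kappa T0 - tau q)/nu
    with T0 = Tr(Y'Y).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y_t = np.asarray(Y_t, float)
    if Y_t.ndim == 1:
        Y_t = Y_t[:, None]
    tau, kappa, nu = _kernel_moments(R_t)
    if abs(nu) <= 1e-8:
        raise ValueError("model unidentifiable: nu(R) ~ 0")
    T0 = float(np.sum(Y_t * Y_t))
    W = Y_t @ Y_t.T
    if observed is None:
        q0 = float(np.sum(R_t * W))
        s_c = (q0 - tau * T0) / nu
        s_e = (kappa * T0 - tau * q0) / nu
        observed = s_c / (s_c + s_e) if (s_c + s_e) != 0 else 0.0
    rng = np.random.default_rng(seed)
    N = R_t.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(N)
        q = float(np.sum(R_t * W[np.ix_(perm, perm)]))
        s_c = (q - tau * T0) / nu
        s_e = (kappa * T0 - tau * q) / nu
        tot = s_c + s_e
        m = s_c / tot if tot != 0 else 0.0
        if m >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# similarity construction helper (local import breaks a cycle)

def _similarity_from_stack(stack: np.ndarray, edge_positions: np.ndarray) -> np.ndarray:
    from .templates import similarity_matrix
    return similarity_matrix(stack[:, edge_positions])


# ---------------------------------------------------------------------------
# resampled contrasts between two templates

def _fractions_only(Y: np.ndarray, R: np.ndarray,
                    U: np.ndarray) -> np.ndarray:
    """Per-measure (clipped) fractions plus overall, without SE machinery.

    ``U`` is the precomputed orthonormal complement of the design columns.
    """
    Y_t = U.T @ Y
    R_t = U.T @ R @ U
    N = R_t.shape[0]
    tau, kappa, nu = _kernel_moments(R_t)
    if abs(nu) <= 1e-8:
        raise ValueError("model unidentifiable: nu(R) ~ 0")
    AY = R_t @ Y_t - tau * Y_t          # (R - tau I) Y
    sc_diag = np.einsum("ij,ij->j", Y_t, AY) / nu
    se_diag = (kappa * np.einsum("ij,ij->j", Y_t, Y_t)
               - tau * np.einsum("ij,ij->j", Y_t, R_t @ Y_t)) / nu
    tot = sc_diag + se_diag
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = np.where(tot != 0, sc_diag / tot, 0.0)
    m_overall = sc_diag.sum() / tot.sum() if tot.sum() != 0 else 0.0
    return np.clip(np.r_[mi, m_overall], 0.0, 1.0)


def _design_complement(X: np.ndarray | None, N: int) -> np.ndarray:
    ones = np.ones((N, 1))
    D = ones if X is None else np.column_stack([ones, np.asarray(X, float)])
    return null_space(D.T)


def _fit_fraction_pair(stack: np.ndarray, mask_a: np.ndarray,
                       mask_b: np.ndarray, Y: np.ndarray,
                       X: np.ndarray | None,
                       U: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-measure (and appended overall) fractions for the two masks."""
    if U is None:
        U = _design_complement(X, Y.shape[0])
    out = []
    for mask in (mask_a, mask_b):
        R = _similarity_from_stack(stack, mask)
        out.append(_fractions_only(Y, R, U))
    return out[0], out[1]


def bootstrap_contrast(Y: np.ndarray, X: np.ndarray | None,
                       ese_patients: np.ndarray, mask_hen: np.ndarray,
                       mask_len: np.ndarray, n_boot: int = 1000,
                       alpha: float = 0.05, n_tests: int = 1,
                       seed: int = 0, max_redraw: int = 10) -> pd.DataFrame:
    """Bias-corrected bootstrap CIs for per-measure and overall
    (M_HEN - M_LEN).

    Patients are resampled with replacement; both similarity matrices are
    rebuilt from the resampled entropy vectors and both models refit. The
    confidence level is Bonferroni-adjusted to alpha / n_tests.
    """
    Y = np.asarray(Y, float)
    stack = np.asarray(ese_patients, float)
    N = Y.shape[0]
    a_hen, a_len = _fit_fraction_pair(stack, mask_hen, mask_len, Y, X)
    observed = a_hen - a_len
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, observed.size))
    for b in range(n_boot):
        for attempt in range(max_redraw):
            idx = rng.integers(0, N, N)
            try:
                bh, bl = _fit_fraction_pair(
                    stack[idx], mask_hen, mask_len, Y[idx],
                    None if X is None else np.asarray(X, float)[idx])
                boots[b] = bh - bl
                break
            except ValueError:
                continue  # degenerate resample (nu ~ 0); redraw
        else:
            boots[b] = observed  # neutral fallback after max_redraw failures
    level = alpha / n_tests
    lo = np.empty(observed.size)
    hi = np.empty(observed.size)
    for k in range(observed.size):
        lo[k], hi[k] = _bc_interval(boots[:, k], observed[k], level)
    names = [f"measure_{p}" for p in range(observed.size - 1)] + ["overall"]
    return pd.DataFrame({
        "difference": observed, "ci_lo": lo, "ci_hi": hi,
        "excludes_zero": (lo > 0) | (hi < 0),
    }, index=names)


def _bc_interval(boot: np.ndarray, observed: float,
                 level: float) -> tuple[float, float]:
    """Bias-corrected (BC) percentile interval."""
    boot = boot[np.isfinite(boot)]
    prop = np.mean(boot < observed)
    prop = min(max(prop, 1.0 / (len(boot) + 1)), 1 - 1.0 / (len(boot) + 1))
    z0 = stats.norm.ppf(prop)
    z_lo, z_hi = stats.norm.ppf(level / 2), stats.norm.ppf(1 - level / 2)
    a_lo = stats.norm.cdf(2 * z0 + z_lo)
    a_hi = stats.norm.cdf(2 * z0 + z_hi)
    return (float(np.quantile(boot, a_lo)), float(np.quantile(boot, a_hi)))


def jackknife_contrast(Y: np.ndarray, X: np.ndarray | None,
                       ese_patients: np.ndarray, mask_hen: np.ndarray,
                       mask_len: np.ndarray, alpha: float = 0.05,
                       n_tests: int = 1) -> pd.DataFrame:
    """Leave-one-patient-out (jackknife) normal-approximation CIs for the
    same per-measure and overall contrasts as :func:`bootstrap_contrast`."""
    Y = np.asarray(Y, float)
    stack = np.asarray(ese_patients, float)
    N = Y.shape[0]
    if N < 10:
        raise ValueError("jackknife needs at least 10 subjects")
    a_hen, a_len = _fit_fraction_pair(stack, mask_hen, mask_len, Y, X)
    observed = a_hen - a_len
    loo = np.empty((N, observed.size))
    for i in range(N):
        idx = np.r_[0:i, i + 1:N]
        bh, bl = _fit_fraction_pair(
            stack[idx], mask_hen, mask_len, Y[idx],
            None if X is None else np.asarray(X, float)[idx])
        loo[i] = bh - bl
    mean_loo = loo.mean(axis=0)
    var_jack = (N - 1) / N * np.sum((loo - mean_loo) ** 2, axis=0)
    se = np.sqrt(var_jack)
    z = stats.norm.ppf(1 - (alpha / n_tests) / 2)
    names = [f"measure_{p}" for p in range(observed.size - 1)] + ["overall"]
    return pd.DataFrame({
        "difference": observed, "se": se,
        "ci_lo": observed - z * se, "ci_hi": observed + z * se,
        "excludes_zero": (observed - z * se > 0) | (observed + z * se < 0),
    }, index=names)


# ---------------------------------------------------------------------------
# edgewise univariate variant

def edgewise_variance(Y: np.ndarray, X: np.ndarray | None,
                      ese_patients: np.ndarray,
                      mask: np.ndarray) -> np.ndarray:
    """Mean variance explained per edge, averaged over measures.

    For each edge the similarity kernel is the rank-one product of the
    patientwise z-scored entropy values (diagonal replaced by 1); a
    univariate fit is run per measure and the edge value is the mean of the
    P clipped fractions. Zero-variance edges yield NaN.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    stack = np.asarray(ese_patients, float)
    N, P = Y.shape
    ones = np.ones((N, 1))
    D = ones if X is None else np.column_stack([ones, np.asarray(X, float)])
    U = null_space(D.T)
    Y_t = U.T @ Y
    out = np.full(len(mask), np.nan)
    for k, e in enumerate(np.asarray(mask, int)):
        v = stack[:, e]
        sd = v.std()
        if sd == 0 or not np.isfinite(sd):
            continue
        z = (v - v.mean()) / sd
        R_e = np.outer(z, z)
        np.fill_diagonal(R_e, 1.0)
        R_t = U.T @ R_e @ U
        try:
            fracs = [
                _fit_projected(Y_t[:, [p]], R_t).m_overall for p in range(P)
            ]
        except ValueError:
            continue
        out[k] = float(np.mean(fracs))
    return out
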