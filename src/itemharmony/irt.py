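"""Per-study two-parameter logistic (2PL) IRT estimation and fit checking.

The 2PL models the probability that respondent with latent trait theta
endorses item j as

    P_j(theta) = 1 / (1 + exp(-a_j (theta - b_j)))

where a_j is the discrimination (analogous to a factor loading) and b_j
the difficulty: the trait level at which endorsement probability is 50%.
Estimation is marginal maximum likelihood via the EM algorithm over a
fixed Gauss-Hermite quadrature grid with a standard-normal prior on the
trait. Missing responses contribute nothing to their item's likelihood
term.

Fitting each study separately and checking fit is a configural-invariance
check: the same unidimensional structure should hold in every study
before any pooled calibration is attempted. Fit is assessed with
limited-information statistics built from univariate and bivariate
margins (an M2-type quadratic form), from which RMSEA and CFI are
derived; SRMR summarizes residual inter-item correlations. Local
dependence ("couplets") is flagged from residual correlations and
standardized residuals of the pairwise 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .core import is_missing
from .errors import DegenerateItemError, EstimationError

__all__ = [
    "IRTConfig",
    "TwoPLParams",
    "FitStats",
    "ResidualReport",
    "IRTFitResult",
    "fit_2pl",
    "fit_statistics",
    "classify_fit",
    "residual_report",
    "model_probabilities",
    "marginal_loglik",
]


@dataclass
class IRTConfig:
    """Estimation settings.

    n_quad: quadrature nodes for the latent-trait integral (default 41).
    tol: EM convergence tolerance on the marginal log-likelihood.
    max_iter: EM iteration cap; non-convergence is reported, not raised.
    a_max: bound on |discrimination| -- near-duplicate items would
        otherwise drive slopes toward infinity; bounding keeps their
        local dependence visible to the residual diagnostics.
    """

    n_quad: int = 41
    tol: float = 1e-6
    max_iter: int = 500
    a_max: float = 5.0


@dataclass
class TwoPLParams:
    item_names: list
    a: np.ndarray  # discrimination, positive after sign identification
    b: np.ndarray  # difficulty on the latent-trait scale
    se_a: np.ndarray
    se_b: np.ndarray


@dataclass
class FitStats:
    rmsea: float
    cfi: float
    srmr: float
    m2: float
    df: int
    m2_baseline: float = float("nan")
    df_baseline: int = 0
    n: int = 0
    labels: dict = field(default_factory=dict)


@dataclass
class ResidualReport:
    """Pairwise misfit diagnostics.

    univariate: per-pair residual correlations (observed minus
        model-implied Pearson correlation of the two binary items).
    bivariate: per-pair maximum |standardized residual| over the four
        cells of the observed-vs-expected 2x2 cross-table.
    flagged_pairs: pairs crossing either threshold -- "couplet"
        candidates for local dependence.
    """

    univariate: dict
    bivariate: dict
    flagged_pairs: list
    thresholds: tuple = (0.3, 3.0)


@dataclass
class IRTFitResult:
    study_id: str
    params: TwoPLParams
    theta_grid: tuple  # (nodes, normalized weights)
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    n_respondents: int
    fit: FitStats | None = None
    residuals: ResidualReport | None = None


def gauss_hermite_grid(n_quad: int):
    """Quadrature nodes and standard-normal weights (weights sum to 1)."""
    nodes, w = np.polynomial.hermite_e.hermegauss(n_quad)
    w = w / np.sqrt(2.0 * np.pi)
    return nodes, w / w.sum()


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def model_probabilities(a, b, theta):
    """P(x=1 | theta) per item (J x K) at the given trait values."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[:, None]
    return _logistic(a * (np.asarray(theta, dtype=float)[None, :] - b))


def _prepare(responses, item_names):
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2:
        raise EstimationError("responses must be a respondent-by-item matrix")
    n, J = X.shape
    if item_names is None:
        item_names = [f"item{j}" for j in range(J)]
    obs = ~is_missing(X)
    vals = X[obs]
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise EstimationError(
            "non-binary responses reached the IRT stage; ordinal items must "
            "be dichotomized upstream"
        )
    n_var = 0
    for j in range(J):
        col = X[obs[:, j], j]
        if col.size == 0:
            raise DegenerateItemError(f"item {item_names[j]!r} is entirely missing")
        p = col.mean()
        if p in (0.0, 1.0):
            raise DegenerateItemError(
                f"item {item_names[j]!r} has {p:.0%} endorsement; remove it with "
                f"the no-variability QC filter before model fitting"
            )
        n_var += 1
    if n_var < 3:
        raise EstimationError("need at least 3 items with variability")
    return X, obs, list(item_names)


def _item_objective(theta, r, nn, a, c):
    p = _logistic(a * theta + c)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(r @ np.log(p) + (nn - r) @ np.log(1.0 - p))


def _mstep_item(theta, r, nn, a, c, a_max, tol=1e-11, max_newton=60):
    """Maximize the expected complete-data log-likelihood for one item.

    Weighted Bernoulli regression on the quadrature grid: r endorsements
    out of nn responses at each node. Newton with step-halving; the slope
    is kept within [-a_max, a_max]. The objective never decreases from its
    starting value, which preserves EM monotonicity.
    """
    f0 = _item_objective(theta, r, nn, a, c)
    for _ in range(max_newton):
        p = _logistic(a * theta + c)
        w = nn * p * (1.0 - p)
        g = np.array([(r - nn * p) @ theta, np.sum(r - nn * p)])
        H = np.array(
            [[w @ (theta * theta), w @ theta], [w @ theta, np.sum(w)]]
        )
        if np.max(np.abs(g)) < tol:
            break
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(2), g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        improved = False
        for _ in range(40):
            a_new = float(np.clip(a + scale * step[0], -a_max, a_max))
            c_new = c + scale * step[1]
            if _item_objective(theta, r, nn, a_new, c_new) >= f0:
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
        a, c = a_new, c_new
        f0 = _item_objective(theta, r, nn, a, c)
    return a, c


def marginal_loglik(responses, a, b, theta, weights):
    """Marginal log-likelihood of the data at (a, b) over a trait grid.

    Serves both the EM trace and independent verification against a fine
    deterministic grid.
    """
    X = np.asarray(responses, dtype=float)
    obs = ~is_missing(X)
    P = model_probabilities(a, b, theta)
    logP = np.log(np.clip(P, 1e-300, 1.0))
    logQ = np.log(np.clip(1.0 - P, 1e-300, 1.0))
    X0 = np.where(obs, X, 0.0)
    ll_nk = X0 @ logP + (obs.astype(float) - X0) @ logQ  # n x K
    ll_nk = ll_nk + np.log(weights)[None, :]
    mx = ll_nk.max(axis=1, keepdims=True)
    return float(np.sum(mx.ravel() + np.log(np.exp(ll_nk - mx).sum(axis=1))))


def fit_2pl(responses, item_names=None, study_id: str = "", config: IRTConfig | None = None) -> IRTFitResult:
    """Fit a unidimensional 2PL by marginal maximum likelihood (EM).

    ``responses`` is an n x J binary matrix with NaN for missing. The
    latent trait carries a standard-normal prior; the trait's sign is
    identified by orienting the mean discrimination positive.
    """
    config = config or IRTConfig()
    X, obs, item_names = _prepare(responses, item_names)
    n, J = X.shape
    theta, w = gauss_hermite_grid(config.n_quad)

    # start values: unit slopes, intercepts from marginal endorsement
    p_marg = np.array([X[obs[:, j], j].mean() for j in range(J)])
    a_sl = np.ones(J)
    c_ic = np.log(p_marg / (1.0 - p_marg))

    X0 = np.where(obs, X, 0.0)
    obs_f = obs.astype(float)
    logw = np.log(w)
    trace = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        # E-step: posterior over quadrature nodes per respondent
        Z = a_sl[:, None] * theta[None, :] + c_ic[:, None]  # J x K logits
        logP = -np.logaddexp(0.0, -Z)
        logQ = -np.logaddexp(0.0, Z)
        ll_nk = X0 @ logP + (obs_f - X0) @ logQ + logw[None, :]
        mx = ll_nk.max(axis=1, keepdims=True)
        post = np.exp(ll_nk - mx)
        norm = post.sum(axis=1, keepdims=True)
        ll = float(np.sum(mx.ravel() + np.log(norm.ravel())))
        trace.append(ll)
        post /= norm
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < config.tol:
            converged = True
            break
        # expected endorsement and response counts per item and node
        r_jk = (X0 * obs_f).T @ post  # J x K
        n_jk = obs_f.T @ post
        # M-step: per-item weighted logistic regression on the grid
        for j in range(J):
            a_sl[j], c_ic[j] = _mstep_item(
                theta, r_jk[j], n_jk[j], a_sl[j], c_ic[j], config.a_max
            )

    # sign identification: the trait is oriented so mean discrimination > 0
    if a_sl.mean() < 0:
        a_sl = -a_sl

    a_hat = a_sl.copy()
    b_hat = -c_ic / a_sl

    # standard errors from the per-item expected information on the grid
    # (block-diagonal approximation; cross-item terms ignored)
    Z = a_sl[:, None] * theta[None, :] + c_ic[:, None]
    P = _logistic(Z)
    logP = np.log(np.clip(P, 1e-300, 1))
    logQ = np.log(np.clip(1 - P, 1e-300, 1))
    ll_nk = X0 @ logP + (obs_f - X0) @ logQ + logw[None, :]
    mx = ll_nk.max(axis=1, keepdims=True)
    post = np.exp(ll_nk - mx)
    post /= post.sum(axis=1, keepdims=True)
    n_jk = obs_f.T @ post
    se_a = np.full(J, np.nan)
    se_b = np.full(J, np.nan)
    for j in range(J):
        wj = n_jk[j] * P[j] * (1 - P[j])
        info = np.array(
            [[wj @ (theta * theta), wj @ theta], [wj @ theta, wj.sum()]]
        )
        try:
            cov_ac = np.linalg.inv(info)
            # delta method for b = -c/a
            Jc = np.array([[1.0, 0.0], [c_ic[j] / a_sl[j] ** 2, -1.0 / a_sl[j]]])
            cov_ab = Jc @ cov_ac @ Jc.T
            se_a[j] = np.sqrt(max(cov_ab[0, 0], 0.0))
            se_b[j] = np.sqrt(max(cov_ab[1, 1], 0.0))
        except np.linalg.LinAlgError:
            pass

    params = TwoPLParams(item_names, a_hat, b_hat, se_a, se_b)
    return IRTFitResult(
        study_id=study_id,
        params=params,
        theta_grid=(theta, w),
        loglik=trace[-1],
        n_iter=it,
        converged=converged,
        loglik_trace=np.asarray(trace),
        n_respondents=n,
    )


# ---------------------------------------------------------------------------
# limited-information fit statistics
# ---------------------------------------------------------------------------


def _pair_index(J):
    return [(j, l) for j in range(J) for l in range(j + 1, J)]


def _union_prob(P, w, items):
    """P(all items in the set = 1): quadrature integral of the product."""
    prod = np.ones_like(w)
    for j in items:
        prod = prod * P[j]
    return float(prod @ w)


def _margin_sets(J):
    sets = [(j,) for j in range(J)]
    sets += [p for p in _pair_index(J)]
    return sets


def _sample_margins(X, obs):
    """Univariate and bivariate sample proportions, pairwise complete."""
    n, J = X.shape
    p_uni = np.array([X[obs[:, j], j].mean() for j in range(J)])
    pairs = _pair_index(J)
    p_bi = np.zeros(len(pairs))
    n_pair = np.zeros(len(pairs), dtype=int)
    for idx, (j, l) in enumerate(pairs):
        ok = obs[:, j] & obs[:, l]
        n_pair[idx] = ok.sum()
        p_bi[idx] = np.mean(X[ok, j] * X[ok, l]) if ok.any() else np.nan
    return p_uni, p_bi, n_pair


def _model_margins(a, b, theta, w):
    J = len(a)
    P = model_probabilities(a, b, theta)
    pi_uni = P @ w
    pairs = _pair_index(J)
    pi_bi = np.array([float((P[j] * P[l]) @ w) for j, l in pairs])
    return P, pi_uni, pi_bi


def _moment_cov(P, w, sets):
    """Covariance matrix of the margin indicators under the model.

    Entry (A, B) is P(union of A and B all endorsed) - P(A)P(B); union
    probabilities integrate the item-probability product over the trait.
    """
    m = len(sets)
    pi = np.array([_union_prob(P, w, s) for s in sets])
    Sigma = np.empty((m, m))
    for i in range(m):
        for k in range(i, m):
            union = tuple(sorted(set(sets[i]) | set(sets[k])))
            pu = _union_prob(P, w, union)
            Sigma[i, k] = Sigma[k, i] = pu - pi[i] * pi[k]
    return Sigma, pi


def _jacobian_2pl(a, b, theta, w, sets):
    """d pi / d (a_1..a_J, b_1..b_J) for univariate+bivariate margins."""
    J = len(a)
    P = model_probabilities(a, b, theta)
    dP_da = P * (1 - P) * (theta[None, :] - np.asarray(b)[:, None])
    dP_db = -np.asarray(a)[:, None] * P * (1 - P)
    m = len(sets)
    Delta = np.zeros((m, 2 * J))
    for i, s in enumerate(sets):
        for j in s:
            others = np.ones_like(w)
            for l in s:
                if l != j:
                    others = others * P[l]
            Delta[i, j] = (dP_da[j] * others) @ w
            Delta[i, J + j] = (dP_db[j] * others) @ w
    return Delta


def _m2_quadform(e, Sigma, Delta, N):
    """M2 = N e' C e with C the residual weight orthogonal to the model."""
    Sig = Sigma + 1e-10 * np.eye(Sigma.shape[0])
    Si_e = linalg.solve(Sig, e, assume_a="sym")
    Si_D = linalg.solve(Sig, Delta, assume_a="sym")
    mid = Delta.T @ Si_D
    rhs = Delta.T @ Si_e
    corr = rhs @ linalg.pinv(mid) @ rhs
    return float(N * (e @ Si_e - corr))


def _limited_info_components(fit: IRTFitResult, X, obs):
    """Margins, residuals, moment covariance and Jacobian shared by the
    M2 statistic and the standardized-residual diagnostics."""
    n, J = X.shape
    a, b = fit.params.a, fit.params.b
    theta, w = fit.theta_grid
    sets = _margin_sets(J)
    pairs = _pair_index(J)
    p_uni, p_bi, n_pair = _sample_margins(X, obs)
    P, pi_uni, pi_bi = _model_margins(a, b, theta, w)
    e = np.concatenate([p_uni - pi_uni, p_bi - pi_bi])
    Sigma, _ = _moment_cov(P, w, sets)
    Delta = _jacobian_2pl(a, b, theta, w, sets)
    return {
        "sets": sets,
        "pairs": pairs,
        "p_uni": p_uni,
        "p_bi": p_bi,
        "n_pair": n_pair,
        "P": P,
        "pi_uni": pi_uni,
        "pi_bi": pi_bi,
        "e": e,
        "Sigma": Sigma,
        "Delta": Delta,
    }


def fit_statistics(fit: IRTFitResult, responses) -> FitStats:
    """Limited-information fit of a converged 2PL.

    M2 is a quadratic form in the univariate+bivariate margin residuals,
    weighted orthogonally to the fitted parameter directions; its degrees
    of freedom are (number of margins) - 2J. RMSEA and CFI derive from M2
    with the mutual-independence model (free thresholds) as the CFI
    baseline. SRMR is the root mean squared difference between observed
    and model-implied inter-item correlations.
    """
    X = np.asarray(responses, dtype=float)
    obs = ~is_missing(X)
    n, J = X.shape
    if len(_pair_index(J)) < 2:
        raise EstimationError("fit statistics need at least 2 item pairs")
    theta, w = fit.theta_grid
    comp = _limited_info_components(fit, X, obs)
    sets, pairs = comp["sets"], comp["pairs"]
    p_uni, p_bi = comp["p_uni"], comp["p_bi"]
    pi_uni, pi_bi = comp["pi_uni"], comp["pi_bi"]
    m2 = max(_m2_quadform(comp["e"], comp["Sigma"], comp["Delta"], n), 0.0)
    df = len(sets) - 2 * J

    # baseline: mutual independence with thresholds fixed at the sample margins
    P_base = np.repeat(p_uni[:, None], len(w), axis=1)
    pi_bi_base = np.array([p_uni[j] * p_uni[l] for j, l in pairs])
    e_base = np.concatenate([np.zeros(J), p_bi - pi_bi_base])
    Sigma_base, _ = _moment_cov(P_base, w, sets)
    Delta_base = np.zeros((len(sets), J))
    for i, s in enumerate(sets):
        for j in s:
            others = 1.0
            for l in s:
                if l != j:
                    others *= p_uni[l]
            Delta_base[i, j] = others
    m2_base = max(_m2_quadform(e_base, Sigma_base, Delta_base, n), 0.0)
    df_base = len(sets) - J

    rmsea = float(np.sqrt(max(m2 - df, 0.0) / (df * n))) if df > 0 else float("nan")
    denom = max(m2_base - df_base, 0.0)
    numer = max(m2 - df, 0.0)
    cfi = float(1.0 - numer / denom) if denom > 0 else float("nan")

    # SRMR over inter-item correlations
    def _corr(p_j, p_l, p_jl):
        den = np.sqrt(p_j * (1 - p_j) * p_l * (1 - p_l))
        return (p_jl - p_j * p_l) / den if den > 0 else np.nan

    r_obs = np.array([_corr(p_uni[j], p_uni[l], p_bi[i]) for i, (j, l) in enumerate(pairs)])
    r_mod = np.array([_corr(pi_uni[j], pi_uni[l], pi_bi[i]) for i, (j, l) in enumerate(pairs)])
    srmr = float(np.sqrt(np.nanmean((r_obs - r_mod) ** 2)))

    stats = FitStats(
        rmsea=rmsea,
        cfi=cfi,
        srmr=srmr,
        m2=m2,
        df=df,
        m2_baseline=m2_base,
        df_baseline=df_base,
        n=n,
    )
    stats.labels = classify_fit(stats)
    return stats


def classify_fit(fit: FitStats) -> dict:
    """Label each index against conventional cutoffs.

    RMSEA: < 0.05 excellent; 0.05-0.08 (inclusive) mediocre; > 0.08 poor.
    CFI: >= 0.90 good, else poor. SRMR: < 0.08 good, else poor.
    Non-finite statistics are labelled "not computable".
    """
    labels = {}
    if not np.isfinite(fit.rmsea):
        labels["rmsea"] = "not computable"
    elif fit.rmsea < 0.05:
        labels["rmsea"] = "excellent"
    elif fit.rmsea <= 0.08:
        labels["rmsea"] = "mediocre"
    else:
        labels["rmsea"] = "poor"
    if not np.isfinite(fit.cfi):
        labels["cfi"] = "not computable"
    else:
        labels["cfi"] = "good" if fit.cfi >= 0.90 else "poor"
    if not np.isfinite(fit.srmr):
        labels["srmr"] = "not computable"
    else:
        labels["srmr"] = "good" if fit.srmr < 0.08 else "poor"
    return labels


def residual_report(fit: IRTFitResult, responses, thresholds=(0.3, 3.0)) -> ResidualReport:
    """Pairwise local-dependence diagnostics.

    Residual correlations are observed minus model-implied inter-item
    correlations (flag when |.| > thresholds[0]). Bivariate standardized
    residuals divide each pair's joint-endorsement residual (observed
    minus expected frequency of the (1, 1) cell) by its asymptotic
    standard error with the parameter-estimation correction -- the same
    weighting that underlies the M2 statistic -- so they are approximately
    standard normal when the model holds (flag when |.| > thresholds[1]).
    Flagged pairs are "couplet" candidates: conceptually overlapping
    items or an undetected skip pattern.
    """
    X = np.asarray(responses, dtype=float)
    obs = ~is_missing(X)
    n, J = X.shape
    names = fit.params.item_names
    comp = _limited_info_components(fit, X, obs)
    pairs = comp["pairs"]
    p_uni, p_bi = comp["p_uni"], comp["p_bi"]
    pi_uni, pi_bi = comp["pi_uni"], comp["pi_bi"]
    Sigma, Delta = comp["Sigma"], comp["Delta"]

    # residual covariance of the margins after parameter estimation:
    # V = Sigma - Delta (Delta' Sigma^-1 Delta)^-1 Delta'
    m = Sigma.shape[0]
    Sig = Sigma + 1e-10 * np.eye(m)
    Si_D = linalg.solve(Sig, Delta, assume_a="sym")
    V = Sigma - Delta @ linalg.pinv(Delta.T @ Si_D) @ Delta.T
    v_diag = np.maximum(np.diag(V), 0.0)

    univariate = {}
    bivariate = {}
    flagged = []
    for idx, (j, l) in enumerate(pairs):
        n_pair = int(comp["n_pair"][idx])
        if n_pair == 0:
            continue
        p_j, p_l, p_jl = p_uni[j], p_uni[l], p_bi[idx]
        den_o = np.sqrt(p_j * (1 - p_j) * p_l * (1 - p_l))
        den_m = np.sqrt(pi_uni[j] * (1 - pi_uni[j]) * pi_uni[l] * (1 - pi_uni[l]))
        r_obs = (p_jl - p_j * p_l) / den_o if den_o > 0 else np.nan
        r_mod = (pi_bi[idx] - pi_uni[j] * pi_uni[l]) / den_m
        resid_r = float(r_obs - r_mod)

        var = v_diag[J + idx] / n_pair
        z = float(abs(p_jl - pi_bi[idx]) / np.sqrt(var)) if var > 1e-14 else 0.0

        pair = (names[j], names[l])
        univariate[pair] = resid_r
        bivariate[pair] = z
        if (np.isfinite(resid_r) and abs(resid_r) > thresholds[0]) or z > thresholds[1]:
            flagged.append(pair)
    return ResidualReport(univariate, bivariate, flagged, tuple(thresholds))
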