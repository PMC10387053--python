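"""Log-link Tweedie regression of root growth on design factors.

The response (new-root length per window area per month) is modelled as
Tweedie(μ, p, φ) with

    log μ = β₀ + ecosystem + season + depth + pairwise interactions,

all factors categorical under sum-to-zero contrasts.  For a fixed power
index p the coefficient MLE is the ordinary GLM/IRLS solution (it does not
depend on φ); φ is then estimated by maximising the series log-likelihood,
and p is selected on a grid by profile likelihood.  Inference products are
Type-III Wald chi-square tests per term, estimated marginal means with
delta-method SEs on the response scale, and Tukey-adjusted pairwise
comparisons.

An optional tube-level normal random intercept (shared by all measurements
from one tube) is supported through adaptive Gauss–Hermite marginalisation;
the default is the fixed-effects model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import chi2, studentized_range

from .data import ObservationSet
from .tweedie import estimate_phi_ml, tweedie_logpdf

__all__ = [
    "ModelSpec",
    "FitResult",
    "AnovaTable",
    "MarginalMeanTable",
    "FitError",
    "fit",
    "type3_anova",
    "marginal_means",
    "pairwise_tukey",
    "aicc_compare",
    "build_design",
]

#: Factor name -> (data column, patsy factor expression with sum coding).
_FACTORS = {
    "ecosystem": ("ecosystem", "C(ecosystem, Sum)"),
    "season": ("season", "C(season, Sum)"),
    "depth": ("depth_top_cm", "C(depth_top_cm, Sum)"),
}

DEFAULT_TERMS: tuple[str, ...] = (
    "ecosystem",
    "season",
    "depth",
    "ecosystem:season",
    "ecosystem:depth",
    "season:depth",
)

DEFAULT_POWER_GRID: tuple[float, ...] = tuple(
    round(p, 2) for p in np.arange(1.10, 1.90 + 1e-9, 0.05)
)


class FitError(RuntimeError):
    """The model cannot be fitted on the given data."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of the fixed-effects structure and family options.

    ``fixed_terms`` uses factor names ``ecosystem``, ``season``, ``depth``
    and ``:``-joined pairwise interactions.  ``power_grid`` lists the
    candidate Tweedie power indices (all in the open interval (1, 2));
    a single-element grid fixes p.  ``include_tube_intercept`` switches on
    the Gauss–Hermite marginalised tube random intercept.
    """

    fixed_terms: tuple[str, ...] = DEFAULT_TERMS
    power_grid: tuple[float, ...] = DEFAULT_POWER_GRID
    include_tube_intercept: bool = False

    def __post_init__(self) -> None:
        for p in self.power_grid:
            if not 1.0 < p < 2.0:
                raise ValueError(f"power grid value {p} outside (1, 2)")
        for term in self.fixed_terms:
            for f in term.split(":"):
                if f not in _FACTORS:
                    raise ValueError(f"unknown factor {f!r} in term {term!r}")


def _active_terms(df: pd.DataFrame, terms: Sequence[str]) -> list[str]:
    """Drop terms involving factors with fewer than two observed levels."""
    n_levels = {
        name: df[col].nunique() for name, (col, _) in _FACTORS.items() if col in df.columns
    }
    keep = []
    for term in terms:
        factors = term.split(":")
        if all(n_levels.get(f, 0) >= 2 for f in factors):
            keep.append(term)
    return keep


def _formula(terms: Sequence[str]) -> str:
    parts = []
    for term in terms:
        parts.append(":".join(_FACTORS[f][1] for f in term.split(":")))
    return "1" if not parts else "1 + " + " + ".join(parts)


def build_design(df: pd.DataFrame, terms: Sequence[str] = DEFAULT_TERMS):
    """Sum-to-zero-coded design matrix for the given factorial terms.

    Returns ``(X, design_info, active_terms)`` where ``X`` is an
    (n × k) ndarray and ``design_info`` the patsy metadata used to rebuild
    matrices on prediction grids.
    """
    active = _active_terms(df, terms)
    mat = patsy.dmatrix(_formula(active), df, return_type="dataframe")
    return np.asarray(mat), mat.design_info, active


@dataclass
class FitResult:
    """A fitted Tweedie regression.

    ``beta_hat`` is indexed by patsy column names; ``cov_beta`` is the
    coefficient covariance at the ML dispersion; ``term_slices`` maps each
    model term to its coefficient block.
    """

    beta_hat: pd.Series
    cov_beta: pd.DataFrame
    power_hat: float
    phi_hat: float
    deviance: float
    loglik: float
    aicc: float
    n_obs: int
    n_params: int
    terms: tuple[str, ...]
    term_slices: dict[str, slice]
    design_info: object
    data: pd.DataFrame = field(repr=False)
    spec: ModelSpec = field(repr=False, default=None)
    tube_sigma: float | None = None
    profile: pd.DataFrame | None = field(repr=False, default=None)

    @property
    def resid_df(self) -> int:
        return self.n_obs - self.n_params

    def predict_eta(self, grid: pd.DataFrame) -> np.ndarray:
        (X,) = patsy.build_design_matrices([self.design_info], grid)
        return np.asarray(X) @ self.beta_hat.values


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns via the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise FitError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); aliased: {bad or 'unknown'}"
        )


def _aicc(loglik: float, k: int, n: int) -> float:
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return float("inf")  # small-sample correction diverges
    return aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def fit(obs: ObservationSet | pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """Fit the log-link Tweedie regression defined by ``spec``.

    Coefficients are IRLS maximum likelihood for each candidate power;
    dispersion is profiled out by series-likelihood maximisation and the
    power index picked as the profile-likelihood argmax over
    ``spec.power_grid``.  Deterministic given data and spec.
    """
    spec = spec or ModelSpec()
    df = obs.to_frame() if isinstance(obs, ObservationSet) else obs.copy()
    y = np.asarray(df["frp_length"], dtype=float)
    if len(df) == 0:
        raise FitError("no observations")
    if np.all(y == 0):
        raise FitError("all responses are zero; the log-link mean model is degenerate")

    X, design_info, active = build_design(df, spec.fixed_terms)
    names = list(design_info.column_names)
    _check_design(X, names)

    # start IRLS from the intercept-only solution: robust when the model
    # fits (near-)perfectly and the default first-guess scale degenerates
    start = np.zeros(X.shape[1])
    intercept_idx = names.index("Intercept") if "Intercept" in names else 0
    start[intercept_idx] = np.log(y.mean())

    best = None
    rows = []
    for p in spec.power_grid:
        fam = sm.families.Tweedie(var_power=p, link=sm.families.links.Log())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam).fit(start_params=start, maxiter=300, tol=1e-10)
        mu = np.clip(res.fittedvalues, 1e-12, None)
        phi_hat, ll = estimate_phi_ml(y, mu, p)
        rows.append({"power": p, "phi": phi_hat, "loglik": ll})
        if best is None or ll > best["loglik"]:
            best = {"power": p, "phi": phi_hat, "loglik": ll, "res": res, "mu": mu}

    res = best["res"]
    phi_hat = best["phi"]
    p_hat = best["power"]
    k = X.shape[1] + 1 + (len(spec.power_grid) > 1)  # beta, phi, (power)
    loglik = best["loglik"]

    result = FitResult(
        beta_hat=pd.Series(res.params, index=names),
        cov_beta=pd.DataFrame(res.normalized_cov_params * phi_hat, index=names, columns=names),
        power_hat=p_hat,
        phi_hat=phi_hat,
        deviance=float(res.deviance),
        loglik=loglik,
        aicc=_aicc(loglik, k, len(y)),
        n_obs=len(y),
        n_params=X.shape[1],
        terms=tuple(active),
        term_slices={
            t.name(): design_info.term_name_slices[t.name()] for t in design_info.terms
        },
        design_info=design_info,
        data=df,
        spec=spec,
        profile=pd.DataFrame(rows),
    )
    if spec.include_tube_intercept:
        result = _refit_with_tube_intercept(result, y, X, df)
    return result


def _refit_with_tube_intercept(fx: FitResult, y, X, df) -> FitResult:
    """Marginal ML over a shared N(0, σ²) intercept per tube (Gauss–Hermite).

    The fixed-effects fit provides starting values; the likelihood
    integrates each tube's contribution over the intercept with 21-node
    Gauss–Hermite quadrature and is maximised over (β, log σ, log φ) at
    the fixed-effects power index.
    """
    tubes, tube_idx = np.unique(
        df["ecosystem"].astype(str) + "/" + df["tube_id"].astype(str), return_inverse=True
    )
    nodes, weights = np.polynomial.hermite_e.hermegauss(21)  # probabilists'
    log_w = np.log(weights) - 0.5 * np.log(2.0 * np.pi)
    p = fx.power_hat

    n_tubes = len(tubes)

    def nll(theta: np.ndarray) -> float:
        beta, log_sigma, log_phi = theta[:-2], theta[-2], theta[-1]
        sigma, phi = np.exp(log_sigma), np.exp(log_phi)
        eta = X @ beta
        # (n_obs, n_nodes) conditional log-densities in one broadcast call
        mu = np.exp(np.clip(eta[:, None] + sigma * nodes[None, :], -30.0, 30.0))
        ll_obs = tweedie_logpdf(y[:, None], mu, p, phi)
        # sum within tube for each node, then integrate per tube
        per_tube_node = np.zeros((n_tubes, len(nodes)))
        np.add.at(per_tube_node, tube_idx, ll_obs)
        return -float(np.sum(logsumexp(per_tube_node + log_w[None, :], axis=1)))

    theta0 = np.concatenate([fx.beta_hat.values, [np.log(0.25), np.log(fx.phi_hat)]])
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", options={"maxiter": 200})
    beta = res.x[:-2]
    sigma, phi = float(np.exp(res.x[-2])), float(np.exp(res.x[-1]))
    loglik = -float(res.fun)
    k = len(beta) + 2 + (len(fx.spec.power_grid) > 1)

    # observed-information covariance of beta via numerical Hessian
    hess = _numeric_hessian(nll, res.x)
    cov_all = np.linalg.pinv(hess)
    cov_beta = cov_all[: len(beta), : len(beta)]

    names = list(fx.beta_hat.index)
    return FitResult(
        beta_hat=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        power_hat=p,
        phi_hat=phi,
        deviance=fx.deviance,
        loglik=loglik,
        aicc=_aicc(loglik, k, fx.n_obs),
        n_obs=fx.n_obs,
        n_params=fx.n_params,
        terms=fx.terms,
        term_slices=fx.term_slices,
        design_info=fx.design_info,
        data=fx.data,
        spec=fx.spec,
        tube_sigma=sigma,
        profile=fx.profile,
    )


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    fx = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei) - f(x + ej) + fx
            ) / eps**2
    return h


@dataclass
class AnovaTable:
    """Type-III Wald chi-square tests, one row per model term."""

    table: pd.DataFrame  # columns: term, chi_square, df, p_value

    def __str__(self) -> str:
        lines = [f"{'Variable':<22}{'Chi-square':>12}{'df':>5}{'p':>12}"]
        for r in self.table.itertuples(index=False):
            p = "< 0.001" if r.p_value < 1e-3 else f"{r.p_value:.3f}"
            lines.append(f"{r.term:<22}{r.chi_square:>12.3f}{r.df:>5d}{p:>12}")
        return "\n".join(lines)


def _friendly_term(term: str) -> str:
    """Map patsy term names back to factor names (e.g. ``ecosystem:depth``)."""
    rev = {expr: name for name, (_, expr) in _FACTORS.items()}
    return ":".join(rev.get(piece, piece) for piece in term.split(":"))


def type3_anova(fx: FitResult, include_intercept: bool = True) -> AnovaTable:
    """Wald chi-square test of each term's coefficient block being zero.

    With sum-to-zero contrasts these are Type-III tests: each term is
    assessed in the presence of every other term, including interactions
    containing it.
    """
    rows = []
    cov = fx.cov_beta.values
    beta = fx.beta_hat.values
    for raw_term, sl in fx.term_slices.items():
        term = _friendly_term(raw_term)
        if term == "Intercept" and not include_intercept:
            continue
        b = beta[sl]
        v = cov[sl, sl]
        try:
            w = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular covariance for term {term!r}") from exc
        df_t = len(b)
        rows.append(
            {"term": term, "chi_square": w, "df": df_t, "p_value": float(chi2.sf(w, df_t))}
        )
    return AnovaTable(pd.DataFrame(rows))


@dataclass
class MarginalMeanTable:
    """Estimated marginal means on the response scale.

    Each row averages the linear predictor, with equal weights, over the
    levels of every factor not in ``by``, then back-transforms through the
    log link; SEs are delta-method.  Link-scale rows (``eta``, ``se_eta``)
    and the averaging matrix are retained for downstream contrasts.
    """

    by: tuple[str, ...]
    table: pd.DataFrame  # by-columns + mean, se, eta, se_eta
    L: np.ndarray = field(repr=False)  # averaged design rows, one per table row
    cov_beta: np.ndarray = field(repr=False)
    resid_df: int = 0

    def __len__(self) -> int:
        return len(self.table)


def marginal_means(fx: FitResult, by: Sequence[str] = ()) -> MarginalMeanTable:
    """Estimated marginal means per level-combination of the ``by`` factors.

    ``by=()`` gives the single grand mean; ``by`` equal to all model
    factors reproduces the fitted cell means exactly.
    """
    by = tuple(by)
    model_factors = {f for t in fx.terms for f in t.split(":")}
    for f in by:
        if f not in _FACTORS:
            raise ValueError(f"unknown factor {f!r}")
    # factors collapsed out of the model (single observed level) may still
    # be grouped on: they contribute one constant level to the grid
    grid_factors = sorted(model_factors | set(by), key=list(_FACTORS).index)

    levels = {}
    for f in grid_factors:
        col = _FACTORS[f][0]
        obs_col = fx.data[col]
        if isinstance(obs_col.dtype, pd.CategoricalDtype):
            levels[f] = [l for l in obs_col.cat.categories if l in set(obs_col)]
        else:
            levels[f] = sorted(obs_col.unique())

    # full reference grid, one row per cell
    grid = pd.DataFrame(
        list(itertools.product(*[levels[f] for f in grid_factors])),
        columns=[_FACTORS[f][0] for f in grid_factors],
    )
    for f in grid_factors:
        col = _FACTORS[f][0]
        if isinstance(fx.data[col].dtype, pd.CategoricalDtype):
            grid[col] = pd.Categorical(grid[col],
                                       categories=fx.data[col].cat.categories,
                                       ordered=True)
    (Xg,) = patsy.build_design_matrices([fx.design_info], grid)
    Xg = np.asarray(Xg)

    by_cols = [_FACTORS[f][0] for f in by]
    if by:
        groups = list(grid.groupby(by_cols, observed=True, sort=True).groups.items())
    else:
        groups = [((), grid.index)]

    L = np.vstack([Xg[idx].mean(axis=0) for _, idx in groups])
    eta = L @ fx.beta_hat.values
    var_eta = np.einsum("ij,jk,ik->i", L, fx.cov_beta.values, L)
    se_eta = np.sqrt(np.maximum(var_eta, 0.0))

    rows = []
    for (key, _), e, s in zip(groups, eta, se_eta):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by_cols, key))
        row.update(
            {"eta": e, "se_eta": s, "mean": float(np.exp(e)), "se": float(np.exp(e) * s)}
        )
        rows.append(row)
    return MarginalMeanTable(
        by=by,
        table=pd.DataFrame(rows),
        L=L,
        cov_beta=fx.cov_beta.values,
        resid_df=fx.resid_df,
    )


def pairwise_tukey(mm: MarginalMeanTable) -> pd.DataFrame:
    """All pairwise contrasts of marginal means with Tukey-adjusted p-values.

    Contrasts are on the link (log) scale, so ``estimate`` is a log ratio
    and ``ratio`` its back-transform.  Adjustment uses the studentised
    range with k = number of means and the model's residual df.
    """
    k = len(mm)
    if k < 2:
        return pd.DataFrame(
            columns=["level_1", "level_2", "estimate", "se", "ratio", "q", "p_adj"]
        )
    labels = [
        " / ".join(str(v) for v in row) if mm.by else "overall"
        for row in mm.table[[c for c in mm.table.columns if c not in
                             ("eta", "se_eta", "mean", "se")]].itertuples(index=False)
    ]
    eta = mm.table["eta"].values
    rows = []
    df = max(mm.resid_df, 1)
    for i, j in itertools.combinations(range(k), 2):
        l = mm.L[i] - mm.L[j]
        var = float(l @ mm.cov_beta @ l)
        se = float(np.sqrt(max(var, 0.0)))
        diff = float(eta[i] - eta[j])
        if se == 0.0:
            q = 0.0 if diff == 0.0 else np.inf
        else:
            q = abs(diff) / se * np.sqrt(2.0)
        p = float(studentized_range.sf(q, k, df)) if np.isfinite(q) else 0.0
        rows.append(
            {
                "level_1": labels[i],
                "level_2": labels[j],
                "estimate": diff,
                "se": se,
                "ratio": float(np.exp(diff)),
                "q": q,
                "p_adj": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)


def aicc_compare(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits (on identical data) by AICc, ascending, with ΔAICc."""
    ns = {f.n_obs for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits use different sample sizes: {sorted(ns)}")
    rows = [
        {
            "model": i,
            "terms": " + ".join(f.terms),
            "aicc": f.aicc,
            "loglik": f.loglik,
            "diverged": not np.isfinite(f.aicc),
        }
        for i, f in enumerate(fits)
    ]
    out = pd.DataFrame(rows).sort_values("aicc", kind="mergesort", ignore_index=True)
    out["delta_aicc"] = out["aicc"] - out["aicc"].iloc[0]
    return out
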