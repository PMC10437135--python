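"""Bayesian Gaussian (mixed) linear regression for unusualness.

Model
-----
For standardized response :math:`y_i` and covariates :math:`x_i`,

.. math::

    y_i = \\alpha + x_i^\\top \\beta + u_{j[i]} + \\varepsilon_i,
    \\quad u_j \\sim N(0, \\tau^2), \\quad \\varepsilon_i \\sim N(0, \\sigma^2)

with an optional society random intercept :math:`u_j`. Priors are weakly
informative: :math:`N(0, 2.5^2)` on intercept and slopes and
half-Student-t(3, 0, 2.5) on the scale parameters :math:`\\sigma, \\tau`.

Sampling uses a blocked Gibbs sampler. The half-t prior is represented as
an inverse-gamma scale mixture (sigma^2 | a ~ InvGamma(nu/2, nu/a),
a ~ InvGamma(1/2, 1/A^2)), which makes every conditional conjugate:
coefficients and group intercepts are Gaussian, variances inverse-gamma.
Convergence and efficiency are monitored with R-hat and effective sample
size (arviz); predictive comparison uses PSIS-LOO ELPD.

Two substantive model configurations mirror the study design:

* **Model 1** — contact/isolation/trait covariates plus a society random
  intercept (variance partitioned into marginal vs conditional R²);
* **Model 2** — the same covariates plus the society-mean-LOO "style"
  covariate in place of the random intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL1_EFFECTS = ["neighbours", "phylo_nn", "kinship_u", "economic_u"]
MODEL2_EFFECTS = MODEL1_EFFECTS + ["society_mean_loo"]

_NU = 3.0  # half-t degrees of freedom for scale priors


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one regression fit.

    ``iterations`` is the total per-chain length including ``warmup``
    (so the default 4 chains x 4000 iterations with 2000 warmup retains
    8000 posterior draws). ``ci_level`` is the equal-tailed credible
    interval mass (0.89 by default; ``hpd=True`` switches to HPD).
    """

    response: str = "response"
    fixed_effects: tuple[str, ...] = tuple(MODEL1_EFFECTS)
    group: str | None = "society_id"
    chains: int = 4
    iterations: int = 4000
    warmup: int = 2000
    ci_level: float = 0.89
    seed: int = 0
    coef_prior_sd: float = 2.5
    scale_prior_sd: float = 2.5
    hpd: bool = False
    intercept_only: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must lie in (0, 1)")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if not self.fixed_effects and not self.intercept_only:
            raise ValueError("fixed_effects empty; set intercept_only=True for a null model")


@dataclass
class ModelFit:
    """Posterior summaries and diagnostics for one fitted model."""

    spec: ModelSpec
    coef_names: list[str]
    summary: pd.DataFrame  # per-coefficient mean, sd, interval, rhat, ess
    sigma: float
    tau: float | None
    marginal_r2: float
    conditional_r2: float
    idata: az.InferenceData = field(repr=False)
    n_obs: int = 0
    row_ids: tuple = ()
    converged: bool = True
    max_rhat: float = 1.0
    _elpd: object | None = field(default=None, repr=False)

    def loo(self) -> az.ELPDData:
        """PSIS-LOO ELPD (cached)."""
        if self._elpd is None:
            self._elpd = az.loo(self.idata, pointwise=True)
        return self._elpd


def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def _gibbs_chain(
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray | None,
    n_groups: int,
    spec: ModelSpec,
    seed_seq: np.random.SeedSequence,
):
    """One chain; returns post-warmup draws of beta, sigma2, tau2, u."""
    rng = np.random.default_rng(seed_seq)
    n, p = X.shape
    XtX = X.T @ X
    prior_prec = np.eye(p) / spec.coef_prior_sd**2
    A2 = spec.scale_prior_sd**2

    # initial values: ridge solution and residual scale
    beta = np.linalg.solve(XtX + prior_prec, X.T @ y)
    resid = y - X @ beta
    sigma2 = max(float(resid @ resid) / max(n - p, 1), 1e-6)
    a_sigma = A2
    u = np.zeros(n_groups)
    tau2, a_tau = 0.25, A2

    keep = spec.iterations - spec.warmup
    out_beta = np.empty((keep, p))
    out_sigma2 = np.empty(keep)
    out_tau2 = np.empty(keep) if group_idx is not None else None
    out_u = np.empty((keep, n_groups)) if group_idx is not None else None

    for it in range(spec.iterations):
        zu = u[group_idx] if group_idx is not None else 0.0
        # beta | rest
        prec = XtX / sigma2 + prior_prec
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, X.T @ (y - zu) / sigma2)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
        r = y - X @ beta
        if group_idx is not None:
            # u_j | rest (independent across groups)
            nj = np.bincount(group_idx, minlength=n_groups)
            sj = np.bincount(group_idx, weights=r, minlength=n_groups)
            var_j = 1.0 / (nj / sigma2 + 1.0 / tau2)
            u = var_j * sj / sigma2 + np.sqrt(var_j) * rng.standard_normal(n_groups)
            # tau2 and its mixing parameter
            tau2 = _inv_gamma(rng, (_NU + n_groups) / 2, _NU / a_tau + 0.5 * float(u @ u))
            a_tau = _inv_gamma(rng, (_NU + 1) / 2, _NU / tau2 + 1.0 / A2)
            r = r - u[group_idx]
        # sigma2 and its mixing parameter
        sigma2 = _inv_gamma(rng, (_NU + n) / 2, _NU / a_sigma + 0.5 * float(r @ r))
        a_sigma = _inv_gamma(rng, (_NU + 1) / 2, _NU / sigma2 + 1.0 / A2)

        if it >= spec.warmup:
            k = it - spec.warmup
            out_beta[k] = beta
            out_sigma2[k] = sigma2
            if group_idx is not None:
                out_tau2[k] = tau2
                out_u[k] = u
    return out_beta, out_sigma2, out_tau2, out_u


def _log_lik(y, X, beta, sigma2, u, group_idx, chunk=500):
    """Pointwise conditional log-likelihood, (chains, draws, n)."""
    c, d, _ = beta.shape
    n = len(y)
    out = np.empty((c, d, n))
    for ci in range(c):
        for start in range(0, d, chunk):
            end = min(start + chunk, d)
            mu = beta[ci, start:end] @ X.T  # (chunk, n)
            if u is not None:
                mu = mu + u[ci, start:end][:, group_idx]
            s2 = sigma2[ci, start:end, None]
            out[ci, start:end] = -0.5 * (np.log(2 * np.pi * s2) + (y[None, :] - mu) ** 2 / s2)
    return out


def fit_model(predictors: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit the Gaussian (mixed) regression by Gibbs sampling.

    Uses complete-case rows (the ``complete`` flag when present, otherwise
    rows without missing values in the model columns). Raises on a singular
    fixed-effect design; a fit with any R-hat > 1.05 is returned with
    ``converged=False``.
    """
    fixed = [] if spec.intercept_only else list(spec.fixed_effects)
    cols = [spec.response] + fixed + ([spec.group] if spec.group else [])
    df = predictors
    if "complete" in df.columns:
        df = df[df["complete"]]
    df = df.dropna(subset=[c for c in cols if c in df.columns])
    n = len(df)
    if n == 0:
        raise ValueError("no complete-case rows to fit")
    if fixed and n < 10 * len(fixed):
        logger.warning("only %d rows for %d fixed effects (<10x)", n, len(fixed))

    y = df[spec.response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float) for c in fixed])
    coef_names = ["intercept"] + fixed
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix: collinear fixed effects")

    if spec.group:
        codes, groups = pd.factorize(df[spec.group].astype(str), sort=True)
        group_idx, n_groups = codes.astype(np.intp), len(groups)
    else:
        group_idx, n_groups, groups = None, 0, None

    seqs = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    draws = [
        _gibbs_chain(y, X, group_idx, n_groups, spec, s) for s in seqs
    ]
    beta = np.stack([d[0] for d in draws])  # (chains, keep, p)
    sigma2 = np.stack([d[1] for d in draws])
    tau2 = np.stack([d[2] for d in draws]) if spec.group else None
    u = np.stack([d[3] for d in draws]) if spec.group else None

    posterior = {name: beta[:, :, i] for i, name in enumerate(coef_names)}
    posterior["sigma"] = np.sqrt(sigma2)
    if spec.group:
        posterior["tau"] = np.sqrt(tau2)
        posterior["u"] = u
    log_lik = _log_lik(y, X, beta, sigma2, u, group_idx)
    dims = {"u": ["group"]} if spec.group else None
    coords = {"group": list(groups)} if spec.group else None
    idata = az.from_dict(
        posterior=posterior,
        log_likelihood={"y": log_lik},
        dims=dims,
        coords=coords,
    )

    scalar_vars = coef_names + ["sigma"] + (["tau"] if spec.group else [])
    rhat = az.rhat(idata, var_names=scalar_vars)
    ess = az.ess(idata, var_names=scalar_vars)
    max_rhat = float(max(rhat[v].item() for v in scalar_vars))
    converged = max_rhat <= 1.05
    if not converged:
        logger.warning("fit flagged non-converged: max R-hat %.3f", max_rhat)

    lo_q, hi_q = (1 - spec.ci_level) / 2, 1 - (1 - spec.ci_level) / 2
    rows = []
    for name in coef_names:
        d = posterior[name].reshape(-1)
        if spec.hpd:
            lo, hi = az.hdi(posterior[name], hdi_prob=spec.ci_level)
        else:
            lo, hi = np.quantile(d, [lo_q, hi_q])
        rows.append(
            {
                "coef": name,
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "rhat": float(rhat[name].item()),
                "ess_bulk": float(ess[name].item()),
            }
        )
    summary = pd.DataFrame(rows).set_index("coef")

    # variance partition per draw (Nakagawa-style, on the model variances)
    mu_fixed = beta.reshape(-1, X.shape[1]) @ X.T  # (draws, n)
    var_f = mu_fixed.var(axis=1, ddof=1)
    var_e = sigma2.reshape(-1)
    var_g = tau2.reshape(-1) if spec.group else np.zeros_like(var_e)
    denom = var_f + var_g + var_e
    marginal = float(np.mean(var_f / denom))
    conditional = float(np.mean((var_f + var_g) / denom))

    return ModelFit(
        spec=spec,
        coef_names=coef_names,
        summary=summary,
        sigma=float(np.sqrt(sigma2).mean()),
        tau=float(np.sqrt(tau2).mean()) if spec.group else None,
        marginal_r2=marginal,
        conditional_r2=conditional,
        idata=idata,
        n_obs=n,
        row_ids=tuple(df["unit_id"]) if "unit_id" in df.columns else tuple(df.index),
        converged=converged,
        max_rhat=max_rhat,
    )


def r2_partition(fit: ModelFit) -> tuple[float, float]:
    """(marginal, conditional) R²: fixed-effects share vs fixed+group share
    of the model variance, averaged over posterior draws. Models without a
    group effect have the two equal."""
    return fit.marginal_r2, fit.conditional_r2


def compare_elpd(fits: dict[str, ModelFit]) -> pd.DataFrame:
    """Rank models by PSIS-LOO ELPD on identical rows.

    Returns one row per model with ``elpd``, its SE, the difference to the
    best model and the SE of that difference (from pointwise ELPD values).
    Raises if the fits do not share the same observation set.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    row_sets = {name: f.row_ids for name, f in fits.items()}
    first = next(iter(row_sets.values()))
    if any(r != first for r in row_sets.values()):
        raise ValueError("fits were made on different row sets; refit on common rows")
    loos = {name: f.loo() for name, f in fits.items()}
    points = {name: np.asarray(l.loo_i) for name, l in loos.items()}
    best = max(loos, key=lambda nm: loos[nm].elpd_loo)
    rows = []
    for name, l in sorted(loos.items(), key=lambda kv: -kv[1].elpd_loo):
        diff = points[name] - points[best]
        rows.append(
            {
                "model": name,
                "elpd": float(l.elpd_loo),
                "se": float(l.se),
                "d_elpd": float(diff.sum()),
                "d_se": float(np.sqrt(len(diff) * diff.var(ddof=1))) if name != best else 0.0,
                "pareto_k_max": float(np.asarray(l.pareto_k).max()),
            }
        )
    return pd.DataFrame(rows).set_index("model")


def select_radius(
    predictor_variants: dict[float, pd.DataFrame],
    spec: ModelSpec,
    tie_threshold: float = 4.0,
) -> tuple[float, pd.DataFrame]:
    """Choose the neighbour-count radius by bivariate ELPD comparison.

    Fits ``response ~ neighbours`` with a society random intercept for each
    supplied radius and ranks by PSIS-LOO ELPD. Radii within
    ``tie_threshold`` of the best are flagged equivalent; the best-ranked is
    returned.
    """
    radii = sorted(predictor_variants)
    if len(radii) == 1:
        only = radii[0]
        return only, pd.DataFrame(
            [{"model": f"radius_{only:g}km", "elpd": np.nan, "tied_with_best": True}]
        ).set_index("model")
    bispec = replace(spec, fixed_effects=("neighbours",), intercept_only=False)
    fits = {
        f"radius_{r:g}km": fit_model(predictor_variants[r], bispec) for r in radii
    }
    table = compare_elpd(fits)
    table["tied_with_best"] = table["d_elpd"].abs() < tie_threshold
    chosen = float(table.index[0].removeprefix("radius_").removesuffix("km"))
    return chosen, table


def _held_out_lpd(test_df, spec, fit_arrays, coef_names):
    """log mean predictive density for held-out rows given posterior draws."""
    beta, sigma2, tau2, u, groups = fit_arrays
    fixed = [c for c in coef_names if c != "intercept"]
    Xt = np.column_stack(
        [np.ones(len(test_df))] + [test_df[c].to_numpy(dtype=float) for c in fixed]
    )
    yt = test_df[spec.response].to_numpy(dtype=float)
    mu = beta @ Xt.T  # (draws, m)
    var = sigma2[:, None] * np.ones_like(mu)
    if spec.group:
        glist = list(groups)
        gpos = {g: i for i, g in enumerate(glist)}
        for j, g in enumerate(test_df[spec.group].astype(str)):
            if g in gpos:
                mu[:, j] += u[:, gpos[g]]
            else:  # unseen group: marginalize over the random intercept
                var[:, j] += tau2
    ll = -0.5 * (np.log(2 * np.pi * var) + (yt[None, :] - mu) ** 2 / var)
    m = ll.max(axis=0)
    return m + np.log(np.exp(ll - m).mean(axis=0))  # log-mean-exp per point


def _flat_arrays(fit: ModelFit):
    post = fit.idata.posterior
    beta = np.column_stack(
        [post[name].values.reshape(-1) for name in fit.coef_names]
    )
    sigma2 = post["sigma"].values.reshape(-1) ** 2
    if fit.spec.group:
        tau2 = post["tau"].values.reshape(-1) ** 2
        u = post["u"].values.reshape(-1, post["u"].shape[-1])
        groups = list(post["group"].values)
    else:
        tau2, u, groups = None, None, None
    return beta, sigma2, tau2, u, groups


def kfold_cv(predictors: pd.DataFrame, spec: ModelSpec, k: int = 10, seed: int = 0) -> dict:
    """k-fold cross-validation by seeded shuffle and k refits.

    Returns per-row held-out log predictive density, the fold assignment,
    the total ``elpd_kfold`` and per-fold coefficient means (a stability
    check). Held-out rows from societies unseen in training are predicted
    with the random intercept marginalized out.
    """
    df = predictors
    if "complete" in df.columns:
        df = df[df["complete"]]
    df = df.reset_index(drop=True)
    n = len(df)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, k)):
        folds[chunk] = f

    lpd = np.empty(n)
    coef_by_fold = []
    for f in range(k):
        train, test = df[folds != f], df[folds == f]
        sub = replace(spec, seed=int(np.random.SeedSequence([spec.seed, f]).generate_state(1)[0] % (2**31)))
        fit = fit_model(train, sub)
        lpd[folds == f] = _held_out_lpd(test, spec, _flat_arrays(fit), fit.coef_names)
        coef_by_fold.append(fit.summary["mean"].rename(f"fold_{f}"))
    return {
        "elpd_kfold": float(lpd.sum()),
        "pointwise": pd.Series(lpd, index=df["unit_id"] if "unit_id" in df else df.index),
        "folds": folds,
        "coefficients": pd.concat(coef_by_fold, axis=1),
    }


def exact_refit_loo(predictors: pd.DataFrame, spec: ModelSpec) -> dict:
    """Exact leave-one-out: refit with each row held out in turn.

    Intended for small instances as an oracle for approximate LOO/k-fold.
    """
    df = predictors
    if "complete" in df.columns:
        df = df[df["complete"]]
    df = df.reset_index(drop=True)
    n = len(df)
    lpd = np.empty(n)
    for i in range(n):
        train = df.drop(index=i)
        test = df.iloc[[i]]
        sub = replace(spec, seed=int(np.random.SeedSequence([spec.seed, 7919, i]).generate_state(1)[0] % (2**31)))
        fit = fit_model(train, sub)
        lpd[i] = _held_out_lpd(test, spec, _flat_arrays(fit), fit.coef_names)[0]
    return {
        "elpd_loo": float(lpd.sum()),
        "pointwise": pd.Series(lpd, index=df["unit_id"] if "unit_id" in df else df.index),
    }
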