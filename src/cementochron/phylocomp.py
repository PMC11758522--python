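"""Phylogenetically informed regression and group comparison.

Traits of related species are not independent samples: under Brownian
motion (BM) their covariance is proportional to shared branch length.
Generalized least squares with that covariance (PGLS) gives unbiased
slopes and honest intervals for cross-species allometries such as body
mass vs life span.  This module provides:

* :func:`pgls_fit` — linear PGLS under BM;
* :func:`pgnlr_fit` — nonlinear (exponential) or linear mean models
  with BM or Ornstein-Uhlenbeck (OU) error structure, compared by
  maximum likelihood (AIC) and, secondarily, by rejection ABC;
* :func:`phylo_ancova` — slope-homogeneity and group-separation tests
  for two clades sharing a predictor;
* :func:`pooled_anova` — ordinary one-way ANOVA with Cohen's d and
  Shapiro-Wilk normality reporting for pooled growth-rate comparisons.

Trees are dendropy trees; tip labels are matched to trait tables
case-insensitively with spaces/underscores normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthgen import shared_path_matrix

__all__ = [
    "PglsFit",
    "pgls_fit",
    "pgnlr_fit",
    "phylo_ancova",
    "pooled_anova",
    "normalize_label",
]


def normalize_label(label: str) -> str:
    """Canonical tip-name form: lower case, underscores for spaces."""
    return label.strip().lower().replace(" ", "_")


def _align(tree, *series: pd.Series):
    """Shared-path matrix and trait vectors aligned on normalized names."""
    C, taxa = shared_path_matrix(tree)
    norm_taxa = [normalize_label(t) for t in taxa]
    frames = []
    for s in series:
        s = pd.Series(s)
        s.index = [normalize_label(str(i)) for i in s.index]
        frames.append(s)
    common = [t for t in norm_taxa if all(t in f.index for f in frames)]
    if len(common) < 3:
        raise ValueError("fewer than 3 tips with complete trait data")
    idx = [norm_taxa.index(t) for t in common]
    C = C[np.ix_(idx, idx)]
    return C, common, [f.loc[common].to_numpy(dtype=float) for f in frames]


def _chol_solve(V: np.ndarray):
    """Cholesky factor of V, with a clear error for singular trees."""
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "phylogenetic covariance matrix is singular — duplicated tips or "
            "zero-length terminal branch pairs make tip traits perfectly "
            "correlated; collapse duplicates or assign positive branch lengths"
        ) from None


def _gls(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """GLS by whitening: returns (beta, rss_gls, XtViX_inv, L)."""
    L = _chol_solve(V)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ Xw.T @ yw
    resid = yw - Xw @ beta
    return beta, float(resid @ resid), XtX_inv, L


@dataclass
class PglsFit:
    """Brownian-motion PGLS of y on x (both typically log10 traits)."""

    slope: float
    intercept: float
    r2: float
    sigma2: float
    ci95_slope: float  # half-width
    ci95_intercept: float
    n: int
    taxa: list[str] = field(default_factory=list)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def prediction_interval(self, x, X_design_info=None) -> np.ndarray:
        """Half-width of the 95% predictor interval at new x (approximate:
        ignores the phylogenetic position of the new tip)."""
        x = np.asarray(x, dtype=float)
        tcrit = stats.t.ppf(0.975, self.n - 2)
        return tcrit * np.sqrt(self.sigma2) * np.ones_like(x)


def pgls_fit(tree, x: pd.Series, y: pd.Series) -> PglsFit:
    """Linear PGLS under Brownian motion.

    On a star phylogeny (all tips equidistant from the root, no shared
    internal branches) the covariance is proportional to the identity
    and the estimates equal ordinary least squares exactly.

    r² is computed on the whitened (phylogenetically decorrelated)
    scale: 1 − RSS_gls / TSS_gls, with TSS from the GLS intercept-only
    model.
    """
    C, taxa, (xv, yv) = _align(tree, x, y)
    n = len(taxa)
    X = np.column_stack([np.ones(n), xv])
    beta, rss, XtX_inv, L = _gls(X, yv, C)
    beta0, tss, *_ = _gls(np.ones((n, 1)), yv, C)
    sigma2 = rss / (n - 2)
    tcrit = stats.t.ppf(0.975, n - 2)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    return PglsFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r2=float(1.0 - rss / tss) if tss > 0 else np.nan,
        sigma2=float(sigma2),
        ci95_slope=float(tcrit * se[1]),
        ci95_intercept=float(tcrit * se[0]),
        n=n,
        taxa=taxa,
    )


# ---------------------------------------------------------------------------
# nonlinear phylogenetic regression with BM/OU error structure


def _mean_models():
    return {
        "exponential": (
            lambda x, p: p[0] * np.exp(p[1] * x) + p[2],
            3,
        ),
        "linear": (
            lambda x, p: p[0] + p[1] * x,
            2,
        ),
    }


def _error_corr(C: np.ndarray, evolution: str, alpha: float) -> np.ndarray:
    """Tip correlation under BM (shared paths) or stationary OU."""
    if evolution == "brownian":
        return C / C.diagonal().mean()
    if evolution == "ou":
        depth = C.diagonal()
        d = depth[:, None] + depth[None, :] - 2.0 * C  # patristic distances
        return np.exp(-alpha * d)
    raise ValueError(f"unknown evolution model {evolution!r}")


def _profile_loglik(e: np.ndarray, V: np.ndarray) -> float:
    """Gaussian log-likelihood with the residual variance profiled out."""
    n = e.size
    L = _chol_solve(V)
    w = np.linalg.solve(L, e)
    s2 = float(w @ w) / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)


def _fit_one_pgnlr(xv, yv, C, mean_model, evolution):
    f, npar = _mean_models()[mean_model]
    # data-driven initial mean parameters
    b1 = np.polyfit(xv, yv, 1)
    if mean_model == "linear":
        p0s = [np.array([b1[1], b1[0]])]
    else:
        p0s = [
            np.array([yv.std() + 1e-3, s, yv.mean()]) for s in (0.3, -0.3, 1.0)
        ]

    def neg_ll(theta):
        with np.errstate(all="ignore"):
            p = theta[:npar]
            alpha = (
                np.exp(np.clip(theta[npar], -20.0, 12.0))
                if evolution == "ou"
                else None
            )
            e = yv - f(xv, p)
            if not np.all(np.isfinite(e)):
                return 1e10
            V = _error_corr(C, evolution, alpha if alpha is not None else 0.0)
        try:
            return -_profile_loglik(e, V + 1e-10 * np.eye(len(e)))
        except np.linalg.LinAlgError:
            return 1e10

    extra = [0.0] if evolution == "ou" else []
    best = None
    for p0 in p0s:
        theta0 = np.concatenate([p0, extra])
        sol = optimize.minimize(neg_ll, theta0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or sol.fun < best.fun:
            best = sol
    k = npar + 1 + (1 if evolution == "ou" else 0)  # + residual variance (+ alpha)
    alpha = (
        float(np.exp(np.clip(best.x[npar], -20.0, 12.0)))
        if evolution == "ou"
        else None
    )
    at_bound = evolution == "ou" and (alpha > 1e4 or alpha < 1e-6)
    return {
        "mean_model": mean_model,
        "evolution": evolution,
        "params": best.x[:npar],
        "alpha": alpha,
        "alpha_at_bound": bool(at_bound),
        "loglik": -float(best.fun),
        "aic": 2.0 * k + 2.0 * float(best.fun),
        "k": k,
    }


def pgnlr_fit(
    tree,
    x: pd.Series,
    y: pd.Series,
    mean_models: tuple[str, ...] = ("exponential", "linear"),
    evolutions: tuple[str, ...] = ("brownian", "ou"),
    abc_reps: int = 500,
    abc_quantile: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fit and compare phylogenetic nonlinear regression models.

    All combinations of mean model (exponential ``a·exp(b·x)+c`` or
    linear) and error structure (BM or stationary OU with rate alpha)
    are fitted by maximum likelihood (residual variance profiled out)
    and ranked by AIC.  A rejection-ABC comparison — simulate tip data
    under each fitted model with parameters drawn around the ML
    estimates, accept the ``abc_quantile`` of draws closest in RMS to
    the observed tips, and report each model's share of acceptances as
    a posterior probability — is run as a secondary check with
    ``abc_reps`` draws per model.

    Returns a dict with ``fits`` (per-combination results), ``best``
    (lowest AIC), and ``abc_posterior``.
    """
    if len(pd.Series(y)) < 5:
        raise ValueError("pgnlr_fit needs at least 5 tips")
    C, taxa, (xv, yv) = _align(tree, x, y)
    fits = [
        _fit_one_pgnlr(xv, yv, C, mm, ev)
        for mm in mean_models
        for ev in evolutions
    ]
    for fit in fits:
        if fit["alpha_at_bound"]:
            warnings.warn(
                f"OU rate alpha at bound for {fit['mean_model']}/ou; "
                "covariance is effectively independent or fully correlated",
                stacklevel=2,
            )
    best = min(fits, key=lambda f: f["aic"])

    # --- rejection ABC (secondary): wide parameter perturbations around ML
    rng = np.random.default_rng(seed)
    records = []
    for fit in fits:
        f, npar = _mean_models()[fit["mean_model"]]
        V = _error_corr(
            C, fit["evolution"], fit["alpha"] if fit["alpha"] is not None else 0.0
        )
        e_ml = yv - f(xv, fit["params"])
        L = _chol_solve(V + 1e-10 * np.eye(len(yv)))
        w = np.linalg.solve(L, e_ml)
        s_ml = np.sqrt(float(w @ w) / len(yv))
        scale = np.maximum(np.abs(fit["params"]), 0.1)
        for _ in range(abc_reps):
            p = fit["params"] + rng.uniform(-1.0, 1.0, npar) * scale
            s = s_ml * rng.uniform(0.5, 2.0)
            with np.errstate(all="ignore"):
                mu = f(xv, p)
            if not np.all(np.isfinite(mu)):
                continue
            ysim = mu + s * (L @ rng.standard_normal(len(yv)))
            dist = float(np.sqrt(np.mean((ysim - yv) ** 2)))
            records.append((f"{fit['mean_model']}/{fit['evolution']}", dist))
    dists = pd.DataFrame(records, columns=["model", "dist"])
    cutoff = dists["dist"].quantile(abc_quantile)
    accepted = dists[dists["dist"] <= cutoff]
    posterior = (accepted["model"].value_counts() / len(accepted)).to_dict()

    return {"fits": fits, "best": best, "abc_posterior": posterior, "taxa": taxa}


# ---------------------------------------------------------------------------
# phylogenetic ANCOVA


def phylo_ancova(tree, x: pd.Series, y: pd.Series, groups: pd.Series) -> dict:
    """Phylogenetic ANCOVA of two groups sharing a continuous predictor.

    Fits nested GLS models under the BM covariance and F-tests:

    * slope homogeneity — full model (separate slopes) vs common slope;
    * group separation — common slope model vs no group term.

    Reports F, degrees of freedom, p, and partial eta² for each test.
    """
    C, taxa, (xv, yv) = _align(tree, x, y)
    g = pd.Series(groups)
    g.index = [normalize_label(str(i)) for i in g.index]
    missing = [t for t in taxa if t not in g.index]
    if missing:
        raise ValueError(f"tips missing a group label: {missing[:5]}")
    gv = g.loc[taxa]
    levels = pd.unique(gv)
    if len(levels) != 2:
        raise ValueError("phylo_ancova needs exactly two groups")
    ind = (gv == levels[1]).to_numpy(dtype=float)
    for lev in levels:
        if (gv == lev).sum() < 3:
            raise ValueError(f"group {lev!r} has fewer than 3 tips")

    n = len(taxa)
    X_full = np.column_stack([np.ones(n), xv, ind, xv * ind])
    X_common = X_full[:, :3]
    X_nogroup = X_full[:, :2]
    _, rss_full, _, _ = _gls(X_full, yv, C)
    _, rss_common, _, _ = _gls(X_common, yv, C)
    _, rss_nogroup, _, _ = _gls(X_nogroup, yv, C)

    def ftest(rss_r, rss_f, q, df_f):
        F = ((rss_r - rss_f) / q) / (rss_f / df_f)
        p = stats.f.sf(F, q, df_f)
        eta2 = 1.0 - rss_f / rss_r if rss_r > 0 else 0.0
        return {"F": float(max(F, 0.0)), "df": (q, df_f), "p": float(p), "partial_eta2": float(max(eta2, 0.0))}

    return {
        "slope_test": ftest(rss_common, rss_full, 1, n - 4),
        "group_test": ftest(rss_nogroup, rss_common, 1, n - 3),
        "groups": list(levels),
        "n": n,
    }


# ---------------------------------------------------------------------------
# pooled ANOVA


def pooled_anova(group1, group2) -> dict:
    """One-way ANOVA between two pooled msGR samples, with effect size.

    Returns F, (df_between, df_within), p, Cohen's d (pooled-SD form;
    positive when group2's mean exceeds group1's), and per-group
    Shapiro-Wilk W/p (reported, never used to gate the test).
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    s2a, s2b = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(
        ((a.size - 1) * s2a + (b.size - 1) * s2b) / (a.size + b.size - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled variance; ANOVA undefined")
    F, p = stats.f_oneway(a, b)
    sw_a = stats.shapiro(a)
    sw_b = stats.shapiro(b)
    return {
        "F": float(F),
        "df": (1, a.size + b.size - 2),
        "p": float(p),
        "cohens_d": float((b.mean() - a.mean()) / pooled),
        "shapiro": {
            "group1": (float(sw_a.statistic), float(sw_a.pvalue)),
            "group2": (float(sw_b.statistic), float(sw_b.pvalue)),
        },
        "n": (int(a.size), int(b.size)),
    }
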