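"""Two-component beta-regression mixture for proportion responses.

Potential rubble cover is a proportion in [0, 1] whose distribution across
transects is strongly bimodal: most transects trap little rubble while a
minority is heavily susceptible. A single beta regression misfits such
data, so the response is modelled as a two-component mixture of beta
regressions, each with a logit-linked mean over depth-class and
aspect-class covariates and its own precision:

    y_i ~ pi * Beta(mu_1i * phi_1, (1 - mu_1i) * phi_1)
        + (1 - pi) * Beta(mu_2i * phi_2, (1 - mu_2i) * phi_2),
    logit(mu_ki) = x_i' beta_k.

Exact zeros and ones are first mapped into (0, 1) with the
Smithson-Verkuilen compression y* = (y (n - 1) + 0.5) / n. Fitting is by
EM with weighted maximum-likelihood M-steps and multiple seeded restarts;
Wald z statistics come from the observed information of the full mixture
likelihood.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, logit
from scipy.stats import chi2, norm
from statsmodels.tools.numdiff import approx_hess1

DESIGN_COLUMNS = ("intercept", "deep", "E", "S", "W")


def compress_proportions(y: np.ndarray, n_obs: int | None = None) -> np.ndarray:
    """Smithson-Verkuilen compression of [0, 1] responses into (0, 1).

    y* = (y * (n - 1) + 0.5) / n with n the number of observations in the
    analysed table (the default when ``n_obs`` is omitted).
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    n = y.size if n_obs is None else n_obs
    if n < 2:
        raise ValueError("compression needs at least 2 observations")
    return (y * (n - 1) + 0.5) / n


def build_design(
    table: pd.DataFrame, interaction: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Design matrix from depth_class/aspect_class columns.

    Dummy coding with references shallow and N: columns intercept, deep,
    E, S, W (plus deep x aspect interactions when requested).
    """
    n = len(table)
    deep = (table["depth_class"] == "deep").to_numpy(float)
    cols = [np.ones(n), deep]
    names = ["intercept", "deep"]
    for a in ("E", "S", "W"):
        cols.append((table["aspect_class"] == a).to_numpy(float))
        names.append(a)
    if interaction:
        for a in ("E", "S", "W"):
            cols.append(deep * (table["aspect_class"] == a).to_numpy(float))
            names.append(f"deep:{a}")
    return np.column_stack(cols), names


def _beta_loglik_terms(y, logit_y_terms, mu, phi):
    """Pointwise beta log-density in the mean-precision parameterisation."""
    ln_y, ln_1my = logit_y_terms
    a = mu * phi
    b = (1 - mu) * phi
    return gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1) * ln_y + (b - 1) * ln_1my


def _fit_weighted_beta(X, y, w, beta0, log_phi0):
    """Weighted ML beta regression (logit mean link, log precision).

    Maximises sum_i w_i log Beta(y_i; mu_i, phi) with analytic gradients;
    warm-started from the previous M-step for speed.
    """
    ln_y = np.log(y)
    ln_1my = np.log1p(-y)
    p = X.shape[1]

    def negloglik_grad(theta):
        beta, log_phi = theta[:p], theta[p]
        phi = np.exp(log_phi)
        eta = X @ beta
        mu = expit(eta)
        ll = w @ _beta_loglik_terms(y, (ln_y, ln_1my), mu, phi)
        ystar = ln_y - ln_1my
        mustar = digamma(mu * phi) - digamma((1 - mu) * phi)
        dmu = w * phi * (ystar - mustar) * mu * (1 - mu)
        gbeta = X.T @ dmu
        dphi = w @ (
            digamma(phi)
            - mu * digamma(mu * phi)
            - (1 - mu) * digamma((1 - mu) * phi)
            + mu * ln_y
            + (1 - mu) * ln_1my
        )
        glogphi = dphi * phi
        return -ll, -np.concatenate([gbeta, [glogphi]])

    theta0 = np.concatenate([beta0, [log_phi0]])
    res = minimize(negloglik_grad, theta0, jac=True, method="L-BFGS-B")
    return res.x[:p], res.x[p]


class BetaMixtureRegression:
    """Mixture of beta regressions fitted by EM, sklearn-style.

    Parameters
    ----------
    n_components : int
        Number of mixture components (2 for bimodal rubble-cover data; 1
        reduces to an ordinary beta regression).
    n_restarts : int
        Number of EM restarts; the first uses a deterministic
        quantile-split initialisation on logit(y), the rest random seeded
        splits. The best likelihood wins.
    tol : float
        Convergence tolerance on the relative log-likelihood change.
    max_iter : int
        Maximum EM iterations per restart.
    random_state : int or None
        Seed for the restart initialisations.

    Attributes (after fit)
    ----------------------
    coef_ : ndarray (n_components, n_features) — logit-scale coefficients,
        components sorted ascending by intercept.
    precision_ : ndarray (n_components,) — per-component phi.
    weights_ : ndarray (n_components,) — mixing proportions (sum to 1).
    posterior_ : ndarray (n, n_components) — responsibilities on the
        training data.
    labels_ : ndarray (n,) — argmax-posterior component (1-based; ties to
        the first component).
    loglik_ : float — maximised observed-data log-likelihood.
    loglik_path_ : ndarray — per-iteration log-likelihood of the winning
        restart (non-decreasing).
    bse_, zvalues_, pvalues_ : ndarray (n_components, n_features) — Wald
        inference from the observed information.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_restarts: int = 10,
        tol: float = 1e-8,
        max_iter: int = 1000,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "n_restarts": self.n_restarts,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "BetaMixtureRegression":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # ---- likelihood machinery -------------------------------------------------

    def _component_loglik(self, X, y, coefs, phis):
        """(n, K) matrix of per-component log densities."""
        ln_y, ln_1my = np.log(y), np.log1p(-y)
        out = np.empty((y.size, self.n_components))
        for k in range(self.n_components):
            mu = expit(X @ coefs[k])
            out[:, k] = _beta_loglik_terms(y, (ln_y, ln_1my), mu, phis[k])
        return out

    def _mixture_loglik(self, X, y, coefs, phis, weights):
        comp = self._component_loglik(X, y, coefs, phis) + np.log(weights)
        m = comp.max(axis=1, keepdims=True)
        return float(np.sum(m.squeeze(1) + np.log(np.exp(comp - m).sum(axis=1))))

    def _posteriors(self, X, y, coefs, phis, weights):
        comp = self._component_loglik(X, y, coefs, phis) + np.log(weights)
        comp -= comp.max(axis=1, keepdims=True)
        r = np.exp(comp)
        return r / r.sum(axis=1, keepdims=True)

    def _em(self, X, y, init_labels):
        K = self.n_components
        n, p = X.shape
        coefs = np.zeros((K, p))
        phis = np.full(K, 5.0)
        weights = np.full(K, 1.0 / K)
        # initial M-step from hard labels
        resp = np.zeros((n, K))
        resp[np.arange(n), init_labels] = 1.0
        resp = np.clip(resp, 1e-3, None)
        path = []
        for iteration in range(self.max_iter):
            for k in range(K):
                w = resp[:, k]
                coefs[k], log_phi = _fit_weighted_beta(
                    X, y, w, coefs[k], np.log(phis[k])
                )
                phis[k] = np.exp(log_phi)
            weights = resp.mean(axis=0)
            weights /= weights.sum()
            ll = self._mixture_loglik(X, y, coefs, phis, weights)
            if path and ll < path[-1] - 1e-6 * max(1.0, abs(path[-1])):
                raise RuntimeError(
                    f"EM log-likelihood decreased ({path[-1]:.6f} -> {ll:.6f})"
                )
            converged = path and abs(ll - path[-1]) <= self.tol * max(1.0, abs(path[-1]))
            path.append(ll)
            if converged:
                break
            resp = self._posteriors(X, y, coefs, phis, weights)
        return coefs, phis, weights, np.asarray(path)

    # ---- public API -----------------------------------------------------------

    def fit(self, X, y, feature_names: list[str] | None = None):
        """Fit the mixture to compressed proportions.

        X : (n, p) design matrix including the intercept column (see
            :func:`build_design`), or a DataFrame with depth_class /
            aspect_class columns to be expanded automatically.
        y : proportions strictly inside (0, 1); apply
            :func:`compress_proportions` first if zeros/ones occur.
        """
        if isinstance(X, pd.DataFrame) and "depth_class" in X.columns:
            X, feature_names = build_design(X)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X and y have incompatible shapes")
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError("responses must lie strictly in (0, 1); compress first")
        if y.size < self.n_components * X.shape[1] + self.n_components:
            raise ValueError("too few observations for the requested model")
        self.feature_names_ = list(feature_names) if feature_names else [
            f"x{j}" for j in range(X.shape[1])
        ]
        rng = np.random.default_rng(self.random_state)
        n = y.size
        z = logit(y)
        best = None
        for restart in range(max(1, self.n_restarts)):
            if self.n_components == 1:
                labels = np.zeros(n, dtype=int)
            elif restart == 0:
                # deterministic quantile split on logit(y)
                qs = np.quantile(z, np.linspace(0, 1, self.n_components + 1)[1:-1])
                labels = np.searchsorted(qs, z)
            else:
                centers = rng.choice(z, size=self.n_components, replace=False)
                labels = np.argmin(np.abs(z[:, None] - centers[None, :]), axis=1)
                if len(np.unique(labels)) < self.n_components:
                    continue
            try:
                coefs, phis, weights, path = self._em(X, y, labels)
            except (RuntimeError, FloatingPointError) as err:
                warnings.warn(f"EM restart {restart} failed: {err}")
                continue
            if best is None or path[-1] > best[3][-1]:
                best = (coefs, phis, weights, path)
            if self.n_components == 1:
                break
        if best is None:
            raise RuntimeError("EM failed to converge in every restart")
        coefs, phis, weights, path = best
        order = np.argsort(coefs[:, 0])  # identifiability: sort by intercept
        self.coef_ = coefs[order]
        self.precision_ = phis[order]
        self.weights_ = weights[order]
        self.loglik_path_ = path
        self.loglik_ = float(path[-1])
        if np.any(self.weights_ < 1e-3):
            warnings.warn("a mixture component is nearly empty (weight < 1e-3)")
        self.posterior_ = self._posteriors(X, y, self.coef_, self.precision_, self.weights_)
        self.labels_ = self.posterior_.argmax(axis=1) + 1
        self._wald(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _pack(self):
        parts = [self.coef_.ravel(), np.log(self.precision_)]
        if self.n_components > 1:
            parts.append(logit(self.weights_[:-1]))
        return np.concatenate(parts)

    def _unpack(self, theta):
        K, p = self.n_components, self.coef_.shape[1]
        coefs = theta[: K * p].reshape(K, p)
        phis = np.exp(theta[K * p : K * p + K])
        if K > 1:
            w = expit(theta[K * p + K :])
            weights = np.concatenate([w, [1 - w.sum()]])
        else:
            weights = np.ones(1)
        return coefs, phis, weights

    def _wald(self, X, y):
        """SEs, z and p values from the observed information (numeric Hessian)."""
        theta = self._pack()

        def nll(t):
            coefs, phis, weights = self._unpack(t)
            if np.any(phis <= 0) or np.any(weights <= 0) or np.any(weights >= 1):
                return np.inf
            return -self._mixture_loglik(X, y, coefs, phis, weights)

        K, p = self.n_components, self.coef_.shape[1]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hess = approx_hess1(theta, nll)
                cov = np.linalg.inv(hess)
            var = np.diag(cov)[: K * p]
            var = np.where(var > 0, var, np.nan)
            self.bse_ = np.sqrt(var).reshape(K, p)
        except np.linalg.LinAlgError:
            warnings.warn("observed information is singular; no Wald inference")
            self.bse_ = np.full((K, p), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.zvalues_ = self.coef_ / self.bse_
            self.pvalues_ = 2 * norm.sf(np.abs(self.zvalues_))

    def predict(self, X) -> np.ndarray:
        """Marginal mean proportion pi-weighted over components."""
        if isinstance(X, pd.DataFrame) and "depth_class" in X.columns:
            X, _ = build_design(X)
        X = np.asarray(X, dtype=float)
        mus = np.column_stack([expit(X @ b) for b in self.coef_])
        return mus @ self.weights_

    def summary(self) -> pd.DataFrame:
        """Coefficient table (component, variable, estimate, se, z, p)."""
        rows = []
        for k in range(self.n_components):
            for j, name in enumerate(self.feature_names_):
                rows.append(
                    {
                        "component": k + 1,
                        "variable": name,
                        "estimate": self.coef_[k, j],
                        "se": self.bse_[k, j],
                        "z": self.zvalues_[k, j],
                        "p": self.pvalues_[k, j],
                    }
                )
        return pd.DataFrame(rows)


def fit_beta_mixture(
    table: pd.DataFrame,
    n_components: int = 2,
    seed: int | None = 0,
    compress: bool = True,
    **kwargs,
) -> BetaMixtureRegression:
    """Fit the mixture to an observation table.

    The table needs columns proportion, depth_class, aspect_class. With
    ``compress`` (default) the Smithson-Verkuilen transform is applied
    with n equal to the table length.
    """
    X, names = build_design(table)
    y = table["proportion"].to_numpy(float)
    if compress:
        y = compress_proportions(y)
    model = BetaMixtureRegression(
        n_components=n_components, random_state=seed, **kwargs
    )
    return model.fit(X, y, feature_names=names)


def assign_components(fit: BetaMixtureRegression) -> np.ndarray:
    """1-based component labels by maximum posterior (ties -> component 1)."""
    post = fit.posterior_
    # argmax ties resolve to the lowest index, i.e. component 1
    return post.argmax(axis=1) + 1


def interaction_test(
    table: pd.DataFrame, seed: int | None = 0, **kwargs
) -> pd.DataFrame:
    """Likelihood-ratio test of the depth x aspect interaction per component.

    Observations are first assigned to mixture components by posterior
    probability; within each component an ordinary beta regression is fit
    with and without the three deep:aspect interaction terms and compared
    by a chi-square LRT on 3 degrees of freedom.
    """
    fit = fit_beta_mixture(table, seed=seed, **kwargs)
    labels = assign_components(fit)
    y_all = compress_proportions(table["proportion"].to_numpy(float))
    rows = []
    for k in (1, 2):
        sub = table[labels == k]
        y = y_all[labels == k]
        X0, _ = build_design(sub, interaction=False)
        X1, _ = build_design(sub, interaction=True)
        # degenerate designs (a component missing a covariate level) are
        # reduced to their non-constant full-rank columns
        m0 = BetaMixtureRegression(n_components=1, random_state=seed).fit(X0, y)
        m1 = BetaMixtureRegression(n_components=1, random_state=seed).fit(X1, y)
        lr = 2 * (m1.loglik_ - m0.loglik_)
        if lr < -1e-6:
            raise RuntimeError("nested log-likelihood ordering violated")
        df = X1.shape[1] - X0.shape[1]
        rows.append(
            {
                "component": k,
                "loglik_null": m0.loglik_,
                "loglik_interaction": m1.loglik_,
                "lr_statistic": max(lr, 0.0),
                "df": df,
                "p": chi2.sf(max(lr, 0.0), df),
            }
        )
    return pd.DataFrame(rows)
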