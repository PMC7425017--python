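"""Two-component Poisson mixture for USF interaction scores.

Hi-C ligation events come from two populations: random collisions between
fragments (low mean) and genuine proximity ligations (high mean).  The
observed score D_l of fragment pair l is modeled as

    D_l ~ omega_1 Poisson(lambda_1) + omega_2 Poisson(lambda_2),

with omega_1 + omega_2 = 1 and, by convention, lambda_1 <= lambda_2
(component 1 = random, component 2 = proximate).  Parameters are estimated
by EM; the E-step computes responsibilities

    p(k|l) = omega_k g_k(D_l; lambda_k) / sum_k' omega_k' g_k'(D_l; lambda_k'),

and the M-step sets omega_k to the mean responsibility and lambda_k to the
responsibility-weighted mean of D.  A bootstrap scheme with inner-fence
outlier trimming robustifies the point estimates.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

__all__ = ["PoissonMixture", "em_fit", "bic", "select_components",
           "bootstrap_fit", "inner_fence_mean"]


def _validate_scores(scores) -> np.ndarray:
    d = np.asarray(scores)
    if d.ndim == 2 and d.shape[1] == 1:  # sklearn-style column vector
        d = d.ravel()
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need a 1-D array of at least 2 scores")
    if np.any(d < 0) or not np.allclose(d, np.round(d)):
        raise ValueError("scores must be non-negative integers")
    d = d.astype(np.int64)
    if np.all(d == 0):
        raise ValueError("all scores are zero; Poisson means undefined")
    return d


def _poisson_logpmf(d: np.ndarray, lam: float) -> np.ndarray:
    lam = max(lam, 1e-300)
    return d * np.log(lam) - lam - gammaln(d + 1.0)


class PoissonMixture(BaseEstimator):
    """EM-fitted mixture of ``n_components`` Poisson distributions.

    Parameters
    ----------
    n_components : int, default 2
        Number of mixture components (2 for the random/proximate model;
        1 is supported for BIC comparison).
    tol : float, default 1e-6
        Convergence threshold on the change in log-likelihood.
    max_iter : int, default 1000
    init_weights, init_lambdas : array-like or None
        Explicit initialization.  Defaults: lambdas at the 25th and 90th
        score percentiles (random ligations dominate Hi-C libraries, so the
        low component starts near the bulk of the data), weights (0.9, 0.1).

    Attributes
    ----------
    weights_ : ndarray of shape (k,)
        Mixing proportions, summing to 1.
    lambdas_ : ndarray of shape (k,)
        Poisson means, sorted ascending.
    converged_ : bool
    degenerate_ : bool
        True when all scores are identical (lambdas tie, weights keep their
        initial values).
    n_iter_ : int
    loglik_ : float
        Final observed-data log-likelihood.
    loglik_path_ : ndarray
        Log-likelihood after each EM iteration (non-decreasing).
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-6,
                 max_iter: int = 1000, init_weights=None, init_lambdas=None):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.init_weights = init_weights
        self.init_lambdas = init_lambdas

    # -- core ------------------------------------------------------------

    def _initial_params(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = self.n_components
        if self.init_lambdas is not None:
            lam = np.asarray(self.init_lambdas, dtype=float)
        elif k == 1:
            lam = np.array([d.mean()])
        else:
            qs = np.linspace(25, 90, k)
            lam = np.maximum(np.percentile(d, qs).astype(float), 0.5)
            lam += np.arange(k) * 1e-6  # break exact ties in init
        if self.init_weights is not None:
            w = np.asarray(self.init_weights, dtype=float)
        elif k == 2:
            w = np.array([0.9, 0.1])
        else:
            w = np.full(k, 1.0 / k)
        if len(w) != k or len(lam) != k:
            raise ValueError("init arrays must have length n_components")
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("initial weights must be positive and sum to 1")
        return w.copy(), lam.copy()

    def fit(self, X, y=None):
        """Fit by EM on integer scores ``X`` (1-D or single-column 2-D)."""
        d = _validate_scores(X)
        # collapse to unique values: the likelihood depends on scores only
        # through their multiplicities, and Hi-C score supports are small
        vals, counts = np.unique(d, return_counts=True)
        n = d.size
        w, lam = self._initial_params(d)
        k = self.n_components

        self.degenerate_ = bool(vals.size == 1)
        if self.degenerate_:
            lam = np.full(k, float(vals[0]))

        loglik_path = []
        loglik = -np.inf
        converged = False
        resp = np.full((vals.size, k), 1.0 / k)
        for it in range(1, self.max_iter + 1):
            # E-step in log space
            log_comp = np.stack(
                [np.log(w[j]) + _poisson_logpmf(vals, lam[j]) for j in range(k)],
                axis=1,
            )
            log_norm = logsumexp(log_comp, axis=1)
            resp = np.exp(log_comp - log_norm[:, None])
            new_loglik = float(np.dot(counts, log_norm))
            loglik_path.append(new_loglik)
            if self.degenerate_:
                converged = True
                loglik = new_loglik
                break
            if np.isfinite(loglik) and abs(new_loglik - loglik) < self.tol:
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik
            # M-step
            nk = (resp * counts[:, None]).sum(axis=0)
            w = nk / n
            lam = (resp * (counts * vals)[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
            lam = np.maximum(lam, 1e-12)

        order = np.argsort(lam, kind="stable")
        self.weights_ = w[order]
        self.lambdas_ = lam[order]
        self.converged_ = converged
        self.n_iter_ = len(loglik_path)
        self.loglik_ = loglik
        self.loglik_path_ = np.asarray(loglik_path)
        self._order = order
        return self

    def score(self, X, y=None) -> float:
        """Observed-data log-likelihood of ``X`` under the fitted model."""
        d = _validate_scores(X)
        log_comp = np.stack(
            [np.log(self.weights_[j]) + _poisson_logpmf(d, self.lambdas_[j])
             for j in range(len(self.lambdas_))],
            axis=1,
        )
        return float(logsumexp(log_comp, axis=1).sum())

    def predict_proba(self, X) -> np.ndarray:
        """Responsibilities p(k | D_l); rows sum to 1."""
        d = _validate_scores(X)
        log_comp = np.stack(
            [np.log(self.weights_[j]) + _poisson_logpmf(d, self.lambdas_[j])
             for j in range(len(self.lambdas_))],
            axis=1,
        )
        return np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        """Hard component assignment (0 = random, 1 = proximate for k=2)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def bic(self, X) -> float:
        """p·ln(N) − 2·ln(L̂) with p = 2k−1 free parameters; lower is better."""
        d = _validate_scores(X)
        p = 2 * self.n_components - 1
        return p * np.log(d.size) - 2.0 * self.score(d)

    def to_dict(self) -> dict:
        out = {}
        for j in range(self.n_components):
            out[f"omega{j + 1}"] = float(self.weights_[j])
            out[f"lambda{j + 1}"] = float(self.lambdas_[j])
        out.update(loglik=float(self.loglik_), iterations=int(self.n_iter_),
                   converged=bool(self.converged_), degenerate=bool(self.degenerate_))
        return out


# ---------------------------------------------------------------------------
# functional wrappers


def em_fit(scores, init: PoissonMixture | None = None, tol: float = 1e-6,
           max_iter: int = 1000) -> tuple[PoissonMixture, np.ndarray]:
    """Fit the two-component mixture; returns (model, responsibilities)."""
    model = init if init is not None else PoissonMixture(tol=tol, max_iter=max_iter)
    model.fit(scores)
    return model, model.predict_proba(scores)


def bic(scores, model: PoissonMixture) -> float:
    return model.bic(scores)


def select_components(scores, tol: float = 1e-6, max_iter: int = 1000) -> dict:
    """BIC diagnostic comparing k=1 vs k=2 fits."""
    out = {}
    for k in (1, 2):
        m = PoissonMixture(n_components=k, tol=tol, max_iter=max_iter).fit(scores)
        out[k] = {"model": m, "bic": m.bic(scores)}
    out["best_k"] = min((1, 2), key=lambda k: out[k]["bic"])
    return out


def bootstrap_fit(scores, n_boot: int = 50, seed: int = 0, tol: float = 1e-6,
                  max_iter: int = 1000) -> PoissonMixture:
    """Bootstrap-robustified mixture fit.

    Each round resamples M observations with replacement from the M scores
    and refits by EM.  Per parameter, round estimates outside the inner
    fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are discarded and the mean of the
    survivors is returned; averaged weights are renormalized to sum to 1.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap rounds")
    d = _validate_scores(scores)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_boot):
        sample = rng.choice(d, size=d.size, replace=True)
        if np.all(sample == 0):
            continue
        m = PoissonMixture(tol=tol, max_iter=max_iter).fit(sample)
        if m.converged_:
            rows.append([m.weights_[0], m.weights_[1], m.lambdas_[0], m.lambdas_[1]])
    if not rows:
        raise RuntimeError("no bootstrap round converged")
    est = np.asarray(rows)
    trimmed = np.array([inner_fence_mean(est[:, p]) for p in range(4)])
    w = np.array([trimmed[0], trimmed[1]])
    w = w / w.sum()
    lam = np.sort(trimmed[2:4])
    model = PoissonMixture()
    model.weights_ = w
    model.lambdas_ = lam
    model.converged_ = True
    model.degenerate_ = bool(np.isclose(lam[0], lam[1]))
    model.n_iter_ = n_boot
    model.loglik_ = model.score(d)
    model.loglik_path_ = np.array([model.loglik_])
    model.bootstrap_estimates_ = est  # columns: omega1, omega2, lambda1, lambda2
    return model


def inner_fence_mean(estimates) -> float:
    """Mean after dropping values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]."""
    x = np.asarray(estimates, dtype=float)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    keep = (x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)
    return float(x[keep].mean())
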