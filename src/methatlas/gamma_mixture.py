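"""Two-component gamma mixture fitted by expectation-maximization.

Used to impute the promoter methylation of a silenced gene: across a
matched DNAm/expression compendium, promoter beta values of samples where
the gene is off are modeled as a mixture of a low- and a high-methylation
gamma component, and the mean of the high component is taken as the
imputed silent-state beta.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


def _solve_gamma_shape(c: float) -> float:
    """Solve log(a) - digamma(a) = c for the gamma shape a (c > 0)."""
    if c <= 0:
        # zero-variance weighted sample; push toward a very peaked gamma
        return 1e6

    def f(log_a: float) -> float:
        a = np.exp(log_a)
        return np.log(a) - special.digamma(a) - c

    # log(a) - digamma(a) is decreasing in a, ~1/(2a) for large a
    lo, hi = -12.0, 16.0
    if f(lo) < 0:
        return float(np.exp(lo))
    if f(hi) > 0:
        return float(np.exp(hi))
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-12)))


def _weighted_gamma_mle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted maximum-likelihood gamma (shape, rate) estimates."""
    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    mean_log = float((w * np.log(x)).sum() / wsum)
    c = np.log(mean) - mean_log
    shape = _solve_gamma_shape(c)
    rate = shape / mean
    return shape, rate


class TwoGammaMixture(BaseEstimator):
    """EM fit of a two-state gamma mixture on strictly positive values.

    Components are ordered by increasing mean, so index 1 is the
    high-methylation state. The M-step solves the weighted gamma
    likelihood exactly (shape via the digamma equation), which makes the
    log-likelihood non-decreasing across iterations.

    Parameters
    ----------
    max_iter : int
        Maximum EM iterations.
    tol : float
        Convergence threshold on the log-likelihood increase.
    n_init : int
        Number of initializations; the first splits the data at the
        median, further ones split at random quantiles drawn from the
        seeded generator. The best final log-likelihood wins.
    min_samples : int
        Minimum number of observations required.
    random_state : int
        Seed for the extra initializations.

    Attributes
    ----------
    shapes_, rates_ : ndarray of shape (2,)
    weights_ : ndarray of shape (2,)
        Mixing proportions.
    means_ : ndarray of shape (2,)
        Component means shape/rate, ascending.
    loglik_trace_ : ndarray
        Log-likelihood after every EM iteration of the winning run.
    responsibilities_ : ndarray of shape (n, 2)
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        max_iter: int = 500,
        tol: float = 1e-8,
        n_init: int = 1,
        min_samples: int = 20,
        random_state: int = 0,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.min_samples = min_samples
        self.random_state = random_state

    def fit(self, X, y=None) -> "TwoGammaMixture":
        x = np.asarray(X, dtype=float).ravel()
        if x.size < self.min_samples:
            raise ValueError(
                f"need at least {self.min_samples} values, got {x.size}"
            )
        if (x <= 0).any():
            raise ValueError("gamma mixture requires strictly positive values")
        if np.ptp(x) == 0:
            raise ValueError("degenerate input: all values identical")
        rng = np.random.default_rng(self.random_state)
        quantiles = [0.5] + [rng.uniform(0.25, 0.75) for _ in range(self.n_init - 1)]
        best = None
        for q in quantiles:
            run = self._fit_once(x, q)
            if best is None or run["loglik"][-1] > best["loglik"][-1]:
                best = run
        self.shapes_ = best["shapes"]
        self.rates_ = best["rates"]
        self.weights_ = best["weights"]
        self.means_ = self.shapes_ / self.rates_
        self.loglik_trace_ = np.asarray(best["loglik"])
        self.responsibilities_ = best["resp"]
        self.n_iter_ = len(best["loglik"])
        self.converged_ = best["converged"]
        return self

    def _fit_once(self, x: np.ndarray, split_quantile: float) -> dict:
        cut = np.quantile(x, split_quantile)
        low = x <= cut
        if low.all() or (~low).all():
            order = np.argsort(x)
            low = np.zeros_like(x, dtype=bool)
            low[order[: x.size // 2]] = True
        shapes = np.empty(2)
        rates = np.empty(2)
        for j, mask in enumerate([low, ~low]):
            xj = x[mask]
            m, v = xj.mean(), xj.var()
            v = max(v, 1e-8 * m * m + 1e-12)
            shapes[j] = m * m / v
            rates[j] = m / v
        weights = np.array([low.mean(), 1 - low.mean()])

        loglik: list[float] = []
        converged = False
        resp = np.full((x.size, 2), 0.5)
        for _ in range(self.max_iter):
            logp = np.column_stack(
                [
                    np.log(weights[j])
                    + stats.gamma.logpdf(x, shapes[j], scale=1.0 / rates[j])
                    for j in range(2)
                ]
            )
            norm = special.logsumexp(logp, axis=1)
            ll = float(norm.sum())
            resp = np.exp(logp - norm[:, None])
            if loglik and ll - loglik[-1] < self.tol:
                loglik.append(max(ll, loglik[-1]))
                converged = True
                break
            loglik.append(ll)
            weights = resp.mean(axis=0)
            weights = np.clip(weights, 1e-10, None)
            weights /= weights.sum()
            for j in range(2):
                shapes[j], rates[j] = _weighted_gamma_mle(x, resp[:, j])
        order = np.argsort(shapes / rates)
        return {
            "shapes": shapes[order],
            "rates": rates[order],
            "weights": weights[order],
            "resp": resp[:, order],
            "loglik": loglik,
            "converged": converged,
        }

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "shapes_")
        x = np.asarray(X, dtype=float).ravel()
        logp = np.column_stack(
            [
                np.log(self.weights_[j])
                + stats.gamma.logpdf(x, self.shapes_[j], scale=1.0 / self.rates_[j])
                for j in range(2)
            ]
        )
        return np.exp(logp - special.logsumexp(logp, axis=1)[:, None])

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per observation."""
        check_is_fitted(self, "shapes_")
        x = np.asarray(X, dtype=float).ravel()
        logp = np.column_stack(
            [
                np.log(self.weights_[j])
                + stats.gamma.logpdf(x, self.shapes_[j], scale=1.0 / self.rates_[j])
                for j in range(2)
            ]
        )
        return float(special.logsumexp(logp, axis=1).mean())


def fit_gamma_mixture(
    values,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
    n_init: int = 1,
) -> TwoGammaMixture:
    """Fit a two-state gamma mixture; see :class:`TwoGammaMixture`."""
    return TwoGammaMixture(
        max_iter=max_iter, tol=tol, n_init=n_init, random_state=seed
    ).fit(values)
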