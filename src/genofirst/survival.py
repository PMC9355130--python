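"""Age-scale survival estimation: Kaplan-Meier and Cox proportional hazards.

Both estimators are implemented from first principles (the point of this
module), in fitter style: construct, ``fit``, then read trailing-underscore
attributes.

* ``KaplanMeierEstimator`` - product-limit survival with Greenwood variance
  and a log-log-transformed 95% confidence band (keeps the bounds inside
  [0, 1]); cumulative incidence is reported as 1 - S(t).
* ``CoxPH`` - partial-likelihood maximization by Newton-Raphson with Efron
  (default) or Breslow handling of tied event times, standard errors from
  the observed information, Wald confidence intervals, and step-halving on
  likelihood decrease.  Monotone-likelihood divergence (a covariate group
  with all or no events) is detected and raised, never silently returned.

Time is age from birth; delayed entry (age at recruitment) is available via
``entry`` for sensitivity analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .domain import ConvergenceError

_Z95 = 1.959963984540054


class KaplanMeierEstimator:
    """Product-limit estimator of S(t) with Greenwood 95% bands."""

    def __init__(self, alpha: float = 0.05):
        if not (0 < alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        self.alpha = alpha

    def fit(self, durations, events, entry=None) -> "KaplanMeierEstimator":
        durations = np.asarray(durations, dtype=float)
        events = np.asarray(events, dtype=bool)
        if durations.size == 0:
            raise ValueError("at least one record is required")
        if durations.shape != events.shape:
            raise ValueError("durations and events must align")
        if entry is not None:
            entry = np.asarray(entry, dtype=float)
            if np.any(entry >= durations):
                raise ValueError("entry age must precede exit age")

        times = np.unique(durations[events])
        n_risk = np.empty(len(times), dtype=int)
        n_event = np.empty(len(times), dtype=int)
        for i, t in enumerate(times):
            at_risk = durations >= t
            if entry is not None:
                at_risk &= entry < t
            n_risk[i] = at_risk.sum()
            n_event[i] = (events & (durations == t)).sum()

        frac = 1.0 - n_event / n_risk
        surv = np.cumprod(frac)
        # Greenwood: var(S) = S^2 * cumsum d / (n (n - d))
        with np.errstate(divide="ignore", invalid="ignore"):
            green = np.cumsum(n_event / (n_risk * (n_risk - n_event)))
            var = surv**2 * green  # 0 * inf -> nan only where S = 0

        z = _Z95 if self.alpha == 0.05 else float(-_norm_ppf(self.alpha / 2))
        lo = np.empty_like(surv)
        hi = np.empty_like(surv)
        for i, s in enumerate(surv):
            if s <= 0.0 or s >= 1.0 or not np.isfinite(green[i]):
                lo[i], hi[i] = (0.0, 0.0) if s <= 0 else (s, s)
                continue
            # log(-log S) scale keeps the band inside [0, 1]
            se_c = np.sqrt(green[i]) / abs(np.log(s))
            lo[i] = s ** np.exp(z * se_c)
            hi[i] = s ** np.exp(-z * se_c)

        self.event_times_ = times
        self.n_risk_ = n_risk
        self.n_event_ = n_event
        self.survival_ = surv
        self.variance_ = var
        self.ci_lower_ = lo
        self.ci_upper_ = hi
        return self

    def survival_at(self, age: float) -> float:
        i = np.searchsorted(self.event_times_, age, side="right") - 1
        return 1.0 if i < 0 else float(self.survival_[i])

    def cumulative_incidence_at(self, age: float) -> tuple[float, tuple[float, float]]:
        """Step-function 1 - S at the largest event time <= age, with CI."""
        i = np.searchsorted(self.event_times_, age, side="right") - 1
        if i < 0:
            return 0.0, (0.0, 0.0)
        return (
            float(1.0 - self.survival_[i]),
            (float(1.0 - self.ci_upper_[i]), float(1.0 - self.ci_lower_[i])),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.event_times_,
                "n_risk": self.n_risk_,
                "n_event": self.n_event_,
                "survival": self.survival_,
                "ci_lower": self.ci_lower_,
                "ci_upper": self.ci_upper_,
                "cumulative_incidence": 1.0 - self.survival_,
            }
        )


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


class CoxPH:
    """Cox proportional-hazards regression on the age scale.

    Parameters
    ----------
    ties:
        "efron" (default, matches the reference R implementation) or
        "breslow"; the two agree exactly when no event times are tied.
    tol:
        Newton stop criterion on the gradient max-norm.
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-9, max_iter: int = 50):
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, durations, events, X) -> "CoxPH":
        t = np.asarray(durations, dtype=float)
        d = np.asarray(events, dtype=bool)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if t.shape[0] != n or d.shape[0] != n:
            raise ValueError("durations, events and X must align")
        if not d.any():
            raise ValueError("at least one event is required")

        # sort ascending by time; within a time, events processed as a tied set
        order = np.argsort(t, kind="stable")
        t, d, X = t[order], d[order], X[order]
        # center covariates for numerical stability
        xbar = X.mean(axis=0)
        Xc = X - xbar

        beta = np.zeros(p)
        ll = self._loglik(beta, t, d, Xc)[0]
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            ll, grad, info = self._loglik(beta, t, d, Xc, derivs=True)
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as err:
                raise ConvergenceError(f"singular information matrix: {err}") from err
            # step-halving on likelihood decrease; the tolerance is relative
            # because round-off in the partial log-likelihood scales with |ll|
            ll_tol = 1e-10 * (abs(ll) + 1.0)
            new_beta = beta + step
            new_ll = self._loglik(new_beta, t, d, Xc)[0]
            halvings = 0
            while new_ll < ll - ll_tol and halvings < 30:
                step /= 2.0
                new_beta = beta + step
                new_ll = self._loglik(new_beta, t, d, Xc)[0]
                halvings += 1
            beta = new_beta
            if np.max(np.abs(beta)) > 50:
                raise ConvergenceError(
                    "diverging coefficient (|beta| > 50): likely a monotone "
                    "partial likelihood - a covariate level with all or no events"
                )
        else:
            ll, grad, info = self._loglik(beta, t, d, Xc, derivs=True)
            converged = bool(np.max(np.abs(grad)) < self.tol)
        if not converged:
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {self.max_iter} iterations"
            )

        _, grad, info = self._loglik(beta, t, d, Xc, derivs=True)
        cov = np.linalg.inv(info)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))
        # a monotone partial likelihood flattens out at an absurd boundary:
        # huge coefficient with an exploding standard error
        if np.any(np.abs(beta) > 15) or not np.all(np.isfinite(se)) or np.any(se > 100):
            raise ConvergenceError(
                "diverging coefficient estimate: monotone partial likelihood "
                "(a covariate level with all or no events)"
            )
        self.coef_ = beta
        self.se_ = se
        self.hr_ = np.exp(beta)
        self.ci95_ = np.exp(np.stack([beta - _Z95 * se, beta + _Z95 * se], axis=1))
        self.loglik_ = float(ll)
        self.n_iter_ = n_iter
        self.converged_ = True
        self.score_norm_ = float(np.max(np.abs(grad)))
        return self

    def _loglik(self, beta, t, d, X, derivs: bool = False):
        """Partial log-likelihood (and gradient / information if asked).

        Inputs are pre-sorted ascending in time.  Risk-set aggregates are
        suffix sums; tied events at one time use the Efron correction
        (each tied subject's own contribution leaves the denominator in
        equal fractions) unless Breslow is selected.
        """
        n, p = X.shape
        eta = X @ beta
        eta -= eta.max()  # overflow guard; the partial likelihood is shift-invariant
        w = np.exp(eta)
        wX = w[:, None] * X
        # suffix sums over the risk set {j : t_j >= t_i}
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wX[::-1], axis=0)[::-1]
        if derivs:
            wXX = wX[:, :, None] * X[:, None, :]
            S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

        # risk-set aggregates are evaluated at the first index of each time
        first_idx = np.searchsorted(t, t, side="left")
        ev_idx = np.nonzero(d)[0]
        ev_first = first_idx[ev_idx]
        tied = len(np.unique(t[ev_idx])) < len(ev_idx)
        if self.ties == "breslow" or not tied:
            # vectorized path: Efron and Breslow coincide without tied events
            r1 = S1[ev_first] / S0[ev_first, None]
            ll = float(eta[ev_idx].sum() - np.log(S0[ev_first]).sum())
            if not derivs:
                return (ll,)
            grad = (X[ev_idx] - r1).sum(axis=0)
            info = (S2[ev_first] / S0[ev_first, None, None]).sum(axis=0)
            info -= np.einsum("ip,iq->pq", r1, r1)
            return ll, grad, info

        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        i = 0
        while i < n:
            j = i
            while j < n and t[j] == t[i]:
                j += 1
            ev = np.nonzero(d[i:j])[0] + i
            m = len(ev)
            if m:
                s0 = S0[i]
                s1 = S1[i]
                s2 = S2[i] if derivs else None
                xd = X[ev]
                wd = w[ev]
                ll += eta[ev].sum()
                if self.ties == "efron" and m > 1:
                    d0 = wd.sum()
                    d1 = (wd[:, None] * xd).sum(axis=0)
                    d2 = (
                        (wd[:, None, None] * xd[:, :, None] * xd[:, None, :]).sum(axis=0)
                        if derivs
                        else None
                    )
                else:
                    d0, d1, d2 = 0.0, 0.0, 0.0
                for l in range(m):
                    f = l / m if (self.ties == "efron" and m > 1) else 0.0
                    denom = s0 - f * d0
                    ll -= np.log(denom)
                    if derivs:
                        num = s1 - f * d1
                        grad -= num / denom
                        a = (s2 - f * d2) / denom
                        b = np.outer(num, num) / denom**2
                        info += a - b
                if derivs:
                    grad += xd.sum(axis=0)
            i = j
        return (ll, grad, info) if derivs else (ll,)
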