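"""Multivariate Cox model building with the study protocol.

Procedure: every candidate covariate is screened univariately and kept
when its Wald p-value is below ``screen_alpha`` (0.20 by default); the
survivors enter a joint model; covariates are then removed backward one
at a time — at each step the covariate whose omission is least harmful
by the likelihood-ratio test is dropped, until every remaining covariate
has an LR removal p-value below ``stay_alpha``. Model stability is
assessed by refitting the whole screen-plus-backward procedure on
bootstrap resamples of patients and recording how often each candidate
ends up in the final model.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .survival import CoxResult, SurvivalData, cox_fit


def _fast_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
              max_iter: int = 50, tol: float = 1e-9
              ) -> tuple[np.ndarray, float, np.ndarray]:
    """Newton-Raphson maximisation of the Cox partial likelihood (Efron ties).

    Lean inner-loop fitter used by the screening / backward-elimination /
    bootstrap machinery, where only coefficients, standard errors and the
    log-likelihood are needed. Returns (beta, log-likelihood, covariance).
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    X = X[order]
    t = time[order]
    e = event[order]
    # tied-time groups, ascending
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    ends = np.r_[starts[1:], n]
    # per-group event counts; groups with d == 1 (no event ties) are the
    # common case and are fully vectorised, d >= 2 groups fall back to a loop
    d_g = np.add.reduceat(e.astype(int), starts)
    single = np.flatnonzero(d_g == 1)
    multi = np.flatnonzero(d_g >= 2)
    ev = np.flatnonzero(e)

    beta = np.zeros(p)
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        eta = eta - eta.max()  # guard overflow; offset cancels exactly
        w = np.exp(eta)
        wx = w[:, None] * X
        wxx = np.einsum("i,ij,ik->ijk", w, X, X)
        # suffix (at-risk) cumulative sums from the end
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wx[::-1], axis=0)[::-1]
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

        ll = float(eta[ev].sum())
        grad = X[ev].sum(axis=0)
        hess = np.zeros((p, p))

        if len(single):
            s = starts[single]
            phi0 = S0[s]
            phi1 = S1[s]
            r1 = phi1 / phi0[:, None]
            ll -= float(np.log(phi0).sum())
            grad -= r1.sum(axis=0)
            hess -= (np.einsum("gij,g->ij", S2[s], 1.0 / phi0)
                     - np.einsum("gi,gj->ij", r1, r1))
        for gi in multi:
            s, f = starts[gi], ends[gi]
            d_idx = np.flatnonzero(e[s:f]) + s
            d = len(d_idx)
            tie0 = w[d_idx].sum()
            tie1 = wx[d_idx].sum(axis=0)
            tie2 = wxx[d_idx].sum(axis=0)
            frac = np.arange(d) / d
            phi0 = S0[s] - frac * tie0                        # (d,)
            phi1 = S1[s][None, :] - frac[:, None] * tie1      # (d, p)
            phi2 = S2[s][None] - frac[:, None, None] * tie2   # (d, p, p)
            ll -= float(np.log(phi0).sum())
            grad -= (phi1 / phi0[:, None]).sum(axis=0)
            hess -= (np.einsum("kij,k->ij", phi2, 1.0 / phi0)
                     - np.einsum("ki,kj,k->ij", phi1, phi1, 1.0 / phi0 ** 2))
        if not np.isfinite(ll):
            raise ValueError("Cox partial likelihood diverged")
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular information matrix: {err}") from err
        beta = beta + step
        if abs(ll - ll_prev) < tol:
            ll_prev = ll
            break
        ll_prev = ll
    else:
        if np.max(np.abs(step)) > 1e-4:
            raise ValueError("Cox fit failed to converge (possible separation)")
    cov = np.linalg.inv(info)
    # report the ll with the eta offset removed: offset cancels exactly
    return beta, float(ll_prev), cov


def _fast_wald_p(X: pd.DataFrame, surv: SurvivalData) -> dict:
    """Univariate Wald p-value and |z| per column via the lean fitter."""
    out = {}
    for c in X.columns:
        try:
            beta, _, cov = _fast_cox(X[[c]].to_numpy(float), surv.time,
                                     surv.event)
            z = beta[0] / np.sqrt(cov[0, 0])
            out[c] = (2.0 * stats.norm.sf(abs(z)), abs(z))
        except ValueError:
            out[c] = (1.0, 0.0)
    return out


def _drop_collinear(X: pd.DataFrame, surv: SurvivalData,
                    wald: dict | None = None) -> pd.DataFrame:
    """Reduce X to a full-rank column set.

    Among exactly collinear columns the one with the larger univariate
    Wald |z| is kept; ties broken by column order.
    """
    cols = list(X.columns)
    if wald is None:
        wald = _fast_wald_p(X, surv)
    order = sorted(cols, key=lambda c: (-wald[c][1], cols.index(c)))
    kept: list[str] = []
    M = X.to_numpy(float)
    M = M - M.mean(axis=0)
    for c in order:
        trial = kept + [c]
        sub = M[:, [cols.index(k) for k in trial]]
        if np.linalg.matrix_rank(sub) == len(trial):
            kept.append(c)
    return X[[c for c in cols if c in kept]]


def _empty_result() -> CoxResult:
    summary = pd.DataFrame(columns=["coef", "se", "z", "hr", "ci_low", "ci_high", "p"])
    summary.index.name = "covariate"
    return CoxResult(summary=summary, log_likelihood=float("nan"), included=())


def _screen(X: pd.DataFrame, surv: SurvivalData, screen_alpha: float) -> list[str]:
    varying = X[[c for c in X.columns if X[c].nunique() > 1]]
    wald = _fast_wald_p(varying, surv)
    return [c for c in varying.columns if wald[c][0] < screen_alpha]


def _ll_of(X: pd.DataFrame, cols: list, surv: SurvivalData) -> float:
    if not cols:
        return _null_log_likelihood(surv)
    _, ll, _ = _fast_cox(X[cols].to_numpy(float), surv.time, surv.event)
    return ll


def _backward(X: pd.DataFrame, surv: SurvivalData, stay_alpha: float,
              wald: dict | None = None) -> list[str]:
    X = X[[c for c in X.columns if X[c].nunique() > 1]]
    if X.shape[1] == 0:
        return []
    current = list(_drop_collinear(X, surv, wald).columns)
    while current:
        try:
            ll_full = _ll_of(X, current, surv)
        except ValueError:
            # degenerate model (e.g. separation in a bootstrap resample):
            # fall back to dropping the weakest covariate outright
            wald = _fast_wald_p(X[current], surv)
            current.remove(min(current, key=lambda c: wald[c][1]))
            continue
        removal_p = {}
        for c in current:
            rest = [k for k in current if k != c]
            try:
                ll_red = _ll_of(X, rest, surv)
            except ValueError:
                removal_p[c] = 0.0
                continue
            lr = 2.0 * (ll_full - ll_red)
            removal_p[c] = float(stats.chi2.sf(max(lr, 0.0), df=1))
        worst = max(current, key=lambda c: (removal_p[c], current.index(c)))
        if removal_p[worst] >= stay_alpha:
            current.remove(worst)
        else:
            break
    return current


def _null_log_likelihood(surv: SurvivalData) -> float:
    """Cox partial log-likelihood of the empty (beta = 0) model."""
    order = np.argsort(surv.time, kind="stable")
    t = surv.time[order]
    e = surv.event[order]
    n = len(t)
    ll = 0.0
    # Efron reduces to Breslow at beta=0 only without ties; handle ties exactly
    i = 0
    at_risk = n
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        # at beta = 0 every risk score is 1, so the Efron denominator for
        # the k-th of d tied events is simply (at_risk - k)
        for k in range(d):
            ll -= np.log(at_risk - k)
        at_risk -= j - i
        i = j
    return float(ll)


class StepwiseCoxPH(BaseEstimator):
    """Cox model with univariate screening, backward LR elimination and
    bootstrap stability assessment.

    Parameters
    ----------
    screen_alpha : float, default 0.20
        Univariate Wald p-value below which a candidate enters the joint model.
    stay_alpha : float, default 0.05
        A covariate stays in the model while its LR removal p-value is below this.
    n_bootstrap : int, default 1000
        Bootstrap resamples (patients with replacement) for selection
        frequencies; 0 disables the bootstrap.
    random_state : int or None
        Seed for the bootstrap resampling.

    Attributes
    ----------
    result_ : CoxResult for the final model (empty model if nothing survives).
    selected_ : tuple of retained covariate names.
    selection_frequencies_ : dict covariate -> bootstrap inclusion frequency.
    """

    def __init__(self, screen_alpha: float = 0.20, stay_alpha: float = 0.05,
                 n_bootstrap: int = 1000, random_state: int | None = None):
        self.screen_alpha = screen_alpha
        self.stay_alpha = stay_alpha
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: SurvivalData) -> "StepwiseCoxPH":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        if X.shape[1] == 0:
            raise ValueError("at least one candidate covariate required")
        surv = y if isinstance(y, SurvivalData) else SurvivalData(*np.asarray(y).T)

        selected = self._select(X, surv)
        if selected:
            self.result_ = cox_fit(X[selected], surv)
        else:
            self.result_ = _empty_result()
        self.selected_ = tuple(selected)

        freqs = {c: 0.0 for c in X.columns}
        if self.n_bootstrap:
            rng = np.random.default_rng(self.random_state)
            n = len(X)
            counts = {c: 0 for c in X.columns}
            for _ in range(self.n_bootstrap):
                idx = rng.integers(0, n, size=n)
                Xb = X.iloc[idx].reset_index(drop=True)
                sb = SurvivalData(surv.time[idx], surv.event[idx])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    for c in self._select(Xb, sb):
                        counts[c] += 1
            freqs = {c: counts[c] / self.n_bootstrap for c in X.columns}
        self.selection_frequencies_ = freqs
        self.result_ = CoxResult(summary=self.result_.summary,
                                 log_likelihood=self.result_.log_likelihood,
                                 included=self.result_.included,
                                 selection_frequencies=freqs if self.n_bootstrap else None)
        return self

    def _select(self, X: pd.DataFrame, surv: SurvivalData) -> list[str]:
        varying = [c for c in X.columns if X[c].nunique() > 1]
        if not varying:
            return []
        wald = _fast_wald_p(X[varying], surv)
        screened = [c for c in varying if wald[c][0] < self.screen_alpha]
        if not screened:
            return []
        joint = _drop_collinear(X[screened], surv, wald)
        return _backward(joint, surv, self.stay_alpha, wald)


def build_multivariate(candidates: pd.DataFrame, surv: SurvivalData,
                       screen_alpha: float = 0.20, stay_alpha: float = 0.05,
                       n_bootstrap: int = 1000,
                       seed: int | None = None) -> CoxResult:
    """Run the full model-building protocol; returns the final CoxResult.

    When no candidate passes the univariate screen an empty-model result
    (no covariates) is returned rather than raising.
    """
    model = StepwiseCoxPH(screen_alpha=screen_alpha, stay_alpha=stay_alpha,
                          n_bootstrap=n_bootstrap, random_state=seed)
    model.fit(candidates, surv)
    return model.result_
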