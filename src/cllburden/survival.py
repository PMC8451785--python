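"""Survival and association statistics for treatment-free survival (TFS) analyses.

The central quantity is Harrell's concordance index for a binary marker
against right-censored survival times, implemented here from first
principles with explicit pair accounting: a pair of patients is *usable*
when the ordering of their survival times is determinable under right
censoring, and the index is the proportion of usable pairs in which the
marker ordering agrees with the time ordering (marker ties credited 0.5).
With markers coded 1 = present / 0 = absent, c < 0.5 means the marker is
associated with shorter TFS, c > 0.5 with longer TFS, and 0.5 is
uninformative; the farther from 0.5, the more informative the marker.

Kaplan-Meier estimation, the logrank test and Cox proportional-hazards
fits are delegated to lifelines; contingency-table and rank tests to
scipy.stats. Their results are repackaged into plain containers so the
rest of the package does not depend on library internals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


class UndefinedResultError(ValueError):
    """Raised when a statistic is undefined for the given data (e.g. no usable pairs)."""


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival outcomes.

    Parameters
    ----------
    time : array of non-negative floats
        Follow-up times (TFS in years). ``time[i]`` is the time of the
        event if ``event[i]`` is True, otherwise the censoring time.
    event : boolean array
        True when the event (start of treatment) was observed.
    ids : optional sequence of patient identifiers.
    """

    time: np.ndarray
    event: np.ndarray
    ids: tuple = field(default=None)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=bool)
        if t.ndim != 1 or e.shape != t.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise ValueError("times must be finite and non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        if self.ids is not None:
            ids = tuple(self.ids)
            if len(ids) != len(t):
                raise ValueError("ids length mismatch")
            object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.time)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, time_col: str = "tfs_years",
                   event_col: str = "event", id_col: str = "patient_id") -> "SurvivalData":
        ids = tuple(df[id_col]) if id_col in df.columns else None
        return cls(df[time_col].to_numpy(float), df[event_col].to_numpy(bool), ids)

    def subset(self, mask: np.ndarray) -> "SurvivalData":
        mask = np.asarray(mask, dtype=bool)
        ids = tuple(np.asarray(self.ids, dtype=object)[mask]) if self.ids is not None else None
        return SurvivalData(self.time[mask], self.event[mask], ids)


@dataclass(frozen=True)
class CIndexResult:
    """Concordance statistic with its pair-accounting breakdown."""

    c: float
    n_usable: int
    n_concordant: int
    n_discordant: int
    n_tied_x: int

    def __post_init__(self):
        if self.n_concordant + self.n_discordant + self.n_tied_x != self.n_usable:
            raise ValueError("pair counts do not sum to n_usable")


def _pair_orientation(time: np.ndarray, event: np.ndarray):
    """Vectorised pair usability and effective time ordering.

    Returns (usable, i_first) boolean matrices over ordered pairs (i, j):
    ``usable[i, j]`` — the time ordering of i and j is determinable;
    ``i_first[i, j]`` — patient i effectively fails before patient j.

    A pair with distinct times is usable iff the shorter time is an
    event. A pair with tied times is usable iff exactly one is an event,
    in which case the event is taken to precede the censored follow-up.
    """
    t_i = time[:, None]
    t_j = time[None, :]
    e_i = event[:, None]
    e_j = event[None, :]
    lt = t_i < t_j
    gt = t_i > t_j
    tie = t_i == t_j
    usable = (lt & e_i) | (gt & e_j) | (tie & (e_i ^ e_j))
    i_first = (lt & e_i) | (tie & e_i & ~e_j)
    return usable, i_first


def harrell_c_index(x: Sequence, surv: SurvivalData) -> CIndexResult:
    """Harrell's concordance index of a 0/1 marker against censored survival.

    A usable pair is concordant when the patient with the smaller marker
    value is the one that fails first (so a deleterious marker, coded 1,
    yields c < 0.5). Marker ties among usable pairs are credited 0.5.

    Raises
    ------
    UndefinedResultError
        If no pair is usable.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != surv.time.shape:
        raise ValueError("x and survival data length mismatch")
    usable, i_first = _pair_orientation(surv.time, surv.event)
    iu = np.triu_indices(len(x), k=1)
    usable_pair = usable[iu] | usable.T[iu]
    # orientation on the unordered pair {i, j}: does i fail first?
    first = i_first[iu]
    dx = (x[:, None] - x[None, :])[iu]

    n_usable = int(usable_pair.sum())
    if n_usable == 0:
        raise UndefinedResultError("no usable pairs: concordance index undefined")

    tied = usable_pair & (dx == 0)
    # concordant: smaller x fails later  <=>  (i fails first and x_i < x_j) is discordant?
    # Definition: pair concordant iff x_i < x_j and T_i < T_j (or symmetrically
    # x_i > x_j and T_i > T_j): the patient with the larger marker survives longer.
    conc = usable_pair & ((first & (dx < 0)) | (~first & (dx > 0)))
    disc = usable_pair & ~tied & ~conc

    n_tied = int(tied.sum())
    n_conc = int(conc.sum())
    n_disc = int(disc.sum())
    if n_tied == n_usable:
        warnings.warn("marker is constant on all usable pairs; c = 0.5 exactly",
                      stacklevel=2)
    c = (n_conc + 0.5 * n_tied) / n_usable
    return CIndexResult(c=c, n_usable=n_usable, n_concordant=n_conc,
                        n_discordant=n_disc, n_tied_x=n_tied)


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit estimate as step-function tables."""

    times: np.ndarray            # distinct event/censor times, ascending
    survival: np.ndarray         # S(t) right after each time
    at_risk: np.ndarray          # number at risk just before each time
    median: float                # first t with S(t) <= 0.5, nan if never reached

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk})


def kaplan_meier(surv: SurvivalData) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimate of the TFS function.

    The median is reported as the first time at which the estimated
    survival drops to 0.5 or below (NaN when never reached).
    """
    if len(surv) == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, event_observed=surv.event)
    tab = kmf.event_table
    times = tab.index.to_numpy(float)
    surv_fn = kmf.survival_function_["KM_estimate"].to_numpy(float)
    # lifelines includes a leading t=0 row when no observation at 0
    at_risk = tab["at_risk"].to_numpy(float)
    below = surv_fn <= 0.5
    median = float(times[below][0]) if below.any() else float("nan")
    return KaplanMeierEstimate(times=times, survival=surv_fn, at_risk=at_risk,
                               median=median)


def logrank_test(group: Sequence, surv: SurvivalData) -> tuple[float, float]:
    """Two-group unstratified logrank test; returns (chi-square, p), 1 df."""
    g = np.asarray(group, dtype=bool)
    if g.shape != surv.time.shape:
        raise ValueError("group and survival data length mismatch")
    if g.all() or (~g).all():
        raise ValueError("logrank test requires two non-empty groups")
    res = _ll_logrank(surv.time[g], surv.time[~g],
                      event_observed_A=surv.event[g],
                      event_observed_B=surv.event[~g])
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Cox proportional-hazards fit results.

    ``summary`` has one row per covariate with columns hr, ci_low, ci_high,
    p (Wald), coef, se, z. ``selection_frequencies`` is filled only by the
    stepwise/bootstrap procedure.
    """

    summary: pd.DataFrame
    log_likelihood: float
    included: tuple
    selection_frequencies: dict = field(default=None)

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.summary["hr"]


def cox_fit(covariates: pd.DataFrame, surv: SurvivalData,
            alpha: float = 0.05) -> CoxResult:
    """Fit a Cox proportional-hazards model (Efron tie handling).

    Parameters
    ----------
    covariates : DataFrame, one column per covariate (numeric; binary markers 0/1).
    surv : SurvivalData aligned row-wise with ``covariates``.

    Raises
    ------
    ValueError
        On constant covariates, fewer events than covariates, or exact
        collinearity; ``ConvergenceError`` from the optimiser is re-raised
        as a ValueError naming the offending covariates.
    """
    X = covariates.astype(float)
    if len(X) != len(surv):
        raise ValueError("covariates and survival data length mismatch")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    if int(surv.event.sum()) < X.shape[1]:
        raise ValueError("fewer events than covariates")
    if np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(0)) < X.shape[1]:
        raise ValueError(f"collinear covariates among {list(X.columns)}")
    df = X.copy()
    df["_time"] = surv.time
    df["_event"] = surv.event.astype(int)
    cph = CoxPHFitter(alpha=alpha)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as err:
        raise ValueError(
            f"Cox fit failed to converge for covariates {list(X.columns)}: {err}"
        ) from err
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "z": s["z"],
        "hr": s["exp(coef)"],
        "ci_low": s[[c for c in s.columns if c.startswith("exp(coef) lower")][0]],
        "ci_high": s[[c for c in s.columns if c.startswith("exp(coef) upper")][0]],
        "p": s["p"],
    })
    summary.index.name = "covariate"
    return CoxResult(summary=summary, log_likelihood=float(cph.log_likelihood_),
                     included=tuple(X.columns))


def association_test(table) -> tuple[str, float, float]:
    """Chi-square test of independence, switching to Fisher's exact test.

    The chi-square statistic is computed without continuity correction.
    For a 2x2 table with any expected count below 5 the test switches to
    Fisher's exact test (two-sided), whose reported statistic is the odds
    ratio.

    Returns (test name, statistic, p-value).
    """
    tab = np.asarray(table)
    if tab.ndim != 2 or np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab = tab.astype(float)
        if np.any(tab != np.round(tab)) or np.any(tab < 0):
            raise ValueError("contingency table must hold non-negative integers")
        tab = tab.astype(int)
    expected = stats.contingency.expected_freq(tab)
    if tab.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(tab, alternative="two-sided")
        return "fisher_exact", float(odds), float(p)
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return "chi_square", float(chi2), float(p)


def mann_whitney(a: Sequence, b: Sequence) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small, tie-free samples (both n <= 20);
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(a.size, b.size) <= 20 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        # plain normal approximation (tie-corrected variance, no
        # continuity correction)
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)
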