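"""Reduced gene-panel derivation by concordance-index minimisation.

The prognostic informativeness of a gene (or gene subset) for TFS is
scored by Harrell's concordance index of its >=1-mutation indicator:
values below 0.5 mark deleterious markers (mutation associated with
shorter TFS), and the farther from 0.5 the more informative. The search
looks for the subset of candidate genes whose indicator *minimises* the
index — deleterious coding — either exhaustively over all subsets up to
a maximum size or by greedy forward selection for large candidate sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .survival import (CIndexResult, SurvivalData, UndefinedResultError,
                       harrell_c_index, logrank_test)
from .variants import MutationMatrix

#: c values closer than this are treated as exact ties in the ranking.
TIE_TOL = 1e-12


def panel_indicator(matrix: MutationMatrix, genes: Sequence) -> np.ndarray:
    """Binary vector: 1 for patients with >= 1 retained mutation in any
    of ``genes``. Warns when no patient carries any subset mutation."""
    genes = list(genes)
    if not genes:
        raise ValueError("gene subset must be non-empty")
    missing = set(genes) - set(matrix.genes)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)}")
    ind = matrix.binary[genes].any(axis=1).to_numpy(int)
    if ind.sum() == 0:
        warnings.warn(f"no patient carries a mutation in {sorted(genes)}",
                      stacklevel=2)
    return ind


@dataclass(frozen=True)
class PanelSearchResult:
    """Ranked gene subsets with their concordance indices."""

    table: pd.DataFrame          # columns: genes, size, c, n_usable, logrank_p
    best: tuple                  # gene names of the top-ranked subset
    mode: str                    # "exhaustive" | "greedy"
    n_evaluated: int
    config: dict

    def __post_init__(self):
        c = self.table["c"].to_numpy()
        if len(c) > 1 and np.any(np.diff(c) < -TIE_TOL):
            raise ValueError("ranking must be non-decreasing in c")


def _score_subset(matrix: MutationMatrix, surv: SurvivalData,
                  genes: tuple) -> tuple[CIndexResult, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ind = panel_indicator(matrix, list(genes))
        res = harrell_c_index(ind, surv)
        if 0 < ind.sum() < len(ind):
            _, p = logrank_test(ind.astype(bool), surv)
        else:
            p = float("nan")
    return res, p


def _rank_key(row) -> tuple:
    # ascending c, ties (within TIE_TOL) broken by smaller subset then
    # lexicographic gene names; quantising c to the tolerance makes the
    # tie-break effective
    return (round(row["c"] / TIE_TOL) * TIE_TOL, row["size"], row["genes"])


def exhaustive_panel_search(matrix: MutationMatrix, surv: SurvivalData,
                            candidate_genes: Sequence, max_size: int,
                            budget: int = 200_000) -> PanelSearchResult:
    """Evaluate every subset of sizes 1..max_size and rank by ascending c.

    Raises a ValueError advising greedy mode when the number of subsets
    exceeds ``budget``.
    """
    cands = sorted(set(candidate_genes))
    if not cands:
        raise ValueError("candidate_genes must be non-empty")
    max_size = min(max_size, len(cands))
    n_subsets = sum(_n_choose_k(len(cands), k) for k in range(1, max_size + 1))
    if n_subsets > budget:
        raise ValueError(
            f"{n_subsets} subsets exceed the evaluation budget ({budget}); "
            "use greedy_panel_search for large candidate sets")
    rows = []
    for k in range(1, max_size + 1):
        for subset in combinations(cands, k):
            res, p = _score_subset(matrix, surv, subset)
            rows.append({"genes": subset, "size": k, "c": res.c,
                         "n_usable": res.n_usable, "logrank_p": p})
    rows.sort(key=_rank_key)
    table = pd.DataFrame(rows)
    return PanelSearchResult(table=table, best=tuple(rows[0]["genes"]),
                             mode="exhaustive", n_evaluated=len(rows),
                             config={"candidate_genes": cands,
                                     "max_size": max_size, "budget": budget})


def _n_choose_k(n: int, k: int) -> int:
    from math import comb
    return comb(n, k)


def greedy_panel_search(matrix: MutationMatrix, surv: SurvivalData,
                        candidate_genes: Sequence,
                        max_size: int) -> PanelSearchResult:
    """Forward selection: start from the single gene with minimal c, then
    repeatedly add the gene giving the largest c decrease; stop when no
    addition decreases c or ``max_size`` is reached. The reported trace
    has strictly decreasing c along the additions."""
    cands = sorted(set(candidate_genes))
    if not cands:
        raise ValueError("candidate_genes must be non-empty")
    max_size = min(max_size, len(cands))

    scored = {}
    for g in cands:
        res, p = _score_subset(matrix, surv, (g,))
        scored[g] = (res, p)
    current = min(cands, key=lambda g: (scored[g][0].c, g))
    subset = (current,)
    res, p = scored[current]
    trace = [{"genes": subset, "size": 1, "c": res.c,
              "n_usable": res.n_usable, "logrank_p": p}]
    n_eval = len(cands)
    while len(subset) < max_size:
        best_gain, best_entry = 0.0, None
        for g in cands:
            if g in subset:
                continue
            trial = tuple(sorted(subset + (g,)))
            r, pv = _score_subset(matrix, surv, trial)
            n_eval += 1
            gain = trace[-1]["c"] - r.c
            if gain > best_gain + TIE_TOL or (
                    best_entry is not None and abs(gain - best_gain) <= TIE_TOL
                    and trial < best_entry["genes"]):
                best_gain = gain
                best_entry = {"genes": trial, "size": len(trial), "c": r.c,
                              "n_usable": r.n_usable, "logrank_p": pv}
        if best_entry is None:
            break
        subset = best_entry["genes"]
        trace.append(best_entry)
    table = pd.DataFrame(sorted(trace, key=_rank_key))
    return PanelSearchResult(table=table, best=trace[-1]["genes"],
                             mode="greedy", n_evaluated=n_eval,
                             config={"candidate_genes": cands,
                                     "max_size": max_size})


def per_gene_cindex_table(matrix: MutationMatrix, surv: SurvivalData,
                          extra_markers: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Marker-by-marker informativeness table.

    One row per gene (>=1-mutation indicator) and per supplied extra
    binary covariate (IGHV status, cytogenetic classes, Binet stage, ...)
    with the number of events among marker-positive patients, the
    concordance index and the logrank p-value, sorted ascending by c.
    Genes mutated in no patient are skipped with a warning.
    """
    rows = []
    for gene in matrix.genes:
        ind = matrix.binary[gene].to_numpy(int)
        if ind.sum() == 0:
            warnings.warn(f"gene {gene} mutated in no patient; excluded",
                          stacklevel=2)
            continue
        rows.append(_marker_row(gene, ind, surv))
    if extra_markers is not None:
        for name in extra_markers.columns:
            ind = extra_markers[name].to_numpy(int)
            if ind.sum() == 0:
                warnings.warn(f"marker {name} positive in no patient; excluded",
                              stacklevel=2)
                continue
            rows.append(_marker_row(name, ind, surv))
    table = pd.DataFrame(rows, columns=["marker", "n_events_positive", "c",
                                        "n_usable", "logrank_p"])
    return table.sort_values(["c", "marker"]).reset_index(drop=True)


def _marker_row(name: str, ind: np.ndarray, surv: SurvivalData) -> dict:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = harrell_c_index(ind, surv)
            c, n_us = res.c, res.n_usable
        except UndefinedResultError:
            c, n_us = float("nan"), 0
        if 0 < ind.sum() < len(ind):
            _, p = logrank_test(ind.astype(bool), surv)
        else:
            p = float("nan")
    n_events = int(surv.event[ind.astype(bool)].sum())
    return {"marker": name, "n_events_positive": n_events, "c": c,
            "n_usable": n_us, "logrank_p": p}


class PanelSelector(BaseEstimator):
    """sklearn-style selector of the c-minimising gene subset.

    Parameters
    ----------
    max_size : int, default 8
        Largest subset size considered.
    mode : {"auto", "exhaustive", "greedy"}, default "auto"
        "auto" uses exhaustive search up to 20 candidates, greedy beyond.
    budget : int
        Exhaustive-subset evaluation budget.

    Attributes
    ----------
    result_ : PanelSearchResult
    best_panel_ : tuple of gene names
    best_c_ : float
    """

    def __init__(self, max_size: int = 8, mode: str = "auto",
                 budget: int = 200_000):
        self.max_size = max_size
        self.mode = mode
        self.budget = budget

    def fit(self, X: MutationMatrix | pd.DataFrame, y: SurvivalData
            ) -> "PanelSelector":
        matrix = X if isinstance(X, MutationMatrix) else MutationMatrix(X)
        nonzero = [g for g in matrix.genes if matrix.binary[g].sum() > 0]
        mode = self.mode
        if mode == "auto":
            k_max = min(self.max_size, len(nonzero))
            n_subsets = sum(_n_choose_k(len(nonzero), k)
                            for k in range(1, k_max + 1))
            mode = "exhaustive" if (len(nonzero) <= 20
                                    and n_subsets <= self.budget) else "greedy"
        if mode == "exhaustive":
            self.result_ = exhaustive_panel_search(matrix, y, nonzero,
                                                   self.max_size, self.budget)
        elif mode == "greedy":
            self.result_ = greedy_panel_search(matrix, y, nonzero, self.max_size)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.best_panel_ = self.result_.best
        self.best_c_ = float(self.result_.table.iloc[0]["c"]
                             if self.result_.mode == "exhaustive"
                             else self.result_.table["c"].min())
        self.matrix_genes_ = tuple(matrix.genes)
        return self

    def transform(self, X: MutationMatrix | pd.DataFrame) -> np.ndarray:
        matrix = X if isinstance(X, MutationMatrix) else MutationMatrix(X)
        return panel_indicator(matrix, list(self.best_panel_)).reshape(-1, 1)

    def get_support(self) -> np.ndarray:
        return np.array([g in self.best_panel_ for g in self.matrix_genes_])
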