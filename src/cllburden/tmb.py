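"""Per-patient tumor mutational burden (TMB) and the reduced-panel estimator.

TMB is the raw count of retained pathogenic mutations per patient over
the sequenced panel (no per-megabase normalisation). Patients are
dichotomised at a threshold of 2 mutations (TMB-high: >= 2), and the
eight-gene estimator flags patients carrying at least one retained
mutation in the reduced panel.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .variants import MutationMatrix

#: The reduced panel whose >=1-mutation indicator estimates TMB prognosis.
EIGHT_GENE_ESTIMATOR = frozenset(
    {"ATM", "SF3B1", "NOTCH1", "BIRC3", "XPO1", "MYD88", "TNFAIP3", "TP53"})

#: TMB-high dichotomy threshold (mutations).
TMB_THRESHOLD = 2


def compute_tmb(matrix: MutationMatrix, mode: str = "count") -> pd.Series:
    """Per-patient mutational burden.

    mode="count" (default) sums retained variants over all panel genes;
    mode="genes" counts distinct mutated genes instead (both are exposed
    because either reading of "accumulated mutations" is defensible).
    """
    if mode == "count":
        s = matrix.counts.sum(axis=1)
    elif mode == "genes":
        s = matrix.binary.sum(axis=1)
    else:
        raise ValueError(f"unknown TMB mode {mode!r}")
    s.name = "tmb"
    s.index.name = "patient_id"
    return s.astype(int)


def dichotomize_tmb(tmb: Mapping | pd.Series, threshold: int = TMB_THRESHOLD) -> pd.Series:
    """TMB-high flag: burden greater than or equal to ``threshold``."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    s = pd.Series(dict(tmb)) if not isinstance(tmb, pd.Series) else tmb
    out = (s >= threshold)
    out.name = "tmb_high"
    return out


def estimator_status(matrix: MutationMatrix,
                     panel: frozenset | set = EIGHT_GENE_ESTIMATOR) -> pd.Series:
    """True for patients with >= 1 retained mutation in any panel gene."""
    panel = set(panel)
    missing = panel - set(matrix.genes)
    if missing:
        raise ValueError(f"panel genes absent from matrix: {sorted(missing)}")
    out = matrix.binary[sorted(panel)].any(axis=1)
    out.name = "estimator_mutated"
    out.index.name = "patient_id"
    return out


def tmb_profile(matrix: MutationMatrix, threshold: int = TMB_THRESHOLD,
                panel: frozenset | set = EIGHT_GENE_ESTIMATOR,
                mode: str = "count") -> pd.DataFrame:
    """Joined per-patient table: tmb, tmb_high, estimator_mutated."""
    tmb = compute_tmb(matrix, mode=mode)
    return pd.DataFrame({
        "tmb": tmb,
        "tmb_high": dichotomize_tmb(tmb, threshold),
        "estimator_mutated": estimator_status(matrix, panel),
    })
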