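"""Synthetic CLL cohort generator.

Emulates the statistical structure of a two-centre CLL study so the
whole analysis chain (variant filtering, TMB, panel selection, survival
modelling) is testable without patient data:

* two series of patients with configurable sizes;
* per-gene mutation indicators drawn Bernoulli, with an IGHV-dependent
  odds shift (unmutated-IGHV patients are enriched for driver
  mutations) and an elevated-burden odds multiplier for previously
  treated patients; ``mutation_freq`` is the *marginal* probability of
  carrying >= 1 mutation in a gene among untreated patients;
* treatment-free survival drawn from an exponential (default) or
  Weibull model whose hazard is the baseline hazard times the product
  of per-gene hazard ratios over the patient's mutated genes;
* independent administrative censoring, uniform on (0, w) with w
  calibrated so the expected censored fraction at the baseline hazard
  matches ``censoring_rate``;
* previously treated patients carry no TFS (excluded from survival
  analyses downstream).

``generate_variant_calls`` re-expands a mutation matrix into raw
annotated calls that pass every retention rule, optionally salted with
noise records that each fail exactly one rule, so the filtering
pipeline can be round-trip tested against the generating matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .variants import MutationMatrix, VariantRecord

CYTO_CLASSES = ("normal", "isolated_del13q", "trisomy12", "del11q", "del17p",
                "complex")

# Binet-stage mix: untreated cohorts are dominated by stage A; previously
# treated patients skew towards B/C.
_BINET_UNTREATED = {"A": 0.80, "B": 0.156, "C": 0.044}
_BINET_TREATED = {"A": 0.35, "B": 0.40, "C": 0.25}


class SpecValidationError(ValueError):
    """Raised when a CohortSpec field is invalid; names the field."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``mutation_freq`` maps gene -> marginal probability of >= 1 mutation
    (among untreated patients); ``hazard_ratio`` maps gene -> hazard
    multiplier for carrying >= 1 mutation in that gene (genes absent
    from the map have HR 1). ``ighv_mutation_enrichment`` is the odds
    multiplier linking unmutated IGHV to per-gene mutation probability.
    """

    n_patients: int
    series_sizes: tuple
    gene_panel: tuple
    mutation_freq: dict
    hazard_ratio: dict
    baseline_median_tfs_years: float = 7.0
    censoring_rate: float = 0.25
    frac_ighv_mutated: float = 0.52
    ighv_mutation_enrichment: float = 4.0
    cytogenetic_class_probs: dict = field(default_factory=lambda: {
        "normal": 0.25, "isolated_del13q": 0.35, "trisomy12": 0.12,
        "del11q": 0.10, "del17p": 0.05, "complex": 0.13})
    treated_fraction: float = 0.23
    seed: int = 0
    tfs_distribution: str = "exponential"   # or "weibull"
    weibull_shape: float = 1.0
    treated_tmb_odds: float = 2.0           # burden-odds multiplier, treated patients
    extra_mutation_rate: float = 0.12       # Poisson rate of additional variants per mutated gene

    def __post_init__(self):
        if self.n_patients < 1:
            raise SpecValidationError("n_patients must be positive")
        if sum(self.series_sizes) != self.n_patients:
            raise SpecValidationError("series_sizes must sum to n_patients")
        for name in ("censoring_rate", "frac_ighv_mutated", "treated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecValidationError(f"{name} must be a probability in [0, 1]")
        if not set(self.mutation_freq) <= set(self.gene_panel):
            extra = set(self.mutation_freq) - set(self.gene_panel)
            raise SpecValidationError(f"mutation_freq keys not in gene_panel: {sorted(extra)}")
        for g, p in self.mutation_freq.items():
            if not 0.0 <= p <= 1.0:
                raise SpecValidationError(f"mutation_freq[{g}] must be in [0, 1]")
        for g, hr in self.hazard_ratio.items():
            if hr <= 0:
                raise SpecValidationError(f"hazard_ratio[{g}] must be positive")
        if self.baseline_median_tfs_years <= 0:
            raise SpecValidationError("baseline_median_tfs_years must be positive")
        if abs(sum(self.cytogenetic_class_probs.values()) - 1.0) > 1e-9:
            raise SpecValidationError("cytogenetic_class_probs must sum to 1")
        if set(self.cytogenetic_class_probs) - set(CYTO_CLASSES):
            raise SpecValidationError("cytogenetic_class_probs has unknown classes")
        if self.tfs_distribution not in ("exponential", "weibull"):
            raise SpecValidationError("tfs_distribution must be exponential or weibull")
        if self.weibull_shape <= 0:
            raise SpecValidationError("weibull_shape must be positive")
        if self.ighv_mutation_enrichment <= 0:
            raise SpecValidationError("ighv_mutation_enrichment must be positive")
        object.__setattr__(self, "series_sizes", tuple(self.series_sizes))
        object.__setattr__(self, "gene_panel", tuple(self.gene_panel))


@dataclass(frozen=True)
class ClinicalRecord:
    """Patient covariates and right-censored TFS outcome.

    ``tfs_years`` is NaN for previously treated patients, which carry no
    treatment-free survival and are excluded from survival analyses.
    """

    patient_id: str
    series: int
    binet_stage: str
    previously_treated: bool
    tfs_years: float
    event: bool
    ighv_status: str          # "mutated" | "unmutated"
    cytogenetic_class: str


# frozen defaults of the paper-like cohort: marginal per-gene frequencies
# (ATM/SF3B1/NOTCH1/BIRC3 top the spectrum, TNFAIP3 rare at ~3%) and hazard
# ratios placing the prognostic signal in the eight estimator genes.
DEFAULT_GENE_FREQ = {
    "ATM": 0.21, "SF3B1": 0.20, "NOTCH1": 0.17, "BIRC3": 0.14, "TP53": 0.08,
    "XPO1": 0.06, "MYD88": 0.05, "TNFAIP3": 0.03,
    "POT1": 0.10, "CHD2": 0.09, "KMT2D": 0.08, "RPS15": 0.08, "NFKBIE": 0.07,
    "EGR2": 0.07, "DDX3X": 0.065, "MGA": 0.06, "FBXW7": 0.06, "BRAF": 0.055,
    "ZMYM3": 0.05, "KRAS": 0.05,
}

DEFAULT_HAZARD_RATIO = {
    "ATM": 3.0, "SF3B1": 3.2, "NOTCH1": 2.8, "BIRC3": 2.5, "XPO1": 2.0,
    "TNFAIP3": 1.6, "MYD88": 1.3, "TP53": 1.3,
}


def default_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The frozen paper-like cohort: 150 patients in series of 80 and 70."""
    kw = dict(
        n_patients=150, series_sizes=(80, 70),
        gene_panel=tuple(DEFAULT_GENE_FREQ),
        mutation_freq=dict(DEFAULT_GENE_FREQ),
        hazard_ratio=dict(DEFAULT_HAZARD_RATIO),
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def _conditional_probs(marginal: float, frac_m: float, enrich: float) -> tuple[float, float]:
    """Split a marginal mutation probability into (p | IGHV-mutated,
    p | IGHV-unmutated) such that odds(p_UM) = enrich * odds(p_M) and the
    mixture at ``frac_m`` recovers the marginal."""
    if marginal <= 0.0:
        return 0.0, 0.0
    if marginal >= 1.0:
        return 1.0, 1.0
    if enrich == 1.0 or frac_m in (0.0, 1.0):
        return marginal, marginal

    def gap(p_m):
        odds = enrich * p_m / (1.0 - p_m)
        p_um = odds / (1.0 + odds)
        return frac_m * p_m + (1.0 - frac_m) * p_um - marginal

    lo, hi = 1e-12, marginal  # p_M <= marginal <= p_UM when enrich > 1
    if enrich < 1.0:
        lo, hi = marginal, 1.0 - 1e-12
    p_m = brentq(gap, lo, hi, xtol=1e-12)
    odds = enrich * p_m / (1.0 - p_m)
    return p_m, odds / (1.0 + odds)


def _odds_shift(p: float, mult: float) -> float:
    if p <= 0.0 or mult == 1.0:
        return p
    odds = mult * p / (1.0 - p)
    return odds / (1.0 + odds)


def _censoring_horizon(spec: CohortSpec) -> float:
    """Uniform(0, w) horizon such that the baseline-hazard censored
    fraction equals censoring_rate."""
    h0 = math.log(2.0) / spec.baseline_median_tfs_years
    target = spec.censoring_rate

    def censored_frac(w):
        return (1.0 - math.exp(-h0 * w)) / (h0 * w) - target

    # censored fraction decreases from 1 (w->0) to 0 (w->inf)
    return brentq(censored_frac, 1e-9, 1e6)


def generate_cohort(spec: CohortSpec) -> tuple[list[ClinicalRecord], MutationMatrix]:
    """Draw a cohort: clinical records plus the mutation-count matrix.

    Deterministic given ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    width = max(4, len(str(n)))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    series = np.concatenate([np.full(sz, i + 1) for i, sz in enumerate(spec.series_sizes)])

    treated = rng.random(n) < spec.treated_fraction
    ighv_mut = rng.random(n) < spec.frac_ighv_mutated

    cyto_classes = list(spec.cytogenetic_class_probs)
    cyto_p = np.array([spec.cytogenetic_class_probs[c] for c in cyto_classes])
    cyto = rng.choice(len(cyto_classes), size=n, p=cyto_p / cyto_p.sum())

    stage_u = list(_BINET_UNTREATED)
    p_u = np.array(list(_BINET_UNTREATED.values()))
    p_t = np.array(list(_BINET_TREATED.values()))
    stage_idx = np.where(treated,
                         rng.choice(3, size=n, p=p_t / p_t.sum()),
                         rng.choice(3, size=n, p=p_u / p_u.sum()))

    # mutation counts per (patient, gene)
    counts = np.zeros((n, len(spec.gene_panel)), dtype=int)
    for j, gene in enumerate(spec.gene_panel):
        marginal = spec.mutation_freq.get(gene, 0.0)
        p_m, p_um = _conditional_probs(marginal, spec.frac_ighv_mutated,
                                       spec.ighv_mutation_enrichment)
        p = np.where(ighv_mut, p_m, p_um)
        if spec.treated_tmb_odds != 1.0:
            p = np.where(treated,
                         [_odds_shift(pi, spec.treated_tmb_odds) for pi in p], p)
        mutated = rng.random(n) < p
        extra = rng.poisson(spec.extra_mutation_rate, size=n)
        counts[:, j] = np.where(mutated, 1 + extra, 0)

    # survival: hazard multiplier is the product of per-gene HRs over mutated genes
    log_hr = np.zeros(n)
    for j, gene in enumerate(spec.gene_panel):
        hr = spec.hazard_ratio.get(gene, 1.0)
        log_hr += (counts[:, j] >= 1) * math.log(hr)
    h0 = math.log(2.0) / spec.baseline_median_tfs_years
    hazard = h0 * np.exp(log_hr)

    u = rng.random(n)
    if spec.tfs_distribution == "exponential":
        t_event = -np.log(u) / hazard
    else:
        k = spec.weibull_shape
        lam = spec.baseline_median_tfs_years / math.log(2.0) ** (1.0 / k)
        t_event = lam * (-np.log(u) / np.exp(log_hr)) ** (1.0 / k)

    if spec.censoring_rate > 0:
        w = _censoring_horizon(spec)
        t_cens = rng.uniform(0.0, w, size=n)
    else:
        t_cens = np.full(n, np.inf)
    tfs = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    records = []
    for i in range(n):
        records.append(ClinicalRecord(
            patient_id=ids[i], series=int(series[i]),
            binet_stage=stage_u[stage_idx[i]],
            previously_treated=bool(treated[i]),
            tfs_years=float("nan") if treated[i] else float(tfs[i]),
            event=False if treated[i] else bool(event[i]),
            ighv_status="mutated" if ighv_mut[i] else "unmutated",
            cytogenetic_class=cyto_classes[cyto[i]],
        ))
    matrix = MutationMatrix(pd.DataFrame(counts, index=ids,
                                         columns=list(spec.gene_panel)))
    return records, matrix


# ---------------------------------------------------------------------------
# raw variant-call synthesis

#: Noise categories: each injected record fails exactly the named rule.
NOISE_KINDS = ("low_depth", "low_alt_reads", "low_vaf", "polymorphism",
               "tolerated", "unannotated")


def _clean_fields(rng) -> dict:
    """Quality/annotation fields that pass every retention rule."""
    depth = int(rng.integers(120, 1000))
    vaf = float(rng.uniform(0.08, 0.5))
    alt = max(5, int(round(vaf * depth)))
    alt = min(alt, depth)
    fields = dict(depth=depth, alt_reads=alt, vaf=alt / depth, is_exonic=True,
                  in_pop_db=False, pop_maf=None)
    mode = rng.integers(0, 3)
    if mode == 0:
        fields.update(is_hotspot=True, sift_class="tolerated",
                      cadd_phred=float(rng.uniform(0, 10)))
    elif mode == 1:
        fields.update(is_hotspot=False, sift_class="deleterious",
                      cadd_phred=float(rng.uniform(25, 40)))
    else:
        fields.update(is_hotspot=False, sift_class=None,
                      cadd_phred=float(rng.uniform(25, 40)))
    return fields


def _noise_fields(kind: str, rng, cadd_cutoff: float = 20.0) -> dict:
    f = _clean_fields(rng)
    if kind == "low_depth":
        depth = int(rng.integers(20, 100))
        alt = max(5, int(round(0.3 * depth)))
        f.update(depth=depth, alt_reads=alt, vaf=alt / depth)
    elif kind == "low_alt_reads":
        alt = int(rng.integers(3, 5))
        depth = int(rng.integers(100, 50 * alt + 1))
        f.update(depth=depth, alt_reads=alt, vaf=alt / depth)
    elif kind == "low_vaf":
        depth = int(rng.integers(600, 2000))
        alt = int(rng.integers(5, max(6, int(0.019 * depth))))
        f.update(depth=depth, alt_reads=alt, vaf=alt / depth)
    elif kind == "polymorphism":
        f.update(in_pop_db=True, pop_maf=float(rng.uniform(0.01, 0.5)))
    elif kind == "tolerated":
        f.update(is_hotspot=False, sift_class="tolerated",
                 cadd_phred=float(rng.uniform(0, cadd_cutoff - 1e-6)))
    elif kind == "unannotated":
        f.update(is_hotspot=False, sift_class=None, cadd_phred=None)
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    return f


def generate_variant_calls(matrix: MutationMatrix, spec: CohortSpec,
                           noise_seed: int = 0,
                           noise_counts: dict | None = None,
                           ) -> list[VariantRecord]:
    """Expand a mutation matrix into raw annotated variant calls.

    Every retained mutation becomes one record passing all retention
    rules. ``noise_counts`` maps noise kind -> number of injected
    records that fail exactly that rule (default 1 each); noise is
    spread over random patients/genes at coordinates disjoint from the
    clean calls, so filtering the output reconstructs ``matrix``
    exactly under the default (exclude-review) policy.
    """
    rng = np.random.default_rng(noise_seed)
    genes = matrix.genes
    gene_chrom = {g: f"chr{1 + i % 22}" for i, g in enumerate(genes)}
    gene_base = {g: 1_000_000 * (i + 1) for i, g in enumerate(genes)}
    bases = ("A", "C", "G", "T")

    records: list[VariantRecord] = []
    offset: dict[tuple, int] = {}
    for pid in matrix.patients:
        for gene in genes:
            k = int(matrix.counts.loc[pid, gene])
            for _ in range(k):
                key = (pid, gene)
                offset[key] = offset.get(key, 0) + 1
                pos = gene_base[gene] + offset[key]
                ref = bases[int(rng.integers(0, 4))]
                alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
                records.append(VariantRecord(
                    patient_id=pid, gene=gene, chrom=gene_chrom[gene],
                    pos=pos, ref=ref, alt=alt, **_clean_fields(rng)))

    counts = {k: 1 for k in NOISE_KINDS}
    if noise_counts is not None:
        counts = {k: int(noise_counts.get(k, 0)) for k in NOISE_KINDS}
        unknown = set(noise_counts) - set(NOISE_KINDS)
        if unknown:
            raise ValueError(f"unknown noise kinds: {sorted(unknown)}")
    noise_pos = 500_000_000  # disjoint coordinate block for noise records
    for kind in NOISE_KINDS:
        for _ in range(counts[kind]):
            pid = matrix.patients[int(rng.integers(0, len(matrix.patients)))]
            gene = genes[int(rng.integers(0, len(genes)))]
            noise_pos += 1
            ref = bases[int(rng.integers(0, 4))]
            alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            records.append(VariantRecord(
                patient_id=pid, gene=gene, chrom=gene_chrom[gene],
                pos=noise_pos, ref=ref, alt=alt, **_noise_fields(kind, rng)))
    return records


# ---------------------------------------------------------------------------
# I/O

CLINICAL_COLUMNS = ["patient_id", "series", "binet_stage", "previously_treated",
                    "tfs_years", "event", "ighv_status", "cytogenetic_class"]


def clinical_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=CLINICAL_COLUMNS)


def write_clinical_csv(records: Sequence[ClinicalRecord], path) -> None:
    clinical_to_frame(records).to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df
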