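"""Somatic variant retention pipeline.

Because a germline counterpart is typically unavailable in routine CLL
resequencing, candidate calls are reduced to plausibly pathogenic,
acquired, exonic mutations by a fixed rule cascade:

1. exonic check — non-exonic (and synonymous) calls are rejected first;
2. quality — depth >= 100x, >= 5 alternate reads, VAF >= 2% (inclusive);
3. population frequency — population MAF >= 0.01 marks a polymorphism;
   a database entry with MAF < 0.01 (or no MAF) goes to manual review;
4. pathogenicity — recurrent hotspots are retained outright; other calls
   need a deleterious SIFT class or a CADD PHRED score above the cutoff;
   calls with neither score available go to manual review; tolerated
   calls below the CADD cutoff are rejected.

The rules are conjunctive, so each record's verdict is independent of
every other record. Every decision carries the ordered rule trace for
auditability; manual-review records are resolved by an explicit policy
(excluded by default). Retained records are aggregated into a
patients x genes mutation-count matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

#: TSV column order for variant tables (the package's text dialect).
TSV_COLUMNS = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt", "depth", "alt_reads",
    "vaf", "is_exonic", "is_hotspot", "sift_class", "cadd_phred", "pop_maf",
    "in_pop_db",
]


@dataclass(frozen=True)
class VariantRecord:
    """One candidate variant call with quality and annotation fields.

    ``sift_class`` is one of {"deleterious", "tolerated", None};
    ``cadd_phred`` and ``pop_maf`` are floats or None when unannotated;
    coordinates are 1-based (VCF convention).
    """

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int | None
    alt_reads: int | None
    vaf: float | None = None
    is_exonic: bool = True
    is_hotspot: bool = False
    sift_class: str | None = None
    cadd_phred: float | None = None
    pop_maf: float | None = None
    in_pop_db: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.sift_class not in ("deleterious", "tolerated", None):
            raise ValueError(f"bad sift_class {self.sift_class!r}")
        if (self.depth is not None and self.alt_reads is not None
                and self.alt_reads > self.depth):
            raise ValueError("alt_reads exceeds depth")

    @property
    def key(self) -> tuple:
        return (self.patient_id, self.chrom, self.pos, self.ref, self.alt)

    def effective_vaf(self, tol: float = 0.005) -> float | None:
        """VAF, recomputed from alt_reads/depth when absent; a mismatch
        beyond ``tol`` between stated and recomputed VAF raises."""
        if self.depth not in (None, 0) and self.alt_reads is not None:
            computed = self.alt_reads / self.depth
            if self.vaf is not None and abs(self.vaf - computed) > tol:
                raise ValueError(
                    f"stated VAF {self.vaf} disagrees with alt_reads/depth "
                    f"{computed:.4f} for {self.key}")
            return self.vaf if self.vaf is not None else computed
        return self.vaf


class Verdict(str, Enum):
    RETAINED = "retained"
    REJECTED = "rejected"
    MANUAL_REVIEW = "manual_review"


@dataclass(frozen=True)
class FilterDecision:
    """Per-record filtering outcome with the ordered rule trace."""

    record: VariantRecord
    verdict: Verdict
    failed_rules: tuple = ()
    rule_trace: tuple = ()   # ordered (rule, outcome) pairs

    def __post_init__(self):
        retained = self.verdict == Verdict.RETAINED
        if retained != (len(self.failed_rules) == 0
                        and self.verdict != Verdict.MANUAL_REVIEW):
            raise ValueError("verdict inconsistent with failed_rules")


class MutationMatrix:
    """Patients x genes matrix of retained mutation counts.

    Wraps an integer DataFrame (rows = patients, columns = genes); the
    ``binary`` view marks cells with at least one retained mutation.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.astype(int)
        if (counts.to_numpy() < 0).any():
            raise ValueError("mutation counts must be non-negative")
        self.counts = counts

    @property
    def patients(self) -> list:
        return list(self.counts.index)

    @property
    def genes(self) -> list:
        return list(self.counts.columns)

    @property
    def binary(self) -> pd.DataFrame:
        return (self.counts >= 1).astype(int)

    def __eq__(self, other) -> bool:
        return isinstance(other, MutationMatrix) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"MutationMatrix({len(self.patients)} patients x {len(self.genes)} genes)"

    @classmethod
    def empty(cls, patients: Sequence, genes: Sequence) -> "MutationMatrix":
        return cls(pd.DataFrame(0, index=list(patients), columns=list(genes)))

    def to_csv(self, path) -> None:
        self.counts.rename_axis("patient_id").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "MutationMatrix":
        return cls(pd.read_csv(path, index_col=0))


# ---------------------------------------------------------------------------
# individual rules

def apply_quality_filters(records: Iterable[VariantRecord], min_depth: int = 100,
                          min_alt_reads: int = 5,
                          min_vaf: float = 0.02) -> list[FilterDecision]:
    """Depth / alternate-read / VAF quality rules (all thresholds inclusive).

    Records missing depth or alt_reads cannot be judged and are flagged
    for manual review with rule ``missing_quality_field``.
    """
    out = []
    for rec in records:
        failed, trace = [], []
        if rec.depth is None or rec.alt_reads is None:
            out.append(FilterDecision(rec, Verdict.MANUAL_REVIEW,
                                      ("missing_quality_field",),
                                      (("missing_quality_field", "review"),)))
            continue
        try:
            vaf = rec.effective_vaf()
        except ValueError:
            # stated VAF contradicts alt_reads/depth: needs human eyes
            out.append(FilterDecision(rec, Verdict.MANUAL_REVIEW,
                                      ("vaf_mismatch",),
                                      (("vaf_mismatch", "review"),)))
            continue
        for rule, ok in (("min_depth", rec.depth >= min_depth),
                         ("min_alt_reads", rec.alt_reads >= min_alt_reads),
                         ("min_vaf", vaf is not None and vaf >= min_vaf)):
            trace.append((rule, "pass" if ok else "fail"))
            if not ok:
                failed.append(rule)
        verdict = Verdict.RETAINED if not failed else Verdict.REJECTED
        out.append(FilterDecision(rec, verdict, tuple(failed), tuple(trace)))
    return out


def classify_pathogenicity(record: VariantRecord, hotspot_list: set | None = None,
                           cadd_cutoff: float = 20.0) -> Verdict:
    """Pathogenicity rule for exonic, quality-passing calls.

    Hotspots (by the record flag or membership of ``hotspot_list``) are
    retained regardless of in-silico scores. Otherwise a deleterious SIFT
    class or CADD PHRED >= cutoff retains the call; both scores missing
    sends it to manual review; anything else (tolerated and/or CADD below
    cutoff) is rejected.
    """
    hotspot = record.is_hotspot or (hotspot_list is not None
                                    and _hotspot_key(record) in hotspot_list)
    if hotspot:
        return Verdict.RETAINED
    sift_del = record.sift_class == "deleterious"
    cadd_high = record.cadd_phred is not None and record.cadd_phred >= cadd_cutoff
    if sift_del or cadd_high:
        return Verdict.RETAINED
    if record.sift_class is None and record.cadd_phred is None:
        return Verdict.MANUAL_REVIEW
    return Verdict.REJECTED


def _hotspot_key(record: VariantRecord) -> tuple:
    return (record.gene, record.chrom, record.pos, record.ref, record.alt)


def filter_polymorphisms(record: VariantRecord, maf_cutoff: float = 0.01) -> str:
    """Population-frequency rule.

    Returns ``"kept"`` (no database entry), ``"rejected_polymorphism"``
    (population MAF >= cutoff, inclusive) or ``"manual_review"``
    (database entry with MAF below cutoff or unavailable).
    """
    if record.pop_maf is not None and record.pop_maf >= maf_cutoff:
        return "rejected_polymorphism"
    if record.in_pop_db:
        return "manual_review"
    return "kept"


# ---------------------------------------------------------------------------
# full pipeline

class FilterConfig:
    """Thresholds and policies for the retention pipeline."""

    def __init__(self, min_depth: int = 100, min_alt_reads: int = 5,
                 min_vaf: float = 0.02, maf_cutoff: float = 0.01,
                 cadd_cutoff: float = 20.0, hotspot_list: set | None = None,
                 review_policy: str = "exclude",
                 review_file: dict | None = None):
        if review_policy not in ("exclude", "include", "defer-to-file"):
            raise ValueError(f"unknown review policy {review_policy!r}")
        if review_policy == "defer-to-file" and review_file is None:
            raise ValueError("defer-to-file policy requires a review_file mapping")
        self.min_depth = min_depth
        self.min_alt_reads = min_alt_reads
        self.min_vaf = min_vaf
        self.maf_cutoff = maf_cutoff
        self.cadd_cutoff = cadd_cutoff
        self.hotspot_list = hotspot_list
        self.review_policy = review_policy
        self.review_file = review_file or {}


def _decide(rec: VariantRecord, cfg: FilterConfig) -> FilterDecision:
    trace: list[tuple[str, str]] = []
    failed: list[str] = []
    review: list[str] = []

    # 1. exonic gate — synonymous/non-exonic calls never progress
    ok = rec.is_exonic
    trace.append(("exonic", "pass" if ok else "fail"))
    if not ok:
        failed.append("exonic")

    # 2. quality
    if not failed:
        qd = apply_quality_filters([rec], cfg.min_depth, cfg.min_alt_reads,
                                   cfg.min_vaf)[0]
        trace.extend(qd.rule_trace)
        if qd.verdict == Verdict.MANUAL_REVIEW:
            review.extend(qd.failed_rules)
        else:
            failed.extend(qd.failed_rules)

    # 3. population frequency
    if not failed and not review:
        poly = filter_polymorphisms(rec, cfg.maf_cutoff)
        trace.append(("polymorphism", poly))
        if poly == "rejected_polymorphism":
            failed.append("polymorphism_maf")
        elif poly == "manual_review":
            review.append("manual_review")

    # 4. pathogenicity
    if not failed and not review:
        patho = classify_pathogenicity(rec, cfg.hotspot_list, cfg.cadd_cutoff)
        trace.append(("pathogenicity", patho.value))
        if patho == Verdict.REJECTED:
            failed.append("pathogenicity")
        elif patho == Verdict.MANUAL_REVIEW:
            review.append("manual_review")

    if failed:
        return FilterDecision(rec, Verdict.REJECTED, tuple(failed), tuple(trace))
    if review:
        return FilterDecision(rec, Verdict.MANUAL_REVIEW, tuple(review),
                              tuple(trace))
    return FilterDecision(rec, Verdict.RETAINED, (), tuple(trace))


def run_filter_pipeline(records: Sequence[VariantRecord],
                        config: FilterConfig | None = None,
                        patients: Sequence | None = None,
                        genes: Sequence | None = None,
                        ) -> tuple[MutationMatrix, list[FilterDecision]]:
    """Apply the full rule cascade and build the mutation-count matrix.

    Duplicate (patient, chrom, pos, ref, alt) records are collapsed to the
    first occurrence with a warning. Manual-review records are resolved by
    ``config.review_policy``: "exclude" (default), "include", or
    "defer-to-file" (per-record verdicts supplied in ``config.review_file``
    keyed by the record key tuple).

    ``patients`` / ``genes`` optionally fix the matrix axes (useful to
    include unmutated patients or genes); otherwise axes are the sorted
    identifiers observed in the input.
    """
    cfg = config or FilterConfig()
    seen: set[tuple] = set()
    unique: list[VariantRecord] = []
    for rec in records:
        if rec.key in seen:
            warnings.warn(f"duplicate variant record {rec.key} dropped", stacklevel=2)
            continue
        seen.add(rec.key)
        unique.append(rec)

    decisions = [_decide(rec, cfg) for rec in unique]

    retained: list[VariantRecord] = []
    for d in decisions:
        if d.verdict == Verdict.RETAINED:
            retained.append(d.record)
        elif d.verdict == Verdict.MANUAL_REVIEW:
            if cfg.review_policy == "include":
                retained.append(d.record)
            elif cfg.review_policy == "defer-to-file":
                if cfg.review_file.get(d.record.key) == "retain":
                    retained.append(d.record)

    pts = list(patients) if patients is not None else sorted({r.patient_id for r in unique})
    gns = list(genes) if genes is not None else sorted({r.gene for r in unique})
    counts = pd.DataFrame(0, index=pts, columns=gns)
    for rec in retained:
        if rec.patient_id not in counts.index or rec.gene not in counts.columns:
            counts.loc[rec.patient_id, rec.gene] = 0  # extend axes on demand
        counts.loc[rec.patient_id, rec.gene] += 1
    counts = counts.fillna(0).astype(int)
    return MutationMatrix(counts), decisions


class VariantFilter(BaseEstimator):
    """sklearn-style wrapper over the retention pipeline.

    ``transform`` maps a list of VariantRecord (or a TSV-dialect
    DataFrame) to the (MutationMatrix, decisions) pair; ``fit`` is a
    no-op kept for pipeline compatibility.
    """

    def __init__(self, min_depth: int = 100, min_alt_reads: int = 5,
                 min_vaf: float = 0.02, maf_cutoff: float = 0.01,
                 cadd_cutoff: float = 20.0, review_policy: str = "exclude"):
        self.min_depth = min_depth
        self.min_alt_reads = min_alt_reads
        self.min_vaf = min_vaf
        self.maf_cutoff = maf_cutoff
        self.cadd_cutoff = cadd_cutoff
        self.review_policy = review_policy

    def _config(self) -> FilterConfig:
        return FilterConfig(min_depth=self.min_depth,
                            min_alt_reads=self.min_alt_reads,
                            min_vaf=self.min_vaf, maf_cutoff=self.maf_cutoff,
                            cadd_cutoff=self.cadd_cutoff,
                            review_policy=self.review_policy)

    def fit(self, X=None, y=None) -> "VariantFilter":
        return self

    def transform(self, X, patients=None, genes=None):
        records = records_from_frame(X) if isinstance(X, pd.DataFrame) else list(X)
        matrix, decisions = run_filter_pipeline(records, self._config(),
                                                patients=patients, genes=genes)
        self.decisions_ = decisions
        return matrix


# ---------------------------------------------------------------------------
# I/O: annotated TSV dialect and VCF

def _na(value):
    return None if (value is None or (isinstance(value, float) and np.isnan(value))
                    or value in ("", ".", "NA")) else value


def records_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    """Typed records from the annotated-TSV dialect (see TSV_COLUMNS)."""
    recs = []
    for row in df.to_dict("records"):
        depth = _na(row.get("depth"))
        alt_reads = _na(row.get("alt_reads"))
        vaf = _na(row.get("vaf"))
        cadd = _na(row.get("cadd_phred"))
        maf = _na(row.get("pop_maf"))
        recs.append(VariantRecord(
            patient_id=str(row["patient_id"]), gene=str(row["gene"]),
            chrom=str(row["chrom"]), pos=int(row["pos"]),
            ref=str(row["ref"]), alt=str(row["alt"]),
            depth=None if depth is None else int(depth),
            alt_reads=None if alt_reads is None else int(alt_reads),
            vaf=None if vaf is None else float(vaf),
            is_exonic=_to_bool(row.get("is_exonic", True)),
            is_hotspot=_to_bool(row.get("is_hotspot", False)),
            sift_class=_na(row.get("sift_class")),
            cadd_phred=None if cadd is None else float(cadd),
            pop_maf=None if maf is None else float(maf),
            in_pop_db=_to_bool(row.get("in_pop_db", False)),
        ))
    return recs


def _to_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in TSV_COLUMNS})
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    return df


def read_variant_tsv(path) -> list[VariantRecord]:
    return records_from_frame(pd.read_csv(path, sep="\t"))


def write_variant_tsv(records: Sequence[VariantRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def decisions_to_frame(decisions: Sequence[FilterDecision]) -> pd.DataFrame:
    """Audit table: one row per record with verdict, failed rules, trace."""
    rows = []
    for d in decisions:
        r = d.record
        rows.append({
            "patient_id": r.patient_id, "gene": r.gene, "chrom": r.chrom,
            "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "verdict": d.verdict.value,
            "failed_rules": ";".join(d.failed_rules),
            "rule_trace": ";".join(f"{rule}={out}" for rule, out in d.rule_trace),
        })
    return pd.DataFrame(rows)


VCF_INFO_KEYS = {
    "sample": "SAMPLE", "gene": "GENE", "depth": "DP", "alt_reads": "AO",
    "sift": "SIFT", "cadd": "CADD", "maf": "POP_AF", "exonic": "EXONIC",
    "hotspot": "HOTSPOT", "in_db": "IN_DB",
}


def read_variant_vcf(path, info_keys: dict | None = None) -> list[VariantRecord]:
    """Read candidate calls from a VCF 4.x file (plain text or bgzipped).

    Annotation fields are pulled from INFO keys (defaults in
    ``VCF_INFO_KEYS``, overridable for other annotators' conventions).
    """
    import pysam

    keys = dict(VCF_INFO_KEYS)
    keys.update(info_keys or {})
    recs = []
    with pysam.VariantFile(str(path)) as vcf:
        for v in vcf:
            info = dict(v.info)
            for alt in v.alts or ():
                depth = info.get(keys["depth"])
                ao = info.get(keys["alt_reads"])
                if isinstance(ao, tuple):
                    ao = ao[0]
                maf = info.get(keys["maf"])
                cadd = info.get(keys["cadd"])
                sift = info.get(keys["sift"])
                recs.append(VariantRecord(
                    patient_id=str(info.get(keys["sample"], "NA")),
                    gene=str(info.get(keys["gene"], "NA")),
                    chrom=str(v.chrom), pos=int(v.pos), ref=str(v.ref),
                    alt=str(alt),
                    depth=None if depth is None else int(depth),
                    alt_reads=None if ao is None else int(ao),
                    vaf=None if (depth in (None, 0) or ao is None) else ao / depth,
                    is_exonic=bool(info.get(keys["exonic"], False)),
                    is_hotspot=bool(info.get(keys["hotspot"], False)),
                    sift_class=None if sift in (None, ".") else str(sift),
                    cadd_phred=None if cadd is None else float(cadd),
                    pop_maf=None if maf is None else float(maf),
                    in_pop_db=bool(info.get(keys["in_db"], False)),
                ))
    return recs


def write_variant_vcf(records: Sequence[VariantRecord], path) -> None:
    """Write records as an uncompressed VCF 4.2 file with the package's INFO keys."""
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Patient identifier">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate observations">',
        '##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT class">',
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD PHRED score">',
        '##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Population MAF">',
        '##INFO=<ID=EXONIC,Number=0,Type=Flag,Description="Exonic variant">',
        '##INFO=<ID=HOTSPOT,Number=0,Type=Flag,Description="Recurrent hotspot">',
        '##INFO=<ID=IN_DB,Number=0,Type=Flag,Description="Present in population databases">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    lines = list(header)
    for r in records:
        info = [f"SAMPLE={r.patient_id}", f"GENE={r.gene}"]
        if r.depth is not None:
            info.append(f"DP={r.depth}")
        if r.alt_reads is not None:
            info.append(f"AO={r.alt_reads}")
        if r.sift_class is not None:
            info.append(f"SIFT={r.sift_class}")
        if r.cadd_phred is not None:
            info.append(f"CADD={r.cadd_phred:g}")
        if r.pop_maf is not None:
            info.append(f"POP_AF={r.pop_maf:g}")
        if r.is_exonic:
            info.append("EXONIC")
        if r.is_hotspot:
            info.append("HOTSPOT")
        if r.in_pop_db:
            info.append("IN_DB")
        lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t" + ";".join(info))
    Path(path).write_text("\n".join(lines) + "\n")
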