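"""Rank candidate diagnoses by combining connectedness and distance evidence.

Each disease is represented by a :class:`DiseaseModel`: its co-perturbation
network, its main disease module, and reference-cohort calibration data.
A patient sample yields two pieces of evidence per disease:

* ``p_ctd`` — the CTD connectedness p-value of the patient's perturbation
  set in the disease network (is the perturbation pattern clustered the way
  the disease clusters metabolites?), and
* ``p_dm`` — the left-tail empirical percentile of the patient's distance
  to the main disease module among reference-sample distances (is the
  patient closer to the disease module than healthy profiles are?).

The two are merged by Brown's method — Fisher's combined probability test
with a correlation correction estimated from reference samples — and
diseases are ranked by the combined p-value.  A differential diagnosis (DD)
list collects diseases passing a Bonferroni-corrected threshold, and
HIT / BORDERLINE calls grade the evidence for variant re-interpretation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ctd_core import ctd_pvalue
from .ctd_distances import (DiseaseModule, ctd_dm, empirical_percentile,
                            main_disease_module)
from .network_inference import CoPerturbationNetwork
from .profile_io import PerturbationSet, ProfileMatrix, extract_perturbations

__all__ = [
    "DiseaseModel",
    "DiagnosisScore",
    "DiagnosisReport",
    "build_disease_model",
    "score_sample",
    "brown_combine",
    "rank_and_dd",
    "classify_hit",
    "classify_variant_evidence",
    "evaluate_cohort",
    "write_reports",
]

MIN_P = 1e-300  # smallest p accepted by the combiners


@dataclass
class DiseaseModel:
    """Everything needed to score a sample against one disease."""

    disease_label: str
    network: CoPerturbationNetwork
    module: DiseaseModule
    reference_dm_null: list[float]
    reference_score_table: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.module.nodes <= set(self.network.nodes()):
            raise ValueError("module nodes must lie inside the network")

    def brown_covariance(self, min_rows: int = 10) -> float | None:
        """Sample covariance of (-2 ln p_ctd, -2 ln p_dm) across references.

        Falls back to ``None`` (plain Fisher) with fewer than *min_rows*
        reference score pairs.
        """
        if len(self.reference_score_table) < min_rows:
            return None
        t = np.array([[-2.0 * math.log(max(p, MIN_P)) for p in row]
                      for row in self.reference_score_table])
        return float(np.cov(t[:, 0], t[:, 1], ddof=1)[0, 1])


@dataclass(frozen=True)
class DiagnosisScore:
    sample_id: str
    disease_label: str
    p_ctd: float
    d_dm: float
    p_dm: float
    p_combined: float
    detected_module: dict[str, float] = field(default_factory=dict, hash=False)


@dataclass
class DiagnosisReport:
    sample_id: str
    ranked: list[DiagnosisScore]           # ascending p_combined
    dd_list: list[str]                     # disease labels passing threshold
    hit_calls: dict[str, str]              # disease -> HIT/BORDERLINE/NONE
    dd_threshold: float
    unscoreable: list[str] = field(default_factory=list)

    @property
    def dd_length(self) -> int:
        return len(self.dd_list)

    def rank_of(self, disease_label: str) -> int | None:
        """1-based rank of a disease, or None if it was unscoreable."""
        for r, s in enumerate(self.ranked, start=1):
            if s.disease_label == disease_label:
                return r
        return None


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def build_disease_model(disease_label: str,
                        network: CoPerturbationNetwork,
                        disease_profiles: ProfileMatrix,
                        reference_profiles: ProfileMatrix,
                        z_threshold: float = 2.0,
                        max_set_size: int = 30) -> DiseaseModel:
    """Assemble a scoreable disease model from a learned network.

    The reference cohort provides both the null distribution of
    module distances and the (p_ctd, p_dm) pairs used to calibrate Brown's
    correlation correction.
    """
    module = main_disease_module(network, disease_profiles,
                                 disease_label=disease_label,
                                 z_threshold=z_threshold)
    universe = set(network.nodes())
    null: list[float] = []
    ref_sets: list[PerturbationSet] = []
    for sid in reference_profiles.sample_ids:
        ps = extract_perturbations(reference_profiles, sid, universe,
                                   z_threshold=z_threshold,
                                   max_set_size=max_set_size)
        if not ps.nodes:
            continue
        ref_sets.append(ps)
        null.append(float(ctd_dm(network, ps, module)))
    if not null:
        raise ValueError(
            f"no reference sample yields a scoreable set for {disease_label!r}"
        )
    table = []
    for ps, d in zip(ref_sets, null):
        res = ctd_pvalue(network, ps.nodes)
        table.append((res.p_value, empirical_percentile(d, null)))
    return DiseaseModel(disease_label=disease_label, network=network,
                        module=module, reference_dm_null=null,
                        reference_score_table=table)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def brown_combine(p_values, covariance_estimate: float | None = None) -> float:
    """Brown's combined p-value for (possibly correlated) tests.

    ``T = -2 * sum(ln p_i)`` follows, under independence, a chi-square with
    ``2k`` degrees of freedom (Fisher).  Brown rescales for correlation:
    with ``E[T] = 2k`` and ``Var[T] = 4k + 2*sum_{i<j} cov_ij``, T/c is
    compared to a chi-square with ``f = 2E^2/Var`` degrees of freedom where
    ``c = Var/(2E)``.  A single p-value is returned unchanged; zero
    covariance reduces exactly to Fisher's method.
    """
    ps = [float(p) for p in p_values]
    for p in ps:
        if p <= 0.0:
            raise ValueError("p-values must be positive; clip to a smallest "
                             "representable value upstream")
        if p > 1.0:
            raise ValueError(f"p-value {p} exceeds 1")
    k = len(ps)
    if k == 0:
        raise ValueError("no p-values to combine")
    if k == 1:
        return ps[0]
    t = -2.0 * sum(math.log(p) for p in ps)
    e = 2.0 * k
    var = 4.0 * k
    if covariance_estimate is not None:
        if k != 2:
            raise ValueError("scalar covariance only supported for k=2")
        var += 2.0 * covariance_estimate
    var = max(var, 1e-12)
    f = 2.0 * e * e / var
    c = var / (2.0 * e)
    return float(stats.chi2.sf(t / c, df=f))


def score_sample(sample: PerturbationSet, model: DiseaseModel
                 ) -> DiagnosisScore | None:
    """Score one perturbation set against one disease model.

    Returns ``None`` when the sample has no measurable overlap with the
    model's network (the caller logs it as unscoreable).
    """
    restricted = sample.restrict_to(set(model.network.nodes()))
    if not restricted.nodes:
        return None
    res = ctd_pvalue(model.network, restricted.nodes)
    p_ctd = max(res.p_value, MIN_P)
    d = float(ctd_dm(model.network, restricted, model.module))
    p_dm = max(empirical_percentile(d, model.reference_dm_null), MIN_P)
    p_comb = brown_combine([p_ctd, p_dm], model.brown_covariance())
    detected = {m: restricted.z_values.get(m)
                for m in sorted(res.optimal_subset)}
    return DiagnosisScore(sample_id=sample.sample_id,
                          disease_label=model.disease_label,
                          p_ctd=p_ctd, d_dm=d, p_dm=p_dm,
                          p_combined=max(p_comb, MIN_P),
                          detected_module=detected)


def classify_hit(p_combined: float) -> str:
    """HIT below 0.05, BORDERLINE in [0.05, 0.15), NONE otherwise."""
    if not 0.0 < p_combined <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p_combined}")
    if p_combined < 0.05:
        return "HIT"
    if p_combined < 0.15:
        return "BORDERLINE"
    return "NONE"


def rank_and_dd(scores: list[DiagnosisScore], n_models: int,
                alpha: float = 0.05, bonferroni: bool = True,
                sample_id: str | None = None,
                unscoreable: list[str] | None = None) -> DiagnosisReport:
    """Rank diseases by combined p-value and build the DD list.

    The DD (differential diagnosis) list holds diseases whose combined p
    beats ``alpha / n_models`` (Bonferroni over the models screened), or
    plain ``alpha`` when *bonferroni* is off.  Ties order by disease label.
    """
    if not scores and not unscoreable:
        raise ValueError("no scoreable disease for this sample")
    ranked = sorted(scores, key=lambda s: (s.p_combined, s.disease_label))
    threshold = alpha / n_models if bonferroni else alpha
    dd = [s.disease_label for s in ranked if s.p_combined < threshold]
    hits = {s.disease_label: classify_hit(s.p_combined) for s in ranked}
    sid = sample_id or (ranked[0].sample_id if ranked else "")
    return DiagnosisReport(sample_id=sid, ranked=ranked, dd_list=dd,
                           hit_calls=hits, dd_threshold=threshold,
                           unscoreable=list(unscoreable or ()))


def diagnose_sample(sample: PerturbationSet, models: list[DiseaseModel],
                    alpha: float = 0.05, bonferroni: bool = True
                    ) -> DiagnosisReport:
    """Score a sample against every model and assemble its report."""
    scores, unscoreable = [], []
    for model in models:
        s = score_sample(sample, model)
        if s is None:
            unscoreable.append(model.disease_label)
        else:
            scores.append(s)
    return rank_and_dd(scores, n_models=len(models), alpha=alpha,
                       bonferroni=bonferroni, sample_id=sample.sample_id,
                       unscoreable=unscoreable)


# ---------------------------------------------------------------------------
# Variant evidence
# ---------------------------------------------------------------------------

def classify_variant_evidence(n_het_pathogenic: int = 0,
                              n_hom_pathogenic: int = 0,
                              n_het_vus: int = 0,
                              n_hom_vus: int = 0,
                              all_benign: bool = False) -> str:
    """Assign the 5-class genotype category for an autosomal recessive gene.

    1: disease case (>=2 het pathogenic or >=1 hom pathogenic); 2: at least
    a carrier (1 het pathogenic plus >=1 het VUS); 3: uncertain (>=1 hom
    VUS or >=2 het VUS); 4: potential carrier (exactly 1 het VUS);
    5: control (all variants benign).  Rules are evaluated in that order;
    anything else is explicitly "unclassified".
    """
    for name, v in (("n_het_pathogenic", n_het_pathogenic),
                    ("n_hom_pathogenic", n_hom_pathogenic),
                    ("n_het_vus", n_het_vus), ("n_hom_vus", n_hom_vus)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    if n_het_pathogenic >= 2 or n_hom_pathogenic >= 1:
        return "1"
    if n_het_pathogenic == 1 and n_het_vus >= 1:
        return "2"
    if n_hom_vus >= 1 or n_het_vus >= 2:
        return "3"
    if n_het_vus == 1:
        return "4"
    if all_benign:
        return "5"
    return "unclassified"


# ---------------------------------------------------------------------------
# Cohort evaluation
# ---------------------------------------------------------------------------

def evaluate_cohort(reports: list[DiagnosisReport],
                    truth_labels: dict[str, str | None],
                    model_labels: list[str]) -> dict:
    """Accuracy metrics over a labeled cohort of diagnosis reports.

    *truth_labels* maps sample id to its true disease label, or ``None`` for
    reference samples.  Disease samples contribute top-1 / top-3 / in-DD
    fractions and the DD-length distribution; reference samples contribute
    their own median DD length (the specificity proxy: ideally 0-1 of the
    models fire on a healthy profile).  Per-disease sensitivity/specificity/
    accuracy come from HIT calls.
    """
    model_set = set(model_labels)
    top1 = top3 = in_dd = 0
    n_disease = 0
    dd_lengths_disease: list[int] = []
    dd_lengths_reference: list[int] = []
    per_disease = {d: {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
                   for d in model_labels}
    for rep in reports:
        truth = truth_labels.get(rep.sample_id)
        if truth is not None and truth not in model_set:
            warnings.warn(f"sample {rep.sample_id!r}: truth label {truth!r} "
                          "is not among the models; skipped")
            continue
        if truth is None:
            dd_lengths_reference.append(rep.dd_length)
        else:
            n_disease += 1
            dd_lengths_disease.append(rep.dd_length)
            rank = rep.rank_of(truth)
            if rank == 1:
                top1 += 1
            if rank is not None and rank <= 3:
                top3 += 1
            if truth in rep.dd_list:
                in_dd += 1
        for d in model_labels:
            called = rep.hit_calls.get(d) == "HIT"
            if truth == d:
                per_disease[d]["tp" if called else "fn"] += 1
            else:
                per_disease[d]["fp" if called else "tn"] += 1
    if n_disease == 0 and not dd_lengths_reference:
        raise ValueError("no labeled samples to evaluate")

    def _frac(x: int) -> float | None:
        return x / n_disease if n_disease else None

    def _pct(vals: list[int], q: float) -> float | None:
        return float(np.percentile(vals, q)) if vals else None

    by_disease = {}
    for d, c in per_disease.items():
        pos, neg = c["tp"] + c["fn"], c["fp"] + c["tn"]
        by_disease[d] = {
            "sensitivity": c["tp"] / pos if pos else None,
            "specificity": c["tn"] / neg if neg else None,
            "accuracy": ((c["tp"] + c["tn"]) / (pos + neg)
                         if pos + neg else None),
        }
    return {
        "n_disease_samples": n_disease,
        "top1": _frac(top1),
        "top3": _frac(top3),
        "in_dd": _frac(in_dd),
        "dd_length_median": _pct(dd_lengths_disease, 50),
        "dd_length_p5": _pct(dd_lengths_disease, 5),
        "dd_length_p95": _pct(dd_lengths_disease, 95),
        "reference_dd_length_median": _pct(dd_lengths_reference, 50),
        "per_disease": by_disease,
    }


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def write_reports(reports: list[DiagnosisReport], tsv_path,
                  json_path=None) -> None:
    """Flat per-(sample, disease) TSV plus optional JSON with modules."""
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tdisease\tp_ctd\td_dm\tp_dm\tp_combined\t"
                 "rank\tin_dd\thit_call\n")
        for rep in reports:
            for rank, s in enumerate(rep.ranked, start=1):
                fh.write("\t".join([
                    rep.sample_id, s.disease_label, repr(s.p_ctd),
                    repr(s.d_dm), repr(s.p_dm), repr(s.p_combined),
                    str(rank), str(s.disease_label in rep.dd_list),
                    rep.hit_calls[s.disease_label],
                ]) + "\n")
    if json_path is not None:
        payload = []
        for rep in reports:
            payload.append({
                "sample_id": rep.sample_id,
                "dd_threshold": rep.dd_threshold,
                "dd_list": rep.dd_list,
                "unscoreable": rep.unscoreable,
                "scores": [{
                    "disease": s.disease_label,
                    "p_ctd": s.p_ctd,
                    "d_dm": s.d_dm,
                    "p_dm": s.p_dm,
                    "p_combined": s.p_combined,
                    "hit": rep.hit_calls[s.disease_label],
                    "detected_module": s.detected_module,
                } for s in rep.ranked],
            })
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, allow_nan=True)
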