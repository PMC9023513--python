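"""Self-contained evaluation scenarios on synthetic cohorts.

Each runner generates data with :mod:`ctdnet.synthetic_data`, executes the
relevant slice of the pipeline, and returns the measured quantities.  They
exist so that the same scenario definitions back the test suite, the
worked examples and the acceptance script.

Problem sizes default to desk-scale versions of the package's study
conditions: cohorts of 8-20 disease and 25-40 reference samples over 24-40
metabolites, 6-node planted modules at 3 reference-SD effect.  One shared
control network is learned per scenario and reused by every disease model,
as the models share one reference cohort.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np

from .ctd_distances import (kmeans_purity, main_disease_module, mds_embed,
                            pairwise_distance_matrix)
from .diagnosis import (DiseaseModel, build_disease_model, diagnose_sample,
                        evaluate_cohort)
from .network_inference import (CoPerturbationNetwork, NetworkConfig,
                                differential_prune, learn_condition_network,
                                learn_disease_network,
                                learn_treatment_network, prune_nodes)
from .profile_io import (ProfileMatrix, extract_perturbations, impute_missing)
from .synthetic_data import (CohortSpec, TreatmentOverlay, make_cohort,
                             make_multidisease_benchmark)

__all__ = [
    "planted_edge_recovery",
    "run_ranking_benchmark",
    "run_treatment_censoring",
    "run_cohort_geometry",
    "three_module_network",
]


def _split(matrix, meta):
    dis = [m.sample_id for m in meta if m.role == "disease"]
    ref = [m.sample_id for m in meta if m.role == "reference"]
    return matrix.select_samples(dis), matrix.select_samples(ref)


# ---------------------------------------------------------------------------
# Planted-module recovery (network learning)
# ---------------------------------------------------------------------------

def planted_edge_recovery(seed: int, spec: CohortSpec | None = None,
                          config: NetworkConfig | None = None) -> dict:
    """Recall/precision of planted module edges after differential pruning.

    The planted truth is the full clique among module nodes (a shared latent
    factor makes every within-module pair conditionally dependent).
    """
    spec = replace(spec or CohortSpec(), seed=seed)
    config = config or NetworkConfig(seed=seed)
    matrix, meta = make_cohort(spec)
    dis, ref = _split(matrix, meta)
    net = learn_disease_network(dis, ref, config,
                                disease_label=spec.disease_label)
    planted = {tuple(sorted(p))
               for p in itertools.combinations(spec.resolved_module(), 2)}
    found = set(net.edges())
    hit = len(planted & found)
    return {
        "recall": hit / len(planted),
        "precision": hit / len(found) if found else 0.0,
        "n_edges": len(found),
        "lambda": net.provenance["lambda_selected"],
    }


# ---------------------------------------------------------------------------
# Multi-disease ranking benchmark
# ---------------------------------------------------------------------------

def _control_network(reference: ProfileMatrix, config: NetworkConfig
                     ) -> CoPerturbationNetwork:
    kept = [m for i, m in enumerate(reference.metabolite_ids)
            if m not in reference.binary_analytes
            and (~reference.missing_mask[i]).mean() > config.min_frac]
    ref_f = reference.select_metabolites(kept)
    ref_imp = impute_missing(ref_f, ref_f)
    net, _ = learn_condition_network(ref_imp.z.T, kept, "control", config,
                                     config.seed)
    return net


def _build_models(cohorts: dict, reference: ProfileMatrix,
                  config: NetworkConfig, z_threshold: float = 2.0,
                  max_set_size: int = 30) -> list[DiseaseModel]:
    control_net = _control_network(reference, config)
    ref_imp = impute_missing(reference, reference)
    models = []
    for label, (dmat, _meta) in sorted(cohorts.items()):
        net = learn_disease_network(dmat, reference, config,
                                    disease_label=label,
                                    control_network=control_net)
        dis_imp = impute_missing(dmat, reference)
        models.append(build_disease_model(label, net, dis_imp, ref_imp,
                                          z_threshold=z_threshold,
                                          max_set_size=max_set_size))
    return models


def run_ranking_benchmark(seed: int, n_diseases: int = 5,
                          n_disease: int = 8, n_reference: int = 25,
                          n_metabolites: int = 34,
                          overlap_fraction: float = 0.0,
                          effect_size: float = 3.0,
                          config: NetworkConfig | None = None) -> dict:
    """Learn one model per disease, diagnose every sample, report accuracy.

    Returns the :func:`ctdnet.diagnosis.evaluate_cohort` metrics: top-1 /
    top-3 / in-DD fractions over disease samples and the median DD length
    of reference samples (the specificity proxy).
    """
    template = CohortSpec(n_metabolites=n_metabolites, n_disease=n_disease,
                          n_reference=n_reference, effect_size=effect_size,
                          seed=seed)
    config = config or NetworkConfig(seed=seed, n_lambdas=20)
    cohorts, reference, truth = make_multidisease_benchmark(
        n_diseases, overlap_fraction, template)
    models = _build_models(cohorts, reference, config)
    universe = set().union(*(m.network.nodes() for m in models))
    labels = [m.disease_label for m in models]

    reports = []
    truth_map: dict[str, str | None] = {}
    for label, (dmat, _meta) in sorted(cohorts.items()):
        dis_imp = impute_missing(dmat, reference)
        for sid in dis_imp.sample_ids:
            ps = extract_perturbations(dis_imp, sid, universe)
            if not ps.nodes:
                continue
            reports.append(diagnose_sample(ps, models))
            truth_map[sid] = label
    ref_imp = impute_missing(reference, reference)
    for sid in ref_imp.sample_ids:
        ps = extract_perturbations(ref_imp, sid, universe)
        if not ps.nodes:
            continue
        reports.append(diagnose_sample(ps, models))
        truth_map[sid] = None
    return evaluate_cohort(reports, truth_map, labels)


# ---------------------------------------------------------------------------
# Treatment censoring
# ---------------------------------------------------------------------------

def run_treatment_censoring(seed: int, n_metabolites: int = 24,
                            n_reference: int = 25) -> dict:
    """Confounded two-disease scenario before/after treatment-node pruning.

    Disease A's cohort is mostly on a treatment whose overlay module shares
    nodes with disease B's module, so B patients light up in A's network
    (false HITs).  The main treatment module is identified from a
    treatment-specific network and its nodes are pruned from A's network;
    the scenario reports false A-HITs among B patients and the top-1
    accuracy of A patients, both before and after pruning.
    """
    mets = CohortSpec(n_metabolites=n_metabolites).metabolite_ids()
    module_a = tuple(mets[0:6])
    overlay = tuple(mets[6:10])
    module_b = tuple(mets[6:12])        # shares all of mets[6:10], the overlay
    # two thirds of A patients are on treatment: the overlay recurs in >50%
    # of the cohort and therefore contaminates A's main disease module,
    # exactly the confounding the censoring step is meant to undo
    spec_a = CohortSpec(n_metabolites=n_metabolites, n_disease=30,
                        n_reference=n_reference, module_nodes=module_a,
                        disease_label="disease_A", seed=seed * 100 + 1,
                        treatment_overlay=TreatmentOverlay(
                            nodes=overlay, effect=3.0, fraction_treated=2 / 3))
    spec_b = CohortSpec(n_metabolites=n_metabolites, n_disease=10,
                        n_reference=n_reference, module_nodes=module_b,
                        disease_label="disease_B", seed=seed * 100 + 2)
    mat_a, meta_a = make_cohort(spec_a)
    mat_b, meta_b = make_cohort(spec_b)
    dis_a, reference = _split(mat_a, meta_a)
    dis_b, _ = _split(mat_b, meta_b)
    config = NetworkConfig(seed=seed, n_lambdas=20)

    control_net = _control_network(reference, config)
    net_a = learn_disease_network(dis_a, reference, config,
                                  disease_label="disease_A",
                                  control_network=control_net)
    net_b = learn_disease_network(dis_b, reference, config,
                                  disease_label="disease_B",
                                  control_network=control_net)

    treated_ids = [m.sample_id for m in meta_a
                   if m.role == "disease" and "treated" in m.treatment_flags]
    untreated_ids = [m.sample_id for m in meta_a
                     if m.role == "disease" and "treated" not in m.treatment_flags]
    # contrast = untreated patients with the same disease, so the shared
    # disease signal cancels and the pooled network is driven by treatment
    untreated_mat = mat_a.select_samples(untreated_ids)
    treatment_net = learn_treatment_network(
        mat_a.select_samples(treated_ids), untreated_mat,
        untreated_mat, config, treatment_label="citrulline_like")
    treated_imp = impute_missing(mat_a.select_samples(treated_ids), reference)
    untreated_imp = impute_missing(untreated_mat, reference)
    if treatment_net.n_edges():
        treatment_module = main_disease_module(
            treatment_net, treated_imp, disease_label="citrulline_like",
            exclude_profiles=untreated_imp)
        censored = set(treatment_module.nodes)
    else:
        censored = set()
    net_a_pruned = prune_nodes(net_a, censored)

    ref_imp = impute_missing(reference, reference)
    dis_a_imp = impute_missing(dis_a, reference)
    dis_b_imp = impute_missing(dis_b, reference)

    def score_world(a_net):
        model_a = build_disease_model("disease_A", a_net, dis_a_imp, ref_imp)
        model_b = build_disease_model("disease_B", net_b, dis_b_imp, ref_imp)
        models = [model_a, model_b]
        universe = set().union(*(m.network.nodes() for m in models))
        false_hits = 0
        for sid in dis_b_imp.sample_ids:
            ps = extract_perturbations(dis_b_imp, sid, universe)
            if not ps.nodes:
                continue
            rep = diagnose_sample(ps, models)
            if rep.hit_calls.get("disease_A") == "HIT":
                false_hits += 1
        top1 = 0
        for sid in dis_a_imp.sample_ids:
            ps = extract_perturbations(dis_a_imp, sid, universe)
            if not ps.nodes:
                continue
            rep = diagnose_sample(ps, models)
            top1 += (rep.rank_of("disease_A") == 1)
        return false_hits, top1 / dis_a_imp.n_samples

    fh_before, top1_before = score_world(net_a)
    fh_after, top1_after = score_world(net_a_pruned)
    return {
        "treatment_module": sorted(censored),
        "false_hits_before": fh_before,
        "false_hits_after": fh_after,
        "top1_before": top1_before,
        "top1_after": top1_after,
    }


# ---------------------------------------------------------------------------
# Cohort geometry
# ---------------------------------------------------------------------------

def three_module_network(n_background: int = 22,
                         module_size: int = 6) -> tuple[CoPerturbationNetwork,
                                                        list[tuple[str, ...]]]:
    """Fixed network with three distal module cliques over a sparse backbone.

    Modules are cliques (weight 0.8) hanging off distant points of a weak
    background chain (weight 0.1), so sets within one module are tightly
    connected while sets in different modules are far apart.
    """
    n_total = 3 * module_size + n_background
    ids = CohortSpec(n_metabolites=n_total).metabolite_ids()
    modules = [tuple(ids[k * module_size:(k + 1) * module_size])
               for k in range(3)]
    background = ids[3 * module_size:]
    net = CoPerturbationNetwork(ids)
    for module in modules:
        for a, b in itertools.combinations(module, 2):
            net.add_edge(a, b, 0.8)
    for a, b in zip(background, background[1:]):
        net.add_edge(a, b, 0.1)
    anchor = [0, len(background) // 2, len(background) - 1]
    for module, pos in zip(modules, anchor):
        net.add_edge(module[0], background[pos], 0.1)
    return net, modules


def run_cohort_geometry(seed: int, n_per_cohort: int = 12,
                        z_threshold: float = 2.0) -> dict:
    """CTDncd distances -> classical MDS -> k-means purity on 3 cohorts.

    The network is the fixed three-module graph of
    :func:`three_module_network`; the cohorts are synthetic patients
    perturbing one module each.
    """
    net, modules = three_module_network()
    ids = net.nodes()
    sets, labels = [], []
    for k, module in enumerate(modules):
        spec = CohortSpec(n_metabolites=len(ids), n_disease=n_per_cohort,
                          n_reference=1, module_nodes=module,
                          disease_label=f"cohort_{k}", seed=seed * 10 + k)
        matrix, meta = make_cohort(spec)
        dis, _ = _split(matrix, meta)
        # missing cells simply do not enter the perturbation set
        for sid in dis.sample_ids:
            ps = extract_perturbations(dis, sid, set(ids),
                                       z_threshold=z_threshold)
            if ps.nodes:
                sets.append(ps)
                labels.append(f"cohort_{k}")
    dm = pairwise_distance_matrix(net, sets)
    coords = mds_embed(dm, dims=2)
    purity = kmeans_purity(coords, labels, k=3, seed=seed)
    return {"purity": purity, "n_samples": len(sets), "coords": coords,
            "labels": labels, "distance_matrix": dm}
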