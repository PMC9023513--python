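"""Network distances between node sets, and cohort geometry built on them.

The normalized compression distance (NCD) idea: two node sets are close if
encoding them jointly costs little more than encoding either alone.  With
``I(.)`` the adaptive-walk encoding length from :mod:`ctdnet.ctd_core`,

    ncd(S1, S2) = max(I(S1,S2) - I(S1), I(S1,S2) - I(S2)) / max(I(S1), I(S2))

where ``I(S1,S2)`` encodes the union.  Applied to two patients' perturbation
sets this is a patient-patient distance; applied to a patient set and a
disease's "main disease module" it is a patient-disease distance.

The cohort-geometry helpers (pairwise distance matrix, classical MDS,
k-means purity, centroid separation) support the population-level view:
patients with distinct diseases should separate into clean clusters under
the patient-patient distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .ctd_core import ctd_pvalue, information_content
from .network_inference import CoPerturbationNetwork
from .profile_io import PerturbationSet, ProfileMatrix

__all__ = [
    "DiseaseModule",
    "DistanceMatrix",
    "NcdValue",
    "joint_information",
    "ctd_ncd",
    "main_disease_module",
    "ctd_dm",
    "empirical_percentile",
    "pairwise_distance_matrix",
    "mds_embed",
    "kmeans_purity",
    "centroid_distance",
    "write_module",
    "read_module",
    "write_distance_matrix",
    "read_distance_matrix",
]


@dataclass(frozen=True)
class DiseaseModule:
    """Representative highly connected perturbed node set of one disease."""

    disease_label: str
    nodes: frozenset[str]
    source: str = "algorithm1_surrogate"

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        if not self.nodes:
            raise ValueError("disease module must be nonempty")


class NcdValue(float):
    """A clipped-to-[0,1] distance that remembers its pre-clip value."""

    raw: float

    def __new__(cls, raw: float):
        obj = super().__new__(cls, min(1.0, max(0.0, raw)))
        obj.raw = float(raw)
        return obj


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if np.abs(self.d - self.d.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) != 0.0:
            raise ValueError("distance matrix diagonal must be zero")
        if self.d.min(initial=0.0) < 0:
            raise ValueError("distances must be nonnegative")


def _as_nodes(s) -> frozenset[str]:
    if isinstance(s, PerturbationSet):
        return frozenset(s.nodes)
    return frozenset(s)


# ---------------------------------------------------------------------------
# NCD distances
# ---------------------------------------------------------------------------

def joint_information(network: CoPerturbationNetwork, s1, s2) -> float:
    """Encoding length of the union of two sets, ``I(S1 union S2)``."""
    u = (_as_nodes(s1) | _as_nodes(s2)) & frozenset(network.nodes())
    if not u:
        raise ValueError("both sets are empty after network intersection")
    bits, _ = information_content(network, u)
    return bits


def ctd_ncd(network: CoPerturbationNetwork, s1, s2) -> NcdValue:
    """Normalized compression distance between two node sets in a network."""
    nodes = frozenset(network.nodes())
    a = _as_nodes(s1) & nodes
    b = _as_nodes(s2) & nodes
    if not a or not b:
        raise ValueError("cannot compute a distance for an empty set")
    i1, _ = information_content(network, a)
    i2, _ = information_content(network, b)
    i12 = i1 if a == b else joint_information(network, a, b)
    raw = max(i12 - i1, i12 - i2) / max(i1, i2)
    return NcdValue(raw)


def _recurrent_nodes(profiles: ProfileMatrix, nodes: frozenset[str],
                     z_threshold: float, recurrence_frac: float) -> list[str]:
    out = []
    for m in profiles.metabolite_ids:
        if m not in nodes:
            continue
        i = profiles.row_index(m)
        row = profiles.z[i]
        obs = ~profiles.missing_mask[i]
        if m in profiles.binary_analytes:
            hits = int((row[obs] == 1.0).sum())
        else:
            hits = int((np.abs(row[obs]) >= z_threshold).sum())
        if hits > recurrence_frac * profiles.n_samples:
            out.append(m)
    return out


def main_disease_module(network: CoPerturbationNetwork,
                        disease_profiles: ProfileMatrix,
                        disease_label: str = "disease",
                        z_threshold: float = 2.0,
                        recurrence_frac: float = 0.5,
                        exclude_profiles: ProfileMatrix | None = None
                        ) -> DiseaseModule:
    """Extract the disease's recurrently perturbed, highly connected module.

    Candidate nodes are network metabolites perturbed (|z| >= *z_threshold*,
    or a present binary analyte) in more than *recurrence_frac* of disease
    samples; the module is the CTD optimal highly connected subset of the
    candidates.  If no node recurs, the fallback candidates are the ten
    network nodes with the largest median |z|.

    *exclude_profiles* makes the recurrence differential: nodes that also
    recur in those profiles are dropped from the candidates.  This is how a
    main *treatment* module is isolated — recurrent in treated patients but
    not in untreated patients with the same disease.
    """
    if disease_profiles.n_samples < 2:
        raise ValueError("need at least 2 disease profiles")
    nodes = frozenset(network.nodes())
    measured = [m for m in disease_profiles.metabolite_ids if m in nodes]
    if not measured:
        raise ValueError("no network nodes are measured in the cohort")
    candidates = _recurrent_nodes(disease_profiles, nodes, z_threshold,
                                  recurrence_frac)
    if exclude_profiles is not None:
        drop = set(_recurrent_nodes(exclude_profiles, nodes, z_threshold,
                                    recurrence_frac))
        candidates = [m for m in candidates if m not in drop]
    if not candidates:
        med = []
        for m in measured:
            i = disease_profiles.row_index(m)
            obs = ~disease_profiles.missing_mask[i]
            vals = np.abs(disease_profiles.z[i][obs])
            med.append((-(float(np.median(vals)) if vals.size else 0.0), m))
        med.sort()
        candidates = [m for _, m in med[:10]]
    result = ctd_pvalue(network, candidates)
    return DiseaseModule(disease_label=disease_label,
                         nodes=result.optimal_subset,
                         source="algorithm1_surrogate")


def ctd_dm(network: CoPerturbationNetwork, patient_set: PerturbationSet,
           module: DiseaseModule) -> NcdValue:
    """Distance between a patient's perturbation set and a disease module."""
    return ctd_ncd(network, patient_set, module.nodes)


def empirical_percentile(value: float, reference_values) -> float:
    """Add-one left-tail percentile of *value* among reference distances.

    ``(#{ref <= value} + 1) / (n_ref + 1)``: a patient closer to the disease
    module than every reference sample gets a small left-tail probability.
    """
    ref = list(reference_values)
    if not ref:
        raise ValueError("empty reference distance list")
    count = sum(1 for r in ref if r <= value)
    return (count + 1) / (len(ref) + 1)


# ---------------------------------------------------------------------------
# Cohort geometry
# ---------------------------------------------------------------------------

def pairwise_distance_matrix(network: CoPerturbationNetwork,
                             sets: list[PerturbationSet]) -> DistanceMatrix:
    """Symmetric patient-patient NCD matrix, one computation per pair."""
    if len(sets) < 2:
        raise ValueError("need at least 2 perturbation sets")
    nodes = frozenset(network.nodes())
    for ps in sets:
        if not _as_nodes(ps) & nodes:
            raise ValueError(f"sample {ps.sample_id!r} has an empty set "
                             "within the network")
    n = len(sets)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(ctd_ncd(network, sets[i], sets[j]))
    return DistanceMatrix(ids=[ps.sample_id for ps in sets], d=d)


def mds_embed(dm: DistanceMatrix, dims: int = 2, seed: int | None = None
              ) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-center ``-D**2 / 2``, take the top *dims* eigenpairs; negative
    eigenvalues (non-Euclidean part) contribute zero coordinates.  The
    embedding is deterministic; axis signs are fixed so that the largest
    magnitude loading on each axis is positive.  *seed* is accepted for
    interface symmetry but unused.
    """
    n = len(dm.ids)
    if not 0 < dims < n:
        raise ValueError(f"dims must be in (0, {n})")
    D2 = dm.d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)  # ascending
    order = np.argsort(vals)[::-1][:dims]
    coords = np.zeros((n, dims))
    # eigenvalues below working precision of the largest are rank noise
    tol = max(np.abs(vals).max(initial=0.0) * 1e-12, 0.0)
    for k, idx in enumerate(order):
        lam = vals[idx]
        if lam <= tol:
            continue
        axis = vecs[:, idx] * math.sqrt(lam)
        pivot = int(np.argmax(np.abs(axis)))
        if axis[pivot] < 0:
            axis = -axis
        coords[:, k] = axis
    return coords


def kmeans_purity(coords: np.ndarray, true_labels, k: int, seed: int = 0,
                  n_init: int = 50) -> float:
    """Cluster purity of seeded k-means on embedded coordinates.

    Purity is the fraction of samples whose cluster's majority class matches
    their own: ``(1/N) * sum_c max_class |c intersect class|``.
    """
    from sklearn.cluster import KMeans

    coords = np.asarray(coords, dtype=float)
    labels = list(true_labels)
    if k > coords.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples {coords.shape[0]}")
    if len(labels) != coords.shape[0]:
        raise ValueError("label count does not match coordinates")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assign = km.fit_predict(coords)
    total = 0
    for c in range(k):
        members = [labels[i] for i in range(len(labels)) if assign[i] == c]
        if members:
            total += max(members.count(x) for x in set(members))
    return total / len(labels)


def centroid_distance(coords: np.ndarray, labels, group_a: str,
                      group_b: str) -> float:
    """Euclidean distance between the mean coordinates of two labeled groups."""
    coords = np.asarray(coords, dtype=float)
    labels = list(labels)
    means = []
    for g in (group_a, group_b):
        rows = [i for i, lab in enumerate(labels) if lab == g]
        if not rows:
            raise ValueError(f"unknown or empty group label {g!r}")
        means.append(coords[rows].mean(axis=0))
    return float(np.linalg.norm(means[0] - means[1]))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_module(module: DiseaseModule, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"disease_label": module.disease_label,
                   "nodes": sorted(module.nodes),
                   "source": module.source}, fh, indent=1)


def read_module(path) -> DiseaseModule:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return DiseaseModule(disease_label=obj["disease_label"],
                         nodes=frozenset(obj["nodes"]),
                         source=obj.get("source", "user_supplied"))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for i, sid in enumerate(dm.ids):
            fh.write(sid + "\t" + "\t".join(repr(float(x)) for x in dm.d[i])
                     + "\n")


def read_distance_matrix(path) -> DistanceMatrix:
    with open(path, encoding="utf-8") as fh:
        ids = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            if line.strip():
                rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
    return DistanceMatrix(ids=ids, d=np.asarray(rows))
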