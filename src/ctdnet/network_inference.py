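"""Learn disease-specific metabolite co-perturbation networks.

A co-perturbation network is a Gaussian graphical model: nodes are
metabolites, and an edge means the two metabolites' z-scores remain
correlated after conditioning on every other metabolite (nonzero entry of
the precision matrix).  Edge weights are partial correlations.

Disease specificity comes from a differential construction.  One network is
learned from pooled disease + control profiles — the disease indicator then
acts as a hidden variable tying together metabolites that move with the
disease — and a second network from control profiles alone.  Edges present
in the control network are background physiology and are pruned from the
pooled network; what remains co-varies specifically under the disease.

The precision matrix is estimated by the graphical lasso along a
regularization path, with the penalty chosen by StARS (stability approach
to regularization selection): the sparsest penalty whose edge set is
reproducible across random subsamples.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .profile_io import ProfileMatrix, filter_by_presence, impute_missing

__all__ = [
    "PrecisionMatrix",
    "CoPerturbationNetwork",
    "StarsSelection",
    "NetworkConfig",
    "glasso_fit",
    "default_lambda_path",
    "stars_select",
    "to_partial_correlation",
    "differential_prune",
    "prune_nodes",
    "learn_condition_network",
    "learn_disease_network",
    "learn_treatment_network",
    "write_network",
    "read_network",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class PrecisionMatrix:
    """Symmetric positive-definite inverse covariance over named metabolites."""

    metabolite_ids: list[str]
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        p = len(self.metabolite_ids)
        if self.theta.shape != (p, p):
            raise ValueError(f"theta shape {self.theta.shape} != ({p}, {p})")
        if np.abs(self.theta - self.theta.T).max(initial=0.0) > 1e-8:
            raise ValueError("theta is not symmetric within 1e-8")
        if p and np.diag(self.theta).min() <= 0:
            raise ValueError("theta diagonal must be strictly positive")


def _canon(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-edge on {a!r}")
    return (a, b) if a < b else (b, a)


class CoPerturbationNetwork:
    """Undirected weighted graph of metabolites; weights are partial correlations."""

    def __init__(self, nodes, edges: dict | None = None,
                 provenance: dict | None = None):
        self._nodes: tuple[str, ...] = tuple(sorted(set(nodes)))
        self._node_set = frozenset(self._nodes)
        self._edges: dict[tuple[str, str], float] = {}
        self.provenance: dict = dict(provenance or {})
        if edges:
            for (a, b), w in edges.items():
                self.add_edge(a, b, w)

    # construction -------------------------------------------------------
    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a not in self._node_set or b not in self._node_set:
            raise ValueError(f"edge endpoint not a node: {a!r}-{b!r}")
        w = float(weight)
        if not -1.0 <= w <= 1.0:
            raise ValueError(f"weight {w} outside [-1, 1] for {a!r}-{b!r}")
        self._edges[_canon(a, b)] = w
        self._adj = None

    # queries ------------------------------------------------------------
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    def n_nodes(self) -> int:
        return len(self._nodes)

    def has_node(self, v: str) -> bool:
        return v in self._node_set

    def edges(self) -> dict[tuple[str, str], float]:
        return dict(self._edges)

    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _canon(a, b) in self._edges

    def weight(self, a: str, b: str) -> float:
        return self._edges[_canon(a, b)]

    def neighbors_weighted(self, v: str):
        """List of ``(neighbor, weight)`` pairs, id-sorted."""
        adj = getattr(self, "_adj", None)
        if adj is None:
            adj = {u: [] for u in self._nodes}
            for (a, b), w in sorted(self._edges.items()):
                adj[a].append((b, w))
                adj[b].append((a, w))
            for u in adj:
                adj[u].sort()
            self._adj = adj
        return adj[v]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        for (a, b), w in self._edges.items():
            g.add_edge(a, b, weight=w)
        return g

    def __eq__(self, other) -> bool:
        return (isinstance(other, CoPerturbationNetwork)
                and self._nodes == other._nodes
                and self._edges == other._edges)

    def __repr__(self) -> str:
        return (f"CoPerturbationNetwork({len(self._nodes)} nodes, "
                f"{len(self._edges)} edges)")


@dataclass
class StarsSelection:
    """Record of one StARS penalty selection."""

    lambda_path: np.ndarray            # decreasing
    instability_per_lambda: np.ndarray  # monotonized, same order
    raw_instability: np.ndarray
    selected_lambda: float
    subsample_count: int
    subsample_size: int
    seed: int
    all_unstable: bool = False


@dataclass
class NetworkConfig:
    """Knobs of the network-learning pipeline."""

    min_frac: float = 0.5
    n_lambdas: int = 30
    lambda_min_ratio: float = 0.01
    n_subsamples: int = 20
    instability_threshold: float = 0.1
    n_surrogates: int = 0
    surrogate_noise_sd: float = 0.1
    seed: int = 0


# ---------------------------------------------------------------------------
# Graphical lasso and StARS
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _correlation(X: np.ndarray) -> np.ndarray:
    Z = _standardize(X)
    n = Z.shape[0]
    C = Z.T @ Z / (n - 1)
    np.fill_diagonal(C, 1.0)
    return C


def _solve_glasso(corr: np.ndarray, lam: float, tol: float = 1e-4,
                  max_iter: int = 200) -> np.ndarray:
    from sklearn.exceptions import ConvergenceWarning

    with np.errstate(all="raise"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            _, prec = _sk_graphical_lasso(corr, alpha=lam, mode="cd",
                                          tol=tol, max_iter=max_iter)
        except FloatingPointError:
            try:
                _, prec = _sk_graphical_lasso(corr, alpha=lam, mode="lars",
                                              max_iter=max_iter)
            except FloatingPointError as exc:
                raise RuntimeError(
                    f"graphical lasso failed to converge at lambda={lam}"
                ) from exc
    return (prec + prec.T) / 2.0


def glasso_fit(data: np.ndarray, lam: float,
               metabolite_ids: list[str] | None = None) -> PrecisionMatrix:
    """L1-penalized precision matrix of a samples x metabolites data matrix.

    Columns are standardized internally, so the penalty acts on the
    correlation scale.
    """
    X = np.asarray(data, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("data contains non-finite values")
    if X.shape[0] < 3:
        raise ValueError(f"need at least 3 samples, got {X.shape[0]}")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    ids = (list(metabolite_ids) if metabolite_ids is not None
           else [f"m{j}" for j in range(X.shape[1])])
    theta = _solve_glasso(_correlation(X), lam)
    return PrecisionMatrix(metabolite_ids=ids, theta=theta)


def default_lambda_path(data: np.ndarray, n_lambdas: int = 30,
                        min_ratio: float = 0.01) -> np.ndarray:
    """Decreasing log-spaced path from lambda_max down to min_ratio*lambda_max.

    lambda_max is the largest absolute off-diagonal sample correlation — the
    smallest penalty at which the graphical lasso support is empty.
    """
    C = _correlation(np.asarray(data, dtype=float))
    off = np.abs(C - np.diag(np.diag(C)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1e-2
    return np.logspace(math.log10(lam_max), math.log10(lam_max * min_ratio),
                       n_lambdas)


def _support(theta: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    off = np.abs(theta) > tol
    np.fill_diagonal(off, False)
    return off


def stars_select(data: np.ndarray, lambda_path: np.ndarray | None = None,
                 n_subsamples: int = 20, instability_threshold: float = 0.1,
                 seed: int = 0) -> StarsSelection:
    """Choose the glasso penalty by edge-selection stability across subsamples.

    For each penalty, the graphical lasso is fit on ``n_subsamples`` random
    subsamples of size ``floor(0.8*n)`` (for n <= 144; ``floor(10*sqrt(n))``
    beyond, where that is the smaller); per-edge instability
    is ``2*f*(1-f)`` with ``f`` the selection frequency, averaged over all
    node pairs.  Instability is monotonized from the sparse end of the path
    and the smallest penalty whose monotonized instability stays at or below
    the threshold is selected.  If no penalty qualifies, the largest penalty
    is returned with ``all_unstable`` set.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError(f"StARS needs at least 10 samples, got {n}")
    if lambda_path is None:
        lambda_path = default_lambda_path(X)
    lambda_path = np.asarray(sorted(lambda_path, reverse=True), dtype=float)
    # 10*sqrt(n) exceeds n itself for n <= 144; fall back to 80% subsamples
    # there so that subsamples actually differ (standard StARS practice).
    b = min(int(math.floor(10 * math.sqrt(n))), int(math.floor(0.8 * n)), n - 1)
    rng = np.random.default_rng(seed)
    n_pairs = p * (p - 1) // 2
    corrs = [_correlation(X[rng.choice(n, size=b, replace=False)])
             for _ in range(n_subsamples)]
    # Walk the path from sparse to dense.  Monotonized instability can only
    # grow along the walk, so once it exceeds the threshold no denser
    # penalty can ever be selected and the remaining fits are skipped;
    # skipped penalties are scored at the maximal instability 0.5, as is
    # any penalty where a subsample fit is ill-conditioned.
    inst = np.full(len(lambda_path), 0.5)
    running_max = 0.0
    for k, lam in enumerate(lambda_path):
        freq = np.zeros((p, p))
        n_ok = 0
        for corr in corrs:
            try:
                # loose tolerance: only the support matters here
                theta = _solve_glasso(corr, lam, tol=1e-3, max_iter=100)
            except RuntimeError:
                break  # ill-conditioned at this penalty
            freq += _support(theta)
            n_ok += 1
        if n_ok == n_subsamples:
            f = freq / n_ok
            inst[k] = ((2.0 * f * (1.0 - f))[np.triu_indices(p, 1)].sum()
                       / n_pairs)
        running_max = max(running_max, inst[k])
        if running_max > instability_threshold:
            break
    monotone = np.maximum.accumulate(inst)  # path is sparse -> dense
    ok = monotone <= instability_threshold
    if ok.any():
        k_sel = int(np.where(ok)[0].max())  # smallest qualifying lambda
        all_unstable = False
    else:
        k_sel = 0
        all_unstable = True
    return StarsSelection(
        lambda_path=lambda_path,
        instability_per_lambda=monotone,
        raw_instability=inst,
        selected_lambda=float(lambda_path[k_sel]),
        subsample_count=n_subsamples,
        subsample_size=b,
        seed=seed,
        all_unstable=all_unstable,
    )


def to_partial_correlation(theta: PrecisionMatrix,
                           provenance: dict | None = None,
                           support_tol: float = 1e-12) -> CoPerturbationNetwork:
    """Convert a precision matrix to a partial-correlation edge network.

    ``w(i,j) = -theta_ij / sqrt(theta_ii * theta_jj)``; edges exist exactly
    where the precision entry is nonzero.
    """
    t = theta.theta
    d = np.diag(t)
    if d.size and d.min() <= 0:
        raise ValueError("non-positive diagonal in precision matrix")
    net = CoPerturbationNetwork(theta.metabolite_ids, provenance=provenance)
    ids = theta.metabolite_ids
    scale = 1.0 / np.sqrt(d)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(t[i, j]) > support_tol:
                w = -t[i, j] * scale[i] * scale[j]
                net.add_edge(ids[i], ids[j], float(np.clip(w, -1.0, 1.0)))
    return net


# ---------------------------------------------------------------------------
# Differential construction
# ---------------------------------------------------------------------------

def differential_prune(target: CoPerturbationNetwork,
                       background: CoPerturbationNetwork) -> CoPerturbationNetwork:
    """Drop every target edge whose node pair also exists in the background.

    Membership is support-only: an edge is "found in both" regardless of
    weight sign or magnitude.  The node set is preserved.
    """
    bg = set(background.edges())
    kept = {pair: w for pair, w in target.edges().items() if pair not in bg}
    prov = dict(target.provenance)
    prov["pruned_against"] = background.provenance.get("condition_label")
    prov["n_edges_before_prune"] = target.n_edges()
    return CoPerturbationNetwork(target.nodes(), kept, prov)


def prune_nodes(network: CoPerturbationNetwork,
                nodes_to_remove) -> CoPerturbationNetwork:
    """Remove nodes and all incident edges; removing absent nodes is a no-op."""
    drop = set(nodes_to_remove)
    keep_nodes = [v for v in network.nodes() if v not in drop]
    kept = {(a, b): w for (a, b), w in network.edges().items()
            if a not in drop and b not in drop}
    prov = dict(network.provenance)
    if drop:
        prov["nodes_pruned"] = sorted(drop & set(network.nodes()))
    return CoPerturbationNetwork(keep_nodes, kept, prov)


def _surrogate_columns(disease: ProfileMatrix, n: int, noise_sd: float,
                       rng: np.random.Generator) -> ProfileMatrix:
    src = rng.integers(0, disease.n_samples, size=n)
    z = disease.z[:, src] + rng.normal(0.0, noise_sd,
                                       size=(disease.n_metabolites, n))
    return ProfileMatrix(
        metabolite_ids=list(disease.metabolite_ids),
        sample_ids=[f"surrogate_{k}" for k in range(n)],
        z=z,
        missing_mask=np.zeros_like(z, dtype=bool),
        binary_analytes=set(),
    )


def learn_condition_network(X: np.ndarray, metabolite_ids: list[str],
                            condition_label: str,
                            config: NetworkConfig,
                            seed: int) -> tuple[CoPerturbationNetwork, StarsSelection]:
    """StARS-selected glasso network from one samples x metabolites matrix.

    Cohorts too small to subsample (n < 10) skip StARS and use the
    rate-based penalty ``sqrt(log(p)/n)`` (capped at lambda_max), flagged in
    provenance; such networks are inevitably coarse.
    """
    path = default_lambda_path(X, config.n_lambdas, config.lambda_min_ratio)
    if X.shape[0] >= 10:
        sel = stars_select(X, path, n_subsamples=config.n_subsamples,
                           instability_threshold=config.instability_threshold,
                           seed=seed)
        lam = sel.selected_lambda
    else:
        sel = None
        lam = min(float(path[0]),
                  math.sqrt(math.log(X.shape[1]) / X.shape[0]))
    theta = glasso_fit(X, lam, metabolite_ids)
    prov = {
        "condition_label": condition_label,
        "lambda_selected": lam,
        "stars_all_unstable": sel.all_unstable if sel else False,
        "stars_skipped_small_n": sel is None,
        "stars_seed": seed,
        "n_samples": int(X.shape[0]),
    }
    return to_partial_correlation(theta, provenance=prov), sel


def _prepare(disease: ProfileMatrix, control: ProfileMatrix,
             config: NetworkConfig):
    kept = filter_by_presence(disease, control, config.min_frac)
    if not kept:
        raise ValueError("presence filter removed every metabolite")
    d = impute_missing(disease.select_metabolites(kept),
                       control.select_metabolites(kept))
    c0 = control.select_metabolites(kept)
    c = impute_missing(c0, c0)
    return kept, d, c


def learn_disease_network(disease_profiles: ProfileMatrix,
                          control_profiles: ProfileMatrix,
                          config: NetworkConfig | None = None,
                          disease_label: str = "disease",
                          control_network: CoPerturbationNetwork | None = None,
                          ) -> CoPerturbationNetwork:
    """Full disease-network pipeline: filter, impute, learn, prune.

    ``control_network`` lets several disease models share one control-only
    network learned from a common reference cohort (it must cover the same
    metabolite namespace); otherwise the control network is learned here.
    """
    config = config or NetworkConfig()
    for name, m, lo in (("disease", disease_profiles, 3),
                        ("control", control_profiles, 3)):
        if m.n_samples < lo:
            raise ValueError(f"{name} cohort has {m.n_samples} samples; "
                             f"need at least {lo}")
    if disease_profiles.n_samples < 5:
        warnings.warn("fewer than 5 disease profiles; network may be unstable")
    if control_profiles.n_samples < 25:
        warnings.warn("fewer than 25 control profiles; network may be unstable")

    kept, d, c = _prepare(disease_profiles, control_profiles, config)
    rng = np.random.default_rng(config.seed)
    n_surr = config.n_surrogates
    if n_surr:
        d = d.hstack(_surrogate_columns(d, n_surr, config.surrogate_noise_sd,
                                        rng))
    pooled = np.vstack([d.z.T, c.z.T])
    pooled_net, pooled_sel = learn_condition_network(
        pooled, kept, f"{disease_label}+control", config, config.seed)
    if control_network is None:
        control_network, control_sel = learn_condition_network(
            c.z.T, kept, "control", config, config.seed + 1)
    result = differential_prune(pooled_net, control_network)
    result.provenance.update({
        "condition_label": disease_label,
        "lambda_selected": pooled_net.provenance["lambda_selected"],
        "lambda_control": control_network.provenance.get("lambda_selected"),
        "n_samples_disease": disease_profiles.n_samples,
        "n_samples_control": control_profiles.n_samples,
        "n_surrogates": n_surr,
        "seed": config.seed,
    })
    return result


def learn_treatment_network(treated: ProfileMatrix,
                            contrast: ProfileMatrix,
                            untreated_same_disease: ProfileMatrix,
                            config: NetworkConfig | None = None,
                            treatment_label: str = "treatment",
                            ) -> CoPerturbationNetwork:
    """Treatment-specific network: treated-vs-contrast minus untreated network.

    The pooled treated + contrast network captures treatment and disease
    signal; the network from untreated patients with the same disease
    captures disease signal alone; pruning shared edges leaves the
    treatment-specific structure.
    """
    config = config or NetworkConfig()
    for name, m in (("treated", treated), ("contrast", contrast),
                    ("untreated", untreated_same_disease)):
        if m.n_samples < 3:
            raise ValueError(f"{name} cohort has {m.n_samples} samples; "
                             "need at least 3")
    kept, t, c = _prepare(treated, contrast, config)
    u = impute_missing(untreated_same_disease.select_metabolites(kept),
                       contrast.select_metabolites(kept))
    pooled = np.vstack([t.z.T, c.z.T])
    net1, _ = learn_condition_network(pooled, kept,
                                      f"{treatment_label}+contrast",
                                      config, config.seed)
    net2, _ = learn_condition_network(u.z.T, kept, "untreated",
                                      config, config.seed + 1)
    result = differential_prune(net1, net2)
    result.provenance.update({
        "condition_label": treatment_label,
        "n_samples_treated": treated.n_samples,
        "n_samples_contrast": contrast.n_samples,
        "n_samples_untreated": untreated_same_disease.n_samples,
        "seed": config.seed,
    })
    return result


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_network(network: CoPerturbationNetwork, edge_path,
                  sidecar_path=None) -> None:
    """TSV edge list plus optional JSON sidecar with node list and provenance."""
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for (a, b), w in sorted(network.edges().items()):
            fh.write(f"{a}\t{b}\t{w!r}\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump({"nodes": list(network.nodes()),
                       "provenance": network.provenance}, fh, indent=1)


def read_network(edge_path, sidecar_path=None) -> CoPerturbationNetwork:
    """Load a network; without a sidecar the edge list implies the node set."""
    edges: dict[tuple[str, str], float] = {}
    with open(edge_path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "node_a\tnode_b\tweight":
            raise ValueError(f"unrecognized edge-list header in {edge_path}")
        for line in fh:
            if not line.strip():
                continue
            a, b, w = line.rstrip("\n").split("\t")
            edges[_canon(a, b)] = float(w)
    nodes = {v for pair in edges for v in pair}
    provenance: dict = {}
    if sidecar_path is not None:
        with open(sidecar_path, encoding="utf-8") as fh:
            sidecar = json.load(fh)
        nodes |= set(sidecar.get("nodes", ()))
        provenance = sidecar.get("provenance", {})
    return CoPerturbationNetwork(nodes, edges, provenance)
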