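"""Synthetic metabolomics cohorts with planted co-perturbation structure.

Reference samples are independent standard normals per metabolite (z-scores
against their own population).  Disease samples add, on a chosen module of
metabolites, a mean shift of ``effect_size`` reference SD plus a shared
per-sample latent factor: the same hidden severity that makes one patient's
whole module swing together.  That latent factor is what induces
co-perturbation edges for the network learner to recover — independent
shifts would move the means but leave nothing to correlate.

Optional layers mirror the messiness of real cohorts: uniform missingness
(peaks below the detection limit), binary presence-only analytes with a
disease-conditional detection probability, and a treatment overlay module
applied to a subset of disease samples.

All randomness flows from the single ``CohortSpec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .profile_io import ProfileMatrix, SampleMetadata

__all__ = [
    "TreatmentOverlay",
    "BinaryAnalyteSpec",
    "CohortSpec",
    "make_cohort",
    "make_multidisease_benchmark",
    "make_surrogates",
]


@dataclass(frozen=True)
class TreatmentOverlay:
    """A treatment-driven module overlaid on a fraction of disease samples."""

    nodes: tuple[str, ...]
    effect: float = 2.0
    fraction_treated: float = 0.5
    correlation: float = 0.6
    flag: str = "treated"


@dataclass(frozen=True)
class BinaryAnalyteSpec:
    """Presence-only analyte with disease-conditional detection probability."""

    metabolite_id: str
    p_present_disease: float = 0.9
    p_present_reference: float = 0.02


@dataclass(frozen=True)
class CohortSpec:
    """Shape and effect sizes of one synthetic disease cohort.

    Defaults reflect the conditions the package is meant to operate under:
    a disease cohort of 20 and a reference cohort of 40 samples over 30
    metabolites, a 6-node disease module shifted by 3 reference SD with a
    latent within-module correlation of 0.6, and 10% missingness.
    """

    n_metabolites: int = 30
    n_disease: int = 20
    n_reference: int = 40
    module_nodes: tuple[str, ...] = ()
    effect_size: float = 3.0
    module_correlation: float = 0.6
    missing_rate: float = 0.1
    treatment_overlay: TreatmentOverlay | None = None
    binary_analytes: tuple[BinaryAnalyteSpec, ...] = ()
    random_sign_per_sample: bool = False
    disease_label: str = "disease_A"
    seed: int = 0

    def metabolite_ids(self) -> list[str]:
        width = max(3, len(str(self.n_metabolites - 1)))
        return [f"met{j:0{width}d}" for j in range(self.n_metabolites)]

    def resolved_module(self) -> tuple[str, ...]:
        if self.module_nodes:
            return tuple(self.module_nodes)
        return tuple(self.metabolite_ids()[:6])

    def validate(self) -> None:
        if min(self.n_metabolites, self.n_disease, self.n_reference) <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 <= self.module_correlation < 1.0:
            raise ValueError("module_correlation must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        namespace = set(self.metabolite_ids())
        unknown = set(self.resolved_module()) - namespace
        if unknown:
            raise ValueError(f"module nodes outside namespace: {sorted(unknown)}")
        if self.treatment_overlay is not None:
            bad = set(self.treatment_overlay.nodes) - namespace
            if bad:
                raise ValueError(f"overlay nodes outside namespace: {sorted(bad)}")
            if not 0.0 <= self.treatment_overlay.fraction_treated <= 1.0:
                raise ValueError("fraction_treated must be in [0, 1]")
        for ba in self.binary_analytes:
            for p in (ba.p_present_disease, ba.p_present_reference):
                if not 0.0 <= p <= 1.0:
                    raise ValueError("binary presence probabilities must be "
                                     "in [0, 1]")


def _module_block(rng: np.random.Generator, n_samples: int, n_nodes: int,
                  effect: float, rho: float, random_sign: bool) -> np.ndarray:
    """Latent-factor perturbation block: shift + correlated noise, unit variance."""
    f = rng.normal(size=n_samples)                       # shared severity
    eps = rng.normal(size=(n_samples, n_nodes))
    block = math.sqrt(rho) * f[:, None] + math.sqrt(1.0 - rho) * eps
    sign = (rng.choice((-1.0, 1.0), size=n_samples) if random_sign
            else np.ones(n_samples))
    return block + effect * sign[:, None]


def make_cohort(spec: CohortSpec) -> tuple[ProfileMatrix, list[SampleMetadata]]:
    """Draw one disease + reference cohort from a cohort spec.

    Missingness is uniform at ``spec.missing_rate`` except that no module
    node may lose more than half of its disease observations — a module that
    vanished from the data would make recovery ill-posed rather than hard.
    Byte-identical output for identical specs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mets = spec.metabolite_ids()
    module = spec.resolved_module()
    met_index = {m: i for i, m in enumerate(mets)}
    n_d, n_r = spec.n_disease, spec.n_reference

    z_ref = rng.normal(size=(len(mets), n_r))
    z_dis = rng.normal(size=(len(mets), n_d))
    rows = [met_index[m] for m in module]
    z_dis[rows, :] = _module_block(
        rng, n_d, len(module), spec.effect_size, spec.module_correlation,
        spec.random_sign_per_sample).T

    treated = np.zeros(n_d, dtype=bool)
    ov = spec.treatment_overlay
    if ov is not None and ov.nodes:
        n_treated = int(round(ov.fraction_treated * n_d))
        treated[rng.permutation(n_d)[:n_treated]] = True
        if n_treated:
            block = _module_block(rng, n_treated, len(ov.nodes), ov.effect,
                                  ov.correlation, False)
            orow = [met_index[m] for m in ov.nodes]
            z_dis[np.ix_(orow, np.flatnonzero(treated))] = block.T

    z = np.hstack([z_dis, z_ref])
    miss = rng.random(z.shape) < spec.missing_rate
    # protect disease observations of module nodes from excessive dropout
    for m in module:
        i = met_index[m]
        drop = np.flatnonzero(miss[i, :n_d])
        allowed = n_d // 2
        if drop.size > allowed:
            miss[i, drop[allowed:]] = False

    binary_names = []
    for ba in spec.binary_analytes:
        pres_d = rng.random(n_d) < ba.p_present_disease
        pres_r = rng.random(n_r) < ba.p_present_reference
        row = np.concatenate([pres_d, pres_r]).astype(float)
        z = np.vstack([z, row[None, :]])
        miss = np.vstack([miss, np.zeros((1, z.shape[1]), dtype=bool)])
        binary_names.append(ba.metabolite_id)

    sample_ids = ([f"{spec.disease_label}_s{k:03d}" for k in range(n_d)]
                  + [f"ref_s{k:03d}" for k in range(n_r)])
    matrix = ProfileMatrix(
        metabolite_ids=mets + binary_names,
        sample_ids=sample_ids,
        z=z,
        missing_mask=miss,
        binary_analytes=set(binary_names),
    )
    metadata = []
    for k in range(n_d):
        flags = frozenset({ov.flag}) if (ov is not None and treated[k]) else frozenset()
        metadata.append(SampleMetadata(sample_id=sample_ids[k], role="disease",
                                       diagnosis_label=spec.disease_label,
                                       treatment_flags=flags))
    for k in range(n_r):
        metadata.append(SampleMetadata(sample_id=sample_ids[n_d + k],
                                       role="reference"))
    return matrix, metadata


def make_multidisease_benchmark(n_diseases: int, overlap_fraction: float,
                                template: CohortSpec,
                                module_size: int = 6):
    """Several disease cohorts with controlled module overlap + shared references.

    Module k shares ``round(overlap_fraction * module_size)`` nodes with
    module k+1 (adjacent pairs), chained across the metabolite namespace.
    Returns ``(cohorts, reference, truth)`` where *cohorts* maps disease
    label to its ``(ProfileMatrix, metadata)`` restricted to disease samples,
    *reference* is the shared reference cohort, and *truth* maps sample id
    to disease label.
    """
    if n_diseases < 2:
        raise ValueError("need at least 2 diseases")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    shared = int(round(overlap_fraction * module_size))
    step = module_size - shared
    needed = module_size + step * (n_diseases - 1)
    if needed > template.n_metabolites:
        raise ValueError(
            f"namespace of {template.n_metabolites} metabolites cannot hold "
            f"{n_diseases} modules of {module_size} at overlap {overlap_fraction}"
        )
    mets = template.metabolite_ids()
    modules = [tuple(mets[k * step:k * step + module_size])
               for k in range(n_diseases)]

    # one shared reference cohort, drawn once
    ref_spec = replace(template, module_nodes=modules[0], effect_size=0.0,
                       n_disease=1, disease_label="null",
                       seed=template.seed * 1000 + 999)
    ref_matrix, _ = make_cohort(ref_spec)
    reference = ref_matrix.select_samples(
        [s for s in ref_matrix.sample_ids if s.startswith("ref_")])

    cohorts = {}
    truth: dict[str, str] = {}
    for k, module in enumerate(modules):
        label = f"disease_{chr(ord('A') + k)}"
        spec_k = replace(template, module_nodes=module, disease_label=label,
                         seed=template.seed * 1000 + k)
        matrix, metadata = make_cohort(spec_k)
        keep = [s for s in matrix.sample_ids if s.startswith(label)]
        cohorts[label] = (matrix.select_samples(keep),
                          [m for m in metadata if m.sample_id in set(keep)])
        for s in keep:
            truth[s] = label
    return cohorts, reference, truth


def make_surrogates(profiles: ProfileMatrix, n: int, noise_sd: float = 0.1,
                    seed: int = 0) -> tuple[ProfileMatrix, list[SampleMetadata]]:
    """Bootstrap-resampled columns with additive Gaussian noise.

    Surrogates pad small disease cohorts before network learning; they are
    tagged with role "surrogate" so downstream accounting can separate them
    from real samples.
    """
    if profiles.n_samples < 1:
        raise ValueError("need at least one source profile")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    src = rng.integers(0, profiles.n_samples, size=n)
    z = profiles.z[:, src].copy()
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=z.shape)
        for i, met in enumerate(profiles.metabolite_ids):
            if met in profiles.binary_analytes:
                noise[i] = 0.0  # presence flags stay 0/1
        z = z + noise
    miss = profiles.missing_mask[:, src].copy()
    z[miss] = np.nan
    sample_ids = [f"surrogate_s{k:03d}" for k in range(n)]
    matrix = ProfileMatrix(
        metabolite_ids=list(profiles.metabolite_ids),
        sample_ids=sample_ids,
        z=z,
        missing_mask=miss,
        binary_analytes=set(profiles.binary_analytes) or set(),
    )
    metadata = [SampleMetadata(sample_id=s, role="surrogate")
                for s in sample_ids]
    return matrix, metadata
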