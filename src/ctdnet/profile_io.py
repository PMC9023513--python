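"""Read, write and preprocess z-scored untargeted metabolomics profiles.

Profiles are matrices of per-analyte z-scores (abundance expressed in
reference-population standard deviations), metabolites in rows and samples in
columns.  Blank or ``NA`` cells are missing: untargeted platforms only report
an analyte when its peak is detected.  A small number of analytes (e.g.
argininosuccinate) are essentially absent from healthy reference plasma and
cannot be z-scored at all; those are carried as binary presence flags instead.

This module implements the preprocessing used before network learning —
presence filtering, minimum-z imputation — and the extraction of a sample's
perturbation set (the strongly perturbed metabolites handed to the network
scorer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "SampleMetadata",
    "PerturbationSet",
    "read_profiles",
    "write_profiles",
    "read_metadata",
    "write_metadata",
    "filter_by_presence",
    "impute_missing",
    "extract_perturbations",
]

ROLES = ("disease", "reference", "surrogate")


@dataclass
class ProfileMatrix:
    """Metabolites x samples z-score matrix with an explicit missingness mask.

    Parameters
    ----------
    metabolite_ids
        Ordered, unique metabolite names (rows).
    sample_ids
        Ordered, unique sample names (columns).
    z
        Float matrix of z-scores; missing cells hold ``nan``.
    missing_mask
        Boolean matrix, ``True`` where the platform reported no value.
    binary_analytes
        Metabolites whose values are 0/1 presence flags rather than z-scores.
    """

    metabolite_ids: list[str]
    sample_ids: list[str]
    z: np.ndarray
    missing_mask: np.ndarray
    binary_analytes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n_m, n_s = len(self.metabolite_ids), len(self.sample_ids)
        if self.z.shape != (n_m, n_s):
            raise ValueError(
                f"z has shape {self.z.shape}, expected {(n_m, n_s)}"
            )
        if self.missing_mask.shape != self.z.shape:
            raise ValueError("missing_mask shape differs from z")
        for name, ids in (("metabolite", self.metabolite_ids),
                          ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id: {dup!r}")
        bad = self.binary_analytes - set(self.metabolite_ids)
        if bad:
            raise ValueError(f"binary analytes not in matrix: {sorted(bad)}")
        for met in sorted(self.binary_analytes):
            row = self.z[self.row_index(met)]
            vals = row[~np.isnan(row)]
            if vals.size and not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError(
                    f"binary analyte {met!r} has values outside {{0,1}}"
                )

    # -- indexing helpers -------------------------------------------------
    def row_index(self, metabolite_id: str) -> int:
        try:
            return self._row_lookup[metabolite_id]
        except AttributeError:
            self._row_lookup = {m: i for i, m in enumerate(self.metabolite_ids)}
            return self._row_lookup[metabolite_id]

    def col_index(self, sample_id: str) -> int:
        try:
            return self._col_lookup[sample_id]
        except AttributeError:
            self._col_lookup = {s: j for j, s in enumerate(self.sample_ids)}
            return self._col_lookup[sample_id]

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_column(self, sample_id: str) -> dict[str, float]:
        """Observed (non-missing) values of one sample, keyed by metabolite."""
        j = self.col_index(sample_id)
        col, miss = self.z[:, j], self.missing_mask[:, j]
        return {m: float(col[i]) for i, m in enumerate(self.metabolite_ids)
                if not miss[i]}

    def select_metabolites(self, keep: list[str]) -> "ProfileMatrix":
        idx = [self.row_index(m) for m in keep]
        return ProfileMatrix(
            metabolite_ids=list(keep),
            sample_ids=list(self.sample_ids),
            z=self.z[idx, :].copy(),
            missing_mask=self.missing_mask[idx, :].copy(),
            binary_analytes=self.binary_analytes & set(keep),
        )

    def select_samples(self, keep: list[str]) -> "ProfileMatrix":
        idx = [self.col_index(s) for s in keep]
        return ProfileMatrix(
            metabolite_ids=list(self.metabolite_ids),
            sample_ids=list(keep),
            z=self.z[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
            binary_analytes=set(self.binary_analytes),
        )

    def hstack(self, other: "ProfileMatrix") -> "ProfileMatrix":
        """Concatenate samples of two matrices sharing a metabolite order."""
        if other.metabolite_ids != self.metabolite_ids:
            raise ValueError("metabolite namespaces differ")
        return ProfileMatrix(
            metabolite_ids=list(self.metabolite_ids),
            sample_ids=list(self.sample_ids) + list(other.sample_ids),
            z=np.hstack([self.z, other.z]),
            missing_mask=np.hstack([self.missing_mask, other.missing_mask]),
            binary_analytes=self.binary_analytes | other.binary_analytes,
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Cohort bookkeeping for one profiled sample."""

    sample_id: str
    role: str
    diagnosis_label: str | None = None
    treatment_flags: frozenset[str] = frozenset()
    age_group: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role == "disease" and not self.diagnosis_label:
            raise ValueError(
                f"sample {self.sample_id!r}: disease role requires a diagnosis label"
            )
        object.__setattr__(self, "treatment_flags",
                           frozenset(self.treatment_flags))


@dataclass(frozen=True)
class PerturbationSet:
    """The perturbed metabolites of one sample, as fed to the CTD scorer."""

    sample_id: str
    nodes: frozenset[str]
    z_values: dict[str, float] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))

    def restrict_to(self, node_universe: set[str]) -> "PerturbationSet":
        kept = self.nodes & frozenset(node_universe)
        return PerturbationSet(
            sample_id=self.sample_id,
            nodes=kept,
            z_values={m: v for m, v in self.z_values.items() if m in kept},
        )


def _first_duplicate(ids) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_profiles(path, metadata_path=None, binary_analytes=None):
    """Read a profile matrix (and optionally its metadata table).

    The table has a header row of sample ids, metabolite ids in the first
    column and blank or ``NA`` cells for missing values.

    Returns ``ProfileMatrix`` alone, or ``(ProfileMatrix, list[SampleMetadata])``
    when *metadata_path* is given.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False, na_values=[""])
    if df.shape[0] == 0:
        raise ValueError(f"no metabolites in {path}")
    metabolite_ids = [str(m) for m in df.index]
    sample_ids = [str(s) for s in df.columns]
    dup = _first_duplicate(metabolite_ids)
    if dup is not None:
        raise ValueError(f"duplicate metabolite id in {path}: {dup!r}")
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise ValueError(f"duplicate sample id in {path}: {dup!r}")

    raw = df.to_numpy()
    z = np.full(raw.shape, np.nan)
    missing = np.zeros(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                missing[i, j] = True
                continue
            cell = str(cell).strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                missing[i, j] = True
                continue
            try:
                z[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at metabolite "
                    f"{metabolite_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
    matrix = ProfileMatrix(
        metabolite_ids=metabolite_ids,
        sample_ids=sample_ids,
        z=z,
        missing_mask=missing,
        binary_analytes=set(binary_analytes or ()),
    )
    if metadata_path is None:
        return matrix
    return matrix, read_metadata(metadata_path)


def write_profiles(matrix: ProfileMatrix, path) -> None:
    """Write a profile matrix; finite values round-trip bit-identically."""
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metabolite" + sep + sep.join(matrix.sample_ids) + "\n")
        for i, met in enumerate(matrix.metabolite_ids):
            cells = []
            for j in range(matrix.n_samples):
                if matrix.missing_mask[i, j]:
                    cells.append("")
                else:
                    cells.append(repr(float(matrix.z[i, j])))
            fh.write(met + sep + sep.join(cells) + "\n")


def read_metadata(path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                     keep_default_na=False, na_values=[""])
    required = {"sample_id", "role"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        flags = row.get("treatment_flags")
        flags = frozenset(
            f for f in str(flags).split(";") if f
        ) if isinstance(flags, str) else frozenset()
        diag = row.get("diagnosis_label")
        diag = diag if isinstance(diag, str) and diag else None
        age = row.get("age_group")
        age = age if isinstance(age, str) and age else None
        out.append(SampleMetadata(sample_id=str(row["sample_id"]),
                                  role=str(row["role"]),
                                  diagnosis_label=diag,
                                  treatment_flags=flags,
                                  age_group=age))
    return out


def write_metadata(metadata: list[SampleMetadata], path) -> None:
    sep = _sep_for(path)
    cols = ["sample_id", "role", "diagnosis_label", "treatment_flags",
            "age_group"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(cols) + "\n")
        for m in metadata:
            fh.write(sep.join([
                m.sample_id,
                m.role,
                m.diagnosis_label or "",
                ";".join(sorted(m.treatment_flags)),
                m.age_group or "",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_by_presence(disease: ProfileMatrix, reference: ProfileMatrix,
                       min_frac: float = 0.5) -> list[str]:
    """Metabolites observed in strictly more than *min_frac* of both cohorts.

    Only consistently detected analytes carry usable covariance information;
    the rest would be dominated by imputed values.  Binary analytes are
    excluded (they cannot enter a Gaussian model).
    """
    if disease.n_samples == 0 or reference.n_samples == 0:
        raise ValueError("empty cohort")
    shared = [m for m in disease.metabolite_ids
              if m in set(reference.metabolite_ids)]
    kept = []
    for m in shared:
        if m in disease.binary_analytes or m in reference.binary_analytes:
            continue
        obs_d = (~disease.missing_mask[disease.row_index(m)]).mean()
        obs_r = (~reference.missing_mask[reference.row_index(m)]).mean()
        if obs_d > min_frac and obs_r > min_frac:
            kept.append(m)
    return kept


def impute_missing(m: ProfileMatrix, reference: ProfileMatrix) -> ProfileMatrix:
    """Fill missing cells with the analyte's minimum observed reference z.

    A missing peak in untargeted metabolomics usually means the analyte sat
    below the detection limit, so the most conservative quantitative stand-in
    is the lowest z-score ever observed for it in a large reference
    population.  Binary analytes are imputed to 0 (absent).
    """
    if not m.missing_mask.any():
        return m
    z = m.z.copy()
    ref_rows = {met: i for i, met in enumerate(reference.metabolite_ids)}
    no_reference = []
    minima: dict[str, float] = {}
    for i, met in enumerate(m.metabolite_ids):
        if not m.missing_mask[i].any():
            continue
        if met in m.binary_analytes:
            minima[met] = 0.0
            continue
        ri = ref_rows.get(met)
        if ri is None:
            no_reference.append(met)
            continue
        row = reference.z[ri]
        obs = row[~reference.missing_mask[ri]]
        if obs.size == 0:
            no_reference.append(met)
            continue
        minima[met] = float(obs.min())
    if no_reference:
        raise ValueError(
            "analytes with no observed reference values: "
            + ", ".join(sorted(no_reference))
        )
    for i, met in enumerate(m.metabolite_ids):
        miss = m.missing_mask[i]
        if miss.any():
            z[i, miss] = minima[met]
    return replace(m, z=z, missing_mask=np.zeros_like(m.missing_mask))


def extract_perturbations(matrix: ProfileMatrix, sample_id: str,
                          node_universe: set[str],
                          z_threshold: float = 2.0,
                          max_set_size: int = 30) -> PerturbationSet:
    """Collect a sample's strongly perturbed metabolites within a network.

    A metabolite qualifies when |z| >= *z_threshold* (2 reference SD, the
    conventional clinical abnormality bound) or when it is a binary analyte
    observed present.  If more than *max_set_size* qualify, the largest |z|
    win (binary presences always kept); ties break by metabolite id so the
    result is deterministic.
    """
    if not node_universe:
        raise ValueError("empty node universe")
    observed = matrix.sample_column(sample_id)
    chosen: list[tuple[float, str, float]] = []  # (-priority, id, z)
    for met, val in observed.items():
        if met not in node_universe:
            continue
        if met in matrix.binary_analytes:
            if val == 1.0:
                chosen.append((-math.inf, met, val))
        elif abs(val) >= z_threshold:
            chosen.append((-abs(val), met, val))
    chosen.sort(key=lambda t: (t[0], t[1]))
    chosen = chosen[:max_set_size]
    return PerturbationSet(
        sample_id=sample_id,
        nodes=frozenset(met for _, met, _ in chosen),
        z_values={met: val for _, met, val in chosen},
    )
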