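"""Descriptor vectors and z-score normalization.

Each system is described by a fixed-length vector of 29 descriptors computed
from the record alone (no 3-D geometry).  The default schema devotes its
first 16 slots to element counts in atomic-number order — for SiF4 that
places the fluorine count (4.0) in slot 8 and the silicon count (1.0) in
slot 12 — followed by 13 scalar descriptors derived from the charge,
multiplicity, size and per-atom energy components.  The schema is pluggable:
any ordered list of named, record-computable descriptors of length 29 is a
valid schema.

Normalization is the usual z-score with statistics frozen on the training
set: ``normalized = (features - mean) / std`` with the population (1/n)
standard deviation; zero-variance slots have their std clamped to 1 so that
constant features normalize to zero instead of blowing up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .data_model import SystemRecord

__all__ = [
    "N_FEATURES",
    "ELEMENT_SLOTS",
    "FeatureSchema",
    "Normalizer",
    "default_schema",
    "build_features",
    "fit_normalizer",
    "apply_normalizer",
]

#: fixed descriptor-vector length
N_FEATURES = 29

#: elements with a dedicated count slot, in atomic-number order
ELEMENT_SLOTS = ("H", "Li", "Be", "B", "C", "N", "O", "F",
                 "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Br")

_ATOMIC_NUMBER = {"H": 1, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
                  "F": 9, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
                  "S": 16, "Cl": 17, "Br": 35}

_VAR_CLAMP = 1e-12


@dataclass(frozen=True)
class FeatureDef:
    name: str
    fn: Callable[["SystemRecord"], float]
    doc: str = ""


@dataclass(frozen=True)
class FeatureSchema:
    """An ordered, named list of 29 record-computable descriptors."""

    schema_id: str
    features: Sequence[FeatureDef]

    def __post_init__(self) -> None:
        if len(self.features) != N_FEATURES:
            raise ValueError(f"schema must define {N_FEATURES} features, got {len(self.features)}")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]


def _total_electrons(rec: "SystemRecord") -> int:
    z = sum(_ATOMIC_NUMBER.get(el, 0) * n for el, n in rec.composition.items())
    return z - rec.charge


def _n_heavy(rec: "SystemRecord") -> int:
    return sum(n for el, n in rec.composition.items() if el != "H")


def default_schema() -> FeatureSchema:
    """The packaged descriptor schema (id ``count-energy-v1``)."""
    from .energy_model import delta_terms  # deferred: avoid import cycle

    feats: list[FeatureDef] = [
        FeatureDef(f"n_{el}", (lambda el: lambda r: float(r.composition.get(el, 0)))(el),
                   f"count of {el} atoms")
        for el in ELEMENT_SLOTS
    ]

    def per_atom(fn):
        return lambda r: fn(r) / r.n_atoms

    def ratio(r):
        dc, db = delta_terms(r)
        return db / dc if abs(dc) > 1e-300 else 0.0

    feats += [
        FeatureDef("charge", lambda r: float(r.charge), "net charge"),
        FeatureDef("multiplicity", lambda r: float(r.multiplicity), "spin multiplicity"),
        FeatureDef("n_atoms", lambda r: float(r.n_atoms), "total atom count"),
        FeatureDef("n_heavy", lambda r: float(_n_heavy(r)), "non-hydrogen atom count"),
        FeatureDef("n_electrons", lambda r: float(_total_electrons(r)), "total electron count"),
        FeatureDef("e_ref_per_atom", per_atom(lambda r: r.e_ref),
                   "reference energy per atom (hartree)"),
        FeatureDef("de_corr_per_atom", per_atom(lambda r: delta_terms(r)[0]),
                   "correlation increment per atom (hartree)"),
        FeatureDef("de_basis_per_atom", per_atom(lambda r: delta_terms(r)[1]),
                   "basis-set increment per atom (hartree)"),
        FeatureDef("zpe_per_atom", per_atom(lambda r: r.zpe),
                   "zero-point energy per atom (hartree)"),
        FeatureDef("h_thermal", lambda r: r.h_thermal,
                   "H(298K)-H(0K) increment (hartree)"),
        FeatureDef("basis_corr_ratio", ratio,
                   "basis increment / correlation increment"),
        FeatureDef("mean_atomic_number", lambda r: (
            sum(_ATOMIC_NUMBER.get(el, 0) * n for el, n in r.composition.items()) / r.n_atoms),
            "composition-weighted mean Z"),
        FeatureDef("de_corr_per_electron", lambda r: (
            delta_terms(r)[0] / max(_total_electrons(r), 1)),
            "correlation increment per electron (hartree)"),
    ]
    return FeatureSchema(schema_id="count-energy-v1", features=feats)


def build_features(record: "SystemRecord", schema: FeatureSchema | None = None) -> np.ndarray:
    """Evaluate the schema on one record, returning a finite 29-vector."""
    from .data_model import SchemaError

    schema = schema or default_schema()
    out = np.empty(N_FEATURES, dtype=float)
    for i, f in enumerate(schema.features):
        try:
            out[i] = float(f.fn(record))
        except Exception as exc:
            raise SchemaError(f"feature {f.name!r} not computable for {record.id}: {exc}") from exc
    if not np.all(np.isfinite(out)):
        bad = [schema.features[i].name for i in np.flatnonzero(~np.isfinite(out))]
        raise SchemaError(f"non-finite feature(s) {bad} for {record.id}")
    return out


@dataclass(frozen=True)
class Normalizer:
    """Frozen per-feature z-score statistics (population std, clamped)."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float))
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must have the same length")
        if np.any(self.std <= 0):
            raise ValueError("std entries must be positive")


def fit_normalizer(train: Sequence[np.ndarray] | np.ndarray) -> Normalizer:
    """Per-feature mean and population standard deviation over training vectors.

    Slots whose std falls below 1e-12 are clamped to 1 (constant features).
    Requires at least two vectors.
    """
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_normalizer needs at least 2 feature vectors")
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population (1/n) convention
    std = np.where(std < _VAR_CLAMP, 1.0, std)
    return Normalizer(mean=mean, std=std)


def apply_normalizer(v: np.ndarray, norm: Normalizer) -> np.ndarray:
    """Elementwise ``(v - mean) / std``; accepts a vector or a (n, p) matrix."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != norm.mean.shape[0]:
        raise ValueError(f"feature length {v.shape[-1]} != normalizer length {norm.mean.shape[0]}")
    return (v - norm.mean) / norm.std
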