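"""Core domain types and file I/O.

A :class:`SystemRecord` holds the user-supplied energy components of one atom
or molecule: the HF/aug-cc-pVDZ reference energy, the QCISD(T) and MP2
single-point energies that define the correlation and basis-set increments,
the scaled harmonic zero-point energy, the atomic spin-orbit correction, the
thermal enthalpy increment H(298.15 K) - H(0 K), and the elemental
composition.  Electronic energies are in hartree; reference enthalpies of
formation in kcal/mol (see :mod:`adaptivecomposite.units`).

Records travel as CSV (one header row, ``.`` decimal, UTF-8) or JSON (one
top-level list of objects).  A trained model is serialized as a single JSON
document (:class:`ModelBundle`).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .classify import ANNModel
from .featurize import Normalizer

__all__ = [
    "ScaleParams",
    "SystemRecord",
    "AtomReferenceTable",
    "ModelBundle",
    "SchemaError",
    "RecordValidationError",
    "AssemblyError",
    "ReferenceTableError",
    "BundleError",
    "read_records",
    "write_records",
    "read_model_bundle",
    "write_model_bundle",
    "load_atom_references",
    "parse_composition",
    "format_composition",
]


class SchemaError(ValueError):
    """A table is missing a mandatory column or a feature source is unknown."""


class RecordValidationError(ValueError):
    """A record violates a type invariant (non-finite energy, bad composition...)."""


class AssemblyError(ValueError):
    """Atom records do not cover a molecule's composition."""


class ReferenceTableError(KeyError):
    """An element is missing from the atomic reference table."""


class BundleError(ValueError):
    """A model bundle is internally inconsistent or corrupt on disk."""


# Mandatory record columns, in canonical order.
RECORD_COLUMNS = (
    "id", "kind", "composition", "charge", "multiplicity",
    "e_ref", "e_qcisd_t", "e_mp2_dz", "e_mp2_tz",
    "zpe", "e_so", "h_thermal",
)

_ENERGY_FIELDS = ("e_ref", "e_qcisd_t", "e_mp2_dz", "e_mp2_tz", "zpe", "e_so", "h_thermal")


@dataclass(frozen=True)
class ScaleParams:
    """The four multiplicative scale factors.

    ``a``/``c`` scale the correlation and basis-set increments of molecules,
    ``b``/``d`` those of free atoms.  The unscaled composite corresponds to
    (1, 1, 1, 1).
    """

    a: float = 1.0
    b: float = 1.0
    c: float = 1.0
    d: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if not math.isfinite(getattr(self, name)):
                raise RecordValidationError(f"scale factor {name} is not finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "ScaleParams":
        a, b, c, d = (float(v) for v in arr)
        return cls(a, b, c, d)


def parse_composition(text: str) -> dict[str, int]:
    """Parse ``"Si:1,F:4"`` into ``{"Si": 1, "F": 4}``."""
    comp: dict[str, int] = {}
    for part in str(text).split(","):
        part = part.strip()
        if not part:
            continue
        try:
            el, n = part.split(":")
            count = int(n)
        except ValueError as exc:
            raise SchemaError(f"malformed composition entry {part!r}") from exc
        if count < 0:
            raise RecordValidationError(f"negative count for element {el!r}")
        comp[el.strip()] = comp.get(el.strip(), 0) + count
    if not comp:
        raise RecordValidationError(f"empty composition {text!r}")
    return comp


def format_composition(comp: Mapping[str, int]) -> str:
    return ",".join(f"{el}:{int(n)}" for el, n in comp.items())


@dataclass
class SystemRecord:
    """One atom or molecule with its energy components.

    Invariants: the composition is non-empty with non-negative counts; an
    atom has exactly one element with count 1, ``zpe == 0`` and conventionally
    ``h_thermal == 0``; a molecule has ``e_so == 0``; the four single-point
    energies are finite.
    """

    id: str
    kind: str  # "atom" | "molecule"
    composition: dict[str, int]
    e_ref: float
    e_qcisd_t: float
    e_mp2_dz: float
    e_mp2_tz: float
    zpe: float = 0.0
    e_so: float = 0.0
    h_thermal: float = 0.0
    charge: int = 0
    multiplicity: int = 1
    dhf_exp: float | None = None
    features: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_atoms(self) -> int:
        return int(sum(self.composition.values()))

    def validate(self) -> None:
        if self.kind not in ("atom", "molecule"):
            raise RecordValidationError(f"{self.id}: kind must be atom|molecule, got {self.kind!r}")
        if not self.composition or all(n == 0 for n in self.composition.values()):
            raise RecordValidationError(f"{self.id}: empty composition")
        if any(n < 0 for n in self.composition.values()):
            raise RecordValidationError(f"{self.id}: negative element count")
        for name in _ENERGY_FIELDS:
            v = getattr(self, name)
            if v is None or not math.isfinite(float(v)):
                raise RecordValidationError(f"{self.id}: non-finite {name}")
        if self.multiplicity < 1:
            raise RecordValidationError(f"{self.id}: multiplicity must be positive")
        if self.kind == "atom":
            nonzero = {el: n for el, n in self.composition.items() if n}
            if len(nonzero) != 1 or next(iter(nonzero.values())) != 1:
                raise RecordValidationError(f"{self.id}: atom must have one element, count 1")
            if self.zpe != 0.0:
                raise RecordValidationError(f"{self.id}: atom must have zpe = 0")
            if self.h_thermal != 0.0:
                raise RecordValidationError(f"{self.id}: atom carries h_thermal = 0 by convention")
        else:
            if self.e_so != 0.0:
                raise RecordValidationError(f"{self.id}: molecule must have e_so = 0")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if not np.all(np.isfinite(self.features)):
                raise RecordValidationError(f"{self.id}: non-finite feature entries")

    @property
    def element(self) -> str:
        """The element symbol of an atom record."""
        if self.kind != "atom":
            raise ValueError(f"{self.id} is not an atom record")
        return next(el for el, n in self.composition.items() if n)


@dataclass(frozen=True)
class AtomReferenceTable:
    """Experimental atomic reference data (kcal/mol).

    ``dhf_atom_0K`` is the enthalpy of formation of the gaseous atom at 0 K;
    ``h_thermal_element`` the H(298 K)-H(0 K) increment of the element's
    standard state, per atom.
    """

    dhf_atom_0K: Mapping[str, float]
    h_thermal_element: Mapping[str, float]

    def require(self, elements: Iterable[str]) -> None:
        missing = sorted(set(elements) - set(self.dhf_atom_0K))
        missing += sorted(set(elements) - set(self.h_thermal_element))
        if missing:
            raise ReferenceTableError(
                f"elements missing from atomic reference table: {sorted(set(missing))}"
            )


def load_atom_references(path: str | Path | None = None) -> AtomReferenceTable:
    """Load the atomic reference table (packaged defaults if ``path`` is None)."""
    if path is None:
        with resources.files("adaptivecomposite.data").joinpath("atom_references.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    dhf = {el: float(v["dhf_atom_0K"]) for el, v in raw.items()}
    hth = {el: float(v["h_thermal_element"]) for el, v in raw.items()}
    return AtomReferenceTable(dhf_atom_0K=dhf, h_thermal_element=hth)


# ---------------------------------------------------------------------------
# record I/O

def _record_from_row(row: Mapping, feature_cols: list[str]) -> SystemRecord:
    def opt_float(v):
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return float(v)

    kind = str(row["kind"]).strip()
    feats = None
    if feature_cols:
        vals = [opt_float(row.get(c)) for c in feature_cols]
        if any(v is not None for v in vals):
            if any(v is None for v in vals):
                raise SchemaError(f"record {row['id']}: partially filled feature columns")
            feats = np.array(vals, dtype=float)
    energies = {}
    for name in _ENERGY_FIELDS:
        v = opt_float(row.get(name))
        if v is None:
            raise SchemaError(f"record {row['id']}: missing value for column {name!r}")
        energies[name] = v
    known = set(RECORD_COLUMNS) | {"dhf_exp"} | set(feature_cols)
    extra = {k: row[k] for k in row.keys()
             if k not in known and not (isinstance(row[k], float) and math.isnan(row[k]))}
    return SystemRecord(
        id=str(row["id"]),
        kind=kind,
        composition=parse_composition(row["composition"]),
        charge=int(row.get("charge", 0) or 0),
        multiplicity=int(row.get("multiplicity", 1) or 1),
        dhf_exp=opt_float(row.get("dhf_exp")),
        features=feats,
        extra=extra,
        **energies,
    )


def read_records(path: str | Path, format: str | None = None) -> list[SystemRecord]:
    """Read a record table (CSV or JSON) into validated :class:`SystemRecord` s.

    ``format`` defaults to the file extension.  Missing mandatory columns
    raise :class:`SchemaError` naming the column; invalid values raise
    :class:`RecordValidationError` naming the record.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        rows = df.to_dict(orient="records")
        columns = list(df.columns)
    elif fmt == "json":
        with open(path) as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise SchemaError("JSON record file must contain a top-level list")
        columns = sorted({k for r in rows for k in r})
    else:
        raise ValueError(f"unknown record format {fmt!r}")

    missing = [c for c in RECORD_COLUMNS if c not in columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    feature_cols = sorted(
        (c for c in columns if c.startswith("f") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    return [_record_from_row(row, feature_cols) for row in rows]


def _record_to_row(rec: SystemRecord) -> dict:
    row = {
        "id": rec.id,
        "kind": rec.kind,
        "composition": format_composition(rec.composition),
        "charge": rec.charge,
        "multiplicity": rec.multiplicity,
        "e_ref": rec.e_ref,
        "e_qcisd_t": rec.e_qcisd_t,
        "e_mp2_dz": rec.e_mp2_dz,
        "e_mp2_tz": rec.e_mp2_tz,
        "zpe": rec.zpe,
        "e_so": rec.e_so,
        "h_thermal": rec.h_thermal,
        "dhf_exp": rec.dhf_exp,
    }
    if rec.features is not None:
        for i, v in enumerate(rec.features):
            row[f"f{i}"] = float(v)
    row.update(rec.extra)
    return row


def write_records(records: Iterable[SystemRecord], path: str | Path,
                  format: str | None = None) -> None:
    """Write records to CSV or JSON (inverse of :func:`read_records`)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    rows = [_record_to_row(r) for r in records]
    if fmt == "csv":
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"unknown record format {fmt!r}")


# ---------------------------------------------------------------------------
# model bundle

@dataclass
class ModelBundle:
    """Everything needed to predict on a new system.

    The number of groups ties the pieces together: ``len(group_params)`` must
    equal the classifier's output width.
    """

    group_params: list[ScaleParams]
    ann: ANNModel
    normalizer: Normalizer
    schema_id: str
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        k = len(self.group_params)
        if k == 0:
            raise BundleError("bundle has no group parameters")
        if self.ann.n_groups != k:
            raise BundleError(
                f"classifier output width {self.ann.n_groups} != number of "
                f"parameter groups {k}"
            )
        if self.ann.n_features != self.normalizer.mean.shape[0]:
            raise BundleError("classifier input width does not match normalizer length")

    def params_table(self) -> np.ndarray:
        """Group parameters as a (k, 4) array, rows in group order."""
        return np.vstack([p.as_array() for p in self.group_params])


def write_model_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Serialize a bundle to a single JSON document, losslessly."""
    bundle.validate()
    doc = {
        "schema_id": bundle.schema_id,
        "group_params": [list(p.as_array()) for p in bundle.group_params],
        "ann": bundle.ann.to_dict(),
        "normalizer": {
            "mean": bundle.normalizer.mean.tolist(),
            "std": bundle.normalizer.std.tolist(),
        },
        "metadata": bundle.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_model_bundle(path: str | Path) -> ModelBundle:
    """Load a bundle written by :func:`write_model_bundle`."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        bundle = ModelBundle(
            group_params=[ScaleParams.from_array(p) for p in doc["group_params"]],
            ann=ANNModel.from_dict(doc["ann"]),
            normalizer=Normalizer(
                mean=np.array(doc["normalizer"]["mean"], dtype=float),
                std=np.array(doc["normalizer"]["std"], dtype=float),
            ),
            schema_id=doc["schema_id"],
            metadata=doc.get("metadata", {}),
        )
    except (KeyError, TypeError) as exc:
        raise BundleError(f"corrupt model bundle {path}: {exc}") from exc
    try:
        bundle.validate()
    except BundleError as exc:
        raise BundleError(f"corrupt model bundle {path}: {exc}") from exc
    return bundle
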