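"""End-to-end prediction: classify, blend group parameters, assemble dHf.

Two evaluation modes exist.  ``average`` (the default) forms the softmax-
weighted convex combination of the per-group scale factors; ``max_prob``
commits to the single most probable group's factors, with argmax ties going
to the smallest group index.  The blended factors are used jointly: the
molecule takes (a, c) and its atoms take (b, d) from the same blended set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ann_forward
from .data_model import AtomReferenceTable, ModelBundle, ScaleParams, SystemRecord
from .energy_model import atomization_energy, heat_of_formation_298, scaled_energy
from .featurize import apply_normalizer, build_features, default_schema

__all__ = [
    "PredictionRow",
    "blend_params",
    "select_params",
    "predict_dhf",
    "predict_many",
    "mae_report",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class PredictionRow:
    """All intermediates of one prediction."""

    id: str
    probabilities: np.ndarray
    params: ScaleParams
    scaled_energy_hartree: float
    atomization_energy_kcal: float
    dhf_kcal: float
    deviation_kcal: float | None  # calc - exp when a reference is present


def blend_params(prob: Sequence[float], table: Sequence[ScaleParams]) -> ScaleParams:
    """Probability-weighted convex combination of the group parameter sets."""
    p = np.asarray(prob, dtype=float)
    if len(p) != len(table):
        raise ValueError(f"{len(p)} probabilities for {len(table)} parameter groups")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"probabilities sum to {p.sum():.12f}, not 1")
    stacked = np.vstack([t.as_array() for t in table])
    return ScaleParams.from_array(p @ stacked)


def select_params(prob: Sequence[float], table: Sequence[ScaleParams],
                  mode: str = "average") -> ScaleParams:
    """Blend (``average``) or commit to the most probable group (``max_prob``)."""
    if mode == "average":
        return blend_params(prob, table)
    if mode == "max_prob":
        p = np.asarray(prob, dtype=float)
        if len(p) != len(table):
            raise ValueError(f"{len(p)} probabilities for {len(table)} parameter groups")
        if abs(p.sum() - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities sum to {p.sum():.12f}, not 1")
        return table[int(np.argmax(p))]
    raise ValueError(f"unknown mode {mode!r}")


def predict_dhf(record: SystemRecord, atoms: Sequence[SystemRecord],
                bundle: ModelBundle, ref: AtomReferenceTable,
                mode: str = "average") -> PredictionRow:
    """Features -> normalize -> classify -> select parameters -> dHf(298 K)."""
    bundle.validate()
    feats = record.features if record.features is not None else build_features(
        record, default_schema())
    z = apply_normalizer(feats, bundle.normalizer)
    prob = ann_forward(bundle.ann, z)
    params = select_params(prob, bundle.group_params, mode=mode)
    dhf = heat_of_formation_298(record, atoms, params, ref)
    return PredictionRow(
        id=record.id,
        probabilities=prob,
        params=params,
        scaled_energy_hartree=scaled_energy(record, params).total_scaled,
        atomization_energy_kcal=atomization_energy(record, atoms, params),
        dhf_kcal=dhf,
        deviation_kcal=None if record.dhf_exp is None else dhf - record.dhf_exp,
    )


def predict_many(records: Sequence[SystemRecord], atoms: Sequence[SystemRecord],
                 bundle: ModelBundle, ref: AtomReferenceTable,
                 mode: str = "average") -> list[PredictionRow]:
    return [predict_dhf(r, atoms, bundle, ref, mode=mode) for r in records]


def mae_report(rows: Sequence[PredictionRow],
               subsets: Mapping[str, Sequence[str]]) -> dict[str, float]:
    """Mean absolute deviation (kcal/mol) per named id subset."""
    by_id = {row.id: row for row in rows}
    out = {}
    for name, ids in subsets.items():
        ids = list(ids)
        if not ids:
            raise ValueError(f"subset {name!r} is empty")
        devs = []
        for i in ids:
            row = by_id[i]
            if row.deviation_kcal is None:
                raise ValueError(f"{i}: no reference value, deviation undefined")
            devs.append(abs(row.deviation_kcal))
        out[name] = float(np.mean(devs))
    return out


def rows_to_frame(rows: Sequence[PredictionRow]) -> pd.DataFrame:
    """Tabular view of prediction rows (one probability column per group)."""
    k = len(rows[0].probabilities) if rows else 0
    data = []
    for row in rows:
        rec = {
            "id": row.id,
            "a": row.params.a, "b": row.params.b,
            "c": row.params.c, "d": row.params.d,
            "scaled_energy_hartree": row.scaled_energy_hartree,
            "atomization_energy_kcal": row.atomization_energy_kcal,
            "dhf_kcal": row.dhf_kcal,
            "deviation_kcal": row.deviation_kcal,
        }
        for g in range(k):
            rec[f"p_group{g}"] = row.probabilities[g]
        data.append(rec)
    return pd.DataFrame(data)
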