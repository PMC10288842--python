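"""Composite tumor-burden biomarker from MTV and chromogranin A.

MTV (imaging tumor burden) and chromogranin A (blood tumor burden) are
strongly correlated and individually violate proportional hazards, so
they are merged into one predictor: each marker is log-transformed
(both are right-skewed), z-standardized on the cohort, and the two
z-scores averaged.  The composite is dimensionless with cohort mean 0,
and invariant to the units of either raw marker (a positive rescaling
becomes an additive shift under log, which the z-step removes) and to
the logarithm base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MarkerVector", "CompositeScore", "log_transform", "z_standardize", "composite_score"]


class DegenerateSpreadError(ValueError):
    """z-standardization is undefined for a (near-)constant vector."""


@dataclass(frozen=True)
class MarkerVector:
    """Per-patient values of one marker (MTV ml, CgA ug/l, gamma-GT U/l...)."""

    patient_ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(self.patient_ids)
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1 or len(ids) != vals.size:
            raise ValueError("patient_ids and values must be 1D and equal length")
        object.__setattr__(self, "patient_ids", ids)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def from_items(cls, ids: Sequence, values: Sequence[float]) -> "MarkerVector":
        return cls(patient_ids=tuple(ids), values=np.asarray(values, dtype=np.float64))


@dataclass(frozen=True)
class CompositeScore:
    patient_ids: tuple
    scores: np.ndarray


def log_transform(m: MarkerVector) -> MarkerVector:
    """Elementwise natural log; every value must be strictly positive."""
    bad = np.flatnonzero(~(m.values > 0))
    if bad.size:
        raise ValueError(
            f"log-transform requires positive values; offending patients: "
            f"{[m.patient_ids[i] for i in bad[:5]]}"
        )
    return MarkerVector(patient_ids=m.patient_ids, values=np.log(m.values))


def z_standardize(m: MarkerVector) -> MarkerVector:
    """(x - mean) / sd with sample sd (n-1); output has mean 0, sd 1."""
    if len(m) < 2:
        raise ValueError("z-standardization needs at least 2 values")
    sd = float(np.std(m.values, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSpreadError("constant marker vector cannot be z-standardized")
    return MarkerVector(patient_ids=m.patient_ids, values=(m.values - m.values.mean()) / sd)


def composite_score(mtv: MarkerVector, cga: MarkerVector) -> CompositeScore:
    """Average of the z-scores of log MTV and log chromogranin A.

    The two vectors must carry identical, identically ordered patient
    ids.  Symmetric in its arguments; cohort mean is 0 by construction.
    """
    if mtv.patient_ids != cga.patient_ids:
        raise ValueError("MTV and CgA vectors are not aligned on patient ids")
    z_mtv = z_standardize(log_transform(mtv))
    z_cga = z_standardize(log_transform(cga))
    return CompositeScore(
        patient_ids=mtv.patient_ids,
        scores=0.5 * (z_mtv.values + z_cga.values),
    )
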