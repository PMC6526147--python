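"""Trueness and precision of measured isotopologue distributions.

Measured CIDs come from replicate chromatographic peak areas: per replicate
each channel area is divided by the replicate's total, giving fractions
that sum to 100%.  Validation compares the replicate-mean CID against the
predicted (binomial) or theoretical (isotope-pattern) distribution:

* trueness bias — measured fraction minus predicted fraction, per channel;
* precision — sample standard deviation across technical replicates.

A large positive M0 bias with the heavier channels biased downward is the
signature of contamination by the unlabeled compound (e.g. succinate picked
up from labware), and is flagged as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracer import CIDVector

__all__ = [
    "MeasurementSet",
    "ValidationReport",
    "cid_from_areas",
    "trueness_bias",
    "precision",
    "build_report",
]


@dataclass(frozen=True)
class MeasurementSet:
    """Replicate peak areas for one metabolite (replicates x channels)."""

    metabolite: str
    channels: tuple[str, ...]
    areas: np.ndarray
    polarity: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.areas, dtype=float))
        if a.shape[1] != len(self.channels):
            raise ValueError("area columns must match channel labels")
        if np.any(a < 0):
            raise ValueError("peak areas must be non-negative")
        if a.shape[0] < 1:
            raise ValueError("need at least one replicate")
        object.__setattr__(self, "areas", a)

    @property
    def n_replicates(self) -> int:
        return self.areas.shape[0]


def _nonzero_replicates(ms: MeasurementSet) -> np.ndarray:
    totals = ms.areas.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise ValueError(f"{ms.metabolite}: every replicate has zero total area")
    if not keep.all():
        warnings.warn(
            f"{ms.metabolite}: excluding {(~keep).sum()} all-zero replicate(s)",
            stacklevel=3,
        )
    return ms.areas[keep]


def cid_from_areas(ms: MeasurementSet) -> tuple[np.ndarray, CIDVector]:
    """Per-replicate CIDs (percent) and their mean.

    Replicates whose areas are all zero are excluded with a warning.
    """
    areas = _nonzero_replicates(ms)
    fractions = areas / areas.sum(axis=1, keepdims=True) * 100.0
    return fractions, CIDVector(fractions=fractions.mean(axis=0))


def trueness_bias(measured: CIDVector, theoretical: CIDVector) -> np.ndarray:
    """Per-channel measured minus theoretical fraction, in percentage points.

    Since both vectors sum to 100 the biases sum to zero.
    """
    if len(measured) != len(theoretical):
        raise ValueError("measured and theoretical CIDs differ in length")
    return measured.fractions - theoretical.fractions


def precision(ms: MeasurementSet) -> np.ndarray:
    """Sample standard deviation (n-1) of replicate fractions, per channel."""
    fractions, _ = cid_from_areas(ms)
    if fractions.shape[0] < 2:
        raise ValueError("precision requires at least two usable replicates")
    return fractions.std(axis=0, ddof=1)


@dataclass(frozen=True)
class ValidationReport:
    """Per-channel comparison of predicted and measured CIDs for one metabolite."""

    metabolite: str
    table: pd.DataFrame  # channel, cid_pred, pred_error, cid_meas, trueness_bias, precision
    contamination_suspect: bool = False
    interference_suspect: bool = False
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df.insert(0, "metabolite", self.metabolite)
        df["contamination_suspect"] = self.contamination_suspect
        df["interference_suspect"] = self.interference_suspect
        return df


def build_report(
    predicted: CIDVector,
    measurements: MeasurementSet,
    *,
    interference_flag: bool = False,
    contamination_sigma: float = 3.0,
    contamination_floor: float = 1.0,
) -> ValidationReport:
    """Assemble predicted vs measured CIDs with bias and precision.

    The contamination flag fires when the M0 bias exceeds both
    ``contamination_sigma`` times the predicted M0 error and the absolute
    floor (percentage points), while the heavier channels are on balance
    biased downward — the mixing signature of an unlabeled contaminant.
    """
    if len(predicted) != len(measurements.channels):
        raise ValueError("predicted CID length must match measurement channels")
    fractions, mean_cid = cid_from_areas(measurements)
    bias = trueness_bias(mean_cid, predicted)
    if fractions.shape[0] >= 2:
        prec = fractions.std(axis=0, ddof=1)
    else:
        prec = np.full(len(predicted), np.nan)
    pred_err = (
        predicted.uncertainty
        if predicted.uncertainty is not None
        else np.zeros(len(predicted))
    )
    threshold = max(contamination_floor, contamination_sigma * pred_err[0])
    contaminated = bool(bias[0] > threshold and bias[1:].sum() < 0)
    notes = []
    if contaminated:
        notes.append(
            f"M0 bias {bias[0]:+.2f} exceeds {threshold:.2f} with heavier "
            "channels deflated: unlabeled contaminant suspected"
        )
    table = pd.DataFrame(
        {
            "channel": list(measurements.channels),
            "cid_pred": predicted.fractions,
            "pred_error": pred_err,
            "cid_meas": mean_cid.fractions,
            "trueness_bias": bias,
            "precision": prec,
        }
    )
    return ValidationReport(
        metabolite=measurements.metabolite,
        table=table,
        contamination_suspect=contaminated,
        interference_suspect=interference_flag,
        notes=tuple(notes),
    )
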