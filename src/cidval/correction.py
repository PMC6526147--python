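"""Resolution-aware natural-abundance correction of isotopologue areas.

At high resolving power many heavy-isotope species of non-tracer elements
(2H, 15N, 18O, 34S, ...) are mass-resolved from the 13C channels and never
contaminate them, so a correction matrix built from nominal masses would
over-correct.  Here the matrix entry (j, k) is the probability that a
molecule carrying k tracer 13C atoms is *measured* in channel j, decided
with the same FWHM merge criterion the pattern engine uses: an isotopic
species contributes to the channel whose anchor mass it cannot be resolved
from; species resolved from every channel are lost from the measurement
(columns may sum to less than 1).

For a reference material whose carbon pattern is itself the quantity of
interest, correcting for natural 13C would destroy the signal; the
``carbon_correction`` flag therefore defaults to off, treating carbon as
100% 12C so only non-tracer elements are corrected.

Measured areas are unmixed by non-negative least squares rather than matrix
inversion, guaranteeing non-negative fractions on noisy data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .chem import Formula, IsotopeTable, default_table
from .pattern import InstrumentModel, fine_pattern_custom
from .tracer import CIDVector

__all__ = ["CorrectionMatrix", "build_correction_matrix", "correct_areas"]


@dataclass(frozen=True)
class CorrectionMatrix:
    """Forward mixing matrix from true tracer CIDs to measured channels."""

    matrix: np.ndarray
    formula: Formula
    instrument: InstrumentModel
    carbon_correction: bool
    tracer_purity: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correction matrix must be square")
        if np.any(m < -1e-12):
            raise ValueError("correction matrix entries must be non-negative")
        if np.any(m.sum(axis=0) > 1.0 + 1e-9):
            raise ValueError("a column of the correction matrix exceeds unit mass")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0] - 1


def _effective_isotopes(
    el_masses: np.ndarray,
    el_abunds: np.ndarray,
    step: float,
    fwhm_fn,
    base_mass: float,
):
    """Drop heavy isotopes that are resolved from every carbon channel.

    A heavy isotope with mass offset d (relative to the element's lightest
    isotope) feeds a tracer channel only if d is unresolved from some
    multiple of the 13C-12C spacing at the instrument's peak width.  A
    resolved isotope produces its own peak outside all channels; since the
    non-tracer composition is identical in every channel, that loss scales
    all channels equally and cancels on normalization, so the isotope is
    removed and the element's abundances renormalized.
    """
    keep_m, keep_a = [el_masses[0]], [el_abunds[0]]
    for m, a in zip(el_masses[1:], el_abunds[1:]):
        d = m - el_masses[0]
        j = round(d / step)
        gap = abs(d - j * step)
        if gap < fwhm_fn(base_mass + j * step):
            keep_m.append(m)
            keep_a.append(a)
    keep_a = np.array(keep_a)
    return np.array(keep_m), keep_a / keep_a.sum()


def build_correction_matrix(
    formula: Formula,
    instrument: InstrumentModel,
    carbon_correction: bool = False,
    *,
    tracer_purity: float = 1.0,
    table: IsotopeTable | None = None,
    prune_threshold: float = 1e-10,
) -> CorrectionMatrix:
    """Correction matrix for a carbon tracer in ``formula``.

    Column k is built by fixing k carbons as pure 13C (degraded by
    ``tracer_purity`` if below 1), giving the remaining carbons either
    natural abundance (``carbon_correction=True``) or pure 12C (default),
    convolving the full fine structure, and binning each species to the
    nearest channel anchor at the FWHM merge criterion.
    """
    table = table or default_table()
    n = formula.n_carbons
    if n < 1 and "C" not in formula.counts:
        raise ValueError("formula contains no carbon; no tracer channels")
    if not 0.0 < tracer_purity <= 1.0:
        raise ValueError("tracer purity must be in (0, 1]")
    c = table["C"]
    c_masses = np.array(c.masses)
    c_abunds = np.array(c.abundances)
    step = c_masses[1] - c_masses[0]
    light = sum(cnt * table[s].lightest_mass for s, cnt in formula.counts.items())
    anchors = light + step * np.arange(n + 1)

    # per-element isotope distributions with resolved isotopes removed
    eff: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sym, cnt in formula.counts.items():
        if sym == "C":
            continue
        iso = table[sym]
        eff[sym] = _effective_isotopes(
            np.array(iso.masses), np.array(iso.abundances), step, instrument.fwhm, light
        )

    if tracer_purity == 1.0:
        labeled = (c_masses[1:2], np.array([1.0]))
    else:
        labeled = (
            np.array([c_masses[0], c_masses[1]]),
            np.array([1.0 - tracer_purity, tracer_purity]),
        )
    unlabeled = (
        (c_masses, c_abunds) if carbon_correction else (c_masses[:1], np.array([1.0]))
    )

    matrix = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        comps = [
            (eff[sym][0], eff[sym][1], cnt)
            for sym, cnt in formula.counts.items()
            if sym != "C"
        ]
        comps.append((unlabeled[0], unlabeled[1], n - k))
        comps.append((labeled[0], labeled[1], k))
        fp = fine_pattern_custom(comps, prune_threshold)
        nearest = np.abs(fp.masses[:, None] - anchors[None, :]).argmin(axis=1)
        for m, a, j in zip(fp.masses, fp.abundances, nearest):
            if abs(m - anchors[j]) < instrument.fwhm((m + anchors[j]) / 2.0):
                matrix[j, k] += a
    return CorrectionMatrix(
        matrix=matrix,
        formula=formula,
        instrument=instrument,
        carbon_correction=carbon_correction,
        tracer_purity=tracer_purity,
    )


def correct_areas(areas: np.ndarray, cm: CorrectionMatrix) -> tuple[CIDVector, float]:
    """Unmix measured channel areas into a corrected CID.

    Solves ``cm.matrix @ x = areas`` for x >= 0 by non-negative least
    squares and returns the normalized CID (percent) together with the
    relative residual norm of the fit.  A large residual signals a
    degenerate fit or areas inconsistent with the formula's pattern.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.ndim != 1 or len(areas) != cm.matrix.shape[0]:
        raise ValueError("area vector length must match matrix dimension")
    if np.any(areas < 0):
        raise ValueError("areas must be non-negative")
    total = areas.sum()
    if total <= 0:
        raise ValueError("all-zero area vector cannot be corrected")
    x, rnorm = nnls(cm.matrix, areas / total)
    if x.sum() <= 0:
        raise ValueError("degenerate correction: NNLS returned the zero vector")
    rel_residual = float(rnorm)
    if rel_residual > 0.5:
        warnings.warn(
            f"correction fit residual {rel_residual:.3g} is large; "
            "areas may be inconsistent with the formula",
            stacklevel=2,
        )
    return CIDVector(fractions=x / x.sum() * 100.0), rel_residual
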