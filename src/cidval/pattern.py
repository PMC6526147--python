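"""Isotope fine-structure patterns and resolution-dependent centroiding.

A *fine* pattern lists every retained isotopic species of a molecule with its
exact mass and probability.  An orbitrap acquiring at finite resolving power
cannot separate species closer than roughly one peak width, so the fine
pattern is merged into *centroids*: left-to-right single-linkage clustering
on the mass axis, where two adjacent species merge when their mass gap is
below the FWHM at their abundance-weighted mean mass.  Centroids are then
grouped into tracer channels (M0..Mn for carbon, or the isotopes of a
marker element such as selenium) by nearest theoretical anchor mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chem import Formula, IsotopeTable, default_table

__all__ = [
    "IsotopePattern",
    "InstrumentModel",
    "IsotopologueGrouping",
    "fine_pattern",
    "fine_pattern_custom",
    "centroid_pattern",
    "group_by_tracer_channel",
]

# Species closer than this are the same mass for bookkeeping purposes
# (floating-point duplicates produced by convolution), far below any
# physically resolvable difference.
_MASS_MERGE_EPS = 1e-9


@dataclass(frozen=True)
class InstrumentModel:
    """Resolving power model of the mass analyzer.

    Orbitrap resolving power is quoted at a reference m/z (200 by
    convention) and falls off as 1/sqrt(m); a flat law is available for
    analyzers with mass-independent resolving power.  ``resolving_power``
    may be ``math.inf`` for the ideal-instrument limit.
    """

    resolving_power: float
    ref_mz: float = 200.0
    scaling: str = "inverse_sqrt"  # or "flat"

    def __post_init__(self) -> None:
        if not self.resolving_power > 0:
            raise ValueError("resolving power must be positive")
        if self.scaling not in ("inverse_sqrt", "flat"):
            raise ValueError(f"unknown scaling law {self.scaling!r}")

    def resolving_power_at(self, mz: float) -> float:
        if self.scaling == "flat" or math.isinf(self.resolving_power):
            return self.resolving_power
        return self.resolving_power * math.sqrt(self.ref_mz / mz)

    def fwhm(self, mz: float) -> float:
        """Peak full width at half maximum at ``mz`` (Da)."""
        return mz / self.resolving_power_at(mz)


@dataclass(frozen=True)
class IsotopePattern:
    """List of isotopic species: exact masses (Da) and abundances (fractions).

    ``kind`` is ``"fine"`` or ``"centroided"``; abundances sum to the
    retained probability mass (1 minus whatever pruning discarded).
    """

    masses: np.ndarray
    abundances: np.ndarray
    kind: str = "fine"
    instrument: InstrumentModel | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        if m.shape != a.shape or m.ndim != 1:
            raise ValueError("masses and abundances must be equal-length 1-D")
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "abundances", a)

    def __len__(self) -> int:
        return len(self.masses)

    @property
    def total_abundance(self) -> float:
        return float(self.abundances.sum())


@dataclass(frozen=True)
class IsotopologueGrouping:
    """Centroids assigned to tracer channels, renormalized to percent."""

    labels: tuple[str, ...]
    assignment: np.ndarray  # centroid index -> label index, -1 = outside all channels
    fractions_percent: np.ndarray  # per label, sums to 100

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.fractions_percent.tolist()))


class _Pruner:
    """Tracks a shared abundance budget across convolution steps so total
    discarded probability never exceeds the requested threshold."""

    def __init__(self, budget: float):
        self.remaining = budget

    def prune(self, masses: np.ndarray, abunds: np.ndarray):
        if self.remaining <= 0 or len(masses) == 0:
            return masses, abunds
        order = np.argsort(abunds)
        csum = np.cumsum(abunds[order])
        ndrop = int(np.searchsorted(csum, self.remaining, side="right"))
        if ndrop == 0:
            return masses, abunds
        self.remaining -= float(csum[ndrop - 1])
        keep = np.sort(order[ndrop:])
        return masses[keep], abunds[keep]


def _dedupe(masses: np.ndarray, abunds: np.ndarray):
    """Sort by mass and sum abundances of numerically identical masses."""
    order = np.argsort(masses)
    m, a = masses[order], abunds[order]
    if len(m) < 2:
        return m, a
    new_group = np.concatenate(([True], np.diff(m) > _MASS_MERGE_EPS))
    idx = np.cumsum(new_group) - 1
    out_a = np.zeros(idx[-1] + 1)
    np.add.at(out_a, idx, a)
    out_m = np.zeros_like(out_a)
    # abundance-weighted mean mass within each duplicate group
    np.add.at(out_m, idx, m * a)
    with np.errstate(invalid="ignore"):
        out_m = np.where(out_a > 0, out_m / out_a, m[new_group])
    return out_m, out_a


def _convolve(p, q, pruner: _Pruner):
    pm, pa = p
    qm, qa = q
    masses = (pm[:, None] + qm[None, :]).ravel()
    abunds = (pa[:, None] * qa[None, :]).ravel()
    masses, abunds = _dedupe(masses, abunds)
    return pruner.prune(masses, abunds)


def _element_power(masses, abunds, count: int, pruner: _Pruner):
    """Spectrum of ``count`` atoms of one element by binary exponentiation."""
    result = (np.array([0.0]), np.array([1.0]))
    base = (np.asarray(masses, float), np.asarray(abunds, float))
    k = count
    while k:
        if k & 1:
            result = _convolve(result, base, pruner)
        k >>= 1
        if k:
            base = _convolve(base, base, pruner)
    return result


def fine_pattern_custom(
    components: list[tuple[np.ndarray, np.ndarray, int]],
    prune_threshold: float = 1e-10,
) -> IsotopePattern:
    """Fine pattern from explicit per-component isotope distributions.

    ``components`` is a list of (isotope masses, isotope abundances, atom
    count).  This is the workhorse behind :func:`fine_pattern` and lets the
    correction machinery substitute modified distributions (e.g. carbon
    fixed to pure 12C, or k atoms fixed to pure 13C).
    """
    if not 0 <= prune_threshold < 1e-4:
        raise ValueError("prune_threshold must be in [0, 1e-4)")
    pruner = _Pruner(prune_threshold)
    total = (np.array([0.0]), np.array([1.0]))
    for masses, abunds, count in components:
        if count == 0:
            continue
        spec = _element_power(masses, abunds, count, pruner)
        total = _convolve(total, spec, pruner)
    m, a = total
    return IsotopePattern(masses=m, abundances=a, kind="fine")


def fine_pattern(
    formula: Formula,
    prune_threshold: float = 1e-10,
    *,
    table: IsotopeTable | None = None,
) -> IsotopePattern:
    """Full isotope fine structure of ``formula`` at natural abundance.

    Built by iterative convolution of per-element multinomial expansions;
    species with total probability below ``prune_threshold`` may be dropped,
    so the retained abundance is at least ``1 - prune_threshold``.
    """
    table = table or default_table()
    comps = []
    for el, n in sorted(formula.counts.items()):
        iso = table[el]
        comps.append((np.array(iso.masses), np.array(iso.abundances), n))
    return fine_pattern_custom(comps, prune_threshold)


def merged(gap: float, mean_mz: float, instrument: InstrumentModel) -> bool:
    """The single merge criterion: gap below the FWHM at the mean mass."""
    return gap < instrument.fwhm(mean_mz)


def centroid_pattern(fine: IsotopePattern, instrument: InstrumentModel) -> IsotopePattern:
    """Merge fine species the instrument cannot resolve into centroids.

    Left-to-right single-linkage on the sorted mass axis: the next species
    joins the current cluster when its gap to the cluster's last member is
    below the FWHM at the abundance-weighted mean of the two.  Merged
    centroids take the abundance-weighted mean mass and summed abundance.
    """
    if fine.kind != "fine":
        raise ValueError("centroid_pattern expects a fine pattern")
    if len(fine) == 0:
        raise ValueError("cannot centroid an empty pattern")
    order = np.argsort(fine.masses)
    m, a = fine.masses[order], fine.abundances[order]
    clusters = [[0]]
    for i in range(1, len(m)):
        j = clusters[-1][-1]
        gap = m[i] - m[j]
        wmean = (m[i] * a[i] + m[j] * a[j]) / (a[i] + a[j])
        if merged(gap, wmean, instrument):
            clusters[-1].append(i)
        else:
            clusters.append([i])
    cm = np.array([float(np.average(m[c], weights=a[c])) for c in clusters])
    ca = np.array([float(a[c].sum()) for c in clusters])
    return IsotopePattern(masses=cm, abundances=ca, kind="centroided", instrument=instrument)


def group_by_tracer_channel(
    centroided: IsotopePattern,
    formula: Formula,
    channel_element: str = "C",
    *,
    table: IsotopeTable | None = None,
) -> IsotopologueGrouping:
    """Assign centroids to tracer channels and renormalize to 100%.

    For a carbon tracer the channels are M0..Mn anchored at the
    monoisotopic mass plus k x (13C - 12C).  For a marker element such as
    selenium the channels are its isotopes, anchored at the all-light
    molecule shifted by each isotope's mass offset.  A centroid belongs to
    the nearest anchor only when the instrument cannot resolve it from that
    anchor (mass gap below the FWHM); resolved centroids form their own
    peaks outside every channel and are excluded — this is the "main
    isotopologues, sum set to 100%" reporting convention.  The retained
    group abundances are renormalized so their sum is exactly 100%.
    """
    table = table or default_table()
    el = table[channel_element]
    if el.n_isotopes < 2:
        raise ValueError(f"{channel_element} has fewer than 2 isotopes")
    light = sum(n * table[s].lightest_mass for s, n in formula.counts.items())
    if channel_element == "C":
        n = formula.n_carbons
        step = el.masses[1] - el.masses[0]
        anchors = np.array([light + k * step for k in range(n + 1)])
        labels = tuple(f"M{k}" for k in range(n + 1))
    else:
        if formula.counts.get(channel_element, 0) < 1:
            raise ValueError(f"{channel_element} absent from {formula}")
        offsets = np.array(el.masses) - el.lightest_mass
        anchors = light + offsets
        labels = tuple(f"{round(m)}{channel_element}" for m in el.masses)
    if len(centroided) == 0:
        raise ValueError("no centroids to assign")
    gaps = np.abs(centroided.masses[:, None] - anchors[None, :])
    assignment = gaps.argmin(axis=1)
    min_gap = gaps[np.arange(len(assignment)), assignment]
    if centroided.instrument is not None:
        widths = np.array([centroided.instrument.fwhm(m) for m in centroided.masses])
    else:  # no instrument context: exact anchor matches only
        widths = np.zeros(len(assignment))
    retained = min_gap <= np.maximum(widths, _MASS_MERGE_EPS)
    assignment = np.where(retained, assignment, -1)
    totals = np.zeros(len(anchors))
    np.add.at(totals, assignment[retained], centroided.abundances[retained])
    if totals.sum() <= 0:
        raise ValueError("no abundance assignable to any channel")
    fractions = totals / totals.sum() * 100.0
    return IsotopologueGrouping(labels=labels, assignment=assignment, fractions_percent=fractions)
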