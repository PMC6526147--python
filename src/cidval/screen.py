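"""Isobaric interference and blank-contamination screening of target lists.

Two targets interfere when they elute within a retention-time window of each
other in the same polarity and any of their tracer-channel m/z values agree
within a ppm tolerance — e.g. the M0 of a co-eluting compound sitting on a
target's M3 channel.  Both tolerances are inclusive; the defaults (5 ppm,
+/-0.5 min) are typical targeted-evaluation settings.

Blank screening quantifies exogenous (unlabeled) contamination as the ratio
of the peak area in a procedural blank to that in the sample, classified as
negligible (<0.1%), minor (0.1-5%) or major (>5%).
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import ADDUCTS, Adduct, Formula, isotopologue_mz_list, parse_formula

__all__ = [
    "TargetEntry",
    "InterferenceHit",
    "BlankResult",
    "screen_interferences",
    "blank_contamination",
]


@dataclass(frozen=True)
class TargetEntry:
    """One metabolite in the targeted panel."""

    name: str
    formula: Formula
    rt_min: float
    polarity: str  # "positive" | "negative"
    adduct: Adduct | None = None

    def __post_init__(self) -> None:
        if self.rt_min < 0:
            raise ValueError("retention time must be non-negative")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")

    def resolved_adduct(self) -> Adduct:
        if self.adduct is not None:
            return self.adduct
        return ADDUCTS["[M+H]+"] if self.polarity == "positive" else ADDUCTS["[M-H]-"]

    def channel_mzs(self) -> list[float]:
        return isotopologue_mz_list(self.formula, self.resolved_adduct())


def target_from_row(
    name: str, formula: str, rt_min: float, polarity: str, adduct: str = ""
) -> TargetEntry:
    add = ADDUCTS[adduct] if adduct else None
    return TargetEntry(
        name=name,
        formula=parse_formula(formula, label=name),
        rt_min=float(rt_min),
        polarity=polarity.strip().lower(),
        adduct=add,
    )


@dataclass(frozen=True)
class InterferenceHit:
    """A channel of ``affected`` overlapped by a channel of ``interferer``."""

    affected: str
    affected_channel: int
    interferer: str
    interferer_channel: int
    ppm: float
    delta_rt: float


def screen_interferences(
    targets: list[TargetEntry],
    ppm_tol: float = 5.0,
    rt_window: float = 0.5,
    max_channels: dict[str, int] | None = None,
) -> list[InterferenceHit]:
    """All channel-level isobaric overlaps within the target panel.

    Every unordered pair of distinct same-polarity targets within the RT
    window is checked channel against channel; a matching pair is reported
    once, in the canonical direction where the *affected* target is the one
    with the higher channel index (ties broken by name) — its enriched
    isotopologue is the signal being contaminated.  The ppm difference is
    computed relative to the affected channel's m/z; both tolerance bounds
    are inclusive.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    if rt_window < 0:
        raise ValueError("RT window must be non-negative")
    max_channels = max_channels or {}
    mzs: dict[str, list[float]] = {}
    for t in targets:
        chan = t.channel_mzs()
        limit = max_channels.get(t.name)
        mzs[t.name] = chan if limit is None else chan[: limit + 1]
    hits: list[InterferenceHit] = []
    for i, a in enumerate(targets):
        for b in targets[i + 1 :]:
            if a.polarity != b.polarity:
                continue
            drt = abs(a.rt_min - b.rt_min)
            if drt > rt_window:
                continue
            for ja, mza in enumerate(mzs[a.name]):
                for jb, mzb in enumerate(mzs[b.name]):
                    # canonical direction: higher channel index is affected
                    if (ja, a.name) >= (jb, b.name):
                        aff, ja_, mza_, inter, jb_, mzb_ = a, ja, mza, b, jb, mzb
                    else:
                        aff, ja_, mza_, inter, jb_, mzb_ = b, jb, mzb, a, ja, mza
                    ppm = (mzb_ - mza_) / mza_ * 1e6
                    # inclusive bound; tiny epsilon absorbs float error at
                    # an exactly-on-boundary difference
                    if abs(ppm) <= ppm_tol + 1e-9:
                        hits.append(
                            InterferenceHit(
                                affected=aff.name,
                                affected_channel=ja_,
                                interferer=inter.name,
                                interferer_channel=jb_,
                                ppm=ppm,
                                delta_rt=drt,
                            )
                        )
    hits.sort(key=lambda h: (h.affected, h.affected_channel, h.interferer, h.interferer_channel))
    return hits


@dataclass(frozen=True)
class BlankResult:
    """Blank-to-sample area ratio for one target."""

    name: str
    ratio_percent: float | None
    classification: str  # negligible | minor | major | blank-only


def blank_contamination(
    blank_areas: dict[str, float],
    sample_areas: dict[str, float],
    *,
    minor_threshold: float = 0.1,
    major_threshold: float = 5.0,
) -> list[BlankResult]:
    """Classify blank contamination per target by blank/sample area ratio.

    Ratios are percentages of the sample area; the default bands follow the
    common reporting convention of negligible below 0.1%, minor between
    0.1% and 5%, and major above 5%.  A target detected in the blank but
    absent from the sample is classified ``blank-only`` with no ratio.
    """
    results = []
    for name in sorted(set(blank_areas) | set(sample_areas)):
        blank = float(blank_areas.get(name, 0.0))
        sample = float(sample_areas.get(name, 0.0))
        if blank < 0 or sample < 0:
            raise ValueError(f"{name}: negative peak area")
        if sample <= 0:
            if blank > 0:
                results.append(BlankResult(name, None, "blank-only"))
            else:
                results.append(BlankResult(name, 0.0, "negligible"))
            continue
        ratio = blank / sample * 100.0
        if ratio < minor_threshold:
            cls = "negligible"
        elif ratio <= major_threshold:
            cls = "minor"
        else:
            cls = "major"
        results.append(BlankResult(name, ratio, cls))
    return results
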