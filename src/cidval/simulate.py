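"""Synthetic replicate peak-area tables with the structure validation assumes.

The generator emulates the targeted-evaluation output of a labeled
reference-material run: each metabolite's true channel pattern is a mixture
of the binomial tracer CID and (optionally) the natural-abundance channel
envelope of an unlabeled contaminant, scaled to a total intensity,
perturbed by multiplicative lognormal noise per replicate and channel, and
truncated at a detection limit (channels below it report zero area —
the missing-peak failure mode of low-abundance isotopologues).

All draws come from one seeded generator, so a configuration reproduces its
tables exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import IsotopeTable, default_table
from .pattern import InstrumentModel, centroid_pattern, fine_pattern, group_by_tracer_channel
from .screen import TargetEntry
from .tracer import TracerSpec, predict_cid
from .validate import MeasurementSet

__all__ = ["SimulationConfig", "natural_channel_envelope", "simulate_measurements", "simulate_blank"]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated measurement campaign.

    Defaults mirror a typical labeled-reference-material run: four
    technical replicates, ~1% multiplicative area noise, no contamination,
    and an instrument at resolving power 120000 (at m/z 200).
    """

    targets: tuple[TargetEntry, ...]
    tracer: TracerSpec
    instrument: InstrumentModel = field(
        default_factory=lambda: InstrumentModel(resolving_power=120000.0)
    )
    total_intensity: float = 1e8
    replicates: int = 4
    noise_cv: float = 0.01
    contaminant_fraction: dict[str, float] = field(default_factory=dict)
    detection_limit: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("target list must not be empty")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if any(not 0.0 <= f <= 1.0 for f in self.contaminant_fraction.values()):
            raise ValueError("contaminant fractions must be in [0, 1]")
        if self.detection_limit < 0:
            raise ValueError("detection limit must be non-negative")


def natural_channel_envelope(
    target: TargetEntry,
    instrument: InstrumentModel,
    *,
    table: IsotopeTable | None = None,
) -> np.ndarray:
    """Natural-abundance fractions (percent) binned into the M0..Mn channels.

    This is what an unlabeled contaminant of the same formula contributes
    to each tracer channel at the configured resolving power.
    """
    table = table or default_table()
    fp = fine_pattern(target.formula, table=table)
    cp = centroid_pattern(fp, instrument)
    grouping = group_by_tracer_channel(cp, target.formula, "C", table=table)
    return grouping.fractions_percent


def _lognormal_factors(rng: np.ndarray, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def simulate_measurements(config: SimulationConfig) -> dict[str, MeasurementSet]:
    """Replicate area tables per target under the configured conditions.

    Area(replicate, k) = I x [(1-f) CID_pred_k + f natural_k]/100 x noise,
    zeroed when below the detection limit; f is the target's unlabeled
    contaminant fraction and natural_k its natural channel envelope.
    """
    rng = np.random.default_rng(config.seed)
    out: dict[str, MeasurementSet] = {}
    for target in config.targets:
        n = target.formula.n_carbons
        cid = predict_cid(n, config.tracer.p).fractions
        f = config.contaminant_fraction.get(target.name, 0.0)
        if f > 0:
            natural = natural_channel_envelope(target, config.instrument)
            true_pattern = (1.0 - f) * cid + f * natural
        else:
            true_pattern = cid
        base = config.total_intensity * true_pattern / 100.0
        noise = _lognormal_factors(rng, config.noise_cv, (config.replicates, n + 1))
        areas = base[None, :] * noise
        if config.detection_limit > 0:
            areas = np.where(areas < config.detection_limit, 0.0, areas)
        out[target.name] = MeasurementSet(
            metabolite=target.name,
            channels=tuple(f"M{k}" for k in range(n + 1)),
            areas=areas,
            polarity=target.polarity,
            method="simulated",
        )
    return out


def simulate_blank(
    config: SimulationConfig, blank_fraction: dict[str, float]
) -> dict[str, np.ndarray]:
    """Procedural-blank channel areas per target (one injection each).

    The blank carries the natural-abundance pattern of each contaminated
    target scaled by its blank fraction of the campaign intensity, with the
    same multiplicative noise model.
    """
    if any(f < 0 for f in blank_fraction.values()):
        raise ValueError("blank fractions must be non-negative")
    rng = np.random.default_rng(config.seed + 1)
    out: dict[str, np.ndarray] = {}
    for target in config.targets:
        n = target.formula.n_carbons
        f = blank_fraction.get(target.name, 0.0)
        if f == 0:
            out[target.name] = np.zeros(n + 1)
            continue
        natural = natural_channel_envelope(target, config.instrument)
        base = f * config.total_intensity * natural / 100.0
        noise = _lognormal_factors(rng, config.noise_cv, n + 1)
        areas = base * noise
        if config.detection_limit > 0:
            areas = np.where(areas < config.detection_limit, 0.0, areas)
        out[target.name] = areas
    return out
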