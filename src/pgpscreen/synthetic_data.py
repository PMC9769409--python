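"""Seeded generators for synthetic screening campaigns and pot trials.

Real campaign data live in lab notebooks; these generators produce tables
with the same statistical structure so every analysis stage is testable
end-to-end without any download. Defaults emulate the packaged campaign:
51 isolates, the printed detection prevalences and value ranges (IAA
4.0-43.8 µg/ml, phosphate solubilization 61.1-289.7 µg/ml, ammonia 0.9-5.9
µmol/ml, siderophore 10-61.2%), a ~26%-dense inhibition matrix with values
in 26.1-92.2%, and a 4-treatment x 2-timepoint x 5-replicate trial with
configurable per-treatment fold changes (printed range roughly 1.3-5.3) and
multiplicative lognormal replicate noise.

Values are drawn uniformly within each printed min-max by default (only
ranges are published, not distributions); log-uniform is available. A single
integer master seed is combined with a fixed per-component stream id, so
adding a generator never perturbs the output of an existing one.

What these tables deliberately lack: correlation among traits, phylogenetic
signal, and genus-dependent trait distributions — none of which is estimable
from published summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .trait_model import (
    BINARY_TRAITS,
    PATHOGENS,
    InhibitionMatrix,
    IsolateRecord,
    Measurement,
    TraitProfile,
)
from .growth_trial import PARAMETERS, TIMEPOINTS, TREATMENTS, GrowthRecord

import pandas as pd

#: fixed per-component stream ids (never renumber; append only)
_STREAMS = {"roster": 1, "traits": 2, "inhibition": 3, "trial": 4, "standards": 5}


def _rng(component: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[component], int(seed)])


#: genus frequencies of the packaged campaign (counts / 51)
DEFAULT_GENUS_PROBS = {
    "Streptomyces": 29 / 51,
    "Actinomadura": 6 / 51,
    "Nocardia": 4 / 51,
    "Nocardiopsis": 4 / 51,
    "Pseudonocardia": 3 / 51,
    "Nocardioides": 3 / 51,
    "Microbacterium": 1 / 51,
    "Mycolicibacterium": 1 / 51,
}

#: per-trait detection probability (non-ND / positive counts over 51)
DEFAULT_DETECTION_PROBS = {
    "iaa": 27 / 51,
    "p_solub": 25 / 51,
    "ammonia": 35 / 51,
    "siderophore": 13 / 51,
    "n2_fixation": 17 / 51,
    "acc_deaminase": 14 / 51,
    "chitinase": 19 / 51,
    "protease": 22 / 51,
    "cellulase": 12 / 51,
    "pectinase": 11 / 51,
}

#: printed min-max value ranges of detected quantitative traits
DEFAULT_VALUE_RANGES = {
    "iaa": (4.0, 43.8),
    "p_solub": (61.1, 289.7),
    "ammonia": (0.9, 5.9),
    "siderophore": (10.0, 61.2),
}


@dataclass(frozen=True)
class ScreenSimConfig:
    """Configuration of a synthetic screening campaign."""

    n_isolates: int = 51
    detection_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_PROBS)
    )
    value_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VALUE_RANGES)
    )
    log_uniform: bool = False
    genus_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENUS_PROBS)
    )
    root_prob: float = 33 / 51
    inhibition_density: float = 132 / 510
    inhibition_range: tuple[float, float] = (26.1, 92.2)
    pathogens: tuple[str, ...] = PATHOGENS
    relative_se: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        probs = {**self.detection_probs, "root": self.root_prob,
                 "density": self.inhibition_density, **self.genus_probs}
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"probability {name}={p} outside [0, 1]")
        if abs(sum(self.genus_probs.values()) - 1) > 1e-9:
            raise ConfigurationError("genus probabilities must sum to 1")
        for name, (lo, hi) in {**self.value_ranges,
                               "inhibition": self.inhibition_range}.items():
            if lo > hi or lo < 0:
                raise ConfigurationError(f"range {name}=({lo}, {hi}) is invalid")
        if self.n_isolates < 1:
            raise ConfigurationError("n_isolates must be >= 1")


def _draw_value(rng, lo: float, hi: float, log_uniform: bool) -> float:
    if lo == hi:
        return lo
    if log_uniform:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


def simulate_screen(
    config: ScreenSimConfig | None = None,
) -> tuple[list[IsolateRecord], list[TraitProfile], InhibitionMatrix]:
    """Generate a roster, trait table and inhibition matrix.

    Deterministic given ``config.seed``: detected values are drawn within the
    configured ranges, undetected cells are ND/absent, and every cell of the
    inhibition matrix is active independently with the configured density.
    """
    config = config or ScreenSimConfig()
    config.validate()
    width = len(str(config.n_isolates))
    ids = [f"SYN{i + 1:0{width}d}" for i in range(config.n_isolates)]

    rng = _rng("roster", config.seed)
    genera = list(config.genus_probs)
    gprobs = np.array([config.genus_probs[g] for g in genera])
    gprobs = gprobs / gprobs.sum()
    roster = [
        IsolateRecord(
            isolate_id=iid,
            tissue="root" if rng.random() < config.root_prob else "leaf",
            genus=genera[int(rng.choice(len(genera), p=gprobs))],
        )
        for iid in ids
    ]

    rng = _rng("traits", config.seed)
    profiles = []
    for iid in ids:
        quant = {}
        for trait, (lo, hi) in config.value_ranges.items():
            p = config.detection_probs.get(trait, 0.0)
            if rng.random() < p:
                mean = _draw_value(rng, lo, hi, config.log_uniform)
                mean = round(mean, 1)
                se = round(max(mean * config.relative_se, 0.01), 2)
                quant[trait] = Measurement(mean=mean, se=se, n=3)
            else:
                quant[trait] = None
        flags = {
            t: bool(rng.random() < config.detection_probs.get(t, 0.0))
            for t in BINARY_TRAITS
        }
        profiles.append(TraitProfile(isolate_id=iid, **quant, **flags))

    rng = _rng("inhibition", config.seed)
    lo, hi = config.inhibition_range
    vals = pd.DataFrame(np.nan, index=ids, columns=list(config.pathogens))
    errs = pd.DataFrame(np.nan, index=ids, columns=list(config.pathogens))
    for iid in ids:
        for p in config.pathogens:
            if rng.random() < config.inhibition_density:
                v = round(_draw_value(rng, lo, hi, False), 1)
                vals.at[iid, p] = v
                errs.at[iid, p] = round(max(v * config.relative_se, 0.01), 2)
    return roster, profiles, InhibitionMatrix(vals, errs)


# ---------------------------------------------------------------------------
# pot trial


#: plausible control-plant means for a young chili pot trial, per timepoint
DEFAULT_CONTROL_MEANS = {
    35: {
        "leaf_count": 8.0,
        "shoot_length": 12.0,
        "root_length": 6.0,
        "shoot_fresh_wt": 1.5,
        "root_fresh_wt": 0.5,
        "shoot_dry_wt": 0.25,
        "root_dry_wt": 0.08,
        "chl_a": 1.1,
        "chl_b": 0.5,
    },
    70: {
        "leaf_count": 14.0,
        "shoot_length": 20.0,
        "root_length": 10.0,
        "shoot_fresh_wt": 3.5,
        "root_fresh_wt": 1.2,
        "shoot_dry_wt": 0.6,
        "root_dry_wt": 0.2,
        "chl_a": 1.4,
        "chl_b": 0.65,
    },
}

#: per-treatment fold changes inside the printed 1.3-5.3 band; the consortium
#: outperforms the single-strain treatments, as reported
DEFAULT_FOLD_CHANGES = {"control": 1.0, "T1": 1.6, "T2": 1.8, "consortium": 2.6}


@dataclass(frozen=True)
class TrialSimConfig:
    """Configuration of a synthetic pot trial."""

    treatments: tuple[str, ...] = TREATMENTS
    timepoints: tuple[int, ...] = TIMEPOINTS
    replicates: int = 5
    control_means: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            tp: dict(m) for tp, m in DEFAULT_CONTROL_MEANS.items()
        }
    )
    fold_changes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOLD_CHANGES)
    )
    noise_cv: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise CV must be >= 0")
        for trt in self.treatments:
            fc = self.fold_changes.get(trt)
            if fc is None or fc <= 0:
                raise ConfigurationError(
                    f"treatment {trt!r} needs a positive fold change, got {fc}"
                )
        for tp in self.timepoints:
            means = self.control_means.get(tp)
            if means is None:
                raise ConfigurationError(f"no control means for timepoint {tp}")
            for p in PARAMETERS:
                if means.get(p, 0) <= 0:
                    raise ConfigurationError(
                        f"control mean for {p!r} at {tp} d must be > 0"
                    )


def simulate_trial(config: TrialSimConfig | None = None) -> list[GrowthRecord]:
    """Generate pot-trial records.

    Each replicate value = control mean x treatment fold change x
    multiplicative lognormal noise with the configured coefficient of
    variation (mean-1 noise, so expectations equal the configured products;
    CV = 0 reproduces them exactly). Seeded and deterministic.
    """
    config = config or TrialSimConfig()
    config.validate()
    rng = _rng("trial", config.seed)
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    records = []
    for tp in config.timepoints:
        for trt in config.treatments:
            fc = config.fold_changes[trt]
            for rep in range(1, config.replicates + 1):
                params = {}
                for p in PARAMETERS:
                    base = config.control_means[tp][p] * fc
                    if sigma > 0:
                        noise = float(
                            np.exp(rng.normal(-(sigma**2) / 2, sigma))
                        )
                    else:
                        noise = 1.0
                    params[p] = base * noise
                records.append(
                    GrowthRecord(
                        treatment=trt, timepoint=tp, replicate=rep,
                        parameters=params,
                    )
                )
    return records


def synthetic_standards(
    slope: float,
    intercept: float = 0.0,
    n_points: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_concentration: float = 50.0,
) -> list[tuple[float, float]]:
    """An equally spaced standard series with absorbance = slope * c +
    intercept + N(0, noise_sd) noise; stands in for unpublished IAA /
    KH2PO4 / ammonium-sulfate standard curves."""
    if n_points < 3:
        raise ConfigurationError(f"need >= 3 standard points, got {n_points}")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = _rng("standards", seed)
    conc = np.linspace(0.0, max_concentration, n_points)
    absb = slope * conc + intercept
    if noise_sd > 0:
        absb = absb + rng.normal(0.0, noise_sd, size=n_points)
    return [(float(c), float(a)) for c, a in zip(conc, absb)]


def null_trial_config(seed: int = 0, **overrides) -> TrialSimConfig:
    """A no-effect trial (all fold changes 1) for calibration studies."""
    cfg = TrialSimConfig(
        fold_changes={t: 1.0 for t in TREATMENTS}, seed=seed
    )
    return replace(cfg, **overrides) if overrides else cfg
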