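"""Community-level descriptive statistics over a screening campaign.

Prevalence counts treat a quantitative trait as positive iff it was detected
(non-ND), with no magnitude threshold, and a binary trait as positive iff its
flag is set. Percentages are reported over all profiled isolates, rounded
half-up to two decimals to match the conventional reporting style
(e.g. 25/51 = 49.02%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DomainError
from .trait_model import (
    BINARY_TRAITS,
    QUANT_TRAITS,
    InhibitionMatrix,
    IsolateRecord,
    TraitProfile,
)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (what a bench scientist writes by hand)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TraitPrevalence:
    trait: str
    count: int
    denominator: int

    @property
    def percentage(self) -> float:
        return round_half_up(100.0 * self.count / self.denominator)


@dataclass
class PrevalenceReport:
    """Per-trait positive counts over a campaign."""

    traits: dict[str, TraitPrevalence]
    denominator: int
    positivity_rule: str = (
        "quantitative: detected (non-ND); binary: flag set; no magnitude threshold"
    )

    def __getitem__(self, trait: str) -> TraitPrevalence:
        return self.traits[trait]

    def to_dict(self) -> dict:
        return {
            "denominator": self.denominator,
            "positivity_rule": self.positivity_rule,
            "traits": {
                t: {"count": p.count, "denominator": p.denominator,
                    "percentage": p.percentage}
                for t, p in self.traits.items()
            },
        }


def trait_prevalence(profiles: Sequence[TraitProfile]) -> PrevalenceReport:
    """Count, per trait, how many isolates are positive."""
    if not profiles:
        raise DomainError("need at least one trait profile")
    n = len(profiles)
    traits: dict[str, TraitPrevalence] = {}
    for t in QUANT_TRAITS:
        count = sum(p.detected(t) for p in profiles)
        traits[t] = TraitPrevalence(trait=t, count=count, denominator=n)
    for t in BINARY_TRAITS:
        count = sum(bool(getattr(p, t)) for p in profiles)
        traits[t] = TraitPrevalence(trait=t, count=count, denominator=n)
    return PrevalenceReport(traits=traits, denominator=n)


@dataclass
class SpectrumReport:
    """Per-pathogen antagonist counts and broad-spectrum detection."""

    per_pathogen: dict[str, int]
    any_pathogen_count: int
    broad_spectrum: list[str]
    n_isolates: int

    def to_dict(self) -> dict:
        return asdict(self)


def antagonism_spectrum(matrix: InhibitionMatrix) -> SpectrumReport:
    """Summarize the inhibition matrix: an isolate counts against a pathogen
    iff a value is present; broad-spectrum isolates inhibit every pathogen."""
    if not matrix.isolates:
        raise DomainError("inhibition matrix has no isolate rows")
    present = matrix.values.notna()
    per_pathogen = {p: int(present[p].sum()) for p in matrix.pathogens}
    any_count = int(present.any(axis=1).sum())
    broad = [i for i in matrix.isolates if bool(present.loc[i].all())]
    return SpectrumReport(
        per_pathogen=per_pathogen,
        any_pathogen_count=any_count,
        broad_spectrum=broad,
        n_isolates=len(matrix.isolates),
    )


@dataclass
class CompositionSummary:
    genus_counts: dict[str, int]
    genus_percentages: dict[str, float]
    tissue_counts: dict[str, int]
    tissue_percentages: dict[str, float]
    n_isolates: int

    def to_dict(self) -> dict:
        return asdict(self)


def composition_summary(roster: Sequence[IsolateRecord]) -> CompositionSummary:
    """Per-genus and per-tissue counts with half-up 2 dp percentages.

    Isolates without a genus label are grouped under ``"unknown"``.
    """
    n = len(roster)
    genus_counts: dict[str, int] = {}
    tissue_counts: dict[str, int] = {}
    for r in roster:
        g = r.genus or "unknown"
        genus_counts[g] = genus_counts.get(g, 0) + 1
        tissue_counts[r.tissue] = tissue_counts.get(r.tissue, 0) + 1
    pct = lambda c: round_half_up(100.0 * c / n) if n else 0.0
    return CompositionSummary(
        genus_counts=genus_counts,
        genus_percentages={g: pct(c) for g, c in genus_counts.items()},
        tissue_counts=tissue_counts,
        tissue_percentages={t: pct(c) for t, c in tissue_counts.items()},
        n_isolates=n,
    )


@dataclass
class Extremum:
    """An extreme trait value with every isolate (and pathogen) attaining it."""

    value: float
    attained_by: list[tuple]  # (isolate_id,) or (isolate_id, pathogen)


@dataclass
class ExtremesReport:
    maxima: dict[str, Extremum] = field(default_factory=dict)
    minima: dict[str, Extremum] = field(default_factory=dict)
    all_nd: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        conv = lambda d: {
            k: {"value": e.value, "attained_by": [list(t) for t in e.attained_by]}
            for k, e in d.items()
        }
        return {"maxima": conv(self.maxima), "minima": conv(self.minima),
                "all_nd": self.all_nd}


def value_extremes(
    profiles: Sequence[TraitProfile] | None = None,
    matrix: InhibitionMatrix | None = None,
) -> ExtremesReport:
    """Per-trait detected max/min with isolate attribution; ties return all
    attaining isolates (order-independent determinism). Traits with no
    detected value are listed under ``all_nd``."""
    report = ExtremesReport()
    if profiles:
        for t in QUANT_TRAITS:
            pairs = [(p.isolate_id, p.value(t)) for p in profiles if p.detected(t)]
            if not pairs:
                report.all_nd.append(t)
                continue
            values = [v for _, v in pairs]
            vmax, vmin = max(values), min(values)
            report.maxima[t] = Extremum(
                value=vmax,
                attained_by=sorted((i,) for i, v in pairs if v == vmax),
            )
            report.minima[t] = Extremum(
                value=vmin,
                attained_by=sorted((i,) for i, v in pairs if v == vmin),
            )
    if matrix is not None:
        arr = matrix.values.to_numpy(dtype=float)
        if np.all(np.isnan(arr)):
            report.all_nd.append("inhibition")
        else:
            vmax = float(np.nanmax(arr))
            vmin = float(np.nanmin(arr))
            pairs_max, pairs_min = [], []
            for i, iid in enumerate(matrix.isolates):
                for j, p in enumerate(matrix.pathogens):
                    if np.isnan(arr[i, j]):
                        continue
                    if arr[i, j] == vmax:
                        pairs_max.append((iid, p))
                    if arr[i, j] == vmin:
                        pairs_min.append((iid, p))
            report.maxima["inhibition"] = Extremum(vmax, sorted(pairs_max))
            report.minima["inhibition"] = Extremum(vmin, sorted(pairs_min))
    return report


def campaign_report(
    roster: Sequence[IsolateRecord] | None,
    profiles: Sequence[TraitProfile],
    matrix: InhibitionMatrix,
    path: str | Path | None = None,
) -> dict:
    """Bundle prevalence, composition, antagonism spectrum and extremes into
    one JSON-serializable campaign summary."""
    report = {
        "prevalence": trait_prevalence(profiles).to_dict(),
        "antagonism": antagonism_spectrum(matrix).to_dict(),
        "extremes": value_extremes(profiles, matrix).to_dict(),
    }
    if roster is not None:
        report["composition"] = composition_summary(roster).to_dict()
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
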