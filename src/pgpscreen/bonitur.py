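"""Bonitur scoring: an additive 41-point scale ranking isolates by their
combined plant-growth-promoting and biocontrol profile.

Quantitative traits earn 0-3 points by upper-inclusive binning:

* IAA (µg/ml): not detected -> 0, (0, 15] -> 1, (15, 30] -> 2, > 30 -> 3
* phosphate solubilization (µg/ml): (0, 100] -> 1, (100, 200] -> 2, > 200 -> 3
* per-pathogen growth inhibition (%): absent or <= 10 -> 0, (10, 30] -> 1,
  (30, 60] -> 2, (60, 100] -> 3

Five further traits (ammonia, N2 fixation, ACC deaminase, siderophore,
chitinase) score 1 point each when positive; a detected quantitative value
counts as positive. With ten pathogens the maximum is
3 + 3 + 5 + 10 * 3 = 41.

Ranking is dense: tied totals share a rank and the next distinct total takes
the next integer. ``audit_scores`` reconciles recomputed score cards with a
published score table, flagging cell-level disagreements and published rows
whose own points do not sum to their printed total — mismatches are reported,
never auto-corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError
from .trait_model import PATHOGENS, TraitProfile

#: binary traits worth one point each, in published column order
DEFAULT_BINARY_TRAITS = (
    "ammonia",
    "n2_fixation",
    "acc_deaminase",
    "siderophore",
    "chitinase",
)

#: quantitative-trait keys that are binary-scored (detected -> positive)
_DETECTABLE = {"ammonia", "siderophore"}


@dataclass(frozen=True)
class BoniturRuleSet:
    """The scoring rules: bin thresholds, 1-point traits, scale maximum."""

    iaa_bins: tuple[float, float] = (15.0, 30.0)
    ps_bins: tuple[float, float] = (100.0, 200.0)
    gi_bins: tuple[float, float, float] = (10.0, 30.0, 60.0)
    binary_traits: tuple[str, ...] = DEFAULT_BINARY_TRAITS
    n_pathogens: int = 10
    max_total: int = 41

    def __post_init__(self):
        for name, bins in (("iaa_bins", self.iaa_bins), ("ps_bins", self.ps_bins),
                           ("gi_bins", self.gi_bins)):
            if list(bins) != sorted(bins) or len(set(bins)) != len(bins):
                raise ConfigurationError(f"{name} must be strictly increasing: {bins}")
        implied = 3 + 3 + len(self.binary_traits) + 3 * self.n_pathogens
        if implied != self.max_total:
            raise ConfigurationError(
                f"rule set is inconsistent: 3 + 3 + {len(self.binary_traits)} "
                f"+ 3*{self.n_pathogens} = {implied} != max_total {self.max_total}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BoniturRuleSet":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("iaa_bins", "ps_bins", "gi_bins", "binary_traits"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("n_pathogens", "max_total"):
            if key in raw:
                kwargs[key] = int(raw[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "iaa_bins": list(self.iaa_bins),
                    "ps_bins": list(self.ps_bins),
                    "gi_bins": list(self.gi_bins),
                    "binary_traits": list(self.binary_traits),
                    "n_pathogens": self.n_pathogens,
                    "max_total": self.max_total,
                },
                sort_keys=False,
            )
        )


@dataclass
class ScoreCard:
    """Per-trait points, subtotals, total and (dense) rank for one isolate."""

    isolate_id: str
    trait_points: dict[str, int]
    pathogen_points: dict[str, int]
    rank: int | None = None

    @property
    def pgp_subtotal(self) -> int:
        return sum(self.trait_points.values())

    @property
    def antifungal_subtotal(self) -> int:
        return sum(self.pathogen_points.values())

    @property
    def total(self) -> int:
        return self.pgp_subtotal + self.antifungal_subtotal

    def to_dict(self) -> dict:
        return {
            "isolate_id": self.isolate_id,
            **self.trait_points,
            **self.pathogen_points,
            "pgp_subtotal": self.pgp_subtotal,
            "antifungal_subtotal": self.antifungal_subtotal,
            "total": self.total,
            "rank": self.rank,
        }


def score_quant_trait(
    value: float | None, bins: tuple[float, float]
) -> int:
    """Bin a quantitative trait value into 0-3 points (upper-inclusive).

    ND (None) and 0 score 0; (0, t1] -> 1; (t1, t2] -> 2; (t2, inf) -> 3.
    """
    if value is None or value == 0:
        return 0
    if value < 0:
        raise DomainError(f"trait value must be >= 0, got {value}")
    t1, t2 = bins
    if value <= t1:
        return 1
    if value <= t2:
        return 2
    return 3


def score_inhibition(
    gi: float | None, bins: tuple[float, float, float] = (10.0, 30.0, 60.0)
) -> int:
    """Bin a percent-inhibition value into 0-3 points (upper-inclusive).

    Absent (no activity) or <= 10 -> 0; (10, 30] -> 1; (30, 60] -> 2;
    (60, 100] -> 3.
    """
    if gi is None:
        return 0
    if not 0 <= gi <= 100:
        raise DomainError(f"inhibition percent outside [0, 100]: {gi}")
    t0, t1, t2 = bins
    if gi <= t0:
        return 0
    if gi <= t1:
        return 1
    if gi <= t2:
        return 2
    return 3


def score_isolate(
    profile: TraitProfile,
    inhibition_row: Mapping[str, float] | None = None,
    rules: BoniturRuleSet | None = None,
    pathogens: Sequence[str] = PATHOGENS,
) -> ScoreCard:
    """Score one isolate from its trait profile and inhibition row.

    ``inhibition_row`` maps pathogen label -> percent inhibition; pathogens
    missing from the mapping count as no activity (0 points).
    """
    rules = rules or BoniturRuleSet()
    inhibition_row = inhibition_row or {}
    if len(inhibition_row) > rules.n_pathogens:
        raise ConfigurationError(
            f"inhibition row has {len(inhibition_row)} pathogens; "
            f"rules allow {rules.n_pathogens}"
        )
    unknown = set(inhibition_row) - set(pathogens)
    if unknown:
        raise ConfigurationError(f"unknown pathogen label(s): {sorted(unknown)}")

    trait_points = {
        "iaa": score_quant_trait(profile.value("iaa"), rules.iaa_bins),
        "p_solub": score_quant_trait(profile.value("p_solub"), rules.ps_bins),
    }
    for name in rules.binary_traits:
        if name in _DETECTABLE:
            positive = profile.detected(name)
        elif hasattr(profile, name):
            positive = bool(getattr(profile, name))
        else:
            raise ConfigurationError(f"unknown trait name in rules: {name!r}")
        trait_points[name] = 1 if positive else 0

    pathogen_points = {
        p: score_inhibition(inhibition_row.get(p), rules.gi_bins)
        for p in pathogens
    }
    return ScoreCard(
        isolate_id=profile.isolate_id,
        trait_points=trait_points,
        pathogen_points=pathogen_points,
    )


def rank_isolates(cards: Sequence[ScoreCard]) -> list[ScoreCard]:
    """Assign dense ranks by descending total; ties share a rank.

    Returns the cards sorted by rank (ties kept in input order).
    """
    if not cards:
        raise DomainError("need at least one score card to rank")
    ordered = sorted(cards, key=lambda c: -c.total)
    rank, prev_total = 0, None
    for card in ordered:
        if card.total != prev_total:
            rank += 1
            prev_total = card.total
        card.rank = rank
    return ordered


def cards_to_frame(cards: Sequence[ScoreCard]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in cards]).set_index("isolate_id")


# ---------------------------------------------------------------------------
# audit against a published score table


@dataclass
class CellMismatch:
    column: str
    recomputed: int
    published: int


@dataclass
class IsolateAudit:
    isolate_id: str
    cell_mismatches: list[CellMismatch] = field(default_factory=list)
    recomputed_total: int = 0
    published_total: int = 0
    published_cells_sum: int = 0

    @property
    def internal_sum_mismatch(self) -> bool:
        """Published row's own points do not add up to its printed total."""
        return self.published_cells_sum != self.published_total

    @property
    def consistent(self) -> bool:
        return not self.cell_mismatches and not self.internal_sum_mismatch

    def to_dict(self) -> dict:
        return {
            "isolate_id": self.isolate_id,
            "cell_mismatches": [asdict(m) for m in self.cell_mismatches],
            "recomputed_total": self.recomputed_total,
            "published_total": self.published_total,
            "published_cells_sum": self.published_cells_sum,
            "internal_sum_mismatch": self.internal_sum_mismatch,
            "consistent": self.consistent,
        }


@dataclass
class AuditReport:
    audits: list[IsolateAudit]

    @property
    def flagged(self) -> list[str]:
        """Isolates whose published rows disagree with recomputation or
        with their own printed total."""
        return [a.isolate_id for a in self.audits if not a.consistent]

    @property
    def empty(self) -> bool:
        return not self.flagged

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"flagged": self.flagged, "audits": [a.to_dict() for a in self.audits]},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def audit_scores(
    cards: Sequence[ScoreCard], published: pd.DataFrame
) -> AuditReport:
    """Reconcile recomputed score cards with a published score table.

    ``published`` is indexed by isolate_id with one integer column per scored
    trait/pathogen plus ``total``. Only shared isolates are audited. For each
    one the report lists cells where the recomputed points differ from the
    published points, and whether the published row's own points sum to its
    printed total. Nothing is corrected.
    """
    by_id = {c.isolate_id: c for c in cards}
    point_cols = [c for c in published.columns if c not in ("total", "rank")]
    audits = []
    for iid in published.index:
        if iid not in by_id:
            continue
        card = by_id[iid]
        recomputed = {**card.trait_points, **card.pathogen_points}
        row = published.loc[iid]
        audit = IsolateAudit(
            isolate_id=iid,
            recomputed_total=card.total,
            published_total=int(row["total"]),
            published_cells_sum=int(sum(int(row[c]) for c in point_cols)),
        )
        for col in point_cols:
            if col not in recomputed:
                raise ConfigurationError(
                    f"published column {col!r} has no recomputed counterpart"
                )
            if int(row[col]) != recomputed[col]:
                audit.cell_mismatches.append(
                    CellMismatch(
                        column=col,
                        recomputed=recomputed[col],
                        published=int(row[col]),
                    )
                )
        audits.append(audit)
    return AuditReport(audits=audits)
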