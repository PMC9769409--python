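"""Pot-trial statistics: per-treatment summaries, log2 fold change versus
control, classic one-way ANOVA per parameter, and PCA of the standardized
parameter matrix.

The trial design is a small greenhouse experiment: a control and inoculated
treatments, a handful of replicates per treatment (five by default), harvests
at two timepoints, and nine vegetative parameters per plant (leaf count,
shoot/root length, fresh and dry shoot/root weight, chlorophyll a and b).
Analyses are run per parameter per timepoint. Fold change compares treatment
means to the control mean and is reported on the log2 scale so up- and
down-regulation are symmetric about zero. No multiple-testing correction is
applied across parameters; p-values are raw.

PCA standardizes every parameter to zero mean and unit variance (parameters
mix counts, centimetres, grams and mg/g) and eigendecomposes the correlation
matrix; explained percentages are non-increasing and sum to 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateColumnError, DomainError
from .trait_model import Measurement

#: vegetative parameters recorded per plant, in reporting order
PARAMETERS = (
    "leaf_count",
    "shoot_length",
    "root_length",
    "shoot_fresh_wt",
    "root_fresh_wt",
    "shoot_dry_wt",
    "root_dry_wt",
    "chl_a",
    "chl_b",
)

TREATMENTS = ("control", "T1", "T2", "consortium")
TIMEPOINTS = (35, 70)


@dataclass(frozen=True)
class GrowthRecord:
    """One replicate plant's nine vegetative parameters at one timepoint."""

    treatment: str
    timepoint: int
    replicate: int
    parameters: dict[str, float]

    def __post_init__(self):
        missing = [p for p in PARAMETERS if p not in self.parameters]
        if missing:
            raise DomainError(f"growth record missing parameter(s) {missing}")
        for name, v in self.parameters.items():
            if v < 0:
                raise DomainError(f"{name} must be >= 0, got {v}")


def records_to_frame(records: Sequence[GrowthRecord]) -> pd.DataFrame:
    """Long-format frame: treatment, timepoint, replicate, parameter, value."""
    rows = [
        {
            "treatment": r.treatment,
            "timepoint": r.timepoint,
            "replicate": r.replicate,
            "parameter": p,
            "value": r.parameters[p],
        }
        for r in records
        for p in PARAMETERS
    ]
    df = pd.DataFrame(rows)
    dup = df.duplicated(["treatment", "timepoint", "replicate", "parameter"])
    if dup.any():
        raise DomainError("replicate indices must be unique within a cell")
    return df


def frame_to_records(df: pd.DataFrame) -> list[GrowthRecord]:
    records = []
    for (trt, tp, rep), g in df.groupby(
        ["treatment", "timepoint", "replicate"], sort=False
    ):
        params = dict(zip(g["parameter"], g["value"].astype(float)))
        records.append(
            GrowthRecord(
                treatment=str(trt), timepoint=int(tp), replicate=int(rep),
                parameters=params,
            )
        )
    return records


def summarize_treatments(records: Sequence[GrowthRecord]) -> pd.DataFrame:
    """Mean ± SE per (treatment, timepoint, parameter) cell.

    SE = sd / sqrt(n) with the sample (n - 1) standard deviation. Cells with
    fewer than two replicates raise, since an SE is not estimable.
    """
    df = records_to_frame(records)
    out = []
    for (trt, tp, p), g in df.groupby(["treatment", "timepoint", "parameter"],
                                      sort=False):
        vals = g["value"].to_numpy(dtype=float)
        if vals.size < 2:
            raise DomainError(
                f"cell ({trt}, {tp}, {p}) has {vals.size} replicate(s); need >= 2"
            )
        out.append(
            {
                "treatment": trt,
                "timepoint": tp,
                "parameter": p,
                "mean": float(vals.mean()),
                "se": float(np.std(vals, ddof=1) / math.sqrt(vals.size)),
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(out)


def cell_measurement(summary: pd.DataFrame, treatment: str, timepoint: int,
                     parameter: str) -> Measurement:
    row = summary[
        (summary["treatment"] == treatment)
        & (summary["timepoint"] == timepoint)
        & (summary["parameter"] == parameter)
    ]
    if row.empty:
        raise DomainError(f"no cell ({treatment}, {timepoint}, {parameter})")
    r = row.iloc[0]
    return Measurement(mean=float(r["mean"]), se=float(r["se"]), n=int(r["n"]))


def log2_fold_change(treatment_mean: float, control_mean: float) -> float:
    """log2(treatment mean / control mean); both means must be positive."""
    if treatment_mean <= 0 or control_mean <= 0:
        raise DomainError(
            "fold change needs positive means, got "
            f"{treatment_mean} vs {control_mean}"
        )
    return math.log2(treatment_mean / control_mean)


def fold_change_table(
    records: Sequence[GrowthRecord], control: str = "control"
) -> pd.DataFrame:
    """log2 fold change of every non-control treatment vs the control mean,
    per timepoint and parameter. Uses means of replicates, not per-replicate
    ratios."""
    summary = summarize_treatments(records)
    controls = summary[summary["treatment"] == control]
    if controls.empty:
        raise DomainError(f"no control treatment {control!r} in records")
    rows = []
    for _, r in summary[summary["treatment"] != control].iterrows():
        c = controls[
            (controls["timepoint"] == r["timepoint"])
            & (controls["parameter"] == r["parameter"])
        ]
        if c.empty:
            raise DomainError(
                f"no control cell for ({r['timepoint']}, {r['parameter']})"
            )
        cmean = float(c.iloc[0]["mean"])
        rows.append(
            {
                "treatment": r["treatment"],
                "timepoint": r["timepoint"],
                "parameter": r["parameter"],
                "treatment_mean": float(r["mean"]),
                "control_mean": cmean,
                "fold_change": float(r["mean"]) / cmean,
                "log2_fold_change": log2_fold_change(float(r["mean"]), cmean),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float

    def to_dict(self) -> dict:
        return asdict(self)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classic (equal-variance) one-way ANOVA from the Fisher decomposition.

    F = MS_between / MS_within; p is the upper tail of F(df_between,
    df_within). Degenerate inputs follow the natural limits: all values
    identical -> F = 0, p = 1; zero within-group variance with unequal means
    -> F = inf, p = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DomainError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise DomainError("every group needs at least two values")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between, df_within = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(F=0.0, df_between=df_between,
                               df_within=df_within, p=1.0)
        return AnovaResult(F=math.inf, df_between=df_between,
                           df_within=df_within, p=0.0)
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within, p=p)


def anova_table(records: Sequence[GrowthRecord]) -> pd.DataFrame:
    """One-way ANOVA across treatments, run per parameter per timepoint."""
    df = records_to_frame(records)
    rows = []
    for (tp, p), g in df.groupby(["timepoint", "parameter"], sort=False):
        groups = [
            grp["value"].to_numpy(dtype=float)
            for _, grp in g.groupby("treatment", sort=False)
        ]
        res = one_way_anova(groups)
        rows.append({"timepoint": tp, "parameter": p, **res.to_dict()})
    return pd.DataFrame(rows)


@dataclass
class PcaResult:
    """Loadings (parameters x components) and explained variance shares."""

    loadings: pd.DataFrame
    explained_variance_pct: np.ndarray

    def to_dict(self) -> dict:
        return {
            "explained_variance_pct": [float(v) for v in
                                       self.explained_variance_pct],
            "loadings": {
                c: {p: float(self.loadings.at[p, c]) for p in self.loadings.index}
                for c in self.loadings.columns
            },
        }


def pca(
    matrix: np.ndarray | pd.DataFrame,
    feature_names: Sequence[str] | None = None,
) -> PcaResult:
    """PCA on the correlation matrix of an observations x parameters table.

    Columns are standardized to zero mean and unit variance, the correlation
    matrix is eigendecomposed, and explained variance percentages are
    returned in descending order (they sum to 100). A constant column cannot
    be standardized and raises, naming the column.
    """
    if isinstance(matrix, pd.DataFrame):
        feature_names = feature_names or list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        feature_names = list(feature_names) if feature_names else [
            f"x{j}" for j in range(X.shape[1])
        ]
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise DomainError("PCA needs >= 2 observations and >= 2 parameters")
    sd = X.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            raise DegenerateColumnError(
                f"column {feature_names[j]!r} is constant; cannot standardize",
                column=feature_names[j],
            )
    corr = np.corrcoef((X - X.mean(axis=0)) / sd, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    pct = 100.0 * eigvals / eigvals.sum()
    loadings = pd.DataFrame(
        eigvecs,
        index=feature_names,
        columns=[f"PC{i + 1}" for i in range(len(eigvals))],
    )
    return PcaResult(loadings=loadings, explained_variance_pct=pct)


def trial_pca(records: Sequence[GrowthRecord], timepoint: int) -> PcaResult:
    """PCA of the replicate x parameter matrix at one harvest timepoint."""
    df = records_to_frame(records)
    sub = df[df["timepoint"] == timepoint]
    if sub.empty:
        raise DomainError(f"no records at timepoint {timepoint}")
    wide = sub.pivot_table(
        index=["treatment", "replicate"], columns="parameter", values="value"
    )[list(PARAMETERS)]
    return pca(wide)
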