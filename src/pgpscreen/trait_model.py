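"""Domain model and delimited-text I/O for an isolate screening campaign.

The campaign data are three tables:

* a roster of isolates (id, host tissue, optional morphology and genus),
* a trait table of quantitative PGP assays (IAA, phosphate solubilization,
  ammonia, siderophore) and binary traits (N2 fixation, ACC deaminase and
  extracellular enzymes), and
* an isolate x pathogen matrix of dual-culture percent mycelial inhibition.

"Not detected" (ND) is a first-class state, kept distinct from a measured
zero: quantitative fields hold either a :class:`Measurement` or ``None``.
Downstream modules decide what ND means numerically (the bonitur scorer maps
it to zero points; prevalence counts it as negative).

CSV conventions follow the printed tables: comma-separated, UTF-8, header
row; quantitative cells are ``"mean ± se"`` (plain numbers also accepted);
flags are ``+`` / ``-`` (en-dash and minus-sign variants accepted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, TableParseError, ValidationError

ND_TOKEN = "ND"

#: dash-like tokens accepted as a negative flag or a no-activity cell
_DASH_TOKENS = {"-", "–", "—", "−", ""}

#: quantitative traits in trait-table column order
QUANT_TRAITS = ("iaa", "p_solub", "ammonia", "siderophore")

#: binary traits in trait-table column order
BINARY_TRAITS = (
    "n2_fixation",
    "acc_deaminase",
    "chitinase",
    "protease",
    "cellulase",
    "pectinase",
)

TRAIT_COLUMNS = (
    "isolate_id",
    "iaa",
    "p_solub",
    "ammonia",
    "n2_fixation",
    "siderophore",
    "acc_deaminase",
    "chitinase",
    "protease",
    "cellulase",
    "pectinase",
)

#: fixed pathogen column order of the packaged inhibition matrix
PATHOGENS = (
    "P. hypobrunnea",
    "F. solani",
    "R. solani",
    "F. oxysporum",
    "C. capsici",
    "P. lamaensis",
    "P. theae",
    "C. eragrostidis",
    "N. sphaerica",
    "G. cingulata",
)


@dataclass(frozen=True)
class Measurement:
    """A replicate-averaged assay value: ``mean ± se`` over ``n`` replicates."""

    mean: float
    se: float = 0.0
    n: int = 3

    def __post_init__(self):
        if self.se < 0:
            raise ValidationError(f"standard error must be >= 0, got {self.se}")
        if self.n < 1:
            raise ValidationError(f"replicate count must be >= 1, got {self.n}")


@dataclass(frozen=True)
class IsolateRecord:
    """One isolate of the campaign roster."""

    isolate_id: str
    tissue: str  # "root" or "leaf"
    genus: str | None = None
    host_species: str | None = None
    morphology: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.isolate_id:
            raise ValidationError("isolate_id must be non-empty")
        if self.tissue not in ("root", "leaf"):
            raise ValidationError(
                f"tissue must be 'root' or 'leaf', got {self.tissue!r}"
            )


@dataclass(frozen=True)
class TraitProfile:
    """One isolate's PGP trait readouts.

    Quantitative traits are ``Measurement`` or ``None`` (not detected);
    binary traits are plain booleans. ``chitinase_gene`` is an optional
    PCR flag, consumed as-is.
    """

    isolate_id: str
    iaa: Measurement | None = None
    p_solub: Measurement | None = None
    ammonia: Measurement | None = None
    siderophore: Measurement | None = None
    n2_fixation: bool = False
    acc_deaminase: bool = False
    chitinase: bool = False
    protease: bool = False
    cellulase: bool = False
    pectinase: bool = False
    chitinase_gene: bool | None = None

    def __post_init__(self):
        if not self.isolate_id:
            raise ValidationError("isolate_id must be non-empty")
        for name in QUANT_TRAITS:
            m = getattr(self, name)
            if m is None:
                continue
            if m.mean < 0:
                raise ValidationError(
                    f"{self.isolate_id}: detected {name} must be >= 0, got {m.mean}"
                )
        if self.siderophore is not None and not 0 <= self.siderophore.mean <= 100:
            raise ValidationError(
                f"{self.isolate_id}: siderophore percent outside [0, 100]: "
                f"{self.siderophore.mean}"
            )

    def value(self, trait: str) -> float | None:
        """Mean of a quantitative trait, or None when not detected."""
        m = getattr(self, trait)
        return None if m is None else m.mean

    def detected(self, trait: str) -> bool:
        return getattr(self, trait) is not None


class InhibitionMatrix:
    """Isolate x pathogen percent-inhibition values; absent = no activity.

    Backed by two aligned DataFrames (means and standard errors) with NaN
    marking no-activity cells, so the pandas machinery stays available while
    the domain API speaks in isolates/pathogens.
    """

    def __init__(self, values: pd.DataFrame, errors: pd.DataFrame | None = None):
        if errors is None:
            errors = pd.DataFrame(
                np.nan, index=values.index, columns=values.columns
            )
        if not values.index.equals(errors.index) or not values.columns.equals(
            errors.columns
        ):
            raise ValidationError("value and error frames must be aligned")
        present = values.to_numpy(dtype=float)
        bad = (present < 0) | (present > 100)
        if np.any(bad & ~np.isnan(present)):
            raise ValidationError("inhibition percentages must lie in [0, 100]")
        self.values = values.astype(float)
        self.errors = errors.astype(float)

    @property
    def isolates(self) -> list[str]:
        return list(self.values.index)

    @property
    def pathogens(self) -> list[str]:
        return list(self.values.columns)

    def row(self, isolate_id: str) -> dict[str, float]:
        """Present (non-NaN) inhibition values for one isolate."""
        s = self.values.loc[isolate_id]
        return {p: float(v) for p, v in s.items() if not np.isnan(v)}

    def get(self, isolate_id: str, pathogen: str) -> float | None:
        v = self.values.at[isolate_id, pathogen]
        return None if np.isnan(v) else float(v)

    def __eq__(self, other) -> bool:
        if not isinstance(other, InhibitionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.errors.equals(other.errors)


# ---------------------------------------------------------------------------
# cell parsing


def parse_measurement(
    cell: str, *, nd_token: str = ND_TOKEN, row=None, column=None, n: int = 3
) -> Measurement | None:
    """Parse a ``"mean ± se"`` / ``"mean"`` / ND cell into a Measurement.

    Returns None for the ND token. Raises :class:`TableParseError` for any
    other non-numeric content, naming the row and column.
    """
    text = str(cell).strip()
    if text == nd_token or text.lower() == "nan":
        return None
    parts = text.replace("±", " ± ").split("±")
    try:
        mean = float(parts[0])
        se = float(parts[1]) if len(parts) > 1 else 0.0
    except (ValueError, IndexError):
        raise TableParseError(
            f"cannot parse cell {text!r} at row {row!r}, column {column!r}",
            row=row,
            column=column,
        ) from None
    return Measurement(mean=mean, se=se, n=n)


def parse_flag(cell: str, *, row=None, column=None) -> bool:
    text = str(cell).strip()
    if text == "+":
        return True
    if text in _DASH_TOKENS or text.lower() == "nan":
        return False
    raise TableParseError(
        f"cannot parse flag {text!r} at row {row!r}, column {column!r}",
        row=row,
        column=column,
    )


def _format_measurement(m: Measurement | None, nd_token: str = ND_TOKEN) -> str:
    if m is None:
        return nd_token
    if m.se:
        return f"{m.mean!s} ± {m.se!s}"
    return str(m.mean)


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# roster I/O


def read_roster(path: str | Path) -> list[IsolateRecord]:
    """Read a roster CSV (columns: isolate_id, tissue, optional genus/...)."""
    df = _read_csv(path)
    _require_columns(df, ["isolate_id", "tissue"], "roster")
    extra = [c for c in df.columns if c not in ("isolate_id", "tissue", "genus",
                                                "host_species")]
    records = []
    for _, r in df.iterrows():
        morph = {c: r[c] for c in extra if str(r[c]).strip()}
        genus = str(r["genus"]).strip() if "genus" in df.columns else ""
        host = str(r["host_species"]).strip() if "host_species" in df.columns else ""
        records.append(
            IsolateRecord(
                isolate_id=str(r["isolate_id"]).strip(),
                tissue=str(r["tissue"]).strip().lower(),
                genus=genus or None,
                host_species=host or None,
                morphology=morph,
            )
        )
    return records


def write_roster(records: Sequence[IsolateRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {"isolate_id": rec.isolate_id, "tissue": rec.tissue}
        if rec.genus:
            row["genus"] = rec.genus
        if rec.host_species:
            row["host_species"] = rec.host_species
        row.update(rec.morphology)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trait table I/O


def read_trait_table(
    path: str | Path, *, nd_token: str = ND_TOKEN
) -> list[TraitProfile]:
    """Read a trait table CSV into TraitProfiles.

    Expects the ten trait columns of the packaged fixture (an optional
    ``chitinase_gene`` column is honoured). ND cells map to None, never 0.
    """
    df = _read_csv(path)
    _require_columns(df, TRAIT_COLUMNS, "trait table")
    profiles = []
    for _, r in df.iterrows():
        iid = str(r["isolate_id"]).strip()
        quant = {
            name: parse_measurement(r[name], nd_token=nd_token, row=iid, column=name)
            for name in QUANT_TRAITS
        }
        flags = {
            name: parse_flag(r[name], row=iid, column=name) for name in BINARY_TRAITS
        }
        gene = None
        if "chitinase_gene" in df.columns and str(r["chitinase_gene"]).strip():
            gene = parse_flag(r["chitinase_gene"], row=iid, column="chitinase_gene")
        profiles.append(TraitProfile(isolate_id=iid, **quant, **flags,
                                     chitinase_gene=gene))
    return profiles


def write_trait_table(
    profiles: Sequence[TraitProfile], path: str | Path, *, nd_token: str = ND_TOKEN
) -> None:
    rows = []
    has_gene = any(p.chitinase_gene is not None for p in profiles)
    for p in profiles:
        row = {"isolate_id": p.isolate_id}
        for name in TRAIT_COLUMNS[1:]:
            if name in QUANT_TRAITS:
                row[name] = _format_measurement(getattr(p, name), nd_token)
            else:
                row[name] = "+" if getattr(p, name) else "-"
        if has_gene:
            row["chitinase_gene"] = (
                "" if p.chitinase_gene is None else ("+" if p.chitinase_gene else "-")
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# inhibition matrix I/O


def read_inhibition_matrix(path: str | Path) -> InhibitionMatrix:
    """Read an inhibition matrix CSV (first column isolate ids, one column
    per pathogen; ``-`` or empty cells mean no activity)."""
    df = _read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("inhibition matrix needs an id column and >= 1 pathogen")
    id_col = df.columns[0]
    pathogens = list(df.columns[1:])
    ids = [str(v).strip() for v in df[id_col]]
    vals = pd.DataFrame(np.nan, index=ids, columns=pathogens)
    errs = pd.DataFrame(np.nan, index=ids, columns=pathogens)
    for iid, (_, r) in zip(ids, df.iterrows()):
        for p in pathogens:
            text = str(r[p]).strip()
            if text in _DASH_TOKENS:
                continue
            m = parse_measurement(text, row=iid, column=p)
            if m is None:
                continue
            if not 0 <= m.mean <= 100:
                raise ValidationError(
                    f"{iid} / {p}: inhibition {m.mean} outside [0, 100]"
                )
            vals.at[iid, p] = m.mean
            errs.at[iid, p] = m.se
    return InhibitionMatrix(vals, errs)


def write_inhibition_matrix(matrix: InhibitionMatrix, path: str | Path) -> None:
    rows = []
    for iid in matrix.isolates:
        row = {"isolate_id": iid}
        for p in matrix.pathogens:
            v = matrix.values.at[iid, p]
            if np.isnan(v):
                row[p] = "-"
            else:
                e = matrix.errors.at[iid, p]
                row[p] = (
                    str(float(v))
                    if np.isnan(e) or e == 0
                    else f"{float(v)!s} ± {float(e)!s}"
                )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cross-table validation


@dataclass
class ValidationReport:
    """Report-based cross-table consistency check; never raises."""

    duplicate_ids: dict[str, list[str]] = field(default_factory=dict)
    missing_from: dict[str, list[str]] = field(default_factory=dict)
    out_of_range: list[str] = field(default_factory=list)
    tissue_code_mismatches: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            any(self.duplicate_ids.values())
            or any(self.missing_from.values())
            or self.out_of_range
            or self.tissue_code_mismatches
        )

    def to_dict(self) -> dict:
        return asdict(self) | {"ok": self.ok}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _dupes(ids: Sequence[str]) -> list[str]:
    seen, dup = set(), []
    for i in ids:
        if i in seen and i not in dup:
            dup.append(i)
        seen.add(i)
    return dup


def validate_roster(
    roster: Sequence[IsolateRecord] | None = None,
    traits: Sequence[TraitProfile] | None = None,
    matrix: InhibitionMatrix | None = None,
) -> ValidationReport:
    """Reconcile roster, trait table and inhibition matrix.

    Flags ids present in one table but not another, duplicate ids,
    out-of-range values, and roster tissue entries that contradict the
    isolate-code convention (3rd/4th letters RA = root, LA = leaf).
    Inconsistencies are reported, never raised.
    """
    report = ValidationReport()
    tables: dict[str, list[str]] = {}
    if roster is not None:
        tables["roster"] = [r.isolate_id for r in roster]
    if traits is not None:
        tables["traits"] = [p.isolate_id for p in traits]
    if matrix is not None:
        tables["matrix"] = list(matrix.isolates)

    for name, ids in tables.items():
        d = _dupes(ids)
        if d:
            report.duplicate_ids[name] = d
    if len(tables) > 1:
        universe = set.union(*(set(ids) for ids in tables.values()))
        for name, ids in tables.items():
            absent = sorted(universe - set(ids))
            if absent:
                report.missing_from[name] = absent

    if traits is not None:
        for p in traits:
            for t in QUANT_TRAITS:
                m = getattr(p, t)
                if m is None:
                    continue
                if m.mean < 0 or (t == "siderophore" and m.mean > 100):
                    report.out_of_range.append(f"{p.isolate_id}.{t}={m.mean}")
    if matrix is not None:
        arr = matrix.values.to_numpy()
        if np.any((arr < 0) | (arr > 100)):
            report.out_of_range.append("inhibition matrix outside [0, 100]")

    if roster is not None:
        for r in roster:
            code = r.isolate_id.upper()
            hint = None
            if "RA" in code[2:]:
                hint = "root"
            if "LA" in code[2:]:
                hint = "leaf"
            if hint is not None and hint != r.tissue:
                report.tissue_code_mismatches.append(
                    f"{r.isolate_id}: tissue {r.tissue!r} but code suggests {hint!r}"
                )
        n_root = sum(r.tissue == "root" for r in roster)
        n_leaf = sum(r.tissue == "leaf" for r in roster)
        report.notes.append(f"tissue counts: {n_root} root / {n_leaf} leaf")
    return report
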