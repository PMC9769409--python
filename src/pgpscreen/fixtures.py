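"""Loaders for the packaged screening-campaign tables.

The package ships text transcriptions of the published campaign: the
51-isolate roster, the trait table, the 51 x 10 inhibition matrix and the
published bonitur score table, plus a metadata file recording every known
internal inconsistency of the printed source (see ``fixture_metadata()``).
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from . import trait_model
from .trait_model import InhibitionMatrix, IsolateRecord, TraitProfile


def _path(name: str):
    return resources.files("pgpscreen.data").joinpath(name)


def load_roster() -> list[IsolateRecord]:
    """The packaged 51-isolate roster (morphology + tissue origin)."""
    with resources.as_file(_path("table1_roster.csv")) as p:
        return trait_model.read_roster(p)


def load_trait_table() -> list[TraitProfile]:
    """The packaged 51-isolate PGP trait table."""
    with resources.as_file(_path("table2_traits.csv")) as p:
        return trait_model.read_trait_table(p)


def load_inhibition_matrix() -> InhibitionMatrix:
    """The packaged 51 x 10 percent-inhibition matrix."""
    with resources.as_file(_path("table3_inhibition.csv")) as p:
        return trait_model.read_inhibition_matrix(p)


def load_published_scores() -> pd.DataFrame:
    """The published bonitur score table, as printed (isolate_id-indexed)."""
    with resources.as_file(_path("table4_published_scores.csv")) as p:
        return pd.read_csv(p, index_col="isolate_id")


def fixture_metadata() -> dict:
    """Provenance notes and known discrepancies of the packaged tables."""
    return json.loads(_path("fixture_metadata.json").read_text())
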