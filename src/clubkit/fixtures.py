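"""Packaged reference confusion matrices from the published clinical evaluation.

Four matrices ship with the package (names ``table6``, ``table8``,
``table10``, ``table12``); the metric suite reproduces every internally
consistent cell of the corresponding published metric tables from them.
Published cells that do *not* recompute from their own matrix (a handful of
truncated or inconsistent entries) are enumerated in the fixture metadata
and are deliberately not asserted anywhere.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .errors import ValidationError
from .evaluate import ConfusionMatrix

__all__ = ["FIXTURE_NAMES", "load_fixture", "fixture_metadata", "fixture_header"]

FIXTURE_NAMES = ("table6", "table8", "table10", "table12")


def _resource(name: str):
    return resources.files("clubkit").joinpath("data", name)


def load_fixture(name: str) -> ConfusionMatrix:
    """Load one packaged confusion matrix by name (e.g. ``table6``)."""
    if name not in FIXTURE_NAMES:
        raise ValidationError("fixture", f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    with _resource(f"{name}.csv").open("r") as fh:
        df = pd.read_csv(fh, comment="#", index_col=0)
    return ConfusionMatrix(counts=df.to_numpy(), labels=tuple(df.columns))


def fixture_header(name: str) -> str:
    """The provenance comment header of a fixture file."""
    if name not in FIXTURE_NAMES:
        raise ValidationError("fixture", f"unknown fixture {name!r}")
    lines = _resource(f"{name}.csv").read_text().splitlines()
    return "\n".join(l for l in lines if l.startswith("#"))


def fixture_metadata(name: str = None) -> dict:
    """Fixture notes, including the list of non-recomputable published cells."""
    notes = json.loads(_resource("fixture_notes.json").read_text())
    if name is None:
        return notes
    if name not in notes:
        raise ValidationError("fixture", f"unknown fixture {name!r}")
    return notes[name]
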