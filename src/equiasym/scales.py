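"""Machine-readable definitions of the four equine pain scales.

The package models four published composite pain scales for horses:

* **HGS** — Horse Grimace Scale (6 facial-expression items, scored 0-2)
* **EQUUS_FAP** — Equine Utrecht University Scale of Facial Assessment of
  Pain (9 facial items, 0-2)
* **EPS** — Equine Pain Scale (9 behavioral/facial items, 0-4)
* **CPS** — Composite Pain Scale (9 behavioral items plus 4 objectively
  measured physiological items, 0-3)

Only item identity and score ranges are modeled, not the published scoring
rubrics.  Physiological CPS items carry ``is_physiological=True`` so the
reliability analysis can exclude them (they are instrument readings, not
observer judgements).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources

import pandas as pd

SCALE_IDS = ("HGS", "EQUUS_FAP", "EPS", "CPS")

__all__ = [
    "ScaleItem",
    "SCALE_IDS",
    "load_scales",
    "load_published_w",
    "scale_index",
    "validate_scores",
]


@dataclass(frozen=True)
class ScaleItem:
    """One scorable item of a pain scale.

    Attributes
    ----------
    scale_id : str
        One of ``HGS``, ``EQUUS_FAP``, ``EPS``, ``CPS``.
    item_id : str
        Short abbreviation used in statistical outputs (e.g. ``orb`` for
        orbital tightening).  Unique within a scale.
    label : str
        Human-readable item name.
    min_score, max_score : int
        Inclusive ordinal score range; ``min_score`` is always 0.
    is_physiological : bool
        True for the CPS instrument-measured items (temperature, heart
        rate, respiratory rate, digestive sounds).
    is_behavioral : bool
        True for observer-judged behavior/facial-expression items.
    """

    scale_id: str
    item_id: str
    label: str
    min_score: int
    max_score: int
    is_physiological: bool
    is_behavioral: bool

    @property
    def column_prefix(self) -> str:
        """Prefix used for factor-encoded design columns, e.g. ``hgs_orb``."""
        scale = {"EQUUS_FAP": "fap"}.get(self.scale_id, self.scale_id.lower())
        return f"{scale}_{self.item_id}"


class ScaleConfigurationError(RuntimeError):
    """Raised when the packaged scale definition resource is malformed."""


def load_scales() -> list[ScaleItem]:
    """Load all scale items from the packaged ``scales.json`` resource.

    Returns items in scale order (HGS, EQUUS_FAP, EPS, CPS) and, within a
    scale, in published row order with physiological items last.
    """
    try:
        raw = resources.files("equiasym.data").joinpath("scales.json").read_text()
        records = json.loads(raw)
        items = [ScaleItem(**rec) for rec in records]
    except (OSError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise ScaleConfigurationError(f"bad packaged scale definitions: {exc}") from exc
    _check(items)
    return items


def _check(items: list[ScaleItem]) -> None:
    expected_max = {"HGS": 2, "EQUUS_FAP": 2, "EPS": 4, "CPS": 3}
    seen: set[tuple[str, str]] = set()
    for it in items:
        if it.scale_id not in SCALE_IDS:
            raise ScaleConfigurationError(f"unknown scale {it.scale_id!r}")
        if it.min_score != 0 or it.max_score != expected_max[it.scale_id]:
            raise ScaleConfigurationError(f"bad score range for {it.scale_id}/{it.item_id}")
        key = (it.scale_id, it.item_id)
        if key in seen:
            raise ScaleConfigurationError(f"duplicate item {key}")
        seen.add(key)


def scale_index(scales: list[ScaleItem]) -> dict[tuple[str, str], ScaleItem]:
    """Index items by ``(scale_id, item_id)``."""
    return {(it.scale_id, it.item_id): it for it in scales}


def load_published_w() -> pd.DataFrame:
    """Published inter-observer Kendall's W coefficients for the 33 behavioral
    items of the four scales, from the induced orthopedic pain study this
    package emulates.  Columns: ``scale``, ``item``, ``w``.

    These are reference inputs (e.g. for checking the agreement banding
    rule), not outputs of this package.
    """
    path = resources.files("equiasym.data").joinpath("published_kendall_w.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def validate_scores(table: pd.DataFrame, scales: list[ScaleItem]) -> list[str]:
    """Validate a long-format score table against the scale definitions.

    Parameters
    ----------
    table : DataFrame
        Long format with at least columns ``scale``, ``item``, ``score``.
    scales : list of ScaleItem

    Returns
    -------
    list of str
        One message per violation (unknown item, non-integer score, or
        score outside the item's range).  Empty iff the table is valid.
    """
    index = scale_index(scales)
    violations: list[str] = []
    for row in table.itertuples(index=False):
        key = (row.scale, row.item)
        item = index.get(key)
        if item is None:
            violations.append(f"unknown item {row.scale}/{row.item}")
            continue
        score = row.score
        if not float(score).is_integer():
            violations.append(f"non-integer score {score!r} for {row.scale}/{row.item}")
            continue
        score = int(score)
        if not item.min_score <= score <= item.max_score:
            violations.append(
                f"score {score} out of range [{item.min_score}, {item.max_score}] "
                f"for {row.scale}/{row.item}"
            )
    return violations
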