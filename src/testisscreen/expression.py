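"""Tissue-expression classification.

Two scales are used throughout the screen:

* an **absolute** eight-point ordinal scale per tissue, from ``none`` (no
  detected expression) through ``very_low`` up to ``extremely_high`` — the
  scale used by modENCODE-style tissue expression summaries;
* a **relative** category per gene with respect to a focal tissue (the
  testis): ``exclusive``, ``predominant``, ``ubiquitous`` or
  ``not_expressed``.  The four categories are mutually exclusive and
  exhaustive.

The relative rule, with its defaults, reads:

* *not expressed* — no detectable expression in the focal tissue;
* *exclusive* — expressed in the focal tissue (at any level), tolerating
  expression in a configurable set of tissues (accessory gland, imaginal
  disc) at any level plus at most ``max_other_expressed`` (default 1) other
  tissue strictly below ``side_tissue_max_level`` (default moderately high);
* *predominant* — expressed strictly higher in the focal tissue than in
  every other tissue (ties are *not* predominant);
* *ubiquitous* — everything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_sets import GeneSet

logger = logging.getLogger(__name__)


class AbsoluteLevel(IntEnum):
    """Ordinal absolute-expression level; ``NONE`` means not detected."""

    NONE = 0
    VERY_LOW = 1
    LOW = 2
    MODERATE = 3
    MODERATELY_HIGH = 4
    HIGH = 5
    VERY_HIGH = 6
    EXTREMELY_HIGH = 7


#: Accepted spellings for each ordinal level in input tables.
LEVEL_STRINGS: dict[str, AbsoluteLevel] = {
    "none": AbsoluteLevel.NONE,
    "no expression": AbsoluteLevel.NONE,
    "not expressed": AbsoluteLevel.NONE,
    "": AbsoluteLevel.NONE,
    "very low": AbsoluteLevel.VERY_LOW,
    "low": AbsoluteLevel.LOW,
    "moderate": AbsoluteLevel.MODERATE,
    "moderately high": AbsoluteLevel.MODERATELY_HIGH,
    "high": AbsoluteLevel.HIGH,
    "very high": AbsoluteLevel.VERY_HIGH,
    "extremely high": AbsoluteLevel.EXTREMELY_HIGH,
}


def parse_level(text: str) -> AbsoluteLevel:
    """Map a level string (case/underscore tolerant) to its ordinal code."""
    key = str(text).strip().lower().replace("_", " ")
    try:
        return LEVEL_STRINGS[key]
    except KeyError:
        accepted = sorted(s for s in LEVEL_STRINGS if s)
        raise ValueError(
            f"unknown expression level {text!r}; accepted: {accepted}"
        ) from None


def level_name(level: AbsoluteLevel) -> str:
    return level.name.lower().replace("_", " ")


class RelativeCategory(str, Enum):
    EXCLUSIVE = "exclusive"
    PREDOMINANT = "predominant"
    UBIQUITOUS = "ubiquitous"
    NOT_EXPRESSED = "not_expressed"


@dataclass(frozen=True)
class ClassificationRule:
    """Parameters of the relative classification with respect to one tissue.

    ``side_tissue_max_level`` is a *strict* upper bound: the one tolerated
    extra tissue must sit strictly below it.
    """

    focal_tissue: str = "testis"
    tolerated_tissues: frozenset[str] = field(
        default_factory=lambda: frozenset({"accessory_gland", "imaginal_disc"})
    )
    side_tissue_max_level: AbsoluteLevel = AbsoluteLevel.MODERATELY_HIGH
    max_other_expressed: int = 1

    def __post_init__(self) -> None:
        if self.focal_tissue in self.tolerated_tissues:
            raise ValueError("focal tissue cannot be in the tolerated set")
        if self.max_other_expressed < 0:
            raise ValueError("max_other_expressed must be >= 0")


def bin_absolute(
    value: float, thresholds: Sequence[float]
) -> AbsoluteLevel:
    """Bin a non-negative numeric value onto the eight-level ordinal scale.

    ``thresholds`` are the seven strictly increasing cutpoints between
    adjacent levels; a value below the first cutpoint is ``NONE`` and a value
    at or above the last is ``EXTREMELY_HIGH``.  Binning is monotone.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.shape != (7,):
        raise ValueError("exactly 7 cutpoints are required")
    if not np.all(np.diff(thr) > 0):
        raise ValueError("cutpoints must be strictly increasing")
    if value < 0:
        raise ValueError(f"negative expression value: {value}")
    return AbsoluteLevel(int(np.searchsorted(thr, value, side="right")))


def classify_relative(
    profile: Mapping[str, AbsoluteLevel], rule: ClassificationRule
) -> RelativeCategory:
    """Classify one gene's ordinal tissue profile into a relative category."""
    if rule.focal_tissue not in profile:
        raise ValueError(
            f"focal tissue {rule.focal_tissue!r} missing from profile"
        )
    focal = profile[rule.focal_tissue]
    if focal == AbsoluteLevel.NONE:
        return RelativeCategory.NOT_EXPRESSED
    others = {t: l for t, l in profile.items() if t != rule.focal_tissue}
    side = [
        l
        for t, l in others.items()
        if t not in rule.tolerated_tissues and l > AbsoluteLevel.NONE
    ]
    if len(side) <= rule.max_other_expressed and all(
        l < rule.side_tissue_max_level for l in side
    ):
        return RelativeCategory.EXCLUSIVE
    if all(focal > l for l in others.values()):
        return RelativeCategory.PREDOMINANT
    return RelativeCategory.UBIQUITOUS


def classify_relative_numeric(
    profile: Mapping[str, float],
    rule: ClassificationRule,
    side_threshold: float,
    detection_threshold: float = 0.0,
) -> RelativeCategory:
    """Relative classification on a numeric (EST/TPM-style) profile.

    The predominance comparison is done on the raw values (strictly higher
    in the focal tissue than anywhere else); the *exclusive* side condition
    uses ``side_threshold``, the numeric equivalent of the ordinal bound.
    """
    if rule.focal_tissue not in profile:
        raise ValueError(
            f"focal tissue {rule.focal_tissue!r} missing from profile"
        )
    focal = float(profile[rule.focal_tissue])
    if focal < 0 or any(v < 0 for v in profile.values()):
        raise ValueError("negative expression value in profile")
    if focal <= detection_threshold:
        return RelativeCategory.NOT_EXPRESSED
    others = {t: v for t, v in profile.items() if t != rule.focal_tissue}
    side = [
        v
        for t, v in others.items()
        if t not in rule.tolerated_tissues and v > detection_threshold
    ]
    if len(side) <= rule.max_other_expressed and all(
        v < side_threshold for v in side
    ):
        return RelativeCategory.EXCLUSIVE
    if all(focal > v for v in others.values()):
        return RelativeCategory.PREDOMINANT
    return RelativeCategory.UBIQUITOUS


def octile_cutpoints(values: np.ndarray) -> np.ndarray:
    """Default numeric→ordinal cutpoints: octiles of the positive values."""
    pos = np.asarray(values, dtype=float)
    pos = pos[pos > 0]
    if pos.size == 0:
        raise ValueError("no positive values to calibrate cutpoints from")
    qs = np.quantile(pos, np.arange(1, 8) / 8.0)
    # enforce strict increase for degenerate (heavily tied) inputs
    eps = max(1e-9, 1e-9 * float(qs[-1]))
    for i in range(1, 7):
        if qs[i] <= qs[i - 1]:
            qs[i] = qs[i - 1] + eps
    return qs


def classify_table(table, rule: ClassificationRule) -> pd.Series:
    """Relative category for every gene of an expression table.

    Accepts either dialect: ordinal tables are classified on their level
    codes, numeric tables via :func:`classify_relative_numeric` with
    octile-calibrated side threshold.
    """
    df = table.values
    if rule.focal_tissue not in df.columns:
        raise ValueError(
            f"focal tissue {rule.focal_tissue!r} missing from table"
        )
    if table.dialect == "ordinal":
        cats = {
            g: classify_relative(
                {t: AbsoluteLevel(int(v)) for t, v in row.items()}, rule
            ).value
            for g, row in df.iterrows()
        }
    else:
        cut = octile_cutpoints(df.to_numpy())
        side_thr = float(cut[int(rule.side_tissue_max_level) - 1])
        cats = {
            g: classify_relative_numeric(row.to_dict(), rule, side_thr).value
            for g, row in df.iterrows()
        }
    return pd.Series(cats, name="relative_category")


def meets_absolute_cutoff(
    profile: Mapping[str, AbsoluteLevel],
    min_level: AbsoluteLevel,
    focal_tissue: str = "testis",
) -> bool:
    """True iff the focal-tissue absolute level is at or above ``min_level``."""
    if focal_tissue not in profile:
        raise ValueError(f"focal tissue {focal_tissue!r} missing from profile")
    return profile[focal_tissue] >= min_level


def screen_source_species(table, rule: ClassificationRule) -> GeneSet:
    """Screen a numeric expression table for focal-tissue biased genes.

    Returns the genes classified *exclusive* or *predominant* with respect
    to the rule's focal tissue — the source-species entry point of the
    comparative screen (e.g. the EST-profile screen for testis-biased
    genes).
    """
    if table.dialect != "numeric":
        raise ValueError("source screening requires a numeric-dialect table")
    if len(table.values) == 0:
        logger.warning("screen_source_species: empty expression table")
        return GeneSet(
            label="source_screen",
            members=frozenset(),
            species=table.species,
        )
    cats = classify_table(table, rule)
    keep = cats[
        cats.isin(
            [RelativeCategory.EXCLUSIVE.value, RelativeCategory.PREDOMINANT.value]
        )
    ].index
    base = GeneSet(
        label="all_genes",
        members=frozenset(table.values.index),
        species=table.species,
    )
    return base.derive(
        "source_screen",
        frozenset(keep),
        operation="screen_source_species",
        params={
            "focal_tissue": rule.focal_tissue,
            "n_exclusive": int((cats == RelativeCategory.EXCLUSIVE.value).sum()),
            "n_predominant": int(
                (cats == RelativeCategory.PREDOMINANT.value).sum()
            ),
        },
    )
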