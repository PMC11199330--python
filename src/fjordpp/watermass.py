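"""T-S water-mass classification for Svalbard fjords.

Each observation (T, S) is assigned to the first matching box of a
priority-ordered ruleset in the Cottier-type fjord taxonomy:

    SW   surface water            S < 34.00 and T > 1 degC
    AW   Atlantic Water
    TAW  Transformed Atlantic Water
    IW   Intermediate Water
    ArW  Arctic Water
    LW   Local Water

Only the SW box is fixed by observation-based definition (glacier-meltwater
influenced surface layer); the remaining boundaries follow the published
classification scheme and ship as an editable CSV table
(``data/watermass_rules.csv``) — fjord literature revises these boxes, so
they are configuration, not code.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .profiles import Cast

__all__ = ["WaterMassRule", "default_ruleset", "load_ruleset", "classify", "classify_cast"]

UNCLASSIFIED = "Unclassified"


class WaterMassError(ValueError):
    pass


@dataclass(frozen=True)
class WaterMassRule:
    """One rectangular T-S box with explicit boundary inclusivity."""

    label: str
    priority: int
    t_min: float = -math.inf
    t_max: float = math.inf
    s_min: float = -math.inf
    s_max: float = math.inf
    t_min_inc: bool = True
    t_max_inc: bool = True
    s_min_inc: bool = True
    s_max_inc: bool = True

    def __post_init__(self) -> None:
        if self.t_min >= self.t_max or self.s_min >= self.s_max:
            raise WaterMassError(f"degenerate box for {self.label}")

    def matches(self, t: float, s: float) -> bool:
        ok_t = (t >= self.t_min if self.t_min_inc else t > self.t_min) and (
            t <= self.t_max if self.t_max_inc else t < self.t_max
        )
        ok_s = (s >= self.s_min if self.s_min_inc else s > self.s_min) and (
            s <= self.s_max if self.s_max_inc else s < self.s_max
        )
        return ok_t and ok_s


def _rules_from_frame(df: pd.DataFrame) -> list[WaterMassRule]:
    required = {"label", "priority"}
    if not required.issubset(df.columns):
        raise WaterMassError(f"ruleset table missing columns {sorted(required - set(df.columns))}")
    rules = []
    for _, row in df.iterrows():
        def bound(col: str, default: float) -> float:
            v = row.get(col)
            return default if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        def inc(col: str) -> bool:
            v = row.get(col)
            return True if v is None or (isinstance(v, float) and math.isnan(v)) else bool(int(v))

        rules.append(
            WaterMassRule(
                label=str(row["label"]),
                priority=int(row["priority"]),
                t_min=bound("t_min", -math.inf),
                t_max=bound("t_max", math.inf),
                s_min=bound("s_min", -math.inf),
                s_max=bound("s_max", math.inf),
                t_min_inc=inc("t_min_inc"),
                t_max_inc=inc("t_max_inc"),
                s_min_inc=inc("s_min_inc"),
                s_max_inc=inc("s_max_inc"),
            )
        )
    rules.sort(key=lambda r: r.priority)
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise WaterMassError("rule priorities must be distinct")
    return rules


def load_ruleset(path) -> list[WaterMassRule]:
    """Load a ruleset from a delimited-text table (see data/watermass_rules.csv)."""
    return _rules_from_frame(pd.read_csv(path))


def default_ruleset() -> list[WaterMassRule]:
    """The packaged fjord taxonomy (SW box per definition, others configurable)."""
    with resources.files("fjordpp.data").joinpath("watermass_rules.csv").open("rb") as fh:
        return _rules_from_frame(pd.read_csv(fh))


def classify(temperature_C: float, salinity_psu: float,
             ruleset: list[WaterMassRule] | None = None) -> str:
    """Label for one (T, S) observation: first matching box in priority order,
    ``Unclassified`` when no box matches."""
    if not (math.isfinite(temperature_C) and math.isfinite(salinity_psu)):
        raise WaterMassError("non-finite T or S")
    for rule in ruleset if ruleset is not None else default_ruleset():
        if rule.matches(temperature_C, salinity_psu):
            return rule.label
    return UNCLASSIFIED


def classify_cast(cast: Cast, ruleset: list[WaterMassRule] | None = None
                  ) -> tuple[list[str], Counter]:
    """Per-level labels plus the cast's label inventory (label -> level count)."""
    rules = ruleset if ruleset is not None else default_ruleset()
    labels = [classify(lv.temperature_C, lv.salinity_psu, rules) for lv in cast.levels]
    return labels, Counter(labels)
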