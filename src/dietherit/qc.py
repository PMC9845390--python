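"""Per-questionnaire credibility filters and item encoding.

A 24HR record is kept only if it reports a credible total energy intake
(>= 1,000 kJ and <= 20 MJ for males / 18 MJ for females), describes typical
diet, was completed, took at least 5 minutes, and the respondent was neither
pregnant nor diagnosed with cancer within the preceding year. Exclusion
counts are attributed to the first failing rule in a fixed order; the
retained set does not depend on that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class QCConfig:
    """Thresholds and switches for the per-questionnaire credibility filters."""

    energy_min_kj: float = 1_000.0
    energy_max_kj_male: float = 20_000.0
    energy_max_kj_female: float = 18_000.0
    min_duration_min: float = 5.0
    require_typical_diet: bool = True
    require_completion: bool = True
    exclude_pregnancy: bool = True
    exclude_cancer: bool = True

    def __post_init__(self) -> None:
        if not (self.energy_min_kj < self.energy_max_kj_male
                and self.energy_min_kj < self.energy_max_kj_female):
            raise ValueError("energy_min_kj must be below both sex-specific maxima")
        if self.min_duration_min < 0:
            raise ValueError("min_duration_min must be non-negative")


# first-failure attribution order (mirrors how the rules are usually listed);
# affects only the report, never the retained set
RULE_ORDER = (
    "energy_low",
    "energy_high",
    "typical_diet",
    "duration",
    "completion",
    "pregnancy",
    "cancer",
)


@dataclass
class QCReport:
    """Per-rule first-failure exclusion counts plus before/after totals."""

    excluded_by_rule: dict[str, int]
    records_in: int
    records_out: int
    individuals_out: int

    def __post_init__(self) -> None:
        if self.records_out > self.records_in:
            raise ValueError("records_out cannot exceed records_in")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "excluded": self.excluded_by_rule.get(r, 0)} for r in RULE_ORDER]
        rows.append({"rule": "records_in", "excluded": self.records_in})
        rows.append({"rule": "records_out", "excluded": self.records_out})
        rows.append({"rule": "individuals_out", "excluded": self.individuals_out})
        return pd.DataFrame(rows)


@dataclass
class ItemDefinition:
    """How a raw questionnaire column maps to analysis item columns.

    ``binary`` and ``continuous`` items pass through; a ``categorical`` item
    expands each response option into its own 1/0 column, optionally with
    combined columns that are 1 when any of a set of options applies (e.g. a
    vegetarian-or-vegan column over the vegetarian and vegan options).
    """

    item_id: str
    kind: str
    options: list[str] = field(default_factory=list)
    combined: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous", "categorical"):
            raise ValueError(f"unknown item kind {self.kind!r}")
        if self.kind == "categorical" and len(self.options) < 1:
            raise ValueError("categorical items must list at least one option")


def filter_questionnaires(
    q: pd.DataFrame, sex: pd.Series, cfg: QCConfig | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the credibility filters record-wise; return retained records + report.

    ``sex`` maps individual id to 1 (male) / 0 (female). All thresholds are
    inclusive as stated (>=, <=): a 5-minute questionnaire passes, a
    1,000 kJ energy passes, a 20,000 kJ male record passes.
    """
    cfg = cfg if cfg is not None else QCConfig()
    if q.empty:
        report = QCReport({r: 0 for r in RULE_ORDER}, 0, 0, 0)
        return q.copy(), report

    missing = set(q["iid"]) - set(sex.index)
    if missing:
        raise KeyError(f"no sex record for individual(s): {sorted(missing)[:5]}")

    s = sex.reindex(q["iid"]).to_numpy()
    energy = q["energy_kj"].to_numpy(dtype=float)
    emax = np.where(s == 1, cfg.energy_max_kj_male, cfg.energy_max_kj_female)

    fails = {
        "energy_low": energy < cfg.energy_min_kj,
        "energy_high": energy > emax,
        "typical_diet": (q["typical_diet"].to_numpy() == 0)
        if cfg.require_typical_diet else np.zeros(len(q), bool),
        "duration": q["duration_min"].to_numpy(dtype=float) < cfg.min_duration_min,
        "completion": (q["completed"].to_numpy() == 0)
        if cfg.require_completion else np.zeros(len(q), bool),
        "pregnancy": (q["pregnant_recent"].to_numpy() == 1)
        if cfg.exclude_pregnancy else np.zeros(len(q), bool),
        "cancer": (q["cancer_recent"].to_numpy() == 1)
        if cfg.exclude_cancer else np.zeros(len(q), bool),
    }

    any_fail = np.zeros(len(q), dtype=bool)
    counts: dict[str, int] = {}
    for rule in RULE_ORDER:
        first_fail = fails[rule] & ~any_fail
        counts[rule] = int(first_fail.sum())
        any_fail |= fails[rule]

    kept = q.loc[~any_fail].copy()
    report = QCReport(
        excluded_by_rule=counts,
        records_in=len(q),
        records_out=len(kept),
        individuals_out=kept["iid"].nunique(),
    )
    return kept, report


def encode_items(q: pd.DataFrame, items: list[ItemDefinition]) -> pd.DataFrame:
    """Convert raw item columns into the analysis item matrix.

    Binary items emit 1/0 (absence of a response within a completed
    questionnaire counts as not consumed); each categorical response option
    becomes its own 1/0 column named ``itemID.option``; continuous quantities
    pass through unchanged.
    """
    out = q[["iid", "qidx"]].copy()
    for item in items:
        if item.kind == "binary":
            col = q[item.item_id] if item.item_id in q else pd.Series(0, index=q.index)
            out[item.item_id] = col.fillna(0).astype(int).clip(0, 1)
        elif item.kind == "continuous":
            out[item.item_id] = q[item.item_id].fillna(0.0).astype(float)
        elif item.kind == "categorical":
            raw = q[item.item_id].astype("string")
            for opt in item.options:
                out[f"{item.item_id}.{opt}"] = (raw == opt).astype(int)
            for name, opts in item.combined.items():
                out[f"{item.item_id}.{name}"] = raw.isin(opts).astype(int)
        else:  # pragma: no cover - guarded in ItemDefinition
            raise ValueError(f"unknown item kind {item.kind!r}")
    return out
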