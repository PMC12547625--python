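"""Cohort-level quality-control exclusions on a participant table.

Rules are applied sequentially, each within the sub-cohort still eligible
for that modality, which mirrors how imaging cohorts report per-modality
exclusion counts.  Percentile thresholds ("top 1% motion") are computed
in-table per invocation with the "higher" interpolation convention, so "top
1%" means metric >= the 99th percentile; missing values never trip a
percentile rule and are tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError

__all__ = ["QcRule", "QcReport", "DEFAULT_RULES", "apply_exclusions", "load_rules"]

_OPS = ("top_percent", "less_than", "greater_equal", "flag")


@dataclass(frozen=True)
class QcRule:
    """One exclusion rule: a column, an operator, and a value.

    Operators:
      * ``top_percent``: exclude rows with metric >= the in-table
        (100 - value)th percentile ("higher" interpolation).
      * ``less_than`` / ``greater_equal``: exclude rows where the column is
        < / >= the fixed threshold.
      * ``flag``: exclude rows where the boolean column is truthy.
    """

    name: str
    column: str
    op: str
    value: float | None = None

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ConfigError(f"rule {self.name!r}: unknown op {self.op!r}")
        if self.op != "flag" and self.value is None:
            raise ConfigError(f"rule {self.name!r}: op {self.op!r} needs a value")


#: the published exclusion sequence: T1 motion top 1% -> DWI motion top 1%
#: -> CSF-voxel minimum -> negative coupling -> fMRI motion top 1%
DEFAULT_RULES = (
    QcRule("t1_motion_top1pct", "t1_motion", "top_percent", 1.0),
    QcRule("dwi_motion_top1pct", "dwi_motion", "top_percent", 1.0),
    QcRule("csf_voxels_min5", "csf_voxel_count", "less_than", 5.0),
    QcRule("negative_coupling", "coupling", "less_than", 0.0),
    QcRule("fmri_motion_top1pct", "fmri_motion", "top_percent", 1.0),
)


@dataclass
class QcReport:
    n_input: int
    n_survivors: int
    per_rule_excluded: dict  # rule name -> count
    per_rule_missing: dict  # rule name -> count of missing values seen
    thresholds: dict  # rule name -> numeric threshold actually applied
    hits: pd.DataFrame  # boolean hit matrix, index = participant order

    def to_dict(self) -> dict:
        return {
            "n_input": int(self.n_input),
            "n_survivors": int(self.n_survivors),
            "per_rule_excluded": {k: int(v) for k, v in self.per_rule_excluded.items()},
            "per_rule_missing": {k: int(v) for k, v in self.per_rule_missing.items()},
            "thresholds": {k: float(v) for k, v in self.thresholds.items()},
        }


def _percentile_higher(values: np.ndarray, q: float) -> float:
    """Quantile with the 'higher' convention: smallest value >= the quantile."""
    return float(np.quantile(values, q / 100.0, method="higher"))


def apply_exclusions(
    table: pd.DataFrame, rules=DEFAULT_RULES
) -> tuple[pd.DataFrame, QcReport]:
    """Apply exclusion rules sequentially and return survivors plus a report.

    Percentile rules compute their threshold on the non-missing values of
    the rows still eligible when the rule runs.  The report tallies
    per-rule exclusions, missing values, and the thresholds actually used,
    so a rerun on the same table is fully reproducible.
    """
    if len(table) == 0:
        raise ValidationError("participant table is empty")
    for rule in rules:
        if rule.column not in table.columns:
            raise ConfigError(
                f"rule {rule.name!r} references unknown column {rule.column!r}"
            )

    eligible = np.ones(len(table), dtype=bool)
    hits = pd.DataFrame(False, index=table.index, columns=[r.name for r in rules])
    per_rule_excluded: dict[str, int] = {}
    per_rule_missing: dict[str, int] = {}
    thresholds: dict[str, float] = {}

    for rule in rules:
        col = table[rule.column]
        missing = col.isna().to_numpy()
        per_rule_missing[rule.name] = int((missing & eligible).sum())
        vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float) if rule.op != "flag" else None

        if rule.op == "top_percent":
            pool = vals[eligible & ~missing]
            if pool.size == 0:
                thresholds[rule.name] = float("nan")
                per_rule_excluded[rule.name] = 0
                continue
            thr = _percentile_higher(pool, 100.0 - float(rule.value))
            hit = eligible & ~missing & (vals >= thr)
            thresholds[rule.name] = thr
        elif rule.op == "less_than":
            hit = eligible & ~missing & (vals < float(rule.value))
            thresholds[rule.name] = float(rule.value)
        elif rule.op == "greater_equal":
            hit = eligible & ~missing & (vals >= float(rule.value))
            thresholds[rule.name] = float(rule.value)
        else:  # flag
            truthy = col.fillna(False).astype(bool).to_numpy()
            hit = eligible & truthy
            thresholds[rule.name] = 1.0

        hits.loc[hit, rule.name] = True
        per_rule_excluded[rule.name] = int(hit.sum())
        eligible &= ~hit

    survivors = table.loc[eligible].copy()
    report = QcReport(
        n_input=len(table),
        n_survivors=int(eligible.sum()),
        per_rule_excluded=per_rule_excluded,
        per_rule_missing=per_rule_missing,
        thresholds=thresholds,
        hits=hits,
    )
    return survivors, report


def load_rules(path) -> tuple[QcRule, ...]:
    """Load QC rules from YAML: a list of {name, column, op, value} mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ConfigError(f"{path}: rules file must be a YAML list")
    rules = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict):
            raise ConfigError(f"{path}: rule #{i} is not a mapping")
        try:
            rules.append(
                QcRule(
                    name=str(entry.get("name", f"rule_{i}")),
                    column=entry["column"],
                    op=entry["op"],
                    value=entry.get("value"),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: rule #{i} missing key {exc}") from exc
    return tuple(rules)
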