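"""The molecule feature table and the group-comparison statistic.

A :class:`FeatureTable` is a pandas DataFrame of named numeric features
(3D PSA, tPSA, counts, chromatography measurements, multiparameter scores)
with a three-level class label per molecule: CNS-positive (penetrates the
blood-brain barrier), CNS-negative, or efflux-transporter substrate/
inhibitor.  Missing cells are allowed and handled downstream by the ML
pipeline.

``group_compare`` reproduces the normality-gated test choice used for the
per-class descriptor comparisons: Shapiro-Wilk on each group at alpha 0.05;
a two-sided two-sample t-test when both groups look normal, otherwise a
two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import SampleSizeError, SchemaError

__all__ = [
    "ALLOWED_LABELS",
    "FeatureTable",
    "GroupComparison",
    "read_feature_table",
    "write_feature_table",
    "class_summary",
    "group_compare",
]

ALLOWED_LABELS = ("cns_pos", "cns_neg", "efflux")
NORMALITY_ALPHA = 0.05

DEFAULT_SCHEMA: dict = {
    # best-effort aliases for deposited-style column headers
    "column_map": {
        "3D PSA": "psa3d",
        "3D_PSA": "psa3d",
        "PSA (ACD)": "psa_acd",
        "PSA_ACD": "psa_acd",
        "tPSA": "tpsa",
        "TPSA": "tpsa",
        "MW": "mw",
        "HBD": "hbd",
        "HBA": "hba",
        "BBB score": "bbb_score",
        "CNS MPO": "cns_mpo",
        "CNS MPO PET": "cns_mpo_pet",
        "class": "label",
        "Class": "label",
        "target": "label",
    },
    "label_map": {
        "CNS+": "cns_pos",
        "CNS-": "cns_neg",
        "CNS positive": "cns_pos",
        "CNS negative": "cns_neg",
        "efflux transporter": "efflux",
        "Efflux": "efflux",
    },
    "missing_tokens": ["", "NA", "N/A", "NaN", "nan", "None", "-"],
}


@dataclass
class FeatureTable:
    """Molecules x features plus a class label column.

    ``data`` is indexed by unique molecule ids; ``label_column`` holds
    values from :data:`ALLOWED_LABELS`; every other numeric column is a
    feature.
    """

    data: pd.DataFrame
    label_column: str = "label"

    def __post_init__(self) -> None:
        if self.label_column not in self.data.columns:
            raise SchemaError(f"missing label column {self.label_column!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate molecule ids: {dupes}")
        bad = set(self.data[self.label_column].dropna()) - set(ALLOWED_LABELS)
        if bad:
            raise SchemaError(f"unknown class label(s): {sorted(bad)}")
        if not self.feature_columns:
            raise SchemaError("table has no feature columns")

    @property
    def feature_columns(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if c != self.label_column and pd.api.types.is_numeric_dtype(self.data[c])
        ]

    @property
    def labels(self) -> pd.Series:
        return self.data[self.label_column]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a normality-gated two-group comparison."""

    feature: str
    group_a: str
    group_b: str
    test: str  # "t_test" or "mann_whitney_u"
    statistic: float
    p_value: float
    normality_p: dict[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _apply_schema(df: pd.DataFrame, schema: Mapping) -> pd.DataFrame:
    df = df.rename(columns=dict(schema.get("column_map", {})))
    label_map = dict(schema.get("label_map", {}))
    if "label" in df.columns and label_map:
        df["label"] = df["label"].replace(label_map)
    return df


def read_feature_table(
    path: str | Path,
    schema: Mapping | str | Path | None = None,
    id_column: str | None = None,
) -> FeatureTable:
    """Read a CSV feature table, resolving column/label aliases via the
    schema map and turning missing tokens into NaN.

    ``schema`` may be a mapping or a path to a YAML file with keys
    ``column_map``, ``label_map`` and ``missing_tokens``.
    """
    if isinstance(schema, (str, Path)):
        with open(schema, encoding="utf-8") as fh:
            schema = yaml.safe_load(fh)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(
        path, na_values=list(schema.get("missing_tokens", [])), keep_default_na=True
    )
    df = _apply_schema(df, schema)
    if id_column is None:
        id_column = next((c for c in ("id", "molecule", "name") if c in df.columns), None)
    if id_column is not None:
        if df[id_column].duplicated().any():
            raise SchemaError(f"duplicate ids in column {id_column!r}")
        df = df.set_index(id_column)
    if "label" not in df.columns:
        raise SchemaError("no label column after alias resolution")
    feature_cols = [c for c in df.columns if c != "label"]
    df[feature_cols] = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    return FeatureTable(data=df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.data.to_csv(path, index=True, index_label="id")


def class_summary(table: FeatureTable) -> pd.DataFrame:
    """Per-class counts and percentages (1 decimal), e.g. 68/154 -> 44.2."""
    if len(table) == 0:
        raise SchemaError("empty table")
    counts = table.labels.value_counts()
    out = pd.DataFrame({"count": counts})
    out["percent"] = (100.0 * out["count"] / len(table)).round(1)
    return out


def group_compare(
    table: FeatureTable, feature: str, label_a: str, label_b: str
) -> GroupComparison:
    """Compare ``feature`` between two classes.

    Shapiro-Wilk tests each group at alpha 0.05; only when *both* groups
    pass is a two-sided two-sample t-test used, otherwise a two-sided
    Mann-Whitney U.  Requires >= 3 non-missing values per group.
    """
    if feature not in table.feature_columns:
        raise SchemaError(f"unknown feature {feature!r}")
    groups = {}
    for label in (label_a, label_b):
        vals = table.data.loc[table.labels == label, feature].dropna().to_numpy(float)
        if len(vals) < 3:
            raise SampleSizeError(
                f"group {label!r} has {len(vals)} non-missing values for {feature!r}; need >= 3"
            )
        groups[label] = vals
    a, b = groups[label_a], groups[label_b]
    norm_p = {lab: float(stats.shapiro(v).pvalue) for lab, v in groups.items()}
    if all(p > NORMALITY_ALPHA for p in norm_p.values()):
        res = stats.ttest_ind(a, b, alternative="two-sided")
        test = "t_test"
    else:
        # exact null distribution for small samples without ties, normal
        # approximation with tie correction otherwise
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        test = "mann_whitney_u"
    return GroupComparison(
        feature=feature,
        group_a=label_a,
        group_b=label_b,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=norm_p,
    )
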