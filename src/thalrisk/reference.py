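"""Loaders for the small reference tables packaged with thalrisk.

These are the worked-example artifacts of the AHP-TOPSIS risk framework:
a 10-record cohort excerpt, the 10x10 expert pairwise-comparison judgments,
the published criterion weights, a min-max normalized decision-matrix
excerpt, and the corresponding relative-closeness/risk-category excerpt.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .schema import Cohort, default_schema, read_cohort


def _path(name: str):
    return resources.files("thalrisk.fixtures").joinpath(name)


def load_table3_cohort() -> Cohort:
    """10-record patient/blood-test excerpt under the 16-feature schema."""
    with resources.as_file(_path("table3_cohort.csv")) as p:
        return read_cohort(p, default_schema())


def load_table7_judgments():
    """Expert pairwise judgments over the ten AHP criteria (long form)."""
    from .ahp import PairwiseJudgments

    with resources.as_file(_path("table7_pairwise.csv")) as p:
        return PairwiseJudgments.from_long_csv(p)


def load_table9_weights() -> pd.Series:
    """Published AHP criterion weights (4-decimal rounding)."""
    with resources.as_file(_path("table9_weights.csv")) as p:
        df = pd.read_csv(p)
    return pd.Series(df["weight"].values, index=df["feature"].values, name="weight")


def load_table10_normalized() -> pd.DataFrame:
    """Min-max normalized decision-matrix excerpt (10 samples x 10 criteria)."""
    with resources.as_file(_path("table10_normalized.csv")) as p:
        return pd.read_csv(p, index_col="entry")


def load_table11_closeness() -> pd.DataFrame:
    """Published relative closeness, rank and risk category excerpt."""
    with resources.as_file(_path("table11_closeness.csv")) as p:
        return pd.read_csv(p, index_col="id")
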