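"""Synthetic survey-cohort generator.

Emulates the statistical structure the risk framework assumes: a
two-population mixture of thalassemia carriers and non-carriers in which
carriers show the classic trait phenotype — microcytosis (low MCV, low
MCH), elevated RDW and RBC count, mildly reduced hemoglobin and
hematocrit — while demographics are shared.  Hereditary flags (family
history, genetic marker) are enriched in carriers.

Continuous features are drawn from bounded normals: a per-patient latent
erythropoietic factor induces the strong positive correlation that CBC
indices show in real blood counts (Hct, Hb and RBC are arithmetically
linked; RDW moves opposite), each feature adds independent noise, and
draws are clipped to wide clinical bounds.  Categorical features come from
explicit probability tables.

Randomness uses one root seed with per-feature substreams keyed on the
feature name, so adding a feature leaves the draws of the others unchanged.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .schema import Cohort, FeatureSchema, default_schema

GROUPS = ("non_carrier", "carrier")


@dataclass(frozen=True)
class NumericDist:
    """Bounded-normal parameters for one feature in one group.

    ``latent_loading`` is the correlation of the feature with the shared
    latent hematologic factor (0 = independent; negative = moves opposite).
    """

    mean: float
    sd: float
    minimum: float
    maximum: float
    latent_loading: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError(f"sd must be >= 0, got {self.sd}")
        if not (self.minimum <= self.mean <= self.maximum):
            raise ConfigError(
                f"need min <= mean <= max, got {self.minimum}, {self.mean}, {self.maximum}"
            )
        if not (-1.0 <= self.latent_loading <= 1.0):
            raise ConfigError("latent_loading must lie in [-1, 1]")


@dataclass(frozen=True)
class CohortGenSpec:
    """Full parameterization of the synthetic cohort."""

    n: int
    seed: int
    carrier_prevalence: float
    numeric: dict[str, dict[str, NumericDist]]  # feature -> group -> dist
    categorical: dict[str, dict[str, float]]  # feature -> level -> prob (non-carrier)
    #: carrier odds multipliers applied to the hereditary "Yes" levels
    family_history_enrichment: float = 4.0
    genetic_marker_enrichment: float = 30.0
    integer_features: tuple[str, ...] = ("Age", "Parity")

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError(f"n must be >= 0, got {self.n}")
        if not (0.0 <= self.carrier_prevalence <= 1.0):
            raise ConfigError("carrier_prevalence must lie in [0, 1]")
        for feat, table in self.categorical.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{feat!r} category probabilities sum to {total}")
        for feat, groups in self.numeric.items():
            for g in groups:
                if g not in GROUPS:
                    raise ConfigError(f"{feat!r}: unknown group {g!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def default_spec(n: int = 1000, seed: int = 0) -> CohortGenSpec:
    """Default generator settings.

    Carrier prevalence 0.20 reflects the enriched antenatal screening
    context the framework targets (and the carrier fraction of the packaged
    worked-example records).  Hematologic group means encode the carrier
    trait phenotype: MCV 66 vs 82 fL, MCH 21 vs 27 pg, RDW 16 vs 13.5 %,
    RBC 5.4 vs 4.6 M/uL, Hb 10.2 vs 11.3 g/dL.  Latent loadings mirror the
    physiologic coupling of the red-cell indices.  Bounds are wide clinical
    ranges covering all values seen in the worked-example records.
    """
    d = NumericDist
    numeric = {
        "Age": {
            "non_carrier": d(27.0, 6.5, 15.0, 45.0),
            "carrier": d(27.0, 6.5, 15.0, 45.0),
        },
        "BMI": {
            "non_carrier": d(23.0, 3.5, 14.0, 40.0),
            "carrier": d(23.0, 3.5, 14.0, 40.0),
        },
        "Hemoglobin_Level": {
            "non_carrier": d(11.3, 1.2, 6.5, 16.0, latent_loading=0.80),
            "carrier": d(10.2, 1.1, 6.5, 16.0, latent_loading=0.80),
        },
        "Parity": {
            "non_carrier": d(1.6, 1.4, 0.0, 8.0),
            "carrier": d(1.6, 1.4, 0.0, 8.0),
        },
        "Hct": {
            "non_carrier": d(34.0, 3.2, 22.0, 48.0, latent_loading=0.85),
            "carrier": d(31.5, 3.0, 22.0, 48.0, latent_loading=0.85),
        },
        "MCV": {
            "non_carrier": d(82.0, 5.0, 55.0, 110.0, latent_loading=0.60),
            "carrier": d(66.0, 5.0, 55.0, 110.0, latent_loading=0.60),
        },
        "MCH": {
            "non_carrier": d(27.0, 2.5, 14.0, 36.0, latent_loading=0.70),
            "carrier": d(21.0, 2.2, 14.0, 36.0, latent_loading=0.70),
        },
        "MCHC": {
            "non_carrier": d(32.5, 1.2, 27.0, 38.0, latent_loading=0.45),
            "carrier": d(31.2, 1.2, 27.0, 38.0, latent_loading=0.45),
        },
        "RDW": {
            "non_carrier": d(13.5, 1.3, 10.0, 22.0, latent_loading=-0.35),
            "carrier": d(16.0, 1.6, 10.0, 22.0, latent_loading=-0.35),
        },
        "RBC_Count": {
            "non_carrier": d(4.6, 0.5, 2.5, 7.5, latent_loading=0.50),
            "carrier": d(5.4, 0.5, 2.5, 7.5, latent_loading=0.50),
        },
    }
    categorical = {
        "Family_History_Thalassemia": {"No": 0.85, "Yes": 0.15},
        "Genetic_Marker_Presence": {"No": 0.97, "Yes": 0.03},
        "Socioeconomic_Status": {"Low": 0.40, "Middle": 0.45, "High": 0.15},
        "Education_Level": {
            "No formal education": 0.10,
            "Primary": 0.25,
            "Secondary": 0.35,
            "Higher Secondary": 0.20,
            "Graduate": 0.10,
        },
        "Residence": {"Urban": 0.45, "Rural": 0.55},
    }
    return CohortGenSpec(
        n=n,
        seed=seed,
        carrier_prevalence=0.20,
        numeric=numeric,
        categorical=categorical,
    )


def _feature_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-feature substream keyed on the feature name."""
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(name.encode()))))


def _enriched_prob(p_yes: float, odds_multiplier: float) -> float:
    odds = p_yes / (1.0 - p_yes) * odds_multiplier
    return odds / (1.0 + odds)


def generate(spec: CohortGenSpec, schema: FeatureSchema | None = None) -> Cohort:
    """Draw a cohort of ``spec.n`` records under the default schema."""
    schema = schema or default_schema()
    n = spec.n

    carrier_rng = _feature_rng(spec.seed, "Carrier_Status")
    is_carrier = carrier_rng.random(n) < spec.carrier_prevalence
    latent = _feature_rng(spec.seed, "__latent__").standard_normal(n)

    data: dict[str, object] = {}
    for fs in schema:
        name = fs.name
        if name == "Carrier_Status":
            data[name] = np.where(is_carrier, fs.levels[1], fs.levels[0]).astype(object)
            continue
        rng = _feature_rng(spec.seed, name)
        if fs.kind == "numeric":
            dists = spec.numeric[name]
            eps = rng.standard_normal(n)
            vals = np.empty(n)
            for grp, mask in (("non_carrier", ~is_carrier), ("carrier", is_carrier)):
                d = dists.get(grp, dists["non_carrier"])
                if not mask.any():
                    continue
                rho = d.latent_loading
                noise = rho * latent[mask] + np.sqrt(1.0 - rho**2) * eps[mask]
                vals[mask] = np.clip(d.mean + d.sd * noise, d.minimum, d.maximum)
            if name in spec.integer_features:
                vals = np.round(vals)
            data[name] = vals
        else:
            table = spec.categorical[name]
            levels = list(fs.levels)
            probs = np.array([table[lvl] for lvl in levels])
            u = rng.random(n)
            draws = np.asarray(levels, dtype=object)[
                np.searchsorted(np.cumsum(probs), u, side="right").clip(max=len(levels) - 1)
            ]
            # hereditary flags are enriched among carriers
            enrich = {
                "Family_History_Thalassemia": spec.family_history_enrichment,
                "Genetic_Marker_Presence": spec.genetic_marker_enrichment,
            }.get(name)
            if enrich is not None and is_carrier.any():
                p_car = _enriched_prob(table["Yes"], enrich)
                draws = draws.copy()
                draws[is_carrier] = np.where(u[is_carrier] < p_car, "Yes", "No").astype(object)
            data[name] = draws

    frame = pd.DataFrame(data, columns=schema.names)
    ids = pd.Series(np.arange(1, n + 1).astype(str), name="Patient_ID")
    return Cohort(schema=schema, data=frame, ids=ids)
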