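"""Cohort handling: diet-group classification, exclusions, energy and age-gender standardization.

Participants are classified into six diet groups from four screening answers
(any meat? any fish? any eggs? any dairy?) plus daily meat grams for the
meat-eating groups: vegans answer No to all four, vegetarians No to meat and
fish, fish-eaters No to meat only, and meat-eaters split at 50 and 100 g/day
into low, medium and high.  Eligibility exclusions, 2,000 kcal energy
standardization and the age-gender strata used for direct standardization
also live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ClassificationError, DataError

#: Canonical diet-group order, plant-based first.
GROUP_ORDER = ("vegan", "vegetarian", "fish_eater", "low_meat", "medium_meat", "high_meat")

#: Daily meat-gram cut-offs separating low/medium/high meat-eaters.
DEFAULT_MEAT_CUTOFFS = (50.0, 100.0)

KCAL_TO_MJ = 0.004184

ITEM_PREFIX = "item_"
ITEM_SUFFIX = "_g"

REQUIRED_COLUMNS = [
    "id", "age", "gender", "q_meat", "q_fish", "q_eggs", "q_dairy", "energy_kcal",
]

_YES = {"yes", "y", "true", "1", "1.0"}
_NO = {"no", "n", "false", "0", "0.0"}


def item_columns(df: pd.DataFrame) -> list[str]:
    """Intake columns following the ``item_<id>_g`` convention."""
    return [c for c in df.columns if c.startswith(ITEM_PREFIX) and c.endswith(ITEM_SUFFIX)]


def item_column(item_id: str) -> str:
    return f"{ITEM_PREFIX}{item_id}{ITEM_SUFFIX}"


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV and validate the schema (strict on required columns)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort table is missing columns {missing}")
    if not item_columns(df):
        raise DataError("cohort table has no item_<id>_g intake columns")
    return df


def _as_answer(value) -> bool:
    """Normalize a screening answer to a bool; raise on missing/unreadable."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ClassificationError("missing screening answer")
    s = str(value).strip().lower()
    if s in _YES:
        return True
    if s in _NO:
        return False
    raise ClassificationError(f"unreadable screening answer {value!r}")


def classify_diet_group(q_meat, q_fish, q_eggs, q_dairy, meat_g_per_day: float,
                        cutoffs: tuple[float, float] = DEFAULT_MEAT_CUTOFFS) -> str:
    """Classify one participant into a diet group.

    Meat-eaters are split by grams per day: ``< cutoffs[0]`` low,
    ``[cutoffs[0], cutoffs[1])`` medium, ``>= cutoffs[1]`` high (both
    boundaries inclusive on the heavier side).
    """
    lo, hi = cutoffs
    if not (0 < lo < hi):
        raise DataError(f"meat cut-offs must be strictly increasing and > 0, got {cutoffs}")
    meat = _as_answer(q_meat)
    if meat:
        g = float(meat_g_per_day)
        if not np.isfinite(g) or g < 0:
            raise ClassificationError(f"meat intake must be finite and >= 0, got {meat_g_per_day!r}")
        if g < lo:
            return "low_meat"
        return "medium_meat" if g < hi else "high_meat"
    fish = _as_answer(q_fish)
    if fish:
        return "fish_eater"
    eggs = _as_answer(q_eggs)
    dairy = _as_answer(q_dairy)
    return "vegan" if not (eggs or dairy) else "vegetarian"


def meat_grams(df: pd.DataFrame, meat_items) -> pd.Series:
    """Total daily meat grams: the sum over the meat-flagged FFQ items."""
    cols = [item_column(m) for m in meat_items]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"cohort table is missing meat intake columns {missing}")
    return df[cols].sum(axis=1)


def classify_cohort(df: pd.DataFrame, meat_items, cutoffs=DEFAULT_MEAT_CUTOFFS) -> pd.Series:
    """Diet group per participant (Series aligned to ``df.index``)."""
    grams = meat_grams(df, meat_items)
    out = [
        classify_diet_group(r.q_meat, r.q_fish, r.q_eggs, r.q_dairy, g, cutoffs)
        for r, g in zip(df.itertuples(index=False), grams)
    ]
    return pd.Series(pd.Categorical(out, categories=list(GROUP_ORDER)), index=df.index, name="diet_group")


@dataclass(frozen=True)
class ExclusionRules:
    """Eligibility rules applied before analysis.

    Ages outside ``[age_min, age_max)`` years, FFQ completion below
    ``min_completion``, unclassifiable screening answers, and daily energy
    outside gender-specific feasibility bounds (in MJ) are excluded, in that
    order; the first matching rule is the recorded reason.
    """

    age_min: float = 20.0
    age_max: float = 80.0
    min_completion: float = 0.8
    energy_bounds_mj: dict = field(default_factory=lambda: {"M": (3.3, 16.7), "F": (2.1, 14.7)})
    kcal_to_mj: float = KCAL_TO_MJ

    def __post_init__(self):
        if not self.age_min < self.age_max:
            raise DataError("age bounds must satisfy age_min < age_max")
        for g, (lo, hi) in self.energy_bounds_mj.items():
            if not lo < hi:
                raise DataError(f"energy bounds for gender {g!r} must satisfy lower < upper")


@dataclass
class ExclusionReport:
    """Counts of excluded participants by (first matching) reason."""

    n_input: int
    n_retained: int
    counts: dict

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained

    def to_json(self) -> dict:
        return {"n_input": self.n_input, "n_retained": self.n_retained,
                "n_excluded": self.n_excluded, "by_reason": dict(self.counts)}


_GENDER_MAP = {"m": "M", "male": "M", "man": "M", "men": "M",
               "f": "F", "female": "F", "woman": "F", "women": "F"}


def normalize_gender(value) -> str:
    s = str(value).strip().lower()
    if s not in _GENDER_MAP:
        raise DataError(f"unreadable gender {value!r}")
    return _GENDER_MAP[s]


def apply_exclusions(df: pd.DataFrame, rules: ExclusionRules | None = None,
                     cutoffs=DEFAULT_MEAT_CUTOFFS, meat_items=("meat",)):
    """Apply eligibility rules; return ``(retained_df, ExclusionReport)``.

    Reason order is fixed (malformed, age, completion, classification,
    energy) so that counts are reproducible.  Rows whose age, gender or
    energy cannot be parsed count as "malformed".
    """
    rules = rules or ExclusionRules()
    reasons = ["malformed", "age", "completion", "classification", "energy"]
    counts = dict.fromkeys(reasons, 0)
    keep = np.ones(len(df), dtype=bool)
    completion = df["ffq_completion"] if "ffq_completion" in df.columns else pd.Series(1.0, index=df.index)
    for pos, (idx, row) in enumerate(df.iterrows()):
        reason = None
        try:
            age = float(row["age"])
            gender = normalize_gender(row["gender"])
            energy = float(row["energy_kcal"])
            if not (np.isfinite(age) and np.isfinite(energy)):
                raise DataError("non-finite age or energy")
        except (DataError, TypeError, ValueError):
            reason = "malformed"
        else:
            if not (rules.age_min <= age < rules.age_max):
                reason = "age"
            elif float(completion.loc[idx]) < rules.min_completion:
                reason = "completion"
            else:
                try:
                    classify_diet_group(row["q_meat"], row["q_fish"], row["q_eggs"], row["q_dairy"],
                                        meat_grams(df.loc[[idx]], meat_items).iloc[0], cutoffs)
                except ClassificationError:
                    reason = "classification"
                else:
                    lo, hi = rules.energy_bounds_mj[gender]
                    mj = energy * rules.kcal_to_mj
                    if not (lo <= mj <= hi):
                        reason = "energy"
        if reason is not None:
            counts[reason] += 1
            keep[pos] = False
    retained = df.loc[keep].copy()
    return retained, ExclusionReport(len(df), len(retained), counts)


def energy_standardize(df: pd.DataFrame, target_kcal: float = 2000.0) -> pd.DataFrame:
    """Scale every intake by ``target_kcal / energy_kcal``; set energy to the target.

    Proportional scaling isolates diet *composition* from diet *amount*; it is
    idempotent and, because diet footprints are linear in intakes, commutes
    with footprint computation.
    """
    energy = df["energy_kcal"].to_numpy(dtype=float)
    if not np.isfinite(energy).all() or (energy <= 0).any():
        raise DataError("energy_kcal must be finite and > 0 for energy standardization")
    out = df.copy()
    scale = target_kcal / energy
    cols = item_columns(df)
    out[cols] = df[cols].to_numpy(dtype=float) * scale[:, None]
    out["energy_kcal"] = float(target_kcal)
    return out


def assign_age_band(ages, width: float = 10.0, age_min: float = 20.0, age_max: float = 80.0) -> pd.Series:
    """Age band label per participant (lower edge of the band, clipped to range)."""
    a = np.clip(np.asarray(ages, dtype=float), age_min, np.nextafter(age_max, -np.inf))
    band = age_min + np.floor((a - age_min) / width) * width
    return pd.Series(band, index=getattr(ages, "index", None), name="age_band")


def strata(df: pd.DataFrame, age_band_width: float = 10.0) -> pd.Series:
    """Age-band x gender stratum label per participant (e.g. ``"40|F"``)."""
    band = assign_age_band(df["age"], width=age_band_width)
    gender = df["gender"].map(normalize_gender)
    labels = [f"{int(b)}|{g}" for b, g in zip(band, gender)]
    return pd.Series(labels, index=df.index, name="stratum")


def stratum_weights(df: pd.DataFrame, age_band_width: float = 10.0) -> pd.Series:
    """Direct-standardization weights: whole-cohort stratum shares, summing to 1."""
    if len(df) == 0:
        raise DataError("cannot compute stratum weights for an empty cohort")
    counts = strata(df, age_band_width).value_counts().sort_index()
    return counts / counts.sum()


class DietGroupClassifier(BaseEstimator):
    """Rule-based diet-group classifier in estimator clothing.

    ``predict`` maps a cohort DataFrame (screening answers + intake columns)
    to the six diet-group labels.  ``fit`` only validates the configuration,
    so the classifier composes with sklearn pipelines and clone semantics.
    """

    def __init__(self, cutoffs=DEFAULT_MEAT_CUTOFFS, meat_items=("meat",)):
        self.cutoffs = cutoffs
        self.meat_items = meat_items

    def fit(self, X=None, y=None):
        lo, hi = self.cutoffs
        if not (0 < lo < hi):
            raise DataError(f"meat cut-offs must be strictly increasing and > 0, got {self.cutoffs}")
        self.classes_ = np.asarray(GROUP_ORDER, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "classes_"):
            self.fit()
        return classify_cohort(X, self.meat_items, self.cutoffs).to_numpy()


class EnergyStandardizer(BaseEstimator, TransformerMixin):
    """Transformer scaling all intakes to a common daily energy (default 2,000 kcal)."""

    def __init__(self, target_kcal: float = 2000.0):
        self.target_kcal = target_kcal

    def fit(self, X=None, y=None):
        if not self.target_kcal > 0:
            raise DataError("target_kcal must be > 0")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return energy_standardize(X, self.target_kcal)
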