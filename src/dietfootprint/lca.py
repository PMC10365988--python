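"""Life-cycle-assessment records: containers, gas disaggregation, medians and draws.

An LCA record describes the environmental burden of producing 1 kg of a food
category up to retail.  GHG emissions arrive as stage-level CO2e (enteric
fermentation, fertilizer application, everything else) and are disaggregated
into native gas masses by inverting the characterization factors that were
used to aggregate them: stages dominated by CH4 (enteric fermentation) are
converted back to grams of CH4, fertilizer-dominated stages to grams of N2O,
and the remainder is treated as CO2.  Re-aggregating with the same factors
reproduces the stage total exactly.

Seven indicators are carried throughout the package, in this fixed order::

    co2_kg                 kg CO2 per kg food (or per diet-day)
    ch4_g                  g CH4
    n2o_g                  g N2O
    land_m2                m^2 agricultural land (cropland + pasture)
    water_m3               m^3 agricultural freshwater
    eutrophication_gpo4e   g PO4 equivalents
    biodiversity           terrestrial-vertebrate extinction units, x1e-12 species
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .errors import CategoryLookupError, DataError

log = logging.getLogger(__name__)

#: Canonical indicator order used by every array in the package.
INDICATORS = (
    "co2_kg",
    "ch4_g",
    "n2o_g",
    "land_m2",
    "water_m3",
    "eutrophication_gpo4e",
    "biodiversity",
)

N_INDICATORS = len(INDICATORS)

#: Default characterization factors assumed to have been applied when the
#: database aggregated gas masses into stage CO2e (AR6 GWP100 values).
DEFAULT_CH4_FACTOR = 27.0
DEFAULT_N2O_FACTOR = 273.0

#: Column dictionary for the LCA CSV interchange format.
LCA_COLUMNS = [
    "category",
    "enteric_co2e",
    "fertilizer_co2e",
    "other_co2e",
    "land_m2",
    "water_m3",
    "eutrophication_gpo4e",
    "biodiversity",
    "organic",
    "source_id",
]

_NUMERIC_LCA_COLUMNS = [
    "enteric_co2e",
    "fertilizer_co2e",
    "other_co2e",
    "land_m2",
    "water_m3",
    "eutrophication_gpo4e",
    "biodiversity",
]


@dataclass(frozen=True)
class EmissionBundle:
    """Native gas masses for a food amount or a whole diet-day."""

    co2_kg: float
    ch4_g: float
    n2o_g: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise DataError(f"EmissionBundle.{f.name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.co2_kg, self.ch4_g, self.n2o_g], dtype=float)


@dataclass(frozen=True)
class IndicatorVector:
    """One value per reported indicator (per kg food or per diet-day)."""

    co2_kg: float
    ch4_g: float
    n2o_g: float
    land_m2: float
    water_m3: float
    eutrophication_gpo4e: float
    biodiversity: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise DataError(f"IndicatorVector.{f.name} must be finite and >= 0, got {v!r}")

    @classmethod
    def from_array(cls, values) -> "IndicatorVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_INDICATORS,):
            raise DataError(f"expected {N_INDICATORS} indicator values, got shape {values.shape}")
        return cls(*values)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in INDICATORS], dtype=float)

    @property
    def emissions(self) -> EmissionBundle:
        return EmissionBundle(self.co2_kg, self.ch4_g, self.n2o_g)


@dataclass(frozen=True)
class LCARecord:
    """A single LCA observation of a food category (per kg at retail)."""

    category: str
    enteric_co2e: float
    fertilizer_co2e: float
    other_co2e: float
    land_m2: float
    water_m3: float
    eutrophication_gpo4e: float
    biodiversity: float
    organic: bool = False
    source_id: str = ""

    def __post_init__(self):
        for name in _NUMERIC_LCA_COLUMNS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DataError(f"LCARecord.{name} must be finite and >= 0, got {v!r}")

    @property
    def total_co2e(self) -> float:
        return self.enteric_co2e + self.fertilizer_co2e + self.other_co2e


def disaggregate_ghg(
    record,
    source_factor_ch4: float = DEFAULT_CH4_FACTOR,
    source_factor_n2o: float = DEFAULT_N2O_FACTOR,
) -> EmissionBundle:
    """Invert stage-level CO2e into native gas masses.

    ``record`` may be an :class:`LCARecord`, a mapping, or a pandas row with
    ``enteric_co2e``, ``fertilizer_co2e`` and ``other_co2e`` fields (kg CO2e
    per kg food).  Enteric CO2e is attributed to CH4, fertilizer CO2e to N2O,
    and the remainder stays CO2.

    Returns gas masses with CH4 and N2O in grams, CO2 in kilograms.
    """
    if source_factor_ch4 <= 0 or source_factor_n2o <= 0:
        raise DataError("characterization source factors must be > 0")
    get = (lambda k: getattr(record, k)) if hasattr(record, "enteric_co2e") else record.__getitem__
    enteric, fertilizer, other = (float(get(k)) for k in ("enteric_co2e", "fertilizer_co2e", "other_co2e"))
    for name, v in (("enteric_co2e", enteric), ("fertilizer_co2e", fertilizer), ("other_co2e", other)):
        if not np.isfinite(v) or v < 0:
            raise DataError(f"stage value {name} must be finite and >= 0, got {v!r}")
    return EmissionBundle(
        co2_kg=other,
        ch4_g=enteric * 1000.0 / source_factor_ch4,
        n2o_g=fertilizer * 1000.0 / source_factor_n2o,
    )


class LCADatabase:
    """In-memory LCA database keyed by food category.

    Wraps a DataFrame in the :data:`LCA_COLUMNS` schema and exposes
    component-wise category medians and joint record draws, both on the
    seven-indicator scale (gas masses recovered with the database's
    characterization factors).

    Parameters
    ----------
    frame
        Records in the :data:`LCA_COLUMNS` schema.  Unknown columns are
        preserved but ignored.
    ch4_factor, n2o_factor
        Characterization factors assumed for stage-CO2e disaggregation.
    """

    def __init__(self, frame: pd.DataFrame, ch4_factor: float = DEFAULT_CH4_FACTOR,
                 n2o_factor: float = DEFAULT_N2O_FACTOR):
        missing = [c for c in LCA_COLUMNS if c not in frame.columns]
        if missing:
            raise DataError(f"LCA table is missing columns {missing}")
        vals = frame[_NUMERIC_LCA_COLUMNS].to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise DataError("LCA indicator values must be finite and >= 0")
        if ch4_factor <= 0 or n2o_factor <= 0:
            raise DataError("characterization factors must be > 0")
        self.frame = frame.reset_index(drop=True)
        self.ch4_factor = float(ch4_factor)
        self.n2o_factor = float(n2o_factor)
        self._vectors: dict[tuple[str, bool | None], np.ndarray] = {}
        self._warned_organic: set[str] = set()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records, **kwargs) -> "LCADatabase":
        rows = [vars(r) if isinstance(r, LCARecord) else dict(r) for r in records]
        return cls(pd.DataFrame(rows, columns=LCA_COLUMNS), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "LCADatabase":
        frame = pd.read_csv(path)
        if "organic" in frame.columns:
            frame["organic"] = frame["organic"].astype(bool)
        return cls(frame, **kwargs)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # -- lookups -----------------------------------------------------------

    @property
    def categories(self) -> list[str]:
        return list(dict.fromkeys(self.frame["category"]))

    def n_records(self, category: str) -> int:
        return int((self.frame["category"] == category).sum())

    def vectors(self, category: str, organic: bool | None = None) -> np.ndarray:
        """(n_records, 7) per-kg indicator vectors for a category.

        ``organic=True`` restricts to organic-flagged records, falling back to
        all records (with a warning) when the category has none.
        """
        key = (category, organic)
        cached = self._vectors.get(key)
        if cached is not None:
            return cached
        sub = self.frame[self.frame["category"] == category]
        if sub.empty:
            raise CategoryLookupError(f"unknown LCA category {category!r}")
        if organic is not None:
            flagged = sub[sub["organic"].astype(bool) == organic]
            if flagged.empty and organic:
                if category not in self._warned_organic:
                    log.warning("category %r has no organic records; using all records", category)
                    self._warned_organic.add(category)
            else:
                sub = flagged
        stage = sub[["enteric_co2e", "fertilizer_co2e", "other_co2e"]].to_numpy(dtype=float)
        out = np.empty((len(sub), N_INDICATORS))
        out[:, 0] = stage[:, 2]                                  # CO2 = remaining component
        out[:, 1] = stage[:, 0] * 1000.0 / self.ch4_factor       # enteric -> CH4 g
        out[:, 2] = stage[:, 1] * 1000.0 / self.n2o_factor       # fertilizer -> N2O g
        out[:, 3:] = sub[["land_m2", "water_m3", "eutrophication_gpo4e", "biodiversity"]].to_numpy(dtype=float)
        out.setflags(write=False)
        self._vectors[key] = out
        return out

    def category_median(self, category: str, organic: bool | None = None) -> np.ndarray:
        """Component-wise median over a category's records (length-7 array)."""
        return np.median(self.vectors(category, organic), axis=0)

    def category_median_vector(self, category: str, organic: bool | None = None) -> IndicatorVector:
        return IndicatorVector.from_array(self.category_median(category, organic))

    def category_draw(self, category: str, rng: np.random.Generator,
                      mode: str = "record", organic: bool | None = None) -> np.ndarray:
        """One sampled per-kg indicator vector (empirical resampling)."""
        return self.category_draw_block(category, rng, 1, mode=mode, organic=organic)[0]

    def category_draw_block(self, category: str, rng: np.random.Generator, n: int,
                            mode: str = "record", organic: bool | None = None) -> np.ndarray:
        """(n, 7) sampled vectors.

        ``mode='record'`` resamples whole records jointly, preserving
        cross-indicator coherence within a food; ``mode='marginal'`` samples
        each indicator independently across the category's records.
        """
        vecs = self.vectors(category, organic)
        m = len(vecs)
        if mode == "record":
            return vecs[rng.integers(0, m, size=n)]
        if mode == "marginal":
            idx = rng.integers(0, m, size=(n, N_INDICATORS))
            return vecs[idx, np.arange(N_INDICATORS)]
        raise DataError(f"unknown draw mode {mode!r} (expected 'record' or 'marginal')")


def category_median(db: LCADatabase, category: str) -> IndicatorVector:
    """Median indicator vector of a category (thin wrapper over the database)."""
    return db.category_median_vector(category)


def category_draw(db: LCADatabase, category: str, rng: np.random.Generator,
                  mode: str = "record") -> IndicatorVector:
    """One random indicator vector drawn from a category's records."""
    return IndicatorVector.from_array(db.category_draw(category, rng, mode=mode))
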