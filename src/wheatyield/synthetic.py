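"""Seeded generator of multi-source winter-wheat season records.

Because the study-scale observational dataset is private, this module
produces statistically analogous records with a *known* yield function so
that every downstream stage (feature extraction, fusion, prediction,
ablations) can be tested against recoverable ground truth:

* monthly vegetation indices (NDVI, EVI) as a smooth unimodal green-up
  curve peaking at jointing--heading (March--April),
* seven monthly climate variables as seasonal sinusoids with per
  region-year anomalies,
* four monthly dynamic soil variables (moisture/temperature at two
  depths),
* a 16-component static soil vector that is constant across years for a
  given region,
* yield = linear terms + a remote-sensing x climate interaction +
  region effect + year trend + Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

SEASON_MONTHS: tuple[str, ...] = (
    "oct", "nov", "dec", "jan", "feb", "mar", "apr", "may", "jun")
N_MONTHS = len(SEASON_MONTHS)

RS_VARS: tuple[str, ...] = ("ndvi", "evi")
CLIMATE_VARS: tuple[str, ...] = (
    "evap", "lwrad", "swrad", "pressure", "precip", "airtemp", "wind")
SOIL_DYN_VARS: tuple[str, ...] = (
    "moist_0_10", "moist_10_40", "temp_0_10", "temp_10_40")
SOIL_STATIC_VARS: tuple[str, ...] = tuple(
    f"{prop}_{layer}"
    for prop in ("bulkdens", "orgcarbon", "ph", "sand", "clay", "silt",
                 "cec_soil", "cec_clay")
    for layer in ("surf", "deep"))

# index of March / April in the season (Oct = 0)
_MAR, _APR = 5, 6


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic season generator."""

    n_regions: int = 196
    year_start: int = 2001
    year_end: int = 2022
    test_years: frozenset[int] = frozenset({2021, 2022})
    noise_sd: float = 300.0
    interaction_weight: float = 250.0
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 1:
            raise ConfigError(f"n_regions must be positive, got {self.n_regions}")
        if self.year_end < self.year_start:
            raise ConfigError("year_end must be >= year_start")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        object.__setattr__(self, "test_years", frozenset(self.test_years))

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1


@dataclasses.dataclass
class SeasonRecord:
    """One region-year: monthly series, static soil, covariates, yield."""

    region_id: int
    year: int
    rs: np.ndarray          # (9, 2)  NDVI, EVI in [-1, 1]
    climate: np.ndarray     # (9, 7)
    soil_dyn: np.ndarray    # (9, 4)
    soil_static: np.ndarray  # (16,)
    planting_area: float    # hm^2
    yield_kg_hm2: float

    def copy(self) -> "SeasonRecord":
        return SeasonRecord(
            region_id=self.region_id, year=self.year,
            rs=self.rs.copy(), climate=self.climate.copy(),
            soil_dyn=self.soil_dyn.copy(), soil_static=self.soil_static.copy(),
            planting_area=self.planting_area, yield_kg_hm2=self.yield_kg_hm2)


# Yield-function coefficients.  Calibrated so that with defaults the yield
# distribution lands near mean 6000 kg/hm^2, sd 1500 kg/hm^2.
_BASE_COEFS = {
    "b0": -2250.0,       # intercept
    "b_ndvi": 1400.0,    # per unit of season-summed NDVI
    "b_precip": 170.0,   # per unit of season-summed precipitation rate
    "b_temp": 40.0,      # per unit of season-summed air temperature anomaly
    "region_sd": 600.0,  # sd of the fixed region effect
    "year_trend": 90.0,  # kg/hm^2 per year since year_start
}


def closed_form_yield(record: SeasonRecord, coefs: dict) -> float:
    """Deterministic part of the generating yield function.

    y = b0 + b_ndvi * sum_m NDVI_m
         + b_precip * sum_m precip_m + b_temp * sum_m (temp_m - 10)
         + w * sum_m NDVI_m * precip_m
         + region_effect + year_trend * (year - year_start)
    """
    ndvi = record.rs[:, 0]
    precip = record.climate[:, CLIMATE_VARS.index("precip")]
    temp = record.climate[:, CLIMATE_VARS.index("airtemp")]
    y = (coefs["b0"]
         + coefs["b_ndvi"] * ndvi.sum()
         + coefs["b_precip"] * precip.sum()
         + coefs["b_temp"] * (temp - 10.0).sum()
         + coefs["interaction_weight"] * float(ndvi @ precip)
         + coefs["region_effects"][record.region_id]
         + coefs["year_trend"] * (record.year - coefs["year_start"]))
    return float(y)


def generate_dataset(cfg: SimConfig) -> tuple[list[SeasonRecord], dict]:
    """Generate ``cfg.n_regions x cfg.n_years`` season records.

    Returns the record list and the generator-coefficient dictionary
    (for parameter-recovery tests).  Same config => bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    m = np.arange(N_MONTHS, dtype=float)

    # fixed per-region attributes
    peak = rng.uniform(_MAR, _APR, size=cfg.n_regions)          # Mar--Apr
    amp = rng.uniform(0.30, 0.60, size=cfg.n_regions)
    region_effects = rng.normal(0.0, _BASE_COEFS["region_sd"], size=cfg.n_regions)
    soil_static_all = np.empty((cfg.n_regions, len(SOIL_STATIC_VARS)))
    ss_mean = np.array([1.3, 1.5, 12.0, 6.0, 7.2, 7.5, 40.0, 35.0,
                        25.0, 22.0, 30.0, 33.0, 20.0, 18.0, 45.0, 48.0])
    ss_sd = np.array([0.1, 0.1, 4.0, 2.0, 0.5, 0.5, 8.0, 8.0,
                      6.0, 6.0, 7.0, 7.0, 5.0, 5.0, 9.0, 9.0])
    # reorder to (prop, layer) pairs as in SOIL_STATIC_VARS
    soil_static_all[:] = ss_mean + ss_sd * rng.standard_normal(
        (cfg.n_regions, len(SOIL_STATIC_VARS)))

    cl_mean = np.array([2.5, -60.0, 160.0, 98.0, 2.0, 10.0, 3.0])
    cl_seas = np.array([1.0, 15.0, 40.0, 1.5, 1.0, 9.0, 0.8])
    cl_noise = np.array([0.3, 5.0, 10.0, 0.5, 0.30, 1.0, 0.4])
    sd_mean = np.array([0.25, 0.28, 9.0, 10.0])
    sd_seas = np.array([0.05, 0.04, 8.0, 7.5])
    sd_noise = np.array([0.02, 0.015, 0.8, 0.7])
    # month phase: season index 0 = October (calendar month 10)
    calendar = (m + 9.0) % 12.0
    phase = np.sin(2.0 * np.pi * (calendar - 3.0) / 12.0)  # peak near June

    coefs = dict(_BASE_COEFS)
    coefs.update(
        interaction_weight=cfg.interaction_weight,
        year_start=cfg.year_start,
        region_effects=region_effects,
        noise_sd=cfg.noise_sd,
    )

    records: list[SeasonRecord] = []
    for r in range(cfg.n_regions):
        bump_base = np.exp(-((m - peak[r]) ** 2) / (2.0 * 1.2 ** 2))
        for year in cfg.years:
            amp_ry = amp[r] + rng.normal(0.0, 0.04)
            ndvi = np.clip(0.18 + amp_ry * bump_base, -1.0, 1.0)
            evi = np.clip(0.8 * ndvi + rng.normal(0.0, 0.01, N_MONTHS), -1.0, 1.0)
            rs = np.column_stack([ndvi, evi])

            wet_anom = rng.normal(0.0, 0.5)    # shared season wetness
            temp_anom = rng.normal(0.0, 1.0)   # shared season warmth
            climate = (cl_mean[None, :] + cl_seas[None, :] * phase[:, None]
                       + cl_noise[None, :] * rng.standard_normal((N_MONTHS, 7)))
            climate[:, CLIMATE_VARS.index("precip")] += wet_anom
            climate[:, CLIMATE_VARS.index("airtemp")] += temp_anom
            climate[:, CLIMATE_VARS.index("precip")] = np.maximum(
                climate[:, CLIMATE_VARS.index("precip")], 0.0)

            soil_dyn = (sd_mean[None, :] + sd_seas[None, :] * phase[:, None]
                        + sd_noise[None, :] * rng.standard_normal((N_MONTHS, 4)))
            soil_dyn[:, 0] += 0.05 * wet_anom
            soil_dyn[:, 1] += 0.04 * wet_anom

            area = float(np.exp(rng.normal(8.0, 0.4)))
            rec = SeasonRecord(
                region_id=r, year=year, rs=rs, climate=climate,
                soil_dyn=soil_dyn, soil_static=soil_static_all[r].copy(),
                planting_area=area, yield_kg_hm2=0.0)
            noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
            rec.yield_kg_hm2 = closed_form_yield(rec, coefs) + noise
            records.append(rec)
    return records, coefs


def inject_missing(records: list[SeasonRecord], rate: float,
                   seed: int) -> list[SeasonRecord]:
    """Mask exactly ``floor(rate * n_cells)`` monthly cells with NaN.

    Cells are drawn uniformly over all (record, series, month) monthly
    cells but never at the first or last month of a series, so linear
    interpolation between present neighbours is always defined.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    out = [r.copy() for r in records]
    n_series_per_rec = len(RS_VARS) + len(CLIMATE_VARS) + len(SOIL_DYN_VARS)
    n_cells = len(records) * n_series_per_rec * N_MONTHS
    n_mask = int(np.floor(rate * n_cells))
    if n_mask == 0:
        return out
    rng = np.random.default_rng(seed)
    # eligible cells: interior months only
    n_interior = len(records) * n_series_per_rec * (N_MONTHS - 2)
    chosen = rng.choice(n_interior, size=n_mask, replace=False)
    for flat in chosen:
        month = 1 + flat % (N_MONTHS - 2)
        series = (flat // (N_MONTHS - 2)) % n_series_per_rec
        rec = out[flat // ((N_MONTHS - 2) * n_series_per_rec)]
        if series < len(RS_VARS):
            rec.rs[month, series] = np.nan
        elif series < len(RS_VARS) + len(CLIMATE_VARS):
            rec.climate[month, series - len(RS_VARS)] = np.nan
        else:
            rec.soil_dyn[month, series - len(RS_VARS) - len(CLIMATE_VARS)] = np.nan
    return out


# ---------------------------------------------------------------------------
# CSV layout: one row per region-year;
# columns rs_<var>_<month>, cl_<var>_<month>, sd_<var>_<month>, ss_<var>.
# ---------------------------------------------------------------------------

def _columns() -> list[str]:
    cols = ["region_id", "year", "planting_area", "yield"]
    cols += [f"rs_{v}_{mo}" for v in RS_VARS for mo in SEASON_MONTHS]
    cols += [f"cl_{v}_{mo}" for v in CLIMATE_VARS for mo in SEASON_MONTHS]
    cols += [f"sd_{v}_{mo}" for v in SOIL_DYN_VARS for mo in SEASON_MONTHS]
    cols += [f"ss_{v}" for v in SOIL_STATIC_VARS]
    return cols


def records_to_frame(records: list[SeasonRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = [r.region_id, r.year, r.planting_area, r.yield_kg_hm2]
        row += list(r.rs.T.ravel())
        row += list(r.climate.T.ravel())
        row += list(r.soil_dyn.T.ravel())
        row += list(r.soil_static)
        rows.append(row)
    return pd.DataFrame(rows, columns=_columns())


def frame_to_records(df: pd.DataFrame) -> list[SeasonRecord]:
    records = []
    for _, row in df.iterrows():
        rs = np.array([[row[f"rs_{v}_{mo}"] for v in RS_VARS]
                       for mo in SEASON_MONTHS])
        climate = np.array([[row[f"cl_{v}_{mo}"] for v in CLIMATE_VARS]
                            for mo in SEASON_MONTHS])
        soil_dyn = np.array([[row[f"sd_{v}_{mo}"] for v in SOIL_DYN_VARS]
                             for mo in SEASON_MONTHS])
        soil_static = np.array([row[f"ss_{v}"] for v in SOIL_STATIC_VARS])
        records.append(SeasonRecord(
            region_id=int(row["region_id"]), year=int(row["year"]),
            rs=rs, climate=climate, soil_dyn=soil_dyn, soil_static=soil_static,
            planting_area=float(row["planting_area"]),
            yield_kg_hm2=float(row["yield"])))
    return records


def write_dataset(records: list[SeasonRecord], coefs: dict, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(out_dir / "dataset.csv", index=False)
    serializable = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in coefs.items()
    }
    (out_dir / "coefficients.json").write_text(
        json.dumps(serializable, indent=2))


def read_dataset(data_dir) -> tuple[list[SeasonRecord], dict | None]:
    data_dir = Path(data_dir)
    df = pd.read_csv(data_dir / "dataset.csv")
    records = frame_to_records(df)
    coefs = None
    coef_path = data_dir / "coefficients.json"
    if coef_path.exists():
        coefs = json.loads(coef_path.read_text())
        if "region_effects" in coefs:
            coefs["region_effects"] = np.asarray(coefs["region_effects"])
    return records, coefs
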