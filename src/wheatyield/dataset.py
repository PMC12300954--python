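"""Data model: monthly resampling, interpolation of missing time nodes,
train/val/test partitioning, normalization, and covariate encoding.

The season runs October through June (9 months, index 0 = October).
Missing monthly cells are represented as NaN.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt

import numpy as np

from .synthetic import (N_MONTHS, SEASON_MONTHS, SeasonRecord)

__all__ = [
    "DatasetSplit", "NormalizerState", "CovariateEncoding",
    "monthly_aggregate", "interpolate_missing", "interpolate_records",
    "split_dataset", "window_subset", "prefix_window", "stage_months",
    "Preprocessor", "stack_records",
]

# calendar month number -> season index (October = 0 ... June = 8)
_CAL_TO_SEASON = {10: 0, 11: 1, 12: 2, 1: 3, 2: 4, 3: 5, 4: 6, 5: 7, 6: 8}

# growth stages: emergence--tillering, winter dormancy, jointing--heading,
# heading--maturity
STAGES: dict[str, tuple[str, ...]] = {
    "T1": ("oct", "nov"),
    "T2": ("dec", "jan", "feb"),
    "T3": ("mar", "apr"),
    "T4": ("may", "jun"),
}


def monthly_aggregate(samples) -> np.ndarray:
    """Aggregate (timestamp, value) samples into a 9-vector of monthly means.

    Timestamps may be ``datetime.date``/``datetime.datetime`` or calendar
    month numbers; every sample must fall in the Oct--Jun window.  Months
    without samples are NaN.  Empty input yields an all-NaN vector.
    """
    sums = np.zeros(N_MONTHS)
    counts = np.zeros(N_MONTHS)
    for ts, value in samples:
        if isinstance(ts, (_dt.date, _dt.datetime)):
            cal = ts.month
        else:
            cal = int(ts)
        if cal not in _CAL_TO_SEASON:
            raise ValueError(f"timestamp month {cal} outside the Oct-Jun season")
        idx = _CAL_TO_SEASON[cal]
        sums[idx] += value
        counts[idx] += 1
    out = np.full(N_MONTHS, np.nan)
    present = counts > 0
    out[present] = sums[present] / counts[present]
    return out


def interpolate_missing(series: np.ndarray) -> np.ndarray:
    """Fill NaN runs by straight-line interpolation between flanking values.

    Missing boundary months are filled with the nearest present value
    (flat extension).  An all-missing series is unusable.
    """
    series = np.asarray(series, dtype=float)
    mask = np.isnan(series)
    if mask.all():
        raise ValueError("cannot interpolate an all-missing series")
    if not mask.any():
        return series.copy()
    idx = np.arange(series.size)
    # np.interp does linear interpolation inside and flat extension outside
    return np.interp(idx, idx[~mask], series[~mask])


def interpolate_records(records: list[SeasonRecord]) -> list[SeasonRecord]:
    """Apply ``interpolate_missing`` column-wise to every monthly series."""
    out = []
    for r in records:
        r = r.copy()
        for mat in (r.rs, r.climate, r.soil_dyn):
            for j in range(mat.shape[1]):
                if np.isnan(mat[:, j]).any():
                    mat[:, j] = interpolate_missing(mat[:, j])
        out.append(r)
    return out


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    """Index-based train/val/test partition.

    Test = every record whose year is in ``test_years``; the remaining
    records are split 8:2 into train/val, stratified by region so each
    region contributes ~20% of its non-test years to validation.
    """

    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]
    seed: int

    def __post_init__(self):
        all_ids = set(self.train) | set(self.val) | set(self.test)
        n = len(self.train) + len(self.val) + len(self.test)
        if len(all_ids) != n:
            raise ValueError("split partitions overlap")


def split_dataset(records: list[SeasonRecord], test_years,
                  seed: int) -> DatasetSplit:
    test_years = set(test_years)
    if not records:
        raise ValueError("no records to split")
    test = [i for i, r in enumerate(records) if r.year in test_years]
    rest = [i for i, r in enumerate(records) if r.year not in test_years]
    if not rest:
        raise ValueError("every record falls in the test years; nothing to train on")
    by_region: dict[int, list[int]] = {}
    for i in rest:
        by_region.setdefault(records[i].region_id, []).append(i)
    rng = np.random.default_rng(seed)
    train: list[int] = []
    val: list[int] = []
    for region in sorted(by_region):
        ids = sorted(by_region[region])
        perm = rng.permutation(len(ids))
        n_val = int(round(0.2 * len(ids)))
        val.extend(ids[p] for p in perm[:n_val])
        train.extend(ids[p] for p in perm[n_val:])
    return DatasetSplit(train=tuple(sorted(train)), val=tuple(sorted(val)),
                        test=tuple(sorted(test)), seed=seed)


def _month_indices(months) -> list[int]:
    idx = [SEASON_MONTHS.index(m) for m in months]
    if not idx:
        raise ValueError("empty month selection")
    if sorted(idx) != list(range(min(idx), max(idx) + 1)):
        raise ValueError(f"months {months} are not contiguous in the season")
    return sorted(idx)


def window_subset(record: SeasonRecord, months) -> SeasonRecord:
    """Truncate all monthly matrices to a contiguous set of month labels.

    Static features (soil_static, covariates, yield) are untouched.
    """
    idx = _month_indices(months)
    out = record.copy()
    out.rs = out.rs[idx, :]
    out.climate = out.climate[idx, :]
    out.soil_dyn = out.soil_dyn[idx, :]
    return out


def prefix_window(n_months: int) -> tuple[str, ...]:
    """The first ``n_months`` of the season (Oct onward)."""
    if not 1 <= n_months <= N_MONTHS:
        raise ValueError(f"prefix length must be in [1, {N_MONTHS}]")
    return SEASON_MONTHS[:n_months]


def stage_months(stage: str) -> tuple[str, ...]:
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(STAGES)}")
    return STAGES[stage]


# ---------------------------------------------------------------------------
# Normalization & covariates
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NormalizerState:
    """Per-feature location/scale statistics fitted on training data only."""

    loc: np.ndarray
    scale: np.ndarray
    mode: str = "global"  # {"instance", "global"}

    @classmethod
    def fit(cls, x: np.ndarray, mode: str = "global") -> "NormalizerState":
        x = np.asarray(x, dtype=float)
        loc = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)  # constant features: scale 1
        return cls(loc=loc, scale=scale, mode=mode)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.loc) / self.scale

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.scale + self.loc


def instance_normalize(series: np.ndarray,
                       eps: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reversible per-sample normalization of monthly series.

    series: (..., months, vars).  Statistics are taken over the month axis
    independently for every sample and variable; returns (normalized, loc,
    scale) so the transform can be inverted exactly.
    """
    series = np.asarray(series, dtype=float)
    loc = series.mean(axis=-2, keepdims=True)
    scale = series.std(axis=-2, keepdims=True) + eps
    return (series - loc) / scale, loc, scale


def instance_denormalize(z: np.ndarray, loc: np.ndarray,
                         scale: np.ndarray) -> np.ndarray:
    return z * scale + loc


@dataclasses.dataclass
class CovariateEncoding:
    """Encoded covariates for a batch of records."""

    time: np.ndarray    # (B, 1) linear map of year
    region: np.ndarray  # (B, n_regions) one-hot
    area: np.ndarray    # (B, 1) z-scored planting area (train stats)


def stack_records(records: list[SeasonRecord], ids=None) -> dict[str, np.ndarray]:
    """Stack records into batched arrays keyed rs/cl/sd/ss/year/region/area/y."""
    if ids is None:
        ids = range(len(records))
    sel = [records[i] for i in ids]
    return {
        "rs": np.stack([r.rs for r in sel]),
        "cl": np.stack([r.climate for r in sel]),
        "sd": np.stack([r.soil_dyn for r in sel]),
        "ss": np.stack([r.soil_static for r in sel]),
        "year": np.array([r.year for r in sel], dtype=float),
        "region": np.array([r.region_id for r in sel], dtype=int),
        "area": np.array([r.planting_area for r in sel], dtype=float),
        "y": np.array([r.yield_kg_hm2 for r in sel], dtype=float),
    }


class Preprocessor:
    """Fits normalization statistics on the training split only and encodes
    model inputs.

    Dynamic monthly series are instance-normalized per sample (reversible,
    ``mode='instance'``) or z-scored with train statistics
    (``mode='global'``).  Static soil, planting area, the year feature and
    the yield target are always z-scored with train statistics.
    """

    def __init__(self, n_regions: int, mode: str = "global"):
        if mode not in ("instance", "global"):
            raise ValueError(f"unknown normalization mode {mode!r}")
        self.n_regions = n_regions
        self.mode = mode
        self.fitted = False

    def fit(self, train_arrays: dict[str, np.ndarray]) -> "Preprocessor":
        self.ss_norm = NormalizerState.fit(train_arrays["ss"])
        self.area_norm = NormalizerState.fit(train_arrays["area"][:, None])
        self.year_norm = NormalizerState.fit(train_arrays["year"][:, None])
        self.y_norm = NormalizerState.fit(train_arrays["y"][:, None])
        if self.mode == "global":
            self.series_norm = {
                key: NormalizerState.fit(
                    train_arrays[key].reshape(-1, train_arrays[key].shape[-1]))
                for key in ("rs", "cl", "sd")
            }
        self.fitted = True
        return self

    def encode_series(self, arrays: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for key in ("rs", "cl", "sd"):
            if self.mode == "instance":
                out[key], _, _ = instance_normalize(arrays[key])
            else:
                out[key] = self.series_norm[key].transform(arrays[key])
        out["ss"] = self.ss_norm.transform(arrays["ss"])
        return out

    def encode_covariates(self, arrays: dict[str, np.ndarray]) -> CovariateEncoding:
        region = np.zeros((len(arrays["region"]), self.n_regions))
        region[np.arange(len(arrays["region"])), arrays["region"]] = 1.0
        return CovariateEncoding(
            time=self.year_norm.transform(arrays["year"][:, None]),
            region=region,
            area=self.area_norm.transform(arrays["area"][:, None]),
        )

    def encode_target(self, y: np.ndarray) -> np.ndarray:
        return self.y_norm.transform(y[:, None])[:, 0]

    def decode_target(self, z: np.ndarray) -> np.ndarray:
        return self.y_norm.inverse(np.asarray(z)[:, None])[:, 0]

    def save(self, path) -> None:
        if not self.fitted:
            raise ValueError("cannot save an unfitted preprocessor")
        arrays = {"mode": np.array(self.mode),
                  "n_regions": np.array(self.n_regions)}
        for name in ("ss", "area", "year", "y"):
            norm = getattr(self, f"{name}_norm")
            arrays[f"{name}_loc"] = norm.loc
            arrays[f"{name}_scale"] = norm.scale
        if self.mode == "global":
            for key, norm in self.series_norm.items():
                arrays[f"series_{key}_loc"] = norm.loc
                arrays[f"series_{key}_scale"] = norm.scale
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Preprocessor":
        with np.load(path) as d:
            prep = cls(int(d["n_regions"]), mode=str(d["mode"]))
            for name in ("ss", "area", "year", "y"):
                setattr(prep, f"{name}_norm",
                        NormalizerState(d[f"{name}_loc"], d[f"{name}_scale"]))
            if prep.mode == "global":
                prep.series_norm = {
                    key: NormalizerState(d[f"series_{key}_loc"],
                                         d[f"series_{key}_scale"])
                    for key in ("rs", "cl", "sd")
                }
        prep.fitted = True
        return prep
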