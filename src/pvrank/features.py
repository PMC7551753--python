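"""Sub-sequence summary-statistic feature extraction.

Each PV time series yields 42 features: 6 sample statistics (min, max,
mean, std, skewness, number of measurements) on each of 7 sub-sequences
of the episode — the full series plus the first 10%/25%/50% and last
50%/25%/10% *of the time axis* (fractions of stay duration, closed
intervals, so boundary points may fall in several windows).

Two equivalent implementations are provided: ``featurize_episode`` (the
readable per-episode reference) and ``featurize_cohort`` (vectorized over
a whole cohort via segment reductions); a property test pins their
agreement.  Statistics use population (n-denominator) moments; empty
windows produce NaN sentinels for the five value statistics and 0 for the
count, to be filled by ``impute_and_standardize``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .catalog import PV_CATALOG
from .etl import EpisodeTimeSeries

__all__ = [
    "WINDOWS",
    "STATS",
    "N_FEATURES_PER_PV",
    "FeatureVector",
    "FeatureMatrix",
    "Standardizer",
    "subsequences",
    "sample_stats",
    "featurize_episode",
    "featurize_cohort",
    "feature_columns",
    "impute_and_standardize",
]

#: the 7 windows as (name, lo, hi) fractions of episode duration
WINDOWS: tuple[tuple[str, float, float], ...] = (
    ("full", 0.0, 1.0),
    ("first10", 0.0, 0.1),
    ("first25", 0.0, 0.25),
    ("first50", 0.0, 0.5),
    ("last50", 0.5, 1.0),
    ("last25", 0.75, 1.0),
    ("last10", 0.9, 1.0),
)

#: the 6 statistics, in fixed inner order
STATS: tuple[str, ...] = ("min", "max", "mean", "std", "skew", "n")

N_FEATURES_PER_PV = len(WINDOWS) * len(STATS)  # 42

# relative threshold below which a window's variance counts as zero
_ZERO_VAR_RTOL = 1e-9


@dataclass
class FeatureVector:
    stay_id: str
    pv_set: tuple[str, ...]
    values: np.ndarray  # length 42 * |pv_set|; NaN marks missing

    @property
    def mask(self) -> np.ndarray:
        """True where the entry is observed (not a missing sentinel)."""
        return ~np.isnan(self.values)


@dataclass
class Standardizer:
    """Training-row imputation means and z-scoring parameters."""

    impute_means: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        filled = np.where(np.isnan(values), self.impute_means[None, :], values)
        sds = np.where(self.sds > 0, self.sds, 1.0)
        out = (filled - self.means[None, :]) / sds[None, :]
        out[:, self.sds == 0] = 0.0
        return out


@dataclass
class FeatureMatrix:
    """Row-aligned feature vectors for a cohort of stays."""

    values: np.ndarray  # (n_stays, 42 * |pv_set|)
    columns: list[str]
    stay_ids: list[str]
    pv_set: tuple[str, ...]
    scaler: Standardizer | None = None

    def select_pvs(self, pv_subset: tuple[str, ...] | list[str]) -> "FeatureMatrix":
        """Column-restrict to a PV subset (used for leave-one-out sets).

        Imputation and z-scoring act column-wise, so restricting after
        standardization equals standardizing the restricted matrix.
        """
        unknown = [pv for pv in pv_subset if pv not in self.pv_set]
        if unknown:
            raise ValueError(f"PVs not in this matrix: {unknown}")
        idx = np.concatenate(
            [
                np.arange(N_FEATURES_PER_PV) + self.pv_set.index(pv) * N_FEATURES_PER_PV
                for pv in pv_subset
            ]
        )
        scaler = None
        if self.scaler is not None:
            scaler = Standardizer(
                self.scaler.impute_means[idx], self.scaler.means[idx], self.scaler.sds[idx]
            )
        return FeatureMatrix(
            values=self.values[:, idx],
            columns=[self.columns[i] for i in idx],
            stay_ids=self.stay_ids,
            pv_set=tuple(pv_subset),
            scaler=scaler,
        )


def feature_columns(pv_set: tuple[str, ...] | list[str]) -> list[str]:
    """Column names, PV outer / window middle / statistic inner."""
    return [f"{pv}.{w}.{s}" for pv in pv_set for (w, _, _) in WINDOWS for s in STATS]


def subsequences(
    times: np.ndarray, values: np.ndarray, duration_h: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split one sorted series into the 7 closed time-fraction windows."""
    if duration_h <= 0:
        raise ValueError(f"duration_h must be > 0, got {duration_h}")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    out = []
    for _, lo, hi in WINDOWS:
        sel = (times >= lo * duration_h) & (times <= hi * duration_h)
        out.append((times[sel], values[sel]))
    return out


def sample_stats(values: np.ndarray) -> tuple[float, float, float, float, float, int]:
    """(min, max, mean, std, skewness, n) with population moments.

    Empty input gives NaN for the five value statistics and n = 0; a
    singleton or zero-variance window gives std 0 and skewness 0.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return (math.nan, math.nan, math.nan, math.nan, math.nan, 0)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite value in series (cleaning should have removed it)")
    m1 = float(v.mean())
    d = v - m1
    m2 = float(np.mean(d * d))
    std = math.sqrt(m2)
    if m2 <= (_ZERO_VAR_RTOL * (1.0 + abs(m1))) ** 2:
        skew = 0.0
    else:
        skew = float(np.mean(d**3)) / m2**1.5
    return (float(v.min()), float(v.max()), m1, std, skew, n)


def _check_pv_set(pv_set) -> None:
    unknown = [pv for pv in pv_set if pv not in PV_CATALOG]
    if unknown:
        raise ValueError(f"unknown PVs (not in the canonical catalog): {unknown}")


def featurize_episode(
    episode: EpisodeTimeSeries, pv_set: tuple[str, ...] | list[str]
) -> FeatureVector:
    """42 features per PV for one episode, in canonical column order."""
    _check_pv_set(pv_set)
    vals = np.empty(len(pv_set) * N_FEATURES_PER_PV)
    for i, pv in enumerate(pv_set):
        t, v = episode.get(pv)
        for j, (sub_t, sub_v) in enumerate(subsequences(t, v, episode.duration_h)):
            vals[i * N_FEATURES_PER_PV + j * len(STATS) : i * N_FEATURES_PER_PV + (j + 1) * len(STATS)] = sample_stats(sub_v)
    return FeatureVector(stay_id=episode.stay_id, pv_set=tuple(pv_set), values=vals)


def featurize_cohort(
    episodes: list[EpisodeTimeSeries], pv_set: tuple[str, ...] | list[str]
) -> FeatureMatrix:
    """Vectorized extraction over a whole cohort (segment reductions)."""
    pv_set = tuple(pv_set)
    _check_pv_set(pv_set)
    n_ep = len(episodes)
    n_pv = len(pv_set)
    pv_index = {pv: i for i, pv in enumerate(pv_set)}

    t_parts, v_parts, ep_parts, pv_parts, dur_parts = [], [], [], [], []
    for e_idx, ep in enumerate(episodes):
        if ep.duration_h <= 0:
            raise ValueError(f"episode {ep.stay_id}: duration_h must be > 0")
        for pv, (t, v) in ep.series.items():
            if pv not in pv_index:
                continue
            t_parts.append(np.asarray(t, dtype=float))
            v_parts.append(np.asarray(v, dtype=float))
            k = len(t_parts[-1])
            ep_parts.append(np.full(k, e_idx, dtype=np.int64))
            pv_parts.append(np.full(k, pv_index[pv], dtype=np.int64))
            dur_parts.append(np.full(k, ep.duration_h))

    out = np.full((n_ep, n_pv * N_FEATURES_PER_PV), np.nan)
    n_groups = n_ep * n_pv
    if t_parts:
        t = np.concatenate(t_parts)
        v = np.concatenate(v_parts)
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite value in series (cleaning should have removed it)")
        g_all = np.concatenate(ep_parts) * n_pv + np.concatenate(pv_parts)
        dur = np.concatenate(dur_parts)
    else:
        t = v = dur = np.empty(0)
        g_all = np.empty(0, dtype=np.int64)

    n_stats = len(STATS)
    for w_idx, (_, lo, hi) in enumerate(WINDOWS):
        if len(t):
            sel = (t >= lo * dur) & (t <= hi * dur)
            g = g_all[sel]
            vw = v[sel]
        else:
            g = g_all
            vw = v
        n = np.bincount(g, minlength=n_groups)
        has = n > 0
        safe_n = np.where(has, n, 1)
        mean = np.bincount(g, weights=vw, minlength=n_groups) / safe_n
        d = vw - mean[g]
        m2 = np.bincount(g, weights=d * d, minlength=n_groups) / safe_n
        m3 = np.bincount(g, weights=d**3, minlength=n_groups) / safe_n
        std = np.sqrt(m2)
        zero_var = m2 <= (_ZERO_VAR_RTOL * (1.0 + np.abs(mean))) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            skew = np.where(zero_var, 0.0, m3 / np.where(zero_var, 1.0, m2) ** 1.5)
        vmin = np.full(n_groups, np.inf)
        vmax = np.full(n_groups, -np.inf)
        np.minimum.at(vmin, g, vw)
        np.maximum.at(vmax, g, vw)

        stats = np.column_stack([vmin, vmax, mean, std, skew, n.astype(float)])
        stats[~has, :5] = np.nan
        stats[~has, 5] = 0.0
        # scatter: group index -> (episode row, pv block)
        cols = (np.arange(n_groups) % n_pv) * N_FEATURES_PER_PV + w_idx * n_stats
        rows = np.arange(n_groups) // n_pv
        for s_idx in range(n_stats):
            out[rows, cols + s_idx] = stats[:, s_idx]

    return FeatureMatrix(
        values=out,
        columns=feature_columns(pv_set),
        stay_ids=[ep.stay_id for ep in episodes],
        pv_set=pv_set,
    )


def impute_and_standardize(
    matrix: FeatureMatrix, training_rows: np.ndarray | list[int]
) -> FeatureMatrix:
    """Fill missing sentinels with training-row column means, then z-score.

    Both the imputation means and the z-scoring mean/sd come from the
    training rows only; sd-0 columns map to 0.  The fitted parameters are
    attached to the result for reuse on later rows.
    """
    training_rows = np.asarray(training_rows, dtype=int)
    if training_rows.size == 0:
        raise ValueError("training_rows must be non-empty")
    train = matrix.values[training_rows]
    all_missing = np.all(np.isnan(train), axis=0)
    if all_missing.any():
        bad = [matrix.columns[i] for i in np.flatnonzero(all_missing)]
        raise ValueError(f"columns missing in every training row: {bad}")
    impute_means = np.nanmean(train, axis=0)
    train_filled = np.where(np.isnan(train), impute_means[None, :], train)
    means = train_filled.mean(axis=0)
    sds = train_filled.std(axis=0)
    scaler = Standardizer(impute_means=impute_means, means=means, sds=sds)
    return replace(matrix, values=scaler.transform(matrix.values), scaler=scaler)
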