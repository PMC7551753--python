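"""Synthetic ICU cohort generator with planted disease-PV effect sizes.

Generative model (fixed, documented):

* per stay ``s`` and PV ``p``, a latent level ``z[s, p] ~ N(0, 1)``;
* measurements of PV ``p`` in stay ``s`` arrive at homogeneous-Poisson
  times over the stay, with value ``mu_p + sigma_p * (z[s,p] +
  noise_sd * eps)`` (clipped to the plausible range; binary PVs are
  thresholded instead);
* disease labels ``y[s, d] ~ Bernoulli(sigmoid(alpha_d + B[d, :] @ z[s, :]))``
  — multi-label, diseases co-occur through the shared latents;
* an entire PV is unmeasured in a stay with probability ``missing_pv_prob``.

``B[d, p]`` is the log-odds shift of disease ``d`` per 1-SD change in the
stay-level latent of PV ``p``; the row-wise magnitude order of ``B`` is the
recovery target for the downstream importance ranking.  Everything is
deterministic given ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import DISEASE_CATALOG, PHYSIOLOGY, PV_CATALOG, PVProfile

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "SyntheticCohort",
    "ArtifactSpec",
    "generate_cohort",
    "inject_artifacts",
    "write_cohort",
]

# latent threshold above which a binary PV reads 1 (abnormal)
_BINARY_THRESHOLD = 1.0


class ConfigError(ValueError):
    """Invalid synthetic configuration; the message names the field."""


@dataclass
class SyntheticConfig:
    n_stays: int
    pv_catalog: tuple[str, ...] = PV_CATALOG
    disease_catalog: tuple[str, ...] = DISEASE_CATALOG
    effect_matrix: np.ndarray | None = None  # (n_diseases, n_pvs) log-odds/SD
    intercepts: np.ndarray | None = None  # (n_diseases,) controls prevalence
    sampling_rate: float = 10.0  # mean measurements per PV per stay
    stay_duration_hours: float | tuple[float, float] = 48.0
    missing_pv_prob: float = 0.05
    noise_sd: float = 0.5  # measurement noise, in units of sigma_p
    age_range: tuple[float, float] = (18.0, 90.0)
    physiology: dict[str, PVProfile] = field(default_factory=lambda: dict(PHYSIOLOGY))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_matrix is None:
            self.effect_matrix = np.zeros((len(self.disease_catalog), len(self.pv_catalog)))
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        if self.intercepts is None:
            self.intercepts = np.full(len(self.disease_catalog), -1.0)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_stays < 1:
            raise ConfigError(f"n_stays must be >= 1, got {self.n_stays}")
        if len(set(self.pv_catalog)) != len(self.pv_catalog):
            raise ConfigError("pv_catalog contains duplicate names")
        unknown = [pv for pv in self.pv_catalog if pv not in self.physiology]
        if unknown:
            raise ConfigError(f"pv_catalog names missing from physiology table: {unknown}")
        shape = (len(self.disease_catalog), len(self.pv_catalog))
        if self.effect_matrix.shape != shape:
            raise ConfigError(
                f"effect_matrix must have shape {shape}, got {self.effect_matrix.shape}"
            )
        if self.intercepts.shape != (len(self.disease_catalog),):
            raise ConfigError(
                f"intercepts must have shape ({len(self.disease_catalog)},), "
                f"got {self.intercepts.shape}"
            )
        if self.sampling_rate <= 0:
            raise ConfigError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not 0.0 <= self.missing_pv_prob <= 1.0:
            raise ConfigError(f"missing_pv_prob must be in [0, 1], got {self.missing_pv_prob}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        dur = self.stay_duration_hours
        if isinstance(dur, (int, float)):
            if dur <= 0:
                raise ConfigError(f"stay_duration_hours must be > 0, got {dur}")
        else:
            lo, hi = dur
            if not 0 < lo <= hi:
                raise ConfigError(f"stay_duration_hours range invalid: {dur}")


@dataclass
class SyntheticCohort:
    """Generated tables plus the ground truth used to make them.

    ``latents`` (stays x PVs) is kept so tests can check the generative
    link between latent levels and labels directly.
    """

    events: pd.DataFrame
    stays: pd.DataFrame
    labels: pd.DataFrame
    truth: SyntheticConfig
    latents: np.ndarray


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort. Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_stays
    pvs = list(config.pv_catalog)
    n_pv = len(pvs)

    width = max(6, len(str(n)))
    stay_ids = np.array([f"s{i:0{width}d}" for i in range(n)])
    stays = pd.DataFrame(
        {
            "stay_id": stay_ids,
            "patient_id": [f"p{i:0{width}d}" for i in range(n)],
            "admission_id": [f"a{i:0{width}d}" for i in range(n)],
            "age_years": np.round(rng.uniform(*config.age_range, size=n), 1),
            "duration_h": _durations(config, rng, n),
            "stays_in_admission": np.ones(n, dtype=int),
            "transferred": np.zeros(n, dtype=int),
        }
    )

    z = rng.standard_normal((n, n_pv))

    logits = config.intercepts[None, :] + z @ config.effect_matrix.T
    prob = 1.0 / (1.0 + np.exp(-logits))
    y = (rng.random(prob.shape) < prob).astype(int)
    labels = pd.DataFrame(y, columns=list(config.disease_catalog))
    labels.insert(0, "stay_id", stay_ids)

    missing = rng.random((n, n_pv)) < config.missing_pv_prob
    counts = rng.poisson(config.sampling_rate, size=(n, n_pv))
    counts[missing] = 0
    flat = counts.ravel()  # cell order: stay-major, PV inner
    ev_stay = np.repeat(np.repeat(np.arange(n), n_pv), flat)
    ev_pv = np.repeat(np.tile(np.arange(n_pv), n), flat)
    total = int(flat.sum())

    durations = stays["duration_h"].to_numpy()
    times = rng.random(total) * durations[ev_stay]
    eps = rng.standard_normal(total)
    latent = z[ev_stay, ev_pv] + config.noise_sd * eps

    mu = np.array([config.physiology[p].mean for p in pvs])
    sigma = np.array([config.physiology[p].sd for p in pvs])
    lo = np.array([config.physiology[p].lo for p in pvs])
    hi = np.array([config.physiology[p].hi for p in pvs])
    binary = np.array([config.physiology[p].binary for p in pvs])

    values = mu[ev_pv] + sigma[ev_pv] * latent
    values = np.clip(values, lo[ev_pv], hi[ev_pv])
    is_bin = binary[ev_pv]
    values[is_bin] = (latent[is_bin] > _BINARY_THRESHOLD).astype(float)

    units = np.array([config.physiology[p].unit for p in pvs], dtype=object)
    events = pd.DataFrame(
        {
            "stay_id": stay_ids[ev_stay],
            "patient_id": stays["patient_id"].to_numpy()[ev_stay],
            "variable": np.array(pvs, dtype=object)[ev_pv],
            "time_h": np.round(times, 4),
            "value": np.round(values, 4),
            "unit": units[ev_pv],
        }
    )
    return SyntheticCohort(events=events, stays=stays, labels=labels, truth=config, latents=z)


def _durations(config: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    dur = config.stay_duration_hours
    if isinstance(dur, (int, float)):
        return np.full(n, float(dur))
    lo, hi = dur
    return np.round(rng.uniform(lo, hi, size=n), 2)


# ---------------------------------------------------------------------------
# artifact injection


@dataclass
class ArtifactSpec:
    """Counts of each artifact class to insert into the events table."""

    n_blank_stay_id: int = 0
    n_out_of_range: int = 0
    n_wrong_unit_temp: int = 0
    n_negative_time: int = 0
    seed: int = 0

    @property
    def total(self) -> int:
        return (
            self.n_blank_stay_id
            + self.n_out_of_range
            + self.n_wrong_unit_temp
            + self.n_negative_time
        )


def inject_artifacts(
    cohort: SyntheticCohort, spec: ArtifactSpec
) -> tuple[SyntheticCohort, pd.DataFrame]:
    """Insert the requested artifact rows; return the new cohort + manifest.

    The manifest has one row per inserted artifact with its positional row
    index in the returned events table, its class, and whether the ETL
    cleaner is expected to remove it (``invalid``) or repair it in place
    (wrong-unit temperatures are converted, not dropped).
    """
    events = cohort.events.reset_index(drop=True)
    if spec.total == 0:
        return (
            SyntheticCohort(events, cohort.stays, cohort.labels, cohort.truth, cohort.latents),
            pd.DataFrame(columns=["row", "kind", "invalid"]),
        )
    for name in ("n_blank_stay_id", "n_out_of_range", "n_wrong_unit_temp", "n_negative_time"):
        count = getattr(spec, name)
        if count < 0 or count > len(events):
            raise ValueError(f"{name}={count} exceeds events table size {len(events)}")

    rng = np.random.default_rng(spec.seed)
    stay_pool = cohort.stays
    rows: list[dict] = []
    kinds: list[tuple[str, bool]] = []

    def pick_stay() -> pd.Series:
        return stay_pool.iloc[int(rng.integers(len(stay_pool)))]

    for _ in range(spec.n_blank_stay_id):
        s = pick_stay()
        rows.append(
            {
                "stay_id": "",
                "patient_id": s["patient_id"],
                "variable": "HR",
                "time_h": round(float(rng.uniform(0, s["duration_h"])), 4),
                "value": round(float(rng.uniform(60, 100)), 4),
                "unit": "bpm",
            }
        )
        kinds.append(("blank_stay_id", True))
    for _ in range(spec.n_out_of_range):
        s = pick_stay()
        rows.append(
            {
                "stay_id": s["stay_id"],
                "patient_id": s["patient_id"],
                "variable": "HR",
                "time_h": round(float(rng.uniform(0, s["duration_h"])), 4),
                "value": round(float(rng.uniform(5000, 9000)), 4),
                "unit": "bpm",
            }
        )
        kinds.append(("out_of_range", True))
    for _ in range(spec.n_wrong_unit_temp):
        s = pick_stay()
        rows.append(
            {
                "stay_id": s["stay_id"],
                "patient_id": s["patient_id"],
                "variable": "TEMP",
                "time_h": round(float(rng.uniform(0, s["duration_h"])), 4),
                # plausible body temperature, recorded in Fahrenheit
                "value": round(float(rng.uniform(96.0, 104.0)), 4),
                "unit": "F",
            }
        )
        kinds.append(("wrong_unit_temp", False))
    for _ in range(spec.n_negative_time):
        s = pick_stay()
        rows.append(
            {
                "stay_id": s["stay_id"],
                "patient_id": s["patient_id"],
                "variable": "RR",
                "time_h": round(float(-rng.uniform(0.1, 10.0)), 4),
                "value": round(float(rng.uniform(10, 30)), 4),
                "unit": "insp/min",
            }
        )
        kinds.append(("negative_time", True))

    injected = pd.DataFrame(rows)
    out_events = pd.concat([events, injected], ignore_index=True)
    manifest = pd.DataFrame(
        {
            "row": np.arange(len(events), len(out_events)),
            "kind": [k for k, _ in kinds],
            "invalid": [inv for _, inv in kinds],
        }
    )
    out = SyntheticCohort(out_events, cohort.stays, cohort.labels, cohort.truth, cohort.latents)
    return out, manifest


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write events/stays/labels CSVs plus a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.events.to_csv(outdir / "events.csv", index=False)
    cohort.stays.to_csv(outdir / "stays.csv", index=False)
    cohort.labels.to_csv(outdir / "labels.csv", index=False)
    cfg = cohort.truth
    truth = {
        "seed": cfg.seed,
        "n_stays": cfg.n_stays,
        "pv_catalog": list(cfg.pv_catalog),
        "disease_catalog": list(cfg.disease_catalog),
        "effect_matrix": cfg.effect_matrix.tolist(),
        "intercepts": cfg.intercepts.tolist(),
        "sampling_rate": cfg.sampling_rate,
        "missing_pv_prob": cfg.missing_pv_prob,
        "noise_sd": cfg.noise_sd,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
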