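"""Synthetic five-group longitudinal cohorts with a known generative LME.

Emulates an ADNI-like longitudinal hippocampal-volume study: five clinical
groups (stable/converter healthy controls, stable/converter MCI, AD at
baseline), a four-visit schedule at roughly 0 / 0.5 / 1 / 2 years with small
per-visit timing jitter, group-specific linear atrophy slopes on the
standardized hippocampal-volume (HV) scale, correlated per-subject random
intercepts and slopes, demographic covariate effects (baseline age, sex,
APOE-e4 carrier status and its interaction with time, intracranial volume),
Gaussian residual noise, and optional monotone dropout.

Every downstream stage of the package (REML fitting, Satterthwaite
contrasts, Gibbs sampling, removal simulations) is testable against the
known generative parameters through this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUP_LABELS = ("sHC", "cHC", "sMCI", "cMCI", "AD")

#: canonical long-format column order
DATA_COLUMNS = (
    "subject_id",
    "group",
    "visit_time",
    "hv",
    "icv",
    "baseline_age",
    "sex",
    "apoe",
)


class ConfigurationError(ValueError):
    """An invalid generator configuration; names the offending field."""


class DegenerateDataError(ValueError):
    """Raised when a requested operation is undefined for the data (e.g.
    standardizing a zero-variance column)."""


@dataclass(frozen=True)
class GroupProfile:
    """Demographics and generative effect sizes for one clinical group.

    ``intercept_offset`` is the group's mean HV shift at baseline relative to
    the reference healthy group (standardized-HV units); ``slope_offset`` is
    the group-by-time coefficient relative to the reference slope
    (standardized-HV units per year).
    """

    name: str
    n_subjects: int
    baseline_age_mean: float
    baseline_age_sd: float
    female_fraction: float
    apoe_carrier_fraction: float
    intercept_offset: float
    slope_offset: float

    def validate(self) -> None:
        if self.name not in GROUP_LABELS:
            raise ConfigurationError(
                f"GroupProfile.name: unknown group label {self.name!r}; "
                f"expected one of {GROUP_LABELS}"
            )
        if self.n_subjects < 0:
            raise ConfigurationError("GroupProfile.n_subjects: must be >= 0")
        if self.baseline_age_sd <= 0:
            raise ConfigurationError("GroupProfile.baseline_age_sd: must be > 0")
        for fname in ("female_fraction", "apoe_carrier_fraction"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"GroupProfile.{fname}: must be in [0, 1]")


def default_profiles() -> tuple[GroupProfile, ...]:
    """Group profiles emulating a balanced 670-subject ADNI-like cohort.

    Sizes, age distributions, sex ratios and APOE-e4 carrier fractions follow
    the balanced four-visit cohort of the emulated study; intercept and slope
    offsets are on the standardized-HV scale, with the group-by-time slopes
    anchored to the published posterior estimates (cHC -0.03, sMCI -0.02,
    cMCI -0.08, AD -0.11 per year relative to stable controls).
    """
    return (
        GroupProfile("sHC", 172, 74.2, 5.6, 76 / 172, 39 / 172, 0.0, 0.0),
        GroupProfile("cHC", 53, 76.1, 5.4, 29 / 53, 20 / 53, -0.1, -0.03),
        GroupProfile("sMCI", 187, 72.0, 6.9, 83 / 187, 71 / 187, -0.7, -0.02),
        GroupProfile("cMCI", 186, 71.6, 7.6, 79 / 186, 114 / 186, -0.9, -0.08),
        GroupProfile("AD", 72, 74.2, 7.9, 32 / 72, 51 / 72, -1.2, -0.11),
    )


@dataclass(frozen=True)
class GenerativeConfig:
    """Full specification of the generative linear mixed-effects model.

    The outcome model for subject i of group g at visit time t is::

        hv = b0 + intercept_offset_g
             + (base_slope + slope_offset_g) * t
             + beta_age * age_i + beta_sex * sex_i + beta_apoe * apoe_i
             + beta_apoe_time * apoe_i * t + beta_icv * icv_i
             + u0_i + u1_i * t + eps

    with (u0, u1) bivariate normal (sds ``random_intercept_sd`` /
    ``random_slope_sd``, correlation ``random_corr``) and eps iid
    Normal(0, residual_sd^2).  Ages enter in years centred at 74 so the
    intercept stays on the standardized-HV scale.
    """

    profiles: tuple[GroupProfile, ...] = field(default_factory=default_profiles)
    visit_times_mean: tuple[float, ...] = (0.0, 0.51, 1.01, 2.02)
    visit_times_sd: tuple[float, ...] = (0.0, 0.05, 0.06, 0.08)
    intercept: float = 0.0
    base_slope: float = -0.01
    beta_age: float = -0.02
    beta_sex: float = 0.1
    beta_apoe: float = -0.1
    beta_apoe_time: float = -0.02
    beta_icv: float = 0.3
    random_intercept_sd: float = 0.9
    random_slope_sd: float = 0.05
    random_corr: float = 0.2
    residual_sd: float = 0.15
    dropout_hazard_per_visit: float = 0.0
    age_center: float = 74.0
    seed: int = 0

    def validate(self) -> None:
        for p in self.profiles:
            p.validate()
        if len(self.visit_times_mean) != len(self.visit_times_sd):
            raise ConfigurationError(
                "GenerativeConfig.visit_times_sd: length must match visit_times_mean"
            )
        vt = np.asarray(self.visit_times_mean, dtype=float)
        if len(vt) == 0 or vt[0] != 0.0:
            raise ConfigurationError(
                "GenerativeConfig.visit_times_mean: first visit must be exactly 0"
            )
        if np.any(np.diff(vt) <= 0):
            raise ConfigurationError(
                "GenerativeConfig.visit_times_mean: must be strictly increasing"
            )
        if np.any(np.asarray(self.visit_times_sd) < 0):
            raise ConfigurationError("GenerativeConfig.visit_times_sd: must be >= 0")
        for fname in ("random_intercept_sd", "random_slope_sd"):
            if getattr(self, fname) < 0:
                raise ConfigurationError(f"GenerativeConfig.{fname}: must be >= 0")
        if not -1.0 < self.random_corr < 1.0:
            raise ConfigurationError("GenerativeConfig.random_corr: must be in (-1, 1)")
        if self.residual_sd <= 0:
            raise ConfigurationError("GenerativeConfig.residual_sd: must be > 0")
        if not 0.0 <= self.dropout_hazard_per_visit <= 1.0:
            raise ConfigurationError(
                "GenerativeConfig.dropout_hazard_per_visit: must be in [0, 1]"
            )

    def scaled(self, size_factor: float = 1.0, effect_factor: float = 1.0) -> "GenerativeConfig":
        """A copy with group sizes and/or group-by-time slopes rescaled.

        ``size_factor`` multiplies every group's subject count (rounded,
        minimum 1 where the original count is positive); ``effect_factor``
        multiplies each group's slope offset.  Used to run desk-scale
        variants of the study conditions.
        """
        profiles = tuple(
            replace(
                p,
                n_subjects=(max(1, round(p.n_subjects * size_factor)) if p.n_subjects else 0),
                slope_offset=p.slope_offset * effect_factor,
            )
            for p in self.profiles
        )
        return replace(self, profiles=profiles)


@dataclass
class LongitudinalDataset:
    """Long-format subject-visit records; the currency between all stages.

    ``data`` holds one row per subject-visit with columns
    ``subject_id, group, visit_time, hv, icv, baseline_age, sex, apoe``
    (sex coded 0=M/1=F, apoe 0=non-carrier/1=carrier).  ``standardized``
    marks whether hv/icv are on the zero-mean unit-sd scale;
    ``standardization`` records the constants used (for reporting and for
    mapping results back to raw units).
    """

    data: pd.DataFrame
    standardized: bool = False
    standardization: dict | None = None

    def __post_init__(self) -> None:
        missing = [c for c in DATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"LongitudinalDataset missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    def groups_present(self) -> list[str]:
        present = set(self.data["group"])
        return [g for g in GROUP_LABELS if g in present]

    def subject_groups(self) -> pd.Series:
        """Group label per subject (indexed by subject_id)."""
        return self.data.groupby("subject_id", sort=False)["group"].first()

    def counts_per_group(self) -> dict[str, int]:
        g = self.subject_groups().value_counts()
        return {lbl: int(g.get(lbl, 0)) for lbl in GROUP_LABELS}

    # -- filtering (stable subject ids) ----------------------------------
    def filter_subjects(self, keep: Iterable) -> "LongitudinalDataset":
        keep = set(keep)
        sub = self.data[self.data["subject_id"].isin(keep)]
        return LongitudinalDataset(sub.copy(), self.standardized, self.standardization)

    def drop_record(self, subject_id, visit_time) -> "LongitudinalDataset":
        mask = ~(
            (self.data["subject_id"] == subject_id)
            & (self.data["visit_time"] == visit_time)
        )
        return LongitudinalDataset(self.data[mask].copy(), self.standardized, self.standardization)

    def visits_per_subject(self) -> pd.Series:
        return self.data.groupby("subject_id", sort=False)["visit_time"].size()


# ---------------------------------------------------------------------------
# generation


def generate_cohort(config: GenerativeConfig, seed: int | None = None) -> LongitudinalDataset:
    """Draw a cohort from the generative mixed model.

    Deterministic given the seed (``seed`` overrides ``config.seed`` when
    given).  Visit jitter is truncated at +-3 sd so visit times stay positive
    and ordered; the baseline visit is at exactly 0.  Monotone dropout: the
    baseline visit is always observed, and each later visit is retained with
    probability ``1 - dropout_hazard_per_visit`` given the previous visit was
    retained.

    The emitted hv/icv are on the standardized scale of the generative
    parameters, so the dataset is marked ``standardized=True``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    vt_mean = np.asarray(config.visit_times_mean, dtype=float)
    vt_sd = np.asarray(config.visit_times_sd, dtype=float)
    n_visits = len(vt_mean)

    # random-effect Cholesky factor (valid even when an sd is zero)
    s0, s1, rho = config.random_intercept_sd, config.random_slope_sd, config.random_corr
    chol = np.array([[s0, 0.0], [rho * s1, s1 * np.sqrt(1.0 - rho**2)]])

    frames = []
    sid = 0
    for prof in config.profiles:
        n = prof.n_subjects
        if n == 0:
            continue
        age = prof.baseline_age_mean + prof.baseline_age_sd * rng.standard_normal(n)
        sex = (rng.random(n) < prof.female_fraction).astype(int)
        apoe = (rng.random(n) < prof.apoe_carrier_fraction).astype(int)
        icv = rng.standard_normal(n)  # standardized ICV
        b = rng.standard_normal((n, 2)) @ chol.T

        jitter = np.clip(rng.standard_normal((n, n_visits)), -3.0, 3.0) * vt_sd
        times = vt_mean + jitter
        times[:, 0] = 0.0

        slope = config.base_slope + prof.slope_offset
        level = (
            config.intercept
            + prof.intercept_offset
            + config.beta_age * (age - config.age_center)
            + config.beta_sex * sex
            + config.beta_apoe * apoe
            + config.beta_icv * icv
            + b[:, 0]
        )
        rate = slope + config.beta_apoe_time * apoe + b[:, 1]
        eps = config.residual_sd * rng.standard_normal((n, n_visits))
        hv = level[:, None] + rate[:, None] * times + eps

        # monotone dropout mask (baseline always observed)
        keep = np.ones((n, n_visits), dtype=bool)
        if config.dropout_hazard_per_visit > 0 and n_visits > 1:
            drop_draws = rng.random((n, n_visits - 1)) < config.dropout_hazard_per_visit
            keep[:, 1:] = np.logical_and.accumulate(~drop_draws, axis=1)

        ids = np.array([f"S{sid + i:04d}" for i in range(n)])
        sid += n
        idx_s, idx_v = np.nonzero(keep)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": ids[idx_s],
                    "group": prof.name,
                    "visit_time": times[idx_s, idx_v],
                    "hv": hv[idx_s, idx_v],
                    "icv": icv[idx_s],
                    "baseline_age": age[idx_s],
                    "sex": sex[idx_s],
                    "apoe": apoe[idx_s],
                }
            )
        )
    if not frames:
        raise ConfigurationError("GenerativeConfig.profiles: no subjects to generate")
    data = pd.concat(frames, ignore_index=True)
    return LongitudinalDataset(data, standardized=True)


def standardize_fisher_z(
    dataset: LongitudinalDataset, columns: Sequence[str] = ("hv", "icv")
) -> LongitudinalDataset:
    """Z-score the chosen columns to zero mean and unit sd over all records.

    Uses the sample (n-1) standard deviation, pooled over every record in
    the dataset.  The constants are recorded in ``standardization`` so raw
    units can be recovered.  Idempotent up to floating tolerance.
    """
    if dataset.n_obs == 0:
        raise DegenerateDataError("cannot standardize an empty dataset")
    bad = [c for c in columns if c not in ("hv", "icv")]
    if bad:
        raise ValueError(f"standardize_fisher_z: unsupported columns {bad}")
    data = dataset.data.copy()
    constants = dict(dataset.standardization or {})
    for col in columns:
        x = data[col].to_numpy(dtype=float)
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise DegenerateDataError(f"column {col!r} has zero variance")
        data[col] = (x - mu) / sd
        constants[col] = {"mean": mu, "sd": sd}
    return LongitudinalDataset(data, standardized=True, standardization=constants)


def derive_variants(dataset: LongitudinalDataset) -> dict[str, LongitudinalDataset]:
    """The four analysis datasets derived from a full cohort.

    - ``dataset1``: the input unchanged (all groups, all visits).
    - ``dataset2``: only sMCI and cMCI subjects.
    - ``dataset3``: only subjects observed at all four visits (balanced).
    - ``dataset4``: the intersection of both filters.

    Empty variants are permitted (e.g. a cohort without MCI groups).
    """
    n_target = dataset.data.groupby("subject_id", sort=False)["visit_time"].size()
    complete = set(n_target[n_target >= 4].index)
    mci = set(
        dataset.data.loc[dataset.data["group"].isin(["sMCI", "cMCI"]), "subject_id"]
    )
    return {
        "dataset1": dataset,
        "dataset2": dataset.filter_subjects(mci),
        "dataset3": dataset.filter_subjects(complete),
        "dataset4": dataset.filter_subjects(mci & complete),
    }
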