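"""Sequential random-removal simulations for borderline-significance harvesting.

Two procedures mimic the degradation of a real longitudinal study:

- **minimum-N**: repeatedly remove one uniformly random subject (all of its
  visits), refit the frequentist mixed model and re-test the contrast of
  interest; stop when the p-value first exceeds alpha and keep the last
  significant dataset as the *borderline significant database*.
- **missing timepoints**: repeatedly remove one uniformly random
  subject-visit record; before each refit check the estimability rule that
  the frequentist fit needs more observations than random-effect
  coefficients (n_obs > q * n_subjects, i.e. N x 2 for the
  intercept-and-slope model), and stop on either p > alpha or an
  estimability violation.

Each procedure is repeated over many iterations with per-iteration seeds,
and every trajectory is recorded step by step so the stopping property can
be re-verified from the trace by independent refits.

The significance check inside the loops is the single named contrast,
uncorrected, at alpha = 0.05; Bonferroni correction belongs to the
full-battery analysis, not to the stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flme_inference import ContrastSpec, f_test_satterthwaite, make_contrast
from .lme_core import DesignMatrices, FitError, ModelSpec, build_design, fit_lme
from .synthetic_data import GROUP_LABELS, LongitudinalDataset


class SimulationOutlier(RuntimeError):
    """An iteration whose refits failed repeatedly (recorded, not fatal in
    batch runs)."""


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class RemovalStep:
    step_index: int
    removed_unit: object  # subject_id or (subject_id, visit_time)
    n_subjects_after: int
    n_obs_after: int
    p_value_after: float | None
    estimable: bool


@dataclass
class BorderlineDataset:
    """The last dataset meeting the significance criterion, with its trace."""

    dataset: LongitudinalDataset
    stop_reason: str  # p_exceeded | estimability_failed | exhausted
    final_p: float
    trace: list[RemovalStep]
    iteration_seed: int | None = None

    @property
    def n_subjects(self) -> int:
        return self.dataset.n_subjects

    @property
    def n_obs(self) -> int:
        return self.dataset.n_obs


@dataclass
class SimulationSummary:
    n_iterations: int
    kind: str
    contrast_name: str
    final_n_mean: float
    final_n_sd: float
    final_n_sd_defined: bool
    group_counts: pd.DataFrame  # one row per iteration, one column per group
    n_outlier_iterations: int
    stop_reasons: dict[str, int]
    mean_missing_per_subject: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": self.kind,
                    "contrast": self.contrast_name,
                    "n_iterations": self.n_iterations,
                    "final_n_mean": self.final_n_mean,
                    "final_n_sd": self.final_n_sd,
                    "n_outliers": self.n_outlier_iterations,
                    "mean_missing_per_subject": self.mean_missing_per_subject,
                    **{f"stop_{k}": v for k, v in self.stop_reasons.items()},
                }
            ]
        )


def check_estimability(
    dataset: LongitudinalDataset | tuple[int, int],
    random_structure: str = "intercept_and_slope",
) -> dict:
    """The frequentist estimability rule: n_obs must exceed q * n_subjects.

    Accepts a dataset or an ``(n_obs, n_subjects)`` pair.
    """
    q = 2 if random_structure == "intercept_and_slope" else 1
    if isinstance(dataset, LongitudinalDataset):
        n_obs, n_subjects = dataset.n_obs, dataset.n_subjects
    else:
        n_obs, n_subjects = dataset
    threshold = q * n_subjects
    return {"estimable": n_obs > threshold, "n_obs": n_obs, "threshold": threshold}


class _RemovalState:
    """Shared fast path: the full design is built once and every refit runs
    on a boolean row mask, so a removal step costs one warm-started REML fit
    plus the Satterthwaite test."""

    def __init__(self, dataset: LongitudinalDataset, spec: ModelSpec,
                 contrast_name: str, scope: str):
        # freeze a subject-contiguous row order aligned with the design
        codes, _ = pd.factorize(dataset.data["subject_id"], sort=False)
        order = np.argsort(codes, kind="stable")
        self.df = dataset.data.iloc[order].reset_index(drop=True)
        self.base = LongitudinalDataset(
            self.df, dataset.standardized, dataset.standardization
        )
        self.design = build_design(self.base, spec)
        self.spec = spec
        self.q = spec.q
        self.contrast: ContrastSpec = make_contrast(
            contrast_name, self.design.x_labels, scope=scope
        )
        self.row_code = self.design.subject_codes
        self.row_subject = self.design.subject_ids[self.design.subject_codes]
        self.row_time = self.design.Z[:, 1] if self.q == 2 else (
            self.df["visit_time"].to_numpy()
        )
        self.mask = np.ones(self.design.n_obs, dtype=bool)
        self.theta_warm: np.ndarray | None = None

    def counts(self, mask: np.ndarray) -> tuple[int, int]:
        return int(mask.sum()), int(np.unique(self.row_code[mask]).size)

    def fit_and_test(self, mask: np.ndarray):
        codes = self.row_code[mask]
        alive, codes_m = np.unique(codes, return_inverse=True)
        sub = DesignMatrices(
            y=self.design.y[mask],
            X=self.design.X[mask],
            Z=self.design.Z[mask],
            subject_codes=codes_m,
            subject_ids=self.design.subject_ids[alive],
            x_labels=self.design.x_labels,
            q=self.q,
        )
        fit = fit_lme(sub, "reml", theta0=self.theta_warm)
        res = f_test_satterthwaite(fit, self.contrast)
        return fit, res

    def dataset_for(self, mask: np.ndarray) -> LongitudinalDataset:
        return LongitudinalDataset(
            self.df[mask].copy(), self.base.standardized, self.base.standardization
        )


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def min_n_simulation(
    dataset: LongitudinalDataset,
    contrast_name: str,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    spec: ModelSpec | None = None,
    scope: str = "slope_terms",
    max_resample: int = 10,
) -> BorderlineDataset:
    """Remove random subjects until the contrast loses significance.

    Returns the last significant dataset and the full removal trace; subjects
    are removed without regard to group, so per-group counts drift freely.
    If the starting dataset is already non-significant, returns it unchanged
    with ``stop_reason='exhausted'``.  Refits that fail (non-convergence or a
    design made rank-deficient by an emptied group) cause the removal target
    to be resampled up to ``max_resample`` times, after which the iteration
    is abandoned as a :class:`SimulationOutlier`.
    """
    rng = _as_rng(rng)
    spec = spec or _default_spec(dataset)
    state = _RemovalState(dataset, spec, contrast_name, scope)
    mask = state.mask.copy()

    fit, res = state.fit_and_test(mask)
    if res.p_value > alpha:
        return BorderlineDataset(
            dataset=state.dataset_for(mask),
            stop_reason="exhausted",
            final_p=res.p_value,
            trace=[],
        )
    state.theta_warm = fit.theta[:-1]
    current_p = res.p_value
    trace: list[RemovalStep] = []
    step = 0
    while True:
        alive = pd.unique(state.row_subject[mask])
        if len(alive) == 0:
            stop_reason, final_mask, final_p = "exhausted", mask, current_p
            break
        candidates = list(rng.permutation(alive))
        placed = False
        for attempt, subj in enumerate(candidates[: max_resample + 1]):
            trial = mask & (state.row_subject != subj)
            n_obs, n_subj = state.counts(trial)
            if n_obs <= state.design.p:
                # too few records left to fit the fixed effects: data exhausted
                return BorderlineDataset(
                    dataset=state.dataset_for(mask),
                    stop_reason="exhausted",
                    final_p=current_p,
                    trace=trace,
                )
            est = check_estimability((n_obs, n_subj), spec.random_structure)
            if not est["estimable"]:
                step += 1
                trace.append(
                    RemovalStep(step, subj, n_subj, n_obs, None, False)
                )
                return BorderlineDataset(
                    dataset=state.dataset_for(mask),
                    stop_reason="estimability_failed",
                    final_p=current_p,
                    trace=trace,
                )
            try:
                fit, res = state.fit_and_test(trial)
            except (FitError, np.linalg.LinAlgError):
                continue
            placed = True
            break
        if not placed:
            if len(candidates) <= max_resample + 1:
                # every remaining subject was tried: nothing can be fitted
                # beyond this point, so the data are exhausted
                return BorderlineDataset(
                    dataset=state.dataset_for(mask),
                    stop_reason="exhausted",
                    final_p=current_p,
                    trace=trace,
                )
            raise SimulationOutlier(
                f"min-N step {step + 1}: {max_resample + 1} candidate removals "
                "all failed to refit"
            )
        step += 1
        trace.append(
            RemovalStep(step, subj, n_subj, n_obs, res.p_value, True)
        )
        if res.p_value > alpha:
            return BorderlineDataset(
                dataset=state.dataset_for(mask),
                stop_reason="p_exceeded",
                final_p=current_p,
                trace=trace,
            )
        mask = trial
        current_p = res.p_value
        state.theta_warm = fit.theta[:-1]

    return BorderlineDataset(
        dataset=state.dataset_for(final_mask),
        stop_reason=stop_reason,
        final_p=final_p,
        trace=trace,
    )


def missing_points_simulation(
    dataset: LongitudinalDataset,
    contrast_name: str,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    spec: ModelSpec | None = None,
    scope: str = "slope_terms",
    allow_subject_loss: bool = False,
    max_resample: int = 10,
) -> BorderlineDataset:
    """Remove random single visits until p > alpha or estimability fails.

    By default a subject's last remaining record is not removable, so visit
    deletion never silently drops subjects; ``allow_subject_loss=True``
    permits it (the subject disappears when its final record is removed).
    The estimability rule is checked *before* each refit; a violating step is
    recorded in the trace (with no p-value) and refused.
    """
    rng = _as_rng(rng)
    spec = spec or _default_spec(dataset)
    state = _RemovalState(dataset, spec, contrast_name, scope)
    mask = state.mask.copy()

    fit, res = state.fit_and_test(mask)
    if res.p_value > alpha:
        return BorderlineDataset(
            dataset=state.dataset_for(mask),
            stop_reason="exhausted",
            final_p=res.p_value,
            trace=[],
        )
    state.theta_warm = fit.theta[:-1]
    current_p = res.p_value
    trace: list[RemovalStep] = []
    step = 0
    while True:
        if allow_subject_loss:
            idx_alive = np.flatnonzero(mask)
        else:
            counts = np.bincount(
                state.row_code[mask], minlength=state.design.n_subjects
            )
            idx_alive = np.flatnonzero(mask & (counts[state.row_code] > 1))
        if len(idx_alive) == 0:
            return BorderlineDataset(
                dataset=state.dataset_for(mask),
                stop_reason="exhausted",
                final_p=current_p,
                trace=trace,
            )
        candidates = rng.permutation(idx_alive)
        placed = False
        for i in candidates[: max_resample + 1]:
            trial = mask.copy()
            trial[i] = False
            n_obs, n_subj = state.counts(trial)
            unit = (state.row_subject[i], float(state.row_time[i]))
            est = check_estimability((n_obs, n_subj), spec.random_structure)
            if not est["estimable"]:
                step += 1
                trace.append(RemovalStep(step, unit, n_subj, n_obs, None, False))
                return BorderlineDataset(
                    dataset=state.dataset_for(mask),
                    stop_reason="estimability_failed",
                    final_p=current_p,
                    trace=trace,
                )
            try:
                fit, res = state.fit_and_test(trial)
            except (FitError, np.linalg.LinAlgError):
                continue
            placed = True
            break
        if not placed:
            raise SimulationOutlier(
                f"missing-points step {step + 1}: {max_resample + 1} candidate "
                "removals all failed to refit"
            )
        step += 1
        trace.append(RemovalStep(step, unit, n_subj, n_obs, res.p_value, True))
        if res.p_value > alpha:
            return BorderlineDataset(
                dataset=state.dataset_for(mask),
                stop_reason="p_exceeded",
                final_p=current_p,
                trace=trace,
            )
        mask = trial
        current_p = res.p_value
        state.theta_warm = fit.theta[:-1]


def _default_spec(dataset: LongitudinalDataset) -> ModelSpec:
    present = dataset.groups_present()
    if not present:
        raise SimulationError("dataset has no recognised clinical groups")
    return ModelSpec(reference_group=present[0])


def run_many(
    simulation_kind: str,
    dataset: LongitudinalDataset,
    contrast_name: str,
    n_iterations: int = 500,
    base_seed: int = 0,
    alpha: float = 0.05,
    spec: ModelSpec | None = None,
    scope: str = "slope_terms",
    allow_subject_loss: bool = False,
) -> tuple[SimulationSummary, list[BorderlineDataset]]:
    """Repeat a removal simulation with per-iteration seeds and aggregate.

    Iteration i uses seed ``base_seed + i``.  Failed iterations
    (:class:`SimulationOutlier`) are counted, not raised.  The summary's
    ``mean_missing_per_subject`` compares each borderline dataset's mean
    visits per remaining subject with the starting dataset's.
    """
    if simulation_kind not in ("min_n", "missing_points"):
        raise SimulationError(f"unknown simulation kind {simulation_kind!r}")
    if n_iterations < 1:
        raise SimulationError("n_iterations must be >= 1")
    runner = min_n_simulation if simulation_kind == "min_n" else missing_points_simulation
    kwargs = {} if simulation_kind == "min_n" else {
        "allow_subject_loss": allow_subject_loss
    }
    start_visits = dataset.n_obs / dataset.n_subjects

    results: list[BorderlineDataset] = []
    outliers = 0
    for i in range(n_iterations):
        seed = base_seed + i
        try:
            bd = runner(
                dataset, contrast_name, alpha=alpha,
                rng=np.random.default_rng(seed), spec=spec, scope=scope, **kwargs
            )
        except SimulationOutlier:
            outliers += 1
            continue
        bd.iteration_seed = seed
        results.append(bd)

    finals = np.array([bd.n_subjects for bd in results], dtype=float)
    group_rows = [bd.dataset.counts_per_group() for bd in results]
    group_counts = pd.DataFrame(group_rows, columns=list(GROUP_LABELS)) if group_rows else (
        pd.DataFrame(columns=list(GROUP_LABELS))
    )
    reasons: dict[str, int] = {"p_exceeded": 0, "estimability_failed": 0, "exhausted": 0}
    for bd in results:
        reasons[bd.stop_reason] += 1
    missing = [
        start_visits - bd.n_obs / bd.n_subjects for bd in results if bd.n_subjects
    ]
    sd_defined = len(finals) > 1
    return (
        SimulationSummary(
            n_iterations=n_iterations,
            kind=simulation_kind,
            contrast_name=contrast_name,
            final_n_mean=float(finals.mean()) if len(finals) else float("nan"),
            final_n_sd=float(finals.std(ddof=1)) if sd_defined else 0.0,
            final_n_sd_defined=sd_defined,
            group_counts=group_counts,
            n_outlier_iterations=outliers,
            stop_reasons=reasons,
            mean_missing_per_subject=float(np.mean(missing)) if missing else 0.0,
        ),
        results,
    )


def verify_borderline(
    bd: BorderlineDataset,
    contrast_name: str,
    alpha: float = 0.05,
    spec: ModelSpec | None = None,
    scope: str = "slope_terms",
) -> dict:
    """Re-check a borderline dataset's stopping property by cold refits.

    Confirms (a) the kept dataset is significant at alpha, and (b) applying
    the trace's final removal reproduces the stop condition: p > alpha for
    ``p_exceeded``, or n_obs <= q * n_subjects for ``estimability_failed``.
    """
    spec = spec or _default_spec(bd.dataset)
    design = build_design(bd.dataset, spec)
    fit = fit_lme(design, "reml")
    contrast = make_contrast(contrast_name, design.x_labels, scope=scope)
    res = f_test_satterthwaite(fit, contrast)
    out = {"kept_p": res.p_value, "kept_significant": res.p_value <= alpha,
           "stop_reason": bd.stop_reason, "stop_confirmed": False}
    if bd.stop_reason == "exhausted":
        out["stop_confirmed"] = not bd.trace
        return out
    last = bd.trace[-1]
    if isinstance(last.removed_unit, tuple):
        nxt = bd.dataset.drop_record(*last.removed_unit)
    else:
        nxt = bd.dataset.filter_subjects(
            set(bd.dataset.subject_ids) - {last.removed_unit}
        )
    est = check_estimability(nxt, spec.random_structure)
    if bd.stop_reason == "estimability_failed":
        out["stop_confirmed"] = not est["estimable"]
    else:
        nfit = fit_lme(build_design(nxt, spec), "reml")
        nres = f_test_satterthwaite(
            nfit, make_contrast(contrast_name, nfit.beta_labels, scope=scope)
        )
        out["next_p"] = nres.p_value
        out["stop_confirmed"] = nres.p_value > alpha
    return out
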