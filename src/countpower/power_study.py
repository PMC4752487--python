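"""Experiment driver: batch simulation + analysis, error-rate tabulation,
ROC/AUC, effect-strength calibration and the sample-size search.

A scenario is one cell of the experimental design: an effect type, a
generating count family, a dataset size and an effect strength.  For each
replicate the driver simulates a count dataset, projects it to
frequencies, scores both representations with the effect-vs-no-effect
log-BML difference, and aggregates the scores into false-negative /
false-positive rates and ROC curves.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .distributions import CountFamily
from .inference import (
    FAST_MCMC,
    McmcConfig,
    ModelSpec,
    PriorSpec,
    build_evaluator,
    detect_effect,
    estimate_log_bml,
    sample_posterior,
)
from .simulate import (
    EffectSpec,
    ExposureSpec,
    default_n_rows,
    simulate_dataset,
    solve_exposure_params,
    to_frequency,
)

__all__ = [
    "Scenario",
    "AnalysisConfig",
    "BatchResult",
    "RocCurve",
    "CalibrationResult",
    "SampleSizeResult",
    "count_model_specs",
    "frequency_model_specs",
    "score_dataset",
    "run_batch",
    "error_rates",
    "calibrate_effect_strength",
    "roc_curve",
    "sample_size_search",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings shared by every model fit in a batch."""

    mcmc: McmcConfig = FAST_MCMC
    n_is_draws: int = 1200
    prior: PriorSpec = field(default_factory=PriorSpec)
    zi_link: str = "corrected"


@dataclass(frozen=True)
class Scenario:
    """One cell of the design: generating family x effect specification."""

    family: CountFamily
    effect: EffectSpec
    n_rows: int | None = None
    exposure: ExposureSpec | None = None
    name: str | None = None

    @property
    def effect_type(self) -> str:
        return self.effect.effect_type

    @property
    def rows(self) -> int:
        return self.n_rows if self.n_rows is not None else default_n_rows(self.effect_type)

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        tag = "effect" if self.effect.effect_present else "null"
        return f"{self.effect_type}-{self.family.family}-{tag}"

    def resolved_exposure(self) -> ExposureSpec:
        return self.exposure if self.exposure is not None else solve_exposure_params()

    def with_strength(self, strength: float) -> "Scenario":
        return dataclasses.replace(
            self, effect=dataclasses.replace(self.effect, strength=strength)
        )

    def null_version(self) -> "Scenario":
        return dataclasses.replace(
            self, effect=dataclasses.replace(self.effect, effect_present=False), name=None
        )

    def with_rows(self, n: int) -> "Scenario":
        return dataclasses.replace(self, n_rows=int(n))


@dataclass
class BatchResult:
    """Per-dataset detection scores for one scenario batch."""

    truth: bool
    scores_count: np.ndarray
    scores_freq: np.ndarray
    flags: list[str]
    scenario: Scenario
    master_seed: int

    @property
    def n_datasets(self) -> int:
        return max(len(self.scores_count), len(self.scores_freq))


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # score threshold generating each point (desc)
    auc: float  # Mann-Whitney probability of correct ranking (ties = 1/2)

    @property
    def trapezoid_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass
class CalibrationResult:
    strength: float
    fn_rate: float
    trace: list[tuple[float, float]]  # (strength, estimated FN)


@dataclass
class SampleSizeResult:
    n: int
    fn_rate: float
    trace: list[tuple[int, float]]


# ---------------------------------------------------------------------------
# model sets and per-dataset scoring
# ---------------------------------------------------------------------------

def count_model_specs(effect_type: str, n_categories: int = 5) -> list[ModelSpec]:
    """The six count models: {Poisson, NB, ZINB} x {no effect, effect}."""
    specs = []
    for fam in ("poisson", "negbinom", "zi_negbinom"):
        for structure in ("none", "mean_only"):
            specs.append(ModelSpec("count", fam, structure, effect_type, n_categories))
    return specs


def frequency_model_specs(effect_type: str, n_categories: int = 5) -> list[ModelSpec]:
    """The three frequency models: no effect, effect on the expectancy, and
    effect on both the expectancy and the zero-inflation."""
    return [
        ModelSpec("frequency", "zi_gamma", s, effect_type, n_categories)
        for s in ("none", "mean_only", "mean_and_zi")
    ]


def score_dataset(dataset, specs: list[ModelSpec], analysis: AnalysisConfig,
                  seed: np.random.SeedSequence) -> tuple[float, dict[str, float]]:
    """Fit every model, estimate its log BML, and return the detection score.

    The score is the log Bayes factor of the best effect model against the
    best no-effect model.
    """
    seeds = seed.spawn(len(specs))
    log_bmls: dict[str, float] = {}
    effect, null = [], []
    for spec, s in zip(specs, seeds):
        s_mcmc, s_is = s.spawn(2)
        ev = build_evaluator(spec, dataset, analysis.prior, analysis.zi_link)
        chains = sample_posterior(ev, analysis.mcmc, s_mcmc)
        with warnings.catch_warnings():
            # degeneracy is recorded on the estimate; don't spam per replicate
            warnings.simplefilter("ignore", RuntimeWarning)
            est = estimate_log_bml(chains, n_draws=analysis.n_is_draws, seed=s_is)
        log_bmls[spec.label] = est.log_bml
        (effect if spec.is_effect_model else null).append(est.log_bml)
    return detect_effect(effect, null).score, log_bmls


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------

def run_batch(scenario: Scenario, n_datasets: int, master_seed: int = 0,
              data_kinds: tuple[str, ...] = ("count", "frequency"),
              analysis: AnalysisConfig = AnalysisConfig()) -> BatchResult:
    """Simulate and analyze ``n_datasets`` replicates of one scenario.

    Per-replicate seeds derive deterministically from ``master_seed``, so a
    batch is exactly reproducible and can be sharded by replicate index.
    Individual replicate failures are recorded as NaN scores plus a flag,
    not raised.
    """
    exposure = scenario.resolved_exposure()
    n_rows = scenario.rows
    want_count = "count" in data_kinds
    want_freq = "frequency" in data_kinds
    c_specs = count_model_specs(scenario.effect_type, scenario.effect.n_categories)
    f_specs = frequency_model_specs(scenario.effect_type, scenario.effect.n_categories)

    scores_count = np.full(n_datasets if want_count else 0, np.nan)
    scores_freq = np.full(n_datasets if want_freq else 0, np.nan)
    flags: list[str] = []
    for rep in range(n_datasets):
        ss = np.random.SeedSequence((master_seed, rep))
        s_sim, s_count, s_freq = ss.spawn(3)
        rng = np.random.default_rng(s_sim)
        ds = simulate_dataset(scenario.family, scenario.effect, exposure, n_rows, rng)
        if want_count:
            try:
                scores_count[rep], _ = score_dataset(ds, c_specs, analysis, s_count)
            except Exception as exc:  # noqa: BLE001 - replicate failures are data
                flags.append(f"rep {rep} count: {exc}")
        if want_freq:
            fds = to_frequency(ds)
            try:
                scores_freq[rep], _ = score_dataset(fds, f_specs, analysis, s_freq)
            except Exception as exc:  # noqa: BLE001
                flags.append(f"rep {rep} frequency: {exc}")
    return BatchResult(
        truth=scenario.effect.effect_present,
        scores_count=scores_count,
        scores_freq=scores_freq,
        flags=flags,
        scenario=scenario,
        master_seed=master_seed,
    )


def _rate(scores: np.ndarray, threshold: float, want_found: bool) -> tuple[float, float]:
    scores = scores[~np.isnan(scores)]  # +-inf are legitimate (decisive) scores
    if scores.size == 0:
        return np.nan, np.nan
    found = scores > np.log(threshold)
    frac = float(np.mean(found != want_found))
    se = float(np.sqrt(frac * (1.0 - frac) / scores.size))
    return frac, se


def error_rates(effect_batch: BatchResult, null_batch: BatchResult,
                threshold: float = 1.0) -> dict[str, float]:
    """False-negative and false-positive rates for both data representations.

    FN = fraction of effect datasets where no effect was declared; FP =
    fraction of null datasets where one was.  ``*_se`` entries carry the
    binomial standard errors of the estimates.
    """
    if not effect_batch.truth or null_batch.truth:
        raise ValueError("expected (effect batch, null batch) in that order")
    if effect_batch.n_datasets == 0 or null_batch.n_datasets == 0:
        raise ValueError("cannot tabulate error rates from an empty batch")
    out: dict[str, float] = {}
    out["fn_count"], out["fn_count_se"] = _rate(effect_batch.scores_count, threshold, True)
    out["fp_count"], out["fp_count_se"] = _rate(null_batch.scores_count, threshold, False)
    out["fn_freq"], out["fn_freq_se"] = _rate(effect_batch.scores_freq, threshold, True)
    out["fp_freq"], out["fp_freq_se"] = _rate(null_batch.scores_freq, threshold, False)
    return out


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_curve(effect_scores, null_scores) -> RocCurve:
    """Threshold-swept ROC over the empirical score values.

    The AUC is the Mann-Whitney probability that a random effect dataset
    outscores a random null dataset (ties counting one half); by
    construction it equals the trapezoidal area under the step curve.
    """
    pos = np.asarray(effect_scores, dtype=float)
    neg = np.asarray(null_scores, dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need nonempty effect and null score vectors")

    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    # declare "found" when score >= t, sweeping t downward through the data
    tpr = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = np.concatenate([[0.0], fpr])
    tpr = np.concatenate([[0.0], tpr])
    thresholds = np.concatenate([[np.inf], thresholds])

    ranks = rankdata(np.concatenate([pos, neg]))  # midranks handle ties
    n1, n2 = pos.size, neg.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n2))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


# ---------------------------------------------------------------------------
# calibration and sample-size search
# ---------------------------------------------------------------------------

def _default_fn_estimator(scenario: Scenario, batch_size: int,
                          analysis: AnalysisConfig, data_kind: str, threshold: float):
    kind = (data_kind,)

    def estimate(value, seed: int) -> float:
        if data_kind == "count":
            scen = scenario.with_strength(float(value))
        else:
            scen = scenario.with_rows(int(value))
        batch = run_batch(scen, batch_size, master_seed=seed, data_kinds=kind,
                          analysis=analysis)
        scores = batch.scores_count if data_kind == "count" else batch.scores_freq
        scores = scores[np.isfinite(scores)]
        if scores.size == 0:
            raise RuntimeError("no replicate produced a usable score")
        return float(np.mean(scores <= np.log(threshold)))

    return estimate


def calibrate_effect_strength(
    scenario: Scenario,
    target_fn: float = 0.1,
    batch_size: int = 200,
    tolerance: float = 0.02,
    max_iter: int = 12,
    master_seed: int = 0,
    analysis: AnalysisConfig = AnalysisConfig(),
    threshold: float = 1.0,
    fn_estimator=None,
) -> CalibrationResult:
    """Search the effect strength whose count-data false-negative rate hits
    ``target_fn``.

    FN is monotonically decreasing in the strength, so the search brackets
    by doubling/halving and then bisects on the log strength.  Each
    evaluation runs a fresh count-analysis batch (seeded from
    ``master_seed``); ``tolerance`` should be at least two binomial
    standard errors of a ``batch_size`` estimate.  ``fn_estimator`` can be
    injected for testing (callable ``(strength, seed) -> fn``).
    """
    if not 0.0 < target_fn < 1.0:
        raise ValueError("target_fn must be in (0, 1)")
    if fn_estimator is None:
        fn_estimator = _default_fn_estimator(scenario, batch_size, analysis,
                                             "count", threshold)
    trace: list[tuple[float, float]] = []
    seed_stream = iter(np.random.SeedSequence((master_seed, 0xCA11B)).generate_state(4 * max_iter))

    def fn_at(s: float) -> float:
        val = fn_estimator(s, int(next(seed_stream)))
        trace.append((s, val))
        return val

    s = scenario.effect.strength if scenario.effect.strength > 0 else 1.0
    fn = fn_at(s)
    evals = 1
    lo = hi = None  # lo: too weak (fn > target), hi: too strong (fn < target)
    if fn > target_fn:
        lo = s
    else:
        hi = s
    # bracket by doubling / halving
    while (lo is None or hi is None) and evals < max_iter:
        if abs(fn - target_fn) <= tolerance:
            return CalibrationResult(strength=s, fn_rate=fn, trace=trace)
        s = s * 2.0 if hi is None else s / 2.0
        fn = fn_at(s)
        evals += 1
        if fn > target_fn:
            lo = s
        else:
            hi = s
    if lo is None or hi is None:
        raise RuntimeError(
            f"could not bracket target FN {target_fn} in {max_iter} evaluations; trace={trace}"
        )
    best = min(trace, key=lambda t: abs(t[1] - target_fn))
    while evals < max_iter and abs(best[1] - target_fn) > tolerance:
        s = float(np.sqrt(lo * hi))  # bisection on the log scale
        fn = fn_at(s)
        evals += 1
        if fn > target_fn:
            lo = s
        else:
            hi = s
        if abs(fn - target_fn) < abs(best[1] - target_fn):
            best = (s, fn)
    if abs(best[1] - target_fn) > tolerance:
        raise RuntimeError(
            f"calibration did not reach |FN - {target_fn}| <= {tolerance} "
            f"after {max_iter} evaluations; trace={trace}"
        )
    return CalibrationResult(strength=best[0], fn_rate=best[1], trace=trace)


def sample_size_search(
    scenario: Scenario,
    fixed_strength: float,
    target_fn: float = 0.1,
    data_kind: str = "frequency",
    bracket: tuple[int, int] = (30, 240),
    batch_size: int = 200,
    tolerance: float = 0.02,
    max_iter: int = 10,
    master_seed: int = 0,
    analysis: AnalysisConfig = AnalysisConfig(),
    threshold: float = 1.0,
    fn_estimator=None,
) -> SampleSizeResult:
    """Rows per dataset needed for ``data_kind`` to reach ``target_fn``.

    Holds the (previously calibrated) effect strength fixed and bisects on
    the dataset size; FN is nonincreasing in n, within Monte Carlo noise.
    """
    scen = scenario.with_strength(fixed_strength)
    if fn_estimator is None:
        fn_estimator = _default_fn_estimator(scen, batch_size, analysis,
                                             data_kind, threshold)
    trace: list[tuple[int, float]] = []
    seed_stream = iter(np.random.SeedSequence((master_seed, 0x5A3)).generate_state(max_iter + 4))

    def fn_at(n: int) -> float:
        val = fn_estimator(n, int(next(seed_stream)))
        trace.append((int(n), val))
        return val

    lo, hi = int(bracket[0]), int(bracket[1])
    fn_lo = fn_at(lo)
    if abs(fn_lo - target_fn) <= tolerance:
        return SampleSizeResult(n=lo, fn_rate=fn_lo, trace=trace)
    if fn_lo < target_fn:
        raise RuntimeError(
            f"FN at the lower bracket n={lo} is already {fn_lo:.3f} < target {target_fn}"
        )
    fn_hi = fn_at(hi)
    if fn_hi > target_fn + tolerance:
        raise RuntimeError(
            f"target FN {target_fn} unattainable within bracket: FN({hi}) = {fn_hi:.3f}"
        )
    best = (hi, fn_hi)
    evals = 2
    while hi - lo > 1 and evals < max_iter:
        mid = (lo + hi) // 2
        fn = fn_at(mid)
        evals += 1
        if abs(fn - target_fn) < abs(best[1] - target_fn):
            best = (mid, fn)
        if abs(fn - target_fn) <= tolerance:
            return SampleSizeResult(n=mid, fn_rate=fn, trace=trace)
        if fn > target_fn:
            lo = mid
        else:
            hi = mid
    return SampleSizeResult(n=best[0], fn_rate=best[1], trace=trace)
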