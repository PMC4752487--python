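"""Dataset generation: exposure sampling, covariate construction, effect-to-
rate mapping, count sampling and the count -> frequency projection.

Each simulated row is an independent observation event: a number of flowers
watched for a fixed time (the exposure), a covariate value, and a visit
count.  The frequency representation divides visits by flowers and discards
the exposure column — deliberately, since quantifying that information loss
is the point of the downstream experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .distributions import CountFamily, count_sample

__all__ = [
    "EffectSpec",
    "ExposureSpec",
    "CountDataset",
    "FrequencyDataset",
    "solve_exposure_params",
    "sample_exposure",
    "make_covariates",
    "draw_random_effects",
    "effect_rate",
    "simulate_dataset",
    "to_frequency",
    "default_n_rows",
]

EFFECT_TYPES = ("fixed_categorical", "fixed_linear", "random_intercept", "random_slope")

#: rows per dataset used in the reference experiments
DEFAULT_N_ROWS = {
    "fixed_categorical": 30,
    "fixed_linear": 30,
    "random_intercept": 75,
    "random_slope": 300,
}

#: probability that the binary covariate equals 1 ("yes")
BINARY_P_YES = 0.6


def default_n_rows(effect_type: str) -> int:
    return DEFAULT_N_ROWS[effect_type]


@dataclass(frozen=True)
class EffectSpec:
    """How a covariate modulates the per-flower visit rate.

    ``strength`` is the fixed-effect slope beta, or the random-effect scale
    (sigma_RE for random intercepts, sigma_RS for random slopes).  With
    ``effect_present=False`` the strength is ignored and the rate is the
    constant baseline ``lambda0``.
    """

    effect_type: str
    lambda0: float = 0.02
    strength: float = 0.0
    n_categories: int = 5
    effect_present: bool = True

    def __post_init__(self) -> None:
        if self.effect_type not in EFFECT_TYPES:
            raise ValueError(f"unknown effect_type {self.effect_type!r}")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be > 0")
        if self.effect_type in ("random_intercept", "random_slope") and self.strength < 0:
            raise ValueError("random-effect strength (a scale) must be >= 0")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")


@dataclass(frozen=True)
class ExposureSpec:
    """Negative binomial distribution of the number of flowers observed.

    Calibrated so that ``P(lower <= N <= upper) = coverage``; draws of zero
    are rejected and redrawn.
    """

    nb_mean: float
    nb_size: float
    lower: int = 10
    upper: int = 1000
    coverage: float = 0.95

    @property
    def nb_p(self) -> float:
        return self.nb_size / (self.nb_size + self.nb_mean)


@dataclass
class CountDataset:
    """Rows of observation events in the count representation."""

    flowers: np.ndarray
    visits: np.ndarray
    category: np.ndarray | None = None
    x: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.flowers)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"flowers": self.flowers})
        df["category"] = self.category if self.category is not None else pd.NA
        df["x"] = self.x if self.x is not None else pd.NA
        df["visits"] = self.visits
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write rows as CSV plus a ``<stem>.meta.json`` sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        _write_meta(path, self.meta)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountDataset":
        path = Path(path)
        df = pd.read_csv(path)
        return cls(
            flowers=df["flowers"].to_numpy(dtype=np.int64),
            visits=df["visits"].to_numpy(dtype=np.int64),
            category=_opt_col(df, "category", np.int64),
            x=_opt_col(df, "x", float),
            meta=_read_meta(path),
        )


@dataclass
class FrequencyDataset:
    """Observation events reduced to visits-per-flower ratios (exposure dropped)."""

    freq: np.ndarray
    category: np.ndarray | None = None
    x: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.freq)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame()
        df["category"] = self.category if self.category is not None else pd.NA
        df["x"] = self.x if self.x is not None else pd.NA
        df["freq"] = self.freq
        return df

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        _write_meta(path, self.meta)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrequencyDataset":
        path = Path(path)
        df = pd.read_csv(path)
        return cls(
            freq=df["freq"].to_numpy(dtype=float),
            category=_opt_col(df, "category", np.int64),
            x=_opt_col(df, "x", float),
            meta=_read_meta(path),
        )


def _opt_col(df: pd.DataFrame, name: str, dtype):
    if name not in df or df[name].isna().all():
        return None
    return df[name].to_numpy(dtype=dtype)


def _write_meta(path: Path, meta: dict) -> None:
    side = path.with_suffix(".meta.json")
    side.write_text(json.dumps(meta, indent=2, default=_jsonable))
    return None


def _read_meta(path: Path) -> dict:
    side = path.with_suffix(".meta.json")
    if side.exists():
        return json.loads(side.read_text())
    return {}


def _jsonable(obj):
    if isinstance(obj, (CountFamily, EffectSpec, ExposureSpec)):
        return asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")


# ---------------------------------------------------------------------------
# exposure
# ---------------------------------------------------------------------------

def solve_exposure_params(
    lower: int = 10, upper: int = 1000, coverage: float = 0.95
) -> ExposureSpec:
    """Solve for the negative binomial exposure parameters.

    The two parameters (mean, size) are pinned down by the two symmetric
    tail equations ``P(N < lower) = P(N > upper) = (1 - coverage) / 2``.
    """
    if not lower < upper:
        raise ValueError("need lower < upper")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    tail = (1.0 - coverage) / 2.0

    def equations(log_params):
        mean, size = np.exp(log_params)
        p = size / (size + mean)
        # log-scale residuals keep the system well conditioned for tiny tails
        lo_tail = max(stats.nbinom.cdf(lower - 1, size, p), 1e-300)
        hi_tail = max(stats.nbinom.sf(upper, size, p), 1e-300)
        return [np.log(lo_tail) - np.log(tail), np.log(hi_tail) - np.log(tail)]

    sol = None
    for size0 in (1.0, 0.3, 3.0, 10.0):
        guess = np.log([np.sqrt(float(lower) * float(upper)), size0])
        sol = optimize.root(equations, guess, method="hybr")
        if sol.success:
            break
    if sol is None or not sol.success:
        raise RuntimeError(f"exposure solver failed: {sol.message}; residual {sol.fun}")
    mean, size = np.exp(sol.x)
    spec = ExposureSpec(nb_mean=float(mean), nb_size=float(size),
                        lower=lower, upper=upper, coverage=coverage)
    achieved = stats.nbinom.cdf(upper, size, spec.nb_p) - stats.nbinom.cdf(lower - 1, size, spec.nb_p)
    if abs(achieved - coverage) > 1e-3:
        raise RuntimeError(
            f"exposure solution violates coverage: got {achieved:.5f}, wanted {coverage}"
        )
    return spec


def sample_exposure(spec: ExposureSpec, rng: np.random.Generator, size: int | None = None):
    """Draw flower counts; zero draws are resampled so every row has N >= 1."""
    scalar = size is None
    n = 1 if scalar else int(size)
    out = rng.negative_binomial(spec.nb_size, spec.nb_p, size=n)
    bad = out == 0
    while bad.any():
        out[bad] = rng.negative_binomial(spec.nb_size, spec.nb_p, size=int(bad.sum()))
        bad = out == 0
    return int(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# covariates and effects
# ---------------------------------------------------------------------------

def make_covariates(
    effect_type: str,
    n: int,
    rng: np.random.Generator,
    n_categories: int = 5,
) -> dict[str, np.ndarray]:
    """Build the covariate columns for one dataset.

    fixed_categorical: binary x ~ Bernoulli(0.6); fixed_linear: x ~ U(0, 1);
    random_intercept: categories cycled so each appears n/n_categories times;
    random_slope: the category cycle crossed with an equally spaced grid of
    x in [0, 1] within each category.
    """
    if effect_type == "fixed_categorical":
        return {"x": (rng.random(n) < BINARY_P_YES).astype(float)}
    if effect_type == "fixed_linear":
        return {"x": rng.random(n)}
    if effect_type in ("random_intercept", "random_slope"):
        if n % n_categories != 0:
            raise ValueError(
                f"n={n} not divisible by n_categories={n_categories} for {effect_type}"
            )
        per = n // n_categories
        category = np.repeat(np.arange(n_categories), per)
        if effect_type == "random_intercept":
            return {"category": category}
        grid = np.linspace(0.0, 1.0, per)
        return {"category": category, "x": np.tile(grid, n_categories)}
    raise ValueError(f"unknown effect_type {effect_type!r}")


def draw_random_effects(spec: EffectSpec, rng: np.random.Generator) -> np.ndarray | None:
    """Per-category effect draws (one set per dataset), or None for fixed effects."""
    if spec.effect_type in ("fixed_categorical", "fixed_linear"):
        return None
    scale = spec.strength if spec.effect_present else 0.0
    return rng.normal(0.0, scale, size=spec.n_categories)


def effect_rate(
    spec: EffectSpec,
    covariates: dict[str, np.ndarray],
    random_draws: np.ndarray | None = None,
) -> np.ndarray:
    """Per-row rate lambda through the log link.

    fixed: ``lambda = lambda0 * exp(beta * x)``; random intercept:
    ``lambda0 * exp(eps[category])``; random slope:
    ``lambda0 * exp(b[category] * x)``.  A null effect gives ``lambda0``.
    """
    lam0 = spec.lambda0
    if spec.effect_type in ("fixed_categorical", "fixed_linear"):
        beta = spec.strength if spec.effect_present else 0.0
        return lam0 * np.exp(beta * np.asarray(covariates["x"], dtype=float))
    if random_draws is None:
        raise ValueError(f"{spec.effect_type} requires per-category random draws")
    cat = np.asarray(covariates["category"])
    if cat.max() >= len(random_draws):
        raise ValueError("category index exceeds the supplied random draws")
    if spec.effect_type == "random_intercept":
        return lam0 * np.exp(random_draws[cat])
    return lam0 * np.exp(random_draws[cat] * np.asarray(covariates["x"], dtype=float))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def simulate_dataset(
    family: CountFamily,
    spec: EffectSpec,
    exposure: ExposureSpec,
    n: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> CountDataset:
    """Simulate one count dataset row by row (exposure, covariate, count).

    ``rng`` may be a Generator or an integer seed; the seed recorded in the
    metadata reproduces the dataset exactly.
    """
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = int(rng) if rng is not None else 0
        rng = np.random.default_rng(seed)
    if n is None:
        n = default_n_rows(spec.effect_type)
    flowers = sample_exposure(exposure, rng, size=n)
    cov = make_covariates(spec.effect_type, n, rng, spec.n_categories)
    draws = draw_random_effects(spec, rng)
    rate = effect_rate(spec, cov, draws)
    visits = count_sample(rate, flowers, family, rng)
    meta = {
        "effect": spec,
        "family": family,
        "exposure": exposure,
        "n": n,
        "seed": seed,
        "random_draws": draws,
    }
    return CountDataset(
        flowers=np.asarray(flowers, dtype=np.int64),
        visits=np.asarray(visits, dtype=np.int64),
        category=cov.get("category"),
        x=cov.get("x"),
        meta=meta,
    )


def to_frequency(ds: CountDataset) -> FrequencyDataset:
    """Project a count dataset to visitation frequencies (visits / flowers).

    The exposure column is dropped from the rows by design; it stays
    available in the metadata so the projection can be inverted for audits.
    """
    if np.any(ds.flowers <= 0):
        raise ValueError("flowers must be >= 1")
    meta = dict(ds.meta)
    meta["flowers"] = np.asarray(ds.flowers).copy()
    return FrequencyDataset(
        freq=ds.visits / ds.flowers,
        category=None if ds.category is None else ds.category.copy(),
        x=None if ds.x is None else ds.x.copy(),
        meta=meta,
    )
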