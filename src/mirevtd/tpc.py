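"""Bayesian thermal performance curve (TPC) fitting.

A thermal performance curve describes how a trait — here, typically juvenile
development rate of a mosquito — varies with temperature: zero below a
critical minimum T_min, rising to a peak at T_pk, and collapsing to zero at a
critical maximum T_max.  This module fits the Briere-1 form,

    rate(T) = q * T * (T - T_min) * sqrt(T_max - T)   for T_min < T < T_max,
    rate(T) = 0                                        otherwise,

the standard asymmetric choice for arthropod development rate, with a
Gaussian observation model and independent uniform ("weakly informative")
priors on (q, T_min, T_max, sigma).  Sampling is single-chain random-walk
Metropolis with component-wise updates whose proposal scales adapt during
burn-in toward a 25-40% acceptance rate and are then frozen, preserving
detailed balance in the sampling phase.

The point of fitting both individual observations and per-temperature
averages with the same priors is to show, on data with known truth, that
aggregation irreversibly loses information: posterior intervals for the
thermal limits widen when only the averages are kept.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._errors import InferenceError

_PARAM_NAMES = ("q", "t_min", "t_max", "sigma")
_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TPCModel:
    """One point in TPC parameter space.

    q: rate scaling constant (> 0), trait units per (degC^2 * degC^0.5);
    t_min, t_max: critical thermal limits in degC (t_min < t_max);
    sigma: observation noise SD (> 0), trait units.
    """

    q: float
    t_min: float
    t_max: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise InferenceError("q must be > 0")
        if not self.sigma > 0:
            raise InferenceError("sigma must be > 0")
        if not self.t_min < self.t_max:
            raise InferenceError("t_min must be < t_max")


def briere(t, q: float, t_min: float, t_max: float):
    """Briere-1 curve, vectorized over temperature; 0 at and outside the limits."""
    if not t_min < t_max:
        raise InferenceError("t_min must be < t_max")
    t = np.asarray(t, dtype=float)
    inside = (t > t_min) & (t < t_max)
    out = np.zeros_like(t)
    ti = t[inside]
    out[inside] = q * ti * (ti - t_min) * np.sqrt(t_max - ti)
    if out.ndim == 0:
        return float(out)
    return out


def derived_tpk(params: TPCModel) -> float:
    """Temperature of peak performance, from the closed-form argmax.

    Setting d/dT log briere = 0 gives 5 T^2 - (4 T_max + 3 T_min) T
    + 2 T_min T_max = 0; the root inside (T_min, T_max) is the peak.  With
    T_min = 0 this reduces to 0.8 T_max.  Independent of q.
    """
    return _tpk(params.t_min, params.t_max)


def _tpk(t_min, t_max):
    t_min = np.asarray(t_min, dtype=float)
    t_max = np.asarray(t_max, dtype=float)
    b = 4.0 * t_max + 3.0 * t_min
    disc = np.sqrt(16.0 * np.square(t_max) + 9.0 * np.square(t_min)
                   - 16.0 * t_min * t_max)
    # both stationary points can fall inside (t_min, t_max) when t_min < 0;
    # the peak is whichever root gives the larger curve value
    lo = (b - disc) / 10.0
    hi = (b + disc) / 10.0
    eps = 1e-12 * np.maximum(t_max - t_min, 1.0)
    lo_c = np.clip(lo, t_min + eps, t_max - eps)
    hi_c = np.clip(hi, t_min + eps, t_max - eps)

    def f(t):
        return t * (t - t_min) * np.sqrt(np.maximum(t_max - t, 0.0))

    return np.where(f(lo_c) >= f(hi_c), lo_c, hi_c) + 0.0


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform prior bounds per parameter.

    A degenerate bound (lo == hi) pins that parameter at the value and
    removes it from sampling.  The joint support additionally requires
    t_min < t_max.
    """

    q: tuple[float, float] = (0.0, 1.0)
    t_min: tuple[float, float] = (-10.0, 25.0)
    t_max: tuple[float, float] = (25.0, 50.0)
    sigma: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InferenceError(f"prior for {name} has lo > hi")
        if self.t_min[0] >= self.t_max[1]:
            raise InferenceError("t_min and t_max supports leave no t_min < t_max")

    def bounds(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _PARAM_NAMES], dtype=float)

    @classmethod
    def for_data(cls, y, q_upper: float = 1.0) -> "PriorSpec":
        """Weakly informative defaults with sigma scaled to the trait.

        The sigma upper bound is 10x the sample SD of the observations (or
        10x the mean magnitude if the SD is degenerate), so the prior stays
        diffuse on whatever scale the trait is measured.
        """
        y = np.asarray(y, dtype=float)
        scale = float(np.std(y))
        if not scale > 0:
            scale = max(float(np.mean(np.abs(y))), 1.0)
        return cls(q=(0.0, q_upper), sigma=(0.0, 10.0 * scale))

    def to_json(self) -> str:
        return json.dumps({n: list(getattr(self, n)) for n in _PARAM_NAMES}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PriorSpec":
        doc = json.loads(text)
        return cls(**{n: tuple(doc[n]) for n in _PARAM_NAMES if n in doc})


# ---------------------------------------------------------------------------
# posterior
# ---------------------------------------------------------------------------

def _log_post_vec(x: np.ndarray, t: np.ndarray, y: np.ndarray,
                  bounds: np.ndarray) -> float:
    """Unnormalized log posterior at parameter vector x = (q, t_min, t_max, sigma)."""
    q, t_min, t_max, sigma = x
    # support: inside the (possibly degenerate) box, ordered limits, positive q/sigma
    if np.any(x < bounds[:, 0]) or np.any(x > bounds[:, 1]):
        return -np.inf
    if not (t_min < t_max) or q <= 0.0 or sigma <= 0.0:
        return -np.inf
    if t.size == 0:
        return 0.0  # prior-only: flat within support
    mu = briere(t, q, t_min, t_max)
    resid = y - mu
    n = t.size
    return float(-0.5 * n * _LOG_2PI - n * math.log(sigma)
                 - 0.5 * float(resid @ resid) / (sigma * sigma))


def log_posterior(params: TPCModel, data, priors: PriorSpec) -> float:
    """Log posterior (up to the uniform-prior constant) of a TPCModel.

    ``data`` is a sequence of (temperature, trait value) pairs.  Returns
    -inf outside the prior support; with a flat prior the in-support value
    equals the Gaussian log likelihood.
    """
    t, y = _split_data(data, allow_empty=True)
    x = np.array([params.q, params.t_min, params.t_max, params.sigma])
    return _log_post_vec(x, t, y, priors.bounds())


def _split_data(data, allow_empty: bool = False):
    arr = np.asarray(list(data), dtype=float)
    if arr.size == 0:
        if allow_empty:
            return np.empty(0), np.empty(0)
        raise InferenceError("data is empty")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InferenceError("data must be (temperature, value) pairs")
    return arr[:, 0].copy(), arr[:, 1].copy()


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCConfig:
    """Random-walk Metropolis settings.

    n_iter kept draws after n_burn adaptive burn-in sweeps; one sweep updates
    each free parameter once.  Proposal scales start at ``initial_scale_frac``
    of each prior width and are multiplied by exp(acc - 0.325) per adaptation
    window during burn-in (targeting 25-40% acceptance), then frozen.
    """

    n_iter: int = 20000
    n_burn: int = 5000
    seed: int = 0
    initial_scale_frac: float = 0.1
    adapt_interval: int = 50


@dataclass
class TPCChain:
    """Post-burn-in samples plus diagnostics from one fit."""

    samples: np.ndarray  # (n_iter, 4) in order (q, t_min, t_max, sigma)
    param_names: tuple[str, ...]
    acceptance_rate: float
    seed: int
    ok: bool  # False flags chain degeneracy (acceptance < 1%)
    proposal_scales: np.ndarray = field(default=None)

    def get(self, name: str) -> np.ndarray:
        return self.samples[:, self.param_names.index(name)]

    def tpk_samples(self) -> np.ndarray:
        return _tpk(self.get("t_min"), self.get("t_max"))

    def peak_rate_samples(self) -> np.ndarray:
        tpk = self.tpk_samples()
        q = self.get("q")
        t_min = self.get("t_min")
        t_max = self.get("t_max")
        return q * tpk * (tpk - t_min) * np.sqrt(np.maximum(t_max - tpk, 0.0))


def fit_tpc(data, priors: PriorSpec, config: MCMCConfig) -> TPCChain:
    """Fit the Briere TPC by adaptive random-walk Metropolis.

    ``data`` is a sequence of (temperature, value) pairs; at least four
    distinct temperatures are required (one per free parameter).  An empty
    sequence is allowed and samples the prior (useful for prior-recovery
    checks).  Identical (data, priors, config) give an identical chain.
    """
    t, y = _split_data(data, allow_empty=True)
    if 0 < len(np.unique(t)) < 4:
        raise InferenceError(
            f"need >= 4 distinct temperatures, got {len(np.unique(t))}")
    bounds = priors.bounds()
    widths = bounds[:, 1] - bounds[:, 0]
    free = np.nonzero(widths > 0)[0]
    if free.size == 0:
        raise InferenceError("all parameters are pinned; nothing to sample")
    rng = np.random.default_rng(config.seed)

    x = _draw_initial(rng, bounds)
    lp = _log_post_vec(x, t, y, bounds)
    scales = np.where(widths > 0, config.initial_scale_frac * widths, 0.0)

    n_total = config.n_burn + config.n_iter
    samples = np.empty((config.n_iter, 4))
    acc_window = np.zeros(4)
    n_window = 0
    accepted_post = 0
    proposed_post = 0

    for it in range(n_total):
        burn = it < config.n_burn
        for j in free:
            prop = x.copy()
            prop[j] += scales[j] * rng.standard_normal()
            lp_prop = _log_post_vec(prop, t, y, bounds)
            if lp_prop - lp > math.log(rng.uniform()):
                x, lp = prop, lp_prop
                acc_window[j] += 1
                if not burn:
                    accepted_post += 1
            if not burn:
                proposed_post += 1
        n_window += 1
        if burn and n_window == config.adapt_interval:
            rate = acc_window[free] / n_window
            scales[free] *= np.exp(np.clip(rate - 0.325, -1.0, 1.0))
            scales[free] = np.clip(scales[free], 1e-12 * widths[free], widths[free])
            acc_window[:] = 0.0
            n_window = 0
        elif not burn and n_window == config.adapt_interval:
            acc_window[:] = 0.0
            n_window = 0
        if not burn:
            samples[it - config.n_burn] = x

    acc_rate = accepted_post / max(proposed_post, 1)
    return TPCChain(
        samples=samples,
        param_names=_PARAM_NAMES,
        acceptance_rate=acc_rate,
        seed=config.seed,
        ok=acc_rate >= 0.01,
        proposal_scales=scales,
    )


def _draw_initial(rng, bounds: np.ndarray) -> np.ndarray:
    for _ in range(1000):
        x = rng.uniform(bounds[:, 0], bounds[:, 1])
        if x[1] < x[2] and x[0] > 0 and x[3] > 0:
            return x
    raise InferenceError("could not draw an initial point with t_min < t_max")


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hpd_interval(samples, prob: float) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(prob * n) sorted samples.

    Ties between equally short windows are broken by the lowest start.
    """
    arr = np.sort(np.asarray(samples, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("no samples")
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    m = math.ceil(prob * n)
    if m >= n:
        return float(arr[0]), float(arr[-1])
    widths = arr[m - 1:] - arr[: n - m + 1]
    start = int(np.argmin(widths))  # argmin returns the first (lowest) minimum
    return float(arr[start]), float(arr[start + m - 1])


@dataclass(frozen=True)
class ParamSummary:
    median: float
    hpd_low: float
    hpd_high: float

    @property
    def width(self) -> float:
        return self.hpd_high - self.hpd_low


@dataclass(frozen=True)
class PosteriorSummary:
    """Medians and 95% HPD intervals per parameter, plus derived T_pk and
    peak rate, and chain diagnostics."""

    params: dict[str, ParamSummary]
    acceptance_rate: float
    n_samples: int
    seed: int
    ok: bool
    prob: float = 0.95

    def to_json(self) -> str:
        doc = {
            "prob": self.prob,
            "acceptance_rate": self.acceptance_rate,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "ok": self.ok,
            "params": {
                name: {"median": s.median, "hpd_low": s.hpd_low,
                       "hpd_high": s.hpd_high}
                for name, s in self.params.items()
            },
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PosteriorSummary":
        doc = json.loads(text)
        return cls(
            params={
                name: ParamSummary(d["median"], d["hpd_low"], d["hpd_high"])
                for name, d in doc["params"].items()
            },
            acceptance_rate=doc["acceptance_rate"],
            n_samples=doc["n_samples"],
            seed=doc["seed"],
            ok=doc["ok"],
            prob=doc["prob"],
        )


def summarize_chain(chain: TPCChain, prob: float = 0.95) -> PosteriorSummary:
    """Median and HPD summary of a chain, including derived quantities."""
    params: dict[str, ParamSummary] = {}
    for name in chain.param_names:
        s = chain.get(name)
        lo, hi = hpd_interval(s, prob)
        params[name] = ParamSummary(float(np.median(s)), lo, hi)
    for name, s in (("t_pk", chain.tpk_samples()),
                    ("peak_rate", chain.peak_rate_samples())):
        lo, hi = hpd_interval(s, prob)
        params[name] = ParamSummary(float(np.median(s)), lo, hi)
    return PosteriorSummary(
        params=params,
        acceptance_rate=chain.acceptance_rate,
        n_samples=chain.samples.shape[0],
        seed=chain.seed,
        ok=chain.ok,
        prob=prob,
    )


# ---------------------------------------------------------------------------
# comparison of fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitComparison:
    """Aggregated-vs-individual fit contrast per parameter.

    median_diff is (aggregated - individual); width_ratio is the ratio of
    HPD widths (aggregated / individual), 1.0 when both widths are zero.
    """

    median_diff: dict[str, float]
    width_ratio: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {"median_diff": self.median_diff, "width_ratio": self.width_ratio},
            indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FitComparison":
        doc = json.loads(text)
        return cls(median_diff=dict(doc["median_diff"]),
                   width_ratio=dict(doc["width_ratio"]))

    def render_text(self) -> str:
        lines = ["Aggregated vs individual fit",
                 f"{'parameter':<12}{'median diff':>14}{'HPD width ratio':>18}"]
        for name in self.median_diff:
            lines.append(
                f"{name:<12}{self.median_diff[name]:>14.6g}"
                f"{self.width_ratio[name]:>18.6g}")
        return "\n".join(lines) + "\n"


def compare_fits(fit_individual: PosteriorSummary,
                 fit_aggregated: PosteriorSummary) -> FitComparison:
    """Contrast two posterior summaries fitted with the same priors."""
    diffs: dict[str, float] = {}
    ratios: dict[str, float] = {}
    for name in fit_individual.params:
        if name not in fit_aggregated.params:
            continue
        a = fit_aggregated.params[name]
        b = fit_individual.params[name]
        diffs[name] = a.median - b.median
        if b.width == 0.0:
            ratios[name] = 1.0 if a.width == 0.0 else math.inf
        else:
            ratios[name] = a.width / b.width
    return FitComparison(median_diff=diffs, width_ratio=ratios)


# ---------------------------------------------------------------------------
# dataset glue
# ---------------------------------------------------------------------------

def dataset_to_xy(dataset, axis_field: str = "axis_1_value"):
    """Extract (temperature, trait value) pairs from a TraitDataset."""
    t = dataset.numeric_column(axis_field)
    y = dataset.numeric_column("trait_value")
    return list(zip(t, y))


def fit_dataset(dataset, axis_field: str = "axis_1_value",
                priors: PriorSpec | None = None,
                config: MCMCConfig | None = None) -> tuple[TPCChain, PosteriorSummary]:
    """Convenience: fit a TraitDataset's trait against one numeric axis."""
    data = dataset_to_xy(dataset, axis_field)
    if priors is None:
        priors = PriorSpec.for_data([y for _, y in data])
    chain = fit_tpc(data, priors, config or MCMCConfig())
    return chain, summarize_chain(chain)
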