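"""Maximum-likelihood fitting, AICc multimodel inference and profile CIs.

Positive parameters (baseline rate, Weibull shape, social transmission
rates) are optimised on the log scale so the box constraints become an
unconstrained problem; covariate effects are unconstrained.  Model
comparison uses AICc with the number of acquisition events as the sample
size, Akaike weights, and summed weights per transmission hypothesis.
Confidence intervals are profile-likelihood intervals (nuisance parameters
re-optimised at each fixed value of the target, including a reparameterised
profile for the difference of two transmission rates).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    CHI2_95_HALF,
    ConfigurationError,
    DiffusionData,
    DiffusionDesign,
    IndividualCovariates,
    ModelSpec,
    NetworkStack,
    ValidationError,
    build_design,
    loglik_from_design,
)

__all__ = [
    "FitResult",
    "ModelSetResult",
    "ProfileCI",
    "fit_model",
    "aicc",
    "akaike_weights",
    "model_average",
    "likelihood_interval",
    "profile_ci",
    "percent_social",
    "PercentSocial",
    "fit_model_set",
    "classify_spec",
    "build_candidate_specs",
    "evaluate_at",
]

log = logging.getLogger(__name__)

_BIG = 1e12  # objective value returned for numerically invalid points


# ---------------------------------------------------------------------------
# parameter layout
# ---------------------------------------------------------------------------


@dataclass
class ParamLayout:
    """Mapping between named natural parameters and the optimiser vector."""

    spec: ModelSpec
    layer_names: list[str]  # design layers ("homogeneous" collapses to one)
    ilv_cols: list[str]
    names: list[str] = field(init=False)
    positive: dict[str, bool] = field(init=False)
    s_names: list[str] = field(init=False)

    def __post_init__(self):
        spec = self.spec
        names = ["lambda0"]
        if spec.baseline == "weibull":
            names.append("kappa")
        if spec.layer_constraint == "free":
            s_names = [f"s_{l}" for l in self.layer_names]
        elif spec.layer_constraint == "zero":
            s_names = [
                f"s_{l}" for l in self.layer_names if l not in spec.zero_layers
            ]
        elif spec.layer_constraint in ("shared", "homogeneous"):
            s_names = ["s"]
        else:  # asocial
            s_names = []
        names.extend(s_names)
        beta_names = [f"beta_{c}" for c in self.ilv_cols]
        names.extend(beta_names)
        self.names = names
        self.s_names = s_names
        self.positive = {n: not n.startswith("beta_") for n in names}

    def s_vector(self, values: Mapping[str, float]) -> np.ndarray:
        """Expand named s parameters to one rate per design layer."""
        spec = self.spec
        if spec.layer_constraint == "asocial":
            return np.zeros(len(self.layer_names))
        if spec.layer_constraint in ("shared",):
            return np.full(len(self.layer_names), values["s"])
        if spec.layer_constraint == "homogeneous":
            return np.array([values["s"]])
        out = np.zeros(len(self.layer_names))
        for k, l in enumerate(self.layer_names):
            name = f"s_{l}"
            if name in values:
                out[k] = values[name]
        return out

    def beta_vector(self, values: Mapping[str, float]) -> np.ndarray:
        return np.array([values[f"beta_{c}"] for c in self.ilv_cols])


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate model."""

    spec: ModelSpec
    estimates: dict[str, float]
    loglik: float
    aicc: float
    n_params: int
    n_events: int
    converged: bool
    message: str = ""
    layout: ParamLayout | None = field(default=None, repr=False)
    designs: list[DiffusionDesign] | None = field(default=None, repr=False)

    def params_dict(self) -> dict:
        """Estimates in the form the model layer expects."""
        assert self.layout is not None
        out: dict = {"lambda0": self.estimates["lambda0"]}
        if self.spec.baseline == "weibull":
            out["kappa"] = self.estimates["kappa"]
        out["s"] = self.layout.s_vector(self.estimates)
        out["beta"] = self.layout.beta_vector(self.estimates)
        return out


# ---------------------------------------------------------------------------
# core optimisation machinery
# ---------------------------------------------------------------------------


def _prepare(
    diffusions: Sequence[DiffusionData],
    stacks: Mapping[str, NetworkStack],
    cov: IndividualCovariates | None,
    spec: ModelSpec,
) -> tuple[list[DiffusionDesign], ParamLayout]:
    if not diffusions:
        raise ValidationError("no diffusions supplied")
    layer_names = None
    designs = []
    for diff in diffusions:
        if diff.site not in stacks:
            raise ConfigurationError(
                f"trial {diff.trial_id}: no network stack for site {diff.site!r}"
            )
        stack = stacks[diff.site]
        if layer_names is None:
            layer_names = list(stack.layer_names)
        elif list(stack.layer_names) != layer_names:
            raise ConfigurationError("stacks must share layer names across sites")
        designs.append(build_design(diff, stack, cov, spec))
    if sum(d.n_events for d in designs) < 1:
        raise ValidationError("at least one acquisition event is required")
    design_layers = (
        ["homogeneous"] if spec.layer_constraint == "homogeneous" else layer_names
    )
    ilv_cols = designs[0].ilv_cols
    layout = ParamLayout(spec=spec, layer_names=design_layers, ilv_cols=ilv_cols)
    return designs, layout


def _total_loglik_values(
    designs: Sequence[DiffusionDesign],
    spec: ModelSpec,
    layout: ParamLayout,
    values: Mapping[str, float],
) -> float:
    lambda0 = values["lambda0"]
    kappa = values.get("kappa") if spec.baseline == "weibull" else None
    s = layout.s_vector(values)
    beta = layout.beta_vector(values)
    return sum(
        loglik_from_design(d, spec, lambda0, s, beta, kappa) for d in designs
    )


def _maximize(
    designs: Sequence[DiffusionDesign],
    spec: ModelSpec,
    layout: ParamLayout,
    start_values: Mapping[str, float],
    fixed: Mapping[str, float] | None = None,
    diff_fix: tuple[str, str, float] | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[dict[str, float], float, bool, str]:
    """Maximise the total log-likelihood over the free parameters.

    ``fixed`` pins named parameters at natural values (they leave the
    optimiser vector).  ``diff_fix = (a, b, d)`` pins the difference of two
    transmission rates, value(a) - value(b) = d, replacing both with one
    free parameter for value(b) constrained to keep both rates >= 0.
    """
    fixed = dict(fixed or {})
    diff_names: tuple[str, ...] = ()
    if diff_fix is not None:
        a, b, d = diff_fix
        diff_names = (a, b)
        for nm in (a, b):
            if nm not in layout.names:
                raise ConfigurationError(f"unknown parameter {nm!r}")
    free = [n for n in layout.names if n not in fixed and n not in diff_names]
    vec_names = free + (["__diff_base"] if diff_fix is not None else [])

    def to_values(theta: np.ndarray) -> dict[str, float]:
        vals = dict(fixed)
        for k, name in enumerate(free):
            x = theta[k]
            vals[name] = float(np.exp(x)) if layout.positive[name] else float(x)
        if diff_fix is not None:
            a, b, d = diff_fix
            base = max(0.0, -d) + float(np.exp(theta[len(free)]))
            vals[b] = base
            vals[a] = base + d
        return vals

    def to_theta(vals: Mapping[str, float]) -> np.ndarray:
        theta = np.empty(len(vec_names))
        for k, name in enumerate(free):
            v = vals[name]
            theta[k] = np.log(max(v, 1e-300)) if layout.positive[name] else v
        if diff_fix is not None:
            a, b, d = diff_fix
            base = max(vals.get(b, 1.0), max(0.0, -d) + 1e-6)
            theta[len(free)] = np.log(base - max(0.0, -d) + 1e-12)
        return theta

    def nll(theta: np.ndarray) -> float:
        if not np.all(np.isfinite(theta)) or np.any(theta > 700):
            return _BIG
        vals = to_values(theta)
        try:
            ll = _total_loglik_values(designs, spec, layout, vals)
        except FloatingPointError:
            return _BIG
        if not np.isfinite(ll):
            return _BIG
        return -ll

    if not vec_names:  # everything fixed: nothing to optimise
        vals = to_values(np.empty(0))
        ll = _total_loglik_values(designs, spec, layout, vals)
        return vals, ll, True, "all parameters fixed"

    rng = np.random.default_rng(seed)
    theta0 = to_theta(start_values)
    best = None
    message = ""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for start in range(max(1, n_starts)):
            theta = theta0 if start == 0 else theta0 + rng.normal(0.0, 1.0, theta0.shape)
            res = optimize.minimize(nll, theta, method="L-BFGS-B")
            log.debug(
                "start %d: nll=%.6f success=%s nit=%d", start, res.fun, res.success,
                res.nit,
            )
            if best is None or res.fun < best.fun:
                best = res
        # polish the winner with Nelder-Mead, which is robust near ridges
        polish = optimize.minimize(
            nll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if polish.fun <= best.fun:
            best = polish
    ok = bool(np.isfinite(best.fun)) and best.fun < _BIG / 2
    message = str(getattr(best, "message", ""))
    return to_values(best.x), -float(best.fun), ok, message


def _default_start(
    designs: Sequence[DiffusionDesign], spec: ModelSpec, layout: ParamLayout
) -> dict[str, float]:
    n_events = sum(d.n_events for d in designs)
    exposure = sum(
        float(np.sum((d.seg_hi - d.seg_lo)[:, None] * d.risk)) for d in designs
    )
    lam0 = n_events / max(exposure, 1e-300)
    start = {"lambda0": max(lam0, 1e-300)}
    if spec.baseline == "weibull":
        start["kappa"] = 1.0
        # with kappa=1 the Weibull baseline equals the constant one
    for name in layout.s_names:
        start[name] = 1.0
    for c in layout.ilv_cols:
        start[f"beta_{c}"] = 0.0
    return start


def fit_model(
    diffusions: Sequence[DiffusionData],
    stacks: Mapping[str, NetworkStack],
    cov: IndividualCovariates | None,
    spec: ModelSpec,
    seed: int = 0,
    n_starts: int = 5,
) -> FitResult:
    """Fit one candidate model by maximum likelihood (multi-start)."""
    designs, layout = _prepare(diffusions, stacks, cov, spec)
    start = _default_start(designs, spec, layout)
    values, ll, ok, message = _maximize(
        designs, spec, layout, start, n_starts=n_starts, seed=seed
    )
    n_events = sum(d.n_events for d in designs)
    k = len(layout.names)
    crit = aicc(ll, k, n_events)
    estimates = {n: values[n] for n in layout.names}
    return FitResult(
        spec=spec,
        estimates=estimates,
        loglik=ll,
        aicc=crit,
        n_params=k,
        n_events=n_events,
        converged=ok,
        message=message,
        layout=layout,
        designs=designs,
    )


def evaluate_at(
    diffusions: Sequence[DiffusionData],
    stacks: Mapping[str, NetworkStack],
    cov: IndividualCovariates | None,
    spec: ModelSpec,
    values: Mapping[str, float],
) -> FitResult:
    """Evaluate one model at fixed named parameter values (no optimisation).

    Useful for computing the likelihood or the social/asocial decomposition
    at known (e.g. generative) parameters.
    """
    designs, layout = _prepare(diffusions, stacks, cov, spec)
    missing = [n for n in layout.names if n not in values]
    if missing:
        raise ConfigurationError(f"missing parameter value(s): {missing}")
    vals = {n: float(values[n]) for n in layout.names}
    ll = _total_loglik_values(designs, spec, layout, vals)
    n_events = sum(d.n_events for d in designs)
    k = len(layout.names)
    return FitResult(
        spec=spec,
        estimates=vals,
        loglik=ll,
        aicc=aicc(ll, k, n_events) if n_events - k - 1 > 0 else np.nan,
        n_params=k,
        n_events=n_events,
        converged=True,
        message="evaluated at fixed parameters",
        layout=layout,
        designs=designs,
    )


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------


def aicc(loglik: float, k: int, n: int) -> float:
    """Corrected AIC: -2 loglik + 2k + 2k(k+1)/(n-k-1).

    ``n`` is the number of acquisition events summed over diffusions.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n - k - 1 > 0)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """Akaike weights exp(-delta/2) normalised; non-finite entries get 0."""
    arr = np.asarray(aiccs, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one model")
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("no model has a finite AICc")
    if not finite.all():
        warnings.warn("models with non-finite AICc excluded from Akaike weights")
    delta = arr - np.min(arr[finite])
    raw = np.where(finite, np.exp(-np.where(finite, delta, 0.0) / 2.0), 0.0)
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# model set
# ---------------------------------------------------------------------------


@dataclass
class ModelSetResult:
    """Fits, AICc table, Akaike weights and hypothesis-level support."""

    fits: list[FitResult]
    weights: np.ndarray
    table: pd.DataFrame
    hypothesis_support: dict[str, float]

    def best(self) -> FitResult:
        idx = int(np.argmax(self.weights))
        return self.fits[idx]


def classify_spec(spec: ModelSpec, layer_names: Sequence[str]) -> str:
    """Transmission hypothesis class of one candidate model."""
    c = spec.layer_constraint
    if c == "asocial":
        return "asocial"
    if c == "homogeneous":
        return "homogeneous"
    if c == "shared":
        return "same_rate"
    if c == "free":
        return "different_rate"
    remaining = [l for l in layer_names if l not in spec.zero_layers]
    return "+".join(remaining) + "_only"


def fit_model_set(
    diffusions: Sequence[DiffusionData],
    stacks: Mapping[str, NetworkStack],
    cov: IndividualCovariates | None,
    specs: Sequence[ModelSpec],
    seed: int = 0,
    n_starts: int = 5,
) -> ModelSetResult:
    """Fit every candidate model; AICc table, weights, hypothesis support."""
    if len(specs) < 2:
        raise ValueError("a model set needs at least two candidate models")
    layer_names = list(next(iter(stacks.values())).layer_names)
    fits = []
    for i, spec in enumerate(specs):
        fits.append(
            fit_model(diffusions, stacks, cov, spec, seed=seed + i, n_starts=n_starts)
        )
    if not any(f.converged for f in fits):
        raise RuntimeError("no candidate model converged")
    for f in fits:
        if not f.converged:
            warnings.warn(f"model {f.spec.name} did not converge; excluded")
    crits = [f.aicc if f.converged else np.inf for f in fits]
    weights = akaike_weights(crits)
    support: dict[str, float] = {}
    for f, w in zip(fits, weights):
        cls = classify_spec(f.spec, layer_names)
        support[cls] = support.get(cls, 0.0) + float(w)
    table = pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "df": [f.n_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "aicc": crits,
            "weight": weights,
            "hypothesis": [classify_spec(f.spec, layer_names) for f in fits],
        }
    ).sort_values("aicc", kind="stable", ignore_index=True)
    return ModelSetResult(
        fits=fits, weights=weights, table=table, hypothesis_support=support
    )


def model_average(
    result: ModelSetResult, param: str
) -> tuple[float, float]:
    """Model-averaged estimate of one parameter.

    Returns ``(conditional, full)``: the conditional average renormalises
    weights over models containing the parameter; the full average counts
    models without it as contributing 0.
    """
    num = 0.0
    wsum = 0.0
    present = False
    for f, w in zip(result.fits, result.weights):
        if param in f.estimates and f.converged:
            present = True
            num += w * f.estimates[param]
            wsum += w
    if not present:
        raise KeyError(f"parameter {param!r} appears in no converged model")
    conditional = num / wsum if wsum > 0 else np.nan
    full = num  # absent models contribute 0 with their full weight
    return conditional, full


def build_candidate_specs(
    layer_names: Sequence[str] = ("intra", "inter"),
    ilv_subsets: Sequence[tuple[str, ...]] = ((),),
    baselines: Sequence[str] = ("constant", "weibull"),
    modes: Sequence[str] = ("additive", "multiplicative"),
    always_ilv: tuple[str, ...] = (),
    use_ties: bool = True,
) -> list[ModelSpec]:
    """Enumerate the candidate grid: 6 transmission hypotheses x baseline x
    covariate-mode x covariate subset (``always_ilv`` enters every model,
    e.g. a site indicator).

    Asocial models are generated once per (baseline, subset): with no social
    term the additive and multiplicative forms coincide.
    """
    specs: list[ModelSpec] = []
    constraints: list[tuple[str, tuple[str, ...]]] = [
        ("free", ()),
        ("shared", ()),
        ("homogeneous", ()),
    ]
    for l in layer_names:
        others = tuple(x for x in layer_names if x != l)
        constraints.append(("zero", others))  # transmission on layer l only
    for baseline, subset in itertools.product(baselines, ilv_subsets):
        ilvs = tuple(dict.fromkeys(always_ilv + tuple(subset)))
        mode_list = list(modes) if ilvs else ["none"]
        for mode in mode_list:
            for constraint, zeros in constraints:
                specs.append(
                    ModelSpec(
                        baseline=baseline,
                        ilv_mode=mode,
                        layer_constraint=constraint,
                        zero_layers=zeros,
                        ilv_names=ilvs if mode != "none" else (),
                        use_ties=use_ties,
                    )
                )
        # asocial: covariate mode is irrelevant without a social term
        specs.append(
            ModelSpec(
                baseline=baseline,
                ilv_mode="additive" if ilvs else "none",
                layer_constraint="asocial",
                ilv_names=ilvs,
                use_ties=use_ties,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


@dataclass
class ProfileCI:
    """Profile-likelihood interval with boundary/open-end diagnostics."""

    param: str
    level: float
    lower: float
    upper: float
    mle: float
    lower_at_boundary: bool = False
    lower_open: bool = False
    upper_open: bool = False


def likelihood_interval(
    profile_fun: Callable[[float], float],
    mle_value: float,
    max_loglik: float,
    level: float = 0.95,
    lower_domain: float | None = None,
    search_range: float | None = None,
    xtol: float = 1e-6,
) -> ProfileCI:
    """Invert a 1-d profile log-likelihood around its maximum.

    Finds the two points where ``profile_fun`` drops ``chi2_1(level)/2``
    below ``max_loglik``, expanding a bracket geometrically from the MLE and
    bisecting.  ``lower_domain`` clips the lower bound at a domain boundary
    (0 for rate parameters) and sets a flag when the profile never crosses
    the threshold there; ends that stay above the threshold within
    ``search_range`` are flagged open.
    """
    drop = stats.chi2.ppf(level, df=1) / 2.0
    target = max_loglik - drop

    def g(v: float) -> float:
        return profile_fun(v) - target

    scale = max(abs(mle_value), 1.0)
    if search_range is None:
        search_range = 1e4 * scale

    # upper bound
    upper_open = False
    hi = mle_value + 0.5 * scale
    prev = mle_value
    while g(hi) > 0:
        prev = hi
        hi = mle_value + 2.0 * (hi - mle_value)
        if hi - mle_value > search_range:
            upper_open = True
            break
    if upper_open:
        upper = mle_value + search_range
    else:
        upper = float(optimize.brentq(g, prev, hi, xtol=xtol))

    # lower bound
    lower_open = False
    lower_at_boundary = False
    if lower_domain is not None:
        lo_lim = lower_domain
        # walk down toward the boundary
        lo = mle_value - 0.5 * scale
        prev = mle_value
        crossed = False
        while lo > lo_lim:
            if g(lo) <= 0:
                crossed = True
                break
            prev = lo
            lo = mle_value - 2.0 * (mle_value - lo)
        if not crossed:
            if g(lo_lim) <= 0:
                lower = float(optimize.brentq(g, lo_lim, prev, xtol=xtol))
            else:
                lower = lo_lim
                lower_at_boundary = True
        else:
            lower = float(optimize.brentq(g, lo, prev, xtol=xtol))
    else:
        lo = mle_value - 0.5 * scale
        prev = mle_value
        while g(lo) > 0:
            prev = lo
            lo = mle_value - 2.0 * (mle_value - lo)
            if mle_value - lo > search_range:
                lower_open = True
                break
        if lower_open:
            lower = mle_value - search_range
        else:
            lower = float(optimize.brentq(g, lo, prev, xtol=xtol))

    return ProfileCI(
        param="",
        level=level,
        lower=lower,
        upper=upper,
        mle=mle_value,
        lower_at_boundary=lower_at_boundary,
        lower_open=lower_open,
        upper_open=upper_open,
    )


def _parse_difference(param: str, layout: ParamLayout) -> tuple[str, str] | None:
    """Detect 'name_a-name_b' difference syntax over two rate parameters."""
    if "-" not in param or param in layout.names:
        return None
    for cut in range(1, len(param)):
        if param[cut] != "-":
            continue
        a, b = param[:cut], param[cut + 1:]
        if a in layout.s_names and b in layout.s_names:
            return a, b
    return None


def profile_ci(
    diffusions: Sequence[DiffusionData],
    stacks: Mapping[str, NetworkStack],
    cov: IndividualCovariates | None,
    spec: ModelSpec,
    param: str,
    level: float = 0.95,
    fit: FitResult | None = None,
    seed: int = 0,
    search_range: float | None = None,
) -> ProfileCI:
    """Profile-likelihood CI for one parameter of one model.

    ``param`` may also name a difference of two transmission rates, e.g.
    ``"s_inter-s_intra"``, profiled via the reparameterisation
    ``s_a = s_b + d`` with ``d`` fixed on a grid.
    """
    if fit is None:
        fit = fit_model(diffusions, stacks, cov, spec, seed=seed)
    layout = fit.layout
    designs = fit.designs
    assert layout is not None and designs is not None

    diff_pair = _parse_difference(param, layout)
    if diff_pair is None and param not in layout.names:
        raise KeyError(f"parameter {param!r} not in model {spec.name}")

    start = dict(fit.estimates)

    if diff_pair is not None:
        a, b = diff_pair
        mle_value = fit.estimates[a] - fit.estimates[b]
        lower_domain = None

        def profile_fun(v: float) -> float:
            _, ll, _, _ = _maximize(
                designs, spec, layout, start, diff_fix=(a, b, v),
                n_starts=1, seed=seed,
            )
            return ll

    else:
        mle_value = fit.estimates[param]
        lower_domain = 0.0 if layout.positive[param] else None

        def profile_fun(v: float) -> float:
            _, ll, _, _ = _maximize(
                designs, spec, layout, start, fixed={param: v},
                n_starts=1, seed=seed,
            )
            return ll

    ci = likelihood_interval(
        profile_fun,
        mle_value,
        fit.loglik,
        level=level,
        lower_domain=lower_domain,
        search_range=search_range,
    )
    ci.param = param
    if ci.lower > mle_value or ci.upper < mle_value:  # numeric safety net
        ci.lower = min(ci.lower, mle_value)
        ci.upper = max(ci.upper, mle_value)
    return ci


# ---------------------------------------------------------------------------
# social/asocial decomposition of discovery events
# ---------------------------------------------------------------------------


@dataclass
class PercentSocial:
    """Per-event decomposition of discoveries into social and asocial."""

    overall: float  # mean over events of total social probability
    per_layer: dict[str, float]
    per_species: dict[str, float]
    per_event: pd.DataFrame
    n_events: int


def percent_social(
    fit: FitResult,
    diffusions: Sequence[DiffusionData] | None = None,
    stacks: Mapping[str, NetworkStack] | None = None,
    cov: IndividualCovariates | None = None,
) -> PercentSocial:
    """Estimated share of discoveries due to social transmission.

    For each acquisition event the probability that it was social on layer k
    is the layer's share of the acquirer's total hazard at the event time
    (the baseline cancels for constant-in-state pieces); the asocial share
    is the remainder.  The first discoverer of a diffusion has no informed
    associates, hence social probability 0 by construction.
    """
    if not fit.converged:
        raise RuntimeError("percent_social requires a converged fit")
    layout = fit.layout
    designs = fit.designs
    assert layout is not None and designs is not None
    spec = fit.spec
    s = layout.s_vector(fit.estimates)
    rows = []
    for design in designs:
        A = (
            np.exp(design.V @ layout.beta_vector(fit.estimates))
            if design.V.shape[1]
            else np.ones(len(design.node_ids))
        )
        for e in range(design.n_events):
            m, i = design.ev_seg[e], design.ev_ind[e]
            w = design.W[m, i, :]  # (K,)
            soc = s * w
            S = float(soc.sum())
            if spec.ilv_mode == "additive":
                denom = S + A[i]
            elif spec.ilv_mode == "multiplicative":
                denom = S + 1.0
            else:
                denom = S + 1.0
            assert denom > 0, "total rate must be positive at an observed event"
            p_layers = soc / denom
            rows.append(
                {
                    "trial": design.trial_id,
                    "individual": design.node_ids[i],
                    "time": float(design.ev_time[e]),
                    **{
                        f"p_{name}": float(p)
                        for name, p in zip(design.layer_names, p_layers)
                    },
                    "p_social": float(p_layers.sum()),
                }
            )
    per_event = pd.DataFrame(rows)
    layer_cols = [f"p_{name}" for name in designs[0].layer_names]
    per_layer = {
        name: float(per_event[f"p_{name}"].mean()) for name in designs[0].layer_names
    }
    per_species: dict[str, float] = {}
    if cov is not None and "species" in cov.table.columns:
        sp = cov.table["species"].astype(str)
        per_event = per_event.assign(
            species=per_event["individual"].map(sp).to_numpy()
        )
        per_species = {
            k: float(v) for k, v in per_event.groupby("species")["p_social"].mean().items()
        }
    return PercentSocial(
        overall=float(per_event["p_social"].mean()) if len(per_event) else 0.0,
        per_layer=per_layer,
        per_species=per_species,
        per_event=per_event,
        n_events=len(per_event),
    )
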