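"""Multi-network continuous time-of-acquisition diffusion model.

The hazard with which a naive individual ``i`` acquires information at time
``t`` combines a baseline (asocial) rate ``lambda0(t)`` with social
transmission along each of ``M`` association networks::

    lam_i(t) = lambda0(t) * (1 - z_i(t)) * f(S_i(t), A_i)
    S_i(t)   = sum_k s_k * sum_j a_ijk * z_j(t) * T_ij

where ``z_j(t)`` is the informed state, ``a_ijk`` the edge weight in layer
``k``, ``s_k`` the per-layer social transmission rate (per unit connection,
relative to baseline), ``T_ij`` a tie mask that zeroes dyads which arrived
within a short window of each other (likely co-discoveries), and ``A_i =
exp(sum_v beta_v V_vi)`` an individual-level covariate factor.  ``f`` is
``S + A`` for additive covariate models and ``A * (S + 1)`` for
multiplicative ones.  The baseline is either constant or a Weibull hazard
``lambda0 * kappa * t**(kappa - 1)``.

Because the informed state is a step function of the arrival times, the
hazard is piecewise separable between consecutive arrivals and the survival
integral has a closed form on every piece; the per-diffusion log-likelihood
is the usual counting-process form (event log-hazards minus integrated
hazard for every individual up to acquisition or censoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .networks import AssociationNetwork

__all__ = [
    "NetworkStack",
    "IndividualCovariates",
    "DiffusionData",
    "ModelSpec",
    "DiffusionDesign",
    "ValidationError",
    "ConfigurationError",
    "ParameterError",
    "tie_matrix",
    "acquisition_rate",
    "build_design",
    "loglik_from_design",
    "diffusion_loglik",
    "total_loglik",
    "CHI2_95_HALF",
]

#: half the 95% quantile of chi-square(1); the profile-likelihood drop
CHI2_95_HALF = 1.9207293216  # chi2.ppf(0.95, 1) / 2

DEFAULT_TIE_WINDOW_S = 600.0  # 10 min co-arrival window
DEFAULT_BLOCK_SECONDS = 15  # logger sampling granularity


class ValidationError(ValueError):
    """Input data violates a documented contract."""


class ConfigurationError(ValueError):
    """Model components are wired together inconsistently."""


class ParameterError(ValueError):
    """Parameter values outside their domain (s >= 0, lambda0 > 0, kappa > 0)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class NetworkStack:
    """Co-indexed association network layers over one ordered node set."""

    layers: list[AssociationNetwork]
    layer_names: list[str]

    def __post_init__(self):
        if not self.layers:
            raise ValueError("a network stack needs at least one layer")
        if len(self.layers) != len(self.layer_names):
            raise ValueError("layer_names must match layers one-to-one")
        ref = self.layers[0].node_ids
        for layer in self.layers[1:]:
            if layer.node_ids != ref:
                raise ValueError("all layers must share an identical ordered node set")

    @property
    def node_ids(self) -> list[str]:
        return self.layers[0].node_ids

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def matrices(self) -> np.ndarray:
        """Stacked (K, n, n) weight array."""
        return np.stack([l.weights for l in self.layers])


class IndividualCovariates:
    """Individual-level variables (ILVs) with a fixed design-matrix encoding.

    Categorical columns (species, site, ...) are dummy-coded against a
    declared reference level; numeric columns listed in ``standardize`` are
    centred and scaled using statistics of the full table so that encodings
    agree across sites and diffusions.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        reference: Mapping[str, str] | None = None,
        standardize: Sequence[str] = ("n_obs",),
    ):
        if "id" in table.columns:
            table = table.set_index("id")
        self.table = table.copy()
        self.table.index = self.table.index.astype(str)
        if self.table.index.has_duplicates:
            raise ValidationError("covariate table has duplicate individual ids")
        self.reference = dict(reference or {})
        self.standardize = tuple(standardize)
        self._stats = {
            c: (float(self.table[c].mean()), float(self.table[c].std(ddof=0)) or 1.0)
            for c in self.standardize
            if c in self.table.columns
        }

    def column_levels(self, name: str) -> list[str]:
        levels = sorted(self.table[name].astype(str).unique())
        ref = self.reference.get(name, levels[0])
        if ref not in levels:
            raise ConfigurationError(f"reference level {ref!r} absent from {name!r}")
        return [ref] + [l for l in levels if l != ref]

    def design_columns(self, ilv_names: Sequence[str]) -> list[str]:
        cols: list[str] = []
        for name in ilv_names:
            if name not in self.table.columns:
                raise ConfigurationError(f"unknown covariate {name!r}")
            if self.table[name].dtype.kind in "OUS" or isinstance(
                self.table[name].dtype, pd.CategoricalDtype
            ):
                cols.extend(f"{name}[{l}]" for l in self.column_levels(name)[1:])
            else:
                cols.append(name)
        return cols

    def design_matrix(
        self, node_ids: Sequence[str], ilv_names: Sequence[str]
    ) -> tuple[np.ndarray, list[str]]:
        missing = [i for i in node_ids if i not in self.table.index]
        if missing:
            raise ValidationError(f"individuals without covariates: {missing}")
        sub = self.table.loc[list(node_ids)]
        blocks: list[np.ndarray] = []
        for name in ilv_names:
            col = sub[name]
            if col.dtype.kind in "OUS" or isinstance(col.dtype, pd.CategoricalDtype):
                for level in self.column_levels(name)[1:]:
                    blocks.append((col.astype(str) == level).to_numpy(float))
            else:
                x = col.to_numpy(float)
                if name in self._stats:
                    mu, sd = self._stats[name]
                    x = (x - mu) / sd
                blocks.append(x)
        cols = self.design_columns(ilv_names)
        if not blocks:
            return np.zeros((len(node_ids), 0)), []
        return np.column_stack(blocks), cols


@dataclass
class DiffusionData:
    """Arrival times of one diffusion trial, right-censored at ``t_end``.

    Individuals absent from ``arrivals`` never acquired and contribute only
    survival probability up to the horizon.  The risk set defaults to every
    node of the trial site's network stack.
    """

    trial_id: str
    site: str
    t_end: float
    arrivals: dict[str, float]
    tie_window: float = DEFAULT_TIE_WINDOW_S
    seeded: tuple[str, ...] = ()  # demonstrators: informed at t=0, not at risk

    def __post_init__(self):
        self.arrivals = {str(k): float(v) for k, v in self.arrivals.items()}
        self.seeded = tuple(str(s) for s in self.seeded)
        clash = set(self.seeded) & set(self.arrivals)
        if clash:
            raise ValidationError(
                f"trial {self.trial_id}: seeded demonstrators with arrival "
                f"times: {sorted(clash)}"
            )
        if self.t_end < 0:
            raise ValidationError(f"trial {self.trial_id}: t_end must be >= 0")
        if self.tie_window < 0:
            raise ValidationError(f"trial {self.trial_id}: tie_window must be >= 0")
        for ind, t in self.arrivals.items():
            if not (0 < t <= self.t_end):
                raise ValidationError(
                    f"trial {self.trial_id}: arrival of {ind!r} at {t} outside "
                    f"(0, {self.t_end}]"
                )

    @property
    def n_events(self) -> int:
        return len(self.arrivals)


_BASELINES = ("constant", "weibull")
_ILV_MODES = ("additive", "multiplicative", "none")
_CONSTRAINTS = ("free", "shared", "zero", "homogeneous", "asocial")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: baseline form, covariate mode, layer constraint.

    ``layer_constraint``:
      * ``free`` — one transmission rate per network layer;
      * ``shared`` — a single rate applied to all layers;
      * ``zero`` — layers named in ``zero_layers`` forced to s = 0;
      * ``homogeneous`` — every possible edge replaced by 1 (one rate);
      * ``asocial`` — no social transmission at all.
    """

    baseline: str = "constant"
    ilv_mode: str = "none"
    layer_constraint: str = "free"
    zero_layers: tuple[str, ...] = ()
    ilv_names: tuple[str, ...] = ()
    use_ties: bool = True

    def __post_init__(self):
        if self.baseline not in _BASELINES:
            raise ConfigurationError(f"baseline must be one of {_BASELINES}")
        if self.ilv_mode not in _ILV_MODES:
            raise ConfigurationError(f"ilv_mode must be one of {_ILV_MODES}")
        if self.layer_constraint not in _CONSTRAINTS:
            raise ConfigurationError(f"layer_constraint must be one of {_CONSTRAINTS}")
        if self.ilv_mode == "none" and self.ilv_names:
            raise ConfigurationError("ilv_names given but ilv_mode is 'none'")
        if self.zero_layers and self.layer_constraint != "zero":
            raise ConfigurationError("zero_layers requires layer_constraint='zero'")
        if self.layer_constraint == "zero" and not self.zero_layers:
            raise ConfigurationError("layer_constraint='zero' needs zero_layers")

    @property
    def name(self) -> str:
        bits = [self.layer_constraint]
        if self.zero_layers:
            bits.append("no_" + "+".join(self.zero_layers))
        bits.append(self.baseline)
        if self.ilv_mode != "none":
            bits.append(self.ilv_mode)
            bits.append("+".join(self.ilv_names) if self.ilv_names else "noilv")
        if not self.use_ties:
            bits.append("noties")
        return ":".join(bits)


# ---------------------------------------------------------------------------
# tie masking
# ---------------------------------------------------------------------------


def tie_matrix(diff: DiffusionData, node_ids: Sequence[str]) -> np.ndarray:
    """Binary mask: 0 where two arrivals fall within the tie window, else 1.

    Pairs of individuals that discovered the resource within ``tie_window``
    of each other are treated as co-discoveries and excluded from the social
    transmission term.  Ties are pairwise, not transitively chained.
    """
    if diff.tie_window < 0:
        raise ValidationError("tie_window must be >= 0")
    n = len(node_ids)
    t = np.full(n, np.nan)
    for k, ind in enumerate(node_ids):
        if ind in diff.arrivals:
            t[k] = diff.arrivals[ind]
    T = np.ones((n, n))
    arrived = ~np.isnan(t)
    both = np.outer(arrived, arrived)
    with np.errstate(invalid="ignore"):
        close = np.abs(t[:, None] - t[None, :]) <= diff.tie_window
    T[both & close] = 0.0
    np.fill_diagonal(T, 1.0)
    return T


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def _check_params(lambda0: float, kappa: float | None, s: np.ndarray) -> None:
    if lambda0 <= 0:
        raise ParameterError(f"lambda0 must be > 0, got {lambda0}")
    if kappa is not None and kappa <= 0:
        raise ParameterError(f"kappa must be > 0, got {kappa}")
    if np.any(s < 0):
        raise ParameterError(f"social rates must be >= 0, got {s}")


def _normalize_s(
    s: Mapping[str, float] | Sequence[float] | float | None, layer_names: Sequence[str]
) -> np.ndarray:
    if s is None:
        return np.zeros(len(layer_names))
    if isinstance(s, Mapping):
        return np.array([float(s.get(name, 0.0)) for name in layer_names])
    arr = np.atleast_1d(np.asarray(s, dtype=float))
    if arr.size == 1 and len(layer_names) > 1:
        arr = np.repeat(arr, len(layer_names))
    if arr.size != len(layer_names):
        raise ParameterError(
            f"expected {len(layer_names)} social rates, got {arr.size}"
        )
    return arr


def baseline_hazard(t: float | np.ndarray, lambda0: float, kappa: float | None):
    """``lambda0`` (constant) or ``lambda0 * kappa * t**(kappa-1)`` (Weibull)."""
    if kappa is None:
        return lambda0 * np.ones_like(np.asarray(t, dtype=float))
    return lambda0 * kappa * np.asarray(t, dtype=float) ** (kappa - 1.0)


# ---------------------------------------------------------------------------
# reference (single-point) rate evaluation
# ---------------------------------------------------------------------------


def acquisition_rate(
    individual: str,
    t: float,
    informed: Iterable[str],
    stack: NetworkStack,
    cov: IndividualCovariates | None,
    spec: ModelSpec,
    params: Mapping,
) -> float:
    """Hazard of acquisition for one individual at one time point.

    Direct, unvectorised evaluation of the model rate; the likelihood uses a
    precomputed piecewise design instead, and tests check the two agree.
    """
    layer_names = (
        ["homogeneous"] if spec.layer_constraint == "homogeneous" else stack.layer_names
    )
    lambda0 = float(params["lambda0"])
    kappa = params.get("kappa") if spec.baseline == "weibull" else None
    s = _normalize_s(params.get("s"), layer_names)
    if spec.layer_constraint == "asocial":
        s = np.zeros_like(s)
    _check_params(lambda0, kappa, s)

    node_ids = stack.node_ids
    if individual not in node_ids:
        raise ValidationError(f"unknown individual {individual!r}")
    i = node_ids.index(individual)
    informed = set(informed)
    if individual in informed:
        return 0.0

    tie = params.get("tie_mask")
    T = np.ones((stack.n_nodes, stack.n_nodes)) if tie is None else np.asarray(tie)
    if not spec.use_ties:
        T = np.ones_like(T)

    z = np.array([1.0 if j in informed else 0.0 for j in node_ids])
    if spec.layer_constraint == "homogeneous":
        ones = np.ones((stack.n_nodes, stack.n_nodes))
        np.fill_diagonal(ones, 0.0)
        mats = ones[None, :, :]
    else:
        mats = stack.matrices()
    S = float(sum(s[k] * np.dot(mats[k][i] * T[i], z) for k in range(len(s))))

    if spec.ilv_mode == "none" or not spec.ilv_names or cov is None:
        A = 1.0
    else:
        V, _ = cov.design_matrix([individual], spec.ilv_names)
        beta = np.asarray(params.get("beta", np.zeros(V.shape[1])), dtype=float)
        A = float(np.exp(V @ beta).item())

    lam0_t = float(baseline_hazard(t, lambda0, kappa))
    if spec.ilv_mode == "multiplicative":
        return lam0_t * A * (S + 1.0)
    if spec.ilv_mode == "additive":
        return lam0_t * (S + A)
    return lam0_t * (S + 1.0)


# ---------------------------------------------------------------------------
# piecewise likelihood design
# ---------------------------------------------------------------------------


@dataclass
class DiffusionDesign:
    """Parameter-independent structure of one diffusion's likelihood.

    Segments are the intervals between consecutive distinct arrival times
    (plus the censoring horizon); within a segment the informed state, and
    hence every individual's social connection sum ``W[m, i, k]``, is
    constant, so the survival integral is closed-form piece by piece.
    """

    node_ids: list[str]
    layer_names: list[str]
    seg_lo: np.ndarray  # (M,)
    seg_hi: np.ndarray  # (M,)
    risk: np.ndarray  # (M, n) bool — naive during segment m
    W: np.ndarray  # (M, n, K) masked social connection sums
    ev_seg: np.ndarray  # (E,) segment whose upper bound is the event time
    ev_ind: np.ndarray  # (E,) acquirer node index
    ev_time: np.ndarray  # (E,)
    V: np.ndarray  # (n, p) covariate design matrix
    ilv_cols: list[str]
    n_events: int
    trial_id: str = ""


def build_design(
    diff: DiffusionData,
    stack: NetworkStack,
    cov: IndividualCovariates | None,
    spec: ModelSpec,
) -> DiffusionDesign:
    """Precompute segments, risk sets and masked social sums for one trial."""
    node_ids = stack.node_ids
    unknown = [i for i in (*diff.arrivals, *diff.seeded) if i not in node_ids]
    if unknown:
        raise ValidationError(
            f"trial {diff.trial_id}: arrivals for individuals not in the "
            f"network: {unknown}"
        )
    n = stack.n_nodes
    arr = np.full(n, np.inf)
    for k, ind in enumerate(node_ids):
        if ind in diff.arrivals:
            arr[k] = diff.arrivals[ind]

    times = np.unique(arr[np.isfinite(arr)])
    bounds = np.concatenate([[0.0], times])
    if diff.t_end > (times[-1] if times.size else 0.0):
        bounds = np.concatenate([bounds, [diff.t_end]])
    seg_lo, seg_hi = bounds[:-1], bounds[1:]
    M = len(seg_lo)

    T = tie_matrix(diff, node_ids) if spec.use_ties else np.ones((n, n))
    if spec.layer_constraint == "homogeneous":
        ones = np.ones((n, n))
        np.fill_diagonal(ones, 0.0)
        mats = ones[None, :, :]
        layer_names = ["homogeneous"]
    else:
        mats = stack.matrices()
        layer_names = list(stack.layer_names)
    masked = mats * T[None, :, :]  # (K, n, n)

    seeded = np.array([ind in diff.seeded for ind in node_ids])
    risk = (arr[None, :] > seg_lo[:, None]) & ~seeded[None, :]
    # informed during (lo, hi]: arrived at or before lo, or seeded at t=0
    z = ((arr[None, :] <= seg_lo[:, None]) | seeded[None, :]).astype(float)
    # W[m, i, k] = sum_j masked[k, i, j] * z[m, j]
    W = np.einsum("kij,mj->mik", masked, z)

    ev_order = np.argsort(arr, kind="stable")
    ev_ind = ev_order[np.isfinite(arr[ev_order])]
    ev_time = arr[ev_ind]
    ev_seg = np.searchsorted(seg_hi, ev_time)

    if spec.ilv_mode != "none" and spec.ilv_names:
        if cov is None:
            raise ConfigurationError("model uses covariates but none were given")
        V, cols = cov.design_matrix(node_ids, spec.ilv_names)
    else:
        V, cols = np.zeros((n, 0)), []

    return DiffusionDesign(
        node_ids=list(node_ids),
        layer_names=layer_names,
        seg_lo=seg_lo,
        seg_hi=seg_hi,
        risk=risk,
        W=W,
        ev_seg=ev_seg,
        ev_ind=ev_ind,
        ev_time=ev_time,
        V=V,
        ilv_cols=cols,
        n_events=len(ev_ind),
        trial_id=diff.trial_id,
    )


def loglik_from_design(
    design: DiffusionDesign,
    spec: ModelSpec,
    lambda0: float,
    s: np.ndarray,
    beta: np.ndarray,
    kappa: float | None = None,
) -> float:
    """Closed-form piecewise log-likelihood for one precomputed diffusion."""
    if design.n_events == 0 and len(design.seg_lo) == 0:
        return 0.0
    A = np.exp(design.V @ beta) if design.V.shape[1] else np.ones(len(design.node_ids))
    S = design.W @ s  # (M, n)
    if spec.ilv_mode == "multiplicative":
        coef = A[None, :] * (S + 1.0)
    elif spec.ilv_mode == "additive":
        coef = S + A[None, :]
    else:
        coef = S + 1.0

    if spec.baseline == "weibull":
        if kappa is None:
            raise ParameterError("Weibull baseline requires kappa")
        piece = design.seg_hi**kappa - design.seg_lo**kappa
        ev_base = np.log(lambda0 * kappa) + (kappa - 1.0) * np.log(design.ev_time)
    else:
        piece = design.seg_hi - design.seg_lo
        ev_base = np.full(design.n_events, np.log(lambda0))

    integral = lambda0 * float(np.sum(piece[:, None] * (design.risk * coef)))
    ev_coef = coef[design.ev_seg, design.ev_ind]
    events = float(np.sum(ev_base + np.log(ev_coef)))
    return events - integral


def _expand_params(
    spec: ModelSpec, layer_names: Sequence[str], params: Mapping
) -> tuple[float, float | None, np.ndarray, np.ndarray]:
    lambda0 = float(params["lambda0"])
    kappa = float(params["kappa"]) if spec.baseline == "weibull" else None
    names = ["homogeneous"] if spec.layer_constraint == "homogeneous" else layer_names
    s = _normalize_s(params.get("s"), names)
    if spec.layer_constraint == "asocial":
        s = np.zeros_like(s)
    if spec.layer_constraint == "zero":
        for zl in spec.zero_layers:
            if zl not in names:
                raise ConfigurationError(f"unknown layer to zero: {zl!r}")
            s[list(names).index(zl)] = 0.0
    beta = np.asarray(params.get("beta", []), dtype=float)
    _check_params(lambda0, kappa, s)
    return lambda0, kappa, s, beta


def diffusion_loglik(
    diff: DiffusionData,
    stack: NetworkStack,
    cov: IndividualCovariates | None,
    spec: ModelSpec,
    params: Mapping,
) -> float:
    """Log-likelihood contribution of a single diffusion trial."""
    design = build_design(diff, stack, cov, spec)
    lambda0, kappa, s, beta = _expand_params(spec, stack.layer_names, params)
    if design.V.shape[1] and beta.size != design.V.shape[1]:
        raise ConfigurationError(
            f"beta has {beta.size} entries but the design has "
            f"{design.V.shape[1]} columns ({design.ilv_cols})"
        )
    if not design.V.shape[1]:
        beta = np.zeros(0)
    return loglik_from_design(design, spec, lambda0, s, beta, kappa)


def total_loglik(
    diffusions: Sequence[DiffusionData],
    stacks: Mapping[str, NetworkStack],
    cov: IndividualCovariates | None,
    spec: ModelSpec,
    params: Mapping,
) -> float:
    """Summed log-likelihood over diffusions (shared s and covariate effects)."""
    total = 0.0
    for diff in diffusions:
        if diff.site not in stacks:
            raise ConfigurationError(
                f"trial {diff.trial_id}: no network stack for site {diff.site!r}"
            )
        total += diffusion_loglik(diff, stacks[diff.site], cov, spec, params)
    return total
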