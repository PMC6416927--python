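"""Three-state kinetic models of ancestral-state loss.

Two systems share the rate symbols x, y, w, z:

* pair model, states (O, I, II) — duplicate pairs where both, exactly one,
  or neither copy retains the ancestral state::

      d/dt (O, I, II)^T = [[-x,      y,      0],
                           [ x, -(y+w),      z],
                           [ 0,      w,     -z]] (O, I, II)^T

  so x is the O->I rate, y I->O, w I->II, z II->I.

* single-copy model, states (O, +, -) — one duplicate keeping the
  ancestral expression quartile, moving above it, or below it::

      d/dt (O, +, -)^T = [[-(x+y),  w,  z],
                          [     x, -w,  0],
                          [     y,  0, -z]] (O, +, -)^T

  (mass-conserving form: every column sums to zero), with x = O->+,
  y = O->-, w = +->O, z = -->O.

Solutions are by eigendecomposition of the generator (series-based matrix
exponential fallback for near-defective cases). Rates are fit by maximum
likelihood on per-observation categorical data (class, d_s), with the
synonymous substitution rate d_s of each duplicate pair standing in for
time. Constrained variants tie rates into groups; nested variants are
compared with the likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

__all__ = [
    "PAIR_STATES",
    "SINGLE_STATES",
    "OdeSystem",
    "OdeFit",
    "LrtResult",
    "generator",
    "rate_groups",
    "ode_solution",
    "fit_ode",
    "fit_single_copy_model",
    "likelihood_ratio_test",
]

PAIR_STATES = ("O", "I", "II")
SINGLE_STATES = ("O", "+", "-")
RATE_NAMES = ("x", "y", "w", "z")

#: named constraint variants -> tied rate groups
_VARIANTS = {
    "pair": {
        "one": (("x", "y", "w", "z"),),
        "two": (("x", "y"), ("w", "z")),
        "four": (("x",), ("y",), ("w",), ("z",)),
    },
    "single": {
        "one": (("x", "y", "w", "z"),),
        # "up branch" (O<->+) vs "down branch" (O<->-) rates, so the
        # two-parameter model lets the O->+ and O->- rates differ
        "two": (("x", "w"), ("y", "z")),
        "four": (("x",), ("y",), ("w",), ("z",)),
    },
}


def rate_groups(kind: str, variant) -> tuple[tuple[str, ...], ...]:
    """Resolve a variant name (or explicit group tuple) to rate groups."""
    if isinstance(variant, str):
        return _VARIANTS[kind][variant]
    groups = tuple(tuple(g) for g in variant)
    flat = [r for g in groups for r in g]
    if sorted(flat) != sorted(RATE_NAMES):
        raise ValueError(f"groups must partition {RATE_NAMES}: {groups}")
    return groups


def generator(kind: str, x: float, y: float, w: float, z: float) -> np.ndarray:
    """Column-generator matrix A with d p / dt = A p (columns sum to 0)."""
    if min(x, y, w, z) < 0:
        raise ValueError("rates must be nonnegative")
    if kind == "pair":
        return np.array([
            [-x, y, 0.0],
            [x, -(y + w), z],
            [0.0, w, -z],
        ])
    if kind == "single":
        return np.array([
            [-(x + y), w, z],
            [x, -w, 0.0],
            [y, 0.0, -z],
        ])
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class OdeSystem:
    """A concrete three-state system: kind, rates, and initial condition."""

    kind: str = "pair"
    x: float = 0.0
    y: float = 0.0
    w: float = 0.0
    z: float = 0.0
    p0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, dtype=float)
        if self.p0.shape != (3,) or abs(self.p0.sum() - 1.0) > 1e-9:
            raise ValueError("p0 must be a 3-vector summing to 1")
        self.A = generator(self.kind, self.x, self.y, self.w, self.z)

    @property
    def states(self) -> tuple[str, ...]:
        return PAIR_STATES if self.kind == "pair" else SINGLE_STATES

    @property
    def rates(self) -> dict[str, float]:
        return dict(zip(RATE_NAMES, (self.x, self.y, self.w, self.z)))


def _solve_eigen(A: np.ndarray, p0: np.ndarray, t: np.ndarray) -> np.ndarray:
    lam, V = np.linalg.eig(A)
    condV = np.linalg.cond(V)
    if not np.isfinite(condV) or condV > 1e8:
        # near-defective generator: fall back to the matrix exponential
        return np.stack([expm(A * ti) @ p0 for ti in t])
    c = np.linalg.solve(V, p0)
    out = np.real(np.einsum("ik,tk->ti", V, np.exp(np.outer(t, lam)) * c))
    return out


def ode_solution(system: OdeSystem, t) -> np.ndarray:
    """State frequencies at time(s) t; shape (3,) scalar t, else (n, 3).

    Frequencies are clipped to [0, 1] and renormalized only against
    accumulated round-off (the analytic solution conserves mass exactly).
    """
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    p = _solve_eigen(system.A, system.p0, t_arr)
    np.clip(p, 0.0, 1.0, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if scalar else p


def stationary_distribution(system: OdeSystem) -> np.ndarray:
    """Null-space eigenvector of the generator, normalized to sum 1."""
    lam, V = np.linalg.eig(system.A)
    i = int(np.argmin(np.abs(lam)))
    v = np.real(V[:, i])
    return v / v.sum()


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class OdeFit:
    kind: str
    variant: object
    rates: dict[str, float]
    log_likelihood: float
    n_free: int
    p0: np.ndarray
    n_obs: int
    boundary: bool
    starts: list[dict] = field(default_factory=list)

    def system(self) -> OdeSystem:
        return OdeSystem(self.kind, p0=self.p0, **self.rates)


@dataclass
class LrtResult:
    statistic: float
    df: int
    p_value: float


def _class_indices(classes, states) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(states)}
    try:
        return np.array([lookup[c] for c in classes], dtype=int)
    except KeyError as e:
        raise ValueError(f"unknown class label {e.args[0]!r}") from None


def _log_likelihood(kind, rates4, p0, cls_idx, ts) -> float:
    A = generator(kind, *rates4)
    p = _solve_eigen(A, p0, ts)
    np.clip(p, 0.0, 1.0, out=p)
    probs = p[np.arange(len(ts)), cls_idx]
    return float(np.log(np.clip(probs, 1e-300, None)).sum())


def fit_ode(
    observations,
    variant="four",
    kind: str = "pair",
    init_condition=(1.0, 0.0, 0.0),
    n_starts: int = 20,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> OdeFit:
    """ML rates for the three-state model from (class, d_s) observations.

    ``observations`` is an iterable of (class_label, d_s) or a 2-column
    DataFrame. Rates are optimized on the log scale (positivity);
    ``n_starts`` random initializations guard against local optima. A data
    set whose likelihood is identically -inf for every admissible rate
    vector (impossible classes under the initial condition, e.g. non-O
    observations with all rates forced to zero) raises a ValueError.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = list(observations) if not hasattr(observations, "itertuples") else [
        (r[0], r[1]) for r in observations.itertuples(index=False)
    ]
    if len(obs) < 10:
        raise ValueError("need at least 10 observations")
    classes, ts = zip(*obs)
    ts = np.asarray(ts, dtype=float)
    if np.any(ts <= 0):
        raise ValueError("d_s must be positive")
    states = PAIR_STATES if kind == "pair" else SINGLE_STATES
    cls_idx = _class_indices(classes, states)
    p0 = np.asarray(init_condition, dtype=float)
    groups = rate_groups(kind, variant)
    n_free = len(groups)

    def expand(theta):
        r = dict.fromkeys(RATE_NAMES, 0.0)
        theta = np.clip(theta, np.log(1e-8), np.log(1e3))
        for g, v in zip(groups, np.exp(theta)):
            for name in g:
                r[name] = v
        return np.array([r[n] for n in RATE_NAMES])

    def neg_ll(theta):
        return -_log_likelihood(kind, expand(theta), p0, cls_idx, ts)

    best = None
    starts = []
    for _ in range(max(1, n_starts)):
        x0 = rng.uniform(np.log(0.01), np.log(3.0), size=n_free)
        res = minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        starts.append({"x0": np.exp(x0), "ll": -float(res.fun),
                       "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise ValueError(
            "likelihood is -inf at every start: observed classes are "
            "impossible under the initial condition"
        )
    rates4 = expand(best.x)
    boundary = bool(np.any(rates4 < 1e-6) or np.any(rates4 > 1e3))
    return OdeFit(
        kind=kind,
        variant=variant,
        rates=dict(zip(RATE_NAMES, map(float, rates4))),
        log_likelihood=-float(best.fun),
        n_free=n_free,
        p0=p0,
        n_obs=len(obs),
        boundary=boundary,
        starts=starts,
    )


def fit_single_copy_model(observations, variant="two", **kwargs) -> OdeFit:
    """Fit the single-copy (O, +, -) model; see :func:`fit_ode`."""
    return fit_ode(observations, variant=variant, kind="single", **kwargs)


def likelihood_ratio_test(fit_null: OdeFit, fit_alt: OdeFit) -> LrtResult:
    """2 * delta-lnL against chi-square with df = difference in free rates.

    The null's rate groups must be a coarsening of the alternative's
    (strict nesting) and both fits must be of the same kind and data size.
    """
    if fit_null.kind != fit_alt.kind or fit_null.n_obs != fit_alt.n_obs:
        raise ValueError("fits are not on the same model kind and data")
    g0 = rate_groups(fit_null.kind, fit_null.variant)
    g1 = rate_groups(fit_alt.kind, fit_alt.variant)
    if len(g1) <= len(g0):
        raise ValueError("alternative must have more free parameters")
    for fine in g1:
        if not any(set(fine) <= set(coarse) for coarse in g0):
            raise ValueError(
                f"variants not nested: {fit_null.variant} vs {fit_alt.variant}"
            )
    stat = 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood)
    if stat < -1e-6:
        import warnings

        warnings.warn(
            f"alternative log-likelihood below null ({stat/2:.3g}); refit "
            "with more starts"
        )
    stat = max(stat, 0.0)
    df = fit_alt.n_free - fit_null.n_free
    return LrtResult(statistic=float(stat), df=df,
                     p_value=float(chi2.sf(stat, df)))
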