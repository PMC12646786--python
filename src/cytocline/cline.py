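"""Geographic cline models for hybrid-zone ancestry.

The model family is the standard hybrid-zone sigmoid

    Psi_sig(x) = (1 + tanh(2 (x - c) / w)) / 2

with center ``c`` (scaled transect position of the midpoint) and width
``w`` = 1 / maximum slope, optionally extended by

* *scaling*: the cline runs from ``pmin`` to ``pmax`` instead of 0..1
  (``fixed`` pins them at empirical end-frequencies, ``free`` estimates
  them), and
* *tails*: exponential introgression tails attached continuously at
  ``c - dL`` and/or ``c + dR`` with rates ``4*tau/w`` (stepped-cline
  convention).

Fitting is bounded multi-start maximum likelihood; model choice across
the 15 scaling x tail variants is by AIC; uncertainty is summarised with
2-log-likelihood-unit profile support intervals (approximately 95% for
one degree of freedom).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

SCALINGS = ("none", "fixed", "free")
TAILS = ("none", "left", "right", "mirror", "both")

_P_CLAMP = 1e-9  # keeps log-likelihood finite at probability boundaries
_VAR_FLOOR = 1e-12

DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "center": (0.0, 1.0),
    "width": (1e-3, 2.0),
    "pmin": (0.0, 1.0),
    "pmax": (0.0, 1.0),
    "delta_l": (0.0, 1.0),
    "delta_r": (0.0, 1.0),
    "tau_l": (1e-3, 1.0),
    "tau_r": (1e-3, 1.0),
}


class NoConvergentModelError(RuntimeError):
    """Raised by select_model when no candidate variant converges."""

    def __init__(self, statuses: Mapping[tuple[str, str], str]):
        self.statuses = dict(statuses)
        lines = ", ".join(f"{k}: {v}" for k, v in self.statuses.items())
        super().__init__(f"no convergent cline variant ({lines})")


@dataclass(frozen=True)
class ClineModelSpec:
    """A cline variant plus its parameter values.

    ``mirror`` tails share ``delta_l``/``tau_l`` for both sides;
    ``delta_r``/``tau_r`` are ignored for that variant.
    """

    scaling: str = "none"
    tails: str = "none"
    center: float = 0.5
    width: float = 0.1
    pmin: float = 0.0
    pmax: float = 1.0
    delta_l: float = 0.0
    delta_r: float = 0.0
    tau_l: float = 1.0
    tau_r: float = 1.0

    def __post_init__(self) -> None:
        if self.scaling not in SCALINGS:
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.tails not in TAILS:
            raise ValueError(f"unknown tails {self.tails!r}")
        if not (0.0 < self.center < 1.0):
            raise ValueError("center must lie in (0, 1)")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if not (0.0 <= self.pmin < self.pmax <= 1.0):
            raise ValueError("need 0 <= pmin < pmax <= 1")
        if min(self.delta_l, self.delta_r) < 0:
            raise ValueError("tail offsets must be non-negative")
        if not (0.0 < self.tau_l <= 1.0 and 0.0 < self.tau_r <= 1.0):
            raise ValueError("tail rates must lie in (0, 1]")

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Names of the parameters estimated for this variant, in order."""
        names = ["center", "width"]
        if self.scaling == "free":
            names += ["pmin", "pmax"]
        if self.tails in ("left", "mirror"):
            names += ["delta_l", "tau_l"]
        elif self.tails == "right":
            names += ["delta_r", "tau_r"]
        elif self.tails == "both":
            names += ["delta_l", "tau_l", "delta_r", "tau_r"]
        return tuple(names)

    @property
    def k(self) -> int:
        return len(self.free_parameters)


@dataclass(frozen=True)
class ClineData:
    """Observations along the transect.

    ``likelihood_kind`` selects the error model: ``bernoulli`` for 0/1
    chlorotype, ``binomial2`` for diploid ancestry counts in {0,1,2},
    ``gaussian`` for continuous mean ancestry in [0,1] (sigma^2 profiled
    out analytically).
    """

    x: np.ndarray
    y: np.ndarray
    likelihood_kind: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.likelihood_kind not in ("bernoulli", "binomial2", "gaussian"):
            raise ValueError(f"unknown likelihood_kind {self.likelihood_kind!r}")
        if self.likelihood_kind == "bernoulli" and not np.isin(self.y, (0, 1)).all():
            raise ValueError("bernoulli data must be 0/1")
        if self.likelihood_kind == "binomial2" and not np.isin(self.y, (0, 1, 2)).all():
            raise ValueError("binomial2 data must be counts in {0,1,2}")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class ClineFit:
    spec: ClineModelSpec
    loglik: float
    n_obs: int
    converged: bool
    boundary: bool
    seed: int
    support_intervals: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.spec.k - 2.0 * self.loglik


def _tail_psi(x: np.ndarray, spec: ClineModelSpec) -> np.ndarray:
    c, w = spec.center, spec.width
    psi = 0.5 * (1.0 + np.tanh(2.0 * (x - c) / w))
    left = spec.tails in ("left", "mirror", "both")
    right = spec.tails in ("right", "mirror", "both")
    if spec.tails == "mirror":
        dl = dr = spec.delta_l
        tl = tr = spec.tau_l
    else:
        dl, dr, tl, tr = spec.delta_l, spec.delta_r, spec.tau_l, spec.tau_r
    if left:
        xl = c - dl
        mask = x < xl
        if np.any(mask):
            base = 0.5 * (1.0 + np.tanh(-2.0 * dl / w))
            # exponent <= 0 on the tail side; clip so the unmasked branch
            # never overflows before np.where discards it
            arg = np.minimum(4.0 * tl * (x - xl) / w, 0.0)
            psi = np.where(mask, base * np.exp(arg), psi)
    if right:
        xr = c + dr
        mask = x > xr
        if np.any(mask):
            base = 0.5 * (1.0 + np.tanh(2.0 * dr / w))
            arg = np.minimum(-4.0 * tr * (x - xr) / w, 0.0)
            psi = np.where(mask, 1.0 - (1.0 - base) * np.exp(arg), psi)
    return psi


def cline_probability(x, spec: ClineModelSpec) -> np.ndarray | float:
    """Expected trichocarpa-ancestry probability at transect position x."""
    xarr = np.asarray(x, dtype=float)
    p = spec.pmin + (spec.pmax - spec.pmin) * _tail_psi(np.atleast_1d(xarr), spec)
    return float(p[0]) if xarr.ndim == 0 else p


def loglik(data: ClineData, spec: ClineModelSpec) -> float:
    """Log-likelihood of the data under the cline, by likelihood kind."""
    if data.n == 0:
        raise ValueError("empty data")
    p = np.clip(cline_probability(data.x, spec), _P_CLAMP, 1.0 - _P_CLAMP)
    y = data.y
    if data.likelihood_kind == "bernoulli":
        return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
    if data.likelihood_kind == "binomial2":
        lchoose = np.where(y == 1.0, np.log(2.0), 0.0)
        return float(np.sum(lchoose + y * np.log(p) + (2.0 - y) * np.log1p(-p)))
    # gaussian with sigma^2 profiled at its MLE
    resid = y - p
    s2 = max(float(np.mean(resid * resid)), _VAR_FLOOR)
    n = data.n
    return float(-0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0))


def _empirical_end_freqs(data: ClineData) -> tuple[float, float]:
    """Mean observed frequency in the outer deciles of the transect."""
    ymax = 2.0 if data.likelihood_kind == "binomial2" else 1.0
    freq = data.y / ymax
    lo_cut, hi_cut = np.quantile(data.x, [0.1, 0.9])
    lo = float(np.mean(freq[data.x <= lo_cut]))
    hi = float(np.mean(freq[data.x >= hi_cut]))
    pmin, pmax = min(lo, hi), max(lo, hi)
    if pmax - pmin < 1e-3:  # degenerate: fall back to the full range
        return 0.0, 1.0
    return pmin, pmax


def _build_spec(scaling: str, tails: str, theta: np.ndarray, names: Sequence[str],
                fixed_scale: tuple[float, float] | None) -> ClineModelSpec:
    kw = dict(zip(names, (float(t) for t in theta)))
    if "pmin" in kw and "pmax" in kw and kw["pmin"] >= kw["pmax"]:
        # free-scaling box allows inversion; order and keep a minimal gap
        lo, hi = sorted((kw["pmin"], kw["pmax"]))
        kw["pmin"], kw["pmax"] = lo, max(hi, lo + 1e-6)
    if fixed_scale is not None:
        kw["pmin"], kw["pmax"] = fixed_scale
    kw["center"] = min(max(kw["center"], 1e-9), 1.0 - 1e-9)
    kw["pmax"] = min(kw.get("pmax", 1.0), 1.0)
    return ClineModelSpec(scaling=scaling, tails=tails, **kw)


def fit_cline(
    data: ClineData,
    scaling: str = "none",
    tails: str = "none",
    *,
    n_starts: int = 20,
    seed: int = 0,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    fixed_parameters: Mapping[str, float] | None = None,
) -> ClineFit:
    """Bounded multi-start maximum-likelihood fit of one cline variant.

    Deterministic given ``seed``: start points come from a seeded
    Latin-hypercube design plus a moment-based initial guess, each refined
    with L-BFGS-B; the best optimum is returned. ``fixed_parameters`` pins
    named parameters (used for profile likelihoods and constrained fits) and
    may also narrow a parameter's box via ``bounds``.

    Degenerate data (all observations identical) is not an error: the fit
    returns with ``boundary=True``.
    """
    if data.n == 0:
        raise ValueError("empty data")
    proto = ClineModelSpec(scaling=scaling, tails=tails, center=0.5, width=0.1)
    names = list(proto.free_parameters)
    fixed = dict(fixed_parameters or {})
    free_names = [n for n in names if n not in fixed]
    box = {**DEFAULT_BOUNDS, **(bounds or {})}
    fixed_scale = _empirical_end_freqs(data) if scaling == "fixed" else None

    lo = np.array([box[n][0] for n in free_names])
    hi = np.array([box[n][1] for n in free_names])

    def unpack(theta_free: np.ndarray) -> ClineModelSpec:
        full = []
        it = iter(theta_free)
        for n in names:
            full.append(fixed[n] if n in fixed else next(it))
        return _build_spec(scaling, tails, np.array(full), names, fixed_scale)

    def nll(theta_free: np.ndarray) -> float:
        try:
            return -loglik(data, unpack(theta_free))
        except ValueError:
            return 1e12

    # moment-based guess: center near where frequency crosses 0.5
    ymax = 2.0 if data.likelihood_kind == "binomial2" else 1.0
    freq = data.y / ymax
    order = np.argsort(data.x)
    guess_c = float(np.interp(0.5, np.clip(np.cumsum(freq[order] + 1e-9) /
                                           (np.sum(freq) + 1e-6), 0, 1),
                              data.x[order])) if np.sum(freq) > 0 else 0.5
    guess = {"center": min(max(guess_c, 0.05), 0.95), "width": 0.2,
             "pmin": 0.01, "pmax": 0.99, "delta_l": 0.05, "delta_r": 0.05,
             "tau_l": 0.5, "tau_r": 0.5}
    starts = [np.array([min(max(guess[n], box[n][0]), box[n][1]) for n in free_names])]
    if n_starts > 1 and free_names:
        sampler = qmc.LatinHypercube(d=len(free_names), seed=seed)
        starts.extend(lo + sampler.random(n_starts - 1) * (hi - lo))

    cands = []
    for x0 in starts:
        if free_names:
            res = minimize(nll, x0, method="L-BFGS-B",
                           bounds=list(zip(lo, hi)),
                           options={"maxiter": 200, "ftol": 1e-12})
            cands.append((float(-res.fun), res.x, bool(res.success)))
        else:
            cands.append((float(-nll(np.empty(0))), np.empty(0), True))
    best_ll = max(c[0] for c in cands)
    # a start whose line search aborted at the shared optimum is still a
    # converged fit; prefer a successful run that ties the best value
    tied_ok = [c for c in cands if c[2] and c[0] >= best_ll - 1e-6]
    ll, theta, ok = (max(tied_ok, key=lambda c: c[0]) if tied_ok
                     else next(c for c in cands if c[0] == best_ll))
    spec = unpack(theta)
    at_bound = bool(free_names) and bool(
        np.any(np.isclose(theta, lo, atol=1e-6)) or np.any(np.isclose(theta, hi, atol=1e-6))
    )
    degenerate = bool(np.all(data.y == data.y[0] if data.n else True))
    return ClineFit(spec=spec, loglik=ll, n_obs=data.n,
                    converged=bool(ok), boundary=at_bound or degenerate, seed=seed)


def support_interval(
    data: ClineData,
    fit: ClineFit,
    parameter: str,
    delta: float = 2.0,
    *,
    tol: float = 1e-4,
    n_starts: int = 3,
) -> tuple[float, float]:
    """Profile-likelihood support interval at ``delta`` log-likelihood units.

    Bisection on each side of the point estimate for the value where the
    profile log-likelihood (other parameters re-optimized) drops ``delta``
    below the maximum; returns the box bound on a side where the profile
    never drops that far. Approximately a 95% CI for 1 df at delta=2.
    """
    if not fit.converged:
        raise ValueError("support interval requires a converged fit")
    if parameter not in fit.spec.free_parameters:
        raise ValueError(f"{parameter!r} is not a free parameter of this variant")
    lo_b, hi_b = DEFAULT_BOUNDS[parameter]
    mle = getattr(fit.spec, parameter)
    target = fit.loglik - delta

    def profile(value: float) -> float:
        pf = fit_cline(data, fit.spec.scaling, fit.spec.tails,
                       n_starts=n_starts, seed=fit.seed,
                       fixed_parameters={parameter: value})
        return pf.loglik

    def solve(side_bound: float) -> float:
        if profile(side_bound) >= target:
            return side_bound  # profile never drops: interval hits the box
        a, b = sorted((mle, side_bound))
        # invariant: profile >= target at the MLE end, < target at the bound end
        for _ in range(60):
            m = 0.5 * (a + b)
            pm = profile(m)
            if abs(pm - target) < tol or (b - a) < 1e-7:
                return m
            inside_is_a = abs(a - mle) < abs(b - mle)
            if pm >= target:
                if inside_is_a:
                    a = m
                else:
                    b = m
            else:
                if inside_is_a:
                    b = m
                else:
                    a = m
        return 0.5 * (a + b)

    lo = solve(lo_b)
    hi = solve(hi_b)
    return (min(lo, mle), max(hi, mle))


def all_variants() -> list[tuple[str, str]]:
    return list(itertools.product(SCALINGS, TAILS))


def select_model(
    data: ClineData,
    variants: Iterable[tuple[str, str]] | None = None,
    *,
    n_starts: int = 20,
    seed: int = 0,
) -> ClineFit:
    """Fit each candidate variant and return the minimum-AIC converged fit.

    Ties (to 1e-9 in AIC) break toward fewer parameters, then toward
    tails=none, then by variant order for determinism.
    """
    cands = list(variants) if variants is not None else all_variants()
    fits: list[ClineFit] = []
    statuses: dict[tuple[str, str], str] = {}
    for scaling, tails in cands:
        try:
            f = fit_cline(data, scaling, tails, n_starts=n_starts, seed=seed)
        except ValueError as e:
            statuses[(scaling, tails)] = f"error: {e}"
            continue
        statuses[(scaling, tails)] = "converged" if f.converged else "not converged"
        if f.converged:
            fits.append(f)
    if not fits:
        raise NoConvergentModelError(statuses)
    return min(
        fits,
        key=lambda f: (round(f.aic, 9), f.spec.k, 0 if f.spec.tails == "none" else 1,
                       SCALINGS.index(f.spec.scaling), TAILS.index(f.spec.tails)),
    )
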