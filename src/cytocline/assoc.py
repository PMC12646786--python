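"""Firth bias-reduced logistic regression of chlorotype on climate.

Ordinary maximum-likelihood logistic regression fails under complete
separation (estimates diverge), which is common when a climate gradient
splits the two chlorotypes cleanly along a transect. Firth's penalty adds
half the log-determinant of the Fisher information to the log-likelihood,

    l*(beta) = l(beta) + 1/2 log det I(beta),

whose maximizer is always finite. The fit uses modified-score Newton
iterations with hat-value-adjusted residuals and step-halving.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class RankDeficientDesignError(ValueError):
    pass


@dataclass(frozen=True)
class FirthFit:
    coefficients: np.ndarray  # log-odds per predictor unit, intercept first
    standard_errors: np.ndarray
    penalized_loglik: float
    n_iter: int
    converged: bool


def _logistic(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-eta))


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log-likelihood written to stay finite for large |eta|
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = _logistic(eta)
    W = p * (1.0 - p)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_fit(
    design: np.ndarray,
    response: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    max_halvings: int = 5,
) -> FirthFit:
    """Maximize the Firth-penalized logistic log-likelihood.

    ``design`` must include an intercept column; ``response`` is 0/1.
    Convergence when the max absolute modified score falls below ``tol``.
    Estimates are finite for any data, including complete separation.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design/response shape mismatch")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("response must be binary 0/1")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        _, r = np.linalg.qr(X)
        dep = [j for j in range(X.shape[1]) if abs(r[min(j, r.shape[0] - 1), j]) < 1e-10]
        raise RankDeficientDesignError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"dependent column index(es): {dep or 'unknown'}"
        )

    beta = np.zeros(X.shape[1])
    pll = _penalized_loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = _logistic(eta)
        W = p * (1.0 - p)
        XW = X * W[:, None]
        info = X.T @ XW
        info_inv = np.linalg.inv(info)
        # leverages of the weighted design
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (y - p + h * (0.5 - p))  # modified (bias-corrected) score
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = info_inv @ score
        # step-halving: accept only non-decreasing penalized likelihood
        factor = 1.0
        for _ in range(max_halvings + 1):
            cand = beta + factor * step
            pll_new = _penalized_loglik(X, y, cand)
            if pll_new >= pll - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        assert pll_new >= pll - 1e-6, "penalized likelihood decreased"
        pll = pll_new
    eta = X @ beta
    p = _logistic(eta)
    info = X.T @ (X * (p * (1 - p))[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return FirthFit(
        coefficients=beta,
        standard_errors=se,
        penalized_loglik=_penalized_loglik(X, y, beta),
        n_iter=it,
        converged=converged,
    )


CLIMATE_VARIABLES = ("TD", "MAT", "MAP", "CMD", "RH", "PAS")


@dataclass(frozen=True)
class ClimateAssociation:
    contact_zone: str
    variable: str
    slope: float | None  # log-odds of PT chlorotype per natural unit
    se: float | None
    converged: bool
    status: str  # "ok", "monomorphic", "constant_predictor"
    n: int


def climate_scan(
    samples,
    climate,
    zones: Sequence[str] | None = None,
    variables: Sequence[str] = CLIMATE_VARIABLES,
    *,
    min_samples: int = 5,
) -> list[ClimateAssociation]:
    """Per-zone, per-variable univariate Firth fits of chlorotype on climate.

    Chlorotype is coded 0 = PB, 1 = PT; OTHER/MISSING samples are excluded.
    Slopes are log-odds per natural unit (per degree C, per %, per mm). A zone
    fixed for one chlorotype is flagged monomorphic; a constant predictor in a
    zone is flagged without aborting the scan.
    """
    clim = {c.sample_id: c for c in climate}
    usable = [s for s in samples if s.chlorotype in ("PB", "PT") and s.sample_id in clim]
    if zones is None:
        zones = sorted({s.contact_zone for s in usable})
    out: list[ClimateAssociation] = []
    for zone in zones:
        zs = [s for s in usable if s.contact_zone == zone]
        y = np.array([1.0 if s.chlorotype == "PT" else 0.0 for s in zs])
        for var in variables:
            x = np.array([getattr(clim[s.sample_id], var) for s in zs])
            n = len(zs)
            if len(set(y)) < 2:
                out.append(ClimateAssociation(zone, var, None, None, False, "monomorphic", n))
                continue
            if n < min_samples:
                out.append(ClimateAssociation(zone, var, None, None, False, "too_few_samples", n))
                continue
            if np.ptp(x) == 0:
                out.append(
                    ClimateAssociation(zone, var, None, None, False, "constant_predictor", n)
                )
                continue
            X = np.column_stack([np.ones(n), x])
            fit = firth_fit(X, y)
            out.append(
                ClimateAssociation(
                    zone, var, float(fit.coefficients[1]), float(fit.standard_errors[1]),
                    fit.converged, "ok", n,
                )
            )
    return out
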