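"""Quantitative genetics of cytonuclear trait effects.

Two mixed models are fitted by restricted maximum likelihood (REML):

* per-garden heritability: ``y = mu + genotype + block + e`` with genotype
  and block random; broad-sense heritability is
  ``H2 = V_G / (V_G + V_E + V_eps)`` (clonal replicates, so V_G captures the
  total genotypic variance);
* the cytonuclear trait model: fixed effects of nuclear ancestry N (continuous
  proportion of P. trichocarpa ancestry), chlorotype C (0 = PB, 1 = PT),
  their interaction N x C, and garden; a random intercept for block nested in
  garden; Wald tests per coefficient and Nakagawa-style marginal/conditional
  R-squared.

REML is computed by EM iterations on Henderson's mixed-model equations,
which keeps variance components non-negative and the REML objective
monotone; estimates reaching the zero boundary are truncated and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

_REML_TOL = 1e-8
_REML_MAX_ITER = 5000
_VAR_FLOOR = 1e-12


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class VarianceComponents:
    V_G: float
    V_E: float
    V_eps: float
    H2: float
    boundary: bool
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.H2 <= 1.0, "H2 outside [0,1]"
        assert min(self.V_G, self.V_E, self.V_eps) >= 0.0


@dataclass(frozen=True)
class CytonuclearModelFit:
    beta: Mapping[str, float]  # intercept, N, C, NxC, garden effect(s)
    se: Mapping[str, float]
    wald_p: Mapping[str, float]
    V_block_in_garden: float
    V_eps: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_excluded: int
    converged: bool

    def __post_init__(self) -> None:
        assert self.r2_marginal <= self.r2_conditional + 1e-12 <= 1.0 + 1e-12


def _reml_loglik(n: int, p: int, sig_e: float, sigmas: Sequence[float],
                 q_sizes: Sequence[int], logdet_M: float, yPy: float) -> float:
    q = sum(q_sizes)
    val = (n - p) * np.log(2 * np.pi)
    val += (n - p - q) * np.log(sig_e)
    val += sum(qk * np.log(sk) for qk, sk in zip(q_sizes, sigmas))
    val += logdet_M + yPy
    return -0.5 * val


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    Z_blocks: Sequence[np.ndarray],
    *,
    tol: float = _REML_TOL,
    max_iter: int = _REML_MAX_ITER,
) -> dict:
    """EM-REML for ``y = X b + sum_k Z_k u_k + e`` with i.i.d. components.

    Returns point estimates of each sigma_k^2 and sigma_e^2, BLUEs/BLUPs,
    the fixed-effect covariance, and the REML log-likelihood trace (asserted
    non-decreasing). Small problems only: the mixed-model equations are
    dense, of dimension p + sum q_k.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    Z = np.hstack(Z_blocks) if Z_blocks else np.empty((n, 0))
    q_sizes = [Zk.shape[1] for Zk in Z_blocks]
    q = sum(q_sizes)
    W = np.hstack([X, Z])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)

    tot_var = float(np.var(y, ddof=1)) if n > 1 else 1.0
    if tot_var <= 0:
        raise DegenerateDataError("response has zero variance")
    K = len(Z_blocks)
    sigmas = [tot_var / (K + 1)] * K
    sig_e = tot_var / (K + 1)

    idx = []  # slices of each u_k inside the MME solution
    off = p
    for qk in q_sizes:
        idx.append(slice(off, off + qk))
        off += qk

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = WtW.copy()
        for k, sl in enumerate(idx):
            alpha = sig_e / max(sigmas[k], _VAR_FLOOR)
            M[sl, sl] += alpha * np.eye(q_sizes[k])
        C = np.linalg.inv(M)
        sol = C @ Wty
        yPy = (yty - float(sol @ Wty)) / sig_e
        sign, logdet_M = np.linalg.slogdet(M)
        ll = _reml_loglik(n, p, sig_e, [max(s, _VAR_FLOOR) for s in sigmas],
                          q_sizes, logdet_M, yPy)
        # EM-REML ascends the restricted likelihood; the guarantee is only
        # meaningful away from the zero-residual boundary, where the floored
        # variance makes the objective numerically ill-defined
        if sig_e > 1e6 * _VAR_FLOOR:
            assert ll >= ll_prev - 1e-6 * (1.0 + abs(ll_prev)), \
                "REML objective decreased in EM"
        new_sigmas = []
        for k, sl in enumerate(idx):
            uk = sol[sl]
            new_sigmas.append((float(uk @ uk) + sig_e * float(np.trace(C[sl, sl])))
                              / q_sizes[k])
        new_sig_e = max((yty - float(sol @ Wty)) / (n - p), _VAR_FLOOR)
        rel = abs(new_sig_e - sig_e) / max(sig_e, _VAR_FLOOR)
        for s_new, s_old in zip(new_sigmas, sigmas):
            rel = max(rel, abs(s_new - s_old) / max(s_old, _VAR_FLOOR))
        sigmas = [max(s, _VAR_FLOOR) for s in new_sigmas]
        sig_e = new_sig_e
        ll_prev = ll
        if rel < tol:
            converged = True
            break

    # truncate boundary components, then solve once more with those
    # components effectively removed (huge ridge) so BLUEs are not shrunk
    # toward spurious random effects
    boundary = any(s <= 10 * _VAR_FLOOR or s < 1e-8 * tot_var for s in sigmas)
    sigmas_out = [0.0 if (s <= 10 * _VAR_FLOOR or s < 1e-8 * tot_var) else s
                  for s in sigmas]
    M = WtW.copy()
    for k, sl in enumerate(idx):
        alpha = sig_e / sigmas_out[k] if sigmas_out[k] > 0 else 1e15 * (1 + sig_e)
        M[sl, sl] += alpha * np.eye(q_sizes[k])
    C = np.linalg.inv(M)
    sol = C @ Wty
    return {
        "sigma2": sigmas_out,
        "sigma2_e": sig_e,
        "beta": sol[:p],
        "u": [sol[sl] for sl in idx],
        "beta_cov": C[:p, :p] * sig_e,
        "loglik": ll_prev,
        "n_iter": it,
        "converged": converged,
        "boundary": boundary,
        "fitted_fixed": X @ sol[:p],
    }


def _indicator(levels: Sequence) -> tuple[np.ndarray, list]:
    uniq = sorted(set(levels))
    Z = np.zeros((len(levels), len(uniq)))
    pos = {u: j for j, u in enumerate(uniq)}
    for i, lv in enumerate(levels):
        Z[i, pos[lv]] = 1.0
    return Z, uniq


def estimate_h2(trait_records, garden: str, trait_name: str | None = None) -> VarianceComponents:
    """REML variance components and broad-sense heritability for one garden.

    Fits genotype and block as crossed random effects on the records of a
    single garden (and a single trait). Requires >= 2 genotypes; zero trait
    variance is a degenerate-data error.
    """
    recs = [r for r in trait_records if r.garden == garden]
    traits = sorted({r.trait_name for r in recs})
    if trait_name is None:
        if len(traits) != 1:
            raise ValueError(f"multiple traits present {traits}; pass trait_name")
        trait_name = traits[0]
    recs = [r for r in recs if r.trait_name == trait_name]
    genos = sorted({r.genotype_id for r in recs})
    if len(genos) < 2:
        raise ValueError("need at least 2 genotypes to estimate H2")
    y = np.array([r.value for r in recs])
    if np.var(y) == 0:
        raise DegenerateDataError(f"trait {trait_name} has zero variance in {garden}")
    Zg, _ = _indicator([r.genotype_id for r in recs])
    Zb, _ = _indicator([r.block for r in recs])
    X = np.ones((len(recs), 1))
    res = em_reml(y, X, [Zg, Zb])
    vg, ve = res["sigma2"]
    veps = res["sigma2_e"]
    h2 = vg / (vg + ve + veps)
    return VarianceComponents(V_G=vg, V_E=ve, V_eps=veps, H2=float(h2),
                              boundary=res["boundary"], converged=res["converged"],
                              n_iter=res["n_iter"])


def fit_cytonuclear(trait_records, sample_ancestry, trait_name: str | None = None) -> CytonuclearModelFit:
    """Fit the cytonuclear-interaction trait model.

    ``sample_ancestry`` maps genotype_id to ``(nuclear_q, chlorotype)`` with
    chlorotype in {"PB", "PT"} (or OTHER/MISSING, which are excluded with a
    count). The model has fixed effects N, C, N x C and garden, a random
    intercept for block nested in garden, and reports Wald p-values plus
    marginal and conditional R-squared.
    """
    if not isinstance(sample_ancestry, Mapping):
        sample_ancestry = {
            s.genotype_id: (s.nuclear_q, s.chlorotype) for s in sample_ancestry
        }
    recs = list(trait_records)
    traits = sorted({r.trait_name for r in recs})
    if trait_name is None:
        if len(traits) != 1:
            raise ValueError(f"multiple traits present {traits}; pass trait_name")
    else:
        recs = [r for r in recs if r.trait_name == trait_name]
    rows, excluded = [], 0
    for r in recs:
        anc = sample_ancestry.get(r.genotype_id)
        if anc is None:
            excluded += 1
            continue
        nq, chl = anc
        if chl not in ("PB", "PT") or nq is None:
            excluded += 1
            continue
        rows.append((r, float(nq), 1.0 if chl == "PT" else 0.0))
    if not rows:
        raise ValueError("no usable records after exclusions")
    c_vals = {c for _, _, c in rows}
    if len(c_vals) < 2:
        raise ValueError("all records share one chlorotype; C is not estimable")
    gardens = sorted({r.garden for r, _, _ in rows})
    y = np.array([r.value for r, _, _ in rows])
    N = np.array([nq for _, nq, _ in rows])
    Cc = np.array([c for _, _, c in rows])
    names = ["intercept", "N", "C", "NxC"]
    cols = [np.ones_like(y), N, Cc, N * Cc]
    for g in gardens[1:]:  # treatment coding against the first garden
        names.append(f"garden[{g}]")
        cols.append(np.array([1.0 if r.garden == g else 0.0 for r, _, _ in rows]))
    X = np.column_stack(cols)
    Zb, _ = _indicator([f"{r.garden}:{r.block}" for r, _, _ in rows])
    res = em_reml(y, X, [Zb])
    beta = res["beta"]
    se = np.sqrt(np.maximum(np.diag(res["beta_cov"]), 0.0))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * norm.sf(np.abs(z))
    v_fixed = float(np.var(res["fitted_fixed"]))
    v_block = res["sigma2"][0]
    v_eps = res["sigma2_e"]
    denom = v_fixed + v_block + v_eps
    return CytonuclearModelFit(
        beta=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se.tolist())),
        wald_p=dict(zip(names, pvals.tolist())),
        V_block_in_garden=v_block,
        V_eps=v_eps,
        r2_marginal=v_fixed / denom,
        r2_conditional=(v_fixed + v_block) / denom,
        n_obs=len(rows),
        n_excluded=excluded,
        converged=res["converged"],
    )
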