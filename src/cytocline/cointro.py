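"""Co-introgression classification of nuclear-chloroplast (N-cp) genes.

A gene co-introgresses with the chloroplast when its geographic cline is
concordant with the chloroplast cline but not with the reference cline of
non-interacting nuclear genes. Concordance is read off support intervals:
a gene "overlaps" a reference iff BOTH its center and width point
estimates fall inside that reference's respective intervals (the stricter
both-parameter rule). Each gene additionally gets two constrained-model
likelihood-ratio tests (1 df): the gene's selected cline refitted with its
center bounded to the reference's center interval, compared to the free
fit by 2*(lnL_free - lnL_constrained) against chi-square(1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .cline import (
    ClineData,
    ClineFit,
    fit_cline,
    select_model,
    support_interval,
)
from .io_tables import AncestryMatrix, GeneAnnotation

DEFAULT_SCAN_VARIANTS = (("none", "none"), ("free", "none"))


@dataclass(frozen=True)
class ReferenceCline:
    label: str  # "chloroplast" or "nuclear_mean"
    fit: ClineFit
    center_ci: tuple[float, float]
    width_ci: tuple[float, float]


@dataclass(frozen=True)
class CoIntrogressionVerdict:
    gene_id: str
    gene_fit: ClineFit | None
    overlap_cp: bool
    overlap_nuc: bool
    classification: str  # co_introgressing / independent / ambiguous / unevaluable
    lrt_cp: tuple[float, float] | None  # (statistic, p)
    lrt_nuc: tuple[float, float] | None


@dataclass(frozen=True)
class ScanSummary:
    n_genes: int
    n_co_introgressing: int
    n_independent: int
    n_ambiguous: int
    n_unevaluable: int

    def __post_init__(self) -> None:
        total = (self.n_co_introgressing + self.n_independent
                 + self.n_ambiguous + self.n_unevaluable)
        assert total == self.n_genes, "verdict counts do not partition the genes"


def build_reference(
    label: str,
    data: ClineData,
    *,
    variants=DEFAULT_SCAN_VARIANTS,
    n_starts: int = 10,
    seed: int = 0,
) -> ReferenceCline:
    """Fit a reference cline (chloroplast or mean nuclear) and its support
    intervals for center and width."""
    fit = select_model(data, variants, n_starts=n_starts, seed=seed)
    c_ci = support_interval(data, fit, "center")
    w_ci = support_interval(data, fit, "width")
    return ReferenceCline(label=label, fit=fit, center_ci=c_ci, width_ci=w_ci)


def _param_overlaps(fit: ClineFit, param: str, ref_ci: tuple[float, float]) -> bool:
    # interval-interval overlap when the gene fit carries its own support
    # interval; point-in-interval otherwise
    gene_ci = fit.support_intervals.get(param)
    if gene_ci is not None:
        return gene_ci[0] <= ref_ci[1] and ref_ci[0] <= gene_ci[1]
    est = getattr(fit.spec, param)
    return ref_ci[0] <= est <= ref_ci[1]


def _overlaps(fit: ClineFit, ref: ReferenceCline) -> bool:
    return (_param_overlaps(fit, "center", ref.center_ci)
            and _param_overlaps(fit, "width", ref.width_ci))


def classify_gene(
    gene_fit: ClineFit | None,
    cp_ref: ReferenceCline,
    nuc_ref: ReferenceCline,
) -> tuple[bool, bool, str]:
    """Apply the overlap rule. Returns (overlap_cp, overlap_nuc, class).

    A gene overlaps a reference iff BOTH its center and width are
    concordant with the reference's support intervals — the gene's own
    support interval intersecting the reference interval when the fit
    carries one, the point estimate falling inside it otherwise.
    co_introgressing iff the gene overlaps the chloroplast reference and
    not the nuclear one; ambiguous iff it overlaps both; a non-converged
    (or absent) gene fit is recorded unevaluable rather than raising.
    """
    if gene_fit is None or not gene_fit.converged:
        return False, False, "unevaluable"
    ocp = _overlaps(gene_fit, cp_ref)
    onuc = _overlaps(gene_fit, nuc_ref)
    if ocp and not onuc:
        cls = "co_introgressing"
    elif ocp and onuc:
        cls = "ambiguous"
    else:
        cls = "independent"
    return ocp, onuc, cls


def constrained_lrt(
    gene_data: ClineData,
    gene_fit: ClineFit,
    reference_ci: tuple[float, float],
    *,
    reference_center: float | None = None,
    mode: str = "point",
    n_starts: int = 10,
) -> tuple[float, float]:
    """LRT of the gene's cline against a center constrained by a reference.

    ``mode="point"`` (default) refits the gene's selected variant with the
    center fixed at a value within the reference CI — ``reference_center``
    when given, the CI midpoint otherwise — yielding a standard nested
    model with exactly one constrained degree of freedom, so the statistic
    2*(lnL_free - lnL_constrained) is chi-square(1) calibrated when the
    gene truly shares the reference center.

    ``mode="interval"`` instead bounds the center to the CI (best
    achievable constrained likelihood); a free center already inside the
    CI then gives statistic 0, p = 1. This reading is conservative: its
    null rejection rate is far below the nominal level.
    """
    lo, hi = reference_ci
    if not (lo <= hi):
        raise ValueError("empty reference interval")
    if mode not in ("point", "interval"):
        raise ValueError(f"unknown mode {mode!r}")
    spec = gene_fit.spec
    if mode == "interval":
        if lo <= spec.center <= hi:
            return 0.0, 1.0
        cfit = fit_cline(
            gene_data, spec.scaling, spec.tails,
            n_starts=n_starts, seed=gene_fit.seed,
            bounds={"center": (max(lo, 1e-9), min(hi, 1.0 - 1e-9))},
        )
    else:
        c0 = reference_center if reference_center is not None else 0.5 * (lo + hi)
        if not (lo - 1e-12 <= c0 <= hi + 1e-12):
            raise ValueError("reference_center lies outside the reference CI")
        cfit = fit_cline(
            gene_data, spec.scaling, spec.tails,
            n_starts=n_starts, seed=gene_fit.seed,
            fixed_parameters={"center": float(np.clip(c0, 1e-9, 1 - 1e-9))},
        )
    if not cfit.converged:
        raise RuntimeError("constrained fit did not converge")
    stat = max(0.0, 2.0 * (gene_fit.loglik - cfit.loglik))
    return stat, float(chi2.sf(stat, df=1))


def gene_ancestry_data(
    matrix: AncestryMatrix,
    gene: GeneAnnotation,
    transect: Mapping[str, float],
    flank: int = 100,
) -> ClineData:
    """Per-individual diploid trichocarpa ancestry counts for one gene.

    Positions within the gene span +/- ``flank`` bp contribute; each
    haplotype's gene ancestry is its majority state across those positions
    and the diploid count (0, 1, 2) is the sum over the two haplotypes.
    Individuals missing from ``transect`` are skipped.
    """
    lo, hi = gene.start - flank, gene.end + flank
    cols = [i for i, (chrom, pos) in enumerate(matrix.positions)
            if chrom == gene.chromosome and lo <= pos <= hi]
    if not cols:
        raise ValueError(f"no ancestry positions within {gene.gene_id} +/- {flank} bp")
    xs, ys = [], []
    for ind in matrix.individual_ids:
        if ind not in transect:
            continue
        r1, r2 = matrix.haplotype_rows(ind)
        k = 0
        for r in (r1, r2):
            k += int(matrix.values[r, cols].mean() >= 0.5)
        xs.append(transect[ind])
        ys.append(k)
    return ClineData(np.array(xs), np.array(ys), "binomial2")


def mean_nuclear_data(
    matrix: AncestryMatrix,
    genes: Sequence[GeneAnnotation],
    transect: Mapping[str, float],
    flank: int = 100,
) -> ClineData:
    """Per-individual mean trichocarpa ancestry across the given genes
    (continuous in [0,1]; gaussian likelihood)."""
    per_gene = [gene_ancestry_data(matrix, g, transect, flank) for g in genes]
    inds = [i for i in matrix.individual_ids if i in transect]
    xs = np.array([transect[i] for i in inds])
    mat = np.stack([d.y / 2.0 for d in per_gene])  # genes x individuals
    return ClineData(xs, mat.mean(axis=0), "gaussian")


def scan(
    genes_ancestry: Mapping[str, ClineData],
    cp_data: ClineData,
    nuc_mean_data: ClineData,
    *,
    variants=DEFAULT_SCAN_VARIANTS,
    n_starts: int = 10,
    seed: int = 0,
    cp_ref: ReferenceCline | None = None,
    nuc_ref: ReferenceCline | None = None,
) -> tuple[list[CoIntrogressionVerdict], ScanSummary]:
    """Classify every gene against the chloroplast and nuclear references.

    References are fitted first unless passed in (any reference failure
    aborts with a diagnostic); each gene is then fitted, classified by the
    overlap rule, and tested with both constrained LRTs. Verdict order
    follows input order; verdicts themselves are order-invariant.
    """
    if cp_ref is None:
        try:
            cp_ref = build_reference("chloroplast", cp_data, variants=variants,
                                     n_starts=n_starts, seed=seed)
        except Exception as e:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"chloroplast reference cline failed: {e}") from e
    if nuc_ref is None:
        try:
            nuc_ref = build_reference("nuclear_mean", nuc_mean_data, variants=variants,
                                      n_starts=n_starts, seed=seed)
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"nuclear reference cline failed: {e}") from e

    verdicts: list[CoIntrogressionVerdict] = []
    counts = {"co_introgressing": 0, "independent": 0, "ambiguous": 0, "unevaluable": 0}
    for gene_id, gdata in genes_ancestry.items():
        try:
            gfit = select_model(gdata, variants, n_starts=n_starts, seed=seed)
            cis = {
                p: support_interval(gdata, gfit, p, n_starts=3)
                for p in ("center", "width")
            }
            gfit = dataclasses.replace(gfit, support_intervals=cis)
        except Exception:  # noqa: BLE001 - gene-level failure is a verdict, not a crash
            gfit = None
        ocp, onuc, cls = classify_gene(gfit, cp_ref, nuc_ref)
        lrt_cp = lrt_nuc = None
        if gfit is not None and gfit.converged:
            try:
                lrt_cp = constrained_lrt(
                    gdata, gfit, cp_ref.center_ci,
                    reference_center=cp_ref.fit.spec.center, n_starts=n_starts)
                lrt_nuc = constrained_lrt(
                    gdata, gfit, nuc_ref.center_ci,
                    reference_center=nuc_ref.fit.spec.center, n_starts=n_starts)
            except RuntimeError:
                pass
        counts[cls] += 1
        verdicts.append(
            CoIntrogressionVerdict(
                gene_id=gene_id, gene_fit=gfit, overlap_cp=ocp, overlap_nuc=onuc,
                classification=cls, lrt_cp=lrt_cp, lrt_nuc=lrt_nuc,
            )
        )
    summary = ScanSummary(
        n_genes=len(verdicts),
        n_co_introgressing=counts["co_introgressing"],
        n_independent=counts["independent"],
        n_ambiguous=counts["ambiguous"],
        n_unevaluable=counts["unevaluable"],
    )
    return verdicts, summary
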