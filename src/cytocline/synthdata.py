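"""Synthetic hybrid-zone data with recorded ground truth.

Generates every input the pipeline consumes — sample table with transect
positions and chlorotypes, haplotype-level local-ancestry matrix, gene
annotations, climate table, trait table, and a chloroplast alignment with
planted fixed differences — from a single top-level seed. All generator
parameters are recorded in a SyntheticTruth object so recovery tests can
compare estimates against what was planted.

The generator emulates the statistical structure of a two-species poplar
contact zone: sample positions uniform on the scaled transect, chlorotype
drawn Bernoulli from a chloroplast cline, the two haplotypes of each gene
drawn independently from the gene's own cline (Hardy-Weinberg at the local
frequency), climate covariates monotone in transect distance, and traits
from a fixed-effects cytonuclear model with block/garden variance
components. Linkage between genes and demographic structure are
deliberately absent.

All randomness flows from ``numpy.random.SeedSequence(seed)`` through
named substreams; reruns with the same (config, seed) are bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cline import ClineModelSpec, cline_probability
from .io_tables import (
    AncestryMatrix,
    ClimateRecord,
    GeneAnnotation,
    SampleRecord,
    TraitRecord,
)

_SUBSTREAMS = ("positions", "chlorotype", "ancestry", "climate", "traits", "alignment")


def _rng(seed: int, stream: str) -> np.random.Generator:
    if stream not in _SUBSTREAMS:
        raise ValueError(f"unknown substream {stream!r}")
    root = np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS.index(stream),))
    return np.random.default_rng(root)


@dataclass
class SyntheticTruth:
    """Everything the generator decided, for recovery tests."""

    seed: int
    transect: dict[str, float] = field(default_factory=dict)
    cp_cline: ClineModelSpec | None = None
    nuclear_cline: ClineModelSpec | None = None
    gene_clines: dict[str, ClineModelSpec] = field(default_factory=dict)
    co_introgressing: dict[str, bool] = field(default_factory=dict)
    climate_slopes: dict[str, float] = field(default_factory=dict)
    trait_betas: dict[str, float] = field(default_factory=dict)
    variance_components: dict[str, float] = field(default_factory=dict)
    planted_fixed_diffs: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class HybridZoneConfig:
    """Study conditions for the simulated contact zone.

    Defaults echo the steep-cline zone of the study system: a chloroplast
    cline at c=0.43, w=0.05, a nuclear reference cline at c=0.5, w=0.3,
    and a co-introgressing fraction of genes sharing the chloroplast cline.
    """

    n_samples: int = 300
    n_genes: int = 100
    snps_per_gene: int = 5
    contact_zone: str = "zone1"
    cp_center: float = 0.43
    cp_width: float = 0.05
    nuc_center: float = 0.5
    nuc_width: float = 0.3
    co_fraction: float = 0.1
    center_jitter_sd: float = 0.01
    gene_span_bp: int = 2000
    gene_gap_bp: int = 10000
    capture: str | None = None  # "PT" or "PB": chlorotype fixed zone-wide

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples < 10: too small to fit clines")
        if not (0.0 <= self.co_fraction <= 1.0):
            raise ValueError("co_fraction must lie in [0,1]")
        if self.capture not in (None, "PT", "PB"):
            raise ValueError("capture must be None, 'PT' or 'PB'")


def generate_hybrid_zone(
    config: HybridZoneConfig, seed: int
) -> tuple[list[SampleRecord], AncestryMatrix, list[GeneAnnotation], SyntheticTruth]:
    """Sample table + local-ancestry matrix + gene annotations + truth.

    Sample positions are uniform on [0,1] and mapped to longitudes along a
    constant-latitude transect so the geometry module reproduces the scaled
    positions. Chlorotype is Bernoulli in the chloroplast cline; each
    gene's two haplotype ancestries are independent Bernoulli draws from
    the gene's cline probability, constant across the SNPs of the gene
    (gene-scale linkage blocks, no intragenic recombination).
    """
    truth = SyntheticTruth(seed=seed)
    rng_pos = _rng(seed, "positions")
    x = np.sort(rng_pos.uniform(0.0, 1.0, config.n_samples))
    x[0], x[-1] = 0.0, 1.0  # pin the anchor and far end of the transect
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    truth.transect = dict(zip(sample_ids, x.tolist()))

    cp_spec = ClineModelSpec(center=config.cp_center, width=config.cp_width)
    nuc_spec = ClineModelSpec(center=config.nuc_center, width=config.nuc_width)
    truth.cp_cline, truth.nuclear_cline = cp_spec, nuc_spec

    rng_chl = _rng(seed, "chlorotype")
    if config.capture is not None:
        # chloroplast capture: one chlorotype fixed across the whole zone
        chloro = np.full(config.n_samples, config.capture == "PT")
    else:
        p_cp = np.asarray(cline_probability(x, cp_spec))
        chloro = rng_chl.random(config.n_samples) < p_cp

    # transect along a parallel at 52 N spanning ~8 degrees of longitude
    lat0, lon0, lon_span = 52.0, -128.0, 8.0
    samples = []
    rng_anc = _rng(seed, "ancestry")
    n_co = int(round(config.co_fraction * config.n_genes))
    hap_ids: list[str] = []
    for sid in sample_ids:
        hap_ids += [f"{sid}_1", f"{sid}_2"]
    positions: list[tuple[str, int]] = []
    annotations: list[GeneAnnotation] = []
    values = np.zeros((2 * config.n_samples, config.n_genes * config.snps_per_gene),
                      dtype=np.int8)
    col = 0
    cursor = 1
    for g in range(config.n_genes):
        gid = f"gene{g:04d}"
        co = g < n_co
        base = cp_spec if co else nuc_spec
        jitter = float(rng_anc.normal(0.0, config.center_jitter_sd))
        center = float(np.clip(base.center + jitter, 1e-3, 1 - 1e-3))
        spec = ClineModelSpec(center=center, width=base.width)
        truth.gene_clines[gid] = spec
        truth.co_introgressing[gid] = co
        start = cursor
        end = start + config.gene_span_bp - 1
        annotations.append(GeneAnnotation(gid, "chr1", start, end, "+"))
        snp_pos = np.linspace(start, end, config.snps_per_gene).astype(int)
        positions += [("chr1", int(p)) for p in snp_pos]
        p_gene = np.asarray(cline_probability(x, spec))
        hap_draw = rng_anc.random((config.n_samples, 2)) < p_gene[:, None]
        for s in range(config.n_samples):
            values[2 * s, col : col + config.snps_per_gene] = hap_draw[s, 0]
            values[2 * s + 1, col : col + config.snps_per_gene] = hap_draw[s, 1]
        col += config.snps_per_gene
        cursor = end + config.gene_gap_bp

    nuc_mean = values.reshape(2 * config.n_samples, -1).mean(axis=1)
    q_by_sample = 0.5 * (nuc_mean[0::2] + nuc_mean[1::2])
    for i, sid in enumerate(sample_ids):
        samples.append(
            SampleRecord(
                sample_id=sid,
                contact_zone=config.contact_zone,
                lat=lat0,
                lon=lon0 + lon_span * x[i],
                chlorotype="PT" if chloro[i] else "PB",
                nuclear_q=float(q_by_sample[i]),
                genotype_id=sid,
            )
        )
    matrix = AncestryMatrix(hap_ids, positions, values)
    return samples, matrix, annotations, truth


@dataclass(frozen=True)
class ClimateConfig:
    """Linear climate trends over the scaled transect, with noise.

    The transect runs from the low-trichocarpa end (x=0) to the
    high-trichocarpa end (x=1); default slopes make the trichocarpa end
    warmer, wetter and less continental, so that chlorotype-climate
    associations carry the sign pattern of a maritime-vs-boreal contrast
    (PT positive with MAT, RH, MAP, PAS; negative with TD, CMD).
    """

    slopes: Mapping[str, float] = field(
        default_factory=lambda: {
            "TD": -12.0, "MAT": 8.0, "MAP": 1500.0,
            "CMD": -150.0, "RH": 15.0, "PAS": 300.0,
        }
    )
    intercepts: Mapping[str, float] = field(
        default_factory=lambda: {
            "TD": 24.0, "MAT": 0.0, "MAP": 500.0,
            "CMD": 200.0, "RH": 60.0, "PAS": 100.0,
        }
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "TD": 1.0, "MAT": 0.8, "MAP": 100.0,
            "CMD": 20.0, "RH": 2.0, "PAS": 30.0,
        }
    )


def generate_climate(
    config: ClimateConfig, seed: int, samples: Sequence[SampleRecord],
    transect: Mapping[str, float], truth: SyntheticTruth | None = None,
) -> tuple[list[ClimateRecord], SyntheticTruth]:
    truth = truth or SyntheticTruth(seed=seed)
    rng = _rng(seed, "climate")
    records = []
    for s in samples:
        x = transect[s.sample_id]
        vals = {}
        for var in ("TD", "MAT", "MAP", "CMD", "RH", "PAS"):
            v = (config.intercepts[var] + config.slopes[var] * x
                 + rng.normal(0.0, config.noise_sd[var]))
            if var in ("MAP", "CMD", "PAS"):
                v = max(v, 0.0)
            if var == "RH":
                v = min(max(v, 0.0), 100.0)
            vals[var] = float(v)
        records.append(ClimateRecord(sample_id=s.sample_id, **vals))
    truth.climate_slopes = dict(config.slopes)
    return records, truth


@dataclass(frozen=True)
class TraitConfig:
    """Cytonuclear trait-model generator settings.

    The interaction default −0.11 matches the scale of the photosystem-II
    efficiency effect the model is meant to detect; blocks-within-garden
    and residual variances are moderate relative to the fixed effects.
    """

    trait_name: str = "PhiPSII"
    mu: float = 0.6
    beta_N: float = 0.05
    beta_C: float = 0.02
    beta_NxC: float = -0.11
    beta_E: float = -0.03  # VA garden contrast vs VT
    V_block: float = 0.002
    V_eps: float = 0.01
    gardens: tuple[str, ...] = ("VT", "VA")
    blocks_per_garden: int = 3

    def __post_init__(self) -> None:
        if self.V_eps <= 0:
            raise ValueError("V_eps must be positive")


def generate_traits(
    config: TraitConfig, seed: int, samples: Sequence[SampleRecord],
    truth: SyntheticTruth | None = None,
) -> tuple[list[TraitRecord], SyntheticTruth]:
    """Trait table under y = mu + bN*N + bC*C + bNxC*N*C + bE*E + block + eps.

    One replicate per genotype per block (blocks_per_garden replicates per
    garden), mirroring a randomized complete block design with clonal
    replicates.
    """
    truth = truth or SyntheticTruth(seed=seed)
    rng = _rng(seed, "traits")
    block_eff = {
        (g, b): float(rng.normal(0.0, np.sqrt(config.V_block)))
        for g in config.gardens
        for b in range(1, config.blocks_per_garden + 1)
    }
    records = []
    for s in samples:
        if s.chlorotype not in ("PB", "PT") or s.nuclear_q is None:
            continue
        N = s.nuclear_q
        C = 1.0 if s.chlorotype == "PT" else 0.0
        for g in config.gardens:
            E = 1.0 if g == "VA" else 0.0
            for b in range(1, config.blocks_per_garden + 1):
                y = (config.mu + config.beta_N * N + config.beta_C * C
                     + config.beta_NxC * N * C + config.beta_E * E
                     + block_eff[(g, b)]
                     + float(rng.normal(0.0, np.sqrt(config.V_eps))))
                records.append(
                    TraitRecord(genotype_id=s.genotype_id, garden=g,
                                block=f"B{b}", trait_name=config.trait_name,
                                value=y)
                )
    truth.trait_betas = {
        "beta_N": config.beta_N, "beta_C": config.beta_C,
        "beta_NxC": config.beta_NxC, "beta_E": config.beta_E,
    }
    truth.variance_components = {"V_block": config.V_block, "V_eps": config.V_eps}
    return records, truth


@dataclass(frozen=True)
class H2Config:
    """Single-garden clonal design for heritability recovery."""

    n_genotypes: int = 100
    n_blocks: int = 3
    V_G: float = 2.0
    V_E: float = 1.0
    V_eps: float = 1.0
    garden: str = "VT"
    trait_name: str = "Npct"
    mu: float = 2.0


def _standardize(draws: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale draws so their sample variance equals target_var.

    The generator plants *realized* variance components: the recorded truth
    is the variance actually present in the data, not just its expectation.
    This is what makes component-recovery tests meaningful for factors with
    few levels (three blocks give the raw draws a chi-square_2 spread).
    """
    if target_var == 0.0:
        return np.zeros_like(draws)
    d = draws - draws.mean()
    sv = d.var(ddof=1)
    if sv == 0.0:
        raise ValueError("degenerate draws cannot be standardized")
    return d * np.sqrt(target_var / sv)


def generate_h2_traits(config: H2Config, seed: int) -> tuple[list[TraitRecord], SyntheticTruth]:
    """Balanced genotype x block trait table with known variance components."""
    truth = SyntheticTruth(seed=seed)
    rng = _rng(seed, "traits")
    g_eff = _standardize(rng.normal(0.0, 1.0, config.n_genotypes), config.V_G)
    b_eff = _standardize(rng.normal(0.0, 1.0, config.n_blocks), config.V_E)
    eps = _standardize(
        rng.normal(0.0, 1.0, config.n_genotypes * config.n_blocks), config.V_eps
    ).reshape(config.n_genotypes, config.n_blocks)
    records = []
    for i in range(config.n_genotypes):
        for j in range(config.n_blocks):
            y = config.mu + g_eff[i] + b_eff[j] + eps[i, j]
            records.append(
                TraitRecord(genotype_id=f"G{i:03d}", garden=config.garden,
                            block=f"B{j + 1}", trait_name=config.trait_name,
                            value=y)
            )
    truth.variance_components = {
        "V_G": config.V_G, "V_E": config.V_E, "V_eps": config.V_eps,
    }
    return records, truth


@dataclass(frozen=True)
class AlignmentConfig:
    """Planted chloroplast alignment: scale mirrors a two-chlorotype plastome.

    62 fixed differences with 9 nonsynonymous echoes the divergence scale
    between the two study chlorotypes; within-group polymorphism is placed
    only at non-planted positions so it can never create or destroy a
    planted fixed difference.
    """

    n_per_group: int = 4
    genome_length: int = 9000
    n_genes: int = 6
    gene_length: int = 900  # divisible by 3
    n_synonymous: int = 33
    n_nonsynonymous: int = 9
    n_noncoding: int = 20
    polymorphism_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.gene_length % 3:
            raise ValueError("gene_length must be divisible by 3")


_SYN_SETS = {  # codons whose third-position change is synonymous
    "CT": "L", "GT": "V", "TC": "S", "CC": "P", "AC": "T", "GC": "A",
    "CG": "R", "GG": "G",
}


def generate_cp_alignment(
    config: AlignmentConfig, seed: int
) -> tuple[dict[str, str], list[GeneAnnotation], SyntheticTruth]:
    """Two-group alignment with planted fixed differences of known effect.

    Synonymous substitutions are planted at third positions of fourfold-
    degenerate codons; nonsynonymous ones at first codon positions chosen
    to change the amino acid; noncoding ones between genes. Group A carries
    the reference allele everywhere.
    """
    truth = SyntheticTruth(seed=seed)
    rng = _rng(seed, "alignment")
    L = config.genome_length
    ref = rng.choice(list("ACGT"), L)

    # lay genes with intergenic gaps; coordinates 1-based inclusive
    gap = (L - config.n_genes * config.gene_length) // (config.n_genes + 1)
    if gap < 10:
        raise ValueError("genome too short for requested genes")
    annots = []
    pos = gap + 1
    for g in range(config.n_genes):
        annots.append(
            GeneAnnotation(f"cpgene{g}", "cp", pos, pos + config.gene_length - 1,
                           "+" if g % 2 == 0 else "-")
        )
        pos += config.gene_length + gap

    coding = np.zeros(L, bool)
    for a in annots:
        coding[a.start - 1 : a.end] = True

    # candidate sites per class
    syn_sites, nonsyn_sites = [], []
    for a in annots:
        for ci in range((a.end - a.start + 1) // 3):
            if a.strand == "+":
                first = a.start - 1 + 3 * ci
                third = first + 2
                codon = "".join(ref[first : first + 3])
            else:
                third = a.start - 1 + 3 * ci  # genomic left end = coding 3rd pos
                first = third + 2
                comp = str.maketrans("ACGT", "TGCA")
                codon = "".join(ref[third : third + 3]).translate(comp)[::-1]
            win = min(first, third)  # genomic left end of the codon window
            if codon[:2] in _SYN_SETS:
                syn_sites.append((third, win, a))
            if codon not in ("TGG", "ATG") and codon[:2] not in ("TG", "AT"):
                nonsyn_sites.append((first, win, a, codon))
    noncod_sites = list(np.where(~coding)[0])

    if (len(syn_sites) < config.n_synonymous
            or len(nonsyn_sites) < config.n_nonsynonymous
            or len(noncod_sites) < config.n_noncoding):
        raise ValueError("requested planted count exceeds available sites")

    rng.shuffle(syn_sites)
    rng.shuffle(nonsyn_sites)
    noncod_pick = rng.choice(len(noncod_sites), config.n_noncoding, replace=False)

    from Bio.Seq import Seq

    comp = str.maketrans("ACGT", "TGCA")
    alt = ref.copy()
    planted: list[dict] = []
    used: set[int] = set()

    def plant(idx0: int, effect: str, window: tuple[int, ...]) -> None:
        base = ref[idx0]
        choices = [b for b in "ACGT" if b != base]
        alt[idx0] = choices[int(rng.integers(len(choices)))]
        used.update(window)
        planted.append({"position": idx0 + 1, "allele_A": str(base),
                        "allele_B": str(alt[idx0]), "effect": effect})

    n_syn = 0
    for third, win, a in syn_sites:
        if n_syn >= config.n_synonymous:
            break
        codon_window = (win, win + 1, win + 2)
        if used & set(codon_window):
            continue
        plant(third, "synonymous", codon_window)
        n_syn += 1
    n_non = 0
    for first, win, a, codon in nonsyn_sites:
        if n_non >= config.n_nonsynonymous:
            break
        codon_window = (win, win + 1, win + 2)
        if used & set(codon_window):
            continue
        base = ref[first]
        aa_ref = str(Seq(codon).translate(table=11))
        ok = None
        for b in "ACGT":
            if b == base:
                continue
            b_cod = b if a.strand == "+" else b.translate(comp)
            cand = b_cod + codon[1:]
            if str(Seq(cand).translate(table=11)) not in (aa_ref, "*"):
                ok = b
                break
        if ok is None:
            continue
        alt[first] = ok
        used.update(codon_window)
        planted.append({"position": first + 1, "allele_A": str(base),
                        "allele_B": ok, "effect": "nonsynonymous"})
        n_non += 1
    if n_non < config.n_nonsynonymous:
        raise ValueError("could not place all nonsynonymous differences")
    for k in noncod_pick:
        idx0 = int(noncod_sites[k])
        if idx0 in used:
            continue
        plant(idx0, "noncoding", (idx0,))
    planted.sort(key=lambda d: d["position"])
    truth.planted_fixed_diffs = planted

    # within-group polymorphism at non-planted, non-adjacent-codon positions
    free = np.array(sorted(set(range(L)) - used))
    n_poly = int(config.polymorphism_rate * L)
    poly_pos = rng.choice(free, min(n_poly, len(free)), replace=False)

    aln: dict[str, str] = {}
    for grp, base_seq in (("A", ref), ("B", alt)):
        for i in range(config.n_per_group):
            s = base_seq.copy()
            # the first sequence of each group keeps the group allele at every
            # polymorphic site, so within-group variation can never fix
            if i > 0:
                for p in poly_pos:
                    if rng.random() < 0.3:
                        cands = [b for b in "ACGT" if b != base_seq[p]]
                        s[p] = cands[int(rng.integers(3))]
            aln[f"{grp}{i}"] = "".join(s)
    return aln, annots, truth
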