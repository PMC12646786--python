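"""Chloroplast divergence scanning and polarization.

Finds alignment columns fixed between the two chlorotype groups, classifies
coding substitutions as synonymous or nonsynonymous by codon translation
(plastid/bacterial translation table 11), and polarizes substitutions with
neighbour-joining gene trees on Jukes-Cantor distances against outgroups.

Columns carrying any gap or ambiguity code are ineligible as fixed
differences (strict missing-data rule); indel columns can be listed
separately but are never counted as substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

PLASTID_TABLE = 11
_NUCS = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SaturationError(ValueError):
    """Jukes-Cantor distance undefined: mismatch proportion >= 3/4."""


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class FixedDifference:
    position: int  # 1-based alignment column
    allele_A: str
    allele_B: str
    region: str = "noncoding"  # "coding" or "noncoding"
    gene_id: str | None = None
    codon_index: int | None = None  # 1-based codon within the CDS
    effect: str = "noncoding"  # synonymous / nonsynonymous / noncoding
    aa_A: str | None = None
    aa_B: str | None = None
    multi_site: bool = False  # two+ fixed differences in one codon

    def __post_init__(self) -> None:
        if self.allele_A == self.allele_B:
            raise ValueError("fixed difference requires distinct alleles")
        if (self.effect == "noncoding") != (self.gene_id is None):
            raise ValueError("effect=noncoding iff gene_id is none")


@dataclass(frozen=True)
class PolarizationCall:
    gene_id: str
    site: int
    ancestral_group: str  # "A", "B" or "unresolved"
    method_note: str


def read_alignment(path: str | Path) -> dict[str, str]:
    """Multi-FASTA alignment as an id -> uppercase sequence mapping."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError(f"unequal alignment lengths: {sorted(lengths)}")
    return seqs


def find_fixed_differences(
    alignment: Mapping[str, str],
    group_A_ids: Sequence[str],
    group_B_ids: Sequence[str],
) -> list[FixedDifference]:
    """Columns where group A and group B carry different fixed nucleotides.

    A column qualifies iff every A sequence shares one nucleotide, every B
    sequence shares a different nucleotide, and no sequence in either group
    has a gap or ambiguity code there.
    """
    if set(group_A_ids) & set(group_B_ids):
        raise ValueError("groups overlap")
    for gid in list(group_A_ids) + list(group_B_ids):
        if gid not in alignment:
            raise KeyError(f"sequence id {gid!r} not in alignment")
    if len(group_A_ids) < 2 or len(group_B_ids) < 2:
        raise ValueError("each group needs >= 2 sequences")
    A = np.array([list(alignment[g]) for g in group_A_ids])
    B = np.array([list(alignment[g]) for g in group_B_ids])
    out: list[FixedDifference] = []
    for col in range(A.shape[1]):
        a = set(A[:, col])
        b = set(B[:, col])
        if len(a) == 1 and len(b) == 1 and a != b:
            na, nb = next(iter(a)), next(iter(b))
            if na in _NUCS and nb in _NUCS:
                out.append(FixedDifference(position=col + 1, allele_A=na, allele_B=nb))
    return out


def gap_columns(alignment: Mapping[str, str], ids: Sequence[str] | None = None) -> list[int]:
    """1-based columns containing a gap in any of the given sequences."""
    seqs = [alignment[i] for i in (ids or alignment)]
    arr = np.array([list(s) for s in seqs])
    return [int(c) + 1 for c in np.where((arr == "-").any(axis=0))[0]]


def _locate(position: int, cds_annotations) -> tuple | None:
    for ann in cds_annotations:
        if ann.start <= position <= ann.end:
            if (ann.end - ann.start + 1) % 3 != 0:
                raise AnnotationError(
                    f"CDS {ann.gene_id} length not divisible by 3"
                )
            return ann
    return None


def _codon_context(position: int, ann, reference: str) -> tuple[int, int, str]:
    """(codon_index_1based, offset_in_codon, reference codon on coding strand)."""
    cds = reference[ann.start - 1 : ann.end]
    if ann.strand == "-":
        cds = cds.translate(_COMPLEMENT)[::-1]
        pos_in_cds = ann.end - position
    else:
        pos_in_cds = position - ann.start
    ci, within = divmod(pos_in_cds, 3)
    return ci + 1, within, cds[3 * ci : 3 * ci + 3]


def classify_effect(
    fixed_diff: FixedDifference,
    cds_annotations,
    reference_sequence: str,
) -> FixedDifference:
    """Fill region/gene/codon/effect fields of a fixed difference.

    Minus-strand codons are reverse-complemented before translation
    (table 11); effect is synonymous iff the two alleles encode the same
    amino acid in the reference codon context.
    """
    ann = _locate(fixed_diff.position, cds_annotations)
    if ann is None:
        return replace(fixed_diff, region="noncoding", gene_id=None, effect="noncoding")
    ci, within, codon = _codon_context(fixed_diff.position, ann, reference_sequence)

    def aa_for(allele: str) -> str:
        base = allele.translate(_COMPLEMENT) if ann.strand == "-" else allele
        cv = codon[:within] + base + codon[within + 1 :]
        return str(Seq(cv).translate(table=PLASTID_TABLE))

    aa_a, aa_b = aa_for(fixed_diff.allele_A), aa_for(fixed_diff.allele_B)
    return replace(
        fixed_diff,
        region="coding",
        gene_id=ann.gene_id,
        codon_index=ci,
        effect="synonymous" if aa_a == aa_b else "nonsynonymous",
        aa_A=aa_a,
        aa_B=aa_b,
    )


def classify_effects(
    diffs: Sequence[FixedDifference],
    cds_annotations,
    reference_sequence: str,
) -> list[FixedDifference]:
    """Classify a list of fixed differences, handling shared codons jointly.

    When two or more fixed differences fall in the same codon of the same
    gene, the amino acids are computed with all group-A (resp. group-B)
    alleles substituted together and each site is flagged ``multi_site``.
    """
    classified = [classify_effect(d, cds_annotations, reference_sequence) for d in diffs]
    by_codon: dict[tuple, list[int]] = {}
    for i, d in enumerate(classified):
        if d.gene_id is not None:
            by_codon.setdefault((d.gene_id, d.codon_index), []).append(i)
    for (gid, ci), members in by_codon.items():
        if len(members) < 2:
            continue
        ann = next(a for a in cds_annotations if a.gene_id == gid)
        _, _, codon = _codon_context(classified[members[0]].position, ann, reference_sequence)
        var_a, var_b = list(codon), list(codon)
        for i in members:
            d = classified[i]
            _, within, _ = _codon_context(d.position, ann, reference_sequence)
            a = d.allele_A.translate(_COMPLEMENT) if ann.strand == "-" else d.allele_A
            b = d.allele_B.translate(_COMPLEMENT) if ann.strand == "-" else d.allele_B
            var_a[within], var_b[within] = a, b
        aa_a = str(Seq("".join(var_a)).translate(table=PLASTID_TABLE))
        aa_b = str(Seq("".join(var_b)).translate(table=PLASTID_TABLE))
        effect = "synonymous" if aa_a == aa_b else "nonsynonymous"
        for i in members:
            classified[i] = replace(
                classified[i], effect=effect, aa_A=aa_a, aa_B=aa_b, multi_site=True
            )
    return classified


def jc_distance(seq1: str, seq2: str) -> float:
    """Jukes-Cantor distance, substitutions per site.

    Only pairwise-complete sites (both nucleotides in ACGT) are compared;
    raises SaturationError when the mismatch proportion reaches 3/4.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    s1, s2 = seq1.upper(), seq2.upper()
    pairs = [(a, b) for a, b in zip(s1, s2) if a in _NUCS and b in _NUCS]
    if not pairs:
        raise ValueError("no pairwise-complete sites")
    p_hat = sum(a != b for a, b in pairs) / len(pairs)
    if p_hat >= 0.75:
        raise SaturationError(f"mismatch proportion {p_hat:.3f} >= 0.75")
    return float(-0.75 * np.log1p(-(4.0 / 3.0) * p_hat))


def nj_tree(distance_matrix: np.ndarray, taxon_labels: Sequence[str]) -> str:
    """Neighbour-joining tree as a newick string (unrooted, trifurcating).

    Deterministic: Q-matrix ties break by the lexicographically smallest
    (cluster, cluster) label pair, with a cluster labelled by its smallest
    member taxon. Negative branch lengths are clamped to zero and the
    deficit moved to the sister branch (the usual NJ repair).
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = len(taxon_labels)
    if D.shape != (n, n):
        raise ValueError("matrix/label size mismatch")
    if np.max(np.abs(D - D.T)) > 1e-9:
        raise ValueError("distance matrix is asymmetric beyond 1e-9")
    if n < 3:
        raise ValueError("need >= 3 taxa")
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    nodes = [f"{lbl}" for lbl in taxon_labels]  # newick fragments
    labels = [str(lbl) for lbl in taxon_labels]  # tie-break keys
    active = list(range(n))
    Dw = D.copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = Dw[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                key = tuple(sorted((labels[active[ai]], labels[active[aj]])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, ai, aj)
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        new_frag = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        new_label = min(labels[i], labels[j])
        # distances from the new node to all remaining clusters
        newrow = np.zeros(Dw.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (Dw[i, k] + Dw[j, k] - dij)
        Dw = np.pad(Dw, ((0, 1), (0, 1)))
        Dw[-1, :-1] = newrow[:-1]
        Dw[:-1, -1] = newrow[:-1]
        nodes.append(new_frag)
        labels.append(new_label)
        active = [k for k in active if k not in (i, j)] + [Dw.shape[0] - 1]

    a, b, c = active
    la = 0.5 * (Dw[a, b] + Dw[a, c] - Dw[b, c])
    lb = 0.5 * (Dw[a, b] + Dw[b, c] - Dw[a, c])
    lc = 0.5 * (Dw[a, c] + Dw[b, c] - Dw[a, b])
    la, lb, lc = (max(v, 0.0) for v in (la, lb, lc))
    order = sorted(range(3), key=lambda t: labels[[a, b, c][t]])
    frags = [(nodes[[a, b, c][t]], (la, lb, lc)[t]) for t in order]
    inner = ",".join(f"{f}:{l:.10g}" for f, l in frags)
    return f"({inner});"


def _splits(newick: str, taxa: set[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted newick tree, as leaf sets."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    out: set[frozenset[str]] = set()
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is None or head.is_leaf() or head.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in head.leaf_iter())
        if 1 < len(clade) < len(taxa):
            out.add(clade)
            out.add(frozenset(taxa - clade))
    return out


def polarize(
    codon_alignment: Mapping[str, str],
    group_labels: Mapping[str, Sequence[str]],
    outgroup_labels: Sequence[str],
    gene_id: str = "",
    site: int = 0,
) -> PolarizationCall:
    """Assign the ancestral chlorotype for one codon (or short region).

    ``group_labels`` maps "A" and "B" to their sequence ids. The ancestral
    group is the one whose sequences cluster with the outgroups in the NJ
    tree on JC distances — equivalently, the *other* group forms a clade
    excluding all outgroups. Identical-state shortcuts are applied first;
    the call is unresolved when outgroups are split between the two codon
    states or neither grouping is clean.
    """
    if not outgroup_labels:
        raise ValueError("at least one outgroup is required")
    a_ids, b_ids = list(group_labels["A"]), list(group_labels["B"])
    a_states = {codon_alignment[i] for i in a_ids}
    b_states = {codon_alignment[i] for i in b_ids}
    out_states = [codon_alignment[i] for i in outgroup_labels]
    if len(a_states) == 1 and len(b_states) == 1:
        a_st, b_st = next(iter(a_states)), next(iter(b_states))
        n_a = sum(o == a_st for o in out_states)
        n_b = sum(o == b_st for o in out_states)
        if n_a and n_b:
            return PolarizationCall(gene_id, site, "unresolved",
                                    "outgroups split between both codon states")
        if n_a == len(out_states):
            return PolarizationCall(gene_id, site, "A", "all outgroups match group A state")
        if n_b == len(out_states):
            return PolarizationCall(gene_id, site, "B", "all outgroups match group B state")
    # fall back to tree-based clustering
    ids = a_ids + b_ids + list(outgroup_labels)
    m = len(ids)
    if m < 3:
        return PolarizationCall(gene_id, site, "unresolved", "too few sequences for a tree")
    D = np.zeros((m, m))
    try:
        for i in range(m):
            for j in range(i + 1, m):
                D[i, j] = D[j, i] = jc_distance(codon_alignment[ids[i]], codon_alignment[ids[j]])
    except SaturationError:
        return PolarizationCall(gene_id, site, "unresolved", "saturated distances")
    newick = nj_tree(D, ids)
    splits = _splits(newick, set(ids))
    a_mono = frozenset(a_ids) in splits
    b_mono = frozenset(b_ids) in splits
    if a_mono and not b_mono:
        return PolarizationCall(gene_id, site, "B", "group A forms a derived clade in the NJ tree")
    if b_mono and not a_mono:
        return PolarizationCall(gene_id, site, "A", "group B forms a derived clade in the NJ tree")
    if a_mono and b_mono:
        # both clean: the ancestral group is the one nearer the outgroups
        d_a = np.mean([D[ids.index(x), ids.index(o)] for x in a_ids for o in outgroup_labels])
        d_b = np.mean([D[ids.index(x), ids.index(o)] for x in b_ids for o in outgroup_labels])
        if abs(d_a - d_b) < 1e-12:
            return PolarizationCall(gene_id, site, "unresolved", "both groups equidistant from outgroups")
        grp = "A" if d_a < d_b else "B"
        return PolarizationCall(gene_id, site, grp,
                                "both groups monophyletic; nearer group to outgroups called ancestral")
    return PolarizationCall(gene_id, site, "unresolved", "neither grouping is clean")
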