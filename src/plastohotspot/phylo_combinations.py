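"""Exhaustive hotspot-combination analysis scored by mean bootstrap support.

Every non-empty subset of the top hotspot loci is concatenated into a
supermatrix; a point tree is inferred by neighbor joining on
Jukes-Cantor distances (pairwise deletion of gap/N sites) and its
internal bipartitions receive nonparametric bootstrap supports
(column resampling).  Each combination is scored by the arithmetic
mean support over ingroup internal edges; a per-size regression and
plateau analysis then identifies the smallest combination size whose
mean support is within tolerance of the best.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations as _combinations
from typing import Sequence
import warnings

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from Bio import Align

from .indel_analysis import global_align
from .stats_core import StatResult, ols_line, spearman
from .sv_hotspots import SyntenicLocus

MAX_JC_DISTANCE = 5.0


@dataclass
class LocusMSA:
    """A multiple alignment of one locus (taxa missing it get gap rows)."""

    name: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError(f"{self.name}: rows differ in length")
        if len(self.taxa) != len(self.rows):
            raise ValueError(f"{self.name}: taxa/rows mismatch")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass
class BootstrapTree:
    """Point NJ tree with bipartition bootstrap supports."""

    newick: str
    taxa: list[str]
    outgroups: list[str]
    supports: dict[frozenset, int] = field(default_factory=dict)


@dataclass
class CombinationResult:
    loci: tuple[str, ...]
    k: int
    concat_length: int
    combo_sv: float
    tree: BootstrapTree
    mean_bs: float


# ---------------------------------------------------------------------------
# Center-star multiple alignment
# ---------------------------------------------------------------------------

def build_locus_msa(locus: SyntenicLocus,
                    aligner: Align.PairwiseAligner | None = None,
                    taxa_universe: Sequence[str] | None = None) -> LocusMSA:
    """Center-star progressive alignment of one locus.

    The center is the present taxon maximizing the summed pairwise
    alignment score to the others; pairwise alignments against the
    center are merged under "once a gap, always a gap".  Taxa in
    ``taxa_universe`` missing the locus get all-gap rows.
    """
    present = sorted(locus.present_taxa())
    if len(present) < 3:
        raise ValueError(f"{locus.name}: need >= 3 present taxa")
    seqs = {t: locus.seq_by_taxon[t] for t in present}

    score_sum = {t: 0.0 for t in present}
    cache = {}
    for a, b in _combinations(present, 2):
        s = global_align(seqs[a], seqs[b], aligner).score
        cache[(a, b)] = s
        score_sum[a] += s
        score_sum[b] += s
    center = max(present, key=lambda t: (score_sum[t], t))

    # master holds the gapped center; rows are gapped relative to master
    master = list(seqs[center])
    rows: dict[str, list[str]] = {center: list(seqs[center])}
    for taxon in present:
        if taxon == center:
            continue
        aln = global_align(seqs[center], seqs[taxon], aligner)
        _merge_into_master(master, rows, aln.aligned_a, aln.aligned_b, taxon)

    length = len(master)
    taxa = list(taxa_universe) if taxa_universe is not None else present
    out_rows = []
    for t in taxa:
        if t in rows:
            out_rows.append("".join(rows[t]))
        else:
            out_rows.append("-" * length)
    return LocusMSA(name=locus.name, taxa=list(taxa), rows=out_rows)


def _merge_into_master(master: list[str], rows: dict[str, list[str]],
                       aligned_center: str, aligned_new: str, taxon: str) -> None:
    """Merge a center/new pairwise alignment into the growing master."""
    merged_master: list[str] = []
    new_row: list[str] = []
    updates = {t: [] for t in rows}
    mi = 0  # index into master
    pi = 0  # index into pairwise alignment
    n_m, n_p = len(master), len(aligned_center)
    while mi < n_m or pi < n_p:
        m_char = master[mi] if mi < n_m else None
        p_char = aligned_center[pi] if pi < n_p else None
        if m_char == "-" and (p_char is None or p_char != "-"):
            # gap already in master (from an earlier merge): keep it
            merged_master.append("-")
            for t in updates:
                updates[t].append(rows[t][mi])
            new_row.append("-")
            mi += 1
        elif p_char == "-":
            # new gap in the center introduced by this pairwise alignment
            merged_master.append("-")
            for t in updates:
                updates[t].append("-")
            new_row.append(aligned_new[pi])
            pi += 1
        else:
            merged_master.append(m_char)
            for t in updates:
                updates[t].append(rows[t][mi])
            new_row.append(aligned_new[pi])
            mi += 1
            pi += 1
    master[:] = merged_master
    for t in updates:
        rows[t][:] = updates[t]
    rows[taxon] = new_row


# ---------------------------------------------------------------------------
# Combinations and concatenation
# ---------------------------------------------------------------------------

def enumerate_combinations(hotspot_names: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically."""
    names = sorted(hotspot_names)
    if not 1 <= len(names) <= 16:
        raise ValueError("need between 1 and 16 hotspot names")
    out = []
    for k in range(1, len(names) + 1):
        out.extend(_combinations(names, k))
    return out


def concatenate(msas: Sequence[LocusMSA],
                taxa_order: Sequence[str]) -> tuple[LocusMSA, list[tuple[str, int, int]]]:
    """Column-wise concatenation; returns (supermatrix, partition table)."""
    parts = []
    rows = {t: [] for t in taxa_order}
    pos = 0
    for msa in msas:
        for t in taxa_order:
            if t in msa.taxa:
                rows[t].append(msa.row(t))
            else:
                rows[t].append("-" * msa.length)
        parts.append((msa.name, pos, pos + msa.length))
        pos += msa.length
    concat = LocusMSA(name="+".join(m.name for m in msas),
                      taxa=list(taxa_order),
                      rows=["".join(rows[t]) for t in taxa_order])
    return concat, parts


# ---------------------------------------------------------------------------
# Distances, NJ, bootstrap
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_msa(msa: LocusMSA) -> np.ndarray:
    """Int8 matrix; gaps and ambiguous characters become -1."""
    arr = np.full((len(msa.taxa), msa.length), -1, dtype=np.int8)
    for i, row in enumerate(msa.rows):
        arr[i] = [_CODE.get(c, -1) for c in row]
    return arr


def jc_distance_matrix(valid: np.ndarray, diff: np.ndarray,
                       taxa: Sequence[str],
                       columns: np.ndarray | None = None) -> np.ndarray:
    """Jukes-Cantor distances from per-pair column masks.

    ``valid``/``diff`` are (n_pairs, L) boolean arrays in ``combinations``
    order.  Saturated pairs (mismatch fraction >= 0.75) are capped at
    ``MAX_JC_DISTANCE`` with a warning; pairs with no shared columns
    raise, naming the pair.
    """
    if columns is not None:
        valid = valid[:, columns]
        diff = diff[:, columns]
    shared = valid.sum(axis=1)
    mism = diff.sum(axis=1)
    n = len(taxa)
    dm = np.zeros((n, n))
    for idx, (i, j) in enumerate(_combinations(range(n), 2)):
        if shared[idx] == 0:
            raise ValueError(
                f"taxa {taxa[i]!r} and {taxa[j]!r} share no non-gap columns")
        p = mism[idx] / shared[idx]
        if p >= 0.75:
            warnings.warn(f"JC distance saturated for {taxa[i]}/{taxa[j]}; capped")
            d = MAX_JC_DISTANCE
        else:
            d = -0.75 * math.log(1 - 4.0 * p / 3.0)
        dm[i, j] = dm[j, i] = d
    return dm


def _pair_masks(arr: np.ndarray):
    n = arr.shape[0]
    pairs = list(_combinations(range(n), 2))
    valid = np.empty((len(pairs), arr.shape[1]), dtype=bool)
    diff = np.empty_like(valid)
    for k, (i, j) in enumerate(pairs):
        v = (arr[i] >= 0) & (arr[j] >= 0)
        valid[k] = v
        diff[k] = v & (arr[i] != arr[j])
    return valid, diff


def _nj_bipartitions(dm: np.ndarray, taxa: Sequence[str]) -> tuple:
    """NJ tree and its internal bipartitions (as ingroup-free frozensets).

    Each bipartition is represented by the side not containing
    ``taxa[0]`` (canonical for an unrooted tree).
    """
    tree = nj(DistanceMatrix(dm, list(taxa)))
    anchor = taxa[0]
    n = len(taxa)
    bips = set()
    for node in tree.non_tips():
        clade = frozenset(t.name for t in node.tips())
        if anchor in clade:
            clade = frozenset(taxa) - clade
        if 2 <= len(clade) <= n - 2:
            bips.add(clade)
    return tree, bips


def bootstrap_tree(msa: LocusMSA, n_replicates: int = 1000, seed: int = 0,
                   outgroups: Sequence[str] = ()) -> BootstrapTree:
    """NJ point tree with nonparametric bootstrap supports.

    Supports are the percentage of replicate NJ trees (alignment columns
    resampled with replacement) containing each internal bipartition of
    the point tree.  Identical seeds give identical supports.
    """
    if len(msa.taxa) < 4:
        raise ValueError("need at least 4 taxa")
    missing = set(outgroups) - set(msa.taxa)
    if missing:
        raise ValueError(f"outgroups absent from alignment: {sorted(missing)}")
    arr = encode_msa(msa)
    valid, diff = _pair_masks(arr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dm = jc_distance_matrix(valid, diff, msa.taxa)
    tree, point_bips = _nj_bipartitions(dm, msa.taxa)

    counts = {b: 0 for b in point_bips}
    rng = np.random.default_rng(seed)
    L = msa.length
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rdm = jc_distance_matrix(valid, diff, msa.taxa, columns=cols)
        except ValueError:
            continue  # replicate lost all shared columns for some pair
        _, rbips = _nj_bipartitions(rdm, msa.taxa)
        for b in point_bips:
            if b in rbips:
                counts[b] += 1
    supports = {b: round(100.0 * c / n_replicates) for b, c in counts.items()}

    for node in tree.non_tips():
        clade = frozenset(t.name for t in node.tips())
        canon = clade if msa.taxa[0] not in clade else frozenset(msa.taxa) - clade
        if canon in supports:
            node.name = str(supports[canon])
    newick = tree.__str__().strip()
    return BootstrapTree(newick=newick, taxa=list(msa.taxa),
                         outgroups=list(outgroups), supports=supports)


def mean_bs(tree: BootstrapTree, outgroups: Sequence[str] | None = None,
            scope: str = "ingroup") -> float:
    """Mean bootstrap support over internal edges.

    With ``scope='ingroup'`` (default) only bipartitions nested strictly
    inside the ingroup count: the outgroup side, the root edge and edges
    within the outgroup clade are excluded.
    """
    outgroups = set(outgroups if outgroups is not None else tree.outgroups)
    ingroup = set(tree.taxa) - outgroups
    values = []
    for bip, support in tree.supports.items():
        side = set(bip)
        other = set(tree.taxa) - side
        if scope == "all":
            values.append(support)
            continue
        inner = side if not side & outgroups else other
        if inner & outgroups:
            continue  # edge inside the outgroup clade
        if 2 <= len(inner) <= len(ingroup) - 1:
            values.append(support)
    if not values:
        raise ValueError("no internal ingroup edges with support values")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# The combination scan and its summaries
# ---------------------------------------------------------------------------

def combination_scan(msas: dict[str, LocusMSA], sv_by_locus: dict[str, float],
                     outgroups: Sequence[str], n_replicates: int = 1000,
                     seed: int = 0) -> list[CombinationResult]:
    """Score every non-empty hotspot subset by mean bootstrap support."""
    names = sorted(msas)
    taxa = list(msas[names[0]].taxa)
    results = []
    for idx, combo in enumerate(enumerate_combinations(names)):
        concat, _ = concatenate([msas[n] for n in combo], taxa)
        tree = bootstrap_tree(concat, n_replicates=n_replicates,
                              seed=(seed * 100003 + idx) % (2**31 - 1),
                              outgroups=outgroups)
        results.append(CombinationResult(
            loci=combo, k=len(combo), concat_length=concat.length,
            combo_sv=float(np.mean([sv_by_locus[n] for n in combo])),
            tree=tree, mean_bs=mean_bs(tree)))
    return results


def plateau_analysis(results: Sequence[CombinationResult],
                     tolerance: float = 2.0) -> dict:
    """Per-size mean/SD of mean BS, an OLS fit over all combinations,
    and the plateau size (smallest k within ``tolerance`` BS points of
    the best per-size mean)."""
    ks = sorted({r.k for r in results})
    per_k_mean = {}
    per_k_sd = {}
    for k in ks:
        vals = [r.mean_bs for r in results if r.k == k]
        per_k_mean[k] = float(np.mean(vals))
        per_k_sd[k] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    slope, intercept, r2 = ols_line([r.k for r in results],
                                    [r.mean_bs for r in results])
    best = max(per_k_mean.values())
    plateau_k = min(k for k in ks if per_k_mean[k] >= best - tolerance)
    return {"per_k_mean": per_k_mean, "per_k_sd": per_k_sd, "slope": slope,
            "intercept": intercept, "r_squared": r2, "plateau_k": plateau_k}


def combo_correlations(results: Sequence[CombinationResult]) -> dict[str, StatResult]:
    """Spearman of mean BS against combination SV and concatenated length."""
    if len(results) < 3:
        raise ValueError("need at least 3 combinations")
    bs = [r.mean_bs for r in results]
    out = {}
    for key, vec in (("mean_bs_vs_combo_sv", [r.combo_sv for r in results]),
                     ("mean_bs_vs_concat_length",
                      [float(r.concat_length) for r in results])):
        try:
            out[key] = spearman(bs, vec)
        except ValueError:
            out[key] = StatResult(statistic=float("nan"), p_value=float("nan"),
                                  method="spearman", n=len(results))
    return out


def top_combinations(results: Sequence[CombinationResult],
                     n: int = 10) -> tuple[list[CombinationResult], CombinationResult]:
    """Top-n combinations by mean BS and the minimal-k member among them.

    Ties are broken by smaller k, then lexicographic locus tuple; the
    second return value is the recommendation (the smallest combination
    that still ranks in the top n).
    """
    ranked = sorted(results, key=lambda r: (-r.mean_bs, r.k, r.loci))
    top = ranked[:n]
    recommended = min(top, key=lambda r: (r.k, -r.mean_bs, r.loci))
    return top, recommended
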