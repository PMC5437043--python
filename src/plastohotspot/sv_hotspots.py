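"""Syntenic locus extraction and the sequence-variability (SV) statistic.

A syntenic locus is an intergenic spacer (same flanking genes, same
order, across taxa) or an intron, at least 150 bp in the reference
taxon.  For a taxon pair the locus sequences are globally aligned,
terminal gap runs are trimmed, and

    SV = (mutations + InDel events)
         / (conserved sites + mutations + InDel events) * 100

where mutations are mismatching non-gap columns, conserved sites are
identical non-gap columns, and each maximal internal gap run (in either
row) is one InDel event.  The per-locus mean SV over all unordered taxon
pairs ranks mutational hotspots; rank stability is assessed over nested
random taxon subsets of increasing size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align

from .indel_analysis import gap_runs, global_align
from .io_formats import PlastomeRecord, revcomp
from .stats_core import StatResult, spearman

MIN_LOCUS_LEN = 150


@dataclass
class SyntenicLocus:
    """One spacer or intron with a (possibly absent) sequence per taxon."""

    name: str
    locus_type: str                  # spacer | intron
    region: str                      # LSC | SSC | IR
    reference_id: str
    seq_by_taxon: dict[str, str] = field(default_factory=dict)

    def present_taxa(self) -> list[str]:
        return [t for t, s in self.seq_by_taxon.items() if s]


@dataclass(frozen=True)
class SVRecord:
    locus: str
    locus_type: str
    region: str
    mean_sv: float
    gc_percent: float
    n_pairs: int
    rank: int


def _gene_like(feat) -> bool:
    return feat.kind in ("gene", "tRNA", "rRNA")


def _gene_order(record: PlastomeRecord):
    """Gene-level features sorted by start, IRa copies excluded."""
    ira = record.region_bounds["IRa"]
    feats = [f for f in record.features
             if _gene_like(f) and not (ira[0] <= f.interval[0] < ira[1])]
    return sorted(feats, key=lambda f: f.interval[0])


def extract_syntenic_loci(records: Sequence[PlastomeRecord],
                          reference_id: str | None = None,
                          min_len: int = MIN_LOCUS_LEN) -> list[SyntenicLocus]:
    """Spacers between adjacent genes and introns, syntenic across taxa.

    Locus discovery follows the reference taxon's gene order; a locus is
    kept iff its reference sequence is >= ``min_len`` bp and it is
    present in at least two taxa.  Sequences are normalized to the
    orientation of the reference left flank (minus-strand flanks are
    reverse-complemented).  A taxon with discordant gene order at a
    locus is recorded absent with a warning.
    """
    if not records:
        return []
    reference_id = reference_id or records[0].taxon_id
    by_id = {r.taxon_id: r for r in records}
    reference = by_id[reference_id]

    ref_order = _gene_order(reference)
    orders = {t: _gene_order(r) for t, r in by_id.items()}
    index = {t: {f.name: i for i, f in enumerate(o)} for t, o in orders.items()}

    loci: list[SyntenicLocus] = []

    def spacer_seq(record, order, idx, left, right):
        """Sequence between two named genes if adjacent in this taxon."""
        iA, iB = idx.get(left), idx.get(right)
        if iA is None or iB is None:
            return None
        if iB != iA + 1:
            warnings.warn(
                f"{record.taxon_id}: genes {left}/{right} not adjacent; "
                f"locus recorded absent")
            return None
        lo = order[iA].interval[1]
        hi = order[iB].interval[0]
        if hi <= lo:
            return ""
        return record.sequence[lo:hi]

    # --- spacers from adjacent gene pairs in the reference order ---
    for a, b in zip(ref_order, ref_order[1:]):
        name = f"{a.name}-{b.name}"
        ref_seq = spacer_seq(reference, ref_order, index[reference_id], a.name, b.name)
        if ref_seq is None or len(ref_seq) < min_len:
            continue
        flip = a.strand == "-"
        seqs = {}
        for taxon, record in by_id.items():
            s = spacer_seq(record, orders[taxon], index[taxon], a.name, b.name)
            if s:
                seqs[taxon] = revcomp(s) if flip else s
        if len(seqs) < 2:
            continue
        region = reference.region_of(a.interval[1])
        loci.append(SyntenicLocus(
            name=name, locus_type="spacer",
            region="IR" if region in ("IRa", "IRb") else region,
            reference_id=reference_id, seq_by_taxon=seqs))

    # --- introns ---
    ira = reference.region_bounds["IRa"]
    ref_introns = [f for f in reference.features if f.kind == "intron"
                   and not (ira[0] <= f.interval[0] < ira[1])]
    by_gene: dict[str, int] = {}
    for f in sorted(ref_introns, key=lambda f: f.interval[0]):
        by_gene[f.name] = by_gene.get(f.name, 0) + 1
        n_total = sum(1 for g in ref_introns if g.name == f.name)
        name = f"{f.name} intron" if n_total == 1 else f"{f.name} intron{by_gene[f.name]}"
        ref_seq = reference.sequence[f.interval[0]:f.interval[1]]
        if len(ref_seq) < min_len:
            continue
        flip = f.strand == "-"
        k = by_gene[f.name]
        seqs = {}
        for taxon, record in by_id.items():
            t_ira = record.region_bounds["IRa"]
            cand = [g for g in record.features if g.kind == "intron"
                    and g.name == f.name
                    and not (t_ira[0] <= g.interval[0] < t_ira[1])]
            cand.sort(key=lambda g: g.interval[0])
            if len(cand) >= k:
                g = cand[k - 1]
                s = record.sequence[g.interval[0]:g.interval[1]]
                if s:
                    seqs[taxon] = revcomp(s) if flip else s
        if len(seqs) < 2:
            continue
        region = reference.region_of(f.interval[0])
        loci.append(SyntenicLocus(
            name=name, locus_type="intron",
            region="IR" if region in ("IRa", "IRb") else region,
            reference_id=reference_id, seq_by_taxon=seqs))

    return loci


def pairwise_sv(seq_a: str, seq_b: str,
                aligner: Align.PairwiseAligner | None = None) -> float:
    """SV percentage for one taxon pair at one locus.

    Aligns globally, trims terminal gap runs, then applies the SV
    formula.  Returns ``nan`` (with a warning) if nothing remains after
    trimming.  The formula is symmetric in the two sequences, so inputs
    are put in a canonical order first — the engine's choice among
    co-optimal alignments then cannot depend on argument order.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot compute SV of an empty sequence")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    aln = global_align(seq_a, seq_b, aligner)
    a, b = _trim_terminal_gaps(aln.aligned_a, aln.aligned_b)
    if not a:
        warnings.warn("alignment empty after terminal-gap trimming; SV undefined")
        return float("nan")
    conserved = mutations = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            conserved += 1
        else:
            mutations += 1
    n_events = len(gap_runs(a, b, include_terminal=True))
    denom = conserved + mutations + n_events
    if denom == 0:
        warnings.warn("no scorable columns; SV undefined")
        return float("nan")
    return 100.0 * (mutations + n_events) / denom


def _trim_terminal_gaps(a: str, b: str) -> tuple[str, str]:
    start = 0
    n = len(a)
    while start < n and (a[start] == "-" or b[start] == "-"):
        start += 1
    end = n
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    return a[start:end], b[start:end]


def mean_sv_table(loci: Sequence[SyntenicLocus],
                  taxa_subset: Sequence[str] | None = None,
                  aligner: Align.PairwiseAligner | None = None) -> list[SVRecord]:
    """Mean SV per locus over all unordered distinct taxon pairs.

    GC% is computed on the reference taxon's sequence.  Records are
    ranked by mean SV descending, ties broken by locus name.  Loci
    present in fewer than two subset taxa are excluded with a warning.
    """
    rows = []
    for locus in loci:
        taxa = locus.present_taxa()
        if taxa_subset is not None:
            taxa = [t for t in taxa if t in set(taxa_subset)]
        taxa = sorted(taxa)
        if len(taxa) < 2:
            warnings.warn(f"locus {locus.name}: <2 taxa in subset; excluded")
            continue
        svs = []
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                sv = pairwise_sv(locus.seq_by_taxon[taxa[i]],
                                 locus.seq_by_taxon[taxa[j]], aligner)
                if not np.isnan(sv):
                    svs.append(sv)
        if not svs:
            continue
        gc_seq = locus.seq_by_taxon.get(locus.reference_id) or \
            locus.seq_by_taxon[taxa[0]]
        gc = 100.0 * sum(gc_seq.count(b) for b in "GC") / len(gc_seq)
        rows.append((locus, float(np.mean(svs)), gc, len(svs)))

    rows.sort(key=lambda r: (-r[1], r[0].name))
    return [
        SVRecord(locus=loc.name, locus_type=loc.locus_type, region=loc.region,
                 mean_sv=sv, gc_percent=gc, n_pairs=n, rank=i + 1)
        for i, (loc, sv, gc, n) in enumerate(rows)
    ]


def sv_gc_correlation(sv_records: Sequence[SVRecord]) -> StatResult:
    """Spearman correlation of per-locus mean SV against GC content."""
    if len(sv_records) < 3:
        raise ValueError("need at least 3 loci")
    return spearman([r.mean_sv for r in sv_records],
                    [r.gc_percent for r in sv_records])


def rank_stability(loci: Sequence[SyntenicLocus],
                   group_sizes: Sequence[int] = (2, 5, 10, 15, 20, 25),
                   n_reference_top: int = 10,
                   seed: int = 0,
                   taxa: Sequence[str] | None = None,
                   aligner: Align.PairwiseAligner | None = None):
    """Hotspot rank across nested random taxon subsets of growing size.

    The reference top loci are taken from the full-set ranking; each
    group extends the previous one (nested subsets).  Returns a dict
    ``{locus: {size: rank or None}}``; None marks a locus outside the
    top ``n_reference_top`` for that group.
    """
    all_taxa = sorted(taxa) if taxa is not None else sorted(
        {t for locus in loci for t in locus.present_taxa()})
    if max(group_sizes) > len(all_taxa):
        raise ValueError(
            f"group size {max(group_sizes)} exceeds {len(all_taxa)} taxa")
    full = mean_sv_table(loci, aligner=aligner)
    top = [r.locus for r in full if r.rank <= n_reference_top]

    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(all_taxa))
    table: dict[str, dict[int, int | None]] = {name: {} for name in top}
    for size in sorted(group_sizes):
        subset = shuffled[:size]
        sub = mean_sv_table(loci, taxa_subset=subset, aligner=aligner)
        ranks = {r.locus: r.rank for r in sub}
        for name in top:
            r = ranks.get(name)
            table[name][size] = r if (r is not None and r <= n_reference_top) else None
    return table
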