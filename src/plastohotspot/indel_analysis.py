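"""Pairwise alignment against a reference plastome and InDel-event analysis.

Each taxon is aligned to the reference region by region (LSC with LSC,
SSC with SSC, one IR copy with one IR copy) with a global affine-gap
aligner; every maximal internal run of gap characters is one InDel
event, classified by region and by proximity to annotated ndh features.
The module also computes the signed changed length of NDH-related vs
NDH-unrelated InDels and the distribution/correlation tests relating
InDel placement to plastome-size variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .genome_structure import ChangedLengths
from .io_formats import PlastomeRecord
from .stats_core import StatResult, mann_whitney_two_sided, spearman

NDH_WINDOW = 50  # bp around an ndh feature that still counts as NDH-related


@dataclass(frozen=True)
class PairwiseAlignment:
    taxon_a: str
    taxon_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")


@dataclass(frozen=True)
class IndelEvent:
    kind: str           # insertion | deletion, relative to the reference
    ref_position: int   # 0-based position in the ungapped reference
    length: int
    region: str         # LSC | SSC | IR
    ndh_related: bool


def make_aligner(match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -4.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    """Global affine-gap aligner; a gap of length L costs open + L*extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


_DEFAULT_ALIGNER = make_aligner()


def global_align(seq_a: str, seq_b: str,
                 aligner: Align.PairwiseAligner | None = None,
                 taxon_a: str = "a", taxon_b: str = "b") -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with affine gap penalties.

    Defaults: match +1, mismatch -1, gap open -4, gap extend -0.5.  The
    first optimal path reported by the engine is used, so results are
    deterministic for given inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = aligner or _DEFAULT_ALIGNER
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return PairwiseAlignment(taxon_a=taxon_a, taxon_b=taxon_b,
                             aligned_a=str(aln[0]), aligned_b=str(aln[1]),
                             score=float(aln.score))


def gap_runs(aligned_a: str, aligned_b: str, include_terminal: bool = False):
    """Maximal gap runs as (row, start_col, length); row 0 = a, 1 = b."""
    runs = []
    n = len(aligned_a)
    for row, s in ((0, aligned_a), (1, aligned_b)):
        col = 0
        while col < n:
            if s[col] == "-":
                start = col
                while col < n and s[col] == "-":
                    col += 1
                if include_terminal or (start > 0 and col < n):
                    runs.append((row, start, col - start))
            else:
                col += 1
    return sorted(runs, key=lambda r: (r[1], r[0]))


def extract_indel_events(aln: PairwiseAlignment,
                         reference: PlastomeRecord,
                         region: str,
                         ref_offset: int = 0) -> list[IndelEvent]:
    """InDel events from an alignment whose second row is the reference.

    One maximal internal gap run = one event; terminal runs are not
    counted.  ``ref_offset`` is the reference coordinate of the aligned
    slice's first base (region-wise alignment).  An event is NDH-related
    when its reference interval (insertions use the flanking base) lies
    within ``NDH_WINDOW`` bp of an annotated ndh feature.
    """
    if reference.taxon_id != aln.taxon_b:
        raise ValueError(
            f"alignment reference is {aln.taxon_b!r}, record is {reference.taxon_id!r}")
    ndh_intervals = [
        f.interval for f in reference.features
        if f.name.startswith("ndh") and f.kind in ("gene", "tRNA", "rRNA")
    ]

    def near_ndh(lo: int, hi: int) -> bool:
        return any(lo < e + NDH_WINDOW and hi > s - NDH_WINDOW
                   for s, e in ndh_intervals)

    # map alignment columns to ungapped reference positions
    ref_pos = []
    p = 0
    for ch in aln.aligned_b:
        ref_pos.append(p)
        if ch != "-":
            p += 1
    events = []
    for row, start, length in gap_runs(aln.aligned_a, aln.aligned_b):
        pos = ref_pos[start] + ref_offset
        if row == 0:
            kind = "deletion"      # gap in the taxon row: taxon lost ref bases
            lo, hi = pos, pos + length
        else:
            kind = "insertion"     # gap in the reference row: taxon gained bases
            lo, hi = pos, pos + 1  # zero-length in ref; use flanking base
        events.append(IndelEvent(kind=kind, ref_position=pos, length=length,
                                 region="IR" if region in ("IRa", "IRb") else region,
                                 ndh_related=near_ndh(lo, hi)))
    return events


def align_to_reference(record: PlastomeRecord, reference: PlastomeRecord,
                       aligner: Align.PairwiseAligner | None = None
                       ) -> list[IndelEvent]:
    """Region-by-region alignment of one taxon to the reference; all events."""
    events = []
    for region in ("LSC", "SSC", "IRb"):
        a = record.region_seq(region)
        b = reference.region_seq(region)
        aln = global_align(a, b, aligner, taxon_a=record.taxon_id,
                           taxon_b=reference.taxon_id)
        events.extend(extract_indel_events(
            aln, reference, region, ref_offset=reference.region_bounds[region][0]))
    return events


@dataclass(frozen=True)
class IndelProfile:
    taxon_id: str
    n_total: int
    n_lsc: int
    n_ssc: int
    n_ir: int
    pct_lsc: float


def indel_profile(records: Sequence[PlastomeRecord], reference_id: str,
                  aligner: Align.PairwiseAligner | None = None):
    """Per-taxon InDel counts by region vs the reference.

    Returns ``(profiles, events_by_taxon)``; taxon order in the output is
    sorted, independent of input order.
    """
    by_id = {r.taxon_id: r for r in records}
    if reference_id not in by_id:
        raise KeyError(f"reference taxon {reference_id!r} not among records")
    reference = by_id[reference_id]
    profiles = []
    events_by_taxon: dict[str, list[IndelEvent]] = {}
    for taxon in sorted(by_id):
        if taxon == reference_id:
            continue
        events = align_to_reference(by_id[taxon], reference, aligner)
        events_by_taxon[taxon] = events
        n_lsc = sum(e.region == "LSC" for e in events)
        n_ssc = sum(e.region == "SSC" for e in events)
        n_ir = sum(e.region == "IR" for e in events)
        n = len(events)
        profiles.append(IndelProfile(
            taxon_id=taxon, n_total=n, n_lsc=n_lsc, n_ssc=n_ssc, n_ir=n_ir,
            pct_lsc=100.0 * n_lsc / n if n else 0.0))
    return profiles, events_by_taxon


def indel_changed_length(events: Sequence[IndelEvent]) -> dict[str, int]:
    """Signed bp change (insertions - deletions) split by NDH-relatedness."""
    out = {"ndh_related_delta": 0, "ndh_unrelated_delta": 0}
    for e in events:
        key = "ndh_related_delta" if e.ndh_related else "ndh_unrelated_delta"
        out[key] += e.length if e.kind == "insertion" else -e.length
    return out


def indel_tests(profiles: Sequence[IndelProfile],
                deltas_by_taxon: dict[str, dict[str, int]],
                changed: Sequence[ChangedLengths]) -> dict[str, StatResult]:
    """Distribution and correlation tests on the InDel profiles.

    * Mann-Whitney of per-taxon LSC InDel proportions vs SSC+IR proportions.
    * Mann-Whitney of |NDH-unrelated| vs |NDH-related| changed lengths.
    * Spearman of NDH-unrelated changed length vs whole-plastome change.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 taxa")
    pct_lsc = [p.pct_lsc for p in profiles]
    pct_rest = [100.0 - p.pct_lsc for p in profiles]
    unrelated = [deltas_by_taxon[p.taxon_id]["ndh_unrelated_delta"] for p in profiles]
    related = [deltas_by_taxon[p.taxon_id]["ndh_related_delta"] for p in profiles]
    dt = {c.taxon_id: c.delta_total for c in changed}
    out = {
        "lsc_share_vs_rest": mann_whitney_two_sided(pct_lsc, pct_rest),
        "abs_unrelated_vs_abs_related": mann_whitney_two_sided(
            [abs(v) for v in unrelated], [abs(v) for v in related]),
    }
    try:
        out["unrelated_delta_vs_delta_total"] = spearman(
            unrelated, [dt[p.taxon_id] for p in profiles])
    except (KeyError, ValueError) as exc:
        warnings.warn(f"changed-length correlation unavailable: {exc}")
    return out
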