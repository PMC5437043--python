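"""Quadripartite length accounting and changed-length correlations.

Each plastome is summarized as total/LSC/SSC/IR lengths, AT content and
the total extent of retained NDH genes (truncated residues included,
the IR-duplicated ndhB counted once).  Changed lengths are signed bp
differences against a designated reference plastome; their Spearman
correlations against whole-plastome change quantify which region drives
size variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import PlastomeRecord
from .stats_core import StatResult, spearman


@dataclass(frozen=True)
class StructureSummary:
    taxon_id: str
    total_bp: int
    lsc_bp: int
    ssc_bp: int
    ir_bp: int          # one IR copy
    at_percent: float
    ndh_retained_bp: int


@dataclass(frozen=True)
class ChangedLengths:
    taxon_id: str
    delta_total: int
    delta_lsc: int
    delta_ssc: int
    delta_ir: int


def summarize_structure(record: PlastomeRecord) -> StructureSummary:
    """Region lengths, AT% (Ns ignored) and retained-NDH extent."""
    seq = record.sequence
    counts = {b: seq.count(b) for b in "ACGT"}
    acgt = sum(counts.values())
    at = 100.0 * (counts["A"] + counts["T"]) / acgt if acgt else 0.0

    ndh_bp = 0
    seen_ndhb = False
    for feat in record.features:
        if feat.kind in ("gene", "tRNA", "rRNA") and feat.name.startswith("ndh"):
            if feat.name == "ndhB":
                if seen_ndhb:
                    continue  # count the IR duplicate once
                seen_ndhb = True
            ndh_bp += feat.length

    return StructureSummary(
        taxon_id=record.taxon_id,
        total_bp=len(seq),
        lsc_bp=record.region_len("LSC"),
        ssc_bp=record.region_len("SSC"),
        ir_bp=record.region_len("IRb"),
        at_percent=at,
        ndh_retained_bp=ndh_bp,
    )


def changed_lengths(records: Sequence[PlastomeRecord],
                    reference_id: str) -> list[ChangedLengths]:
    """Signed bp differences of each taxon vs the reference (excluded)."""
    by_id = {r.taxon_id: summarize_structure(r) for r in records}
    if reference_id not in by_id:
        raise KeyError(f"reference taxon {reference_id!r} not among records")
    ref = by_id[reference_id]
    out = []
    for taxon, s in by_id.items():
        if taxon == reference_id:
            continue
        out.append(ChangedLengths(
            taxon_id=taxon,
            delta_total=s.total_bp - ref.total_bp,
            delta_lsc=s.lsc_bp - ref.lsc_bp,
            delta_ssc=s.ssc_bp - ref.ssc_bp,
            delta_ir=s.ir_bp - ref.ir_bp,
        ))
    return out


def structure_correlations(changed: Sequence[ChangedLengths],
                           summaries: Sequence[StructureSummary]
                           ) -> dict[str, StatResult]:
    """Spearman r of each region's changed length vs total change, plus
    retained-NDH length vs plastome length."""
    if len(changed) < 3:
        raise ValueError("need at least 3 non-reference taxa")
    dt = [c.delta_total for c in changed]
    out = {
        "delta_lsc_vs_delta_total": spearman([c.delta_lsc for c in changed], dt),
        "delta_ssc_vs_delta_total": spearman([c.delta_ssc for c in changed], dt),
        "delta_ir_vs_delta_total": spearman([c.delta_ir for c in changed], dt),
    }
    if len(summaries) >= 3:
        out["ndh_retained_vs_total"] = spearman(
            [s.ndh_retained_bp for s in summaries],
            [s.total_bp for s in summaries],
        )
    return out
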