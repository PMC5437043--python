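"""Detection and cross-species comparison of chloroplast microsatellites.

Perfect tandem repeats of 1-6 bp motifs are reported when they reach 8
units (mononucleotide) or 5 units (multinucleotide).  Repeats are
matched across taxa by locus plus 20-bp flanking context (allowing up
to 2 mismatches per flank), kept when present in a minimum number of
species, and called polymorphic when repeat counts differ.  A
transcription of the printed 47-record polymorphic-SSR table ships as a
fixture for summary checks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io_formats import data_path
from .sv_hotspots import SyntenicLocus

FLANK_LEN = 20


@dataclass(frozen=True)
class SSRHit:
    """One perfect tandem repeat in a single sequence."""

    motif: str        # canonical rotation of the repeat unit
    start: int        # 0-based
    units: int

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def span(self) -> int:
        return self.units * len(self.motif)


@dataclass
class SSRRecord:
    """One SSR site tracked across taxa at a syntenic locus."""

    locus: str
    region: str                       # LSC | SSC | IR
    location: str                     # spacer | intron
    motif: str
    unit_length: int
    units_by_taxon: dict[str, int] = field(default_factory=dict)
    polymorphic: bool = False
    flank_left: str = ""
    flank_right: str = ""


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of the repeat unit."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def find_ssrs(sequence: str, min_mono: int = 8, min_multi: int = 5,
              max_unit: int = 6) -> list[SSRHit]:
    """Maximal perfect tandem repeats meeting the unit-count thresholds.

    Overlapping reports are collapsed to the longest span (mononucleotide
    runs inside a reported longer-motif repeat are not re-reported); the
    motif is reported as its canonical rotation on the given strand.
    """
    seq = sequence.upper()
    n = len(seq)
    candidates: list[SSRHit] = []
    for unit in range(1, max_unit + 1):
        i = 0
        while i + unit <= n:
            # extend the maximal period-`unit` run starting at i
            j = i + unit
            while j < n and seq[j] == seq[j - unit]:
                j += 1
            run = j - i                      # bases with period `unit`
            units = run // unit
            min_units = min_mono if unit == 1 else min_multi
            motif = seq[i:i + unit]
            if units >= min_units and _is_primitive(motif):
                candidates.append(SSRHit(motif=canonical_motif(motif),
                                         start=i, units=units))
            # next possible run of this period starts after the run
            i = j - unit + 1 if run > unit else i + 1
    # collapse overlaps: keep longest spans first
    candidates.sort(key=lambda h: (-h.span, h.start, h.unit_length))
    kept: list[SSRHit] = []
    for h in candidates:
        if all(h.start + h.span <= k.start or h.start >= k.start + k.span
               for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def _flank_match(a: str, b: str, max_mismatch: int) -> bool:
    if not a or not b:
        return True
    k = min(len(a), len(b))
    mism = sum(1 for x, y in zip(a[-k:], b[-k:]) if x != y)
    return mism <= max_mismatch


def cross_species_ssrs(loci: Sequence[SyntenicLocus], min_species: int = 15,
                       min_mono: int = 8, min_multi: int = 5,
                       max_unit: int = 6, flank: int = FLANK_LEN,
                       max_flank_mismatch: int = 2) -> list[SSRRecord]:
    """SSR sites shared across taxa, anchored on the reference sequence.

    Each SSR found in the reference copy of a locus is matched in every
    other taxon by motif identity plus flanking-context similarity; the
    record is kept when present in >= ``min_species`` taxa and marked
    polymorphic when unit counts differ among them.
    """
    records: list[SSRRecord] = []
    for locus in loci:
        ref_seq = locus.seq_by_taxon.get(locus.reference_id)
        if not ref_seq:
            continue
        anchors = find_ssrs(ref_seq, min_mono, min_multi, max_unit)
        hits_by_taxon = {
            taxon: find_ssrs(s, min_mono, min_multi, max_unit)
            for taxon, s in locus.seq_by_taxon.items() if s
        }
        for anchor in anchors:
            left = ref_seq[max(0, anchor.start - flank):anchor.start]
            right = ref_seq[anchor.start + anchor.span:
                            anchor.start + anchor.span + flank]
            units_by_taxon: dict[str, int] = {}
            for taxon, hits in hits_by_taxon.items():
                best = None
                for h in hits:
                    if h.motif != anchor.motif:
                        continue
                    h_left = locus.seq_by_taxon[taxon][max(0, h.start - flank):h.start]
                    h_right = locus.seq_by_taxon[taxon][
                        h.start + h.span:h.start + h.span + flank]
                    if _flank_match(left, h_left, max_flank_mismatch) and \
                       _flank_match(right[::-1], h_right[::-1], max_flank_mismatch):
                        if best is None or abs(h.start - anchor.start) < \
                           abs(best.start - anchor.start):
                            best = h
                if best is not None:
                    units_by_taxon[taxon] = best.units
            if len(units_by_taxon) >= min_species:
                records.append(SSRRecord(
                    locus=locus.name, region=locus.region,
                    location=locus.locus_type, motif=anchor.motif,
                    unit_length=anchor.unit_length,
                    units_by_taxon=units_by_taxon,
                    polymorphic=len(set(units_by_taxon.values())) >= 2,
                    flank_left=left, flank_right=right))
    return records


def motif_class(motif: str) -> str:
    if len(motif) == 1:
        return "mono_AT" if motif in "AT" else "mono_CG"
    return "di" if len(motif) == 2 else "higher"


def ssr_summary(records: Sequence) -> dict[str, dict[str, int]]:
    """Tallies by motif class, region and location.

    Accepts :class:`SSRRecord` objects or any objects exposing
    ``motif``, ``region`` and ``location``.
    """
    by_motif: Counter = Counter()
    by_region: Counter = Counter()
    by_location: Counter = Counter()
    for r in records:
        by_motif[motif_class(r.motif)] += 1
        by_region[r.region] += 1
        by_location[r.location] += 1
    return {
        "motif_class": dict(by_motif),
        "region": dict(by_region),
        "location": dict(by_location),
        "total": {"records": len(list(records))},
    }


@dataclass(frozen=True)
class PublishedSSR:
    """One row of the published polymorphic-SSR table (primers included)."""

    no: int
    locus: str
    region: str
    location: str
    motif: str
    min_units: int
    max_units: int
    primer_f: str
    primer_r: str
    product_bp: int
    tm_c: int


def load_published_ssrs(path: str | Path | None = None) -> list[PublishedSSR]:
    """The 47 published polymorphic cpSSRs (shipped fixture)."""
    path = Path(path) if path else data_path("table3_ssrs.tsv")
    df = pd.read_csv(path, sep="\t")
    return [PublishedSSR(**{k: row[k] for k in PublishedSSR.__dataclass_fields__})
            for _, row in df.iterrows()]
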