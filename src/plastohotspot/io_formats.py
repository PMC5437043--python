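"""Reading, writing and validation of the formats the pipeline touches.

Sequences travel as FASTA (via Bio.SeqIO), per-taxon annotations as GFF3
with four custom ``region`` features (LSC, IRb, SSC, IRa) carrying the
quadripartite boundaries, and every result table as tab-separated UTF-8.

Internal coordinates are 0-based half-open on the forward strand; GFF3 I/O
converts from/to the standard 1-based closed convention.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REGION_ORDER = ("LSC", "IRb", "SSC", "IRa")
FEATURE_KINDS = ("gene", "exon", "intron", "tRNA", "rRNA")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PlastomeError(ValueError):
    """Raised when a plastome record or its annotation is inconsistent."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the forward strand of a plastome.

    ``interval`` is 0-based half-open.  ``pseudo`` marks truncated or
    pseudogenized copies (NDH residues).
    """

    name: str
    kind: str
    interval: tuple[int, int]
    strand: str = "+"
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise PlastomeError(f"unknown feature kind {self.kind!r} for {self.name}")
        if self.strand not in "+-":
            raise PlastomeError(f"bad strand {self.strand!r} for {self.name}")
        s, e = self.interval
        if not (0 <= s < e):
            raise PlastomeError(f"bad interval {self.interval} for {self.name}")

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class PlastomeRecord:
    """One taxon's plastome: sequence, features, quadripartite boundaries.

    ``region_bounds`` maps LSC/IRb/SSC/IRa to 0-based half-open intervals
    that must tile the sequence in that order, with IRb and IRa of equal
    length.  ``meta`` is a free-form scratch dict (not serialized, ignored
    in comparisons); the synthetic generator uses it.
    """

    taxon_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    region_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise PlastomeError(f"{self.taxon_id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise PlastomeError(f"{self.taxon_id}: non-ACGTN characters {sorted(bad)}")
        if set(self.region_bounds) != set(REGION_ORDER):
            raise PlastomeError(
                f"{self.taxon_id}: region bounds must name exactly {REGION_ORDER}"
            )
        cursor = 0
        for region in REGION_ORDER:
            s, e = self.region_bounds[region]
            if s != cursor or e <= s:
                raise PlastomeError(
                    f"{self.taxon_id}: regions do not tile the sequence "
                    f"(expected {region} to start at {cursor}, got [{s}, {e}))"
                )
            cursor = e
        if cursor != n:
            raise PlastomeError(
                f"{self.taxon_id}: regions end at {cursor}, sequence length {n}"
            )
        if self.region_len("IRb") != self.region_len("IRa"):
            raise PlastomeError(f"{self.taxon_id}: IRb and IRa lengths differ")
        for feat in self.features:
            if feat.interval[1] > n:
                raise PlastomeError(
                    f"{self.taxon_id}: feature {feat.name} ({feat.kind}) "
                    f"extends past sequence end ({feat.interval[1]} > {n})"
                )

    def region_len(self, region: str) -> int:
        s, e = self.region_bounds[region]
        return e - s

    def region_seq(self, region: str) -> str:
        s, e = self.region_bounds[region]
        return self.sequence[s:e]

    def region_of(self, position: int) -> str:
        """Region label at a position; IRa and IRb both report as given."""
        for region in REGION_ORDER:
            s, e = self.region_bounds[region]
            if s <= position < e:
                return region
        raise PlastomeError(f"{self.taxon_id}: position {position} out of range")

    def feature_seq(self, feat: GeneFeature) -> str:
        """Feature sequence, reverse-complemented for minus-strand features."""
        raw = self.sequence[feat.interval[0] : feat.interval[1]]
        return revcomp(raw) if feat.strand == "-" else raw


# ---------------------------------------------------------------------------
# FASTA + GFF3
# ---------------------------------------------------------------------------

def read_genomes(fasta_path: str | Path, annotation_path: str | Path) -> list[PlastomeRecord]:
    """Read a FASTA of plastome sequences plus a GFF3 of annotations.

    Every FASTA record must have annotations (including the four ``region``
    features) under the same seqid; violations raise
    :class:`PlastomeError` naming the offending taxon or feature.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    feats, regions = _parse_gff3(annotation_path)
    records = []
    for taxon, seq in seqs.items():
        if taxon not in regions:
            raise PlastomeError(f"no region annotation for taxon {taxon}")
        records.append(
            PlastomeRecord(
                taxon_id=taxon,
                sequence=seq,
                features=feats.get(taxon, []),
                region_bounds=regions[taxon],
            )
        )
    return records


def write_genomes(records: Iterable[PlastomeRecord], fasta_path: str | Path,
                  annotation_path: str | Path) -> None:
    """Write records as FASTA + GFF3 (inverse of :func:`read_genomes`)."""
    records = list(records)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.taxon_id, description="") for r in records),
        str(fasta_path), "fasta",
    )
    lines = ["##gff-version 3"]
    for r in records:
        for region in REGION_ORDER:
            s, e = r.region_bounds[region]
            lines.append(_gff3_line(r.taxon_id, "region", s, e, "+", f"Name={region}"))
        for f in r.features:
            attrs = f"Name={f.name}"
            if f.pseudo:
                attrs += ";pseudo=true"
            lines.append(
                _gff3_line(r.taxon_id, f.kind, f.interval[0], f.interval[1], f.strand, attrs)
            )
    Path(annotation_path).write_text("\n".join(lines) + "\n")


def _gff3_line(seqid: str, kind: str, start0: int, end0: int, strand: str, attrs: str) -> str:
    # 0-based half-open -> 1-based closed
    return "\t".join([seqid, "plastohotspot", kind, str(start0 + 1), str(end0),
                      ".", strand, ".", attrs])


def _parse_gff3(path: str | Path):
    feats: dict[str, list[GeneFeature]] = {}
    regions: dict[str, dict[str, tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise PlastomeError(f"{path}:{lineno}: expected 9 GFF3 columns")
        seqid, _src, kind, start, end, _score, strand, _phase, attr_col = cols
        attrs = dict(
            item.split("=", 1) for item in attr_col.split(";") if "=" in item
        )
        name = attrs.get("Name") or attrs.get("ID")
        if name is None:
            raise PlastomeError(f"{path}:{lineno}: feature without Name/ID")
        interval = (int(start) - 1, int(end))  # 1-based closed -> 0-based half-open
        if kind == "region":
            regions.setdefault(seqid, {})[name] = interval
        else:
            feats.setdefault(seqid, []).append(
                GeneFeature(
                    name=name, kind=kind, interval=interval,
                    strand=strand if strand in "+-" else "+",
                    pseudo=attrs.get("pseudo", "").lower() == "true",
                )
            )
    return feats, regions


# ---------------------------------------------------------------------------
# Generic TSV tables for result records
# ---------------------------------------------------------------------------

def write_table(records: Sequence, path: str | Path, schema: type | None = None) -> None:
    """Serialize dataclass records (or dicts) to a TSV with a header.

    ``schema`` (a dataclass type) is required only when ``records`` is
    empty, so the header can still be written.
    """
    if records:
        first = records[0]
        if dataclasses.is_dataclass(first):
            rows = [dataclasses.asdict(r) for r in records]
        else:
            rows = [dict(r) for r in records]
        rows = [
            {k: json.dumps(v, sort_keys=True) if isinstance(v, (dict, list)) else v
             for k, v in row.items()}
            for row in rows
        ]
        df = pd.DataFrame(rows)
    else:
        if schema is None or not dataclasses.is_dataclass(schema):
            raise ValueError("schema dataclass required for an empty record list")
        df = pd.DataFrame(columns=[f.name for f in dataclasses.fields(schema)])
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, schema: type) -> list:
    """Read a TSV written by :func:`write_table` back into dataclasses."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fields = {f.name: f.type for f in dataclasses.fields(schema)}
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for name, typ in fields.items():
            raw = row[name]
            typ = str(typ)
            if "dict" in typ or "list" in typ:
                kwargs[name] = json.loads(raw)
            elif "bool" in typ:
                kwargs[name] = raw in ("True", "true", "1")
            elif "int" in typ:
                kwargs[name] = int(raw)
            elif "float" in typ:
                kwargs[name] = float(raw)
            else:
                kwargs[name] = raw
        out.append(schema(**kwargs))
    return out


def data_path(name: str) -> Path:
    """Path to a packaged data fixture (e.g. the transcribed paper tables)."""
    return Path(__file__).parent / "data" / name
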