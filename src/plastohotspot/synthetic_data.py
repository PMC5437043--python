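"""Synthetic annotated plastome sets with known ground truth.

The generator emulates the statistical structure a comparative plastome
analysis consumes: a quadripartite genome (LSC / IRb / SSC / IRa, the two
IRs kept as exact mirror copies), a shared gene order with named
intergenic spacers and introns, designated fast-evolving (hotspot) loci,
region-biased InDel rates, seeded microsatellite tracts with replication
slippage, and lineage-specific truncation or loss of SSC ndh genes.  All
edits are applied to an internal segment model so feature coordinates
remain valid, and every planted event is recorded in a replayable
ground truth.

Defaults mirror a Dendrobium-like study: ~25 ingroup taxa, ~150 kb
genomes, ~92 syntenic loci, ten hotspot loci with a 5x substitution-rate
multiplier.  :meth:`SimConfig.desk` gives a 15 kb / 12-locus
configuration sized for fast tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io_formats import GeneFeature, PlastomeRecord, revcomp

SSC_NDH_GENES = ("ndhF", "ndhD", "ndhE", "ndhG", "ndhH", "ndhA",
                 "ndhI", "ndhC", "ndhK", "ndhJ")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Minimal rooted tree for simulation (name on leaves only)."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def depths(self) -> list[float]:
        """Root-to-tip path lengths."""
        out: list[float] = []

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.length
            if node.is_leaf:
                out.append(acc)
            for c in node.children:
                walk(c, acc)

        walk(self, 0.0)
        return out

    def scale(self, factor: float) -> None:
        for node in self.walk():
            node.length *= factor

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"

        return fmt(self).rsplit(":", 1)[0] + ";"


def simulate_tree(n_taxa: int, seed: int, prefix: str = "t") -> TreeNode:
    """Rooted bifurcating Yule tree with exponential branch lengths.

    The topology grows by uniformly splitting a random extant lineage;
    branch lengths are iid Exponential(1), then rescaled so the mean
    root-to-tip path length is 1 (rates downstream are "expected events
    per site from root to a typical tip").
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    tree = _yule_topology(n_taxa, rng, prefix)
    _assign_lengths(tree, rng)
    return tree


def _yule_topology(n_taxa: int, rng: np.random.Generator, prefix: str) -> TreeNode:
    root = TreeNode(children=[TreeNode(name=f"{prefix}01"), TreeNode(name=f"{prefix}02")])
    leaves = root.children[:]
    for i in range(3, n_taxa + 1):
        target = leaves[rng.integers(len(leaves))]
        old = TreeNode(name=target.name)
        new = TreeNode(name=f"{prefix}{i:02d}")
        target.name = None
        target.children = [old, new]
        leaves.remove(target)
        leaves.extend([old, new])
    return root


def _assign_lengths(tree: TreeNode, rng: np.random.Generator, depth: float = 1.0) -> None:
    for node in tree.walk():
        if node is not tree:
            node.length = float(rng.exponential(1.0))
    mean_depth = float(np.mean(tree.depths()))
    tree.scale(depth / mean_depth)


def attach_outgroup(ingroup: TreeNode, outgroup_names: Iterable[str],
                    rng: np.random.Generator, stem: float = 1.2) -> TreeNode:
    """Join an ingroup tree and a divergent outgroup clade under one root."""
    names = list(outgroup_names)
    if len(names) == 1:
        og = TreeNode(name=names[0], length=stem)
    else:
        og = _yule_topology(len(names), rng, "x")
        for leaf, name in zip(og.leaves(), names):
            leaf.name = name
        _assign_lengths(og, rng, depth=0.5)
        og.length = stem
    ingroup.length = 0.3
    return TreeNode(children=[ingroup, og])


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one simulated plastome set.

    Rates are expected events per site over a root-to-tip path of the
    (depth-normalized) ingroup tree.  ``hotspot_loci`` may be left None
    to let the builder pick ``n_hotspots`` LSC spacer loci.
    """

    n_taxa: int = 25
    genome_scale: int = 150_000
    n_loci: int = 92
    n_hotspots: int = 10
    hotspot_loci: tuple[str, ...] | None = None
    hotspot_multiplier: float = 5.0
    substitution_rate: float = 0.02
    indel_rate_per_region: dict[str, float] = field(
        default_factory=lambda: {"LSC": 1.2e-3, "SSC": 6e-4, "IR": 1.5e-4})
    indel_geom_p: float = 0.3
    indel_max_len: int = 30
    indel_min_len: int = 1
    indel_min_spacing: int = 20
    ssr_seeds: tuple[tuple[str, str, int], ...] | None = None
    slippage_rate: float = 0.25
    ndh_loss_lineages: dict[str, tuple[tuple[str, str], ...]] | None = None
    outgroup_taxa: tuple[str, ...] = ("og1", "og2", "og3")
    n_decoy_loci: int = 2
    background_gc: float = 0.37
    hotspot_gc: float = 0.26
    include_reference: bool = True
    reference_name: str = "REF"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.indel_rate_per_region.values()):
            raise ValueError("indel rates must be >= 0")
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")
        if self.hotspot_multiplier <= 1:
            raise ValueError("hotspot multiplier must be > 1")
        ingroup = {f"t{i:02d}" for i in range(1, self.n_taxa + 1)}
        if ingroup & set(self.outgroup_taxa):
            raise ValueError("outgroup names collide with ingroup names")

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Reduced 15 kb / 12-locus configuration used by the test suite."""
        kwargs = dict(
            n_taxa=10, genome_scale=15_000, n_loci=12, n_hotspots=4,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def ingroup_names(self) -> list[str]:
        return [f"t{i:02d}" for i in range(1, self.n_taxa + 1)]


@dataclass(frozen=True)
class PlantedIndel:
    """One insertion/deletion planted on a branch, in ground-truth terms."""

    kind: str            # insertion | deletion (relative to the ancestor)
    region: str          # LSC | SSC | IR
    length: int
    locus: str           # locus or gene name of the edited segment
    ndh_related: bool


@dataclass
class GroundTruth:
    true_tree: str
    true_indels: dict[str, list[PlantedIndel]]
    true_ssr_units: dict[str, dict[str, int]]
    true_hotspots: tuple[str, ...]


# ---------------------------------------------------------------------------
# Segment model
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """A run of sequence with one role; the genome is a segment list.

    Only LSC, IRb and SSC are stored; IRa is emitted as the mirror of
    IRb.  ``uid`` survives copying so per-tract bookkeeping (SSR units,
    indel spacing) can follow a segment through the tree.
    """

    seq: str
    kind: str                   # gene | exon | intron | spacer
    region: str                 # LSC | IRb | SSC
    gene: str | None = None
    locus: str | None = None
    strand: str = "+"
    pseudo: bool = False
    motif: str | None = None    # SSR tract segments only
    units: int | None = None
    exon_index: int | None = None
    uid: int = -1

    def copy(self) -> "Segment":
        return dataclasses.replace(self)


def _ssr_seq(motif: str, units: int) -> str:
    """A perfect tandem tract bounded by guard bases outside the motif,
    so neighbouring sequence can never extend the repeat run."""
    guard = "C" if "C" not in motif else "A"
    return guard + motif * units + guard


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def build_ancestral_plastome(config: SimConfig) -> PlastomeRecord:
    """Ancestral quadripartite genome hosting the configured loci.

    The returned record's ``meta`` dict carries the internal segment
    model (``meta['segments']``) and the resolved hotspot locus names
    (``meta['hotspot_loci']``); :func:`evolve_plastomes` requires both.
    """
    rng = np.random.default_rng(config.seed)
    segments, hotspots = _build_segments(config, rng)
    record = segments_to_record("ancestor", segments)
    record.meta["segments"] = segments
    record.meta["hotspot_loci"] = hotspots
    return record


def _build_segments(cfg: SimConfig, rng: np.random.Generator):
    lsc_len = int(cfg.genome_scale * 0.555)
    ir_len = int(cfg.genome_scale * 0.175)
    ssc_len = cfg.genome_scale - lsc_len - 2 * ir_len

    n_introns = 2 if cfg.n_loci >= 6 else 0
    n_lsc_spacers = cfg.n_loci - 2 - n_introns  # one IR + one SSC locus
    if n_lsc_spacers < 1:
        raise ValueError("n_loci too small: need at least 4 loci")
    n_genes = n_lsc_spacers + cfg.n_decoy_loci + 1

    pad = 60
    budget = lsc_len - 2 * pad - 120 * cfg.n_decoy_loci
    spacer_like = n_lsc_spacers + n_introns
    spacer_base = budget * 0.55 / max(spacer_like, 1)
    gene_base = budget * 0.45 / n_genes
    if spacer_base < 220 or gene_base < 90:
        raise ValueError(
            f"genome_scale {cfg.genome_scale} too small to host {cfg.n_loci} loci")

    gene_names = [f"g{i:02d}" for i in range(1, n_genes + 1)]
    spacer_kinds = ["locus"] * n_lsc_spacers + ["decoy"] * cfg.n_decoy_loci
    rng.shuffle(spacer_kinds)
    intron_genes = set()
    if n_introns:
        intron_genes = set(rng.choice(gene_names, size=n_introns, replace=False))

    # resolve hotspot names among LSC locus spacers
    locus_names = []
    gi = iter(range(len(gene_names) - 1))
    for k, kind in enumerate(spacer_kinds):
        i = next(gi)
        if kind == "locus":
            locus_names.append(f"{gene_names[i]}-{gene_names[i+1]}")
    if cfg.hotspot_loci is not None:
        hotspots = tuple(cfg.hotspot_loci)
        unknown = set(hotspots) - set(locus_names)
        if unknown:
            raise ValueError(f"hotspot loci not in genome: {sorted(unknown)}")
    else:
        k = min(cfg.n_hotspots, len(locus_names))
        hotspots = tuple(sorted(map(str, rng.choice(locus_names, size=k, replace=False))))

    ssr_seeds = cfg.ssr_seeds
    if ssr_seeds is None:
        ssr_seeds = _default_ssr_seeds(locus_names, hotspots)
    seeds_by_locus: dict[str, list[tuple[str, int]]] = {}
    for locus, motif, units in ssr_seeds:
        seeds_by_locus.setdefault(locus, []).append((motif, units))

    segments: list[Segment] = []

    def add(seg: Segment) -> None:
        seg.uid = len(segments)
        segments.append(seg)

    def gc_for(name: str | None) -> float:
        return cfg.hotspot_gc if name in hotspots else cfg.background_gc

    def add_noncoding(length: int, region: str, kind: str, locus: str | None) -> None:
        """Spacer/intron, split around any seeded SSR tracts."""
        tracts = seeds_by_locus.pop(locus, []) if locus else []
        flank = 30
        needed = sum(len(m) * u for m, u in tracts) + flank * (len(tracts) + 1)
        length = max(length, needed)
        if not tracts:
            add(Segment(seq=_rand_seq(rng, length, gc_for(locus)), kind=kind,
                        region=region, locus=locus))
            return
        gap = (length - sum(len(m) * u for m, u in tracts)) // (len(tracts) + 1)
        for motif, units in tracts:
            add(Segment(seq=_rand_seq(rng, gap, gc_for(locus)), kind=kind,
                        region=region, locus=locus))
            add(Segment(seq=_ssr_seq(motif, units), kind=kind, region=region,
                        locus=locus, motif=motif, units=units))
        add(Segment(seq=_rand_seq(rng, gap, gc_for(locus)), kind=kind,
                    region=region, locus=locus))

    def add_gene(name: str, length: int, region: str, with_intron: bool = False,
                 intron_len: int = 0, intron_locus: str | None = None) -> None:
        if with_intron:
            half = length // 2
            add(Segment(seq=_rand_seq(rng, half, 0.40), kind="exon", region=region,
                        gene=name, exon_index=1))
            add_noncoding(intron_len, region, "intron", intron_locus)
            for s in segments:
                if s.kind == "intron" and s.locus == intron_locus:
                    s.gene = name
            add(Segment(seq=_rand_seq(rng, length - half, 0.40), kind="exon",
                        region=region, gene=name, exon_index=2))
        else:
            add(Segment(seq=_rand_seq(rng, length, 0.40), kind="gene", region=region,
                        gene=name))

    def jitter(base: float, lo: float = 0.8, hi: float = 1.2) -> int:
        return max(60, int(base * rng.uniform(lo, hi)))

    # ----- LSC -----
    add(Segment(seq=_rand_seq(rng, pad, cfg.background_gc), kind="spacer",
                region="LSC", locus=None))
    spacer_iter = iter(spacer_kinds)
    for i, gname in enumerate(gene_names):
        if gname in intron_genes:
            add_gene(gname, jitter(gene_base), "LSC", with_intron=True,
                     intron_len=jitter(spacer_base), intron_locus=f"{gname}_intron")
        else:
            add_gene(gname, jitter(gene_base), "LSC")
        if i < len(gene_names) - 1:
            kind = next(spacer_iter)
            if kind == "locus":
                add_noncoding(jitter(spacer_base), "LSC", "spacer",
                              f"{gname}-{gene_names[i+1]}")
            else:
                add_noncoding(int(rng.integers(100, 141)), "LSC", "spacer",
                              f"{gname}-{gene_names[i+1]}")
    add(Segment(seq=_rand_seq(rng, pad, cfg.background_gc), kind="spacer",
                region="LSC", locus=None))

    # ----- IRb: ndhB plus two rRNA genes with one syntenic spacer -----
    add(Segment(seq=_rand_seq(rng, 40, cfg.background_gc), kind="spacer",
                region="IRb", locus=None))
    add_gene("ndhB", max(150, ir_len // 5), "IRb")
    add_noncoding(max(70, ir_len // 20), "IRb", "spacer", "ndhB-rrn1")
    add_gene("rrn1", max(150, ir_len // 5), "IRb")
    add_noncoding(max(220, ir_len // 8), "IRb", "spacer", "rrn1-rrn2")
    add_gene("rrn2", max(150, ir_len // 4), "IRb")
    used = sum(len(s.seq) for s in segments if s.region == "IRb")
    add(Segment(seq=_rand_seq(rng, max(30, ir_len - used), cfg.background_gc),
                kind="spacer", region="IRb", locus=None))

    # ----- SSC: the ndh gene cluster with one syntenic spacer -----
    ndh_len = max(70, ssc_len // 16)
    add(Segment(seq=_rand_seq(rng, 40, cfg.background_gc), kind="spacer",
                region="SSC", locus=None))
    add_gene(SSC_NDH_GENES[0], ndh_len, "SSC")
    add_noncoding(max(200, ssc_len // 8), "SSC", "spacer",
                  f"{SSC_NDH_GENES[0]}-{SSC_NDH_GENES[1]}")
    for prev, gname in zip(SSC_NDH_GENES[1:], SSC_NDH_GENES[2:]):
        add_gene(prev, ndh_len, "SSC")
        add_noncoding(int(rng.integers(40, 90)), "SSC", "spacer", None)
    add_gene(SSC_NDH_GENES[-1], ndh_len, "SSC")
    add(Segment(seq=_rand_seq(rng, 40, cfg.background_gc), kind="spacer",
                region="SSC", locus=None))

    if seeds_by_locus:
        raise ValueError(f"SSR seeds reference unknown loci: {sorted(seeds_by_locus)}")
    return segments, hotspots


def _default_ssr_seeds(locus_names: list[str], hotspots: tuple[str, ...]):
    """Mostly A/T mononucleotide tracts, one AT dinucleotide, one IR G tract."""
    seeds = []
    motifs = [("A", 11), ("T", 12), ("AT", 6), ("T", 10), ("A", 9), ("T", 14)]
    targets = list(hotspots) + [n for n in locus_names if n not in hotspots]
    for (motif, units), locus in zip(motifs, targets):
        seeds.append((locus, motif, units))
    seeds.append(("rrn1-rrn2", "G", 8))
    seeds.append((f"{SSC_NDH_GENES[0]}-{SSC_NDH_GENES[1]}", "T", 10))
    return tuple(seeds)


# ---------------------------------------------------------------------------
# Emission: segments -> PlastomeRecord
# ---------------------------------------------------------------------------

def segments_to_record(taxon_id: str, segments: list[Segment]) -> PlastomeRecord:
    """Assemble LSC + IRb + SSC segments and the mirrored IRa into a record."""
    fwd = [s for s in segments if len(s.seq) > 0]
    ira = [
        dataclasses.replace(s, seq=revcomp(s.seq), region="IRa",
                            strand="-" if s.strand == "+" else "+")
        for s in reversed([s for s in fwd if s.region == "IRb"])
    ]
    ordered = ([s for s in fwd if s.region == "LSC"]
               + [s for s in fwd if s.region == "IRb"]
               + [s for s in fwd if s.region == "SSC"]
               + ira)

    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    bounds: dict[str, tuple[int, int]] = {}
    pos = 0
    region_start = 0
    current_region = ordered[0].region
    open_gene: dict | None = None

    def close_gene() -> None:
        nonlocal open_gene
        if open_gene is None:
            return
        g = open_gene
        kind = "rRNA" if g["name"].startswith("rrn") else (
            "tRNA" if g["name"].startswith("trn") else "gene")
        features.append(GeneFeature(name=g["name"], kind=kind,
                                    interval=(g["start"], g["end"]),
                                    strand=g["strand"], pseudo=g["pseudo"]))
        features.extend(g["parts"])
        open_gene = None

    for seg in ordered:
        if seg.region != current_region:
            close_gene()
            bounds[current_region] = (region_start, pos)
            region_start = pos
            current_region = seg.region
        start, end = pos, pos + len(seg.seq)
        if seg.gene is not None:
            if open_gene is None or open_gene["name"] != seg.gene:
                close_gene()
                open_gene = {"name": seg.gene, "start": start, "end": end,
                             "strand": seg.strand, "pseudo": seg.pseudo, "parts": []}
            open_gene["end"] = end
            open_gene["pseudo"] = open_gene["pseudo"] or seg.pseudo
            if seg.kind == "exon":
                open_gene["parts"].append(GeneFeature(
                    name=seg.gene, kind="exon", interval=(start, end),
                    strand=seg.strand))
            elif seg.kind == "intron":
                open_gene["parts"].append(GeneFeature(
                    name=seg.gene, kind="intron", interval=(start, end),
                    strand=seg.strand))
        else:
            close_gene()
        seq_parts.append(seg.seq)
        pos = end
    close_gene()
    bounds[current_region] = (region_start, pos)

    return PlastomeRecord(taxon_id=taxon_id, sequence="".join(seq_parts),
                          features=features, region_bounds=bounds)


# ---------------------------------------------------------------------------
# Evolution along the tree
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_MUTABLE = ("gene", "exon", "intron", "spacer")


def evolve_plastomes(tree: TreeNode, ancestor: PlastomeRecord, config: SimConfig):
    """Evolve the ancestral genome down a tree; return records + truth.

    Per branch: Jukes-Cantor substitutions (rate x branch length, times
    the hotspot multiplier inside hotspot loci), Poisson InDel events
    with region-specific rates and geometric lengths confined to
    non-coding segments, SSR slippage at seeded tracts, and - on the
    terminal branches named in ``ndh_loss_lineages`` - truncation or
    deletion of SSC ndh genes.  IRb edits are mirrored into IRa at
    emission, so each IR event exists once and is labelled "IR".
    """
    if "segments" not in ancestor.meta:
        raise ValueError("ancestor must come from build_ancestral_plastome")
    segments0: list[Segment] = ancestor.meta["segments"]
    hotspots: tuple[str, ...] = tuple(ancestor.meta["hotspot_loci"])
    rng = np.random.default_rng(config.seed + 1)

    losses = config.ndh_loss_lineages
    if losses is None:
        losses = _default_ndh_losses(tree, config, rng)

    spacing_used: dict[int, list[int]] = {}
    leaves: dict[str, tuple[list[Segment], list[PlantedIndel]]] = {}

    def descend(node: TreeNode, segs: list[Segment], events: list[PlantedIndel]) -> None:
        for child in node.children:
            csegs = [s.copy() for s in segs]
            cevents = list(events)
            _mutate_branch(csegs, child.length, config, hotspots, rng)
            cevents += _indel_branch(csegs, child.length, config, rng, spacing_used)
            _slippage_branch(csegs, config, rng)
            if child.is_leaf and child.name in losses:
                cevents += _apply_ndh_loss(csegs, losses[child.name], rng)
            if child.is_leaf:
                leaves[child.name] = (csegs, cevents)
            else:
                descend(child, csegs, cevents)

    descend(tree, segments0, [])

    records = []
    true_indels: dict[str, list[PlantedIndel]] = {}
    true_ssr: dict[str, dict[str, int]] = {}
    for name in tree.leaf_names():
        segs, events = leaves[name]
        records.append(segments_to_record(name, segs))
        true_indels[name] = events
        true_ssr[name] = {
            f"{s.locus}:{s.motif}": s.units
            for s in segs if s.motif is not None and len(s.seq) > 0
        }
    if config.include_reference:
        ref = segments_to_record(config.reference_name, segments0)
        ref.meta.update(ancestor.meta)
        records.insert(0, ref)

    truth = GroundTruth(
        true_tree=tree.newick(),
        true_indels=true_indels,
        true_ssr_units=true_ssr,
        true_hotspots=hotspots,
    )
    return records, truth


def _default_ndh_losses(tree: TreeNode, cfg: SimConfig, rng: np.random.Generator):
    """About half the ingroup taxa lose 1-3 SSC ndh genes; 15% full deletions."""
    ingroup = [n for n in tree.leaf_names()
               if n not in cfg.outgroup_taxa]
    losses: dict[str, tuple[tuple[str, str], ...]] = {}
    for name in ingroup:
        if rng.random() < 0.5:
            genes = rng.choice(SSC_NDH_GENES, size=int(rng.integers(1, 4)),
                               replace=False)
            losses[name] = tuple(
                (str(g), "delete" if rng.random() < 0.15 else "truncate")
                for g in genes
            )
    return losses


def _mutate_branch(segs: list[Segment], bl: float, cfg: SimConfig,
                   hotspots: tuple[str, ...], rng: np.random.Generator) -> None:
    if cfg.substitution_rate <= 0 or bl <= 0:
        return
    for seg in segs:
        if seg.kind not in _MUTABLE or seg.motif is not None or not seg.seq:
            continue
        rate = cfg.substitution_rate * bl
        if seg.locus in hotspots:
            rate *= cfg.hotspot_multiplier
        p = min(rate, 0.75)
        k = rng.binomial(len(seg.seq), p)
        if k == 0:
            continue
        pos = rng.choice(len(seg.seq), size=k, replace=False)
        chars = list(seg.seq)
        for i in pos:
            alt = [b for b in "ACGT" if b != chars[i]]
            chars[i] = alt[rng.integers(3)]
        seg.seq = "".join(chars)


def _geom_len(cfg: SimConfig, rng: np.random.Generator) -> int:
    length = int(rng.geometric(cfg.indel_geom_p))
    return int(min(max(length, cfg.indel_min_len), cfg.indel_max_len))


def _indel_branch(segs: list[Segment], bl: float, cfg: SimConfig,
                  rng: np.random.Generator,
                  spacing_used: dict[int, list[int]]) -> list[PlantedIndel]:
    events: list[PlantedIndel] = []
    if bl <= 0:
        return events
    for region, label in (("LSC", "LSC"), ("SSC", "SSC"), ("IRb", "IR")):
        rate = cfg.indel_rate_per_region.get(label, 0.0)
        if rate <= 0:
            continue
        region_segs = [s for s in segs if s.region == region]
        total = sum(len(s.seq) for s in region_segs)
        n_events = rng.poisson(rate * bl * total)
        eligible = [s for s in region_segs
                    if s.kind in ("spacer", "intron") and s.motif is None
                    and len(s.seq) >= 40]
        if not eligible or n_events == 0:
            continue
        weights = np.array([len(s.seq) for s in eligible], dtype=float)
        weights /= weights.sum()
        for _ in range(n_events):
            seg = eligible[rng.choice(len(eligible), p=weights)]
            length = _geom_len(cfg, rng)
            placed = _place_event(seg, length, cfg, rng, spacing_used)
            if placed is None:
                continue
            kind, length = placed
            ndh = bool(seg.gene and seg.gene.startswith("ndh")) or bool(
                seg.locus and "ndh" in seg.locus)
            events.append(PlantedIndel(kind=kind, region=label, length=length,
                                       locus=seg.locus or seg.gene or "-",
                                       ndh_related=ndh))
    return events


def _place_event(seg: Segment, length: int, cfg: SimConfig,
                 rng: np.random.Generator,
                 spacing_used: dict[int, list[int]]):
    margin = 5
    if len(seg.seq) < length + 2 * margin + 2:
        return None
    used = spacing_used.setdefault(seg.uid, [])
    guard = cfg.indel_min_spacing + cfg.indel_max_len
    for _ in range(10):
        pos = int(rng.integers(margin, len(seg.seq) - length - margin))
        if all(abs(pos - u) > guard for u in used):
            break
    else:
        return None
    used.append(pos)
    if rng.random() < 0.5:
        gc = 0.35
        ins = _rand_seq(rng, length, gc)
        seg.seq = seg.seq[:pos] + ins + seg.seq[pos:]
        return ("insertion", length)
    seg.seq = seg.seq[:pos] + seg.seq[pos + length:]
    return ("deletion", length)


def _slippage_branch(segs: list[Segment], cfg: SimConfig,
                     rng: np.random.Generator) -> None:
    for seg in segs:
        if seg.motif is None or not seg.seq:
            continue
        if rng.random() < cfg.slippage_rate:
            delta = 1 if rng.random() < 0.5 else -1
            seg.units = max(3, seg.units + delta)
            seg.seq = _ssr_seq(seg.motif, seg.units)


def _apply_ndh_loss(segs: list[Segment], losses, rng: np.random.Generator):
    events = []
    for gene, mode in losses:
        for seg in segs:
            if seg.gene == gene and seg.region == "SSC" and len(seg.seq) > 0:
                if mode == "delete":
                    removed = len(seg.seq)
                    seg.seq = ""
                else:
                    keep = int(len(seg.seq) * rng.uniform(0.4, 0.7))
                    removed = len(seg.seq) - keep
                    seg.seq = seg.seq[:keep]
                    seg.pseudo = True
                if removed:
                    events.append(PlantedIndel(
                        kind="deletion", region="SSC", length=removed,
                        locus=gene, ndh_related=True))
    return events


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig):
    """Tree + ancestor + evolution in one deterministic call.

    Returns ``(records, truth)``.  When ``config.include_reference`` is
    set (default) the unevolved ancestor is included as the first record
    under ``config.reference_name``, giving downstream pairwise analyses
    an exact reference, as a real study designates one published plastome.
    """
    ingroup = simulate_tree(config.n_taxa, config.seed)
    rng = np.random.default_rng(config.seed + 7)
    tree = attach_outgroup(ingroup, config.outgroup_taxa, rng) \
        if config.outgroup_taxa else ingroup
    ancestor = build_ancestral_plastome(config)
    return evolve_plastomes(tree, ancestor, config)
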