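"""Syntenic locus extraction and the SV statistic."""

import warnings

import numpy as np
import pytest

from plastohotspot.io_formats import GeneFeature, PlastomeRecord, revcomp
from plastohotspot.sv_hotspots import (SyntenicLocus, extract_syntenic_loci,
                                       mean_sv_table, pairwise_sv,
                                       rank_stability, sv_gc_correlation)

# anchors long and unique enough that the optimal alignment is forced
L_ANCHOR = "ACGGATTCAGCTTAGGCTAA"
R_ANCHOR = "TTCGACCATGGATCCGATCC"


class TestPairwiseSV:
    def test_identical_sequences_have_zero_sv(self):
        assert pairwise_sv(L_ANCHOR, L_ANCHOR) == 0.0

    def test_two_mismatches_no_gaps(self):
        a = L_ANCHOR + "AATTCCAAGG" + R_ANCHOR
        b = L_ANCHOR + "AATGCCATGG" + R_ANCHOR  # 2 substitutions
        # conserved 48, mutations 2, events 0 -> 2/50
        assert pairwise_sv(a, b) == pytest.approx(100 * 2 / 50)

    def test_single_internal_gap_counts_one_event(self):
        a = L_ANCHOR + "GGGG" + R_ANCHOR
        b = L_ANCHOR + R_ANCHOR
        # conserved 40, mutations 0, events 1 -> 1/41
        assert pairwise_sv(a, b) == pytest.approx(100 * 1 / 41)

    def test_terminal_overhang_is_trimmed(self):
        a = L_ANCHOR + R_ANCHOR + "AAAAAAAA"
        b = L_ANCHOR + R_ANCHOR
        assert pairwise_sv(a, b) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            a = "".join(rng.choice(list("ACGT"), size=60))
            b = "".join(rng.choice(list("ACGT"), size=55))
            assert pairwise_sv(a, b) == pytest.approx(pairwise_sv(b, a))

    def test_bounded_between_zero_and_hundred(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 80))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 80))))
            assert 0.0 <= pairwise_sv(a, b) <= 100.0


def _two_taxon_records():
    """Two tiny genomes: geneA(+) spacer geneB(-) spacer geneC(+)."""
    spacer1 = "ACGGATTCAGCTTAGGCTAATTCGACCATGGATCCGATCC" * 4  # 160 bp
    spacer2 = "GGTTAACCGGTTAACCGGTA" * 8                       # 160 bp
    gene = "ATGGCCTTAA"
    recs = []
    for taxon, twist in (("r1", ""), ("r2", "TTTT")):
        seq = gene + spacer1 + gene + spacer2[:80] + twist + spacer2[80:] + gene
        seq += "CC" + "GG" + "AA" + "CC"  # IRb/SSC/IRa stubs
        n = len(seq)
        feats = [
            GeneFeature("geneA", "gene", (0, 10), "+"),
            GeneFeature("geneB", "gene", (170, 180), "-"),
            GeneFeature("geneC", "gene",
                        (180 + 160 + len(twist), 190 + 160 + len(twist)), "+"),
        ]
        recs.append(PlastomeRecord(
            taxon_id=taxon, sequence=seq, features=feats,
            region_bounds={"LSC": (0, n - 8), "IRb": (n - 8, n - 6),
                           "SSC": (n - 6, n - 2), "IRa": (n - 2, n)}))
    return recs


class TestExtraction:
    def test_short_loci_are_filtered(self, desk_dataset, desk_loci):
        cfg, records, _ = desk_dataset
        ref = next(r for r in records if r.taxon_id == "REF")
        # decoy spacers exist in the genome but are below 150 bp
        locus_lengths = {}
        for s in ref.meta["segments"]:
            if s.locus and s.kind == "spacer" and s.region == "LSC":
                locus_lengths[s.locus] = locus_lengths.get(s.locus, 0) + len(s.seq)
        decoys = {n for n, l in locus_lengths.items() if l < 150}
        assert decoys
        assert decoys.isdisjoint({l.name for l in desk_loci})

    def test_intron_loci_discovered(self, desk_loci):
        assert sum(l.locus_type == "intron" for l in desk_loci) == 2

    def test_minus_strand_left_flank_reverse_complements(self):
        recs = _two_taxon_records()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loci = extract_syntenic_loci(recs, reference_id="r1")
        by_name = {l.name: l for l in loci}
        locus = by_name["geneB-geneC"]
        raw = recs[0].sequence[180:340]
        assert locus.seq_by_taxon["r1"] == revcomp(raw)
        plus = by_name["geneA-geneB"]
        assert plus.seq_by_taxon["r1"] == recs[0].sequence[10:170]

    def test_all_taxa_present_on_synthetic_set(self, desk_dataset, desk_loci):
        _, records, _ = desk_dataset
        for locus in desk_loci:
            assert len(locus.present_taxa()) >= 2
            for taxon, seq in locus.seq_by_taxon.items():
                assert seq, (locus.name, taxon)


class TestMeanSVTable:
    def test_two_taxa_single_pair(self):
        recs = _two_taxon_records()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loci = extract_syntenic_loci(recs, reference_id="r1")
            table = mean_sv_table(loci)
        assert all(r.n_pairs == 1 for r in table)
        # the planted 4 bp insertion makes geneB-geneC the variable locus
        assert table[0].locus == "geneB-geneC"
        assert table[0].mean_sv > 0

    def test_mean_matches_direct_pair_average(self, desk_loci, desk_sv_table):
        locus = next(l for l in desk_loci if l.name == desk_sv_table[0].locus)
        taxa = sorted(locus.present_taxa())
        svs = [pairwise_sv(locus.seq_by_taxon[a], locus.seq_by_taxon[b])
               for i, a in enumerate(taxa) for b in taxa[i + 1:]]
        assert desk_sv_table[0].mean_sv == pytest.approx(float(np.mean(svs)))
        assert desk_sv_table[0].n_pairs == len(svs)

    def test_ranks_are_dense_and_deterministic(self, desk_sv_table):
        assert [r.rank for r in desk_sv_table] == \
            list(range(1, len(desk_sv_table) + 1))
        svs = [r.mean_sv for r in desk_sv_table]
        assert svs == sorted(svs, reverse=True)

    def test_planted_hotspots_rank_top(self, desk_dataset, desk_sv_table):
        _, _, truth = desk_dataset
        k = len(truth.true_hotspots)
        top = {r.locus for r in desk_sv_table[:k]}
        assert top == set(truth.true_hotspots)


def test_sv_gc_correlation_is_negative_by_construction(desk_sv_table):
    res = sv_gc_correlation(desk_sv_table)
    assert res.statistic < 0


def test_gc_constant_propagates_error():
    from plastohotspot.sv_hotspots import SVRecord
    recs = [SVRecord(f"l{i}", "spacer", "LSC", float(i), 40.0, 3, i + 1)
            for i in range(4)]
    with pytest.raises(ValueError, match="constant"):
        sv_gc_correlation(recs)


class TestRankStability:
    def test_full_group_reproduces_global_ranks(self, desk_dataset, desk_loci,
                                                desk_sv_table):
        _, records, _ = desk_dataset
        n = len(records)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = rank_stability(desk_loci, group_sizes=(n,),
                                   n_reference_top=5, seed=1)
        global_rank = {r.locus: r.rank for r in desk_sv_table}
        for locus, by_size in table.items():
            assert by_size[n] == global_rank[locus]

    def test_same_seed_is_deterministic(self, desk_loci):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t1 = rank_stability(desk_loci, group_sizes=(2, 5), seed=42)
            t2 = rank_stability(desk_loci, group_sizes=(2, 5), seed=42)
        assert t1 == t2

    def test_oversized_group_rejected(self, desk_loci):
        with pytest.raises(ValueError, match="exceeds"):
            rank_stability(desk_loci, group_sizes=(999,))
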