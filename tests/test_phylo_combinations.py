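"""Combination enumeration, alignment merging, NJ/bootstrap engine."""

import numpy as np
import pytest

from plastohotspot.phylo_combinations import (BootstrapTree, CombinationResult,
                                              LocusMSA, _nj_bipartitions,
                                              bootstrap_tree, build_locus_msa,
                                              combo_correlations, concatenate,
                                              enumerate_combinations, mean_bs,
                                              plateau_analysis,
                                              top_combinations)
from plastohotspot.sv_hotspots import SyntenicLocus


class TestEnumeration:
    @pytest.mark.parametrize("n, expected", [(1, 1), (3, 7), (10, 1023)])
    def test_counts(self, n, expected):
        names = [f"l{i:02d}" for i in range(n)]
        combos = enumerate_combinations(names)
        assert len(combos) == expected
        assert len(set(combos)) == expected

    def test_ordering_by_size_then_lexicographic(self):
        combos = enumerate_combinations(["b", "a", "c"])
        assert combos[:3] == [("a",), ("b",), ("c",)]
        assert combos[3] == ("a", "b")
        assert combos[-1] == ("a", "b", "c")

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError):
            enumerate_combinations([f"l{i}" for i in range(17)])


def _locus(seqs, name="loc"):
    return SyntenicLocus(name=name, locus_type="spacer", region="LSC",
                         reference_id=sorted(seqs)[0], seq_by_taxon=seqs)


class TestCenterStar:
    def test_identical_sequences_align_gap_free(self):
        msa = build_locus_msa(_locus({t: "ACGTACGTAC" for t in "abc"}))
        assert msa.rows == ["ACGTACGTAC"] * 3

    def test_degapping_recovers_every_input(self):
        seqs = {"a": "ACGGATTCAGCTTAGGCTAATT",
                "b": "ACGGATTCAGCTAGGCTAATT",      # 1 bp deletion
                "c": "ACGGATTCAGCTTAGGCCCCTAATT",  # 4 bp insertion
                "d": "ACGGATTCAGCTTAGGCTAATT"}
        msa = build_locus_msa(_locus(seqs))
        for taxon in seqs:
            assert msa.row(taxon).replace("-", "") == seqs[taxon]

    def test_single_indel_produces_expected_columns(self):
        seqs = {"a": "AACCGGTTAACC", "b": "AACCTTAACC", "c": "AACCGGTTAACC"}
        msa = build_locus_msa(_locus(seqs))
        assert msa.length == 12
        assert msa.row("a") == "AACCGGTTAACC"
        assert msa.row("b").count("-") == 2

    def test_achieves_optimal_sp_score_on_easy_triples(self):
        """Exhaustive 3-way DP oracle (linear gap costs) on tiny inputs."""
        cases = [
            ("ACGTAC", "ACGTAC", "ACGTAC"),
            ("ACGTAC", "ACTAC", "ACGTAC"),    # one deletion
            ("ACGTAC", "ACGTAC", "ACCTAC"),   # one substitution
            ("AAGGCC", "AAGCC", "AAGGCC"),
        ]
        for a, b, c in cases:
            msa = build_locus_msa(_locus({"a": a, "b": b, "c": c}))
            got = _sp_score([msa.row("a"), msa.row("b"), msa.row("c")])
            assert got == _optimal_3way_sp(a, b, c), (a, b, c)

    def test_missing_taxon_gets_gap_row(self):
        msa = build_locus_msa(_locus({t: "ACGTACGTAC" for t in "abc"}),
                              taxa_universe=["a", "b", "c", "zz"])
        assert msa.row("zz") == "-" * msa.length

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            build_locus_msa(_locus({"a": "ACGT", "b": "ACGT"}))


_MATCH, _MISMATCH, _GAP = 1, -1, -2


def _pair_score(x, y):
    if x == "-" and y == "-":
        return 0
    if x == "-" or y == "-":
        return _GAP
    return _MATCH if x == y else _MISMATCH


def _sp_score(rows):
    total = 0
    for col in zip(*rows):
        for i in range(len(col)):
            for j in range(i + 1, len(col)):
                total += _pair_score(col[i], col[j])
    return total


def _optimal_3way_sp(a, b, c):
    """Exact 3-D dynamic program over all gapped 3-way alignments."""
    import itertools
    la, lb, lc = len(a), len(b), len(c)
    NEG = float("-inf")
    dp = np.full((la + 1, lb + 1, lc + 1), NEG)
    dp[0, 0, 0] = 0.0
    moves = [m for m in itertools.product((0, 1), repeat=3) if any(m)]
    for i in range(la + 1):
        for j in range(lb + 1):
            for k in range(lc + 1):
                if dp[i, j, k] == NEG:
                    continue
                for di, dj, dk in moves:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if ni > la or nj > lb or nk > lc:
                        continue
                    col = (a[i] if di else "-", b[j] if dj else "-",
                           c[k] if dk else "-")
                    s = (_pair_score(col[0], col[1])
                         + _pair_score(col[0], col[2])
                         + _pair_score(col[1], col[2]))
                    if dp[i, j, k] + s > dp[ni, nj, nk]:
                        dp[ni, nj, nk] = dp[i, j, k] + s
    return dp[la, lb, lc]


class TestConcatenate:
    def _msa(self, name, taxa, length, fill="A"):
        return LocusMSA(name=name, taxa=list(taxa),
                        rows=[fill * length for _ in taxa])

    def test_lengths_are_additive(self):
        m1 = self._msa("x", "abc", 100)
        m2 = self._msa("y", "abc", 150, fill="C")
        concat, parts = concatenate([m1, m2], list("abc"))
        assert concat.length == 250
        assert parts == [("x", 0, 100), ("y", 100, 250)]

    def test_identity_on_single_msa(self):
        m = self._msa("x", "abc", 40)
        concat, _ = concatenate([m], list("abc"))
        assert concat.rows == m.rows

    def test_partition_table_recovers_blocks(self):
        m1 = self._msa("x", "ab", 10)
        m2 = self._msa("y", "ab", 20, fill="G")
        concat, parts = concatenate([m1, m2], list("ab"))
        for (name, lo, hi), src in zip(parts, (m1, m2)):
            assert [r[lo:hi] for r in concat.rows] == src.rows

    def test_absent_taxon_padded_with_gaps(self):
        m1 = self._msa("x", "ab", 10)
        concat, _ = concatenate([m1], list("abz"))
        assert concat.row("z") == "-" * 10


def _signal_msa(n_diag=50):
    """Six ingroup taxa + outgroup; (e, f) is a clade with diagnostic columns."""
    rng = np.random.default_rng(41)
    base = "".join(rng.choice(list("ACGT"), size=300))
    rows = {}
    for t in "abcdef":
        rows[t] = list(base)
    for t in "og1", "og2", "og3":
        row = list(base)
        for i in range(0, 90, 2):
            row[i] = "T" if row[i] != "T" else "G"
        rows[t] = row
    for pos in range(100, 100 + n_diag):
        for t in ("e", "f"):
            rows[t][pos] = "C" if base[pos] != "C" else "G"
    # make remaining ingroup taxa individually distinct
    for i, t in enumerate("abcd"):
        for pos in range(200 + 10 * i, 205 + 10 * i):
            rows[t][pos] = "A" if base[pos] != "A" else "T"
    taxa = list("abcdef") + ["og1", "og2", "og3"]
    return LocusMSA(name="sig", taxa=taxa,
                    rows=["".join(rows[t]) for t in taxa])


class TestBootstrap:
    def test_unanimous_clade_gets_full_support(self):
        msa = _signal_msa()
        tree = bootstrap_tree(msa, n_replicates=50, seed=3,
                              outgroups=["og1", "og2", "og3"])
        assert tree.supports[frozenset({"e", "f"})] == 100

    def test_same_seed_reproduces_supports(self):
        msa = _signal_msa()
        t1 = bootstrap_tree(msa, n_replicates=30, seed=7,
                            outgroups=["og1", "og2", "og3"])
        t2 = bootstrap_tree(msa, n_replicates=30, seed=7,
                            outgroups=["og1", "og2", "og3"])
        assert t1.supports == t2.supports
        assert t1.newick == t2.newick

    def test_supports_bounded(self):
        msa = _signal_msa()
        tree = bootstrap_tree(msa, n_replicates=30, seed=11,
                              outgroups=["og1", "og2", "og3"])
        assert all(0 <= s <= 100 for s in tree.supports.values())

    def test_nj_recovers_additive_four_taxon_topology(self):
        # tree ((A,B),(C,D)) with additive path distances
        #   A-v: 1, B-v: 2, v-w: 1, C-w: 3, D-w: 1
        taxa = ["A", "B", "C", "D"]
        dm = np.array([
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0],
        ], dtype=float)
        _, bips = _nj_bipartitions(dm, taxa)
        assert bips == {frozenset({"C", "D"})}

    def test_missing_outgroup_rejected(self):
        msa = _signal_msa()
        with pytest.raises(ValueError, match="absent"):
            bootstrap_tree(msa, n_replicates=5, seed=1, outgroups=["nope"])


class TestMeanBS:
    def _tree(self, supports):
        taxa = list("abcdef") + ["og1", "og2", "og3"]
        return BootstrapTree(newick="", taxa=taxa,
                             outgroups=["og1", "og2", "og3"],
                             supports=supports)

    def test_all_hundred(self):
        t = self._tree({frozenset("ab"): 100, frozenset("abc"): 100})
        assert mean_bs(t) == 100.0

    def test_hand_arithmetic(self):
        t = self._tree({frozenset("ab"): 60, frozenset("cd"): 80,
                        frozenset("abc"): 100})
        assert mean_bs(t) == pytest.approx(80.0)

    def test_outgroup_edges_excluded(self):
        t = self._tree({frozenset("ab"): 60,
                        frozenset({"og1", "og2"}): 100,          # outgroup edge
                        frozenset("abcdef"): 100})               # root edge
        assert mean_bs(t) == 60.0
        assert mean_bs(t, scope="all") == pytest.approx((60 + 100 + 100) / 3)

    def test_no_ingroup_edges_rejected(self):
        t = self._tree({frozenset({"og1", "og2"}): 90})
        with pytest.raises(ValueError):
            mean_bs(t)


class TestPlateauAndRanking:
    def _result(self, loci, bs, length=100, sv=None):
        return CombinationResult(
            loci=tuple(loci), k=len(loci), concat_length=length,
            combo_sv=float(len(loci)) if sv is None else sv,
            tree=BootstrapTree("", [], []), mean_bs=bs)

    def test_constant_bs_gives_flat_fit_and_plateau_one(self):
        results = [self._result(c, 80.0)
                   for c in enumerate_combinations(["a", "b", "c"])]
        out = plateau_analysis(results)
        assert out["slope"] == 0.0
        assert out["plateau_k"] == 1

    def test_increasing_bs_moves_plateau_right(self):
        bs_by_k = {1: 50.0, 2: 65.0, 3: 71.0, 4: 71.5}
        results = [self._result(c, bs_by_k[len(c)])
                   for c in enumerate_combinations(list("abcd"))]
        out = plateau_analysis(results)
        assert out["plateau_k"] == 3
        assert out["slope"] > 0

    def test_tie_broken_by_smaller_k(self):
        r5 = self._result(list("abcde"), 90.0)
        r7 = self._result(list("abcdefg"), 90.0)
        top, recommended = top_combinations([r7, r5], n=10)
        assert top[0] is r5
        assert recommended is r5

    def test_top_n_larger_than_results(self):
        results = [self._result(["a"], 50.0), self._result(["b"], 60.0)]
        top, _ = top_combinations(results, n=10)
        assert len(top) == 2
        assert top[0].mean_bs == 60.0

    def test_constant_length_correlation_reported_as_nan(self):
        results = [self._result([c], 50.0 + i, length=100, sv=float(i))
                   for i, c in enumerate("abc")]
        out = combo_correlations(results)
        assert np.isnan(out["mean_bs_vs_concat_length"].statistic)
        assert not np.isnan(out["mean_bs_vs_combo_sv"].statistic)
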