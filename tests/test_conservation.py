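"""Branch-length scores, signal:background, P_CT, gene-count simulation."""

import itertools

import numpy as np
import pytest

from flyseed.conservation import (
    MultipleAlignment,
    BlsRecord,
    PctParameters,
    TreeIndex,
    aggregate_pct,
    bin_utrs,
    control_kmers,
    dinucleotide_conservation_rates,
    expected_kmer_conservation,
    fit_bin_trees,
    fit_pct_parameters,
    lower_confidence_limit,
    pct_score,
    signal_background_curve,
    simulate_conserved_gene_count,
    site_bls,
)
from flyseed.site_finder import Region, SiteMatch, SiteType, site_patterns
from flyseed.synthetic import evolve_alignment

from conftest import TOY_MIRNA, random_rna

FAMILY = TOY_MIRNA[1:8]
TOY_TREE = "((ref:0.1,A:0.2):0.05,(B:0.3,C:0.4):0.05);"
FLY_TREE = "((dmel:0.2,dsim:0.2):0.3,(dyak:0.4,dana:0.4):0.2,dpse:0.8);"


def _aln_with_site(species_with_site, length=60, start=20,
                   site_type=SiteType.EIGHTMER, tree_species=("ref", "A", "B", "C")):
    pat = site_patterns(FAMILY)[site_type]
    ref = "G" * start + pat + "G" * (length - start - len(pat))
    rows = {}
    for sp in tree_species:
        rows[sp] = ref if sp in species_with_site else "C" * len(ref)
    rows["ref"] = ref
    return MultipleAlignment(rows=rows, reference="ref")


def _site(start=20, site_type=SiteType.EIGHTMER):
    length = {SiteType.EIGHTMER: 8, SiteType.SEVENMER_M8: 7}[site_type]
    return SiteMatch("g", Region.UTR3, start, start + length, site_type, FAMILY)


class TestSpanningSubtree:
    def test_hand_computed_four_leaf_example(self):
        tree = TreeIndex.from_newick(TOY_TREE)
        assert tree.spanning_length({"ref", "A"}) == pytest.approx(0.3)

    def test_reference_only_scores_zero(self):
        tree = TreeIndex.from_newick(TOY_TREE)
        assert tree.spanning_length({"ref"}) == 0.0

    def test_all_species_span_the_whole_tree(self):
        tree = TreeIndex.from_newick(TOY_TREE)
        assert tree.spanning_length({"ref", "A", "B", "C"}) == pytest.approx(
            tree.total_length
        )

    def test_adding_a_species_never_decreases_the_score(self):
        tree = TreeIndex.from_newick(TOY_TREE)
        species = ["A", "B", "C"]
        for r in range(len(species) + 1):
            for subset in itertools.combinations(species, r):
                base = tree.spanning_length({"ref", *subset})
                for extra in set(species) - set(subset):
                    grown = tree.spanning_length({"ref", *subset, extra})
                    assert grown >= base - 1e-12
                assert 0.0 <= base <= tree.total_length + 1e-12


class TestSiteBls:
    def test_reference_only_site(self):
        tree = TreeIndex.from_newick(TOY_TREE)
        aln = _aln_with_site({"ref"})
        assert site_bls(_site(), aln, tree) == 0.0

    def test_site_in_ref_and_sister(self):
        tree = TreeIndex.from_newick(TOY_TREE)
        aln = _aln_with_site({"ref", "A"})
        assert site_bls(_site(), aln, tree) == pytest.approx(0.3)

    def test_site_in_all_species(self):
        tree = TreeIndex.from_newick(TOY_TREE)
        aln = _aln_with_site({"ref", "A", "B", "C"})
        assert site_bls(_site(), aln, tree) == pytest.approx(tree.total_length)

    def test_site_outside_alignment_rejected(self):
        tree = TreeIndex.from_newick(TOY_TREE)
        aln = _aln_with_site({"ref"})
        with pytest.raises(ValueError):
            site_bls(_site(start=70), aln, tree)


class TestBinning:
    def test_conservation_extremes_and_rank_order(self):
        tree = TreeIndex.from_newick(FLY_TREE)
        rng = np.random.default_rng(0)
        rates = np.linspace(2.0, 0.0, 10)  # strictly increasing conservation
        alignments = {}
        for i, rate in enumerate(rates):
            seq = random_rna(rng, 400)
            alignments[f"u{i}"] = evolve_alignment(
                seq, tree, rate=float(rate), reference="dmel", rng=rng
            )
        bins = bin_utrs(alignments, tree)
        ordered = [bins[f"u{i}"] for i in range(10)]
        assert ordered == sorted(ordered)
        assert ordered[0] == 1 and ordered[-1] == 5

    def test_missing_utr_falls_back_to_bin_one(self):
        tree = TreeIndex.from_newick(FLY_TREE)
        rng = np.random.default_rng(1)
        alignments = {
            f"u{i}": evolve_alignment(
                random_rna(rng, 100), tree, 0.5, reference="dmel", rng=rng
            )
            for i in range(5)
        }
        bins = bin_utrs(alignments, tree, utr_ids=["absent"])
        assert bins["absent"] == 1


class TestBranchLengthFitting:
    def test_identical_alignment_gives_near_zero_lengths(self):
        tree = TreeIndex.from_newick(FLY_TREE)
        rng = np.random.default_rng(2)
        aln = evolve_alignment(random_rna(rng, 500), tree, 0.0,
                               reference="dmel", rng=rng)
        fitted = fit_bin_trees([aln], tree)
        assert fitted.total_length <= 1e-5

    def test_recovery_within_ten_percent_at_10kb(self):
        tree = TreeIndex.from_newick(FLY_TREE)
        rng = np.random.default_rng(3)
        aln = evolve_alignment(random_rna(rng, 10000), tree, 1.0,
                               reference="dmel", rng=rng)
        fitted = fit_bin_trees([aln], tree)
        true = sorted(length for _, length in tree._edges)
        got = sorted(length for _, length in fitted._edges)
        for t, g in zip(true, got):
            assert g == pytest.approx(t, rel=0.10, abs=0.02)

    def test_doubling_the_rate_roughly_doubles_fitted_lengths(self):
        tree = TreeIndex.from_newick(FLY_TREE)
        rng = np.random.default_rng(4)
        seq = random_rna(rng, 8000)
        slow = fit_bin_trees(
            [evolve_alignment(seq, tree, 0.5, reference="dmel", rng=rng)], tree
        )
        fast = fit_bin_trees(
            [evolve_alignment(seq, tree, 1.0, reference="dmel", rng=rng)], tree
        )
        assert fast.total_length / slow.total_length == pytest.approx(2.0, rel=0.15)


class TestControlKmers:
    def _database(self, seed=0, n=60, length=120):
        rng = np.random.default_rng(seed)
        return [random_rna(rng, length) for _ in range(n)]

    def test_cardinality_and_exclusions(self):
        seqs = self._database()
        rates = {a + b: 0.5 for a in "ACGU" for b in "ACGU"}
        site = site_patterns(FAMILY)[SiteType.SEVENMER_M8]
        controls = control_kmers(site, seqs, rates, [FAMILY], n=50)
        assert len(controls) == 50
        assert site not in controls
        assert not any(c in site_patterns(FAMILY).values() for c in controls)

    def test_controls_bracket_the_site_expectation(self):
        seqs = self._database(seed=1)
        rng = np.random.default_rng(9)
        rates = {a + b: float(rng.uniform(0.2, 0.9)) for a in "ACGU" for b in "ACGU"}
        site = site_patterns(FAMILY)[SiteType.SEVENMER_M8]
        controls = control_kmers(site, seqs, rates, [], n=50)
        target = expected_kmer_conservation(site, rates)
        values = [expected_kmer_conservation(c, rates) for c in controls]
        assert min(values) <= target <= max(values)

    def test_fewer_candidates_than_requested_warns(self):
        rates = {a + b: 0.5 for a in "ACGU" for b in "ACGU"}
        with pytest.warns(UserWarning, match="control candidates"):
            out = control_kmers("ACGUACG", ["ACGUACGUA"], rates, n=50)
        assert len(out) < 50

    def test_dinucleotide_rates_from_perfect_conservation(self):
        aln = MultipleAlignment(
            rows={"ref": "ACGUACGU", "A": "ACGUACGU"}, reference="ref"
        )
        rates = dinucleotide_conservation_rates([aln])
        assert all(v == 1.0 for v in rates.values())


class TestSignalBackground:
    def test_cutoff_zero_counts_everything(self):
        site_vals = {1: np.array([0.5, 1.0, 2.0])}
        controls = {1: [np.array([0.5, 1.0, 2.0])] * 5}
        curve = signal_background_curve(
            FAMILY, SiteType.EIGHTMER, site_vals, controls, np.array([0.0, 1.0])
        )
        assert curve.signal[0] == 3
        # identical controls: background equals the site count exactly
        assert curve.ratio[0] == pytest.approx(1.0)

    def test_planted_conservation_gives_ratio_above_one(self):
        rng = np.random.default_rng(5)
        site_vals = {1: rng.uniform(1.5, 2.5, size=40)}  # deeply conserved
        controls = {1: [rng.uniform(0.0, 2.0, size=30) for _ in range(50)]}
        curve = signal_background_curve(
            FAMILY, SiteType.EIGHTMER, site_vals, controls,
            np.array([0.5, 1.0, 1.4]),
        )
        assert np.all(curve.ratio > 1.0)
        assert np.all(np.diff(curve.signal) <= 0)  # signal non-increasing

    def test_signal_above_is_negative_when_no_site_passes(self):
        site_vals = {1: np.array([0.1, 0.2])}
        controls = {1: [np.array([2.0, 2.0])] * 3}
        curve = signal_background_curve(
            FAMILY, SiteType.EIGHTMER, site_vals, controls, np.array([1.0])
        )
        assert curve.signal[0] == 0
        assert curve.signal_above[0] <= 0

    def test_zero_sites_yield_empty_curve(self):
        curve = signal_background_curve(
            FAMILY, SiteType.EIGHTMER, {}, {}, np.array([0.0, 1.0])
        )
        assert curve.cutoffs.size == 0

    def test_lower_confidence_limit(self):
        site_vals = {1: np.array([1.5, 1.5, 1.5])}
        identical = {1: [np.array([0.5])] * 4}
        curve = signal_background_curve(
            FAMILY, SiteType.EIGHTMER, site_vals, identical, np.array([1.0])
        )
        assert curve.background_sd[0] == 0.0
        assert lower_confidence_limit(curve)[0] == pytest.approx(
            curve.signal_above[0]
        )
        spread = {1: [np.full(4, v) for v in (0.0, 0.5, 1.0, 2.0)]}
        curve2 = signal_background_curve(
            FAMILY, SiteType.EIGHTMER, site_vals, spread, np.array([1.0])
        )
        assert lower_confidence_limit(curve2)[0] < curve2.signal_above[0]


class TestPct:
    def _params(self, signal, background, cutoffs=(0.0, 1.0, 2.0)):
        return fit_pct_parameters(
            FAMILY, SiteType.EIGHTMER,
            {1: (np.array(cutoffs), np.array(signal), np.array(background))},
        )

    def _record(self, bls):
        return BlsRecord(site=_site(), bls=bls, bin=1)

    def test_signal_equal_background_scores_zero(self):
        params = self._params([100, 100, 100], [100, 100, 100])
        assert pct_score(self._record(1.5), params) == 0.0

    def test_zero_background_scores_one(self):
        params = self._params([100, 80, 60], [0, 0, 0])
        assert pct_score(self._record(2.0), params) == 1.0

    def test_printed_ratio_example(self):
        params = self._params([200, 200, 200], [200, 50, 50])
        assert pct_score(self._record(1.0), params) == pytest.approx(0.75)

    def test_below_lowest_cutoff_scores_zero(self):
        params = self._params([100, 80, 60], [50, 20, 10], cutoffs=(1.0, 2.0, 3.0))
        assert pct_score(self._record(0.5), params) == 0.0

    def test_missing_curve_warns_and_scores_zero(self):
        with pytest.warns(UserWarning, match="no P_CT curve"):
            assert pct_score(self._record(1.0), PctParameters()) == 0.0

    def test_curves_are_monotone_even_for_noisy_input(self):
        params = self._params([100, 90, 80], [60, 10, 40])
        values = [pct_score(self._record(b), params) for b in (0.0, 1.0, 2.0)]
        assert values == sorted(values)
        assert all(0.0 <= v <= 1.0 for v in values)

    def test_aggregate_pct(self):
        assert aggregate_pct([0.6]) == pytest.approx(0.6)
        assert aggregate_pct([0.5, 0.5]) == pytest.approx(0.75)
        assert aggregate_pct([]) == 0.0
        sites = [0.2, 0.7, 0.4]
        assert aggregate_pct(sites) >= max(sites)


class TestGeneCountSimulation:
    def test_single_gene_pool(self):
        mean, (lo, hi) = simulate_conserved_gene_count(
            ["g1"] * 4, ["g1"] * 6, n5_dist=(2, 0.0), n3_dist=(3, 0.0),
            reps=200, seed=0,
        )
        assert mean == 1.0 and lo == hi == 1.0

    def test_matches_exact_enumeration_on_toy_pool(self):
        pool = ["g1", "g1", "g2", "g2", "g3", "g3"]
        n = 3
        subsets = list(itertools.combinations(range(6), n))
        exact = np.mean([len({pool[i] for i in s}) for s in subsets])
        mean, _ = simulate_conserved_gene_count(
            [], pool, n5_dist=(0, 0.0), n3_dist=(n, 0.0), reps=4000, seed=1
        )
        assert mean == pytest.approx(exact, abs=0.05)

    def test_fixed_seed_is_bitwise_reproducible(self):
        args = dict(n5_dist=(3, 1.0), n3_dist=(5, 1.0), reps=100)
        a = simulate_conserved_gene_count(
            ["a", "b"] * 3, ["c", "d", "e"] * 4, seed=42, **args
        )
        b = simulate_conserved_gene_count(
            ["a", "b"] * 3, ["c", "d", "e"] * 4, seed=42, **args
        )
        assert a == b
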