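"""Optimizer: objective, proposals, pre-selection and the hill climb."""

import itertools
import math

import numpy as np
import pytest

from codonlib import (
    AminoAcidDistribution,
    BaseCodon,
    InfeasibleTargetError,
    LibraryDesigner,
    SpikedCodon,
    benchmark,
    dist,
    encoded_symbols,
    excludes,
    mixture_distribution,
    preselect_pool,
    propose_codon,
    summarize_benchmark,
)
from codonlib.codons import STOP_CODONS, enumerate_base_codons

# A frozen 8-codon pool (stop-free) with the uniform target over the
# residues it can encode; small enough for exhaustive enumeration.
SMALL_POOL = ["WTB", "DHY", "RMS", "BTS", "VGT", "VTD", "TSS", "HKC"]


@pytest.fixture(scope="module")
def small_instance():
    pool = [BaseCodon.from_iupac(s) for s in SMALL_POOL]
    residues = sorted(set().union(*[encoded_symbols(b) for b in pool]) - {"*"})
    target = AminoAcidDistribution.uniform(residues)
    return pool, target


class TestDistance:
    def test_zero_at_the_optimum(self, code, target20):
        nnk = SpikedCodon.from_iupac("NNK")
        mix = mixture_distribution([nnk], code)
        assert dist(mix, [nnk]) == pytest.approx(0.0, abs=1e-12)
        assert dist(mix, [nnk], "L1") == pytest.approx(0.0, abs=1e-12)
        assert dist(mix, [nnk], "Linf") == pytest.approx(0.0, abs=1e-12)

    def test_uniform_vs_single_met_closed_form(self, target20):
        atg = SpikedCodon.from_iupac("ATG")
        expected = math.sqrt(0.95 ** 2 + 19 * 0.05 ** 2)
        assert dist(target20, [atg]) == pytest.approx(expected)
        assert dist(target20, [atg], "L1") == pytest.approx(0.95 + 19 * 0.05)
        assert dist(target20, [atg], "Linf") == pytest.approx(0.95)

    def test_norm_ordering(self, rng, target20):
        pool = enumerate_base_codons(forbidden=STOP_CODONS)
        for _ in range(25):
            m = [propose_codon(pool, "spiked", rng) for _ in range(4)]
            linf = dist(target20, m, "Linf")
            l2 = dist(target20, m, "L2")
            l1 = dist(target20, m, "L1")
            assert linf <= l2 + 1e-12 <= l1 + 1e-12

    def test_unknown_norm_rejected(self, target20):
        with pytest.raises(ValueError):
            dist(target20, [SpikedCodon.from_iupac("ATG")], norm="L3")


class TestProposals:
    def test_single_codon_pool_is_deterministic(self, rng):
        pool = [BaseCodon.from_codon("ATG")]
        c = propose_codon(pool, "degenerate", rng)
        assert c == SpikedCodon.from_iupac("ATG")

    def test_degenerate_proposals_are_equimolar(self, rng):
        pool = enumerate_base_codons(forbidden=STOP_CODONS)
        for _ in range(50):
            c = propose_codon(pool, "degenerate", rng)
            assert c.is_degenerate

    def test_spiked_flat_dirichlet_means(self, rng):
        """10^4 draws over NNS: mean fractions 1/4 at pos 1-2, 1/2 at pos 3."""
        pool = [BaseCodon.from_iupac("NNS")]
        draws = np.array([propose_codon(pool, "spiked", rng).fractions
                          for _ in range(10_000)])
        mean = draws.mean(axis=0).reshape(3, 4)
        se4 = math.sqrt(3 / 80) / 100  # SD of flat Dirichlet(1,1,1,1) comp.
        se2 = math.sqrt(1 / 12) / 100  # SD of Beta(1,1)
        assert np.all(np.abs(mean[:2] - 0.25) < 3 * se4)
        assert abs(mean[2, 1] - 0.5) < 3 * se2  # C
        assert abs(mean[2, 3] - 0.5) < 3 * se2  # G
        assert mean[2, 0] == mean[2, 2] == 0.0  # T, A off support

    def test_empty_pool_is_an_error(self, rng):
        with pytest.raises(InfeasibleTargetError):
            propose_codon([], "degenerate", rng)


class TestPreselection:
    def test_unconstrained_pool_is_3375(self):
        # Target with weight on all 21 symbols, stops allowed.
        target = AminoAcidDistribution.uniform(list("ACDEFGHIKLMNPQRSTVWY*"))
        pool = preselect_pool(target, forbid_stops=False)
        assert len(pool) == 3375

    def test_met_only_pool(self):
        target = AminoAcidDistribution.from_mapping({"M": 1.0})
        pool = preselect_pool(target)
        assert [b.to_iupac() for b in pool] == ["ATG"]

    def test_early_alphabet_pool_matches_bruteforce(self, code, target10):
        allowed = set(target10.support)
        oracle = [
            BaseCodon(bits) for bits in
            (b.bits for b in enumerate_base_codons())
            if all(code[c] in allowed for c in BaseCodon(bits).expand())
        ]
        pool = preselect_pool(target10)
        assert pool == oracle
        assert 0 < len(pool) < 3375

    def test_usage_filter_removes_rare_codons(self):
        target = AminoAcidDistribution.from_mapping({"L": 1.0})
        usage = {c: 0.5 for c in ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG")}
        usage["CTA"] = 0.01
        pool = preselect_pool(target, codon_usage=usage, min_usage=0.1)
        assert all(excludes(b, "CTA") for b in pool)

    def test_stop_weight_conflicts_with_forbidden_stops(self):
        target = AminoAcidDistribution.from_mapping({"M": 0.9, "*": 0.1})
        with pytest.raises(InfeasibleTargetError):
            preselect_pool(target, forbid_stops=True)


class TestOptimize:
    def test_unique_optimum_is_found_exactly(self):
        designer = LibraryDesigner({"M": 1.0}, 1, "degenerate")
        result = designer.fit(0)
        assert result.as_iupac() == "ATG"
        assert result.final_distance == pytest.approx(0.0, abs=1e-12)

    def test_small_instance_matches_exhaustive_oracle(self, small_instance):
        """l=2 over 8 codons: the hill climb finds the exhaustive optimum
        in at least 9 of 10 seeded runs."""
        pool, target = small_instance
        optimum = min(
            dist(target, [SpikedCodon.equimolar(a), SpikedCodon.equimolar(b)])
            for a, b in itertools.combinations_with_replacement(pool, 2)
        )
        designer = LibraryDesigner(target, 2, "degenerate", pool=pool)
        hits = sum(
            abs(designer.fit(seed).final_distance - optimum) < 1e-9
            for seed in range(10)
        )
        assert hits >= 9

    @pytest.mark.parametrize("mode", ["degenerate", "spiked"])
    def test_trace_monotone_and_distance_recomputable(self, mode, target10):
        designer = LibraryDesigner(target10, 8, mode)
        result = designer.fit(3)
        trace = np.array(result.distance_trace)
        assert (np.diff(trace) <= 1e-15).all()
        recomputed = dist(result.target, result.multiset, designer.norm)
        assert result.final_distance == pytest.approx(recomputed, abs=1e-12)
        assert result.final_distance == pytest.approx(trace[-1], rel=1e-9)

    def test_no_forbidden_codon_is_producible(self, target20):
        forbidden = {"GGG", "AAA", "CTG"}
        designer = LibraryDesigner(target20, 6, "spiked", forbidden=forbidden)
        result = designer.fit(11)
        for codon in result.multiset:
            for f in forbidden | STOP_CODONS:
                assert excludes(codon, f)

    def test_result_mixture_is_a_distribution(self, target10):
        result = LibraryDesigner(target10, 5, "spiked").fit(2)
        assert result.achieved.weights.sum() == pytest.approx(1.0)
        assert (result.achieved.weights >= 0).all()

    @pytest.mark.parametrize("mode", ["degenerate", "spiked"])
    def test_seeded_determinism(self, mode, target10):
        designer = LibraryDesigner(target10, 5, mode)
        a, b = designer.fit(99), designer.fit(99)
        assert a.multiset == b.multiset
        assert a.final_distance == b.final_distance
        assert a.distance_trace == b.distance_trace
        assert a.accepted_count == b.accepted_count

    def test_rejection_budget_scales_with_length(self, target10):
        result = LibraryDesigner(target10, 3, "degenerate",
                                 rejection_factor=10).fit(0)
        # The final run of consecutive rejections is at most the budget.
        assert result.rejected_count >= 10 * 3

    def test_infeasible_residue_reported(self):
        pool = [BaseCodon.from_codon("ATG")]
        with pytest.raises(InfeasibleTargetError, match="W"):
            LibraryDesigner({"M": 0.5, "W": 0.5}, 2, "degenerate", pool=pool)

    def test_spiked_not_worse_than_degenerate_on_average(self, target20):
        """Paired seeded replicates: free nucleotide ratios achieve at
        least the precision of equimolar codons."""
        deg = LibraryDesigner(target20, 10, "degenerate").fit_replicates(10, 0)
        spk = LibraryDesigner(target20, 10, "spiked").fit_replicates(10, 0)
        assert spk.distances.mean() <= deg.distances.mean()

    def test_replicates_bookkeeping(self, target10):
        reps = LibraryDesigner(target10, 4, "degenerate").fit_replicates(3, 5)
        assert [r.seed for r in reps.results] == [5, 6, 7]
        assert reps.best.final_distance == reps.distances.min()
        frame = reps.summary_frame()
        assert list(frame.columns) == ["replicate", "seed", "distance", "accepted"]

    def test_summary_contains_key_fields(self, target10):
        result = LibraryDesigner(target10, 3, "degenerate").fit(1)
        text = result.summary()
        assert "L2 distance" in text and "spiked" not in text
        assert result.as_iupac() in text


class TestBenchmark:
    def test_single_replicate_reduces_to_one_fit(self, target10):
        frame = benchmark({"early10": target10}, [3], replicates=1,
                          mode="degenerate", seed=4)
        assert len(frame) == 1
        direct = LibraryDesigner(target10, 3, "degenerate").fit(4)
        assert frame["distance"].iloc[0] == pytest.approx(direct.final_distance)

    def test_tidy_output_and_summary(self, target10):
        frame = benchmark({"early10": target10}, [2, 4], replicates=2,
                          mode="degenerate", seed=0)
        assert set(frame.columns) == {"distribution_id", "length", "replicate",
                                      "mode", "seed", "distance"}
        assert len(frame) == 4
        summary = summarize_benchmark(frame)
        assert {"mean", "cv"}.issubset(summary.columns)
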