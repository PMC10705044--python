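"""Paired rarefaction, transcript:gene ratios, and the active-community caller."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from granulefate.active_community import (
    CountMatrix,
    PairedLibraries,
    active_relative_abundance,
    aggregate_family,
    call_active,
    diversity_indices,
    pair_samples,
    rarefy,
    ratio_one_trial,
)
from granulefate.errors import PairingError, RarefactionError


class TestRarefy:
    def test_full_depth_is_identity(self):
        counts = np.array([5, 0, 12, 3])
        assert (rarefy(counts, 20, seed=0) == counts).all()

    def test_depth_one_is_single_read(self):
        out = rarefy(np.array([5, 0, 12, 3]), 1, seed=0)
        assert out.sum() == 1 and (out >= 0).all() and (out <= 1).all()

    def test_depth_exceeding_total_raises(self):
        with pytest.raises(RarefactionError):
            rarefy(np.array([1, 2]), 10, seed=0)

    def test_sum_is_exact_and_seed_deterministic(self, rng):
        counts = rng.integers(0, 500, size=30)
        for depth in (1, 10, int(counts.sum() // 2)):
            a = rarefy(counts, depth, seed=42)
            assert a.sum() == depth
            assert (a == rarefy(counts, depth, seed=42)).all()
        assert (rarefy(counts, 100, seed=1) != rarefy(counts, 100, seed=2)).any()

    def test_hypergeometric_expectation(self):
        """Mean rarefied count over many trials matches depth * proportion."""
        counts = np.array([40, 25, 20, 10, 5])
        depth, trials = 30, 10000
        rng = np.random.default_rng(7)
        acc = np.zeros(len(counts))
        for _ in range(trials):
            acc += rarefy(counts, depth, rng)
        mean = acc / trials
        p = counts / counts.sum()
        expect = depth * p
        # hypergeometric variance, finite-population corrected
        n = counts.sum()
        var = depth * p * (1 - p) * (n - depth) / (n - 1)
        se = np.sqrt(var / trials)
        assert (np.abs(mean - expect) <= 3 * se).all()


class TestRatioOneTrial:
    def _pair(self, dna, cdna):
        idx = [f"z{i}" for i in range(len(dna))]
        return PairedLibraries(
            "s", pd.Series(dna, index=idx), pd.Series(cdna, index=idx)
        )

    def test_identical_vectors_give_unit_ratios(self):
        pair = self._pair([10, 20, 30], [10, 20, 30])
        r = ratio_one_trial(pair, 60, 60, seed=0)  # full depth: deterministic
        assert np.allclose(r.to_numpy(), 1.0)

    def test_phantom_gets_one_hundred(self):
        pair = self._pair([50, 0], [20, 50])
        r = ratio_one_trial(pair, 50, 70, seed=0)
        assert r["z1"] == 100.0

    def test_absent_taxon_has_no_value(self):
        pair = self._pair([50, 0], [50, 0])
        r = ratio_one_trial(pair, 50, 50, seed=0)
        assert np.isnan(r["z1"])

    def test_unequal_depths_use_relative_abundance(self):
        # composition identical, depths differ 10x: ratios still 1
        pair = self._pair([100, 300], [10, 30])
        r = ratio_one_trial(pair, 400, 40, seed=0)
        assert np.allclose(r.to_numpy(), 1.0)


class TestCallActive:
    def test_structural_phantom_always_active(self, tiny_pair):
        dna, cdna = tiny_pair
        for seed in (0, 1, 99):
            for depth in (20, 50, None):
                calls = call_active(
                    dna, cdna, n_trials=10, depth=depth, seed=seed
                )
                ph = calls[calls["zotu_id"] == "d"]
                assert (ph["mean_ratio"] == 100.0).all()
                assert ph["active"].all()

    def test_infinite_threshold_empties_active_set(self, tiny_pair):
        dna, cdna = tiny_pair
        calls = call_active(dna, cdna, n_trials=5, threshold=np.inf, seed=0)
        assert not calls["active"].any()

    def test_seed_determinism_and_seed_sensitivity(self, tiny_pair):
        dna, cdna = tiny_pair
        a = call_active(dna, cdna, n_trials=20, depth=30, seed=5)
        b = call_active(dna, cdna, n_trials=20, depth=30, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_sample_mismatch_raises(self, tiny_pair):
        dna, cdna = tiny_pair
        clipped = CountMatrix(
            cdna.counts[["s1"]], "cDNA", cdna.sample_meta.loc[["s1"]]
        )
        with pytest.raises(PairingError):
            call_active(dna, clipped, n_trials=2)

    def test_strong_composition_ratio_called_active(self):
        """A taxon with 3x transcript:gene composition at depth 5000 is
        essentially always active (Monte-Carlo check on the full caller)."""
        rng = np.random.default_rng(0)
        n = 20
        base = np.full(n, 1 / n)
        cdna_comp = base.copy()
        cdna_comp[0] *= 3.0
        cdna_comp /= cdna_comp.sum()
        hits = 0
        for rep in range(20):
            dna_counts = rng.multinomial(5000, base)
            cdna_counts = rng.multinomial(5000, cdna_comp)
            idx = [f"z{i}" for i in range(n)]
            meta = pd.DataFrame({"reactor": ["t"], "day": [0]}, index=["s"])
            dna = CountMatrix(pd.DataFrame({"s": dna_counts}, index=idx), "DNA", meta)
            cdna = CountMatrix(pd.DataFrame({"s": cdna_counts}, index=idx), "cDNA", meta)
            calls = call_active(dna, cdna, n_trials=25, seed=rep)
            hits += int(calls.loc[calls["zotu_id"] == "z0", "active"].iloc[0])
        assert hits >= 19


class TestComposition:
    def test_single_active_zotu_has_abundance_one(self, tiny_pair):
        dna, _ = tiny_pair
        calls = pd.DataFrame(
            {
                "sample_id": ["s1"] * 4,
                "zotu_id": ["a", "b", "c", "d"],
                "mean_ratio": [2.0, 0.5, 0.1, 100.0],
                "active": [True, False, False, False],
                "dna_reads": [60, 30, 10, 0],
            }
        )
        comp = active_relative_abundance(calls, dna)
        assert comp.loc["a", "s1"] == 1.0
        assert comp.loc["b", "s1"] == 0.0

    def test_abundances_sum_to_one_when_active_nonempty(self, community):
        calls = call_active(
            community.dna["test"], community.cdna["test"], n_trials=10, seed=0
        )
        comp = active_relative_abundance(calls, community.dna["test"])
        sums = comp.sum(axis=0)
        assert np.allclose(sums.dropna(), 1.0)

    def test_empty_active_set_flagged_as_nan(self, tiny_pair):
        dna, _ = tiny_pair
        calls = pd.DataFrame(
            {
                "sample_id": ["s1"], "zotu_id": ["a"], "mean_ratio": [0.2],
                "active": [False], "dna_reads": [60],
            }
        )
        comp = active_relative_abundance(calls, dna)
        assert comp["s1"].isna().all()

    def test_ranking_matches_truth_on_strong_compositions(self, community):
        """Active-community abundance ranking mirrors the DNA read ranking
        restricted to the active set (sanity on simulated truth)."""
        dna = community.dna["control"]
        calls = call_active(dna, community.cdna["control"], n_trials=10, seed=3)
        comp = active_relative_abundance(calls, dna)
        sid = comp.columns[0]
        active = calls[(calls["sample_id"] == sid) & calls["active"]]["zotu_id"]
        reads = dna.counts.loc[active, sid]
        abund = comp.loc[active, sid]
        assert (reads.rank().sort_index() == abund.rank().sort_index()).all()


class TestFamiliesAndDiversity:
    def test_family_partition_preserves_sums(self, community):
        dna = community.dna["test"]
        comp = dna.counts / dna.counts.sum(axis=0)
        fam = aggregate_family(comp, community.taxonomy)
        assert np.allclose(fam.full.sum(axis=0), comp.sum(axis=0))

    def test_reporting_filter_drops_only_rare_families(self):
        comp = pd.DataFrame(
            {"s1": [0.995, 0.005], "s2": [0.995, 0.005]},
            index=["z1", "z2"],
        )
        tax = pd.DataFrame(
            {"zotu_id": ["z1", "z2"], "family": ["Big", "Rare"]}
        )
        fam = aggregate_family(comp, tax, min_plot_abundance=0.01)
        assert set(fam.full.index) == {"Big", "Rare"}
        assert set(fam.reporting.index) == {"Big"}

    def test_all_one_family(self):
        comp = pd.DataFrame({"s1": [0.6, 0.4]}, index=["z1", "z2"])
        tax = pd.DataFrame({"zotu_id": ["z1", "z2"], "family": ["F", "F"]})
        fam = aggregate_family(comp, tax)
        assert fam.full.loc["F", "s1"] == pytest.approx(1.0)

    def test_unlabelled_zotu_goes_unclassified(self):
        comp = pd.DataFrame({"s1": [1.0]}, index=["zX"])
        tax = pd.DataFrame({"zotu_id": ["zY"], "family": ["F"]})
        fam = aggregate_family(comp, tax)
        assert fam.full.index.tolist() == ["unclassified"]

    def test_diversity_closed_forms(self):
        meta = pd.DataFrame({"reactor": ["t"] * 3, "day": [0, 1, 2]},
                            index=["s1", "s2", "s3"])
        counts = pd.DataFrame(
            {"s1": [100, 0, 0, 0], "s2": [25, 25, 25, 25], "s3": [0, 0, 0, 0]},
            index=list("abcd"),
        )
        div = diversity_indices(CountMatrix(counts, "DNA", meta))
        assert div.loc["s1", "richness"] == 1
        assert div.loc["s1", "shannon"] == 0.0
        assert div.loc["s2", "shannon"] == pytest.approx(np.log(4))
        assert np.isnan(div.loc["s3", "shannon"])

    def test_shannon_matches_hand_formula(self, rng, community):
        dna = community.dna["test"]
        div = diversity_indices(dna)
        sid = dna.sample_ids[0]
        p = dna.counts[sid].to_numpy(dtype=float)
        p = p[p > 0] / p.sum()
        assert div.loc[sid, "shannon"] == pytest.approx(-np.sum(p * np.log(p)))
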