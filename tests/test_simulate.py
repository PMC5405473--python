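"""Coalescent generator: neutral expectations, regimes, bundle round-trips."""

import numpy as np
import pandas as pd
import pytest

from tajscan.contrasts import ExpressionClass
from tajscan.popgen import mean_pairwise_differences, tajima_constants, tajimas_d
from tajscan.simulate import (Mutation, Regime, SimSpec, drop_mutations,
                              emit_genome_bundle, make_regime_map,
                              plant_expression_classes, simulate_genealogy)


def sites_from_mutations(muts, n):
    from tajscan.popgen import SiteAlleleCounts
    out = []
    for m in muts:
        k = len(m.carriers)
        out.append(SiteAlleleCounts(m.position, (n - k, k)))
    return out


class TestGenealogy:
    def test_pair_mean_height_is_one(self, rng):
        heights = [simulate_genealogy(2, rng=rng).height for _ in range(10_000)]
        assert np.mean(heights) == pytest.approx(1.0, abs=0.03)

    def test_neutral_total_length_expectation(self, rng):
        # E[L] = 2 * a1(n); for n = 10 that is 5.658
        a1 = tajima_constants(10).a1
        lengths = [simulate_genealogy(10, rng=rng).total_length
                   for _ in range(10_000)]
        assert np.mean(lengths) == pytest.approx(2 * a1, rel=0.02)

    def test_star_all_pairwise_distances_equal(self, rng):
        tree = simulate_genealogy(8, Regime.SWEEP, rng=rng)
        dists = {round(tree.pairwise_distance(i, j), 12)
                 for i in range(8) for j in range(i + 1, 8)}
        assert len(dists) == 1

    def test_branch_count_and_leaf_partition(self, rng):
        tree = simulate_genealogy(6, rng=rng)
        # 2(n-1) branches for a binary rooted tree without the root branch
        assert len(tree.branches) == 10
        singletons = [b for b in tree.branches if len(b.leaves) == 1]
        assert len(singletons) == 6

    def test_balancing_stretches_root_children(self, rng):
        seed_rng = np.random.default_rng(123)
        neutral = simulate_genealogy(10, Regime.NEUTRAL,
                                     rng=np.random.default_rng(99))
        stretched = simulate_genealogy(10, Regime.BALANCING, stretch=5.0,
                                       rng=np.random.default_rng(99))
        assert stretched.total_length > neutral.total_length
        assert stretched.height > neutral.height


class TestDropMutations:
    def test_zero_theta_no_mutations(self, rng):
        tree = simulate_genealogy(10, rng=rng)
        assert drop_mutations(tree, 0.0, 1000, rng) == []

    def test_mean_segregating_sites_theta_a1(self, rng):
        # E[S] = theta * a1(n) under the per-window scaled coalescent
        theta, n = 5.0, 10
        a1 = tajima_constants(n).a1
        total = 0
        reps = 5000
        for _ in range(reps):
            tree = simulate_genealogy(n, rng=rng)
            total += len(drop_mutations(tree, theta, 1000, rng))
        assert total / reps == pytest.approx(theta * a1, rel=0.03)

    def test_star_genealogy_all_singletons_negative_d(self, rng):
        n = 10
        tree = simulate_genealogy(n, Regime.SWEEP, rng=rng)
        muts = drop_mutations(tree, 20.0, 1000, rng)
        assert all(len(m.carriers) == 1 for m in muts)
        sites = sites_from_mutations(muts, n)
        k = mean_pairwise_differences(sites, n)
        d = tajimas_d(len(muts), k, n)
        assert d.value < -1.0

    def test_positions_unique_and_inside_window(self, rng):
        tree = simulate_genealogy(10, rng=rng)
        muts = drop_mutations(tree, 50.0, 200, rng)
        positions = [m.position for m in muts]
        assert len(set(positions)) == len(positions)
        assert all(0 <= p < 200 for p in positions)
        assert positions == sorted(positions)

    def test_saturation_caps_at_window_length(self, rng):
        tree = simulate_genealogy(10, rng=rng)
        muts = drop_mutations(tree, 10_000.0, 20, rng)
        assert len(muts) <= 20


class TestRegimeSeparation:
    def test_mean_d_ordering(self, rng):
        n, theta = 10, 5.0
        means = {}
        for regime in Regime:
            ds = []
            for _ in range(500):
                tree = simulate_genealogy(n, regime, stretch=5.0, rng=rng)
                muts = drop_mutations(tree, theta, 1000, rng)
                if not muts:
                    continue
                sites = sites_from_mutations(muts, n)
                d = tajimas_d(len(muts),
                              mean_pairwise_differences(sites, n), n)
                if d.value is not None:
                    ds.append(d.value)
            means[regime] = np.mean(ds)
        assert means[Regime.BALANCING] > means[Regime.NEUTRAL] > means[Regime.SWEEP]


class TestBundle:
    def test_identical_seed_byte_identical(self, tmp_path):
        spec = SimSpec(contig_lengths=(20_000,), n_genes=10, seed=5)
        b1 = emit_genome_bundle(spec, tmp_path / "a")
        b2 = emit_genome_bundle(spec, tmp_path / "b")
        for attr in ("fasta", "fai", "vcf", "mask_bed", "gff3",
                     "windows_truth", "genes_truth"):
            assert getattr(b1, attr).read_bytes() == getattr(b2, attr).read_bytes()

    def test_different_seed_differs(self, tmp_path):
        s1 = SimSpec(contig_lengths=(20_000,), n_genes=10, seed=5)
        s2 = SimSpec(contig_lengths=(20_000,), n_genes=10, seed=6)
        b1 = emit_genome_bundle(s1, tmp_path / "a")
        b2 = emit_genome_bundle(s2, tmp_path / "b")
        assert b1.vcf.read_bytes() != b2.vcf.read_bytes()

    def test_masked_fraction_near_target(self, tmp_path):
        spec = SimSpec(contig_lengths=(100_000,), masked_fraction=0.2,
                       n_genes=10, seed=3)
        b = emit_genome_bundle(spec, tmp_path / "m")
        bed = pd.read_csv(b.mask_bed, sep="\t",
                          names=["chrom", "start", "end"])
        frac = (bed["end"] - bed["start"]).sum() / 100_000
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_theta_sweep_monotone_in_s(self, tmp_path):
        means = []
        for theta in (1.0, 5.0, 20.0):
            spec = SimSpec(contig_lengths=(50_000,), theta_per_window=theta,
                           n_genes=5, seed=11)
            b = emit_genome_bundle(spec, tmp_path / f"t{theta}")
            truth = pd.read_csv(b.windows_truth, sep="\t")
            means.append(truth["n_mutations"].mean())
        assert means[0] < means[1] < means[2]

    def test_regime_map_recorded_in_truth(self, tmp_path):
        spec = SimSpec(contig_lengths=(10_000,), n_genes=2, seed=1,
                       regime_map={0: Regime.BALANCING, 3: Regime.SWEEP})
        b = emit_genome_bundle(spec, tmp_path / "r")
        truth = pd.read_csv(b.windows_truth, sep="\t")
        assert truth.loc[0, "regime"] == "balancing"
        assert truth.loc[3, "regime"] == "sweep"
        assert truth.loc[1, "regime"] == "neutral"


class TestRegimeMap:
    def test_fractions_respected(self, rng):
        m = make_regime_map(10_000, 0.1, 0.2, rng)
        counts = pd.Series([r.value for r in m.values()]).value_counts()
        assert counts["balancing"] / 10_000 == pytest.approx(0.1, abs=0.02)
        assert counts["sweep"] / 10_000 == pytest.approx(0.2, abs=0.02)

    def test_invalid_fractions_rejected(self, rng):
        with pytest.raises(ValueError):
            make_regime_map(10, 0.7, 0.7, rng)


class TestPlantExpression:
    def test_infinite_enrichment_all_balancing_differential(self, planted_bundle, rng):
        _, bundle = planted_bundle
        table = plant_expression_classes(bundle.genes_truth, float("inf"), rng)
        truth = pd.read_csv(bundle.genes_truth, sep="\t",
                            keep_default_na=False)
        for _, r in truth.iterrows():
            if "balancing" in str(r["regimes"]).split(","):
                assert table[r["gene_id"]] is ExpressionClass.DIFFERENTIAL

    def test_neutral_multiplier_independent_of_regime(self, planted_bundle):
        from tajscan.contrasts import ContingencyTable2x2, chi_square_2x2
        _, bundle = planted_bundle
        truth = pd.read_csv(bundle.genes_truth, sep="\t",
                            keep_default_na=False)
        balancing = {r["gene_id"] for _, r in truth.iterrows()
                     if "balancing" in str(r["regimes"]).split(",")}
        nonsig = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            table = plant_expression_classes(bundle.genes_truth, 1.0, rng)
            a = sum(1 for g in balancing
                    if table[g] is ExpressionClass.DIFFERENTIAL)
            b = len(balancing) - a
            c = sum(1 for g, v in table.items()
                    if g not in balancing and v is ExpressionClass.DIFFERENTIAL)
            d = len(table) - len(balancing) - c
            try:
                p = chi_square_2x2(ContingencyTable2x2(a, b, c, d)).p_value
            except ValueError:
                continue
            if p >= 0.05:
                nonsig += 1
        assert nonsig >= 16  # ~95% of calibrated replicates non-significant
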