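"""Synthetic genome/group/contact-map generators and fixture bundles."""

import numpy as np
import pytest
from scipy import stats as sps

from cofunc.genome import linear_distance, load_family_table, load_gene_positions
from cofunc.groups import load_groups
from cofunc.spatial import load_contact_map
from cofunc.stats import chromosomes_involved
from cofunc.synthetic import (
    SyntheticConfig,
    choose_planted_pairs,
    generate_contact_map,
    generate_families,
    generate_genome,
    generate_groups,
    write_fixture_bundle,
)


class TestGenerateGenome:
    def test_counts_and_ordering(self):
        cfg = SyntheticConfig(n_chromosomes=2, genes_per_chromosome=(50, 50), seed=0)
        layout = generate_genome(cfg)
        assert layout.n_genes == 100
        for c in layout.chromosome_names:
            starts = [g.start for g in layout.genes_on(c)]
            ends = [g.end for g in layout.genes_on(c)]
            assert all(a < b for a, b in zip(starts, starts[1:]))
            assert all(e <= s for e, s in zip(ends, starts[1:]))  # no overlap

    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(seed=7)
        assert generate_genome(cfg) == generate_genome(cfg)
        assert generate_genome(cfg) != generate_genome(SyntheticConfig(seed=8))

    def test_gap_mean_recovered(self):
        cfg = SyntheticConfig(
            n_chromosomes=1, genes_per_chromosome=(1000,), gap_mean=30_000, seed=1
        )
        layout = generate_genome(cfg)
        genes = layout.genes_on("chr1")
        gaps = [b.start - a.end for a, b in zip(genes, genes[1:])]
        se = np.std(gaps) / np.sqrt(len(gaps))
        assert abs(np.mean(gaps) - 30_000) <= 3 * se


class TestGenerateGroups:
    def test_null_and_zero_rho_planted_agree_in_distribution(self):
        cfg = SyntheticConfig(n_groups=200, rho=0.0, seed=5)
        layout = generate_genome(cfg)
        null = generate_groups(layout, cfg, "null", seed=100)
        planted = generate_groups(layout, cfg, "chrom_concentrated", seed=200)
        a = [chromosomes_involved(g, layout) for g in null]
        b = [chromosomes_involved(g, layout) for g in planted]
        assert sps.ks_2samp(a, b).pvalue > 0.01

    def test_full_rho_concentrates_on_one_chromosome(self):
        cfg = SyntheticConfig(n_groups=30, rho=1.0, seed=6)
        layout = generate_genome(cfg)
        coll = generate_groups(layout, cfg, "chrom_concentrated")
        assert all(chromosomes_involved(g, layout) == 1 for g in coll)

    def test_full_rho_linear_window_bounds_pair_distances(self):
        cfg = SyntheticConfig(
            n_groups=25, rho=1.0, window_fraction=0.3,
            group_size_min=2, group_size_max=4, seed=7,
        )
        layout = generate_genome(cfg)
        coll = generate_groups(layout, cfg, "linear_clustered")
        for group in coll:
            genes = [layout.get(m) for m in group.members]
            chrom = genes[0].chromosome
            window = cfg.window_fraction * layout.genes_on(chrom)[-1].end
            for i, a in enumerate(genes):
                for b in genes[i + 1:]:
                    d = linear_distance(a, b)
                    assert d is not None and d <= window

    def test_oversized_group_errors(self):
        cfg = SyntheticConfig(
            n_chromosomes=1, genes_per_chromosome=(5,), group_size_min=6,
            group_size_max=6, n_groups=1, seed=0,
        )
        layout = generate_genome(cfg)
        with pytest.raises(ValueError, match="size"):
            generate_groups(layout, cfg, "null")

    def test_ppi_type_gives_pairs(self):
        cfg = SyntheticConfig(group_type="ppi", n_groups=10, seed=1)
        layout = generate_genome(cfg)
        coll = generate_groups(layout, cfg, "null")
        assert all(g.size == 2 for g in coll)


class TestGenerateContactMap:
    def test_sigma_zero_planted_pairs_look_like_background(self):
        cfg = SyntheticConfig(sigma=0.0, seed=8)
        layout = generate_genome(cfg)
        coll = generate_groups(layout, cfg, "null")
        planted = choose_planted_pairs(layout, coll, cfg)
        cmap = generate_contact_map(layout, cfg, planted)
        D = cmap.distance_matrix()
        inter = np.zeros_like(D, dtype=bool)
        b0, n0 = cmap.chrom_block(cmap.chromosome_names[0])
        inter[b0 : b0 + n0, b0 + n0 :] = True
        planted_d = np.array([D[a, b] for a, b in planted])
        background = D[inter]
        background = background[~np.isnan(background)]
        se = background.std() / np.sqrt(len(planted_d))
        assert abs(planted_d.mean() - background.mean()) <= 3 * se

    def test_sigma_one_planted_pairs_attain_minimum(self):
        cfg = SyntheticConfig(sigma=1.0, noise=0.0, seed=9)
        layout = generate_genome(cfg)
        coll = generate_groups(layout, cfg, "null")
        planted = choose_planted_pairs(layout, coll, cfg, n_pairs=5)
        cmap = generate_contact_map(layout, cfg, planted)
        D = cmap.distance_matrix()
        inter_min = np.inf
        for i in range(cmap.n_segments):
            for j in range(i + 1, cmap.n_segments):
                if cmap.chroms[i] != cmap.chroms[j] and not np.isnan(D[i, j]):
                    inter_min = min(inter_min, D[i, j])
        for a, b in planted:
            assert D[a, b] == pytest.approx(inter_min, abs=1e-9)
            assert D[a, b] == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_decay_is_monotone(self):
        cfg = SyntheticConfig(
            n_chromosomes=1, genes_per_chromosome=(80,), noise=0.0,
            segment_size=200_000, min_overlap=5, seed=10,
        )
        layout = generate_genome(cfg)
        cmap = generate_contact_map(layout, cfg)
        D = cmap.distance_matrix()
        n = cmap.n_segments
        means = [
            np.nanmean([D[i, i + s] for i in range(n - s)])
            for s in range(1, n // 2)
        ]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_planted_intra_pair_rejected(self):
        cfg = SyntheticConfig(seed=11)
        layout = generate_genome(cfg)
        with pytest.raises(ValueError, match="intra"):
            generate_contact_map(layout, cfg, [(0, 1)])


class TestFixtureBundle:
    def test_round_trip_identity(self, tmp_path):
        cfg = SyntheticConfig(n_groups=8, group_type="complex", seed=12)
        layout = generate_genome(cfg)
        families = generate_families(layout, cfg)
        coll = generate_groups(layout, cfg, "null")
        cmap = generate_contact_map(layout, cfg)
        manifest = write_fixture_bundle(layout, families, [coll], cmap, tmp_path)
        assert load_gene_positions(tmp_path / manifest["genome"], "bed") == layout
        assert load_family_table(tmp_path / manifest["families"]) == families
        back = load_groups(
            tmp_path / manifest["groups_complex"], "gmt", "complex"
        )
        assert [g.members for g in back] == [g.members for g in coll]
        assert load_contact_map(
            tmp_path / manifest["contact_map"], "dense_tsv",
            cfg.segment_size, cfg.min_overlap,
        ).equals(cmap)

    def test_empty_collection_list_noted(self, tmp_path):
        cfg = SyntheticConfig(seed=13)
        layout = generate_genome(cfg)
        manifest = write_fixture_bundle(layout, {}, [], None, tmp_path)
        assert manifest["groups"] == ""
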