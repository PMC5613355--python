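"""Generator contracts: layout fractions and determinism, per-molecule mark
configurations under the three generative modes, and pull-down sampling
against closed-form enumeration oracles."""

import numpy as np
import pytest

import duomark as dm
from duomark.synthetic_data import (CONFIG_BOTH, CONFIG_K9, CONFIG_K36,
                                    CONFIG_NONE, READ_LENGTH, ReaderModel,
                                    _STATE_INDEX)


def layout_fingerprint(layout):
    return (layout.regions.to_csv(), layout.gene_table.to_csv(),
            layout.factor_sites.df.to_csv())


class TestBuildLayout:
    def test_state_base_fractions_match_config(self):
        cfg = dm.SimConfig(chrom_sizes={"c1": 5_000_000, "c2": 5_000_000},
                           seed=7)
        fr = dm.build_layout(cfg).state_base_fractions()
        for name, target in zip(("neither", "k9_only", "k36_only", "bivalent"),
                                cfg.state_fractions):
            assert abs(fr[name] - target) < 0.02
        assert 0.13 <= fr["bivalent"] <= 0.17

    def test_degenerate_fractions_all_neither(self):
        cfg = dm.SimConfig(chrom_sizes={"c1": 1_000_000},
                           state_fractions=(1.0, 0.0, 0.0, 0.0),
                           n_factor_sites=0, seed=3)
        layout = dm.build_layout(cfg)
        assert set(layout.regions["state"]) == {"neither"}

    def test_fixed_seed_reproducible(self, small_config):
        a = dm.build_layout(small_config)
        b = dm.build_layout(small_config)
        assert layout_fingerprint(a) == layout_fingerprint(b)

    def test_chromosome_too_short_raises_with_name(self):
        cfg = dm.SimConfig(seed=1)
        cfg.chrom_sizes = {"tiny": 1_000}
        with pytest.raises(ValueError, match="tiny"):
            dm.build_layout(cfg)

    def test_regions_tile_without_gaps(self, small_layout, small_config):
        for chrom, L in small_config.chrom_sizes.items():
            sub = small_layout.regions[small_layout.regions["chrom"] == chrom]
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == L
            assert (sub["start"].iloc[1:].to_numpy()
                    == sub["end"].iloc[:-1].to_numpy()).all()

    def test_low_expression_genes_sit_in_bivalent_regions(self, small_layout):
        groups = dict(zip(small_layout.gene_table["gene_id"],
                          small_layout.gene_table["group"]))
        by_state = {}
        for gene in small_layout.genes:
            mid = (gene.start + gene.end) // 2
            hit = small_layout.regions[
                (small_layout.regions["chrom"] == gene.chrom)
                & (small_layout.regions["start"] <= mid)
                & (small_layout.regions["end"] > mid)]
            by_state.setdefault(hit["state"].iloc[0], []).append(
                groups[gene.gene_id])
        assert set(by_state["bivalent"]) <= {"low_1", "low_2"}
        assert set(by_state["k36_only"]) <= {"medium", "high"}

    def test_factor_sites_track_configured_bivalent_fraction(self):
        cfg = dm.SimConfig(seed=9, n_factor_sites=400,
                           factor_bivalent_fraction=0.6)
        layout = dm.build_layout(cfg)
        frac = dm.fraction_sites_overlaid(layout.factor_sites,
                                          layout.state_peaks("bivalent"))
        se = np.sqrt(0.6 * 0.4 / 400)
        assert abs(frac - 0.6) <= 3 * se


class TestPopulateMolecules:
    def test_unknown_mode_rejected(self, small_layout, small_config):
        with pytest.raises(ValueError, match="unknown mode"):
            dm.populate_molecules(small_layout, "blend", small_config)

    def test_counts_sum_to_molecules_per_position(self, small_layout,
                                                  small_config):
        pop = dm.populate_molecules(small_layout, "coexistence", small_config)
        assert (pop.counts.sum(axis=1) >= 1).all()
        assert (pop.counts >= 0).all()

    def test_coexistence_saturating_density_all_both(self):
        cfg = dm.SimConfig(chrom_sizes={"c": 400_000}, mod_density=1.0,
                           occupancy_sigma=0.0, n_factor_sites=10, seed=5)
        layout = dm.build_layout(cfg)
        pop = dm.populate_molecules(layout, "coexistence", cfg)
        biv = pop.region_state == _STATE_INDEX["bivalent"]
        assert (pop.counts[biv, CONFIG_BOTH]
                == pop.counts[biv].sum(axis=1)).all()
        assert pop.counts[biv, CONFIG_K9].sum() == 0

    def test_mixture_never_double_marks_and_splits_evenly(self):
        cfg = dm.SimConfig(chrom_sizes={"c": 2_000_000}, mod_density=1.0,
                           occupancy_sigma=0.0, n_factor_sites=10, seed=5)
        layout = dm.build_layout(cfg)
        pop = dm.populate_molecules(layout, "mixture", cfg)
        biv = pop.region_state == _STATE_INDEX["bivalent"]
        n_k9 = int(pop.counts[biv, CONFIG_K9].sum())
        n_k36 = int(pop.counts[biv, CONFIG_K36].sum())
        assert int(pop.counts[biv, CONFIG_BOTH].sum()) == 0
        # binomial oracle: each marked molecule is K9 or K36 with equal odds
        total = n_k9 + n_k36
        se = np.sqrt(total * 0.25)
        assert abs(n_k9 - total / 2) <= 3 * se

    def test_default_density_recovered_in_k9_regions(self, small_layout,
                                                     small_config):
        pop = dm.populate_molecules(small_layout, "coexistence", small_config)
        k9 = pop.region_state == _STATE_INDEX["k9_only"]
        marked = int(pop.counts[k9, CONFIG_K9].sum())
        molecules = int(pop.counts[k9].sum())
        d = small_config.mod_density
        se = np.sqrt(d * (1 - d) / molecules)
        assert abs(marked / molecules - d) <= 3 * se

    def test_adjacent_mode_alternates_pure_positions(self):
        cfg = dm.SimConfig(chrom_sizes={"c": 1_000_000}, occupancy_sigma=0.0,
                           n_factor_sites=10, seed=5)
        layout = dm.build_layout(cfg)
        pop = dm.populate_molecules(layout, "adjacent", cfg)
        biv = np.flatnonzero(pop.region_state == _STATE_INDEX["bivalent"])
        assert int(pop.counts[biv, CONFIG_BOTH].sum()) == 0
        # no single position carries molecules of both marks
        both_kinds = ((pop.counts[biv, CONFIG_K9] > 0)
                      & (pop.counts[biv, CONFIG_K36] > 0))
        assert not both_kinds.any()
        assert pop.counts[biv, CONFIG_K9].sum() > 0
        assert pop.counts[biv, CONFIG_K36].sum() > 0

    def test_single_mark_regions_identical_across_modes(self, small_layout,
                                                        small_config):
        pops = {m: dm.populate_molecules(small_layout, m, small_config)
                for m in ("coexistence", "mixture", "adjacent")}
        nonbiv = pops["coexistence"].region_state != _STATE_INDEX["bivalent"]
        for m in ("mixture", "adjacent"):
            assert (pops[m].counts[nonbiv]
                    == pops["coexistence"].counts[nonbiv]).all()

    def test_double_marked_never_exceed_k9_carrying(self, small_layout,
                                                    small_config):
        for mode in ("coexistence", "mixture"):
            pop = dm.populate_molecules(small_layout, mode, small_config)
            k9_total, _ = pop.marginal_mark_counts()
            assert int(pop.counts[:, CONFIG_BOTH].sum()) <= k9_total


class TestReaderModels:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            ReaderModel("bad", 0.0, 1.5, 0.1, 0.9)

    def test_wt_reader_satisfies_and_logic_ordering(self):
        r = dm.wt_and_reader()
        assert r.p_both > r.p_k9 >= r.p_k36 >= r.p_none

    def test_and_logic_check_rejects_or_table(self):
        with pytest.raises(ValueError, match="AND-logic"):
            dm.or_reader().check_and_logic()


class TestSimulatePulldown:
    @pytest.fixture
    def flat_pop(self):
        cfg = dm.SimConfig(chrom_sizes={"c": 1_000_000}, occupancy_sigma=0.0,
                           n_factor_sites=10, seed=5)
        layout = dm.build_layout(cfg)
        return dm.populate_molecules(layout, "coexistence", cfg)

    def test_zero_depth_gives_empty_readset(self, flat_pop):
        rs = dm.simulate_pulldown(flat_pop, dm.wt_and_reader(), 0, seed=1)
        assert len(rs) == 0

    def test_empty_captured_pool_raises(self, flat_pop):
        dead = ReaderModel("dead", 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="background"):
            dm.simulate_pulldown(flat_pop, dead, 100, seed=1)

    def test_and_reader_read_share_matches_weighted_enumeration(self):
        # 50/50 both/K9-only pool: expected read share from doubly modified
        # molecules is p_both / (p_both + p_k9) = 0.8/1.1
        cfg = dm.SimConfig(chrom_sizes={"c": 2_000_000}, mod_density=1.0,
                           state_fractions=(0.0, 0.5, 0.0, 0.5),
                           occupancy_sigma=0.0, n_factor_sites=10, seed=5)
        layout = dm.build_layout(cfg)
        pop = dm.populate_molecules(layout, "coexistence", cfg)
        reader = ReaderModel("wt0", 0.0, 0.3, 0.0, 0.8)
        depth = 50_000
        rs = dm.simulate_pulldown(pop, reader, depth, seed=9)
        share = float((rs.configs == CONFIG_BOTH).mean())
        expected = 0.8 / 1.1
        se = np.sqrt(expected * (1 - expected) / depth) + 0.01
        assert abs(share - expected) <= 3 * se

    def test_k36_pocket_dead_reader_blind_to_second_mark(self):
        # equal-sized bivalent and K9-only territory: a K9-only readout
        # yields a 1:1 read split between them
        cfg = dm.SimConfig(chrom_sizes={"c": 2_000_000},
                           state_fractions=(0.0, 0.5, 0.0, 0.5),
                           occupancy_sigma=0.0, n_factor_sites=10, seed=5)
        layout = dm.build_layout(cfg)
        pop = dm.populate_molecules(layout, "coexistence", cfg)
        # background capture off so the enumeration is exactly a 1:1 split
        reader = dm.pwwp_dead_reader(background=0.0)
        rs = dm.simulate_pulldown(pop, reader, 40_000, seed=9)
        from_biv = float((rs.configs == CONFIG_BOTH).mean())
        assert abs(from_biv - 0.5) <= 3 * np.sqrt(0.25 / 40_000) + 0.02

    def test_reads_have_nucleosome_footprints_inside_genome(self, flat_pop):
        rs = dm.simulate_pulldown(flat_pop, dm.wt_and_reader(), 5_000, seed=2)
        assert ((rs.df["end"] - rs.df["start"]) == READ_LENGTH).all()
        assert (rs.df["start"] >= 0).all()
        assert (rs.df["end"] <= 1_000_000).all()

    def test_fixed_seed_reproducible(self, flat_pop):
        a = dm.simulate_pulldown(flat_pop, dm.wt_and_reader(), 5_000, seed=3)
        b = dm.simulate_pulldown(flat_pop, dm.wt_and_reader(), 5_000, seed=3)
        assert a.df.equals(b.df)


class TestSequentialAndInput:
    @pytest.fixture
    def layout_cfg(self):
        cfg = dm.SimConfig(chrom_sizes={"c": 2_000_000}, occupancy_sigma=0.0,
                           n_factor_sites=10, seed=5)
        return cfg, dm.build_layout(cfg)

    def test_identity_second_reader_matches_single_pulldown_composition(
            self, layout_cfg):
        cfg, layout = layout_cfg
        pop = dm.populate_molecules(layout, "coexistence", cfg)
        passthrough = ReaderModel("all", 1.0, 1.0, 1.0, 1.0)
        seq = dm.simulate_sequential(pop, dm.k9_single_reader(), passthrough,
                                     40_000, seed=4)
        single = dm.simulate_pulldown(pop, dm.k9_single_reader(), 40_000,
                                      seed=4)
        for cfg_code in (CONFIG_NONE, CONFIG_K9, CONFIG_BOTH):
            a = float((seq.configs == cfg_code).mean())
            b = float((single.configs == cfg_code).mean())
            assert abs(a - b) < 0.02

    def test_mixture_sequential_yields_no_double_marked_reads(self, layout_cfg):
        cfg, layout = layout_cfg
        pop = dm.populate_molecules(layout, "mixture", cfg)
        seq = dm.simulate_sequential(pop, dm.k9_single_reader(),
                                     dm.k36_single_reader(), 20_000, seed=4)
        assert int((seq.configs == CONFIG_BOTH).sum()) == 0

    def test_coexistence_sequential_concentrates_on_double_marked(
            self, layout_cfg):
        cfg, layout = layout_cfg
        pop = dm.populate_molecules(layout, "coexistence", cfg)
        seq = dm.simulate_sequential(pop, dm.k9_single_reader(),
                                     dm.k36_single_reader(), 20_000, seed=4)
        assert float((seq.configs == CONFIG_BOTH).mean()) > 0.9

    def test_input_counts_poisson_like_over_uniform_population(self):
        cfg = dm.SimConfig(chrom_sizes={"c": 1_000_000}, occupancy_sigma=0.0,
                           n_factor_sites=10, seed=5)
        layout = dm.build_layout(cfg)
        pop = dm.populate_molecules(layout, "coexistence", cfg)
        depth = 50_000
        inp = dm.simulate_input(pop, depth, seed=6)
        bins = dm.tile_genome(cfg.chrom_sizes, 10_000)
        counts = dm.count_reads(inp, bins)
        lam = depth / bins.n_bins
        # Poisson oracle: variance/mean ratio near 1, means near lambda
        assert abs(counts.mean() - lam) < 4 * np.sqrt(lam / bins.n_bins)
        assert 0.7 < counts.var() / counts.mean() < 1.4

    def test_input_zero_depth_empty_and_seeded(self, layout_cfg):
        cfg, layout = layout_cfg
        pop = dm.populate_molecules(layout, "coexistence", cfg)
        assert len(dm.simulate_input(pop, 0, seed=1)) == 0
        a = dm.simulate_input(pop, 1_000, seed=2)
        b = dm.simulate_input(pop, 1_000, seed=2)
        assert a.df.equals(b.df)


class TestModeInvariants:
    def test_wt_reader_captures_more_under_coexistence_than_mixture(
            self, small_layout, small_config):
        # expected captured molecules, by enumeration over the count tables
        p = dm.wt_and_reader().probabilities
        expected = {}
        for mode in ("coexistence", "mixture"):
            pop = dm.populate_molecules(small_layout, mode, small_config)
            expected[mode] = float((pop.counts * p[np.newaxis, :]).sum())
        assert expected["coexistence"] > expected["mixture"]

    def test_presence_maps_cannot_distinguish_modes(self, small_config):
        """Single-mark state maps agree across generative modes (the premise
        that simple overlap cannot separate coexistence from mixture)."""
        from duomark import state_caller as st

        layout = dm.build_layout(small_config)
        bins = dm.tile_genome(small_config.chrom_sizes, 3_000)
        maps = {}
        for mode in ("coexistence", "mixture", "adjacent"):
            pop = dm.populate_molecules(layout, mode, small_config)
            k9 = dm.simulate_pulldown(pop, dm.k9_single_reader(), 100_000,
                                      seed=1)
            k36 = dm.simulate_pulldown(pop, dm.k36_single_reader(), 100_000,
                                       seed=2)
            inp = dm.simulate_input(pop, 300_000, seed=3)
            ti = dm.quantify(inp, bins)
            e9 = dm.enrichment_over_input(dm.quantify(k9, bins), ti)
            e36 = dm.enrichment_over_input(dm.quantify(k36, bins), ti)
            sv = st.classify_states(
                st.call_presence(e9, st.MARK_PRESENCE),
                st.call_presence(e36, st.MARK_PRESENCE), bins)
            maps[mode] = sv.states
        agree_mix = float((maps["coexistence"] == maps["mixture"]).mean())
        agree_adj = float((maps["coexistence"] == maps["adjacent"]).mean())
        assert agree_mix > 0.95
        assert agree_adj > 0.95
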