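"""Generator contracts: determinism, placement, kinetics, conservation."""

import math

import numpy as np
import pytest
from scipy import stats

from h3turnover.genomic import GenomicInterval
from h3turnover.simulate import (SimConfig, SiteTruth, build_genome,
                                 expected_occupancy, simulate_dataset,
                                 simulate_marks, simulate_timecourse)
from conftest import small_config


class TestConfig:
    def test_default_time_points(self):
        cfg = SimConfig()
        assert list(cfg.time_points_h) == [0, 1, 2, 3, 4, 5, 6, 12, 18, 24, 48, 72]

    @pytest.mark.parametrize("bad", [
        dict(time_points_h=(1, 2, 3)),                # must start at 0
        dict(time_points_h=(0, 2, 2, 4)),             # strictly increasing
        dict(rate_fast=(0.01, 0.02)),                 # not above intermediate
        dict(depth_per_library=0),
        dict(mark_coupling={"H3K4me9": {}}),          # unknown mark
    ])
    def test_invalid_configs(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=5)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestBuildGenome:
    def test_no_genes_only_repeat_sites(self):
        cfg = small_config(n_genes=0, n_enhancers=0)
        g = build_genome(cfg)
        assert all(s.klass in ("telomere_slow", "trna_fast", "rrna_intermediate")
                   for s in g.sites)

    def test_deterministic_serialization(self):
        cfg = small_config(seed=7)
        a = build_genome(cfg).serialize()
        b = build_genome(small_config(seed=7)).serialize()
        assert a == b
        assert build_genome(small_config(seed=8)).serialize() != a

    def test_genebody_sites_inside_genes(self):
        """Exhaustive containment: every gene-body site within its gene span."""
        g = build_genome(small_config(seed=2))
        spans = {gene.name: (gene.start, gene.end) for gene in g.genes}
        body_sites = [s for s in g.sites if s.klass == "genebody_intermediate"]
        assert body_sites
        for s in body_sites:
            lo, hi = spans[s.gene]
            assert lo <= s.site.start and s.site.end <= hi

    def test_expressed_genes_have_promoter_sites(self):
        g = build_genome(small_config(seed=2))
        prom = {s.gene for s in g.sites if s.klass == "promoter_fast"}
        expressed = {x.name for x in g.genes if (x.expression or 0) > 0}
        assert prom == expressed

    def test_telomere_blocks_abut_ends_and_carry_slow_sites(self):
        cfg = small_config(seed=2)
        g = build_genome(cfg)
        tel = [iv for iv, c in g.repeat_blocks if c == "telomere"]
        for chrom, L in g.chromosomes.items():
            starts = {t.start for t in tel if t.chrom == chrom}
            ends = {t.end for t in tel if t.chrom == chrom}
            assert 0 in starts and L in ends
        tel_sites = [s for s in g.sites if s.klass == "telomere_slow"]
        assert len(tel_sites) == 2 * cfg.n_chromosomes * cfg.sites_per_telomere
        for s in tel_sites:
            assert any(t.overlap(s.site) == s.site.length for t in tel)

    def test_sizing_error_names_feature(self):
        cfg = small_config(genome_length=400_000, n_genes=200)
        with pytest.raises(ValueError, match="gene"):
            build_genome(cfg)

    def test_every_gene_has_exons(self):
        g = build_genome(small_config(seed=4))
        assert all(len(x.exons) >= 1 for x in g.genes)

    def test_rate_class_ordering(self):
        g = build_genome(SimConfig(seed=1))
        by = {}
        for s in g.sites:
            by.setdefault(s.klass, []).append(s.k)
        assert np.mean(by["promoter_fast"]) > np.mean(by["genebody_intermediate"]) \
            > np.mean(by["telomere_slow"])


class TestExpectedOccupancy:
    def _site(self, A, k):
        return SiteTruth(GenomicInterval("chr1", 0, 100), "enhancer_fast", k, A)

    def test_zero_time(self):
        assert expected_occupancy(self._site(1.0, 2.0), 0.0) == 0.0

    def test_half_life_identity(self):
        s = self._site(1.0, math.log(2) / 1.5)
        assert expected_occupancy(s, 1.5) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # A(1 - e^{-kt}) at A=2, k=0.1, t=10 ~= 1.2642, against an
        # independently evaluated closed form
        s = self._site(2.0, 0.1)
        expected = float(2 * (1 - np.exp(-1.0)))
        assert expected_occupancy(s, 10.0) == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_saturating(self):
        s = self._site(1.7, 0.3)
        t = np.linspace(0, 100, 200)
        occ = np.array([expected_occupancy(s, x) for x in t])
        assert np.all(np.diff(occ) >= 0)
        assert occ[-1] == pytest.approx(1.7, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            expected_occupancy(self._site(1, 1), -0.1)

    def test_pericentromere_silent(self):
        s = SiteTruth(GenomicInterval("chr1", 0, 100), "pericentromere_none", 1.0, 1.0)
        assert expected_occupancy(s, 100.0) == 0.0


class TestSimulateTimecourse:
    def test_depth_conserved(self, small_dataset):
        cfg = small_dataset.config
        for lib in small_dataset.chip_libs:
            assert lib.total_mapped == cfg.depth_per_library
        assert small_dataset.input_lib.total_mapped == cfg.depth_per_library

    def test_time_zero_is_background_only(self, small_dataset):
        """No site holds more reads at t=0 than a generous Poisson bound."""
        lib0 = [lb for lb in small_dataset.chip_libs if lb.hours == 0][0]
        g = small_dataset.genome
        G = sum(g.chromosomes.values())
        from h3turnover.genomic import count_tags
        for s in g.sites:
            lam = lib0.total_mapped * s.site.length / G
            bound = stats.poisson.ppf(1 - 1e-6, lam)
            assert count_tags(lib0, s.site, shift=small_dataset.config.shift) <= bound

    def test_zero_weights_rejected(self):
        """At t=0 with zero background no read can be allocated anywhere."""
        cfg = small_config(background_fraction=0.0, n_genes=0, n_enhancers=4,
                           n_trna=0, n_rrna=0, sites_per_telomere=0)
        g = build_genome(cfg)
        with pytest.raises(ValueError, match="background"):
            simulate_timecourse(g, cfg)

    def test_fast_slow_ratio_binomial_oracle(self):
        """Two equal-amplitude sites at saturation split reads by length."""
        cfg = small_config(n_genes=0, n_enhancers=0, n_trna=0, n_rrna=0,
                          sites_per_telomere=0, background_fraction=0.01,
                          depth_per_library=20_000, time_points_h=(0, 36, 72))
        g = build_genome(cfg)
        s1 = SiteTruth(GenomicInterval("chr1", 100_000, 101_000), "enhancer_fast", 1.0, 1.0)
        s2 = SiteTruth(GenomicInterval("chr1", 300_000, 303_000), "trna_fast", 1.2, 1.0)
        g.sites.extend([s1, s2])
        from h3turnover.genomic import count_tags
        devs = []
        for seed in range(20):
            libs, _ = simulate_timecourse(g, cfg, seed_offset=seed)
            last = libs[-1]
            c1 = count_tags(last, s1.site, cfg.shift)
            c2 = count_tags(last, s2.site, cfg.shift)
            n, p = c1 + c2, 1 / 4  # length ratio 1:3
            devs.append(abs(c1 - n * p) / math.sqrt(n * p * (1 - p)))
        assert np.mean(devs) < 3

    def test_read_share_decline_of_fast_site(self, default_dataset):
        """Expected fast-site reads at 72 h sit below the per-course maximum."""
        from h3turnover.genomic import count_tags
        g = default_dataset.genome
        fast = [s for s in g.sites if s.klass == "promoter_fast"][:20]
        declined = 0
        for s in fast:
            series = [count_tags(lb, s.site, default_dataset.config.shift)
                      for lb in default_dataset.chip_libs]
            if series[-1] < max(series):
                declined += 1
        assert declined >= 15  # decline is the rule, not the exception


class TestSimulateMarks:
    def test_degenerate_probability_one(self):
        cfg = small_config(seed=9)
        for m in cfg.mark_coupling:
            cfg.mark_coupling[m] = {"promoter_fast": 1.0}
        g = build_genome(cfg)
        ms = simulate_marks(g, cfg)
        prom = [s for s in g.sites if s.klass == "promoter_fast"]
        for mark, ivs in ms.items():
            for s in prom:
                assert mark in s.marks
                assert any(iv.overlap(s.site) > 0 for iv in ivs)

    def test_probability_zero_empty_on_sites(self):
        cfg = small_config(seed=9)
        for m in cfg.mark_coupling:
            cfg.mark_coupling[m] = {}
        g = build_genome(cfg)
        simulate_marks(g, cfg)
        assert all(not s.marks for s in g.sites)

    def test_binomial_assignment_fraction(self):
        """Coupling 0.8 over ~200 fast sites lands within 3 binomial SDs."""
        cfg = small_config(seed=11, n_genes=0, n_enhancers=200,
                           genome_length=4_000_000, enhancer_slow_fraction=0.0)
        cfg.mark_coupling = {"H3K27ac": {"enhancer_fast": 0.8}}
        g = build_genome(cfg)
        simulate_marks(g, cfg)
        enh = [s for s in g.sites if s.klass == "enhancer_fast"]
        frac = np.mean([("H3K27ac" in s.marks) for s in enh])
        assert abs(frac - 0.8) <= 3 * math.sqrt(0.8 * 0.2 / len(enh))

    def test_unknown_mark_rejected(self):
        cfg = small_config()
        cfg.mark_coupling["H4K20me3"] = {}
        g_cfg_err = pytest.raises(ValueError)
        with g_cfg_err:
            cfg.validate()


class TestSimulateExpression:
    def test_inactive_gene_rpkm_zero(self, small_dataset):
        tab = small_dataset.rpkm.set_index("gene")
        for gene in small_dataset.genome.genes:
            if (gene.expression or 0) == 0:
                assert tab.loc[gene.name, "rpkm"] == 0

    def test_rna_reads_confined_to_exons(self, small_dataset):
        g = small_dataset.genome
        rna = small_dataset.rna_lib
        exonic = {}
        for gene in g.genes:
            for ex in gene.exons:
                exonic.setdefault(gene.chrom, []).append((ex.start, ex.end))
        for code, name in enumerate(rna.chrom_names):
            for p in rna.pos[rna.chrom_codes == code][:500]:
                assert any(s <= p < e for s, e in exonic.get(name, []))

    def test_rpkm_formula_by_hand(self, small_dataset):
        """RPKM recomputed from reads, exonic kb and library total."""
        tab = small_dataset.rpkm
        total = tab["reads"].sum()
        for _, row in tab.iterrows():
            if row["reads"] == 0:
                continue
            expected = row["reads"] / (row["exonic_kb"] * total / 1e6)
            assert row["rpkm"] == pytest.approx(expected, rel=1e-12)

    def test_amplitude_monotone_in_expression(self):
        from h3turnover.simulate import _expression_amplitude_factor
        xs = np.linspace(0, 100, 50)
        fs = [_expression_amplitude_factor(x) for x in xs]
        assert all(b >= a for a, b in zip(fs, fs[1:]))


class TestDatasetBundle:
    def test_write_dataset_round_trip(self, small_dataset, tmp_path):
        from h3turnover.simulate import write_dataset
        from h3turnover.genomic import read_tag_bed, read_refflat, read_bed
        paths = write_dataset(small_dataset, tmp_path)
        lib = read_tag_bed(paths["chip_72h"], hours=72)
        assert lib.total_mapped == small_dataset.config.depth_per_library
        genes = read_refflat(paths["genes"])
        assert len(genes) == len(small_dataset.genome.genes)
        repeats = read_bed(paths["repeats"])
        assert len(repeats) == len(small_dataset.genome.repeat_blocks)

    def test_bit_identical_reruns(self):
        cfg = small_config(seed=17)
        a = simulate_dataset(cfg)
        b = simulate_dataset(small_config(seed=17))
        assert a.genome.serialize() == b.genome.serialize()
        for la, lb in zip(a.chip_libs, b.chip_libs):
            assert np.array_equal(la.pos, lb.pos)
            assert np.array_equal(la.chrom_codes, lb.chrom_codes)
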