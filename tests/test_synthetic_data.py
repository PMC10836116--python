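import numpy as np
import pandas as pd
import pytest

from apa_rhythm.synthetic_data import (
    SimConfig,
    circadian_design,
    full_design,
    simulate_counts,
    simulate_fastq,
    simulate_genome,
    simulate_tags,
    write_gtf,
)


class TestConfigValidation:
    def test_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(pas_per_gene_probs=(0.5, 0.5, 0.5, 0.0))

    def test_amplitude_range(self):
        with pytest.raises(ValueError, match="amplitude"):
            SimConfig(rel_amplitude_range=(0.5, 1.5))

    def test_layout_budget(self):
        with pytest.raises(ValueError, match="too small"):
            SimConfig(n_genes=100, chrom_length_nt=1000)

    def test_negative_jitter(self):
        with pytest.raises(ValueError):
            SimConfig(tag_jitter_sd_nt=-1.0)


class TestSimulateGenome:
    def test_degenerate_distribution_single_pas(self):
        cfg = SimConfig(seed=1, n_genes=30, pas_per_gene_probs=(1, 0, 0, 0))
        _, truth = simulate_genome(cfg)
        assert len(truth) == 30
        assert (truth["region"] == "utr3_terminal").all()

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=99, n_genes=25)
        g1, t1 = simulate_genome(cfg)
        g2, t2 = simulate_genome(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        write_gtf(g1, str(tmp_path / "a.gtf"))
        write_gtf(g2, str(tmp_path / "b.gtf"))
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_mean_pas_per_gene(self):
        # E[n_pas] = 0.55 + 2*0.26 + 3*0.12 + 4*0.07 = 1.71 (direct-draw oracle)
        cfg = SimConfig(seed=5, n_genes=200, pas_per_gene_probs=(0.55, 0.26, 0.12, 0.07))
        _, truth = simulate_genome(cfg)
        assert truth.groupby("gene_id").size().mean() == pytest.approx(1.71, abs=0.15)

    def test_pas_spacing_over_25(self):
        cfg = SimConfig(seed=2, n_genes=60, pas_per_gene_probs=(0, 0, 0, 1))
        _, truth = simulate_genome(cfg)
        for _, grp in truth.groupby("gene_id"):
            coords = np.sort(grp["coord"].to_numpy())
            assert (np.diff(coords) > 25).all()

    def test_pas_within_gene_or_distal_window(self):
        cfg = SimConfig(seed=3, n_genes=50, pas_per_gene_probs=(0, 0, 0, 1))
        genes, truth = simulate_genome(cfg)
        spans = {g.gene_id: (g.span, g.strand, g.terminus) for g in genes}
        for r in truth.itertuples():
            (lo, hi), strand, term = spans[r.gene_id]
            if lo <= r.coord <= hi:
                continue
            d = r.coord - term if strand == "+" else term - r.coord
            assert 0 < d <= 5000


class TestSimulateCounts:
    def test_null_model_amplitude_centered_on_zero(self, circ_samples):
        from apa_rhythm.detectors import cosinor_matrix
        from apa_rhythm.rhythm import condition_hours

        cfg = SimConfig(seed=4, n_genes=150, frac_cycling_24=0.0, frac_cycling_12=0.0)
        _, truth = simulate_genome(cfg)
        counts = simulate_counts(cfg, circ_samples, truth)
        hours = np.array([condition_hours(s.condition) for s in circ_samples])
        # amplitude relative to mean should scatter around 0
        rel = (
            cosinor_matrix(hours, counts.to_numpy(float), 24.0)["amplitude"]
            / np.maximum(counts.to_numpy(float).mean(axis=1), 1)
        )
        assert np.median(rel) < 0.2

    def test_poisson_limit(self):
        # dispersion -> 0 with equal libraries: var/mean -> 1 over >= 1e4 draws
        cfg = SimConfig(seed=6, n_genes=1, nb_dispersion=0.0)
        truth = pd.DataFrame(
            [{"pas_id": f"p{i}", "gene_id": "G", "chrom": "chr1", "strand": "+",
              "coord": 100, "region": "utr3_terminal", "period": 0,
              "rel_amplitude": 0.0, "phase_h": 0.0, "sd_log2fc": 0.0,
              "base_mean": 100.0} for i in range(400)]
        )
        samples = circadian_design([10_000_000] * 30)
        counts = simulate_counts(cfg, samples, truth)
        vals = counts.to_numpy(float).ravel()  # 12,000 draws at mu = 100
        assert vals.var() / vals.mean() == pytest.approx(1.0, abs=0.05)

    def test_cosinor_mean_formula(self):
        # m=100, a=0.5, phi=6, T=24 at ZT6 and library 1e7 -> mean 150
        cfg = SimConfig(seed=8, n_genes=1, nb_dispersion=0.0)
        truth = pd.DataFrame(
            [{"pas_id": f"p{i}", "gene_id": "G", "chrom": "chr1", "strand": "+",
              "coord": 100, "region": "utr3_terminal", "period": 24,
              "rel_amplitude": 0.5, "phase_h": 6.0, "sd_log2fc": 0.0,
              "base_mean": 100.0} for i in range(4000)]
        )
        samples = [s for s in circadian_design([10_000_000] * 30) if s.condition == "ZT6"]
        counts = simulate_counts(cfg, samples, truth)
        assert counts.to_numpy().mean() == pytest.approx(150.0, rel=0.02)

    def test_sd_effect_applied(self):
        cfg = SimConfig(seed=9, n_genes=1, nb_dispersion=0.0, sd_effect_log2fc=2.0)
        truth = pd.DataFrame(
            [{"pas_id": f"p{i}", "gene_id": "G", "chrom": "chr1", "strand": "+",
              "coord": 100, "region": "utr3_terminal", "period": 0,
              "rel_amplitude": 0.0, "phase_h": 0.0, "sd_log2fc": 2.0,
              "base_mean": 50.0} for i in range(2000)]
        )
        samples = full_design([10_000_000] * 55)
        counts = simulate_counts(cfg, samples, truth)
        r0 = [s.sample_id for s in samples if s.condition == "R0"]
        zt6 = [s.sample_id for s in samples if s.condition == "ZT6"]
        ratio = counts[r0].to_numpy().mean() / counts[zt6].to_numpy().mean()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_amplitude_above_one_rejected(self, circ_samples):
        cfg = SimConfig(seed=10, n_genes=5)
        _, truth = simulate_genome(cfg)
        truth.loc[truth.index[0], "rel_amplitude"] = 1.5
        with pytest.raises(ValueError, match="negative NB mean"):
            simulate_counts(cfg, circ_samples, truth)


class TestSimulateTags:
    def test_jitter_zero_exact(self, small_config, circ_samples):
        _, truth = simulate_genome(small_config)
        counts = simulate_counts(small_config, circ_samples, truth)
        tags = simulate_tags(small_config, truth, counts)
        coords = dict(zip(truth["pas_id"], truth["coord"]))
        sites_by_pas = {}
        for t in tags:
            sites_by_pas.setdefault((t.chrom, t.site), 0)
        truth_sites = {(r.chrom, r.coord) for r in truth.itertuples()}
        assert set(sites_by_pas) <= truth_sites

    def test_conservation(self, small_config, circ_samples):
        _, truth = simulate_genome(small_config)
        counts = simulate_counts(small_config, circ_samples, truth)
        tags = simulate_tags(small_config, truth, counts)
        per_sample = {}
        for t in tags:
            per_sample[t.sample_id] = per_sample.get(t.sample_id, 0) + 1
        for s in circ_samples:
            assert per_sample.get(s.sample_id, 0) == counts[s.sample_id].sum()

    def test_zero_counts_no_tags(self, small_config, circ_samples):
        _, truth = simulate_genome(small_config)
        counts = simulate_counts(small_config, circ_samples, truth)
        counts.iloc[:, :] = 0
        assert simulate_tags(small_config, truth, counts) == []

    def test_jitter_bounded_and_mostly_close(self, circ_samples):
        cfg = SimConfig(seed=11, n_genes=10, tag_jitter_sd_nt=3.0)
        _, truth = simulate_genome(cfg)
        counts = simulate_counts(cfg, circ_samples, truth)
        tags = simulate_tags(cfg, truth, counts)
        coords = {
            (r.chrom, r.strand, r.gene_id, r.region): r.coord for r in truth.itertuples()
        }
        truth_by_site = {}
        for r in truth.itertuples():
            truth_by_site.setdefault((r.chrom, r.strand), []).append(r.coord)
        devs = []
        for t in tags[:2000]:
            nearest = min(abs(t.site - c) for c in truth_by_site[(t.chrom, t.strand)])
            devs.append(nearest)
        devs = np.array(devs)
        assert devs.max() <= 12
        assert (devs <= 10).mean() >= 0.99


class TestSimulateFastq:
    def test_no_prefix_mode(self, tmp_path):
        cfg = SimConfig(seed=12, t_prefix_prob=0.0)
        truth = simulate_fastq(cfg, str(tmp_path / "r.fq"), n_reads=200)
        assert (~truth["has_prefix"]).all()
        seqs = (tmp_path / "r.fq").read_text().splitlines()[1::4]
        assert all(not s.startswith("TTT") for s in seqs)

    def test_all_prefixed(self, tmp_path):
        cfg = SimConfig(seed=13, t_prefix_prob=1.0)
        truth = simulate_fastq(cfg, str(tmp_path / "r.fq"), n_reads=200)
        assert truth["has_prefix"].all()
        assert (truth["prefix_len"] >= 5).all()

    def test_determinism(self, tmp_path):
        cfg = SimConfig(seed=14)
        t1 = simulate_fastq(cfg, str(tmp_path / "a.fq"), n_reads=100)
        t2 = simulate_fastq(cfg, str(tmp_path / "b.fq"), n_reads=100)
        pd.testing.assert_frame_equal(t1, t2)
        assert (tmp_path / "a.fq").read_bytes() == (tmp_path / "b.fq").read_bytes()


class TestDesigns:
    def test_circadian_design_shape(self):
        samples = circadian_design(seed=0)
        assert len(samples) == 30
        conds = {s.condition for s in samples}
        assert conds == {"ZT2", "ZT6", "ZT10", "ZT14", "ZT18", "ZT22"}

    def test_full_design_55_samples(self):
        samples = full_design(seed=0)
        assert len(samples) == 55
        for cond in ("R0", "R2", "R4", "R8", "ZT8"):
            assert sum(s.condition == cond for s in samples) == 5

    def test_library_sizes_straddle_cutoff(self):
        sizes = [s.library_size for s in full_design(seed=0)]
        assert min(sizes) < 1_700_000 < max(sizes)
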