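"""The synthetic-data generator: structure, determinism, planted truth."""

import filecmp
import os

import numpy as np
import pytest

from mirisc_shift.decay_qpcr import fit_halflife
from mirisc_shift.seedmatch import seed_of
from mirisc_shift.synthetic_data import (
    SimConfig, plant_candidates, simulate_all, simulate_annotation, simulate_decay,
    simulate_densitometry, simulate_counts, simulate_eclip_peaks, simulate_mirnome,
    write_all,
)


class TestConfig:
    @pytest.mark.parametrize("kw", [
        dict(n_mirnas=0), dict(n_families=0), dict(n_mirnas=3, n_families=5),
        dict(library_size=-1), dict(nb_dispersion=-0.1), dict(frac_candidates=1.5),
        dict(ct_noise_sd=-1), dict(peak_length=900),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_nonpositive_halflife_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(decay_halflives_h={"G": {"cytoplasm": {"low_density": 0.0}}})


class TestAnnotation:
    def test_single_gene_has_one_less_intron_than_exons(self):
        ann = simulate_annotation(SimConfig(n_genes=1, rng_seed=7))
        g = ann.genes[0]
        assert len(g.introns) == len(g.exons) - 1 >= 1

    def test_empty_annotation_errors(self):
        with pytest.raises(ValueError):
            simulate_annotation(SimConfig(n_genes=0, rng_seed=7))

    def test_genes_pairwise_non_overlapping(self):
        ann = simulate_annotation(SimConfig(n_genes=500, rng_seed=3))
        ivs = sorted((g.start, g.end) for g in ann.genes)
        # brute-force sweep over all consecutive pairs after sorting
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2
        assert len(ivs) == 500

    def test_utr_inside_terminal_exon(self):
        ann = simulate_annotation(SimConfig(n_genes=50, rng_seed=5))
        for g in ann.genes:
            us, ue = g.utr3
            exon = g.exons[-1] if g.strand == "+" else g.exons[0]
            assert exon[0] <= us < ue <= exon[1]

    def test_sequences_over_acgt(self):
        ann = simulate_annotation(SimConfig(n_genes=5, rng_seed=5))
        assert set(ann.genome["chr1"]) <= set("ACGT")


class TestMirnome:
    def test_family_count_by_construction(self):
        cfg = SimConfig(n_mirnas=6, n_families=3, rng_seed=1)
        mirnas, truth = simulate_mirnome(cfg)
        assert len({seed_of(s) for s in mirnas.values()}) == 3
        assert len(truth.family_members) == 3

    def test_one_family_per_mirna_when_equal(self):
        cfg = SimConfig(n_mirnas=8, n_families=8, rng_seed=2)
        mirnas, _ = simulate_mirnome(cfg)
        assert len({seed_of(s) for s in mirnas.values()}) == 8

    def test_seed_recomputation_matches_planted_assignment(self):
        mirnas, truth = simulate_mirnome(SimConfig(rng_seed=3))
        for seed, members in truth.family_members.items():
            for m in members:
                assert seed_of(mirnas[m]) == seed

    def test_lengths_and_alphabet(self):
        mirnas, _ = simulate_mirnome(SimConfig(rng_seed=4))
        for s in mirnas.values():
            assert 20 <= len(s) <= 24 and set(s) <= set("ACGU")


class TestCounts:
    def test_null_config_centered_at_zero(self):
        cfg = SimConfig(n_genes=800, frac_candidates=0.0, rng_seed=5)
        ann = simulate_annotation(cfg)
        _, truth = simulate_mirnome(cfg)
        plant_candidates(cfg, ann, truth)
        ex, _, _ = simulate_counts(cfg, ann, truth)
        lo = ex.filter(like="low").mean(axis=1)
        hi = ex.filter(like="high").mean(axis=1)
        l2 = np.log2((hi + 0.5) / (lo + 0.5))
        se = l2.std() / np.sqrt(len(l2))
        assert abs(l2.mean()) < 3 * se + 1e-3

    def test_poisson_limit_variance_matches_mean(self):
        """At phi = 0 the per-gene replicate variance matches the mean."""
        cfg = SimConfig(n_genes=3000, nb_dispersion=0.0, rng_seed=6, frac_candidates=0.0)
        ann = simulate_annotation(cfg)
        _, truth = simulate_mirnome(cfg)
        plant_candidates(cfg, ann, truth)
        ex, _, _ = simulate_counts(cfg, ann, truth)
        sub = ex.filter(like="low").values.astype(float)
        m = sub.mean(axis=1)
        keep = m > 50
        ratio = sub.var(axis=1, ddof=1)[keep] / m[keep]
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)

    def test_planted_ptx_effect_recovered_in_expectation(self):
        """Mean exon/intron fold-change ratio over 200 draws ~ 2^1.5."""
        fc_ex_all, fc_it_all = [], []
        for seed in range(200):
            cfg = SimConfig(n_genes=20, frac_candidates=0.1, tx_effect_log2=0.4,
                            ptx_effect_log2=1.5, rng_seed=seed)
            ann = simulate_annotation(cfg)
            _, truth = simulate_mirnome(cfg)
            plant_candidates(cfg, ann, truth)
            ex, it, _ = simulate_counts(cfg, ann, truth)
            for g in truth.candidate_gene_ids:
                if ex.loc[g].filter(like="low").mean() < 500:
                    continue  # low-count ratios carry small-sample bias
                fc_ex_all.append(ex.loc[g].filter(like="high").mean()
                                 / ex.loc[g].filter(like="low").mean())
                fc_it_all.append(it.loc[g].filter(like="high").mean()
                                 / it.loc[g].filter(like="low").mean())
        ratio = np.mean(fc_ex_all) / np.mean(fc_it_all)
        assert ratio == pytest.approx(2 ** 1.5, rel=0.05)

    def test_column_sums_near_library_size(self, small_sim):
        sums = small_sim.exonic.filter(like="low").sum(axis=0)
        assert np.allclose(sums, small_sim.cfg.library_size, rtol=0.25)

    def test_smallrna_global_shift(self, small_sim):
        lo = small_sim.smallrna.filter(like="low").values.sum()
        hi = small_sim.smallrna.filter(like="high").values.sum()
        assert np.log2(hi / lo) == pytest.approx(small_sim.cfg.mirna_global_log2fc, abs=0.3)


class TestEclipPeaks:
    def test_no_candidates_no_planted_site_peaks(self):
        cfg = SimConfig(n_genes=40, frac_candidates=0.0, rng_seed=8)
        ann = simulate_annotation(cfg)
        _, truth = simulate_mirnome(cfg)
        plant_candidates(cfg, ann, truth)
        peaks = simulate_eclip_peaks(cfg, ann, truth)
        from mirisc_shift.seedmatch import sites_for_seed
        utrs = ann.utr_seqs()
        for row in peaks.itertuples():
            if row.compartment != "cyto":
                continue
            utr = utrs.get(row.name)
            if utr is None:
                continue
            for seed in truth.family_abundance:
                hits = sites_for_seed(utr, seed)
                by_id = {g.gene_id: g for g in ann.genes}
                from mirisc_shift.seedmatch import genome_to_utr
                g = by_id[row.name]
                if not (g.utr3[0] <= row.start and row.end <= g.utr3[1]):
                    continue
                us, ue = genome_to_utr(row.start, row.end, g)
                assert not any(us <= h.start and h.end <= ue for h in hits)

    def test_planted_peaks_inside_utr(self, small_sim):
        by_id = {g.gene_id: g for g in small_sim.annotation.genes}
        for gid, pks in small_sim.truth.planted_peaks.items():
            utr_len = by_id[gid].utr3[1] - by_id[gid].utr3[0]
            for pk in pks:
                assert 0 <= pk["utr_start"] < pk["utr_end"] <= utr_len

    def test_planted_peaks_scannable(self, small_sim):
        """Cross-module closure: scanning a planted peak finds its site."""
        from mirisc_shift.seedmatch import sites_for_seed
        utrs = small_sim.annotation.utr_seqs()
        for gid, pks in small_sim.truth.planted_peaks.items():
            for pk in pks:
                hits = sites_for_seed(utrs[gid], pk["seed"])
                assert any(pk["utr_start"] <= h.start and h.end <= pk["utr_end"]
                           for h in hits)

    def test_planted_site_types_preserved(self, small_sim):
        from mirisc_shift.seedmatch import sites_for_seed
        utrs = small_sim.annotation.utr_seqs()
        for gid, pks in small_sim.truth.planted_peaks.items():
            for pk in pks:
                hits = {(h.start, h.site_type) for h in sites_for_seed(utrs[gid], pk["seed"])}
                start = pk["site_utr_offset"]
                assert (start, pk["site_type"]) in hits

    def test_peak_longer_than_utr_errors(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=10, peak_length=700, utr_length=600)


class TestDecay:
    def test_one_halving_is_one_ct(self):
        cfg = SimConfig(ct_noise_sd=0.0, rng_seed=9,
                        decay_halflives_h={"X": {"cytoplasm": {"low_density": 8.0}}})
        ct = simulate_decay(cfg)
        sub = ct[(ct.gene == "X") & (ct.timepoint_h.isin([0, 8]))]
        by_t = sub.groupby("timepoint_h").ct.mean()
        assert by_t[8] - by_t[0] == pytest.approx(1.0, abs=1e-9)

    def test_infinite_halflife_is_flat(self):
        cfg = SimConfig(ct_noise_sd=0.0, rng_seed=9,
                        decay_halflives_h={"X": {"cytoplasm": {"low_density": np.inf}}})
        ct = simulate_decay(cfg)
        sub = ct[ct.gene == "X"]
        assert sub.ct.nunique() == 1

    def test_noise_free_roundtrip_recovers_halflife(self):
        cfg = SimConfig(ct_noise_sd=0.0, rng_seed=10,
                        decay_halflives_h={"X": {"cytoplasm": {"low_density": 7.3}}})
        ct = simulate_decay(cfg)
        sub = ct[(ct.gene == "X")].groupby("timepoint_h").ct.mean()
        abundance = 2.0 ** (-(sub - sub[0]))
        hl = fit_halflife(sub.index.values, abundance.values)
        assert hl.t_half_h == pytest.approx(7.3, rel=1e-9)

    def test_reference_genes_flat_in_expectation(self, small_sim):
        refs = small_sim.ct[small_sim.ct.gene == "HPRT1"]
        per_t = refs.groupby("timepoint_h").ct.mean()
        assert per_t.max() - per_t.min() < 0.5


class TestDensitometry:
    def test_zero_noise_slope_exact(self):
        cfg = SimConfig(densitometry_noise_sd=0.0, rng_seed=11)
        std, _ = simulate_densitometry(cfg)
        from mirisc_shift.quantitation import fit_standard_curve
        curve = fit_standard_curve(std.mass_ng, std.intensity_au)
        assert curve.slope == pytest.approx(cfg.densitometry_slope, rel=1e-12)
        assert curve.r2 == pytest.approx(1.0)

    def test_doubling_volume_doubles_intensity(self):
        a = SimConfig(densitometry_noise_sd=0.0, loaded_volume_ul=10.0, rng_seed=12)
        b = SimConfig(densitometry_noise_sd=0.0, loaded_volume_ul=20.0, rng_seed=12)
        _, sa = simulate_densitometry(a)
        _, sb = simulate_densitometry(b)
        assert np.allclose(sb.intensity_au, 2 * sa.intensity_au)


class TestDeterminism:
    def test_identical_config_gives_identical_files(self, tmp_path):
        cfg = SimConfig(n_genes=30, rng_seed=42)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_all(simulate_all(cfg), d1)
        p2 = write_all(simulate_all(SimConfig(n_genes=30, rng_seed=42)), d2)
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        a = write_all(simulate_all(SimConfig(n_genes=10, rng_seed=1)), tmp_path / "a")
        b = write_all(simulate_all(SimConfig(n_genes=10, rng_seed=2)), tmp_path / "b")
        assert not filecmp.cmp(a["genome"], b["genome"], shallow=False)
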