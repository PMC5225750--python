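"""Breeding-population generator: haplotypes, pedigree, gene drop and
phenotypes."""

import numpy as np
import pandas as pd
import pytest

import clonegs as cg


class TestFounderHaplotypes:
    def test_shapes_and_determinism(self):
        cfg = cg.SimConfig(n_parents=8, n_markers=120, n_lgs=3, n_qtl=20, seed=5)
        h1, map1 = cg.simulate_founder_haplotypes(cfg)
        h2, map2 = cg.simulate_founder_haplotypes(cfg)
        assert h1.shape == (8, 2, 120)
        np.testing.assert_array_equal(h1, h2)
        pd.testing.assert_frame_equal(map1.df, map2.df)

    def test_zero_block_length_no_ld(self):
        cfg = cg.SimConfig(n_parents=400, n_markers=60, n_lgs=1,
                           n_qtl=10, block_cm=0.0, seed=6)
        haps, gmap = cg.simulate_founder_haplotypes(cfg)
        flat = haps.reshape(-1, 60).astype(float)
        keep = flat.std(axis=0) > 0
        corr = np.corrcoef(flat[:, keep], rowvar=False)
        adjacent = np.abs(np.diag(corr, k=1))
        assert np.mean(adjacent ** 2) < 0.01

    def test_block_structure_gives_distance_decay(self):
        cfg = cg.SimConfig(n_parents=500, n_markers=120, n_lgs=1,
                           n_qtl=20, lg_length_cm=60, block_cm=5.0, seed=6)
        haps, gmap = cg.simulate_founder_haplotypes(cfg)
        flat = haps.reshape(-1, 120).astype(float)
        pos = gmap.markers_on(gmap.linkage_groups[0])["cm"].to_numpy()
        keep = flat.std(axis=0) > 0
        flat, pos = flat[:, keep], pos[keep]
        corr2 = np.corrcoef(flat, rowvar=False) ** 2
        iu, ju = np.triu_indices(flat.shape[1], k=1)
        d = np.abs(pos[iu] - pos[ju])
        r2 = corr2[iu, ju]
        assert r2[d < 1.0].mean() > r2[d > 10.0].mean()

    def test_frequency_law_respected(self):
        cfg = cg.SimConfig(n_parents=300, n_markers=200, n_lgs=2, n_qtl=20,
                           founder_freq_range=(0.3, 0.7), block_cm=0.0, seed=2)
        haps, _ = cg.simulate_founder_haplotypes(cfg)
        freqs = haps.reshape(-1, 200).mean(axis=0)
        assert freqs.min() > 0.2 and freqs.max() < 0.8

    def test_empty_config_rejected(self):
        cfg = cg.SimConfig(n_markers=28, n_lgs=28, n_qtl=5, seed=0)
        cfg.n_markers = 0          # bypass a valid construction
        with pytest.raises(ValueError):
            cg.simulate_founder_haplotypes(cfg)


class TestCircularPedigree:
    def test_four_parents_wraparound(self):
        ped = cg.make_circular_pedigree(["1", "2", "3", "4"],
                                        progeny_per_cross=1)
        crosses = [(s, d) for _, s, d in ped.records if s is not None]
        assert crosses == [("1", "2"), ("2", "3"), ("3", "4"), ("4", "1")]

    def test_family_count_matches_parent_count(self):
        ped = cg.make_circular_pedigree([f"p{i}" for i in range(22)],
                                        progeny_per_cross=3)
        fams = {f for g, f in ped.families().items() if "x" in f}
        assert len(fams) == 22

    def test_extra_crosses_appended(self):
        ped = cg.make_circular_pedigree(["a", "b", "c"], progeny_per_cross=2,
                                        extra_crosses=[("a", "c")])
        fams = {f for g, f in ped.families().items() if "x" in f}
        assert "axc" in fams and len(fams) == 4

    def test_two_parents_rejected(self):
        with pytest.raises(ValueError):
            cg.make_circular_pedigree(["a", "b"])

    def test_duplicate_parents_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cg.make_circular_pedigree(["a", "a", "b"])


class TestGeneDrop:
    def test_zero_distance_transmits_intact_haplotypes(self):
        cfg = cg.SimConfig(n_parents=4, n_markers=40, n_lgs=1, n_qtl=5,
                           lg_length_cm=0.0, seed=3)
        haps, gmap = cg.simulate_founder_haplotypes(cfg)
        ped = cg.make_circular_pedigree([f"F{i:03d}" for i in range(4)],
                                        progeny_per_cross=5)
        m = cg.gene_drop(ped, haps, gmap, seed=4)
        parent_haps = {f"F{i:03d}": haps[i] for i in range(4)}
        for rid, sire, dam in ped.records:
            if sire is None:
                continue
            row = m.dosages[m.individual_ids.index(rid)]
            ok = False
            for hs in parent_haps[sire]:
                for hd in parent_haps[dam]:
                    if np.array_equal(row, hs.astype(float) + hd):
                        ok = True
            assert ok, f"{rid} dosage is not a sum of intact parental haplotypes"

    def test_haldane_recombination_fraction(self):
        """Two markers 50 cM apart recombine at 0.5(1 - e^-1) = 0.316."""
        gmap = cg.GeneticMap(pd.DataFrame({
            "marker": ["a", "b"], "lg": "1", "cm": [0.0, 50.0]}))
        # heterozygous parent in coupling phase: haplotypes 11 / 00
        founder = np.array([[[1, 1], [0, 0]]], dtype=np.int8)
        records = [("P", None, None), ("Q", None, None)]
        # many offspring of P x Q where Q is 00/00 (testcross)
        founder = np.concatenate([founder,
                                  np.zeros((1, 2, 2), dtype=np.int8)])
        for i in range(4000):
            records.append((f"o{i}", "P", "Q"))
        ped = cg.PedigreeTable(records)
        m = cg.gene_drop(ped, founder, gmap, seed=9)
        d = m.dosages[2:]              # offspring dosages = P gamete + 0
        recomb = np.mean(d[:, 0] != d[:, 1])
        expected = 0.5 * (1 - np.exp(-1.0))
        assert recomb == pytest.approx(expected, abs=0.02)

    def test_allele_frequencies_conserved(self):
        cfg = cg.SimConfig(n_parents=30, progeny_per_cross=20, n_markers=300,
                           n_lgs=3, seed=12)
        haps, gmap = cg.simulate_founder_haplotypes(cfg)
        ped = cg.make_circular_pedigree([f"F{i:03d}" for i in range(30)],
                                        progeny_per_cross=20)
        m = cg.gene_drop(ped, haps, gmap, seed=13)
        founder_freq = haps.reshape(-1, 300).mean(axis=0)
        prog_rows = [i for i, rid in enumerate(m.individual_ids)
                     if "x" in rid]
        prog_freq = m.dosages[prog_rows].mean(axis=0) / 2.0
        # paired over markers: no systematic drift in expectation
        diff = prog_freq - founder_freq
        assert abs(diff.mean()) < 3 * diff.std() / np.sqrt(300)

    def test_full_sib_grm_half(self, sim_single, sim_single_qc):
        A = cg.grm_yang(sim_single_qc, complete_case=False)
        fam = sim_single.pedigree.families()
        idx = {g: i for i, g in enumerate(A.labels)}
        groups: dict[str, list[str]] = {}
        for g in A.labels:
            groups.setdefault(fam[g], []).append(g)
        sib_vals = [A.values[idx[a], idx[b]]
                    for mem in groups.values()
                    for i, a in enumerate(mem) for b in mem[i + 1:]]
        assert np.mean(sib_vals) == pytest.approx(0.5, abs=0.06)


class TestPhenotypes:
    def test_no_noise_equals_genetic_value(self):
        cfg = cg.SimConfig(n_parents=6, progeny_per_cross=4, n_markers=100,
                           n_lgs=2, n_qtl=20, h2=0.6, family_frac=0.2,
                           clone_frac=0.2, bed_frac=0.0, plot_frac=0.0,
                           n_reps=1, seed=8)
        b = cg.simulate_trials(cfg)
        tg = b.truth["total_genetic"]["T1"]
        df = b.trial_data.df.set_index("genotype")
        for g in tg.index:
            assert df.loc[g, "trait"] == pytest.approx(tg[g], abs=1e-10)

    def test_additive_variance_scaled_to_target(self):
        cfg = cg.SimConfig(n_parents=25, progeny_per_cross=40, n_markers=400,
                           n_lgs=4, n_qtl=60, h2=0.4, seed=14)
        b = cg.simulate_trials(cfg)
        a = b.truth["additive"]["T1"].to_numpy()
        assert np.var(a) == pytest.approx(0.4, rel=1e-9)

    def test_two_trial_additive_correlation(self):
        cfg = cg.SimConfig(n_parents=20, progeny_per_cross=25, n_markers=400,
                           n_lgs=4, n_qtl=60, h2=0.4, type_b=0.6, seed=15)
        b = cg.simulate_trials(cfg, trials=("T1", "T2"))
        a1 = b.truth["additive"]["T1"]
        a2 = b.truth["additive"]["T2"]
        r = np.corrcoef(a1, a2)[0, 1]
        assert r == pytest.approx(0.6, abs=0.08)

    def test_trial_overlap_fraction(self):
        cfg = cg.SimConfig(n_parents=20, progeny_per_cross=10,
                           n_markers=200, n_lgs=2, trial_overlap_frac=0.2,
                           seed=16)
        b = cg.simulate_trials(cfg, trials=("T1", "T2"))
        mem = b.truth["trial_members"]
        shared = set(mem["T1"]) & set(mem["T2"])
        n_g = len(b.genotyped_ids)
        assert len(shared) == round(0.2 * n_g)
        assert set(mem["T1"]) | set(mem["T2"]) == set(b.genotyped_ids)

    def test_fraction_sum_validation(self):
        with pytest.raises(ValueError, match="fractions"):
            cg.SimConfig(h2=0.6, family_frac=0.3, clone_frac=0.3)

    def test_too_many_qtl_rejected(self):
        with pytest.raises(ValueError, match="QTL"):
            cg.SimConfig(n_markers=50, n_qtl=100)

    def test_same_seed_reproducible(self):
        cfg = cg.SimConfig(n_parents=6, progeny_per_cross=4, n_markers=60,
                           n_lgs=2, n_qtl=10, seed=77)
        b1 = cg.simulate_trials(cfg)
        b2 = cg.simulate_trials(cfg)
        pd.testing.assert_frame_equal(b1.trial_data.df, b2.trial_data.df)
        np.testing.assert_array_equal(b1.markers.dosages, b2.markers.dosages)
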