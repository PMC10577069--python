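import numpy as np
import pytest
from scipy import stats

from reinforcescan import simulate as sim
from reinforcescan.popgen import windowed_tajima_d
from reinforcescan.windowing import WindowSet


def params(**kw):
    kw.setdefault("n_sites", 2000)
    kw.setdefault("sites_per_window", 200)
    kw.setdefault("n_planted", 0)
    kw.setdefault("seed", 3)
    return sim.SimulationParams(**kw)


class TestParams:
    def test_f_range_validated(self):
        with pytest.raises(ValueError, match="F must be"):
            params(F_species=1.5)

    def test_planted_outside_contig_rejected(self):
        with pytest.raises(ValueError, match="outside contig"):
            params(planted_windows=(sim.PlantedWindow(0, 10**9),))

    def test_overlapping_planted_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            params(planted_windows=(sim.PlantedWindow(0, 2000),
                                    sim.PlantedWindow(1000, 3000)))


class TestDrawFrequencies:
    def test_invariant_sites_all_zero(self, rng):
        p = params(variant_fraction=0.0)
        f = sim.draw_window_frequencies(p, None, 500, rng)
        for arr in (f.p_anc, f.p_mul_sp, f.p_fas_sp, f.p_am, f.p_pm,
                    f.p_af, f.p_pf):
            assert np.all(arr == 0.0)

    def test_small_F_limit_tracks_ancestral(self, rng):
        p = params(F_species=1e-4, F_pop=1e-4, variant_fraction=1.0)
        f = sim.draw_window_frequencies(p, None, 3000, rng)
        assert np.mean(np.abs(f.p_mul_sp - f.p_anc)) < 0.02
        assert np.mean(np.abs(f.p_pf - f.p_anc)) < 0.02

    def test_f_boost_raises_expected_parapatric_fst(self, rng):
        """Monte-Carlo: E[F_ST] between parapatric pops is larger in a
        planted window than the Balding-Nichols null expectation."""
        p = params(variant_fraction=1.0)
        n = 3000
        null = sim.draw_window_frequencies(p, None, n, rng)
        planted = sim.draw_window_frequencies(
            p, sim.PlantedWindow(0, 10, F_boost=0.5, singleton_fraction=0.0),
            n, rng)

        def efst(f):
            num = (f.p_pm - f.p_pf) ** 2
            den = f.p_pm * (1 - f.p_pf) + f.p_pf * (1 - f.p_pm)
            return num.sum() / den.sum()

        assert efst(planted) > efst(null) + 0.1

    def test_singleton_sites_fixed_everywhere(self, rng):
        p = params(variant_fraction=1.0)
        pw = sim.PlantedWindow(0, 10, singleton_fraction=0.4)
        f = sim.draw_window_frequencies(p, pw, 1000, rng)
        assert f.singleton.sum() == 400
        for arr in (f.p_am, f.p_pm, f.p_af, f.p_pf):
            assert np.all(arr[f.singleton] == 0.0)


class TestSampleGenotypes:
    def test_q_zero_matches_pure_fascicularis(self, rng):
        """With q=0 parapatric fascicularis is identical in law to a pure
        fascicularis cohort drawn from the same frequencies."""
        p = params(q_intro=0.0, variant_fraction=1.0)
        f = sim.draw_window_frequencies(p, None, 2000, rng)
        dosage, q_true = sim.sample_genotypes(f, p, None, rng)
        assert np.all(q_true == 0)
        pf = dosage[:, 30:40]
        pure = rng.binomial(2, f.p_pf[:, None], (2000, 10))
        table = np.array([[pf.sum(), 2 * pf.size - pf.sum()],
                          [pure.sum(), 2 * pure.size - pure.sum()]])
        _, pval, _, _ = stats.chi2_contingency(table)[0:4]
        assert pval > 0.01

    def test_q_one_draws_from_parapatric_mulatta(self, rng):
        p = params(q_intro=1.0, variant_fraction=1.0)
        f = sim.draw_window_frequencies(p, None, 200, rng)
        f.p_pm[:] = 1.0        # mulatta source fixed alt
        f.p_pf[:] = 0.0        # fascicularis source fixed ref
        dosage, q_true = sim.sample_genotypes(f, p, None, rng)
        assert np.all(q_true == 1)
        assert np.all(dosage[:, 30:40] == 2)

    def test_fixed_frequency_all_homozygous(self, rng):
        p = params()
        f = sim.draw_window_frequencies(p, None, 100, rng)
        for arr in (f.p_am, f.p_pm, f.p_af, f.p_pf):
            arr[:] = 1.0
        dosage, _ = sim.sample_genotypes(f, p, None, rng)
        assert np.all(dosage == 2)

    def test_singletons_planted_as_single_copy(self, rng):
        p = params(variant_fraction=1.0)
        pw = sim.PlantedWindow(0, 10, singleton_fraction=0.5)
        f = sim.draw_window_frequencies(p, pw, 400, rng)
        dosage, _ = sim.sample_genotypes(f, p, pw, rng)
        sing = dosage[f.singleton]
        assert np.all(sing.sum(axis=1) == 1)           # exactly one copy
        assert np.all(sing[:, :30] == 0)               # private to para_fas


class TestGenerateDataset:
    def test_determinism_byte_identical(self, tmp_path):
        p = params(n_sites=1000, sites_per_window=100, n_planted=1)
        sim.generate_dataset(p, out_dir=tmp_path / "a")
        sim.generate_dataset(p, out_dir=tmp_path / "b")
        for name in ("sim.vcf", "ref.fasta", "genes.gtf", "sift.tsv",
                     "motifs.meme", "truth_windows.tsv"):
            assert (tmp_path / "a" / name).read_bytes() \
                == (tmp_path / "b" / name).read_bytes(), name

    def test_no_planted_windows_in_truth(self):
        ds = sim.generate_dataset(params(n_planted=0))
        assert not ds.truth_windows["planted"].any()

    def test_planted_gene_inside_every_planted_window(self):
        ds = sim.generate_dataset(params(n_sites=4000, sites_per_window=200,
                                         n_planted=3))
        planted = ds.truth_windows[ds.truth_windows["planted"]]
        gtf = "\n".join(ds.genes_gtf)
        for _, row in planted.iterrows():
            genes = [ln for ln in ds.genes_gtf
                     if ln.split("\t")[2] == "gene"
                     and row.start < int(ln.split("\t")[3]) <= row.end]
            assert genes, f"no gene inside planted window {row.start}"

    def test_popmap_roundtrip_sizes(self):
        ds = sim.generate_dataset(params())
        assert ds.popmap.group_sizes() == {l: 10 for l in
                                           ("ALLO_MUL", "PARA_MUL",
                                            "ALLO_FAS", "PARA_FAS")}


class TestPlantedSignatures:
    def test_singleton_planting_negative_tajima(self, rng):
        """Mean parapatric-fascicularis Tajima's D over 100 replicate
        planted windows is negative."""
        p = sim.SimulationParams(
            n_sites=100 * 60, sites_per_window=60, variant_fraction=1.0,
            planted_windows=tuple(
                sim.PlantedWindow(s, s + 600, F_boost=0.0,
                                  singleton_fraction=0.3)
                for s in range(0, 60_000, 600)),
            seed=5)
        G, _, grid, tw, _, _ = sim.generate_matrix(p)
        pf = np.arange(30, 40)
        D, S, pi = windowed_tajima_d(G, pf, grid)
        assert len(D) == 100
        assert np.nanmean(D) < 0

    def test_exchangeable_world_fst_near_zero(self, rng):
        p = params(F_species=1e-4, F_pop=1e-4, q_intro=0.0,
                   variant_fraction=1.0, n_sites=4000)
        ds = sim.generate_dataset(p)
        from reinforcescan.popgen import windowed_fst_dxy

        fst, _, _ = windowed_fst_dxy(
            ds.G, ds.popmap.indices(ds.G, "PARA_MUL"),
            ds.popmap.indices(ds.G, "PARA_FAS"), ds.windows)
        assert abs(np.nanmean(fst)) < 0.01
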