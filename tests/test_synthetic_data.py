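import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccgpipe.quantify import count_exonic, count_terminal_window
from ccgpipe.synthetic_data import (
    SimulationConfig,
    build_toy_annotation,
    build_truth,
    default_dispersion,
    expected_means,
    kinetic_rna_response,
    read_truth,
    rng_for,
    simulate_condition_pair,
    simulate_timecourse,
    write_truth,
)


class TestKineticResponse:
    def test_instantaneous_turnover_limit(self):
        r = kinetic_rna_response(1e6, 22.0)
        assert r.attenuation == pytest.approx(1.0, abs=1e-9)
        assert r.delay_hours == pytest.approx(0.0, abs=1e-5)

    def test_k_equal_omega(self):
        # closed form of the linear ODE at k = omega
        w = 2 * math.pi / 22.0
        r = kinetic_rna_response(w, 22.0)
        assert r.attenuation == pytest.approx(1 / math.sqrt(2), abs=1e-12)
        assert r.delay_hours == pytest.approx(22.0 / 8.0, abs=1e-12)

    def test_slow_turnover(self):
        w = 2 * math.pi / 22.0
        r = kinetic_rna_response(w / 10.0, 22.0)
        assert r.delay_hours == pytest.approx(math.atan(10.0) / w, abs=1e-9)
        assert r.attenuation == pytest.approx(1 / math.sqrt(101), abs=1e-9)

    @pytest.mark.parametrize("k,period", [(0.0, 22.0), (-1.0, 22.0), (1.0, 0.0)])
    def test_invalid_inputs(self, k, period):
        with pytest.raises(ValueError):
            kinetic_rna_response(k, period)

    @given(
        k1=st.floats(0.01, 10.0),
        k2=st.floats(0.01, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_attenuation_increases_delay_decreases_in_k(self, k1, k2):
        lo, hi = sorted([k1, k2])
        if hi - lo < 1e-9:
            return
        a, b = kinetic_rna_response(lo, 22.0), kinetic_rna_response(hi, 22.0)
        assert b.attenuation > a.attenuation
        assert b.delay_hours < a.delay_hours


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_rhythmic=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(period_hours=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_timepoints=3)

    def test_rng_splitting_reproducible(self):
        a = rng_for(5, "truth").integers(0, 1 << 30, 4)
        b = rng_for(5, "truth").integers(0, 1 << 30, 4)
        c = rng_for(5, "annotation").integers(0, 1 << 30, 4)
        assert (a == b).all()
        assert (a != c).any()


class TestToyAnnotation:
    def test_disjoint_case(self):
        cfg = SimulationConfig(n_genes=10, n_overlap_pairs=0, seed=1)
        ann = build_toy_annotation(cfg)
        assert len(ann) == 10
        assert ann.overlaps == []

    def test_all_genes_paired(self):
        cfg = SimulationConfig(n_genes=4, n_overlap_pairs=2, seed=1)
        ann = build_toy_annotation(cfg)
        partners = {g: 0 for g in ann.gene_ids}
        for rec in ann.overlaps:
            partners[rec.gene_a] += 1
            partners[rec.gene_b] += 1
        assert all(v == 1 for v in partners.values())
        for rec in ann.overlaps:
            assert rec.length == cfg.overlap_length

    def test_gff3_byte_identical_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(n_genes=12, n_overlap_pairs=3, seed=9)
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        build_toy_annotation(cfg).to_gff3(p1)
        build_toy_annotation(cfg).to_gff3(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_too_many_pairs_rejected(self):
        with pytest.raises(ValueError):
            build_toy_annotation(SimulationConfig(n_genes=3, n_overlap_pairs=2))


class TestTruth:
    def test_arrhythmic_amplitude_one(self, small_bundle):
        _, _, truth = small_bundle
        flat = truth[~truth["is_rhythmic"]]
        assert (flat["true_fold_amplitude"] == 1.0).all()
        assert flat["true_phase"].isna().all()

    def test_phases_within_period(self, small_bundle):
        cfg, _, truth = small_bundle
        ph = truth.loc[truth["is_rhythmic"], "true_phase"]
        assert ((ph >= 0) & (ph < cfg.period_hours)).all()

    def test_json_round_trip(self, tmp_path, small_bundle):
        _, _, truth = small_bundle
        p = tmp_path / "truth.json"
        write_truth(truth, p)
        back = read_truth(p)
        assert list(back.index) == list(truth.index)
        assert back["is_rhythmic"].tolist() == truth["is_rhythmic"].tolist()

    def test_dawn_dusk_bimodality(self):
        cfg = SimulationConfig(n_genes=4000, frac_rhythmic=1.0, seed=11)
        truth = build_truth(cfg)
        ph = truth["true_phase"].to_numpy()
        hist, _ = np.histogram(ph, bins=11, range=(0, 22))
        # two modes roughly half a period apart: bins at CT 0 and CT 11
        top2 = np.argsort(hist)[-2:]
        centers = (top2 + 0.5) * 2.0
        gap = abs(centers[0] - centers[1])
        assert min(gap, 22 - gap) == pytest.approx(11.0, abs=2.0)


class TestSimulateTimecourse:
    def test_frac_rhythmic_zero_flat(self):
        cfg = SimulationConfig(n_genes=50, frac_rhythmic=0.0, seed=2)
        truth = build_truth(cfg)
        assert (truth["true_fold_amplitude"] == 1.0).all()

    def test_noiseless_limit_traces_cosine(self):
        cfg = SimulationConfig(
            n_genes=5,
            frac_rhythmic=1.0,
            frac_light_spike=0.0,
            dispersion_fn=lambda mu: np.asarray(mu, float),  # Poisson floor
            seed=3,
        )
        truth = build_truth(cfg)
        mu = expected_means(truth, cfg, "rnapii")
        t = cfg.times
        for i, (_, row) in enumerate(truth.iterrows()):
            expect = row["baseline_mean"] * np.exp(
                row["true_amplitude"]
                * np.cos(cfg.omega * (t - row["true_phase"]))
            )
            np.testing.assert_allclose(mu[i], expect, rtol=1e-12)

    def test_nb_moments(self):
        # law-of-large-numbers check on the NB sampler
        cfg = SimulationConfig(n_genes=2, seed=4)
        rng = rng_for(4, "x")
        from ccgpipe.synthetic_data import _nb_draw

        draws = _nb_draw(rng, np.full(10_000, 100.0), lambda m: 2.0 * m)
        assert np.mean(draws) == pytest.approx(100.0, rel=0.02)
        assert np.var(draws) == pytest.approx(200.0, rel=0.10)

    def test_bad_dispersion_rejected(self):
        cfg = SimulationConfig(n_genes=5, seed=5, dispersion_fn=lambda mu: 0.5 * np.asarray(mu))
        truth = build_truth(cfg)
        with pytest.raises(ValueError, match="variance < mean"):
            simulate_timecourse(None, truth, cfg, "rna")

    def test_light_spike_multiplies_t0(self):
        cfg = SimulationConfig(n_genes=200, frac_light_spike=0.5, seed=6)
        truth = build_truth(cfg)
        mu = expected_means(truth, cfg, "rnapii")
        spiked = truth["light_spike"].to_numpy()
        flat = ~truth["is_rhythmic"].to_numpy()
        base = truth["baseline_mean"].to_numpy()
        np.testing.assert_allclose(
            mu[spiked & flat, 0], cfg.light_spike_factor * base[spiked & flat]
        )
        np.testing.assert_allclose(mu[~spiked & flat, 0], base[~spiked & flat])

    def test_rna_attenuated_and_delayed(self):
        cfg = SimulationConfig(n_genes=300, frac_rhythmic=1.0, frac_light_spike=0.0, seed=8)
        truth = build_truth(cfg)
        mu_rna = expected_means(truth, cfg, "rna")
        mu_pol = expected_means(truth, cfg, "rnapii")
        # log-amplitude of RNA surface never exceeds the polymerase surface
        amp = lambda M: (np.log(M).max(axis=1) - np.log(M).min(axis=1))
        assert (amp(mu_rna) <= amp(mu_pol) + 1e-9).all()

    def test_reads_recount_exact(self, small_bundle):
        cfg, ann, truth = small_bundle
        sim = simulate_timecourse(ann, truth, cfg, "rna", emit_reads=True)
        recount = count_exonic(sim.reads, ann)
        pd.testing.assert_frame_equal(recount.data, sim.counts.data)
        sim2 = simulate_timecourse(ann, truth, cfg, "rnapii", emit_reads=True)
        recount2 = count_terminal_window(sim2.reads, ann)
        pd.testing.assert_frame_equal(recount2.data, sim2.counts.data)

    def test_deterministic(self, small_bundle):
        cfg, ann, truth = small_bundle
        a = simulate_timecourse(ann, truth, cfg, "rna").counts.data
        b = simulate_timecourse(ann, truth, cfg, "rna").counts.data
        pd.testing.assert_frame_equal(a, b)


class TestConditionPair:
    def test_null_case_identical_distributions(self):
        cfg = SimulationConfig(n_genes=1000, frac_rhythmic=0.0, seed=10)
        truth = build_truth(cfg)
        t, c = simulate_condition_pair(truth, cfg)
        from scipy import stats

        ks = stats.ks_2samp(t.data.mean(axis=1), c.data.mean(axis=1))
        assert ks.pvalue > 0.01

    def test_log2fc_construction(self):
        cfg = SimulationConfig(
            n_genes=400, frac_rhythmic=0.0, seed=12,
            mean_expr_dist=lambda rng, n: np.full(n, 500.0),
        )
        truth = build_truth(cfg)
        truth["de_log2fc"] = 2.0
        t, c = simulate_condition_pair(truth, cfg, n_replicates=10)
        ratio = t.data.to_numpy().mean() / c.data.to_numpy().mean()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_deterministic_tsv_bundle(self, tmp_path):
        cfg = SimulationConfig(n_genes=50, seed=13)
        truth = build_truth(cfg)
        for sub in ("a", "b"):
            d = tmp_path / sub
            d.mkdir()
            t, c = simulate_condition_pair(truth, cfg)
            t.to_tsv(d / "treat.tsv")
            c.to_tsv(d / "control.tsv")
        assert (tmp_path / "a/treat.tsv").read_bytes() == (tmp_path / "b/treat.tsv").read_bytes()
        assert (tmp_path / "a/control.tsv").read_bytes() == (tmp_path / "b/control.tsv").read_bytes()


def test_default_dispersion_shape():
    mu = np.array([1.0, 10.0, 100.0, 1000.0])
    v = default_dispersion(mu)
    assert (v > mu).all()
    phi = (v - mu) / mu**2
    assert (np.diff(phi) < 0).all()  # dispersion decreases with mean
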