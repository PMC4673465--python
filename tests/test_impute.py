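import itertools

import numpy as np
import pandas as pd
import pytest

import popdiff as pp
from conftest import make_snp_map
from oracles import li_stephens_dosage_paths


def ref_panel(rows, pops=None):
    rows = np.asarray(rows, dtype=np.uint8)
    n = rows.shape[0] // 2
    return pp.HaplotypePanel(rows, [f"r{i}" for i in range(n)],
                             pops or ["ref"] * n, make_snp_map(rows.shape[1]))


class TestMakeMask:
    def test_mask_sizes(self):
        sm = make_snp_map(1607)
        mask = pp.make_mask(sm, 400, seed=0)
        assert mask.n_masked == 400
        assert len(mask.typed_idx()) == 1207

    def test_boundary_single_typed_marker(self):
        sm = make_snp_map(10)
        mask = pp.make_mask(sm, 9, seed=1)
        assert len(mask.typed_idx()) == 1

    def test_deterministic_under_seed(self):
        sm = make_snp_map(100)
        assert pp.make_mask(sm, 30, 7).masked_ids == pp.make_mask(sm, 30, 7).masked_ids

    def test_masking_everything_rejected(self):
        sm = make_snp_map(10)
        with pytest.raises(ValueError):
            pp.make_mask(sm, 10, seed=0)


class TestLiStephensDosage:
    def test_single_reference_forces_posterior(self):
        ref = ref_panel([[1, 0, 1], [1, 0, 1]])
        # both rows identical: dosage = eps + (1-2eps) * allele regardless of data
        mask = pp.make_mask(ref.snp_map, 1, seed=3)
        params = pp.CopyingModelParams(epsilon=0.1, rho=0.2)
        target = np.array([0, 1, 0], dtype=np.uint8)
        d = pp.li_stephens_dosage(target, ref, params, mask)
        expected = 0.1 + 0.8 * ref.values[0, mask.masked_idx[0]]
        assert d[0] == pytest.approx(expected)

    def test_identical_target_small_rates_recovers_row(self):
        ref = ref_panel([[1, 0, 1, 1], [0, 1, 0, 0]])
        params = pp.CopyingModelParams(epsilon=1e-9, rho=1e-9)
        mask = pp.make_mask(ref.snp_map, 1, seed=0)
        target = ref.values[0].copy()
        d = pp.li_stephens_dosage(target, ref, params, mask)
        assert d[0] == pytest.approx(ref.values[0, mask.masked_idx[0]], abs=1e-6)

    @pytest.mark.parametrize("n_mark,n_ref,eps,rho", [
        (3, 2, 0.05, 0.1), (3, 3, 0.01, 0.3), (4, 2, 0.2, 0.05), (4, 3, 0.1, 0.4)])
    def test_matches_path_enumeration(self, n_mark, n_ref, eps, rho):
        rng = np.random.default_rng(n_mark * 10 + n_ref)
        params = pp.CopyingModelParams(epsilon=eps, rho=rho)
        sm = make_snp_map(n_mark)
        for trial in range(30):
            ref_rows = rng.integers(0, 2, size=(n_ref, n_mark))
            # panels hold two rows per sample; pad odd pools by duplicating
            # the last haplotype (a duplicated copying state is equivalent)
            if n_ref % 2:
                rows = np.vstack([ref_rows, ref_rows[-1:]])
            else:
                rows = ref_rows
            panel = pp.HaplotypePanel(rows.astype(np.uint8),
                                      [f"r{i}" for i in range(rows.shape[0] // 2)],
                                      ["ref"] * (rows.shape[0] // 2), sm)
            target = rng.integers(0, 2, size=n_mark).astype(np.uint8)
            n_masked = rng.integers(1, n_mark)
            masked = np.sort(rng.choice(n_mark, size=n_masked, replace=False))
            mask = pp.MaskPlan(tuple(sm.snp_ids[masked]), masked, 0, n_mark)
            typed = np.ones(n_mark, dtype=bool)
            typed[masked] = False
            got = pp.li_stephens_dosage(target, panel, params, mask)
            want = li_stephens_dosage_paths(target, typed, panel.values,
                                            eps, rho, masked)
            assert np.allclose(got, want, atol=1e-10)

    def test_posterior_normalisation(self):
        from popdiff.impute import _forward_backward
        rng = np.random.default_rng(8)
        ref = rng.integers(0, 2, size=(6, 40))
        target = rng.integers(0, 2, size=40)
        typed = rng.random(40) > 0.3
        post = _forward_backward(target, typed, ref, 0.02, 0.1)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_map_mismatch_rejected(self):
        ref = ref_panel([[0, 1], [1, 0]])
        mask = pp.make_mask(make_snp_map(3), 1, seed=0)
        with pytest.raises(ValueError, match="maps differ"):
            pp.li_stephens_dosage(np.array([0, 1]), ref, pp.CopyingModelParams(), mask)


class TestImputeTargets:
    def _setup(self, eps=0.01):
        cfg = pp.SyntheticConfig(n_pops=1, n_samples_per_pop=20, n_snps=30, seed=5)
        panel = pp.founder_mosaic_panel(cfg).panel
        ref, tgt = pp.split_reference_target(panel, 5, seed=2)
        mask = pp.make_mask(panel.snp_map, 8, seed=1)
        return ref, tgt, mask, pp.CopyingModelParams(epsilon=eps)

    def test_overfitting_guard(self):
        ref, tgt, mask, params = self._setup()
        with pytest.raises(ValueError, match="overfitting guard"):
            pp.impute_targets(ref, ref, params, mask)

    def test_dosages_bounded_by_emission_limits(self):
        ref, tgt, mask, params = self._setup(eps=0.05)
        d = pp.impute_targets(tgt, ref, params, mask).to_numpy()
        assert d.min() >= 2 * 0.05 - 1e-12
        assert d.max() <= 2 - 2 * 0.05 + 1e-12

    def test_uninformative_epsilon_gives_dosage_one(self):
        ref, tgt, mask, _ = self._setup()
        params = pp.CopyingModelParams(epsilon=0.499999)
        d = pp.impute_targets(tgt, ref, params, mask).to_numpy()
        assert np.allclose(d, 1.0, atol=1e-4)


class TestEvaluateDiscordance:
    def _truth(self, values):
        values = np.asarray(values, dtype=np.int8)
        return pp.GenotypeMatrix(values, [f"s{i}" for i in range(values.shape[0])],
                                 ["p"] * values.shape[0], make_snp_map(values.shape[1]))

    def test_perfect_dosages_give_zero_discordance(self):
        truth = self._truth([[0, 1], [2, 1], [1, 0], [0, 2]])
        dosages = pd.DataFrame(truth.values.astype(float),
                               index=truth.sample_ids, columns=["snp1", "snp2"])
        res = pp.evaluate_discordance(truth, dosages)
        assert res.discordance == pytest.approx(0.0, abs=1e-12)
        assert res.n_eval == 2 and res.n_skipped == 0

    def test_anticorrelated_dosages_also_score_r2_one(self):
        truth = self._truth([[0, 1], [2, 1], [1, 0], [0, 2]])
        dosages = pd.DataFrame(2.0 - truth.values,
                               index=truth.sample_ids, columns=["snp1", "snp2"])
        res = pp.evaluate_discordance(truth, dosages)
        assert res.discordance == pytest.approx(0.0, abs=1e-12)

    def test_random_dosages_near_total_discordance(self):
        rng = np.random.default_rng(0)
        n, m = 19, 400
        truth = self._truth(rng.integers(0, 3, size=(n, m)))
        dosages = pd.DataFrame(rng.uniform(0, 2, size=(n, m)),
                               index=[f"s{i}" for i in range(n)],
                               columns=[f"snp{j+1}" for j in range(m)])
        res = pp.evaluate_discordance(truth, dosages)
        # independent r^2 has mean ~ 1/(n-1)
        assert res.mean_r2 == pytest.approx(1 / (n - 1), abs=0.02)
        assert res.discordance > 0.9

    def test_zero_variance_markers_skipped_and_counted(self):
        truth = self._truth([[1, 0], [1, 2], [1, 1]])
        dosages = pd.DataFrame([[0.5, 0.1], [0.7, 1.8], [0.2, 1.0]],
                               index=truth.sample_ids, columns=["snp1", "snp2"])
        res = pp.evaluate_discordance(truth, dosages)
        assert res.n_skipped == 1 and res.n_eval == 1

    def test_invariant_to_sample_order_and_allele_relabel(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 3, size=(10, 5))
        truth = self._truth(vals)
        dos = pd.DataFrame(rng.uniform(0, 2, size=(10, 5)),
                           index=truth.sample_ids,
                           columns=[f"snp{j+1}" for j in range(5)])
        base = pp.evaluate_discordance(truth, dos).discordance
        # allele relabelling applied consistently: g -> 2-g, dosage -> 2-d
        flipped = self._truth(2 - vals)
        assert pp.evaluate_discordance(flipped, 2.0 - dos).discordance \
            == pytest.approx(base, abs=1e-12)
        perm = rng.permutation(10)
        truth_p = truth.subset_samples(perm)
        dos_p = dos.iloc[perm]
        assert pp.evaluate_discordance(truth_p, dos_p).discordance \
            == pytest.approx(base, abs=1e-12)


class TestPanelComparison:
    def test_duplicate_panel_gives_identical_columns(self):
        cfg = pp.SyntheticConfig(n_pops=2, n_samples_per_pop=15, n_snps=40, seed=6)
        panel = pp.founder_mosaic_panel(cfg).panel
        ref, tgt = pp.split_reference_target(panel, 4, seed=0)
        mask = pp.make_mask(panel.snp_map, 10, seed=1)
        refs = ref.by_population()
        out = pp.panel_comparison(
            {"pop1": tgt.by_population()["pop1"]},
            {"a": refs["pop1"], "b": refs["pop1"]},
            pp.CopyingModelParams(), mask)
        assert out["a"].tolist() == out["b"].tolist()

    def test_matched_panel_beats_disjoint_founder_panel(self):
        # two populations built on disjoint founder pools: the matched
        # reference panel must impute better than the mismatched one
        wins = 0
        for seed in range(5):
            cfg1 = pp.SyntheticConfig(n_pops=1, n_samples_per_pop=40, n_snps=120,
                                      n_founders=6, seed=seed)
            cfg2 = pp.SyntheticConfig(n_pops=1, n_samples_per_pop=40, n_snps=120,
                                      n_founders=6, seed=seed + 1000)
            ds1, ds2 = pp.founder_mosaic_panel(cfg1), pp.founder_mosaic_panel(cfg2)
            p2 = pp.HaplotypePanel(ds2.panel.values,
                                   [s + "_b" for s in ds2.panel.sample_ids],
                                   ["pop2"] * ds2.panel.n_samples,
                                   ds1.panel.snp_map)
            ref1, tgt1 = pp.split_reference_target(ds1.panel, 8, seed=seed)
            mask = pp.make_mask(ds1.panel.snp_map, 30, seed=seed)
            out = pp.panel_comparison({"pop1": tgt1},
                                      {"matched": ref1, "mismatched": p2},
                                      pp.CopyingModelParams(), mask)
            if out.loc["pop1", "matched"] < out.loc["pop1", "mismatched"]:
                wins += 1
        assert wins >= 4

    def test_larger_matched_panel_not_worse_in_expectation(self):
        deltas = []
        for seed in range(10):
            cfg = pp.SyntheticConfig(n_pops=1, n_samples_per_pop=60, n_snps=80,
                                     seed=seed, n_founders=8)
            panel = pp.founder_mosaic_panel(cfg).panel
            ref, tgt = pp.split_reference_target(panel, 6, seed=seed)
            small = ref.subset_samples(range(10))
            mask = pp.make_mask(panel.snp_map, 20, seed=seed)
            out = pp.panel_comparison({"pop1": tgt},
                                      {"small": small, "large": ref},
                                      pp.CopyingModelParams(), mask)
            deltas.append(out.loc["pop1", "small"] - out.loc["pop1", "large"])
        assert np.mean(deltas) > -0.01  # larger panel no worse, within noise
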