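"""Quantitation chain: filters, normalisation, imputation, concentrations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from eggcomp import quant


def long_table(values_by_sample_rep, protein_ids=None):
    """Build a long intensity table from {(sample, rep): [values per protein]}."""
    rows = []
    for (sid, rid, bid), vals in values_by_sample_rep.items():
        for i, v in enumerate(vals):
            pid = protein_ids[i] if protein_ids else f"P{i:02d}"
            rows.append({"protein_id": pid, "compartment": "albumen",
                         "sample_id": sid, "replicate_id": rid,
                         "batch_id": bid, "intensity": v})
    return pd.DataFrame(rows)


class TestFilterIdentified:
    @pytest.mark.parametrize("reps,expected", [
        ([5.0, np.nan, 3.0], True),
        ([5.0, np.nan, np.nan], False),
        ([0.0, 2.0, 3.0], True),
        ([0.0, 0.0, 3.0], False),
    ])
    def test_two_positive_replicates_rule(self, reps, expected):
        t = long_table({("S1", r + 1, 1): [v] for r, v in enumerate(reps)})
        flags = quant.filter_identified(t)
        assert bool(flags["identified"].iloc[0]) is expected

    def test_single_replicate_never_identified(self, caplog):
        t = long_table({("S1", 1, 1): [9.0]})
        with caplog.at_level("WARNING"):
            flags = quant.filter_identified(t)
        assert not flags["identified"].iloc[0]
        assert "single replicate" in caplog.text

    def test_detection_fraction_matches_binomial(self):
        """Independent detection at p=0.5 over 3 replicates: the identified
        fraction approaches P(>=2 of 3) = 0.5."""
        rng = np.random.default_rng(99)
        n_prot = 4000
        data = {}
        for r in (1, 2, 3):
            vals = np.where(rng.uniform(size=n_prot) < 0.5, 1.0, np.nan)
            data[("S1", r, 1)] = vals
        flags = quant.filter_identified(long_table(data))
        frac = flags["identified"].mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n_prot)

    def test_duplicate_keys_rejected(self):
        t = long_table({("S1", 1, 1): [1.0]})
        with pytest.raises(ValueError, match="duplicate"):
            quant.filter_identified(pd.concat([t, t]))


class TestFilterQuantitated:
    def _flags(self, pattern, groups):
        rows = [{"protein_id": "P", "sample_id": f"S{i}", "identified": bool(b)}
                for i, b in enumerate(pattern)]
        labels = {f"S{i}": g for i, g in enumerate(groups)}
        return pd.DataFrame(rows), labels

    def test_kept_when_half_of_one_group(self):
        flags, labels = self._flags([1] * 6 + [0] * 4 + [0] * 10,
                                    ["A"] * 10 + ["B"] * 10)
        assert quant.filter_quantitated(flags, labels) == {"P"}

    def test_dropped_when_below_half_everywhere(self):
        flags, labels = self._flags([1] * 4 + [0] * 6 + [1] * 4 + [0] * 6,
                                    ["A"] * 10 + ["B"] * 10)
        assert quant.filter_quantitated(flags, labels) == set()

    def test_exhaustive_patterns_match_rule(self):
        """All 2^6 identification patterns over two groups of 3 agree with a
        direct evaluation of the rule."""
        labels = {f"S{i}": ("A" if i < 3 else "B") for i in range(6)}
        for pattern in itertools.product([0, 1], repeat=6):
            flags, _ = self._flags(pattern, ["A"] * 3 + ["B"] * 3)
            kept = quant.filter_quantitated(flags, labels)
            expect = sum(pattern[:3]) >= 2 or sum(pattern[3:]) >= 2
            assert (("P" in kept) == expect), pattern

    def test_missing_group_label_rejected(self):
        flags, labels = self._flags([1, 1], ["A", "A"])
        with pytest.raises(ValueError, match="without a group label"):
            quant.filter_quantitated(flags, {"S0": "A"})


class TestNormalize:
    def test_values_become_shares(self):
        t = long_table({("S1", 1, 1): [2.0, 3.0, 5.0]})
        out = quant.normalize_total_signal(t)
        assert np.allclose(sorted(out["intensity"]), [0.2, 0.3, 0.5])

    def test_single_protein_identity(self):
        t = long_table({("S1", 1, 1): [7.0]})
        out = quant.normalize_total_signal(t)
        assert out["intensity"].iloc[0] == 1.0

    def test_zero_total_names_replicate(self):
        t = long_table({("S1", 1, 1): [np.nan, np.nan]})
        with pytest.raises(ValueError, match="S1"):
            quant.normalize_total_signal(t)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(2, 8), st.integers(1, 3), st.integers(0, 10_000))
    def test_replicate_sums_are_one(self, n_prot, n_rep, seed):
        rng = np.random.default_rng(seed)
        data = {("S1", r, 1): rng.uniform(0.1, 100, size=n_prot)
                for r in range(1, n_rep + 1)}
        out = quant.normalize_total_signal(long_table(data))
        sums = out.groupby(["sample_id", "replicate_id"])["intensity"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestImpute:
    def _one_run(self, observed, n_missing, seed=0):
        vals = list(observed) + [np.nan] * n_missing
        t = long_table({("S1", 1, 1): vals})
        norm = t.copy()  # already treat values as normalized shares
        return quant.impute_missing(norm, seed=seed)

    def test_values_within_bounds(self):
        obs = np.linspace(0.001, 0.02, 200)
        out = self._one_run(obs, 50)
        imput = out["intensity"].iloc[200:]
        lo, hi = 0.001, np.quantile(obs, 0.01)
        assert ((imput >= lo) & (imput <= hi)).all()

    def test_degenerate_interval_gives_constant(self):
        out = self._one_run([0.004, 0.004, 0.004], 5)
        assert np.allclose(out["intensity"], 0.004)

    def test_empty_run_rejected(self):
        t = long_table({("S1", 1, 1): [np.nan, np.nan]})
        with pytest.raises(ValueError, match="bounds undefined"):
            quant.impute_missing(t)

    def test_uniform_distribution(self):
        """10,000 imputed values in one run pass a KS test for uniformity."""
        obs = np.linspace(0.001, 0.05, 300)
        out = self._one_run(obs, 10_000, seed=3)
        imput = out["intensity"].iloc[300:].to_numpy()
        lo, hi = 0.001, np.quantile(obs, 0.01)
        p = stats.kstest(imput, stats.uniform(lo, hi - lo).cdf).pvalue
        assert p > 0.01

    def test_deterministic_and_order_invariant(self):
        obs = [0.01, 0.002, 0.03, np.nan, np.nan]
        t = long_table({("S1", 1, 1): obs})
        a = quant.impute_missing(t, seed=9)
        shuffled = t.sample(frac=1.0, random_state=1)
        b = quant.impute_missing(shuffled, seed=9).sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestConcentration:
    def test_arithmetic_with_field_means(self):
        """Share 0.2 of 43.4 mg albumen protein in 0.83 g albumen."""
        t = long_table({("S1", 1, 1): [0.2, 0.8]})
        out = quant.estimate_concentration(t, {"S1": 43.4}, {"S1": 0.83})
        got = out.loc[out["protein_id"] == "P00", "concentration"].iloc[0]
        assert got == pytest.approx(0.2 * 43.4 / 0.83, abs=5e-4)
        assert got == pytest.approx(10.458, abs=1e-3)

    def test_single_protein_equals_total_over_weight(self):
        t = long_table({("S1", 1, 1): [1.0]})
        out = quant.estimate_concentration(t, {"S1": 10.0}, {"S1": 2.0})
        assert out["concentration"].iloc[0] == pytest.approx(5.0)

    def test_conservation(self):
        rng = np.random.default_rng(4)
        raw = long_table({("S1", r, 1): rng.uniform(1, 50, 7)
                          for r in (1, 2)})
        norm = quant.normalize_total_signal(raw)
        out = quant.estimate_concentration(norm, {"S1": 20.0}, {"S1": 0.5})
        sums = out.groupby("replicate_id")["concentration"].sum()
        assert np.allclose(sums, 40.0, rtol=1e-6)

    def test_missing_total_rejected(self):
        t = long_table({("S1", 1, 1): [1.0]})
        with pytest.raises(ValueError, match="total protein"):
            quant.estimate_concentration(t, {}, {"S1": 1.0})


class TestSummarize:
    def _conc(self, rows):
        return pd.DataFrame(rows, columns=["protein_id", "sample_id",
                                           "replicate_id", "batch_id",
                                           "concentration"])

    def test_single_batch_collapses_to_mean(self):
        c = self._conc([("P", "S1", r, 1, v)
                        for r, v in enumerate([10.0, 12.0, 14.0], 1)])
        out = quant.summarize_replicates(c)
        assert out["concentration"].iloc[0] == pytest.approx(12.0)

    def test_single_measurement_identity(self):
        c = self._conc([("P", "S1", 1, 1, 3.5)])
        out = quant.summarize_replicates(c)
        assert out["concentration"].iloc[0] == pytest.approx(3.5)

    def test_batch_model_beats_raw_means(self):
        """With additive batch offsets, the mixed-model estimates are closer
        to the batch-free truth than raw replicate means (simulation)."""
        rng = np.random.default_rng(11)
        n_samples, n_prot = 12, 60
        rmse_model, rmse_mean = [], []
        for p in range(n_prot):
            truth = rng.uniform(5, 15, size=n_samples)
            offs = {1: rng.normal(0, 2.0), 2: rng.normal(0, 2.0)}
            rows = []
            for s in range(n_samples):
                batches = rng.choice([1, 2], size=2)
                for r, b in enumerate(batches, 1):
                    rows.append((f"P{p}", f"S{s:02d}", r, int(b),
                                 truth[s] + offs[int(b)] + rng.normal(0, 0.3)))
            c = self._conc(rows)
            if c["batch_id"].nunique() < 2:
                continue
            est = quant.summarize_replicates(c).set_index("sample_id")
            est = est.loc[[f"S{s:02d}" for s in range(n_samples)],
                          "concentration"].to_numpy()
            means = c.groupby("sample_id")["concentration"].mean().to_numpy()
            # a common offset is unidentifiable; compare centred errors
            rmse_model.append(np.sqrt(np.mean(
                ((est - est.mean()) - (truth - truth.mean())) ** 2)))
            rmse_mean.append(np.sqrt(np.mean(
                ((means - means.mean()) - (truth - truth.mean())) ** 2)))
        assert np.mean(rmse_model) < np.mean(rmse_mean)
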