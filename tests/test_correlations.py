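import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from droughtnet import correlations, io_prep, synth


def brute_force_bh(p):
    """Step-up oracle: q_i = min_{j >= rank(i)} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        j = m - rank_from_top
        prev = min(prev, m * p[idx] / j)
        q[idx] = min(prev, 1.0)
    return q


def brute_force_spearman(x, y):
    rx, ry = rankdata(x), rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearmanRecords:
    def make_table(self, cols):
        return pd.DataFrame(cols)

    def test_monotone_pair_rho_one(self):
        t = self.make_table({"a": [1, 2, 3, 4, 5], "b": [10, 20, 40, 80, 100]})
        recs = correlations.spearman_records(t)
        assert recs["rho"].iloc[0] == pytest.approx(1.0)

    def test_negation_rho_minus_one(self):
        t = self.make_table({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        assert correlations.spearman_records(t)["rho"].iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        t = self.make_table({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        assert correlations.spearman_records(t)["rho"].iloc[0] == pytest.approx(0.8)

    def test_matches_brute_force_on_random_tables(self, rng):
        t = pd.DataFrame(rng.integers(0, 30, size=(12, 5)), columns=list("abcde"))
        recs = correlations.spearman_records(t).set_index(["taxon_a", "taxon_b"])
        for (a, b), row in recs.iterrows():
            assert row["rho"] == pytest.approx(brute_force_spearman(t[a], t[b]))

    def test_constant_taxon_dropped(self):
        t = self.make_table({"a": [1, 2, 3, 4], "b": [2, 2, 2, 2], "c": [4, 3, 2, 1]})
        recs = correlations.spearman_records(t)
        pairs = set(map(tuple, recs[["taxon_a", "taxon_b"]].to_numpy()))
        assert pairs == {("a", "c")}

    def test_too_few_samples_rejected(self):
        t = self.make_table({"a": [1, 2, 3], "b": [3, 2, 1]})
        with pytest.raises(ValueError, match="at least 4"):
            correlations.spearman_records(t)

    def test_invariant_to_monotone_transform(self, rng):
        t = pd.DataFrame(rng.integers(1, 50, size=(10, 4)))
        a = correlations.spearman_records(t)
        b = correlations.spearman_records(np.log(t * 3))
        np.testing.assert_allclose(a["rho"], b["rho"], atol=1e-12)


class TestBhFdr:
    def test_hand_applied_step_up(self):
        q = correlations.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_p_unchanged(self):
        q = correlations.bh_fdr(np.full(5, 0.2))
        np.testing.assert_allclose(q, 0.2)

    def test_single_p_identity(self):
        assert correlations.bh_fdr(np.array([0.07]))[0] == pytest.approx(0.07)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            correlations.bh_fdr(np.array([0.5, 1.2]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 60))
        np.testing.assert_allclose(correlations.bh_fdr(p), brute_force_bh(p), atol=1e-12)


class TestLinkClasses:
    def kingdoms(self):
        return pd.Series(
            {"b1": "bacteria", "b2": "bacteria", "f1": "fungi", "f2": "fungi"}
        )

    def test_two_by_two_combinatorics(self):
        taxa = ["b1", "b2", "f1", "f2"]
        pairs = [(a, b) for i, a in enumerate(taxa) for b in taxa[i + 1:]]
        recs = pd.DataFrame(pairs, columns=["taxon_a", "taxon_b"])
        recs["rho"], recs["p"], recs["q"] = 0.5, 0.01, 0.02
        out = correlations.partition_link_classes(recs, self.kingdoms())
        counts = out["link_class"].value_counts()
        assert counts["BB"] == 1 and counts["FF"] == 1 and counts["BF"] == 4

    def test_unknown_kingdom_rejected(self):
        recs = pd.DataFrame({"taxon_a": ["b1"], "taxon_b": ["zz"]})
        with pytest.raises(ValueError, match="zz"):
            correlations.partition_link_classes(recs, self.kingdoms())

    def test_classes_exhaustive(self, small_dataset):
        table = pd.concat(
            [small_dataset.bacteria.iloc[:12, :6], small_dataset.fungi.iloc[:12, :6]],
            axis=1,
        )
        recs = correlations.spearman_records(table)
        out = correlations.partition_link_classes(recs, small_dataset.taxonomy["kingdom"])
        assert out["link_class"].isin(["BB", "FF", "BF"]).all()


class TestSummarize:
    def test_symmetric_example(self):
        recs = pd.DataFrame({"rho": [0.5, -0.5]})
        s = correlations.summarize(recs)
        assert s["mean_combined"] == 0
        assert s["mean_positive"] == 0.5
        assert s["mean_negative_x_minus1"] == 0.5
        assert s["fraction_positive"] == 0.5

    def test_all_positive_fraction_one(self):
        s = correlations.summarize(pd.DataFrame({"rho": [0.1, 0.9]}))
        assert s["fraction_positive"] == 1 and s["mean_negative_x_minus1"] is None

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(20):
            rho = rng.uniform(-1, 1, size=rng.integers(2, 40))
            s = correlations.summarize(pd.DataFrame({"rho": rho}))
            assert s["mean_combined"] == pytest.approx(rho.mean())
            assert s["fraction_positive"] == pytest.approx((rho > 0).mean())
            if (rho > 0).any():
                assert s["mean_positive"] == pytest.approx(rho[rho > 0].mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            correlations.summarize(pd.DataFrame({"rho": []}))


class TestSghContrast:
    def test_zero_permutations_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            correlations.sgh_contrast({}, small_dataset.taxonomy["kingdom"], n_perm=0)

    def test_drought_activated_ff_block_detected(self):
        """A stress-only FF block shows as a positive-correlation increase.

        Under compositional closure a planted block's positive pairs are
        partly offset by induced negative block-vs-rest correlations, so
        the detection target is the positive-correlation estimate (the
        mean over rho > 0), which the block moves cleanly.
        """
        eff = synth.EffectSpec(
            kingdom_drought_shift={"bacteria": 0, "fungi": 0},
            kingdom_recovery_rate={"bacteria": 0, "fungi": 0},
            correlation_blocks=(
                synth.CorrelationBlock(8, 0.9, "FF", condition="stressed"),
            ),
            stress_factor_loading=0.0,
        )
        design = synth.DesignSpec(compartments=("rhizosphere",))
        hits = 0
        for seed in range(5):
            data = synth.generate_counts(design, eff, 20, 40, seed=seed)
            bact = io_prep.rarefy(data.bacteria, 10_000, seed)
            fung = io_prep.rarefy(data.fungi, 10_000, seed + 1)
            meta = data.metadata
            win, wmeta = io_prep.split_windows(
                pd.concat([bact, fung], axis=1), meta
            )["drought"]
            tabs = {
                tr: win.loc[wmeta["treatment"] == tr] for tr in ("control", "drought")
            }
            sg = correlations.sgh_contrast(
                {"rhizosphere": (tabs["control"], tabs["drought"])},
                data.taxonomy["kingdom"], n_perm=99, seed=seed,
            )
            row = sg[(sg.stratum == "rhizosphere") & (sg.link_class == "FF")
                     & (sg.statistic == "mean_positive")].iloc[0]
            hits += (row["effect"] > 0) and (row["direction"] == "increase")
        assert hits >= 4

    def test_permutation_p_valid_under_exchangeability(self, null_dataset):
        """Treatment == control in distribution: p should not be extreme."""
        bact = io_prep.rarefy(null_dataset.bacteria, 10_000, seed=3)
        win, wmeta = io_prep.split_windows(bact.iloc[:, :15], null_dataset.metadata)["drought"]
        tabs = {tr: win.loc[wmeta["treatment"] == tr] for tr in ("control", "drought")}
        sg = correlations.sgh_contrast(
            {"rhizosphere": (tabs["control"], tabs["drought"])},
            null_dataset.taxonomy["kingdom"], n_perm=199, seed=0,
        )
        assert (sg["p"] >= 1 / 200).all() and (sg["p"] <= 1).all()
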