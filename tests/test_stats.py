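import itertools

import numpy as np
import pytest

from nonbscan.stats import (
    bh_adjust,
    iqr_trim,
    ks_two_sample,
    one_sample_t,
    rank_by_mean_likelihood,
    temperature_sweep_report,
)
from nonbscan.tracks import SistTable


def brute_ks_d(a, b):
    """Oracle: scan |ECDF_a - ECDF_b| at every pooled point."""
    a, b = np.sort(a), np.sort(b)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


class TestIqrTrim:
    def test_worked_example(self):
        # Q1=2, Q3=4 (linear interpolation), IQR=2, upper fence 7
        assert iqr_trim([1, 2, 3, 4, 100]).tolist() == [1, 2, 3, 4]

    def test_constant_unchanged(self):
        assert iqr_trim([5, 5, 5, 5, 5]).tolist() == [5] * 5

    def test_fewer_than_four_warns(self):
        with pytest.warns(UserWarning):
            out = iqr_trim([1, 100])
        assert out.tolist() == [1, 100]

    def test_order_preserved(self):
        assert iqr_trim([4, 1, 100, 3, 2]).tolist() == [4, 1, 3, 2]

    def test_second_pass_is_subset(self, rng):
        # single-pass trimming (quartiles of the input data) is not
        # strictly idempotent: removing points shrinks the IQR; a second
        # pass may only ever remove further values, never restore any
        for _ in range(20):
            vals = rng.normal(size=30)
            once = set(iqr_trim(vals).tolist())
            twice = set(iqr_trim(list(once)).tolist())
            assert twice <= once

    def test_normal_trim_fraction(self, rng):
        """Monte Carlo: expected trim fraction on clean normal data ~0.7%."""
        trimmed = 0
        total = 0
        for _ in range(300):
            vals = rng.normal(size=100)
            trimmed += len(vals) - len(iqr_trim(vals))
            total += len(vals)
        frac = trimmed / total
        assert 0.002 < frac < 0.02


class TestOneSampleT:
    def test_worked_example_against_formula(self):
        vals = [0.10, 0.12, 0.11, 0.09, 0.08]
        res = one_sample_t(vals, 0.20, trim=False)
        m, s = np.mean(vals), np.std(vals, ddof=1)
        t_oracle = (m - 0.20) / (s / np.sqrt(5))
        assert res.statistic == pytest.approx(t_oracle)
        assert res.direction == "centromere_higher"
        assert res.p_value < 0.05 and res.significant

    def test_equal_mean_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = one_sample_t(vals, float(np.mean(vals)), trim=False)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_degenerate_equal(self):
        res = one_sample_t([2.0] * 6, 2.0)
        assert res.degenerate and res.p_value == 1.0 and not res.significant

    def test_degenerate_different(self):
        res = one_sample_t([2.0] * 6, 3.0)
        assert res.degenerate and res.p_value == 0.0
        assert res.direction == "centromere_higher" and not res.significant

    def test_lower_centromere_not_enriched(self):
        res = one_sample_t([0.5, 0.6, 0.55, 0.52, 0.58], 0.1, trim=False)
        assert res.direction == "controls_higher"
        assert res.p_value < 0.05 and not res.significant
        assert res.verdict == "controls_enriched"

    def test_trimming_applied_to_controls(self):
        vals = [0.1, 0.11, 0.09, 0.1, 5.0]
        res = one_sample_t(vals, 0.3)
        assert res.n_trimmed == 1
        assert 5.0 not in res.control_values

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 2.0], 0.5, trim=False)


class TestKs:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = ks_two_sample([0, 0, 0], [1, 1, 1])
        assert res.statistic == 1.0

    def test_worked_half(self):
        res = ks_two_sample([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.statistic == pytest.approx(0.5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_oracle_equivalence_random_integer_samples(self, rng):
        for _ in range(300):
            na, nb = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            a = rng.integers(0, 6, size=na)
            b = rng.integers(0, 6, size=nb)
            res = ks_two_sample(a, b)
            assert res.statistic == pytest.approx(brute_ks_d(a, b))

    def test_oracle_equivalence_exhaustive_binary(self):
        for na, nb in itertools.product((1, 2, 3), repeat=2):
            for a in itertools.product((0, 1), repeat=na):
                for b in itertools.product((0, 1), repeat=nb):
                    res = ks_two_sample(list(a), list(b))
                    assert res.statistic == pytest.approx(
                        brute_ks_d(np.array(a), np.array(b))
                    )

    def test_direction_from_means(self):
        res = ks_two_sample([5, 6, 7], [1, 2, 3])
        assert res.direction == "centromere_higher"


class TestRanking:
    def test_basic_ranks(self):
        tracks = {
            "a": np.full(10, 2.0),
            "b": np.full(10, 1.0),
            "c": np.full(10, 3.0),
        }
        df = rank_by_mean_likelihood(tracks)
        by_unit = df.set_index("unit")["rank"].to_dict()
        assert by_unit == {"c": 1, "a": 2, "b": 3}

    def test_zero_track_last(self):
        tracks = {"a": np.full(5, 1.0), "z": np.zeros(5)}
        df = rank_by_mean_likelihood(tracks)
        assert df[df.unit == "z"]["rank"].item() == 2

    def test_ties_share_min_rank_and_flagged(self):
        tracks = {"a": np.full(5, 1.0), "b": np.full(5, 1.0), "c": np.zeros(5)}
        df = rank_by_mean_likelihood(tracks)
        assert set(df[df.tied]["unit"]) == {"a", "b"}
        assert df[df.unit == "a"]["rank"].item() == 1
        assert df[df.unit == "b"]["rank"].item() == 1
        assert df[df.unit == "c"]["rank"].item() == 3

    def test_percentile(self):
        tracks = {f"c{i}": np.full(3, float(i)) for i in range(10)}
        df = rank_by_mean_likelihood(tracks)
        assert df.iloc[0]["percentile"] == pytest.approx(0.1)

    def test_interval_units(self):
        from nonbscan.seqio import Interval

        tracks = {"a": np.concatenate([np.zeros(5), np.full(5, 3.0)])}
        units = [Interval("a", 0, 5), Interval("a", 5, 10)]
        df = rank_by_mean_likelihood(tracks, units)
        assert df.iloc[0]["unit"] == "a:5-10"

    def test_zero_length_unit_errors(self):
        with pytest.raises(ValueError):
            rank_by_mean_likelihood({"a": np.zeros(0)})


class TestTemperatureSweep:
    def _tables(self, rng, mean_map, n=4000):
        """mean_map: (structure, temp) -> mean for centromere; controls flat 0.1."""
        import itertools as it

        temps = (18, 22, 25, 30, 35)
        k = 80.0
        cen, ctl = {}, {}
        for t in temps:
            vals = {}
            for s in ("melt", "cruciform", "zdna"):
                m = mean_map.get((s, t), 0.1)
                vals[s] = rng.beta(m * k, (1 - m) * k, size=n)
            cen[t] = SistTable("cen", t, vals["melt"], vals["cruciform"], vals["zdna"])
            ctl[t] = [
                SistTable(
                    f"c{i}",
                    t,
                    rng.beta(0.1 * k, 0.9 * k, size=n),
                    rng.beta(0.1 * k, 0.9 * k, size=n),
                    rng.beta(0.1 * k, 0.9 * k, size=n),
                )
                for i in range(3)
            ]
        return cen, ctl

    def test_planted_pattern_recovered(self, rng):
        cen, ctl = self._tables(rng, {("melt", 25): 0.3, ("melt", 30): 0.3})
        df = temperature_sweep_report(cen, ctl)
        enriched = {
            (r.structure, r.temperature)
            for r in df.itertuples()
            if r.verdict == "centromere_enriched"
        }
        assert {("melt", 25), ("melt", 30)} <= enriched

    def test_identical_tables_not_significant(self):
        vals = np.full(500, 0.1)
        cen = {25: SistTable("cen", 25, vals, vals, vals)}
        ctl = {25: [SistTable("c1", 25, vals, vals, vals)]}
        df = temperature_sweep_report(cen, ctl)
        assert (df.verdict == "not_significant").all()

    def test_monotone_means_reported(self, rng):
        mean_map = {("melt", t): 0.1 + 0.02 * i for i, t in enumerate((18, 22, 25, 30, 35))}
        cen, ctl = self._tables(rng, mean_map, n=2000)
        df = temperature_sweep_report(cen, ctl)
        melt = df[df.structure == "melt"].sort_values("temperature")
        assert melt.centromere_mean.is_monotonic_increasing

    def test_missing_temperature_warns(self, rng):
        cen, ctl = self._tables(rng, {}, n=200)
        del ctl[30]
        with pytest.warns(UserWarning):
            df = temperature_sweep_report(cen, ctl)
        assert 30 not in set(df.temperature)


class TestBh:
    def test_monotone_and_bounded(self, rng):
        p = rng.random(20)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)

    def test_known_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj[0] == pytest.approx(0.04)
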