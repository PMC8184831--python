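"""Δmet profiles, dispersion-shrunk testing, HMR calling, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hitransmet as ht
from hitransmet import diffmeth as dm


def meth_table(offsets, pcts, n=100, masked=None):
    offsets = np.asarray(offsets)
    pcts = np.asarray(pcts, dtype=float)
    masked = np.zeros(len(offsets), dtype=bool) if masked is None else np.asarray(masked)
    n_total = np.full(len(offsets), n)
    return pd.DataFrame(
        {
            "offset": offsets,
            "n_meth": np.round(pcts / 100 * n_total).astype(int),
            "n_total": n_total,
            "pct": pcts,
            "masked": masked,
        }
    )


def stats_profile(offsets, y_wt, y_sc, n=500, motif="X"):
    y_wt, y_sc = np.asarray(y_wt), np.asarray(y_sc)
    prof = pd.DataFrame(
        {
            "motif": motif,
            "offset": np.asarray(offsets),
            "n_meth_wt": y_wt,
            "n_total_wt": n,
            "pct_wt": 100 * y_wt / n,
            "n_meth_sc": y_sc,
            "n_total_sc": n,
            "pct_sc": 100 * y_sc / n,
        }
    )
    prof["delta"] = prof["pct_wt"] - prof["pct_sc"]
    return dm.add_statistics(prof)


class TestDeltaMet:
    def test_difference_in_percentage_points(self):
        wt = meth_table([0], [30.0])
        sc = meth_table([0], [50.0])
        prof = ht.delta_met(wt, sc, "m")
        assert prof["delta"].iloc[0] == pytest.approx(-20.0)

    def test_identical_tables_give_zero(self):
        t = meth_table([0, 10, 40], [30.0, 60.0, 90.0])
        assert (ht.delta_met(t, t)["delta"] == 0).all()

    def test_masked_offset_absent(self):
        wt = meth_table([0, 10], [30.0, 40.0], masked=[True, False])
        sc = meth_table([0, 10], [50.0, 50.0])
        with pytest.warns(UserWarning, match="unmatched"):
            prof = ht.delta_met(wt, sc)
        assert prof["offset"].tolist() == [10]

    def test_no_shared_cpgs_warns_empty(self):
        wt = meth_table([0], [30.0])
        sc = meth_table([5], [50.0])
        with pytest.warns(UserWarning):
            prof = ht.delta_met(wt, sc)
        assert prof.empty


class TestSmooth:
    def _profile(self, offsets, deltas, weights=None):
        n = len(offsets)
        w = np.full(n, 100) if weights is None else np.asarray(weights)
        return pd.DataFrame(
            {
                "offset": offsets,
                "delta": deltas,
                "n_total_wt": w,
                "n_total_sc": w,
            }
        )

    def test_isolated_cpg_unchanged(self):
        prof = self._profile([0, 100], [-10.0, -30.0])
        assert ht.smooth(prof).tolist() == [-10.0, -30.0]

    def test_two_close_cpgs_average(self):
        prof = self._profile([0, 10], [-10.0, -30.0])
        assert ht.smooth(prof).tolist() == [-20.0, -20.0]

    def test_constant_profile_is_fixed_point(self):
        prof = self._profile([0, 10, 20, 30], [-15.0] * 4)
        assert ht.smooth(prof).tolist() == [-15.0] * 4

    def test_coverage_weighting(self):
        prof = self._profile([0, 10], [-10.0, -40.0], weights=[300, 100])
        # weighted mean: (-10*600 - 40*200) / 800 = -17.5
        assert ht.smooth(prof).tolist() == [-17.5, -17.5]

    def test_tiling_cluster_preserves_weighted_mean(self):
        prof = self._profile([0, 8, 16], [-10.0, -20.0, -60.0])
        sm = ht.smooth(prof)
        assert np.average(sm, weights=[200] * 3) == pytest.approx(-30.0)


class TestTestCpg:
    def test_identical_counts_give_p_one(self):
        p, q = ht.test_cpg([50], [100], [50], [100])
        assert p[0] == 1.0 and q[0] == 1.0

    def test_extreme_difference_matches_two_proportion_z(self):
        p, _ = ht.test_cpg([0], [200], [200], [200], dispersion=0.0)
        pbar = 0.5
        z = -1.0 / np.sqrt(pbar * (1 - pbar) * (2 / 200))
        oracle = 2 * stats.norm.sf(abs(z))
        assert p[0] == pytest.approx(oracle, rel=0.1)

    def test_reduces_to_two_proportion_z_as_dispersion_vanishes(self):
        rng = np.random.default_rng(0)
        y1 = rng.binomial(100, 0.4, size=50)
        y2 = rng.binomial(100, 0.5, size=50)
        n = np.full(50, 100.0)
        p, _ = ht.test_cpg(y1, n, y2, n, dispersion=0.0)
        pbar = (y1 + y2) / 200
        z = (y1 / 100 - y2 / 100) / np.sqrt(pbar * (1 - pbar) * (2 / 100))
        oracle = 2 * stats.norm.sf(np.abs(z))
        assert np.allclose(p, oracle)

    def test_zero_variance_gives_p_one(self):
        p, _ = ht.test_cpg([0, 100], [100, 100], [0, 100], [100, 100])
        assert (p == 1.0).all()

    def test_dispersion_estimate_recovers_truth_under_null(self):
        rng = np.random.default_rng(4)
        n, phi = 200, 0.05
        s = (1 - phi) / phi
        p = rng.beta(0.6 * s, 0.4 * s, size=(2, 2000))
        y1, y2 = rng.binomial(n, p[0]), rng.binomial(n, p[1])
        tot = np.full(2000, float(n))
        _, phi_bar = dm.estimate_dispersion(
            y1.astype(float), tot, y2.astype(float), tot
        )
        assert phi_bar == pytest.approx(phi, rel=0.25)


def run_profile(offsets, deltas, q=0.001):
    """Profile with explicit delta/q columns, to exercise the run rule."""
    deltas = np.asarray(deltas, dtype=float)
    return pd.DataFrame(
        {
            "motif": "X",
            "offset": np.asarray(offsets),
            "delta": deltas,
            "smoothed_delta": deltas,
            "q_value": np.broadcast_to(q, deltas.shape).astype(float),
        }
    )


class TestCallHmrs:
    def test_three_qualifying_cpgs_spanning_sixty(self):
        hmrs = ht.call_hmrs(run_profile([0, 30, 60], [-20, -20, -20]))
        assert len(hmrs) == 1
        h = hmrs[0]
        assert (h.start, h.end, h.n_cpgs) == (0, 60, 3)

    def test_span_of_forty_rejected(self):
        assert ht.call_hmrs(run_profile([0, 20, 40], [-20, -20, -20])) == []

    def test_flat_profile_yields_nothing(self):
        assert ht.call_hmrs(run_profile([0, 30, 60], [0, 0, 0])) == []

    def test_two_qualifying_cpgs_rejected(self):
        assert ht.call_hmrs(run_profile([0, 60], [-20, -20])) == []

    def test_non_significant_run_rejected(self):
        prof = run_profile([0, 30, 60], [-20, -20, -20], q=0.2)
        assert ht.call_hmrs(prof) == []

    def test_hyper_direction_flag(self):
        prof = run_profile([0, 30, 60], [20, 20, 20])
        assert ht.call_hmrs(prof) == []
        assert len(ht.call_hmrs(prof, direction="hyper")) == 1

    def test_significant_deep_profile_end_to_end(self):
        # a realistic profile: mostly null CpGs plus one deep WT-hypo run
        offsets = [-200, -150, -100, -60, 0, 30, 60, 100, 150, 200]
        y_sc = [400] * 10
        y_wt = [400, 400, 400, 400, 300, 300, 300, 400, 400, 400]
        prof = stats_profile(offsets, y_wt, y_sc)
        hmrs = ht.call_hmrs(prof)
        assert len(hmrs) == 1 and (hmrs[0].start, hmrs[0].end) == (0, 60)

    def test_matches_exhaustive_run_scan_oracle(self):
        # random profiles with precomputed delta/q columns vs a brute-force
        # scan over all candidate windows
        def oracle(offsets, delta, q, min_span=50.0, min_cpgs=3,
                   min_delta=10.0, max_q=0.05):
            ok = (delta <= -min_delta) & (q <= max_q)
            found = []
            n = len(offsets)
            for i in range(n):
                for j in range(i + min_cpgs - 1, n):
                    window = ok[i : j + 1]
                    if not window.all():
                        continue
                    # maximal runs only
                    if i > 0 and ok[i - 1]:
                        continue
                    if j < n - 1 and ok[j + 1]:
                        continue
                    if offsets[j] - offsets[i] > min_span:
                        found.append((offsets[i], offsets[j], j - i + 1))
            return found

        rng = np.random.default_rng(77)
        for _ in range(300):
            m = rng.integers(3, 25)
            offsets = np.sort(rng.choice(500, size=m, replace=False))
            delta = rng.uniform(-30, 10, size=m)
            q = rng.uniform(0, 0.2, size=m)
            prof = pd.DataFrame(
                {
                    "motif": "X",
                    "offset": offsets,
                    "delta": delta,
                    "smoothed_delta": delta,
                    "q_value": q,
                }
            )
            got = [(h.start, h.end, h.n_cpgs) for h in ht.call_hmrs(prof, use_smoothed=False)]
            assert got == oracle(offsets, delta, q)


class TestDeltaDelta:
    def _prof(self, offsets, deltas):
        return pd.DataFrame({"offset": offsets, "delta": deltas})

    def test_identical_profiles_give_zero(self):
        p = self._prof([0, 10], [-30.0, -10.0])
        assert ht.delta_delta(p, p, "m").ddmet == 0.0

    def test_constant_difference(self):
        esc = self._prof([0, 10], [-30.0, -30.0])
        npp = self._prof([0, 10], [-10.0, -10.0])
        assert ht.delta_delta(esc, npp, "m").ddmet == pytest.approx(-20.0)

    def test_disjoint_offsets_warn_nan(self):
        with pytest.warns(UserWarning):
            rec = ht.delta_delta(self._prof([0], [-1.0]), self._prof([5], [-2.0]))
        assert np.isnan(rec.ddmet)


class TestCorrelateExpression:
    def test_perfect_negative_line(self):
        records = [
            dm.DeltaDeltaRecord(f"m{i}", float(i), -2.0 * i + 1) for i in range(5)
        ]
        r, p = ht.correlate_expression(records)
        assert r == pytest.approx(-1.0)
        assert p < 1e-6

    def test_fewer_than_three_records_rejected(self):
        records = [dm.DeltaDeltaRecord("a", 1.0, 1.0), dm.DeltaDeltaRecord("b", 2.0, 2.0)]
        with pytest.raises(dm.DiffMethError):
            ht.correlate_expression(records)

    def test_zero_variance_rejected(self):
        records = [dm.DeltaDeltaRecord(f"m{i}", 1.0, float(i)) for i in range(4)]
        with pytest.raises(dm.DiffMethError):
            ht.correlate_expression(records)

    def test_permuted_pairing_decorrelates(self):
        rng = np.random.default_rng(0)
        x = np.arange(20.0)
        rs = []
        for _ in range(200):
            y = rng.permutation(-2 * x)
            records = [
                dm.DeltaDeltaRecord(f"m{i}", x[i], y[i]) for i in range(20)
            ]
            rs.append(abs(ht.correlate_expression(records)[0]))
        assert np.mean(rs) < 0.3


class TestClusterMotifs:
    def _naive_complete_linkage(self, X):
        """O(n^3) agglomerative complete linkage; returns merge heights."""
        clusters = {i: [i] for i in range(len(X))}
        heights = []
        d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
        while len(clusters) > 1:
            best = None
            for a, b in itertools.combinations(sorted(clusters), 2):
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
            h, a, b = best
            heights.append(h)
            clusters[a] = clusters[a] + clusters.pop(b)
        return sorted(heights)

    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["a", "b", "c"]
        )
        linkage, order = ht.cluster_motifs(m)
        assert linkage[0, 2] == 0.0  # first merge at distance zero
        assert abs(order.index("a") - order.index("b")) == 1

    def test_merge_heights_match_naive_oracle(self):
        rng = np.random.default_rng(5)
        for n_leaves in (4, 5, 6):
            for _ in range(10):
                X = rng.normal(size=(n_leaves, 6))
                m = pd.DataFrame(X, index=[f"m{i}" for i in range(n_leaves)])
                linkage, _ = ht.cluster_motifs(m)
                assert np.allclose(
                    sorted(linkage[:, 2]), self._naive_complete_linkage(X)
                )

    def test_deterministic_under_row_permutation(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 4))
        m = pd.DataFrame(X, index=list("abcde"))
        _, order1 = ht.cluster_motifs(m)
        _, order2 = ht.cluster_motifs(m.iloc[[3, 1, 4, 0, 2]])
        assert order1 == order2

    def test_all_missing_row_dropped_with_warning(self):
        m = pd.DataFrame(
            [[1.0, 2.0], [np.nan, np.nan], [3.0, 1.0]], index=["a", "b", "c"]
        )
        with pytest.warns(UserWarning, match="all-missing"):
            _, order = ht.cluster_motifs(m)
        assert set(order) == {"a", "c"}

    def test_newick_output_parseable_with_all_leaves(self):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"))
        linkage, _ = ht.cluster_motifs(m)
        tree = Phylo.read(StringIO(ht.linkage_to_newick(linkage, list("abcde"))), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("abcde")
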