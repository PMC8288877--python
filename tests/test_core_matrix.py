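"""Expanded-matrix construction, filtering, shuffling and edge-list I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netpredict.core_matrix import (
    ExpandedMatrix,
    TemporalNetwork,
    build_expanded_matrix,
    filter_matrix,
    quantize_weights,
    read_temporal_edgelist,
    shuffle_matrix,
)

from conftest import make_filtered


def random_network(rng, n=4, T=5, weights=(1, 2, 3)):
    snaps = []
    for _ in range(T):
        edges = []
        for _ in range(int(rng.integers(0, 5))):
            u, v = int(rng.integers(n)), int(rng.integers(n))
            edges.append((u, v, int(rng.choice(weights))))
        # deduplicate links within a snapshot to keep the round trip exact
        edges = list({(u, v): (u, v, w) for u, v, w in edges}.values())
        snaps.append(edges)
    return TemporalNetwork(n=n, snapshots=snaps, directed=True)


class TestBuildExpandedMatrix:
    def test_row_count_is_n_squared(self, rng):
        M = build_expanded_matrix(random_network(rng, n=4))
        assert M.L == 16

    def test_single_edge_placement(self):
        net = TemporalNetwork(n=2, snapshots=[[(0, 1, 3)], []])
        M = build_expanded_matrix(net)
        assert M.values.shape == (4, 2)
        assert M.values[0 * 2 + 1].tolist() == [3, 0]
        assert M.values.sum() == 3

    def test_column_reproduces_snapshot_round_trip(self, rng):
        for _ in range(10):
            net = random_network(rng)
            M = build_expanded_matrix(net)
            rebuilt = build_expanded_matrix(
                TemporalNetwork(n=net.n, snapshots=M.to_snapshots())
            )
            assert np.array_equal(M.values, rebuilt.values)

    def test_undirected_populates_both_pairs(self):
        net = TemporalNetwork(
            n=3, snapshots=[[(0, 1, 1)]], directed=False
        )
        M = build_expanded_matrix(net)
        assert M.values[0 * 3 + 1, 0] == 1
        assert M.values[1 * 3 + 0, 0] == 1

    def test_continuous_weights_require_quantization(self):
        net = TemporalNetwork(n=2, snapshots=[[(0, 1, 0.37)]])
        with pytest.raises(ValueError, match="quantize"):
            build_expanded_matrix(net)
        M = build_expanded_matrix(net, bins=10)
        assert M.values.max() >= 1

    def test_csv_round_trip_labels(self, tmp_path, rng):
        M = build_expanded_matrix(random_network(rng, n=3))
        path = tmp_path / "m.csv"
        M.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header.startswith("link,t0,")


class TestQuantize:
    def test_zeros_preserved_and_alphabet_finite(self):
        vals = np.array([[0.0, 0.2, 1.7], [0.0, 0.9, 0.2]])
        q = quantize_weights(vals, bins=4)
        assert q[0, 0] == 0 and q[1, 0] == 0
        assert set(np.unique(q)) <= set(range(5))
        assert q[0, 2] == 4  # max value lands in the top bin


class TestFilterMatrix:
    @staticmethod
    def from_rates(rates, T=20):
        rows = []
        for a in rates:
            row = np.zeros(T, dtype=int)
            row[: int(round(a * T))] = 1
            rows.append(row)
        links = np.array([(0, i) for i in range(len(rates))])
        return ExpandedMatrix(values=np.array(rows), row_links=links, n_nodes=1)

    def test_sixty_percent_rule(self):
        # rates (0.9, 0.5, 0.05): 0.6·total = 0.87 is reached by the first row
        Mf = filter_matrix(self.from_rates([0.9, 0.5, 0.05]), m_theta=1000)
        assert Mf.m == 1
        assert Mf.activation_rates[0] == pytest.approx(0.9)

    def test_m_theta_branch_keeps_most_active(self):
        # 2000 identical low-activity rows: m60 = 1200 >= m_theta, m10 = 0
        Mf = filter_matrix(self.from_rates([0.05] * 2000), m_theta=1000)
        assert Mf.m == 1000

    def test_single_full_row_kept_unchanged(self):
        Mf = filter_matrix(self.from_rates([1.0]))
        assert Mf.m == 1
        assert (Mf.values == 1).all()

    def test_rows_sorted_descending_with_stable_ties(self):
        Mf = filter_matrix(self.from_rates([0.5, 0.9, 0.5, 0.7]), m_theta=1000)
        assert (np.diff(Mf.activation_rates) <= 0).all()
        # the two tied 0.5-rows keep original order (links (0,0) then (0,2))
        tied = Mf.row_links[Mf.activation_rates == 0.5][:, 1].tolist()
        assert tied == sorted(tied)

    def test_refiltering_is_identity(self):
        Mf = filter_matrix(self.from_rates([0.9, 0.7, 0.5]), m_theta=1000)
        again = filter_matrix(
            ExpandedMatrix(values=Mf.values, row_links=Mf.row_links, n_nodes=1),
            m_theta=1000,
        )
        assert np.array_equal(Mf.values[: again.m], again.values)

    def test_all_zero_rows_never_retained(self):
        Mf = filter_matrix(self.from_rates([0.4, 0.0, 0.3], T=10), m_theta=1000)
        assert (Mf.activation_rates > 0).all()

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="no active links"):
            filter_matrix(self.from_rates([0.0, 0.0]))

    def test_filtering_never_edits_entries(self, rng):
        net = random_network(rng, n=5, T=8)
        M = build_expanded_matrix(net)
        Mf = filter_matrix(M)
        assert set(np.unique(Mf.values)) <= set(np.unique(M.values))


class TestShuffleMatrix:
    def test_value_multiset_preserved(self, rng):
        Mf = make_filtered(rng.integers(0, 4, (6, 9)))
        for mode in ("global", "per_row"):
            out = shuffle_matrix(Mf, mode, seed=3)
            assert np.array_equal(
                np.sort(out.values.ravel()), np.sort(Mf.values.ravel())
            )

    def test_single_cell_unchanged(self):
        Mf = make_filtered(np.array([[7]]))
        assert shuffle_matrix(Mf, "global", seed=0).values[0, 0] == 7

    def test_per_row_preserves_activation_rates(self, rng):
        for seed in range(20):
            Mf = make_filtered(rng.integers(0, 2, (5, 12)))
            out = shuffle_matrix(Mf, "per_row", seed=seed)
            assert np.array_equal(
                (out.values != 0).sum(axis=1), (Mf.values != 0).sum(axis=1)
            )

    def test_seed_determinism_and_mode_validation(self, rng):
        Mf = make_filtered(rng.integers(0, 3, (4, 6)))
        a = shuffle_matrix(Mf, "global", seed=11).values
        b = shuffle_matrix(Mf, "global", seed=11).values
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            shuffle_matrix(Mf, "diagonal", seed=0)


class TestReadTemporalEdgelist:
    def test_window_binning(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a\tb\t0\na\tb\t5\nb\tc\t12\n")
        net = read_temporal_edgelist(p, window=10)
        assert net.T == 2
        # two events of the same link in one window aggregate by sum
        assert net.snapshots[0] == [(0, 1, 2.0)]

    def test_undirected_symmetrization(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("0\t1\t0\n")
        net = read_temporal_edgelist(p, window=1, directed=False)
        M = build_expanded_matrix(net)
        assert M.values[0 * 2 + 1, 0] == 1 and M.values[1 * 2 + 0, 0] == 1

    def test_comments_only_is_empty(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("# just a comment\n\n")
        with pytest.raises(ValueError, match="no events"):
            read_temporal_edgelist(p, window=1)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("0\t1\t0\n0\t1\n")
        with pytest.raises(ValueError, match=":2"):
            read_temporal_edgelist(p, window=1)

    def test_nonpositive_window_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("0\t1\t0\n")
        with pytest.raises(ValueError):
            read_temporal_edgelist(p, window=0)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    st.lists(st.integers(0, 3), min_size=4, max_size=24)
    .filter(lambda xs: any(xs))
    .map(lambda xs: xs[: len(xs) - len(xs) % 2])
)
def test_shuffle_conservation_property(values):
    vals = np.array(values).reshape(2, -1)
    Mf = make_filtered(vals)
    out = shuffle_matrix(Mf, "global", seed=1)
    assert sorted(out.values.ravel()) == sorted(vals.ravel())
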