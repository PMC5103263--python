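import numpy as np
import pandas as pd
import pytest

from digraphlets import (
    CohortRecord,
    DirectedNetwork,
    consensus,
    consensus_mask,
    regional_class_comparison,
    read_manifest,
    significance_mask,
    write_network,
)
from digraphlets.counts import SIGNATURE_COLUMNS
from digraphlets.gcm import GraphletCorrelationMatrix

COLS = list(SIGNATURE_COLUMNS)


def gcm_with(entries: dict[tuple[int, int], float]) -> GraphletCorrelationMatrix:
    """A 16x16 GCM with unit diagonal, given symmetric entries, zeros
    elsewhere; NaN entries allowed."""
    v = np.eye(16)
    for (i, j), r in entries.items():
        v[i, j] = v[j, i] = r
    df = pd.DataFrame(v, index=COLS, columns=COLS)
    return GraphletCorrelationMatrix(df, df.notna())


class TestConsensus:
    def test_hand_computed_percentages(self):
        """Entry values (0.8, 0.9, 0.75, -0.2, 0.71) over 5 subjects: 4 of 5
        exceed 0.7, none are below -0.7."""
        gcms = [gcm_with({(0, 1): r}) for r in (0.8, 0.9, 0.75, -0.2, 0.71)]
        m = consensus(gcms)
        assert m.positive_pct.iloc[0, 1] == pytest.approx(80.0)
        assert m.negative_pct.iloc[0, 1] == pytest.approx(0.0)

    def test_identical_negative_entry_gives_100(self):
        gcms = [gcm_with({(2, 3): -0.9})] * 4
        m = consensus(gcms)
        assert m.negative_pct.iloc[2, 3] == pytest.approx(100.0)

    def test_single_subject_reproduces_its_mask(self):
        c = gcm_with({(0, 1): 0.9, (0, 2): -0.8, (3, 4): 0.5})
        m = consensus([c])
        mask = significance_mask(c)
        assert np.array_equal(
            m.positive_pct.to_numpy() == 100.0, mask.to_numpy() == 1
        )
        assert np.array_equal(
            m.negative_pct.to_numpy() == 100.0, mask.to_numpy() == -1
        )

    def test_subject_order_invariance(self):
        gcms = [gcm_with({(0, 1): r}) for r in (0.8, -0.9, 0.2, 0.75)]
        a = consensus(gcms)
        b = consensus(gcms[::-1])
        assert a.positive_pct.equals(b.positive_pct)
        assert a.negative_pct.equals(b.negative_pct)

    def test_undefined_entries_count_as_not_significant(self):
        gcms = [gcm_with({(0, 1): np.nan}), gcm_with({(0, 1): 0.9})]
        m = consensus(gcms)
        assert m.positive_pct.iloc[0, 1] == pytest.approx(50.0)

    def test_planted_fraction_recovered(self):
        """70% of subjects with a strongly correlated column pair: the
        consensus percentage equals the planted fraction exactly when the
        per-subject correlation is deterministic."""
        rng = np.random.default_rng(11)
        gcms = []
        for s in range(20):
            r = 0.95 if s < 14 else float(rng.uniform(-0.5, 0.5))
            gcms.append(gcm_with({(5, 11): r}))
        m = consensus(gcms)
        assert m.positive_pct.iloc[5, 11] == pytest.approx(70.0)


class TestConsensusMask:
    def test_strict_at_min_percent(self):
        gcms = [gcm_with({(0, 1): 0.9})] * 3 + [gcm_with({})] * 2
        m = consensus(gcms)  # 60% exactly
        assert consensus_mask(m, 60).iloc[0, 1] == 0
        assert consensus_mask(m, 59.9).iloc[0, 1] == 1

    def test_negative_side(self):
        gcms = [gcm_with({(0, 1): -0.9})] * 7 + [gcm_with({})] * 3
        assert consensus_mask(consensus(gcms), 60).iloc[0, 1] == -1

    def test_monotone_in_percent(self):
        rng = np.random.default_rng(5)
        gcms = [
            gcm_with({(0, 1): rng.uniform(-1, 1), (2, 3): rng.uniform(-1, 1)})
            for _ in range(10)
        ]
        m = consensus(gcms)
        prev = np.abs(consensus_mask(m, 10).to_numpy())
        for p in (30, 50, 70, 90):
            cur = np.abs(consensus_mask(m, p).to_numpy())
            assert np.all(cur <= prev)  # raising p only turns entries off
            prev = cur

    def test_invalid_percent(self):
        m = consensus([gcm_with({})])
        with pytest.raises(ValueError, match="min_percent"):
            consensus_mask(m, 0)


def out_star(labels, centre, leaves):
    return [(centre, leaf) for leaf in leaves]


def build_cohort(n_regions=40, n_subjects=5, planted_frac=0.3, seed=0):
    """Subjects whose inhibitory network gives a planted subset of regions an
    out-star (W_out excess) absent from the excitatory network."""
    rng = np.random.default_rng(seed)
    labels = [f"r{k}" for k in range(n_regions)]
    planted = set(range(int(planted_frac * n_regions)))
    # leaves live on a reserved tail of vertices so stars stay induced
    records = []
    for s in range(n_subjects):
        base = [(labels[2 * k], labels[2 * k + 1]) for k in range(3)]
        exc = DirectedNetwork.from_arcs_labelled(base, labels=labels)
        inh_pairs = list(base)
        for r in planted:
            leaves = rng.choice(np.arange(n_regions - 8, n_regions), 4, replace=False)
            inh_pairs += out_star(labels, labels[r], [labels[l] for l in leaves])
        inh = DirectedNetwork.from_arcs_labelled(inh_pairs, labels=labels)
        records.append(CohortRecord(f"s{s}", exc, inh))
    return records, planted


class TestRegionalComparison:
    def test_identical_deltas_flag_nothing(self):
        labels = ["a", "b", "c", "d"]
        net = DirectedNetwork.from_arcs_labelled([("a", "b")], labels=labels)
        cohort = [CohortRecord(f"s{k}", net, net) for k in range(3)]
        res = regional_class_comparison(cohort, "W_out")
        assert res.pct_greater_inhibitory == 0
        assert res.pct_greater_excitatory == 0

    def test_outlier_region_flagged_inhibitory(self):
        labels = [f"r{k}" for k in range(12)]
        exc = DirectedNetwork.from_arcs_labelled([("r10", "r11")], labels=labels)
        inh_pairs = [("r10", "r11")] + [("r0", f"r{k}") for k in range(4, 9)]
        inh = DirectedNetwork.from_arcs_labelled(inh_pairs, labels=labels)
        cohort = [CohortRecord(f"s{k}", exc, inh) for k in range(3)]
        res = regional_class_comparison(cohort, "W_out")
        assert res.table.loc["r0", "verdict"] == "greater_in_inhibitory"

    def test_planted_fraction_recovered(self):
        records, planted = build_cohort(n_regions=40, planted_frac=0.3, seed=3)
        res = regional_class_comparison(records, "W_out")
        flagged = set(
            np.flatnonzero(res.table["verdict"] == "greater_in_inhibitory")
        )
        assert flagged == planted
        assert res.pct_greater_inhibitory == pytest.approx(30.0)

    def test_mismatched_labels_rejected(self):
        a = DirectedNetwork(["x", "y", "z"], [])
        b = DirectedNetwork(["x", "y", "w"], [])
        with pytest.raises(ValueError):
            CohortRecord("s0", a, b)

    def test_needs_two_subjects(self):
        net = DirectedNetwork(["a", "b", "c"], [])
        with pytest.raises(ValueError, match="2 subjects"):
            regional_class_comparison([CohortRecord("s", net, net)])


def test_manifest_round_trip(tmp_path):
    labels = ["a", "b", "c"]
    exc = DirectedNetwork.from_arcs_labelled([("a", "b")], labels=labels)
    inh = DirectedNetwork.from_arcs_labelled([("b", "c"), ("c", "b")], labels=labels)
    write_network(exc, tmp_path / "s0_exc.tsv")
    write_network(inh, tmp_path / "s0_inh.tsv")
    (tmp_path / "manifest.tsv").write_text("s0\ts0_exc.tsv\ts0_inh.tsv\n")
    (rec,) = read_manifest(tmp_path / "manifest.tsv")
    assert rec.subject_id == "s0"
    assert rec.excitatory == exc and rec.inhibitory == inh
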