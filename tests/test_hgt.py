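import pytest

from phyprof import simulate
from phyprof.classify import SequenceRecord
from phyprof.hgt import (HgtCall, IncomparableError, anomaly_score,
                         assign_donor, cluster_events, flag, identity,
                         origin_fractions)
from phyprof.taxa import read_newick


def run_calls(bench, threshold=0.10):
    """Score every focal-clade sequence of a benchmark."""
    focal = set(bench.config.get("recipient_clades", ["Archaea"]))
    calls = []
    for rec in bench.records:
        if bench.clades[rec.taxon] not in focal:
            continue
        calls.append(flag(anomaly_score(rec, bench.records, bench.clades),
                          threshold))
    return calls


class TestIdentity:
    def test_equal_strings(self):
        assert identity("ACDE", "ACDE") == 1.0

    def test_hamming_path(self):
        assert identity("AAAA", "AATT") == 0.5

    def test_unequal_lengths_aligned(self):
        # one terminal residue missing: identity over aligned pairs
        assert identity("ACDEFGHIKL", "ACDEFGHIK") >= 0.9


class TestAnomalyScore:
    def test_vertical_genes_score_negative(self):
        # two well-separated clades: within-clade divergence is much
        # smaller than between-clade divergence for every vertical gene
        stree = read_newick("((A:0.2,B:0.2,C:0.2)L:1.0,"
                            "(D:0.2,E:0.2,F:0.2)R:1.0)root;")
        cfg = simulate.SimConfig(seed=23, loss_rate=0.0, families=["cathL"],
                                 species_tree=stree)
        content, _, stree = simulate.simulate_content(cfg)
        records, _ = simulate.simulate_sequences(cfg, content, stree)
        left = {"A", "B", "C"}
        clades = {r.taxon: ("L" if r.taxon in left else "R") for r in records}
        for rec in records:
            call = anomaly_score(rec, records, clades)
            assert call.score < 0, rec.id

    def test_transferred_scores_high(self, five_cases):
        calls = {c.sequence_id: c for c in run_calls(five_cases)}
        assert calls["hgt_Rotifer_A"].score > 0.1
        assert calls["hgt_Rotifer_B"].score > 0.1

    def test_identical_ingroup_member_scores_nonpositive(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 5
        records = [
            SequenceRecord("q", "sp1", seq),
            SequenceRecord("twin", "sp2", seq),
            SequenceRecord("out", "sp3", "W" * 100),
        ]
        clades = {"sp1": "A", "sp2": "A", "sp3": "B"}
        call = anomaly_score(records[0], records, clades)
        assert call.score <= 0

    def test_no_ingroup_comparator(self):
        records = [SequenceRecord("q", "sp1", "ACDE" * 10),
                   SequenceRecord("out", "sp2", "WYWY" * 10)]
        clades = {"sp1": "A", "sp2": "B"}
        with pytest.raises(IncomparableError):
            anomaly_score(records[0], records, clades)

    def test_same_taxon_excluded_from_ingroup(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 5
        records = [
            SequenceRecord("q", "sp1", seq),
            SequenceRecord("dup", "sp1", seq),       # recent duplicate
            SequenceRecord("rel", "sp2", "W" * 100),  # true in-group
            SequenceRecord("out", "sp3", seq),
        ]
        clades = {"sp1": "A", "sp2": "A", "sp3": "B"}
        call = anomaly_score(records[0], records, clades)
        assert call.in_identity < 0.3  # the duplicate must not count
        assert call.score > 0.5


class TestFlag:
    def test_above_threshold(self):
        call = HgtCall("s", "A", 0.4, 0.65, 0.25)
        assert flag(call, 0.10).flagged

    def test_boundary_inclusive(self):
        call = HgtCall("s", "A", 0.5, 0.6, 0.10)
        assert flag(call, 0.10).flagged

    def test_negative_not_flagged(self):
        call = HgtCall("s", "A", 0.8, 0.5, -0.3)
        assert not flag(call, 0.10).flagged


class TestClusterEvents:
    def test_five_case_fixture(self, five_cases):
        calls = run_calls(five_cases)
        flagged_ids = {c.sequence_id for c in calls if c.flagged}
        assert flagged_ids == five_cases.true_transferred
        taxon_of = {r.id: r.taxon for r in five_cases.records}
        calls = [assign_donor(c, five_cases.tree, five_cases.clades,
                              taxon_of, flagged_ids) if c.flagged else c
                 for c in calls]
        clustered = cluster_events(calls, five_cases.tree)
        events = {c.event_id for c in clustered if c.event_id is not None}
        assert len(events) == five_cases.expected_events == 5

    def test_all_same_donor_monophyletic_one_cluster(self):
        tree = read_newick("((a,b)T,(x,y)D)R;")
        calls = [
            HgtCall("a", "Euk", 0.3, 0.7, 0.4, "Bact", flagged=True),
            HgtCall("b", "Euk", 0.3, 0.7, 0.4, "Bact", flagged=True),
        ]
        clustered = cluster_events(calls, tree)
        assert len({c.event_id for c in clustered}) == 1

    def test_same_donor_different_recipients_separate(self):
        # two independent transfers with donor tips between them
        tree = read_newick("((a,d1),(b,d2))R;")
        calls = [
            HgtCall("a", "CladeA", 0.3, 0.7, 0.4, "Bact", flagged=True),
            HgtCall("b", "CladeB", 0.3, 0.7, 0.4, "Bact", flagged=True),
        ]
        clustered = cluster_events(calls, tree)
        assert len({c.event_id for c in clustered}) == 2

    def test_missing_tip_is_placement_error(self):
        tree = read_newick("(a,b)R;")
        calls = [HgtCall("zz", "A", 0.3, 0.7, 0.4, "B", flagged=True)]
        with pytest.raises(KeyError):
            cluster_events(calls, tree)

    def test_cluster_count_bounded_by_flags(self, five_cases):
        calls = run_calls(five_cases)
        flagged_ids = {c.sequence_id for c in calls if c.flagged}
        taxon_of = {r.id: r.taxon for r in five_cases.records}
        calls = [assign_donor(c, five_cases.tree, five_cases.clades,
                              taxon_of, flagged_ids) if c.flagged else c
                 for c in calls]
        for rule in ("donor", "donor_recipient"):
            clustered = cluster_events(calls, five_cases.tree, link_rule=rule)
            events = {c.event_id for c in clustered if c.event_id is not None}
            assert len(events) <= len(flagged_ids)

    def test_looser_rule_never_more_clusters(self, five_cases):
        calls = run_calls(five_cases)
        flagged_ids = {c.sequence_id for c in calls if c.flagged}
        taxon_of = {r.id: r.taxon for r in five_cases.records}
        calls = [assign_donor(c, five_cases.tree, five_cases.clades,
                              taxon_of, flagged_ids) if c.flagged else c
                 for c in calls]
        strict = cluster_events(calls, five_cases.tree, "donor_recipient")
        loose = cluster_events(calls, five_cases.tree, "donor")
        n_strict = len({c.event_id for c in strict if c.event_id})
        n_loose = len({c.event_id for c in loose if c.event_id})
        assert n_loose <= n_strict


class TestOriginFractions:
    def test_arithmetic(self):
        calls = [HgtCall(f"s{i}", "A", 0.5, 0.4, -0.1, flagged=i < 4)
                 for i in range(10)]
        native, transferred, _ = origin_fractions(calls)
        assert (native, transferred) == (0.6, 0.4)

    def test_sums_to_one(self):
        calls = [HgtCall(f"s{i}", "A", 0.5, 0.4, -0.1, flagged=i % 3 == 0)
                 for i in range(7)]
        native, transferred, _ = origin_fractions(calls)
        assert native + transferred == 1.0

    def test_all_native(self):
        calls = [HgtCall(f"s{i}", "A", 0.5, 0.4, -0.1) for i in range(5)]
        assert origin_fractions(calls)[:2] == (1.0, 0.0)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            origin_fractions([])

    def test_archaea_default_recovers_mixture(self):
        bench = simulate.archaea_default(seed=42, n=200)
        calls = []
        for rec in bench.records:
            if bench.clades[rec.taxon] != "Archaea":
                continue
            calls.append(flag(anomaly_score(rec, bench.records, bench.clades)))
        _, transferred, _ = origin_fractions(calls)
        configured = bench.config["transferred_fraction"]
        assert abs(transferred - configured) <= 0.05


class TestPrecisionRecall:
    def test_detector_quality_over_replicates(self):
        tp = fp = fn = 0
        for rep in range(20):
            bench = simulate.archaea_default(seed=31 + rep, n=40)
            flagged = set()
            for rec in bench.records:
                if bench.clades[rec.taxon] != "Archaea":
                    continue
                call = flag(anomaly_score(rec, bench.records, bench.clades))
                if call.flagged:
                    flagged.add(call.sequence_id)
            tp += len(flagged & bench.true_transferred)
            fp += len(flagged - bench.true_transferred)
            fn += len(bench.true_transferred - flagged)
        assert tp / (tp + fp) >= 0.9
        assert tp / (tp + fn) >= 0.9
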