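"""Independent pair extraction: prefilter, events, representatives, filtering."""

import numpy as np
import pytest

from oxygc.pairing import (
    LabellingError,
    OrganismRecord,
    PairRecord,
    extract_independent_pairs,
    filter_pairs_by_identity,
    find_state_change_events,
    identity_threshold_sweep,
    merge_state,
    select_representative,
    taxonomic_prefilter,
)
from oxygc.synthetic import simulate_oxygen_states, simulate_tree
from oxygc.treekit import read_newick


class TestMergeState:
    @pytest.mark.parametrize(
        "raw,merged",
        [("aerobe", "aerobic"), ("obligate aerobe", "aerobic"),
         ("obligate_anaerobe", "anaerobic"), ("Anaerobe", "anaerobic")],
    )
    def test_merging(self, raw, merged):
        assert merge_state(raw) == merged

    def test_unknown_state(self):
        with pytest.raises(LabellingError):
            merge_state("facultative")


class TestPrefilter:
    def rec(self, oid, state, **taxa):
        return OrganismRecord(oid, state, taxonomy=taxa)

    def test_mixed_species_kept_at_species_rank(self):
        recs = [
            self.rec("s1", "aerobe", species="E. mixta", genus="E"),
            self.rec("s2", "anaerobe", species="E. mixta", genus="E"),
        ]
        out = taxonomic_prefilter(recs)
        assert [(r.organism_id, rank) for r, rank in out] == [
            ("s1", "species"), ("s2", "species")
        ]

    def test_all_same_state_empty(self):
        recs = [self.rec(f"s{i}", "aerobe", species=f"sp{i}", genus="G") for i in range(4)]
        assert taxonomic_prefilter(recs) == []

    def test_mixed_genus_no_mixed_species(self):
        recs = [
            self.rec("a", "aerobe", species="A", genus="G"),
            self.rec("b", "anaerobe", species="B", genus="G"),
            self.rec("c", "aerobe", species="C", genus="H"),
        ]
        out = taxonomic_prefilter(recs)
        assert {(r.organism_id, rank) for r, rank in out} == {
            ("a", "genus"), ("b", "genus")
        }

    def test_lower_rank_claims_before_higher(self):
        # s1/s2 mixed within species; s3 only mixes with them at genus rank,
        # but they are already claimed, so s3 finds no partner
        recs = [
            self.rec("s1", "aerobe", species="X", genus="G"),
            self.rec("s2", "anaerobe", species="X", genus="G"),
            self.rec("s3", "anaerobe", species="Y", genus="G"),
        ]
        out = taxonomic_prefilter(recs)
        assert {(r.organism_id, rank) for r, rank in out} == {
            ("s1", "species"), ("s2", "species")
        }

    def test_empty_input(self):
        assert taxonomic_prefilter([]) == []


class TestEvents:
    def test_worked_example_three_events(self, fig1a_tree, fig1a_states):
        events = find_state_change_events(fig1a_tree, fig1a_states)
        assert len(events) == 3
        groups = {(ev.aerobic_tips, ev.anaerobic_tips) for ev in events}
        assert (frozenset({"strain1"}), frozenset({"strain2"})) in groups
        assert (
            frozenset({"sp7", "sp8"}),
            frozenset({"sp4", "sp5", "sp6"}),
        ) in groups
        assert (frozenset({"sp11"}), frozenset({"sp10"})) in groups

    def test_uniform_tree_no_events(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);", rooted=True)
        assert find_state_change_events(tree, dict.fromkeys("abcd", "aerobe")) == []

    def test_two_tip_tree_one_event(self):
        tree = read_newick("(a:1,b:1);", rooted=True)
        ev = find_state_change_events(tree, {"a": "aerobe", "b": "anaerobe"})
        assert len(ev) == 1

    def test_unlabelled_tip(self, fig1a_tree, fig1a_states):
        del fig1a_states["sp9"]
        with pytest.raises(LabellingError):
            find_state_change_events(fig1a_tree, fig1a_states)

    @staticmethod
    def _run_scan_oracle(states):
        """Independent edge scan of a caterpillar: walk maximal same-state
        runs from the deep end; a run boundary yields an event whenever the
        deeper side still has an unused tip, which then consumes one tip of
        the shallower run."""
        rev = states[::-1]
        runs = []
        for s in rev:
            if runs and runs[-1][0] == s:
                runs[-1][1] += 1
            else:
                runs.append([s, 1])
        events, avail = 0, runs[0][1]
        for _, size in runs[1:]:
            if avail > 0:
                events += 1
                avail = size - 1
            else:
                avail = size
        return events

    def test_caterpillar_matches_run_scan_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(3, 15))
            states = ["aerobe" if rng.random() < 0.5 else "anaerobe" for _ in range(n)]
            nwk = f"t{n}:1"
            for i in range(n - 1, 0, -1):
                nwk = f"(t{i}:1,{nwk}):1"
            tree = read_newick(nwk + ";", rooted=True)
            smap = {f"t{i + 1}": states[i] for i in range(n)}
            expected = self._run_scan_oracle(states)
            assert len(find_state_change_events(tree, smap)) == expected, states


class TestRepresentative:
    def test_slow_fast_from_worked_example(self, fig1a_tree):
        group = frozenset({"sp4", "sp5", "sp6"})
        assert select_representative(group, fig1a_tree, "slow") == "sp6"
        assert select_representative(group, fig1a_tree, "fast") == "sp5"

    def test_singleton(self, fig1a_tree):
        assert select_representative(frozenset({"sp9"}), fig1a_tree, "slow") == "sp9"
        assert select_representative(frozenset({"sp9"}), fig1a_tree, "fast") == "sp9"

    def test_annotation_count_tie_break(self):
        tree = read_newick("((a:1,b:1):1,c:2);", rooted=True)
        counts = {"a": 2500, "b": 3000}
        assert select_representative(frozenset("ab"), tree, "slow", counts) == "b"
        counts = {"a": 3000, "b": 2500}
        assert select_representative(frozenset("ab"), tree, "slow", counts) == "a"
        # equal depth, equal counts -> lexicographic
        assert select_representative(frozenset("ab"), tree, "slow", {}) == "a"


class TestPairs:
    def test_worked_example_pairs(self, fig1a_tree, fig1a_states):
        slow = extract_independent_pairs(fig1a_tree, fig1a_states, "slow")
        fast = extract_independent_pairs(fig1a_tree, fig1a_states, "fast")
        assert len(slow) == len(fast) == 3
        assert ("sp7", "sp6") in {(p.aerobic_tip, p.anaerobic_tip) for p in slow}
        assert ("sp8", "sp5") in {(p.aerobic_tip, p.anaerobic_tip) for p in fast}
        # duplicated analysis: same events, possibly different representatives
        assert [p.event_id for p in slow] == [p.event_id for p in fast]

    def test_single_state_tree_empty(self):
        tree = read_newick("((a:1,b:1):1,c:2);", rooted=True)
        assert extract_independent_pairs(tree, dict.fromkeys("abc", "anaerobe")) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_independence_on_random_trees(self, seed):
        """No tip ever appears in two pairs; events never exceed transitions."""
        tree = simulate_tree(30, seed=seed)
        n_tr = 1 + seed % 6
        states = simulate_oxygen_states(tree, n_tr, seed=seed)
        if len(set(states.values())) < 2:
            return
        for mode in ("slow", "fast"):
            pairs = extract_independent_pairs(tree, states, mode)
            tips = [t for p in pairs for t in (p.aerobic_tip, p.anaerobic_tip)]
            assert len(tips) == len(set(tips))
            assert len(pairs) <= n_tr
            for p in pairs:
                assert states[p.aerobic_tip] == "aerobe"
                assert states[p.anaerobic_tip] == "anaerobe"


class TestIdentityFilter:
    def pairs(self, idents):
        return [
            PairRecord(i, f"a{i}", f"n{i}", "slow", identity_16s=v)
            for i, v in enumerate(idents)
        ]

    def test_threshold_counts(self):
        assert len(filter_pairs_by_identity(self.pairs([97, 90, 80]), 85)) == 2
        assert len(filter_pairs_by_identity(self.pairs([97, 90, 80]), 0)) == 3
        kept = filter_pairs_by_identity(self.pairs([100, 99.9]), 100)
        assert [p.identity_16s for p in kept] == [100]

    def test_missing_identity_excluded_with_warning(self, caplog):
        import logging

        ps = self.pairs([97, None])
        with caplog.at_level(logging.WARNING):
            kept = filter_pairs_by_identity(ps, 90)
        assert len(kept) == 1 and caplog.records

    def test_sweep(self):
        sweep = identity_threshold_sweep(self.pairs([97, 90, 80]), [0, 85, 95])
        assert {t: len(v) for t, v in sweep.items()} == {0: 3, 85: 2, 95: 1}
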