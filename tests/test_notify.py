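"""Significance filter: what fires, what stays silent, determinism."""

import logging

import pytest

from pgdbnotify.diff import diff_snapshot
from pgdbnotify.model import Snapshot
from pgdbnotify.notify import evaluate_gene_or_pathway, evaluate_term, run_notifications
from pgdbnotify.subscriptions import Registry, Subscription, subscribe
from pgdbnotify.synth import EXCLUSION_KINDS, Edit, EditScript, apply_script, copy_snapshot, generate_base, random_script, sample_registry

from conftest import add_obj

GENE_SUB = Subscription("u@example.org", "ECOLI", "GENE", "TRPA", "NONE")
PWY_SUB = Subscription("u@example.org", "ECOLI", "PATHWAY", "PWY-TRP", "NONE")


def _eval(sub, old, new):
    return (evaluate_gene_or_pathway if sub.kind in ("GENE", "PATHWAY") else evaluate_term)(
        sub, old, new, diff_snapshot(old, new)
    )


class TestGenePathwayCriterion:
    def test_typo_edits_alone_never_fire(self, fixture_b):
        new = copy_snapshot(fixture_b)
        for oid in ("TRPA", "TRPA-MONOMER", "TRPAB", "PWY-TRP", "CPD-TRP"):
            sv = new.objects[oid].slots["COMMON-NAME"][0]
            sv.value = sv.value[:-1] + "x"
        assert _eval(GENE_SUB, fixture_b, new) is None
        assert _eval(PWY_SUB, fixture_b, new) is None

    def test_citation_on_enzyme_complex_fires_gene_subscription(self, fixture_b):
        new = copy_snapshot(fixture_b)
        new.objects["TRPAB"].add_value("CITATIONS", "PMID:555")
        item = _eval(GENE_SUB, fixture_b, new)
        assert item is not None
        assert item.trigger_ids == {"TRPAB"}
        assert item.new_publications == {"PMID:555"}
        assert {d.id for d in item.member_diffs} == {"TRPAB"}

    def test_citation_outside_closure_does_not_fire(self, fixture_b):
        new = copy_snapshot(fixture_b)
        add_obj(new, "UNRELATED", ["PROTEIN"], {"CITATIONS": ["PMID:9"]})
        new.objects["CPD-IGP"].add_value("CITATIONS", "PMID:10")  # metabolite: outside gene closure
        assert _eval(GENE_SUB, fixture_b, new) is None
        # ... but the metabolite is inside the pathway closure
        assert _eval(PWY_SUB, fixture_b, new) is not None

    def test_attribute_level_citation_fires(self, fixture_b):
        new = copy_snapshot(fixture_b)
        new.objects["TRPA"].slots["COMMON-NAME"][0].annotations["CITATIONS"] = ["PMID:777"]
        item = _eval(GENE_SUB, fixture_b, new)
        assert item is not None and item.trigger_ids == {"TRPA"}

    def test_merged_away_anchor_returns_none_with_warning(self, fixture_b, caplog):
        new = copy_snapshot(fixture_b)
        new.objects["TRPAB"].add_value("MERGED-FROM", "TRPA")
        del new.objects["TRPA"]
        with caplog.at_level(logging.WARNING):
            assert _eval(GENE_SUB, fixture_b, new) is None
        assert any("TRPA" in r.message for r in caplog.records)

    def test_brand_new_object_without_citation_never_triggers(self, fixture_b):
        new = copy_snapshot(fixture_b)
        add_obj(new, "REG-NEW", ["REGULATION"], {"REGULATED-ENTITY": ["TRPAB"]})
        assert _eval(GENE_SUB, fixture_b, new) is None


class TestTermCriterion:
    @pytest.fixture
    def go_pair(self):
        old = Snapshot("ECOLI", "1.0")
        add_obj(old, "GO:1", ["GO-TERM"])
        add_obj(old, "GO:2", ["GO-TERM"], {"PARENTS": ["GO:1"]})
        add_obj(old, "G1", ["GENE"], {"GO-TERMS": ["GO:2"], "CITATIONS": ["PMID:1"]})
        add_obj(old, "G2", ["GENE"], {"GO-TERMS": ["GO:2"]})
        add_obj(old, "G3", ["GENE"], {"PRODUCT": ["M3"]})
        add_obj(old, "M3", ["PROTEIN"], {"GENE": ["G3"]})
        return old, copy_snapshot(old)

    def test_annotation_to_descendant_fires_new_members(self, go_pair):
        old, new = go_pair
        new.objects["G3"].add_value("GO-TERMS", "GO:2")
        sub = Subscription("u@x.org", "ECOLI", "GO-TERM", "GO:1", "NEW-MEMBERS")
        item = _eval(sub, old, new)
        assert item is not None and item.new_members == {"G3"}

    def test_annotation_removal_never_fires(self, go_pair):
        old, new = go_pair
        del new.objects["G2"].slots["GO-TERMS"]
        for mode in ("NEW-MEMBERS", "MEMBER-CHANGES"):
            sub = Subscription("u@x.org", "ECOLI", "GO-TERM", "GO:1", mode)
            assert _eval(sub, old, new) is None

    def test_member_changes_fires_on_member_enzyme_citation(self, go_pair):
        old, new = go_pair
        # G3 becomes annotated in BOTH releases so membership is stable
        for snap in (old, new):
            snap.objects["G3"].add_value("GO-TERMS", "GO:2")
        new.objects["M3"].add_value("CITATIONS", "PMID:42")
        sub = Subscription("u@x.org", "ECOLI", "GO-TERM", "GO:1", "MEMBER-CHANGES")
        item = _eval(sub, old, new)
        assert item is not None and item.trigger_ids == {"M3"}
        # the NEW-MEMBERS mode stays silent: membership did not grow
        assert _eval(Subscription("u@x.org", "ECOLI", "GO-TERM", "GO:1", "NEW-MEMBERS"), old, new) is None

    def test_unknown_term_in_both_releases_returns_none(self, go_pair, caplog):
        old, new = go_pair
        sub = Subscription("u@x.org", "ECOLI", "GO-TERM", "GO:999", "NEW-MEMBERS")
        with caplog.at_level(logging.WARNING):
            assert _eval(sub, old, new) is None


class TestRunNotifications:
    def test_empty_registry(self, fixture_b):
        assert run_notifications(Registry(), fixture_b, fixture_b) == []

    def test_identical_snapshots_silent_for_any_registry(self, fixture_b):
        reg = Registry()
        subscribe(reg, GENE_SUB)
        subscribe(reg, PWY_SUB)
        assert run_notifications(reg, fixture_b, copy_snapshot(fixture_b)) == []

    def test_other_database_entries_skipped(self, fixture_b):
        new = copy_snapshot(fixture_b)
        new.objects["TRPA"].add_value("CITATIONS", "PMID:555")
        reg = Registry()
        subscribe(reg, Subscription("u@x.org", "META", "GENE", "TRPA", "NONE"))
        assert run_notifications(reg, fixture_b, new) == []

    @pytest.mark.parametrize("seed", [3, 11])
    def test_exclusion_scripts_yield_zero_firings(self, seed):
        old = generate_base(seed=seed)
        reg = sample_registry(old, seed)
        for kind in EXCLUSION_KINDS:
            script = random_script(old, seed, n_edits=3, kinds=(kind,))
            new, truth = apply_script(old, script, reg)
            assert truth.fired == set()
            assert run_notifications(reg, old, new) == []

    @pytest.mark.parametrize("seed", [5, 21])
    def test_extra_citation_edit_never_unfires(self, seed):
        """Monotonicity: one more new-citation edit can only add firings."""
        old = generate_base(seed=seed)
        reg = sample_registry(old, seed)
        script = random_script(old, seed, n_edits=5)
        new, _ = apply_script(old, script)
        before = {i.subscription for i in run_notifications(reg, old, new)}
        target = sorted(
            o.id for o in old.objects.values()
            if "PROTEIN" in o.classes and o.id not in {t for e in script.edits for t in e.targets}
        )[0]
        extra = EditScript(seed, script.edits + [Edit("ADD-CITATION", (target,), ("PMID:999999", "object"))])
        new2, _ = apply_script(old, extra)
        after = {i.subscription for i in run_notifications(reg, old, new2)}
        assert before <= after

    def test_deterministic_order(self, fixture_b):
        new = copy_snapshot(fixture_b)
        new.objects["TRPAB"].add_value("CITATIONS", "PMID:555")
        reg = Registry()
        subscribe(reg, GENE_SUB)
        subscribe(reg, PWY_SUB)
        subscribe(reg, Subscription("a@example.org", "ECOLI", "GENE", "TRPA", "NONE"))
        items = run_notifications(reg, fixture_b, new)
        keys = [(i.subscription.user, i.subscription.kind, i.anchor_id) for i in items]
        assert keys == sorted(keys)
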