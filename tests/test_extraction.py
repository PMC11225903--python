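import copy
import datetime
import math

import pytest

from emat import (ExtractionConfig, Lexicon, Story, build_action_cluster,
                  build_verb_lexicon, deduplicate, extract_entity_from_sentence,
                  find_date, parse_sentence, parse_stories, process_story,
                  tag_story, assign_actor_target)
from emat.extraction import EMATEntity
from emat.story_io import read_story_file, tokenize_sentences
from emat.text import tokenize

CFG = ExtractionConfig()


class TestActionCluster:
    def test_exact_and_partial_membership(self, poacher_taxonomy):
        best, cluster = build_action_cluster(("arrested",), poacher_taxonomy)
        assert best == "1"
        assert cluster == {"1"}

    def test_no_match_anywhere(self, poacher_taxonomy):
        best, cluster = build_action_cluster(("migrated",), poacher_taxonomy)
        assert best is None and cluster == frozenset()

    def test_tie_breaks_to_lowest_id(self, poacher_taxonomy):
        from emat import add_equivalence_member
        t = add_equivalence_member(poacher_taxonomy, "2", "verb", "arrested")
        best, cluster = build_action_cluster(("arrested",), t)
        assert cluster == {"1", "2"}
        assert best == "1"


class TestCascade:
    def _parse(self, text, taxonomy):
        return parse_sentence(tokenize(text), build_verb_lexicon(taxonomy))

    def test_object_route_on_printed_sentence(self, poacher_taxonomy,
                                              printed_sentence):
        parse = self._parse(printed_sentence, poacher_taxonomy)
        entity, trace = extract_entity_from_sentence(parse, poacher_taxonomy)
        assert entity is not None
        assert entity.action_id == "1"
        assert trace.decision_route == "object"
        assert trace.SIMD == pytest.approx(math.tanh(2))
        assert trace.SIMP <= CFG.prep_accept

    def test_no_object_no_prep_returns_none(self, poacher_taxonomy):
        parse = self._parse("suspects arrested quietly yesterday evening",
                            poacher_taxonomy)
        entity, trace = extract_entity_from_sentence(parse, poacher_taxonomy)
        assert entity is None
        assert trace.verb == ("arrested",)
        assert trace.actionD is None and trace.actionP is None

    def test_prep_route_on_identical_prep(self, poacher_taxonomy):
        parse = self._parse("offenders sentenced to prison for life",
                            poacher_taxonomy)
        entity, trace = extract_entity_from_sentence(parse, poacher_taxonomy)
        assert entity is not None and entity.action_id == "2"
        assert trace.decision_route == "prep"
        assert trace.SIMP >= math.tanh(2) - 1e-9

    def test_no_verb_returns_none_with_trace(self, poacher_taxonomy):
        parse = self._parse("the herd moved north across the river",
                            poacher_taxonomy)
        entity, trace = extract_entity_from_sentence(parse, poacher_taxonomy)
        assert entity is None and trace.verb is None

    def test_cascade_soundness_invariant(self, toy_taxonomy):
        """An entity is only emitted with verb above the gate and either
        an accepted prep score or an object score beating the prep score."""
        from emat import FixtureSpec, generate_story_file
        from emat.fixtures import lexicons_from_manifest
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            sf, man = generate_story_file(
                FixtureSpec(10, 2, 0.3, 0.1, True, 11), toy_taxonomy,
                os.path.join(d, "s.txt"))
            g, r = lexicons_from_manifest(man)
            db = parse_stories(sf, toy_taxonomy, g, r)
        for tr in db.traces:
            if tr.decision is not None:
                assert tr.verb_score > CFG.verb_gate
                assert (tr.SIMP > CFG.prep_accept) or (tr.SIMD > tr.SIMP)


class TestTagging:
    def test_date_from_sentence(self):
        story = Story(0, "Rangers met on June 10, 2019 near the gate.")
        tokenize_sentences(story)
        date, _, _ = tag_story(story, Lexicon(()), Lexicon(()))
        assert date == datetime.date(2019, 6, 10)

    def test_date_battery_orders(self):
        assert find_date("seen 10 June 2019 there") == datetime.date(2019, 6, 10)
        assert find_date("logged 2019-06-10 ok") == datetime.date(2019, 6, 10)
        assert find_date('<meta content="2020-02-02">June 3, 2019') == \
            datetime.date(2020, 2, 2)
        assert find_date("no date here") is None

    def test_group_hit(self, groups_lexicon, regions_lexicon):
        story = Story(0, "Kenya Wildlife Services arrested five poachers "
                         "in Tsavo on June 10, 2019.")
        tokenize_sentences(story)
        date, ghits, rhits = tag_story(story, groups_lexicon, regions_lexicon)
        assert [h.name for h in ghits] == ["Kenya Wildlife Services"]
        assert [h.name for h in rhits] == ["Tsavo"]

    def test_empty_lexicons_still_date(self):
        story = Story(0, "Something happened on June 10, 2019 here.")
        tokenize_sentences(story)
        date, ghits, rhits = tag_story(story, Lexicon(()), Lexicon(()))
        assert date is not None and ghits == [] and rhits == []


class TestActorTarget:
    def test_sentence_level_actor_and_target(self, poacher_taxonomy,
                                             groups_lexicon, regions_lexicon):
        text = "Kenya Wildlife Services arrested five poachers in Tsavo"
        story = Story(0, text)
        tokenize_sentences(story)
        _, ghits, rhits = tag_story(story, groups_lexicon, regions_lexicon)
        parse = parse_sentence(story.sentences[0],
                               build_verb_lexicon(poacher_taxonomy))
        draft = EMATEntity(action_id="1", story_id=0, sentence_index=0)
        ent = assign_actor_target(draft, parse, ghits, rhits,
                                  poacher_taxonomy["1"], verb_start=3)
        assert ent.actor == "Kenya Wildlife Services"
        assert ent.target == "Tsavo"
        assert ent.actor_rule == "sentence"

    def test_archetype_fallback(self, poacher_taxonomy):
        parse = parse_sentence(tokenize("suspects were arrested yesterday"),
                               build_verb_lexicon(poacher_taxonomy))
        draft = EMATEntity(action_id="1", story_id=0, sentence_index=0)
        ent = assign_actor_target(draft, parse, [], [],
                                  poacher_taxonomy["1"], verb_start=2)
        assert ent.actor == "rangers" and ent.actor_rule == "archetype"

    def test_no_hits_no_archetypes(self, poacher_taxonomy):
        parse = parse_sentence(tokenize("offenders sentenced to prison"),
                               build_verb_lexicon(poacher_taxonomy))
        draft = EMATEntity(action_id="2", story_id=0, sentence_index=0)
        ent = assign_actor_target(draft, parse, [], [],
                                  poacher_taxonomy["2"], verb_start=1)
        assert ent.actor is None and ent.target is None


def _mk(action_id, story_id=0, date=None, actor="A", target="T"):
    return EMATEntity(action_id=action_id, story_id=story_id, date=date,
                      sentence_index=0, actor=actor, target=target)


class TestDeduplicate:
    def test_adjacent_duplicate(self):
        a, b = _mk("1"), _mk("2")
        assert [e.action_id for e in deduplicate([a, copy.copy(a), b])] == \
            ["1", "2"]

    def test_rescan_removes_all_later_copies(self):
        a1, b, a2, a3 = _mk("1"), _mk("2"), _mk("1"), _mk("1")
        out = deduplicate([a1, b, a2, a3])
        assert [e.action_id for e in out] == ["1", "2"]

    def test_unique_list_unchanged_and_idempotent(self):
        ents = [_mk("1"), _mk("2"), _mk("1", date=datetime.date(2020, 1, 1))]
        once = deduplicate(ents)
        assert once == ents
        assert deduplicate(once) == once


class TestParseStories:
    def test_boilerplate_only_story_fails_parse(self, poacher_taxonomy,
                                                groups_lexicon,
                                                regions_lexicon, tmp_path):
        p = tmp_path / "junk.txt"
        p.write_text("beginarticle 0\nCopyright subscribe login wrapper "
                     "div sidebar.\n")
        db = parse_stories(read_story_file(p), poacher_taxonomy,
                           groups_lexicon, regions_lexicon)
        assert db.entities == []
        assert any(r == "no content sentences" for _, r in db.parse_failures)

    def test_rerun_outputs_byte_identical(self, toy_taxonomy, tmp_path):
        from emat import FixtureSpec, generate_story_file
        from emat.fixtures import lexicons_from_manifest
        sf, man = generate_story_file(FixtureSpec(8, 2, 0.3, 0.0, True, 3),
                                      toy_taxonomy, tmp_path / "s.txt")
        g, r = lexicons_from_manifest(man)
        outs1 = {k: tmp_path / f"{k}1" for k in ("ents", "sdb", "pf", "chk")}
        outs2 = {k: tmp_path / f"{k}2" for k in ("ents", "sdb", "pf", "chk")}
        for outs in (outs1, outs2):
            parse_stories(sf, toy_taxonomy, g, r,
                          out_entities=outs["ents"], out_sdb=outs["sdb"],
                          out_parsefailed=outs["pf"],
                          out_assessment=outs["chk"])
        for k in outs1:
            assert outs1[k].read_bytes() == outs2[k].read_bytes()

    def test_story_independence(self, toy_taxonomy, tmp_path):
        """Extraction over a concatenation equals per-file extraction."""
        from emat import FixtureSpec, concatenate_story_files, generate_story_file
        from emat.fixtures import lexicons_from_manifest
        sfa, mana = generate_story_file(FixtureSpec(4, 2, 0.3, 0.0, False, 5),
                                        toy_taxonomy, tmp_path / "a.txt")
        sfb, manb = generate_story_file(FixtureSpec(3, 2, 0.3, 0.0, False, 6),
                                        toy_taxonomy, tmp_path / "b.txt")
        g = Lexicon(tuple(dict.fromkeys(mana.groups + manb.groups)))
        r = Lexicon(tuple(dict.fromkeys(mana.regions + manb.regions)))
        sfc = concatenate_story_files([tmp_path / "a.txt", tmp_path / "b.txt"],
                                      tmp_path / "c.txt")
        db_a = parse_stories(sfa, toy_taxonomy, g, r)
        db_b = parse_stories(sfb, toy_taxonomy, g, r)
        db_c = parse_stories(sfc, toy_taxonomy, g, r)
        sep = ([(e.action_id, e.actor, e.target, e.date)
                for e in db_a.entities]
               + [(e.action_id, e.actor, e.target, e.date)
                  for e in db_b.entities])
        joint = [(e.action_id, e.actor, e.target, e.date)
                 for e in db_c.entities]
        assert joint == sep

    def test_per_story_exception_does_not_abort(self, poacher_taxonomy,
                                                monkeypatch, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("beginarticle 0\nSuspects were arrested at the park "
                     "by the rangers on June 10, 2019.\n"
                     "beginarticle 0\nOffenders were sentenced to prison "
                     "by the court on June 11, 2019.\n")
        import emat.extraction as ex
        real = ex.process_story
        calls = {"n": 0}

        def flaky(story, *a, **k):
            calls["n"] += 1
            if story.story_id == 0:
                raise RuntimeError("boom")
            return real(story, *a, **k)

        monkeypatch.setattr(ex, "process_story", flaky)
        db = ex.parse_stories(read_story_file(p), poacher_taxonomy,
                              Lexicon(()), Lexicon(()))
        assert calls["n"] == 2
        assert any("exception" in reason for _, reason in db.parse_failures)
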