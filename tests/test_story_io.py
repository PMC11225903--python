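import datetime

import pytest
from hypothesis import given, settings, strategies as st

from emat import (ContentFilterConfig, STORY_DELIMITER, Story,
                  concatenate_story_files, content_fragment, detect_source,
                  format_eco_story, is_content_sentence, read_story_file,
                  segment_sentences, strip_html, write_story_file)
from emat.story_io import StoryFile, tokenize_sentences
from emat.text import tokenize


class TestDelimitedFiles:
    def test_concat_two_files(self, tmp_path):
        (tmp_path / "story1.txt").write_text("Poachers were arrested.\n")
        (tmp_path / "story2.txt").write_text("A treaty was signed.\n")
        out = tmp_path / "all.txt"
        sf = concatenate_story_files(
            [tmp_path / "story1.txt", tmp_path / "story2.txt"], out)
        assert len(sf) == 2
        assert out.read_text().count(STORY_DELIMITER) == 2

    def test_concat_empty_list(self, tmp_path):
        out = tmp_path / "empty.txt"
        sf = concatenate_story_files([], out)
        assert len(sf) == 0 and out.read_text() == ""

    def test_predelimited_input_not_doubled(self, tmp_path):
        src = tmp_path / "pre.txt"
        src.write_text(f"{STORY_DELIMITER}\nAlready delimited text.\n")
        out = tmp_path / "out.txt"
        sf = concatenate_story_files([src], out)
        assert len(sf) == 1
        assert out.read_text().count(STORY_DELIMITER) == 1

    def test_unreadable_input_names_file(self, tmp_path):
        with pytest.raises(OSError, match="missing.txt"):
            concatenate_story_files([tmp_path / "missing.txt"],
                                    tmp_path / "out.txt")

    def test_three_delimiters_three_stories(self, tmp_path):
        p = tmp_path / "f.txt"
        p.write_text(f"{STORY_DELIMITER}\nA.\n{STORY_DELIMITER}\nB.\n"
                     f"{STORY_DELIMITER}\nC.\n")
        assert len(read_story_file(p)) == 3

    def test_leading_text_becomes_story_zero(self, tmp_path):
        p = tmp_path / "f.txt"
        p.write_text(f"orphan text\n{STORY_DELIMITER}\nA.\n")
        sf = read_story_file(p)
        assert len(sf) == 2
        assert sf.stories[0].raw_text.strip() == "orphan text"

    def test_write_read_round_trip(self, tmp_path):
        sf = StoryFile(stories=[Story(0, "First story text."),
                                Story(1, "Second story\nwith two lines.")])
        p = tmp_path / "rt.txt"
        write_story_file(sf, p)
        back = read_story_file(p)
        assert len(back) == 2
        assert [s.raw_text.strip() for s in back] == [
            "First story text.", "Second story\nwith two lines."]


class TestStripHtml:
    def test_tags_removed_text_kept(self):
        assert strip_html("<p>Poachers <b>arrested</b>.</p>").strip() == \
            "Poachers arrested."

    def test_script_content_dropped(self):
        assert "var" not in strip_html("<script>var x=1;</script>Text")
        assert "Text" in strip_html("<script>var x=1;</script>Text")

    def test_nested_blocklisted_inside_kept(self):
        raw = "<div>Keep this <footer>drop <b>this</b></footer> and this</div>"
        out = strip_html(raw)
        assert "Keep this" in out and "and this" in out
        assert "drop" not in out

    def test_entities_decoded(self):
        assert "&" in strip_html("<p>law &amp; order</p>")

    def test_plain_text_passthrough(self):
        assert strip_html("no markup here") == "no markup here"


class TestDetectSource:
    def test_url_domain(self):
        s = Story(0, "From https://www.example-news.co.ke/article today.")
        assert detect_source(s) == "example-news.co.ke"

    def test_long_first_line_unknown(self):
        s = Story(0, "word " * 20 + "\nmore text")
        assert detect_source(s) == "unknown"

    def test_short_masthead_line(self):
        s = Story(0, "Daily Nation\nPoachers were arrested yesterday.")
        assert detect_source(s) == "Daily Nation"


class TestSegmentation:
    def test_printed_sentence_is_one_unit(self, printed_sentence):
        assert segment_sentences(printed_sentence) == [printed_sentence]

    def test_two_sentences(self):
        assert segment_sentences("It rained. Poachers fled.") == \
            ["It rained.", "Poachers fled."]

    def test_initials_do_not_split(self):
        assert len(segment_sentences("A. B. saw it happen.")) == 1

    def test_abbreviations_do_not_split(self):
        assert len(segment_sentences("Dr. Otieno of the U.S. team spoke.")) == 1

    def test_decimals_do_not_split(self):
        assert len(segment_sentences("Rainfall was 3.5 mm that day.")) == 1


class TestContentFilter:
    def test_content_sentence_accepted(self):
        toks = tokenize("the poachers were arrested at the park with rifles")
        assert is_content_sentence(toks)

    def test_boilerplate_rejected(self):
        toks = tokenize("div class wrapper sidebar navigation header")
        assert not is_content_sentence(toks)

    def test_single_irrelevant_word_rejected(self):
        assert not is_content_sentence(["copyright"])

    def test_http_prefix_counts_as_irrelevant(self):
        toks = ["https://x.org", "http://y.org", "httpserver"]
        cfg = ContentFilterConfig(max_irrelevant_frac=0.5)
        assert not is_content_sentence(toks, cfg)

    @given(st.permutations(tokenize(
        "the poachers were arrested at the park with copyright rifles")))
    @settings(derandomize=True, max_examples=50)
    def test_order_invariance(self, shuffled):
        reference = is_content_sentence(tokenize(
            "the poachers were arrested at the park with copyright rifles"))
        assert is_content_sentence(list(shuffled)) == reference

    def test_fragment_filters_and_preserves_order(self):
        story = Story(0, "")
        story.sentences = [
            tokenize("the poachers were arrested at the park with rifles"),
            tokenize("div class wrapper sidebar navigation header"),
            tokenize("rangers moved the herd from the river to the north gate"),
        ]
        frag = content_fragment(story)
        assert len(frag.sentences) == 2
        assert frag.sentences[0][1] == "poachers"

    def test_fragment_idempotent(self):
        story = Story(0, "")
        story.sentences = [
            tokenize("the poachers were arrested at the park"),
            tokenize("copyright login subscribe wrapper div"),
        ]
        once = content_fragment(story)
        twice = content_fragment(once)
        assert once.sentences == twice.sentences

    def test_all_boilerplate_story_empties(self):
        story = Story(0, "")
        story.sentences = [tokenize("copyright login subscribe wrapper div")]
        assert content_fragment(story).sentences == []


class TestEcoStory:
    def test_template_sentence(self):
        s = format_eco_story("Kenya Wildlife Services", "abundance",
                             "cheetah", "Laikipia", "Kenya",
                             datetime.date(2009, 1, 1),
                             datetime.date(2013, 12, 31))
        assert s == ("Kenya Wildlife Services collected abundance data on "
                     "cheetah in Laikipia, Kenya during the period "
                     "2009-01-01 to 2013-12-31.")

    def test_ndvi_forces_species_na(self):
        s = format_eco_story("TerraServer", "NDVI", "cheetah", "Laikipia",
                             "Kenya", "2009-01-01", "2013-12-31")
        assert "on N/A" in s

    def test_invalid_data_type(self):
        with pytest.raises(ValueError, match="data_type"):
            format_eco_story("g", "biomass", "x", "r", "c",
                             "2009-01-01", "2010-01-01")


def test_tokenize_sentences_populates_story():
    story = Story(0, "It rained. Poachers fled.")
    tokenize_sentences(story)
    assert story.sentences == [["it", "rained"], ["poachers", "fled"]]
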