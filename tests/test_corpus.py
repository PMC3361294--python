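"""Corpus types, native file round-trips, eligibility filters, generator."""

import pytest
from hypothesis import given, settings, strategies as st

from miwsd import (
    CorpusFormatError,
    GeneratorSpec,
    Instance,
    LabeledCorpus,
    PreprocessConfig,
    ValidationError,
    count_contingency,
    extract_context,
    filter_eligible_senses,
    filter_species_entities,
    generate_corpus,
    planted_words,
    read_corpus,
    write_corpus,
)
from miwsd.corpus import corpus_from_instances, read_instances, shuffle_labels


def _mk(n_a, n_b, sense_a="A", sense_b="B", target="term"):
    insts = [
        Instance(f"a{i}", target, sense_a, f"ctx{i} {target} more") for i in range(n_a)
    ] + [
        Instance(f"b{i}", target, sense_b, f"other {target} ctx{i}") for i in range(n_b)
    ]
    return corpus_from_instances(insts)


class TestReadWrite:
    def test_grouping_by_sense(self, tmp_path):
        path = tmp_path / "c.tsv"
        write_corpus(_mk(5, 5), path)
        corpus = read_corpus(path)
        assert corpus.N == 10
        assert corpus.class_sizes() == {"A": 5, "B": 5}

    def test_input_order_preserved_within_class(self, tmp_path):
        path = tmp_path / "c.tsv"
        write_corpus(_mk(3, 2), path)
        corpus = read_corpus(path)
        assert [i.id for i in corpus.classes["A"]] == ["a0", "a1", "a2"]

    def test_text_lacking_target_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("x1\tterm\tA\tno mention here\n")
        with pytest.raises(ValidationError, match="does not contain target"):
            read_corpus(path)

    def test_mixed_targets_rejected(self, tmp_path):
        path = tmp_path / "mixed.tsv"
        path.write_text("x1\tfoo\tA\ta foo b\nx2\tbar\tA\ta bar b\n")
        with pytest.raises(ValidationError, match="mixed targets"):
            read_corpus(path)

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("x1\tterm\tA\tok term text\nonly two\tfields\n")
        with pytest.raises(CorpusFormatError, match="line 2"):
            read_corpus(path)

    def test_header_optional(self, tmp_path):
        with_header = tmp_path / "h.tsv"
        without = tmp_path / "n.tsv"
        write_corpus(_mk(2, 2), with_header, header=True)
        write_corpus(_mk(2, 2), without, header=False)
        assert read_corpus(with_header).instances() == read_corpus(without).instances()

    def test_empty_class_written_file_has_only_other_records(self, tmp_path):
        corpus = LabeledCorpus("term", {"A": _mk(3, 1).classes["A"], "B": []})
        path = tmp_path / "c.tsv"
        write_corpus(corpus, path)
        assert len(read_instances(path)) == 3

    @settings(max_examples=40, deadline=None)
    @given(
        texts=st.lists(
            st.text(
                alphabet=st.characters(blacklist_categories=("Cs",)), max_size=40
            ),
            min_size=1,
            max_size=6,
        ),
        senses=st.data(),
    )
    def test_roundtrip_identity_arbitrary_text(self, tmp_path_factory, texts, senses):
        """Escaping survives tabs, newlines, backslashes in text fields."""
        insts = [
            Instance(
                f"i{n}",
                "zzterm",
                senses.draw(st.sampled_from(["s1", "s2"])),
                f"{t} zzterm {t}",
            )
            for n, t in enumerate(texts)
        ]
        corpus = corpus_from_instances(insts)
        path = tmp_path_factory.mktemp("rt") / "c.tsv"
        write_corpus(corpus, path)
        again = read_corpus(path)
        assert again.target == corpus.target
        assert again.instances() == corpus.instances()


class TestEligibility:
    def test_single_real_sense_plus_none_is_ineligible(self):
        corpus = _mk(85, 15, sense_a="s1", sense_b="none")
        result = filter_eligible_senses(corpus, 2)
        assert not result.eligible
        assert result.corpus is None

    def test_rare_second_sense_is_ineligible(self):
        insts = (
            [Instance("a0", "t", "s1", "x t y")]
            + [Instance(f"b{i}", "t", "s2", "x t y") for i in range(74)]
            + [Instance(f"n{i}", "t", "none", "x t y") for i in range(25)]
        )
        result = filter_eligible_senses(corpus_from_instances(insts), 2)
        assert not result.eligible

    def test_balanced_word_unchanged(self):
        corpus = _mk(50, 50)
        result = filter_eligible_senses(corpus, 2)
        assert result.eligible
        assert result.corpus.class_sizes() == {"A": 50, "B": 50}

    def test_none_instances_removed_from_eligible_word(self):
        insts = (
            [Instance(f"a{i}", "t", "s1", "x t") for i in range(5)]
            + [Instance(f"b{i}", "t", "s2", "x t") for i in range(5)]
            + [Instance(f"n{i}", "t", "none", "x t") for i in range(3)]
        )
        result = filter_eligible_senses(corpus_from_instances(insts), 2)
        assert result.eligible
        assert "none" not in result.corpus.classes
        assert result.corpus.N == 10


class TestSpeciesFilter:
    @pytest.mark.parametrize(
        "sizes,kept",
        [
            ({"human": 7, "mouse": 4}, True),
            ({"human": 12}, False),
            ({"human": 3, "mouse": 2}, False),
        ],
    )
    def test_entity_eligibility(self, sizes, kept):
        classes = {
            sp: [Instance(f"{sp}{i}", "gene1", sp, f"w gene1 w") for i in range(n)]
            for sp, n in sizes.items()
        }
        corpora = {"gene1": LabeledCorpus("gene1", classes)}
        out = filter_species_entities(corpora, min_species=2, min_occ=3)
        assert ("gene1" in out) is kept

    def test_small_classes_dropped_within_kept_entity(self):
        classes = {
            sp: [Instance(f"{sp}{i}", "g", sp, "w g w") for i in range(n)]
            for sp, n in {"human": 5, "mouse": 4, "rat": 1}.items()
        }
        out = filter_species_entities({"g": LabeledCorpus("g", classes)}, 2, 3)
        assert sorted(out["g"].classes) == ["human", "mouse"]


class TestGenerator:
    def test_deterministic_under_seed(self):
        spec = GeneratorSpec(seed=7)
        a, b = generate_corpus(spec), generate_corpus(spec)
        assert [i.text for i in a.instances()] == [i.text for i in b.instances()]

    def test_different_seeds_differ(self):
        a = generate_corpus(GeneratorSpec(seed=1))
        b = generate_corpus(GeneratorSpec(seed=2))
        assert [i.text for i in a.instances()] != [i.text for i in b.instances()]

    def test_label_balance(self):
        corpus = generate_corpus(GeneratorSpec(n_senses=3, instances_per_sense=7))
        assert all(n == 7 for n in corpus.class_sizes().values())
        assert corpus.N == 21

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorSpec(p_in=0.2, p_out=0.5).validate()
        with pytest.raises(ValidationError):
            GeneratorSpec(n_senses=1).validate()

    def test_deterministic_planted_counts_in_extreme_case(self, config):
        """p_in=1, p_out=0: the planted word is present in every own-class
        instance and no other, so its contingency row is (5, 0, 0, 5)."""
        spec = GeneratorSpec(
            p_in=1.0,
            p_out=0.0,
            instances_per_sense=5,
            planted_words_per_sense=1,
            background_word_prob=0.0,
            seed=0,
        )
        corpus = generate_corpus(spec)
        bags = {
            s: [extract_context(i, config) for i in corpus.classes[s]]
            for s in corpus.senses
        }
        counts = {
            c.word: c for c in count_contingency(bags["sense1"], bags["sense2"])
        }
        word = planted_words(spec)["sense1"][0]
        c = counts[word]
        assert (c.a, c.b, c.c, c.d) == (5, 0, 0, 5)

    def test_planted_marginals_match_p_in(self, config):
        """Empirical in-class document frequency of each planted word is
        within 3 sigma (binomial) of p_in."""
        spec = GeneratorSpec(instances_per_sense=200, seed=13)
        corpus = generate_corpus(spec)
        n = spec.instances_per_sense
        sigma = (spec.p_in * (1 - spec.p_in) / n) ** 0.5
        for sense, words in planted_words(spec).items():
            bags = [extract_context(i, config) for i in corpus.classes[sense]]
            for w in words:
                freq = sum(1 for b in bags if w in b) / n
                assert abs(freq - spec.p_in) <= 3 * sigma

    def test_tokens_survive_preprocessing(self, noisy_corpus, config):
        """Generated pseudo-tokens are lowercase, stopword-free and
        stem-stable, so the context bag sees them verbatim."""
        from miwsd.preprocess import normalize, tokenize

        for inst in noisy_corpus.instances()[:10]:
            tokens = tokenize(inst.text)
            assert normalize(tokens, config) == tokens

    def test_shuffle_labels_preserves_sizes(self, noisy_corpus):
        shuffled = shuffle_labels(noisy_corpus, seed=3)
        assert sorted(shuffled.class_sizes().values()) == sorted(
            noisy_corpus.class_sizes().values()
        )
        assert shuffled.N == noisy_corpus.N
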