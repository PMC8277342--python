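"""Bundled small-English lookup tables for lemmatization and POS tagging.

Full NLP toolchains are deliberately not a dependency: the pipeline accepts
any ``word -> lemma`` and ``word -> Penn Treebank tag`` callable, and these
tables are the batteries-included default, sized for the short, concrete
vocabulary of obsession reports (wash, check, germ, door, lock, harm, ...).
Unknown words fall back to identity (lemma) and ``NN`` (tag).
"""

from __future__ import annotations

__all__ = ["DEFAULT_LEMMA_TABLE", "DEFAULT_POS_TABLE",
           "default_lemmatizer", "default_tagger", "DEFAULT_EXCLUDED_TAGS"]

# inflected form -> lemma; values are lemmas (never keys of further rules),
# so applying the table twice equals applying it once.
DEFAULT_LEMMA_TABLE: dict[str, str] = {
    # common domain verbs
    "washing": "wash", "washed": "wash", "washes": "wash",
    "checking": "check", "checked": "check", "checks": "check",
    "cleaning": "clean", "cleaned": "clean", "cleans": "clean",
    "counting": "count", "counted": "count", "counts": "count",
    "touching": "touch", "touched": "touch", "touches": "touch",
    "locking": "lock", "locked": "lock", "locks": "lock",
    "harming": "harm", "harmed": "harm", "harms": "harm",
    "hurting": "hurt", "hurts": "hurt",
    "killing": "kill", "killed": "kill", "kills": "kill",
    "stabbing": "stab", "stabbed": "stab", "stabs": "stab",
    "dying": "die", "died": "die", "dies": "die",
    "worrying": "worry", "worried": "worry", "worries": "worry",
    "fearing": "fear", "feared": "fear", "fears": "fear",
    "thinking": "think", "thinks": "think",
    "driving": "drive", "drove": "drive", "drives": "drive",
    "leaving": "leave", "left": "leave", "leaves": "leave",
    "forgetting": "forget", "forgot": "forget", "forgets": "forget",
    "losing": "lose", "lost": "lose", "loses": "lose",
    "repeating": "repeat", "repeated": "repeat", "repeats": "repeat",
    "praying": "pray", "prayed": "pray", "prays": "pray",
    "contaminating": "contaminate", "contaminated": "contaminate",
    "was": "be", "were": "be", "been": "be", "being": "be", "is": "be",
    "are": "be", "am": "be",
    "going": "go", "went": "go", "goes": "go", "gone": "go",
    "doing": "do", "did": "do", "does": "do", "done": "do",
    "having": "have", "had": "have", "has": "have",
    "getting": "get", "got": "get", "gets": "get",
    "making": "make", "made": "make", "makes": "make",
    "saying": "say", "said": "say", "says": "say",
    "felt": "feel", "feels": "feel",
    # common domain nouns, plural -> singular
    "hands": "hand", "germs": "germ", "doors": "door",
    "knives": "knife", "knobs": "knob", "doorknobs": "doorknob",
    "thoughts": "thought", "obsessions": "obsession",
    "compulsions": "compulsion", "rituals": "ritual",
    "numbers": "number", "stoves": "stove", "ovens": "oven",
    "windows": "window", "cars": "car", "keys": "key",
    "diseases": "disease", "illnesses": "illness", "symptoms": "symptom",
    "chemicals": "chemical", "toilets": "toilet", "surfaces": "surface",
    "bacteria": "bacterium", "viruses": "virus", "bodies": "body",
    "babies": "baby", "children": "child", "kids": "kid",
    "people": "person", "families": "family", "friends": "friend",
    "mistakes": "mistake", "accidents": "accident", "fires": "fire",
    "floods": "flood", "intruders": "intruder", "strangers": "stranger",
    "words": "word", "images": "image", "urges": "urge",
    "sins": "sin", "prayers": "prayer", "relationships": "relationship",
    "feelings": "feeling", "emotions": "emotion", "sensations": "sensation",
    # comparative/superlative
    "dirtier": "dirty", "dirtiest": "dirty",
    "cleaner": "clean", "cleanest": "clean",
    "worse": "bad", "worst": "bad", "better": "good", "best": "good",
}

# word -> Penn Treebank tag for the closed-class and frequent words the
# default POS filter needs to recognize; everything else defaults to NN.
DEFAULT_POS_TABLE: dict[str, str] = {
    # adverbs
    "quickly": "RB", "really": "RB", "very": "RB", "always": "RB",
    "never": "RB", "constantly": "RB", "again": "RB", "too": "RB",
    "maybe": "RB", "accidentally": "RB", "not": "RB", "just": "RB",
    "enough": "RB", "somehow": "RB", "here": "RB", "there": "RB",
    "more": "RBR", "most": "RBS",
    # modals
    "will": "MD", "would": "MD", "could": "MD", "should": "MD",
    "might": "MD", "must": "MD", "can": "MD", "may": "MD",
    # 3rd-person singular present verbs
    "is": "VBZ", "has": "VBZ", "does": "VBZ", "happens": "VBZ",
    "makes": "VBZ", "gets": "VBZ", "feels": "VBZ", "touches": "VBZ",
    # gerunds
    "washing": "VBG", "checking": "VBG", "being": "VBG", "going": "VBG",
    "thinking": "VBG", "doing": "VBG", "having": "VBG", "getting": "VBG",
    "cleaning": "VBG", "touching": "VBG", "counting": "VBG",
    "worrying": "VBG", "harming": "VBG", "hurting": "VBG",
    # past participles
    "done": "VBN", "gone": "VBN", "been": "VBN", "contaminated": "VBN",
    "locked": "VBN", "washed": "VBN", "checked": "VBN", "forgotten": "VBN",
    "hurt": "VBN", "broken": "VBN",
    # to
    "to": "TO",
    # prepositions / subordinating conjunctions
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN",
    "with": "IN", "about": "IN", "from": "IN", "into": "IN", "if": "IN",
    "because": "IN", "while": "IN", "after": "IN", "before": "IN",
    "during": "IN", "without": "IN", "over": "IN", "under": "IN",
    "through": "IN",
    # personal pronouns
    "i": "PRP", "me": "PRP", "you": "PRP", "he": "PRP", "him": "PRP",
    "she": "PRP", "her": "PRP", "it": "PRP", "we": "PRP", "us": "PRP",
    "they": "PRP", "them": "PRP", "myself": "PRP", "someone": "PRP",
    # determiners / misc (tagged but not excluded by default)
    "the": "DT", "a": "DT", "an": "DT", "my": "PRP$", "and": "CC",
    "or": "CC", "that": "DT", "this": "DT",
}

#: tags removed by default: adverbs, modals, 3rd-person-singular-present
#: verbs, gerunds, past participles, "to", prepositions/subordinating
#: conjunctions, personal pronouns.
DEFAULT_EXCLUDED_TAGS = frozenset(
    {"RB", "RBR", "RBS", "MD", "VBZ", "VBG", "VBN", "TO", "IN", "PRP"})


def default_lemmatizer(word: str) -> str:
    """Lookup lemmatizer with identity fallback."""
    return DEFAULT_LEMMA_TABLE.get(word, word)


def default_tagger(word: str) -> str:
    """Lookup POS tagger; unknown words are tagged ``NN``."""
    return DEFAULT_POS_TABLE.get(word, "NN")
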