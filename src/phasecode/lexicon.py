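"""Stimulus lexicon and connectivity for the two-level categorization model.

The model distinguishes four Dutch CVC words that differ along a consonant
(/x/ vs /d/) and a vowel (/ɑ/ vs /a/) dimension.  Each contrastive unit
(consonant, vowel, whole word) carries a corpus log frequency and a derived
binary frequency class (``high``/``low``); the frequency class is what the
model's sensitivity mechanism acts on.  An additional "empty" word/phoneme
node pair carries the rhythmic entrainment stimulus, which has no linguistic
content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Contrastive phoneme inventory (the /t/ coda is shared by all four words and
# carries no category information, so it is not represented).
CONS_LOW = "x"
CONS_HIGH = "d"
VOWEL_LOW = "a"
VOWEL_HIGH = "ɑ"  # IPA open back unrounded vowel, ɑ
EMPTY = "-"

PHONEMES = (CONS_LOW, CONS_HIGH, VOWEL_LOW, VOWEL_HIGH, EMPTY)

# Word identifiers are their IPA transcriptions (minus the /t/ coda node).
W_XAT_SHORT = CONS_LOW + VOWEL_HIGH + "t"   # Dutch "gat",  /xɑt/, cVw
W_DAT_SHORT = CONS_HIGH + VOWEL_HIGH + "t"  # Dutch "dat",  /dɑt/, CVW
W_XAT_LONG = CONS_LOW + VOWEL_LOW + "t"     # Dutch "gaat", /xat/, cvW
W_DAT_LONG = CONS_HIGH + VOWEL_LOW + "t"    # Dutch "daad", /dat/, Cvw

WORDS = (W_XAT_SHORT, W_DAT_SHORT, W_XAT_LONG, W_DAT_LONG, EMPTY)

# Corpus log frequencies (natural-log scale, relative corpus counts).
PHONEME_LOG_FREQUENCY = {
    CONS_LOW: -2.53,
    CONS_HIGH: -1.87,
    VOWEL_LOW: -2.29,
    VOWEL_HIGH: -1.96,
}
WORD_LOG_FREQUENCY = {
    W_XAT_SHORT: -10.47,
    W_DAT_SHORT: -3.82,
    W_XAT_LONG: -6.41,
    W_DAT_LONG: -11.66,
}

# Three-letter frequency denotation: consonant, vowel, word; upper = high.
FREQUENCY_DENOTATION = {
    W_XAT_SHORT: "cVw",
    W_DAT_SHORT: "CVW",
    W_XAT_LONG: "cvW",
    W_DAT_LONG: "Cvw",
}


@dataclass(frozen=True)
class TraitLexicon:
    """The study lexicon: words, phonemes, and per-trait frequency classes.

    Attributes
    ----------
    words, phonemes : tuple of str
        Node identifiers in canonical order; the last entry of each is the
        empty (entrainment) node.
    word_to_phonemes : dict
        Maps each real word to its set of contrastive phonemes (consonant
        and vowel); the empty word maps to the empty phoneme.
    trait_class : dict
        ``(unit, trait) -> "high" | "low"`` where ``trait`` is one of
        ``"consonant"``, ``"vowel"``, ``"word"``.
    log_frequency : dict
        Natural-log corpus frequency per unit (phonemes and words).
    """

    words: tuple = WORDS
    phonemes: tuple = PHONEMES
    word_to_phonemes: dict = field(default_factory=dict)
    trait_class: dict = field(default_factory=dict)
    log_frequency: dict = field(default_factory=dict)

    @property
    def real_words(self):
        return tuple(w for w in self.words if w != EMPTY)

    @property
    def real_phonemes(self):
        return tuple(p for p in self.phonemes if p != EMPTY)

    def word_index(self, word):
        return self.words.index(word)

    def phoneme_index(self, phoneme):
        return self.phonemes.index(phoneme)

    def high_units(self, level):
        """Units of the given level ('phoneme' or 'word') with class high."""
        if level == "phoneme":
            return tuple(
                p for p in self.real_phonemes
                if self.trait_class[(p, _phoneme_trait(p))] == "high"
            )
        if level == "word":
            return tuple(
                w for w in self.real_words
                if self.trait_class[(w, "word")] == "high"
            )
        raise ValueError(f"unknown level: {level!r}")

    def differing_trait(self, word_a, word_b):
        """The single trait ('consonant' or 'vowel') in which two words differ."""
        pa, pb = self.word_to_phonemes[word_a], self.word_to_phonemes[word_b]
        diff = pa ^ pb
        cons = {CONS_LOW, CONS_HIGH}
        if diff and diff <= cons:
            return "consonant"
        if diff and diff <= {VOWEL_LOW, VOWEL_HIGH}:
            return "vowel"
        raise ValueError(
            f"words {word_a!r}/{word_b!r} do not differ in exactly one trait"
        )


def _phoneme_trait(p):
    return "consonant" if p in (CONS_LOW, CONS_HIGH) else "vowel"


def build_lexicon() -> TraitLexicon:
    """Return the fixed study lexicon.

    Frequency classes follow the log-frequency ordering within each trait:
    within a contrastive pair the unit with higher corpus frequency is
    ``high``.  For whole words the two highest-frequency words (/dɑt/ and
    /xat/) are ``high``.
    """
    word_to_phonemes = {
        w: {w[0], w[1]} for w in WORDS if w != EMPTY
    }
    word_to_phonemes[EMPTY] = {EMPTY}

    trait_class = {}
    for pair in ((CONS_LOW, CONS_HIGH), (VOWEL_LOW, VOWEL_HIGH)):
        lo, hi = sorted(pair, key=lambda p: PHONEME_LOG_FREQUENCY[p])
        trait = _phoneme_trait(lo)
        trait_class[(lo, trait)] = "low"
        trait_class[(hi, trait)] = "high"
    ranked = sorted(WORD_LOG_FREQUENCY, key=WORD_LOG_FREQUENCY.get)
    for w in ranked[:2]:
        trait_class[(w, "word")] = "low"
    for w in ranked[2:]:
        trait_class[(w, "word")] = "high"
    # Per-word consonant/vowel classes inherit from the phoneme inventory.
    for w in WORDS:
        if w == EMPTY:
            continue
        for p in word_to_phonemes[w]:
            trait = _phoneme_trait(p)
            trait_class[(w, trait)] = trait_class[(p, trait)]

    log_frequency = dict(PHONEME_LOG_FREQUENCY)
    log_frequency.update(WORD_LOG_FREQUENCY)

    return TraitLexicon(
        word_to_phonemes=word_to_phonemes,
        trait_class=trait_class,
        log_frequency=log_frequency,
    )


@dataclass(frozen=True)
class Connectivity:
    """Feedforward connectivity between the input and the two analysis levels.

    ``input_to_phoneme[i, j]`` is 1 iff phoneme ``j`` belongs to input word
    ``i`` (the empty word connects to the empty phoneme).  ``input_to_word``
    is the identity.  ``phoneme_to_word`` is present only for the
    hierarchical variant, with entry ``[j, k]`` = 1 iff phoneme ``j`` belongs
    to word ``k``.
    """

    input_to_phoneme: np.ndarray
    input_to_word: np.ndarray
    phoneme_to_word: np.ndarray | None = None


def build_connectivity(lexicon: TraitLexicon, topology: str = "parallel") -> Connectivity:
    """Build connectivity matrices for the given topology.

    Parameters
    ----------
    topology : {"parallel", "hierarchical"}
        In the parallel topology both levels receive the input directly.  In
        the hierarchical variant the word level is driven by the phoneme
        level instead.
    """
    if topology not in ("parallel", "hierarchical"):
        raise ValueError(f"unknown topology: {topology!r}")
    n_w, n_p = len(lexicon.words), len(lexicon.phonemes)
    c_ip = np.zeros((n_w, n_p))
    for i, w in enumerate(lexicon.words):
        for p in lexicon.word_to_phonemes[w]:
            c_ip[i, lexicon.phoneme_index(p)] = 1.0
    c_iw = np.eye(n_w)
    c_pw = None
    if topology == "hierarchical":
        c_pw = c_ip.T.copy()  # phoneme j in word k iff word k contains j
    return Connectivity(input_to_phoneme=c_ip, input_to_word=c_iw,
                        phoneme_to_word=c_pw)
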