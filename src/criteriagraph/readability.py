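"""Word counts and Flesch-Kincaid reading grade level for criterion text.

The grade level approximates the U.S. school grade needed to understand a
text from its words-per-sentence and syllables-per-word ratios:

    grade = 0.39 * (words / sentences) + 11.8 * (syllables / words) - 15.59

Tokenization and syllable counting follow a fixed, documented heuristic
(vowel-group counting with a silent-e rule) so that results are exactly
reproducible; published readability calculators differ in unpublished
details, so grades from other tools may deviate by fractions of a grade.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "TextProfile",
    "count_words",
    "count_syllables",
    "count_sentences",
    "fk_grade",
    "text_profile",
    "ReadabilityError",
]


class ReadabilityError(ValueError):
    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"{code}: {message}")


@dataclass(frozen=True)
class TextProfile:
    criterion_id: str
    word_count: int
    sentence_count: int
    syllable_count: int
    fk_grade: float


_ALNUM = re.compile(r"[0-9A-Za-z]")
# sentence break: terminal punctuation followed by whitespace/end, or a
# newline (bullet-point fragments without punctuation count as sentences)
_SENT_SPLIT = re.compile(r"[.!?;](?:\s+|$)|\n+")

_DIGIT_SYLLABLES = {  # syllables of the spoken digit names
    "0": 2, "1": 1, "2": 1, "3": 1, "4": 1,
    "5": 1, "6": 1, "7": 2, "8": 1, "9": 1,
}

_VOWEL_GROUP = re.compile(r"[aeiouy]+")


def _tokens(text: str) -> list[str]:
    """Whitespace tokens that contain at least one alphanumeric character."""
    return [t for t in text.split() if _ALNUM.search(t)]


def count_words(text: str) -> int:
    """Number of whitespace-delimited tokens carrying an alphanumeric.

    Pure punctuation tokens (a stray ``+`` or dash) are dropped; hyphenated
    words count once.
    """
    return len(_tokens(text))


def count_sentences(text: str) -> int:
    """Sentence count; a non-empty text always has at least one sentence."""
    if not text.strip():
        return 0
    parts = [p for p in _SENT_SPLIT.split(text) if p and p.strip()]
    return max(1, len(parts))


def _syllables_of_part(part: str) -> int:
    """Syllables of one hyphen-free part; 0 if it has no letters or digits."""
    letters = "".join(ch for ch in part.lower() if ch.isalpha())
    digits = [ch for ch in part if ch.isdigit()]
    syl = sum(_DIGIT_SYLLABLES[d] for d in digits)
    if letters:
        groups = _VOWEL_GROUP.findall(letters)
        n = len(groups)
        # silent terminal 'e' — unless '-le' after a consonant ("stable")
        if (
            n > 1
            and letters.endswith("e")
            and not (
                letters.endswith("le")
                and len(letters) >= 3
                and letters[-3] not in "aeiouy"
            )
        ):
            n -= 1
        syl += max(1, n)
    return syl


def count_syllables(word: str) -> int:
    """Heuristic syllable count of one token, floored at 1.

    Vowel groups (a e i o u y) count one syllable each; a terminal silent
    'e' is subtracted except in consonant+'le' endings; numerals contribute
    the syllables of their digit-by-digit reading; hyphenated parts sum.
    """
    total = sum(_syllables_of_part(p) for p in re.split(r"[-–—]", word))
    return max(1, total)


def fk_grade(text: str) -> float:
    """Flesch-Kincaid grade level of a text; may be negative, never clamped."""
    words = _tokens(text)
    if not words:
        raise ReadabilityError("EMPTY_TEXT", "cannot grade empty text")
    w = len(words)
    s = count_sentences(text)
    syl = sum(count_syllables(t) for t in words)
    return 0.39 * (w / s) + 11.8 * (syl / w) - 15.59


def text_profile(criterion_id: str, text: str) -> TextProfile:
    """Full readability profile of one criterion's verbatim text."""
    words = _tokens(text)
    w = len(words)
    s = count_sentences(text)
    syl = sum(count_syllables(t) for t in words)
    grade = 0.39 * (w / s) + 11.8 * (syl / w) - 15.59 if w else float("nan")
    return TextProfile(criterion_id, w, s, syl, grade)
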