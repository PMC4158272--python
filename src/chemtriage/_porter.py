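"""Classic Porter stemming algorithm (Porter 1980).

This is the original five-step suffix-stripping algorithm, without the later
"Porter2"/Snowball revisions or the NLTK extensions (no ``logi -> log`` rule,
no special-casing of short words beyond the length-2 guard). Words are assumed
to be lowercase ASCII; anything of length <= 2 is returned unchanged.
"""

from __future__ import annotations

from functools import lru_cache

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel-consonant sequences ``m`` in C?(VC){m}V?."""
    n = len(stem)
    i = 0
    while i < n and _is_consonant(stem, i):
        i += 1
    m = 0
    while i < n:
        while i < n and not _is_consonant(stem, i):
            i += 1
        if i >= n:
            break
        m += 1
        while i < n and _is_consonant(stem, i):
            i += 1
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # *o condition: stem ends consonant-vowel-consonant, final cons not w/x/y
    if len(word) < 3:
        return False
    if not (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


# Step 2 and 3 rule tables: suffix -> replacement, applied when measure(stem) > 0.
_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

# Step 4 suffixes are deleted when measure(stem) > 1; "ion" additionally
# requires the stem to end in s or t. Longest-match order.
_STEP4 = (
    "ement", "ance", "ence", "able", "ible", "ment", "ent", "ion", "ism",
    "ate", "iti", "ous", "ive", "ize", "ant", "al", "er", "ic", "ou",
)


def _longest_match(word: str, suffixes) -> str | None:
    for suf in sorted({s[0] if isinstance(s, tuple) else s for s in suffixes},
                      key=len, reverse=True):
        if word.endswith(suf):
            return suf
    return None


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies"):
        return word[:-2]
    if word.endswith("ss"):
        return word
    if word.endswith("s"):
        return word[:-1]
    return word


def _step1b(word: str) -> str:
    if word.endswith("eed"):
        if _measure(word[:-3]) > 0:
            return word[:-1]
        return word
    stripped = None
    if word.endswith("ed") and _contains_vowel(word[:-2]):
        stripped = word[:-2]
    elif word.endswith("ing") and _contains_vowel(word[:-3]):
        stripped = word[:-3]
    if stripped is None:
        return word
    if stripped.endswith(("at", "bl", "iz")):
        return stripped + "e"
    if _ends_double_consonant(stripped) and stripped[-1] not in "lsz":
        return stripped[:-1]
    if _measure(stripped) == 1 and _ends_cvc(stripped):
        return stripped + "e"
    return stripped


def _step1c(word: str) -> str:
    if word.endswith("y") and _contains_vowel(word[:-1]):
        return word[:-1] + "i"
    return word


def _apply_table(word: str, table) -> str:
    # Porter semantics: only the longest matching suffix is considered; if its
    # measure condition fails, no shorter suffix is tried.
    suf = _longest_match(word, table)
    if suf is None:
        return word
    repl = dict(table)[suf]
    stem = word[: -len(suf)]
    if _measure(stem) > 0:
        return stem + repl
    return word


def _step4(word: str) -> str:
    suf = _longest_match(word, _STEP4)
    if suf is None:
        return word
    stem = word[: -len(suf)]
    if _measure(stem) <= 1:
        return word
    if suf == "ion" and not stem.endswith(("s", "t")):
        return word
    return stem


def _step5(word: str) -> str:
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            word = stem
    if word.endswith("ll") and _measure(word) > 1:
        word = word[:-1]
    return word


@lru_cache(maxsize=65536)
def porter_stem(word: str) -> str:
    """Stem one lowercase word with the classic Porter algorithm."""
    if len(word) <= 2:
        return word
    word = _step1a(word)
    word = _step1b(word)
    word = _step1c(word)
    word = _apply_table(word, _STEP2)
    word = _apply_table(word, _STEP3)
    word = _step4(word)
    word = _step5(word)
    return word
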