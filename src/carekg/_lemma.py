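"""Dictionary + suffix-rule English lemmatizer.

Covers noun plurals and the common verbal inflections (-ing, -ed, -s) with a
small irregular-form dictionary on top.  It is intentionally conservative:
a suffix is only stripped when enough of the stem remains, and stripping is
idempotent (``lemmatize(lemmatize(w)) == lemmatize(w)``), which the corpus
pipeline relies on.  The same lemmatizer instance must be used for both
document preprocessing and lexicon compilation so that surface forms and
document tokens meet in lemma space.
"""

from __future__ import annotations

_IRREGULAR = {
    # nouns
    "children": "child",
    "men": "man",
    "women": "woman",
    "feet": "foot",
    "teeth": "tooth",
    "mice": "mouse",
    "geese": "goose",
    "people": "person",
    "lives": "life",
    # be / have / do and frequent irregular verbs
    "is": "be",
    "am": "be",
    "are": "be",
    "was": "be",
    "were": "be",
    "been": "be",
    "being": "be",
    "has": "have",
    "had": "have",
    "having": "have",
    "does": "do",
    "did": "do",
    "done": "do",
    "goes": "go",
    "went": "go",
    "gone": "go",
    "ran": "run",
    "said": "say",
    "made": "make",
    "got": "get",
    "took": "take",
    "taken": "take",
    "gave": "give",
    "given": "give",
    "found": "find",
    "saw": "see",
    "seen": "see",
    "hit": "hit",
    "hits": "hit",
}

_VOWELS = set("aeiou")

# suffixes whose removal would leave a non-word too often
_S_EXCEPTIONS = ("ss", "us", "is")


def _undouble(stem: str) -> str:
    """running -> runn -> run; stopped -> stopp -> stop.  Keep -ll/-ss."""
    if (
        len(stem) >= 3
        and stem[-1] == stem[-2]
        and stem[-1] not in _VOWELS
        and stem[-1] not in "ls"
    ):
        return stem[:-1]
    return stem


def lemmatize(word: str) -> str:
    """Return the lemma of a single lowercase token."""
    w = word
    if w in _IRREGULAR:
        return _IRREGULAR[w]
    if len(w) < 4 or not w.isalpha():
        return w
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith(("ches", "shes", "xes", "zes")):
        return w[:-2]
    if w.endswith("ing") and len(w) - 3 >= 3:
        return _undouble(w[:-3])
    if w.endswith("ed") and len(w) - 2 >= 3:
        return _undouble(w[:-2])
    if w.endswith("s") and not w.endswith(_S_EXCEPTIONS):
        return w[:-1]
    return w
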