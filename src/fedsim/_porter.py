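"""Porter (1980) suffix-stripping stemmer.

Implements the original algorithm: five sequential rule steps driven by the
*measure* m of a stem, where a word is analysed as ``[C](VC)^m[V]`` over
consonant (C) and vowel (V) runs.  Tokens of length <= 2 are returned
unchanged, and rules that do not match (e.g. on digit-bearing tokens such as
``mk2``) leave the token as is.

Only lowercase ``[a-z0-9]`` input is expected; digits are treated as
consonants, which keeps them inert under every rule.
"""

from __future__ import annotations

_VOWELS = "aeiou"


class _Stem:
    """Mutable word buffer with the measure/shape predicates of the algorithm."""

    def __init__(self, word: str) -> None:
        self.b = word

    def _cons(self, i: int) -> bool:
        ch = self.b[i]
        if ch in _VOWELS:
            return False
        if ch == "y":
            return True if i == 0 else not self._cons(i - 1)
        return True

    def measure(self, stem: str) -> int:
        """m of ``[C](VC)^m[V]`` computed on an explicit stem string."""
        saved, self.b = self.b, stem
        try:
            n = len(stem)
            i = 0
            while i < n and self._cons(i):
                i += 1
            m = 0
            while True:
                while i < n and not self._cons(i):
                    i += 1
                if i >= n:
                    return m
                while i < n and self._cons(i):
                    i += 1
                m += 1
        finally:
            self.b = saved

    def vowel_in(self, stem: str) -> bool:
        saved, self.b = self.b, stem
        try:
            return any(not self._cons(i) for i in range(len(stem)))
        finally:
            self.b = saved

    def ends_double_cons(self, stem: str) -> bool:
        if len(stem) < 2 or stem[-1] != stem[-2]:
            return False
        saved, self.b = self.b, stem
        try:
            return self._cons(len(stem) - 1)
        finally:
            self.b = saved

    def ends_cvc(self, stem: str) -> bool:
        """Consonant-vowel-consonant ending where the final consonant is not w/x/y."""
        if len(stem) < 3:
            return False
        saved, self.b = self.b, stem
        try:
            n = len(stem)
            return (
                self._cons(n - 1)
                and not self._cons(n - 2)
                and self._cons(n - 3)
                and stem[-1] not in "wxy"
            )
        finally:
            self.b = saved


def _apply_map(word: str, rules: list[tuple[str, str]], helper: _Stem, min_m: int) -> str:
    for suffix, repl in rules:
        if word.endswith(suffix):
            stem = word[: len(word) - len(suffix)]
            if helper.measure(stem) > min_m:
                return stem + repl
            return word
    return word


def stem(word: str) -> str:
    """Return the Porter stem of a lowercase token."""
    if len(word) <= 2:
        return word
    h = _Stem(word)
    w = word

    # Step 1a: plurals
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b: -ed / -ing
    if w.endswith("eed"):
        if h.measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        cleaned = False
        if w.endswith("ed") and h.vowel_in(w[:-2]):
            w = w[:-2]
            cleaned = True
        elif w.endswith("ing") and h.vowel_in(w[:-3]):
            w = w[:-3]
            cleaned = True
        if cleaned:
            if w.endswith(("at", "bl", "iz")):
                w = w + "e"
            elif h.ends_double_cons(w) and not w.endswith(("l", "s", "z")):
                w = w[:-1]
            elif h.measure(w) == 1 and h.ends_cvc(w):
                w = w + "e"

    # Step 1c: terminal y -> i when a vowel precedes it
    if w.endswith("y") and h.vowel_in(w[:-1]):
        w = w[:-1] + "i"

    # Step 2 (m > 0)
    w = _apply_map(
        w,
        [
            ("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
            ("anci", "ance"), ("izer", "ize"), ("abli", "able"),
            ("alli", "al"), ("entli", "ent"), ("eli", "e"), ("ousli", "ous"),
            ("ization", "ize"), ("ation", "ate"), ("ator", "ate"),
            ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
            ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"),
            ("biliti", "ble"),
        ],
        h,
        min_m=0,
    )

    # Step 3 (m > 0)
    w = _apply_map(
        w,
        [
            ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
            ("ical", "ic"), ("ful", ""), ("ness", ""),
        ],
        h,
        min_m=0,
    )

    # Step 4 (m > 1); -ion needs a preceding s or t
    for suffix in (
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ):
        if w.endswith(suffix):
            stem_ = w[: len(w) - len(suffix)]
            if suffix == "ion" and not stem_.endswith(("s", "t")):
                break
            if h.measure(stem_) > 1:
                w = stem_
            break

    # Step 5a: drop terminal e
    if w.endswith("e"):
        m = h.measure(w[:-1])
        if m > 1 or (m == 1 and not h.ends_cvc(w[:-1])):
            w = w[:-1]

    # Step 5b: -ll -> -l when m > 1
    if h.ends_double_cons(w) and w.endswith("l") and h.measure(w[:-1]) > 1:
        w = w[:-1]

    return w
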