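"""Porter suffix-stripping stemmer.

Classic Porter (1980) algorithm, implemented from the published
description so that grammatical variants collapse onto one term
(work, works, working -> "work").  Outputs are pinned by a golden
test against the algorithm's published example vectors.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


class _Word:
    """Mutable buffer b[0..k] with the algorithm's j marker."""

    __slots__ = ("b", "k", "j")

    def __init__(self, word: str) -> None:
        self.b = list(word)
        self.k = len(word) - 1
        self.j = 0

    def cons(self, i: int) -> bool:
        ch = self.b[i]
        if ch in _VOWELS:
            return False
        if ch == "y":
            return True if i == 0 else not self.cons(i - 1)
        return True

    def m(self) -> int:
        # number of VC sequences in b[0..j]
        n = 0
        i = 0
        while True:
            if i > self.j:
                return n
            if not self.cons(i):
                break
            i += 1
        i += 1
        while True:
            while True:
                if i > self.j:
                    return n
                if self.cons(i):
                    break
                i += 1
            i += 1
            n += 1
            while True:
                if i > self.j:
                    return n
                if not self.cons(i):
                    break
                i += 1
            i += 1

    def vowel_in_stem(self) -> bool:
        return any(not self.cons(i) for i in range(self.j + 1))

    def doublec(self, j: int) -> bool:
        return j >= 1 and self.b[j] == self.b[j - 1] and self.cons(j)

    def cvc(self, i: int) -> bool:
        if i < 2 or not self.cons(i) or self.cons(i - 1) or not self.cons(i - 2):
            return False
        return self.b[i] not in ("w", "x", "y")

    def ends(self, s: str) -> bool:
        length = len(s)
        if length > self.k + 1 or self.b[self.k - length + 1 : self.k + 1] != list(s):
            return False
        self.j = self.k - length
        return True

    def setto(self, s: str) -> None:
        self.b[self.j + 1 : self.k + 1] = list(s)
        self.k = self.j + len(s)

    def r(self, s: str) -> None:
        if self.m() > 0:
            self.setto(s)


def _step1ab(w: _Word) -> None:
    if w.b[w.k] == "s":
        if w.ends("sses"):
            w.k -= 2
        elif w.ends("ies"):
            w.setto("i")
        elif w.b[w.k - 1] != "s":
            w.k -= 1
    if w.ends("eed"):
        if w.m() > 0:
            w.k -= 1
    elif (w.ends("ed") or w.ends("ing")) and w.vowel_in_stem():
        w.k = w.j
        if w.ends("at"):
            w.setto("ate")
        elif w.ends("bl"):
            w.setto("ble")
        elif w.ends("iz"):
            w.setto("ize")
        elif w.doublec(w.k):
            w.k -= 1
            if w.b[w.k] in ("l", "s", "z"):
                w.k += 1
        elif w.m() == 1 and w.cvc(w.k):
            w.setto("e")


def _step1c(w: _Word) -> None:
    if w.ends("y") and w.vowel_in_stem():
        w.b[w.k] = "i"


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("bli", "ble"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    ("logi", "log"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _step2(w: _Word) -> None:
    for suffix, repl in _STEP2:
        if w.ends(suffix):
            w.r(repl)
            return


def _step3(w: _Word) -> None:
    for suffix, repl in _STEP3:
        if w.ends(suffix):
            w.r(repl)
            return


def _step4(w: _Word) -> None:
    for suffix in _STEP4:
        if w.ends(suffix):
            if suffix == "ion" and w.b[w.j] not in ("s", "t"):
                continue
            if w.m() > 1:
                w.k = w.j
            return


def _step5(w: _Word) -> None:
    w.j = w.k
    if w.b[w.k] == "e":
        a = w.m()
        if a > 1 or (a == 1 and not w.cvc(w.k - 1)):
            w.k -= 1
    if w.b[w.k] == "l" and w.doublec(w.k) and w.m() > 1:
        w.k -= 1


def porter_stem(token: str) -> str:
    """Stem one lower-case token; words of length <= 2 pass through."""
    if len(token) <= 2:
        return token
    w = _Word(token)
    _step1ab(w)
    _step1c(w)
    _step2(w)
    _step3(w)
    _step4(w)
    _step5(w)
    return "".join(w.b[: w.k + 1])
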