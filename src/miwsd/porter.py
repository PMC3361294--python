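"""Porter stemming algorithm (Porter, 1980).

A self-contained implementation of the classic suffix-stripping stemmer,
following the reference algorithm's five steps, including the widely used
revisions ``bli -> ble`` and ``logi -> log`` in step 2.  Words of length
one or two are returned unchanged, as in the reference implementation.

Only lowercase ASCII input is expected (the preprocessing pipeline
lowercases before stemming); tokens containing digits pass through the
steps untouched because no suffix rule matches them.
"""

__all__ = ["stem"]

_VOWELS = "aeiou"


class _Stemmer:
    """Mutable working state for one word; mirrors the reference structure.

    ``b`` is the buffer, ``k`` the offset of the last letter of the current
    string, ``j`` a general offset set by :meth:`ends`.
    """

    def __init__(self) -> None:
        self.b = ""
        self.k = 0
        self.j = 0

    # -- character classes -------------------------------------------------

    def cons(self, i: int) -> bool:
        ch = self.b[i]
        if ch in _VOWELS:
            return False
        if ch == "y":
            return True if i == 0 else not self.cons(i - 1)
        return True

    def m(self) -> int:
        """Measure of consonant-vowel sequences in b[0..j]."""
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

    def double_c(self, j: int) -> bool:
        if j < 1:
            return False
        if self.b[j] != self.b[j - 1]:
            return False
        return self.cons(j)

    def cvc(self, i: int) -> bool:
        """consonant-vowel-consonant ending at i, final consonant not w/x/y."""
        if i < 2 or not self.cons(i) or self.cons(i - 1) or not self.cons(i - 2):
            return False
        return self.b[i] not in "wxy"

    # -- suffix machinery --------------------------------------------------

    def ends(self, s: str) -> bool:
        length = len(s)
        if length > self.k + 1:
            return False
        if self.b[self.k - length + 1 : self.k + 1] != s:
            return False
        self.j = self.k - length
        return True

    def set_to(self, s: str) -> None:
        self.b = self.b[: self.j + 1] + s + self.b[self.j + 1 + len(s) :]
        self.k = self.j + len(s)

    def r(self, s: str) -> None:
        if self.m() > 0:
            self.set_to(s)

    # -- the five steps ----------------------------------------------------

    def step1ab(self) -> None:
        if self.b[self.k] == "s":
            if self.ends("sses"):
                self.k -= 2
            elif self.ends("ies"):
                self.set_to("i")
            elif self.b[self.k - 1] != "s":
                self.k -= 1
        if self.ends("eed"):
            if self.m() > 0:
                self.k -= 1
        elif (self.ends("ed") or self.ends("ing")) and self.vowel_in_stem():
            self.k = self.j
            if self.ends("at"):
                self.set_to("ate")
            elif self.ends("bl"):
                self.set_to("ble")
            elif self.ends("iz"):
                self.set_to("ize")
            elif self.double_c(self.k):
                if self.b[self.k] not in "lsz":
                    self.k -= 1
            elif self.m() == 1 and self.cvc(self.k):
                self.j = self.k
                self.set_to("e")

    def step1c(self) -> None:
        if self.ends("y") and self.vowel_in_stem():
            self.b = self.b[: self.k] + "i" + self.b[self.k + 1 :]

    _STEP2 = {
        "a": (("ational", "ate"), ("tional", "tion")),
        "c": (("enci", "ence"), ("anci", "ance")),
        "e": (("izer", "ize"),),
        "g": (("logi", "log"),),
        "l": (("bli", "ble"), ("alli", "al"), ("entli", "ent"), ("eli", "e"), ("ousli", "ous")),
        "o": (("ization", "ize"), ("ation", "ate"), ("ator", "ate")),
        "s": (("alism", "al"), ("iveness", "ive"), ("fulness", "ful"), ("ousness", "ous")),
        "t": (("aliti", "al"), ("iviti", "ive"), ("biliti", "ble")),
    }

    _STEP3 = {
        "e": (("icate", "ic"), ("ative", ""), ("alize", "al")),
        "i": (("iciti", "ic"),),
        "l": (("ical", "ic"), ("ful", "")),
        "s": (("ness", ""),),
    }

    def _apply_map(self, table: dict, key_index: int) -> None:
        if self.k < 1:
            return
        rules = table.get(self.b[self.k + key_index])
        if not rules:
            return
        for suffix, repl in rules:
            if self.ends(suffix):
                self.r(repl)
                return

    def step2(self) -> None:
        self._apply_map(self._STEP2, -1)

    def step3(self) -> None:
        self._apply_map(self._STEP3, 0)

    _STEP4 = {
        "a": ("al",),
        "c": ("ance", "ence"),
        "e": ("er",),
        "i": ("ic",),
        "l": ("able", "ible"),
        "n": ("ant", "ement", "ment", "ent"),
        "o": ("ion", "ou"),
        "s": ("ism",),
        "t": ("ate", "iti"),
        "u": ("ous",),
        "v": ("ive",),
        "z": ("ize",),
    }

    def step4(self) -> None:
        if self.k < 1:
            return
        suffixes = self._STEP4.get(self.b[self.k - 1])
        if not suffixes:
            return
        for suffix in suffixes:
            if self.ends(suffix):
                # "ion" is only removed after s or t
                if suffix == "ion" and (self.j < 0 or self.b[self.j] not in "st"):
                    continue
                if self.m() > 1:
                    self.k = self.j
                return

    def step5(self) -> None:
        self.j = self.k
        if self.b[self.k] == "e":
            a = self.m()
            if a > 1 or (a == 1 and not self.cvc(self.k - 1)):
                self.k -= 1
        if self.b[self.k] == "l" and self.double_c(self.k) and self.m() > 1:
            self.k -= 1

    def stem(self, word: str) -> str:
        if len(word) <= 2:
            return word
        self.b = word
        self.k = len(word) - 1
        self.step1ab()
        self.step1c()
        self.step2()
        self.step3()
        self.step4()
        self.step5()
        return self.b[: self.k + 1]


def stem(word: str) -> str:
    """Return the Porter stem of a lowercase word."""
    return _Stemmer().stem(word)
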