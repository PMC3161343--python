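"""Deterministic text normalization shared by every classifier.

Tokenization splits the narrative on any run of non-alphanumeric
characters and case-folds, so hyphenated compounds yield their parts
("work-related" -> work, related); each narrative is treated as one
undivided context block — there is no sentence segmentation anywhere,
because triage text is rarely grammatical prose.  Stemming is classic
Porter suffix stripping so grammatical variants collapse onto a single
term (work, works, working -> "work").
"""

from __future__ import annotations

import re
from collections.abc import Iterable
from dataclasses import dataclass, field
from importlib import resources

from ._porter import porter_stem

_TOKEN_RE = re.compile(r"[0-9a-z]+")


def stem(token: str) -> str:
    """Porter stem of a single non-empty lower-case token (idempotent)."""
    if not token:
        raise ValueError("cannot stem an empty token")
    return porter_stem(token)


@dataclass(frozen=True)
class TokenStream:
    """Parallel lists of lower-cased tokens and their stems."""

    tokens: tuple[str, ...]
    stems: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.stems):
            raise ValueError("tokens and stems must be parallel")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def stemmed_text(self) -> str:
        """Space-joined stems; substring searches on this honour stems."""
        return " ".join(self.stems)

    def stem_set(self) -> frozenset[str]:
        return frozenset(self.stems)


def tokenize(text: str) -> TokenStream:
    """Total, deterministic tokenization of a narrative (empty text allowed)."""
    tokens = tuple(_TOKEN_RE.findall(text.casefold()))
    return TokenStream(tokens, tuple(porter_stem(t) for t in tokens))


def _load_stems(lines: Iterable[str]) -> frozenset[str]:
    out = set()
    for line in lines:
        word = line.split("#", 1)[0].strip().casefold()
        if word:
            out.add(porter_stem(word))
    return frozenset(out)


@dataclass(frozen=True)
class StopList:
    """Stems excluded from concept learning, minus retained overrides.

    The shipped default excludes common English function words but
    rescues words that can name body parts (back, face, feet),
    mechanisms of injury (cut) or injurious objects (saw).
    """

    excluded: frozenset[str] = field(default_factory=frozenset)
    retained_overrides: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        # resolve: overrides win, so the two sets end up disjoint
        object.__setattr__(self, "excluded", self.excluded - self.retained_overrides)

    def is_stopped(self, stem_: str) -> bool:
        return stem_ in self.excluded

    @classmethod
    def from_lines(cls, stop_lines: Iterable[str], override_lines: Iterable[str] = ()) -> "StopList":
        return cls(_load_stems(stop_lines), _load_stems(override_lines))

    @classmethod
    def from_files(cls, stop_path: str, override_path: str | None = None) -> "StopList":
        with open(stop_path, encoding="utf-8") as fh:
            stops = fh.readlines()
        overrides: list[str] = []
        if override_path:
            with open(override_path, encoding="utf-8") as fh:
                overrides = fh.readlines()
        return cls.from_lines(stops, overrides)

    @classmethod
    def default(cls) -> "StopList":
        pkg = resources.files("worknarr.data")
        return cls.from_lines(
            pkg.joinpath("stoplist.txt").read_text(encoding="utf-8").splitlines(),
            pkg.joinpath("stop_overrides.txt").read_text(encoding="utf-8").splitlines(),
        )


def apply_stoplist(stream: TokenStream, stops: StopList) -> TokenStream:
    """Drop tokens whose stems are stop-listed; order is preserved."""
    kept = [(t, s) for t, s in zip(stream.tokens, stream.stems) if not stops.is_stopped(s)]
    if not kept:
        return TokenStream((), ())
    tokens, stems = zip(*kept)
    return TokenStream(tokens, stems)
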