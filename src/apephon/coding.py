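"""Rule-based coding of free orthographic transcriptions into phoneme slots.

Listeners type whatever they heard ("mama", "Ma-ma!", "nya-nya", "Homo-mo").
This module reduces each response to four slots — first consonant (C1), first
vowel (V1), second consonant (C2), second vowel (V2) — so that agreement can
be computed across listeners. The rules:

1. Equivalent spellings collapse: case, punctuation, diacritics and geminate
   consonant letters are normalization noise, so "mama", "ma-ma" and "mamma"
   all code identically.
2. A two-letter nucleus is one diphthong label (/ai/), not two vowels.
3. A multi-letter onset is one cluster label (/fn/), not its first letter.
4. Responses that are real words ("my house") are excluded as n/a.
5. Responses of other than two syllables are excluded as n/a under the
   ``strict`` scheme; under the ``relabeled`` scheme a three- or
   four-syllable response contributes its final two syllables (listeners
   sometimes transcribe a leading noise burst as extra syllables, e.g.
   "Ash-ma-ma").

Slot labels are lower-case letter strings: consonant letters map one-to-one
to phoneme-class labels (only "y" is relabeled to the glide /j/); an empty
onset is recorded as the vowel-initial marker ``"V"``.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Sequence

VOWEL_LETTERS = frozenset("aeiou")
NA_REASONS = ("none", "real_word", "wrong_syllable_count", "empty", "unparseable")
VOWEL_INITIAL = "V"

#: Onset consonant letters map to phoneme-class labels. The letters that occur
#: in practice ("m", "n", "p", "b", ...) stand for the matching phoneme; "y"
#: in onset position is the palatal glide /j/.
GRAPHEME_TO_PHONEME = {c: c for c in "bcdfghjklmnpqrstvwxz"} | {"y": "j"}
PHONEME_TO_GRAPHEME = {v: k for k, v in GRAPHEME_TO_PHONEME.items() if v != "j"} | {"j": "y"}

_SEPARATOR_RUN = re.compile(r"[ \-]+")
_GEMINATE = re.compile(r"([b-df-hj-np-tv-z])\1+")
_NON_TEXT = re.compile(r"[^a-z \-]")


class UnparseableError(ValueError):
    """A chunk of a transcription contains no vowel letter to anchor a nucleus."""


@dataclass(frozen=True)
class RawTranscription:
    """One listener's free-text response to one utterance."""

    listener_id: str
    utterance_id: str
    text: str
    native_language: str = ""
    experience: str = "none"

    def __post_init__(self) -> None:
        if not self.listener_id or not self.utterance_id:
            raise ValueError("listener_id and utterance_id must be non-empty")
        if self.experience not in ("none", "some", "extensive"):
            raise ValueError(f"experience must be none/some/extensive, got {self.experience!r}")


@dataclass(frozen=True)
class Syllable:
    """Onset + nucleus (+ coda) in orthographic letters; nucleus is 1-2 vowel letters."""

    onset: str
    nucleus: str
    coda: str = ""

    def __post_init__(self) -> None:
        if not self.nucleus:
            raise ValueError("syllable nucleus must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.onset}{self.nucleus}{self.coda}"


@dataclass(frozen=True)
class CodingScheme:
    """Which rule set applies, and the lexicon used for real-word exclusion.

    ``strict`` sends every response that is not exactly two syllables to n/a;
    ``relabeled`` additionally codes the final two syllables of three- and
    four-syllable responses. The real-word lexicon is explicit and supplied
    with the dataset: entries are compared after normalization against the
    whole response and against each space-separated token.
    """

    variant: str = "strict"
    real_word_lexicon: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.variant not in ("strict", "relabeled"):
            raise ValueError(f"variant must be 'strict' or 'relabeled', got {self.variant!r}")
        object.__setattr__(
            self, "real_word_lexicon", frozenset(normalize_text(w) for w in self.real_word_lexicon)
        )


@dataclass(frozen=True)
class CodedUtterance:
    """Four phoneme slots for one listener/utterance pair.

    A slot holds a label (``"m"``, ``"fn"``, ``"a"``, ``"au"``, ``"V"``) or
    ``None`` for n/a. When the per-utterance exclusion rules fire,
    ``na_reason`` records why and all four slots are ``None``; slot-level
    ``None`` with ``na_reason == "none"`` is permitted for fixture data where
    positions were excluded independently.
    """

    listener_id: str
    utterance_id: str
    c1: str | None
    v1: str | None
    c2: str | None
    v2: str | None
    na_reason: str = "none"
    relabeled: bool = False

    def __post_init__(self) -> None:
        if self.na_reason not in NA_REASONS:
            raise ValueError(f"unknown na_reason {self.na_reason!r}")
        if self.na_reason != "none" and any(
            s is not None for s in (self.c1, self.v1, self.c2, self.v2)
        ):
            raise ValueError("slots must all be None when na_reason is set")

    def slot(self, position: str) -> str | None:
        return {"C1": self.c1, "V1": self.v1, "C2": self.c2, "V2": self.v2}[position]


def normalize_text(text: str) -> str:
    """Collapse a raw response to lower-case base letters with separators.

    Diacritics are stripped by compatibility decomposition (the listener pool
    is multilingual and may type accented Latin characters), punctuation other
    than hyphen/space is dropped, digits and non-Latin characters are dropped,
    separator runs collapse to a single hyphen (if any hyphen was present) or
    space, and doubled consonant letters are collapsed ("mamma" -> "mama").
    Vowel pairs are never collapsed: "aa" is a diphthong spelling, not a
    geminate. Total and idempotent.
    """
    decomposed = unicodedata.normalize("NFKD", text)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    lowered = stripped.lower()
    lowered = _NON_TEXT.sub("", lowered)

    def _collapse_sep(match: re.Match[str]) -> str:
        return "-" if "-" in match.group(0) else " "

    collapsed = _SEPARATOR_RUN.sub(_collapse_sep, lowered).strip(" -")
    return _GEMINATE.sub(r"\1", collapsed)


def _chunk_syllables(chunk: str) -> list[Syllable]:
    """Parse one separator-free chunk into syllables.

    Nuclei are maximal runs of vowel letters capped at two (a three-vowel run
    splits two-then-one, left to right); every consonant between two nuclei
    joins the onset of the following syllable (onset maximization), and only
    the final syllable may carry a coda. "y" counts as a vowel letter only in
    chunks containing no other vowel candidate ("my"), otherwise it is an
    onset consonant ("nya").
    """
    vowels = VOWEL_LETTERS if any(c in VOWEL_LETTERS for c in chunk) else VOWEL_LETTERS | {"y"}
    if not any(c in vowels for c in chunk):
        raise UnparseableError(f"no vowel letter in {chunk!r}")

    nuclei: list[tuple[int, int]] = []  # [start, end) spans of nuclei
    i = 0
    while i < len(chunk):
        if chunk[i] in vowels:
            j = i
            while j < len(chunk) and chunk[j] in vowels:
                j += 1
            run = chunk[i:j]
            k = 0
            while k < len(run):
                width = min(2, len(run) - k)
                nuclei.append((i + k, i + k + width))
                k += width
            i = j
        else:
            i += 1

    syllables = []
    prev_end = 0
    for idx, (start, end) in enumerate(nuclei):
        onset = chunk[prev_end:start]
        coda = chunk[end:] if idx == len(nuclei) - 1 else ""
        syllables.append(Syllable(onset=onset, nucleus=chunk[start:end], coda=coda))
        prev_end = end
    return syllables


def syllabify(normalized: str) -> tuple[Syllable, ...]:
    """Split a normalized string into syllables.

    Explicit separators (hyphen, space) are syllable boundaries; unseparated
    runs are parsed by :func:`_chunk_syllables`. Raises
    :class:`UnparseableError` when any chunk has no vowel letter.
    """
    chunks = [c for c in re.split(r"[ \-]", normalized) if c]
    out: list[Syllable] = []
    for chunk in chunks:
        out.extend(_chunk_syllables(chunk))
    return tuple(out)


def map_slots(syllables: Sequence[Syllable]) -> tuple[str, str, str, str]:
    """Map exactly two syllables onto (C1, V1, C2, V2) labels.

    Onset letters map through the grapheme table; multi-letter onsets stay
    intact as one cluster label; an empty onset becomes the vowel-initial
    marker; a two-letter nucleus is a single diphthong label. Codas carry no
    slot of their own and are ignored.
    """
    if len(syllables) != 2:
        raise ValueError(f"map_slots requires exactly 2 syllables, got {len(syllables)}")
    labels = []
    for syl in syllables:
        onset = "".join(GRAPHEME_TO_PHONEME[c] for c in syl.onset) or VOWEL_INITIAL
        labels.extend([onset, syl.nucleus])
    return labels[0], labels[1], labels[2], labels[3]


def _na(t: RawTranscription, reason: str, relabeled: bool = False) -> CodedUtterance:
    return CodedUtterance(t.listener_id, t.utterance_id, None, None, None, None,
                          na_reason=reason, relabeled=relabeled)


def code(transcription: RawTranscription, scheme: CodingScheme) -> CodedUtterance:
    """Run the full coding pipeline on one response.

    normalize -> real-word exclusion -> syllabify -> syllable-count rules
    (with relabeling of 3-4 syllable responses under the ``relabeled``
    scheme) -> slot mapping. Never raises on content: every failure is
    encoded as n/a with a reason.
    """
    norm = normalize_text(transcription.text)
    if not norm:
        return _na(transcription, "empty")
    tokens = norm.split(" ")
    if norm in scheme.real_word_lexicon or any(t in scheme.real_word_lexicon for t in tokens):
        return _na(transcription, "real_word")
    try:
        syllables = syllabify(norm)
    except UnparseableError:
        return _na(transcription, "unparseable")

    n = len(syllables)
    relabeled = False
    if n == 2:
        pass
    elif n in (3, 4) and scheme.variant == "relabeled":
        syllables = syllables[-2:]
        relabeled = True
    else:
        return _na(transcription, "wrong_syllable_count")

    c1, v1, c2, v2 = map_slots(syllables)
    return CodedUtterance(transcription.listener_id, transcription.utterance_id,
                          c1, v1, c2, v2, relabeled=relabeled)


def code_dataset(
    transcriptions: Iterable[RawTranscription], scheme: CodingScheme
) -> list[CodedUtterance]:
    """Code every transcription under one scheme, preserving input order."""
    return [code(t, scheme) for t in transcriptions]
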