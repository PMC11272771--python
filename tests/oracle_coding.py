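"""Independent brute-force oracle for the transcription-coding rules.

Enumerates every segmentation of a string into syllables and selects the
parse the rules prescribe, instead of scanning left-to-right like the
implementation. Used to cross-check apephon.coding on exhaustive small
alphabets.
"""

from __future__ import annotations

from functools import lru_cache

VOWELS = set("aeiou")


def collapse_geminates(text: str) -> str:
    out = []
    for ch in text:
        if out and out[-1] == ch and ch not in VOWELS:
            continue
        out.append(ch)
    return "".join(out)


@lru_cache(maxsize=None)
def _parses(chunk: str, is_final: bool) -> tuple[tuple[tuple[str, str, str], ...], ...]:
    """All segmentations of ``chunk`` into (onset, nucleus, coda) syllables.

    A syllable is C*V{1,2}, with a consonant coda allowed only on the final
    syllable of the final chunk. Every vowel letter must sit in a nucleus.
    """
    vowels = VOWELS if any(c in VOWELS for c in chunk) else VOWELS | {"y"}
    results = []

    def split(rest: str, acc: tuple) -> None:
        if not rest:
            if acc:
                results.append(acc)
            return
        # choose onset length, then nucleus length (1 or 2)
        for onset_len in range(len(rest)):
            if any(c in vowels for c in rest[:onset_len]):
                break  # onset may not contain a vowel letter
            for nuc_len in (1, 2):
                start, end = onset_len, onset_len + nuc_len
                if end > len(rest):
                    continue
                if not all(c in vowels for c in rest[start:end]):
                    continue
                remainder = rest[end:]
                if remainder and not any(c in vowels for c in remainder):
                    # tail of consonants: legal only as coda of a final syllable
                    if is_final:
                        results.append(acc + ((rest[:start], rest[start:end], remainder),))
                    continue
                split(remainder, acc + ((rest[:start], rest[start:end], ""),))

    split(chunk, ())
    return tuple(results)


def oracle_syllabify(normalized: str):
    """Best parse per rules: maximal nuclei left-to-right, onset maximization."""
    chunks = [c for c in normalized.replace("-", " ").split() if c]
    out = []
    for i, chunk in enumerate(chunks):
        parses = _parses(chunk, is_final=(i == len(chunks) - 1))
        if not parses:
            return None
        best = max(parses, key=lambda p: tuple(len(s[1]) for s in p))
        out.extend(best)
    return out


def oracle_code(text: str, variant: str, lexicon: frozenset[str] = frozenset()):
    """Full rule pipeline, independently implemented; returns the slot tuple
    (c1, v1, c2, v2, na_reason, relabeled) on lower-case separator-normalized
    input (this oracle does not re-implement Unicode folding)."""
    text = collapse_geminates(text)
    if not text.strip(" -"):
        return (None, None, None, None, "empty", False)
    if text in lexicon or any(t in lexicon for t in text.split(" ")):
        return (None, None, None, None, "real_word", False)
    syllables = oracle_syllabify(text)
    if syllables is None:
        return (None, None, None, None, "unparseable", False)
    relabeled = False
    if len(syllables) in (3, 4) and variant == "relabeled":
        syllables = syllables[-2:]
        relabeled = True
    if len(syllables) != 2:
        return (None, None, None, None, "wrong_syllable_count", False)
    labels = []
    for onset, nucleus, _coda in syllables:
        labels.append("".join("j" if c == "y" else c for c in onset) or "V")
        labels.append(nucleus)
    return (*labels, "none", relabeled)
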