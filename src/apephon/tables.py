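"""Published listener-study tallies used as fixture inputs.

The listening study collected N = 61 free transcriptions per chimpanzee
utterance (Johnny and Renata). Consonant-position counts are published as
raw integers and are entered here verbatim, except that the aggregate
"Other" cell is expanded into distinct low-frequency filler labels (one
cluster, one velar) so that records can be materialized; the rendered
"Other" bin total is unchanged.

Vowel-position counts were published only as percentages at footnoted Ns;
the integer counts below are reconstructed from those percentages (they
reproduce every printed vowel percentage under both denominators), with the
unlisted remainder padded by filler labels at counts too small to disturb
the printed top-three. Reconstructed/padded portions are marked; they feed
unit tests and demos, not headline numbers.
"""

from __future__ import annotations

from apephon.agreement import PositionTally

N_LISTENERS = 61

#: Consonant counts, published verbatim ("Other" expanded into fillers).
JOHNNY_C1 = {"m": 32, "n": 3, "w": 1, "p": 1, "b": 1, "h": 5, "V": 11, "fn": 1, "g": 1}
JOHNNY_C1_NA = 5
JOHNNY_C2 = {"m": 48, "n": 4, "w": 2, "h": 1, "g": 1}
JOHNNY_C2_NA = 5
RENATA_C1 = {"m": 29, "n": 5, "f": 1, "fn": 1}
RENATA_C1_NA = 25
RENATA_C2 = {"m": 27, "n": 6, "d": 1, "r": 2}
RENATA_C2_NA = 25

#: Vowel counts, reconstructed from printed percentages (filler-padded tail).
JOHNNY_V1 = {"a": 34, "o": 11, "u": 8, "e": 2, "i": 1}
JOHNNY_V1_NA = 5
JOHNNY_V2 = {"a": 51, "o": 5}
JOHNNY_V2_NA = 5
RENATA_V1 = {"a": 25, "e": 5, "o": 3, "u": 2, "i": 2, "y": 2}
RENATA_V1_NA = 22
RENATA_V2 = {"o": 10, "a": 8, "au": 8, "u": 4, "e": 3, "i": 2, "y": 2, "ou": 2}
RENATA_V2_NA = 22

#: Renata under the relabeled scheme (modal/top-three counts reconstructed
#: from printed percentages; non-modal consonant tail is synthetic padding).
RENATA_C1_RELABELED = {"m": 45, "n": 5, "h": 3, "fn": 2}
RENATA_C1_RELABELED_NA = 6
RENATA_C2_RELABELED = {"m": 41, "n": 6, "r": 4, "d": 3, "g": 2}
RENATA_C2_RELABELED_NA = 5
RENATA_V1_RELABELED = {"a": 41, "e": 5, "o": 4, "u": 2, "i": 2, "y": 2}
RENATA_V1_RELABELED_NA = 5
RENATA_V2_RELABELED = {"au": 11, "u": 10, "o": 10, "a": 9, "e": 9, "i": 8}
RENATA_V2_RELABELED_NA = 4

#: Labels given their own row in the published consonant table; everything
#: else renders under "Other".
CONSONANT_REPORT_ROWS = ("m", "n", "w", "p", "b", "h", "f", "d", "r", "V")


def _tallies(spec: dict[str, tuple[dict[str, int], int]]) -> dict[str, PositionTally]:
    return {
        pos: PositionTally(position=pos, counts=counts, n_na=n_na, N=N_LISTENERS)
        for pos, (counts, n_na) in spec.items()
    }


def johnny_tallies() -> dict[str, PositionTally]:
    """Per-position tallies for Johnny's utterance (strict scheme)."""
    return _tallies({
        "C1": (JOHNNY_C1, JOHNNY_C1_NA),
        "V1": (JOHNNY_V1, JOHNNY_V1_NA),
        "C2": (JOHNNY_C2, JOHNNY_C2_NA),
        "V2": (JOHNNY_V2, JOHNNY_V2_NA),
    })


def renata_tallies() -> dict[str, PositionTally]:
    """Per-position tallies for Renata's utterance (strict scheme)."""
    return _tallies({
        "C1": (RENATA_C1, RENATA_C1_NA),
        "V1": (RENATA_V1, RENATA_V1_NA),
        "C2": (RENATA_C2, RENATA_C2_NA),
        "V2": (RENATA_V2, RENATA_V2_NA),
    })


def renata_relabeled_tallies() -> dict[str, PositionTally]:
    """Renata's tallies after relabeling 3-4-syllable responses."""
    return _tallies({
        "C1": (RENATA_C1_RELABELED, RENATA_C1_RELABELED_NA),
        "V1": (RENATA_V1_RELABELED, RENATA_V1_RELABELED_NA),
        "C2": (RENATA_C2_RELABELED, RENATA_C2_RELABELED_NA),
        "V2": (RENATA_V2_RELABELED, RENATA_V2_RELABELED_NA),
    })
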