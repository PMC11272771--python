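"""Percentage-agreement statistics over coded phoneme slots.

Agreement is raw modal share: the fraction of listeners assigning the most
common label at a position. Two denominators are reported — ``with_na``
divides by all N listeners, ``without_na`` by the codable listeners
N - n_na — and both are computed for the strict and relabeled coding
schemes. Vowel agreement is summarized by the three most transcribed
labels per vowel position (agreement over mid-central vowel quality is
diffuse across orthographies, so a single modal letter would understate
it). Consonant labels additionally roll up to place-of-articulation
classes (labial /m w p b/, alveolar /n d r t/, glottal /h/, ...).

No chance correction (kappa, alpha) is applied; percentages are raw by
design and chance-corrected coefficients are left as an extension point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from apephon.coding import CodedUtterance, VOWEL_INITIAL

POSITIONS = ("C1", "V1", "C2", "V2")
CONSONANT_POSITIONS = ("C1", "C2")
VOWEL_POSITIONS = ("V1", "V2")
DENOMINATORS = ("with_na", "without_na")

#: Fixed place table for single-phoneme consonant labels; anything else
#: (clusters, the vowel-initial marker, unknown letters) is "other".
PLACE_OF_ARTICULATION: Mapping[str, str] = {
    "m": "labial", "w": "labial", "p": "labial", "b": "labial",
    "f": "labiodental", "v": "labiodental",
    "n": "alveolar", "d": "alveolar", "r": "alveolar", "t": "alveolar",
    "s": "alveolar", "z": "alveolar", "l": "alveolar",
    "j": "palatal",
    "k": "velar", "g": "velar",
    "h": "glottal",
}


@dataclass(frozen=True)
class PositionTally:
    """Label counts plus the n/a count for one slot position across listeners.

    Conservation holds by construction: sum(counts) + n_na == N.
    """

    position: str
    counts: Mapping[str, int]
    n_na: int
    N: int

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}, got {self.position!r}")
        if self.n_na < 0 or any(c < 0 for c in self.counts.values()):
            raise ValueError("counts and n_na must be non-negative")
        if sum(self.counts.values()) + self.n_na != self.N:
            raise ValueError(
                f"conservation violated at {self.position}: "
                f"sum(counts)={sum(self.counts.values())} + n_na={self.n_na} != N={self.N}"
            )
        object.__setattr__(self, "counts", dict(self.counts))

    def modal_label(self) -> str:
        """Most frequent label; ties break lexicographically."""
        if not self.counts:
            raise ValueError(f"no codable responses at {self.position}")
        return min(self.counts, key=lambda lab: (-self.counts[lab], lab))


def tally(coded: Iterable[CodedUtterance], position: str) -> PositionTally:
    """Count every observed label at ``position`` across listeners.

    All records must concern the same utterance. A ``None`` slot counts as
    n/a regardless of the recorded reason. Raises on an empty input (no data
    is distinct from zero agreement).
    """
    records = list(coded)
    if not records:
        raise ValueError("tally of an empty coded set")
    utts = {r.utterance_id for r in records}
    if len(utts) > 1:
        raise ValueError(f"tally mixes utterances: {sorted(utts)}")
    counts: dict[str, int] = {}
    n_na = 0
    for r in records:
        label = r.slot(position)
        if label is None:
            n_na += 1
        else:
            counts[label] = counts.get(label, 0) + 1
    return PositionTally(position=position, counts=counts, n_na=n_na, N=len(records))


def percent(tally: PositionTally, label: str, denominator: str = "with_na") -> float:
    """Share of listeners using ``label``, as a percentage.

    ``with_na`` divides by all N listeners; ``without_na`` by the codable
    N - n_na. Full precision; round only at render time.
    """
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    count = tally.counts.get(label, 0)
    if denominator == "with_na":
        return 100.0 * count / tally.N
    codable = tally.N - tally.n_na
    if codable == 0:
        raise ZeroDivisionError(
            f"without_na percentage undefined: all {tally.N} responses are n/a"
        )
    return 100.0 * count / codable


def top_k_vowels(tally: PositionTally, k: int = 3) -> list[str]:
    """The k most transcribed vowel labels, descending count, lexicographic ties."""
    if tally.position not in VOWEL_POSITIONS:
        raise ValueError(f"top_k_vowels applies to vowel positions, got {tally.position}")
    ordered = sorted(tally.counts, key=lambda lab: (-tally.counts[lab], lab))
    return ordered[:k]


def place_of_articulation(label: str) -> str:
    """Place class for a consonant phoneme label; unknown labels map to 'other'."""
    return PLACE_OF_ARTICULATION.get(label, "other")


@dataclass(frozen=True)
class AgreementReport:
    """Per-position tallies for one utterance under both coding schemes.

    ``tallies[variant][position]`` is a :class:`PositionTally`; ``variant``
    is ``"strict"`` or ``"relabeled"``. The four reported scheme conditions
    are the cross of variant x denominator.
    """

    utterance_id: str
    tallies: Mapping[str, Mapping[str, PositionTally]]

    def tally(self, position: str, variant: str = "strict") -> PositionTally:
        return self.tallies[variant][position]

    def modal(self, position: str, variant: str = "strict") -> str:
        return self.tally(position, variant).modal_label()

    def modal_percent(
        self, position: str, variant: str = "strict", denominator: str = "with_na"
    ) -> float:
        t = self.tally(position, variant)
        return percent(t, t.modal_label(), denominator)

    def top_vowels(self, position: str, variant: str = "strict", k: int = 3) -> list[str]:
        return top_k_vowels(self.tally(position, variant), k)

    def place_tally(self, position: str, variant: str = "strict") -> dict[str, int]:
        """Roll consonant counts up to place-of-articulation classes."""
        if position not in CONSONANT_POSITIONS:
            raise ValueError(f"place tally applies to consonant positions, got {position}")
        out: dict[str, int] = {}
        for label, count in self.tally(position, variant).counts.items():
            place = "vowel_initial" if label == VOWEL_INITIAL else place_of_articulation(label)
            out[place] = out.get(place, 0) + count
        return out


def build_report(
    coded_by_variant: Mapping[str, Sequence[CodedUtterance]], utterance_id: str
) -> AgreementReport:
    """Assemble an :class:`AgreementReport` from coded records per scheme variant."""
    tallies = {
        variant: {pos: tally(records, pos) for pos in POSITIONS}
        for variant, records in coded_by_variant.items()
    }
    return AgreementReport(utterance_id=utterance_id, tallies=tallies)


def consonant_agreement_summary(report: AgreementReport, variant: str = "strict") -> float:
    """Mean modal-consonant agreement over C1 and C2, excluding n/a.

    The cross-species comparison statistic: arithmetic mean of the two
    consonant positions' modal percentages under the without-n/a denominator.
    """
    values = []
    for pos in CONSONANT_POSITIONS:
        t = report.tally(pos, variant)
        values.append(percent(t, t.modal_label(), "without_na"))
    return math.fsum(values) / len(values)


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero, matching hand-rounded printed tables."""
    factor = 10.0 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)
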