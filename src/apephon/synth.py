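"""Synthetic listener data and source-filter audio.

Two generators make the whole pipeline runnable without any recordings:

* :func:`simulate_transcriptions` draws multinomial slot labels per listener
  and renders them back to orthography (with separators, capitalization,
  occasional geminates, real-word substitutions, and noise-burst prefix
  syllables), emulating the free-transcription experiment;
* :func:`synthesize_utterance` builds /mama/-like audio from a pulse-train
  source and cascaded formant resonators, with a ``closure_completeness``
  dial that morphs the inter-vowel consonant from an abrupt full bilabial
  closure with low-level nasal murmur (/m/-like, value 1) to a gradual
  amplitude/formant glide (/w/-like, value 0).

:func:`fixture_from_tallies` deterministically materializes a listener set
from published per-position counts, so printed tables round-trip exactly
through tally().
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from apephon.acoustics import Waveform
from apephon.agreement import POSITIONS, PositionTally
from apephon.coding import (
    PHONEME_TO_GRAPHEME,
    VOWEL_INITIAL,
    CodedUtterance,
    RawTranscription,
)
from apephon import tables

DEFAULT_REAL_WORDS = ("my house", "mother", "hello")
DEFAULT_NOISE_SYLLABLES = ("ku", "ash", "ho")

#: Optional vowel-letter confusion preset reflecting the cross-linguistic
#: tendency to transcribe mid-central (schwa-like) quality with "a", "o",
#: "u" rather than "i"/"y". The factory probability vectors derived from
#: the published tallies already embody this tendency, so the simulator's
#: default confusion table is the identity.
SCHWA_CONFUSION = {
    "i": {"i": 0.4, "a": 0.25, "o": 0.2, "u": 0.15},
    "y": {"y": 0.4, "a": 0.25, "o": 0.2, "u": 0.15},
}

_LANGUAGES = (
    ("English", 0.33), ("Swedish", 0.23), ("Dutch", 0.10), ("Spanish", 0.10),
    ("Italian", 0.05), ("German", 0.05), ("French", 0.04), ("Portuguese", 0.03),
    ("Russian", 0.03), ("Hungarian", 0.02), ("Gujarati", 0.01), ("Arabic", 0.01),
)
_EXPERIENCE = (("none", 0.508), ("some", 0.361), ("extensive", 0.131))


# ---------------------------------------------------------------------------
# Listener-response simulation


@dataclass(frozen=True)
class TranscriptionSimSpec:
    """Generative settings for one utterance's listener pool.

    ``slot_probs`` holds, per position, label probabilities conditional on a
    codable response. ``na_rate`` is the probability of a real-word
    substitution; ``extra_syllable_rate`` the probability of a 1-2-syllable
    noise prefix (which makes the response 3-4 syllables, n/a under the
    strict scheme). Rendering quirks (separators, capitals, geminates) are
    coding-equivalent noise.
    """

    n_listeners: int = tables.N_LISTENERS
    slot_probs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    na_rate: float = 0.0
    extra_syllable_rate: float = 0.0
    vowel_confusion: Mapping[str, Mapping[str, float]] | None = None
    real_words: tuple[str, ...] = DEFAULT_REAL_WORDS
    noise_syllables: tuple[str, ...] = DEFAULT_NOISE_SYLLABLES
    separator_prob: float = 0.5
    capitalize_prob: float = 0.2
    geminate_prob: float = 0.1
    utterance_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_listeners <= 0:
            raise ValueError("n_listeners must be positive")
        for rate_name in ("na_rate", "extra_syllable_rate", "separator_prob",
                          "capitalize_prob", "geminate_prob"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{rate_name} must be in [0, 1], got {rate}")
        if set(self.slot_probs) != set(POSITIONS):
            raise ValueError(f"slot_probs must cover positions {POSITIONS}")
        for pos, probs in self.slot_probs.items():
            total = math.fsum(probs.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
                raise ValueError(f"probabilities at {pos} must be non-negative and sum to 1")


def _render_label(label: str, is_vowel: bool) -> str:
    if is_vowel:
        return label
    if label == VOWEL_INITIAL:
        return ""
    return "".join(PHONEME_TO_GRAPHEME.get(c, c) for c in label)


def _sample(rng: np.random.Generator, items: Sequence[str], probs: Sequence[float]) -> str:
    return items[int(rng.choice(len(items), p=np.asarray(probs) / math.fsum(probs)))]


def simulate_transcriptions(spec: TranscriptionSimSpec) -> list[RawTranscription]:
    """Draw one free-text response per simulated listener. Seed-reproducible."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_listeners):
        listener_id = f"L{i + 1:03d}"
        language = _sample(rng, *zip(*_LANGUAGES))
        experience = _sample(rng, *zip(*_EXPERIENCE))
        if rng.random() < spec.na_rate:
            text = spec.real_words[int(rng.integers(len(spec.real_words)))]
        else:
            labels = {}
            for pos in POSITIONS:
                probs = spec.slot_probs[pos]
                keys = sorted(probs)
                labels[pos] = _sample(rng, keys, [probs[k] for k in keys])
            if spec.vowel_confusion is not None:
                for pos in ("V1", "V2"):
                    conf = spec.vowel_confusion.get(labels[pos])
                    if conf:
                        keys = sorted(conf)
                        labels[pos] = _sample(rng, keys, [conf[k] for k in keys])
            syl1 = _render_label(labels["C1"], False) + _render_label(labels["V1"], True)
            syl2 = _render_label(labels["C2"], False) + _render_label(labels["V2"], True)
            if rng.random() < spec.geminate_prob and syl2 and syl2[0] not in "aeiou":
                syl2 = syl2[0] + syl2  # "mamma"-style spelling, coding-equivalent
            sep = "-" if rng.random() < spec.separator_prob else ""
            text = syl1 + sep + syl2
            if rng.random() < spec.extra_syllable_rate:
                n_extra = int(rng.integers(1, 3))
                prefix = [spec.noise_syllables[int(rng.integers(len(spec.noise_syllables)))]
                          for _ in range(n_extra)]
                text = "-".join(prefix + [text])
            if rng.random() < spec.capitalize_prob:
                text = text.capitalize()
        out.append(RawTranscription(listener_id=listener_id, utterance_id=spec.utterance_id,
                                    text=text, native_language=language, experience=experience))
    return out


def _conditional_probs(tally: PositionTally) -> dict[str, float]:
    codable = tally.N - tally.n_na
    return {label: count / codable for label, count in tally.counts.items()}


def johnny_like_spec(seed: int = 0, n_listeners: int = tables.N_LISTENERS) -> TranscriptionSimSpec:
    """Simulation matched to the published tallies for Johnny's utterance.

    Codable-response label probabilities are the published conditional
    frequencies; the n/a mass (5/61) is attributed to the noise-prefix
    process.
    """
    t = tables.johnny_tallies()
    return TranscriptionSimSpec(
        n_listeners=n_listeners,
        slot_probs={pos: _conditional_probs(t[pos]) for pos in POSITIONS},
        extra_syllable_rate=tables.JOHNNY_C1_NA / tables.N_LISTENERS,
        utterance_id="johnny",
        seed=seed,
    )


def renata_like_spec(seed: int = 0, n_listeners: int = tables.N_LISTENERS) -> TranscriptionSimSpec:
    """Simulation matched to the published tallies for Renata's utterance
    (n/a mass 25/61 from 3-4-syllable responses, per the study)."""
    t = tables.renata_tallies()
    return TranscriptionSimSpec(
        n_listeners=n_listeners,
        slot_probs={pos: _conditional_probs(t[pos]) for pos in POSITIONS},
        extra_syllable_rate=tables.RENATA_C1_NA / tables.N_LISTENERS,
        utterance_id="renata",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Exact fixtures from published counts


def fixture_from_tallies(
    tallies: Mapping[str, PositionTally], utterance_id: str = "fixture"
) -> list[CodedUtterance]:
    """Materialize a deterministic listener set reproducing given tallies.

    Per position, labels are laid out in descending-count (lexicographic on
    ties) order followed by the n/a block, and dealt to listeners in index
    order; re-running tally() on the result is the identity on counts.
    Positions may have different n/a counts (slot-level n/a, reason "none").
    """
    missing = set(POSITIONS) - set(tallies)
    if missing:
        raise ValueError(f"tallies missing positions: {sorted(missing)}")
    ns = {pos: tallies[pos].N for pos in POSITIONS}
    if len(set(ns.values())) != 1:
        raise ValueError(f"inconsistent N across positions: {ns}")
    n = next(iter(ns.values()))

    per_position: dict[str, list[str | None]] = {}
    for pos in POSITIONS:
        t = tallies[pos]
        expanded: list[str | None] = []
        for label in sorted(t.counts, key=lambda lab: (-t.counts[lab], lab)):
            expanded.extend([label] * t.counts[label])
        expanded.extend([None] * t.n_na)
        per_position[pos] = expanded

    return [
        CodedUtterance(
            listener_id=f"L{i + 1:03d}",
            utterance_id=utterance_id,
            c1=per_position["C1"][i],
            v1=per_position["V1"][i],
            c2=per_position["C2"][i],
            v2=per_position["V2"][i],
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Source-filter utterance synthesis


@dataclass(frozen=True)
class UtteranceSynthSpec:
    """Parameters for a /mama/-like disyllable at 44.1 kHz.

    The source is a glottal pulse train following a linear f0 contour with
    -6 dB/oct spectral tilt; the filter is a cascade of second-order formant
    resonators. Each syllable is a (closure, vowel) duration pair in
    seconds. ``closure_completeness`` in [0, 1] controls the consonant:
    1 = abrupt full closure, oral output cut to a nasal murmur with an
    instantaneous switch to nasal resonances; 0 = slow partial narrowing
    with a continuous oral-formant glide and no full dip.
    """

    f0: tuple[float, float] = (230.0, 190.0)
    formants: tuple[float, ...] = (800.0, 1900.0, 2600.0)
    bandwidths: tuple[float, ...] = (90.0, 120.0, 180.0)
    nasal_formants: tuple[float, ...] = (250.0, 1000.0, 2300.0)
    nasal_bandwidths: tuple[float, ...] = (150.0, 250.0, 300.0)
    syllables: tuple[tuple[float, float], ...] = ((0.10, 0.18), (0.10, 0.18))
    closure_completeness: float = 1.0
    murmur_level_db: float = -18.0
    rate: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.closure_completeness <= 1.0:
            raise ValueError("closure_completeness must lie in [0, 1]")
        if len(self.formants) != len(self.bandwidths):
            raise ValueError("formants and bandwidths must align")
        if any(f2 <= f1 for f1, f2 in zip(self.formants, self.formants[1:])):
            raise ValueError("formant targets must be strictly increasing")
        if any(d <= 0 for pair in self.syllables for d in pair):
            raise ValueError("segment durations must be positive")

    @property
    def duration(self) -> float:
        return float(sum(c + v for c, v in self.syllables))


def _pulse_train(f0_start: float, f0_end: float, n: int, rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Unit impulses at the instantaneous f0, with -6 dB/oct tilt and a
    faint noise floor so silence never goes exactly to zero energy."""
    f0 = np.linspace(f0_start, f0_end, n)
    phase = np.cumsum(f0) / rate
    pulses = np.zeros(n)
    pulses[np.nonzero(np.diff(np.floor(phase), prepend=0.0) > 0)[0]] = 1.0
    tilted = lfilter([1.0], [1.0, -0.97], pulses)  # one leaky integration
    return tilted + 1e-4 * rng.standard_normal(n)


def _resonator_cascade(x: np.ndarray, formants: Sequence[float],
                       bandwidths: Sequence[float], rate: float) -> np.ndarray:
    y = x
    for f, bw in zip(formants, bandwidths):
        r = math.exp(-math.pi * bw / rate)
        theta = 2 * math.pi * f / rate
        a = [1.0, -2 * r * math.cos(theta), r * r]
        pole = np.exp(1j * theta)
        gain = abs(np.polyval(a[::-1], pole ** -1))  # unit gain at resonance
        y = lfilter([gain], a, y)
    return y


def _raised_cosine_gate(n: int, spans: list[tuple[int, int, float, float]],
                        base: float) -> np.ndarray:
    """Piecewise-constant gain with raised-cosine transitions.

    Each span (start, end, level, ramp_samples) overrides ``base`` on
    [start, end), easing in/out over ramp_samples around the edges.
    """
    gate = np.full(n, base)
    for start, end, level, ramp in spans:
        ramp = max(2, int(ramp))
        lo, hi = max(0, start), min(n, end)
        gate[lo:hi] = level
        fade = 0.5 * (1 - np.cos(np.linspace(0, math.pi, ramp)))
        a, b = max(0, start - ramp), start
        if b > a:
            gate[a:b] = base + (level - base) * fade[-(b - a):]
        a, b = end, min(n, end + ramp)
        if b > a:
            gate[a:b] = level + (base - level) * fade[: b - a]
    return gate


def synthesize_utterance(spec: UtteranceSynthSpec) -> Waveform:
    """Render the disyllable described by ``spec``; bit-reproducible by seed.

    The excitation is filtered once through the oral (vowel) resonator
    cascade and once through the nasal cascade; time-varying gains mix the
    two paths. With full closure the oral path gates to zero within ~5 ms
    and the nasal murmur carries the closure; with incomplete closure the
    oral path only sags (to ~0.6 amplitude at completeness 0) over a ~60 ms
    glide and no murmur appears.
    """
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate
    n = int(round(spec.duration * rate))
    exc = _pulse_train(spec.f0[0], spec.f0[1], n, rate, rng)
    oral = _resonator_cascade(exc, spec.formants, spec.bandwidths, rate)
    nasal = _resonator_cascade(exc, spec.nasal_formants, spec.nasal_bandwidths, rate)

    c = spec.closure_completeness
    ramp_s = 0.060 - 0.055 * c  # 60 ms glide at c=0 -> 5 ms snap at c=1
    ramp = int(round(ramp_s * rate))
    oral_closure_gain = (1.0 - c) * 0.6
    murmur_gain = c * 10.0 ** (spec.murmur_level_db / 20.0)

    oral_spans, nasal_spans = [], []
    cursor = 0
    for closure_dur, vowel_dur in spec.syllables:
        c_n = int(round(closure_dur * rate))
        oral_spans.append((cursor, cursor + c_n, oral_closure_gain, ramp))
        nasal_spans.append((cursor, cursor + c_n, murmur_gain, ramp))
        cursor += c_n + int(round(vowel_dur * rate))

    g_oral = _raised_cosine_gate(n, oral_spans, base=1.0)
    g_nasal = _raised_cosine_gate(n, nasal_spans, base=0.0)
    out = g_oral * oral + g_nasal * nasal

    edge = int(round(0.01 * rate))  # avoid onset/offset clicks
    taper = 0.5 * (1 - np.cos(np.linspace(0, math.pi, edge)))
    out[:edge] *= taper
    out[-edge:] *= taper[::-1]
    peak = np.max(np.abs(out))
    if peak > 0:
        out = 0.9 * out / peak
    return Waveform(out, rate)


def synthesize_vowel(
    f0: float = 220.0,
    formants: Sequence[float] = (800.0, 1900.0),
    bandwidths: Sequence[float] = (80.0, 120.0),
    duration: float = 0.5,
    rate: int = 44100,
    seed: int = 0,
) -> Waveform:
    """Stationary vowel: pulse train through fixed formant resonators.

    The synthesis-analysis round-trip partner of
    :func:`apephon.acoustics.estimate_formants`.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    exc = _pulse_train(f0, f0, n, rate, rng)
    out = _resonator_cascade(exc, formants, bandwidths, rate)
    edge = int(round(0.01 * rate))
    taper = 0.5 * (1 - np.cos(np.linspace(0, math.pi, edge)))
    out[:edge] *= taper
    out[-edge:] *= taper[::-1]
    peak = np.max(np.abs(out))
    if peak > 0:
        out = 0.9 * out / peak
    return Waveform(out, rate)


def synthesize_foil(seed: int = 0, rate: int = 44100) -> Waveform:
    """Synthetic dysarthric-style disyllabic foil (pipeline placeholder).

    A stand-in distractor with jittered f0 and slowed, incomplete
    articulation; purely synthetic, modeling no particular speaker.
    """
    rng = np.random.default_rng(seed)
    f0_base = float(rng.uniform(110, 180))
    spec = UtteranceSynthSpec(
        f0=(f0_base * float(rng.uniform(0.95, 1.1)), f0_base * float(rng.uniform(0.85, 1.0))),
        formants=(float(rng.uniform(500, 750)), float(rng.uniform(1400, 1800)), 2500.0),
        bandwidths=(110.0, 160.0, 220.0),
        syllables=((0.16, 0.22), (0.16, 0.22)),
        closure_completeness=float(rng.uniform(0.1, 0.35)),
        rate=rate,
        seed=int(rng.integers(2**31)),
    )
    return synthesize_utterance(spec)
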