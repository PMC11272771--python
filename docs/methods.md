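# Methods

## Transcription coding

The coder turns one listener's free orthographic response into four phoneme
slots (C1, V1, C2, V2). The pipeline is deterministic and total: every
response either codes or becomes n/a with a recorded reason
(`real_word`, `wrong_syllable_count`, `empty`, `unparseable`).

Normalization applies NFKD compatibility decomposition and keeps base
letters only (the listener pool is multilingual, so accented Latin input is
folded rather than rejected), lower-cases, drops digits and punctuation
except hyphen/space (kept as syllable separators), and collapses doubled
consonant letters. Vowel pairs are never collapsed, because a two-vowel
nucleus is a diphthong, not a geminate. Digits and non-Latin characters are
treated as noise and stripped; a response left empty by stripping codes
n/a(empty). Normalization is idempotent (property-tested).

Syllabification splits on explicit separators first. Unseparated runs are
parsed with maximal vowel-letter nuclei (runs longer than two split
two-then-rest, left to right) and onset maximization: every consonant
between two nuclei joins the following onset, and only the final syllable
may carry a coda. There is no phonotactic filtering — `"mampa"` parses as
`ma.mpa` — which keeps tie cases deterministic and lets cluster responses
(`"fnaya"` → /fn/) survive intact. `"y"` is an onset consonant (coded as
the glide /j/) unless its chunk contains no other vowel candidate, in which
case it serves as the nucleus (`"my"`). An exhaustive brute-force parser
(independent enumeration of all segmentations with the same preference
rules) agrees with the scanner on every string up to length 6 over a
4-letter test alphabet.

Scheme variants: `strict` codes exactly-2-syllable responses and sends
everything else to n/a; `relabeled` additionally codes the final two
syllables of 3–4-syllable responses and flags them. One-syllable responses
are n/a under both variants: the stimuli being coded are disyllabic, and
the source rules define handling only for 2 and 3–4 syllables. Real-word
exclusion is an explicit lexicon supplied with the dataset (no automated
word detection — exclusions should be auditable), matched against the
normalized response and its space-separated tokens, under both variants.
n/a blanks all four slots per utterance; slot-level n/a (positions excluded
independently) exists for fixture data materialized from per-position
count tables, where the published consonant and vowel Ns differ.

## Agreement statistics

Counts are conserved by construction (`sum(counts) + n_na = N` is a
dataclass invariant). Percentages are computed at full precision and
rounded only at render time, half-up, default one decimal with
configurable precision (the published tables mix one- and two-decimal
cells). Modal-label ties break lexicographically; the one place this
matters against the published tables is a relabeled vowel position where
two labels tie at equal counts and the source printed the other order.
Vowel agreement is reported as the top-three labels per position because
transcription of mid-central (schwa-like) vowel quality scatters across
letters between orthographies; consonant letters map far more consistently
onto phonemes. The cross-species summary statistic is the arithmetic mean
of the two consonant positions' modal percentages excluding n/a. Raw
(chance-uncorrected) agreement is used throughout; kappa-style coefficients
are a deliberate non-feature, as the comparison literature reports raw
percentages.

The published relabeled-scheme "average n/a ≈ 8.45%" is not reproduced as a
target: the footnoted position Ns imply ≈8.2% and the averaging convention
behind 8.45 is not recoverable, so the pipeline reports per-position n/a
shares instead.

## Acoustic analysis

All analysis operates on mono float waveforms; 44.1 kHz is the reference
rate. Spectrograms use contiguous windowed frames (default 5 ms Hann,
half-window hop, 0–4 kHz display range) computed without padding so
per-frame Parseval holds exactly against the windowed time-domain energy.

Formant estimation: downsample to 10 kHz (polyphase), pre-emphasize
(coefficient 0.97), fit an all-pole model of order 2 + (analysis rate in
kHz) = 12, convert pole angles to frequencies and radii to bandwidths,
reject candidates below 90 Hz or with bandwidth above 400 Hz. The normal
equations are solved by trimmed covariance least squares: fit, then twice
drop rows whose residual exceeds 5× the median absolute residual and refit.
The dropped rows are the glottal-pulse instants; with them included (plain
autocorrelation or covariance LPC), pole estimates lock onto the strongest
harmonic under each formant whenever f0 is large relative to formant
bandwidth — at f0 220 Hz that bias reaches tens of Hz, which matters for
small vocal tracts phonating near 200 Hz. With trimming, a seeded
two-resonator grid (F1 300–900 Hz, F2 900–2500 Hz, f0 120/170/220 Hz) is
recovered with every point within 2.1% of target. Near-silent or aperiodic
frames return an `unreliable` flag and no formants. Track-level summaries
use the median over reliable voiced frames.

Voicing: frame-wise normalized autocorrelation (40 ms frames, 10 ms hop);
a frame is voiced when the peak in the 75–500 Hz lag range exceeds 0.35 and
RMS clears a silence floor of 1e-5; f0 is the refined peak lag (parabolic
interpolation). The search range is configurable since chimpanzee f0 is not
known a priori.

Closure abruptness: the Hilbert envelope is low-passed at 40 Hz and
normalized to unit peak; interior minima with prominence ≥ 0.12 mark
candidate closures, and each is scored by the peak absolute envelope slope
(units 1/s) within ±40 ms. The stop/glide threshold is 18.7 /s, the
log-midpoint of the bimodal scores the synthetic closure grid produces at
its extremes (7.3 at closure completeness 0 vs 47.8 at 1 under default
synthesis settings); it is a config value, not a claim about real
chimpanzee audio. A stationary vowel yields an empty profile rather than a
forced classification.

Masking: Gaussian noise is spectrally shaped by the square root of the
signal's Welch PSD and scaled so the realized broadband SNR equals the
request exactly; the octave-band masker-to-signal ratio is then flat across
bands by construction (verified within 6 dB across 250–4000 Hz on synthetic
vowels, the residual coming from Welch smoothing and finite noise draws).

## Synthetic data

The listener simulator's presets are matched to the published study
conditions: N = 61 listeners, per-position label probabilities equal to the
published conditional (codable-response) frequencies, and an
extra-syllable noise-prefix rate equal to the published n/a share (5/61 for
the Johnny preset, 25/61 for Renata, whose n/a responses were
3–4-syllable transcriptions). Prefix syllables come from a small fixed
inventory (`ku`, `ash`, `ho`) mirroring the reported response forms.
Rendering adds coding-equivalent spelling noise (separators with
probability 0.5, capitalization 0.2, geminate doubling 0.1) so the
normalizer is exercised; none of it changes the coded labels, which is what
makes generator-parameter recovery through the full
simulate → code → tally → percent pipeline exact up to binomial noise.
A vowel-letter confusion table is available (with a schwa-favoring preset
mapping `i`/`y` toward `a o u`) but defaults to identity: the preset
probability vectors already embody the schwa-transcription tendency, and
stacking a confusion process on top would double-count it.

Vowel-position count tables are reconstructed from published percentages at
the footnoted Ns (the source prints raw counts only for consonants); the
unlisted remainder is padded with filler labels at counts too small to
disturb the published top-three. These reconstructed tallies drive demos
and top-three unit tests only.

Audio synthesis is a source-filter model: impulse train at a linear f0
contour (default 230→190 Hz), one leaky integration for −6 dB/oct source
tilt (cancelled exactly by the analyzer's 0.97 pre-emphasis), a faint
−80 dB noise floor, and cascaded second-order resonators normalized to
unit gain at resonance (defaults 800/1900/2600 Hz — the first two being
the formant values estimated for one of Renata's recordings — with
90/120/180 Hz bandwidths). Closures mix an oral path and a nasal-murmur
path with raised-cosine gates: at closure completeness c, the oral gain
dips to 0.6·(1−c) over a transition of 60 − 55·c ms while nasal murmur
scales with c (−18 dB); c = 1 therefore gives a ~5 ms collapse to murmur
with an instantaneous switch to nasal resonances, c = 0 a slow partial sag
with no murmur, and the abruptness score is strictly increasing in c across
the grid {0, 0.25, 0.5, 0.75, 1}. The synthetic "foil" generator produces
slowed, jittered, incompletely articulated disyllables purely as pipeline
placeholders for dysarthric-speech distractor stimuli; it models no real
speaker population. What passing tests show is that the analysis stack
inverts this generative family; real chimpanzee recordings add noise
floors, nonstationary vocal-tract shapes, and room acoustics that the
generator deliberately omits, so field recordings should be checked via the
`unreliable`-frame flags and the spectrogram rather than trusted blindly to
the formant tracker.

## Numerical and interface choices

Percentage rounding is half-up (matching hand-rounded tables) rather than
banker's rounding. Tally/percent errors are explicit: empty tallies and
all-n/a without-n/a denominators raise instead of returning NaN. WAV I/O
accepts mono PCM16/float32 and rejects multi-channel files. Pipeline
outputs are byte-reproducible: every CSV carries a header comment with the
config hash and seed, and no timestamps are written. Problem sizes in the
test and acceptance runs (500 ms vowels, 5-point closure grids,
1000-listener simulations, exhaustive coding up to length 6 over 4
letters) were chosen as the smallest sizes at which the checked statistics
are stable against their stated tolerances.

## Known limitations

- The coder is orthography-based: it does not model listeners' native
  grapheme-phoneme conventions (e.g. `"j"` is always /j/, never French /ʒ/),
  and non-Latin scripts are stripped rather than transliterated.
- Formant estimation assumes an all-pole tract; true nasal murmurs have
  zeros, so formant values *during* closures (as opposed to vowel
  portions) are indicative only.
- The closure threshold is calibrated on this package's own synthesis and
  should be recalibrated before classifying other corpora.
- No vocal-tract-length or articulatory inversion is attempted; formant
  values are reported as measured, without anatomical interpretation.
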