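"""CSV and WAV round-tripping.

Transcription tables are UTF-8 CSV with a header row; raw response text is
preserved byte-for-byte (no NA inference, no stripping). Files written by
the pipeline carry leading ``#`` comment lines (config hash, seed) which all
readers here skip. Audio is mono WAV, PCM16 or float32.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from apephon.acoustics import Waveform
from apephon.coding import CodedUtterance, RawTranscription

TRANSCRIPTION_COLUMNS = ("listener_id", "utterance_id", "transcription",
                         "native_language", "experience")
CODED_COLUMNS = ("listener_id", "utterance_id", "C1", "V1", "C2", "V2",
                 "na_reason", "relabeled", "scheme")


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#",
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_transcriptions(path: str | Path) -> list[RawTranscription]:
    """Load listener responses; raw text preserved exactly as typed."""
    df = _read_csv(path, TRANSCRIPTION_COLUMNS)
    return [
        RawTranscription(
            listener_id=row.listener_id,
            utterance_id=row.utterance_id,
            text=row.transcription,
            native_language=row.native_language,
            experience=row.experience or "none",
        )
        for row in df.itertuples(index=False)
    ]


def write_transcriptions(path: str | Path, records: Iterable[RawTranscription],
                         header_comments: Sequence[str] = ()) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(TRANSCRIPTION_COLUMNS)
        for r in records:
            writer.writerow([r.listener_id, r.utterance_id, r.text,
                             r.native_language, r.experience])


def write_coded(path: str | Path, coded: Iterable[CodedUtterance], scheme_variant: str,
                header_comments: Sequence[str] = ()) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(CODED_COLUMNS)
        for r in coded:
            writer.writerow([
                r.listener_id, r.utterance_id,
                *("" if s is None else s for s in (r.c1, r.v1, r.c2, r.v2)),
                r.na_reason, str(r.relabeled).lower(), scheme_variant,
            ])


def read_coded(path: str | Path) -> list[tuple[CodedUtterance, str]]:
    """Load coded records; returns (record, scheme_variant) pairs."""
    df = _read_csv(path, CODED_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        rec = CodedUtterance(
            listener_id=row.listener_id,
            utterance_id=row.utterance_id,
            c1=row.C1 or None, v1=row.V1 or None, c2=row.C2 or None, v2=row.V2 or None,
            na_reason=row.na_reason or "none",
            relabeled=row.relabeled == "true",
        )
        out.append((rec, row.scheme))
    return out


def read_lexicon(path: str | Path) -> frozenset[str]:
    """Plain-text real-word list, one entry per line; blank lines and # comments skipped."""
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line)
    return frozenset(words)


def read_wav(path: str | Path) -> Waveform:
    """Mono PCM16 or float WAV; multi-channel input is rejected."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        samples = data.astype(np.float64) / max(abs(info.min), info.max)
    else:
        samples = data.astype(np.float64)
    return Waveform(samples, float(rate))


def write_wav(path: str | Path, waveform: Waveform, subtype: str = "pcm16") -> None:
    if subtype == "pcm16":
        clipped = np.clip(waveform.samples, -1.0, 1.0)
        data = (clipped * 32767.0).astype(np.int16)
    elif subtype == "float32":
        data = waveform.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported subtype {subtype!r} (pcm16 or float32)")
    wavfile.write(path, int(waveform.rate), data)
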