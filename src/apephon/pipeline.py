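"""End-to-end run configuration, table rendering and the pipeline driver.

``run_pipeline`` reads (or simulates) a transcription table, codes every
response under both schemes, and writes per-utterance agreement tables:

* ``<utt>_coded_<variant>.csv`` — slot codes per listener;
* ``<utt>_place_table.csv`` — consonant counts/percentages in the layout of
  the published place-of-articulation table;
* ``<utt>_summary_table.csv`` — modal consonant and top-three vowels with
  percentages for every scheme variant x denominator condition;
* ``<utt>_tidy.csv`` — long-format (position, label, count, percentage).

Every output starts with ``#`` comment lines carrying the config hash and
seed, so identical configs reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from apephon import io as aio
from apephon.agreement import (
    AgreementReport,
    CONSONANT_POSITIONS,
    DENOMINATORS,
    POSITIONS,
    VOWEL_POSITIONS,
    build_report,
    percent,
    round_half_up,
)
from apephon.coding import CodingScheme, RawTranscription, code_dataset
from apephon.synth import TranscriptionSimSpec, simulate_transcriptions
from apephon.tables import CONSONANT_REPORT_ROWS

logger = logging.getLogger("apephon")

SCHEME_VARIANTS = ("strict", "relabeled")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on; hashable to a stable digest."""

    transcriptions_path: str | None = None
    lexicon_path: str | None = None
    simulation: Mapping | None = None  # TranscriptionSimSpec fields, used when no input file
    out_dir: str = "out"
    precision: int = 1
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def header_comments(self) -> list[str]:
        return [f"apephon config_hash={self.config_hash()} seed={self.seed}"]


@dataclass(frozen=True)
class PipelineResult:
    reports: Mapping[str, AgreementReport]  # by utterance_id
    written: tuple[Path, ...]


def _fmt(value: float, precision: int) -> str:
    return f"{round_half_up(value, precision):.{precision}f}"


def render_place_table(report: AgreementReport, precision: int = 1,
                       variant: str = "strict") -> pd.DataFrame:
    """Consonant-position counts and with-n/a percentages, one row per
    phoneme class; labels outside the listed row set are binned as Other."""
    rows = []
    for label in (*CONSONANT_REPORT_ROWS, "Other", "N/a"):
        row: dict[str, object] = {"label": label if label != "V" else "V (vowel-initial)"}
        for pos in CONSONANT_POSITIONS:
            t = report.tally(pos, variant)
            if label == "N/a":
                count = t.n_na
            elif label == "Other":
                count = sum(c for lab, c in t.counts.items()
                            if lab not in CONSONANT_REPORT_ROWS)
            else:
                count = t.counts.get(label, 0)
            row[f"{pos}_count"] = f"{count}/{t.N}"
            row[f"{pos}_pct"] = _fmt(100.0 * count / t.N, precision)
        rows.append(row)
    return pd.DataFrame(rows)


def render_summary_table(report: AgreementReport, precision: int = 1) -> pd.DataFrame:
    """Modal consonant and top-three vowels per condition (variant x denominator)."""
    rows = []
    for variant in SCHEME_VARIANTS:
        if variant not in report.tallies:
            continue
        for denominator in DENOMINATORS:
            row: dict[str, object] = {"scheme": variant, "denominator": denominator}
            for pos in POSITIONS:
                t = report.tally(pos, variant)
                if pos in CONSONANT_POSITIONS:
                    modal = t.modal_label()
                    row[f"{pos}_phoneme"] = f"/{modal}/"
                    row[f"{pos}_pct"] = _fmt(percent(t, modal, denominator), precision)
                else:
                    top = report.top_vowels(pos, variant)
                    row[f"{pos}_phonemes"] = ", ".join(f"/{v}/" for v in top)
                    row[f"{pos}_pcts"] = ", ".join(
                        _fmt(percent(t, v, denominator), precision) for v in top
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def render_tidy(report: AgreementReport, precision: int = 4) -> pd.DataFrame:
    """Long-format table: one row per (variant, denominator, position, label)."""
    rows = []
    for variant, tallies in report.tallies.items():
        for pos in POSITIONS:
            t = tallies[pos]
            for denominator in DENOMINATORS:
                labels = sorted(t.counts, key=lambda lab: (-t.counts[lab], lab))
                for label in labels:
                    try:
                        pct = percent(t, label, denominator)
                    except ZeroDivisionError:
                        continue
                    rows.append({
                        "utterance_id": report.utterance_id, "scheme": variant,
                        "denominator": denominator, "position": pos, "label": label,
                        "count": t.counts[label], "n_na": t.n_na, "N": t.N,
                        "percent": round(pct, precision),
                    })
    return pd.DataFrame(rows)


def _write_df(path: Path, df: pd.DataFrame, comments: Sequence[str]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def load_inputs(config: RunConfig) -> tuple[list[RawTranscription], frozenset[str]]:
    """Resolve the transcription set (file or simulation) and lexicon."""
    if config.transcriptions_path:
        transcriptions = aio.read_transcriptions(config.transcriptions_path)
        logger.info("read %d transcriptions from %s",
                    len(transcriptions), config.transcriptions_path)
    elif config.simulation is not None:
        spec = TranscriptionSimSpec(**dict(config.simulation, seed=config.seed))
        transcriptions = simulate_transcriptions(spec)
        logger.info("simulated %d transcriptions (seed=%d)", len(transcriptions), config.seed)
    else:
        raise ValueError("config must provide transcriptions_path or simulation")
    lexicon = aio.read_lexicon(config.lexicon_path) if config.lexicon_path else frozenset()
    return transcriptions, lexicon


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Code -> tally -> report -> render, for every utterance in the input.

    Validates inputs and builds every report before any file is written, so
    a failing stage leaves no partial output. Deterministic given config.
    """
    transcriptions, lexicon = load_inputs(config)
    if not transcriptions:
        raise ValueError("no transcriptions to process")

    by_utt: dict[str, list[RawTranscription]] = {}
    for t in transcriptions:
        by_utt.setdefault(t.utterance_id, []).append(t)

    schemes = {v: CodingScheme(variant=v, real_word_lexicon=lexicon) for v in SCHEME_VARIANTS}
    coded = {
        utt: {v: code_dataset(records, schemes[v]) for v in SCHEME_VARIANTS}
        for utt, records in sorted(by_utt.items())
    }
    reports = {utt: build_report(per_variant, utt) for utt, per_variant in coded.items()}

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comments = config.header_comments()
    written: list[Path] = []
    for utt, report in reports.items():
        for variant in SCHEME_VARIANTS:
            p = out_dir / f"{utt}_coded_{variant}.csv"
            aio.write_coded(p, coded[utt][variant], variant, comments)
            written.append(p)
        for name, df in (
            ("place_table", render_place_table(report, config.precision)),
            ("summary_table", render_summary_table(report, config.precision)),
            ("tidy", render_tidy(report)),
        ):
            p = out_dir / f"{utt}_{name}.csv"
            _write_df(p, df, comments)
            written.append(p)
        logger.info("utterance %s: N=%d listeners, outputs in %s",
                    utt, report.tally("C1").N, out_dir)
    return PipelineResult(reports=reports, written=tuple(written))
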