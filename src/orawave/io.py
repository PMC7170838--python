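"""Waveform table I/O, the quality-index filter, and replicate averaging.

An Ocular Response Analyzer (ORA) measurement is a 400-sample applanation
signal plus a vendor quality index in [0, 10].  Measurements are taken in
triplicate per eye; only measurements with quality index strictly above 7.5
(the manufacturer's recommendation) are analysed, and surviving replicates
are averaged pointwise into one trace per eye.

The on-disk format is a plain CSV defined by this package (the vendor
export format is proprietary): one row per measurement with columns
``eye_id, replicate_id, quality_index, s000..s399``.  Eye-level covariates
travel in a second CSV keyed by ``eye_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError

logger = logging.getLogger("orawave")

#: Number of observation points in one ORA waveform.
TRACE_LEN = 400

#: Manufacturer-recommended quality-index cutoff (kept if strictly above).
QUALITY_THRESHOLD = 7.5


def _validate_trace(trace: np.ndarray, trace_len: int) -> np.ndarray:
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.shape[0] != trace_len:
        raise ValueError(
            f"trace must be a 1-D vector of length {trace_len}, got shape {trace.shape}"
        )
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    return trace


@dataclass(eq=False)
class WaveformRecord:
    """One ORA measurement: a trace plus eye/replicate identity and quality.

    ``replicate_id`` is 1-based for raw measurements; the value 0 marks a
    record produced by :func:`average_replicates`.
    """

    eye_id: str
    replicate_id: int
    quality_index: float
    trace: np.ndarray
    trace_len: int = TRACE_LEN

    def __post_init__(self) -> None:
        self.trace = _validate_trace(self.trace, self.trace_len)
        self.quality_index = float(self.quality_index)
        if not np.isfinite(self.quality_index):
            raise ValueError("quality_index must be finite")
        self.replicate_id = int(self.replicate_id)
        if self.replicate_id < 0:
            raise ValueError("replicate_id must be >= 0")


@dataclass(eq=False)
class EyeCovariates:
    """Per-eye clinical covariates and the PRAA response.

    Units: age in years, AL (axial length) in mm, SERE (spherical equivalent
    refractive error) in diopters, keratometry in mm, CH/CRF in mmHg, PRAA
    (peripapillary retinal arteries angle) in degrees.
    """

    eye_id: str
    age: float
    AL: float
    SERE: float
    keratometry: float
    CH: float
    CRF: float
    PRAA: Optional[float] = None

    def __post_init__(self) -> None:
        if self.AL <= 0:
            raise ValueError(f"AL must be positive, got {self.AL} for {self.eye_id}")
        if self.PRAA is not None and not (0.0 < self.PRAA < 360.0):
            raise ValueError(
                f"PRAA must lie in (0, 360) degrees, got {self.PRAA} for {self.eye_id}"
            )


COVARIATE_COLUMNS = ("age", "AL", "SERE", "keratometry", "CH", "CRF", "PRAA")


def _sample_columns(trace_len: int) -> list[str]:
    return [f"s{i:03d}" for i in range(trace_len)]


def write_waveform_table(records: Sequence[WaveformRecord], path) -> None:
    """Write measurements as one CSV row each (``eye_id, replicate_id,
    quality_index, s000..``).  Floats round-trip exactly through
    :func:`read_waveform_table`."""
    if not records:
        raise ValueError("no records to write")
    trace_len = records[0].trace_len
    rows = []
    for r in records:
        row = {"eye_id": r.eye_id, "replicate_id": r.replicate_id,
               "quality_index": r.quality_index}
        row.update(zip(_sample_columns(trace_len), r.trace))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_waveform_table(path, trace_len: int = TRACE_LEN) -> list[WaveformRecord]:
    """Read a waveform CSV, validating trace length and finiteness.

    Raises
    ------
    ParseError
        If the header does not declare exactly ``trace_len`` sample columns,
        or if any data row has missing/non-finite samples (the message cites
        the 1-based data row number).
    FileNotFoundError
        If ``path`` does not exist.
    """
    df = pd.read_csv(path)
    expected = ["eye_id", "replicate_id", "quality_index"] + _sample_columns(trace_len)
    if list(df.columns) != expected:
        raise ParseError(
            f"{path}: expected {len(expected)} columns "
            f"(eye_id, replicate_id, quality_index, s000..s{trace_len - 1:03d}), "
            f"got {len(df.columns)}"
        )
    samples = df[_sample_columns(trace_len)].to_numpy(dtype=float)
    qi = pd.to_numeric(df["quality_index"], errors="coerce").to_numpy(dtype=float)
    bad = ~(np.all(np.isfinite(samples), axis=1) & np.isfinite(qi))
    if np.any(bad):
        rows = ", ".join(str(i + 1) for i in np.flatnonzero(bad)[:10])
        raise ParseError(
            f"{path}: non-finite or missing values in data row(s) {rows} "
            f"(rows are 1-based, excluding the header)"
        )
    records = []
    for i in range(len(df)):
        records.append(
            WaveformRecord(
                eye_id=str(df["eye_id"].iloc[i]),
                replicate_id=int(df["replicate_id"].iloc[i]),
                quality_index=qi[i],
                trace=samples[i],
                trace_len=trace_len,
            )
        )
    return records


def write_covariates_table(covariates: Sequence[EyeCovariates], path) -> None:
    rows = [{"eye_id": c.eye_id, **{k: getattr(c, k) for k in COVARIATE_COLUMNS}}
            for c in covariates]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_covariates_table(path) -> list[EyeCovariates]:
    df = pd.read_csv(path)
    expected = ["eye_id", *COVARIATE_COLUMNS]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    out = []
    for _, row in df.iterrows():
        praa = row["PRAA"]
        out.append(EyeCovariates(
            eye_id=str(row["eye_id"]),
            age=float(row["age"]), AL=float(row["AL"]), SERE=float(row["SERE"]),
            keratometry=float(row["keratometry"]), CH=float(row["CH"]),
            CRF=float(row["CRF"]),
            PRAA=None if pd.isna(praa) else float(praa),
        ))
    return out


def filter_by_quality(
    records: Iterable[WaveformRecord], threshold: float = QUALITY_THRESHOLD
) -> list[WaveformRecord]:
    """Keep records with quality index *strictly greater* than ``threshold``.

    Order is preserved; the number of removed records is logged.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    records = list(records)
    kept = [r for r in records if r.quality_index > threshold]
    removed = len(records) - len(kept)
    if removed:
        logger.info("quality filter (> %.2f): removed %d of %d records",
                    threshold, removed, len(records))
    return kept


class AveragedCohort(NamedTuple):
    """Per-eye averaged records plus the eyes dropped for lack of replicates."""

    records: list[WaveformRecord]
    dropped: list[str]


def average_replicates(
    records: Sequence[WaveformRecord],
    expected_eyes: Optional[Sequence[str]] = None,
) -> AveragedCohort:
    """Average replicate traces pointwise into one record per eye.

    The averaged record carries ``replicate_id = 0`` and the mean quality
    index.  If ``expected_eyes`` is given, eyes with no surviving record are
    reported in ``dropped`` (and a warning is logged) — this happens when the
    quality filter removed all of an eye's measurements.
    """
    by_eye: dict[str, list[WaveformRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.eye_id not in by_eye:
            by_eye[r.eye_id] = []
            order.append(r.eye_id)
        by_eye[r.eye_id].append(r)

    averaged = []
    for eye in order:
        group = by_eye[eye]
        trace = np.mean([g.trace for g in group], axis=0)
        qi = float(np.mean([g.quality_index for g in group]))
        averaged.append(WaveformRecord(eye, 0, qi, trace, group[0].trace_len))

    dropped: list[str] = []
    if expected_eyes is not None:
        dropped = [e for e in expected_eyes if e not in by_eye]
        if dropped:
            logger.warning("eyes dropped (no surviving replicates): %s",
                           ", ".join(dropped))
    return AveragedCohort(averaged, dropped)
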