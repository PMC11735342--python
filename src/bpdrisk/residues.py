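"""Residue tables with left-censored (below-LOD) records.

A residue survey reports, per food sample and analyte, either a measured
concentration (ng/g) or only the fact that the measurement fell below the
limit of detection (LOD).  This module holds the tabular data model, CSV
I/O, Table-1-style descriptive summaries (detection frequency, mean/SD/
range over detected values) and between-analyte Spearman rank correlations.

Censored rows carry their own LOD: surveys typically report LOD *ranges*
per analyte because the detection limit varies by matrix and batch, so a
single shared LOD is only the special case where all records agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, NotFoundError, SchemaError, ValidationError

REQUIRED_COLUMNS = ("sample_id", "food_category", "analyte", "value", "detected", "lod")
OPTIONAL_COLUMNS = ("packaging", "source")

#: tokens in the ``value`` column that mark a non-detect row
_CENSORED_TOKENS = {"", "<lod", "nd", "n.d.", "na"}


@dataclass(frozen=True)
class ResidueRecord:
    """One (sample, analyte) measurement.

    ``value`` is the measured concentration in ng/g and is present exactly
    when ``detected`` is true; values between LOD and LOQ are allowed, so
    ``value >= lod`` is *not* required, only ``value > 0``.
    """

    sample_id: str
    food_category: str
    analyte: str
    lod: float
    detected: bool
    value: float | None = None
    packaging: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.lod <= 0 or not math.isfinite(self.lod):
            raise ValidationError(
                f"record {self.sample_id!r}/{self.analyte!r}: LOD must be positive, got {self.lod}"
            )
        if self.detected:
            if self.value is None or not math.isfinite(self.value) or self.value <= 0:
                raise ValidationError(
                    f"record {self.sample_id!r}/{self.analyte!r}: detected record needs a positive value"
                )
        elif self.value is not None and not (isinstance(self.value, float) and math.isnan(self.value)):
            raise ValidationError(
                f"record {self.sample_id!r}/{self.analyte!r}: non-detect record must not carry a value"
            )


@dataclass(frozen=True)
class AnalyteSummary:
    """Detection frequency and distribution profile for one analyte in one food.

    ``mean``/``sd``/``minimum``/``maximum`` are computed over *detected*
    values only (sample SD, n−1 denominator); they are ``None`` when no
    sample was above the LOD.  This detected-only convention is recorded in
    ``convention`` because surveys are not always explicit about whether
    non-detects are imputed into the reported means.
    """

    analyte: str
    food_category: str
    n: int
    n_detected: int
    mean: float | None
    sd: float | None
    minimum: float | None
    maximum: float | None
    lod_min: float
    lod_max: float
    convention: str = "detected-only"

    @property
    def df_percent(self) -> float:
        return 100.0 * self.n_detected / self.n


class ResidueDataset:
    """A validated residue table, one row per (sample, analyte)."""

    def __init__(self, records: Iterable[ResidueRecord]):
        self._records: list[ResidueRecord] = list(records)

    @property
    def records(self) -> list[ResidueRecord]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResidueDataset):
            return NotImplemented
        return self._records == other._records

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self._records],
                "food_category": [r.food_category for r in self._records],
                "analyte": [r.analyte for r in self._records],
                "value": [r.value if r.detected else np.nan for r in self._records],
                "detected": [r.detected for r in self._records],
                "lod": [r.lod for r in self._records],
                "packaging": [r.packaging for r in self._records],
                "source": [r.source for r in self._records],
            }
        )

    def subset(self, analyte: str | None = None, food_category: str | None = None) -> "ResidueDataset":
        recs = self._records
        if analyte is not None:
            recs = [r for r in recs if r.analyte == analyte]
        if food_category is not None:
            recs = [r for r in recs if r.food_category == food_category]
        return ResidueDataset(recs)

    @property
    def analytes(self) -> list[str]:
        return sorted({r.analyte for r in self._records})

    @property
    def food_categories(self) -> list[str]:
        return sorted({r.food_category for r in self._records})


def _parse_value(raw: object) -> tuple[float | None, bool]:
    """Return (value, detected) for a raw CSV cell."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None, False
    text = str(raw).strip()
    if text.lower() in _CENSORED_TOKENS:
        return None, False
    return float(text), True


def read_residue_table(path, *, strict: bool = True) -> ResidueDataset:
    """Read a residue CSV into a :class:`ResidueDataset`.

    Expected columns: ``sample_id, food_category, analyte, value, detected,
    lod`` (+ optional ``packaging, source``).  Non-detect rows may be marked
    either by ``detected`` being false, or by an empty / ``<LOD`` value cell
    (the ``detected`` column may then be omitted entirely).

    Raises
    ------
    SchemaError
        on missing required columns or an empty file.
    ValidationError
        on rows violating record invariants (e.g. non-positive LOD), naming
        the offending row.
    """
    try:
        frame = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected a residue CSV header") from exc

    have = set(frame.columns)
    needed = {"sample_id", "food_category", "analyte", "value", "lod"}
    missing = needed - have
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    has_detected = "detected" in have

    records = []
    for idx, row in frame.iterrows():
        value, detected_from_value = _parse_value(row["value"])
        if has_detected and not (isinstance(row["detected"], float) and math.isnan(row["detected"])):
            detected = _parse_bool(row["detected"])
            if strict and detected != detected_from_value and detected:
                raise ValidationError(f"{path} row {idx}: detected=true but no numeric value")
        else:
            detected = detected_from_value
        try:
            records.append(
                ResidueRecord(
                    sample_id=str(row["sample_id"]),
                    food_category=str(row["food_category"]),
                    analyte=str(row["analyte"]),
                    value=value if detected else None,
                    detected=detected,
                    lod=float(row["lod"]),
                    packaging=_opt_str(row.get("packaging")),
                    source=_opt_str(row.get("source")),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
    return ResidueDataset(records)


def _parse_bool(raw: object) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    text = str(raw).strip().lower()
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f"}:
        return False
    raise ValidationError(f"cannot interpret {raw!r} as boolean")


def _opt_str(raw: object) -> str | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    return text or None


def write_residue_table(dataset: ResidueDataset, path) -> None:
    """Write a dataset back to the CSV schema :func:`read_residue_table` reads."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False)


def summarize_analyte(dataset: ResidueDataset, analyte: str, food_category: str) -> AnalyteSummary:
    """Detection frequency and detected-value mean/SD/range for one cell.

    Raises :class:`NotFoundError` when the (analyte, food category) pair has
    no records at all.  With records but zero detects, the distribution
    fields are ``None`` and only the detection frequency is meaningful.
    """
    sub = dataset.subset(analyte=analyte, food_category=food_category)
    if len(sub) == 0:
        raise NotFoundError(f"no records for analyte={analyte!r}, food_category={food_category!r}")
    values = np.array([r.value for r in sub.records if r.detected], dtype=float)
    lods = np.array([r.lod for r in sub.records], dtype=float)
    n_det = values.size
    if n_det == 0:
        mean = sd = lo = hi = None
    else:
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if n_det > 1 else None
        lo = float(values.min())
        hi = float(values.max())
    return AnalyteSummary(
        analyte=analyte,
        food_category=food_category,
        n=len(sub),
        n_detected=int(n_det),
        mean=mean,
        sd=sd,
        minimum=lo,
        maximum=hi,
        lod_min=float(lods.min()),
        lod_max=float(lods.max()),
    )


def summary_table(dataset: ResidueDataset) -> pd.DataFrame:
    """Survey-style summary over every (food category × analyte) cell present."""
    rows = []
    for food in dataset.food_categories:
        for analyte in dataset.analytes:
            try:
                s = summarize_analyte(dataset, analyte, food)
            except NotFoundError:
                continue
            rows.append(
                {
                    "food_category": food,
                    "analyte": analyte,
                    "n": s.n,
                    "n_detected": s.n_detected,
                    "df_percent": s.df_percent,
                    "mean": s.mean,
                    "sd": s.sd,
                    "min": s.minimum,
                    "max": s.maximum,
                    "lod_min": s.lod_min,
                    "lod_max": s.lod_max,
                    "convention": s.convention,
                }
            )
    return pd.DataFrame(rows)


def rank_correlation(
    dataset: ResidueDataset, analyte_a: str, analyte_b: str
) -> tuple[float, float]:
    """Spearman rank correlation between two analytes, paired by sample.

    Only samples where *both* analytes were detected enter the correlation
    (non-detects have no measured magnitude to rank).  Ties get average
    ranks; the p-value uses the usual t approximation.

    Returns ``(rho, p_value)``; raises :class:`InsufficientDataError` with
    fewer than 3 complete pairs.
    """
    by_sample_a = {r.sample_id: r.value for r in dataset.records if r.analyte == analyte_a and r.detected}
    by_sample_b = {r.sample_id: r.value for r in dataset.records if r.analyte == analyte_b and r.detected}
    common = sorted(set(by_sample_a) & set(by_sample_b))
    if len(common) < 3:
        raise InsufficientDataError(
            f"need >=3 samples with both {analyte_a!r} and {analyte_b!r} detected, have {len(common)}"
        )
    xs = np.array([by_sample_a[s] for s in common])
    ys = np.array([by_sample_b[s] for s in common])
    res = stats.spearmanr(xs, ys)
    return float(res.statistic), float(res.pvalue)
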