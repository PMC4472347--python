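"""Quantification of QM-MSP copy-number measurements.

Quantitative multiplex methylation-specific PCR (QM-MSP) reports, for each
sample x gene well, the absolute number of methylated (M) and unmethylated
(U) template copies after a methylation-independent pre-amplification.
Percent methylation is 100*M/(M+U); wells whose total copy number does not
exceed a quality-control threshold (default 3000 copies) are rejected and
their percent methylation reported as missing.

Copy numbers are accepted as non-negative reals: qPCR standard-curve
interpolation yields fractional copies. The QC rule is applied per
sample x gene well, not summed over genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import UndefinedMeasurementError, ValidationError

QC_COPY_THRESHOLD = 3000.0

__all__ = [
    "QC_COPY_THRESHOLD",
    "WellMeasurement",
    "MethylationCall",
    "percent_methylation",
    "qc_filter",
    "quantify_plate",
    "read_plate",
]


@dataclass(frozen=True)
class WellMeasurement:
    """Raw methylated/unmethylated copy counts for one sample x gene well."""

    sample_id: str
    gene: str
    methylated_copies: float
    unmethylated_copies: float

    def __post_init__(self) -> None:
        if self.methylated_copies < 0 or self.unmethylated_copies < 0:
            raise ValidationError(
                f"negative copy number for ({self.sample_id}, {self.gene})"
            )


@dataclass(frozen=True)
class MethylationCall:
    """Percent methylation for one well, or missing if QC failed.

    ``percent`` is NaN exactly when ``qc_pass`` is False or the well is
    empty (M+U == 0).
    """

    sample_id: str
    gene: str
    percent: float
    qc_pass: bool
    total_copies: float


def percent_methylation(methylated: float, unmethylated: float) -> float:
    """Return 100*M/(M+U).

    Raises
    ------
    ValidationError
        If either count is negative.
    UndefinedMeasurementError
        If M+U == 0 (an empty well has no defined methylation fraction).
    """
    if methylated < 0 or unmethylated < 0:
        raise ValidationError("copy numbers must be non-negative")
    total = methylated + unmethylated
    if total == 0:
        raise UndefinedMeasurementError(
            "percent methylation undefined for M+U == 0"
        )
    return 100.0 * methylated / total

def qc_filter(
    methylated: float, unmethylated: float, threshold: float = QC_COPY_THRESHOLD
) -> bool:
    """True iff the well's total copy number strictly exceeds ``threshold``."""
    if methylated < 0 or unmethylated < 0:
        raise ValidationError("copy numbers must be non-negative")
    if threshold <= 0:
        raise ValidationError("QC threshold must be positive")
    return methylated + unmethylated > threshold


def quantify_plate(
    wells: Iterable[WellMeasurement], threshold: float = QC_COPY_THRESHOLD
) -> list[MethylationCall]:
    """Convert raw wells to methylation calls, applying QC per well.

    Percent methylation is computed only for wells passing QC; failing
    wells yield a call with NaN percent. Duplicate (sample, gene) pairs
    are rejected.
    """
    wells = list(wells)
    seen: set[tuple[str, str]] = set()
    for w in wells:
        key = (w.sample_id, w.gene)
        if key in seen:
            raise ValidationError(f"duplicate well for {key}")
        seen.add(key)

    calls = []
    for w in wells:
        total = w.methylated_copies + w.unmethylated_copies
        passed = qc_filter(w.methylated_copies, w.unmethylated_copies, threshold)
        pct = (
            percent_methylation(w.methylated_copies, w.unmethylated_copies)
            if passed
            else math.nan
        )
        calls.append(
            MethylationCall(
                sample_id=w.sample_id,
                gene=w.gene,
                percent=pct,
                qc_pass=passed,
                total_copies=total,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[MethylationCall]) -> pd.DataFrame:
    """Tabulate calls as a DataFrame (one row per well)."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "gene": [c.gene for c in calls],
            "percent": [c.percent for c in calls],
            "qc_pass": [c.qc_pass for c in calls],
            "total_copies": [c.total_copies for c in calls],
        }
    )


def read_plate(path) -> list[WellMeasurement]:
    """Read a plate export: CSV with columns sample_id, gene,
    methylated_copies, unmethylated_copies."""
    from .errors import ParseError

    df = pd.read_csv(path)
    required = {"sample_id", "gene", "methylated_copies", "unmethylated_copies"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"plate export missing columns: {sorted(missing)}", line=1)
    wells = []
    for idx, row in df.iterrows():
        try:
            wells.append(
                WellMeasurement(
                    sample_id=str(row["sample_id"]),
                    gene=str(row["gene"]),
                    methylated_copies=float(row["methylated_copies"]),
                    unmethylated_copies=float(row["unmethylated_copies"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(str(exc), line=int(idx) + 2) from exc
    return wells
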