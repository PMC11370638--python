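"""Data model and I/O for infection time series and qPCR calibration.

The central container is :class:`SeriesTable`, a validated long-format table
of abundance measurements (host cells, free virus particles, viral genome
copies) over a one-step infection time course, indexed by
``(treatment, replicate, analyte, time_h)``.  qPCR support covers standard
curve fitting (Cq vs log10 copies), amplification-efficiency computation,
absolute quantification of Cq values, and multiplicative harmonization of
plates through shared internal standards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ANALYTES = frozenset(
    {"host_cells", "virus_particles", "genome_copies_A", "genome_copies_B"}
)

#: canonical column order of the on-disk dialect
SERIES_COLUMNS = [
    "time_h",
    "treatment",
    "replicate",
    "analyte",
    "value",
    "temperature_c",
]


class SeriesValidationError(ValueError):
    """Raised when an ingested table violates the SeriesTable invariants."""


@dataclass(frozen=True)
class TimepointSample:
    """One abundance measurement at one timepoint.

    ``value`` is counts ml^-1 (flow cytometry) or copies ml^-1 (qPCR) and must
    be non-negative; ``time_h`` is hours post infection.
    """

    time_h: float
    treatment: str
    replicate: str
    analyte: str
    value: float
    temperature_c: float = float("nan")

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise SeriesValidationError(f"time_h must be >= 0, got {self.time_h}")
        if self.value < 0:
            raise SeriesValidationError(f"value must be >= 0, got {self.value}")
        if self.analyte not in ANALYTES:
            raise SeriesValidationError(
                f"unknown analyte {self.analyte!r}; expected one of {sorted(ANALYTES)}"
            )


@dataclass
class SeriesTable:
    """Long-format infection time-series table plus the experimental design.

    ``design`` maps each treatment label to a free-form description of the
    treatment (viruses present, inoculation delay, temperature); every
    treatment referenced by ``data`` must appear in it.
    """

    data: pd.DataFrame
    design: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _validate_series_frame(self.data)
        missing = set(self.data["treatment"]) - set(self.design)
        if self.design and missing:
            raise SeriesValidationError(
                f"treatments {sorted(missing)} missing from design"
            )
        if not self.design:
            self.design = {t: {} for t in sorted(set(self.data["treatment"]))}

    def __len__(self) -> int:
        return len(self.data)

    def series(
        self, treatment: str, replicate: str, analyte: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(times, values)`` sorted by time for one series."""
        d = self.data
        sel = d[
            (d["treatment"] == treatment)
            & (d["replicate"] == replicate)
            & (d["analyte"] == analyte)
        ].sort_values("time_h")
        return sel["time_h"].to_numpy(float), sel["value"].to_numpy(float)

    def replicates(self, treatment: str, analyte: str) -> list[str]:
        d = self.data
        sel = d[(d["treatment"] == treatment) & (d["analyte"] == analyte)]
        return sorted(sel["replicate"].unique())

    def groups(self) -> Iterable[tuple[str, str, str]]:
        """Iterate over distinct (treatment, replicate, analyte) series keys."""
        cols = self.data[["treatment", "replicate", "analyte"]].drop_duplicates()
        return [tuple(r) for r in cols.itertuples(index=False)]


def _validate_series_frame(df: pd.DataFrame) -> pd.DataFrame:
    required = {"time_h", "treatment", "replicate", "analyte", "value"}
    missing = required - set(df.columns)
    if missing:
        raise SeriesValidationError(f"missing required column(s): {sorted(missing)}")
    df = df.copy()
    if "temperature_c" not in df.columns:
        df["temperature_c"] = np.nan
    df["time_h"] = pd.to_numeric(df["time_h"])
    df["value"] = pd.to_numeric(df["value"])
    df["replicate"] = df["replicate"].astype(str)

    bad = df.index[df["value"] < 0]
    if len(bad):
        raise SeriesValidationError(
            f"negative value in row(s) {list(bad)}: "
            f"{df.loc[bad, 'value'].tolist()}"
        )
    bad = df.index[df["time_h"] < 0]
    if len(bad):
        raise SeriesValidationError(f"negative time_h in row(s) {list(bad)}")
    bad = df.index[~df["analyte"].isin(ANALYTES)]
    if len(bad):
        raise SeriesValidationError(
            f"unknown analyte in row(s) {list(bad)}: "
            f"{sorted(df.loc[bad, 'analyte'].unique())}"
        )
    key = ["treatment", "replicate", "analyte", "time_h"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        raise SeriesValidationError(
            f"duplicate (treatment, replicate, analyte, time_h) in rows {rows}"
        )
    return df.reset_index(drop=True)


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_series_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    design: Mapping[str, dict] | None = None,
) -> SeriesTable:
    """Read a CSV/TSV series table (delimiter chosen from the extension).

    ``schema`` optionally maps file column names to the canonical field names
    (``time_h``, ``treatment``, ``replicate``, ``analyte``, ``value``,
    ``temperature_c``).  Rows violating the invariants raise
    :class:`SeriesValidationError` naming the offending rows.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if schema:
        df = df.rename(columns=dict(schema))
    return SeriesTable(df, dict(design) if design else {})


def write_series_table(table: SeriesTable, path: str | Path) -> None:
    """Write in the canonical dialect; round-trips losslessly with the reader."""
    table.data[SERIES_COLUMNS].to_csv(path, sep=_sep_for(path), index=False)


# --------------------------------------------------------------------------
# qPCR standard curves and absolute quantification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrCalibration:
    """Fitted qPCR standard curve ``Cq = slope * log10(copies) + intercept``.

    ``efficiency`` is the fractional amplification efficiency
    ``E = 10**(-1/slope) - 1`` (1.0 means perfect doubling each cycle);
    ``plate_factors`` are multiplicative harmonization factors relative to the
    reference plate (factor 1.0).
    """

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    plate_factors: Mapping[str, float] = field(default_factory=dict)

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency

    def with_plate_factors(self, factors: Mapping[str, float]) -> "QpcrCalibration":
        for plate, f in factors.items():
            if not f > 0:
                raise ValueError(f"plate factor for {plate!r} must be > 0, got {f}")
        merged = {**self.plate_factors, **factors}
        return QpcrCalibration(
            self.slope, self.intercept, self.efficiency, self.r_squared, merged
        )


def amplification_efficiency(slope: float) -> float:
    """Fractional efficiency E = 10**(-1/slope) - 1 for a standard-curve slope."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    dilution_series: Sequence[tuple[float, float]] | pd.DataFrame,
) -> QpcrCalibration:
    """Least-squares standard curve from (log10 copies, Cq) pairs.

    Requires at least three distinct dilution levels.  Accepts a sequence of
    pairs or a DataFrame with ``log10_copies`` and ``cq`` columns; technical
    replicates at the same level are used as individual points.
    """
    if isinstance(dilution_series, pd.DataFrame):
        x = dilution_series["log10_copies"].to_numpy(float)
        y = dilution_series["cq"].to_numpy(float)
    else:
        arr = np.asarray(dilution_series, float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("dilution_series must be (log10_copies, cq) pairs")
        x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct dilution levels to fit a standard curve")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10(copies)")
    fit = stats.linregress(x, y)
    return QpcrCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=amplification_efficiency(float(fit.slope)),
        r_squared=float(fit.rvalue**2),
        plate_factors={},
    )


def average_cq(cqs: Sequence[float]) -> float:
    """Average technical replicates on the Cq scale (the measured quantity)."""
    a = np.asarray(cqs, float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite Cq among technical replicates")
    return float(a.mean())


def cq_to_copies(
    cq: float,
    calib: QpcrCalibration,
    plate: str | None = None,
    dilution_factor: float = 1.0,
) -> float:
    """Invert the standard curve: copies = 10**((cq - b)/a) x plate x dilution."""
    if not math.isfinite(cq):
        raise ValueError(f"non-finite Cq: {cq}")
    if plate is None:
        factor = 1.0
    else:
        try:
            factor = calib.plate_factors[plate]
        except KeyError:
            raise KeyError(
                f"unknown plate {plate!r}; known: {sorted(calib.plate_factors)}"
            ) from None
    copies = 10.0 ** ((cq - calib.intercept) / calib.slope)
    return copies * factor * dilution_factor


def copies_to_cq(copies: float, calib: QpcrCalibration) -> float:
    """Forward evaluation of the standard curve (used by the simulator)."""
    if not copies > 0:
        raise ValueError(f"copies must be > 0, got {copies}")
    return calib.slope * math.log10(copies) + calib.intercept


def plate_factor_from_internal_standards(
    ref_values: Sequence[float], new_values: Sequence[float]
) -> float:
    """Multiplicative plate factor: mean over shared standards of ref/new.

    The internal standards are experiment samples quantified on both the
    reference plate and plate k; applying the factor to plate k puts its
    copy numbers on the reference plate's scale.
    """
    ref = np.asarray(ref_values, float)
    new = np.asarray(new_values, float)
    if ref.size == 0 or ref.shape != new.shape:
        raise ValueError("need >= 1 shared internal standard on both plates")
    if np.any(new == 0):
        raise ValueError("internal standard with zero value on the new plate")
    return float(np.mean(ref / new))
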