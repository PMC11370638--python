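"""Min-max normalization against single-infection references.

qPCR genome-copy series from different primer pairs and experiments are not
directly comparable; each replicate series is therefore mapped onto the scale
of the matching single-virus infection treatment: 0 at the averaged replicate
minimum, 1 at the averaged replicate maximum of that reference.  Values are
deliberately not clipped, so suppression (< 1 at the reference maximum) and
overshoot (> 1) remain visible.  Yields from dual treatments are summarised
as a percentage of the single-treatment mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SeriesTable

__all__ = [
    "NormalizedSeries",
    "reference_extrema",
    "minmax_normalize",
    "normalize_table",
    "percent_of_single",
]


@dataclass
class NormalizedSeries:
    """A series mapped to the reference's min-max scale (dimensionless)."""

    source: tuple[str, str, str]  # (treatment, replicate, analyte)
    times: np.ndarray
    values: np.ndarray
    ref_min: float
    ref_max: float


def reference_extrema(
    reference_replicates: Sequence[Sequence[float]],
) -> tuple[float, float]:
    """Averaged extrema: mean of per-replicate minima and of per-replicate maxima."""
    if len(reference_replicates) == 0:
        raise ValueError("need >= 1 reference replicate")
    mins = [float(np.min(np.asarray(r, float))) for r in reference_replicates]
    maxs = [float(np.max(np.asarray(r, float))) for r in reference_replicates]
    ref_min, ref_max = float(np.mean(mins)), float(np.mean(maxs))
    if not ref_max > ref_min:
        raise ValueError(
            f"degenerate reference: averaged max ({ref_max}) <= min ({ref_min})"
        )
    return ref_min, ref_max


def minmax_normalize(
    values: Sequence[float],
    reference_replicates: Sequence[Sequence[float]],
    times: Sequence[float] | None = None,
    source: tuple[str, str, str] = ("", "", ""),
) -> NormalizedSeries:
    """Normalize one series to the averaged extrema of the reference replicates.

    ``x -> (x - ref_min) / (ref_max - ref_min)``; no clipping.
    """
    ref_min, ref_max = reference_extrema(reference_replicates)
    v = np.asarray(values, float)
    t = np.asarray(times, float) if times is not None else np.arange(v.size, dtype=float)
    return NormalizedSeries(
        source=source,
        times=t,
        values=(v - ref_min) / (ref_max - ref_min),
        ref_min=ref_min,
        ref_max=ref_max,
    )


def normalize_table(
    table: SeriesTable,
    analyte: str,
    reference_treatment: str,
    treatments: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Min-max normalize every replicate series of ``analyte`` in ``treatments``
    against the single-infection ``reference_treatment``.

    Returns a long-format frame with ``value_norm`` plus ``ref_min``/``ref_max``
    provenance columns.
    """
    ref_reps = table.replicates(reference_treatment, analyte)
    if not ref_reps:
        raise ValueError(
            f"reference treatment {reference_treatment!r} has no {analyte!r} series"
        )
    ref_series = [
        table.series(reference_treatment, r, analyte)[1] for r in ref_reps
    ]
    ref_min, ref_max = reference_extrema(ref_series)
    if treatments is None:
        treatments = sorted(
            {t for t, _, a in table.groups() if a == analyte}
        )
    rows = []
    for treatment in treatments:
        for rep in table.replicates(treatment, analyte):
            t, v = table.series(treatment, rep, analyte)
            norm = (v - ref_min) / (ref_max - ref_min)
            for ti, vi in zip(t, norm):
                rows.append(
                    {
                        "time_h": ti,
                        "treatment": treatment,
                        "replicate": rep,
                        "analyte": analyte,
                        "value_norm": vi,
                        "ref_treatment": reference_treatment,
                        "ref_min": ref_min,
                        "ref_max": ref_max,
                    }
                )
    return pd.DataFrame(rows)


def percent_of_single(
    metric_dual: Sequence[float], metric_single: Sequence[float]
) -> tuple[float, float]:
    """Express dual-treatment replicate metrics as % of the single-treatment mean.

    Each dual replicate is divided by ``mean(metric_single)`` and scaled by
    100; returns ``(mean, sd)`` across dual replicates (sample sd, ddof=1;
    sd 0 for a single replicate).
    """
    dual = np.asarray(metric_dual, float)
    single = np.asarray(metric_single, float)
    if dual.size == 0 or single.size == 0:
        raise ValueError("both replicate groups must be non-empty")
    denom = float(single.mean())
    if denom <= 0:
        raise ValueError("single-treatment mean must be > 0")
    pct = dual / denom * 100.0
    sd = float(pct.std(ddof=1)) if pct.size > 1 else 0.0
    return float(pct.mean()), sd
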