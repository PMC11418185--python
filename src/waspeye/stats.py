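"""Descriptive statistics for acceptance-angle collections.

Summaries follow boxplot conventions: median, linear-interpolation
quartiles, whiskers at 1.5 x IQR, and a notch-style 95% confidence
interval on the median, median +/- 1.57 * IQR / sqrt(n).  A bootstrap
percentile CI is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CellRecord", "AcuitySummary", "summarize_acceptance_angles"]

logger = logging.getLogger(__name__)

NOTCH_FACTOR = 1.57


@dataclass(frozen=True)
class CellRecord:
    """One cell's fitted acceptance angles and where it was recorded."""

    cell_id: str
    species: str
    eye_region: str  # 'frontal' or 'lateral'
    longitude: float
    latitude: float
    delta_rho_h: float
    delta_rho_v: float

    def __post_init__(self) -> None:
        if self.delta_rho_h <= 0 or self.delta_rho_v <= 0:
            raise ValueError("acceptance angles must be positive")


@dataclass
class AcuitySummary:
    """Boxplot-style summary of one group of acceptance angles (degrees)."""

    n: int
    median: float
    ci_low: float
    ci_high: float
    q1: float
    q3: float
    outliers: np.ndarray = field(default_factory=lambda: np.array([]))
    degenerate_ci: bool = False
    group: tuple = ()

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _summarize(values: np.ndarray, ci_method: str, n_boot: int,
               rng: np.random.Generator | None, group: tuple) -> AcuitySummary:
    values = np.asarray(values, dtype=float)
    n = values.size
    median = float(np.median(values))
    q1, q3 = (float(q) for q in np.quantile(values, [0.25, 0.75]))
    iqr = q3 - q1
    lo_w, hi_w = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = values[(values < lo_w) | (values > hi_w)]
    if ci_method == "notch":
        half = NOTCH_FACTOR * iqr / np.sqrt(n)
        ci = (median - half, median + half)
    elif ci_method == "bootstrap":
        rng = rng or np.random.default_rng(0)
        boots = np.median(
            rng.choice(values, size=(n_boot, n), replace=True), axis=1)
        ci = tuple(np.quantile(boots, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return AcuitySummary(n=n, median=median, ci_low=float(ci[0]),
                         ci_high=float(ci[1]), q1=q1, q3=q3,
                         outliers=np.sort(outliers),
                         degenerate_ci=(n == 1), group=group)


def summarize_acceptance_angles(records, group_keys=None, *,
                                value="delta_rho_v", ci_method="notch",
                                n_boot: int = 2000,
                                rng: np.random.Generator | None = None
                                ) -> list[AcuitySummary]:
    """Boxplot summaries of acceptance angles, optionally per group.

    ``records`` may be a sequence of :class:`CellRecord`, a DataFrame, or
    a bare array of angles.  ``group_keys`` names record fields/columns
    to group by (e.g. ``["species", "eye_region"]``); empty groups are
    omitted with a log entry.  With ``n = 1`` the notch CI degenerates to
    the single value and is flagged.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    elif len(records) and isinstance(records[0], CellRecord):
        df = pd.DataFrame([r.__dict__ for r in records])
    else:
        df = pd.DataFrame({value: np.asarray(records, dtype=float)})

    if df.empty:
        logger.warning("no records to summarize")
        return []
    if group_keys:
        out = []
        for key, g in df.groupby(list(group_keys), sort=True):
            key = key if isinstance(key, tuple) else (key,)
            if g.empty:
                logger.warning("empty group %s omitted", key)
                continue
            out.append(_summarize(g[value].to_numpy(), ci_method, n_boot,
                                  rng, key))
        return out
    return [_summarize(df[value].to_numpy(), ci_method, n_boot, rng, ())]
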