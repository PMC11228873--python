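"""Flight-wise correlations between temporal VI values and trait BLUEs.

For each VI and environment, the per-flight Pearson correlation (over
hybrids) between the hybrid-by-flight BLUP at that flight and the trait
BLUE is computed and summarized as mean +/- sd across flights.  The
ranking of VIs by mean correlation is what selects the secondary trait
(VARI's first FPCA score) for the multitrait prediction model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class TemporalCorrelation:
    """Per-flight correlations of one VI with one trait in one environment."""

    vi_name: str
    environment: str
    trait: str
    per_flight: dict = field(default_factory=dict)  # flight_dap -> Pearson r

    @property
    def mean(self) -> float:
        vals = list(self.per_flight.values())
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sd(self) -> float:
        vals = list(self.per_flight.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vi_name": self.vi_name,
                "environment": self.environment,
                "trait": self.trait,
                "flight_dap": list(self.per_flight),
                "r": list(self.per_flight.values()),
            }
        )


def temporal_correlation(
    blups: pd.DataFrame,
    blues: pd.DataFrame,
    vi_name: str,
    trait: str,
    environment: str,
) -> TemporalCorrelation:
    """Per-flight Pearson correlation between VI BLUPs and trait BLUEs.

    Flights where either side has zero variance are excluded from the
    mean/sd with a logged warning (their correlation is undefined).
    """
    b = blups.loc[
        (blups["vi_name"] == vi_name) & (blups["environment"] == environment)
    ]
    if b.empty:
        raise KeyError(f"no BLUPs for VI {vi_name!r} in {environment!r}")
    e = blues.loc[
        (blues["environment"] == environment) & (blues["trait"] == trait)
    ].set_index("hybrid")["blue"]
    common = sorted(set(b["hybrid"]) & set(e.index))
    if len(common) < 3:
        raise ValueError("need at least 3 hybrids common to BLUPs and BLUEs")
    e = e.loc[common].to_numpy(float)
    wide = b.pivot(index="hybrid", columns="flight_dap", values="blup").loc[common]
    result = TemporalCorrelation(vi_name=vi_name, environment=environment, trait=trait)
    for dap in wide.columns:
        x = wide[dap].to_numpy(float)
        if np.std(x) == 0 or np.std(e) == 0:
            logger.warning(
                "undefined correlation at flight %s for %s/%s (zero variance); excluded",
                dap, vi_name, environment,
            )
            continue
        r = float(np.corrcoef(x, e)[0, 1])
        result.per_flight[int(dap)] = r
    return result


def rank_vis(correlations) -> list:
    """Sort VI correlation summaries by mean r, descending.

    Ties are broken by VI name (lexicographic), so the ranking is
    deterministic.  The first element's VI is the natural secondary-trait
    choice for the multitrait model.
    """
    correlations = list(correlations)
    if not correlations:
        raise ValueError("no correlations supplied")
    return sorted(correlations, key=lambda c: (-c.mean, c.vi_name))


def correlation_summary(correlations) -> pd.DataFrame:
    """Tidy summary table: vi, environment, trait, mean r, sd over flights."""
    rows = [
        {
            "vi_name": c.vi_name,
            "environment": c.environment,
            "trait": c.trait,
            "mean_r": c.mean,
            "sd_r": c.sd,
            "n_flights": len(c.per_flight),
        }
        for c in correlations
    ]
    return pd.DataFrame(rows)
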