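"""SNP-recovery metrics, control-blank analytical thresholds, and
contamination screening.

Recovery is counted against the full capture panel (94,752 SNPs) at 1X,
5X and 10X depth thresholds.  The analytical threshold separating
authentic signal from background is the mean plus ten standard
deviations of the 1X SNP counts observed in clean control blanks,
presented rounded up to the nearest hundred.  A reference sample passes
at >= 1000 SNPs (1X); a skeletal sample fails at <= 300.  A blank that
exceeds its threshold is screened for contamination by running the
kinship comparison against every co-processed sample: a most-likely
relationship of self identifies the contaminating source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import kinship_compare
from .panel_io import SampleProfile

PANEL_SIZE = 94_752
REFERENCE_AT = 1000
SKELETAL_AT = 300


@dataclass(frozen=True)
class RecoveryMetrics:
    """Panel SNP counts at the 1X/5X/10X coverage thresholds."""

    n_1x: int
    n_5x: int
    n_10x: int
    panel_size: int = PANEL_SIZE

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (
            self.n_1x / self.panel_size,
            self.n_5x / self.panel_size,
            self.n_10x / self.panel_size,
        )


@dataclass(frozen=True)
class AnalyticalThreshold:
    """mean + 10 SD of clean-blank 1X SNP counts (raw and rounded)."""

    raw: float
    rounded: int
    n_blanks: int


def snp_recovery(depths, panel_size: int = PANEL_SIZE) -> RecoveryMetrics:
    """Count sites at >=1X, >=5X and >=10X from a site->depth mapping
    (or a :class:`SampleProfile`)."""
    if isinstance(depths, SampleProfile):
        d = depths.depth
    elif isinstance(depths, dict):
        d = np.fromiter(depths.values(), dtype=float, count=len(depths))
    else:
        d = np.asarray(depths, dtype=float)
    return RecoveryMetrics(
        int((d >= 1).sum()), int((d >= 5).sum()), int((d >= 10).sum()), panel_size
    )


def analytical_threshold(blank_counts) -> AnalyticalThreshold:
    """Analytical threshold from clean control-blank 1X SNP counts.

    Raw value is mean + 10 * sample SD (n-1 denominator); the rounded
    presentation value is the raw value rounded up to the nearest 100.
    Requires at least two blanks.
    """
    counts = np.asarray(list(blank_counts), dtype=float)
    if len(counts) < 2:
        raise ValueError("analytical threshold needs at least 2 clean blanks")
    raw = float(counts.mean() + 10.0 * counts.std(ddof=1))
    rounded = int(math.ceil(raw / 100.0) * 100) if raw > 0 else 0
    return AnalyticalThreshold(raw, rounded, len(counts))


def sample_status(
    metrics: RecoveryMetrics,
    sample_type: str,
    reference_at: int = REFERENCE_AT,
    skeletal_at: int = SKELETAL_AT,
) -> str:
    """Pass/fail by sample type.

    The boundary conventions differ deliberately: a reference sample
    passes at >= ``reference_at`` SNPs (1X), while a skeletal sample
    fails at <= ``skeletal_at``.
    """
    if sample_type == "reference":
        return "pass" if metrics.n_1x >= reference_at else "fail"
    if sample_type == "skeletal":
        return "pass" if metrics.n_1x > skeletal_at else "fail"
    raise ValueError(f"unknown sample_type {sample_type!r}")


def blank_contamination_screen(
    blank: SampleProfile,
    co_processed: dict[str, SampleProfile] | list[SampleProfile],
    frequencies,
    ld_table=None,
    population: str | None = None,
    threshold: int = SKELETAL_AT,
) -> pd.DataFrame:
    """Source contamination in a control blank by kinship self-comparison.

    A blank below its analytical threshold is clean and is not compared.
    Otherwise the blank is compared against each co-processed profile;
    rows with ``most_likely == "self"`` flag the contamination source.
    """
    if isinstance(co_processed, list):
        co_processed = {p.sample_id: p for p in co_processed}
    if blank.n_1x < threshold:
        return pd.DataFrame(
            {
                "blank": [blank.sample_id],
                "status": ["clean"],
                "n_1x": [blank.n_1x],
                "compared_to": [None],
                "most_likely": [None],
                "flagged": [False],
            }
        )
    rows = []
    for sid, prof in co_processed.items():
        res = kinship_compare(
            blank, prof, frequencies, ld_table=ld_table, population=population
        )
        rows.append(
            {
                "blank": blank.sample_id,
                "status": "contaminated",
                "n_1x": blank.n_1x,
                "compared_to": sid,
                "most_likely": res.most_likely,
                "flagged": res.most_likely == "self",
            }
        )
    return pd.DataFrame(rows)
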