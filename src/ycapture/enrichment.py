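"""Fold-enrichment between capture conditions and the condition-pair grid.

Fold-enrichment is the ratio of mean unique on-target read counts between
two conditions at matched (down-sampled) sequencing effort. The zero-
denominator convention follows the published table the computation mirrors:
when the baseline condition has a zero on-target mean, the fold value is
the numerator mean itself. Display values are rounded half-up to one
decimal using exact decimal arithmetic (binary-float division of printed
means can land a hair below the .x5 boundary).
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from .accounting import ReplicateSummary

logger = logging.getLogger(__name__)

PRE_CAPTURE = "pre-capture"
YCC = "YCC"
WGC = "WGC"
WGC_YCC = "WGC+YCC"

#: Ordered condition pairs of the standard comparison grid.
CONDITION_PAIRS: tuple[tuple[str, str], ...] = (
    (YCC, PRE_CAPTURE),
    (YCC, WGC),
    (YCC, WGC_YCC),
    (WGC, PRE_CAPTURE),
    (WGC_YCC, PRE_CAPTURE),
    (WGC_YCC, WGC),
)


def fold_enrichment(
    on_target_mean_1: float, on_target_mean_2: float, display: bool = False
) -> float:
    """Fold-enrichment of condition 1 over condition 2.

    Returns mean_1 / mean_2 when mean_2 > 0, else mean_1 (zero-denominator
    rule). With ``display=True`` the value is rounded half-up to one decimal
    in exact decimal arithmetic.
    """
    if on_target_mean_1 < 0 or on_target_mean_2 < 0:
        raise ValueError("on-target means must be non-negative")
    if display:
        m1 = Decimal(repr(on_target_mean_1))
        m2 = Decimal(repr(on_target_mean_2))
        val = m1 / m2 if m2 > 0 else m1
        return float(val.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return on_target_mean_1 / on_target_mean_2 if on_target_mean_2 > 0 else on_target_mean_1


def _mean_on_target(value) -> float:
    if value is None:
        return 0.0
    if isinstance(value, ReplicateSummary):
        return float(value.mean["on_target_unique"])
    return float(value)


def build_enrichment_table(
    summaries: Mapping[tuple[str, str], ReplicateSummary | float | None],
) -> pd.DataFrame:
    """Assemble the per-sample condition-pair fold-enrichment grid.

    ``summaries`` maps (sample, condition) to a ReplicateSummary or directly
    to a mean on-target count (``None`` stands for a missing/zero cell, as
    dashes do in a printed table). Emits one row per sample and standard
    condition pair; pairs whose conditions are absent for a sample are
    omitted with a warning.
    """
    samples = sorted({s for s, _ in summaries})
    rows = []
    for sample in samples:
        conditions = {c for s, c in summaries if s == sample}
        for c1, c2 in CONDITION_PAIRS:
            if c1 not in conditions or c2 not in conditions:
                logger.warning(
                    "sample %s: pair (%s, %s) omitted — condition missing", sample, c1, c2
                )
                continue
            m1 = _mean_on_target(summaries[(sample, c1)])
            m2 = _mean_on_target(summaries[(sample, c2)])
            rows.append(
                {
                    "sample": sample,
                    "condition_1": c1,
                    "condition_2": c2,
                    "on_target_mean_1": m1,
                    "on_target_mean_2": m2,
                    "fold_enrichment": fold_enrichment(m1, m2),
                    "fold_enrichment_display": fold_enrichment(m1, m2, display=True),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "condition_1",
            "condition_2",
            "on_target_mean_1",
            "on_target_mean_2",
            "fold_enrichment",
            "fold_enrichment_display",
        ],
    )
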