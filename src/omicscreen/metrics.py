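"""Selection outcomes and Monte-Carlo metrics.

Three metric families summarize a feature-selection method against ground
truth:

* power — per effect size, the proportion of the truly differential
  features (the four per correlated block sharing one effect size) that
  the method selects;
* Type I error — the proportion of the independent noise features
  selected; correlated-but-null features are never folded into this;
* correlated-non-null selection — per correlated block, the proportion of
  features that are correlated with differential ones but themselves null
  that the method selects (over-selection within blocks).

Estimates average per-replicate proportions; the Monte-Carlo standard
error uses replicate-to-replicate variation, which is robust to the
within-replicate correlation the generator plants by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (
    CATEGORY_CORRELATED,
    CATEGORY_DIFFERENTIAL,
    CATEGORY_NOISE,
    FeatureTruth,
)

__all__ = ["MetricsRecord", "classify_outcomes", "aggregate_metrics", "records_to_frame"]


@dataclass(frozen=True)
class MetricsRecord:
    """One (scenario, method, metric) Monte-Carlo estimate."""

    scenario: str
    method: str
    alpha: float | None
    metric: str  # "power", "type1" or "corr_select"
    delta_or_block: str  # effect size for power/corr_select, "" for type1
    estimate: float
    mc_se: float
    n_replicates: int


def classify_outcomes(
    selection: np.ndarray, truth: FeatureTruth
) -> dict[str, float]:
    """Per-replicate selection proportions by ground-truth category.

    Returns a dict with keys ``power:<delta>`` (one per distinct effect
    size), ``type1`` and ``corr_select:<delta>`` (one per correlated
    block, keyed by that block's effect size).
    """
    selection = np.asarray(selection, dtype=bool)
    if selection.shape[0] != truth.p:
        raise ValueError(
            f"selection has {selection.shape[0]} entries but truth covers "
            f"{truth.p} features"
        )
    out: dict[str, float] = {}
    diff = truth.category == CATEGORY_DIFFERENTIAL
    for delta in np.unique(truth.effect_size[diff]):
        mask = diff & (truth.effect_size == delta)
        out[f"power:{delta:g}"] = float(selection[mask].mean())
    noise = truth.category == CATEGORY_NOISE
    out["type1"] = float(selection[noise].mean()) if noise.any() else 0.0
    corr = truth.category == CATEGORY_CORRELATED
    for b in np.unique(truth.block_id[corr]):
        mask = corr & (truth.block_id == b)
        # key each block by the effect size its differential neighbours carry
        bdiff = diff & (truth.block_id == b)
        delta = truth.effect_size[bdiff][0] if bdiff.any() else 0.0
        out[f"corr_select:{delta:g}"] = float(selection[mask].mean())
    return out


def aggregate_metrics(
    replicate_outcomes: list[dict[str, float]],
    scenario: str,
    method: str,
    alpha: float | None = None,
) -> list[MetricsRecord]:
    """Aggregate per-replicate proportions into MetricsRecords."""
    if not replicate_outcomes:
        raise ValueError("need at least one replicate outcome")
    keys = replicate_outcomes[0].keys()
    records = []
    r = len(replicate_outcomes)
    for key in keys:
        vals = np.array([o[key] for o in replicate_outcomes], dtype=float)
        est = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(r)) if r > 1 else 0.0
        metric, _, tag = key.partition(":")
        records.append(
            MetricsRecord(
                scenario=scenario,
                method=method,
                alpha=alpha,
                metric=metric,
                delta_or_block=tag,
                estimate=est,
                mc_se=se,
                n_replicates=r,
            )
        )
    return records


def records_to_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    """Tidy DataFrame, one record per row."""
    return pd.DataFrame(
        [
            {
                "scenario": rec.scenario,
                "method": rec.method,
                # NaN / "none" sentinels keep column dtypes stable through
                # a CSV round trip (resume reads scenario files back)
                "alpha": np.nan if rec.alpha is None else rec.alpha,
                "metric": rec.metric,
                "delta_or_block": rec.delta_or_block or "none",
                "estimate": rec.estimate,
                "mc_se": rec.mc_se,
                "n_replicates": rec.n_replicates,
            }
            for rec in records
        ]
    )
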