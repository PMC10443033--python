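"""Reversion-assay statistics.

The phenotypic readout of targeted mutagenesis: the reversion frequency is
the number of colony-forming units on selective plates divided by total
CFUs, after scaling both counts to a common plated volume. Reversion proper
and stop-codon suppression are indistinguishable in this assay, so the
statistic is reported as the observed frequency without mechanistic
attribution. Groups of biological replicates are summarized by their
median (the field's convention for these skewed frequencies), with an
optional bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CfuRecord


@dataclass(frozen=True)
class ReversionResult:
    sample_id: str
    frequency: float
    group: tuple[str, ...] = ()


def reversion_frequency(record: CfuRecord, group: tuple[str, ...] = ()) -> ReversionResult:
    """Dilution-corrected reversion frequency for one sample."""
    total = record.corrected_total
    if total <= 0:
        raise ValueError(f"sample {record.sample_id!r}: zero corrected total CFU")
    return ReversionResult(
        sample_id=record.sample_id,
        frequency=record.corrected_selective / total,
        group=group,
    )


def summarize_groups(results: Iterable[ReversionResult],
                     control_group: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-group median/min/max/n, with fold change over a control group.

    The fold change compares each group's median frequency to the control
    group's median (typically the off-target guide).
    """
    rows = [
        {"group": "|".join(r.group) or r.sample_id, "frequency": r.frequency}
        for r in results
    ]
    if not rows:
        raise ValueError("no reversion results to summarize")
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("group")["frequency"]
        .agg(median="median", min="min", max="max", n="size")
        .reset_index()
        .sort_values("group", kind="mergesort")
        .reset_index(drop=True)
    )
    if control_group is not None:
        key = "|".join(control_group)
        control = summary.loc[summary["group"] == key, "median"]
        if control.empty:
            raise ValueError(f"control group {key!r} absent from results")
        denom = float(control.iloc[0])
        summary["fold_change"] = summary["median"] / denom if denom > 0 else np.nan
    return summary


def bootstrap_median_ci(frequencies: Sequence[float], n_boot: int = 2000,
                        alpha: float = 0.05,
                        rng: np.random.Generator | int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI on the median reversion frequency."""
    rng = np.random.default_rng(rng)
    freqs = np.asarray(frequencies, dtype=float)
    if not len(freqs):
        raise ValueError("empty frequency list")
    medians = np.median(
        rng.choice(freqs, size=(n_boot, len(freqs)), replace=True), axis=1
    )
    return (
        float(np.quantile(medians, alpha / 2)),
        float(np.quantile(medians, 1 - alpha / 2)),
    )
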