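"""Relative gene expression by the 2^-ddCT method.

Each sample's target-gene cycle threshold (CT) is normalized to a
housekeeping reference (dCT = CT_target - CT_reference); ddCT is the
sample dCT minus the mean control dCT, and the fold change is 2^-ddCT.
Group means and SEM are computed on the fold-change scale, matching the
convention of reporting mean fold change +/- SEM of the 2^-ddCT data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["ddct_fold_changes"]

_REQUIRED = ("sample", "group", "ct_target", "ct_reference")


def ddct_fold_changes(
    records: pd.DataFrame, control_group: str = "control"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample 2^-ddCT fold changes and per-group (mean, SEM) summary.

    Parameters
    ----------
    records
        Columns ``sample, group, ct_target, ct_reference``; one row per
        technical replicate is allowed — replicates of a sample are
        averaged on the CT scale first.  Rows with a missing reference CT
        are dropped with a warning.
    control_group
        Group label whose mean dCT is the calibrator baseline.

    Returns
    -------
    per_sample, summary
        ``per_sample`` has columns ``sample, group, dct, ddct,
        fold_change``; ``summary`` is indexed by group with
        ``n, fold_change_mean, fold_change_sem``.
    """
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = records.loc[:, list(_REQUIRED)].copy()
    bad = df["ct_reference"].isna() | df["ct_target"].isna()
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} record(s) with missing CT values"
        )
        df = df.loc[~bad]
    outside = ~df[["ct_target", "ct_reference"]].apply(
        lambda s: s.between(5, 40)
    ).all(axis=1)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} sample(s) have CT values outside 5-40"
        )
    # technical replicates: average on the CT scale per sample
    per = (
        df.groupby("sample", sort=False)
        .agg(
            group=("group", "first"),
            ct_target=("ct_target", "mean"),
            ct_reference=("ct_reference", "mean"),
        )
        .reset_index()
    )
    groups = per["group"].unique()
    if control_group not in groups:
        raise ValueError(f"no samples in control group {control_group!r}")
    if len(per) - (per["group"] == control_group).sum() < 1:
        raise ValueError("need at least one non-control sample")
    per["dct"] = per["ct_target"] - per["ct_reference"]
    baseline = per.loc[per["group"] == control_group, "dct"].mean()
    per["ddct"] = per["dct"] - baseline
    per["fold_change"] = 2.0 ** (-per["ddct"])
    summary = (
        per.groupby("group")["fold_change"]
        .agg(
            n="size",
            fold_change_mean="mean",
            fold_change_sem=lambda v: (
                v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
            ),
        )
    )
    return per.drop(columns=["ct_target", "ct_reference"]), summary
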