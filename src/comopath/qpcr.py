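"""Relative qPCR quantification by the 2^-ddCT method.

Per biological sample, technical-replicate crossing-threshold (CT) values
are averaged per gene; the target's mean CT is normalised against the
housekeeping genes (arithmetic mean of their replicate-mean CTs, i.e. the
geometric mean of the linear quantities), giving dCT. Calibrating against
the control group's mean dCT gives ddCT, and the fold change is
2^-ddCT: one cycle earlier than control corresponds to a doubling of
starting template. Group comparison uses an equal-variance two-sample
Student's t-test, performed on ddCT (log2 scale), where the noise model
is closest to Gaussian; folds themselves are log-normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QpcrPlate:
    """Long-format qPCR measurements.

    ``data`` columns: sample, group, gene, replicate, ct. CT values must
    be positive; every sample is expected to measure the housekeeping
    genes (enforced at quantification time, when they are named).
    """

    data: pd.DataFrame

    REQUIRED = ("sample", "group", "gene", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"plate missing columns: {missing}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("non-positive CT values")

    def mean_ct(self) -> pd.DataFrame:
        """Replicate-mean CT per (sample, gene), with group carried along."""
        return (
            self.data.groupby(["sample", "group", "gene"], sort=True)["ct"]
            .mean()
            .reset_index()
        )


@dataclass
class FoldChangeResult:
    """2^-ddCT quantification of one target gene.

    ``per_sample`` has one row per biological sample with columns sample,
    group, dct, ddct, fold. Group-level mean fold and s.e.m. are in
    ``mean_fold`` / ``sem_fold`` (dicts keyed by group name).
    """

    gene: str
    control_group: str
    per_sample: pd.DataFrame
    mean_fold: dict[str, float]
    sem_fold: dict[str, float]
    t_statistic: float
    p_value: float
    n_excluded_samples: int = 0

    def __post_init__(self) -> None:
        if (self.per_sample["fold"] <= 0).any():
            raise AssertionError("non-positive fold change")


def ddct_fold_changes(
    plate: QpcrPlate,
    target: str,
    housekeeping: Sequence[str],
    control_group: str = "control",
) -> FoldChangeResult:
    """Quantify ``target`` relative to housekeeping genes and the control group.

    Samples missing the target or any housekeeping measurement are
    excluded with a warning; an empty control group is an error. By
    construction the control group's mean ddCT is zero, so the geometric
    mean control fold is one (the arithmetic mean fold is ~1 up to noise
    convexity).
    """
    if not housekeeping:
        raise ValueError("at least one housekeeping gene required")
    means = plate.mean_ct()
    wide = means.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    needed = [target, *housekeeping]
    missing_cols = [g for g in needed if g not in wide.columns]
    if missing_cols:
        raise ValueError(f"genes never measured on plate: {missing_cols}")
    complete = wide[needed].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} sample(s) excluded: missing target or housekeeping CT",
            stacklevel=2,
        )
    wide = wide[complete]
    groups = wide.index.get_level_values("group")
    if control_group not in set(groups):
        raise ValueError(f"control group {control_group!r} empty after exclusions")

    normaliser = wide[list(housekeeping)].mean(axis=1)
    dct = wide[target] - normaliser
    calibrator = dct[groups == control_group].mean()
    ddct = dct - calibrator
    fold = np.power(2.0, -ddct)

    per_sample = pd.DataFrame(
        {
            "sample": wide.index.get_level_values("sample"),
            "group": groups,
            "dct": dct.to_numpy(),
            "ddct": ddct.to_numpy(),
            "fold": fold.to_numpy(),
        }
    ).reset_index(drop=True)
    mean_fold = per_sample.groupby("group")["fold"].mean().to_dict()
    sem_fold = {
        g: (stats.sem(v) if len(v) > 1 else 0.0)
        for g, v in per_sample.groupby("group")["fold"]
    }
    t, p = group_ttest(per_sample, control_group)
    return FoldChangeResult(
        gene=target,
        control_group=control_group,
        per_sample=per_sample,
        mean_fold=mean_fold,
        sem_fold=sem_fold,
        t_statistic=t,
        p_value=p,
        n_excluded_samples=n_excluded,
    )


def group_ttest(
    per_sample: pd.DataFrame,
    control_group: str,
    on: str = "ddct",
) -> tuple[float, float]:
    """Equal-variance two-sample t-test of treated vs control.

    Performed on ddCT by default (``on="fold"`` switches to the linear
    scale). Exactly two groups are required, each with at least two
    samples. Degenerate data with zero pooled variance yields p = 1 when
    the group means agree (no evidence of a difference).
    """
    groups = sorted(set(per_sample["group"]))
    if len(groups) != 2:
        raise ValueError(f"t-test needs exactly two groups, have {groups}")
    treated_name = next(g for g in groups if g != control_group)
    treated = per_sample.loc[per_sample["group"] == treated_name, on].to_numpy()
    control = per_sample.loc[per_sample["group"] == control_group, on].to_numpy()
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need >=2 samples per group for the t-test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance input handled below
        t, p = stats.ttest_ind(treated, control, equal_var=True)
    if not np.isfinite(p):  # zero variance in both groups
        equal_means = np.isclose(treated.mean(), control.mean())
        return 0.0 if equal_means else float("inf"), 1.0 if equal_means else 0.0
    return float(t), float(p)


def quantify_targets(
    plate: QpcrPlate,
    targets: Sequence[str],
    housekeeping: Sequence[str],
    control_group: str = "control",
) -> pd.DataFrame:
    """Run 2^-ddCT quantification for several targets; tidy summary table."""
    rows = []
    for target in targets:
        res = ddct_fold_changes(plate, target, housekeeping, control_group)
        treated = next(
            g for g in sorted(res.mean_fold) if g != control_group
        )
        rows.append(
            {
                "gene": target,
                "mean_fold": res.mean_fold[treated],
                "sem": res.sem_fold[treated],
                "t": res.t_statistic,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)
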