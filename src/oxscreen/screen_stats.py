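"""Per-siRNA viability statistics for an oxidative-stress protection screen.

A screen plates each test siRNA against a negative-control siRNA, reads a
viability proxy (resazurin-type reagent) over several timepoints, and asks how
strongly each siRNA shifted survival relative to the control.  The shift is
quantified as Cohen's d (standardized mean difference against the control
replicates, pooled-SD denominator) with a normal-approximation 95% CI, and then
classified into five conventional effect-size bins.  qPCR follow-up uses the
2^-ddCt relative-quantification fold change.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    InfiniteEffectError,
    InsufficientDataError,
    InvalidParameterError,
    MissingReferenceError,
)

#: Effect-size bins, ordered from strongest to no effect.
BINS = ("large", "medium", "small", "very_small", "none")

#: z quantile for the 95% confidence interval (normal approximation).
Z_95 = 1.96

PLATE_COLUMNS = ["condition", "sirna_id", "replicate", "timepoint_h", "reading"]


@dataclass(frozen=True)
class CtQuadruple:
    """The four cycle-threshold values entering a ddCt comparison.

    ``target`` is the transcript of interest, ``ref`` the endogenous reference
    transcript (e.g. cyclophilin A / PPIA); ``treated`` vs ``control`` are the
    two conditions being compared.  All values are qPCR cycles.
    """

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def ddct(self) -> float:
        return (self.ct_target_treated - self.ct_ref_treated) - (
            self.ct_target_control - self.ct_ref_control
        )


def survival_rate(readings: pd.DataFrame, reference_condition: str) -> pd.DataFrame:
    """Express mean readings as percent of the reference condition per timepoint.

    Parameters
    ----------
    readings : DataFrame with columns ``condition``, ``timepoint_h``, ``reading``.
    reference_condition : condition label whose mean defines 100%.

    Returns a DataFrame (condition, timepoint_h, survival_pct) where the
    reference maps to exactly 100.0 at every timepoint.
    """
    required = {"condition", "timepoint_h", "reading"}
    missing = required - set(readings.columns)
    if missing:
        raise InvalidParameterError(f"readings table missing columns: {sorted(missing)}")
    means = (
        readings.groupby(["condition", "timepoint_h"], sort=True)["reading"]
        .mean()
        .rename("mean_reading")
        .reset_index()
    )
    ref = means[means["condition"] == reference_condition].set_index("timepoint_h")[
        "mean_reading"
    ]
    timepoints = means["timepoint_h"].unique()
    absent = sorted(set(timepoints) - set(ref.index))
    if reference_condition not in set(means["condition"]) or absent:
        raise MissingReferenceError(
            f"reference condition {reference_condition!r} missing"
            + (f" at timepoints {absent}" if absent else "")
        )
    if (ref == 0).any():
        bad = sorted(ref.index[ref == 0])
        raise MissingReferenceError(
            f"reference condition {reference_condition!r} has zero mean reading at "
            f"timepoints {bad}"
        )
    out = means.copy()
    out["survival_pct"] = 100.0 * out["mean_reading"] / out["timepoint_h"].map(ref).to_numpy()
    return out[["condition", "timepoint_h", "survival_pct"]]


def _pooled_sd(test: np.ndarray, control: np.ndarray) -> float:
    n1, n2 = len(test), len(control)
    v1 = float(np.var(test, ddof=1))
    v2 = float(np.var(control, ddof=1))
    return math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))


def cohen_delta(test, control) -> tuple[float, float, float]:
    """Cohen's d of *test* vs *control* with a 95% normal-approximation CI.

    d = (mean(test) - mean(control)) / pooled SD, pooled SD Bessel-corrected:
    sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).  The CI is d +/- 1.96*SE with
    SE = sqrt((n1+n2)/(n1*n2) + d^2/(2(n1+n2))).

    Returns ``(delta, ci_low, ci_high)``.  Antisymmetric under swapping the
    samples.  Raises :class:`InsufficientDataError` below 2 replicates per arm
    and :class:`InfiniteEffectError` when the pooled SD is zero but the means
    differ.
    """
    test = np.asarray(test, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = len(test), len(control)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"need >=2 replicates per arm, got n_test={n1}, n_control={n2}"
        )
    if not (np.isfinite(test).all() and np.isfinite(control).all()):
        raise InvalidParameterError("non-finite readings")
    diff = float(np.mean(test) - np.mean(control))
    sd = _pooled_sd(test, control)
    if sd == 0.0:
        if diff != 0.0:
            raise InfiniteEffectError(
                "pooled SD is zero with unequal means; effect size diverges"
            )
        d = 0.0
    else:
        d = diff / sd
    se = math.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2)))
    return d, d - Z_95 * se, d + Z_95 * se


def classify_effect(delta: float) -> str:
    """Map a Cohen's d value to one of the five effect-size bins.

    Boundaries: large (0.8, inf); medium [0.5, 0.8]; small [0.2, 0.5);
    very_small [0.01, 0.2); none (-inf, 0.01).  The convention keeps the
    customary ">0.8" and "<0.01" edges literal and is a total, monotone step
    function of delta.  Negative values (siRNAs reducing survival) fall in
    "none": the screen selects protection, not harm.
    """
    if not math.isfinite(delta):
        raise InvalidParameterError(f"delta must be finite, got {delta}")
    if delta > 0.8:
        return "large"
    if delta >= 0.5:
        return "medium"
    if delta >= 0.2:
        return "small"
    if delta >= 0.01:
        return "very_small"
    return "none"


def effect_sizes(readings: pd.DataFrame, reference_condition: str) -> pd.DataFrame:
    """Per-siRNA, per-timepoint effect sizes against the reference condition.

    Each test condition's replicate readings at a timepoint are compared with
    the reference condition's replicates at the same timepoint.  Effects are
    computed per timepoint with no cross-timepoint pooling.

    Returns a DataFrame with columns sirna_id, timepoint_h, delta, ci_low,
    ci_high, n_test, n_control, bin.
    """
    if reference_condition not in set(readings["condition"]):
        raise MissingReferenceError(reference_condition)
    ref = readings[readings["condition"] == reference_condition]
    rows = []
    for (cond, tp), grp in readings.groupby(["condition", "timepoint_h"], sort=True):
        if cond == reference_condition:
            continue
        ctrl = ref.loc[ref["timepoint_h"] == tp, "reading"].to_numpy()
        if len(ctrl) == 0:
            raise MissingReferenceError(
                f"reference {reference_condition!r} absent at timepoint {tp}"
            )
        d, lo, hi = cohen_delta(grp["reading"].to_numpy(), ctrl)
        rows.append(
            {
                "sirna_id": cond,
                "timepoint_h": tp,
                "delta": d,
                "ci_low": lo,
                "ci_high": hi,
                "n_test": len(grp),
                "n_control": len(ctrl),
                "bin": classify_effect(d),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sirna_id",
            "timepoint_h",
            "delta",
            "ci_low",
            "ci_high",
            "n_test",
            "n_control",
            "bin",
        ],
    )


def summarize_screen(results: pd.DataFrame, timepoint: float) -> dict[str, int]:
    """Count siRNAs per effect-size bin at one timepoint.

    Counts always cover all five bins (zero-filled) and sum to the number of
    distinct siRNAs present at that timepoint.
    """
    at_tp = results[results["timepoint_h"] == timepoint]
    counts = at_tp.groupby("bin")["sirna_id"].nunique().to_dict()
    return {b: int(counts.get(b, 0)) for b in BINS}


def ddct_fold_change(ct: CtQuadruple) -> float:
    """Relative fold change 2^-ddCt of the target transcript.

    ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control, so
    log2 of the returned value is exactly -ddCt.
    """
    values = (
        ct.ct_target_treated,
        ct.ct_ref_treated,
        ct.ct_target_control,
        ct.ct_ref_control,
    )
    if not all(math.isfinite(v) and v > 0 for v in values):
        raise InvalidParameterError("Ct values must be finite and positive")
    return 2.0 ** (-ct.ddct())


def read_plate_csv(path) -> pd.DataFrame:
    """Read a plate reading CSV written by the synthetic generator or a lab export."""
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"plate CSV missing columns: {sorted(missing)}")
    if (df["reading"] < 0).any():
        raise InvalidParameterError("negative readings in plate CSV")
    return df


def write_effects_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bin_counts_json(counts: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
        fh.write("\n")
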