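"""ddCt relative quantitation of candidate species from duplicate-well qPCR.

Ct values from duplicate wells are collapsed to a per-(sample, species) mean,
expressed relative to a designated calibrator (positive-control) sample by
the ddCt method — fold change = 2^(-ddCt) — and compared between case and
control groups.  Censored wells (no amplification by cycle 40) are treated
as non-detection, not as Ct = 40, following standard qPCR practice.

The default implements calibrator-only ddCt (ddCt = Ct_sample - Ct_calibrator
per species); an optional reference (housekeeping) amplicon switches to the
classic two-stage form (dCt = Ct_target - Ct_reference per sample first).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import CohortMetadata

logger = logging.getLogger("stoolmark")

__all__ = [
    "read_ct_table",
    "write_ct_table",
    "collapse_duplicates",
    "delta_delta_ct",
    "compare_groups",
    "MAX_CYCLES",
]

MAX_CYCLES = 40.0
_CT_COLUMNS = ["sample_id", "species", "replicate", "ct"]


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct CSV with columns sample_id, species, replicate, ct[, censored]."""
    df = pd.read_csv(path, comment="#")
    missing = set(_CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if "censored" not in df.columns:
        df["censored"] = df["ct"] >= MAX_CYCLES
    df["censored"] = df["censored"].astype(bool)
    if (df["ct"] <= 0).any() or (df["ct"] > MAX_CYCLES).any():
        raise ValueError("ct values must lie in (0, 40]")
    dup = df.duplicated(subset=["sample_id", "species", "replicate"])
    if dup.any():
        raise ValueError("duplicate (sample, species, replicate) rows in Ct table")
    return df


def write_ct_table(ct: pd.DataFrame, path, seed: int | None = None) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# stoolmark v{__version__}" + (f" seed={seed}" if seed is not None else "") + "\n")
        ct.to_csv(fh, index=False)


def collapse_duplicates(ct: pd.DataFrame, max_spread: float = 1.0) -> pd.DataFrame:
    """Mean Ct over uncensored wells per (sample, species).

    Pairs whose uncensored wells span more than ``max_spread`` cycles are
    flagged ``discordant`` but retained; pairs with no uncensored well are
    flagged ``undetected`` and carry no mean (NaN).
    """
    rows = []
    for (sample, species), grp in ct.groupby(["sample_id", "species"], sort=False):
        good = grp.loc[~grp["censored"], "ct"]
        if good.empty:
            rows.append((sample, species, np.nan, 0, False, True))
            continue
        spread = float(good.max() - good.min())
        rows.append((sample, species, float(good.mean()), len(good), spread > max_spread, False))
    out = pd.DataFrame(
        rows, columns=["sample_id", "species", "mean_ct", "n_wells", "discordant", "undetected"]
    )
    n_disc = int(out["discordant"].sum())
    if n_disc:
        logger.warning("collapse_duplicates: %d discordant well pairs (spread > %.2f)", n_disc, max_spread)
    return out


def delta_delta_ct(
    mean_ct: pd.DataFrame,
    calibrator_id: str,
    reference_species: str | None = None,
) -> pd.DataFrame:
    """Fold changes relative to the calibrator sample, per species.

    Without a reference amplicon, ddCt = mean Ct(sample, species) minus
    mean Ct(calibrator, species).  With one, per-sample dCt = Ct(species) -
    Ct(reference) is formed first and ddCt = dCt(sample) - dCt(calibrator).
    Fold change = 2^(-ddCt); the calibrator's own fold change is 1 exactly.
    Undetected (all-censored) pairs propagate as NaN fold changes.
    """
    df = mean_ct.copy()
    if reference_species is not None:
        ref = df[df["species"] == reference_species].set_index("sample_id")["mean_ct"]
        missing = set(df["sample_id"]) - set(ref.index)
        if missing:
            raise ValueError(f"reference species {reference_species!r} missing for samples {sorted(missing)}")
        df = df[df["species"] != reference_species].copy()
        df["delta_ct"] = df["mean_ct"] - df["sample_id"].map(ref).to_numpy()
    else:
        df["delta_ct"] = df["mean_ct"]

    cal = df[df["sample_id"] == calibrator_id].set_index("species")["delta_ct"]
    missing = set(df["species"]) - set(cal.index)
    if missing:
        raise ValueError(f"calibrator {calibrator_id!r} missing for species {sorted(missing)}")
    if cal.isna().any():
        bad = sorted(cal.index[cal.isna()])
        raise ValueError(f"calibrator {calibrator_id!r} undetected for species {bad}")
    df["delta_delta_ct"] = df["delta_ct"] - df["species"].map(cal).to_numpy()
    df["fold_change"] = np.power(2.0, -df["delta_delta_ct"])
    return df[["sample_id", "species", "mean_ct", "delta_ct", "delta_delta_ct", "fold_change"]]


def compare_groups(
    folds: pd.DataFrame,
    meta: CohortMetadata,
    test: str = "mw",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Case-vs-control comparison of per-sample fold changes, per species.

    Default test is the two-sided Mann-Whitney U (fold changes are
    non-normal); ``test="t"`` selects Welch's t-test.  Group means are
    reported with SEM.  Species with fewer than 2 detected samples in either
    group are skipped with a warning.  Significance flag: P < ``alpha``.
    """
    if test not in ("mw", "t"):
        raise ValueError("test must be 'mw' or 't'")
    group = meta.group
    rows = []
    for species, grp in folds.groupby("species", sort=False):
        sub = grp.dropna(subset=["fold_change"])
        g = sub["sample_id"].map(group)
        ctrl = sub.loc[g == "control", "fold_change"].to_numpy()
        case = sub.loc[g == "case", "fold_change"].to_numpy()
        if len(ctrl) < 2 or len(case) < 2:
            warnings.warn(f"species {species!r}: fewer than 2 samples in a group; skipped")
            continue
        if test == "mw":
            p = float(stats.mannwhitneyu(ctrl, case, alternative="two-sided").pvalue)
        else:
            p = float(stats.ttest_ind(ctrl, case, equal_var=False).pvalue)
        rows.append(
            (
                species,
                float(ctrl.mean()), float(stats.sem(ctrl)) if len(ctrl) > 1 else np.nan,
                float(case.mean()), float(stats.sem(case)) if len(case) > 1 else np.nan,
                p, p < alpha,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "control_mean", "control_sem", "case_mean", "case_sem",
            "p_value", "significant",
        ],
    )
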