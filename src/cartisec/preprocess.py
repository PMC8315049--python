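"""Filtering, imputation, transformation and timepoint summation.

The chain, in the order the analysis applies it:

1. keep proteins observed in every animal (`filter_all_replicates`);
2. keep proteins quantified in at least 5% of samples
   (`filter_min_fraction`, ceiling rounding on the count of samples
   actually present in the design);
3. record the pre-imputation presence mask (`presence_mask`) — imputed
   values never count as "present";
4. replace missing intensities by half the protein's smallest observed
   abundance (`impute_half_min`), the standard proteomics treatment of
   intensities assumed missing because they fell below detection;
5. sum raw-scale abundances over the five sampling days per
   (protein, animal, treatment) cell and log2-transform
   (`sum_over_timepoints`), yielding the matrix on which contrasts are
   tested; the per-sample log2 table (`log2_transform`) is used for PCA.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .data_model import DAYS, AbundanceTable, ValidationError


def filter_all_replicates(table: AbundanceTable) -> AbundanceTable:
    """Keep proteins with at least one quantified record in every animal."""
    animals = table.animals
    obs = table.observed()
    per_protein = obs.groupby("protein")["animal"].nunique()
    keep = set(per_protein[per_protein == len(animals)].index)
    return AbundanceTable(table.df[table.df["protein"].isin(keep)])


def filter_min_fraction(
    table: AbundanceTable, min_frac: float = 0.05
) -> AbundanceTable:
    """Keep proteins quantified in at least ``min_frac`` of samples.

    The denominator is the number of samples present in the design
    (animals x treatments x days found in the table; 120 for the full
    design) and the threshold uses ceiling rounding, the conservative
    choice.
    """
    if not 0 < min_frac <= 1:
        raise ValidationError("min_frac must lie in (0, 1]")
    n_samples = (
        table.df["animal"].nunique()
        * table.df["treatment"].nunique()
        * table.df["day"].nunique()
    )
    threshold = math.ceil(min_frac * n_samples)
    counts = table.observed().groupby("protein").size()
    keep = set(counts[counts >= threshold].index)
    return AbundanceTable(table.df[table.df["protein"].isin(keep)])


def impute_half_min(table: AbundanceTable) -> AbundanceTable:
    """Replace each missing value by half the protein's minimum observed
    abundance (global across animals, treatments and days).

    Adds a per-row boolean ``imputed`` flag to the returned table's
    frame. Non-missing values are never altered.
    """
    df = table.df.copy()
    mins = df.groupby("protein")["abundance"].min()  # skips NaN
    if mins.isna().any():
        offenders = sorted(mins[mins.isna()].index)
        raise ValidationError(
            f"protein(s) with zero observations cannot be imputed: "
            f"{offenders[:5]}{'...' if len(offenders) > 5 else ''} "
            "(they should have been filtered)"
        )
    missing = df["abundance"].isna()
    fill = df["protein"].map(0.5 * mins)
    df.loc[missing, "abundance"] = fill[missing]
    out = AbundanceTable(df)
    out.df["imputed"] = missing.to_numpy()
    return out


def log2_transform(table: AbundanceTable) -> AbundanceTable:
    """Entrywise log2; requires a complete, positive table (post-imputation)."""
    df = table.df.copy()
    if df["abundance"].isna().any():
        raise ValidationError("log2 transform requires an imputed (complete) table")
    values = df["abundance"].to_numpy()
    if np.any(values <= 0):
        raise ValidationError("log2 transform requires strictly positive values")
    df["abundance"] = np.log2(values)
    flags = df.pop("imputed") if "imputed" in df.columns else None
    out = AbundanceTable(df, log2=True)
    if flags is not None:
        out.df["imputed"] = flags.to_numpy()
    return out


def presence_mask(table: AbundanceTable) -> pd.DataFrame:
    """Count non-missing timepoints per (protein, animal, treatment).

    Must be computed from the raw, pre-imputation table; downstream
    presence rules read this mask so imputed records never count.
    Returns a protein-indexed frame with (animal, treatment) columns and
    integer counts in 0..5.
    """
    counts = (
        table.observed()
        .groupby(["protein", "animal", "treatment"])
        .size()
        .unstack(["animal", "treatment"], fill_value=0)
    )
    full_cols = pd.MultiIndex.from_product(
        [table.animals, table.treatments], names=["animal", "treatment"]
    )
    counts = counts.reindex(columns=full_cols, fill_value=0)
    counts = counts.reindex(index=table.proteins, fill_value=0)
    return counts.astype(int)


def sum_over_timepoints(table: AbundanceTable) -> pd.DataFrame:
    """log2 of the raw-scale abundance summed over the five sampling days.

    Requires a complete (imputed) raw-scale table: every
    (protein, animal, treatment) cell must carry all sampled days.
    Returns a protein-indexed frame with (animal, treatment) columns.
    """
    df = table.df
    if df["abundance"].isna().any():
        raise ValidationError(
            "summed matrix requires a complete table; impute missing values first"
        )
    n_days = df["day"].nunique()
    cell_counts = df.groupby(["protein", "animal", "treatment"]).size()
    if (cell_counts != n_days).any():
        raise ValidationError(
            "every (protein, animal, treatment) cell must contain all "
            f"{n_days} sampled days"
        )
    sums = (
        df.groupby(["protein", "animal", "treatment"])["abundance"]
        .sum()
        .unstack(["animal", "treatment"])
    )
    sums = sums.reindex(
        columns=pd.MultiIndex.from_product(
            [table.animals, table.treatments], names=["animal", "treatment"]
        )
    )
    return np.log2(sums)


def zscore(matrix: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Standardize each slice to mean 0, SD 1 (denominator n - 1).

    ``axis="rows"`` standardizes each row across its columns (the
    heatmap normalization across treatment conditions); ``axis="columns"``
    standardizes each column.
    """
    if axis not in ("rows", "columns"):
        raise ValidationError('axis must be "rows" or "columns"')
    work = matrix if axis == "columns" else matrix.T
    mean = work.mean(axis=0)
    sd = work.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        offenders = list(work.columns[zero][:5])
        raise ValidationError(
            f"zero-variance slice(s), cannot z-score: {offenders}"
        )
    z = (work - mean) / sd
    return z if axis == "columns" else z.T
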