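"""PRISM multiplexed barcoded cell-line growth analysis.

Hundreds of stably barcoded cancer cell lines are pooled, grown under
two media conditions, and read out by barcode sequencing.  Per line,
the log2 fold change between conditions and a growth rate in doublings
per day are computed from mean-collapsed replicate counts:

    lfc         = log2(n_u / n_g)
    growth_rate = log2(n_f / n_0) / t

Unexpectedly low replicate counts (sequencing noise) are masked before
collapsing so they do not depress the mean.  Lineage enrichment tests
each tissue-of-origin group against the rest; biomarker correlation
ranks molecular features (transcripts, proteins, copy number) by their
Pearson correlation with growth on the test condition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats as st

from .core import DataValidationError, benjamini_hochberg, t_test_two_sided

__all__ = [
    "filter_low_counts",
    "collapse_replicates",
    "prism_lfc",
    "growth_rate",
    "compute_growth_metrics",
    "lineage_enrichment",
    "biomarker_correlation",
    "DEFAULT_COUNT_FLOOR",
    "DEFAULT_ASSAY_DAYS",
]

logger = logging.getLogger(__name__)

#: conservative sequencing-noise floor on raw barcode counts
DEFAULT_COUNT_FLOOR = 20
#: assay length in days at paper scale
DEFAULT_ASSAY_DAYS = 6.0

LONG_COLUMNS = {"cell_line", "condition", "replicate", "count"}


def _check_long(counts: pd.DataFrame) -> None:
    missing = LONG_COLUMNS - set(counts.columns)
    if missing:
        raise DataValidationError(f"PRISM count table missing columns: {sorted(missing)}")


def filter_low_counts(counts: pd.DataFrame, floor: int = DEFAULT_COUNT_FLOOR) -> pd.DataFrame:
    """Mask replicate counts below ``floor`` (they become missing).

    Operates on a long table (cell_line, condition, replicate, count);
    masked entries are excluded from the replicate mean rather than
    dragging it toward zero.  ``floor = 0`` is a no-op.
    """
    if floor < 0:
        raise DataValidationError("count floor must be >= 0")
    _check_long(counts)
    out = counts.copy()
    out["count"] = out["count"].astype(float)
    masked = out["count"] < floor
    out.loc[masked, "count"] = np.nan
    n = int(masked.sum())
    if n:
        logger.info("masked %d replicate counts below floor %d", n, floor)
    return out


def collapse_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Mean of unmasked replicate counts per cell line and condition.

    Lines whose replicates are all masked in a condition come out as
    missing (NaN), never zero.
    """
    _check_long(counts)
    # groupby keeps all-NaN groups (a fully masked line stays missing)
    wide = counts.groupby(["cell_line", "condition"])["count"].mean().unstack("condition")
    all_masked = wide.isna()
    if all_masked.to_numpy().any():
        for line, cond in zip(*np.where(all_masked)):
            logger.warning(
                "cell line %s has no surviving replicate in condition %s; metric missing",
                wide.index[line], wide.columns[cond],
            )
    return wide


def prism_lfc(n_u, n_g):
    """log2(n_u / n_g); missing (NaN) where either collapsed count is <= 0."""
    n_u = np.asarray(n_u, dtype=float)
    n_g = np.asarray(n_g, dtype=float)
    out = np.full(np.broadcast(n_u, n_g).shape, np.nan)
    ok = (n_u > 0) & (n_g > 0)
    out[ok] = np.log2(n_u[ok] / n_g[ok])
    return out if out.ndim else float(out)


def growth_rate(n_0, n_f, t: float):
    """log2(n_f / n_0) / t, in doublings per day; NaN where counts are <= 0."""
    if t <= 0:
        raise DataValidationError("assay length t must be positive")
    n_0 = np.asarray(n_0, dtype=float)
    n_f = np.asarray(n_f, dtype=float)
    out = np.full(np.broadcast(n_0, n_f).shape, np.nan)
    ok = (n_0 > 0) & (n_f > 0)
    out[ok] = np.log2(n_f[ok] / n_0[ok]) / t
    return out if out.ndim else float(out)


def compute_growth_metrics(
    counts: pd.DataFrame,
    lineages: pd.Series,
    n0: pd.Series | float,
    t: float = DEFAULT_ASSAY_DAYS,
    floor: int = DEFAULT_COUNT_FLOOR,
    conditions: tuple[str, str] = ("glucose", "uridine"),
) -> pd.DataFrame:
    """Filter, collapse and apply the growth equations per cell line.

    Parameters
    ----------
    counts
        Long table (cell_line, condition, replicate, count) of final-
        timepoint barcode counts.
    lineages
        cell_line -> lineage label.
    n0
        Initial-timepoint count per line (Series) or a shared seeding
        count (scalar, e.g. 200 cells per line).
    t
        Assay length in days.
    conditions
        ``(reference, test)``; lfc = log2(n_test / n_reference).

    Returns
    -------
    DataFrame indexed by cell_line with columns lineage, n_<ref>,
    n_<test>, lfc, growth_rate_<ref>, growth_rate_<test>.
    """
    ref, test = conditions
    collapsed = collapse_replicates(filter_low_counts(counts, floor))
    for cond in conditions:
        if cond not in collapsed.columns:
            raise DataValidationError(f"condition {cond!r} absent from count table")
    if np.isscalar(n0):
        n0 = pd.Series(float(n0), index=collapsed.index)
    n0 = n0.reindex(collapsed.index)
    out = pd.DataFrame(index=collapsed.index)
    out["lineage"] = lineages.reindex(collapsed.index)
    out[f"n_{ref}"] = collapsed[ref]
    out[f"n_{test}"] = collapsed[test]
    out["lfc"] = prism_lfc(collapsed[test].to_numpy(), collapsed[ref].to_numpy())
    for cond in conditions:
        out[f"growth_rate_{cond}"] = growth_rate(
            n0.to_numpy(), collapsed[cond].to_numpy(), t
        )
    return out


def lineage_enrichment(metrics: pd.DataFrame, min_members: int = 3) -> pd.DataFrame:
    """Members-vs-rest comparison of lfc for each lineage.

    ``effect`` is mean member lfc minus mean non-member lfc; p from a
    two-sided pooled t-test; q from Benjamini–Hochberg across the tested
    lineages.  Lineages with fewer than ``min_members`` non-missing
    members are flagged (``tested = False``) and excluded from the FDR.
    """
    if "lfc" not in metrics.columns or "lineage" not in metrics.columns:
        raise DataValidationError("metrics table needs 'lfc' and 'lineage' columns")
    usable = metrics.dropna(subset=["lfc", "lineage"])
    lineages = sorted(usable["lineage"].unique())
    if len(lineages) < 2:
        raise DataValidationError("lineage enrichment needs >= 2 lineages")
    rows = []
    for lin in lineages:
        member = usable.loc[usable["lineage"] == lin, "lfc"].to_numpy()
        rest = usable.loc[usable["lineage"] != lin, "lfc"].to_numpy()
        tested = len(member) >= min_members and len(rest) >= 2
        effect = member.mean() - rest.mean() if len(member) else np.nan
        if tested:
            res = t_test_two_sided(member, rest)
            rows.append((lin, len(member), effect, res.t, res.p, True))
        else:
            rows.append((lin, len(member), effect, np.nan, np.nan, False))
    out = pd.DataFrame(
        rows, columns=["lineage", "n_members", "effect", "t", "p", "tested"]
    )
    out["q"] = np.nan
    tested_mask = out["tested"].to_numpy()
    if tested_mask.any():
        out.loc[tested_mask, "q"] = benjamini_hochberg(out.loc[tested_mask, "p"].to_numpy())
    return out.sort_values(["q", "p", "lineage"], kind="mergesort", na_position="last").reset_index(drop=True)


def biomarker_correlation(
    lfc: pd.Series,
    features: pd.DataFrame,
    feature_class: pd.Series | str = "transcript",
    method: str = "pearson",
    min_lines: int = 3,
) -> pd.DataFrame:
    """Rank molecular features by correlation with growth lfc.

    Parameters
    ----------
    lfc
        cell_line -> growth metric (missing values allowed).
    features
        cell_line x feature matrix; missing values handled
        pairwise-complete.
    feature_class
        Label per feature (Series) or one label for all features; the
        FDR adjustment runs within each class.
    method
        ``pearson`` (default, matching linear-correlation axes) or
        ``spearman``.
    min_lines
        Features with fewer pairwise-complete lines are excluded, as
        are constant features (correlation undefined).

    Returns
    -------
    DataFrame (feature, feature_class, n, r, p, q) sorted by |r|
    descending; p is the t-distribution transform of r.
    """
    if method not in {"pearson", "spearman"}:
        raise DataValidationError(f"unknown correlation method: {method!r}")
    common = features.index.intersection(lfc.dropna().index)
    if len(common) < min_lines:
        raise DataValidationError(
            f"only {len(common)} cell lines overlap between metrics and features"
        )
    X = features.loc[common].to_numpy(dtype=float)
    y = lfc.loc[common].to_numpy(dtype=float)
    if method == "spearman":
        y = st.rankdata(y)
        X = np.apply_along_axis(_rank_with_nan, 0, X)

    mask = np.isfinite(X)
    X0 = np.where(mask, X, 0.0)
    n = mask.sum(axis=0).astype(float)
    sy = mask.T @ y
    syy = mask.T @ (y * y)
    sx = X0.sum(axis=0)
    sxx = (X0 * X0).sum(axis=0)
    sxy = X0.T @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r = cov / np.sqrt(varx * vary)

    valid = (n >= min_lines) & (varx > 1e-12 * np.maximum(sxx, 1.0)) & (vary > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning(
            "excluded %d features (constant or < %d complete lines)", n_dropped, min_lines
        )
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.where(np.isfinite(tstat), 2.0 * st.t.sf(np.abs(tstat), np.maximum(n - 2, 1)), 0.0)

    if isinstance(feature_class, str):
        classes = pd.Series(feature_class, index=features.columns)
    else:
        classes = feature_class.reindex(features.columns)
    out = pd.DataFrame(
        {
            "feature": features.columns,
            "feature_class": classes.to_numpy(),
            "n": n.astype(int),
            "r": r,
            "p": p,
        }
    )[valid]
    out["q"] = np.nan
    for cls, group in out.groupby("feature_class"):
        out.loc[group.index, "q"] = benjamini_hochberg(group["p"].to_numpy())
    out["abs_r"] = out["r"].abs()
    out = out.sort_values(["abs_r", "feature"], ascending=[False, True], kind="mergesort")
    return out.drop(columns="abs_r").reset_index(drop=True)


def _rank_with_nan(col: np.ndarray) -> np.ndarray:
    out = np.full(col.shape, np.nan)
    ok = np.isfinite(col)
    out[ok] = st.rankdata(col[ok])
    return out
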