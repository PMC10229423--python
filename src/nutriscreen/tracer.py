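"""Natural-isotope-abundance correction of 13C isotopologue distributions.

A measured mass isotopomer distribution (MID) of an n-carbon metabolite
convolves the tracer-derived labeling with naturally occurring 13C
(about 1.07% of carbon).  Writing the true fractions as x = (M0..Mn),
the expected measurement is C @ x where C is lower triangular with

    C[i, j] = Binomial(n - j, p).pmf(i - j)

— the probability that a molecule already carrying j heavy carbons
picks up i - j more among its n - j light positions.  Correction
inverts this convolution, either exactly (triangular solve; noise can
produce small negatives) or by nonnegative least squares.  Only carbon
is corrected: the tracer here is ring-labeled 13C5-uridine, and N/H/O
isotopes or tracer impurity are out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats as st

from .core import DataValidationError

__all__ = [
    "NATURAL_13C_ABUNDANCE",
    "natural_abundance_matrix",
    "correct_mid",
    "fraction_labeled",
    "mean_enrichment",
    "correct_mid_table",
]

#: IUPAC representative natural 13C abundance (fraction of carbon atoms)
NATURAL_13C_ABUNDANCE = 0.0107


def _check_p(p: float) -> None:
    if not 0.0 <= p < 0.5:
        raise DataValidationError(f"natural 13C abundance must be in [0, 0.5), got {p}")


def natural_abundance_matrix(n: int, p: float = NATURAL_13C_ABUNDANCE) -> np.ndarray:
    """(n+1)x(n+1) natural-abundance convolution matrix for n carbons.

    Columns are probability distributions (each sums to 1); with p = 0
    the matrix is the identity.  ``measured = C @ true``.
    """
    if n < 1:
        raise DataValidationError("carbon count n must be >= 1")
    _check_p(p)
    C = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        extra = np.arange(n - j + 1)
        C[j:, j] = st.binom.pmf(extra, n - j, p)
    return C


def correct_mid(raw, n: int | None = None, p: float = NATURAL_13C_ABUNDANCE,
                method: str = "nnls") -> np.ndarray:
    """Remove natural-abundance contributions from a measured MID.

    Parameters
    ----------
    raw
        Measured intensities M0..Mn (arbitrary units, length n+1).
    n
        Carbon count; inferred from the vector length when omitted.
    method
        ``nnls`` (default; nonnegative least squares, right choice for
        noisy data) or ``inverse`` (exact lower-triangular solve, may
        yield small negatives under noise).

    Returns corrected fractions summing to 1.
    """
    raw = np.asarray(raw, dtype=float)
    if n is None:
        n = raw.size - 1
    if raw.size != n + 1:
        raise DataValidationError(f"expected {n + 1} intensities M0..M{n}, got {raw.size}")
    if np.any(raw < 0) or not np.all(np.isfinite(raw)):
        raise DataValidationError("raw intensities must be finite and nonnegative")
    total = raw.sum()
    if total <= 0:
        raise DataValidationError("all-zero intensity vector cannot be corrected")
    y = raw / total
    C = natural_abundance_matrix(n, p)
    if method == "inverse":
        x = scipy.linalg.solve_triangular(C, y, lower=True)
    elif method == "nnls":
        x, _ = scipy.optimize.nnls(C, y)
    else:
        raise DataValidationError(f"unknown correction method: {method!r}")
    s = x.sum()
    if s <= 0:
        raise DataValidationError("correction produced a non-renormalizable vector")
    return x / s


def fraction_labeled(fractions) -> float:
    """Percent of the pool carrying any 13C label: 100 * (1 - M0)."""
    fractions = np.asarray(fractions, dtype=float)
    return float(100.0 * (1.0 - fractions[0]))


def mean_enrichment(fractions) -> float:
    """Average fraction of labeled carbon positions: sum(i * Mi) / n."""
    fractions = np.asarray(fractions, dtype=float)
    n = fractions.size - 1
    return float(np.dot(np.arange(n + 1), fractions) / n)


def correct_mid_table(df: pd.DataFrame, p: float = NATURAL_13C_ABUNDANCE,
                      method: str = "nnls") -> pd.DataFrame:
    """Correct a table of MIDs (columns: metabolite, n_carbons, M0..Mmax).

    Rows may have different carbon counts; intensity columns beyond a
    row's n_carbons must be empty or zero.  Returns corrected fractions
    plus ``fraction_labeled_pct`` and ``mean_enrichment`` per metabolite.
    """
    if not {"metabolite", "n_carbons"} <= set(df.columns):
        raise DataValidationError("MID table needs columns metabolite, n_carbons")
    m_cols = [c for c in df.columns if c.startswith("M") and c[1:].isdigit()]
    m_cols = sorted(m_cols, key=lambda c: int(c[1:]))
    rows = []
    for _, row in df.iterrows():
        n = int(row["n_carbons"])
        raw = row[m_cols[: n + 1]].to_numpy(dtype=float)
        corrected = correct_mid(raw, n=n, p=p, method=method)
        rec = {"metabolite": row["metabolite"], "n_carbons": n}
        for i, c in enumerate(m_cols):
            rec[c] = corrected[i] if i <= n else np.nan
        rec["fraction_labeled_pct"] = fraction_labeled(corrected)
        rec["mean_enrichment"] = mean_enrichment(corrected)
        rows.append(rec)
    return pd.DataFrame(rows)
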