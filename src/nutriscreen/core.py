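"""Shared containers and statistical primitives for pooled-screen analysis.

The screens handled by this package (gain-of-function ORF competition,
genome-wide CRISPR knockout, multiplexed barcoded cell-line growth) all
reduce to the same raw object: a nonnegative integer count matrix of
library elements by sequenced samples.  This module holds that container,
the depth normalization applied before any comparison, and the two
statistical primitives every downstream module shares — the two-sided
pooled-variance (Student's) t-test and Benjamini–Hochberg FDR adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DataValidationError",
    "CountMatrix",
    "NormalizedMatrix",
    "LibraryMap",
    "TARGETING",
    "CONTROL_NONCUTTING",
    "CONTROL_GENE_PREFIX",
    "normalize_log2_rpm",
    "log2_fold_change",
    "TTestResult",
    "t_test_two_sided",
    "t_test_rows",
    "benjamini_hochberg",
    "auroc",
]

VALID_ROLES = frozenset({"screen", "pre_swap_reference", "day0"})

TARGETING = "targeting"
CONTROL_NONCUTTING = "control_noncutting"
#: non-cutting control elements aggregate under a pseudo-gene with this prefix
CONTROL_GENE_PREFIX = "control:"


class DataValidationError(ValueError):
    """Raised when an input table violates a documented contract."""


def _check_unique(values, what: str) -> None:
    s = pd.Index(values)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass(frozen=True)
class CountMatrix:
    """Element-by-sample sequencing counts with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by ``element_id`` with one integer column per
        sample.  Values must be nonnegative integers.
    sample_meta
        DataFrame indexed by ``sample_id`` with columns ``condition``
        (str), ``replicate`` (positive int), ``day`` (nonnegative number)
        and ``role`` (one of ``screen``, ``pre_swap_reference``, ``day0``).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "element_id")
        _check_unique(self.counts.columns, "sample_id")
        body = self.counts.to_numpy()
        if body.size and not np.issubdtype(body.dtype, np.integer):
            # float columns are acceptable only if integral and finite
            if not np.all(np.isfinite(body)) or np.any(body != np.floor(body)):
                bad = np.argwhere((~np.isfinite(body)) | (body != np.floor(body)))[0]
                raise DataValidationError(
                    "non-integer count at element "
                    f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
                )
            object.__setattr__(self, "counts", self.counts.astype(np.int64))
            body = self.counts.to_numpy()
        if body.size and body.min() < 0:
            bad = np.argwhere(body < 0)[0]
            raise DataValidationError(
                "negative count at element "
                f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
            )
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise DataValidationError(f"samples missing from sample sheet: {sorted(missing)}")
        meta = self.sample_meta.loc[list(self.counts.columns)]
        bad_roles = set(meta["role"]) - VALID_ROLES
        if bad_roles:
            raise DataValidationError(f"unknown sample roles: {sorted(bad_roles)}")
        if (meta["replicate"].astype(float) < 1).any():
            raise DataValidationError("replicate numbers must be positive integers")
        object.__setattr__(self, "sample_meta", meta)

    @property
    def element_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_where(self, **query: object) -> list[str]:
        """Sample ids whose metadata match all keyword equalities."""
        mask = pd.Series(True, index=self.sample_meta.index)
        for key, val in query.items():
            mask &= self.sample_meta[key] == val
        return list(self.sample_meta.index[mask])


@dataclass(frozen=True)
class NormalizedMatrix:
    """log2 reads-per-million (with pseudocount) values, same shape as counts."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame


@dataclass(frozen=True)
class LibraryMap:
    """Map from library element to gene and element class.

    ``table`` is indexed by ``element_id`` with columns ``gene`` and
    ``element_class`` (``targeting`` or ``control_noncutting``).
    Non-cutting control elements are aggregated under a reserved
    pseudo-gene ``control:<group>`` so they can serve as a null pool.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "element_id")
        bad = set(self.table["element_class"]) - {TARGETING, CONTROL_NONCUTTING}
        if bad:
            raise DataValidationError(f"unknown element classes: {sorted(bad)}")

    def gene_labels(self) -> pd.Series:
        """Per-element gene label, controls renamed to their pseudo-gene."""
        genes = self.table["gene"].astype(str).copy()
        ctrl = self.table["element_class"] == CONTROL_NONCUTTING
        genes[ctrl] = CONTROL_GENE_PREFIX + genes[ctrl]
        return genes

    def control_pseudogenes(self) -> list[str]:
        labels = self.gene_labels()
        return sorted(labels[self.table["element_class"] == CONTROL_NONCUTTING].unique())


def normalize_log2_rpm(m: CountMatrix) -> NormalizedMatrix:
    """Depth-normalize counts to log2 reads-per-million with a pseudocount.

    Each cell becomes ``log2(reads / column_total * 1e6 + 1)``.  The
    pseudocount sits inside the log, so a zero count maps to exactly 0
    and every column satisfies ``sum(2**v - 1) == 1e6``.

    Raises
    ------
    DataValidationError
        If any sample has a zero column total.
    """
    totals = m.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DataValidationError(f"zero-total sample columns: {list(zero.index)}")
    rpm = m.counts.to_numpy(dtype=float) / totals.to_numpy(dtype=float) * 1e6
    values = pd.DataFrame(np.log2(rpm + 1.0), index=m.counts.index, columns=m.counts.columns)
    return NormalizedMatrix(values=values, sample_meta=m.sample_meta)


def log2_fold_change(norm: NormalizedMatrix, sample: str, reference: str) -> pd.Series:
    """Per-element LFC: normalized value in ``sample`` minus ``reference``."""
    for sid in (sample, reference):
        if sid not in norm.values.columns:
            raise DataValidationError(f"unknown sample id: {sid!r}")
    lfc = norm.values[sample] - norm.values[reference]
    lfc.name = f"lfc[{sample}-{reference}]"
    return lfc


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float


def t_test_two_sided(a, b) -> TTestResult:
    """Two-sided pooled-variance (Student's) two-sample t-test.

    Degenerate convention: if the pooled variance is exactly zero the
    test is undefined, so p = 1 when the group means are equal and p = 0
    otherwise (a warning is emitted).  This keeps noise-free synthetic
    fixtures deterministic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataValidationError("t-test requires at least 2 values per group")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        warnings.warn("zero pooled variance; applying degenerate p-value convention")
        if diff == 0.0:
            return TTestResult(t=0.0, p=1.0)
        return TTestResult(t=float(np.sign(diff)) * np.inf, p=0.0)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t = diff / se
    p = 2.0 * st.t.sf(abs(t), df)
    return TTestResult(t=float(t), p=float(min(p, 1.0)))


def t_test_rows(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled t-test of ``A`` (n×ka) against ``B`` (n×kb).

    Vectorized analogue of :func:`t_test_two_sided` with the same
    zero-variance convention; returns ``(t, p)`` arrays of length n.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise DataValidationError("t-test requires at least 2 values per group")
    na, nb = A.shape[1], B.shape[1]
    df = na + nb - 2
    pooled = ((na - 1) * A.var(axis=1, ddof=1) + (nb - 1) * B.var(axis=1, ddof=1)) / df
    diff = A.mean(axis=1) - B.mean(axis=1)
    t = np.zeros(len(A))
    p = np.ones(len(A))
    ok = pooled > 0.0
    se = np.sqrt(pooled[ok] * (1.0 / na + 1.0 / nb))
    t[ok] = diff[ok] / se
    p[ok] = np.minimum(2.0 * st.t.sf(np.abs(t[ok]), df), 1.0)
    degen = ~ok
    if degen.any():
        warnings.warn("zero pooled variance; applying degenerate p-value convention")
        nz = degen & (diff != 0.0)
        t[nz] = np.sign(diff[nz]) * np.inf
        p[nz] = 0.0
    return t, p


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Returns adjusted q-values in the input order; monotone with respect
    to p and never below the raw p-value.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise DataValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) identity.

    ``labels`` are boolean/0-1; higher ``scores`` should indicate
    positives.  Ties receive mid-ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataValidationError("AUROC requires both positive and negative labels")
    ranks = st.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
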