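"""Normalized z-score CRISPR essentiality and differential essentiality.

Scoring proceeds exactly in this order: per-sgRNA log2 fold change of
log2-RPM abundance relative to the pre-swap reference; per-gene mean of
its (typically four) sgRNAs within each replicate; mean across
replicates; removal of unexpressed genes (log2 FPKM below a threshold,
default 0); and a z-transform using the mean and sample standard
deviation of an empirical null — either the k lowest-expressed genes
(``expression`` mode, paper-scale default k = 3,726) or the non-cutting
control pseudo-genes (``noncutting`` mode).  Differential essentiality
between two media is the difference of condition z-scores (dz = z_b -
z_a, e.g. z_uridine - z_glucose).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CountMatrix,
    DataValidationError,
    LibraryMap,
    NormalizedMatrix,
    log2_fold_change,
    normalize_log2_rpm,
)

__all__ = [
    "NullModel",
    "gene_level_lfc",
    "filter_expressed",
    "build_null",
    "build_null_noncutting",
    "zscore_genes",
    "differential_essentiality",
    "score_crispr_screen",
    "CrisprScreenResult",
    "PAPER_NULL_K",
]

logger = logging.getLogger(__name__)

#: null-pool size used at full genome scale
PAPER_NULL_K = 3726
#: default null-pool size for synthetic screens: this fraction of genes
DEFAULT_NULL_FRACTION = 0.2


@dataclass(frozen=True)
class NullModel:
    """Empirical null for z-scoring: members, their mean and sample sd."""

    member_genes: frozenset
    mu: float
    sigma: float

    @property
    def k(self) -> int:
        return len(self.member_genes)


def gene_level_lfc(
    norm: NormalizedMatrix,
    lib: LibraryMap,
    reference: str,
    sample: str,
) -> pd.Series:
    """Per-gene mean sgRNA log2 fold change of ``sample`` vs ``reference``.

    Every element present in the normalized matrix must be mapped by the
    library; non-cutting controls aggregate under their reserved
    ``control:`` pseudo-gene.  Library entries absent from the counts
    are an error (they are never silently treated as zero).
    """
    lfc = log2_fold_change(norm, sample, reference)
    genes = lib.gene_labels()
    unmapped = lfc.index.difference(genes.index)
    if len(unmapped):
        raise DataValidationError(f"elements missing from library: {list(unmapped[:5])}")
    absent = genes.index.difference(lfc.index)
    if len(absent):
        raise DataValidationError(
            f"library elements absent from counts: {list(absent[:5])}"
        )
    out = lfc.groupby(genes.reindex(lfc.index)).mean()
    out.name = "mean_lfc"
    return out


def filter_expressed(genes, expr: pd.Series, threshold: float = 0.0) -> set:
    """Retain genes whose log2 FPKM is >= threshold (strict '<' removal).

    Genes with no recorded expression value are removed: what has no
    value cannot be ranked against the threshold.
    """
    genes = set(genes)
    expressed = set(expr.index[expr >= threshold])
    return genes & expressed


def build_null(mean_lfcs: pd.Series, expr: pd.Series, k: int) -> NullModel:
    """Null from the k lowest-expressed genes that have an LFC value.

    Ties at the k-th expression rank break lexicographically by gene id.
    Filtered-out (sub-threshold) genes still qualify as null members as
    long as an expression value is recorded for them.
    """
    candidates = expr[expr.index.isin(mean_lfcs.index)]
    if k < 2:
        raise DataValidationError("null pool needs k >= 2")
    if k > len(candidates):
        raise DataValidationError(
            f"k={k} exceeds the {len(candidates)} genes with expression values"
        )
    order = candidates.rename("expr").rename_axis("gene").reset_index()
    order = order.sort_values(["expr", "gene"], kind="mergesort")
    members = order["gene"].iloc[:k].tolist()
    return _null_from_members(mean_lfcs, members)


def build_null_noncutting(mean_lfcs: pd.Series, lib: LibraryMap) -> NullModel:
    """Null from the non-cutting control pseudo-genes in the library."""
    members = [g for g in lib.control_pseudogenes() if g in mean_lfcs.index]
    if len(members) < 2:
        raise DataValidationError("need >= 2 non-cutting control pseudo-genes for a null")
    return _null_from_members(mean_lfcs, members)


def _null_from_members(mean_lfcs: pd.Series, members: list) -> NullModel:
    vals = mean_lfcs.loc[members].to_numpy(dtype=float)
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=1))
    if sigma == 0.0:
        raise DataValidationError("degenerate null: member LFCs have zero variance")
    return NullModel(member_genes=frozenset(members), mu=mu, sigma=sigma)


def zscore_genes(mean_lfcs: pd.Series, null: NullModel) -> pd.Series:
    """z = (mean_lfc - mu) / sigma for every gene in ``mean_lfcs``."""
    z = (mean_lfcs - null.mu) / null.sigma
    z.name = "z"
    return z


def differential_essentiality(
    z_a: pd.Series,
    z_b: pd.Series,
    essential_z: float = -3.0,
    dispensable_z: float = -1.0,
    label_a: str = "glu",
    label_b: str = "u",
) -> pd.DataFrame:
    """Compare condition z-scores gene by gene.

    ``dz = z_b - z_a``; classes (artifact conventions, not measured
    constants): a gene is *essential* in a condition when its z is at or
    below ``essential_z`` and *dispensable* when above ``dispensable_z``.
    ``<label_b>_specific_essential`` means essential in b, dispensable in
    a (and symmetrically); essential in both is ``shared_essential``;
    everything else is ``neutral``.
    """
    common = z_a.index.intersection(z_b.index)
    if len(common) < len(z_a) or len(common) < len(z_b):
        logger.warning(
            "gene sets differ (%d vs %d); using inner join of %d genes",
            len(z_a), len(z_b), len(common),
        )
    za = z_a.loc[common].to_numpy(dtype=float)
    zb = z_b.loc[common].to_numpy(dtype=float)
    ess_a = za <= essential_z
    ess_b = zb <= essential_z
    disp_a = za > dispensable_z
    disp_b = zb > dispensable_z
    cls = np.full(len(common), "neutral", dtype=object)
    cls[ess_a & ess_b] = "shared_essential"
    cls[ess_b & disp_a] = f"{label_b}_specific_essential"
    cls[ess_a & disp_b] = f"{label_a}_specific_essential"
    out = pd.DataFrame(
        {
            "gene": common,
            f"z_{label_a}": za,
            f"z_{label_b}": zb,
            "dz": zb - za,
            "class": cls,
        }
    )
    return out.sort_values(["dz", "gene"], kind="mergesort").reset_index(drop=True)


@dataclass
class CrisprScreenResult:
    """Scored screen: per-gene table plus the fitted nulls.

    ``table`` holds one row per expressed gene with per-condition mean
    LFC, z, dz and class; ``mean_lfcs``/``nulls`` keep the per-condition
    intermediates (all genes, including null members) for diagnostics.
    """

    table: pd.DataFrame
    mean_lfcs: dict = field(default_factory=dict)
    nulls: dict = field(default_factory=dict)
    expressed_genes: set = field(default_factory=set)


def _replicate_pairs(m: CountMatrix, condition: str) -> list[tuple[str, str]]:
    """(screen sample, pre-swap reference) pairs for one condition.

    A single reference serves all replicates; with several references,
    each screen replicate pairs with the reference of the same replicate
    number.
    """
    refs = m.samples_where(role="pre_swap_reference")
    if not refs:
        raise DataValidationError("no sample with role 'pre_swap_reference'")
    screens = m.samples_where(role="screen", condition=condition)
    if not screens:
        raise DataValidationError(f"no screen samples for condition {condition!r}")
    if len(refs) == 1:
        return [(s, refs[0]) for s in screens]
    ref_by_rep = {m.sample_meta.loc[r, "replicate"]: r for r in refs}
    pairs = []
    for s in screens:
        rep = m.sample_meta.loc[s, "replicate"]
        if rep not in ref_by_rep:
            raise DataValidationError(f"no pre-swap reference for replicate {rep}")
        pairs.append((s, ref_by_rep[rep]))
    return pairs


def score_crispr_screen(
    m: CountMatrix,
    lib: LibraryMap,
    expr: pd.Series,
    conditions: tuple[str, str] | None = None,
    null_mode: str = "expression",
    null_k: int | None = None,
    expression_threshold: float = 0.0,
    essential_z: float = -3.0,
    dispensable_z: float = -1.0,
) -> CrisprScreenResult:
    """Run the full z-score essentiality pipeline for two conditions.

    Parameters
    ----------
    conditions
        Pair ``(a, b)``; ``dz = z_b - z_a``.  Defaults to the sorted
        unique screen conditions (must be exactly two).
    null_mode
        ``expression`` (k lowest-expressed genes) or ``noncutting``
        (control pseudo-genes).
    null_k
        Null-pool size for ``expression`` mode.  Default: 20% of the
        genes with recorded expression (use 3,726 at full genome scale).
    """
    if conditions is None:
        screen = m.sample_meta[m.sample_meta["role"] == "screen"]
        conds = sorted(screen["condition"].unique())
        if len(conds) != 2:
            raise DataValidationError(f"expected exactly 2 screen conditions, found {conds}")
        conditions = (conds[0], conds[1])
    if null_mode not in {"expression", "noncutting"}:
        raise DataValidationError(f"unknown null mode: {null_mode!r}")
    norm = normalize_log2_rpm(m)

    mean_lfcs: dict[str, pd.Series] = {}
    for cond in conditions:
        per_rep = [
            gene_level_lfc(norm, lib, reference=ref, sample=s)
            for s, ref in _replicate_pairs(m, cond)
        ]
        mean_lfcs[cond] = pd.concat(per_rep, axis=1).mean(axis=1).rename("mean_lfc")

    nulls: dict[str, NullModel] = {}
    zs: dict[str, pd.Series] = {}
    expressed: set = set()
    for cond in conditions:
        lfcs = mean_lfcs[cond]
        if null_mode == "expression":
            k = null_k
            if k is None:
                n_candidates = int(expr.index.isin(lfcs.index).sum())
                k = max(2, round(DEFAULT_NULL_FRACTION * n_candidates))
            nulls[cond] = build_null(lfcs, expr, k)
        else:
            nulls[cond] = build_null_noncutting(lfcs, lib)
        expressed = filter_expressed(lfcs.index, expr, expression_threshold)
        zs[cond] = zscore_genes(lfcs.loc[sorted(expressed)], nulls[cond])

    a, b = conditions
    table = differential_essentiality(
        zs[a], zs[b], essential_z=essential_z, dispensable_z=dispensable_z,
        label_a=a, label_b=b,
    )
    for cond in conditions:
        table[f"mean_lfc_{cond}"] = mean_lfcs[cond].reindex(table["gene"]).to_numpy()
    cols = ["gene", f"mean_lfc_{a}", f"mean_lfc_{b}", f"z_{a}", f"z_{b}", "dz", "class"]
    return CrisprScreenResult(
        table=table[cols],
        mean_lfcs=mean_lfcs,
        nulls=nulls,
        expressed_genes=expressed,
    )
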