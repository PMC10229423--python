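"""Gain-of-function ORF screen scoring.

A pooled library of barcoded open-reading-frame overexpression
constructs competes in two media (e.g. glucose vs galactose); barcode
abundance after a fixed number of days is compared between the two
conditions on the log2 reads-per-million scale.  Enrichment in the
restrictive condition implies a proliferation benefit of the
overexpressed gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    CountMatrix,
    DataValidationError,
    LibraryMap,
    normalize_log2_rpm,
    t_test_rows,
)
from .io import write_table

__all__ = ["score_orf_screen", "volcano_table", "NEG_LOG10_P_CAP"]

#: rendering cap for -log10(p) when the degenerate convention yields p == 0
NEG_LOG10_P_CAP = 300.0


def score_orf_screen(
    m: CountMatrix,
    condition_a: str,
    condition_b: str,
    day: float,
    lib: LibraryMap | None = None,
    flag_depletion_below: float | None = None,
) -> pd.DataFrame:
    """Score each ORF element for differential abundance between conditions.

    For every element, ``lfc`` is the mean log2-RPM in ``condition_b``
    minus the mean in ``condition_a`` across replicate samples at the
    requested day, and ``(t, p)`` come from a two-sided pooled-variance
    t-test on the per-replicate normalized values.  No multiplicity
    adjustment is applied.

    Parameters
    ----------
    m
        Count matrix with sample metadata.
    condition_a, condition_b
        Condition labels; positive ``lfc`` means enriched in ``condition_b``.
    day
        Timepoint to contrast (both conditions must have >= 2 replicate
        samples with role ``screen`` at this day).
    lib
        Optional element->gene map; without it the gene column repeats
        the element id (one barcode per ORF).
    flag_depletion_below
        If given, adds a boolean ``depleted_flag`` column marking strong
        depleters (lfc <= threshold), which should be interpreted with
        caution (dropout may reflect recombination artifacts rather than
        biology).

    Returns
    -------
    DataFrame with columns element_id, gene, lfc, t, p sorted by
    descending lfc (element_id breaks ties deterministically).
    """
    samples_a = m.samples_where(role="screen", condition=condition_a, day=day)
    samples_b = m.samples_where(role="screen", condition=condition_b, day=day)
    for cond, samples in ((condition_a, samples_a), (condition_b, samples_b)):
        if len(samples) < 2:
            raise DataValidationError(
                f"condition {cond!r} at day {day} has {len(samples)} replicate(s); need >= 2"
            )
    norm = normalize_log2_rpm(m)
    A = norm.values[samples_a].to_numpy()
    B = norm.values[samples_b].to_numpy()
    lfc = B.mean(axis=1) - A.mean(axis=1)
    with np.errstate(invalid="ignore"):
        t, p = t_test_rows(B, A)
    if lib is not None:
        genes = lib.gene_labels().reindex(m.element_ids)
        if genes.isna().any():
            missing = list(m.element_ids[genes.isna()])[:5]
            raise DataValidationError(f"elements missing from library: {missing}")
    else:
        genes = pd.Series(m.element_ids, index=m.element_ids)
    out = pd.DataFrame(
        {
            "element_id": m.element_ids,
            "gene": genes.to_numpy(),
            "lfc": lfc,
            "t": t,
            "p": p,
        }
    )
    if flag_depletion_below is not None:
        out["depleted_flag"] = out["lfc"] <= flag_depletion_below
    out = out.sort_values(["lfc", "element_id"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def gene_level_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean lfc per gene, for libraries with several barcodes per gene."""
    agg = scores.groupby("gene", sort=True).agg(
        n_elements=("element_id", "size"), lfc=("lfc", "mean")
    )
    return agg.reset_index().sort_values(["lfc", "gene"], ascending=[False, True]).reset_index(drop=True)


def volcano_table(
    scores: pd.DataFrame,
    path=None,
    cap: float = NEG_LOG10_P_CAP,
    header_lines: list[str] | None = None,
) -> pd.DataFrame:
    """Volcano-plot table: element_id, gene, lfc, p, neg_log10_p.

    ``p == 0`` (the zero-variance convention) renders as the documented
    cap rather than infinity so the TSV stays finite.
    """
    if scores.empty:
        raise DataValidationError("cannot render a volcano table from an empty score table")
    out = scores[["element_id", "gene", "lfc", "p"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = np.minimum(-np.log10(out["p"].to_numpy()), cap)
    if path is not None:
        write_table(out, path, header_lines)
    return out
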