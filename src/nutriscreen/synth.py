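"""Synthetic screen generators with planted ground truth.

Every analysis stage in this package has a matching generator here, so
the whole pipeline is exercisable without any external download.  Counts
are drawn negative-binomially (gamma–Poisson) around lognormal baseline
abundances — pooled-screen sequencing counts are overdispersed — with a
configurable dispersion; effects are planted as log2 multipliers on the
expected count over the screen window.  All generators are pure
functions of their parameters and an integer seed: the same call twice
yields bitwise-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CountMatrix, DataValidationError, LibraryMap
from .io import (
    make_library_table,
    provenance_header,
    write_counts,
    write_expression,
    write_library,
    write_table,
)
from .tracer import NATURAL_13C_ABUNDANCE, natural_abundance_matrix

__all__ = [
    "SimulatedCrisprScreen",
    "SimulatedOrfScreen",
    "SimulatedPrism",
    "simulate_crispr_screen",
    "simulate_orf_screen",
    "simulate_prism",
    "simulate_mids",
]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise DataValidationError("NB dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic substreams derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# CRISPR knockout screen
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCrisprScreen:
    counts: CountMatrix
    library: LibraryMap
    expression: pd.Series
    truth: pd.DataFrame
    params: dict


def simulate_crispr_screen(
    n_genes: int = 2000,
    sgrnas_per_gene: int = 4,
    n_noncutting: int = 400,
    replicates: int = 2,
    conditions: tuple[str, str] = ("glucose", "uridine"),
    n_planted: int = 100,
    effect_log2: float = -4.0,
    planted_condition: str = "uridine",
    planted_sets: dict | None = None,
    depth: float = 500.0,
    nb_dispersion: float = 0.1,
    low_expr_fraction: float = 0.2,
    abundance_sigma: float = 0.5,
    day: float = 21.0,
    seed: int = 0,
) -> SimulatedCrisprScreen:
    """Simulate a two-condition knockout screen with a pre-swap reference.

    Baseline sgRNA abundances are lognormal; the pre-swap reference and
    each final sample draw negative-binomial counts around them, the
    final samples multiplied by ``2**effect`` for planted genes in their
    planted condition.  The expression table makes every planted gene
    expressed (log2 FPKM > 0) and assigns ``low_expr_fraction`` of the
    remaining genes sub-zero expression, forming the empirical null pool.
    Non-cutting controls are grouped into pseudo-genes of
    ``sgrnas_per_gene`` elements and carry no expression value.

    Parameters mirror the scoring method's assumptions: ``depth`` is the
    expected reads per sgRNA, ``nb_dispersion`` the NB overdispersion.
    ``planted_sets`` maps gene -> {condition: effect_log2} and overrides
    the convenience arguments when given.
    """
    if n_noncutting % sgrnas_per_gene:
        raise DataValidationError("n_noncutting must be a multiple of sgrnas_per_gene")
    rng_ab, rng_counts, rng_expr, rng_pick = _rngs(seed, 4)

    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    n_ctrl_groups = n_noncutting // sgrnas_per_gene
    ctrl_groups = {
        f"NC{g + 1:03d}": [f"NC{g + 1:03d}_sg{i + 1}" for i in range(sgrnas_per_gene)]
        for g in range(n_ctrl_groups)
    }
    lib = make_library_table(genes, sgrnas_per_gene, ctrl_groups)
    elements = list(lib.table.index)
    n_elem = len(elements)

    effects = {cond: pd.Series(0.0, index=genes) for cond in conditions}
    if planted_sets is None:
        if n_planted > n_genes:
            raise DataValidationError("n_planted exceeds n_genes")
        planted = sorted(rng_pick.choice(genes, size=n_planted, replace=False))
        planted_sets = {g: {planted_condition: effect_log2} for g in planted}
    for gene, per_cond in planted_sets.items():
        if gene not in effects[conditions[0]].index:
            raise DataValidationError(f"planted gene {gene!r} not in library")
        for cond, eff in per_cond.items():
            if cond not in effects:
                raise DataValidationError(f"planted condition {cond!r} not simulated")
            effects[cond][gene] = eff

    # per-element expected count at the reference timepoint
    abundance = rng_ab.lognormal(mean=0.0, sigma=abundance_sigma, size=n_elem)
    base_mean = depth * abundance / abundance.mean()
    elem_gene = lib.table["gene"].to_numpy()
    is_targeting = (lib.table["element_class"] == "targeting").to_numpy()

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for rep in range(1, replicates + 1):
        sid = f"preswap_rep{rep}"
        columns[sid] = _nb_counts(rng_counts, base_mean, nb_dispersion)
        meta_rows.append((sid, "pre_swap", rep, 0.0, "pre_swap_reference"))
    for cond in conditions:
        eff = np.where(
            is_targeting, effects[cond].reindex(elem_gene).fillna(0.0).to_numpy(), 0.0
        )
        cond_mean = base_mean * np.exp2(eff)
        for rep in range(1, replicates + 1):
            sid = f"{cond}_rep{rep}"
            columns[sid] = _nb_counts(rng_counts, cond_mean, nb_dispersion)
            meta_rows.append((sid, cond, rep, day, "screen"))

    counts = pd.DataFrame(columns, index=pd.Index(elements, name="element_id"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "condition", "replicate", "day", "role"]
    ).set_index("sample_id")
    cm = CountMatrix(counts=counts, sample_meta=meta)

    planted_genes = set(planted_sets)
    unplanted = [g for g in genes if g not in planted_genes]
    n_low = int(round(low_expr_fraction * len(unplanted)))
    low_set = set(rng_pick.choice(unplanted, size=n_low, replace=False)) if n_low else set()
    expr_vals = np.empty(n_genes)
    for i, g in enumerate(genes):
        if g in low_set:
            expr_vals[i] = rng_expr.uniform(-4.0, -0.1)
        elif g in planted_genes:
            expr_vals[i] = rng_expr.uniform(1.0, 8.0)
        else:
            expr_vals[i] = rng_expr.uniform(0.1, 8.0)
    expression = pd.Series(expr_vals, index=pd.Index(genes, name="gene"), name="log2_fpkm")

    truth = pd.DataFrame({"gene": genes})
    truth["planted"] = truth["gene"].isin(planted_genes)
    for cond in conditions:
        truth[f"effect_{cond}"] = effects[cond].reindex(truth["gene"]).to_numpy()
    truth["low_expression"] = truth["gene"].isin(low_set)

    params = dict(
        n_genes=n_genes, sgrnas_per_gene=sgrnas_per_gene, n_noncutting=n_noncutting,
        replicates=replicates, conditions=conditions, n_planted=len(planted_genes),
        effect_log2=effect_log2, planted_condition=planted_condition, depth=depth,
        nb_dispersion=nb_dispersion, low_expr_fraction=low_expr_fraction, seed=seed,
    )
    return SimulatedCrisprScreen(cm, lib, expression, truth, params)


# ---------------------------------------------------------------------------
# ORF overexpression screen
# ---------------------------------------------------------------------------

@dataclass
class SimulatedOrfScreen:
    counts: CountMatrix
    truth: pd.DataFrame
    params: dict


def simulate_orf_screen(
    n_orfs: int = 2000,
    replicates: int = 2,
    conditions: tuple[str, str] = ("glucose", "galactose"),
    n_planted: int = 20,
    effect_log2: float = 3.0,
    enriched_condition: str | None = None,
    depth: float = 1000.0,
    nb_dispersion: float = 0.01,
    abundance_sigma: float = 0.5,
    day: float = 21.0,
    seed: int = 0,
) -> SimulatedOrfScreen:
    """Simulate a gain-of-function competition screen (one barcode per ORF).

    Planted ORFs are enriched by ``2**effect_log2`` in
    ``enriched_condition`` (default: the second condition).  With
    ``nb_dispersion = 0.01`` and depth 1000 the count coefficient of
    variation is about 10%.
    """
    rng_ab, rng_counts, rng_pick = _rngs(seed, 3)
    if enriched_condition is None:
        enriched_condition = conditions[1]
    if enriched_condition not in conditions:
        raise DataValidationError(f"enriched condition {enriched_condition!r} not simulated")
    width = len(str(n_orfs))
    orfs = [f"ORF{i + 1:0{width}d}" for i in range(n_orfs)]
    planted = sorted(rng_pick.choice(orfs, size=n_planted, replace=False)) if n_planted else []
    planted_mask = np.isin(orfs, planted)

    abundance = rng_ab.lognormal(mean=0.0, sigma=abundance_sigma, size=n_orfs)
    base_mean = depth * abundance / abundance.mean()

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for cond in conditions:
        eff = np.where(planted_mask & (cond == enriched_condition), effect_log2, 0.0)
        cond_mean = base_mean * np.exp2(eff)
        for rep in range(1, replicates + 1):
            sid = f"{cond}_rep{rep}"
            columns[sid] = _nb_counts(rng_counts, cond_mean, nb_dispersion)
            meta_rows.append((sid, cond, rep, day, "screen"))
    counts = pd.DataFrame(columns, index=pd.Index(orfs, name="element_id"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "condition", "replicate", "day", "role"]
    ).set_index("sample_id")
    cm = CountMatrix(counts=counts, sample_meta=meta)

    truth = pd.DataFrame({"element_id": orfs, "planted": planted_mask,
                          "effect_log2": np.where(planted_mask, effect_log2, 0.0)})
    params = dict(n_orfs=n_orfs, replicates=replicates, conditions=conditions,
                  n_planted=n_planted, effect_log2=effect_log2,
                  enriched_condition=enriched_condition, depth=depth,
                  nb_dispersion=nb_dispersion, seed=seed)
    return SimulatedOrfScreen(cm, truth, params)


# ---------------------------------------------------------------------------
# PRISM barcoded growth assay
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPrism:
    counts: pd.DataFrame            # long: cell_line, condition, replicate, count
    lineages: pd.Series             # cell_line -> lineage
    n0: pd.Series                   # cell_line -> seeding count
    features: pd.DataFrame          # cell_line x feature
    feature_class: pd.Series        # feature -> class label
    truth: dict
    params: dict


def simulate_prism(
    n_lines: int = 482,
    n_lineages: int = 22,
    replicates: int = 3,
    conditions: tuple[str, str] = ("glucose", "uridine"),
    planted_lineage_shift: float = 2.0,
    planted_lineage: str | None = None,
    n_features: int = 2000,
    r_true: float = 0.6,
    baseline_lfc_sd: float = 1.0,
    growth_rate_mean: float = 0.5,
    growth_rate_sd: float = 0.1,
    nb_dispersion: float = 0.01,
    n0: float = 200.0,
    t_days: float = 6.0,
    seed: int = 0,
) -> SimulatedPrism:
    """Simulate a pooled barcoded cell-line competition assay.

    Each line carries a latent uridine-vs-glucose growth lfc drawn from
    N(0, baseline_lfc_sd), shifted by ``planted_lineage_shift`` for one
    planted lineage.  Lines seed at ``n0`` cells; glucose endpoint counts
    grow at a per-line baseline rate (doublings/day) over ``t_days`` and
    uridine counts multiply that by ``2**lfc``, so applying the growth
    equations to the collapsed counts recovers the latent lfc within
    counting noise.  One feature is generated with population correlation
    ``r_true`` to the latent lfc; the rest are independent noise.
    """
    if n_lineages > n_lines:
        raise DataValidationError("n_lineages cannot exceed n_lines")
    rng_latent, rng_counts, rng_feat, rng_pick = _rngs(seed, 4)

    lines = [f"line_{i + 1:04d}" for i in range(n_lines)]
    lineage_names = [f"lineage_{i + 1:02d}" for i in range(n_lineages)]
    lineages = pd.Series(
        [lineage_names[i % n_lineages] for i in range(n_lines)],
        index=pd.Index(lines, name="cell_line"), name="lineage",
    )
    if planted_lineage is None:
        planted_lineage = lineage_names[int(rng_pick.integers(n_lineages))]
    elif planted_lineage not in lineage_names:
        raise DataValidationError(f"planted lineage {planted_lineage!r} not simulated")

    lfc = rng_latent.normal(0.0, baseline_lfc_sd, size=n_lines)
    lfc[(lineages == planted_lineage).to_numpy()] += planted_lineage_shift
    g = rng_latent.normal(growth_rate_mean, growth_rate_sd, size=n_lines)

    ref, test = conditions
    mean_ref = n0 * np.exp2(g * t_days)
    means = {ref: mean_ref, test: mean_ref * np.exp2(lfc)}
    rows = []
    for cond in conditions:
        for rep in range(1, replicates + 1):
            draws = _nb_counts(rng_counts, means[cond], nb_dispersion)
            rows.extend(zip(lines, [cond] * n_lines, [rep] * n_lines, draws))
    counts = pd.DataFrame(rows, columns=["cell_line", "condition", "replicate", "count"])

    feat_names = [f"feature_{j + 1:05d}" for j in range(n_features)]
    planted_feature = feat_names[int(rng_pick.integers(n_features))]
    X = rng_feat.normal(size=(n_lines, n_features))
    z = (lfc - lfc.mean()) / lfc.std()
    j = feat_names.index(planted_feature)
    X[:, j] = r_true * z + np.sqrt(max(0.0, 1.0 - r_true**2)) * rng_feat.normal(size=n_lines)
    features = pd.DataFrame(X, index=pd.Index(lines, name="cell_line"), columns=feat_names)
    feature_class = pd.Series("transcript", index=pd.Index(feat_names, name="feature"),
                              name="feature_class")

    truth = dict(
        planted_lineage=planted_lineage,
        planted_feature=planted_feature,
        r_true=r_true,
        latent_lfc=pd.Series(lfc, index=lines, name="latent_lfc"),
        latent_growth_rate=pd.Series(g, index=lines, name="latent_growth_rate"),
    )
    params = dict(n_lines=n_lines, n_lineages=n_lineages, replicates=replicates,
                  conditions=conditions, planted_lineage_shift=planted_lineage_shift,
                  n_features=n_features, r_true=r_true, baseline_lfc_sd=baseline_lfc_sd,
                  nb_dispersion=nb_dispersion, n0=n0, t_days=t_days, seed=seed)
    n0_series = pd.Series(float(n0), index=pd.Index(lines, name="cell_line"), name="n0")
    return SimulatedPrism(counts, lineages, n0_series, features, feature_class, truth, params)


# ---------------------------------------------------------------------------
# Isotopologue measurements
# ---------------------------------------------------------------------------

def simulate_mids(
    n_carbons: int,
    true_mid,
    p: float = NATURAL_13C_ABUNDANCE,
    noise_cv: float = 0.0,
    n_samples: int = 1,
    intensity: float = 1e6,
    metabolite: str = "metabolite",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate measured MIDs: natural-abundance convolution plus noise.

    ``measured = C(n, p) @ true_mid`` scaled to ``intensity`` total
    counts, each channel multiplied by lognormal noise of coefficient of
    variation ``noise_cv``.  Returns (measurements, truth) in the
    mids.tsv dialect (columns metabolite, n_carbons, M0..Mn).
    """
    true = np.asarray(true_mid, dtype=float)
    if true.size != n_carbons + 1:
        raise DataValidationError(f"true MID must have {n_carbons + 1} entries")
    if np.any(true < 0) or abs(true.sum() - 1.0) > 1e-9:
        raise DataValidationError("true MID must be nonnegative and sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    C = natural_abundance_matrix(n_carbons, p)
    expected = C @ true * intensity
    m_cols = [f"M{i}" for i in range(n_carbons + 1)]
    rows = []
    for s in range(n_samples):
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            noise = rng.lognormal(-sigma**2 / 2.0, sigma, size=expected.size)
        else:
            noise = 1.0
        name = metabolite if n_samples == 1 else f"{metabolite}_{s + 1}"
        rows.append([name, n_carbons, *(expected * noise)])
    measured = pd.DataFrame(rows, columns=["metabolite", "n_carbons", *m_cols])
    truth = pd.DataFrame([[metabolite, n_carbons, *true]],
                         columns=["metabolite", "n_carbons", *m_cols])
    return measured, truth


# ---------------------------------------------------------------------------
# TSV emission (same dialects the scoring commands read)
# ---------------------------------------------------------------------------

def write_crispr_sim(sim: SimulatedCrisprScreen, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    header = provenance_header(params=sim.params)
    paths = {name: outdir / f"{name}.tsv" for name in
             ("counts", "samples", "library", "expression", "truth")}
    write_counts(sim.counts, paths["counts"], paths["samples"], header_lines=header)
    write_library(sim.library, paths["library"], header_lines=header)
    write_expression(sim.expression, paths["expression"], header_lines=header)
    write_table(sim.truth, paths["truth"], header_lines=header)
    return paths


def write_orf_sim(sim: SimulatedOrfScreen, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    header = provenance_header(params=sim.params)
    paths = {name: outdir / f"{name}.tsv" for name in ("counts", "samples", "truth")}
    write_counts(sim.counts, paths["counts"], paths["samples"], header_lines=header)
    write_table(sim.truth, paths["truth"], header_lines=header)
    return paths


def write_prism_sim(sim: SimulatedPrism, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    header = provenance_header(params=sim.params)
    paths = {name: outdir / f"{name}.tsv" for name in
             ("prism_counts", "lineages", "features", "feature_classes", "truth")}
    write_table(sim.counts, paths["prism_counts"], header_lines=header)
    lines = pd.DataFrame({
        "cell_line": sim.lineages.index,
        "lineage": sim.lineages.to_numpy(),
        "n0": sim.n0.reindex(sim.lineages.index).to_numpy(),
    })
    write_table(lines, paths["lineages"], header_lines=header)
    write_table(sim.features.reset_index(), paths["features"], header_lines=header)
    write_table(sim.feature_class.reset_index(), paths["feature_classes"], header_lines=header)
    truth = pd.DataFrame({
        "cell_line": sim.lineages.index,
        "latent_lfc": sim.truth["latent_lfc"].reindex(sim.lineages.index).to_numpy(),
        "planted_lineage": sim.truth["planted_lineage"],
        "planted_feature": sim.truth["planted_feature"],
        "r_true": sim.truth["r_true"],
    })
    write_table(truth, paths["truth"], header_lines=header)
    return paths


def write_mids_sim(measured: pd.DataFrame, truth: pd.DataFrame,
                   outdir: str | Path, params: dict | None = None) -> dict[str, Path]:
    outdir = Path(outdir)
    header = provenance_header(params=params or {})
    paths = {"mids": outdir / "mids.tsv", "truth": outdir / "truth.tsv"}
    write_table(measured, paths["mids"], header_lines=header)
    write_table(truth, paths["truth"], header_lines=header)
    return paths
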