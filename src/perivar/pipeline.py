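"""End-to-end assemblage analyses tying the stages together.

``run_pipeline`` executes the assemblage-appropriate chain
filter -> CV table -> [detrend -> outliers] -> mixed model -> permutation
-> ordination + hulls, persists every stage's output when an output
directory is configured, and records a machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .community import Hull, OrdinationResult, convex_hull, hull_overlap, pca
from .config import PipelineConfig
from .errors import DegenerateHullError, ValidationError
from .io import (
    ensure_dir,
    read_community_csv,
    read_design_csv,
    write_coef_table,
    write_community_csv,
    write_design_csv,
)
from .lmm import LmmFit, build_design_matrix, fit_reml, treatment_means
from .permutation import NullDistribution, PipelineSpec, null_summary, permute_and_refit
from .synthetic import (
    bacteria_params,
    build_design,
    diatom_params,
    simulate_bacterial_profiles,
    simulate_diatom_counts,
    simulate_taxon_targets,
)
from .variability import (
    DetrendFit,
    detrend_records,
    filter_by_prevalence,
    select_common_taxa,
    variability_table,
)

logger = logging.getLogger(__name__)


@dataclass
class ResultBundle:
    """Everything one assemblage analysis produced."""

    config: PipelineConfig
    design: pd.DataFrame
    community: pd.DataFrame
    taxa: list[str]
    records: pd.DataFrame
    detrend_fit: DetrendFit | None
    lmm_fit: LmmFit
    null: NullDistribution
    permutation_summary: pd.DataFrame
    ordination: OrdinationResult
    hulls: dict[str, Hull]
    overlaps: pd.DataFrame
    treatment_means: dict[str, float]
    timings: dict[str, float] = field(default_factory=dict)


def simulate_inputs(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Study-shaped synthetic inputs for the configured assemblage."""
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    s_design, s_targets, s_comm = (int(s.generate_state(1)[0] % 2**31) for s in seeds)
    if config.assemblage == "diatom":
        params = diatom_params(seed=config.seed)
        design = build_design(9 * params.n_slides_per_cell, s_design)
        targets = simulate_taxon_targets(params, s_targets)
        community = simulate_diatom_counts(design, targets, params, s_comm)
    else:
        params = bacteria_params(seed=config.seed)
        design = build_design(9 * params.n_slides_per_cell, s_design)
        community = simulate_bacterial_profiles(
            design, params, s_comm, detection_limit=config.detection_limit
        )
    return community, design


def load_inputs(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.community_path is None or config.design_path is None:
        return simulate_inputs(config)
    return read_community_csv(config.community_path), read_design_csv(config.design_path)


def drop_low_diversity_slides(
    community: pd.DataFrame, design: pd.DataFrame, n_drop: int
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Remove the ``n_drop`` slides with the lowest Shannon diversity.

    Mirrors the removal of anomalously low-diversity fingerprinting samples
    before the bacterial analyses (108 -> 106 in the study).
    """
    if n_drop <= 0:
        return community, design, []
    wide = community.pivot_table(
        index="slide_id", columns="taxon_id", values="abundance", fill_value=0.0
    )
    P = wide.to_numpy(dtype=float)
    totals = P.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, P / totals, 0.0)
        shannon = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    dropped = wide.index[np.argsort(shannon, kind="stable")[:n_drop]].tolist()
    keep_c = ~community["slide_id"].isin(dropped)
    keep_d = ~design["slide_id"].isin(dropped)
    logger.info("dropped %d low-diversity slide(s): %s", n_drop, dropped)
    return community.loc[keep_c].copy(), design.loc[keep_d].copy(), dropped


def relative_abundance_matrix(community: pd.DataFrame, taxa) -> pd.DataFrame:
    """Slides x taxa matrix closed to proportions over all taxa, then cut to
    the retained taxa (no re-closure after the cut)."""
    wide = community.pivot_table(
        index="slide_id", columns="taxon_id", values="abundance", fill_value=0.0
    ).sort_index()
    totals = wide.sum(axis=1)
    if (totals <= 0).any():
        raise ValidationError(f"all-zero slides: {wide.index[totals <= 0].tolist()}")
    return wide.div(totals, axis=0)[list(taxa)]


def ordination_analysis(
    community: pd.DataFrame, design: pd.DataFrame, taxa, reference: str = "AA"
) -> tuple[OrdinationResult, dict[str, Hull], pd.DataFrame]:
    """PCA of relative abundances plus per-treatment hulls in the PC1/PC2
    plane and overlap of every treatment polygon with the reference's."""
    M = relative_abundance_matrix(community, taxa)
    ord_res = pca(M)
    scores = ord_res.scores[["PC1", "PC2"]]
    tmap = design.set_index("slide_id")["treatment"]
    hulls: dict[str, Hull] = {}
    for t, idx in scores.groupby(tmap.reindex(scores.index)).groups.items():
        pts = scores.loc[idx].to_numpy()
        try:
            hulls[str(t)] = convex_hull(pts)
        except DegenerateHullError:
            logger.warning("degenerate hull for treatment %s; skipped", t)
    rows = []
    ref = hulls.get(reference)
    for t, h in sorted(hulls.items()):
        if ref is None or t == reference:
            continue
        rec = hull_overlap(ref, h)
        rows.append(
            {
                "treatment": t,
                "overlaps_reference": rec["overlaps"],
                "fraction_inside_reference": rec["fraction_of_b_points_inside_a"],
            }
        )
    return ord_res, hulls, pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the full assemblage analysis described by ``config``."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    community, design = load_inputs(config)
    community, design, dropped = drop_low_diversity_slides(
        community, design, config.n_drop_low_diversity
    )
    timings["inputs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.assemblage == "diatom":
        taxa = select_common_taxa(community, config.top_k_taxa)
    else:
        taxa = filter_by_prevalence(community, config.min_prevalence)
        if not taxa:
            raise ValidationError("prevalence filter removed every taxon")
    records = variability_table(community, design, taxa)
    detrend_fit = None
    if config.use_detrend:
        records, detrend_fit = detrend_records(records, config.outlier_sd)
    timings["variability"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    resp = config.response_column
    model_rows = records
    if resp == "residual" and config.drop_outliers:
        model_rows = records.loc[~records["outlier"]]
    y = model_rows[resp].to_numpy(dtype=float)
    X = build_design_matrix(model_rows["treatment"])
    fit = fit_reml(y, X, model_rows["taxon_id"].to_numpy())
    timings["lmm"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    perm_seed = int(np.random.SeedSequence(config.seed).spawn(5)[3].generate_state(1)[0] % 2**31)
    spec = PipelineSpec(
        assemblage=config.assemblage,
        detrend=config.detrend,
        outlier_sd=config.outlier_sd,
        drop_outliers=config.drop_outliers,
    )
    null = permute_and_refit(community, design, spec, taxa, config.n_perm, perm_seed)
    summary = null_summary(null)
    timings["permutation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    ord_res, hulls, overlaps = ordination_analysis(community, design, taxa)
    timings["ordination"] = time.perf_counter() - t0

    means = treatment_means(fit)
    bundle = ResultBundle(
        config=config,
        design=design,
        community=community,
        taxa=list(taxa),
        records=records,
        detrend_fit=detrend_fit,
        lmm_fit=fit,
        null=null,
        permutation_summary=summary,
        ordination=ord_res,
        hulls=hulls,
        overlaps=overlaps,
        treatment_means=means,
        timings=timings,
    )
    if config.out_dir is not None:
        persist_bundle(bundle, config.out_dir, dropped)
    return bundle


def persist_bundle(bundle: ResultBundle, out_dir, dropped=()) -> None:
    out = ensure_dir(out_dir)
    cfg = bundle.config
    cfg.to_yaml(out / "config.yaml")
    write_community_csv(bundle.community, out / "community.csv")
    write_design_csv(bundle.design, out / "design.csv")
    bundle.records.to_csv(out / "variability.csv", index=False)
    label = "Taxon" if cfg.assemblage == "diatom" else "OTU"
    write_coef_table(bundle.lmm_fit, out / "coefficients.csv", random_effect_label=label)
    bundle.null.replicates.to_csv(out / "null_distribution.csv", index=False)
    bundle.permutation_summary.to_csv(out / "permutation_summary.csv", index=False)
    bundle.ordination.scores.to_csv(out / "pca_scores.csv")
    bundle.ordination.loadings.to_csv(out / "pca_loadings.csv")
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(bundle.ordination.var_explained))],
            "var_explained_pct": bundle.ordination.var_explained,
        }
    ).to_csv(out / "pca_variance.csv", index=False)
    bundle.overlaps.to_csv(out / "hull_overlap.csv", index=False)
    pd.Series(bundle.treatment_means, name="fitted_mean").rename_axis("treatment").to_csv(
        out / "treatment_means.csv"
    )
    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "n_slides": int(bundle.design.shape[0]),
        "n_taxa_retained": len(bundle.taxa),
        "n_records": int(bundle.records.shape[0]),
        "n_perm_effective": int(bundle.null.replicates.shape[0]),
        "dropped_slides": list(dropped),
        "detrend": (
            None
            if bundle.detrend_fit is None
            else {
                "a": bundle.detrend_fit.a,
                "b": bundle.detrend_fit.b,
                "converged": bundle.detrend_fit.converged,
            }
        ),
        "sigma2_taxon": bundle.lmm_fit.sigma2_taxon,
        "sigma2_resid": bundle.lmm_fit.sigma2_resid,
        "timings_s": {k: round(v, 4) for k, v in bundle.timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
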