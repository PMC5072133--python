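"""Synthetic periphyton experiment generator.

Emulates the study design the analysis assumes: 108 Plexiglas slides in a
3x3 factorial of disturbance conditions (Ambient / Depth / Scoured at two
time points, 12 replicate slides per treatment), taxon abundances whose
within-treatment coefficients of variation respond additively on the
square-root scale to the disturbance indicators plus a per-taxon random
intercept, and relative-abundance (ARISA-style) profiles obtained by closing
latent absolute abundances per slide.

The target sqrt-CV of taxon *k* in treatment *t* is

    s[k, t] = clamp(beta0 + x_t' beta + a_k,  floor),   a_k ~ N(0, sigma_taxon^2),

with x_t the binary factorial predictor row of :mod:`perivar.lmm`.  Abundances
are Gamma with per-taxon mean mu_k (log-uniform) and CV equal to s[k, t]^2,
so the generative model is exactly the fitted model of the variability
analysis and parameter recovery is direct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import BalanceError, ValidationError
from .lmm import DESIGN_COLUMNS, TREATMENTS, build_design_matrix

logger = logging.getLogger(__name__)

CONDITIONS = ("A", "D", "S")

#: Diatom-anchored fixed effects on the sqrt-CV scale, in design-column order
#: (intercept; D@T1, S@T1, D@T2, S@T2; DxD, SxD, DxS, SxS interactions).
DIATOM_BETA = (1.251, -0.156, -0.155, -0.230, -0.158, 0.207, 0.102, 0.109, 0.217)

#: Bacteria-flavoured effects of comparable magnitude (mostly-null single
#: disturbances, negative same/mixed double-disturbance interactions).
BACTERIA_BETA = (0.90, -0.045, 0.057, 0.066, 0.028, -0.143, -0.228, 0.022, -0.176)


@dataclass(frozen=True)
class SimulationParams:
    """Generative truth for one assemblage.

    Attributes
    ----------
    n_taxa:
        Number of taxa/OTUs simulated.
    n_slides_per_cell:
        Replicate slides per treatment (12 in the study design).
    beta0, beta_main, beta_inter:
        Fixed effects on the sqrt-CV scale: intercept, the four main effects
        (D@T1, S@T1, D@T2, S@T2) and the four T1xT2 interactions
        (DxD, SxD, DxS, SxS).
    sigma_taxon:
        SD of the per-taxon random intercept a_k (sqrt-CV scale).
    sigma_resid:
        SD of cell-level noise used when drawing sqrt-CV responses directly
        from the mixed model (matches the sampling noise of a CV estimated
        from ~12 Gamma draws at study-like CV levels).
    taxon_mean_range:
        (low, high) bounds of the log-uniform per-taxon mean abundances.
    sqrtcv_floor:
        Lower clamp for target sqrt-CVs; keeps CVs physical when the random
        intercept pushes the linear predictor below zero.
    """

    n_taxa: int = 8
    n_slides_per_cell: int = 12
    beta0: float = 1.251
    beta_main: tuple[float, float, float, float] = (-0.156, -0.155, -0.230, -0.158)
    beta_inter: tuple[float, float, float, float] = (0.207, 0.102, 0.109, 0.217)
    sigma_taxon: float = float(np.sqrt(0.0240))
    sigma_resid: float = 0.13
    taxon_mean_range: tuple[float, float] = (10.0, 1000.0)
    sqrtcv_floor: float = 0.05
    distribution: str = "gamma"
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 1 or self.n_slides_per_cell < 1:
            raise ValidationError("n_taxa and n_slides_per_cell must be positive")
        if self.sqrtcv_floor <= 0:
            raise ValidationError("sqrtcv_floor must be > 0")
        if self.sigma_taxon < 0 or self.sigma_resid < 0:
            raise ValidationError("sigma_taxon and sigma_resid must be >= 0")
        lo, hi = self.taxon_mean_range
        if not (0 < lo <= hi):
            raise ValidationError("taxon_mean_range must satisfy 0 < low <= high")
        if len(self.beta_main) != 4 or len(self.beta_inter) != 4:
            raise ValidationError("beta_main and beta_inter must each have 4 entries")
        if self.distribution not in ("gamma", "lognormal"):
            raise ValidationError("distribution must be 'gamma' or 'lognormal'")

    @property
    def beta(self) -> np.ndarray:
        """Full 9-vector of fixed effects in design-column order."""
        return np.array((self.beta0, *self.beta_main, *self.beta_inter), dtype=float)


def diatom_params(**overrides) -> SimulationParams:
    """Diatom-shaped defaults: 8 taxa, Table-scale effects, counts per cm^2."""
    base = SimulationParams(
        n_taxa=8,
        beta0=DIATOM_BETA[0],
        beta_main=tuple(DIATOM_BETA[1:5]),
        beta_inter=tuple(DIATOM_BETA[5:9]),
        sigma_taxon=float(np.sqrt(0.0240)),
        taxon_mean_range=(10.0, 1000.0),
    )
    return replace(base, **overrides) if overrides else base


def bacteria_params(**overrides) -> SimulationParams:
    """ARISA-shaped defaults: many OTUs, wide latent mean range (3 decades)."""
    base = SimulationParams(
        n_taxa=150,
        beta0=BACTERIA_BETA[0],
        beta_main=tuple(BACTERIA_BETA[1:5]),
        beta_inter=tuple(BACTERIA_BETA[5:9]),
        sigma_taxon=float(np.sqrt(0.0459)),
        taxon_mean_range=(1.0, 1000.0),
    )
    return replace(base, **overrides) if overrides else base


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-stage random streams from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _taxon_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"T{i + 1:0{width}d}" for i in range(n)]


def build_design(n_slides: int, seed: int) -> pd.DataFrame:
    """Randomized, exactly balanced 3x3 factorial design table.

    Slides are assigned uniformly at random subject to exact balance:
    n/3 per T1 condition and, stratified within each T1 group, n/9 per T2
    condition, so every treatment cell holds n/9 slides (12 of 108 in the
    study layout).

    Returns a DataFrame with columns slide_id, t1, t2, treatment.
    """
    if n_slides % 9 != 0 or n_slides <= 0:
        raise BalanceError(f"n_slides must be a positive multiple of 9, got {n_slides}")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_slides)))
    slides = np.array([f"S{i + 1:0{width}d}" for i in range(n_slides)])
    per_t1 = n_slides // 3
    per_cell = n_slides // 9
    t1 = np.empty(n_slides, dtype="U1")
    t2 = np.empty(n_slides, dtype="U1")
    perm = rng.permutation(n_slides)
    for g, cond in enumerate(CONDITIONS):
        t1[perm[g * per_t1 : (g + 1) * per_t1]] = cond
    for cond in CONDITIONS:
        idx = np.flatnonzero(t1 == cond)
        sub = rng.permutation(idx)
        for g, cond2 in enumerate(CONDITIONS):
            t2[sub[g * per_cell : (g + 1) * per_cell]] = cond2
    df = pd.DataFrame({"slide_id": slides, "t1": t1, "t2": t2})
    df["treatment"] = df["t1"] + df["t2"]
    return df


def simulate_taxon_targets(params: SimulationParams, seed: int) -> pd.DataFrame:
    """Target sqrt-CV matrix (taxa x 9 treatments) from the generative model."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, params.sigma_taxon, size=params.n_taxa)
    X9 = build_design_matrix(TREATMENTS).to_numpy()
    lin = X9 @ params.beta  # per-treatment linear predictor
    s = np.maximum(lin[None, :] + a[:, None], params.sqrtcv_floor)
    return pd.DataFrame(s, index=_taxon_ids(params.n_taxa), columns=list(TREATMENTS))


def _draw_abundances(rng, mu, cv, size, distribution="gamma"):
    """Draws with mean mu and coefficient of variation cv (elementwise)."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    cv = np.broadcast_to(np.asarray(cv, dtype=float), size)
    if np.any(mu <= 0):
        raise ValidationError("taxon mean abundances must be positive")
    out = np.empty(size, dtype=float)
    tiny = cv < 1e-8  # Gamma shape would overflow; CV this small is deterministic to 1e-8
    if distribution == "gamma":
        shape = 1.0 / np.square(cv, where=~tiny, out=np.ones_like(cv))
        scale = mu * np.square(cv)
        ok = ~tiny
        out[ok] = rng.gamma(shape[ok], scale[ok])
    else:  # lognormal with matching mean and CV
        sig2 = np.log1p(np.square(cv))
        ok = ~tiny
        out[ok] = rng.lognormal((np.log(mu) - sig2 / 2.0)[ok], np.sqrt(sig2)[ok])
    out[tiny] = mu[tiny] * (1.0 + cv[tiny] * rng.standard_normal(size)[tiny])
    return np.maximum(out, 0.0)


def _latent_matrix(design: pd.DataFrame, targets: pd.DataFrame, params: SimulationParams, seed: int):
    """Slides x taxa latent abundance matrix; returns (matrix, taxa, mu)."""
    missing = sorted(set(design["treatment"]) - set(targets.columns))
    if missing:
        raise ValidationError(f"targets missing treatments {missing}")
    rng_mu, rng_ab = _spawn(seed, 2)
    taxa = list(targets.index)
    lo, hi = params.taxon_mean_range
    mu = np.exp(rng_mu.uniform(np.log(lo), np.log(hi), size=len(taxa)))
    cv_by_treatment = targets.to_numpy() ** 2  # CV = (sqrt-CV)^2
    tcodes = pd.Categorical(design["treatment"], categories=list(targets.columns)).codes
    cv = cv_by_treatment[:, tcodes].T  # slides x taxa
    mat = _draw_abundances(
        rng_ab, mu[None, :], cv, (len(design), len(taxa)), params.distribution
    )
    return mat, taxa, mu


def _to_long(mat, design, taxa, assemblage) -> pd.DataFrame:
    df = pd.DataFrame(mat, index=design["slide_id"].to_numpy(), columns=taxa)
    long = df.stack().rename("abundance").reset_index()
    long.columns = ["slide_id", "taxon_id", "abundance"]
    long.attrs["assemblage"] = assemblage
    return long


def simulate_diatom_counts(
    design: pd.DataFrame, targets: pd.DataFrame, params: SimulationParams, seed: int
) -> pd.DataFrame:
    """Long community table of per-cm^2 densities for the counted assemblage.

    Each (slide, taxon) abundance is Gamma with the taxon's log-uniform mean
    and the treatment-specific CV implied by ``targets``; independent across
    slides and taxa, deterministic given ``seed``.
    """
    mat, taxa, _ = _latent_matrix(design, targets, params, seed)
    return _to_long(mat, design, taxa, "diatom_density")


def simulate_bacterial_profiles(
    design: pd.DataFrame,
    params: SimulationParams,
    seed: int,
    detection_limit: float = 0.0,
) -> pd.DataFrame:
    """Closed (relative-abundance) profiles emulating normalized ARISA peaks.

    Latent absolute abundances are simulated as for the counts over a wide
    mean range, then divided by the slide total so each slide sums to one.
    ``detection_limit`` optionally zeroes proportions below a threshold
    (followed by re-closure), to exercise the prevalence filter downstream.
    """
    if params.n_taxa < 2:
        raise ValidationError("need at least 2 taxa to form proportions")
    seed_t, seed_l, seed_r = np.random.SeedSequence(seed).spawn(3)
    targets = simulate_taxon_targets(params, seed_t)
    mat, taxa, mu = _latent_matrix(design, targets, params, int(seed_l.generate_state(1)[0] % 2**31))
    totals = mat.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:  # resample degenerate slides (possible only at extreme CVs)
        logger.warning("resampling %d slide(s) with zero total abundance", bad.size)
        rng = np.random.default_rng(seed_r)
        for i in bad:
            while mat[i].sum() <= 0:
                cv = (targets[design["treatment"].iloc[i]].to_numpy()) ** 2
                mat[i] = _draw_abundances(rng, mu, cv, (len(taxa),), params.distribution)
        totals = mat.sum(axis=1)
    prop = mat / totals[:, None]
    if detection_limit > 0:
        prop[prop < detection_limit] = 0.0
        tot = prop.sum(axis=1)
        if np.any(tot <= 0):
            raise ValidationError("detection_limit zeroed out entire slides")
        prop = prop / tot[:, None]
    return _to_long(prop, design, taxa, "relative_abundance")


def simulate_sqrtcv_table(params: SimulationParams, seed: int) -> pd.DataFrame:
    """Draw one sqrt-CV response per (taxon, treatment) directly from the model.

    Returns a DataFrame (taxon_id, treatment, response) where response =
    target sqrt-CV + N(0, sigma_resid^2).  This is the correctly-specified
    simulation for calibration of the mixed-model Wald intervals: the
    alternative route through finite-replicate abundance sampling estimates
    CVs with a small-sample bias (see the methods note), so the generative
    fixed effects are only the estimand of this direct draw.
    """
    seed_t, seed_e = np.random.SeedSequence(seed).spawn(2)
    targets = simulate_taxon_targets(params, seed_t)
    rng = np.random.default_rng(seed_e)
    noise = rng.normal(0.0, params.sigma_resid, size=targets.shape)
    long = (targets + noise).stack().rename("response").reset_index()
    long.columns = ["taxon_id", "treatment", "response"]
    return long
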