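"""Why closing (relativizing) abundance data induces a CV-mean relationship.

Even when every taxon has the same coefficient of variation on the latent
absolute scale, dividing by the per-sample total makes abundant taxa look
*less* variable: a taxon's proportion competes against the summed noise of
the rest of the community, and the larger its share, the more its own
fluctuations cancel out of the ratio.  This module demonstrates the effect by
simulation and provides a first-order delta-method approximation for the CV
of a closed proportion, validated against the simulation.

For independent latent abundances with common CV ``c`` and a focal taxon
with mean share ``q`` of the total (remaining taxa with equal shares),

    CV(p)^2  ~=  c^2 * [ (1 - q)^2  +  sum_{j != focal} s_j^2 ]
             =   c^2 * (1 - q)^2 * (1 + 1/(n_taxa - 1)),

which tends to ``c`` for a rare taxon in a diverse community and to 0 as the
focal taxon dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic import SimulationParams, _draw_abundances


@dataclass
class ScalingCurve:
    """Per-taxon empirical and approximate proportion CVs from one simulation."""

    table: pd.DataFrame  # taxon_id, mean_abundance, mean_proportion, empirical_cv, approx_cv
    n_taxa: int
    n_samples: int
    latent_cv: float
    seed: int


def simulate_proportion_cvs(
    n_taxa: int,
    n_samples: int,
    latent_cv: float,
    mean_spread_decades: float = 3.0,
    seed: int = 0,
    mean_abundances=None,
) -> ScalingCurve:
    """Empirical CVs of closed proportions under a common latent CV.

    Latent abundances are i.i.d. Gamma per taxon with CV ``latent_cv`` and
    means log-uniformly spread over ``mean_spread_decades`` (or given
    explicitly via ``mean_abundances``, e.g. to place a focal taxon at a
    chosen mean share); each sample is closed to proportions and the CV of
    each taxon's proportion is computed across samples.
    """
    if n_taxa < 2:
        raise ValidationError("need at least 2 taxa")
    if n_samples < 10:
        raise ValidationError("need at least 10 samples")
    if latent_cv <= 0:
        raise ValidationError("latent_cv must be > 0")
    rng_mu, rng_ab = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    ]
    if mean_abundances is None:
        mu = np.exp(rng_mu.uniform(0.0, mean_spread_decades * np.log(10.0), size=n_taxa))
    else:
        mu = np.asarray(mean_abundances, dtype=float)
        if mu.size != n_taxa or np.any(mu <= 0):
            raise ValidationError("mean_abundances must be n_taxa positive values")
    lat = _draw_abundances(
        rng_ab, mu[None, :], np.full((n_samples, n_taxa), latent_cv), (n_samples, n_taxa)
    )
    totals = lat.sum(axis=1)
    if np.any(totals <= 0):  # effectively impossible for Gamma draws
        raise ValidationError("a sample closed to zero total")
    prop = lat / totals[:, None]
    emp_cv = prop.std(axis=0, ddof=1) / prop.mean(axis=0)
    q = mu / mu.sum()
    approx = np.array([approx_proportion_cv(qi, latent_cv, n_taxa) for qi in q])
    width = max(2, len(str(n_taxa)))
    table = pd.DataFrame(
        {
            "taxon_id": [f"T{i + 1:0{width}d}" for i in range(n_taxa)],
            "mean_abundance": mu,
            "mean_proportion": prop.mean(axis=0),
            "empirical_cv": emp_cv,
            "approx_cv": approx,
        }
    )
    return ScalingCurve(
        table=table, n_taxa=n_taxa, n_samples=n_samples, latent_cv=latent_cv, seed=seed
    )


def approx_proportion_cv(mean_proportion: float, latent_cv: float, n_taxa: int) -> float:
    """Delta-method CV of a closed proportion with equal-share background.

    Limits: -> latent_cv as mean_proportion -> 0 (in a diverse community,
    where the background share correction 1/(n_taxa-1) vanishes) and -> 0 as
    mean_proportion -> 1.  Decreasing in mean_proportion.
    """
    if not (0.0 < mean_proportion < 1.0):
        raise ValidationError(f"mean_proportion must be in (0, 1), got {mean_proportion}")
    if latent_cv <= 0:
        raise ValidationError("latent_cv must be > 0")
    if n_taxa < 2:
        raise ValidationError("n_taxa must be >= 2")
    q = float(mean_proportion)
    return float(latent_cv * (1.0 - q) * np.sqrt(1.0 + 1.0 / (n_taxa - 1)))


def plot_scaling_curve(curve: ScalingCurve, path=None):
    """Empirical vs approximate proportion CVs against mean proportion (log x)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = curve.table.sort_values("mean_proportion")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(tab["mean_proportion"], tab["empirical_cv"], s=12, label="simulated")
    ax.plot(tab["mean_proportion"], tab["approx_cv"], color="C3", label="delta-method")
    ax.set_xscale("log")
    ax.set_xlabel("mean proportion")
    ax.set_ylabel("CV of proportion")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
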