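"""Taxon-level variability statistics per treatment.

Computes the coefficient of variation of each taxon's abundance across the
replicate slides of each treatment, the square-root transform used as the
modelling response, taxon selection/prevalence filters, negative-exponential
detrending of CVs against log mean abundance (the relativization artifact
seen in closed data), and outlier flagging on the detrend residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    FitError,
    InsufficientReplicatesError,
    SelectionError,
    UndefinedCVError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Columns of a variability-record table.
RECORD_COLUMNS = (
    "taxon_id",
    "treatment",
    "n_slides",
    "mean_abundance",
    "cv",
    "sqrt_cv",
    "residual",
    "outlier",
)


def coefficient_of_variation(values) -> float:
    """Sample CV: standard deviation (n-1 denominator) over the sample mean.

    Requires at least two values and a strictly positive mean; scale
    invariant (CV(c*x) = CV(x) for c > 0).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientReplicatesError(f"need >= 2 values for a CV, got {x.size}")
    m = x.mean()
    if m <= 0:
        raise UndefinedCVError(f"CV undefined for mean {m}")
    return float(x.std(ddof=1) / m)


def select_common_taxa(table: pd.DataFrame, k: int) -> list[str]:
    """The k taxa with the largest total abundance over all slides.

    Ties are broken by lexical taxon_id order, so the selection is
    deterministic.  The study's diatom analysis keeps the 8 most common taxa.
    """
    if table.empty:
        raise ValidationError("community table is empty")
    totals = table.groupby("taxon_id")["abundance"].sum()
    if k > totals.size:
        raise SelectionError(f"asked for {k} taxa but table has {totals.size}")
    ranked = totals.reset_index().sort_values(
        ["abundance", "taxon_id"], ascending=[False, True], kind="stable"
    )
    return ranked["taxon_id"].head(k).tolist()


def filter_by_prevalence(table: pd.DataFrame, min_samples: int) -> list[str]:
    """Taxa present (abundance strictly > 0) in at least ``min_samples`` slides."""
    if min_samples < 1:
        raise ValidationError("min_samples must be >= 1")
    present = table.loc[table["abundance"] > 0].groupby("taxon_id")["slide_id"].nunique()
    return sorted(present.index[present >= min_samples])


def prevalence_scan(table: pd.DataFrame, cutoffs) -> dict[int, list[str]]:
    """Per-cutoff taxon lists for a robustness scan over prevalence thresholds."""
    present = table.loc[table["abundance"] > 0].groupby("taxon_id")["slide_id"].nunique()
    return {int(c): sorted(present.index[present >= int(c)]) for c in cutoffs}


def variability_table(
    table: pd.DataFrame, design: pd.DataFrame, taxa
) -> pd.DataFrame:
    """One variability record per (taxon, treatment).

    Missing (slide, taxon) pairs count as abundance zero: each slide is a
    census of its community.  Returns a DataFrame with
    :data:`RECORD_COLUMNS`; ``residual`` is NaN and ``outlier`` False until
    detrending.  Rows are sorted by (taxon_id, treatment), so the output is
    invariant to the row order of the input table.
    """
    taxa = list(taxa)
    slides_in_design = set(design["slide_id"])
    stray = set(table["slide_id"]) - slides_in_design
    if stray:
        raise ValidationError(f"slides not in design: {sorted(stray)[:5]}...")
    missing_taxa = set(taxa) - set(table["taxon_id"])
    if missing_taxa:
        raise ValidationError(f"taxa not in table: {sorted(missing_taxa)}")
    wide = (
        table.pivot_table(index="slide_id", columns="taxon_id", values="abundance", fill_value=0.0)
        .reindex(index=sorted(slides_in_design), columns=taxa, fill_value=0.0)
    )
    tmap = design.set_index("slide_id")["treatment"]
    counts = tmap.value_counts()
    thin = counts[counts < 2]
    if not thin.empty:
        raise InsufficientReplicatesError(
            f"treatments with < 2 slides: {sorted(thin.index)}"
        )
    grp = wide.groupby(tmap.reindex(wide.index))
    means = grp.mean()
    sds = grp.std(ddof=1)
    ns = grp.size()
    if (means.to_numpy() <= 0).any():
        zero = [
            (tx, tr)
            for tr in means.index
            for tx in means.columns
            if means.loc[tr, tx] <= 0
        ]
        raise UndefinedCVError(f"zero mean abundance in cells {zero[:5]}...")
    cv = sds / means
    rec = pd.DataFrame(
        {
            "taxon_id": np.repeat(taxa, means.shape[0]),
            "treatment": np.tile(means.index.to_numpy(), len(taxa)),
            "n_slides": np.tile(ns.to_numpy(), len(taxa)),
            "mean_abundance": means.to_numpy().T.ravel(),
            "cv": cv.to_numpy().T.ravel(),
        }
    )
    rec["sqrt_cv"] = np.sqrt(rec["cv"])
    rec["residual"] = np.nan
    rec["outlier"] = False
    return rec.sort_values(["taxon_id", "treatment"], kind="stable", ignore_index=True)


@dataclass
class DetrendFit:
    """Fitted negative-exponential trend cv = a*exp(b*x) of CV on log mean."""

    a: float
    b: float
    c: float  # additive offset; 0.0 for the default two-parameter form
    converged: bool
    residuals: np.ndarray
    outlier_sd_threshold: float = 3.0
    model: str = "exponential"

    def predict(self, x) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(x, dtype=float)) + self.c


def fit_detrend(records: pd.DataFrame, offset: bool = False, max_restarts: int = 5) -> DetrendFit:
    """Fit cv = a*exp(b*x) (+ c with ``offset``), x = log(mean_abundance).

    Nonlinear least squares initialized from an OLS fit of log(cv + 1e-9) on
    x (the epsilon guards the log of exact-zero CVs and is never part of the
    objective).  On repeated non-convergence the log-linear initialization
    itself is returned with ``converged=False`` and a warning.

    Residuals (cv - fitted) are aligned to the input row order.
    """
    if len(records) < 3:
        raise ValidationError(f"need >= 3 records to detrend, got {len(records)}")
    if not np.all(records["mean_abundance"].to_numpy() > 0):
        raise ValidationError("all mean abundances must be > 0 for detrending")
    x = np.log(records["mean_abundance"].to_numpy(dtype=float))
    y = records["cv"].to_numpy(dtype=float)
    a, b, c, ok = _fit_exp_arrays(x, y, offset=offset, max_restarts=max_restarts)
    if a <= 0 and ok:
        raise FitError(f"detrend amplitude a={a} <= 0; curve not positive")
    resid = y - (a * np.exp(b * x) + c)
    return DetrendFit(a=a, b=b, c=c, converged=ok, residuals=resid)


def _fit_exp_arrays(
    x: np.ndarray, y: np.ndarray, offset: bool = False, max_restarts: int = 5
) -> tuple[float, float, float, bool]:
    """NLS core for the exponential trend on plain arrays; returns (a, b, c, converged)."""
    slope, icept = np.polyfit(x, np.log(y + 1e-9), 1)
    p0 = [float(np.exp(icept)), float(slope)] + ([0.0] if offset else [])
    if offset:
        fun = lambda x_, a, b, c: a * np.exp(b * x_) + c  # noqa: E731
    else:
        fun = lambda x_, a, b: a * np.exp(b * x_)  # noqa: E731
    rng = np.random.default_rng(0)
    p, ok = None, False
    guess = list(p0)
    for _attempt in range(max_restarts):
        try:
            p, _ = curve_fit(fun, x, y, p0=guess, maxfev=20000)
            ok = True
            break
        except (RuntimeError, ValueError):
            jitter = rng.normal(0, 0.2, size=len(p0))
            guess = [g * (1 + j) + 0.01 * j for g, j in zip(p0, jitter)]
    if not ok:
        logger.warning("detrend NLS failed after %d restarts; using log-linear fit", max_restarts)
        p = p0
    a, b = float(p[0]), float(p[1])
    c = float(p[2]) if offset else 0.0
    return a, b, c, ok


def flag_outliers(residuals, sd_threshold: float = 3.0) -> np.ndarray:
    """Boolean mask of residuals beyond ``sd_threshold`` SDs from their mean.

    A single pass (not iterated); invariant to adding a constant to all
    residuals.  The study removed 6 OTU records beyond 3 SD before modelling.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 2:
        raise ValidationError("need >= 2 residuals to flag outliers")
    sd = r.std(ddof=1)
    if sd == 0:
        return np.zeros(r.size, dtype=bool)
    return np.abs(r - r.mean()) > sd_threshold * sd


def detrend_records(
    records: pd.DataFrame, sd_threshold: float = 3.0, offset: bool = False
) -> tuple[pd.DataFrame, DetrendFit]:
    """Convenience: fit the trend, fill residual/outlier columns, return both."""
    fit = fit_detrend(records, offset=offset)
    out = records.copy()
    out["residual"] = fit.residuals
    out["outlier"] = flag_outliers(fit.residuals, sd_threshold)
    return out, fit
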