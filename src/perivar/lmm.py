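"""Random-intercept linear mixed model for the factorial disturbance design.

The model for the response :math:`y_{kt}` of taxon *k* in treatment *t* is

.. math::

    y_{kt} = \\beta_0 + \\beta_{D1} X_{D1,t} + \\beta_{S1} X_{S1,t}
             + \\beta_{D2} X_{D2,t} + \\beta_{S2} X_{S2,t}
             + \\text{(four T1}\\times\\text{T2 interactions)}
             + \\alpha_k + \\varepsilon_{kt},

with :math:`\\alpha_k \\sim N(0, \\sigma^2_{taxon})` a random intercept per
taxon and :math:`\\varepsilon_{kt} \\sim N(0, \\sigma^2)` residual noise.  The
binary predictors indicate whether the treatment received the depth (D) or
scouring (S) disturbance at the first or second time point; within-time
products (e.g. D and S both at T1) are structurally zero and excluded, so the
nine columns form a saturated reparameterization of the nine treatment cells.

Estimation profiles the restricted likelihood over the single variance ratio
:math:`\\lambda = \\sigma^2_{taxon}/\\sigma^2` on the log scale, with an
explicit check of the :math:`\\lambda = 0` boundary.  Because the random
effect is a single grouping factor, :math:`V(\\lambda) = I + \\lambda Z Z^T`
is block diagonal and all linear algebra is done blockwise in closed form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DesignMatrixError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical treatment codes: first letter = condition at T1, second at T2.
TREATMENTS: tuple[str, ...] = ("AA", "AD", "AS", "DA", "DD", "DS", "SA", "SD", "SS")

#: Fixed-effect column names, in model order.
DESIGN_COLUMNS: tuple[str, ...] = (
    "Intercept",
    "T1D",
    "T1S",
    "T2D",
    "T2S",
    "T1D:T2D",
    "T1S:T2D",
    "T1D:T2S",
    "T1S:T2S",
)

_LOG_LAMBDA_BOUNDS = (-10.0, 10.0)


def build_design_matrix(treatments) -> pd.DataFrame:
    """Binary factorial design matrix for a sequence of treatment codes.

    Parameters
    ----------
    treatments
        Iterable of two-letter codes drawn from :data:`TREATMENTS`.

    Returns
    -------
    pandas.DataFrame
        One row per input code with the nine 0/1 columns of
        :data:`DESIGN_COLUMNS`; interactions are products of the T1 and T2
        main-effect indicators.
    """
    treatments = list(treatments)
    valid = set(TREATMENTS)
    bad = sorted({t for t in treatments if t not in valid})
    if bad:
        raise DesignMatrixError(f"invalid treatment code(s): {bad}; expected one of {sorted(valid)}")
    rows = np.zeros((len(treatments), 9), dtype=float)
    for i, code in enumerate(treatments):
        t1, t2 = code[0], code[1]
        d1, s1 = float(t1 == "D"), float(t1 == "S")
        d2, s2 = float(t2 == "D"), float(t2 == "S")
        rows[i] = (1.0, d1, s1, d2, s2, d1 * d2, s1 * d2, d1 * s2, s1 * s2)
    return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))


@dataclass
class LmmFit:
    """Result of a profiled-REML random-intercept fit."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    p_wald: np.ndarray
    sigma2_taxon: float
    sigma2_resid: float
    lambda_: float
    reml_loglik: float
    taxon_effects: pd.Series
    n_obs: int
    n_groups: int
    at_boundary: bool = False
    fitted: np.ndarray = field(default=None, repr=False)

    def coef_table(self) -> pd.DataFrame:
        """Coefficient table (term, estimate, se, p_value), one row per fixed effect."""
        return pd.DataFrame(
            {"term": self.terms, "estimate": self.beta, "se": self.se, "p_value": self.p_wald}
        )

    def confint(self, level: float = 0.95) -> pd.DataFrame:
        """Two-sided normal-approximation confidence intervals for the fixed effects."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {"term": self.terms, "lower": self.beta - z * self.se, "upper": self.beta + z * self.se}
        )


def _reml_eval(lam: float, y, X, sizes, starts):
    """Profiled REML pieces at a fixed variance ratio lam.

    Rows must be sorted so each group occupies a contiguous block; ``starts``
    are the block offsets and ``sizes`` the block lengths.
    """
    n, p = X.shape
    # V^-1 x = x - (lam/(1+lam*n_k)) * 1 * sum_k(x)
    shrink = np.repeat(lam / (1.0 + lam * sizes), sizes)
    sum_y = np.add.reduceat(y, starts)
    Viy = y - shrink * np.repeat(sum_y, sizes)
    sum_X = np.add.reduceat(X, starts, axis=0)
    ViX = X - shrink[:, None] * np.repeat(sum_X, sizes, axis=0)
    XtViX = X.T @ ViX
    try:
        L = np.linalg.cholesky(XtViX)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
        raise DesignMatrixError("X'V^-1X not positive definite") from exc
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    r = y - X @ beta
    sum_r = np.add.reduceat(r, starts)
    Vir = r - shrink * np.repeat(sum_r, sizes)
    q = float(r @ Vir)
    sigma2 = max(q / (n - p), 1e-300)
    logdet_V = float(np.sum(np.log1p(lam * sizes)))
    logdet_XtViX = 2.0 * float(np.sum(np.log(np.diag(L))))
    neg2 = (n - p) * (math.log(2.0 * math.pi * sigma2) + 1.0) + logdet_V + logdet_XtViX
    return neg2, beta, XtViX, sigma2, Vir


def fit_reml(y, X, groups) -> LmmFit:
    """Fit the random-intercept model by REML profiled over log(lambda).

    Parameters
    ----------
    y
        Response vector (e.g. sqrt CV per taxon-treatment record, or
        detrended CV residuals).
    X
        Factorial design matrix aligned to ``y`` (DataFrame from
        :func:`build_design_matrix` or an array; must be full column rank).
    groups
        Taxon/OTU label per row; the random intercept is shared within a
        label.

    Returns
    -------
    LmmFit
        Fixed effects with Wald standard errors and two-sided normal p-values
        (the intercept's p-value is reported as NaN, mirroring the
        coefficient tables' NA), variance components, the profiled REML
        log-likelihood, and best linear unbiased predictions of the
        per-taxon intercepts.
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        terms = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    glab = np.asarray(groups)
    n, p = Xa.shape
    if ya.shape[0] != n or glab.shape[0] != n:
        raise ValidationError(
            f"length mismatch: y has {ya.shape[0]}, X has {n}, groups has {glab.shape[0]} rows"
        )
    labels, codes = np.unique(glab, return_inverse=True)
    if labels.size < 2:
        raise ValidationError("need at least 2 groups for a random intercept")
    rank = np.linalg.matrix_rank(Xa)
    if rank < p:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(Xa, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(n, p) * np.finfo(float).eps
        collinear = [terms[j] for j in piv[diag < tol]] or [terms[j] for j in piv[rank:]]
        raise DesignMatrixError(f"design matrix rank {rank} < {p}; collinear columns: {collinear}")

    order = np.argsort(codes, kind="stable")
    ys, Xs, cs = ya[order], Xa[order], codes[order]
    sizes = np.bincount(cs)
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))

    def neg2_of_u(u: float) -> float:
        return _reml_eval(math.exp(u), ys, Xs, sizes, starts)[0]

    lo, hi = _LOG_LAMBDA_BOUNDS
    grid = np.linspace(lo, hi, 25)
    vals = [neg2_of_u(u) for u in grid]
    j = int(np.argmin(vals))
    a, b = grid[max(j - 1, 0)], grid[min(j + 1, grid.size - 1)]
    res = optimize.minimize_scalar(neg2_of_u, bounds=(a, b), method="bounded", options={"xatol": 1e-9})
    lam = math.exp(res.x)
    neg2 = res.fun
    # lambda = 0 boundary (pure fixed-effects model)
    neg2_zero = _reml_eval(0.0, ys, Xs, sizes, starts)[0]
    at_boundary = neg2_zero <= neg2
    if at_boundary:
        lam, neg2 = 0.0, neg2_zero
    _, beta, XtViX, sigma2, Vir = _reml_eval(lam, ys, Xs, sizes, starts)
    cov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p_wald = 2.0 * stats.norm.sf(np.abs(z))
    if "Intercept" in terms:
        p_wald = p_wald.copy()
        p_wald[terms.index("Intercept")] = np.nan
    blup = lam * np.add.reduceat(Vir, starts)
    fitted_sorted = Xs @ beta + blup[cs]
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return LmmFit(
        terms=terms,
        beta=beta,
        se=se,
        p_wald=p_wald,
        sigma2_taxon=lam * sigma2,
        sigma2_resid=sigma2,
        lambda_=lam,
        reml_loglik=-0.5 * neg2,
        taxon_effects=pd.Series(blup, index=labels, name="taxon_effect"),
        n_obs=n,
        n_groups=labels.size,
        at_boundary=at_boundary,
        fitted=fitted,
    )


def treatment_means(fit: LmmFit) -> dict[str, float]:
    """Fitted mean response per treatment (random effect at zero).

    With the printed diatom coefficients this reproduces e.g.
    DA = 1.251 - 0.156 = 1.095 and DD = 1.251 - 0.156 - 0.230 + 0.207 = 1.072.
    """
    X9 = build_design_matrix(TREATMENTS)
    vals = X9.to_numpy() @ np.asarray(fit.beta, dtype=float)
    return dict(zip(TREATMENTS, (float(v) for v in vals)))


def quadrant_classification(means_x: dict, means_y: dict) -> dict[str, str]:
    """Classify treatments into quadrants around the grand means of two axes.

    Quadrant I = above both grand means (most variable), II = below x but
    above y, III = below both (least variable), IV = above x but below y.
    Exact ties go to the "above" side and are logged.
    """
    if set(means_x) != set(means_y):
        raise ValidationError(
            f"axis key mismatch: {sorted(set(means_x) ^ set(means_y))}"
        )
    gx = float(np.mean(list(means_x.values())))
    gy = float(np.mean(list(means_y.values())))
    out: dict[str, str] = {}
    for t in means_x:
        x, y = means_x[t], means_y[t]
        if x == gx or y == gy:
            logger.info("treatment %s ties a grand mean; assigned to the 'above' side", t)
        above_x, above_y = x >= gx, y >= gy
        if above_x and above_y:
            out[t] = "I"
        elif not above_x and above_y:
            out[t] = "II"
        elif not above_x and not above_y:
            out[t] = "III"
        else:
            out[t] = "IV"
    return out
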