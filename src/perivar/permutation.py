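"""Permutation null distributions for the mixed-model coefficients.

Treatment labels are shuffled across slides (slides keep their abundance
profiles), the whole CV -> [detrend -> outlier] -> mixed-model pipeline is
recomputed per replicate, and each coefficient's replicate estimates form its
null distribution.  The pseudo-P of a coefficient is the fraction of the null
that falls below (or beyond, for the other alternatives) the observed
estimate; an add-one-corrected variant (count+1)/(n_perm+1) is reported
alongside.

Slides are the exchangeable unit: under the null of no disturbance effect a
slide's community is independent of its treatment label, and permuting whole
slides preserves the within-slide dependence between taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PerivarError, UndefinedCVError, ValidationError
from .lmm import DESIGN_COLUMNS, TREATMENTS, build_design_matrix, fit_reml
from .variability import _fit_exp_arrays, flag_outliers


@dataclass(frozen=True)
class PipelineSpec:
    """Which assemblage-specific chain a permutation replicate recomputes.

    ``assemblage='diatom'`` models sqrt CV directly; ``'bacteria'`` detrends
    the CVs against log mean abundance first and models the residuals with
    the flagged outliers excluded (``drop_outliers=False`` keeps them).
    Taxon filtering is applied before entry: it depends only on the slide
    profiles, not the labels, so it is permutation invariant.
    """

    assemblage: str = "diatom"
    detrend: bool | None = None
    outlier_sd: float = 3.0
    drop_outliers: bool = True

    def __post_init__(self):
        if self.assemblage not in ("diatom", "bacteria"):
            raise ValidationError("assemblage must be 'diatom' or 'bacteria'")

    @property
    def use_detrend(self) -> bool:
        return self.assemblage == "bacteria" if self.detrend is None else self.detrend


@dataclass
class NullDistribution:
    """Replicate coefficient estimates plus the observed fit."""

    replicates: pd.DataFrame  # n_effective x 9 coefficients
    observed: pd.Series
    n_perm: int
    seed: int
    n_failed: int = 0

    @property
    def coefficients(self) -> list[str]:
        return list(self.replicates.columns)


@dataclass(frozen=True)
class PseudoP:
    p: float
    p_add_one: float
    alternative: str
    n_perm: int


def _wide_matrix(community: pd.DataFrame, design: pd.DataFrame, taxa) -> np.ndarray:
    slides = design["slide_id"].tolist()
    wide = (
        community.pivot_table(
            index="slide_id", columns="taxon_id", values="abundance", fill_value=0.0
        )
        .reindex(index=slides, columns=list(taxa), fill_value=0.0)
    )
    return wide.to_numpy(dtype=float)


def _pipeline_coefficients(
    mat: np.ndarray, tcodes: np.ndarray, spec: PipelineSpec
) -> np.ndarray:
    """Coefficient vector of the assemblage pipeline on a slides x taxa matrix.

    ``tcodes`` are integer treatment codes (indices into TREATMENTS).  The
    record order is taxon-major with treatments in canonical order, matching
    the tiled design matrix built once in :func:`permute_and_refit`.
    """
    n_t = len(TREATMENTS)
    n_taxa = mat.shape[1]
    means = np.empty((n_t, n_taxa))
    sds = np.empty((n_t, n_taxa))
    for g in range(n_t):
        block = mat[tcodes == g]
        if block.shape[0] < 2:
            raise ValidationError(f"treatment {TREATMENTS[g]} has < 2 slides")
        means[g] = block.mean(axis=0)
        sds[g] = block.std(axis=0, ddof=1)
    if np.any(means <= 0):
        raise UndefinedCVError("zero mean abundance in a (taxon, treatment) cell")
    cv = (sds / means).T.ravel()  # taxon-major
    X = np.tile(build_design_matrix(TREATMENTS).to_numpy(), (n_taxa, 1))
    groups = np.repeat(np.arange(n_taxa), n_t)
    if spec.use_detrend:
        x = np.log(means.T.ravel())
        a, b, c, _ = _fit_exp_arrays(x, cv)
        resid = cv - (a * np.exp(b * x) + c)
        keep = (
            ~flag_outliers(resid, spec.outlier_sd) if spec.drop_outliers
            else np.ones(resid.size, dtype=bool)
        )
        fit = fit_reml(resid[keep], X[keep], groups[keep])
    else:
        fit = fit_reml(np.sqrt(cv), X, groups)
    return np.asarray(fit.beta, dtype=float)


def permute_and_refit(
    community: pd.DataFrame,
    design: pd.DataFrame,
    pipeline_spec: PipelineSpec,
    taxa,
    n_perm: int = 999,
    seed: int = 0,
    permutations=None,
) -> NullDistribution:
    """Null distribution of the nine coefficients under label shuffling.

    Parameters
    ----------
    community, design
        Long community table and slide -> treatment design.
    pipeline_spec
        Assemblage chain options (see :class:`PipelineSpec`).
    taxa
        Taxa retained by the (label-invariant) filtering step.
    n_perm
        Number of label permutations (default 999).
    permutations
        Test hook: explicit list of index arrays to use instead of random
        permutations (e.g. the identity, which must reproduce the observed
        fit exactly).

    Replicates whose pipeline fails (e.g. a zero-mean cell appearing under
    a detection limit) are recorded and excluded; the effective count is
    ``len(replicates)``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    mat = _wide_matrix(community, design, taxa)
    code_of = {t: i for i, t in enumerate(TREATMENTS)}
    tcodes = design["treatment"].map(code_of).to_numpy()
    if np.any(pd.isna(tcodes)):
        raise ValidationError("design contains unknown treatment codes")
    tcodes = tcodes.astype(int)
    base_counts = np.bincount(tcodes, minlength=len(TREATMENTS))

    observed = _pipeline_coefficients(mat, tcodes, pipeline_spec)
    rng = np.random.default_rng(seed)
    rows, n_failed = [], 0
    for r in range(n_perm):
        if permutations is not None:
            perm = np.asarray(permutations[r])
        else:
            perm = rng.permutation(tcodes.size)
        shuffled = tcodes[perm]
        # label shuffling preserves the design balance by construction
        assert np.array_equal(
            np.bincount(shuffled, minlength=len(TREATMENTS)), base_counts
        ), "permutation broke treatment balance"
        try:
            rows.append(_pipeline_coefficients(mat, shuffled, pipeline_spec))
        except PerivarError:
            n_failed += 1
    reps = pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))
    return NullDistribution(
        replicates=reps,
        observed=pd.Series(observed, index=list(DESIGN_COLUMNS)),
        n_perm=n_perm,
        seed=seed,
        n_failed=n_failed,
    )


def pseudo_p(null: NullDistribution, coefficient: str, alternative: str = "lower") -> PseudoP:
    """Pseudo-P of one coefficient against its permutation null.

    ``lower`` is the fraction of the null strictly below the observed value
    (ties count as "not lower"); ``upper`` is the mirrored strict fraction;
    ``two_sided`` doubles the smaller tail (capped at 1).  ``p_add_one`` is
    the (count+1)/(n_perm+1) variant, which is a valid p-value by
    construction.
    """
    if coefficient not in null.replicates.columns:
        raise ValidationError(f"unknown coefficient {coefficient!r}")
    vals = null.replicates[coefficient].to_numpy()
    obs = float(null.observed[coefficient])
    n = vals.size
    if n < 1:
        raise ValidationError("null distribution has no successful replicates")
    lower = int(np.sum(vals < obs))
    upper = int(np.sum(vals > obs))
    if alternative == "lower":
        return PseudoP(lower / n, (lower + 1) / (n + 1), alternative, n)
    if alternative == "upper":
        return PseudoP(upper / n, (upper + 1) / (n + 1), alternative, n)
    if alternative == "two_sided":
        p = min(1.0, 2.0 * min(lower, upper) / n)
        p1 = min(1.0, 2.0 * (min(lower, upper) + 1) / (n + 1))
        return PseudoP(p, p1, alternative, n)
    raise ValidationError(f"unknown alternative {alternative!r}")


def significance_stars(p: float) -> str:
    """Star convention: * P<0.05, ** P<0.01, *** P<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def null_summary(null: NullDistribution, alternative: str = "lower") -> pd.DataFrame:
    """Summary table: term, observed, pseudo_p, pseudo_p_add_one, stars."""
    rows = []
    for term in null.coefficients:
        pp = pseudo_p(null, term, alternative)
        rows.append(
            {
                "term": term,
                "observed": float(null.observed[term]),
                "pseudo_p": pp.p,
                "pseudo_p_add_one": pp.p_add_one,
                "stars": significance_stars(pp.p),
            }
        )
    return pd.DataFrame(rows)
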