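"""Readers and writers for the package's tabular interchange formats.

All tables are UTF-8 CSV with a header row and '.' decimal: community
tables long-format (slide_id, taxon_id, abundance), design tables
(slide_id, t1, t2, treatment), variability tables, coefficient tables and
square distance matrices with slide ids as header row/column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

COMMUNITY_COLUMNS = ("slide_id", "taxon_id", "abundance")
DESIGN_COLUMNS_CSV = ("slide_id", "t1", "t2", "treatment")


def read_community_csv(path) -> pd.DataFrame:
    """Read and validate a long community table.

    Rejects missing columns, unparseable or negative abundances (reporting
    1-based data line numbers) and duplicated (slide, taxon) pairs.
    """
    df = pd.read_csv(path, dtype={"slide_id": str, "taxon_id": str})
    missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    ab = pd.to_numeric(df["abundance"], errors="coerce")
    bad = df.index[ab.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]  # header is line 1
        raise ValidationError(f"{path}: unparseable abundance at line(s) {lines}")
    df["abundance"] = ab.astype(float)
    neg = df.index[df["abundance"] < 0]
    if len(neg):
        lines = [int(i) + 2 for i in neg[:5]]
        raise ValidationError(f"{path}: negative abundance at line(s) {lines}")
    dup = df.duplicated(subset=["slide_id", "taxon_id"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["slide_id", "taxon_id"]].iloc[0].tolist()
        raise ValidationError(f"{path}: duplicated (slide, taxon) pair {tuple(pair)}")
    return df[list(COMMUNITY_COLUMNS)]


def write_community_csv(table: pd.DataFrame, path) -> None:
    table[list(COMMUNITY_COLUMNS)].to_csv(path, index=False)


def read_design_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in DESIGN_COLUMNS_CSV if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df["slide_id"].duplicated().any():
        dup = df.loc[df["slide_id"].duplicated(), "slide_id"].iloc[0]
        raise ValidationError(f"{path}: duplicated slide_id {dup!r}")
    mism = df.index[df["treatment"] != df["t1"] + df["t2"]]
    if len(mism):
        raise ValidationError(f"{path}: treatment != t1+t2 at line {int(mism[0]) + 2}")
    return df[list(DESIGN_COLUMNS_CSV)]


def write_design_csv(design: pd.DataFrame, path) -> None:
    design[list(DESIGN_COLUMNS_CSV)].to_csv(path, index=False)


def read_wide_matrix(path, normalize: bool = True) -> pd.DataFrame:
    """Import a wide sample x taxon matrix (e.g. ARISA peak heights).

    First column = slide id, remaining columns = taxa.  Rows are closed to
    sum 1 when ``normalize`` (relative peak heights); returns a long
    community table.
    """
    wide = pd.read_csv(path, index_col=0)
    M = wide.to_numpy(dtype=float)
    if (M < 0).any():
        raise ValidationError(f"{path}: negative entries in wide matrix")
    if normalize:
        totals = M.sum(axis=1)
        if (totals <= 0).any():
            empty = wide.index[totals <= 0].tolist()
            raise ValidationError(f"{path}: all-zero rows {empty}")
        M = M / totals[:, None]
    long = (
        pd.DataFrame(M, index=wide.index.astype(str), columns=wide.columns.astype(str))
        .stack()
        .rename("abundance")
        .reset_index()
    )
    long.columns = ["slide_id", "taxon_id", "abundance"]
    long.attrs["assemblage"] = "relative_abundance"
    return long


def write_distance_matrix(dm, path) -> None:
    dm.values.to_csv(path)


def write_coef_table(fit, path, random_effect_label: str = "Taxon") -> None:
    """Coefficient CSV mirroring the published table layout, plus the
    random-effect variance row."""
    tab = fit.coef_table()
    extra = pd.DataFrame(
        {
            "term": [f"Random effect: {random_effect_label}"],
            "estimate": [fit.sigma2_taxon],
            "se": [np.nan],
            "p_value": [np.nan],
        }
    )
    pd.concat([tab, extra], ignore_index=True).to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
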