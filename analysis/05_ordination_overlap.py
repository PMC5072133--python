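"""Ordination: PCA of community composition and treatment-polygon overlap.

For each assemblage, runs covariance PCA on relative abundances, draws the
convex hull of each treatment's slides in the PC1/PC2 plane, and measures
how every treatment polygon overlaps the undisturbed (AA) polygon.  Writes
results/<assemblage>/{pca_*,hull_overlap}.csv and a figure per assemblage.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import perivar as pv
from perivar.io import read_community_csv, read_design_csv
from perivar.pipeline import ordination_analysis

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

design = read_design_csv(args.data / "design.csv")
for assemblage, fname, filt in (
    ("diatom", "diatoms.csv", lambda c: pv.select_common_taxa(c, 8)),
    ("bacteria", "bacteria.csv", lambda c: pv.filter_by_prevalence(c, 30)),
):
    out = args.out / assemblage
    out.mkdir(parents=True, exist_ok=True)
    community = read_community_csv(args.data / fname)
    taxa = filt(community)
    ord_res, hulls, overlaps = ordination_analysis(community, design, taxa)
    ord_res.scores.to_csv(out / "pca_scores.csv")
    ord_res.loadings.to_csv(out / "pca_loadings.csv")
    overlaps.to_csv(out / "hull_overlap.csv", index=False)
    ve = ord_res.var_explained
    print(f"[{assemblage}] PC1 {ve[0]:.1f}%, PC2 {ve[1]:.1f}% "
          f"(PC1+PC2 {ve[0] + ve[1]:.1f}%) of composition variance")
    lead = ord_res.loadings["PC1"].abs().sort_values(ascending=False).head(2)
    lead_str = ", ".join(f"{k}: {float(v):.3f}" for k, v in lead.items())
    print(f"  dominant PC1 loadings: {lead_str}")
    n_olap = int(overlaps["overlaps_reference"].sum())
    print(f"  AA polygon overlaps {n_olap}/{len(overlaps)} other treatment polygons")

    fig, ax = plt.subplots(figsize=(5.5, 5))
    tmap = design.set_index("slide_id")["treatment"]
    sc = ord_res.scores
    colors = tmap.reindex(sc.index).map(
        {t: f"C{i}" for i, t in enumerate(pv.TREATMENTS)}
    )
    ax.scatter(sc["PC1"], sc["PC2"], c=colors, s=14)
    aa = hulls["AA"].vertices
    ax.fill(aa[:, 0], aa[:, 1], alpha=0.15, color="red", label="AA hull")
    ax.set_xlabel(f"PC1 ({ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ve[1]:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "pca_hulls.png", dpi=150)
    plt.close(fig)
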