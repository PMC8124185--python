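"""Cross-layer integration of transcript and protein differential expression.

Genes are matched between layers through an id map, multi-feature genes are
collapsed to a single representative, and each gene is assigned a
concordance group:

* group 1 — up-regulated at both the transcript and protein level
* group 2 — up-regulated transcript, protein measured but unchanged
* group 3 — down-regulated at both levels
* discordant — opposite significant directions in the two layers
* none — everything else (including transcript-up genes whose protein was
  never measured; those form the "grey" node class in network figures,
  distinct from group 2's "red")
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import (
    STATUS_DOWN,
    STATUS_NS,
    STATUS_UP,
    AnalysisThresholds,
    signed_fold_change,
)

logger = logging.getLogger(__name__)

UNMEASURED = "unmeasured"

GROUP1 = "1"
GROUP2 = "2"
GROUP3 = "3"
DISCORDANT = "discordant"
NOGROUP = "none"

# Fig-8-style node classes
CLASS_RED = "red"        # group 2
CLASS_GREY = "grey"      # transcript up, no protein value
CLASS_GREEN = "green"    # transcript up, protein down
CLASS_BACKGROUND = "background"


def _collapse(de: pd.DataFrame, feat2gene: pd.Series, rule: str = "max_abs_fc") -> tuple[pd.DataFrame, list[str]]:
    """Collapse a per-feature DE table to one representative row per gene."""
    unmapped = [f for f in de.index if f not in feat2gene.index]
    if unmapped:
        logger.warning("%d features without gene mapping excluded", len(unmapped))
    de = de.loc[[f for f in de.index if f in feat2gene.index]].copy()
    de["gene_id"] = feat2gene.loc[de.index].to_numpy()
    if rule != "max_abs_fc":
        raise ValueError(f"unknown collapse rule {rule!r}")
    order = de["log2fc"].abs().to_numpy()
    de = de.iloc[np.argsort(-order, kind="stable")]
    multi = de["gene_id"].duplicated(keep=False).sum()
    if multi:
        logger.info("collapsing %d multi-feature rows by max |FC|", multi)
    de = de[~de["gene_id"].duplicated(keep="first")]
    return de.set_index("gene_id"), unmapped


def match_layers(
    transcript_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    id_map: pd.DataFrame,
    collapse: str = "max_abs_fc",
) -> pd.DataFrame:
    """Pair transcript- and protein-layer DE outcomes per gene.

    ``id_map`` needs columns ``transcript_id``, ``protein_id``, ``gene_id``
    (protein_id may be empty/NaN for proteins never assayed).  Returns one
    row per gene present in the transcript layer, with protein columns NaN
    and ``protein_status=\"unmeasured\"`` where the protein layer has no
    measurement.  Unmapped features are logged and excluded.
    """
    id_map = id_map.replace({"transcript_id": {"": np.nan}, "protein_id": {"": np.nan}})
    t2g = id_map.dropna(subset=["transcript_id"]).set_index("transcript_id")["gene_id"]
    p2g = id_map.dropna(subset=["protein_id"]).set_index("protein_id")["gene_id"]
    t2g = t2g[~t2g.index.duplicated()]
    p2g = p2g[~p2g.index.duplicated()]

    t_de, t_unmapped = _collapse(transcript_de, t2g, collapse)
    p_de, p_unmapped = _collapse(protein_de, p2g, collapse)
    if t_unmapped or p_unmapped:
        logger.warning("unmapped features: %s", t_unmapped + p_unmapped)

    out = pd.DataFrame(index=t_de.index)
    out["transcript_status"] = t_de["status"]
    out["transcript_log2fc"] = t_de["log2fc"]
    out["transcript_fc"] = signed_fold_change(t_de["log2fc"].to_numpy())
    out["transcript_fdr"] = t_de["fdr"] if "fdr" in t_de.columns else np.nan

    shared = out.index.intersection(p_de.index)
    out["protein_status"] = UNMEASURED
    out.loc[shared, "protein_status"] = p_de.loc[shared, "status"]
    out["protein_log2fc"] = np.nan
    out.loc[shared, "protein_log2fc"] = p_de.loc[shared, "log2fc"]
    out["protein_fc"] = signed_fold_change(out["protein_log2fc"].to_numpy())
    out.loc[out["protein_status"] == UNMEASURED, "protein_fc"] = np.nan
    out["protein_fdr"] = np.nan
    if "fdr" in p_de.columns:
        out.loc[shared, "protein_fdr"] = p_de.loc[shared, "fdr"]
    return out


def assign_groups(integrated: pd.DataFrame) -> pd.DataFrame:
    """Attach concordance ``group`` and Fig-8-style ``node_class`` columns."""
    out = integrated.copy()
    t, p = out["transcript_status"], out["protein_status"]
    conds = [
        (t == STATUS_UP) & (p == STATUS_UP),
        (t == STATUS_UP) & (p == STATUS_NS),
        (t == STATUS_DOWN) & (p == STATUS_DOWN),
        (t == STATUS_UP) & (p == STATUS_DOWN),
        (t == STATUS_DOWN) & (p == STATUS_UP),
    ]
    out["group"] = np.select(conds, [GROUP1, GROUP2, GROUP3, DISCORDANT, DISCORDANT], default=NOGROUP)
    classes = [
        (out["group"] == GROUP2),
        (t == STATUS_UP) & (p == UNMEASURED),
        (t == STATUS_UP) & (p == STATUS_DOWN),
    ]
    out["node_class"] = np.select(classes, [CLASS_RED, CLASS_GREY, CLASS_GREEN], default=CLASS_BACKGROUND)
    return out


def group_sizes(integrated: pd.DataFrame) -> dict[str, int]:
    counts = integrated["group"].value_counts()
    return {g: int(counts.get(g, 0)) for g in (GROUP1, GROUP2, GROUP3, DISCORDANT, NOGROUP)}


def correlate_fold_changes(integrated: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson correlation of log2 fold changes over co-measured genes.

    Uses every gene measured in both layers (not only significant ones).
    Returns ``(r, two_sided_p, n)``; raises for n < 3.
    """
    both = integrated.dropna(subset=["transcript_log2fc", "protein_log2fc"])
    n = len(both)
    if n < 3:
        raise ValueError(f"need >=3 co-measured genes, have {n}")
    r, p = stats.pearsonr(both["transcript_log2fc"], both["protein_log2fc"])
    return float(r), float(p), n


def group_report(integrated: pd.DataFrame, group: str) -> pd.DataFrame:
    """Per-group report: gene, transcript FC, protein FC, sorted by
    descending transcript FC (the layout of the published group-1 table)."""
    sel = integrated[integrated["group"] == group]
    rep = sel[["transcript_fc", "protein_fc"]].copy()
    rep = rep.sort_values("transcript_fc", ascending=False)
    rep.index.name = "gene_id"
    return rep.reset_index()


def classify_fc_table(
    fc_table: pd.DataFrame,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
) -> pd.DataFrame:
    """Integrate from a pre-computed signed-FC table, bypassing the DE stage.

    ``fc_table`` is indexed by gene with columns ``transcript_fc`` and
    ``protein_fc`` (signed FC scale; NaN protein = unmeasured) and optional
    ``transcript_fdr`` / ``protein_fdr`` (absent means already-filtered
    significant values, treated as fdr 0).
    """
    out = pd.DataFrame(index=fc_table.index)
    for layer in ("transcript", "protein"):
        fc = fc_table[f"{layer}_fc"].astype(float)
        fdr_col = f"{layer}_fdr"
        fdr = fc_table[fdr_col].astype(float) if fdr_col in fc_table.columns else pd.Series(0.0, index=fc_table.index)
        sig = fdr <= thresholds.fdr_cut
        status = np.select(
            [sig & (fc >= thresholds.fc_cut), sig & (fc <= -thresholds.fc_cut)],
            [STATUS_UP, STATUS_DOWN],
            default=STATUS_NS,
        )
        status = np.where(fc.isna(), UNMEASURED if layer == "protein" else STATUS_NS, status)
        out[f"{layer}_status"] = status
        out[f"{layer}_fc"] = fc
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"{layer}_log2fc"] = np.where(fc >= 0, np.log2(fc.abs()), -np.log2(fc.abs()))
        out[f"{layer}_fdr"] = fdr
    return assign_groups(out)


def write_integrated_tsv(integrated: pd.DataFrame, path) -> None:
    cols = [
        "transcript_fc", "transcript_fdr", "protein_fc", "protein_fdr",
        "transcript_status", "protein_status", "group", "node_class",
    ]
    integrated[[c for c in cols if c in integrated.columns]].to_csv(
        path, sep="\t", index_label="gene_id"
    )
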