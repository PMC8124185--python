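"""Per-layer differential expression.

The same engine is applied to both omics layers: complete-case filtering,
log2 transformation, grand-median (``diff.median``-style) normalisation, an
empirical-Bayes moderated t-test with Benjamini-Hochberg adjustment, and
threshold classification into up / down / not-significant at a symmetric
signed fold-change cut and an FDR cut.

The moderated t follows the standard empirical-Bayes variance-shrinkage
model: per-feature residual variances ``s_g^2`` with ``d_g`` residual
degrees of freedom are assumed drawn from a scaled inverse-chi-square prior
with hyperparameters ``(d0, s0^2)``; the posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces ``s_g^2`` in the two-sample t statistic, which then has
``d0 + d_g`` degrees of freedom.  The hyperparameters are estimated by
moment-matching the log-variances through the digamma/trigamma identities
for the log of a chi-square variate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"


class EmptyMatrixError(ValueError):
    """All features were removed by a filtering step."""


@dataclass(frozen=True)
class AnalysisThresholds:
    """Significance cut-offs for the two-layer analysis.

    ``fc_cut`` is on the signed fold-change scale (a symmetric cut: a gene
    is called only when |signed FC| >= fc_cut), ``fdr_cut`` on the BH-adjusted
    p-value scale.
    """

    fc_cut: float = 1.6
    fdr_cut: float = 0.05

    def __post_init__(self) -> None:
        if not self.fc_cut > 1:
            raise ValueError(f"fc_cut must be > 1, got {self.fc_cut}")
        if not 0 < self.fdr_cut < 1:
            raise ValueError(f"fdr_cut must be in (0,1), got {self.fdr_cut}")


@dataclass
class ExpressionMatrix:
    """Feature-by-sample abundance matrix for one omics layer.

    ``values`` is a features x samples DataFrame (may contain NaN for
    identified-but-not-quantified entries); ``conditions`` maps each sample
    id to ``"control"`` or ``"treated"``.
    """

    values: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.conditions = self.conditions.reindex(self.values.columns)
        if self.conditions.isna().any():
            missing = self.conditions.index[self.conditions.isna()][0]
            raise ValueError(f"sample {missing!r} has no condition label")
        bad = set(self.conditions.unique()) - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, conditions=self.conditions.copy())


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read the TSV dialect used throughout: first column feature id, header
    row sample ids of the form ``<condition>_<replicate>``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    conds = {}
    for s in df.columns:
        cond = str(s).rsplit("_", 1)[0]
        if cond not in (CONTROL, TREATED):
            raise ValueError(f"sample id {s!r} does not encode a condition")
        conds[s] = cond
    return ExpressionMatrix(values=df, conditions=pd.Series(conds))


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# Filtering, transformation, normalisation
# ---------------------------------------------------------------------------

def drop_incomplete_features(m: ExpressionMatrix) -> ExpressionMatrix:
    """Reject features identified but not quantified in every sample.

    Keeps exactly the rows with no missing value, in their original order.
    """
    keep = m.values.notna().all(axis=1)
    if not keep.any():
        raise EmptyMatrixError("no feature is quantified in all samples")
    return m.with_values(m.values.loc[keep].copy())


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise log2 of raw abundances (missing entries pass through)."""
    vals = m.values
    bad = (vals <= 0).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive abundance at feature {vals.index[i]!r}, "
            f"sample {vals.columns[j]!r}: {vals.iat[i, j]}"
        )
    return m.with_values(np.log2(vals))


def median_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Shift every sample column so its median matches the grand median.

    Additive on the log scale: column j gets ``grand_median - median_j``.
    Idempotent.
    """
    vals = m.values
    grand = float(np.median(vals.to_numpy()))
    shifts = grand - vals.median(axis=0)
    return m.with_values(vals + shifts)


# ---------------------------------------------------------------------------
# Moderated t-test
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/x scale."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if x <= 0 or not np.isfinite(x):
            return np.inf
        if abs(dif) < tol * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of a scaled inverse-chi-square prior (d0, s0^2)
    to observed residual variances with ``df`` residual degrees of freedom.

    Works on log variances: if s^2 | sigma^2 ~ sigma^2 chi^2_d / d then
    E[log s^2] and Var[log s^2] involve digamma/trigamma terms of d/2 and
    d0/2, which are matched to the sample mean and variance of log s^2.
    Returns (inf, geometric-mean-based s0^2) when the excess variance is
    non-positive (no evidence of variance heterogeneity).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.all():
        # zero sample variances carry no log information; clamp to smallest positive
        floor = s2[ok].min() if ok.any() else 1e-8
        s2 = np.where(ok, s2, floor)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if np.isfinite(d0):
            s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
            return d0, s02
        logger.warning("trigamma solve non-finite; falling back to d0=inf")
    return np.inf, float(np.exp(emean))


def moderated_ttest(m: ExpressionMatrix, d0: float | None = None) -> pd.DataFrame:
    """Two-sample moderated t-test (treated vs control) per feature.

    Parameters
    ----------
    m : normalised log2-scale matrix with no missing values.
    d0 : optional prior degrees of freedom override.  ``0`` gives the
        ordinary pooled-variance t, ``inf`` fully shrunken variances; by
        default the prior is estimated from the data.

    Returns a DataFrame indexed by feature with columns ``mean_control``,
    ``mean_treated``, ``log2fc``, ``t_mod``, ``df_total``, ``p_value``.
    """
    ctrl = m.values[m.samples_of(CONTROL)].to_numpy(dtype=float)
    trt = m.values[m.samples_of(TREATED)].to_numpy(dtype=float)
    n1, n2 = ctrl.shape[1], trt.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 replicates per condition")
    df_resid = n1 + n2 - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    if np.isnan(ctrl).any() or np.isnan(trt).any():
        raise ValueError("missing values present; run drop_incomplete_features first")

    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    log2fc = mean_t - mean_c
    ss = ((ctrl - mean_c[:, None]) ** 2).sum(axis=1) + (
        (trt - mean_t[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if d0 is None:
        if len(s2) < 10:
            warnings.warn(
                "fewer than 10 features: prior estimation unstable, "
                "using ordinary t (d0=0)",
                stacklevel=2,
            )
            d0, s02 = 0.0, 0.0
        else:
            d0, s02 = fit_variance_prior(s2, df_resid)
    elif np.isinf(d0):
        _, s02 = fit_variance_prior(s2, df_resid)
    else:
        s02 = fit_variance_prior(s2, df_resid)[1] if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    return pd.DataFrame(
        {
            "mean_control": mean_c,
            "mean_treated": mean_t,
            "log2fc": log2fc,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_value": p,
        },
        index=m.feature_ids,
    )


# ---------------------------------------------------------------------------
# Multiple testing and classification
# ---------------------------------------------------------------------------

def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(log2fc) -> np.ndarray:
    """Signed FC: ratio for up-regulation, negative reciprocal for down.

    |signed FC| >= 1 always; sign carries direction, so a symmetric cut at
    +/-1.6 means |signed FC| >= 1.6.
    """
    lfc = np.asarray(log2fc, dtype=float)
    return np.where(lfc >= 0, 2.0 ** lfc, -(2.0 ** (-lfc)))


def classify_de(results: pd.DataFrame, thresholds: AnalysisThresholds = AnalysisThresholds()) -> pd.DataFrame:
    """Attach ``signed_fc``, ``fdr`` (if absent) and ``status`` columns.

    status = up   iff signed_fc >=  fc_cut and fdr <= fdr_cut
    status = down iff signed_fc <= -fc_cut and fdr <= fdr_cut
    """
    out = results.copy()
    if "fdr" not in out.columns:
        out["fdr"] = adjust_bh(out["p_value"].to_numpy())
    out["signed_fc"] = signed_fold_change(out["log2fc"].to_numpy())
    sig = out["fdr"] <= thresholds.fdr_cut
    up = sig & (out["signed_fc"] >= thresholds.fc_cut)
    down = sig & (out["signed_fc"] <= -thresholds.fc_cut)
    out["status"] = np.select([up, down], [STATUS_UP, STATUS_DOWN], default=STATUS_NS)
    return out


def run_de(
    m: ExpressionMatrix,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    d0: float | None = None,
) -> pd.DataFrame:
    """Full single-layer pipeline: filter -> log2 -> median-normalise ->
    moderated t -> BH -> classify.  Returns the classified DE table."""
    m = drop_incomplete_features(m)
    m = log2_transform(m)
    m = median_normalize(m)
    res = moderated_ttest(m, d0=d0)
    res["fdr"] = adjust_bh(res["p_value"].to_numpy())
    res = classify_de(res, thresholds)
    counts = res["status"].value_counts()
    logger.info(
        "DE: %d up, %d down, %d ns",
        counts.get(STATUS_UP, 0),
        counts.get(STATUS_DOWN, 0),
        counts.get(STATUS_NS, 0),
    )
    return res


def write_de_tsv(de: pd.DataFrame, path) -> None:
    cols = [c for c in ("log2fc", "signed_fc", "t_mod", "p_value", "fdr", "status") if c in de.columns]
    de[cols].to_csv(path, sep="\t", index_label="feature_id")


def read_de_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")
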