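"""Per-protein differential abundance from log2 feature intensities.

Each protein (within one pool) is modeled with a fixed-effects two-way
additive linear model

    log2_intensity[f, c, r] = feature_offset[f] + condition_effect[c] + error

fitted by least squares. On the balanced designs this pipeline targets,
contrast point estimates coincide with those of mixed-model feature-level
summarization; per-feature additive offsets cancel exactly in condition
contrasts. Pairwise condition contrasts yield log2 fold-changes with
t-based p-values; Benjamini-Hochberg adjustment runs per contrast family
across proteins, optionally restricted to entries passing the fold-change
prefilter before adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProfileMatrix, QuantMatrix

__all__ = [
    "ThresholdConfig",
    "ProteinFit",
    "fit_protein_model",
    "test_contrast",
    "adjust_bh",
    "call_significant",
    "condition_level_abundance",
    "preceding_contrasts",
    "all_pairs_contrasts",
    "differential_analysis",
    "profile_from_quant",
    "exclude_contaminants",
]


@dataclass
class ThresholdConfig:
    """Significance thresholds: fold-change ratio, BH alpha, FC-prefilter flag."""

    fc_threshold: float = 1.5
    alpha: float = 0.05
    prefilter_fc: bool = False

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def log2_fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))


@dataclass
class ProteinFit:
    """Least-squares fit of one protein's feature table within one pool."""

    protein_group: str
    conditions: list[str]                 # estimable conditions, in design order
    effects: dict[str, float]             # condition-effect estimates
    cov_unscaled: pd.DataFrame            # (X'X)^+ restricted to condition params
    sigma2: float                         # pooled residual variance
    df_resid: int
    n_obs: int
    excluded_conditions: list[str] = field(default_factory=list)


def fit_protein_model(subset: pd.DataFrame, protein_group: str = "") -> ProteinFit:
    """Fit the two-way additive model to one protein's long-format rows.

    ``subset`` needs columns feature_id, condition, log2_intensity. Conditions
    with zero observations are excluded from estimable contrasts (flagged on
    the fit), not an error. Single-feature proteins reduce to per-condition
    means with pooled residual variance.
    """
    subset = subset.dropna(subset=["log2_intensity"])
    conditions = list(pd.unique(subset["condition"]))
    if len(conditions) < 2:
        raise ValueError(
            f"protein {protein_group!r}: need >= 2 conditions with data, got {len(conditions)}"
        )
    features = sorted(pd.unique(subset["feature_id"]))
    y = subset["log2_intensity"].to_numpy(dtype=float)
    n = y.size

    cond_idx = pd.Categorical(subset["condition"], categories=conditions).codes
    X_cond = np.zeros((n, len(conditions)))
    X_cond[np.arange(n), cond_idx] = 1.0
    if len(features) > 1:
        feat_idx = pd.Categorical(subset["feature_id"], categories=features).codes
        X_feat = np.zeros((n, len(features) - 1))
        mask = feat_idx > 0
        X_feat[np.flatnonzero(mask), feat_idx[mask] - 1] = 1.0
        X = np.hstack([X_cond, X_feat])
    else:
        X = X_cond

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - int(rank)
    sigma2 = float(resid @ resid / df_resid) if df_resid > 0 else np.nan
    if np.isfinite(sigma2) and sigma2 < 1e-12:  # numerically zero residual variance
        sigma2 = 0.0
    xtx_inv = np.linalg.pinv(X.T @ X)
    k = len(conditions)
    cov_unscaled = pd.DataFrame(xtx_inv[:k, :k], index=conditions, columns=conditions)
    effects = {c: float(beta[i]) for i, c in enumerate(conditions)}
    return ProteinFit(
        protein_group=protein_group,
        conditions=conditions,
        effects=effects,
        cov_unscaled=cov_unscaled,
        sigma2=sigma2,
        df_resid=df_resid,
        n_obs=n,
    )


def test_contrast(fit: ProteinFit, condition_a: str, condition_b: str) -> dict:
    """Two-sided t-test of condition_a - condition_b on a fitted protein model.

    Returns log2fc, se, df, p; p is missing (NaN) with zero residual df or
    zero residual variance rather than claiming certainty.
    """
    for c in (condition_a, condition_b):
        if c not in fit.effects:
            return {
                "log2fc": np.nan, "se": np.nan, "df": np.nan, "p": np.nan,
                "reason": f"condition {c!r} not estimable",
            }
    log2fc = fit.effects[condition_a] - fit.effects[condition_b]
    vu = (
        fit.cov_unscaled.loc[condition_a, condition_a]
        + fit.cov_unscaled.loc[condition_b, condition_b]
        - 2 * fit.cov_unscaled.loc[condition_a, condition_b]
    )
    if fit.df_resid <= 0 or not np.isfinite(fit.sigma2):
        return {"log2fc": log2fc, "se": np.nan, "df": fit.df_resid, "p": np.nan,
                "reason": "zero residual df"}
    se = float(np.sqrt(fit.sigma2 * vu))
    if fit.sigma2 == 0.0:
        return {"log2fc": log2fc, "se": 0.0, "df": fit.df_resid, "p": np.nan,
                "reason": "zero residual variance"}
    t = log2fc / se
    p = float(2 * stats.t.sf(abs(t), fit.df_resid))
    return {"log2fc": log2fc, "se": se, "df": fit.df_resid, "p": max(p, np.finfo(float).tiny),
            "reason": ""}


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    Missing entries (NaN) pass through and are excluded from the family size
    m. Values outside (0, 1] raise.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    observed = ~np.isnan(p)
    pv = p[observed]
    if ((pv <= 0) | (pv > 1)).any():
        bad = pv[(pv <= 0) | (pv > 1)][0]
        raise ValueError(f"p-value {bad} outside (0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[observed] = restored
    return out


def call_significant(table: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Apply BH per contrast family and call significance.

    With ``cfg.prefilter_fc``, adjustment within each contrast runs only over
    entries with |log2fc| > log2(fc_threshold); the rest get missing adj_p and
    significant=False. Significance requires both the fold-change threshold
    and adj_p < alpha.
    """
    cfg = cfg or ThresholdConfig()
    out = table.copy()
    thr = cfg.log2_fc_threshold
    out["adj_p"] = np.nan
    for _, idx in out.groupby("contrast", sort=False).groups.items():
        sub = out.loc[idx]
        if cfg.prefilter_fc:
            eligible = sub.index[np.abs(sub["log2fc"]) > thr]
        else:
            eligible = sub.index
        out.loc[eligible, "adj_p"] = adjust_bh(out.loc[eligible, "p"])
    out["significant"] = (
        (np.abs(out["log2fc"]) > thr) & (out["adj_p"] < cfg.alpha)
    ).fillna(False)
    return out


def preceding_contrasts(design: pd.DataFrame) -> list[tuple[str, str]]:
    """(condition, preceding condition) pairs in time order."""
    conds = (
        design[["condition", "time_value"]]
        .drop_duplicates()
        .sort_values("time_value")["condition"]
        .tolist()
    )
    return [(conds[i], conds[i - 1]) for i in range(1, len(conds))]


def all_pairs_contrasts(design: pd.DataFrame) -> list[tuple[str, str]]:
    """All (later, earlier) condition pairs in time order."""
    conds = (
        design[["condition", "time_value"]]
        .drop_duplicates()
        .sort_values("time_value")["condition"]
        .tolist()
    )
    return [(b, a) for a, b in combinations(conds, 2)]


def differential_analysis(
    matrix: QuantMatrix,
    contrasts: list[tuple[str, str]],
    cfg: ThresholdConfig | None = None,
    min_obs_per_condition: int = 1,
) -> pd.DataFrame:
    """Fit every protein and test the given contrasts; returns the called table.

    One row per (protein_group, contrast) with log2fc, se, df, p, adj_p,
    significant. Contrast labels are "A_vs_B" for the pair (A, B).
    """
    cfg = cfg or ThresholdConfig()
    long = matrix.annotated()
    rows = []
    needed = {c for pair in contrasts for c in pair}
    for protein, sub in long.groupby("protein_group", sort=True):
        counts = sub["condition"].value_counts()
        present = {c for c in needed if counts.get(c, 0) >= min_obs_per_condition}
        if len(present) < 2:
            continue
        try:
            fit = fit_protein_model(sub, protein_group=protein)
        except ValueError:
            continue
        for a, b in contrasts:
            res = test_contrast(fit, a, b)
            rows.append({
                "protein_group": protein,
                "contrast": f"{a}_vs_{b}",
                "condition_a": a,
                "condition_b": b,
                **res,
            })
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    return call_significant(table, cfg)


def condition_level_abundance(matrix: QuantMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize a QuantMatrix to protein-level abundances.

    Returns (condition_level, sample_level): condition level is the median
    across features of per-feature condition means; sample level is the
    median across features of each sample's feature intensities (for
    replicate-correlation analyses).
    """
    long = matrix.annotated()
    per_feature_cond = (
        long.groupby(["protein_group", "condition", "feature_id"], sort=True)["log2_intensity"]
        .mean()
        .reset_index()
    )
    condition_level = (
        per_feature_cond.groupby(["protein_group", "condition"], sort=True)["log2_intensity"]
        .median()
        .reset_index()
        .rename(columns={"log2_intensity": "abundance"})
    )
    sample_level = (
        long.groupby(["protein_group", "sample_id"], sort=True)["log2_intensity"]
        .median()
        .reset_index()
        .rename(columns={"log2_intensity": "abundance"})
    )
    return condition_level, sample_level


def profile_from_quant(matrix: QuantMatrix, pool: str) -> ProfileMatrix:
    """Condition-level abundances of one pool as a protein x time matrix."""
    sub = matrix.subset_pool(pool)
    condition_level, _ = condition_level_abundance(sub)
    time_of = (
        sub.design[["condition", "time_value"]]
        .drop_duplicates()
        .set_index("condition")["time_value"]
    )
    condition_level = condition_level.assign(
        time=condition_level["condition"].map(time_of)
    )
    wide = condition_level.pivot(index="protein_group", columns="time", values="abundance")
    wide = wide.sort_index(axis=1)
    return ProfileMatrix(wide, pool)


def exclude_contaminants(matrix: QuantMatrix, blocklist: set[str]) -> QuantMatrix:
    """Drop features whose protein group contains a blocklisted accession."""
    def hit(group: str) -> bool:
        return any(acc in blocklist for acc in str(group).split(";"))

    keep = ~matrix.data["protein_group"].map(hit)
    return QuantMatrix(matrix.data[keep].reset_index(drop=True), matrix.design)
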