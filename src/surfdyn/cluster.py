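"""Fuzzy c-means clustering of developmental abundance profiles.

Profiles observed in at least ``min_timepoints`` time points are z-scored per
protein (so clustering groups shapes, not levels) and partitioned with fuzzy
c-means: soft memberships u_ik in [0,1] with rows summing to 1, centers as
membership^m-weighted means, memberships by inverse-squared-distance sharing
with exponent 2/(m-1), Euclidean distance. The fuzzifier m defaults to the
Schwämmle-Jensen heuristic (a function of the number of profiles N and the
number of time points D) used by the Mfuzz package's m estimator.

Per-cluster annotation enrichment uses one-sided Fisher exact tests on the
2x2 table (in-cluster vs out-of-cluster, in-term vs out-of-term) over the
universe of clustered proteins, with no multiplicity adjustment; a term is
"specific" when it is enriched (p < alpha) in exactly one cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationCatalog, ProfileMatrix

__all__ = [
    "ClusterModel",
    "select_and_standardize",
    "estimate_fuzzifier",
    "fuzzy_cmeans",
    "enrichment_pvalue",
    "enrich_clusters",
]


def enrichment_pvalue(a, b, c, d, alternative: str = "greater"):
    """Fisher exact p for the 2x2 table [[a, b], [c, d]].

    For the default one-sided enrichment alternative this is the
    hypergeometric upper tail P(X >= a) with N=a+b+c+d draws parameterized by
    the term margin a+c and the cluster margin a+b (vectorized); other
    alternatives fall back to scipy's fisher_exact.
    """
    if alternative == "greater":
        a = np.asarray(a)
        n_total = a + np.asarray(b) + np.asarray(c) + np.asarray(d)
        return stats.hypergeom.sf(a - 1, n_total, a + np.asarray(c), a + np.asarray(b))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return p


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model. hard_labels are 1-based (argmax membership,
    ties to the lowest cluster index)."""

    c: int
    m: float
    centers: np.ndarray            # c x T, standardized units
    memberships: pd.DataFrame      # N x c, rows sum to 1
    hard_labels: pd.Series         # protein -> cluster in 1..c
    seed: int
    n_iter: int
    objective: float
    objective_history: list[float]


def select_and_standardize(
    profiles: ProfileMatrix,
    min_timepoints: int = 7,
) -> tuple[pd.DataFrame, dict]:
    """Per-protein z-scoring of sufficiently observed profiles.

    Proteins observed at fewer than ``min_timepoints`` time points are
    dropped, as are constant profiles (sd = 0). Each retained row is scaled
    to mean 0 / sd 1 over its observed entries; remaining missing entries are
    filled with 0 (the standardized mean). Returns the matrix and a report of
    what was dropped.
    """
    values = profiles.values
    n_obs = values.notna().sum(axis=1)
    enough = values[n_obs >= min_timepoints]
    arr = enough.to_numpy(dtype=float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z = z[~constant]
    out = pd.DataFrame(z, index=enough.index[~constant], columns=values.columns)
    out = out.fillna(0.0)
    report = {
        "n_input": int(values.shape[0]),
        "n_dropped_few_timepoints": int((n_obs < min_timepoints).sum()),
        "n_dropped_constant": int(constant.sum()),
        "n_retained": int(out.shape[0]),
    }
    return out, report


def estimate_fuzzifier(n: int, d: int, override: float | None = None) -> float:
    """Fuzzifier heuristic from the dataset shape (N profiles, D dimensions).

    m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)

    Deterministic in (N, D); ``override`` short-circuits the formula.
    """
    if override is not None:
        if not override > 1:
            raise ValueError("fuzzifier must be > 1")
        return float(override)
    if n < 3:
        raise ValueError("need at least 3 profiles to estimate the fuzzifier")
    term1 = (1418.0 / n + 22.05) * d**-2.0
    term2 = (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    return float(1.0 + term1 + term2)


def _memberships(dist2: np.ndarray, m: float) -> np.ndarray:
    """FCM membership update from squared distances (N x c)."""
    u = np.zeros_like(dist2)
    zero = dist2 <= 1e-300
    any_zero = zero.any(axis=1)
    if any_zero.any():
        # a zero distance pins membership to that center (first on ties)
        rows = np.flatnonzero(any_zero)
        cols = np.argmax(zero[rows], axis=1)
        u[rows, cols] = 1.0
    rest = ~any_zero
    if rest.any():
        power = dist2[rest] ** (-1.0 / (m - 1.0))
        u[rest] = power / power.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(
    X,
    c: int,
    m: float | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_init: int = 5,
) -> ClusterModel:
    """Fuzzy c-means with seeded random-row center initialization.

    Runs ``n_init`` seeded initializations (distinct random rows as starting
    centers) and keeps the solution with the lowest objective
    J = sum_ik u_ik^m ||x_i - v_k||^2, which is non-increasing across the
    alternating updates. Deterministic under a fixed seed.
    """
    if isinstance(X, pd.DataFrame):
        index = X.index
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        index = pd.RangeIndex(arr.shape[0])
    n, d = arr.shape
    if c < 2:
        raise ValueError("need c >= 2 clusters")
    if n <= c:
        raise ValueError(f"need more profiles ({n}) than clusters ({c})")
    if m is None:
        m = estimate_fuzzifier(n, d)
    if not m > 1:
        raise ValueError("fuzzifier m must be > 1")

    best = None
    init_seeds = np.random.SeedSequence(seed).generate_state(n_init) % (2**31)
    for init_seed in init_seeds:
        rng = np.random.default_rng(int(init_seed))
        centers = arr[rng.choice(n, size=c, replace=False)].copy()
        u = None
        n_iter = 0
        history: list[float] = []
        for n_iter in range(1, max_iter + 1):
            dist2 = ((arr[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            u = _memberships(dist2, m)
            history.append(float((u**m * dist2).sum()))
            um = u**m
            new_centers = (um.T @ arr) / um.sum(axis=0)[:, None]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < tol:
                break
        dist2 = ((arr[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u = _memberships(dist2, m)
        objective = float((u**m * dist2).sum())
        history.append(objective)
        if best is None or objective < best[0]:
            best = (objective, centers, u, n_iter, history)
    objective, centers, u, n_iter, history = best
    memberships = pd.DataFrame(u, index=index, columns=range(1, c + 1))
    hard = pd.Series(np.argmax(u, axis=1) + 1, index=index, name="cluster")
    return ClusterModel(
        c=c, m=float(m), centers=centers, memberships=memberships,
        hard_labels=hard, seed=seed, n_iter=n_iter, objective=objective,
        objective_history=history,
    )


def enrich_clusters(
    labels: pd.Series,
    catalog: AnnotationCatalog,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-(term, cluster) Fisher exact enrichment over the clustered universe.

    Terms with no member in the universe are skipped. No multiplicity
    adjustment is applied; ``specific`` marks terms enriched (p < alpha) in
    exactly one cluster.
    """
    universe = set(labels.index)
    n_universe = len(universe)
    clusters = sorted(labels.unique())
    rows = []
    for term_id, members in sorted(catalog.terms.items()):
        in_term = members & universe
        if not in_term:
            continue
        for k in clusters:
            in_cluster = set(labels.index[labels == k])
            a = len(in_cluster & in_term)
            b = len(in_cluster) - a
            cc = len(in_term) - a
            d = n_universe - a - b - cc
            p = enrichment_pvalue(a, b, cc, d, alternative=alternative)
            rows.append({
                "term_id": term_id,
                "term_name": catalog.names.get(term_id, term_id),
                "cluster": k, "a": a, "b": b, "c": cc, "d": d, "p": float(p),
            })
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    enriched = table["p"] < alpha
    n_enriched = table.loc[enriched].groupby("term_id")["cluster"].nunique()
    table["specific"] = enriched & (
        table["term_id"].map(n_enriched).fillna(0).astype(int) == 1
    )
    return table
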