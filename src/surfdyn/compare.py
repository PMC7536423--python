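"""Surface-vs-total pool comparison: matching, coupling, and co-abundance.

Surface and total protein groups are matched when their accession sets
intersect (one-to-one, largest intersection wins, deterministic tie-break).
Coupling between the two pools is then quantified several ways:

- per-protein Spearman correlation of the two abundance time series;
- per-contrast Spearman correlation of log2 fold-changes across proteins,
  grouped by the time interval separating the compared conditions;
- overlap of the significantly changed protein sets per contrast (Jaccard by
  default, intersection-over-smaller-set by flag);
- quadrant directionality: the fraction of significant proteins whose
  surface and total fold-changes agree in sign;
- within-complex vs all-pair Spearman correlation of profiles, probing
  co-abundance of complex members.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ComplexCatalog, ProfileMatrix

__all__ = [
    "match_protein_groups",
    "per_protein_spearman",
    "interval_fc_correlation",
    "interval_medians",
    "interval_trend",
    "significant_overlap",
    "quadrant_directionality",
    "complex_pair_correlation",
]


def _accessions(group: str) -> frozenset[str]:
    return frozenset(a for a in str(group).split(";") if a)


def match_protein_groups(
    surface_groups,
    total_groups,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """One-to-one matching of surface to total protein groups.

    Groups match iff their accession sets intersect; candidate pairs are
    ranked by descending intersection size, ties broken by the
    lexicographically smallest pair of group keys (symmetric: swapping the
    two pools yields the same pair set). Returns the matched-pair table plus
    the unmatched groups of each pool.
    """
    surface_groups = list(dict.fromkeys(surface_groups))
    total_groups = list(dict.fromkeys(total_groups))
    s_acc = {g: _accessions(g) for g in surface_groups}
    t_acc = {g: _accessions(g) for g in total_groups}
    candidates = []
    for sg, sa in s_acc.items():
        for tg, ta in t_acc.items():
            inter = sa & ta
            if inter:
                candidates.append((-len(inter), tuple(sorted((sg, tg))), sg, tg, inter))
    candidates.sort(key=lambda c: (c[0], c[1]))
    used_s: set[str] = set()
    used_t: set[str] = set()
    rows = []
    for _, _, sg, tg, inter in candidates:
        if sg in used_s or tg in used_t:
            continue
        used_s.add(sg)
        used_t.add(tg)
        rows.append({
            "surface_group": sg,
            "total_group": tg,
            "match_key": ";".join(sorted(inter)),
            "n_shared": len(inter),
        })
    matched = pd.DataFrame(rows, columns=["surface_group", "total_group", "match_key", "n_shared"])
    unmatched_s = [g for g in surface_groups if g not in used_s]
    unmatched_t = [g for g in total_groups if g not in used_t]
    return matched, unmatched_s, unmatched_t


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def per_protein_spearman(
    surface: ProfileMatrix,
    total: ProfileMatrix,
    matches: pd.DataFrame | None = None,
    min_shared: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Spearman rho of surface vs total time series for each matched protein.

    Correlations use the time points observed in both pools (average-rank
    ties); proteins with fewer than ``min_shared`` shared points are skipped
    and counted. The summary reports the median rho and the fraction of
    positive correlations.
    """
    if matches is None:
        shared = [p for p in surface.proteins if p in set(total.proteins)]
        matches = pd.DataFrame({"surface_group": shared, "total_group": shared})
    rows = []
    n_skipped = 0
    for _, row in matches.iterrows():
        ys = surface.values.loc[row["surface_group"]].to_numpy(dtype=float)
        yt = total.values.loc[row["total_group"]].to_numpy(dtype=float)
        ok = ~np.isnan(ys) & ~np.isnan(yt)
        if ok.sum() < min_shared:
            n_skipped += 1
            continue
        rows.append({
            "surface_group": row["surface_group"],
            "total_group": row["total_group"],
            "rho": _spearman(ys[ok], yt[ok]),
            "n_shared_timepoints": int(ok.sum()),
        })
    table = pd.DataFrame(rows)
    rhos = table["rho"].dropna() if not table.empty else pd.Series(dtype=float)
    summary = {
        "n_proteins": int(len(table)),
        "n_skipped": n_skipped,
        "median_rho": float(rhos.median()) if len(rhos) else np.nan,
        "fraction_positive": float((rhos > 0).mean()) if len(rhos) else np.nan,
    }
    return table, summary


def _contrast_intervals(diff: pd.DataFrame, condition_times: pd.Series) -> pd.Series:
    ta = diff["condition_a"].map(condition_times)
    tb = diff["condition_b"].map(condition_times)
    return (ta - tb).abs()


def interval_fc_correlation(
    surface_diff: pd.DataFrame,
    total_diff: pd.DataFrame,
    condition_times: pd.Series,
    matches: pd.DataFrame | None = None,
    min_proteins: int = 3,
) -> pd.DataFrame:
    """Per-contrast Spearman rho between surface and total log2 fold-changes.

    Both differential tables must cover the same contrast set; each contrast
    is tagged with its time interval |t_a - t_b|. Proteins enter a contrast's
    correlation when both pools report a fold-change. ``matches`` (from
    match_protein_groups) maps total groups onto surface keys; identity by
    default.
    """
    total_key = "protein_group"
    tdiff = total_diff
    if matches is not None:
        rename = dict(zip(matches["total_group"], matches["surface_group"]))
        tdiff = total_diff.assign(protein_group=total_diff["protein_group"].map(rename))
        tdiff = tdiff.dropna(subset=[total_key])
    rows = []
    t_by_contrast = dict(tdiff.groupby("contrast").groups)
    for contrast, s_idx in surface_diff.groupby("contrast").groups.items():
        if contrast not in t_by_contrast:
            continue
        s = surface_diff.loc[s_idx, ["protein_group", "log2fc", "condition_a", "condition_b"]]
        t = tdiff.loc[t_by_contrast[contrast], ["protein_group", "log2fc"]]
        merged = s.merge(t, on="protein_group", suffixes=("_surface", "_total")).dropna(
            subset=["log2fc_surface", "log2fc_total"]
        )
        if len(merged) < min_proteins:
            continue
        interval = abs(
            condition_times[merged["condition_a"].iloc[0]]
            - condition_times[merged["condition_b"].iloc[0]]
        )
        rows.append({
            "contrast": contrast,
            "interval": float(interval),
            "rho": _spearman(
                merged["log2fc_surface"].to_numpy(), merged["log2fc_total"].to_numpy()
            ),
            "n": int(len(merged)),
        })
    return pd.DataFrame(rows).sort_values(["interval", "contrast"]).reset_index(drop=True)


def interval_medians(interval_stats: pd.DataFrame, column: str = "rho") -> pd.Series:
    """Median of a per-contrast statistic within each interval length."""
    return interval_stats.groupby("interval")[column].median()


def interval_trend(
    interval_stats: pd.DataFrame,
    column: str = "rho",
    on: str = "contrast",
) -> tuple[float, float]:
    """One-sided (increasing) Spearman trend test of a statistic vs interval.

    With ``on='contrast'`` (default) the trend is tested across all
    per-contrast values, which keeps power at the longest intervals where
    only one or two contrasts exist; ``on='median'`` tests the per-interval
    medians instead. Returns (rho, one-sided p).
    """
    if on == "median":
        series = interval_medians(interval_stats, column=column).dropna()
        x, y = series.index.to_numpy(dtype=float), series.to_numpy()
    elif on == "contrast":
        sub = interval_stats.dropna(subset=[column])
        x, y = sub["interval"].to_numpy(dtype=float), sub[column].to_numpy()
    else:
        raise ValueError("on must be 'contrast' or 'median'")
    rho, p_two = stats.spearmanr(x, y)
    p_one = p_two / 2 if rho > 0 else 1 - p_two / 2
    return float(rho), float(p_one)


def significant_overlap(
    surface_diff: pd.DataFrame,
    total_diff: pd.DataFrame,
    condition_times: pd.Series,
    matches: pd.DataFrame | None = None,
    method: str = "jaccard",
) -> pd.DataFrame:
    """Per-contrast overlap (%) of the significant protein sets of both pools.

    method 'jaccard': 100*|S∩T|/|S∪T| (default); 'min': 100*|S∩T|/min(|S|,|T|).
    Contrasts with an empty union/denominator report a missing overlap.
    """
    if method not in ("jaccard", "min"):
        raise ValueError("method must be 'jaccard' or 'min'")
    tdiff = total_diff
    if matches is not None:
        rename = dict(zip(matches["total_group"], matches["surface_group"]))
        tdiff = total_diff.assign(protein_group=total_diff["protein_group"].map(rename))
        tdiff = tdiff.dropna(subset=["protein_group"])
    rows = []
    t_by_contrast = dict(tdiff.groupby("contrast").groups)
    for contrast, s_idx in surface_diff.groupby("contrast").groups.items():
        if contrast not in t_by_contrast:
            continue
        sdf = surface_diff.loc[s_idx]
        tdf = tdiff.loc[t_by_contrast[contrast]]
        s_set = set(sdf.loc[sdf["significant"].fillna(False), "protein_group"])
        t_set = set(tdf.loc[tdf["significant"].fillna(False), "protein_group"])
        interval = abs(
            condition_times[sdf["condition_a"].iloc[0]]
            - condition_times[sdf["condition_b"].iloc[0]]
        )
        denom = len(s_set | t_set) if method == "jaccard" else min(len(s_set), len(t_set))
        overlap = 100.0 * len(s_set & t_set) / denom if denom else np.nan
        rows.append({
            "contrast": contrast, "interval": float(interval),
            "overlap_pct": overlap, "n_surface": len(s_set), "n_total": len(t_set),
            "method": method,
        })
    return pd.DataFrame(rows).sort_values(["interval", "contrast"]).reset_index(drop=True)


def quadrant_directionality(
    surface_fc: pd.Series,
    total_fc: pd.Series,
    significant: pd.Series,
) -> float:
    """Fraction of significant proteins with same-sign surface and total FC.

    All three inputs are indexed by protein group for one contrast;
    ``significant`` marks proteins significant in either pool. Zero
    fold-changes are excluded from the fraction.
    """
    idx = significant[significant.fillna(False)].index
    s = surface_fc.reindex(idx)
    t = total_fc.reindex(idx)
    ok = s.notna() & t.notna() & (s != 0) & (t != 0)
    if not ok.any():
        return np.nan
    return float((np.sign(s[ok]) == np.sign(t[ok])).mean())


def complex_pair_correlation(
    profiles: ProfileMatrix,
    complexes: ComplexCatalog,
    min_shared: int = 3,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Spearman rho of all protein pairs vs pairs sharing a complex.

    Complex membership is matched on individual accessions within each
    profile's protein group; complexes with fewer than two measured members
    are skipped. Returns (all-pair rhos, within-complex rhos, summary with
    both medians).
    """
    proteins = profiles.proteins
    if len(proteins) < 2:
        raise ValueError("need >= 2 proteins for pairwise correlations")
    acc_of = {p: _accessions(p) for p in proteins}
    complex_pairs: set[frozenset[str]] = set()
    for members in complexes.complexes.values():
        measured = [p for p in proteins if acc_of[p] & members]
        if len(measured) < 2:
            continue
        for a, b in combinations(measured, 2):
            complex_pairs.add(frozenset((a, b)))
    arr = profiles.values.to_numpy(dtype=float)
    index = {p: i for i, p in enumerate(proteins)}
    all_rhos, within_rhos = [], []
    for a, b in combinations(proteins, 2):
        ya, yb = arr[index[a]], arr[index[b]]
        ok = ~np.isnan(ya) & ~np.isnan(yb)
        if ok.sum() < min_shared:
            continue
        rho = _spearman(ya[ok], yb[ok])
        all_rhos.append(rho)
        if frozenset((a, b)) in complex_pairs:
            within_rhos.append(rho)
    all_rhos = np.asarray(all_rhos, dtype=float)
    within_rhos = np.asarray(within_rhos, dtype=float)
    summary = {
        "n_all_pairs": int(all_rhos.size),
        "n_complex_pairs": int(within_rhos.size),
        "median_all": float(np.nanmedian(all_rhos)) if all_rhos.size else np.nan,
        "median_within_complex": float(np.nanmedian(within_rhos)) if within_rhos.size else np.nan,
    }
    return all_rhos, within_rhos, summary
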