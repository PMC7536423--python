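"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate a two-pool (surface / total) label-free time-course
experiment on differentiating neuron cultures: 10 time points (2..20 days in
vitro, step 2), 3 biological replicates per pool, log2-scale intensities with
per-peptide offsets and replicate noise, protein trajectories drawn from a
small set of impulse-shaped cluster archetypes, a configurable fraction of
"uncoupled" proteins whose surface trajectory rises late while their total
trajectory is unchanged (the behavior of synaptic-vesicle proteins whose
intracellular pool becomes surface-exposed once synapses form), optional
missingness, and glycopeptide evidence with deamidation planted on
sequon asparagines.

Everything is deterministic under a fixed seed, and every generator returns
the planted truth so downstream recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glyco import PeptideEvidence
from .impulse import ImpulseParams, impulse_value
from .io import ProfileMatrix, QuantMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CLUSTER_ARCHETYPES",
    "simulate_trajectories",
    "simulate_feature_table",
    "simulate_group_comparison",
    "simulate_glyco_evidence",
]

DEFAULT_TIMEPOINTS = tuple(float(t) for t in range(2, 21, 2))


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults mirror the emulated design: 10 time points (DIV 2-20), 3
    replicates per pool, Gaussian log2-scale noise. ``trafficking_sd`` adds a
    surface-only per-time-point component (short-timescale trafficking) on
    top of the shared trajectory.
    """

    n_proteins: int = 600
    n_clusters: int = 6
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    peptides_per_protein: int | tuple[int, int] = (2, 4)
    replicate_sd: float = 0.2
    feature_offset_sd: float = 1.0
    frac_uncoupled: float = 0.0
    frac_differential: float = 0.0
    effect_size: float = 1.0
    missing_rate: float = 0.0
    trafficking_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_uncoupled", "frac_differential", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("replicate_sd", "feature_offset_sd", "trafficking_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size < 2 or not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints must be strictly increasing (>= 2 values)")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")

    def peptide_counts(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.peptides_per_protein, int):
            return np.full(self.n_proteins, self.peptides_per_protein, dtype=int)
        lo, hi = self.peptides_per_protein
        return rng.integers(lo, hi + 1, size=self.n_proteins)


# Impulse-parameter archetypes on the centered-log2 scale (levels around 10):
# monotone rise, steep early rise, early peak, monotone decline, transient dip,
# late switch-on. Qualitative shapes only; per-protein parameters are jittered.
CLUSTER_ARCHETYPES: tuple[ImpulseParams, ...] = (
    ImpulseParams(h0=10.0, h1=11.5, h2=13.0, t1=7.0, t2=15.0, beta=0.7),
    ImpulseParams(h0=10.0, h1=12.8, h2=13.4, t1=4.5, t2=14.0, beta=1.2),
    ImpulseParams(h0=10.0, h1=13.0, h2=10.3, t1=5.0, t2=12.0, beta=1.2),
    ImpulseParams(h0=12.5, h1=11.0, h2=9.5, t1=7.0, t2=15.0, beta=0.7),
    ImpulseParams(h0=12.5, h1=9.8, h2=12.3, t1=6.0, t2=14.0, beta=1.2),
    ImpulseParams(h0=10.0, h1=10.2, h2=13.0, t1=11.0, t2=16.5, beta=1.4),
)


@dataclass
class GroundTruth:
    """Planted truth emitted by the trajectory simulator."""

    proteins: list[str]
    cluster_label: pd.Series                  # protein -> 1..n_clusters
    surface_params: dict[str, ImpulseParams]
    total_params: dict[str, ImpulseParams]
    uncoupled: pd.Series                      # protein -> bool
    surface_mean: pd.DataFrame                # protein x time, noise-free + trafficking
    total_mean: pd.DataFrame                  # protein x time, noise-free
    surface_replicates: np.ndarray = None     # (protein, time, replicate) draws
    total_replicates: np.ndarray = None
    config: SimulationConfig = field(repr=False, default=None)

    def replicate_dict(self, pool: str) -> dict[str, np.ndarray]:
        """Per-protein (time x replicate) arrays for one pool."""
        arr = self.surface_replicates if pool == "surface" else self.total_replicates
        return {p: arr[i] for i, p in enumerate(self.proteins)}


def _jitter_params(base: ImpulseParams, rng: np.random.Generator,
                   t_lo: float, t_hi: float) -> ImpulseParams:
    h0, h1, h2 = (v + rng.normal(0, 0.25) for v in (base.h0, base.h1, base.h2))
    t1 = base.t1 + rng.normal(0, 0.8)
    t2 = base.t2 + rng.normal(0, 0.8)
    t1 = float(np.clip(t1, t_lo, t_hi))
    t2 = float(np.clip(t2, t1, t_hi + 2.0))
    beta = float(base.beta * np.exp(rng.normal(0, 0.15)))
    return ImpulseParams(h0=float(h0), h1=float(h1), h2=float(h2), t1=t1, t2=t2, beta=beta)


def _late_rise_variant(total: ImpulseParams, rng: np.random.Generator,
                       t_hi: float) -> ImpulseParams:
    """Surface trajectory of an uncoupled protein: flat early, rising after
    synapse formation (~DIV 12), regardless of the total-pool shape."""
    base = total.h0
    t1 = float(np.clip(11.0 + rng.normal(0, 0.7), 9.0, t_hi - 2.0))
    return ImpulseParams(
        h0=float(base), h1=float(base + 0.3 + rng.normal(0, 0.1)),
        h2=float(base + 2.5 + rng.normal(0, 0.2)),
        t1=t1, t2=float(t1 + 4.5), beta=1.5,
    )


def simulate_trajectories(
    config: SimulationConfig,
) -> tuple[ProfileMatrix, ProfileMatrix, GroundTruth]:
    """Simulate condition-level surface and total abundance profiles.

    Each protein's noise-free mean trajectory in each pool is an impulse
    curve drawn from one of ``n_clusters`` archetypes (with per-protein
    parameter jitter). Coupled proteins share parameters across pools; an
    exact round(frac_uncoupled * n_proteins) subset gets a late-rising
    surface trajectory with the total trajectory unchanged. The returned
    profiles are per-time-point medians of ``n_replicates`` noisy replicate
    draws around the noise-free mean (so replicate_sd=0 with frac_uncoupled=0
    and trafficking_sd=0 makes both pools identical); the replicate-level
    draws themselves are kept on the ground truth for replicate-aware
    analyses.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.timepoints, dtype=float)
    t_lo, t_hi = float(t.min()), float(t.max())
    n = config.n_proteins
    proteins = [f"PROT{i:04d}" for i in range(n)]
    archetypes = CLUSTER_ARCHETYPES[: config.n_clusters]
    if config.n_clusters > len(CLUSTER_ARCHETYPES):
        raise ValueError(
            f"at most {len(CLUSTER_ARCHETYPES)} cluster archetypes are defined"
        )
    labels = rng.integers(1, config.n_clusters + 1, size=n)
    n_uncoupled = int(round(config.frac_uncoupled * n))
    uncoupled_idx = set(rng.choice(n, size=n_uncoupled, replace=False).tolist())
    # Uncoupled proteins keep early-dynamics totals (the SV2 pattern: total
    # rises early, surface switches on late); a late-switch total would
    # coincide with the late-rising surface and plant no real uncoupling.
    n_early = min(config.n_clusters, 5)
    for i in uncoupled_idx:
        if labels[i] > n_early:
            labels[i] = int(rng.integers(1, n_early + 1))

    total_params: dict[str, ImpulseParams] = {}
    surface_params: dict[str, ImpulseParams] = {}
    total_mean = np.empty((n, t.size))
    surface_mean = np.empty((n, t.size))
    for i, protein in enumerate(proteins):
        base = archetypes[labels[i] - 1]
        p_total = _jitter_params(base, rng, t_lo, t_hi)
        total_params[protein] = p_total
        if i in uncoupled_idx:
            p_surf = _late_rise_variant(p_total, rng, t_hi)
        else:
            p_surf = p_total
        surface_params[protein] = p_surf
        total_mean[i] = impulse_value(p_total, t)
        surface_mean[i] = impulse_value(p_surf, t)

    if config.trafficking_sd > 0:
        surface_mean = surface_mean + rng.normal(0, config.trafficking_sd, size=surface_mean.shape)

    def replicate_draws(mean: np.ndarray) -> np.ndarray:
        noise = (
            rng.normal(0, config.replicate_sd, size=(*mean.shape, config.n_replicates))
            if config.replicate_sd > 0
            else np.zeros((*mean.shape, config.n_replicates))
        )
        return mean[:, :, None] + noise

    # condition-level profile = median across replicates (the convention for
    # per-time-point summaries in this pipeline)
    surface_reps = replicate_draws(surface_mean)
    total_reps = replicate_draws(total_mean)
    surface_obs = np.median(surface_reps, axis=2)
    total_obs = np.median(total_reps, axis=2)

    truth = GroundTruth(
        proteins=proteins,
        cluster_label=pd.Series(labels, index=proteins, name="cluster"),
        surface_params=surface_params,
        total_params=total_params,
        uncoupled=pd.Series([i in uncoupled_idx for i in range(n)], index=proteins,
                            name="uncoupled"),
        surface_mean=pd.DataFrame(surface_mean, index=proteins, columns=t),
        total_mean=pd.DataFrame(total_mean, index=proteins, columns=t),
        surface_replicates=surface_reps,
        total_replicates=total_reps,
        config=config,
    )
    surface = ProfileMatrix(pd.DataFrame(surface_obs, index=proteins, columns=t), "surface")
    total = ProfileMatrix(pd.DataFrame(total_obs, index=proteins, columns=t), "total")
    return surface, total, truth


def _design_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for pool in ("surface", "total"):
        for tp in config.timepoints:
            for rep in range(1, config.n_replicates + 1):
                cond = f"DIV{int(tp):02d}"
                rows.append({
                    "sample_id": f"{pool[0].upper()}_{cond}_R{rep}",
                    "pool": pool, "condition": cond,
                    "replicate": rep, "time_value": float(tp),
                })
    return pd.DataFrame(rows)


def simulate_feature_table(truth: GroundTruth, config: SimulationConfig | None = None) -> QuantMatrix:
    """Peptide-level long table from simulated trajectories.

    log2 intensity = pool trajectory mean + per-feature offset
    ~ N(0, feature_offset_sd) + replicate noise ~ N(0, replicate_sd); rows
    are then dropped independently with probability ``missing_rate``.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    design = _design_frame(config)
    t = np.asarray(config.timepoints, dtype=float)
    n_pep = config.peptide_counts(rng)
    means = {"surface": truth.surface_mean.to_numpy(), "total": truth.total_mean.to_numpy()}

    records = []
    for i, protein in enumerate(truth.proteins):
        offsets = rng.normal(0, config.feature_offset_sd, size=n_pep[i])
        for pool in ("surface", "total"):
            traj = means[pool][i]
            for f in range(n_pep[i]):
                feature_id = f"{protein}_{pool[0]}pep{f + 1}"
                noise = rng.normal(0, config.replicate_sd,
                                   size=(t.size, config.n_replicates))
                for ti, tp in enumerate(t):
                    cond = f"DIV{int(tp):02d}"
                    for rep in range(1, config.n_replicates + 1):
                        records.append((
                            feature_id, protein,
                            f"{pool[0].upper()}_{cond}_R{rep}",
                            traj[ti] + offsets[f] + noise[ti, rep - 1],
                        ))
    data = pd.DataFrame.from_records(
        records, columns=["feature_id", "protein_group", "sample_id", "log2_intensity"]
    )
    if config.missing_rate > 0:
        keep = rng.random(len(data)) >= config.missing_rate
        data = data[keep].reset_index(drop=True)
    return QuantMatrix(data, design)


def simulate_group_comparison(config: SimulationConfig) -> tuple[QuantMatrix, pd.DataFrame]:
    """Two-condition (CTRL vs TREAT) feature table for calibration studies.

    An exact round(frac_differential * n_proteins) subset of proteins gets a
    true log2 effect of ±effect_size (random sign) in TREAT; the rest are
    null. Returns the QuantMatrix and a truth table with columns
    (protein_group, is_differential, true_effect).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = [f"PROT{i:04d}" for i in range(n)]
    n_diff = int(round(config.frac_differential * n))
    diff_idx = set(rng.choice(n, size=n_diff, replace=False).tolist()) if n_diff else set()
    base = rng.uniform(9.0, 14.0, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    effects = np.where([i in diff_idx for i in range(n)], signs * config.effect_size, 0.0)
    n_pep = config.peptide_counts(rng)

    design_rows = []
    for cond in ("CTRL", "TREAT"):
        for rep in range(1, config.n_replicates + 1):
            design_rows.append({
                "sample_id": f"{cond}_R{rep}", "pool": "surface",
                "condition": cond, "replicate": rep, "time_value": np.nan,
            })
    design = pd.DataFrame(design_rows)

    records = []
    for i, protein in enumerate(proteins):
        offsets = rng.normal(0, config.feature_offset_sd, size=n_pep[i])
        for f in range(n_pep[i]):
            feature_id = f"{protein}_pep{f + 1}"
            for cond, shift in (("CTRL", 0.0), ("TREAT", effects[i])):
                noise = rng.normal(0, config.replicate_sd, size=config.n_replicates)
                for rep in range(1, config.n_replicates + 1):
                    records.append((
                        feature_id, protein, f"{cond}_R{rep}",
                        base[i] + offsets[f] + shift + noise[rep - 1],
                    ))
    data = pd.DataFrame.from_records(
        records, columns=["feature_id", "protein_group", "sample_id", "log2_intensity"]
    )
    if config.missing_rate > 0:
        keep = rng.random(len(data)) >= config.missing_rate
        data = data[keep].reset_index(drop=True)
    truth = pd.DataFrame({
        "protein_group": proteins,
        "is_differential": [i in diff_idx for i in range(n)],
        "true_effect": effects,
    })
    return QuantMatrix(data, design), truth


# --- glycopeptide evidence -------------------------------------------------

_FILLER = "ADEFGHILMQVWY"  # no N/K/R/P/S/T/C: no accidental sequons or cut sites


def _filler(rng: np.random.Generator, lo: int, hi: int) -> str:
    k = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(_FILLER), size=k))


def _sequon_peptide(rng: np.random.Generator, third: str) -> tuple[str, int]:
    """A tryptic peptide containing one planted N-X-[third] sequon; returns
    (peptide, 1-based N position within the peptide)."""
    prefix = _filler(rng, 3, 6)
    x = rng.choice(list(_FILLER))
    suffix = _filler(rng, 2, 5)
    pep = prefix + "N" + x + third + suffix + "K"
    return pep, len(prefix) + 1


def simulate_glyco_evidence(
    n_proteins: int = 3,
    seed: int = 0,
) -> tuple[str, list[PeptideEvidence], dict]:
    """Random proteins with planted sequons plus the evidence that covers them.

    The construction exercises every counting rule: each protein carries one
    unambiguous sequon peptide; proteins 1 and 2 share a nonproteotypic
    peptide (assigned to the lexicographically smallest accession by rule
    ii); protein 3 contains one peptide occurring at two positions, only one
    of which completes a sequon through protein context (rule iii). One
    planted sequon uses proline at X (flagged in the truth metadata) and one
    uses cysteine at the third position (countable under N-X-[S/T/C] but not
    quantifiable under N-X-S/T). Decoy peptides with non-sequon deamidation
    and without deamidation are included.

    Returns (FASTA text, evidence list, truth dict) with the unique site
    count after rules i-iii, the site coordinates, and per-peptide
    quantifiability flags.
    """
    if n_proteins < 3:
        raise ValueError("need >= 3 proteins to exercise the counting rules")
    rng = np.random.default_rng(seed)
    accs = [f"GP{i:03d}" for i in range(n_proteins)]
    parts: dict[str, list[str]] = {a: [] for a in accs}
    evidence: list[PeptideEvidence] = []
    sites: set[tuple[str, int]] = set()
    proline_x_sites: list[tuple[str, int]] = []
    quantifiable: list[bool] = []

    def add_regular(acc: str, third: str, proline_x: bool = False) -> None:
        if proline_x:
            prefix = _filler(rng, 3, 6)
            pep = prefix + "NPT" + _filler(rng, 2, 5) + "K"
            npos = len(prefix) + 1
        else:
            pep, npos = _sequon_peptide(rng, third)
        offset = sum(len(p) for p in parts[acc])
        parts[acc].append(pep)
        site = (acc, offset + npos)
        sites.add(site)
        if proline_x:
            proline_x_sites.append(site)
        evidence.append(PeptideEvidence(
            sequence=pep, mods=((npos, 0.984, "Deamidation"),),
            protein_group=(acc,), proteotypic=True,
        ))
        quantifiable.append(third in "ST" and not proline_x)

    # one unambiguous sequon peptide per protein; thirds cycle S/T with one
    # C-variant and one proline-X variant on the later proteins
    thirds = ["S", "T"] * (n_proteins // 2 + 1)
    for i, acc in enumerate(accs):
        add_regular(acc, thirds[i])
    if n_proteins > 3:
        add_regular(accs[3], "C")
    if n_proteins > 4:
        add_regular(accs[4], "T", proline_x=True)

    # rule ii: a shared (nonproteotypic) sequon peptide in proteins 0 and 1
    shared_pep, shared_npos = _sequon_peptide(rng, "T")
    off0 = sum(len(p) for p in parts[accs[0]])
    parts[accs[0]].append(shared_pep)
    off1 = sum(len(p) for p in parts[accs[1]])
    parts[accs[1]].append(shared_pep)
    sites.add((accs[0], off0 + shared_npos))  # assigned to min(acc) = GP000
    evidence.append(PeptideEvidence(
        sequence=shared_pep, mods=((shared_npos, 0.98, "Deamidation"),),
        protein_group=(accs[0], accs[1]), proteotypic=False,
    ))
    quantifiable.append(True)

    # rule iii: a peptide placed twice in protein 2; the sequon completes
    # through protein context ("T" after the first placement only)
    core = _filler(rng, 4, 6) + "NK"  # N at len-1: motif needs the next residue
    npos_multi = len(core) - 1
    off_a = sum(len(p) for p in parts[accs[2]])
    parts[accs[2]].append(core)
    parts[accs[2]].append("T" + _filler(rng, 3, 5) + "K")  # completes N-K-T
    off_b = sum(len(p) for p in parts[accs[2]])
    parts[accs[2]].append(core)
    parts[accs[2]].append("G" + _filler(rng, 3, 5) + "K")  # no sequon here
    start_a, start_b = off_a + 1, off_b + 1
    sites.add((accs[2], off_a + npos_multi))
    evidence.append(PeptideEvidence(
        sequence=core, mods=((npos_multi, 0.98, "Deamidation"),),
        protein_group=(accs[2],), proteotypic=True,
        start_positions={accs[2]: [start_a, start_b]},
    ))
    quantifiable.append(True)

    # decoys: non-sequon deamidation, and a sequon peptide with no deamidation
    decoy = _filler(rng, 3, 5) + "N" + _filler(rng, 3, 5) + "K"
    parts[accs[0]].append(decoy)
    evidence.append(PeptideEvidence(
        sequence=decoy, mods=((decoy.index("N") + 1, 0.98, "Deamidation"),),
        protein_group=(accs[0],), proteotypic=True,
    ))
    quantifiable.append(False)
    unmod, unmod_npos = _sequon_peptide(rng, "S")
    parts[accs[1]].append(unmod)
    evidence.append(PeptideEvidence(
        sequence=unmod, mods=(), protein_group=(accs[1],), proteotypic=True,
    ))
    quantifiable.append(False)

    sequences = {acc: "".join(parts[acc]) for acc in accs}
    fasta = "".join(f">{acc}\n{seq}\n" for acc, seq in sequences.items())
    truth = {
        "n_sites": len(sites),
        "sites": sorted(sites),
        "proline_x_sites": proline_x_sites,
        "quantifiable": quantifiable,
        "n_quantifiable": int(sum(quantifiable)),
        "multi_map_site": (accs[2], off_a + npos_multi),
        "shared_site": (accs[0], off0 + shared_npos),
    }
    return fasta, evidence, truth
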