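"""Extracellular N-glycopeptide filtering and glycosylation-site counting.

Surface-capture chemistry (periodate oxidation, biocytin-hydrazide labeling,
streptavidin enrichment, PNGase F release) leaves a +0.98 Da deamidation on
the asparagine of formerly N-glycosylated peptides. A peptide therefore
reports genuine surface exposure only if a deamidated asparagine sits inside
the N-linked glycosylation sequon (N-X-S/T for quantification, N-X-[S/T/C]
for site counting). This module implements the sequon scan, the
quantifiability filter, and the unique-site counting rules:

i.   only peptides whose deamidated N conforms to the consensus count;
ii.  nonproteotypic peptides are assigned to a single protein of their group
     (deterministically: the lexicographically smallest accession);
iii. a peptide mapping to multiple positions within its protein keeps all
     placements on a tie, otherwise only the placement with the most
     deamidated residues landing on consensus sequons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = [
    "PeptideEvidence",
    "GlycoSiteRecord",
    "DEAMIDATION_MASS",
    "DEAMIDATION_TOL",
    "detect_sequons",
    "filter_quantifiable",
    "count_glyco_sites",
    "compare_to_annotation",
    "read_evidence_tsv",
    "write_evidence_tsv",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

DEAMIDATION_MASS = 0.98
DEAMIDATION_TOL = 0.02


@dataclass(frozen=True)
class PeptideEvidence:
    """One identified peptide with modifications and protein-group membership.

    mods: tuples (position within peptide, 1-based; delta mass in Da; name).
    start_positions: optional accession -> list of 1-based start coordinates
    of the peptide within that protein, when localization is known upstream.
    """

    sequence: str
    mods: tuple[tuple[int, float, str], ...] = ()
    protein_group: tuple[str, ...] = ()
    proteotypic: bool = True
    start_positions: dict[str, list[int]] | None = None

    def __post_init__(self) -> None:
        if not self.protein_group:
            raise ValueError("protein_group must be non-empty")
        for pos, _, name in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification {name!r} at position {pos} outside peptide "
                    f"of length {len(self.sequence)}"
                )

    def deamidated_positions(self) -> list[int]:
        """1-based peptide positions carrying deamidation (+0.98 Da) on N."""
        out = []
        for pos, delta, _ in self.mods:
            if abs(delta - DEAMIDATION_MASS) <= DEAMIDATION_TOL and self.sequence[pos - 1] == "N":
                out.append(pos)
        return out


@dataclass(frozen=True)
class GlycoSiteRecord:
    """A unique glycosylation site: (accession, 1-based protein position)."""

    accession: str
    position: int
    motif: str
    status: str = "unassigned"  # known | novel | unassigned


def detect_sequons(
    sequence: str,
    alphabet: str = "STC",
    exclude_proline_x: bool = False,
) -> list[int]:
    """Return 1-based positions p where sequence[p..p+2] matches N-X-[alphabet].

    With ``exclude_proline_x`` a proline at X disqualifies the motif (the
    common biological convention; off by default). Positions within two
    residues of the C-terminus can never complete a motif.
    """
    seq = sequence.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue letter(s) {sorted(bad)} in sequence")
    allowed = set(alphabet.upper())
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] != "N":
            continue
        if exclude_proline_x and seq[i + 1] == "P":
            continue
        if seq[i + 2] in allowed:
            hits.append(i + 1)
    return hits


def _sequon_contexts(
    pep: PeptideEvidence,
    sequences: dict[str, str] | None,
) -> list[str]:
    """Peptide sequence extended by protein context past its C-terminus for
    every known placement (needed when the deamidated N sits within two
    residues of the peptide's end). Falls back to the bare peptide when no
    localization is available."""
    contexts = []
    if pep.start_positions and sequences:
        for acc, starts in sorted(pep.start_positions.items()):
            seq = sequences.get(acc)
            if seq is None:
                continue
            seq = seq.upper()
            for start in starts:
                end = start - 1 + len(pep.sequence)
                if seq[start - 1 : end] == pep.sequence:
                    contexts.append(seq[start - 1 : min(len(seq), end + 2)])
    return contexts or [pep.sequence]


def filter_quantifiable(
    evidence: list[PeptideEvidence],
    sequences: dict[str, str] | None = None,
    alphabet: str = "ST",
    exclude_proline_x: bool = False,
) -> list[PeptideEvidence]:
    """Retain peptides with >= 1 deamidated asparagine inside an N-X-S/T sequon.

    The sequon is evaluated on the peptide extended by protein context when
    start positions are available, otherwise on the peptide alone. Input
    order is preserved; output is a subset of the input.
    """
    kept = []
    for pep in evidence:
        deam = pep.deamidated_positions()
        if not deam:
            continue
        for context in _sequon_contexts(pep, sequences):
            sequons = set(
                detect_sequons(context, alphabet=alphabet, exclude_proline_x=exclude_proline_x)
            )
            if any(pos in sequons for pos in deam):
                kept.append(pep)
                break
    return kept


def _assigned_accession(pep: PeptideEvidence) -> str:
    if pep.proteotypic or len(pep.protein_group) == 1:
        return pep.protein_group[0]
    # rule ii: deterministic "arbitrary" single-protein assignment
    return min(pep.protein_group)


def _placements(peptide: str, protein: str) -> list[int]:
    """All 1-based start coordinates of exact substring matches."""
    out = []
    start = protein.find(peptide)
    while start != -1:
        out.append(start + 1)
        start = protein.find(peptide, start + 1)
    return out


def count_glyco_sites(
    evidence: list[PeptideEvidence],
    sequences: dict[str, str],
    alphabet: str = "STC",
    exclude_proline_x: bool = False,
) -> tuple[list[GlycoSiteRecord], dict[str, int]]:
    """Count unique glycosylation sites from deamidated peptide evidence.

    Returns the unique (accession, position) site records, sorted, plus a
    report with counts of skipped (unmappable) peptides. Idempotent and
    invariant to the order of the evidence list.
    """
    sites: dict[tuple[str, int], str] = {}
    skipped_unmappable = 0
    for pep in evidence:
        deam = pep.deamidated_positions()
        if not deam:
            continue
        acc = _assigned_accession(pep)
        protein = sequences.get(acc)
        if protein is None:
            raise KeyError(f"no sequence for assigned accession {acc!r}")
        protein = protein.upper()
        starts = _placements(pep.sequence, protein)
        if not starts:
            logger.warning(
                "peptide %s not found in assigned protein %s; skipped", pep.sequence, acc
            )
            skipped_unmappable += 1
            continue
        protein_sequons = set(
            detect_sequons(protein, alphabet=alphabet, exclude_proline_x=exclude_proline_x)
        )
        # rule iii: score each placement by deamidated residues landing on sequons
        scored: list[tuple[int, list[int]]] = []
        for start in starts:
            on_sequon = [start + p - 1 for p in deam if (start + p - 1) in protein_sequons]
            scored.append((start, on_sequon))
        best = max(len(on) for _, on in scored)
        if best == 0:
            continue  # rule i: no consensus-conforming placement
        for start, on_sequon in scored:
            if len(on_sequon) == best:
                for protein_pos in on_sequon:
                    motif = protein[protein_pos - 1 : protein_pos + 2]
                    sites[(acc, protein_pos)] = motif
    records = [
        GlycoSiteRecord(accession=acc, position=pos, motif=motif)
        for (acc, pos), motif in sorted(sites.items())
    ]
    report = {"n_sites": len(records), "n_peptides_skipped_unmappable": skipped_unmappable}
    return records, report


def compare_to_annotation(
    sites: list[GlycoSiteRecord],
    known: set[tuple[str, int]],
) -> tuple[list[GlycoSiteRecord], dict[str, int]]:
    """Label each site known/novel against an annotated (accession, position) set."""
    annotated = [
        GlycoSiteRecord(
            accession=s.accession,
            position=s.position,
            motif=s.motif,
            status="known" if (s.accession, s.position) in known else "novel",
        )
        for s in sites
    ]
    n_known = sum(1 for s in annotated if s.status == "known")
    summary = {"n_known": n_known, "n_novel": len(annotated) - n_known}
    return annotated, summary


def write_evidence_tsv(evidence: list[PeptideEvidence], path) -> None:
    """Write evidence as TSV: sequence, mods 'pos:delta:name;...',
    protein_group ';'-separated, proteotypic 0/1, start_positions
    'acc:pos,pos;...' (empty when unknown)."""
    with open(path, "w") as fh:
        fh.write("sequence\tmods\tprotein_group\tproteotypic\tstart_positions\n")
        for pep in evidence:
            mods = ";".join(f"{p}:{d:g}:{n}" for p, d, n in pep.mods)
            starts = ""
            if pep.start_positions:
                starts = ";".join(
                    f"{acc}:{','.join(map(str, pos))}"
                    for acc, pos in sorted(pep.start_positions.items())
                )
            fh.write(
                f"{pep.sequence}\t{mods}\t{';'.join(pep.protein_group)}\t"
                f"{int(pep.proteotypic)}\t{starts}\n"
            )


def read_evidence_tsv(path) -> list[PeptideEvidence]:
    """Read evidence written by :func:`write_evidence_tsv`."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for req in ("sequence", "mods", "protein_group", "proteotypic"):
            if req not in idx:
                raise ValueError(f"evidence file is missing column {req!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            mods = []
            if fields[idx["mods"]]:
                for item in fields[idx["mods"]].split(";"):
                    pos, delta, name = item.split(":")
                    mods.append((int(pos), float(delta), name))
            starts = None
            if "start_positions" in idx and len(fields) > idx["start_positions"] \
                    and fields[idx["start_positions"]]:
                starts = {}
                for item in fields[idx["start_positions"]].split(";"):
                    acc, positions = item.split(":")
                    starts[acc] = [int(p) for p in positions.split(",")]
            out.append(PeptideEvidence(
                sequence=fields[idx["sequence"]],
                mods=tuple(mods),
                protein_group=tuple(fields[idx["protein_group"]].split(";")),
                proteotypic=bool(int(fields[idx["proteotypic"]])),
                start_positions=starts,
            ))
    return out
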