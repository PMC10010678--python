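"""Placement of glycopeptides on protein sequences and terminus typing.

Each filtered glycopeptide is located on the protein database by exact
substring match, and each of its two termini is tested against the
tryptic boundary rule (cleavage C-terminal to K or R).  A terminus that
fails the test is evidence of O-glycoprotease cleavage; the peptide is
categorized as ``nterm``, ``cterm`` or ``both`` accordingly, and fully
tryptic peptides carry no cleavage evidence at all.

Protein termini are treated as tryptic-like: a peptide flush with the
start or end of its protein contributes no cleavage window on that side,
because a protein terminus says nothing about protease specificity.
With the default ``variable_cleavage`` initiator-methionine policy, a
peptide starting at residue 2 of a protein whose first residue is M is
also tryptic-like at its N-terminus (the Met was removed upstream of any
protease).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .psm_io import GlycoPSM, ProteinRecord

logger = logging.getLogger(__name__)

TRYPTIC_RESIDUES = frozenset("KR")


class TerminusCategory(Enum):
    FULLY_TRYPTIC = "fully_tryptic"
    NTERM = "nterm"
    CTERM = "cterm"
    BOTH = "both"


class MetPolicy(Enum):
    """How an initiator methionine affects N-terminus classification."""

    VARIABLE_CLEAVAGE = "variable_cleavage"
    FIXED = "fixed"


class AmbiguousPolicy(Enum):
    """What to do with peptides that occur at more than one locus."""

    DROP = "drop"
    ENUMERATE_ALL = "enumerate_all"


@dataclass(frozen=True)
class MappedGlycopeptide:
    """A GlycoPSM placed at one protein locus (1-based, inclusive)."""

    psm: GlycoPSM
    accession: str
    start: int
    end: int
    category: TerminusCategory
    ambiguous: bool = False


@dataclass
class MappingStats:
    n_input: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_ambiguous_dropped: int = 0
    category_counts: dict[str, int] | None = None


def locate_peptide(
    peptide: str, proteins: list[ProteinRecord]
) -> list[tuple[str, int]]:
    """All exact occurrences of ``peptide`` across ``proteins``.

    Returns ``(accession, start)`` pairs with 1-based starts, sorted by
    accession then start.  Overlapping occurrences are all reported.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    hits: list[tuple[str, int]] = []
    for protein in proteins:
        offset = protein.sequence.find(peptide)
        while offset != -1:
            hits.append((protein.accession, offset + 1))
            offset = protein.sequence.find(peptide, offset + 1)
    hits.sort()
    return hits


def classify_termini(
    accession: str,
    start: int,
    end: int,
    proteins: dict[str, ProteinRecord],
    cleavage_residues: frozenset[str] = TRYPTIC_RESIDUES,
    met_policy: MetPolicy = MetPolicy.VARIABLE_CLEAVAGE,
    proline_suppression: bool = False,
) -> TerminusCategory:
    """Categorize a peptide locus by which termini look tryptic.

    The N-terminus is tryptic-like when the peptide starts the protein,
    follows a removed initiator methionine (under ``variable_cleavage``),
    or follows a K/R residue.  The C-terminus is tryptic-like when the
    peptide ends the protein or its last residue is K/R.  Optional
    proline suppression vetoes a K/R boundary followed by P.
    """
    protein = proteins[accession]
    seq = protein.sequence
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(f"locus {start}-{end} out of bounds for {accession} (length {len(seq)})")

    n_tryptic = start == 1
    if (
        not n_tryptic
        and start == 2
        and met_policy is MetPolicy.VARIABLE_CLEAVAGE
        and seq[0] == "M"
    ):
        n_tryptic = True
    if not n_tryptic and seq[start - 2] in cleavage_residues:
        n_tryptic = not (proline_suppression and seq[start - 1] == "P")

    c_tryptic = end == len(seq)
    if not c_tryptic and seq[end - 1] in cleavage_residues:
        c_tryptic = not (proline_suppression and seq[end] == "P")

    if n_tryptic and c_tryptic:
        return TerminusCategory.FULLY_TRYPTIC
    if c_tryptic:
        return TerminusCategory.NTERM
    if n_tryptic:
        return TerminusCategory.CTERM
    return TerminusCategory.BOTH


def map_glycopeptides(
    records: list[GlycoPSM],
    proteins: list[ProteinRecord],
    met_policy: MetPolicy = MetPolicy.VARIABLE_CLEAVAGE,
    proline_suppression: bool = False,
    ambiguous_policy: AmbiguousPolicy = AmbiguousPolicy.DROP,
) -> tuple[list[MappedGlycopeptide], MappingStats]:
    """Place each record on the protein database and type its termini.

    Records whose sequence is absent from the database are dropped with
    a warning.  Multi-locus peptides follow ``ambiguous_policy``: the
    default drops them (a peptide at several loci contributes
    conflicting windows); ``enumerate_all`` emits one mapped peptide per
    locus, flagged ambiguous.
    """
    by_accession = {p.accession: p for p in proteins}
    stats = MappingStats(n_input=len(records), category_counts={c.value: 0 for c in TerminusCategory})
    mapped: list[MappedGlycopeptide] = []
    for record in records:
        loci = locate_peptide(record.base_sequence, proteins)
        if not loci:
            stats.n_unmapped += 1
            logger.warning("peptide %s not found in protein database", record.base_sequence)
            continue
        ambiguous = len(loci) > 1
        if ambiguous and ambiguous_policy is AmbiguousPolicy.DROP:
            stats.n_ambiguous_dropped += 1
            logger.info(
                "peptide %s occurs at %d loci; dropped under policy=drop",
                record.base_sequence,
                len(loci),
            )
            continue
        for accession, start in loci:
            end = start + len(record.base_sequence) - 1
            category = classify_termini(
                accession,
                start,
                end,
                by_accession,
                met_policy=met_policy,
                proline_suppression=proline_suppression,
            )
            mapped.append(
                MappedGlycopeptide(
                    psm=record,
                    accession=accession,
                    start=start,
                    end=end,
                    category=category,
                    ambiguous=ambiguous,
                )
            )
            stats.category_counts[category.value] += 1
    stats.n_mapped = len(mapped)
    return mapped, stats


def write_mapped_table(mapped: list[MappedGlycopeptide], path) -> None:
    """Write mapped peptides as TSV (one row per locus)."""
    import pandas as pd

    from .psm_io import _format_sites_cell

    rows = [
        {
            "accession": m.accession,
            "start": m.start,
            "end": m.end,
            "category": m.category.value,
            "ambiguous": str(m.ambiguous).lower(),
            "base_sequence": m.psm.base_sequence,
            "sites": _format_sites_cell(m.psm.sites),
        }
        for m in mapped
    ]
    pd.DataFrame(
        rows,
        columns=["accession", "start", "end", "category", "ambiguous", "base_sequence", "sites"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
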