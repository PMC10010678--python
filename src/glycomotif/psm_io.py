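"""Readers/writers and domain types for glycopeptide identification data.

The canonical in-memory record is :class:`GlycoPSM`, one row per
glycopeptide-spectrum match.  External tables (tab-separated, one header
row) are normalized into that schema through a :class:`ColumnMap`, so the
rest of the pipeline never sees search-engine-specific column names.

Glycan compositions use the single-letter monosaccharide-class code common
in O-glycoproteomics software output: N = HexNAc, H = Hex, A = NeuAc
(N-acetyl-neuraminic acid), G = NeuGc (N-glycolyl-neuraminic acid),
F = Fucose.  Only composition is modeled; structural isomers are out of
scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Canonical monosaccharide-class letters, in rendering order.
MONOSACCHARIDE_ORDER = "NHAGF"
_LETTER_TO_FIELD = {"N": "hexnac", "H": "hex", "A": "neuac", "G": "neugc", "F": "fuc"}
_FIELD_TO_LETTER = {v: k for k, v in _LETTER_TO_FIELD.items()}


class GlycanParseError(ValueError):
    """Raised when a glycan-composition string cannot be interpreted."""


class SchemaError(ValueError):
    """Raised when a PSM table lacks required mapped columns."""


class PsmTableError(ValueError):
    """Raised when rows of a PSM table fail parsing under strict mode."""


class FastaError(ValueError):
    """Raised for malformed protein FASTA content."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide-class counts for one O-glycan.

    Counts are non-negative and at least one monosaccharide must be
    present.  The canonical text rendering concatenates letter+count
    tokens in the fixed order N, H, A, G, F, omitting zero counts
    (e.g. ``"N1H1A1"`` for a mono-sialylated core-1 glycan).
    """

    hexnac: int = 0
    hex: int = 0
    neuac: int = 0
    neugc: int = 0
    fuc: int = 0

    def __post_init__(self) -> None:
        for name in _FIELD_TO_LETTER:
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"{name} count must be a non-negative integer, got {value!r}")
        if self.total == 0:
            raise ValueError("an O-glycan must contain at least one monosaccharide")

    @property
    def total(self) -> int:
        return self.hexnac + self.hex + self.neuac + self.neugc + self.fuc

    @property
    def is_sialylated(self) -> bool:
        """True if the composition contains NeuAc or NeuGc."""
        return self.neuac + self.neugc > 0

    def __str__(self) -> str:
        parts = []
        for letter in MONOSACCHARIDE_ORDER:
            count = getattr(self, _LETTER_TO_FIELD[letter])
            if count:
                parts.append(f"{letter}{count}")
        return "".join(parts)


_GLYCAN_TOKEN = re.compile(r"([A-Za-z])\((\d+)\)|([A-Za-z])(\d+)")


def parse_glycan_composition(text: str) -> GlycanComposition:
    """Parse a glycan composition string into class counts.

    Both the compact (``"N1H1A1"``) and parenthesized (``"N(1)H(1)A(1)"``)
    dialects are accepted; token order is free on input and canonicalized
    on output.  Repeated letters are summed.

    Raises
    ------
    GlycanParseError
        For empty input, unknown letter codes, zero counts, or text
        that is not a sequence of letter+count tokens.
    """
    stripped = text.strip()
    if not stripped:
        raise GlycanParseError("empty glycan composition")
    counts = {name: 0 for name in _FIELD_TO_LETTER}
    pos = 0
    while pos < len(stripped):
        m = _GLYCAN_TOKEN.match(stripped, pos)
        if m is None:
            raise GlycanParseError(f"malformed glycan token at {stripped[pos:]!r} in {text!r}")
        letter = (m.group(1) or m.group(3)).upper()
        count = int(m.group(2) or m.group(4))
        if letter not in _LETTER_TO_FIELD:
            raise GlycanParseError(f"unknown monosaccharide code {letter!r} in {text!r}")
        if count == 0:
            raise GlycanParseError(f"zero count for {letter!r} in {text!r}")
        counts[_LETTER_TO_FIELD[letter]] += count
        pos = m.end()
    return GlycanComposition(**counts)


class LocalizationLevel(Enum):
    """O-Pair-style site-localization confidence categories.

    Level1 means every glycosite on the peptide is confidently and
    unambiguously localized; lower levels carry residual ambiguity.
    ``unmodified`` marks records without any O-glycan.
    """

    LEVEL1 = "Level1"
    LEVEL1B = "Level1b"
    LEVEL2 = "Level2"
    LEVEL3 = "Level3"
    UNMODIFIED = "unmodified"


@dataclass(frozen=True)
class SiteAssignment:
    """One localized O-glycan on a peptide.

    ``peptide_position`` is 1-based within the peptide; the addressed
    residue must be serine or threonine.
    """

    peptide_position: int
    glycan: GlycanComposition
    localization_probability: float

    def __post_init__(self) -> None:
        if self.peptide_position < 1:
            raise ValueError(f"peptide_position must be >= 1, got {self.peptide_position}")
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValueError(
                f"localization_probability must lie in [0, 1], got {self.localization_probability}"
            )


@dataclass(frozen=True)
class GlycoPSM:
    """One glycopeptide-spectrum match."""

    source_file: str
    scan: str
    base_sequence: str
    protein_accession: str
    is_decoy: bool
    q_value: float
    localization_level: LocalizationLevel
    sites: tuple[SiteAssignment, ...] = ()

    def __post_init__(self) -> None:
        if not self.base_sequence or not set(self.base_sequence) <= _AA_SET:
            bad = sorted(set(self.base_sequence) - _AA_SET)
            raise ValueError(f"base_sequence contains non-standard residues {bad}")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value must lie in [0, 1], got {self.q_value}")
        object.__setattr__(self, "sites", tuple(self.sites))
        unmodified = self.localization_level is LocalizationLevel.UNMODIFIED
        if unmodified != (len(self.sites) == 0):
            raise ValueError("sites must be empty exactly for unmodified records")
        positions = [s.peptide_position for s in self.sites]
        if len(positions) != len(set(positions)):
            raise ValueError(f"duplicate site positions {positions}")
        for s in self.sites:
            if s.peptide_position > len(self.base_sequence):
                raise ValueError(
                    f"site position {s.peptide_position} beyond peptide of length "
                    f"{len(self.base_sequence)}"
                )
            residue = self.base_sequence[s.peptide_position - 1]
            if residue not in "ST":
                raise ValueError(
                    f"O-glycosite at position {s.peptide_position} addresses {residue!r}, "
                    "expected S or T"
                )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession (UniProt-style)."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaError(f"empty sequence for {self.accession!r}")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise FastaError(
                f"record {self.accession!r} contains non-standard residue(s) {sorted(bad)}"
            )


# ---------------------------------------------------------------------------
# Column maps


CANONICAL_COLUMNS = (
    "source_file",
    "scan",
    "base_sequence",
    "protein_accession",
    "is_decoy",
    "q_value",
    "localization_level",
    "sites",
)


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical GlycoPSM fields to source-table headers.

    ``decoy_format`` selects how the decoy column is interpreted:
    ``"bool"`` for true/false text (canonical dialect) or ``"tdc"`` for
    the target/decoy marker letters T and D used by search-engine output.
    ``site_format`` names the encoding of the site-assignment cell; the
    canonical dialect uses semicolon-separated ``pos:glycan:prob``
    triplets.
    """

    mapping: dict[str, str]
    decoy_format: str = "bool"
    site_format: str = "canonical"

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.mapping]
        if missing:
            raise SchemaError(f"column map lacks canonical field(s): {missing}")


CANONICAL_COLUMN_MAP = ColumnMap(mapping={c: c for c in CANONICAL_COLUMNS})

#: Best-effort adapter for MetaMorpheus O-Pair Search ``oglyco.psmtsv``
#: headers.  The native header names and localization-string grammar are
#: version-dependent; this map covers the commonly seen v0.0.32x headers
#: and the T/D target-decoy marker.  Validate against a real file before
#: relying on it for production data.
METAMORPHEUS_COLUMN_MAP = ColumnMap(
    mapping={
        "source_file": "File Name",
        "scan": "Scan Number",
        "base_sequence": "Base Sequence",
        "protein_accession": "Protein Accession",
        "is_decoy": "Decoy/Contaminant/Target",
        "q_value": "QValue",
        "localization_level": "GlycanLocalizationLevel",
        "sites": "Localized Glycans",
    },
    decoy_format="tdc",
    site_format="canonical",
)

COLUMN_MAPS = {
    "canonical": CANONICAL_COLUMN_MAP,
    "metamorpheus": METAMORPHEUS_COLUMN_MAP,
}


def _parse_sites_cell(cell: str) -> tuple[SiteAssignment, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    assignments = []
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        parts = token.split(":")
        if len(parts) != 3:
            raise ValueError(f"site token {token!r} is not a pos:glycan:prob triplet")
        pos = int(parts[0])
        glycan = parse_glycan_composition(parts[1])
        prob = float(parts[2])
        assignments.append(SiteAssignment(pos, glycan, prob))
    return tuple(assignments)


def _format_sites_cell(sites: Sequence[SiteAssignment]) -> str:
    return ";".join(
        f"{s.peptide_position}:{s.glycan}:{s.localization_probability!r}" for s in sites
    )


def _parse_decoy(cell: str, decoy_format: str) -> bool:
    text = cell.strip()
    if decoy_format == "tdc":
        if text.upper() in {"D", "DECOY"}:
            return True
        if text.upper() in {"T", "TARGET", "C", "CONTAMINANT"}:
            return False
        raise ValueError(f"unrecognized target/decoy marker {text!r}")
    if text.lower() in {"true", "1", "yes"}:
        return True
    if text.lower() in {"false", "0", "no"}:
        return False
    raise ValueError(f"unrecognized boolean {text!r}")


def read_psm_table(
    path: str | Path,
    column_map: ColumnMap = CANONICAL_COLUMN_MAP,
    strict: bool = True,
) -> list[GlycoPSM]:
    """Read a glycoPSM table into canonical records, preserving file order.

    With ``strict=True`` (default) any malformed row aborts the read with
    a :class:`PsmTableError` listing the offending row numbers; rows are
    never silently dropped.  ``strict=False`` downgrades row failures to
    warnings and logs the skipped-row count.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [
        canonical
        for canonical, source in column_map.mapping.items()
        if source not in frame.columns
    ]
    if missing:
        raise SchemaError(f"{path}: missing mapped column(s) for {missing}")

    records: list[GlycoPSM] = []
    errors: list[str] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        row_dict = dict(zip(frame.columns, row))
        try:
            get = lambda field: row_dict[column_map.mapping[field]]  # noqa: E731
            records.append(
                GlycoPSM(
                    source_file=get("source_file"),
                    scan=get("scan"),
                    base_sequence=get("base_sequence").strip().upper(),
                    protein_accession=get("protein_accession"),
                    is_decoy=_parse_decoy(get("is_decoy"), column_map.decoy_format),
                    q_value=float(get("q_value")),
                    localization_level=LocalizationLevel(get("localization_level").strip()),
                    sites=_parse_sites_cell(get("sites")),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {row_number}: {exc}")
    if errors:
        if strict:
            raise PsmTableError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
        logger.warning("%s: skipped %d malformed row(s)", path, len(errors))
    return records


def write_psm_table(records: Iterable[GlycoPSM], path: str | Path) -> None:
    """Write records as a canonical tab-separated glycoPSM table."""
    rows = [
        {
            "source_file": r.source_file,
            "scan": r.scan,
            "base_sequence": r.base_sequence,
            "protein_accession": r.protein_accession,
            "is_decoy": str(r.is_decoy).lower(),
            "q_value": repr(r.q_value),
            "localization_level": r.localization_level.value,
            "sites": _format_sites_cell(r.sites),
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# FASTA


def _accession_from_header(header: str) -> str:
    first = header.split()[0]
    if first.count("|") >= 2:
        return first.split("|")[1]
    return first


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records, resolving UniProt pipe-delimited accessions.

    For ``>sp|P12345|NAME ...`` headers the accession is the second pipe
    field; otherwise the first whitespace-delimited token.  Duplicate
    accessions and non-standard residues are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = _accession_from_header(entry.description or entry.id)
        if accession in seen:
            raise FastaError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                sequence=str(entry.seq).upper(),
                description=entry.description,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.description or r.accession, description="")
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# Glycan database


def read_glycan_database(path: str | Path) -> list[GlycanComposition]:
    """Read a glycan database: one composition per line, canonical notation.

    Blank lines and ``#`` comments are ignored.
    """
    compositions = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        compositions.append(parse_glycan_composition(line))
    return compositions


def write_glycan_database(compositions: Iterable[GlycanComposition], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\n" for c in compositions))
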