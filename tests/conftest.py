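from __future__ import annotations

import pytest

from glycomotif.mapping import MappedGlycopeptide, TerminusCategory
from glycomotif.motif import GAP, CleavageWindow, WindowSide, window_labels
from glycomotif.psm_io import (
    GlycoPSM,
    LocalizationLevel,
    ProteinRecord,
    SiteAssignment,
    parse_glycan_composition,
)


def make_psm(
    base_sequence: str = "TSAPTTR",
    sites: tuple[tuple[int, str, float], ...] = ((1, "N1", 0.9),),
    q_value: float = 0.005,
    is_decoy: bool = False,
    level: LocalizationLevel | None = None,
    source_file: str = "f1",
    scan: str = "1",
    accession: str = "P00001",
) -> GlycoPSM:
    """Build a GlycoPSM with sensible defaults for tests."""
    if level is None:
        level = LocalizationLevel.LEVEL1 if sites else LocalizationLevel.UNMODIFIED
    return GlycoPSM(
        source_file=source_file,
        scan=scan,
        base_sequence=base_sequence,
        protein_accession=accession,
        is_decoy=is_decoy,
        q_value=q_value,
        localization_level=level,
        sites=tuple(
            SiteAssignment(pos, parse_glycan_composition(g), prob) for pos, g, prob in sites
        ),
    )


def make_window(
    window: str,
    side: WindowSide = WindowSide.N_ALIGNED,
    glycans: dict[str, str] | None = None,
    covered: tuple[bool, ...] | None = None,
    source_file: str = "f1",
    base_sequence: str | None = None,
) -> CleavageWindow:
    """Build a standalone CleavageWindow for direct motif-statistic tests.

    All non-gap positions default to covered (glycan status observable).
    """
    flank = len(window) // 2
    if covered is None:
        covered = tuple(c != GAP for c in window)
    peptide = base_sequence or window.replace(GAP, "") or "AAAAA"
    psm = make_psm(base_sequence=peptide, sites=(), source_file=source_file)
    source = MappedGlycopeptide(
        psm=psm,
        accession="P00001",
        start=1,
        end=len(peptide),
        category=TerminusCategory.NTERM,
    )
    return CleavageWindow(
        window=window,
        side=side,
        accession="P00001",
        cleavage_site=flank,
        glycans_at={
            label: parse_glycan_composition(g) for label, g in (glycans or {}).items()
        },
        covered=covered,
        source=source,
        flank=flank,
    )


@pytest.fixture
def toy_protein() -> ProteinRecord:
    """M K T T S A P T T R — the worked mapping/window fixture."""
    return ProteinRecord(accession="P00001", sequence="MKTTSAPTTR")


@pytest.fixture
def labels10() -> tuple[str, ...]:
    return window_labels(5)
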