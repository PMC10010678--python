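"""Cleavage-window extraction and motif statistics.

Every non-tryptic terminus marks one inferred protease cleavage point.
Windows of five residues on each side of the cut (Schechter-Berger
positions P5..P1 | P1'..P5') are read from the *protein* sequence, so
context beyond the identified peptide is included; positions that fall
off the protein are padded with ``'-'`` and excluded from all
denominators.  N-terminal cleavage evidence aligns the peptide's first
residue at P1'; C-terminal evidence aligns the last residue at P1;
fully non-tryptic peptides contribute one window per side.

Three statistics summarize the windows, mirroring the three panels of a
cleavage-motif figure: a position frequency matrix with per-position
information content (the sequence logo), the percentage of S/T residues
at each position that carry a localized O-glycan, and the distribution
of glycan compositions observed at selected positions.

Glycosylation status is only observable for residues covered by the
identified peptide — a localized glycan cannot be reported for protein
context outside the peptide.  Percent-glycosylated therefore counts, by
default, only peptide-covered S/T residues in its denominator; padded
or uncovered positions are evidence of sequence, not of glycan absence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .mapping import MappedGlycopeptide, TerminusCategory
from .psm_io import AMINO_ACIDS, GlycanComposition, ProteinRecord

logger = logging.getLogger(__name__)

GAP = "-"


def window_labels(flank: int = 5) -> tuple[str, ...]:
    """Position labels P{flank}..P1, P1'..P{flank}' for a symmetric window."""
    unprimed = [f"P{k}" for k in range(flank, 0, -1)]
    primed = [f"P{k}'" for k in range(1, flank + 1)]
    return tuple(unprimed + primed)


#: Default 10-position labels for the standard +-5 residue window.
WINDOW_POSITIONS = window_labels(5)


class WindowSide(Enum):
    N_ALIGNED = "n_aligned"
    C_ALIGNED = "c_aligned"


@dataclass(frozen=True)
class CleavageWindow:
    """One aligned cleavage window.

    ``window`` holds the residues (with ``'-'`` padding) at positions
    P{flank}..P{flank}'.  ``cleavage_site`` is the inter-residue cut
    coordinate on the protein: the cut lies between protein residues
    ``cleavage_site`` and ``cleavage_site + 1``.  ``glycans_at`` maps a
    position label to the localized glycan observed there; ``covered``
    marks the positions that lie inside the identified peptide, i.e.
    where glycosylation status is observable.
    """

    window: str
    side: WindowSide
    accession: str
    cleavage_site: int
    glycans_at: dict[str, GlycanComposition]
    covered: tuple[bool, ...]
    source: MappedGlycopeptide
    flank: int = 5

    def __post_init__(self) -> None:
        if len(self.window) != 2 * self.flank:
            raise ValueError(
                f"window {self.window!r} has length {len(self.window)}, expected {2 * self.flank}"
            )
        labels = window_labels(self.flank)
        for label in self.glycans_at:
            if label not in labels:
                raise ValueError(f"unknown window position {label!r}")
            if self.window[labels.index(label)] not in "ST":
                raise ValueError(f"glycan recorded at non-S/T position {label}")


def _build_window(
    mapped: MappedGlycopeptide,
    protein: ProteinRecord,
    side: WindowSide,
    flank: int,
) -> CleavageWindow:
    seq = protein.sequence
    if side is WindowSide.N_ALIGNED:
        # peptide start occupies P1'; cut between start-1 and start
        first = mapped.start - flank  # protein coordinate at P{flank}
        cleavage_site = mapped.start - 1
    else:
        # peptide end occupies P1; cut between end and end+1
        first = mapped.end - flank + 1
        cleavage_site = mapped.end

    labels = window_labels(flank)
    chars: list[str] = []
    covered: list[bool] = []
    for offset in range(2 * flank):
        pos = first + offset  # 1-based protein coordinate
        if 1 <= pos <= len(seq):
            chars.append(seq[pos - 1])
        else:
            chars.append(GAP)
        covered.append(mapped.start <= pos <= mapped.end)

    glycans_at: dict[str, GlycanComposition] = {}
    for site in mapped.psm.sites:
        protein_pos = mapped.start + site.peptide_position - 1
        offset = protein_pos - first
        if 0 <= offset < 2 * flank:
            glycans_at[labels[offset]] = site.glycan

    return CleavageWindow(
        window="".join(chars),
        side=side,
        accession=mapped.accession,
        cleavage_site=cleavage_site,
        glycans_at=glycans_at,
        covered=tuple(covered),
        source=mapped,
        flank=flank,
    )


def extract_windows(
    mapped: Sequence[MappedGlycopeptide],
    proteins: list[ProteinRecord],
    flank: int = 5,
) -> list[CleavageWindow]:
    """Extract one window per non-tryptic terminus.

    Fully tryptic peptides are dropped here — they carry no protease
    cleavage evidence.  ``nterm`` peptides yield one N-aligned window,
    ``cterm`` one C-aligned window, and ``both`` peptides yield two.
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    by_accession = {p.accession: p for p in proteins}
    windows: list[CleavageWindow] = []
    n_tryptic = 0
    for m in mapped:
        if m.category is TerminusCategory.FULLY_TRYPTIC:
            n_tryptic += 1
            continue
        protein = by_accession[m.accession]
        if m.end > len(protein.sequence):
            raise ValueError(
                f"locus {m.start}-{m.end} inconsistent with {m.accession} "
                f"(length {len(protein.sequence)})"
            )
        if m.category in (TerminusCategory.NTERM, TerminusCategory.BOTH):
            windows.append(_build_window(m, protein, WindowSide.N_ALIGNED, flank))
        if m.category in (TerminusCategory.CTERM, TerminusCategory.BOTH):
            windows.append(_build_window(m, protein, WindowSide.C_ALIGNED, flank))
    if n_tryptic:
        logger.info("extract_windows: dropped %d fully tryptic peptide(s)", n_tryptic)
    return windows


def _flank_of(windows: Sequence[CleavageWindow]) -> int:
    flanks = {w.flank for w in windows}
    if len(flanks) > 1:
        raise ValueError(f"mixed window flanks {sorted(flanks)}")
    return flanks.pop()


def percent_glycosylated(
    windows: Sequence[CleavageWindow],
    observed_only: bool = True,
) -> dict[str, float | None]:
    """Fraction of S/T residues at each position carrying a localized glycan.

    Serine and threonine counts are summed into one aggregate
    denominator per position.  Positions with no S/T in the denominator
    report ``None`` (serialized ``NA``), never 0 — absence of S/T is not
    a claim of zero glycosylation.

    With ``observed_only`` (default), only window positions covered by
    the identified peptide enter the denominator, since glycosylation
    status outside the peptide is unobservable.  Setting it False counts
    every non-gap S/T, reproducing a naive pooled tally.
    """
    if not windows:
        raise ValueError("no windows")
    labels = window_labels(_flank_of(windows))
    numerator = {label: 0 for label in labels}
    denominator = {label: 0 for label in labels}
    for w in windows:
        for idx, label in enumerate(labels):
            if w.window[idx] not in "ST":
                continue
            if observed_only and not w.covered[idx]:
                continue
            denominator[label] += 1
            if label in w.glycans_at:
                numerator[label] += 1
    return {
        label: (numerator[label] / denominator[label] if denominator[label] else None)
        for label in labels
    }


def glycan_distribution(
    windows: Sequence[CleavageWindow],
    positions: Iterable[str] = ("P2", "P1", "P1'"),
) -> dict[str, dict[str, float]]:
    """Fractional distribution of glycan compositions at selected positions.

    Returns, per requested position label, a mapping from canonical
    composition text to its fraction among the glycans observed there
    (empty when none observed).
    """
    if not windows:
        raise ValueError("no windows")
    labels = window_labels(_flank_of(windows))
    positions = list(positions)
    for label in positions:
        if label not in labels:
            raise ValueError(f"unknown window position {label!r}; expected one of {labels}")
    result: dict[str, dict[str, float]] = {}
    for label in positions:
        counts: dict[str, int] = {}
        for w in windows:
            glycan = w.glycans_at.get(label)
            if glycan is not None:
                key = str(glycan)
                counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        result[label] = {k: v / total for k, v in sorted(counts.items())} if total else {}
    return result


def glycan_counts(
    windows: Sequence[CleavageWindow],
    positions: Iterable[str] = ("P2", "P1", "P1'"),
) -> pd.DataFrame:
    """Long-form glycan tally with per-source-file breakdown."""
    labels = window_labels(_flank_of(windows)) if windows else WINDOW_POSITIONS
    rows = []
    for label in positions:
        if label not in labels:
            raise ValueError(f"unknown window position {label!r}")
        tally: dict[tuple[str, str], int] = {}
        for w in windows:
            glycan = w.glycans_at.get(label)
            if glycan is not None:
                key = (str(glycan), w.source.psm.source_file)
                tally[key] = tally.get(key, 0) + 1
        total = sum(tally.values())
        for (composition, source_file), count in sorted(tally.items()):
            rows.append(
                {
                    "position": label,
                    "composition": composition,
                    "source_file": source_file,
                    "count": count,
                    "fraction": count / total,
                }
            )
    return pd.DataFrame(
        rows, columns=["position", "composition", "source_file", "count", "fraction"]
    )


LOG2_20 = math.log2(20)


def compute_logo(
    windows: Sequence[CleavageWindow],
    small_sample_correction: bool = False,
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Position frequency matrix and per-position information content.

    Frequencies are computed over the 20 residues among non-gap
    characters (gaps are excluded from the denominator).  Information
    content is ``log2(20) - H`` bits, where H is the Shannon entropy of
    the column.  The optional small-sample correction subtracts
    ``e(n) = 19 / (2 ln 2 n)`` (clamped at zero), the approximation used
    by classic logo renderers; it is off by default.  All-gap columns
    report ``None``.
    """
    if not windows:
        raise ValueError("no windows")
    labels = window_labels(_flank_of(windows))
    freq = pd.DataFrame(0.0, index=list(labels), columns=list(AMINO_ACIDS))
    ic: dict[str, float | None] = {}
    for idx, label in enumerate(labels):
        residues = [w.window[idx] for w in windows if w.window[idx] != GAP]
        n = len(residues)
        if n == 0:
            ic[label] = None
            continue
        for residue in residues:
            freq.loc[label, residue] += 1.0
        freq.loc[label] /= n
        entropy = -sum(
            f * math.log2(f) for f in freq.loc[label] if f > 0
        )
        content = LOG2_20 - entropy
        if small_sample_correction:
            content -= 19 / (2 * math.log(2) * n)
        ic[label] = max(content, 0.0)
    return freq, ic


@dataclass
class MotifReport:
    """The assembled cleavage-motif summary.

    Bundles the logo matrices, the percent-glycosylated profile, the
    glycan distributions at the configured positions, and bookkeeping
    counts (overall, per source file, per window side).
    """

    n_windows: int
    flank: int
    frequency_matrix: pd.DataFrame
    information_content: dict[str, float | None]
    n_nongap: dict[str, int]
    pct_glycosylated: dict[str, float | None]
    glycan_distribution: dict[str, dict[str, float]]
    glycan_table: pd.DataFrame
    per_file_counts: dict[str, int]
    side_counts: dict[str, int]
    counting_unit: str = "psm"
    small_sample_correction: bool = False

    @property
    def labels(self) -> tuple[str, ...]:
        return window_labels(self.flank)


def _unique_key(w: CleavageWindow):
    sites = tuple(
        sorted((s.peptide_position, str(s.glycan)) for s in w.source.psm.sites)
    )
    return (w.source.psm.base_sequence, sites, w.side.value, w.accession, w.cleavage_site)


def build_motif_report(
    windows: Sequence[CleavageWindow],
    pie_positions: Iterable[str] = ("P2", "P1", "P1'"),
    counting_unit: str = "psm",
    small_sample_correction: bool = False,
    observed_only: bool = True,
) -> MotifReport:
    """Assemble the full motif report from extracted windows.

    ``counting_unit`` selects the tallying unit: ``"psm"`` counts every
    identification record (default), ``"unique"`` collapses windows that
    share (sequence, site assignments, side, locus) to one.
    """
    if not windows:
        raise ValueError("cannot build a motif report from zero windows")
    if counting_unit not in ("psm", "unique"):
        raise ValueError(f"counting_unit must be 'psm' or 'unique', got {counting_unit!r}")
    if counting_unit == "unique":
        seen: dict = {}
        for w in windows:
            seen.setdefault(_unique_key(w), w)
        windows = list(seen.values())

    flank = _flank_of(windows)
    labels = window_labels(flank)
    freq, ic = compute_logo(windows, small_sample_correction=small_sample_correction)
    n_nongap = {
        label: sum(1 for w in windows if w.window[idx] != GAP)
        for idx, label in enumerate(labels)
    }
    per_file: dict[str, int] = {}
    side_counts = {side.value: 0 for side in WindowSide}
    for w in windows:
        f = w.source.psm.source_file
        per_file[f] = per_file.get(f, 0) + 1
        side_counts[w.side.value] += 1
    return MotifReport(
        n_windows=len(windows),
        flank=flank,
        frequency_matrix=freq,
        information_content=ic,
        n_nongap=n_nongap,
        pct_glycosylated=percent_glycosylated(windows, observed_only=observed_only),
        glycan_distribution=glycan_distribution(windows, pie_positions),
        glycan_table=glycan_counts(windows, pie_positions),
        per_file_counts=per_file,
        side_counts=side_counts,
        counting_unit=counting_unit,
        small_sample_correction=small_sample_correction,
    )


# ---------------------------------------------------------------------------
# Serialization


def _na(value: float | None, precision: int = 6) -> str:
    return "NA" if value is None else f"{value:.{precision}g}"


def write_motif_report_tsv(report: MotifReport, path: str | Path) -> None:
    """One row per window position: counts, IC, %glycosylated, frequencies."""
    rows = []
    for label in report.labels:
        frequencies = report.frequency_matrix.loc[label]
        top = frequencies.idxmax() if frequencies.max() > 0 else "NA"
        row = {
            "position": label,
            "n_nongap": report.n_nongap[label],
            "IC_bits": _na(report.information_content[label]),
            "pct_glycosylated": _na(report.pct_glycosylated[label]),
            "top_residue": top,
        }
        for residue in AMINO_ACIDS:
            row[residue] = f"{frequencies[residue]:.6g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_glycan_distribution_tsv(report: MotifReport, path: str | Path) -> None:
    report.glycan_table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_windows_tsv(windows: Sequence[CleavageWindow], path: str | Path) -> None:
    rows = [
        {
            "window": w.window,
            "side": w.side.value,
            "accession": w.accession,
            "cleavage_site": w.cleavage_site,
            "glycans_at": ";".join(f"{label}:{glycan}" for label, glycan in sorted(w.glycans_at.items())),
            "source_file": w.source.psm.source_file,
            "base_sequence": w.source.psm.base_sequence,
        }
        for w in windows
    ]
    pd.DataFrame(
        rows,
        columns=[
            "window",
            "side",
            "accession",
            "cleavage_site",
            "glycans_at",
            "source_file",
            "base_sequence",
        ],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_transfac_matrix(report: MotifReport, path: str | Path, name: str = "motif") -> None:
    """Count matrix in the transfac-like orientation accepted by logo tools."""
    lines = [f"ID {name}", f"BF {name}", "P0 " + " ".join(AMINO_ACIDS)]
    for idx, label in enumerate(report.labels, start=1):
        counts = (report.frequency_matrix.loc[label] * report.n_nongap[label]).round().astype(int)
        lines.append(f"{idx:02d} " + " ".join(str(counts[r]) for r in AMINO_ACIDS))
    lines.append("XX")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")
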