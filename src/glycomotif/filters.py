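"""Identification-quality filters for glycoPSM tables.

The high-confidence set used for motif generation keeps only target
(non-decoy) matches with q-value below 1% FDR, fully localized (Level 1)
glycosites with per-site probability above 0.75, no N-glycosylation
sequon on the peptide, and a minimum peptide length.  Unmodified records
are excluded from the glyco set.  All thresholds live in
:class:`FilterConfig` and every removal is counted, never silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .psm_io import GlycoPSM, LocalizationLevel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the identification-quality filter.

    Defaults reproduce the standard high-confidence O-glycoproteomics
    post-processing: ``q_value < 0.01`` (strict), Level 1 localization
    only, every site probability ``> 0.75`` (strict), exclusion of
    peptides containing an N-sequon (N-X-S/T, X != P), and a minimum
    length of 5 residues.
    """

    max_q: float = 0.01
    allowed_levels: frozenset[LocalizationLevel] = frozenset({LocalizationLevel.LEVEL1})
    min_site_probability: float = 0.75
    exclude_n_sequon: bool = True
    min_peptide_length: int = 5
    targets_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.max_q <= 1.0:
            raise ValueError(f"max_q must lie in (0, 1], got {self.max_q}")
        if not 0.0 <= self.min_site_probability <= 1.0:
            raise ValueError(
                f"min_site_probability must lie in [0, 1], got {self.min_site_probability}"
            )
        object.__setattr__(self, "allowed_levels", frozenset(self.allowed_levels))


#: Criterion names in evaluation order, used for removal accounting.
CRITERIA = (
    "decoy",
    "q_value",
    "localization_level",
    "site_probability",
    "n_sequon",
    "peptide_length",
    "unmodified",
)


@dataclass
class FilterStats:
    """Removal accounting for one filter pass.

    ``first_failure`` attributes each removed record to the first
    criterion (in :data:`CRITERIA` order) it failed; ``any_failure``
    counts every criterion a record failed, so its values can sum to
    more than the number of removed records.
    """

    n_input: int = 0
    n_output: int = 0
    first_failure: dict[str, int] = field(default_factory=dict)
    any_failure: dict[str, int] = field(default_factory=dict)
    per_file_output: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_output


def has_n_sequon(sequence: str) -> bool:
    """True if the sequence contains an N-glycosylation sequon.

    The sequon is N-X-S/T where X is any residue except proline.
    Sequences shorter than three residues return False.
    """
    for i in range(len(sequence) - 2):
        if sequence[i] == "N" and sequence[i + 1] != "P" and sequence[i + 2] in "ST":
            return True
    return False


def _failed_criteria(record: GlycoPSM, cfg: FilterConfig) -> list[str]:
    failed = []
    if cfg.targets_only and record.is_decoy:
        failed.append("decoy")
    if not record.q_value < cfg.max_q:
        failed.append("q_value")
    if record.localization_level not in cfg.allowed_levels:
        failed.append("localization_level")
    if any(not s.localization_probability > cfg.min_site_probability for s in record.sites):
        failed.append("site_probability")
    if cfg.exclude_n_sequon and has_n_sequon(record.base_sequence):
        failed.append("n_sequon")
    if len(record.base_sequence) < cfg.min_peptide_length:
        failed.append("peptide_length")
    if record.localization_level is LocalizationLevel.UNMODIFIED:
        failed.append("unmodified")
    return failed


def filter_with_stats(
    records: list[GlycoPSM], cfg: FilterConfig | None = None
) -> tuple[list[GlycoPSM], FilterStats]:
    """Apply all enabled criteria; return retained records plus accounting."""
    cfg = cfg or FilterConfig()
    stats = FilterStats(
        n_input=len(records),
        first_failure={c: 0 for c in CRITERIA},
        any_failure={c: 0 for c in CRITERIA},
    )
    kept: list[GlycoPSM] = []
    for record in records:
        failed = _failed_criteria(record, cfg)
        if failed:
            stats.first_failure[failed[0]] += 1
            for criterion in failed:
                stats.any_failure[criterion] += 1
        else:
            kept.append(record)
            stats.per_file_output[record.source_file] = (
                stats.per_file_output.get(record.source_file, 0) + 1
            )
    stats.n_output = len(kept)
    for criterion in CRITERIA:
        if stats.any_failure[criterion]:
            logger.info(
                "filter: %d record(s) failed %s", stats.any_failure[criterion], criterion
            )
    logger.info("filter: retained %d of %d records", stats.n_output, stats.n_input)
    return kept, stats


def filter_identifications(
    records: list[GlycoPSM], cfg: FilterConfig | None = None
) -> list[GlycoPSM]:
    """Retain records satisfying every enabled quality criterion."""
    kept, _ = filter_with_stats(records, cfg)
    return kept
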