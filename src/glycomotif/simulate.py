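"""Synthetic glycoproteins, glycan-conditional proteolysis and PSM tables.

No identification search engine can condition cleavage on the presence
of a modification, so the discovery pipeline is sequence-only by design.
This module closes the loop for testing: it simulates the *true*
biology — an O-glycoprotease whose cleavage requires an O-glycan in a
specific register — and emits identification tables in the canonical
dialect, with controllable noise (decoys, q-values above threshold,
mislocalized glycosites).  Running the discovery pipeline on these
tables and checking that the programmed motif is recovered is the
package's core end-to-end test.

The cleavage model is intentionally minimal: every sequence-rule site
whose conditioning residue (P1' for OgpA/IMPa-style enzymes, P2 for
StcE-style) carries an O-glycan is cut independently with a fixed
efficiency, scaled down by a multiplicative penalty when the
conditioning glycan is sialylated (OgpA is far less efficient against
sialylated O-glycans; IMPa is indifferent, multiplier 1).  For
P1'-conditioned enzymes a glycan sitting at P1 blocks the cut by
default, modeling steric occlusion of the scissile bond by the adjacent
glycan — consistent with the observed absence of glycosylated P1
residues in OgpA cleavage motifs.  This is a model choice about the
simulator, not a claim about enzyme kinetics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .protease import OGPA, STCE, ProteaseRule, Specificity, enumerate_cleavage_sites
from .psm_io import (
    GlycanComposition,
    GlycoPSM,
    LocalizationLevel,
    ProteinRecord,
    SiteAssignment,
    write_psm_table,
)

logger = logging.getLogger(__name__)

#: A simple core-1/Tn glycan menu: mostly T-antigen with some Tn-antigen,
#: the composition mix dominating mucin-type O-glycosylation.
DEFAULT_GLYCAN_MENU = {
    GlycanComposition(hexnac=1): 0.3,
    GlycanComposition(hexnac=1, hex=1): 0.7,
}


@dataclass(frozen=True)
class GlycoproteinModel:
    """A protein with per-site O-glycan occupancy and a glycan menu."""

    protein: ProteinRecord
    site_occupancy: dict[int, float]
    glycan_menu: dict[GlycanComposition, float] = field(
        default_factory=lambda: dict(DEFAULT_GLYCAN_MENU)
    )

    def __post_init__(self) -> None:
        for pos, p in self.site_occupancy.items():
            residue = self.protein.sequence[pos - 1]
            if residue not in "ST":
                raise ValueError(f"occupancy at position {pos} addresses {residue!r}, not S/T")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occupancy {p} at position {pos} outside [0, 1]")
        if not self.glycan_menu:
            raise ValueError("glycan_menu must be non-empty")
        for weight in self.glycan_menu.values():
            if weight <= 0:
                raise ValueError("glycan menu weights must be positive")


def random_protein(
    rng: np.random.Generator,
    length: int = 400,
    st_fraction: float = 0.2,
    accession: str = "SYN1",
) -> ProteinRecord:
    """A random protein with a controlled Ser/Thr density.

    S and T each receive half of ``st_fraction``; the remaining mass is
    spread uniformly over the other 18 residues (which keeps K/R at
    ~4.4% each, enough tryptic sites for realistic fragments).  The
    first residue is forced to M, matching translated sequences.
    """
    others = [a for a in "ACDEFGHIKLMNPQRVWY" if a not in "ST"]
    letters = list("ST") + others
    probs = [st_fraction / 2] * 2 + [(1 - st_fraction) / len(others)] * len(others)
    body = "".join(rng.choice(letters, size=length - 1, p=probs))
    return ProteinRecord(accession=accession, sequence="M" + body)


def default_model(
    protein: ProteinRecord,
    occupancy: float = 0.5,
    glycan_menu: dict[GlycanComposition, float] | None = None,
) -> GlycoproteinModel:
    """Uniform-occupancy model over every S/T residue of the protein."""
    sites = {
        i + 1: occupancy for i, residue in enumerate(protein.sequence) if residue in "ST"
    }
    return GlycoproteinModel(
        protein=protein,
        site_occupancy=sites,
        glycan_menu=dict(glycan_menu or DEFAULT_GLYCAN_MENU),
    )


#: One glycoform instance: occupied protein position -> composition.
Glycoform = dict[int, GlycanComposition]


def simulate_glycoforms(
    model: GlycoproteinModel, n: int, rng: np.random.Generator
) -> list[Glycoform]:
    """Draw ``n`` independent glycoforms of the modeled protein."""
    menu = sorted(model.glycan_menu.items(), key=lambda kv: str(kv[0]))
    compositions = [c for c, _ in menu]
    weights = np.array([w for _, w in menu], dtype=float)
    weights /= weights.sum()
    positions = sorted(model.site_occupancy)
    instances: list[Glycoform] = []
    for _ in range(n):
        glycoform: Glycoform = {}
        for pos in positions:
            if rng.random() < model.site_occupancy[pos]:
                glycoform[pos] = compositions[rng.choice(len(compositions), p=weights)]
        instances.append(glycoform)
    return instances


@dataclass(frozen=True)
class GlycoCleavageConfig:
    """Glycan-conditional cleavage parameters for the simulated protease.

    ``conditioned_position`` names the register whose O-glycan licenses
    the cut: ``"p1prime"`` (OgpA/IMPa style, cut immediately N-terminal
    to the glycosylated S/T) or ``"p2"`` (StcE style).  ``efficiency``
    is the per-site cut probability for a licensed site;
    ``sialylation_multiplier`` scales it when the conditioning glycan
    contains NeuAc/NeuGc.  ``blocked_by_p1_glycan`` vetoes a cut whose
    P1 residue itself carries a glycan (see module docstring).
    """

    rule: ProteaseRule = OGPA
    conditioned_position: str = "p1prime"
    efficiency: float = 0.9
    sialylation_multiplier: float = 1.0
    blocked_by_p1_glycan: bool = True

    def __post_init__(self) -> None:
        if self.conditioned_position not in ("p1prime", "p2"):
            raise ValueError("conditioned_position must be 'p1prime' or 'p2'")
        for name in ("efficiency", "sialylation_multiplier"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.rule.specificity is Specificity.NONSPECIFIC:
            raise ValueError("glycan-conditional cleavage needs a specific sequence rule")


def ogpa_style_config(**overrides) -> GlycoCleavageConfig:
    """OgpA-like enzyme: |S / |T conditioned at P1', sialylation-sensitive."""
    defaults = dict(rule=OGPA, conditioned_position="p1prime", blocked_by_p1_glycan=True)
    defaults.update(overrides)
    return GlycoCleavageConfig(**defaults)


def stce_style_config(**overrides) -> GlycoCleavageConfig:
    """StcE-like enzyme: [ST]x|[ST] conditioned at P2, glycan-tolerant at P1."""
    defaults = dict(rule=STCE, conditioned_position="p2", blocked_by_p1_glycan=False)
    defaults.update(overrides)
    return GlycoCleavageConfig(**defaults)


@dataclass(frozen=True)
class NoiseConfig:
    """Noise injected into emitted PSM tables.

    ``q_above_fraction`` of records draw their q-value uniformly from
    ``q_above_range`` (failing the q < 0.01 filter); the rest draw from
    ``q_below_range``.  ``decoy_fraction`` of records are replaced by
    reversed-sequence decoys.  ``false_localization_rate`` of records
    have one glycan moved to a different S/T on the peptide, with the
    site probability and localization level downgraded accordingly.
    """

    false_localization_rate: float = 0.0
    decoy_fraction: float = 0.0
    q_above_fraction: float = 0.0
    q_above_range: tuple[float, float] = (0.011, 0.05)
    q_below_range: tuple[float, float] = (0.0001, 0.009)

    def __post_init__(self) -> None:
        for name in ("false_localization_rate", "decoy_fraction", "q_above_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full study design for one simulated experiment."""

    glyco: GlycoCleavageConfig = field(default_factory=ogpa_style_config)
    trypsin_stage: bool = True
    trypsin_miss_probability: float = 0.0
    n_glycoforms: int = 20
    n_psms: int = 1000
    min_peptide_length: int = 5
    max_peptide_length: int = 60
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    source_files: tuple[str, ...] = ("sim_rep1", "sim_rep2")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_psms < 1:
            raise ValueError(f"n_psms must be >= 1, got {self.n_psms}")
        if self.n_glycoforms < 1:
            raise ValueError("n_glycoforms must be >= 1")
        if not 0.0 <= self.trypsin_miss_probability <= 1.0:
            raise ValueError("trypsin_miss_probability must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedPeptide:
    """A proteolytic fragment carrying its true site assignments."""

    accession: str
    start: int
    end: int
    sequence: str
    sites: dict[int, GlycanComposition]  # protein coordinates
    nterm_origin: str  # "protein" | "glyco" | "tryptic"
    cterm_origin: str


def simulate_digest(
    model: GlycoproteinModel,
    glycoform: Glycoform,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[SimulatedPeptide], list[int]]:
    """Digest one glycoform; return glycopeptide fragments and realized cuts.

    Candidate sites are the sequence-rule sites whose conditioning
    register is occupied on this glycoform (and, for P1'-conditioned
    enzymes with blocking enabled, whose P1 residue is unglycosylated).
    Each candidate is cut independently with probability
    ``efficiency * multiplier``; an optional complete (or leaky) tryptic
    stage follows.  Only fragments within the length bounds that carry
    at least one glycan are returned.
    """
    seq = model.protein.sequence
    length = len(seq)
    glyco_cfg = cfg.glyco

    realized: list[int] = []
    for site in enumerate_cleavage_sites(seq, glyco_cfg.rule):
        conditioning_pos = site + 1 if glyco_cfg.conditioned_position == "p1prime" else site - 1
        glycan = glycoform.get(conditioning_pos)
        if glycan is None:
            continue
        if (
            glyco_cfg.blocked_by_p1_glycan
            and glyco_cfg.conditioned_position == "p1prime"
            and site in glycoform
        ):
            continue
        p = glyco_cfg.efficiency
        if glycan.is_sialylated:
            p *= glyco_cfg.sialylation_multiplier
        # one draw per candidate regardless of outcome, so runs that share a
        # seed but differ in the multiplier stay coupled (same randomness)
        if rng.random() < p:
            realized.append(site)

    cuts = set(realized)
    cut_origin = {site: "glyco" for site in realized}
    if cfg.trypsin_stage:
        for i in range(1, length):
            if seq[i - 1] in "KR" and i not in cuts:
                if cfg.trypsin_miss_probability == 0.0 or rng.random() >= cfg.trypsin_miss_probability:
                    cuts.add(i)
                    cut_origin[i] = "tryptic"

    boundaries = [0] + sorted(cuts) + [length]
    fragments: list[SimulatedPeptide] = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        start, end = a + 1, b
        if not cfg.min_peptide_length <= end - start + 1 <= cfg.max_peptide_length:
            continue
        carried = {pos: g for pos, g in glycoform.items() if start <= pos <= end}
        if not carried:
            continue
        fragments.append(
            SimulatedPeptide(
                accession=model.protein.accession,
                start=start,
                end=end,
                sequence=seq[start - 1 : end],
                sites=carried,
                nterm_origin="protein" if a == 0 else cut_origin[a],
                cterm_origin="protein" if b == length else cut_origin[b],
            )
        )
    return fragments, sorted(realized)


def simulate_experiment(
    models: Sequence[GlycoproteinModel],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimulatedPeptide], dict[str, dict[int, int]]]:
    """Digest ``n_glycoforms`` glycoforms of every model.

    Returns the pooled fragments plus, per accession, a tally of how
    often each glyco-rule cut site was realized (the ground truth for
    recovery scoring).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    fragments: list[SimulatedPeptide] = []
    cut_tally: dict[str, dict[int, int]] = {m.protein.accession: {} for m in models}
    for model in models:
        glycoforms = simulate_glycoforms(model, cfg.n_glycoforms, rng)
        for glycoform in glycoforms:
            frags, realized = simulate_digest(model, glycoform, cfg, rng)
            fragments.extend(frags)
            tally = cut_tally[model.protein.accession]
            for site in realized:
                tally[site] = tally.get(site, 0) + 1
    return fragments, cut_tally


def _reverse_decoy(record: GlycoPSM) -> GlycoPSM:
    length = len(record.base_sequence)
    return replace(
        record,
        base_sequence=record.base_sequence[::-1],
        protein_accession=f"rev_{record.protein_accession}",
        is_decoy=True,
        sites=tuple(
            replace(s, peptide_position=length + 1 - s.peptide_position)
            for s in record.sites
        ),
    )


def _mislocalize(record: GlycoPSM, rng: np.random.Generator) -> GlycoPSM:
    """Move one glycan to a different S/T and downgrade confidence."""
    occupied = {s.peptide_position for s in record.sites}
    candidates = [
        i + 1
        for i, residue in enumerate(record.base_sequence)
        if residue in "ST" and i + 1 not in occupied
    ]
    if not candidates or not record.sites:
        return record
    victim = int(rng.choice(len(record.sites)))
    target = int(candidates[int(rng.choice(len(candidates)))])
    sites = list(record.sites)
    sites[victim] = SiteAssignment(
        peptide_position=target,
        glycan=sites[victim].glycan,
        localization_probability=0.5,
    )
    return replace(record, sites=tuple(sites), localization_level=LocalizationLevel.LEVEL2)


def build_psm_records(
    fragments: Sequence[SimulatedPeptide],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> list[GlycoPSM]:
    """Turn fragments into identification records with configured noise.

    By default ``n_psms`` records are sampled with replacement from the
    fragment pool (emulating repeated spectral sampling of abundant
    species); ``exhaustive`` instead emits each fragment exactly once
    with no resampling.
    """
    if not fragments:
        raise ValueError("no glycopeptide fragments to emit")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    noise = cfg.noise
    if exhaustive:
        chosen = list(fragments)
    else:
        indices = rng.choice(len(fragments), size=cfg.n_psms, replace=True)
        chosen = [fragments[i] for i in indices]

    records: list[GlycoPSM] = []
    for scan, fragment in enumerate(chosen, start=1):
        if noise.q_above_fraction > 0 and rng.random() < noise.q_above_fraction:
            q = float(rng.uniform(*noise.q_above_range))
        else:
            q = float(rng.uniform(*noise.q_below_range))
        sites = tuple(
            SiteAssignment(
                peptide_position=pos - fragment.start + 1,
                glycan=glycan,
                localization_probability=float(rng.uniform(0.8, 1.0)),
            )
            for pos, glycan in sorted(fragment.sites.items())
        )
        record = GlycoPSM(
            source_file=cfg.source_files[(scan - 1) % len(cfg.source_files)],
            scan=str(scan),
            base_sequence=fragment.sequence,
            protein_accession=fragment.accession,
            is_decoy=False,
            q_value=q,
            localization_level=LocalizationLevel.LEVEL1,
            sites=sites,
        )
        if noise.false_localization_rate > 0 and rng.random() < noise.false_localization_rate:
            record = _mislocalize(record, rng)
        if noise.decoy_fraction > 0 and rng.random() < noise.decoy_fraction:
            record = _reverse_decoy(record)
        records.append(record)
    return records


def emit_psm_table(
    fragments: Sequence[SimulatedPeptide],
    cfg: SimulationConfig,
    path: str | Path,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> list[GlycoPSM]:
    """Write a canonical glycoPSM TSV for the simulated experiment."""
    records = build_psm_records(fragments, cfg, rng=rng, exhaustive=exhaustive)
    write_psm_table(records, path)
    return records


def write_ground_truth(
    cut_tally: dict[str, dict[int, int]],
    models: Sequence[GlycoproteinModel],
    path: str | Path,
) -> None:
    """True glyco-rule cleavage sites and their realized counts, as TSV."""
    by_accession = {m.protein.accession: m for m in models}
    rows = []
    for accession, tally in sorted(cut_tally.items()):
        seq = by_accession[accession].protein.sequence
        for site, count in sorted(tally.items()):
            rows.append(
                {
                    "accession": accession,
                    "cleavage_site": site,
                    "p1": seq[site - 1],
                    "p1_prime": seq[site],
                    "n_realized": count,
                }
            )
    pd.DataFrame(
        rows, columns=["accession", "cleavage_site", "p1", "p1_prime", "n_realized"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
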