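"""Declarative protease cleavage rules and in-silico digestion.

A rule is a set of cleavage contexts over the P2-P1-P1' positions
around a candidate scissile bond (cut between P1 and P1'), plus a
specificity mode (full / semi / nonspecific), missed-cleavage budget and
length bounds.  Contexts are written in a compact mini-grammar:

* ``K|``        — cut C-terminal to K (P1 = K), as in trypsin ``K|, R|``
* ``|T``        — cut N-terminal to T (P1' = T), as in the
  O-glycoproteases OgpA and IMPa which cleave immediately N-terminal to
  O-glycosylated Ser/Thr (sequence-only approximation here)
* ``[ST]x|[ST]`` — P2 in {S,T}, P1 free, P1' in {S,T}: the StcE motif
  T/S-X-T/S with cleavage between P1 and P1'

``x`` is the single-position wildcard and ``[..]`` a residue class.
Rules combine by unioning their contexts, which models sequential
digestions such as OgpA-then-trypsin; note that missed-cleavage
accounting then counts *all* sites of the combined rule, so S/T-rich
peptides consume the budget quickly — the reason combined glycoprotease
rules ship with a large default budget (12).

The rule engine is deliberately sequence-only: no identification search
engine conditions cleavage on a modification, so discovered motifs must
be expressible as sequence contexts.  Glycan-conditional cleavage is
modeled in the simulator instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .psm_io import AMINO_ACIDS


class Specificity(Enum):
    FULL = "full"
    SEMI = "semi"
    NONSPECIFIC = "nonspecific"


@dataclass(frozen=True)
class CutSpec:
    """One cleavage context: residue classes at P2, P1, P1' (None = wildcard)."""

    p2: frozenset[str] | None = None
    p1: frozenset[str] | None = None
    p1prime: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name in ("p2", "p1", "p1prime"):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, frozenset(value))

    def compact(self) -> str:
        def token(cls: frozenset[str] | None) -> str:
            if cls is None:
                return "x"
            if len(cls) == 1:
                return next(iter(cls))
            return "[" + "".join(sorted(cls)) + "]"

        left = ""
        if self.p2 is not None:
            left += token(self.p2)
        if self.p2 is not None or self.p1 is not None:
            left += token(self.p1)
        return f"{left}|{token(self.p1prime) if self.p1prime is not None else ''}"


_TOKEN = re.compile(r"\[([A-Z]+)\]|([A-Z])|(x)")


def _tokenize(text: str) -> list[frozenset[str] | None]:
    classes: list[frozenset[str] | None] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise ValueError(f"bad token at {text[pos:]!r}")
        if m.group(1):
            classes.append(frozenset(m.group(1)))
        elif m.group(2):
            classes.append(frozenset(m.group(2)))
        else:
            classes.append(None)
        pos = m.end()
    return classes


def parse_cut_spec(text: str) -> CutSpec:
    """Parse the compact context notation (``K|``, ``|T``, ``[ST]x|[ST]``)."""
    if text.count("|") != 1:
        raise ValueError(f"cut spec {text!r} must contain exactly one '|'")
    left_text, right_text = text.split("|")
    left = _tokenize(left_text.strip())
    right = _tokenize(right_text.strip())
    if len(left) > 2:
        raise ValueError(f"cut spec {text!r}: at most P2 and P1 allowed left of '|'")
    if len(right) > 1:
        raise ValueError(f"cut spec {text!r}: only P1' allowed right of '|'")
    p1 = left[-1] if left else None
    p2 = left[-2] if len(left) == 2 else None
    p1prime = right[0] if right else None
    return CutSpec(p2=p2, p1=p1, p1prime=p1prime)


@dataclass(frozen=True)
class ProteaseRule:
    """A named digestion specification."""

    name: str
    cut_specs: tuple[CutSpec, ...] = ()
    specificity: Specificity = Specificity.FULL
    min_length: int = 5
    max_length: int = 60
    max_missed: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "cut_specs", tuple(self.cut_specs))
        if self.min_length < 1:
            raise ValueError(f"min_length must be >= 1, got {self.min_length}")
        if self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")
        if self.specificity is not Specificity.NONSPECIFIC:
            for spec in self.cut_specs:
                if spec.p1 is None and spec.p1prime is None:
                    raise ValueError(
                        f"rule {self.name!r}: cut spec {spec.compact()!r} constrains "
                        "neither P1 nor P1'"
                    )


def combine_rules(name: str, *rules: ProteaseRule, max_missed: int = 12) -> ProteaseRule:
    """Union of cleavage contexts, modeling sequential protease treatments."""
    specs: list[CutSpec] = []
    for rule in rules:
        specs.extend(rule.cut_specs)
    return ProteaseRule(
        name=name,
        cut_specs=tuple(dict.fromkeys(specs)),
        specificity=Specificity.FULL,
        min_length=min(r.min_length for r in rules),
        max_length=max(r.max_length for r in rules),
        max_missed=max_missed,
    )


_TRYPSIN_SPECS = (parse_cut_spec("K|"), parse_cut_spec("R|"))
_OGPA_SPECS = (parse_cut_spec("|T"), parse_cut_spec("|S"))
_STCE_SPECS = (parse_cut_spec("[ST]x|[ST]"),)

TRYPSIN = ProteaseRule("Trypsin", _TRYPSIN_SPECS, Specificity.FULL, 5, 60, 3)
SEMI_TRYPSIN = ProteaseRule("Semi-Trypsin", _TRYPSIN_SPECS, Specificity.SEMI, 5, 60, 3)
NON_SPECIFIC = ProteaseRule("Non-Specific", (), Specificity.NONSPECIFIC, 5, 60, 0)
OGPA = ProteaseRule("OgpA", _OGPA_SPECS, Specificity.FULL, 5, 60, 3)
IMPA = ProteaseRule("IMPa", _OGPA_SPECS, Specificity.FULL, 5, 60, 3)
STCE = ProteaseRule("StcE", _STCE_SPECS, Specificity.FULL, 5, 60, 3)
OGPA_TRYPSIN = combine_rules("OgpA-Trypsin", OGPA, TRYPSIN, max_missed=12)
STCE_TRYPSIN = combine_rules("StcE-Trypsin", STCE, TRYPSIN, max_missed=12)

BUILTIN_RULES: dict[str, ProteaseRule] = {
    rule.name: rule
    for rule in (
        TRYPSIN,
        SEMI_TRYPSIN,
        NON_SPECIFIC,
        OGPA,
        IMPA,
        STCE,
        OGPA_TRYPSIN,
        STCE_TRYPSIN,
    )
}


def get_rule(name: str, extra: dict[str, ProteaseRule] | None = None) -> ProteaseRule:
    """Look up a rule by name (case-insensitive), raising with suggestions."""
    pool = dict(BUILTIN_RULES)
    if extra:
        pool.update(extra)
    for key, rule in pool.items():
        if key.lower() == name.lower():
            return rule
    raise KeyError(f"unknown protease rule {name!r}; available: {sorted(pool)}")


def enumerate_cleavage_sites(sequence: str, rule: ProteaseRule) -> list[int]:
    """Inter-residue cut positions matched by the rule.

    Site ``i`` denotes a cut between residues ``i`` and ``i+1``
    (1-based), so valid sites run from 1 to ``len(sequence) - 1``.  For
    a nonspecific rule every bond is a site.
    """
    length = len(sequence)
    if length == 0:
        raise ValueError("sequence must be non-empty")
    if rule.specificity is Specificity.NONSPECIFIC:
        return list(range(1, length))
    sites = []
    for i in range(1, length):
        p1 = sequence[i - 1]
        p1prime = sequence[i]
        for spec in rule.cut_specs:
            if spec.p1 is not None and p1 not in spec.p1:
                continue
            if spec.p1prime is not None and p1prime not in spec.p1prime:
                continue
            if spec.p2 is not None:
                if i < 2 or sequence[i - 2] not in spec.p2:
                    continue
            sites.append(i)
            break
    return sites


def digest(
    sequence: str,
    rule: ProteaseRule,
    missed: int | None = None,
    min_length: int | None = None,
    max_length: int | None = None,
    met_variants: bool = False,
) -> list[tuple[int, int]]:
    """Enumerate peptide loci ``(start, end)`` (1-based, inclusive).

    Full specificity yields fragments whose termini both sit at rule
    sites or protein ends, with at most ``missed`` internal sites; semi
    requires one conforming terminus and leaves the other free with the
    same internal-site accounting; nonspecific yields every substring
    within the length bounds.  ``met_variants`` additionally emits, for
    each peptide starting at residue 1 of a Met-initiated sequence, the
    variant with the initiator Met removed.  Results are deduplicated
    and sorted.
    """
    if missed is None:
        missed = rule.max_missed
    if missed < 0:
        raise ValueError("missed must be >= 0")
    lo = rule.min_length if min_length is None else min_length
    hi = rule.max_length if max_length is None else max_length
    length = len(sequence)
    loci: set[tuple[int, int]] = set()

    if rule.specificity is Specificity.NONSPECIFIC:
        for plen in range(lo, min(hi, length) + 1):
            for start in range(1, length - plen + 2):
                loci.add((start, start + plen - 1))
    else:
        sites = enumerate_cleavage_sites(sequence, rule)
        boundaries = [0] + sites + [length]
        if rule.specificity is Specificity.FULL:
            for a in range(len(boundaries) - 1):
                for b in range(a + 1, len(boundaries)):
                    if b - a - 1 > missed:
                        break
                    start, end = boundaries[a] + 1, boundaries[b]
                    if lo <= end - start + 1 <= hi:
                        loci.add((start, end))
        else:  # semi
            boundary_set = set(boundaries)
            # prefix[i] = number of sites <= i
            prefix = [0] * (length + 1)
            site_set = set(sites)
            for i in range(1, length + 1):
                prefix[i] = prefix[i - 1] + (i in site_set)
            for start in range(1, length + 1):
                for end in range(start + lo - 1, min(start + hi - 1, length) + 1):
                    n_conforming = (start - 1 in boundary_set) + (end in boundary_set)
                    if n_conforming == 0:
                        continue
                    internal = prefix[end - 1] - prefix[start - 1]
                    if internal <= missed:
                        loci.add((start, end))

    if met_variants and sequence.startswith("M"):
        for start, end in list(loci):
            if start == 1 and end >= 2 and lo <= end - 1 <= hi:
                loci.add((2, end))

    return sorted(loci)


def digest_sequences(
    sequence: str, rule: ProteaseRule, **kwargs
) -> list[str]:
    """Convenience: the peptide strings for :func:`digest` loci."""
    return [sequence[s - 1 : e] for s, e in digest(sequence, rule, **kwargs)]


# ---------------------------------------------------------------------------
# Definitions file


_DEF_COLUMNS = ("name", "cut_specs", "specificity", "min_length", "max_length", "max_missed")


def write_protease_definitions(rules: Iterable[ProteaseRule], path: str | Path) -> None:
    """Write rules as an editable TSV in the compact context notation."""
    lines = ["\t".join(_DEF_COLUMNS)]
    for rule in rules:
        specs = ",".join(s.compact() for s in rule.cut_specs)
        lines.append(
            "\t".join(
                [
                    rule.name,
                    specs,
                    rule.specificity.value,
                    str(rule.min_length),
                    str(rule.max_length),
                    str(rule.max_missed),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_protease_definitions(path: str | Path) -> dict[str, ProteaseRule]:
    text = Path(path).read_text().splitlines()
    if not text or text[0].split("\t") != list(_DEF_COLUMNS):
        raise ValueError(f"{path}: expected header {_DEF_COLUMNS}")
    rules: dict[str, ProteaseRule] = {}
    for line_number, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_DEF_COLUMNS):
            raise ValueError(f"{path}:{line_number}: expected {len(_DEF_COLUMNS)} fields")
        name, specs_text, specificity, lo, hi, missed = fields
        specs = tuple(
            parse_cut_spec(token) for token in specs_text.split(",") if token.strip()
        )
        rules[name] = ProteaseRule(
            name=name,
            cut_specs=specs,
            specificity=Specificity(specificity),
            min_length=int(lo),
            max_length=int(hi),
            max_missed=int(missed),
        )
    return rules


def rule_from_motif(
    report,
    name: str = "recovered",
    freq_threshold: float = 0.9,
    max_class_size: int = 4,
    combine_with: ProteaseRule | None = None,
    max_missed: int = 12,
) -> ProteaseRule:
    """Derive a candidate cleavage rule from a recovered motif report.

    For each of P2, P1 and P1', the smallest residue set whose summed
    frequency reaches ``freq_threshold`` becomes the context class; if
    that takes more than ``max_class_size`` residues the position is
    left as a wildcard.  This closes the discovery loop: a motif mined
    from one search defines the protease for the next.
    """
    def position_class(label: str) -> frozenset[str] | None:
        frequencies = report.frequency_matrix.loc[label].sort_values(ascending=False)
        chosen: list[str] = []
        cumulative = 0.0
        for residue, f in frequencies.items():
            if f <= 0:
                break
            chosen.append(residue)
            cumulative += f
            if cumulative >= freq_threshold:
                break
        if cumulative >= freq_threshold and len(chosen) <= max_class_size:
            return frozenset(chosen)
        return None

    spec = CutSpec(
        p2=position_class("P2"), p1=position_class("P1"), p1prime=position_class("P1'")
    )
    if spec.p1 is None and spec.p1prime is None:
        raise ValueError(
            "recovered motif constrains neither P1 nor P1'; no usable rule at "
            f"threshold {freq_threshold}"
        )
    rule = ProteaseRule(name=name, cut_specs=(spec,), specificity=Specificity.FULL)
    if combine_with is not None:
        rule = combine_rules(f"{name}-{combine_with.name}", rule, combine_with, max_missed=max_missed)
    return rule
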