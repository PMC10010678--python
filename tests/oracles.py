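"""Brute-force reference implementations used to cross-check the package.

These are deliberately written as direct transcriptions of the
definitions — exhaustive scans over substrings and window slices — and
share no code with the implementation they verify.
"""

from __future__ import annotations

import re

from glycomotif.protease import ProteaseRule, Specificity


def oracle_sites(sequence: str, rule: ProteaseRule) -> set[int]:
    """All inter-residue cut positions, by direct per-bond context checks."""
    if rule.specificity is Specificity.NONSPECIFIC:
        return set(range(1, len(sequence)))
    sites: set[int] = set()
    for i in range(1, len(sequence)):  # cut between residues i and i+1 (1-based)
        for spec in rule.cut_specs:
            ok = True
            if spec.p1 is not None and sequence[i - 1] not in spec.p1:
                ok = False
            if spec.p1prime is not None and sequence[i] not in spec.p1prime:
                ok = False
            if spec.p2 is not None and (i < 2 or sequence[i - 2] not in spec.p2):
                ok = False
            if ok:
                sites.add(i)
                break
    return sites


def oracle_digest(
    sequence: str,
    rule: ProteaseRule,
    missed: int,
    min_length: int,
    max_length: int,
) -> set[tuple[int, int]]:
    """Enumerate every substring and test terminus conformity directly."""
    length = len(sequence)
    result: set[tuple[int, int]] = set()
    if rule.specificity is Specificity.NONSPECIFIC:
        for start in range(1, length + 1):
            for end in range(start, length + 1):
                if min_length <= end - start + 1 <= max_length:
                    result.add((start, end))
        return result

    sites = oracle_sites(sequence, rule)
    boundaries = sites | {0, length}
    for start in range(1, length + 1):
        for end in range(start, length + 1):
            if not min_length <= end - start + 1 <= max_length:
                continue
            internal = sum(1 for s in sites if start <= s <= end - 1)
            if internal > missed:
                continue
            n_conform = (start - 1 in boundaries) + (end in boundaries)
            if rule.specificity is Specificity.FULL and n_conform == 2:
                result.add((start, end))
            elif rule.specificity is Specificity.SEMI and n_conform >= 1:
                result.add((start, end))
    return result


def oracle_window(protein: str, cut: int, flank: int = 5) -> str:
    """Window around the cut between residues ``cut`` and ``cut+1``.

    Slices ``protein[cut-flank .. cut+flank]`` (1-based) with '-'
    padding beyond the termini.
    """
    chars = []
    for pos in range(cut - flank + 1, cut + flank + 1):
        chars.append(protein[pos - 1] if 1 <= pos <= len(protein) else "-")
    return "".join(chars)


N_SEQUON = re.compile(r"N[^P][ST]")


def oracle_has_n_sequon(sequence: str) -> bool:
    return N_SEQUON.search(sequence) is not None
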