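# Methods

## Scope and model

The package infers an O-glycoprotease's substrate preference from
glycopeptide identifications produced by an upstream search (it never
re-scores spectra, recomputes q-values or localization probabilities, or
models FDR). The inference rests on one observation: after a sequential
glycoprotease + trypsin digestion, every peptide terminus that does not
conform to the tryptic rule is a direct record of one glycoprotease
cleavage event. Aligning the local sequence context of those events and
tallying residues and localized glycans per position yields the cleavage
motif.

## Filtering

Defaults (all overridable in `FilterConfig`):

| parameter | default | meaning |
|---|---|---|
| `max_q` | 0.01 | retain q-value strictly `< max_q` |
| `allowed_levels` | {Level1} | fully localized glycosites only |
| `min_site_probability` | 0.75 | every site probability strictly `>` |
| `exclude_n_sequon` | true | drop peptides containing N-X-S/T (X ≠ P) |
| `min_peptide_length` | 5 | residues |
| `targets_only` | true | drop decoy matches |

Comparisons are strict (`<` / `>`) on both thresholds. The Level 1 filter
and the 0.75 probability cut are both applied even though Level 1 is
defined through that probability upstream — applying both is conservative
and idempotent. Unmodified records are excluded from the glyco set. The
N-sequon test runs on the peptide sequence alone, before mapping; peptides
whose sequon is split across the peptide boundary are therefore not
excluded (a post-mapping context check would be an extension, not the
default). Removals are never silent: per-criterion first-failure and
any-failure tallies are logged and written to the run manifest.

## Mapping and terminus classification

Peptides are located by exact substring match (no I/L equivalence). A
terminus is tryptic-like if it follows K/R (proline suppression is an
explicit switch, off by default), sits at a protein terminus, or — for the
N-terminus under the default `variable_cleavage` initiator-Met policy —
starts at residue 2 of a Met-initiated protein. Protein termini count as
tryptic-like deliberately: a peptide flush with the protein end carries no
protease-specificity information on that side, so it contributes no
cleavage window there. Peptides occurring at more than one locus are
dropped by default (their windows would conflict); an `enumerate_all`
policy emits every locus flagged ambiguous.

## Windows and motif statistics

Windows are read from the protein, not the peptide, so P5…P1 context
upstream of an N-terminal cut (and P1′…P5′ downstream of a C-terminal cut)
is included; positions beyond the protein ends are `-` gaps. Gaps are
excluded from every denominator.

Percent-glycosylated at a position is the number of windows with a
localized glycan there over the number of windows with S or T there,
serine and threonine summed into one aggregate. Two conventions matter:

* **Observability.** A localized glycan can only be reported for residues
  inside the identified peptide. Window positions outside the peptide
  (all primed positions of a C-aligned window, all unprimed positions of
  an N-aligned window) carry sequence evidence but no glycan evidence, so
  by default they are excluded from the percent-glycosylated denominator
  (`observed_only=True`). Pooling N- and C-aligned windows without this
  restriction would systematically dilute positions that are in fact
  always glycosylated — a P1′-dependent enzyme would never reach 100% at
  P1′ because every C-aligned window has an (invisible) glycosylated S/T
  there. The naive pooled tally remains available as
  `observed_only=False`.
* **Zero denominators.** A position where no window shows S/T reports the
  undefined marker `NA`, never 0: absence of S/T is not a claim of zero
  glycosylation.

Information content per position is log₂20 − H bits over non-gap residue
frequencies. The small-sample correction e(n) = 19/(2·ln2·n) is available
but off by default (whether the original logo renderings applied one is
not stated in their provenance); the report records which mode was used,
and values are clamped at 0. Tallies default to PSM level (every
identification record counts); a `unique` counting unit collapses windows
sharing (sequence, site assignments, side, locus). Pooled statistics are
primary; per-source-file window counts are always emitted so replicate
averages can be formed downstream.

## Digestion engine

Cleavage contexts are (P2, P1, P1′) residue classes with the cut between
P1 and P1′, written `K|`, `|T`, `[ST]x|[ST]` etc. Specificities: `full`
(both termini at rule sites or protein ends), `semi` (at least one),
`nonspecific` (all substrings in the length bounds). Missed cleavages
count internal rule sites; for combined rules (union of contexts, e.g.
OgpA-Trypsin) *every* site of the union consumes budget, which is why the
combined built-ins default to 12 missed cleavages while plain trypsin
defaults to 3 — an S/T-rich peptide can contain many potential
glycoprotease sites. Built-in length bounds are 5–60 residues. The engine
is validated against a brute-force all-substrings oracle for every
built-in rule.

## Simulator

The simulator is the package's study-condition generator, not a kinetic
model. Defaults define the standard synthetic study: five random
~400-residue proteins with 20% Ser/Thr (uniform background over the other
18 residues, initiator Met), uniform per-site occupancy 0.5, glycan menu
{`N1`: 0.3, `N1H1`: 0.7}, cleavage efficiency 0.9, complete tryptic stage,
20 glycoforms per protein, 1000 PSMs sampled with replacement across two
nominal replicate files. Occupancy 0.5 reflects the partial, heterogeneous
site occupancy of mucin-type glycoproteins; the menu is a plain
Tn/T-antigen mixture.

Cleavage is a per-candidate-site Bernoulli draw: a sequence-rule site is a
candidate when its conditioning register (P1′ or P2) is occupied; the cut
probability is `efficiency × sialylation_multiplier` when the conditioning
glycan contains NeuAc/NeuGc, else `efficiency`. One random draw is made
per candidate regardless of outcome, so runs sharing a seed but differing
in the multiplier are coupled — lowering the multiplier can only remove
cuts, which makes the sialylation-sensitivity property monotone by
construction rather than merely in expectation.

For P1′-conditioned enzymes, a glycan on the P1 residue vetoes the cut by
default (`blocked_by_p1_glycan`). This models steric occlusion of the
scissile bond by the immediately adjacent upstream glycan and matches the
observed absence of glycosylated P1 residues in OgpA-type motifs; without
it, a sub-unit efficiency occasionally leaves an uncut site before an
occupied S/T whose fragment then ends in a glycosylated P1. The flag is a
model choice, defaults off for P2-conditioned (StcE-style) enzymes, and is
documented here precisely because it is a choice, not a measured property.

Noise channels: a configurable fraction of records draw q-values above
0.01; decoys are sequence reversals (accession prefixed `rev_`, site
positions mirrored); false localization moves one glycan to a different
S/T on the peptide and downgrades the record to Level 2 with probability
0.5. q-values are simulated, never estimated — the pipeline consumes them
and must be tested against controlled values. All randomness flows from a
single seed; identical configurations produce byte-identical tables
(outputs contain no timestamps).

**What the simulator does not emulate** — and hence what recovery tests do
not show about real data: spectral quality and its correlation with
peptide properties, intensity/retention behavior, realistic FDR structure,
glycan structural isomers, incomplete tryptic digestion correlated with
modification density, and sequence biases of real proteomes. Passing
recovery demonstrates the *pipeline arithmetic* is correct under known
ground truth, not that any particular enzyme behaves as modeled.

## Problem sizes

The standard recovery study (5 × 400 residues, 20 glycoforms, 1000 PSMs)
yields ≥500 filtered identifications and >1000 windows, enough that the
glycan-menu fractions at P1′ concentrate well inside ±0.05 of their
sampling weights; the digestion oracle sweep uses 500 random sequences of
length ≤ 80 against all eight built-in rules. These sizes were chosen as
the smallest that make the statistical checks stable.

## Known limitations

* Exact native header names and localization-string grammar of
  search-engine output vary by version; the bundled adapter covers the
  common headers and T/D markers and should be validated against a real
  file before production use. The canonical TSV dialect is the contract.
* Exact substring mapping cannot place peptides with I/L ambiguity or
  sequence variants.
* The candidate-rule writer (`rule_from_motif`) constrains a position when
  the smallest residue set reaching the frequency threshold (default 0.9)
  has ≤ 4 members; it proposes one context per motif and does not attempt
  multi-context decompositions.
* Motif matrices are the deliverable; rendering logos or pie charts is
  left to standard tools (the transfac-style count matrix is emitted for
  that purpose).
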