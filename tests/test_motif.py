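import math

import numpy as np
import pytest

from conftest import make_psm, make_window
from glycomotif.mapping import MappedGlycopeptide, TerminusCategory
from glycomotif.motif import (
    LOG2_20,
    WindowSide,
    build_motif_report,
    compute_logo,
    extract_windows,
    glycan_distribution,
    percent_glycosylated,
    window_labels,
)
from glycomotif.psm_io import ProteinRecord
from oracles import oracle_window


def mapped_at(protein, start, end, category, sites=(), **psm_kwargs):
    psm = make_psm(
        base_sequence=protein.sequence[start - 1 : end],
        sites=sites,
        accession=protein.accession,
        **psm_kwargs,
    )
    return MappedGlycopeptide(
        psm=psm, accession=protein.accession, start=start, end=end, category=category
    )


# ---------------------------------------------------------------------------
# Window extraction


def test_nterm_window_alignment(toy_protein):
    # peptide TSAPTTR at 4-10, glycan on its first T (protein position 4)
    m = mapped_at(toy_protein, 4, 10, TerminusCategory.NTERM, sites=((1, "N1", 0.9),))
    (window,) = extract_windows([m], [toy_protein])
    assert window.window == "--MKTTSAPT"
    assert window.side is WindowSide.N_ALIGNED
    assert window.cleavage_site == 3
    assert window.glycans_at == {"P1'": m.psm.sites[0].glycan}
    # P5, P4 are padding; P1' onward lies inside the peptide
    assert window.covered == (False, False, False, False, False, True, True, True, True, True)


def test_cterm_window_alignment(toy_protein):
    # peptide TSAPT at 4-8 ends at a non-tryptic boundary (T8|T9)
    m = mapped_at(toy_protein, 4, 8, TerminusCategory.CTERM, sites=((2, "N1H1", 0.9),))
    (window,) = extract_windows([m], [toy_protein])
    assert window.window == "TSAPTTR---"
    assert window.side is WindowSide.C_ALIGNED
    assert window.cleavage_site == 8
    assert window.glycans_at == {"P4": m.psm.sites[0].glycan}


def test_both_category_yields_two_windows(toy_protein):
    m = mapped_at(toy_protein, 4, 8, TerminusCategory.BOTH, sites=((1, "N1", 0.9),))
    windows = extract_windows([m], [toy_protein])
    assert [w.side for w in windows] == [WindowSide.N_ALIGNED, WindowSide.C_ALIGNED]


def test_fully_tryptic_dropped(toy_protein):
    m = mapped_at(toy_protein, 4, 10, TerminusCategory.FULLY_TRYPTIC, sites=((1, "N1", 0.9),))
    assert extract_windows([m], [toy_protein]) == []


def test_extraction_agrees_with_slicing_oracle():
    """1,000 random (protein, locus, category) triples against slice-with-padding."""
    rng = np.random.default_rng(17)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(1000):
        length = int(rng.integers(8, 40))
        seq = "".join(rng.choice(alphabet, size=length))
        protein = ProteinRecord("X", seq)
        start = int(rng.integers(1, length - 4))
        end = int(rng.integers(start + 4, min(start + 20, length) + 1))
        category = [TerminusCategory.NTERM, TerminusCategory.CTERM, TerminusCategory.BOTH][
            int(rng.integers(3))
        ]
        m = mapped_at(protein, start, end, category, sites=())
        windows = extract_windows([m], [protein])
        for w in windows:
            cut = start - 1 if w.side is WindowSide.N_ALIGNED else end
            assert w.window == oracle_window(seq, cut, flank=5)


def test_flank_validation(toy_protein):
    m = mapped_at(toy_protein, 4, 10, TerminusCategory.NTERM)
    with pytest.raises(ValueError):
        extract_windows([m], [toy_protein], flank=0)
    (w3,) = extract_windows([m], [toy_protein], flank=3)
    assert len(w3.window) == 6 and w3.window == "MKTTSA"


# ---------------------------------------------------------------------------
# Percent glycosylated


def test_percent_glycosylated_worked_example():
    """10 windows with S at P1', 9 carrying a glycan there -> 90%."""
    windows = [
        make_window("--MKASPEPT", glycans={"P1'": "N1"} if i < 9 else {"P5'": "N1"})
        for i in range(10)
    ]
    pct = percent_glycosylated(windows)
    assert pct["P1'"] == pytest.approx(0.90)


def test_zero_denominator_reports_none_not_zero():
    windows = [make_window("AAAAAGGGGG")]
    pct = percent_glycosylated(windows)
    assert all(value is None for value in pct.values())


def test_saturated_position_reports_one():
    windows = [make_window("AAAAATGGGG", glycans={"P1'": "N1"}) for _ in range(5)]
    assert percent_glycosylated(windows)["P1'"] == 1.0


def test_uncovered_positions_excluded_from_denominator():
    # S at P1 is protein context outside the peptide: no glycan evidence
    covered = (False, False, False, False, False, True, True, True, True, True)
    windows = [make_window("----STPEPT", covered=covered, glycans={"P1'": "N1"})]
    pct = percent_glycosylated(windows)
    assert pct["P1"] is None
    assert pct["P1'"] == 1.0
    # the naive pooled tally counts it
    assert percent_glycosylated(windows, observed_only=False)["P1"] == 0.0


def test_permutation_invariance():
    rng = np.random.default_rng(2)
    windows = [
        make_window("AATKASPEPT", glycans={"P1'": "N1"} if i % 3 else {})
        for i in range(9)
    ]
    shuffled = [windows[i] for i in rng.permutation(9)]
    assert percent_glycosylated(windows) == percent_glycosylated(shuffled)
    assert glycan_distribution(windows) == glycan_distribution(shuffled)


# ---------------------------------------------------------------------------
# Glycan distribution


def test_glycan_distribution_counting():
    windows = [
        make_window("AAAAASPEPT", glycans={"P1'": "N1H1"}),
        make_window("AAAAASPEPT", glycans={"P1'": "N1H1"}),
        make_window("AAAAASPEPT", glycans={"P1'": "N1"}),
    ]
    dist = glycan_distribution(windows, positions=("P1'",))
    assert dist["P1'"] == {"N1": pytest.approx(1 / 3), "N1H1": pytest.approx(2 / 3)}


def test_glycan_distribution_empty_position_and_unknown_label():
    windows = [make_window("AAAAASPEPT", glycans={"P1'": "N1"})]
    assert glycan_distribution(windows, positions=("P2",))["P2"] == {}
    with pytest.raises(ValueError, match="P9"):
        glycan_distribution(windows, positions=("P9",))


def test_glycan_conservation():
    """Total tallied glycans equals the sum of per-window glycan counts."""
    rng = np.random.default_rng(8)
    windows = []
    for i in range(30):
        glycans = {}
        if rng.random() < 0.8:
            glycans["P1'"] = "N1"
        if rng.random() < 0.3:
            glycans["P3'"] = "N1H1"
        windows.append(make_window("AAAAASPTPT", glycans=glycans))
    labels = window_labels(5)
    dist_counts = 0
    for label in labels:
        per_label = sum(1 for w in windows if label in w.glycans_at)
        dist_counts += per_label
    assert dist_counts == sum(len(w.glycans_at) for w in windows)


# ---------------------------------------------------------------------------
# Sequence logo


def test_logo_information_content_closed_forms():
    conserved = [make_window("AAAAATGGGG") for _ in range(4)]
    freq, ic = compute_logo(conserved)
    assert ic["P1'"] == pytest.approx(LOG2_20)  # H=0
    assert freq.loc["P1'", "T"] == 1.0

    half = [make_window("AAAAATGGGG"), make_window("AAAAAAGGGG")]
    _, ic_half = compute_logo(half)
    assert ic_half["P1'"] == pytest.approx(LOG2_20 - 1)  # H=1 bit

    uniform = [make_window(f"AAAAA{aa}GGGG") for aa in "ACDEFGHIKLMNPQRSTVWY"]
    _, ic_uniform = compute_logo(uniform)
    assert ic_uniform["P1'"] == pytest.approx(0.0, abs=1e-12)


def test_logo_gap_handling_and_correction():
    windows = [make_window("-----TGGGG"), make_window("-----TGGGG")]
    freq, ic = compute_logo(windows)
    assert ic["P5"] is None  # all-gap column
    assert float(freq.loc["P1'"].sum()) == pytest.approx(1.0)

    _, corrected = compute_logo(windows, small_sample_correction=True)
    assert corrected["P1'"] == pytest.approx(
        max(LOG2_20 - 19 / (2 * math.log(2) * 2), 0.0)
    )
    assert corrected["P1'"] < ic["P1'"]


def test_frequency_columns_sum_to_one():
    rng = np.random.default_rng(9)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    windows = [make_window("".join(rng.choice(alphabet, size=10))) for _ in range(40)]
    freq, _ = compute_logo(windows)
    for label in window_labels(5):
        assert float(freq.loc[label].sum()) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Report assembly


def test_single_window_report_is_one_hot():
    report = build_motif_report([make_window("MKTTASAPTT", glycans={"P1'": "N1"})])
    assert report.n_windows == 1
    for label in report.labels:
        assert float(report.frequency_matrix.loc[label].max()) == 1.0


def test_empty_windows_is_an_error():
    with pytest.raises(ValueError):
        build_motif_report([])


def test_unique_counting_unit_collapses_duplicates():
    w = make_window("AAAAASPEPT", glycans={"P1'": "N1"})
    duplicate = make_window("AAAAASPEPT", glycans={"P1'": "N1"})
    psm_level = build_motif_report([w, duplicate])
    unique_level = build_motif_report([w, duplicate], counting_unit="unique")
    assert psm_level.n_windows == 2
    assert unique_level.n_windows == 1


def test_per_file_counts():
    windows = [
        make_window("AAAAASPEPT", glycans={"P1'": "N1"}, source_file="r1"),
        make_window("AAAAASPEPT", glycans={"P1'": "N1"}, source_file="r1"),
        make_window("AAAAASPEPT", glycans={"P1'": "N1"}, source_file="r2"),
    ]
    report = build_motif_report(windows)
    assert report.per_file_counts == {"r1": 2, "r2": 1}
    assert report.glycan_distribution["P1'"] == {"N1": 1.0}
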