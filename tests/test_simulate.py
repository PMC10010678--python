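import numpy as np
import pytest

from glycomotif.filters import filter_identifications, has_n_sequon
from glycomotif.protease import enumerate_cleavage_sites
from glycomotif.psm_io import (
    GlycanComposition,
    ProteinRecord,
    parse_glycan_composition,
    read_psm_table,
)
from glycomotif.simulate import (
    GlycoproteinModel,
    NoiseConfig,
    SimulationConfig,
    build_psm_records,
    default_model,
    emit_psm_table,
    ogpa_style_config,
    random_protein,
    simulate_digest,
    simulate_experiment,
    simulate_glycoforms,
    stce_style_config,
)


@pytest.fixture
def protein():
    return random_protein(np.random.default_rng(1), length=200, accession="SYN1")


def test_random_protein_composition():
    rng = np.random.default_rng(0)
    protein = random_protein(rng, length=2000, st_fraction=0.2)
    st = sum(protein.sequence.count(c) for c in "ST")
    assert protein.sequence.startswith("M")
    assert len(protein.sequence) == 2000
    # within 4 binomial standard errors of the target density
    se = (0.2 * 0.8 / 2000) ** 0.5
    assert abs(st / 2000 - 0.2) < 4 * se


def test_glycoform_determinism(protein):
    model = default_model(protein)
    a = simulate_glycoforms(model, 5, np.random.default_rng(42))
    b = simulate_glycoforms(model, 5, np.random.default_rng(42))
    assert a == b


def test_degenerate_menu_and_full_occupancy(protein):
    menu = {parse_glycan_composition("N1H1"): 1.0}
    model = default_model(protein, occupancy=1.0, glycan_menu=menu)
    for glycoform in simulate_glycoforms(model, 3, np.random.default_rng(0)):
        assert set(glycoform) == set(model.site_occupancy)
        assert all(str(g) == "N1H1" for g in glycoform.values())


def test_occupancy_binomial_check(protein):
    model = default_model(protein, occupancy=0.5)
    n_sites = len(model.site_occupancy)
    rng = np.random.default_rng(7)
    draws = simulate_glycoforms(model, 200, rng)
    occupied = sum(len(g) for g in draws)
    total = n_sites * 200
    se = (0.5 * 0.5 / total) ** 0.5
    assert abs(occupied / total - 0.5) < 3 * se


def test_model_validation(protein):
    with pytest.raises(ValueError, match="S/T"):
        GlycoproteinModel(protein=protein, site_occupancy={1: 0.5})  # residue 1 is M
    with pytest.raises(ValueError):
        default_model(protein, occupancy=1.5)


def test_ogpa_digest_postcondition_audit(protein):
    """Every non-tryptic N-terminus of an OgpA-style digest is an occupied S/T."""
    model = default_model(protein)
    cfg = SimulationConfig(glyco=ogpa_style_config(), seed=0)
    rng = np.random.default_rng(0)
    for glycoform in simulate_glycoforms(model, 10, rng):
        fragments, realized = simulate_digest(model, glycoform, cfg, rng)
        for f in fragments:
            if f.nterm_origin == "glyco":
                assert protein.sequence[f.start - 1] in "ST"
                assert f.start in glycoform  # the licensing glycan
            if f.cterm_origin == "glyco":
                # cut N-terminal to an occupied S/T beyond the fragment
                assert f.end + 1 in glycoform
        for site in realized:
            assert site + 1 in glycoform


def test_p1_glycan_blocking(protein):
    """With blocking on, no realized cut has a glycan at its P1 residue."""
    model = default_model(protein, occupancy=1.0)
    cfg = SimulationConfig(glyco=ogpa_style_config(efficiency=1.0), seed=0)
    rng = np.random.default_rng(0)
    (glycoform,) = simulate_glycoforms(model, 1, rng)
    _, realized = simulate_digest(model, glycoform, cfg, rng)
    assert realized  # plenty of licensed sites at full occupancy
    for site in realized:
        assert site not in glycoform


def test_sialylation_annihilation(protein):
    """Multiplier 0 with an all-sialylated menu yields zero glyco cuts."""
    menu = {parse_glycan_composition("N1H1A1"): 1.0}
    model = default_model(protein, glycan_menu=menu)
    cfg = SimulationConfig(
        glyco=ogpa_style_config(sialylation_multiplier=0.0), seed=0
    )
    rng = np.random.default_rng(0)
    for glycoform in simulate_glycoforms(model, 5, rng):
        fragments, realized = simulate_digest(model, glycoform, cfg, rng)
        assert realized == []
        assert all(f.nterm_origin != "glyco" and f.cterm_origin != "glyco" for f in fragments)


def test_stce_digest_cut_context(protein):
    """StcE-style cuts occur between P1 and P1' of a licensed T/S-X-T/S context."""
    model = default_model(protein)
    cfg = SimulationConfig(glyco=stce_style_config(), seed=0)
    rng = np.random.default_rng(3)
    seq = protein.sequence
    rule_sites = set(enumerate_cleavage_sites(seq, cfg.glyco.rule))
    for glycoform in simulate_glycoforms(model, 5, rng):
        _, realized = simulate_digest(model, glycoform, cfg, rng)
        for site in realized:
            assert site in rule_sites
            assert seq[site - 2] in "ST" and seq[site] in "ST"
            assert site - 1 in glycoform  # P2 occupied licenses the cut


def test_single_context_stce_hand_check():
    """One licensed T/S-X-T/S context, efficiency 1 -> the cut is realized."""
    protein = ProteinRecord("ONE", "MAAAATVSAAAAK")
    model = GlycoproteinModel(
        protein=protein,
        site_occupancy={6: 1.0},  # the T of T-V-S
        glycan_menu={GlycanComposition(hexnac=1): 1.0},
    )
    cfg = SimulationConfig(
        glyco=stce_style_config(efficiency=1.0), trypsin_stage=False, seed=0
    )
    rng = np.random.default_rng(0)
    (glycoform,) = simulate_glycoforms(model, 1, rng)
    fragments, realized = simulate_digest(model, glycoform, cfg, rng)
    assert realized == [7]  # between V7 and S8: P2=T6 occupied
    assert [f.sequence for f in fragments] == ["MAAAATV"]


def test_experiment_determinism_and_table_round_trip(tmp_path, protein):
    model = default_model(protein)
    cfg = SimulationConfig(n_psms=200, n_glycoforms=5, seed=9)
    frags_a, tally_a = simulate_experiment([model], cfg)
    frags_b, tally_b = simulate_experiment([model], cfg)
    assert frags_a == frags_b and tally_a == tally_b

    path_a, path_b = tmp_path / "a.tsv", tmp_path / "b.tsv"
    records = emit_psm_table(frags_a, cfg, path_a, rng=np.random.default_rng(cfg.seed))
    emit_psm_table(frags_b, cfg, path_b, rng=np.random.default_rng(cfg.seed))
    assert path_a.read_bytes() == path_b.read_bytes()
    assert read_psm_table(path_a) == records


def test_noise_free_table_passes_filters(protein):
    """With zero noise, every emitted record survives the quality filters."""
    model = default_model(protein)
    cfg = SimulationConfig(n_psms=100, n_glycoforms=5, seed=2)
    fragments, _ = simulate_experiment([model], cfg)
    records = build_psm_records(fragments, cfg, rng=np.random.default_rng(2))
    # only the N-sequon criterion can remove noise-free records
    assert len(filter_identifications(records)) == sum(
        1 for r in records if not has_n_sequon(r.base_sequence)
    )


def test_decoy_injection_reproducible(protein):
    model = default_model(protein)
    cfg = SimulationConfig(
        n_psms=500,
        n_glycoforms=5,
        seed=4,
        noise=NoiseConfig(decoy_fraction=0.1),
    )
    fragments, _ = simulate_experiment([model], cfg)
    records_a = build_psm_records(fragments, cfg, rng=np.random.default_rng(4))
    records_b = build_psm_records(fragments, cfg, rng=np.random.default_rng(4))
    n_decoys = sum(r.is_decoy for r in records_a)
    assert records_a == records_b
    # seeded binomial draw: nonzero, below ~3 sigma of the rate
    assert 0 < n_decoys < 500 * 0.1 + 3 * (500 * 0.1 * 0.9) ** 0.5
    decoy = next(r for r in records_a if r.is_decoy)
    assert decoy.protein_accession.startswith("rev_")


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_psms=0)
    with pytest.raises(ValueError):
        NoiseConfig(decoy_fraction=1.5)
    with pytest.raises(ValueError):
        ogpa_style_config(efficiency=2.0)
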