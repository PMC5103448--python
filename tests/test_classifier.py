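"""Catalog content, feature matching in homeodomain coordinates, and the
scoring/margin rules of paralog-group assignment."""

import pytest

from hoxminer import GeneratorSpec, classify, generate_protein
from hoxminer.catalog import DiagnosticFeature, MotifCatalog
from hoxminer.classifier import (
    AMBIGUOUS,
    ASSIGNED,
    UNCLASSIFIED,
    ClassifyParams,
    match_feature,
    score_groups,
)
from hoxminer.hdscan import HomeodomainHit
from hoxminer.synthetic import consensus_homeodomains


def test_default_catalog_label_counts(catalog):
    assert len(catalog.hox_labels) == 11
    assert len(catalog.parahox_labels) == 3
    assert catalog.hox_labels == [
        "Hox1", "Hox2", "Hox3", "Hox4", "Hox5", "Lox5",
        "Antp", "Lox4", "Lox2", "Post2", "Post1",
    ]
    assert catalog.parahox_labels == ["Gsx", "Xlox", "Cdx"]


def test_hox5_motif_is_anchored_molluscan_hexapeptide(catalog):
    (feat,) = [
        f for f in catalog.features_of("Hox5") if f.region == "C_FLANK" and f.pattern
    ]
    assert feat.pattern == "HIAKNM"
    assert feat.offset == 1
    assert feat.scope == "molluscan"


def test_gsx_motif_is_lophotrochozoan_pentapeptide(catalog):
    (feat,) = [f for f in catalog.features_of("Gsx") if f.pattern]
    assert feat.pattern == "LRTCD"
    assert feat.region == "C_FLANK"
    assert feat.scope == "lophotrochozoan"


def test_hox3_al_motif_positions(catalog):
    (feat,) = [f for f in catalog.features_of("Hox3") if f.pattern == "AL"]
    assert feat.positions == (36, 37)
    assert feat.scope == "lophotrochozoan"


def test_placeholders_are_inert(catalog):
    placeholders = [f for f in catalog.features if f.is_placeholder]
    assert placeholders, "default catalog ships unprinted signatures as placeholders"
    assert all(f.weight == 0 for f in placeholders)
    hit = HomeodomainHit(protein_id="p", hd_start=10, score=50.0)
    pep = "A" * 120
    for f in placeholders:
        assert match_feature(pep, hit, f) is None


def _hd_peptide(group, n_flank="G" * 20, c_flank="G" * 20):
    return n_flank + consensus_homeodomains()[group] + c_flank


def test_hd_pos_predicate_match(catalog):
    (feat,) = [f for f in catalog.features_of("Hox1") if f.predicates]
    pep = _hd_peptide("Hox1")
    hit = HomeodomainHit(protein_id="p", hd_start=20, score=100.0)
    m = match_feature(pep, hit, feat)
    assert m is not None
    assert m.matched_text == "SS"  # non-basic residues at positions 2-3
    # a basic residue at position 2 kills the match
    pep2 = pep[:21] + "K" + pep[22:]
    assert match_feature(pep2, hit, feat) is None


def test_exact_offset_flank_match(catalog):
    (feat,) = [f for f in catalog.features_of("Hox5") if f.pattern == "HIAKNM"]
    pep = _hd_peptide("Hox5", c_flank="HIAKNMGGGG")
    hit = HomeodomainHit(protein_id="p", hd_start=20, score=100.0)
    m = match_feature(pep, hit, feat)
    assert m is not None and m.start_aa == 80  # immediately after position 60
    # one residue later is a miss for an anchored motif
    pep2 = _hd_peptide("Hox5", c_flank="GHIAKNMGGG")
    assert match_feature(pep2, hit, feat) is None


def test_windowed_flank_no_match_when_absent(catalog):
    (feat,) = [f for f in catalog.features_of("Hox4") if f.pattern == "YPWM"]
    pep = _hd_peptide("Hox4")
    hit = HomeodomainHit(protein_id="p", hd_start=20, score=100.0)
    assert match_feature(pep, hit, feat) is None


def test_feature_window_past_peptide_end_is_no_match(catalog):
    (feat,) = [f for f in catalog.features_of("Gsx") if f.pattern]
    pep = _hd_peptide("Gsx", c_flank="LR")  # too short for LRTCD
    hit = HomeodomainHit(protein_id="p", hd_start=20, score=100.0)
    assert match_feature(pep, hit, feat) is None


def test_x_never_matches(catalog):
    (feat,) = [f for f in catalog.features_of("Hox1") if f.predicates]
    pep = _hd_peptide("Hox1")
    pep = pep[:21] + "X" + pep[22:]  # X at position 2
    hit = HomeodomainHit(protein_id="p", hd_start=20, score=100.0)
    assert match_feature(pep, hit, feat) is None


def test_ypwm_plus_lpntk_assigns_hox4(catalog, profile, threshold):
    pep, _ = generate_protein("Hox4", catalog, GeneratorSpec(), seed=17)
    r = classify(pep, profile, catalog, scan_threshold=threshold)
    assert r.status == ASSIGNED and r.label == "Hox4"
    assert {m.matched_text for m in r.matches} == {"YPWM", "LPNTK"}


def test_ypwm_alone_is_ambiguous_between_hox4_and_hox5(catalog, profile, threshold):
    pep = "M" + "G" * 30 + "YPWM" + "G" * 10 + consensus_homeodomains()["Hox4"] + "G" * 20
    r = classify(pep, profile, catalog, scan_threshold=threshold)
    assert r.status == AMBIGUOUS
    assert r.candidates == ("Hox4", "Hox5")


def test_gsx_assigned_from_lrtcd(catalog, profile, threshold):
    pep, _ = generate_protein("Gsx", catalog, GeneratorSpec(), seed=23)
    r = classify(pep, profile, catalog, scan_threshold=threshold)
    assert r.status == ASSIGNED and r.label == "Gsx"


def test_hox2_separates_from_hox3_via_required_al(catalog, profile, threshold):
    pep2, _ = generate_protein("Hox2", catalog, GeneratorSpec(), seed=29)
    r2 = classify(pep2, profile, catalog, scan_threshold=threshold)
    assert r2.label == "Hox2"
    pep3, _ = generate_protein("Hox3", catalog, GeneratorSpec(), seed=29)
    r3 = classify(pep3, profile, catalog, scan_threshold=threshold)
    assert r3.label == "Hox3"
    assert r3.scores["Hox3"] > r3.scores["Hox2"]


def test_no_homeodomain_is_unclassified(catalog, profile, threshold, rng):
    pep = "M" + "".join("ACDEFGHIKL"[i] for i in rng.integers(0, 10, 80))
    r = classify(pep, profile, catalog, scan_threshold=threshold)
    assert r.status == UNCLASSIFIED
    assert r.hd_hit is None


def test_all_placeholder_groups_recorded_as_unassignable(catalog, profile, threshold):
    pep, _ = generate_protein("Post1", catalog, GeneratorSpec(), seed=31)
    r = classify(pep, profile, catalog, scan_threshold=threshold)
    assert r.status == AMBIGUOUS and not r.candidates
    assert "Post1" in r.unassignable_groups
    assert "Hox4" not in r.unassignable_groups


def test_determinism(catalog, profile, threshold):
    pep, _ = generate_protein("Hox1", catalog, GeneratorSpec(), seed=37)
    a = classify(pep, profile, catalog, scan_threshold=threshold)
    b = classify(pep, profile, catalog, scan_threshold=threshold)
    assert (a.status, a.label, a.scores) == (b.status, b.label, b.scores)


def test_adding_matched_feature_never_decreases_score(catalog, profile, threshold):
    pep, truth = generate_protein("Hox4", catalog, GeneratorSpec(), seed=41)
    base = classify(pep, profile, catalog, scan_threshold=threshold)
    extra = DiagnosticFeature(
        group="Hox4", region="HD_POS", positions=(1,), pattern="R", weight=0.5
    )
    bigger = MotifCatalog(
        classes=dict(catalog.classes), features=catalog.features + (extra,)
    )
    r = classify(pep, profile, bigger, scan_threshold=threshold)
    assert r.scores["Hox4"] >= base.scores["Hox4"]


def test_noise_free_recovery_for_all_separable_labels(catalog, profile, threshold):
    separable = [g for g in catalog.labels if catalog.scored_features_of(g)]
    assert separable == ["Hox1", "Hox2", "Hox3", "Hox4", "Hox5", "Gsx"]
    for seed in range(10):
        for g in separable:
            pep, _ = generate_protein(g, catalog, GeneratorSpec(), seed=500 + seed)
            r = classify(pep, profile, catalog, scan_threshold=threshold)
            assert r.label == g, f"{g} (seed {seed}) -> {r.status}/{r.label}"


def test_mutation_tolerant_recovery_rate(catalog, profile, threshold):
    """>= 95 % recovery at 10 % homeodomain substitution (diagnostic
    positions protected), 500 seeded proteins."""
    separable = [g for g in catalog.labels if catalog.scored_features_of(g)]
    spec = GeneratorSpec(hd_mut_rate=0.10)
    ok = 0
    n = 500
    for i in range(n):
        g = separable[i % len(separable)]
        pep, _ = generate_protein(g, catalog, spec, seed=9000 + i)
        r = classify(pep, profile, catalog, scan_threshold=threshold)
        ok += r.label == g
    assert ok / n >= 0.95


def test_params_validation():
    with pytest.raises(ValueError):
        ClassifyParams(min_score=0)
    with pytest.raises(ValueError):
        ClassifyParams(min_margin=-1)
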