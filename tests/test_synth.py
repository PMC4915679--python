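import numpy as np
import pandas as pd
import pytest

from orpscan.anchor import fingerprint_query
from orpscan.classify import schiff_base_test
from orpscan.references import DEFAULT_SCHEMA
from orpscan.synth import (
    DEFAULT_CLASS_COUNTS,
    SpectrumPlan,
    SynthConfig,
    generate_genome_annotation,
    generate_proteome,
    generate_spectrum,
    plan_bundle,
)


def test_same_seed_reproduces_identical_outputs():
    cfg = SynthConfig(seed=7)
    r1, t1 = generate_proteome(cfg)
    r2, t2 = generate_proteome(cfg)
    assert r1 == r2
    pd.testing.assert_frame_equal(t1, t2)
    f1, _ = generate_genome_annotation(cfg)
    f2, _ = generate_genome_annotation(cfg)
    assert f1 == f2
    s1 = generate_spectrum(SpectrumPlan(peak_nm=550.0, peak_amplitude=0.3), seed=7)
    s2 = generate_spectrum(SpectrumPlan(peak_nm=550.0, peak_amplitude=0.3), seed=7)
    assert np.array_equal(s1.absorbances, s2.absorbances)


def test_different_seeds_differ():
    r1, _ = generate_proteome(SynthConfig(seed=7))
    r2, _ = generate_proteome(SynthConfig(seed=8))
    assert r1 != r2


def test_truth_table_counts_match_config():
    cfg = SynthConfig(class_counts={"BR": 2, "ORP_A": 5, "ORP_B": 1}, n_decoys=3)
    _, truth = generate_proteome(cfg)
    counts = truth[truth.kind == "opsin"].groupby("class_label").size().to_dict()
    assert counts == {"BR": 2, "ORP_A": 5, "ORP_B": 1}
    assert (truth.kind == "decoy").sum() == 3


def test_truth_covers_every_entity_exactly_once(bundle):
    truth = bundle["proteome_truth"]
    ids = [r.id for r in bundle["records"]]
    assert sorted(ids) == sorted(truth.entity_id)
    assert truth.entity_id.is_unique


def test_planted_fingerprint_edits_are_exact(bundle):
    """Background mutation never touches the planted fingerprint cells."""
    truth = bundle["proteome_truth"].set_index("entity_id")
    by_id = {r.id: r for r in bundle["records"]}
    for eid, row in truth[truth.kind == "opsin"].iterrows():
        fp = fingerprint_query(by_id[eid])
        if row.family == "ORP":
            assert schiff_base_test(fp) == "ORP"
            assert fp[174] == "L"
        else:
            assert schiff_base_test(fp) == "canonical"


def test_planted_context_recovered_and_window_sweep():
    cfg = SynthConfig()
    feats, ctx_truth = generate_genome_annotation(cfg)
    from orpscan.context import classify_locus

    for _, row in ctx_truth.iterrows():
        label = classify_locus(feats[row.genome_id], row.entity_id)
        assert label.category == row.context_category


def test_spectrum_grid_is_276_points():
    s = generate_spectrum(SpectrumPlan(), seed=0)
    assert s.wavelengths.size == 276
    assert s.wavelengths[0] == 250.0 and s.wavelengths[-1] == 800.0


def test_default_condition_mirrors_survey_shape():
    entities, pathway = plan_bundle(SynthConfig())
    opsins = [e for e in entities if e.kind == "opsin"]
    assert len(opsins) == sum(DEFAULT_CLASS_COUNTS.values()) == 25
    a = sum(e.orp_group == "A" for e in opsins)
    b = sum(e.orp_group == "B" for e in opsins)
    assert (a, b) == (3, 6)  # the 1:2 A:B ratio at desk scale
    orp_genomes = {e.genome_id for e in opsins if e.family == "ORP"}
    canon_genomes = {e.genome_id for e in opsins if e.family != "ORP"}
    orp_only = orp_genomes - canon_genomes
    lacking_both = {g for g in orp_only if not pathway[g]}
    assert len(lacking_both) == 3  # plus one partial (brp-only) genome
    assert sum(1 for g in orp_only if pathway[g] == {"brp"}) == 1


def test_config_validation():
    with pytest.raises(ValueError, match="background_rate"):
        SynthConfig(background_rate=1.0)
    with pytest.raises(ValueError, match="non-negative"):
        SynthConfig(n_decoys=-1)
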