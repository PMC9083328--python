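"""Generator determinism, noise calibration, censoring and scenarios."""

import numpy as np
import pytest

from extractbench.detectability import compute_detectability
from extractbench.io import write_measurements
from extractbench.model import ConfigError
from extractbench.synthetic import (
    SyntheticConfig,
    cv_to_sigma_log2,
    default_panel,
    generate,
    plant_scenario,
)

from conftest import SMALL_PANEL_SPEC


def test_default_panel_composition():
    panel = default_panel()
    assert len(panel) == 630
    assert len(panel.classes) == 23
    modes = [m.acquisition_mode.value for m in panel.metabolites]
    assert modes.count("LC") == 107
    assert modes.count("FIA") == 523
    lc_classes = {m.compound_class for m in panel.metabolites
                  if m.acquisition_mode.value == "LC"}
    fia_classes = {m.compound_class for m in panel.metabolites
                   if m.acquisition_mode.value == "FIA"}
    assert len(lc_classes) == 14
    assert len(fia_classes) == 9


def test_default_design_matches_study_layout():
    config = SyntheticConfig()
    assert len(config.protocols) == 7
    assert config.replicates == 3
    table, _ = generate(config)
    assert table.concentrations.shape == (4 * 7 * 3, 630)


def test_cv_sigma_relation_is_exact_lognormal():
    # sigma_ln = sqrt(ln(1 + cv^2)); population CV of the lognormal equals cv
    for cv in (5.0, 15.0, 60.0):
        sigma_ln = cv_to_sigma_log2(cv) * np.log(2.0)
        assert np.sqrt(np.exp(sigma_ln**2) - 1.0) == pytest.approx(cv / 100.0)


def test_generation_is_deterministic_down_to_bytes(tmp_path, small_config):
    t1, _ = generate(small_config)
    t2, _ = generate(small_config)
    assert t1.equals(t2)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_measurements(t1, p1)
    write_measurements(t2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_metabolite_streams_ignore_panel_insertion_order(small_config):
    t1, _ = generate(small_config)
    reordered = dict(reversed(list(SMALL_PANEL_SPEC.items())))
    t2, _ = generate(
        SyntheticConfig(
            panel_spec=reordered,
            matrices=small_config.matrices,
            protocols=small_config.protocols,
            seed=small_config.seed,
        )
    )
    # same metabolites, same values, independent of spec ordering
    assert t1.equals(t2)


def test_zero_cv_gives_identical_replicates():
    config = SyntheticConfig(
        panel_spec=SMALL_PANEL_SPEC,
        matrices=(("mouse", "kidney"),),
        protocols=("P1", "P2"),
        replicate_cv_percent=0.0,
        lod_quantile=0.0,
        loq_quantile=0.0,
        missing_rate=0.0,
        seed=1,
    )
    table, _ = generate(config)
    for prot in ("P1", "P2"):
        rows = table.group_rows(("mouse", "kidney"), prot)
        vals = table.concentrations.iloc[rows].to_numpy()
        assert (vals == vals[0]).all()


def test_replicate_cv_is_recovered_within_sampling_error():
    """200 replicates at target CV 15%: the empirical group CVs center on 15
    and fall in [13.5, 16.5] at the rate the CV's own sampling distribution
    allows (direct lognormal simulation gives 0.946 for that band at n=200,
    binomial SE 0.013 over 120 groups — so the bound is 0.90)."""
    config = SyntheticConfig(
        panel_spec={"amino acids": (60, "LC", "AA")},
        matrices=(("mouse", "kidney"),),
        protocols=("P1", "P2"),
        replicates=200,
        replicate_cv_percent=15.0,
        lod_quantile=0.0,
        loq_quantile=0.0,
        missing_rate=0.0,
        seed=5,
    )
    table, _ = generate(config)
    in_band = 0
    total = 0
    all_cvs = []
    for prot in ("P1", "P2"):
        rows = table.group_rows(("mouse", "kidney"), prot)
        vals = table.concentrations.iloc[rows].to_numpy()
        cvs = 100.0 * vals.std(axis=0, ddof=1) / vals.mean(axis=0)
        in_band += int(((cvs >= 13.5) & (cvs <= 16.5)).sum())
        total += cvs.size
        all_cvs.append(cvs)
    assert in_band / total >= 0.90
    assert np.concatenate(all_cvs).mean() == pytest.approx(15.0, abs=0.3)


def test_censoring_fraction_matches_lod_quantile():
    config = SyntheticConfig(
        panel_spec={"amino acids": (100, "LC", "AA")},
        matrices=(("mouse", "kidney"),),
        protocols=("P1", "P2"),
        replicates=30,
        lod_quantile=0.25,
        loq_quantile=0.4,
        missing_rate=0.0,
        seed=9,
    )
    table, _ = generate(config)
    stat = table.statuses.to_numpy()
    frac_lod = (stat == "below_lod").mean()
    frac_loq_or_less = ((stat == "below_lod") | (stat == "below_loq")).mean()
    assert frac_lod == pytest.approx(0.25, abs=0.02)
    assert frac_loq_or_less == pytest.approx(0.4, abs=0.02)


def test_censoring_is_monotone_in_lod_quantile():
    counts = []
    for q in (0.0, 0.1, 0.3, 0.6):
        config = SyntheticConfig(
            panel_spec=SMALL_PANEL_SPEC,
            matrices=(("mouse", "kidney"),),
            protocols=("P1", "P2"),
            lod_quantile=q,
            loq_quantile=max(q, 0.2),
            missing_rate=0.0,
            seed=13,
        )
        table, _ = generate(config)
        det = compute_detectability(table)[("mouse", "kidney")]
        counts.append(int(det.detectable.sum().sum()))
    assert counts == sorted(counts, reverse=True)


def test_missing_rate_masks_cells():
    config = SyntheticConfig(
        panel_spec=SMALL_PANEL_SPEC,
        matrices=(("mouse", "kidney"),),
        protocols=("P1",),
        replicates=50,
        missing_rate=0.2,
        seed=17,
    )
    table, _ = generate(config)
    stat = table.statuses.to_numpy()
    assert (stat == "missing").mean() == pytest.approx(0.2, abs=0.03)
    assert np.isnan(
        table.concentrations.to_numpy()[stat == "missing"].astype(float)
    ).all()


def test_config_validation():
    with pytest.raises(ConfigError):
        SyntheticConfig(replicates=1)
    with pytest.raises(ConfigError):
        SyntheticConfig(lod_quantile=1.0)
    with pytest.raises(ConfigError):
        SyntheticConfig(lod_quantile=0.3, loq_quantile=0.1)
    with pytest.raises(ConfigError):
        SyntheticConfig(protocol_effects={("nope", "amino acids"): 1.0})
    with pytest.raises(ConfigError):
        SyntheticConfig(protocol_effects={("100IPA", "nope"): 1.0})


def test_global_null_scenario_plants_nothing():
    config = plant_scenario("global_null", seed=3)
    assert config.protocol_effects == {}
    assert config.lod_quantile == 0.0
    assert config.missing_rate == 0.0
    _, truth = generate(config)
    assert (truth.effects.to_numpy() == 0.0).all()
    assert all(w is None for w in truth.planted_winner.values())


def test_one_winner_scenario_raises_every_class():
    config = plant_scenario("one_winner", seed=3, winner_protocol="75EtOH/MTBE")
    _, truth = generate(config)
    assert all(w == "75EtOH/MTBE" for w in truth.planted_winner.values())
    shift = truth.effects["75EtOH/MTBE"]
    assert (shift > 0).all()
    sigma = cv_to_sigma_log2(15.0)
    assert shift.iloc[0] == pytest.approx(4.0 * sigma)


def test_two_tied_winners_have_no_unique_winner():
    config = plant_scenario("two_tied_winners", seed=3)
    _, truth = generate(config)
    assert all(w is None for w in truth.planted_winner.values())
    assert (
        truth.effects["MeOH/CHCl3/H2O"] == truth.effects["75EtOH/MTBE"]
    ).all()


def test_class_specific_winner_touches_one_class():
    config = plant_scenario(
        "class_specific_winner",
        seed=3,
        winner_protocol="MeOH/ACN/H2O+FA",
        target_class="amino acids",
    )
    _, truth = generate(config)
    winners = {c: w for c, w in truth.planted_winner.items() if w is not None}
    assert winners == {"amino acids": "MeOH/ACN/H2O+FA"}


def test_unknown_scenario_is_an_error():
    with pytest.raises(ConfigError, match="unknown scenario"):
        plant_scenario("nope")
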