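"""Forward simulator: allometry, sieving, read generation, determinism."""

import numpy as np
import pandas as pd
import pytest

import sizepool as sp
from sizepool.simulate import (
    SimulationError,
    SpecimenSet,
    allometric_weight,
    fraction_dry_weights,
)


def specimens_from_lengths(lengths, species_ids=None, efficiency=None,
                           config=None):
    """Hand-built SpecimenSet for deterministic sieving/sequencing tests."""
    config = config or sp.SimConfig()
    lengths = np.asarray(lengths, dtype=float)
    if species_ids is None:
        species_ids = [f"OTU{i + 1:04d}" for i in range(len(lengths))]
    uniq = list(dict.fromkeys(species_ids))
    eff = pd.Series(1.0 if efficiency is None else efficiency, index=uniq)
    species = pd.DataFrame({
        "abundance": 1.0,
        "mean_length": [lengths[species_ids.index(u)] for u in uniq],
        "efficiency": eff,
    }, index=pd.Index(uniq, name="species_id"))
    specimens = pd.DataFrame({
        "species_id": species_ids,
        "body_length": lengths,
        "dry_weight": allometric_weight(lengths, config.allometry_a,
                                        config.allometry_b),
        "fraction": pd.Series([None] * len(lengths), dtype=object),
        "is_fragment": False,
    })
    return SpecimenSet(specimens, species)


def test_allometric_weight_matches_formula():
    assert allometric_weight(10.0, 0.0305, 2.62) == pytest.approx(
        0.0305 * 10.0 ** 2.62)


def test_draw_community_deterministic():
    cfg = sp.SimConfig(n_species=40, seed=0)
    a = sp.draw_community(cfg, seed=123)
    b = sp.draw_community(cfg, seed=123)
    pd.testing.assert_frame_equal(a.specimens, b.specimens)
    pd.testing.assert_frame_equal(a.species, b.species)


def test_draw_community_single_species():
    cfg = sp.SimConfig(n_species=1)
    out = sp.draw_community(cfg, seed=5)
    assert set(out.specimens["species_id"]) == {"OTU0001"}


def test_config_validation():
    with pytest.raises(SimulationError):
        sp.SimConfig(n_species=0)
    with pytest.raises(SimulationError):
        sp.SimConfig(mesh_diameters_mm=(2.0, 4.0, 8.0))
    with pytest.raises(SimulationError):
        sp.SimConfig(carryover_prob=1.5)


def test_sieve_retention_rule():
    """k*length against descending meshes; too small for all meshes -> S."""
    cfg = sp.SimConfig(retention_k=0.5, carryover_prob=0.0)
    specs = specimens_from_lengths([1.0, 10.0, 5.0, 20.0])
    sieved, _ = sp.sieve_specimens(specs, cfg, seed=0)
    assert sieved.specimens["fraction"].tolist() == ["S", "L", "M", "XL"]


def test_sieve_no_carryover_single_fraction_and_conservation():
    cfg = sp.SimConfig(carryover_prob=0.0)
    specs = specimens_from_lengths([1.0, 3.0, 9.0, 17.0])
    total_before = specs.specimens["dry_weight"].sum()
    sieved, truth = sp.sieve_specimens(specs, cfg, seed=1)
    assert not sieved.specimens["is_fragment"].any()
    per_fraction = sieved.biomass_by_fraction()
    assert (per_fraction.gt(0).sum(axis=1) == 1).all()
    assert per_fraction.to_numpy().sum() == pytest.approx(total_before)
    # biomass per fraction sums to total biomass per species
    assert truth.per_species[list(sp.FRACTIONS)].sum(axis=1).to_numpy() == \
        pytest.approx(sieved.specimens.groupby("species_id")["dry_weight"]
                      .sum().to_numpy())


def test_sieve_carryover_conserves_mass():
    cfg = sp.SimConfig(carryover_prob=1.0, carryover_mass_frac=0.1)
    specs = specimens_from_lengths([10.0, 20.0, 6.0])
    total_before = specs.specimens["dry_weight"].sum()
    sieved, _ = sp.sieve_specimens(specs, cfg, seed=2)
    assert sieved.specimens["is_fragment"].sum() == 3  # all are above S
    assert sieved.specimens["dry_weight"].sum() == pytest.approx(total_before)
    # fragments land strictly below the parent fraction
    order = {f: i for i, f in enumerate(sp.FRACTIONS)}
    frags = sieved.specimens[sieved.specimens.is_fragment]
    parents = sieved.specimens[~sieved.specimens.is_fragment]
    assert frags["fraction"].map(order).max() < parents["fraction"].map(order).min()


def test_library_columns_sum_to_depth():
    cfg = sp.SimConfig(depth=5000, carryover_prob=0.0, n_replicates=2)
    specs = specimens_from_lengths([1.0, 1.5, 9.0])  # S and L occupied, XL empty
    sieved, _ = sp.sieve_specimens(specs, cfg, seed=0)
    table = sp.simulate_fraction_reads(sieved, cfg, seed=3)
    sums = table.counts.sum(axis=0)
    for sid in table.sample_ids:
        frac = table.meta(sid).fraction
        if frac in ("S", "L"):
            assert sums[sid] == cfg.depth
        else:
            assert sums[sid] == 0


def test_single_species_gets_all_reads():
    cfg = sp.SimConfig(depth=1000, carryover_prob=0.0)
    specs = specimens_from_lengths([5.0], species_ids=["OTU0001"])
    sieved, _ = sp.sieve_specimens(specs, cfg, seed=0)  # 0.5*5 = 2.5 -> M
    table = sp.simulate_fraction_reads(sieved, cfg, seed=1)
    assert table.counts["L1_M_r1"]["OTU0001"] == cfg.depth


def test_multinomial_reads_track_biomass_ratio():
    """Without primer bias, mean read ratio matches the 3:1 biomass ratio."""
    cfg = sp.SimConfig(depth=10_000, bias_sigma=0.0, carryover_prob=0.0,
                       n_replicates=1)
    # both specimens sieve to S; lengths chosen for dry weights 3:1
    l_small = 1.0
    l_big = l_small * 3.0 ** (1.0 / cfg.allometry_b)
    specs = specimens_from_lengths([l_big, l_small],
                                   species_ids=["OTU0001", "OTU0002"])
    sieved, _ = sp.sieve_specimens(specs, cfg, seed=0)
    counts = []
    for seed in range(300):
        t = sp.simulate_fraction_reads(sieved, cfg, seed)
        counts.append(t.counts["L1_S_r1"]["OTU0001"])
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - 7500.0) < 3 * max(se, 1.0)


def test_lysate_equal_scheme_mixes_disjoint_fractions_evenly():
    """Equal volumes of two disjoint, equal-biomass fractions -> 50/50 reads."""
    cfg = sp.SimConfig(depth=10_000, bias_sigma=0.0, carryover_prob=0.0,
                       n_replicates=1)
    specs = specimens_from_lengths([1.0, 9.0])  # one species in S, one in L
    sieved, _ = sp.sieve_specimens(specs, cfg, seed=0)
    # equalize biomass so only the volume proportions drive the mixture
    sieved.specimens["dry_weight"] = 1.0
    scheme = sp.PoolingScheme("half", {"S": 0.5, "L": 0.5})
    counts = []
    for seed in range(300):
        t = sp.simulate_lysate_pool(sieved, scheme, cfg, seed)
        counts.append(t.counts.iloc[0, 0])
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - 5000.0) < 3 * max(se, 1.0)


def test_lysate_weight_scheme_equals_unsorted_sample():
    """Dry-weight pooling reproduces whole-sample biomass shares (uniform lysate)."""
    cfg = sp.SimConfig(depth=10_000, bias_sigma=0.0, carryover_prob=0.0,
                       n_replicates=1)
    specs = specimens_from_lengths([1.0, 3.0, 9.0])
    sieved, _ = sp.sieve_specimens(specs, cfg, seed=0)
    weights = fraction_dry_weights(sieved)
    total = sum(weights.values())
    scheme = sp.PoolingScheme("g", {f: w / total for f, w in weights.items()})
    biomass = sieved.specimens.set_index("species_id")["dry_weight"]
    expected = cfg.depth * biomass / biomass.sum()
    counts = []
    for seed in range(300):
        t = sp.simulate_lysate_pool(sieved, scheme, cfg, seed)
        counts.append(t.counts.iloc[:, 0])
    mean = pd.concat(counts, axis=1).mean(axis=1)
    se = pd.concat(counts, axis=1).std(axis=1, ddof=1) / np.sqrt(len(counts))
    assert (np.abs(mean - expected) < 3 * np.maximum(se, 1.0)).all()


def test_negative_controls_poisson():
    cfg0 = sp.SimConfig(contamination_lambda=0.0, n_negatives=4)
    zeros = sp.simulate_negative_controls(cfg0, ["O1", "O2"], seed=0)
    assert (zeros.counts.to_numpy() == 0).all()

    lam = 0.7
    cfg = sp.SimConfig(contamination_lambda=lam, n_negatives=100)
    table = sp.simulate_negative_controls(cfg, [f"O{i}" for i in range(100)],
                                          seed=1)
    draws = table.counts.to_numpy().ravel()
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - lam) < 3 * se
    again = sp.simulate_negative_controls(cfg, [f"O{i}" for i in range(100)],
                                          seed=1)
    assert table.counts.equals(again.counts)


def test_experiment_deterministic_and_well_formed(experiment):
    cfg = experiment.config
    again = sp.simulate_experiment(cfg)
    assert again.table.counts.equals(experiment.table.counts)
    # 3 sources x (4 fractions + 6 strategies) x 2 replicates + 9 negatives
    assert experiment.table.shape[1] == 3 * (4 + 6) * 2 + 9
    sums = experiment.table.counts.sum(axis=0)
    for s in experiment.table.samples:
        if s.category != "negative_control":
            assert sums[s.sample_id] == cfg.depth
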