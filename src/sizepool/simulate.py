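"""Forward simulation of size-structured Malaise-trap bulk samples.

The generator mirrors the design of the sieving-and-pooling experiment the
package analyses: a bulk arthropod sample is drawn from a lognormal
rank-abundance distribution with lognormal body lengths, specimens get a
dry weight from an allometric length-weight relation, are sieved on
stacked meshes (8, 4, 2 mm) into four size fractions (XL, L, M, S), may
shed small fragments into smaller fractions (broken-off legs, attached
specimens), and are then "sequenced": read counts per library are
multinomial draws at fixed depth with probabilities proportional to
per-species biomass times a fixed per-species amplification efficiency
(primer bias).  Lysate pools mix the within-fraction compositions with the
volume proportions of a pooling scheme; because the lysis buffer is dosed
proportionally to tissue weight, DNA concentration is uniform across
lysates and volume shares weight fractions directly.

Every draw is governed by a single integer seed, spawned per stage with
:class:`numpy.random.SeedSequence`, so a full scenario is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pooling import PoolingScheme, named_scheme
from .table import FRACTIONS, OTUTable, SampleMeta


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters.

    Defaults describe one Malaise-trap bulk sample of a few hundred species
    whose body lengths are mostly small (median ~2 mm) while biomass is
    dominated by the few large species — the regime in which unsorted
    metabarcoding under-detects small taxa.
    """

    n_species: int = 300
    #: lognormal rank-abundance: species mean specimen count ~ LogN(mu_a, sigma_a)
    mu_a: float = 1.0
    sigma_a: float = 1.2
    #: species mean body length (mm) ~ LogN(mu_L, sigma_L), truncated
    mu_L: float = 0.7
    sigma_L: float = 0.9
    length_bounds_mm: tuple[float, float] = (0.5, 30.0)
    #: within-species spread of individual lengths (sd on the log scale)
    length_cv: float = 0.1
    #: dry weight (mg) = a * length(mm) ** b  (general-insect allometry)
    allometry_a: float = 0.0305
    allometry_b: float = 2.62
    #: sieve hole diameters, mm, strictly decreasing; four fractions result
    mesh_diameters_mm: tuple[float, ...] = (8.0, 4.0, 2.0)
    #: effective-width factor: a specimen is retained by mesh m if k*length >= m
    retention_k: float = 0.5
    #: probability a retained specimen sheds a fragment into a smaller fraction
    carryover_prob: float = 0.05
    #: fraction of the specimen's weight carried by that fragment
    carryover_mass_frac: float = 0.02
    #: sd of per-species log10 amplification efficiency (primer bias)
    bias_sigma: float = 0.5
    depth: int = 10_000
    n_replicates: int = 2
    n_negatives: int = 9
    #: expected stray reads per OTU per negative control
    contamination_lambda: float = 0.05
    n_sources: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species <= 0:
            raise SimulationError("n_species must be positive")
        if self.depth < 1:
            raise SimulationError("depth must be >= 1")
        if self.allometry_a <= 0:
            raise SimulationError("allometry coefficient a must be > 0")
        if list(self.mesh_diameters_mm) != sorted(self.mesh_diameters_mm, reverse=True) \
                or len(set(self.mesh_diameters_mm)) != len(self.mesh_diameters_mm):
            raise SimulationError("mesh diameters must be strictly decreasing")
        if len(self.mesh_diameters_mm) != len(FRACTIONS) - 1:
            raise SimulationError(
                f"{len(FRACTIONS) - 1} meshes required for fractions {FRACTIONS}"
            )
        for p in (self.carryover_prob, self.carryover_mass_frac):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("probabilities must lie in [0, 1]")
        if self.contamination_lambda < 0:
            raise SimulationError("contamination_lambda must be >= 0")


@dataclass
class SpecimenSet:
    """Simulated specimens plus the species table they were drawn from.

    ``specimens`` columns: species_id, body_length (mm), dry_weight (mg),
    fraction (None until sieved), is_fragment.
    ``species`` columns (index species_id): abundance, mean_length,
    efficiency (relative amplification efficiency, fixed per species).
    """

    specimens: pd.DataFrame
    species: pd.DataFrame

    @property
    def sieved(self) -> bool:
        return self.specimens["fraction"].notna().all() and len(self.specimens) > 0

    def biomass_by_fraction(self, fragments: bool = True) -> pd.DataFrame:
        """Species x fraction dry-weight matrix (mg)."""
        df = self.specimens if fragments else self.specimens[~self.specimens.is_fragment]
        pivot = df.pivot_table(index="species_id", columns="fraction",
                               values="dry_weight", aggfunc="sum", observed=True)
        return pivot.reindex(index=self.species.index, columns=list(FRACTIONS),
                             fill_value=0.0).fillna(0.0)


@dataclass
class GroundTruth:
    """Per-species truth for parameter-recovery tests.

    ``per_species`` columns: true_class (fraction holding the majority of
    the species' intact biomass), biomass per fraction, efficiency.
    """

    per_species: pd.DataFrame

    @property
    def true_classes(self) -> pd.Series:
        return self.per_species["true_class"]


def combined_true_classes(truths: Mapping[str, "GroundTruth"]) -> pd.Series:
    """True class over several bulk samples: argmax of summed fraction biomass.

    Ties resolve toward the smaller fraction, matching the assignment rule.
    """
    total: pd.DataFrame | None = None
    for gt in truths.values():
        b = gt.per_species[list(FRACTIONS)]
        total = b if total is None else total.add(b, fill_value=0.0)
    if total is None:
        raise SimulationError("no ground truths supplied")
    support = total.sum(axis=1) > 0
    return total.idxmax(axis=1).where(support)


def _truncated_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                         bounds: tuple[float, float], size: int) -> np.ndarray:
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return np.exp(stats.truncnorm.rvs(a, b, loc=mu, scale=sigma,
                                      size=size, random_state=rng))


def allometric_weight(length_mm: np.ndarray | float, a: float, b: float) -> np.ndarray:
    """Dry weight in mg from body length in mm: ``a * length**b``."""
    return a * np.asarray(length_mm, dtype=float) ** b


def draw_species_pool(config: SimConfig, seed: int) -> pd.DataFrame:
    """Draw the regional species pool: abundance, mean length, efficiency.

    Species traits are properties of the taxon, so when several bulk
    samples are simulated from the same pool they share this table.
    """
    rng = np.random.default_rng(seed)
    n = config.n_species
    abundance = rng.lognormal(config.mu_a, config.sigma_a, n)
    mean_length = _truncated_lognormal(rng, config.mu_L, config.sigma_L,
                                       config.length_bounds_mm, n)
    efficiency = 10.0 ** rng.normal(0.0, config.bias_sigma, n)
    ids = [f"OTU{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(
        {"abundance": abundance, "mean_length": mean_length, "efficiency": efficiency},
        index=pd.Index(ids, name="species_id"),
    )


def draw_community(config: SimConfig, seed: int,
                   species: pd.DataFrame | None = None) -> SpecimenSet:
    """Draw one bulk sample: specimens with lengths and dry weights.

    If ``species`` is omitted a fresh pool is drawn from the same seed.
    Every species contributes at least one specimen.
    """
    rng = np.random.default_rng(seed)
    if species is None:
        species = draw_species_pool(config, seed)
    n = len(species)
    counts = rng.poisson(species["abundance"].to_numpy()) + 1
    mean_length = species["mean_length"].to_numpy()
    ids = list(species.index)
    sp_idx = np.repeat(np.arange(n), counts)
    lengths = mean_length[sp_idx] * np.exp(rng.normal(0.0, config.length_cv, sp_idx.size))
    specimens = pd.DataFrame(
        {
            "species_id": np.asarray(ids)[sp_idx],
            "body_length": lengths,
            "dry_weight": allometric_weight(lengths, config.allometry_a,
                                            config.allometry_b),
            "fraction": pd.Series([None] * sp_idx.size, dtype=object),
            "is_fragment": False,
        }
    )
    return SpecimenSet(specimens, species)


def _assign_fraction(lengths: np.ndarray, config: SimConfig) -> np.ndarray:
    """Largest mesh retaining k*length, else the pan fraction S."""
    effective = config.retention_k * lengths
    out = np.full(lengths.size, FRACTIONS[0], dtype=object)  # S by default
    # meshes descending (8,4,2) correspond to fractions XL, L, M
    for mesh, frac in zip(config.mesh_diameters_mm, reversed(FRACTIONS[1:])):
        unset = out == FRACTIONS[0]
        out[unset & (effective >= mesh)] = frac
    return out


def sieve_specimens(specimens: SpecimenSet, config: SimConfig,
                    seed: int) -> tuple[SpecimenSet, GroundTruth]:
    """Assign size fractions and apply fragment carryover.

    Total dry weight is conserved exactly: a fragment's mass is removed
    from its parent specimen.  Ground-truth size class is the fraction
    holding the majority of each species' intact (non-fragment) biomass,
    ties resolved toward the smaller fraction.
    """
    rng = np.random.default_rng(seed)
    df = specimens.specimens.copy()
    if df["fraction"].notna().any():
        raise SimulationError("specimens already sieved")
    df["fraction"] = _assign_fraction(df["body_length"].to_numpy(), config)

    frag_rows = []
    if config.carryover_prob > 0 and config.carryover_mass_frac > 0:
        order = {f: i for i, f in enumerate(FRACTIONS)}
        ranks = df["fraction"].map(order).to_numpy()
        eligible = np.flatnonzero(ranks > 0)
        hit = eligible[rng.random(eligible.size) < config.carryover_prob]
        for i in hit:
            target_rank = rng.integers(0, ranks[i])
            mass = config.carryover_mass_frac * df.at[i, "dry_weight"]
            df.at[i, "dry_weight"] -= mass
            frag_rows.append(
                {
                    "species_id": df.at[i, "species_id"],
                    "body_length": np.nan,
                    "dry_weight": mass,
                    "fraction": FRACTIONS[target_rank],
                    "is_fragment": True,
                }
            )
    if frag_rows:
        df = pd.concat([df, pd.DataFrame(frag_rows)], ignore_index=True)

    sieved = SpecimenSet(df, specimens.species)
    intact = sieved.biomass_by_fraction(fragments=False)
    total = sieved.biomass_by_fraction(fragments=True)
    # idxmax returns the first maximum; FRACTIONS order makes ties small-biased
    true_class = intact.idxmax(axis=1).where(intact.sum(axis=1) > 0)
    per_species = total.copy()
    per_species["true_class"] = true_class
    per_species["efficiency"] = sieved.species["efficiency"]
    return sieved, GroundTruth(per_species)


def _fraction_composition(specimens: SpecimenSet) -> pd.DataFrame:
    """Per-fraction read-probability composition: biomass x efficiency, normalized."""
    biomass = specimens.biomass_by_fraction(fragments=True)
    weighted = biomass.mul(specimens.species["efficiency"], axis=0)
    totals = weighted.sum(axis=0)
    comp = weighted.div(totals.replace(0, 1.0), axis=1)
    return comp


def simulate_fraction_reads(specimens: SpecimenSet, config: SimConfig, seed: int,
                            source: str = "L1") -> OTUTable:
    """Sequence each size fraction individually, with extraction replicates.

    One OTU per species.  Each library is a multinomial draw of ``depth``
    reads with probabilities proportional to within-fraction biomass times
    the species' amplification efficiency.  Empty fractions yield all-zero
    columns.
    """
    if not specimens.sieved:
        raise SimulationError("sieve specimens before sequencing")
    rng = np.random.default_rng(seed)
    comp = _fraction_composition(specimens)
    cols: dict[str, np.ndarray] = {}
    metas: list[SampleMeta] = []
    for frac in FRACTIONS:
        p = comp[frac].to_numpy()
        for rep in range(1, config.n_replicates + 1):
            sid = f"{source}_{frac}_r{rep}"
            if p.sum() > 0:
                cols[sid] = rng.multinomial(config.depth, p)
            else:
                cols[sid] = np.zeros(len(comp), dtype=np.int64)
            metas.append(SampleMeta(sid, source=source, category="fraction",
                                    fraction=frac, replicate=rep))
    counts = pd.DataFrame(cols, index=comp.index)
    return OTUTable(counts, metas)


def simulate_lysate_pool(specimens: SpecimenSet, scheme: PoolingScheme,
                         config: SimConfig, seed: int,
                         source: str = "L1") -> OTUTable:
    """Sequence a lysate pool mixed with the given volume proportions.

    Mixture probabilities are the scheme-weighted sum of within-fraction
    compositions.  Fractions that drew no specimens contribute nothing and
    the mixture is renormalized.
    """
    if not specimens.sieved:
        raise SimulationError("sieve specimens before sequencing")
    unknown = set(scheme.proportions) - set(FRACTIONS)
    if unknown:
        raise SimulationError(f"scheme references unknown fractions: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    comp = _fraction_composition(specimens)
    p = np.zeros(len(comp))
    for frac, share in scheme.proportions.items():
        p = p + share * comp[frac].to_numpy()
    if p.sum() == 0:
        raise SimulationError("mixture is empty: no biomass in any pooled fraction")
    p = p / p.sum()
    cols: dict[str, np.ndarray] = {}
    metas: list[SampleMeta] = []
    for rep in range(1, config.n_replicates + 1):
        sid = f"{source}_{scheme.name}_r{rep}"
        cols[sid] = rng.multinomial(config.depth, p)
        metas.append(SampleMeta(sid, source=source, category="pooled_lysate",
                                strategy=scheme.name, replicate=rep))
    return OTUTable(pd.DataFrame(cols, index=comp.index), metas)


def simulate_negative_controls(config: SimConfig, otu_ids: Sequence[str],
                               seed: int) -> OTUTable:
    """Extraction negatives: independent Poisson stray reads per OTU."""
    rng = np.random.default_rng(seed)
    cols = {}
    metas = []
    for j in range(1, config.n_negatives + 1):
        sid = f"neg_{j}"
        cols[sid] = rng.poisson(config.contamination_lambda, len(otu_ids))
        metas.append(SampleMeta(sid, category="negative_control"))
    counts = pd.DataFrame(cols, index=pd.Index(otu_ids, name="OTU_ID"))
    return OTUTable(counts, metas)


@dataclass
class Experiment:
    """A full simulated study: table, truths, weights and schemes used."""

    table: OTUTable
    ground_truth: dict[str, GroundTruth]
    specimen_sets: dict[str, SpecimenSet]
    fraction_weights: dict[str, dict[str, float]]  # source -> fraction -> mg
    schemes: dict[str, dict[str, PoolingScheme]]  # source -> name -> scheme
    config: SimConfig


def fraction_dry_weights(specimens: SpecimenSet) -> dict[str, float]:
    """Total dry weight (mg) per fraction, fragments included."""
    return specimens.biomass_by_fraction(fragments=True).sum(axis=0).to_dict()


def simulate_experiment(config: SimConfig,
                        strategies: Sequence[str] = ("g", "equ", "invg",
                                                     "fibo", "log", "4x"),
                        ) -> Experiment:
    """Simulate the full study design.

    ``n_sources`` bulk samples are drawn independently; each is sieved,
    its four fractions sequenced in duplicate, and its lysates pooled with
    every named strategy (weight-dependent schemes use that sample's own
    fraction dry weights).  Negative controls are appended.  All columns
    are assembled into one OTU table over the union of species.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_sources * 3 + 2)
    pool_seed = int(children[-2].generate_state(1)[0] % (2**31))
    species_pool = draw_species_pool(config, pool_seed)
    tables: list[OTUTable] = []
    truths: dict[str, GroundTruth] = {}
    sets: dict[str, SpecimenSet] = {}
    weights: dict[str, dict[str, float]] = {}
    schemes: dict[str, dict[str, PoolingScheme]] = {}
    all_otus: list[str] = []

    def child_seed(i: int) -> np.random.SeedSequence:
        return children[i]

    for s in range(config.n_sources):
        source = f"L{s + 1}"
        seeds = [int(c.generate_state(1)[0] % (2**31)) for c in
                 child_seed(3 * s).spawn(2 + len(strategies))]
        community = draw_community(config, seeds[0], species=species_pool)
        sieved, truth = sieve_specimens(
            community, config,
            int(child_seed(3 * s + 1).generate_state(1)[0] % (2**31)))
        w = fraction_dry_weights(sieved)
        frac_table = simulate_fraction_reads(
            sieved, config, int(child_seed(3 * s + 2).generate_state(1)[0] % (2**31)),
            source=source)
        tables.append(frac_table)
        schemes[source] = {}
        for k, name in enumerate(strategies):
            scheme = named_scheme(name, weights=w)
            schemes[source][name] = scheme
            tables.append(simulate_lysate_pool(sieved, scheme, config,
                                               seeds[2 + k], source=source))
        truths[source] = truth
        sets[source] = sieved
        weights[source] = w
        all_otus.extend(o for o in frac_table.otu_ids if o not in all_otus)

    # NB: species ids repeat across sources by construction (OTU0001 ...);
    # they represent the same taxa drawn independently per trap sample.
    union = pd.Index(sorted(set(all_otus)), name="OTU_ID")
    frames = [t.counts.reindex(union, fill_value=0) for t in tables]
    metas = [m for t in tables for m in t.samples]
    combined = pd.concat(frames, axis=1)
    negatives = simulate_negative_controls(
        config, list(union), int(children[-1].generate_state(1)[0] % (2**31)))
    combined = pd.concat([combined, negatives.counts], axis=1)
    metas.extend(negatives.samples)
    return Experiment(OTUTable(combined, metas), truths, sets, weights,
                      schemes, config)
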