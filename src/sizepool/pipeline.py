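"""End-to-end scenario runs: simulate -> filter -> pool -> rarefy -> analyze.

A run is driven by a :class:`RunConfig` (constructible from YAML), writes
every stage output as TSV into one directory, and finishes with a JSON
manifest recording parameters, seed and SHA-256 digests of all outputs —
identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import analysis, filtering, pooling, rarefaction
from .simulate import Experiment, SimConfig, simulate_experiment
from .table import FRACTIONS, OTUTable, write_otu_table, write_sample_metadata


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs."""

    outdir: str = "sizepool_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    threshold_pct: float = 0.01
    sweep_step_pct: int = 5
    sweep_depth: int = 10_000
    quarter_threshold_pct: float = 0.04
    reference_strategy: str = "g"
    reference_depth: int = 50_000
    rarefaction_mode: str = "pooled"  # "pooled": replicates summed, no filtering

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        raw.update(overrides)
        cfg = cls(sim=sim, **raw)
        if cfg.reference_strategy not in ("g", "equ", "invg", "fibo", "log", "4x"):
            raise PipelineError(
                f"unresolvable reference strategy {cfg.reference_strategy!r}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def merged_fraction_columns(filtered: OTUTable,
                            source: str) -> dict[str, pd.Series]:
    """Per-fraction merged columns of one source sample."""
    cols = {}
    for frac in FRACTIONS:
        sub = filtered.select(category="fraction", source=source, fraction=frac)
        if sub.sample_ids:
            cols[frac] = sub.counts[sub.sample_ids[0]]
    return cols


def sweep_for_source(filtered: OTUTable, weights: Mapping[str, float],
                     source: str, step_pct: int = 5, depth: int = 10_000,
                     threshold_pct: float = 0.01) -> rarefaction.RecoveryCurve:
    """S+M vs L+XL ratio sweep from a source's filtered fraction libraries."""
    cols = merged_fraction_columns(filtered, source)
    missing = [f for f in FRACTIONS if f not in cols]
    if missing:
        raise PipelineError(f"{source}: missing fraction libraries {missing}")
    small = pooling.build_combined_fraction(
        {f: cols[f] for f in ("S", "M")}, {f: weights[f] for f in ("S", "M")})
    large = pooling.build_combined_fraction(
        {f: cols[f] for f in ("L", "XL")}, {f: weights[f] for f in ("L", "XL")})
    curve = pooling.two_fraction_sweep(small, large, step_pct=step_pct,
                                       depth=depth, threshold_pct=threshold_pct)
    curve.label = f"{source}_S+M_vs_L+XL"
    return curve


def rarefaction_inputs(table: OTUTable, mode: str = "pooled") -> dict[str, pd.Series]:
    """Per-(source, strategy) lysate columns prepared for rarefaction.

    ``pooled``: negatives subtracted, replicates summed directly (no
    consistency or abundance filtering).  ``filtered``: full quality
    filter first.
    """
    if mode == "pooled":
        cleaned = filtering.subtract_negative_controls(table)
        pairing = filtering.ReplicatePairing.from_table(cleaned)
        prepared = filtering.merge_replicates(cleaned, pairing, require_both=False)
    elif mode == "filtered":
        prepared, _ = filtering.quality_filter(table)
    else:
        raise PipelineError(f"unknown rarefaction mode {mode!r}")
    out: dict[str, pd.Series] = {}
    for s in prepared.samples:
        if s.category == "pooled_lysate":
            out[f"{s.source}:{s.strategy}"] = prepared.counts[s.sample_id]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full scenario and return the manifest (also written)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    experiment = simulate_experiment(sim)
    outputs: list[Path] = []

    def save_frame(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        outputs.append(path)

    write_otu_table(experiment.table, outdir / "table_raw.tsv")
    write_sample_metadata(experiment.table, outdir / "metadata.tsv")
    outputs += [outdir / "table_raw.tsv", outdir / "metadata.tsv"]
    truth = pd.concat(
        {src: gt.per_species for src, gt in experiment.ground_truth.items()},
        names=["source", "species_id"])
    save_frame(truth, "ground_truth.tsv")

    filtered, log = filtering.quality_filter(
        experiment.table, threshold_pct=config.threshold_pct)
    write_otu_table(filtered, outdir / "table_filtered.tsv")
    outputs.append(outdir / "table_filtered.tsv")
    save_frame(log, "filter_log.tsv", index=False)

    fraction_only = filtered.select(category="fraction")
    assignment = analysis.assign_size_classes(fraction_only)
    save_frame(assignment.frame, "size_class_assignment.tsv")
    spectrum = analysis.size_class_spectrum(assignment)
    save_frame(spectrum.rename("percent").to_frame(), "size_class_spectrum.tsv")
    sharing = analysis.fraction_sharing(fraction_only)
    save_frame(sharing.rename("n_otus").to_frame(), "fraction_sharing.tsv")

    sweep_frames = []
    quarter_rows = []
    for source, weights in experiment.fraction_weights.items():
        curve = sweep_for_source(filtered, weights, source,
                                 step_pct=config.sweep_step_pct,
                                 depth=config.sweep_depth,
                                 threshold_pct=config.threshold_pct)
        sweep_frames.append(curve.to_frame())
        cols = merged_fraction_columns(filtered, source)
        quarter = pooling.equal_quarter_pool(
            cols, per_fraction_threshold_pct=config.quarter_threshold_pct)
        equ = filtered.select(category="pooled_lysate", source=source,
                              strategy="equ")
        equ_rich = int((equ.counts.sum(axis=1) > 0).sum()) if equ.sample_ids else 0
        quarter_rows.append({"source": source, "quarter_pool_richness": quarter,
                             "equ_lysate_richness": equ_rich})
    save_frame(pd.concat(sweep_frames, ignore_index=True), "sweep.tsv", index=False)
    save_frame(pd.DataFrame(quarter_rows), "quarter_pool.tsv", index=False)

    columns = rarefaction_inputs(experiment.table, mode=config.rarefaction_mode)
    curves = rarefaction.recovery_curves(columns, mode=config.rarefaction_mode)
    save_frame(pd.concat([c.to_frame() for c in curves], ignore_index=True),
               "rarefaction_curves.tsv", index=False)
    factor_rows = []
    for source in experiment.fraction_weights:
        source_curves = [c for c in curves if c.label.startswith(f"{source}:")]
        ref = f"{source}:{config.reference_strategy}"
        results = rarefaction.depth_equivalence_factor(
            source_curves, ref, config.reference_depth)
        for label, res in results.items():
            factor_rows.append({
                "source": source, "strategy": label.split(":", 1)[1],
                "factor": res.factor if res.reached else "not_reached",
                "matched_depth": res.matched_depth,
                "target_richness": res.target_richness,
                "max_richness": res.max_richness,
            })
    save_frame(pd.DataFrame(factor_rows), "depth_equivalence.tsv", index=False)

    # libraries emptied by filtering (e.g. a barren XL fraction) carry no
    # composition signal; exclude them from the dissimilarity analysis
    empty = [sid for sid in filtered.sample_ids
             if filtered.counts[sid].sum() == 0]
    diss_table = filtered.drop_samples(empty)
    for metric in ("jaccard", "bray_curtis"):
        dm = analysis.dissimilarity(diss_table, metric=metric)
        save_frame(dm.to_frame(), f"dissimilarity_{metric}.tsv")
        _, newick = analysis.cluster_dendrogram(dm)
        path = outdir / f"dendrogram_{metric}.nwk"
        path.write_text(newick + "\n", encoding="utf-8")
        outputs.append(path)

    summary = outdir / "summary.txt"
    with open(summary, "w", encoding="utf-8") as fh:
        fh.write(f"sizepool run (seed {config.seed})\n")
        fh.write(f"raw table: {experiment.table.shape[0]} OTUs x "
                 f"{experiment.table.shape[1]} samples\n")
        fh.write(f"filtered table: {filtered.shape[0]} OTUs x "
                 f"{filtered.shape[1]} samples\n")
        fh.write("size-class spectrum (% of OTUs): "
                 + ", ".join(f"{k}={v:.2f}" for k, v in spectrum.items())
                 + "\n")
    outputs.append(summary)

    manifest = {
        "seed": config.seed,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "sim"},
            "sim": dataclasses.asdict(sim),
        },
        "outputs": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8")
    return manifest
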