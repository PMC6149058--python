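"""End-to-end orchestration: simulate/load -> annotate -> differential ->
tally -> representation -> enrichment, with a reproducible report bundle.

Every stage writes a TSV with a ``#`` metadata header into the output
directory; a ``manifest.json`` records the serialized config, its hash, the
package version and per-table row counts.  Re-running on identical inputs
reproduces identical tables (the manifest timestamp aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential import (
    DepthPair,
    call_differential,
    differential_class_summary,
    differential_frame,
    read_region_counts,
)
from .genome import (
    DEFAULT_PRIORITY,
    build_partition,
    class_occupancy_report,
    load_chrom_sizes,
    load_class_intervals,
    load_repeatmasker,
)
from .peaks import annotated_peaks_frame, read_peaks, tally_classes
from .representation import (
    class_representation_table,
    repeat_representation_table,
    transcript_class_enrichment,
)
from .simulate import (
    SimConfig,
    make_genome,
    simulate_class_counts,
    simulate_peaks,
    simulate_region_counts,
)

log = logging.getLogger("peakrep")

__all__ = ["RunConfig", "run_pipeline"]

_FOLD_CONVENTION = (
    "fold = observed/expected ((k/n)/(K/N) or (O_c/T)/g_c); fold > 1 = over-represented"
)


@dataclass
class RunConfig:
    """Single-file configuration for a full run.

    Either ``simulate = True`` (inputs generated from ``sim``) or explicit
    input paths.  All rule choices carry the analysis defaults: max-overlap
    class assignment, min_fold 2, max_p 1e-4, pseudocount 0.5, chi-square
    without continuity correction.
    """

    outdir: str = "peakrep_out"
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    # input paths (ignored when simulate=True)
    chrom_sizes: str | None = None
    class_beds: dict[str, str] = field(default_factory=dict)
    repeats: str | None = None
    peaks: str | None = None
    peaks_dialect: str = "bed"
    region_counts: str | None = None
    class_counts: str | None = None
    # rule choices
    priority: list[str] = field(default_factory=lambda: list(DEFAULT_PRIORITY))
    assignment_rule: str = "max_overlap"
    min_fold: float = 2.0
    max_p: float = 1e-4
    pseudocount: float = 0.5
    depth_a: int = 1
    depth_b: int = 1
    yates: bool = False

    def validate(self) -> None:
        if self.assignment_rule not in {"max_overlap", "midpoint"}:
            raise ValueError(f"unknown assignment rule {self.assignment_rule!r}")
        if self.min_fold < 1 or not (0 < self.max_p <= 1):
            raise ValueError("need min_fold >= 1 and 0 < max_p <= 1")
        if not self.simulate and self.chrom_sizes is None:
            raise ValueError("non-simulated runs need chrom_sizes and class_beds inputs")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        for key in ("class_enrichment", "fold_map", "class_count_shifts"):
            d["sim"][key] = dict(d["sim"][key])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "fold_map" in sim_raw:
            sim_raw["fold_map"] = {int(k): float(v) for k, v in sim_raw["fold_map"].items()}
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.sim = SimConfig(**sim_raw)
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path, meta: list[str]) -> int:
    with open(path, "w") as fh:
        for line in meta:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict.

    Stage failures abort with the stage name prefixed to the error.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    (outdir / "config.yaml").write_text(config_yaml)
    config_hash = hashlib.sha256(config_yaml.encode()).hexdigest()[:16]

    manifest: dict = {
        "package": "peakrep",
        "version": __version__,
        "config_hash": config_hash,
        "row_counts": {},
        "stages": [],
    }
    meta_base = [f"peakrep {__version__}", f"config_hash {config_hash}", _FOLD_CONVENTION]
    counts = manifest["row_counts"]

    stage = "inputs"
    try:
        if config.simulate:
            partition, catalog, truth = make_genome(config.sim)
            peakset, peak_truth = simulate_peaks(partition, catalog, config.sim)
            regions, region_truth = simulate_region_counts(config.sim)
            class_table, table_truth = simulate_class_counts(config.sim)
            depths = DepthPair(config.sim.depth_a, config.sim.depth_b)
            manifest["ground_truth"] = {
                "n_peaks": len(peakset.peaks),
                "n_regions": len(regions),
                "repeat_total": catalog.total_repeats,
                "enriched_classes": dict(peak_truth.enriched_classes),
                "n_true_differential": sum(
                    1 for f in region_truth.region_folds.values() if f != 1.0
                ),
            }
        else:
            genome_sizes = load_chrom_sizes(config.chrom_sizes)
            class_sets = {
                cls_label: load_class_intervals(path, cls_label)
                for cls_label, path in config.class_beds.items()
            }
            partition = build_partition(class_sets, tuple(config.priority), genome_sizes)
            catalog = load_repeatmasker(config.repeats) if config.repeats else None
            peakset = (
                read_peaks(config.peaks, dialect=config.peaks_dialect) if config.peaks else None
            )
            regions = read_region_counts(config.region_counts) if config.region_counts else []
            class_table = (
                pd.read_csv(config.class_counts, sep="\t", comment="#", index_col=0)
                if config.class_counts
                else None
            )
            depths = DepthPair(config.depth_a, config.depth_b)

        stage = "occupancy"
        occ = class_occupancy_report(partition)
        counts["occupancy.tsv"] = _write_tsv(
            occ, outdir / "occupancy.tsv", meta_base + ["percent = 100*occupancy_bp/genome_bp"]
        )
        manifest["stages"].append(stage)

        stage = "annotate"
        if peakset is not None:
            tally = tally_classes(
                peakset, partition, catalog=catalog, rule=config.assignment_rule
            )
            counts["annotated_peaks.tsv"] = _write_tsv(
                annotated_peaks_frame(peakset), outdir / "annotated_peaks.tsv", meta_base
            )
            tally_df = pd.DataFrame(
                sorted(tally.by_class.items()), columns=["class", "peak_count"]
            )
            counts["class_tally.tsv"] = _write_tsv(
                tally_df,
                outdir / "class_tally.tsv",
                meta_base + ["tallies count peaks, not bp"],
            )
            manifest["stages"].append(stage)

            stage = "representation"
            if catalog is not None and tally.n_with_repeat > 0:
                rep = repeat_representation_table(
                    tally.by_repeat,
                    tally.n_with_repeat,
                    catalog.category_counts,
                    catalog.total_repeats,
                )
                counts["repeat_representation.tsv"] = _write_tsv(
                    rep, outdir / "repeat_representation.tsv", meta_base
                )
            cls_rep = class_representation_table(
                tally.by_class, tally.total, partition.fractions, yates=config.yates
            )
            counts["class_representation.tsv"] = _write_tsv(
                cls_rep, outdir / "class_representation.tsv", meta_base
            )
            manifest["stages"].append(stage)

        stage = "differential"
        if regions:
            calls = call_differential(
                regions,
                depths,
                min_fold=config.min_fold,
                max_p=config.max_p,
                pseudocount=config.pseudocount,
            )
            counts["differential.tsv"] = _write_tsv(
                differential_frame(calls),
                outdir / "differential.tsv",
                meta_base
                + [f"rule: fold >= {config.min_fold} and cumulative Poisson p < {config.max_p}"],
            )
            manifest["stages"].append(stage)
            if not config.simulate or _regions_annotatable(regions, partition):
                stage = "differential_tally"
                summary = differential_class_summary(
                    calls, partition, catalog=catalog, rule=config.assignment_rule
                )
                rows = [
                    {"direction": d, "class": c, "count": n}
                    for d, t in summary.items()
                    for c, n in sorted(t.by_class.items())
                ]
                counts["differential_tally.tsv"] = _write_tsv(
                    pd.DataFrame(rows, columns=["direction", "class", "count"]),
                    outdir / "differential_tally.tsv",
                    meta_base,
                )
                manifest["stages"].append(stage)

        stage = "enrichment"
        if class_table is not None:
            enr = transcript_class_enrichment(class_table)
            counts["transcript_enrichment.tsv"] = _write_tsv(
                enr,
                outdir / "transcript_enrichment.tsv",
                meta_base + ["fold 1 = no enrichment relative to random distribution"],
            )
            manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s stages, outputs in %s", len(manifest["stages"]), outdir)
    return manifest


def _regions_annotatable(regions, partition) -> bool:
    return all(rc.region.chrom in partition.genome_sizes for rc in regions)
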