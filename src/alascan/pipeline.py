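"""Pipeline orchestration: configuration, stage chaining, run manifests.

Two entry points:

* :func:`run_synthetic_study` — in-memory end-to-end run on a simulated
  library (simulate → gate/summarize/classify → normalize/anchor → categorize)
  returning every stage table plus truth-recovery metrics. This is the
  workhorse for the analysis drivers and the test suite.
* :func:`run_pipeline` — file-based orchestration of the same stages driven
  by a :class:`PipelineConfig`, writing each stage's artifacts and a run
  manifest (inputs, config hash, seed, version). Identical config + inputs
  produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from alascan import __version__, io
from alascan.abundance import (
    PUBLISHED_BAND,
    SignificanceBand,
    abundance_chain,
    build_band,
    samples_from_frame,
)
from alascan.annotation import attach_effects, export_annotations, read_sequence, validate_positions
from alascan.effects import assemble_effect_table, category_counts
from alascan.errors import ConfigurationError
from alascan.flow import (
    DEFAULT_GATE_PERCENTILE,
    DEFAULT_MIN_GATED_EVENTS,
    EventTable,
    classify_library,
    compute_library_thresholds,
    gate_events,
    summaries_from_wells,
    well_mean,
)
from alascan.synth import (
    WILD_TYPE_ID,
    SimulationConfig,
    simulate_library,
    spectral_frame,
    truth_frame,
    write_library,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """File-based pipeline configuration.

    Exactly one of ``band_bounds`` or (``band_level``, ``band_log_sd``) must
    be set; the former uses printed bounds verbatim, the latter constructs a
    reciprocal-symmetric band.
    """

    events_dir: str | None = None
    platemap: str | None = None
    spectral_counts: str | None = None
    sequence: str | None = None
    metadata: str | None = None
    outdir: str = "results"
    gate_percentile: float = DEFAULT_GATE_PERCENTILE
    gate_threshold: float | None = None
    min_gated_events: int = DEFAULT_MIN_GATED_EVENTS
    band_bounds: tuple[float, float] | None = (PUBLISHED_BAND.lower, PUBLISHED_BAND.upper)
    band_level: float | None = None
    band_log_sd: float | None = None
    anchor_strain: str = WILD_TYPE_ID
    wild_type_strain: str = WILD_TYPE_ID
    reference_batch: str | None = None
    seed: int | None = None
    display_precision: int = 3
    simulation: SimulationConfig | None = None

    def validate(self) -> None:
        explicit = self.band_bounds is not None
        derived = self.band_level is not None or self.band_log_sd is not None
        if explicit == derived:
            raise ConfigurationError(
                "set exactly one of band_bounds or (band_level, band_log_sd)"
            )
        if derived and (self.band_level is None or self.band_log_sd is None):
            raise ConfigurationError("derived band needs both band_level and band_log_sd")

    def band(self) -> SignificanceBand:
        self.validate()
        if self.band_bounds is not None:
            return SignificanceBand(lower=self.band_bounds[0], upper=self.band_bounds[1])
        return build_band(self.band_log_sd, self.band_level)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation"):
            d["simulation"] = SimulationConfig(**d["simulation"])
        if d.get("band_bounds") is not None:
            d["band_bounds"] = tuple(d["band_bounds"])
        return cls(**d)


def induction_stage(
    events: dict[str, EventTable],
    platemap: pd.DataFrame,
    gate_percentile: float = DEFAULT_GATE_PERCENTILE,
    gate_threshold: float | None = None,
    min_gated_events: int = DEFAULT_MIN_GATED_EVENTS,
):
    """Gate, average, summarize and classify a set of wells.

    Returns (per-strain classification table, thresholds).
    """
    wells = []
    for _, row in platemap.iterrows():
        tab = events[row["well"]]
        gated = gate_events(tab, threshold=gate_threshold, percentile=gate_percentile)
        wells.append(
            well_mean(
                gated,
                strain_id=str(row["strain"]),
                condition=str(row["condition"]),
                replicate=int(row["replicate"]),
                plate_id=str(row.get("plate", "plate1")),
                min_events=min_gated_events,
            )
        )
    summaries = summaries_from_wells(wells)
    thresholds = compute_library_thresholds(summaries)
    return classify_library(summaries, thresholds), thresholds


def run_synthetic_study(
    sim_config: SimulationConfig,
    band: SignificanceBand = PUBLISHED_BAND,
    gate_percentile: float = DEFAULT_GATE_PERCENTILE,
) -> dict:
    """Simulate a library and push it through the complete analysis chain.

    Returns a dict with ``truth``, ``induction``, ``thresholds``,
    ``abundance``, ``effects`` tables and ``recovery`` metrics
    (fraction of mutants whose recovered induction class / effect category
    matches the planted truth).
    """
    lib = simulate_library(sim_config)
    induction, thresholds = induction_stage(
        lib["events"], lib["platemap"], gate_percentile=gate_percentile
    )
    samples = lib["spectral"]
    abundance = abundance_chain(samples, anchor_strain=WILD_TYPE_ID, band=band)
    # drop anchor duplicates from the mutant-level stream (keep strain-unique rows)
    mutant_abundance = abundance[abundance["strain"] != WILD_TYPE_ID].copy()
    effects = assemble_effect_table(induction, mutant_abundance, WILD_TYPE_ID, band=band)

    truth = truth_frame(lib["truths"])
    merged = truth.merge(
        induction.rename(columns={"strain": "mutant_id"}), on="mutant_id", how="left"
    ).merge(effects.rename(columns={"mutant": "mutant_id"}), on="mutant_id", how="left")
    class_ok = merged["induction_class_true"] == merged["induction_class_x"]
    category_ok = merged["category_true"] == merged["category"]
    recovery = {
        "n_mutants": int(len(truth)),
        "induction_class_recovery": float(class_ok.mean()),
        "category_recovery": float(category_ok.mean()),
        "category_counts": category_counts(effects),
    }
    return {
        "truth": truth,
        "induction": induction,
        "thresholds": thresholds,
        "abundance": abundance,
        "effects": effects,
        "recovery": recovery,
        "library": lib,
    }


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the file-based pipeline and write a manifest.

    When ``config.simulation`` is set, the library is simulated first and its
    files written under ``<outdir>/simulated``; otherwise events/platemap/
    spectral counts are read from the configured paths.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    band = config.band()
    artifacts: dict[str, Path] = {}

    if config.simulation is not None:
        lib = simulate_library(config.simulation)
        sim_dir = outdir / "simulated"
        artifacts.update(write_library(lib, sim_dir))
        events = lib["events"]
        platemap = lib["platemap"]
        spectral = spectral_frame(lib["spectral"])
        anchor = wild_type = WILD_TYPE_ID
    else:
        if not (config.events_dir and config.platemap and config.spectral_counts):
            raise ConfigurationError("need events_dir, platemap and spectral_counts (or a simulation)")
        platemap = io.read_table(config.platemap)
        events = {}
        for well in platemap["well"]:
            df = io.read_table(Path(config.events_dir) / f"{well}.tsv")
            events[well] = EventTable.from_frame(str(well), df)
        spectral = io.read_table(config.spectral_counts)
        anchor = config.anchor_strain
        wild_type = config.wild_type_strain

    induction, thresholds = induction_stage(
        events,
        platemap,
        gate_percentile=config.gate_percentile,
        gate_threshold=config.gate_threshold,
        min_gated_events=config.min_gated_events,
    )
    artifacts["induction"] = io.write_table(induction, outdir / "induction_summary.tsv")
    artifacts["thresholds"] = io.write_json(thresholds.to_dict(), outdir / "thresholds.json")

    samples = samples_from_frame(spectral)
    abundance = abundance_chain(
        samples, anchor_strain=anchor, reference_batch=config.reference_batch, band=band
    )
    artifacts["abundance"] = io.write_table(abundance, outdir / "abundance.tsv")
    artifacts["band"] = io.write_json(
        {"lower": band.lower, "upper": band.upper, "level": band.level}, outdir / "band.json"
    )

    mutant_abundance = abundance[abundance["strain"] != wild_type]
    effects = assemble_effect_table(induction, mutant_abundance, wild_type, band=band)
    artifacts["effects"] = io.write_table(effects, outdir / "effects.tsv")
    artifacts["category_counts"] = io.write_json(
        category_counts(effects), outdir / "category_counts.json"
    )

    if config.sequence and config.metadata:
        seq = read_sequence(config.sequence)
        metadata = io.read_table(config.metadata)
        annotations = validate_positions(metadata, seq)
        annotations = attach_effects(annotations, effects, induction)
        artifacts["annotations"] = export_annotations(annotations, outdir / "annotations.tsv")

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed if config.seed is not None else (
            config.simulation.seed if config.simulation else None
        ),
        "version": __version__,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    artifacts["manifest"] = io.write_json(manifest, outdir / "manifest.json")
    return artifacts
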