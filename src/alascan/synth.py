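"""Seeded synthetic alanine-scan libraries with planted effect classes.

The generator emulates the study design end to end: a library of mutants,
each carrying a planted induction phenotype, fold induction, and periplasmic
abundance multiplier; triplicate wells per strain and condition with
log-normal event fluorescence and a sub-gate background sub-population; and
one Poisson spectral-count sample per mutant with sample-depth and batch
effects, plus a wild-type anchor sample in every batch.

All randomness flows from the configured seed through per-record
``numpy.random.default_rng`` streams keyed on (seed, stage, position,
condition, replicate), so any individual well or sample is reproducible in
isolation and the whole library is byte-identical across runs.

Default parameters mirror the published study where it states them
(232 mutants, biological triplicates, class proportions 10/232 non-inducible,
13/232 poorly inducible, ~7% semi-constitutive, wild-type fold 8.3) and
realistic flow-cytometry / LC-MS scales elsewhere; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from alascan import io
from alascan.abundance import PUBLISHED_BAND, SpectralSample, classify_abundance
from alascan.effects import categorize
from alascan.errors import ConfigurationError
from alascan.flow import INDUCED, UNINDUCED, EventTable, InductionClass

# rng stream tags (arbitrary, fixed) so stages draw independent streams
_TRUTH_STREAM = 101
_EVENT_STREAM = 211
_MS_STREAM = 307

#: Strain id of the simulated wild-type reference (position 0).
WILD_TYPE_ID = "WT"

DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    InductionClass.NON_INDUCIBLE.value: 10 / 232,
    InductionClass.POORLY_INDUCIBLE.value: 13 / 232,
    InductionClass.SEMI_CONSTITUTIVE.value: 0.070,
    InductionClass.WILD_TYPE_LIKE.value: 1.0 - 10 / 232 - 13 / 232 - 0.070,
}


@dataclass(frozen=True)
class MutantTruth:
    """Planted ground truth for one simulated mutant."""

    mutant_id: str
    position: int  # mature-protein numbering; 0 reserved for the wild-type reference
    induction_class_true: str
    fold_true: float
    abundance_multiplier_true: float
    category_true: str
    uninduced_mean_true: float
    fluorescence_ratio_true: float

    def __post_init__(self):
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.fold_true <= 0 or self.abundance_multiplier_true < 0:
            raise ValueError(f"{self.mutant_id}: non-positive planted parameters")
        if (
            self.induction_class_true == InductionClass.NON_INDUCIBLE.value
            and self.fold_true > 1.0
        ):
            raise ValueError(f"{self.mutant_id}: non-inducible implies fold <= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic library.

    Fold and abundance draw ranges are per induction class / effect category;
    the defaults plant well-separated classes (non-inducible fold ≤ 0.9,
    semi-constitutive uninduced ≥ 2.5× baseline, abundance multipliers
    ≤ 0.5 or ≥ 1) so end-to-end recovery is a property of the method, not of
    luck.
    """

    seed: int
    n_mutants: int = 232
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    baseline_uninduced_mean: float = 2500.0  # arbitrary fluorescence units
    wild_type_fold: float = 8.3
    event_count_per_well: int = 2000
    event_log_sd: float = 0.4
    background_fraction: float = 0.05
    replicates: int = 3
    ms_depth_mean: int = 20000
    ms_batch_factors: Mapping[str, float] = field(
        default_factory=lambda: {"batch1": 1.0, "batch2": 2.0}
    )
    standard_abundance: float = 0.019  # internal-standard fraction of total spectra
    target_fraction_wt: float = 0.0235  # wild-type target fraction of total spectra
    # dispersion of per-mutant baselines and per-well replicate noise (log scale)
    strain_log_jitter: float = 0.10
    well_log_jitter: float = 0.08
    wild_type_fold_log_jitter: float = 0.08
    wild_type_fold_factor: float = 1.4  # wild-type-like folds stay within this factor
    # planted class separations
    fold_range_non_inducible: tuple[float, float] = (0.5, 0.9)
    fold_range_poorly_inducible: tuple[float, float] = (1.3, 2.0)
    fold_range_semi_constitutive: tuple[float, float] = (3.5, 4.5)
    semi_constitutive_uninduced_factor: tuple[float, float] = (2.8, 3.6)
    # effect-category mix among induction-impaired / semi-constitutive mutants
    impaired_category_probs: tuple[float, float, float] = (0.5, 0.2, 0.3)  # sig, abund, both
    semi_low_abundance_prob: float = 0.15
    # scatter model: gated cells vs sub-gate background particles
    cell_scatter_median: float = 1000.0
    cell_scatter_log_sd: float = 0.25
    background_scatter_median: float = 30.0
    background_scatter_log_sd: float = 0.3
    instrument_floor: float = 30.0
    ms_overdispersion: float | None = None  # optional negative-binomial switch

    def validate(self) -> None:
        props = dict(self.class_proportions)
        missing = {c.value for c in InductionClass} - props.keys()
        if missing:
            raise ConfigurationError(f"class_proportions missing {sorted(missing)}")
        if any(p < 0 for p in props.values()) or abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_proportions must be a simplex summing to 1")
        if self.replicates < 2:
            raise ConfigurationError("replicates must be >= 2 (SD must be computable)")
        if self.n_mutants < 1 or self.event_count_per_well < 1:
            raise ConfigurationError("n_mutants and event_count_per_well must be >= 1")
        if not 0 <= self.background_fraction <= 1:
            raise ConfigurationError("background_fraction must be in [0, 1]")
        if self.event_log_sd < 0 or self.baseline_uninduced_mean <= 0 or self.wild_type_fold <= 0:
            raise ConfigurationError("dispersion and means must be positive")
        if not self.ms_batch_factors or any(f <= 0 for f in self.ms_batch_factors.values()):
            raise ConfigurationError("ms_batch_factors must be positive")

    @property
    def proportion_vector(self) -> tuple[list[str], np.ndarray]:
        order = [c.value for c in InductionClass]
        return order, np.array([self.class_proportions[c] for c in order], dtype=float)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_proportions"] = dict(self.class_proportions)
        d["ms_batch_factors"] = dict(self.ms_batch_factors)
        return d


def _lognormal_mean(rng: np.random.Generator, mean: float, log_sd: float, size=None):
    """Log-normal draws with the given arithmetic mean."""
    if log_sd == 0:
        return np.full(size, mean, dtype=float) if size is not None else float(mean)
    mu = np.log(mean) - 0.5 * log_sd**2
    return np.exp(rng.normal(mu, log_sd, size=size))


def wild_type_truth(config: SimulationConfig) -> MutantTruth:
    """The noiseless wild-type reference strain (position 0)."""
    return MutantTruth(
        mutant_id=WILD_TYPE_ID,
        position=0,
        induction_class_true=InductionClass.WILD_TYPE_LIKE.value,
        fold_true=config.wild_type_fold,
        abundance_multiplier_true=1.0,
        category_true="no_effect",
        uninduced_mean_true=config.baseline_uninduced_mean,
        fluorescence_ratio_true=1.0,
    )


def generate_truth(config: SimulationConfig) -> list[MutantTruth]:
    """Draw the planted ground-truth table for a library.

    Class counts are multinomial in the configured proportions; per class,
    fold inductions and uninduced baselines are drawn from the configured
    ranges, abundance multipliers are drawn per effect category, and the true
    category is then derived from the planted values with the published band
    so truth and rules are always mutually consistent.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _TRUTH_STREAM])
    order, probs = config.proportion_vector
    counts = rng.multinomial(config.n_mutants, probs)
    labels = np.repeat(order, counts)
    rng.shuffle(labels)

    wt_induced = config.baseline_uninduced_mean * config.wild_type_fold
    truths = []
    for i, label in enumerate(labels):
        position = i + 1
        uninduced = config.baseline_uninduced_mean * float(
            _lognormal_mean(rng, 1.0, config.strain_log_jitter)
        )
        if label == InductionClass.NON_INDUCIBLE.value:
            fold = rng.uniform(*config.fold_range_non_inducible)
        elif label == InductionClass.POORLY_INDUCIBLE.value:
            fold = rng.uniform(*config.fold_range_poorly_inducible)
        elif label == InductionClass.SEMI_CONSTITUTIVE.value:
            uninduced *= rng.uniform(*config.semi_constitutive_uninduced_factor)
            fold = rng.uniform(*config.fold_range_semi_constitutive)
        else:
            lo = config.wild_type_fold / config.wild_type_fold_factor
            hi = config.wild_type_fold * config.wild_type_fold_factor
            fold = float(
                np.clip(
                    config.wild_type_fold
                    * np.exp(rng.normal(0.0, config.wild_type_fold_log_jitter)),
                    lo,
                    hi,
                )
            )
        F_true = uninduced * fold / wt_induced

        if label in (InductionClass.NON_INDUCIBLE.value, InductionClass.POORLY_INDUCIBLE.value):
            kind = rng.choice(["signaling", "abundance", "both"], p=config.impaired_category_probs)
            if kind == "signaling":
                mult = rng.uniform(1.0, 1.7)
            elif kind == "abundance":
                mult = float(np.clip(F_true, 0.05, 0.5))  # proportional loss
            else:  # both: abundance loss insufficient to explain F
                mult = float(np.clip(F_true / 0.35, 0.05, 0.5))
        elif label == InductionClass.SEMI_CONSTITUTIVE.value:
            if rng.random() < config.semi_low_abundance_prob:
                mult = rng.uniform(0.3, 0.5)
            else:
                mult = rng.uniform(1.0, 1.6)
        else:
            mult = rng.uniform(1.0, 1.3)

        category = categorize(
            label, F_true, mult, classify_abundance(mult, PUBLISHED_BAND), PUBLISHED_BAND
        ).value
        truths.append(
            MutantTruth(
                mutant_id=f"m{position:03d}A",
                position=position,
                induction_class_true=str(label),
                fold_true=float(fold),
                abundance_multiplier_true=float(mult),
                category_true=category,
                uninduced_mean_true=float(uninduced),
                fluorescence_ratio_true=float(F_true),
            )
        )
    return truths


def simulate_events(
    truth: MutantTruth,
    condition: str,
    config: SimulationConfig,
    replicate: int,
) -> EventTable:
    """Simulate one well's event table for a strain × condition × replicate.

    The well mean is the strain's planted mean (× fold when induced), jittered
    log-normally between replicate wells; event fluorescence is log-normal
    around that mean. A fixed ``background_fraction`` of events are sub-gate
    background particles with low scatter and near-floor fluorescence.
    """
    if condition not in (UNINDUCED, INDUCED):
        raise ConfigurationError(f"unknown condition {condition!r}")
    config.validate()
    cond_idx = 0 if condition == UNINDUCED else 1
    rng = np.random.default_rng(
        [config.seed, _EVENT_STREAM, truth.position, cond_idx, replicate]
    )
    mean = truth.uninduced_mean_true * (truth.fold_true if condition == INDUCED else 1.0)
    well_mean_value = mean * float(_lognormal_mean(rng, 1.0, config.well_log_jitter))

    n = config.event_count_per_well
    n_bg = int(round(config.background_fraction * n))
    n_cells = n - n_bg

    fl_cells = _lognormal_mean(rng, well_mean_value, config.event_log_sd, size=n_cells)
    sc_cells = config.cell_scatter_median * np.exp(
        rng.normal(0.0, config.cell_scatter_log_sd, size=n_cells)
    )
    fl_bg = _lognormal_mean(rng, config.instrument_floor, config.background_scatter_log_sd, size=n_bg)
    sc_bg = config.background_scatter_median * np.exp(
        rng.normal(0.0, config.background_scatter_log_sd, size=n_bg)
    )
    scatter = np.concatenate([sc_cells, sc_bg])
    fluor = np.concatenate([fl_cells, fl_bg])
    perm = rng.permutation(n)
    well_id = f"{truth.mutant_id}_{condition}_r{replicate}"
    return EventTable(well_id, scatter[perm], fluor[perm])


def _count(rng: np.random.Generator, mean: float, overdispersion: float | None) -> int:
    """Poisson count, or gamma-Poisson when an overdispersion is configured."""
    if mean <= 0:
        return 0
    if overdispersion:
        shape = 1.0 / overdispersion
        mean = rng.gamma(shape, mean / shape)
    return int(rng.poisson(mean))


def simulate_spectral_sample(
    truth: MutantTruth, config: SimulationConfig, batch: str
) -> SpectralSample:
    """Simulate one MS sample's exclusive spectrum counts for a strain.

    Target counts are Poisson with rate abundance multiplier × wild-type
    target fraction × depth × batch factor; the internal standard and the
    remaining (other-protein) spectra scale the same way, so the total is
    Poisson at approximately depth × batch factor and always ≥ target +
    standard.
    """
    config.validate()
    if batch not in config.ms_batch_factors:
        raise ConfigurationError(f"batch {batch!r} not in ms_batch_factors")
    batch_idx = sorted(config.ms_batch_factors).index(batch)
    rng = np.random.default_rng([config.seed, _MS_STREAM, truth.position, batch_idx])
    depth = config.ms_depth_mean * config.ms_batch_factors[batch]
    target = _count(
        rng,
        truth.abundance_multiplier_true * config.target_fraction_wt * depth,
        config.ms_overdispersion,
    )
    standard = _count(rng, config.standard_abundance * depth, config.ms_overdispersion)
    other_fraction = max(1.0 - config.target_fraction_wt - config.standard_abundance, 0.0)
    other = _count(rng, other_fraction * depth, config.ms_overdispersion)
    sample_id = truth.mutant_id if truth.position > 0 else f"{truth.mutant_id}({batch})"
    return SpectralSample(
        sample_id=sample_id,
        batch_id=batch,
        target_count=target,
        standard_count=standard,
        total_spectra=target + standard + max(other, 1),
        strain_id=truth.mutant_id,
    )


def simulate_library(config: SimulationConfig) -> dict:
    """Simulate a complete study in memory.

    Returns a dict with:

    * ``truths`` — list of :class:`MutantTruth` (mutants only),
    * ``wild_type`` — the wild-type reference truth,
    * ``platemap`` — well → strain/condition/replicate/plate table,
    * ``events`` — mapping well_id → :class:`EventTable`,
    * ``spectral`` — list of :class:`SpectralSample` (one per mutant,
      batches alternating by position, plus one wild-type anchor per batch).
    """
    config.validate()
    truths = generate_truth(config)
    wt = wild_type_truth(config)
    batches = sorted(config.ms_batch_factors)

    events: dict[str, EventTable] = {}
    platemap_rows = []
    for t in [wt] + truths:
        for condition in (UNINDUCED, INDUCED):
            for rep in range(1, config.replicates + 1):
                tab = simulate_events(t, condition, config, rep)
                events[tab.well_id] = tab
                platemap_rows.append(
                    {
                        "well": tab.well_id,
                        "strain": t.mutant_id,
                        "condition": condition,
                        "replicate": rep,
                        "plate": f"plate{(t.position % 8) + 1}",
                    }
                )
    spectral = [simulate_spectral_sample(wt, config, b) for b in batches]
    spectral += [
        simulate_spectral_sample(t, config, batches[t.position % len(batches)]) for t in truths
    ]
    return {
        "truths": truths,
        "wild_type": wt,
        "platemap": pd.DataFrame(platemap_rows),
        "events": events,
        "spectral": spectral,
    }


def truth_frame(truths: Sequence[MutantTruth]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in truths])


def spectral_frame(samples: Sequence[SpectralSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [s.sample_id for s in samples],
            "strain": [s.strain_id for s in samples],
            "batch": [s.batch_id for s in samples],
            "target_count": [s.target_count for s in samples],
            "standard_count": [s.standard_count for s in samples],
            "total_spectra": [s.total_spectra for s in samples],
        }
    )


def write_library(library: dict, outdir: str | Path, write_events: bool = True) -> dict[str, Path]:
    """Write a simulated library to the package's text formats.

    One event table per well under ``events/``, plus the plate map, spectral
    counts, and truth tables. Returns the written paths.
    """
    outdir = Path(outdir)
    paths = {}
    if write_events:
        events_dir = outdir / "events"
        events_dir.mkdir(parents=True, exist_ok=True)
        for well_id, tab in library["events"].items():
            io.write_table(tab.to_frame(), events_dir / f"{well_id}.tsv")
        paths["events"] = events_dir
    paths["platemap"] = io.write_table(library["platemap"], outdir / "platemap.tsv")
    paths["spectral"] = io.write_table(spectral_frame(library["spectral"]), outdir / "spectral_counts.tsv")
    paths["truth"] = io.write_table(
        truth_frame([library["wild_type"]] + list(library["truths"])), outdir / "truth.tsv"
    )
    return paths
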