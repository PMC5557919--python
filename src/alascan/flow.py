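"""Reporter-induction analysis of event-level flow-cytometry data.

The measurement model: each well of a microtiter plate yields one event table
(forward scatter + green reporter fluorescence per particle). Events are
gated on scatter to remove sub-cellular background particles, the arithmetic
mean fluorescence of the gated population is the well measurement, and
biological triplicates per strain and condition are averaged into a strain
summary with a sample SD (n−1). Fold induction is the ratio of the induced
to the uninduced strain mean.

Classification uses library-wide thresholds: a strain is *semi-constitutive*
when its uninduced mean minus its own SD exceeds the library uninduced mean
plus twice the library SD; it is induction-impaired when its induced mean
falls below the library induced mean minus twice the library SD, and within
the impaired set *non-inducible* means fold ≤ 1 and *poorly inducible*
means fold > 1. Everything else is wild-type-like. Fluorescence values are
deliberately not normalized for plate-to-plate variation; plate identity is
carried as metadata only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from alascan.errors import GatingError, SummarizationError, ThresholdError, UndefinedFoldError

logger = logging.getLogger(__name__)

UNINDUCED = "uninduced"
INDUCED = "induced"

#: Minimum gated events for a well measurement to be trusted downstream.
DEFAULT_MIN_GATED_EVENTS = 100

#: Default scatter gate: drop events below this percentile of the per-well
#: scatter distribution. An absolute threshold can be supplied instead.
DEFAULT_GATE_PERCENTILE = 5.0


class InductionClass(str, Enum):
    """Phenotype of a strain's ribose-induction profile."""

    NON_INDUCIBLE = "non_inducible"
    POORLY_INDUCIBLE = "poorly_inducible"
    SEMI_CONSTITUTIVE = "semi_constitutive"
    WILD_TYPE_LIKE = "wild_type_like"


#: Classes counted as induction-impaired by the effect categorizer.
IMPAIRED_CLASSES = frozenset({InductionClass.NON_INDUCIBLE, InductionClass.POORLY_INDUCIBLE})


@dataclass(frozen=True)
class EventTable:
    """Per-event scatter and fluorescence values for one well."""

    well_id: str
    scatter: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        sc = np.asarray(self.scatter, dtype=float)
        fl = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "scatter", sc)
        object.__setattr__(self, "fluorescence", fl)
        if sc.shape != fl.shape or sc.ndim != 1:
            raise ValueError(f"well {self.well_id}: scatter/fluorescence must be 1-D and aligned")
        if sc.size < 1:
            raise ValueError(f"well {self.well_id}: empty event table")
        if not (np.isfinite(sc).all() and np.isfinite(fl).all()):
            raise ValueError(f"well {self.well_id}: non-finite event values")

    def __len__(self) -> int:
        return int(self.scatter.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_index": np.arange(len(self)),
                "scatter": self.scatter,
                "fluorescence": self.fluorescence,
            }
        )

    @classmethod
    def from_frame(cls, well_id: str, df: pd.DataFrame) -> "EventTable":
        return cls(well_id, df["scatter"].to_numpy(float), df["fluorescence"].to_numpy(float))


@dataclass(frozen=True)
class WellMeasurement:
    """Gated mean fluorescence of one well, with acquisition metadata."""

    strain_id: str
    condition: str
    replicate: int
    gated_mean_fluorescence: float
    n_gated: int
    plate_id: str = "plate1"
    flagged: bool = False  # below the minimum gated-event count


@dataclass(frozen=True)
class StrainInductionSummary:
    """Triplicate-aggregated induction summary for one strain."""

    strain_id: str
    mean_uninduced: float
    sd_uninduced: float
    mean_induced: float
    sd_induced: float
    fold_induction: float
    n_replicates: int


@dataclass(frozen=True)
class LibraryThresholds:
    """Library-wide ±2 SD bounds used for phenotype classification."""

    mean_uninduced_all: float
    sd_uninduced_all: float
    mean_induced_all: float
    sd_induced_all: float
    n_strains: int = 0
    upper_uninduced: float = field(init=False)
    lower_induced: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "upper_uninduced", self.mean_uninduced_all + 2.0 * self.sd_uninduced_all
        )
        object.__setattr__(
            self, "lower_induced", self.mean_induced_all - 2.0 * self.sd_induced_all
        )

    def to_dict(self) -> dict:
        return {
            "mean_uninduced_all": self.mean_uninduced_all,
            "sd_uninduced_all": self.sd_uninduced_all,
            "mean_induced_all": self.mean_induced_all,
            "sd_induced_all": self.sd_induced_all,
            "upper_uninduced": self.upper_uninduced,
            "lower_induced": self.lower_induced,
            "n_strains": self.n_strains,
        }


def gate_events(
    table: EventTable,
    threshold: float | None = None,
    percentile: float = DEFAULT_GATE_PERCENTILE,
) -> EventTable:
    """Remove background particles below a scatter threshold.

    ``threshold`` is an absolute scatter cutoff; when omitted, the cutoff is
    the given lower ``percentile`` of the well's own scatter distribution.
    Events with scatter >= the cutoff are kept.

    Raises
    ------
    GatingError
        If no event survives the gate (names the well).
    """
    cut = float(np.percentile(table.scatter, percentile)) if threshold is None else float(threshold)
    keep = table.scatter >= cut
    if not keep.any():
        raise GatingError(f"well {table.well_id}: scatter gate at {cut:g} removed all events")
    return EventTable(table.well_id, table.scatter[keep], table.fluorescence[keep])


def well_mean(
    table: EventTable,
    strain_id: str,
    condition: str,
    replicate: int,
    plate_id: str = "plate1",
    min_events: int = DEFAULT_MIN_GATED_EVENTS,
) -> WellMeasurement:
    """Arithmetic mean fluorescence of a gated well.

    Wells with fewer than ``min_events`` gated events are returned flagged
    and should be excluded from strain summaries; a warning is logged.
    """
    if condition not in (UNINDUCED, INDUCED):
        raise ValueError(f"unknown condition {condition!r}")
    n = len(table)
    flagged = n < min_events
    if flagged:
        logger.warning(
            "well %s (%s/%s rep %d): only %d gated events (< %d); flagged",
            table.well_id, strain_id, condition, replicate, n, min_events,
        )
    return WellMeasurement(
        strain_id=strain_id,
        condition=condition,
        replicate=replicate,
        gated_mean_fluorescence=float(np.mean(table.fluorescence)),
        n_gated=n,
        plate_id=plate_id,
        flagged=flagged,
    )


def summarize_strain(wells: Sequence[WellMeasurement]) -> StrainInductionSummary:
    """Aggregate replicate well means into a strain induction summary.

    Requires at least two unflagged replicates in each condition. SDs are
    sample standard deviations (n−1) over the replicate well means; fold
    induction is exactly induced mean / uninduced mean.
    """
    wells = [w for w in wells if not w.flagged]
    if not wells:
        raise SummarizationError("no usable wells")
    strain_ids = {w.strain_id for w in wells}
    if len(strain_ids) != 1:
        raise SummarizationError(f"wells from multiple strains: {sorted(strain_ids)}")
    strain_id = wells[0].strain_id
    by_cond = {
        cond: np.array(
            [w.gated_mean_fluorescence for w in wells if w.condition == cond], dtype=float
        )
        for cond in (UNINDUCED, INDUCED)
    }
    for cond, vals in by_cond.items():
        if vals.size == 0:
            raise SummarizationError(f"strain {strain_id}: missing condition {cond!r}")
        if vals.size < 2:
            raise SummarizationError(
                f"strain {strain_id}: need >= 2 replicates in {cond!r}, got {vals.size}"
            )
    mean_u = float(np.mean(by_cond[UNINDUCED]))
    mean_i = float(np.mean(by_cond[INDUCED]))
    if mean_u == 0:
        raise UndefinedFoldError(f"strain {strain_id}: uninduced mean is zero; fold undefined")
    return StrainInductionSummary(
        strain_id=strain_id,
        mean_uninduced=mean_u,
        sd_uninduced=float(np.std(by_cond[UNINDUCED], ddof=1)),
        mean_induced=mean_i,
        sd_induced=float(np.std(by_cond[INDUCED], ddof=1)),
        fold_induction=mean_i / mean_u,
        n_replicates=min(by_cond[UNINDUCED].size, by_cond[INDUCED].size),
    )


def compute_library_thresholds(
    summaries: Sequence[StrainInductionSummary], min_strains: int = 10
) -> LibraryThresholds:
    """Library-wide means and SDs over per-strain means (wild-type included).

    The statistics are taken across the per-strain mean uninduced and mean
    induced values of every summarized strain, mutants plus wild-type.
    """
    if len(summaries) < min_strains:
        raise ThresholdError(
            f"need >= {min_strains} strains for library thresholds, got {len(summaries)}"
        )
    u = np.array([s.mean_uninduced for s in summaries], dtype=float)
    i = np.array([s.mean_induced for s in summaries], dtype=float)
    return LibraryThresholds(
        mean_uninduced_all=float(np.mean(u)),
        sd_uninduced_all=float(np.std(u, ddof=1)),
        mean_induced_all=float(np.mean(i)),
        sd_induced_all=float(np.std(i, ddof=1)),
        n_strains=len(summaries),
    )


def classify_induction(
    summary: StrainInductionSummary, thresholds: LibraryThresholds
) -> InductionClass:
    """Assign exactly one induction phenotype to a strain.

    Ordered rules (first match wins):

    1. semi-constitutive: ``mean_uninduced − sd_uninduced > upper_uninduced``
    2. non-inducible: ``mean_induced < lower_induced`` and ``fold ≤ 1``
    3. poorly inducible: ``mean_induced < lower_induced`` and ``fold > 1``
    4. wild-type-like otherwise

    The semi-constitutive rule is evaluated first; a strain that also meets
    an impairment rule stays semi-constitutive (see
    :func:`secondary_impairment_flag`).
    """
    if summary.mean_uninduced - summary.sd_uninduced > thresholds.upper_uninduced:
        return InductionClass.SEMI_CONSTITUTIVE
    if summary.mean_induced < thresholds.lower_induced:
        if summary.fold_induction <= 1.0:
            return InductionClass.NON_INDUCIBLE
        return InductionClass.POORLY_INDUCIBLE
    return InductionClass.WILD_TYPE_LIKE


def secondary_impairment_flag(
    summary: StrainInductionSummary, thresholds: LibraryThresholds
) -> bool:
    """True when a semi-constitutive strain would also qualify as impaired."""
    return (
        classify_induction(summary, thresholds) is InductionClass.SEMI_CONSTITUTIVE
        and summary.mean_induced < thresholds.lower_induced
    )


def classify_library(
    summaries: Sequence[StrainInductionSummary],
    thresholds: LibraryThresholds | None = None,
    min_strains: int = 10,
) -> pd.DataFrame:
    """Classify every strain of a library; returns the per-strain table.

    Columns: strain, mean_uninduced, sd_uninduced, mean_induced, sd_induced,
    fold_induction, induction_class, secondary_impaired.
    """
    if thresholds is None:
        thresholds = compute_library_thresholds(summaries, min_strains=min_strains)
    rows = []
    for s in summaries:
        rows.append(
            {
                "strain": s.strain_id,
                "mean_uninduced": s.mean_uninduced,
                "sd_uninduced": s.sd_uninduced,
                "mean_induced": s.mean_induced,
                "sd_induced": s.sd_induced,
                "fold_induction": s.fold_induction,
                "induction_class": classify_induction(s, thresholds).value,
                "secondary_impaired": secondary_impairment_flag(s, thresholds),
            }
        )
    return pd.DataFrame(rows)


def summaries_from_wells(wells: Iterable[WellMeasurement]) -> list[StrainInductionSummary]:
    """Group well measurements by strain and summarize each."""
    by_strain: dict[str, list[WellMeasurement]] = {}
    for w in wells:
        by_strain.setdefault(w.strain_id, []).append(w)
    return [summarize_strain(v) for v in by_strain.values()]
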