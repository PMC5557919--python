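"""Spectral-count abundance quantification with internal-standard normalization.

The chain turns exclusive spectrum counts (spectra matched to peptides unique
to one protein) into a periplasmic abundance ratio relative to wild-type:

1. *on-total normalization* — every sample is rescaled to the same total
   identified-spectrum depth (count × T̄/T_sample, with T̄ the mean total);
2. *internal-standard outlier flagging* — samples whose standard protein is
   itself depleted (below half the median standard level, or absent) are
   excluded from the reference;
3. *standard normalization* — target values are rescaled by
   reference / standard, where the reference is the mean standard level over
   unflagged samples; samples with no standard at all get the ``NC`` marker
   ("no correction") and fall back to their on-total value downstream;
4. *batch anchoring* — batches are put on a common scale through a strain
   measured in every batch (the wild-type), multiplying each value by
   anchor(reference batch) / anchor(batch);
5. *abundance ratio* A = batch-corrected value / wild-type value, classified
   against a reciprocal-symmetric confidence band on the ratio.

The published 99% band (0.785, 1.274) is available as
:data:`PUBLISHED_BAND`; bands can also be built from a log-ratio SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from alascan.errors import BatchAnchorError, NormalizationError

#: Marker object/string for "no correction" (internal standard absent).
NC = "NC"

#: Default internal-standard outlier rule: flag samples whose standard
#: on-total value is below this fraction of the median across samples.
DEFAULT_OUTLIER_FRACTION = 0.5


class AbundanceSignificance(str, Enum):
    LOW = "low"
    NORMAL = "normal"
    HIGH = "high"


@dataclass(frozen=True)
class SpectralSample:
    """Exclusive spectrum counts for one MS sample.

    ``sample_id`` identifies the measurement, ``strain_id`` the biological
    strain (so the same strain re-measured in another batch keeps a distinct
    sample id), ``target_count``/``standard_count`` are exclusive counts for
    the target and internal-standard proteins, and ``total_spectra`` is the
    total identified-spectrum count of the sample.
    """

    sample_id: str
    batch_id: str
    target_count: int
    standard_count: int
    total_spectra: int
    strain_id: str | None = None

    def __post_init__(self):
        if self.strain_id is None:
            object.__setattr__(self, "strain_id", self.sample_id)
        if self.total_spectra <= 0:
            raise ValueError(f"sample {self.sample_id}: total_spectra must be > 0")
        if self.target_count < 0 or self.standard_count < 0:
            raise ValueError(f"sample {self.sample_id}: negative counts")
        if self.target_count + self.standard_count > self.total_spectra:
            raise ValueError(
                f"sample {self.sample_id}: target+standard exceed total spectra"
            )


@dataclass(frozen=True)
class SignificanceBand:
    """Reciprocal-symmetric band on an abundance ratio.

    ``lower`` and ``upper`` satisfy lower = 1/upper on the log scale (within
    1e-3 when supplied verbatim from a printed table; exact when
    constructed). Ratios below ``lower`` are significantly low, above
    ``upper`` significantly high.
    """

    lower: float
    upper: float
    level: float = 0.99

    def __post_init__(self):
        if not (0 < self.lower <= 1.0 <= self.upper):
            raise ValueError(f"band must bracket 1: ({self.lower}, {self.upper})")
        if abs(self.lower - 1.0 / self.upper) > 1e-3:
            raise ValueError(
                f"band not reciprocal-symmetric: lower={self.lower}, 1/upper={1.0 / self.upper:.6f}"
            )

    @classmethod
    def from_upper(cls, upper: float, level: float = 0.99) -> "SignificanceBand":
        """Band with the given upper bound and lower = 1/upper exactly."""
        return cls(lower=1.0 / upper, upper=float(upper), level=level)

    @classmethod
    def from_log_sd(cls, log_ratio_sd: float, level: float = 0.99) -> "SignificanceBand":
        return build_band(log_ratio_sd, level)

    def classify(self, ratio: float) -> AbundanceSignificance:
        return classify_abundance(ratio, self)


#: The published 99% confidence band on the abundance ratio.
PUBLISHED_BAND = SignificanceBand(lower=0.785, upper=1.274, level=0.99)


def build_band(log_ratio_sd: float, level: float = 0.99) -> SignificanceBand:
    """Construct a reciprocal-symmetric null band from a log-ratio SD.

    band = (exp(−z·s), exp(+z·s)) with z the two-sided normal quantile at
    ``level``; lower × upper = 1 by construction. ``s = 0`` yields the
    degenerate band (1, 1) under which any ratio ≠ 1 is significant.
    """
    if log_ratio_sd < 0:
        raise ValueError("log_ratio_sd must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * log_ratio_sd
    return SignificanceBand(lower=math.exp(-half), upper=math.exp(half), level=level)


def classify_abundance(ratio: float, band: SignificanceBand) -> AbundanceSignificance:
    """low if ratio < band.lower, high if ratio > band.upper, else normal."""
    if ratio < band.lower:
        return AbundanceSignificance.LOW
    if ratio > band.upper:
        return AbundanceSignificance.HIGH
    return AbundanceSignificance.NORMAL


def normalize_on_total(samples: Sequence[SpectralSample]) -> pd.DataFrame:
    """Rescale counts to a common total-spectrum depth.

    Both proteins are rescaled by T̄/T_sample where T̄ is the mean
    ``total_spectra`` over the sample set. Any common constant would yield
    identical downstream ratios; the mean keeps values on the scale of the
    raw counts.
    """
    if len(samples) == 0:
        raise NormalizationError("empty sample set")
    t = np.array([s.total_spectra for s in samples], dtype=float)
    t_bar = float(np.mean(t))
    factor = t_bar / t
    return pd.DataFrame(
        {
            "sample": [s.sample_id for s in samples],
            "strain": [s.strain_id for s in samples],
            "batch": [s.batch_id for s in samples],
            "target_count": [s.target_count for s in samples],
            "standard_count": [s.standard_count for s in samples],
            "total_spectra": [s.total_spectra for s in samples],
            "target_on_total": np.array([s.target_count for s in samples]) * factor,
            "standard_on_total": np.array([s.standard_count for s in samples]) * factor,
        }
    )


def flag_standard_outliers(
    standard_on_total: Sequence[float], fraction: float = DEFAULT_OUTLIER_FRACTION
) -> np.ndarray:
    """Flag samples whose internal standard is anomalously low.

    A sample is flagged when its standard on-total value is strictly below
    ``fraction`` of the median across all samples; zero values are always
    flagged. Requires at least five samples for the median to be meaningful.
    """
    vals = np.asarray(standard_on_total, dtype=float)
    if vals.size < 5:
        raise NormalizationError("outlier flagging needs >= 5 samples")
    med = float(np.median(vals))
    return (vals == 0) | (vals < fraction * med)


def reference_average(
    standard_on_total: Sequence[float], flags: Sequence[bool] | None = None
) -> float:
    """Mean standard on-total value over unflagged samples."""
    vals = np.asarray(standard_on_total, dtype=float)
    keep = np.ones(vals.shape, dtype=bool) if flags is None else ~np.asarray(flags, dtype=bool)
    if not keep.any():
        raise NormalizationError("all samples flagged; no reference average")
    return float(np.mean(vals[keep]))


def normalize_to_standard(
    target_on_total: float | Sequence[float],
    standard_on_total: float | Sequence[float],
    reference: float,
) -> np.ndarray | float:
    """Internal-standard normalization: target × reference / standard.

    Samples with a standard value of exactly 0 are not correctable and come
    back as NaN (the ``NC`` marker in written tables). Scalar in, scalar out.
    """
    if reference <= 0:
        raise NormalizationError("reference must be > 0")
    t = np.asarray(target_on_total, dtype=float)
    s = np.asarray(standard_on_total, dtype=float)
    ok = s != 0
    out = np.where(ok, t * reference / np.where(ok, s, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def batch_correct(
    values: Sequence[float],
    batches: Sequence[str],
    anchors: Mapping[str, float],
    reference_batch: str,
) -> np.ndarray:
    """Rescale every batch onto the reference batch via anchor values.

    ``anchors`` maps batch → the anchor strain's value measured within that
    batch. Each value is multiplied by anchor(reference)/anchor(batch);
    reference-batch values pass through unchanged. NaN inputs (NC samples)
    stay NaN here — their fallback is handled by the caller, which corrects
    the on-total value instead and propagates the NC marker.
    """
    if reference_batch not in anchors:
        raise BatchAnchorError(f"no anchor for reference batch {reference_batch!r}")
    vals = np.asarray(values, dtype=float)
    out = np.empty_like(vals)
    ref_anchor = float(anchors[reference_batch])
    for i, (v, b) in enumerate(zip(vals, batches)):
        if b not in anchors:
            raise BatchAnchorError(f"no anchor for batch {b!r}")
        out[i] = v * ref_anchor / float(anchors[b])
    return out


def abundance_ratio(corrected: float, wild_type_value: float) -> float:
    """A = batch-corrected value / wild-type reference value."""
    if wild_type_value <= 0:
        raise NormalizationError("wild-type reference value must be > 0")
    return float(corrected) / float(wild_type_value)


def variance_ratio_pvalue(
    ratio: float, standard_on_total: Sequence[float], flags: Sequence[bool] | None = None
) -> float:
    """Variance-ratio (F) test of H0: abundance ratio = 1.

    Alternative significance mode: the null dispersion of log ratios is
    estimated from the unflagged internal-standard values, and
    (log ratio / s)² is referred to an F(1, n−1) distribution. This is an
    approximation — the exact construction of the published test is not
    specified — and the band rule is the default mode.
    """
    vals = np.asarray(standard_on_total, dtype=float)
    keep = np.ones(vals.shape, dtype=bool) if flags is None else ~np.asarray(flags, dtype=bool)
    logs = np.log(vals[keep])
    s = float(np.std(logs, ddof=1))
    if s == 0:
        return 0.0 if ratio != 1.0 else 1.0
    n = int(keep.sum())
    stat = (math.log(ratio) / s) ** 2
    return float(stats.f.sf(stat, 1, n - 1))


def abundance_chain(
    samples: Sequence[SpectralSample],
    anchor_strain: str,
    reference_batch: str | None = None,
    band: SignificanceBand = PUBLISHED_BAND,
    outlier_fraction: float = DEFAULT_OUTLIER_FRACTION,
) -> pd.DataFrame:
    """Run the full normalization chain and call significance per sample.

    The anchor strain must be measured in every batch; its value in the
    reference batch (default: the batch of its first occurrence) is the
    wild-type denominator of the abundance ratio.

    Returns one row per sample with columns: sample, strain, batch,
    target_on_total, standard_on_total, standard_outlier, to_standard,
    nc, batch_corrected, abundance_ratio, significance.
    """
    df = normalize_on_total(samples)
    flags = flag_standard_outliers(df["standard_on_total"], fraction=outlier_fraction)
    ref = reference_average(df["standard_on_total"], flags)
    to_std = normalize_to_standard(
        df["target_on_total"].to_numpy(), df["standard_on_total"].to_numpy(), ref
    )
    nc = np.isnan(to_std)

    anchor_rows = df[df["strain"] == anchor_strain]
    if anchor_rows.empty:
        raise BatchAnchorError(f"anchor strain {anchor_strain!r} not in sample set")
    if reference_batch is None:
        reference_batch = str(anchor_rows["batch"].iloc[0])
    anchors: dict[str, float] = {}
    for b in df["batch"].unique():
        rows = anchor_rows[anchor_rows["batch"] == b]
        if rows.empty:
            raise BatchAnchorError(f"batch {b!r} has no {anchor_strain!r} anchor sample")
        idx = rows.index[0]
        if nc[idx]:
            raise BatchAnchorError(f"anchor sample in batch {b!r} has no internal standard")
        anchors[str(b)] = float(to_std[idx])

    # NC samples are corrected on their on-total value; the marker propagates.
    basis = np.where(nc, df["target_on_total"].to_numpy(), to_std)
    corrected = batch_correct(basis, df["batch"].tolist(), anchors, reference_batch)

    wt_value = anchors[reference_batch]
    ratios = corrected / wt_value
    signif = [classify_abundance(float(r), band).value for r in ratios]

    out = df[["sample", "strain", "batch", "target_on_total", "standard_on_total"]].copy()
    out["reference_average"] = ref
    out["standard_outlier"] = flags
    out["to_standard"] = to_std
    out["nc"] = nc
    out["batch_corrected"] = corrected
    out["abundance_ratio"] = ratios
    out["significance"] = signif
    return out


def samples_from_frame(df: pd.DataFrame) -> list[SpectralSample]:
    """Build samples from a spectral-count table (sample, batch, counts...)."""
    return [
        SpectralSample(
            sample_id=str(r["sample"]),
            batch_id=str(r["batch"]),
            target_count=int(r["target_count"]),
            standard_count=int(r["standard_count"]),
            total_spectra=int(r["total_spectra"]),
            strain_id=str(r["strain"]) if "strain" in df.columns else None,
        )
        for _, r in df.iterrows()
    ]
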