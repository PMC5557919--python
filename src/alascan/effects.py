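"""Mechanistic effect categorization of alanine-scan mutants.

Combines three measurements per mutant — the induction phenotype, the
induced-fluorescence ratio F (mutant induced mean / wild-type induced mean),
and the abundance ratio A — under a proportionality assumption: a pure
abundance defect should diminish reporter output in proportion to the
periplasmic abundance, so F/A ≈ 1. A mutant whose F falls short of A by more
than the abundance band's lower bound has an additional signaling defect.

Ordered categorization rules (first match wins):

1. ``signaling_and_abundance`` — abundance significantly low, induction
   impaired (non- or poorly inducible), and F/A below the band lower bound;
2. ``abundance`` — abundance significantly low (covers semi-constitutive
   mutants with low abundance: induction is maintained);
3. ``signaling`` — induction impaired with normal or high abundance;
4. ``no_effect`` — everything else.

Mutants lacking abundance data are ``unclassified`` with a reason.
"""

from __future__ import annotations

from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from alascan.abundance import (
    PUBLISHED_BAND,
    AbundanceSignificance,
    SignificanceBand,
)
from alascan.errors import JoinError
from alascan.flow import IMPAIRED_CLASSES, InductionClass


class EffectCategory(str, Enum):
    SIGNALING_AND_ABUNDANCE = "signaling_and_abundance"
    ABUNDANCE = "abundance"
    SIGNALING = "signaling"
    NO_EFFECT = "no_effect"
    UNCLASSIFIED = "unclassified"


def fluorescence_ratio(mutant_induced_mean: float, wild_type_induced_mean: float) -> float:
    """F = mutant induced mean / wild-type induced mean, unrounded."""
    if wild_type_induced_mean <= 0:
        raise ValueError("wild-type induced mean must be > 0")
    return float(mutant_induced_mean) / float(wild_type_induced_mean)


def categorize(
    induction_class: InductionClass | str,
    fluorescence_ratio: float,
    abundance_ratio: float,
    significance: AbundanceSignificance | str,
    band: SignificanceBand = PUBLISHED_BAND,
) -> EffectCategory:
    """Assign one mechanistic category to a mutant (total, deterministic)."""
    cls = InductionClass(induction_class)
    sig = AbundanceSignificance(significance)
    impaired = cls in IMPAIRED_CLASSES
    if sig is AbundanceSignificance.LOW:
        if impaired and fluorescence_ratio / abundance_ratio < band.lower:
            return EffectCategory.SIGNALING_AND_ABUNDANCE
        return EffectCategory.ABUNDANCE
    if impaired:
        return EffectCategory.SIGNALING
    return EffectCategory.NO_EFFECT


def assemble_effect_table(
    induction: pd.DataFrame,
    abundance: pd.DataFrame,
    wild_type_id: str,
    band: SignificanceBand = PUBLISHED_BAND,
) -> pd.DataFrame:
    """Join the induction and abundance streams into per-mutant effect records.

    ``induction`` is the per-strain classification table (columns ``strain``,
    ``mean_induced``, ``induction_class``); ``abundance`` is the chain output
    (columns ``strain``, ``abundance_ratio``, ``significance``, ``nc``). The
    wild-type strain must be present in the induction stream (as the F
    denominator); it is used only as a reference, never as a record. Mutants
    with induction data but no abundance sample are returned ``unclassified``.

    Raises
    ------
    JoinError
        If strain ids are duplicated in either stream.
    """
    for name, df, key in (("induction", induction, "strain"), ("abundance", abundance, "strain")):
        dup = df[key][df[key].duplicated()].unique()
        if len(dup):
            raise JoinError(f"duplicate ids in {name} stream: {sorted(map(str, dup))}")
    wt = induction[induction["strain"] == wild_type_id]
    if wt.empty:
        raise JoinError(f"wild-type {wild_type_id!r} missing from induction stream")
    wt_induced = float(wt["mean_induced"].iloc[0])

    ab = abundance.set_index("strain")
    rows = []
    for _, r in induction.iterrows():
        strain = r["strain"]
        if strain == wild_type_id:
            continue
        F = fluorescence_ratio(float(r["mean_induced"]), wt_induced)
        cls = InductionClass(r["induction_class"])
        if strain not in ab.index:
            rows.append(
                {
                    "mutant": strain,
                    "induction_class": cls.value,
                    "fluorescence_ratio": F,
                    "abundance_ratio": np.nan,
                    "significance": "",
                    "proportionality": np.nan,
                    "category": EffectCategory.UNCLASSIFIED.value,
                    "notes": "no abundance sample",
                }
            )
            continue
        a = ab.loc[strain]
        A = float(a["abundance_ratio"])
        sig = str(a["significance"])
        notes = []
        if bool(a.get("nc", False)):
            notes.append("abundance ratio NC-derived (internal standard absent)")
        rows.append(
            {
                "mutant": strain,
                "induction_class": cls.value,
                "fluorescence_ratio": F,
                "abundance_ratio": A,
                "significance": sig,
                "proportionality": F / A if A > 0 else np.nan,
                "category": categorize(cls, F, A, sig, band).value,
                "notes": "; ".join(notes),
            }
        )
    return pd.DataFrame(rows)


def category_counts(effects: pd.DataFrame) -> dict[str, int]:
    """Per-category record counts of an effect table."""
    counts = effects["category"].value_counts().to_dict()
    return {c.value: int(counts.get(c.value, 0)) for c in EffectCategory}
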