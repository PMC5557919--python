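"""Published summary tables of the RbsB alanine-scan study, bundled as text.

Three tables are shipped with the package:

* ``induction_table`` — per-strain reporter fluorescence summaries
  (uninduced/induced mean ± SD over biological triplicates) and fold
  induction for the wild-type and the 32 mutants with significant induction
  changes, grouped as non-inducible / poorly inducible / semi-constitutive.
* ``spectral_table`` — exclusive spectrum counts for the target protein
  (RbsB or mutant) and the MglB internal standard, the printed on-total
  normalized values, and the printed standard-normalized column, for 25
  mutants plus the wild-type measured in two batches.
* ``effects_table`` — the combined per-mutant effect table: induced
  fluorescence, normalized MS expression, fluorescence ratio F, abundance
  ratio A, and the published mechanistic grouping.

These are re-analysis inputs (the event-level and raw MS data were not
deposited); the loaders return plain DataFrames.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from alascan.flow import StrainInductionSummary

#: Replacements that could not be constructed (mature-protein positions).
NOT_OBTAINED_POSITIONS = (135, 136, 145)

#: Strain id of the wild-type reference in all bundled tables.
WILD_TYPE_STRAIN = "RbsB"

#: Published wild-type normalized MS expression level (reference batch).
WILD_TYPE_MS_LEVEL = 47

#: Published anchor values of the wild-type strain in the two MS batches.
PUBLISHED_ANCHORS = {"batch1": 47.0, "batch2": 95.0}


def _load(name: str) -> pd.DataFrame:
    with resources.files("alascan.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def induction_table() -> pd.DataFrame:
    """Per-strain induction summaries (wild-type + 32 mutants)."""
    return _load("table1_induction.tsv")


def spectral_table() -> pd.DataFrame:
    """Spectral counts and printed normalized values (27 MS samples)."""
    df = _load("table2_spectral.tsv")
    df["to_standard_printed"] = pd.to_numeric(df["to_standard_printed"], errors="coerce")
    return df


def effects_table() -> pd.DataFrame:
    """Combined effect table (wild-type + 25 mutants)."""
    df = _load("table3_effects.tsv")
    df["norm_abundance"] = pd.to_numeric(df["norm_abundance"], errors="coerce")
    return df


def induction_summaries(include_wild_type: bool = True) -> list[StrainInductionSummary]:
    """The published induction table as strain summary objects (triplicates)."""
    rows = induction_table()
    out = []
    for _, r in rows.iterrows():
        if not include_wild_type and r["strain"] == WILD_TYPE_STRAIN:
            continue
        out.append(
            StrainInductionSummary(
                strain_id=str(r["strain"]),
                mean_uninduced=float(r["mean_uninduced"]),
                sd_uninduced=float(r["sd_uninduced"]),
                mean_induced=float(r["mean_induced"]),
                sd_induced=float(r["sd_induced"]),
                fold_induction=float(r["mean_induced"]) / float(r["mean_uninduced"]),
                n_replicates=3,
            )
        )
    return out


def synthetic_reference_sequence(seed: int = 20170815) -> str:
    """A synthetic 272-residue stand-in for the mature wild-type sequence.

    The real annotated sequence lives in supplementary material that is not
    bundled; this stand-in is *synthetic* and only guaranteed to be
    consistent with the published per-position facts: every printed mutant
    position carries its printed wild-type residue, the three positions that
    could not be substituted carry their reported residues (135T, 136S,
    145F), the termini are K1 and L272, exactly 37 positions are native
    alanines, and the remaining positions are deterministic non-alanine
    filler. Suitable for position bookkeeping, not for sequence analysis.
    """
    length = 272
    fixed: dict[int, str] = {1: "K", 272: "L", 135: "T", 136: "S", 145: "F"}
    for _, r in induction_table().iterrows():
        pos = int(r["position"])
        if pos > 0:
            fixed[pos] = str(r["wt_residue"])
    rng = np.random.default_rng(seed)
    free = [p for p in range(1, length + 1) if p not in fixed]
    ala_positions = set(rng.choice(free, size=37, replace=False).tolist())
    non_ala = list("CDEFGHIKLMNPQRSTVWY")
    seq = []
    for pos in range(1, length + 1):
        if pos in fixed:
            seq.append(fixed[pos])
        elif pos in ala_positions:
            seq.append("A")
        else:
            seq.append(non_ala[int(rng.integers(len(non_ala)))])
    return "".join(seq)


def mutant_metadata() -> pd.DataFrame:
    """Mutant id / position / wild-type residue for the printed mutants."""
    df = induction_table()
    df = df[df["strain"] != WILD_TYPE_STRAIN]
    return df[["strain", "position", "wt_residue"]].rename(columns={"strain": "mutant"})
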