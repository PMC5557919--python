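"""Per-residue bookkeeping on the mature protein sequence.

Positions use mature-protein, 1-based numbering throughout (the first residue
of the processed periplasmic protein is position 1). Mapping onto a crystal
structure chain is done with an explicit offset parameter, never inferred.

Each position of the reference sequence receives exactly one status:

* ``tested`` — an alanine replacement exists at this position (refined to an
  effect category or induction class when those results are attached);
* ``native_alanine`` — the wild-type residue is already alanine, never
  substituted;
* ``not_obtained`` — replacement could not be constructed;
* ``untested`` — no mutant and not alanine.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from alascan import io
from alascan.errors import ValidationError

STATUS_TESTED = "tested"
STATUS_NATIVE_ALANINE = "native_alanine"
STATUS_NOT_OBTAINED = "not_obtained"
STATUS_UNTESTED = "untested"

#: Single-letter code written to molecular-viewer attribute files.
CATEGORY_CODES = {
    "signaling_and_abundance": "B",  # both defects
    "abundance": "A",
    "signaling": "S",
    "no_effect": "N",
    "unclassified": "U",
    STATUS_TESTED: "T",
    STATUS_NATIVE_ALANINE: "a",
    STATUS_NOT_OBTAINED: "x",
    STATUS_UNTESTED: ".",
}


def read_sequence(path: str | Path) -> str:
    """Read the mature wild-type sequence from a single-record FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"expected exactly one FASTA record in {path}, got {len(records)}")
    return str(records[0].seq).upper()


def validate_positions(
    metadata: pd.DataFrame,
    wt_sequence: str,
    not_obtained: Iterable[int] = (),
) -> pd.DataFrame:
    """Validate mutant metadata against the reference sequence and annotate.

    ``metadata`` needs columns ``mutant``, ``position``, ``wt_residue``; the
    claimed residue must match the sequence at every position, no position
    may be mutagenized twice, and native alanines are never substituted.
    Returns one row per sequence position with columns ``position``,
    ``wt_residue``, ``status``, ``mutant``.
    """
    seq = wt_sequence.upper()
    n = len(seq)
    not_obtained = set(int(p) for p in not_obtained)
    seen: dict[int, str] = {}
    for _, row in metadata.iterrows():
        pos = int(row["position"])
        res = str(row["wt_residue"]).upper()
        if not 1 <= pos <= n:
            raise ValidationError(f"position {pos} outside sequence of length {n}")
        if seq[pos - 1] != res:
            raise ValidationError(
                f"position {pos}: metadata claims {res} but sequence has {seq[pos - 1]}"
            )
        if res == "A":
            raise ValidationError(f"position {pos}: native alanines are never substituted")
        if pos in seen:
            raise ValidationError(f"position {pos} listed twice in metadata")
        seen[pos] = str(row["mutant"])

    rows = []
    for pos in range(1, n + 1):
        res = seq[pos - 1]
        if res == "A":
            status = STATUS_NATIVE_ALANINE
        elif pos in not_obtained:
            status = STATUS_NOT_OBTAINED
        elif pos in seen:
            status = STATUS_TESTED
        else:
            status = STATUS_UNTESTED
        rows.append(
            {
                "position": pos,
                "wt_residue": res,
                "status": status,
                "mutant": seen.get(pos, ""),
            }
        )
    return pd.DataFrame(rows)


def attach_effects(
    annotations: pd.DataFrame,
    effects: pd.DataFrame,
    induction: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach effect categories (and optionally induction classes) by mutant id."""
    out = annotations.copy()
    cat = effects.set_index("mutant")["category"] if len(effects) else pd.Series(dtype=object)
    out["category"] = [
        cat.get(m, "") if m else "" for m in out["mutant"]
    ]
    if induction is not None and len(induction):
        cls = induction.set_index("strain")["induction_class"]
        out["induction_class"] = [cls.get(m, "") if m else "" for m in out["mutant"]]
    return out


def export_annotations(
    annotations: pd.DataFrame,
    path: str | Path,
    format: str = "table",
    offset: int = 0,
) -> Path:
    """Write annotations as a TSV table or a molecular-viewer attribute file.

    ``attribute-script`` emits one ``position<TAB>code`` line per residue,
    with ``offset`` added to map mature numbering onto a structure chain.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "table":
        return io.write_table(annotations, path)
    if format == "attribute-script":
        lines = []
        for _, r in annotations.iterrows():
            label = r.get("category") or r["status"]
            code = CATEGORY_CODES.get(str(label), CATEGORY_CODES[STATUS_UNTESTED])
            lines.append(f"{int(r['position']) + offset}\t{code}")
        path.write_text("\n".join(lines) + "\n")
        return path
    raise ValueError(f"unknown export format {format!r}")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Inverse of the ``table`` export."""
    df = io.read_table(path)
    df["mutant"] = df["mutant"].fillna("")
    if "category" in df.columns:
        df["category"] = df["category"].fillna("")
    return df


def status_counts(annotations: pd.DataFrame) -> dict[str, int]:
    counts = annotations["status"].value_counts().to_dict()
    return {
        s: int(counts.get(s, 0))
        for s in (STATUS_TESTED, STATUS_NATIVE_ALANINE, STATUS_NOT_OBTAINED, STATUS_UNTESTED)
    }
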