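"""Bulk-chemistry bookkeeping for whole cells.

The chemical analysis partitions the freeze-dried cell mass into protein,
lipid, carbohydrate, DNA and RNA classes, with sub-typed conjugates
(lipoprotein, glycoprotein; fatty acids, phospholipids, cholesterol,
glycolipids). This module derives the unconjugated remainders, expresses
analytes as percent of total dry mass, and converts the DNA fraction into a
genome-size estimate at 660 Da per base pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .constants import DA_PER_BP_DNA
from .exceptions import InconsistentInputsError, InvalidParameterError

__all__ = [
    "GenomeEstimate",
    "derive_unconjugated",
    "percent_of_dry_mass",
    "class_totals",
    "closure_residual",
    "genome_size",
    "read_composition_csv",
    "write_composition_report",
]

ANALYTE_CLASSES = ("protein", "lipid", "carbohydrate", "DNA", "RNA")

# which subtypes are subtracted from their class total to leave the
# unconjugated / free remainder
_DERIVED_FROM = {
    "unconjugated_protein": ("protein", ["lipoprotein", "glycoprotein"]),
    "free_lipid": ("lipid", ["fatty_acid", "phospholipid",
                             "cholesterol", "glycolipids"]),
}


@dataclass(frozen=True)
class GenomeEstimate:
    """DNA mass per cell and the implied double-stranded genome size."""

    M_DNA_da: float
    bp: float
    replication_corrected: bool = False


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    required = {"analyte", "class", "is_subtype", "weight_ug"}
    if not required <= set(table.columns):
        raise InvalidParameterError(
            f"composition table needs columns {sorted(required)}")
    if (table.weight_ug < 0).any():
        raise InvalidParameterError("analyte weights must be >= 0")
    return table


def class_totals(table: pd.DataFrame) -> pd.Series:
    """Class total weights (ug), indexed by class name."""
    t = _validate(table)
    return t[~t.is_subtype].set_index("class").weight_ug


def derive_unconjugated(table: pd.DataFrame) -> dict[str, float]:
    """Unconjugated protein and free lipid (ug) by subtracting the measured
    conjugate subtypes from their class totals; free carbohydrate is
    measured directly and passed through."""
    t = _validate(table)
    by_name = t.set_index("analyte").weight_ug
    totals = class_totals(t)
    out: dict[str, float] = {}
    for name, (cls, subtypes) in _DERIVED_FROM.items():
        missing = [s for s in subtypes if s not in by_name.index]
        if cls not in totals.index or missing:
            raise InvalidParameterError(
                f"cannot derive {name}: missing {missing or [cls]}")
        value = totals[cls] - sum(by_name[s] for s in subtypes)
        if value < 0:
            raise InconsistentInputsError(
                f"{cls} subtypes exceed the class total ({value:.2f} ug)")
        out[name] = value
    if "free_carbohydrate" in by_name.index:
        out["free_carbohydrate"] = float(by_name["free_carbohydrate"])
    return out


def percent_of_dry_mass(weight_ug: float, total_ug: float) -> float:
    """Analyte weight as percent of the total dry mass."""
    if total_ug <= 0:
        raise InvalidParameterError("total dry mass must be > 0")
    return 100.0 * weight_ug / total_ug


def closure_residual(table: pd.DataFrame, total_ug: float) -> float:
    """Relative residual between the sum of class totals and the stated
    total dry mass (the table's own closure error)."""
    return abs(total_ug - class_totals(table).sum()) / total_ug


def genome_size(M_cell_da: float, f_DNA: float,
                replication_correction: float | None = None) -> GenomeEstimate:
    """Genome size from total cell mass and the DNA dry-mass fraction.

    Ongoing replication inflates the average DNA mass per cell by up to
    ~50%; an optional correction factor in [1, 1.5] divides it out.
    """
    if not 0 <= f_DNA < 1:
        raise InvalidParameterError("f_DNA must be in [0, 1)")
    M_DNA = M_cell_da * f_DNA
    corrected = False
    if replication_correction is not None:
        if not 1.0 <= replication_correction <= 1.5:
            raise InvalidParameterError(
                "replication correction must be in [1, 1.5]")
        M_DNA /= replication_correction
        corrected = True
    return GenomeEstimate(M_DNA_da=M_DNA, bp=M_DNA / DA_PER_BP_DNA,
                          replication_corrected=corrected)


def read_composition_csv(path) -> pd.DataFrame:
    """Read an analyte table (analyte, class, is_subtype, weight_ug[, sd_ug])."""
    df = pd.read_csv(path)
    df["is_subtype"] = df["is_subtype"].astype(bool)
    return _validate(df)


def write_composition_report(table: pd.DataFrame, total_ug: float, path) -> None:
    """Write the table plus derived rows and a percent-of-dry-mass column."""
    t = _validate(table).copy()
    derived = derive_unconjugated(t)
    extra = pd.DataFrame(
        [(k, _DERIVED_FROM.get(k, ("carbohydrate", []))[0], True, v, float("nan"))
         for k, v in derived.items() if k not in set(t.analyte)],
        columns=t.columns[:5],
    )
    out = pd.concat([t, extra], ignore_index=True)
    out["percent_dry_mass"] = [percent_of_dry_mass(w, total_ug)
                               for w in out.weight_ug]
    out.to_csv(path, index=False)
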