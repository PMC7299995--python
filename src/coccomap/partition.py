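"""Partition coefficients between coccolith calcite and culture solution.

The partition coefficient of element *x*,

    D_x = (x/Ca)_calcite / (x/Ca)_solution,

is a ratio of molar ratios and is therefore invariant to the unit both
ratios are expressed in (mol/mol vs mmol/mol), and independent of the
absolute calcite density.  The default solution table shipped with the
package is a reconstructed stand-in (see its header), overridable by any
user-supplied table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd


class MissingSolutionError(KeyError):
    """Requested element has no entry in the solution composition."""


@dataclass
class SolutionComposition:
    """Culture-medium composition expressed as molar ratios to Ca.

    Construct either from absolute molarities (mol/L, must include Ca) or
    directly from element/Ca molar ratios in mmol/mol.
    """

    ratios_mmol_per_mol: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, v in self.ratios_mmol_per_mol.items():
            if v <= 0:
                raise ValueError(f"solution ratio for {el!r} must be > 0")

    @classmethod
    def from_molarities(cls, molarities: dict[str, float]) -> "SolutionComposition":
        if "Ca" not in molarities or molarities["Ca"] <= 0:
            raise ValueError("molarity table must include Ca > 0")
        ca = molarities["Ca"]
        ratios = {el: 1000.0 * m / ca for el, m in molarities.items()
                  if el != "Ca" and m > 0}
        return cls(ratios)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SolutionComposition":
        df = pd.read_csv(path, comment="#")
        cols = set(df.columns)
        if {"element", "ratio_to_ca_mmol_per_mol"} <= cols:
            return cls(dict(zip(df["element"], df["ratio_to_ca_mmol_per_mol"].astype(float))))
        if {"element", "molarity_mol_per_l"} <= cols:
            return cls.from_molarities(dict(zip(df["element"], df["molarity_mol_per_l"].astype(float))))
        raise ValueError(
            "solution CSV needs columns (element, ratio_to_ca_mmol_per_mol) "
            "or (element, molarity_mol_per_l)")

    def ratio_mmol_per_mol(self, element: str) -> float:
        try:
            return self.ratios_mmol_per_mol[element]
        except KeyError:
            raise MissingSolutionError(
                f"element {element!r} absent from the solution table") from None


def default_solution() -> SolutionComposition:
    """The shipped reconstructed default solution table (Sr, Se)."""
    with resources.as_file(
            resources.files("coccomap.data") / "default_solution_reconstructed.csv") as p:
        return SolutionComposition.from_csv(p)


def partition_coefficient(calcite_ratio_mmol_per_mol: float,
                          solution: SolutionComposition,
                          element: str) -> float:
    """D_x = (x/Ca)_calcite / (x/Ca)_solution (dimensionless, >= 0)."""
    if calcite_ratio_mmol_per_mol < 0:
        raise ValueError("calcite ratio must be nonnegative")
    return calcite_ratio_mmol_per_mol / solution.ratio_mmol_per_mol(element)


def partition_table(element_stats: pd.DataFrame,
                    solution: SolutionComposition) -> pd.DataFrame:
    """Append D (with provenance) to a specimen element-statistics table.

    ``element_stats`` is the ``elements`` frame from
    :func:`coccomap.maps.specimen_stats` (indexed by element with a
    ``mean_ratio_mmol_per_mol`` column).  Elements absent from the
    solution table get no row.
    """
    rows = {}
    for el, rec in element_stats.iterrows():
        try:
            sol = solution.ratio_mmol_per_mol(str(el))
        except MissingSolutionError:
            continue
        calc = float(rec["mean_ratio_mmol_per_mol"])
        rows[el] = {
            "D": partition_coefficient(calc, solution, str(el)),
            "calcite_ratio_mmol_per_mol": calc,
            "solution_ratio_mmol_per_mol": sol,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
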