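"""Cell phenotyping from binary marker calls.

Multiplex-IHC panels report, per segmented cell, a binary positivity call for
each stained marker.  Lineage phenotypes are derived from the lineage markers
(CD3, CD8, FoxP3, CD163, pancytokeratin); the remaining markers (PD-L1, GZMB,
Ki67) flag functional state — checkpoint-ligand expression, cytotoxic granule
content, proliferation — and never change the lineage call.

Phenotype rules (lineage precedence CD3 > CD163 > PanCK):

* ``CD3+ CD8+``            -> cytotoxic T lymphocyte (CTL)
* ``CD3+ CD8- FoxP3-``     -> helper T cell
* ``CD3+ CD8- FoxP3+``     -> regulatory T cell (Treg)
* ``CD3- CD163+``          -> antigen-presenting cell (APC, macrophage-lineage)
* ``CD3- CD163- PanCK+``   -> epithelial (tumor) cell
* ``CD3- CD163- PanCK-``   -> other

Biologically contradictory co-positivity (a cell called both CD3+ and PanCK+,
usually a segmentation artifact) is resolved by the precedence order above and
can be counted with :func:`count_marker_conflicts`.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

#: Marker columns every cell table must carry, in canonical order.
MARKERS: tuple[str, ...] = (
    "CD3", "CD8", "FoxP3", "CD163", "PanCK", "PDL1", "GZMB", "Ki67",
)

#: Markers that determine lineage; the rest are activation/state flags.
LINEAGE_MARKERS: tuple[str, ...] = ("CD3", "CD8", "FoxP3", "CD163", "PanCK")
STATE_MARKERS: tuple[str, ...] = ("PDL1", "GZMB", "Ki67")


class Phenotype(str, Enum):
    """Lineage phenotypes assignable from the marker panel."""

    TCELL_CTL = "TCELL_CTL"
    TCELL_HELPER = "TCELL_HELPER"
    TCELL_TREG = "TCELL_TREG"
    APC = "APC"
    EPITHELIAL = "EPITHELIAL"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def assign_phenotype(markers: dict[str, bool | int]) -> Phenotype:
    """Assign the lineage phenotype for one cell.

    Parameters
    ----------
    markers
        Mapping with all eight marker keys (:data:`MARKERS`); values are
        truthy/falsy positivity calls.

    Returns
    -------
    Phenotype
        Exactly one phenotype; the rule set is total over valid marker maps.

    Raises
    ------
    KeyError
        If any of the eight marker keys is absent.
    """
    missing = [m for m in MARKERS if m not in markers]
    if missing:
        raise KeyError(f"missing marker flags: {missing}")
    cd3, cd8, foxp3 = bool(markers["CD3"]), bool(markers["CD8"]), bool(markers["FoxP3"])
    cd163, panck = bool(markers["CD163"]), bool(markers["PanCK"])
    if cd3:
        if cd8:
            return Phenotype.TCELL_CTL
        return Phenotype.TCELL_TREG if foxp3 else Phenotype.TCELL_HELPER
    if cd163:
        return Phenotype.APC
    if panck:
        return Phenotype.EPITHELIAL
    return Phenotype.OTHER


def assign_phenotypes(cells: pd.DataFrame) -> pd.Series:
    """Vectorised phenotype assignment over a cell table.

    ``cells`` must carry the eight marker columns with 0/1 values.  Returns a
    string Series aligned to ``cells.index``; identical cell-by-cell to
    :func:`assign_phenotype`.
    """
    missing = [m for m in MARKERS if m not in cells.columns]
    if missing:
        raise KeyError(f"missing marker columns: {missing}")
    cd3 = cells["CD3"].to_numpy(dtype=bool)
    cd8 = cells["CD8"].to_numpy(dtype=bool)
    foxp3 = cells["FoxP3"].to_numpy(dtype=bool)
    cd163 = cells["CD163"].to_numpy(dtype=bool)
    panck = cells["PanCK"].to_numpy(dtype=bool)

    out = np.full(len(cells), Phenotype.OTHER.value, dtype=object)
    out[~cd3 & ~cd163 & panck] = Phenotype.EPITHELIAL.value
    out[~cd3 & cd163] = Phenotype.APC.value
    out[cd3 & ~cd8 & ~foxp3] = Phenotype.TCELL_HELPER.value
    out[cd3 & ~cd8 & foxp3] = Phenotype.TCELL_TREG.value
    out[cd3 & cd8] = Phenotype.TCELL_CTL.value
    return pd.Series(out, index=cells.index, name="phenotype")


def count_marker_conflicts(cells: pd.DataFrame) -> int:
    """Count cells with biologically contradictory lineage co-positivity.

    A conflict is CD3 positivity together with CD163 or PanCK, or CD163
    together with PanCK — combinations the precedence rule silently resolves.
    """
    cd3 = cells["CD3"].astype(bool)
    cd163 = cells["CD163"].astype(bool)
    panck = cells["PanCK"].astype(bool)
    return int(((cd3 & (cd163 | panck)) | (~cd3 & cd163 & panck)).sum())


#: Phenotype groups used throughout the analysis.  "T" is all CD3+ cells,
#: "immune" is T cells plus APCs (the infiltration denominator is all cells).
GROUPS: dict[str, frozenset[str]] = {
    "CTL": frozenset({Phenotype.TCELL_CTL.value}),
    "Th": frozenset({Phenotype.TCELL_HELPER.value}),
    "Treg": frozenset({Phenotype.TCELL_TREG.value}),
    "APC": frozenset({Phenotype.APC.value}),
    "EC": frozenset({Phenotype.EPITHELIAL.value}),
    "other": frozenset({Phenotype.OTHER.value}),
    "T": frozenset({
        Phenotype.TCELL_CTL.value,
        Phenotype.TCELL_HELPER.value,
        Phenotype.TCELL_TREG.value,
    }),
    "immune": frozenset({
        Phenotype.TCELL_CTL.value,
        Phenotype.TCELL_HELPER.value,
        Phenotype.TCELL_TREG.value,
        Phenotype.APC.value,
    }),
}


def group_mask(cells: pd.DataFrame, group: str, state: str | None = None) -> np.ndarray:
    """Boolean mask selecting a phenotype group, optionally state-filtered.

    ``group`` is a key of :data:`GROUPS`.  ``state`` is a compact filter such
    as ``"act"`` (GZMB+ and Ki67+), ``"PDL1+"``, ``"PDL1-"``, ``"Ki67+"`` or
    ``"GZMB+"`` applied on top of the group membership.
    """
    if group not in GROUPS:
        raise KeyError(f"unknown phenotype group {group!r}")
    mask = cells["phenotype"].isin(GROUPS[group]).to_numpy()
    if state is None:
        return mask
    if state == "act":
        return mask & cells["GZMB"].to_numpy(dtype=bool) & cells["Ki67"].to_numpy(dtype=bool)
    if state.endswith(("+", "-")):
        marker, sign = state[:-1], state[-1]
        if marker not in MARKERS:
            raise KeyError(f"unknown state marker {marker!r}")
        flag = cells[marker].to_numpy(dtype=bool)
        return mask & (flag if sign == "+" else ~flag)
    raise KeyError(f"unknown state filter {state!r}")
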