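"""Gel-to-methylation quantitation: lanes, LOD, controls, matrix assembly.

Each gel lane carries one (mouse, locus) PCR digest: the uncut band is
unmethylated template, cut bands are methylated template, and percent
methylation is the cut fraction of total lane intensity.  Lanes whose uncut
band is too faint are below the limit of detection (LOD) and masked; each
locus additionally runs an unmethylated (0%) and a highly methylated
control lane that bound conversion/digestion artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LaneQuant",
    "MethylationTable",
    "ControlReport",
    "percent_methylation",
    "apply_lod",
    "validate_controls",
    "assemble_table",
    "read_lanes_tsv",
]

OK = "ok"
BELOW_LOD = "below_lod"
CONTROL = "control"

CONTROL_IDS = {"control_0", "control_high"}


@dataclass
class LaneQuant:
    mouse_id: str
    locus_id: str
    i_uncut: float
    i_cut: float
    flag: str = OK

    def __post_init__(self) -> None:
        if self.i_uncut < 0 or self.i_cut < 0:
            raise ValueError("band intensities must be >= 0")


def percent_methylation(lane: LaneQuant | None = None, *,
                        i_uncut: float | None = None,
                        i_cut: float | None = None,
                        ndigits: int | None = 0) -> float:
    """Percent methylation M = 100 * cut / (cut + uncut).

    Rounded to ``ndigits`` decimals (default nearest integer, matching how
    gel tables are reported); pass ``ndigits=None`` for the raw value.
    Zero total intensity is undefined and raises.
    """
    if lane is not None:
        i_uncut, i_cut = lane.i_uncut, lane.i_cut
    total = i_uncut + i_cut
    if total <= 0:
        raise ValueError("zero total lane intensity: methylation undefined")
    m = 100.0 * i_cut / total
    return m if ndigits is None else round(m, ndigits)


def apply_lod(lanes: Iterable[LaneQuant], min_band_intensity: float) -> list[LaneQuant]:
    """Flag lanes whose uncut (top) band is below the detection limit."""
    out = []
    for lane in lanes:
        if lane.flag != CONTROL and lane.i_uncut < min_band_intensity:
            out.append(replace(lane, flag=BELOW_LOD))
        else:
            out.append(replace(lane))
    return out


@dataclass
class ControlReport:
    passed: bool
    failures: list[str] = field(default_factory=list)
    values: pd.DataFrame | None = None


def validate_controls(control_lanes: Sequence[LaneQuant],
                      tol_zero: float = 5.0,
                      tol_high: float = 90.0,
                      loci: Iterable[str] | None = None) -> ControlReport:
    """Check 0% and high-methylation control digests per locus.

    The unmethylated control must quantify at most ``tol_zero`` percent
    (otherwise incomplete conversion or nonspecific digestion is suspected)
    and the methylated control at least ``tol_high``.  Each failure names
    the locus and control; missing controls fail as absent.
    """
    seen: dict[tuple[str, str], float] = {}
    for lane in control_lanes:
        m = percent_methylation(lane, ndigits=None)
        seen[(lane.locus_id, lane.mouse_id)] = m
    locus_set = set(loci) if loci is not None else {l for l, _ in seen}
    failures = []
    rows = []
    for locus in sorted(locus_set):
        for ctrl, check, why in (
            ("control_0", lambda m: m <= tol_zero,
             "incomplete-conversion/nonspecific digestion suspected"),
            ("control_high", lambda m: m >= tol_high,
             "incomplete digestion suspected"),
        ):
            m = seen.get((locus, ctrl))
            if m is None:
                failures.append(f"{locus}/{ctrl}: control absent")
                rows.append((locus, ctrl, np.nan, False))
            elif not check(m):
                failures.append(f"{locus}/{ctrl}: M={m:.1f}, {why}")
                rows.append((locus, ctrl, m, False))
            else:
                rows.append((locus, ctrl, m, True))
    values = pd.DataFrame(rows, columns=["locus", "control", "percent", "passed"])
    return ControlReport(not failures, failures, values)


LOD_TEXT = "LOD"


class MethylationTable:
    """Mice x loci percent-methylation matrix with a masked-cell annotation.

    ``values`` is a float DataFrame (rows = mice, columns = loci) with NaN
    at masked cells; ``mask_reason`` holds ``"lod"`` for below-LOD lanes and
    ``"absent"`` for structurally missing cells (e.g. a Y-linked locus in
    females).  ``clades`` optionally maps each locus to its clade label.
    """

    def __init__(self, values: pd.DataFrame,
                 mask_reason: pd.DataFrame | None = None,
                 clades: Mapping[str, str] | pd.Series | None = None):
        self.values = values.astype(float)
        if mask_reason is None:
            mask_reason = pd.DataFrame("", index=values.index, columns=values.columns)
            mask_reason = mask_reason.where(~self.values.isna(), "lod")
        self.mask_reason = mask_reason.reindex_like(values).fillna("")
        bad = self.values.notna() & (self.mask_reason != "")
        if bad.any().any():
            raise ValueError("mask_reason set on present cells")
        present = self.values.stack()
        if len(present) and ((present < 0) | (present > 100)).any():
            raise ValueError("methylation values must lie in [0, 100]")
        if clades is not None:
            self.clades = pd.Series(clades).reindex(values.columns)
        else:
            self.clades = None

    # -- basic views -------------------------------------------------------
    @property
    def mice(self) -> list[str]:
        return list(self.values.index)

    @property
    def loci(self) -> list[str]:
        return list(self.values.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack(future_stack=True).rename("percent").reset_index()
        long.columns = ["mouse_id", "locus_id", "percent"]
        return long

    # -- round-trip TSV ----------------------------------------------------
    def to_tsv(self, path: str) -> None:
        out = self.values.copy().astype(object)
        for i in out.index:
            for j in out.columns:
                if pd.isna(out.at[i, j]):
                    out.at[i, j] = LOD_TEXT if self.mask_reason.at[i, j] == "lod" else ""
                else:
                    v = self.values.at[i, j]
                    out.at[i, j] = int(v) if float(v).is_integer() else v
        out.to_csv(path, sep="\t", index_label="mouse_id")

    @classmethod
    def from_tsv(cls, path: str,
                 clades: Mapping[str, str] | None = None) -> "MethylationTable":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        raw.index.name = None
        values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
        reason = pd.DataFrame("", index=raw.index, columns=raw.columns)
        for i in raw.index:
            for j in raw.columns:
                cell = raw.at[i, j].strip()
                if cell == LOD_TEXT:
                    values.at[i, j] = np.nan
                    reason.at[i, j] = "lod"
                elif cell == "":
                    values.at[i, j] = np.nan
                    reason.at[i, j] = "absent"
                else:
                    values.at[i, j] = float(cell)
        return cls(values, reason, clades)


def assemble_table(
    lanes: Sequence[LaneQuant],
    clade_map: Mapping[str, str] | None = None,
    structural_absent: Iterable[tuple[str, str]] = (),
    ndigits: int | None = 0,
) -> MethylationTable:
    """Build the mice x loci matrix from quantified lanes.

    Control lanes are excluded; below-LOD lanes become masked cells with
    reason ``"lod"``; (mouse, locus) pairs listed in ``structural_absent``
    (or simply missing from the lanes) are masked as ``"absent"``.
    Duplicate (mouse, locus) lanes are an error.
    """
    sample = [l for l in lanes if l.flag != CONTROL and l.mouse_id not in CONTROL_IDS]
    seen = set()
    for lane in sample:
        key = (lane.mouse_id, lane.locus_id)
        if key in seen:
            raise ValueError(f"duplicate lane for {key}")
        seen.add(key)
    mice = sorted({l.mouse_id for l in sample})
    loci = sorted({l.locus_id for l in sample})
    values = pd.DataFrame(np.nan, index=mice, columns=loci)
    reason = pd.DataFrame("absent", index=mice, columns=loci)
    for lane in sample:
        if lane.flag == BELOW_LOD:
            reason.at[lane.mouse_id, lane.locus_id] = "lod"
        else:
            values.at[lane.mouse_id, lane.locus_id] = percent_methylation(
                lane, ndigits=ndigits)
            reason.at[lane.mouse_id, lane.locus_id] = ""
    for mouse, locus in structural_absent:
        if mouse in values.index and locus in values.columns:
            values.at[mouse, locus] = np.nan
            reason.at[mouse, locus] = "absent"
    return MethylationTable(values, reason, clade_map)


def read_lanes_tsv(path: str) -> list[LaneQuant]:
    """Read a long-format lane TSV: mouse_id, locus_id, band_role, intensity.

    ``band_role`` is ``uncut`` or ``cut``; multiple cut bands per lane are
    summed (material is conserved across sub-fragments).  Mouse ids
    ``control_0`` / ``control_high`` are flagged as control lanes.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mouse_id": str, "locus_id": str})
    lanes = []
    for (mouse, locus), grp in df.groupby(["mouse_id", "locus_id"], sort=True):
        uncut = float(grp.loc[grp.band_role == "uncut", "intensity"].sum())
        cut = float(grp.loc[grp.band_role == "cut", "intensity"].sum())
        flag = CONTROL if mouse in CONTROL_IDS else OK
        lanes.append(LaneQuant(mouse, locus, uncut, cut, flag))
    return lanes


def write_lanes_tsv(lanes: Sequence[LaneQuant], path: str) -> None:
    rows = []
    for lane in lanes:
        rows.append((lane.mouse_id, lane.locus_id, "uncut", lane.i_uncut))
        rows.append((lane.mouse_id, lane.locus_id, "cut", lane.i_cut))
    pd.DataFrame(rows, columns=["mouse_id", "locus_id", "band_role", "intensity"]) \
        .to_csv(path, sep="\t", index=False)
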