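"""Bundled published data: the 17-mouse x 21-locus CoBRA methylation matrix.

The matrix of CoBRA-quantitated percent methylation across 17 isogenic mice
and 21 IAP LTR loci (7 per phylogenetic clade), as published, with its
below-LOD cells and the Y-linked locus IAP281Y blank in the 10 female mice.
Values are integer percent as printed.  Also bundled: the published PCR
primers and cycling conditions for each assay.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .quant import MethylationTable

__all__ = ["load_cobra_table", "load_assay_conditions", "CLADE_OF_LOCUS", "MALE_MICE"]

# columns ordered red (clade 1), green (clade 2), black (clade 3)
_LOCI = (
    "CabpIAP IAP31 IAP44 IAP51 IAP77 IAP90 IAP110 "
    "IAP176 IAP182 IAP186 IAP195 IAP236 IAP281Y IAP268 "
    "IAP506 IAP655 IAP1112 IAP1248 IAP1252 IAP1259 IAP1334"
).split()

CLADE_OF_LOCUS = {locus: clade for locus, clade in zip(
    _LOCI, ["red"] * 7 + ["green"] * 7 + ["black"] * 7)}

# "." = structurally absent (Y-linked locus in females), "LOD" = below LOD
_MATRIX = """\
74 52 70 77 60 80 71 69 70 61 70 62 .  77 77 76 66 LOD 83 82 88
77 60 77 75 60 71 72 60 71 68 76 68 .  84 86 70 69 83 77 78 86
81 57 77 78 66 76 72 66 74 55 73 67 .  76 71 76 68 84 78 84 LOD
72 61 80 77 65 68 69 56 77 56 54 65 .  73 82 70 60 89 80 81 86
74 59 71 78 61 80 75 65 70 69 69 63 .  80 81 70 LOD 76 78 82 90
76 57 78 74 65 73 71 63 64 67 76 58 64 77 94 76 63 78 LOD 85 86
66 62 80 75 61 73 78 54 67 65 64 66 .  75 75 74 60 85 78 82 86
76 60 75 78 62 72 64 63 71 65 73 60 .  78 93 70 62 81 79 84 LOD
67 62 83 73 64 70 67 69 75 69 74 63 67 76 76 74 68 87 83 86 86
82 62 80 47 68 69 57 57 78 73 65 58 .  82 92 79 60 84 82 81 91
70 60 87 69 65 71 73 65 70 68 72 54 64 80 76 73 63 87 87 84 90
48 61 77 70 66 71 57 63 74 71 76 64 61 84 94 75 64 81 82 81 89
79 64 81 73 64 69 66 67 69 68 75 62 64 80 81 72 66 LOD 77 84 86
79 58 79 72 68 76 57 63 69 68 78 71 .  79 82 77 69 84 84 84 90
74 55 80 75 68 74 71 60 72 66 71 60 .  81 80 71 64 83 84 85 89
73 56 81 71 70 69 48 60 83 71 75 67 57 83 74 73 66 82 79 85 88
76 59 71 78 62 78 72 66 66 67 68 65 65 78 LOD 77 65 82 79 83 91
"""

# mice carrying IAP281Y values are the 7 males
MALE_MICE = ("Mouse6", "Mouse9", "Mouse11", "Mouse12", "Mouse13",
             "Mouse16", "Mouse17")


def load_cobra_table() -> MethylationTable:
    """The published 17 x 21 CoBRA percent-methylation matrix.

    Returns a :class:`~metastable.quant.MethylationTable` whose mask
    distinguishes below-LOD lanes ("lod") from structural absence
    ("absent": the Y-linked IAP281Y column in female mice).
    """
    mice = [f"Mouse{i}" for i in range(1, 18)]
    values = pd.DataFrame(index=mice, columns=_LOCI, dtype=float)
    reason = pd.DataFrame("", index=mice, columns=_LOCI)
    for mouse, line in zip(mice, _MATRIX.strip().splitlines()):
        for locus, cell in zip(_LOCI, line.split()):
            if cell == ".":
                values.at[mouse, locus] = np.nan
                reason.at[mouse, locus] = "absent"
            elif cell == "LOD":
                values.at[mouse, locus] = np.nan
                reason.at[mouse, locus] = "lod"
            else:
                values.at[mouse, locus] = float(cell)
    return MethylationTable(values, reason, CLADE_OF_LOCUS)


_ASSAYS_TSV = """\
locus\tclade\tposition\tforward_primer\treverse_primer\tcycles\tanneal_temp
CabpIAP\tred\tchr2:154179911-154180159\tATTATTTTTTGATTGGTTGTAGTTTATGG\tCACCAACATACAATTAACA\t39\t47
IAP31\tred\tchr1:89356306-89357454\tTAAGAAGTAAGAGAGAGAAGTAA\tCCAAACAAATCCAAAAACCTAA\t45\t52
IAP44\tred\tchr10:77413077-77414228\tGGTTAGGAAGAATATAATAATTAG\tCTAAAAATAAAACCCAAAAACCC\t45\t52
IAP51\tred\tchr12:53835543-53836696\tGGGAAAAATAGAGTATAAGTAG\tTCTAACAACTACCCACAAAAAAT\t40\t52
IAP77\tred\tchr17:64098002-64099153\tAAGTAAGAGAGAGAGAAAAT\tTATAACCCCCAAATAACTAACAT\t45\t52
IAP90\tred\tchr18:47812857-47814008\tGGGAAAAATAGAGTATAAGY\tCACTAAAAACAACAATCTAACAAC\t43\t52
IAP110\tred\tchr2:72112889-72114056\tAAGTAAGAGAGAGTAAGAAGTAA\tCATATACAACACTTAAAACAAAACC\t45\t52
IAP176\tgreen\tchr1:127212941-127214106\tTTTATATTTTTGGGAGTTAGG\tAACACTCTTCTACAATAACATCT\t40\t52
IAP182\tgreen\tchr1:26288894-26290059\tTGTTTATATTTTTGGGAGTTAG\tAACCTACTTCATCTTAAAAC\t45\t52
IAP186\tgreen\tchr10:24567718-24568883\tGTATTATTTTTTGATTGGTTGTAG\tAAACCCACTAATTCTTCCTAT\t40\t52
IAP195\tgreen\tchr12:25079835-25080998\tTTGTTTATATTTTTGGGAGT\tCACCTTATATTCTCCAAAAAAAC\t40\t52
IAP236\tgreen\tchr4:155057154-155058318\tGTATTATTTTTTGATTGGTTGTAG\tAATTTTTTTCCCCTTCAATC\t45\t52
IAP268\tgreen\tchr9:123106561-123107725\tTTTATATTTTTGGGAGTTAGG\tACACCTAACATCATCTAAAT\t45\t52
IAP281Y\tgreen\tchrY:2136760-2137925\tGGTTAGGAAGAATATTATAGA\tTACACCAAAAACAAACCAAA\t45\t52
IAP506\tblack\tchr12:74416066-74417247\tAGTAAGAAGTAAGAGAGTAAGAA\tCTACACCCCAAAAATAATAAAAAC\t45\t52
IAP655\tblack\tchr15:11992027-11993248\tAGAGAAAAGTAAGAGAGAGAAAA\tAAAACAAAAAAAACTACACCC\t45\t52
IAP1112\tblack\tchr6:101092968-101094168\tTAAGAGAGAGAGAAAAGTAAGAGA\tCCACCAAAATAAAAACTCAAAAC\t43\t52
IAP1248\tblack\tchr8:63849572-63850723\tTTTTTAGGAGTTAGAGTGTA\tCTCCTTTCTAATTTTATTCTCCA\t45\t53
IAP1252\tblack\tchr8:47435363-47436559\tAGAAAAAGTAAGAGAGAGAGAAA\tAACCCTAAAATTCCTCAAAAAAC\t40\t54
IAP1259\tblack\tchr8:8319882-8321071\tAAGAAGTAAGAGAGTAAGAAGTAA\tACAAAAAATCAACTAAACTCTAC\t45\t53
IAP1334\tblack\tchr9:121236806-121238001\tAAGTAAGAGAGAGAGAAAAGTAA\tRACTACTACTAAAAACCCACAA\t40\t54
"""


def load_assay_conditions() -> pd.DataFrame:
    """Published CoBRA primers and PCR conditions per locus."""
    return pd.read_csv(io.StringIO(_ASSAYS_TSV), sep="\t")
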