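"""Published reference values for the 19-locus AGCU X-19 STR panel.

Forensic-efficiency parameters reported for a Xinjiang Mongolian population
sample (156 males, 111 females), used as fixed reference inputs for
consistency checks: the closed forms implemented in :mod:`xstrkit.forensic`
must reproduce the internal relationships among these published columns
(PE from Het, PDF from Het/PIC, the cumulative combinations) to printed
precision.

Column order per locus: PIC, Het, PE, PDF, PDM, MEC Kruger, MEC Kishida,
MEC Desmarais Duo.
"""

from __future__ import annotations

__all__ = [
    "REFERENCE_PANEL",
    "REFERENCE_CUMULATIVES",
    "LOCI",
    "DEFAULT_LINKAGE_GROUPS",
]

_COLUMNS = (
    "pic", "het", "pe", "pdf", "pdm",
    "mec_kruger", "mec_kishida", "mec_desmarais_duo",
)

_ROWS = {
    "DXS8378":  (0.6157, 0.6687, 0.3815, 0.8372, 0.6687, 0.4160, 0.6157, 0.4687),
    "DXS7423":  (0.5430, 0.6077, 0.3003, 0.7814, 0.6077, 0.3442, 0.5430, 0.3966),
    "DXS10148": (0.8980, 0.9056, 0.8069, 0.9835, 0.9056, 0.8095, 0.8980, 0.8221),
    "DXS10159": (0.7550, 0.7882, 0.5773, 0.9220, 0.7882, 0.5817, 0.7550, 0.6254),
    "DXS10134": (0.8494, 0.8635, 0.7217, 0.9672, 0.8635, 0.7296, 0.8494, 0.7508),
    "DXS7424":  (0.7185, 0.7499, 0.5096, 0.9061, 0.7499, 0.5457, 0.7185, 0.5830),
    "DXS10164": (0.5334, 0.5915, 0.2808, 0.7750, 0.5915, 0.3406, 0.5334, 0.3867),
    "DXS10162": (0.6804, 0.7199, 0.4598, 0.8820, 0.7199, 0.4958, 0.6804, 0.5393),
    "DXS7132":  (0.7047, 0.7453, 0.5018, 0.8945, 0.7453, 0.5200, 0.7047, 0.5669),
    "DXS10079": (0.7883, 0.8130, 0.6234, 0.9403, 0.8130, 0.6345, 0.7883, 0.6681),
    "DXS6789":  (0.7679, 0.7966, 0.5927, 0.9299, 0.7966, 0.6050, 0.7679, 0.6425),
    "DXS101":   (0.8119, 0.8321, 0.6600, 0.9516, 0.8321, 0.6707, 0.8119, 0.6992),
    "DXS10103": (0.7559, 0.7863, 0.5739, 0.9240, 0.7863, 0.5876, 0.7558, 0.6271),
    "DXS10101": (0.8931, 0.9015, 0.7984, 0.9819, 0.9015, 0.8001, 0.8930, 0.8141),
    "HPRTB":    (0.6781, 0.7244, 0.4669, 0.8777, 0.7244, 0.4844, 0.6781, 0.5362),
    "DXS6809":  (0.7799, 0.8051, 0.6085, 0.9368, 0.8051, 0.6232, 0.7799, 0.6572),
    "DXS10075": (0.6289, 0.6845, 0.4047, 0.8448, 0.6845, 0.4296, 0.6289, 0.4839),
    "DXS10074": (0.7535, 0.7847, 0.5710, 0.9225, 0.7847, 0.5845, 0.7535, 0.6244),
    "DXS10135": (0.9184, 0.9235, 0.8437, 0.9890, 0.9235, 0.8448, 0.9183, 0.8539),
}

#: locus -> {parameter name -> published value}
REFERENCE_PANEL: dict[str, dict[str, float]] = {
    locus: dict(zip(_COLUMNS, vals)) for locus, vals in _ROWS.items()
}

#: published cumulative (multi-locus) statistics, as printed
REFERENCE_CUMULATIVES: dict[str, str] = {
    "pdf": "0.99999999999999999999988761005481",
    "pdm": "0.999999999999903",
    "mec_kruger": "0.999999983245493",
    "mec_kishida": "0.999999999998952",
    "mec_desmarais_duo": "0.9999999969738068321121",
}

#: the 19 loci of the panel, in reported order
LOCI: list[str] = list(_ROWS)

#: the seven linkage groups of the panel (physically close loci whose alleles
#: are reported as joint haplotypes in males)
DEFAULT_LINKAGE_GROUPS: dict[int, list[str]] = {
    1: ["DXS8378", "DXS10148", "DXS10135"],
    2: ["DXS7132", "DXS10079", "DXS10075", "DXS10074"],
    3: ["DXS10103", "DXS10101", "HPRTB"],
    4: ["DXS6809", "DXS6789"],
    5: ["DXS10159", "DXS10162", "DXS10164"],
    6: ["DXS7424", "DXS101"],
    7: ["DXS10134", "DXS7423"],
}
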