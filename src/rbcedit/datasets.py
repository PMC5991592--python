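"""In-text reference tables used as analysis inputs.

Two small published tables drive the desk-scale analyses:

* the NHSBT transfusion-need survey summary (56 alloimmunised or rare-type
  patients over a 15-month window, with per-system alloantibody counts), and
* TMT abundance ratios (knockout : untransduced control, mean of two
  technical replicates) for a selection of red-cell membrane and
  cytoskeletal proteins.

Only summary marginals of the survey are public; per-patient antibody
combinations are not, which is why :mod:`rbcedit.simulate` reconstructs a
consistent cohort realisation instead of loading one.
"""

from __future__ import annotations

from .coverage import BloodGroupSystem as BG

#: Patients with alloantibodies per blood-group system. The Duffy count
#: includes two untransfused Fy(a-b-) individuals yet to form antibodies.
SURVEY_SYSTEM_COUNTS: dict[BG, int] = {
    BG.MNS_GPB: 22,
    BG.RH: 19,
    BG.DUFFY: 12,
    BG.KELL: 10,
    BG.H: 8,
    BG.LUTHERAN: 3,
    BG.KIDD: 3,
}

#: 56 patients in total, two of whom have McLeod syndrome (XK deficiency,
#: unservable by blood-group knockout) and are therefore not profiled in the
#: per-system counts; 19 profiled patients hold antibodies in >= 2 systems.
SURVEY_SUMMARY = {
    "n_patients": 56,
    "n_mcleod": 2,
    "n_multi": 19,
    "n_untransfused_duffy": 2,
}

#: Quantitative proteomics of functionally relevant red-cell proteins:
#: (accession, gene, peptides, unique peptides, mean abundance ratio KO:UT).
RBC_PROTEIN_QUANT: list[tuple[str, str, int, int, float]] = [
    ("P02549", "SPTA1", 136, 136, 0.96),
    ("P11277", "SPTB", 128, 4, 0.96),
    ("P16157", "ANK1", 77, 77, 1.02),
    ("P35611", "ADD1", 21, 20, 1.01),
    ("P35612", "ADD2", 31, 19, 1.28),
    ("P11171", "EPB41", 35, 16, 1.02),
    ("P16452", "EPB42", 27, 27, 1.00),
    ("Q00013", "MPP1", 21, 21, 1.20),
    ("Q08495", "DMTN", 20, 20, 1.00),
    ("P28289", "TMOD1", 15, 15, 1.03),
    ("B4DW52", "ACTB", 14, 1, 0.86),
    ("E2RVJ0", "SLC4A1", 29, 29, 1.04),
    ("A0A0C4DFT7", "GYPA", 5, 5, 1.00),
    ("P04921", "GYPC", 2, 2, 0.99),
    ("P27105", "STOM", 14, 14, 1.35),
    ("E7EMK3", "FLOT2", 15, 15, 0.98),
    ("Q59GX2", "SLC2A1", 9, 9, 1.14),
    ("C8C504", "HBB", 21, 1, 0.93),
    ("P00915", "CA1", 16, 2, 1.27),
    ("H7BY55", "CD55", 6, 6, 1.55),
    ("E9PR17", "CD59", 3, 3, 1.44),
    ("P35613", "BSG", 10, 10, 1.23),
    ("A0A068W6W9", "SLC14A1", 2, 2, 0.94),
    ("A0A068W6H0", "BCAM", 4, 4, 0.69),
    ("P51811", "XK", 5, 5, 0.63),
    ("Q08722", "CD47", 2, 2, 0.61),
    ("P16070", "CD44", 3, 3, 0.51),
    ("Q14773", "ICAM4", 3, 3, 0.07),
    ("B2LR44", "RHD", 2, 2, 0.02),
]

#: Ratios by gene, for convenience.
RBC_PROTEIN_RATIOS: dict[str, float] = {g: r for (_, g, _, _, r) in RBC_PROTEIN_QUANT}
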