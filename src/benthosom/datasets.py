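"""Published reference values from the Lianhuan Lake macroinvertebrate survey.

Small printed tables from the Lianhuan Lake (Heilongjiang, northern China)
biomonitoring study that this package's analysis chain reproduces: the
species-level indicator-value table (42 significant species with their
group, IndVal % and permutation p) and the leading correlation-matrix PCA
eigenvalues of the 13 environmental variables.  These serve as desk-scale
inputs for re-running the downstream classification arithmetic without the
deposited raw data.
"""

from __future__ import annotations

import pandas as pd

#: leading eigenvalues of the environmental correlation-matrix PCA
#: (13 variables): axis 1 and axis 2.
PCA_EIGENVALUES = (3.10, 2.74)
PCA_N_VARIABLES = 13

_INDICATOR_ROWS = [
    # (group, species, indval_percent, p)
    ("I", "Anatopynia sp.", 69.15, 0.001),
    ("I", "Tanytarsus sp.2", 63.19, 0.001),
    ("I", "Corbicula fluminea", 52.80, 0.013),
    ("I", "Polypedilum sp.", 51.82, 0.001),
    ("I", "Chaoborus sp.", 48.98, 0.001),
    ("I", "Ephemera sp.", 48.40, 0.002),
    ("I", "Conchapelopia sp.1", 41.54, 0.001),
    ("II", "Anotogaster sp.", 89.08, 0.001),
    ("II", "Glossiphonia sp.", 89.08, 0.001),
    ("II", "Sphaerium lacustre", 85.78, 0.001),
    ("II", "Sigara sp.1", 84.00, 0.001),
    ("II", "Sigara sp.2", 84.00, 0.001),
    ("II", "Valvata piscinalis", 82.59, 0.001),
    ("II", "Mirconecta sp.1", 79.40, 0.001),
    ("II", "Exopalaemon modestus", 79.21, 0.001),
    ("II", "Branchiura sowerbyi", 74.60, 0.001),
    ("II", "Stenothyra glabra", 74.48, 0.001),
    ("II", "Mirconecta sp.2", 73.71, 0.001),
    ("II", "Herpobdella sp.", 61.31, 0.001),
    ("II", "Radix auricularia", 50.19, 0.004),
    ("II", "Parafossarulus striatulus", 44.47, 0.003),
    ("II", "Einfeldia sp.", 39.32, 0.002),
    ("III", "Demicryptochironomus sp.", 72.29, 0.001),
    ("III", "Procladius sp.2", 51.95, 0.001),
    ("III", "Tanytarsus sp.1", 33.14, 0.004),
    ("IV", "Clinotarypus sp.", 79.24, 0.001),
    ("IV", "Galba pervia", 58.65, 0.001),
    ("IV", "Tanypus sp.", 52.92, 0.001),
    ("IV", "Acricotopus sp.", 40.00, 0.017),
    ("IV", "Limnodrilus sp.3", 37.38, 0.036),
    ("IV", "Conchapelopia sp.2", 35.83, 0.004),
    ("IV", "Culicoides sp.", 35.65, 0.004),
    ("IV", "Procladius sp.1", 31.89, 0.001),
    ("V", "Cricotopus sp.", 83.77, 0.001),
    ("V", "Radix lagotis", 83.77, 0.001),
    ("V", "Chironomus sp.", 67.15, 0.001),
    ("V", "Anodonta woodiana", 62.97, 0.001),
    ("V", "Unio douglasiae", 58.50, 0.001),
    ("V", "Gyraulus albus", 51.76, 0.001),
    ("V", "Galaba sp.", 50.66, 0.002),
    ("V", "Radix ovata", 44.68, 0.001),
    ("V", "Radix pereger", 43.50, 0.002),
]


def lianhuan_indicator_table() -> pd.DataFrame:
    """The survey's significant species with group, IndVal % and p.

    Columns: ``species``, ``group`` (I–V), ``indval`` (percent), ``p``.
    """
    return pd.DataFrame(
        [{"group": g, "species": s, "indval": iv, "p": p}
         for g, s, iv, p in _INDICATOR_ROWS],
        columns=["species", "group", "indval", "p"])
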