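"""Published reference inputs for the 198-tumor clinical association layer.

These are the printed cross-tabulations of clinico-pathological factors
against dichotomized expression (above/below the normal-stomach median)
for the TCGA-style cohort with complete copy-number, expression and
clinical annotation.  They serve as fixed inputs to the association tests;
the package recomputes every statistic from these counts.

The ESRP1-by-molecular-subtype column of the published table is internally
inconsistent (its genomically-stable counts imply a different column total
than every other column) and is therefore not carried here.
"""

from __future__ import annotations

import pandas as pd

LAUREN_LEVELS = ["Diffuse", "Intestinal", "Mixed"]
SUBTYPE_LEVELS = ["CIN", "EBV", "MSI", "GS"]


def _table(rows, index, columns=("above", "below")) -> pd.DataFrame:
    return pd.DataFrame(rows, index=list(index), columns=list(columns))


#: Lauren histotype x FGFR2-IIIc surrogate-exon category.
LAUREN_BY_IIIC = _table([[28, 21], [24, 110], [4, 11]], LAUREN_LEVELS)

#: Vital status x FGFR2-IIIc surrogate-exon category (2x2, Yates-corrected).
VITAL_BY_IIIC = _table([[28, 43], [28, 99]], ["Dead", "Alive"])

#: Molecular subtype x FGFR2-IIIc surrogate-exon category.
SUBTYPE_BY_IIIC = _table([[19, 82], [2, 15], [8, 29], [27, 16]], SUBTYPE_LEVELS)

#: Lauren histotype x ESRP1 category.
LAUREN_BY_ESRP1 = _table([[32, 17], [132, 2], [14, 1]], LAUREN_LEVELS)

ASSOCIATION_TABLES = {
    "lauren_by_iiic": LAUREN_BY_IIIC,
    "vital_by_iiic": VITAL_BY_IIIC,
    "subtype_by_iiic": SUBTYPE_BY_IIIC,
    "lauren_by_esrp1": LAUREN_BY_ESRP1,
}

#: Normal-stomach median expression thresholds of the 27-normal reference
#: set (RPKM for the isoform surrogate exons, FPKM for ESRP1).
NORMAL_MEDIANS = {"FGFR2-IIIb": 2.89, "FGFR2-IIIc": 1.53, "ESRP1": 13.26}
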