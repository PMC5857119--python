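"""Published whole-archive reference values.

Per-amino-acid numbers from a published survey of ion-amino-acid pairs
over a non-redundant subset of the Protein Data Bank.  They are kept
here as reference *inputs* for the grouping summaries: recomputing them
would require the full structure archive, but the group averages derived
from them are pure arithmetic and serve as fixed checks of
:func:`iondist.pair_statistics.group_summary`.
"""

from __future__ import annotations

#: Observed ion-amino-acid pair counts per amino acid (non-redundant
#: archive subset).
PAIR_COUNT_SURVEY: dict[str, int] = {
    "ALA": 3284, "ILE": 2639, "LEU": 3074, "MET": 986, "PHE": 2081,
    "PRO": 1912, "TRP": 514, "VAL": 3250,
    "ASN": 2318, "CYS": 30081, "GLN": 2082, "GLY": 6543, "SER": 3372,
    "THR": 2973, "TYR": 1803,
    "ARG": 2478, "HIS": 12547, "LYS": 3854,
    "ASP": 6541, "GLU": 5416,
}

#: Percentage of paired ions closer to the side-chain center than to the
#: backbone center (undefined for glycine).
SIDECHAIN_PREFERENCE_SURVEY: dict[str, float] = {
    "ALA": 57.5, "ILE": 14.3, "LEU": 37.7, "MET": 66.4, "PHE": 55.0,
    "PRO": 44.7, "TRP": 0.0, "VAL": 56.0,
    "ASN": 67.1, "CYS": 94.5, "GLN": 59.2, "SER": 55.6, "THR": 57.2,
    "TYR": 11.1,
    "ARG": 68.2, "HIS": 98.0, "LYS": 47.0,
    "ASP": 81.7, "GLU": 92.1,
}
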