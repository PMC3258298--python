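"""Bundled example data: differentially expressed miRNAs of zebrafish brain.

The table lists the 25 miRNAs called differentially expressed between a
normal-temperature (NC, 28°C) and a cold-acclimated (WC, 10°C) zebrafish
brain small-RNA library, with raw read counts in each library, the mature
miRNA sequence, genomic coordinate, and the reported normalized fold change
with its direction ("up" = higher in the cold library after library-size
normalization).

The two libraries were sequenced to unequal depth, so raw WC/NC count
ratios overstate up-regulation by a constant library-scaling factor; see
:func:`coldmir.screen.calibrate_norm_factor` for recovering that factor
from the reported folds.
"""

from __future__ import annotations

import pandas as pd

# name, genome coordinate, mature sequence, raw WC count, raw NC count,
# reported normalized fold, direction
_ZEBRAFISH_COLD_MIRNAS = [
    ("dre-mir-9-5-3p", "5:49144568:49144646:-", "UAAAGCUAGAUAACCGAAAGU", 37364, 2559, 7.377, "up"),
    ("dre-mir-30d-5p", "16:23860143:23860227:+", "UGUAAACAUCCCCGACUGGAAGCU", 19903, 3770, 2.667, "up"),
    ("miR_49", "4:52193679:52193757:+", "UUCACUGUGGCGGAAAUGACC", 146, 31, 2.380, "up"),
    ("miR_46", "21:25385786:25385876:+", "AAGAGAAGAGUGAGCGAGUGA", 149, 32, 2.352, "up"),
    ("dre-mir-30e-2-5p", "13:28550257:28550337:+", "UGUAAACAUCCUUGACUGGAAGC", 2856, 617, 2.339, "up"),
    ("dre-mir-24-4-3p", "22:5036700:5036779:+", "UGGCUCAGUUCAGCAGGAACAG", 652, 142, 2.320, "up"),
    ("dre-mir-2191-3p", "20:51108008:51108091:+", "UCACACCUACAAUCCCUGGCA", 435, 99, 2.221, "up"),
    ("dre-mir-146a-5p", "13:11738901:11738980:+", "UGAGAACUGAAUUCCAUAGAUGG", 42728, 10063, 2.145, "up"),
    ("miR_48", "24:36888097:36888173:+", "UGAGGAGUUUAGAGCAAGUAA", 129, 31, 2.102, "up"),
    ("miR_23", "5:8733083:8733158:-", "AGCUGGUGUCCUGCAGAGUUU", 345, 85, 2.051, "up"),
    ("dre-mir-455-5p", "5:66430757:66430834:-", "UAUGUGCCCUUGGACUACAUC", 168, 42, 2.021, "up"),
    ("dre-mir-30b-3p", "16:23860432:23860510:+", "CUGGGCGGAGGGUGUUUGCU", 456, 462, 2.006, "down"),
    ("dre-mir-145-5p", "14:40451735:40451816:+", "GUCCAGUUUUCCCAGGAAUCCC", 104, 106, 2.017, "down"),
    ("dre-mir-129-1-3p", "4:18861279:18861364:-", "AAGCCCUUACCCCAAAAAGUAU", 643, 697, 2.145, "down"),
    ("dre-mir-133a-2-3p", "23:5570884:5570961:-", "UUGGUCCCCUUCAACCAGCU", 117, 130, 2.199, "down"),
    ("miR_13", "5:6754333:6754409:+", "UGUGGUGAUUAGAACAGGCUGA", 159, 181, 2.253, "down"),
    ("miR_3", "Zv8_NA10078:51197:51280:-", "AUGACUCAAACCCGAGGACUU", 1279, 1618, 2.504, "down"),
    ("dre-mir-92a-1-3p", "8:45338553:45338629:+", "UAUUGCACUUGUCCCGGCCU", 9007, 11736, 2.579, "down"),
    ("dre-mir-458-3p", "14:26650559:26650634:-", "AUAGCUCUUUGAAUGGUACU", 17139, 22528, 2.601, "down"),
    ("dre-mir-129-2-3p", "7:50935695:50935777:-", "AAGCCCUUACCCCAAAAAGCAU", 7747, 10824, 2.766, "down"),
    ("dre-mir-152-3p", "3:21062159:21062235:+", "UCAGUGCAUGACAGAACUUUG", 2271, 3467, 3.021, "down"),
    ("dre-mir-183-5p", "4:14884980:14885059:+", "UAUGGCACUGGUAGAAUUCACU", 182, 303, 3.294, "down"),
    ("miR_5", "Zv8_NA3780:11797:11893:+", "GCAUUGGUGGUUCAGUGGGA", 698, 1247, 3.536, "down"),
    ("dre-mir-182-5p", "4:14886067:14886150:+", "UUUGGCAAUGGUAGAACUCACA", 151, 365, 4.783, "down"),
    ("miR_8", "2:35918353:35918422:+", "AGCGGAUCAACUGAUGCGAC", 98, 394, 7.956, "down"),
]


def zebrafish_cold_mirnas() -> pd.DataFrame:
    """Return the zebrafish cold-acclimation differential-miRNA table.

    Returns
    -------
    pandas.DataFrame
        Columns ``mirna_id``, ``coordinate``, ``sequence``, ``count_wc``,
        ``count_nc``, ``reported_fold``, ``reported_direction``.
    """
    return pd.DataFrame(
        _ZEBRAFISH_COLD_MIRNAS,
        columns=[
            "mirna_id",
            "coordinate",
            "sequence",
            "count_wc",
            "count_nc",
            "reported_fold",
            "reported_direction",
        ],
    )
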