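"""Published summary tables from the ten-accession rapeseed resequencing
panel this package's synthetic study emulates.

These printed values are *inputs*: the worked-example arithmetic (pairwise
means and shares, per-chromosome densities, the transition/transversion
ratio, validation false-positive rate) recomputes the study's headline
numbers from them.  The genome-scale discovery itself (126 Gb of reads)
is emulated at desk scale by the synthetic pipeline, not reproduced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ACCESSIONS = [
    "Zhongshuang11", "73290", "08-806-2", "09CB01", "Tapidor",
    "XY15", "09CB03", "PY-2", "Westar", "PY-1",
]

# lower-triangle pairwise SNP counts between resequenced accessions,
# row i vs columns 0..i-1 in ACCESSIONS order
_PAIRWISE_LOWER = [
    [319796],
    [156255, 160437],
    [249524, 269446, 97961],
    [344744, 270812, 124744, 177156],
    [258030, 282982, 104584, 30950, 180195],
    [382962, 331329, 147992, 226364, 206498, 238157],
    [171536, 201921, 84905, 112203, 164533, 120094, 196957],
    [326039, 298382, 81868, 192659, 198336, 206164, 250136, 180579],
    [281047, 385432, 126870, 170614, 266468, 171196, 324297, 106790, 293281],
]


def pairwise_matrix() -> pd.DataFrame:
    """Symmetric 10x10 pairwise SNP count matrix (diagonal zero)."""
    n = len(ACCESSIONS)
    mat = np.zeros((n, n), dtype=np.int64)
    for i, row in enumerate(_PAIRWISE_LOWER, start=1):
        for j, v in enumerate(row):
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=ACCESSIONS, columns=ACCESSIONS)


# per-chromosome SNP distribution: length (bp), SNP count, genetic length (cM)
CHROMOSOME_TABLE = pd.DataFrame(
    [
        ("A01", 24_498_464, 35_077, 82.9),
        ("A02", 24_079_606, 46_736, 130.7),
        ("A03", 32_789_773, 58_046, 134.1),
        ("A04", 20_878_981, 29_458, 111.0),
        ("A05", 23_750_921, 48_510, 142.6),
        ("A06", 26_861_533, 47_409, 186.4),
        ("A07", 23_303_709, 35_591, 86.6),
        ("A08", 19_692_993, 30_693, 71.5),
        ("A09", 35_083_316, 47_753, 188.5),
        ("A10", 19_419_491, 37_475, 99.9),
        ("C01", 38_761_736, 47_790, 99.5),
        ("C02", 44_046_019, 48_405, 158.5),
        ("C03", 57_781_479, 54_055, 161.8),
        ("C04", 40_895_491, 42_218, 127.4),
        ("C05", 32_828_344, 14_756, 134.6),
        ("C06", 48_346_224, 41_742, 101.6),
        ("C07", 40_704_487, 32_438, 133.5),
        ("C08", 41_516_080, 37_983, 137.0),
        ("C09", 40_126_872, 22_359, 126.3),
    ],
    columns=["chrom", "length", "snps", "cM"],
)

BIALLELIC_TOTAL = 892_536
TRIALLELIC_TOTAL = 267

TRANSITION_SHARE_PCT = 57.5
TRANSVERSION_SHARE_PCT = 42.5

AT_SNPS = 108_270
AT_SNPS_ASPCR_SUITABLE = 79_533

# genome-level densities as printed (SNPs per 100 kb)
PRINTED_DENSITY_A = 119
PRINTED_DENSITY_C = 89

VALIDATION_READS = 100
VALIDATION_MATCHING = 93

# genotyping experiment summary
OPA_CANDIDATES = 110
OPA_ASSAYS = 96
DESIGNABILITY_CUTOFF = 0.85
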