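"""Genome model shared across modules: GRCh37 chromosome sizes, ploidy, accessions."""

from __future__ import annotations

# GRCh37 chromosome lengths (bp).
CHROM_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}

AUTOSOMES = [str(i) for i in range(1, 23)]
GONOSOMES = ["X", "Y"]

# X pseudo-autosomal region 1 boundary (GRCh37). Targets below this behave
# like autosomes in both sexes; the tiny PAR2 is ignored.
PAR1_END = 2_699_520

# RefSeq accessions for GRCh37 primary assembly chromosomes.
GRCH37_ACCESSIONS = {
    "1": "NC_000001.10", "2": "NC_000002.11", "3": "NC_000003.11",
    "4": "NC_000004.11", "5": "NC_000005.9", "6": "NC_000006.11",
    "7": "NC_000007.13", "8": "NC_000008.10", "9": "NC_000009.11",
    "10": "NC_000010.10", "11": "NC_000011.9", "12": "NC_000012.11",
    "13": "NC_000013.10", "14": "NC_000014.8", "15": "NC_000015.9",
    "16": "NC_000016.9", "17": "NC_000017.10", "18": "NC_000018.9",
    "19": "NC_000019.9", "20": "NC_000020.10", "21": "NC_000021.8",
    "22": "NC_000022.10", "X": "NC_000023.10", "Y": "NC_000024.9",
}


def ploidy(chrom: str, start: int, sex: str) -> int:
    """Expected copy number of a locus given the carrier's sex.

    X below PAR1_END is pseudo-autosomal (ploidy 2 in both sexes);
    Y is absent in females.
    """
    if chrom == "X":
        if start < PAR1_END:
            return 2
        return 1 if sex == "M" else 2
    if chrom == "Y":
        return 1 if sex == "M" else 0
    return 2
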