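"""Reference genome model: hg19 chromosome lengths and helpers.

The pipeline only needs realistic chromosome proportions for binning, so the
24 hg19 chromosome lengths are hardcoded; no reference download is involved.
Coordinates are 0-based half-open throughout the package (BED convention).
"""

from __future__ import annotations

# hg19 / GRCh37 chromosome lengths (bp)
HG19_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
    "chrX": 155270560,
    "chrY": 59373566,
}

CHROMOSOMES: tuple[str, ...] = tuple(HG19_CHROM_LENGTHS)
AUTOSOMES: tuple[str, ...] = tuple(c for c in CHROMOSOMES if c not in ("chrX", "chrY"))
SEX_CHROMS: frozenset[str] = frozenset({"chrX", "chrY"})

GENOME_LENGTH: int = sum(HG19_CHROM_LENGTHS.values())


def chrom_sort_key(chrom: str) -> int:
    """Karyotype ordering: chr1..chr22, chrX, chrY."""
    return CHROMOSOMES.index(chrom)


def validate_interval(chrom: str, start: int, end: int) -> None:
    """Raise ValueError unless [start, end) is a valid interval on chrom."""
    if chrom not in HG19_CHROM_LENGTHS:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if not (0 <= start < end <= HG19_CHROM_LENGTHS[chrom]):
        raise ValueError(
            f"interval {chrom}:{start}-{end} outside chromosome bounds "
            f"[0, {HG19_CHROM_LENGTHS[chrom]})"
        )
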