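"""Genome models: chromosome names, lengths and autosome/sex-chromosome tags.

A :class:`GenomeModel` is the coordinate frame every other module works in.
Coordinates are 0-based, end-exclusive throughout the package, so the size of
an interval is always ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Chromosome",
    "GenomeModel",
    "toy_genome",
    "survey_array_genome",
]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    is_autosome: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r} has non-positive length")


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of chromosomes with autosome/sex tags."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def autosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes if c.is_autosome]

    @property
    def sex_chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes if not c.is_autosome]

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def length(self, name: str) -> int:
        return self[name].length

    def is_autosome(self, name: str) -> bool:
        return self[name].is_autosome

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def autosomal_length(self) -> int:
        return sum(c.length for c in self.chromosomes if c.is_autosome)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.names,
                "length": [c.length for c in self.chromosomes],
                "is_autosome": [int(c.is_autosome) for c in self.chromosomes],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeModel":
        return cls(
            tuple(
                Chromosome(str(r.chrom), int(r.length), bool(int(r.is_autosome)))
                for r in df.itertuples()
            )
        )


def toy_genome() -> GenomeModel:
    """Small test genome: three ~10 Mb autosomes plus an X chromosome.

    At the default 5.3 kb probe spacing each autosome carries ~2,000 probes,
    which keeps whole-pipeline simulations fast while leaving room for
    planted CNVs of tens to hundreds of kilobases.
    """
    return GenomeModel(
        (
            Chromosome("chr1", 11_000_000, True),
            Chromosome("chr2", 10_600_000, True),
            Chromosome("chr3", 10_000_000, True),
            Chromosome("chrX", 8_000_000, False),
        )
    )


# GRCh37/hg19 chromosome lengths (bp), used only as relative proportions for
# the full-size array preset below.
_HG19_LENGTHS = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560, "chrY": 59_373_566,
}

#: Probe count and mean spacing of the 2x400K survey array design emulated by
#: :func:`survey_array_genome`.
SURVEY_ARRAY_PROBES = 410_739
SURVEY_ARRAY_SPACING_BP = 5_300


def survey_array_genome() -> GenomeModel:
    """Full-size preset emulating a ~410,739-probe design at 5.3 kb spacing.

    The probes of the real array do not tile the whole assembly uniformly
    (410,739 x 5.3 kb is ~2.18 Gb), so this preset scales hg19 chromosome
    proportions down to the genomic span the probes effectively cover.
    Tiling it at 5.3 kb yields ~410,739 probes.
    """
    target = SURVEY_ARRAY_PROBES * SURVEY_ARRAY_SPACING_BP
    scale = target / sum(_HG19_LENGTHS.values())
    return GenomeModel(
        tuple(
            Chromosome(name, int(round(length * scale)), name not in ("chrX", "chrY"))
            for name, length in _HG19_LENGTHS.items()
        )
    )
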