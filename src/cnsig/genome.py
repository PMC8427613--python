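"""Genome coordinate frames for autosome-level copy-number analysis.

Signature analysis operates on the 22 human autosomes; each chromosome
carries a centromere coordinate that splits it into a p and a q arm for
the per-arm breakpoint feature.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths and centromere positions for the 22 autosomes.

    Parameters
    ----------
    name
        Label for the build (e.g. ``"hg19"`` or ``"synthetic"``).
    lengths
        Mapping chromosome name -> length in bp. Must contain exactly the
        autosomes "1".."22".
    centromeres
        Mapping chromosome name -> centromere midpoint in bp; defines the
        p/q arm boundary (p arm is ``[0, centromere]``).
    """

    name: str
    lengths: dict[str, int] = field(repr=False)
    centromeres: dict[str, int] = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(AUTOSOMES) - set(self.lengths)
        if missing:
            raise ValueError(f"genome build missing autosomes: {sorted(missing)}")
        extra = set(self.lengths) - set(AUTOSOMES)
        if extra:
            raise ValueError(f"genome build has non-autosomal chromosomes: {sorted(extra)}")
        for chrom in AUTOSOMES:
            length = self.lengths[chrom]
            cen = self.centromeres.get(chrom)
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {length}")
            if cen is None or not 0 < cen < length:
                raise ValueError(
                    f"chromosome {chrom}: centromere {cen} outside (0, {length})"
                )

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return AUTOSOMES

    def arm(self, chrom: str, pos: int) -> str:
        """Return "p" or "q" for a coordinate; exactly at the centromere -> "p"."""
        return "p" if pos <= self.centromeres[chrom] else "q"

    def total_length(self) -> int:
        return sum(self.lengths[c] for c in AUTOSOMES)

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "chromosomes": {
                c: {"length": int(self.lengths[c]), "centromere": int(self.centromeres[c])}
                for c in AUTOSOMES
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenomeBuild":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        chroms = doc["chromosomes"]
        return cls(
            name=doc.get("name", "unnamed"),
            lengths={c: int(v["length"]) for c, v in chroms.items()},
            centromeres={c: int(v["centromere"]) for c, v in chroms.items()},
        )


def load_hg19() -> GenomeBuild:
    """The bundled hg19/GRCh37 autosome frame (UCSC lengths and centromeres)."""
    ref = importlib.resources.files("cnsig.data").joinpath("hg19_autosomes.yaml")
    with ref.open() as fh:
        doc = yaml.safe_load(fh)
    chroms = doc["chromosomes"]
    return GenomeBuild(
        name=doc["name"],
        lengths={c: int(v["length"]) for c, v in chroms.items()},
        centromeres={c: int(v["centromere"]) for c, v in chroms.items()},
    )


def synthetic_genome(scale: float = 1.0, name: str = "synthetic") -> GenomeBuild:
    """A 22-autosome synthetic karyotype with hg19-like rank order of sizes.

    Chromosome lengths run from ~250 Mb down to ~50 Mb matching the real
    karyotype's ordering, so per-arm and per-10 Mb features have realistic
    support; ``scale`` shrinks all coordinates (useful for brute-force tests
    on ~Mb genomes).
    """
    lengths = {}
    centromeres = {}
    for i, chrom in enumerate(AUTOSOMES):
        length = int((250_000_000 - i * 9_500_000) * scale)
        # acrocentric-ish placement drifts from 0.5 to 0.25 along the karyotype
        frac = 0.5 - 0.25 * i / 21
        lengths[chrom] = length
        centromeres[chrom] = int(length * frac)
    return GenomeBuild(name=name, lengths=lengths, centromeres=centromeres)
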