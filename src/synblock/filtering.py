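"""Extant genome filters applied before the pairwise comparison.

Three modes:

* ``NONE`` — keep everything; lineage-specific gene births then count as
  events that break synteny;
* ``IN_BOTH_SPECIES`` — keep only genes whose family has members in both
  genomes (the classical "anchor genes"); ancestral deletions do not break
  synteny;
* ``IN_COMMON_ANCESTOR`` — keep every gene that descends from a gene of the
  last common ancestor, including genes whose ortholog was lost in the other
  species; ancestral deletions then break synteny.  This is the mode suited
  to ancestral gene-order reconstruction and the default.
"""

from __future__ import annotations

from enum import Enum

from .core_model import Chromosome, FamilySet, Genome

__all__ = ["FilterMode", "filter_genomes"]


class FilterMode(Enum):
    NONE = "None"
    IN_BOTH_SPECIES = "InBothSpecies"
    IN_COMMON_ANCESTOR = "InCommonAncestor"

    @classmethod
    def from_string(cls, s: str) -> "FilterMode":
        for mode in cls:
            if mode.value.lower() == s.lower():
                return mode
        raise ValueError(
            f"unknown filter mode {s!r}; choose from "
            f"{[m.value for m in cls]}"
        )


def _families_in_both(ga: Genome, gb: Genome, fams: FamilySet) -> set[str]:
    def present(genome: Genome) -> set[str]:
        out = set()
        for chrom in genome.chromosomes:
            for g in chrom.genes:
                anc = fams.family_of(g.name)
                if anc is not None:
                    out.add(anc)
        return out

    return present(ga) & present(gb)


def filter_genomes(
    ga: Genome,
    gb: Genome,
    fams: FamilySet,
    mode: FilterMode = FilterMode.IN_COMMON_ANCESTOR,
) -> tuple[Genome, Genome]:
    """Return filtered copies of both genomes (order/orientation preserved).

    Chromosomes emptied by the filter are dropped.  Filtering is idempotent
    and the InBothSpecies gene set is a subset of the InCommonAncestor one.
    """
    if mode is FilterMode.NONE:
        return ga, gb
    if mode is FilterMode.IN_BOTH_SPECIES:
        shared = _families_in_both(ga, gb, fams)

        def keep(name: str) -> bool:
            anc = fams.family_of(name)
            return anc is not None and anc in shared

    else:  # IN_COMMON_ANCESTOR

        def keep(name: str) -> bool:
            return fams.family_of(name) is not None

    def apply(genome: Genome) -> Genome:
        chroms = []
        for chrom in genome.chromosomes:
            genes = [g for g in chrom.genes if keep(g.name)]
            if genes:
                chroms.append(Chromosome(chrom.name, genes))
        return Genome(genome.species, chroms)

    return apply(ga), apply(gb)
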