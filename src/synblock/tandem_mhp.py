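"""Tandem blocks and the sparse matrices of homologies / homology packs.

Adjacent genes of the same family are, under parsimony, tandem duplicates;
they are collapsed into a single *tandem block* (tb).  A tb keeps the shared
orientation of its genes when they all agree and an *unknown* orientation
otherwise.  Rewriting both chromosomes in tbs collapses the vertical /
horizontal / rectangular runs that tandem arrays paint in the gene-level
matrix of homologies (MH) into single cells of the matrix of homology packs
(MHP), which makes synteny blocks appear as (gapped) diagonals.

Axis convention: X is chromosome A left to right, Y is chromosome B bottom
to top; cell (0, 0) is the bottom-left corner.  Both matrices are sparse
maps keyed by coordinates, with values +1 / -1 / None (unknown sign).

Only strictly adjacent same-family genes form a tb (tandem gap 0); a family
recurring at non-adjacent positions yields distinct tbs (dispersed
paralogs), which produce several hps in the same row or column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_model import Chromosome, FamilySet, Gene, Genome

__all__ = [
    "TandemBlock",
    "TbChromosome",
    "MHP",
    "rewrite_in_tbs",
    "rewrite_genome",
    "build_mh",
    "build_mhp",
]


@dataclass
class TandemBlock:
    """A maximal run of adjacent same-family genes, as one oriented unit."""

    family: str
    genes: list[Gene]
    orientation: int | None  # +1 | -1 | None (mixed orientations)

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class TbChromosome:
    """A chromosome rewritten as an ordered list of tandem blocks."""

    name: str
    tbs: list[TandemBlock] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tbs)

    def flatten(self) -> list[Gene]:
        return [g for tb in self.tbs for g in tb.genes]


@dataclass
class MHP:
    """Sparse matrix of homology packs between two tb-rewritten chromosomes."""

    chrom_a: TbChromosome
    chrom_b: TbChromosome
    cells: dict[tuple[int, int], int | None]

    @property
    def n_a(self) -> int:
        return len(self.chrom_a)

    @property
    def n_b(self) -> int:
        return len(self.chrom_b)

    @property
    def n_ab(self) -> int:
        return len(self.cells)


def _pseudo_family(gene: Gene) -> str:
    # Family-less genes (possible without filtering) become singleton
    # pseudo-families that can never match anything in the other genome.
    return f"__solo__{gene.name}"


def rewrite_in_tbs(chrom: Chromosome, fams: FamilySet) -> TbChromosome:
    """Greedy left-to-right grouping of maximal same-family runs."""
    tbs: list[TandemBlock] = []
    for gene in chrom.genes:
        family = fams.family_of(gene.name) or _pseudo_family(gene)
        if tbs and tbs[-1].family == family:
            tb = tbs[-1]
            tb.genes.append(gene)
            if tb.orientation != gene.orientation:
                tb.orientation = None
        else:
            tbs.append(TandemBlock(family, [gene], gene.orientation))
    return TbChromosome(chrom.name, tbs)


def rewrite_genome(genome: Genome, fams: FamilySet) -> list[TbChromosome]:
    return [rewrite_in_tbs(c, fams) for c in genome.chromosomes]


def build_mh(
    ca: Chromosome, cb: Chromosome, fams: FamilySet
) -> dict[tuple[int, int], int]:
    """Gene-level matrix of homologies: (i, j) -> o(g_a,i) * o(g_b,j)."""
    by_family: dict[str, list[int]] = {}
    for j, g in enumerate(cb.genes):
        anc = fams.family_of(g.name)
        if anc is not None:
            by_family.setdefault(anc, []).append(j)
    cells: dict[tuple[int, int], int] = {}
    for i, g in enumerate(ca.genes):
        anc = fams.family_of(g.name)
        if anc is None:
            continue
        for j in by_family.get(anc, ()):
            cells[(i, j)] = g.orientation * cb.genes[j].orientation
    return cells


def build_mhp(ca: TbChromosome, cb: TbChromosome) -> MHP:
    """Tb-level matrix: cell present iff families equal; sign may be unknown."""
    by_family: dict[str, list[int]] = {}
    for j, tb in enumerate(cb.tbs):
        by_family.setdefault(tb.family, []).append(j)
    cells: dict[tuple[int, int], int | None] = {}
    for i, tba in enumerate(ca.tbs):
        for j in by_family.get(tba.family, ()):
            tbb = cb.tbs[j]
            if tba.orientation is None or tbb.orientation is None:
                cells[(i, j)] = None
            else:
                cells[(i, j)] = tba.orientation * tbb.orientation
    return MHP(ca, cb, cells)
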