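"""Domain types for genomes, gene families and synteny blocks, plus TSV I/O.

A genome is an ordered collection of chromosomes; a chromosome is an ordered
list of oriented genes, indexed along the reference orientation (index 0 is
the first gene).  Gene orientation is the transcriptional strand, encoded
+1/-1 relative to the reference orientation of the chromosome.

Families group extant genes that descend from a single gene of the last
common ancestor of the two compared species; they are either read from a
precomputed family table or derived from a reconciled gene forest (see
:mod:`synblock.gene_trees`).

File dialects (all tab-separated, UTF-8, ``#``-prefixed comment lines
ignored on read):

* genome TSV — 5 columns, no header: chromosome, start, end, strand (``1``
  or ``-1``), gene name; coordinates are 0-based half-open and only define
  gene order (this package is gene-order based, not sequence based);
* family TSV — one family per line: ancestral gene name followed by the
  whitespace-separated names of its extant descendants;
* synteny-block TSV — one row per homology pack, block metadata on
  ``#``-prefixed header lines (see :func:`write_synteny_blocks`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Gene",
    "Chromosome",
    "Genome",
    "FamilySet",
    "HpRecord",
    "SyntenyBlock",
    "GenomeParseError",
    "ValidationError",
    "parse_genome",
    "write_genome",
    "parse_families",
    "write_families",
    "write_synteny_blocks",
    "read_synteny_blocks",
]

#: serialisation of an unknown orientation / sign
UNKNOWN = "?"


class GenomeParseError(ValueError):
    """Raised on a malformed input line; the message names the line number."""


class ValidationError(ValueError):
    """Raised when parsed data violates a model invariant."""


@dataclass(frozen=True)
class Gene:
    """An oriented, named gene.

    ``orientation`` is +1 when the gene is transcribed in the reference
    direction of its chromosome, -1 otherwise.  Extant genes always have a
    known orientation.
    """

    name: str
    orientation: int

    def __post_init__(self) -> None:
        if self.orientation not in (1, -1):
            raise ValidationError(
                f"gene {self.name!r}: orientation must be +1 or -1, "
                f"got {self.orientation!r}"
            )


@dataclass
class Chromosome:
    """An ordered list of genes along the reference orientation."""

    name: str
    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)


@dataclass
class Genome:
    """A set of chromosomes of one species; gene names are genome-unique."""

    species: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for chrom in self.chromosomes:
            for g in chrom.genes:
                if g.name in seen:
                    raise ValidationError(
                        f"duplicate gene name {g.name!r} in genome "
                        f"{self.species!r}"
                    )
                seen.add(g.name)

    def __len__(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def gene_names(self) -> set[str]:
        return {g.name for c in self.chromosomes for g in c.genes}

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome {name!r} in genome {self.species!r}")


class FamilySet:
    """Bidirectional map between ancestral genes and their extant descendants.

    Each extant gene belongs to at most one family; lookup in either
    direction is O(1).
    """

    def __init__(self, families: Mapping[str, Iterable[str]]):
        self.families: dict[str, frozenset[str]] = {}
        self.reverse: dict[str, str] = {}
        for anc, members in families.items():
            members = frozenset(members)
            if not members:
                continue
            self.families[anc] = members
            for m in members:
                if m in self.reverse:
                    raise ValidationError(
                        f"extant gene {m!r} listed in two families "
                        f"({self.reverse[m]!r} and {anc!r})"
                    )
                self.reverse[m] = anc

    def family_of(self, gene_name: str) -> str | None:
        """Ancestral gene of ``gene_name``, or None for family-less genes."""
        return self.reverse.get(gene_name)

    def __len__(self) -> int:
        return len(self.families)

    def __contains__(self, anc: str) -> bool:
        return anc in self.families


# ---------------------------------------------------------------------------
# synteny block record types


@dataclass
class HpRecord:
    """One homology pack of a synteny block.

    ``x``/``y`` are tandem-block indices on chromosome A / B, ``sign`` is the
    product of the two tandem-block orientations (None when either is
    unknown), and ``ancestral_orientation`` is the inferred orientation of
    the last common ancestral gene (None when it cannot be inferred).
    """

    x: int
    y: int
    sign: int | None
    genes_a: tuple[str, ...]
    genes_b: tuple[str, ...]
    ancestral_gene: str
    ancestral_orientation: int | None = None


@dataclass
class SyntenyBlock:
    """A statistically validated consistent diagonal of homology packs.

    ``m`` is the number of hps, ``l_a``/``l_b`` the window lengths (bounding
    box spans in tandem blocks) on each chromosome, and ``max_gap`` the
    maximum Chebyshev gap between consecutive hps.
    """

    id: int
    chrom_a: str
    chrom_b: str
    diag_type: str  # "slash" | "backslash" | "undetermined"
    hps: list[HpRecord]
    p_value: float

    @property
    def m(self) -> int:
        return len(self.hps)

    @property
    def l_a(self) -> int:
        xs = [hp.x for hp in self.hps]
        return max(xs) - min(xs) + 1

    @property
    def l_b(self) -> int:
        ys = [hp.y for hp in self.hps]
        return max(ys) - min(ys) + 1

    @property
    def max_gap(self) -> int:
        """Max over consecutive hp pairs of (Chebyshev distance - 1)."""
        g = 0
        for h1, h2 in zip(self.hps, self.hps[1:]):
            cd = max(abs(h2.x - h1.x), abs(h2.y - h1.y))
            g = max(g, cd - 1)
        return g


# ---------------------------------------------------------------------------
# I/O


def _iter_data_lines(path) -> Iterator[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def parse_genome(path, species: str | None = None) -> Genome:
    """Read a 5-column genome TSV into a :class:`Genome`.

    Genes are grouped by chromosome and ordered by start coordinate (ties
    broken by end, then name), so unsorted input files are handled.
    """
    rows: dict[str, list[tuple[int, int, str, Gene]]] = {}
    order: list[str] = []
    for lineno, line in _iter_data_lines(path):
        parts = line.split("\t")
        if len(parts) != 5:
            raise GenomeParseError(
                f"{path}:{lineno}: expected 5 tab-separated columns, "
                f"got {len(parts)}"
            )
        chrom, start_s, end_s, strand_s, name = parts
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GenomeParseError(
                f"{path}:{lineno}: non-integer coordinates "
                f"{start_s!r}/{end_s!r}"
            ) from None
        if start < 0 or end <= start:
            raise GenomeParseError(
                f"{path}:{lineno}: require 0 <= start < end, "
                f"got {start}..{end}"
            )
        if strand_s not in ("1", "-1"):
            raise GenomeParseError(
                f"{path}:{lineno}: strand must be '1' or '-1', got {strand_s!r}"
            )
        if chrom not in rows:
            rows[chrom] = []
            order.append(chrom)
        rows[chrom].append((start, end, name, Gene(name, int(strand_s))))
    chromosomes = []
    for chrom in order:
        entries = sorted(rows[chrom], key=lambda r: (r[0], r[1], r[2]))
        chromosomes.append(Chromosome(chrom, [e[3] for e in entries]))
    if species is None:
        import os

        species = os.path.splitext(os.path.basename(str(path)))[0]
    return Genome(species, chromosomes)


def write_genome(genome: Genome, path) -> None:
    """Write a genome back to the 5-column TSV dialect.

    Synthetic coordinates are emitted from gene rank (1 kb slots) since the
    model stores order only.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in genome.chromosomes:
            for i, g in enumerate(chrom.genes):
                start = i * 1000
                fh.write(
                    f"{chrom.name}\t{start}\t{start + 500}\t"
                    f"{g.orientation}\t{g.name}\n"
                )


def parse_families(path, warn=None) -> FamilySet:
    """Read a family TSV (ancestral name + extant descendant names)."""
    fams: dict[str, list[str]] = {}
    for lineno, line in _iter_data_lines(path):
        parts = line.split()
        if len(parts) < 2:
            if warn is not None:
                warn(f"{path}:{lineno}: empty family line skipped")
            continue
        anc, members = parts[0], parts[1:]
        if anc in fams:
            raise ValidationError(
                f"{path}:{lineno}: ancestral gene {anc!r} listed twice"
            )
        fams[anc] = members
    return FamilySet(fams)


def write_families(fams: FamilySet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for anc in sorted(fams.families):
            members = " ".join(sorted(fams.families[anc]))
            fh.write(f"{anc}\t{members}\n")


def _fmt_sign(v: int | None) -> str:
    return UNKNOWN if v is None else str(v)


def _parse_sign(s: str) -> int | None:
    return None if s == UNKNOWN else int(s)


def write_synteny_blocks(blocks: list[SyntenyBlock], path) -> None:
    """Write blocks as TSV: one '#' header line per block, one row per hp.

    Header: ``# sb <id> <chromA> <chromB> <diagType> m=<m> la=<l_a> lb=<l_b>
    g=<g> pVal=<p>``.  Data row: sbId, chromA, tbIndexA, chromB, tbIndexB,
    sign, ancestralGene, ancestralOrientation, genesA, genesB.  Unknown
    values are rendered ``?``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "# sbId\tchromA\ttbIndexA\tchromB\ttbIndexB\tsign\t"
            "ancestralGene\tancestralOrientation\tgenesA\tgenesB\n"
        )
        for sb in blocks:
            fh.write(
                f"# sb {sb.id} {sb.chrom_a} {sb.chrom_b} {sb.diag_type} "
                f"m={sb.m} la={sb.l_a} lb={sb.l_b} g={sb.max_gap} "
                f"pVal={sb.p_value:.6g}\n"
            )
            for hp in sb.hps:
                fh.write(
                    f"{sb.id}\t{sb.chrom_a}\t{hp.x}\t{sb.chrom_b}\t{hp.y}\t"
                    f"{_fmt_sign(hp.sign)}\t{hp.ancestral_gene}\t"
                    f"{_fmt_sign(hp.ancestral_orientation)}\t"
                    f"{','.join(hp.genes_a)}\t{','.join(hp.genes_b)}\n"
                )


def read_synteny_blocks(path) -> list[SyntenyBlock]:
    """Re-read a synteny-block TSV written by :func:`write_synteny_blocks`.

    Block metadata (diag type, p-value) is recovered from the '#' headers;
    window statistics are recomputed from the hp coordinates.
    """
    meta: dict[int, tuple[str, float]] = {}
    rows: dict[int, list[tuple[str, str, HpRecord]]] = {}
    order: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["sb"]:
                    sb_id = int(parts[1])
                    diag_type = parts[4]
                    pval = float(parts[-1].split("=", 1)[1])
                    meta[sb_id] = (diag_type, pval)
                continue
            f = line.split("\t")
            sb_id = int(f[0])
            hp = HpRecord(
                x=int(f[2]),
                y=int(f[4]),
                sign=_parse_sign(f[5]),
                genes_a=tuple(f[8].split(",")) if f[8] else (),
                genes_b=tuple(f[9].split(",")) if f[9] else (),
                ancestral_gene=f[6],
                ancestral_orientation=_parse_sign(f[7]),
            )
            if sb_id not in rows:
                rows[sb_id] = []
                order.append(sb_id)
            rows[sb_id].append((f[1], f[3], hp))
    blocks = []
    for sb_id in order:
        chrom_a, chrom_b, _ = rows[sb_id][0]
        diag_type, pval = meta.get(sb_id, ("undetermined", float("nan")))
        blocks.append(
            SyntenyBlock(
                id=sb_id,
                chrom_a=chrom_a,
                chrom_b=chrom_b,
                diag_type=diag_type,
                hps=[r[2] for r in rows[sb_id]],
                p_value=pval,
            )
        )
    return blocks
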