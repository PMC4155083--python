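"""Genome evolution simulator, benchmark metrics, and the worked fixture.

The simulator draws an ancestral genome (a user-defined number of genes
randomly composed into chromosomes), then evolves it independently along
two branches.  Each branch applies a configured number of genic events
(de novo births, deletions, tandem and dispersed duplications) and
rearrangements (segmental inversions, reciprocal translocations, chromosome
fusions and fissions) in a uniformly random order at uniformly random
positions.  Segment lengths for inversions and translocated tails are
geometric (the minimal memoryless choice).  Every extant gene that is not a
de novo birth records its ancestral gene of origin, which yields the gene
families and the ground-truth ledger of ancestral adjacencies against which
detected synteny blocks are scored.

The default configuration ships human-mouse-like magnitudes (~20,000
ancestral genes on 20 chromosomes, a few hundred rearrangements per branch);
see docs/methods.md for the rationale behind each rate.

Scoring definitions (``benchmark_metrics``): *coverage* is the fraction of
ancestral genes conserved in both extant genomes that are contained in
blocks; *N50* is the smallest block length L such that blocks of length
>= L contain at least half of the ancestral genes contained in blocks;
*sensitivity* is correctly inferred ancestral adjacencies over ancestral
genes conserved in both (the denominator counts genes, not adjacencies —
kept as defined); *specificity* is correct inferred adjacencies over all
inferred adjacencies.  An inferred adjacency is correct when its two
ancestral genes are consecutive among the conserved genes of an ancestral
chromosome, and, in the orientation-aware variant, when its relative
orientation matches the ancestral one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core_model import (
    Chromosome,
    FamilySet,
    Gene,
    Genome,
    SyntenyBlock,
)

__all__ = [
    "EvolutionConfig",
    "SimulatedPair",
    "BenchmarkMetrics",
    "simulate_pair",
    "figure3_fixture",
    "benchmark_metrics",
    "canonical_adjacency",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Event counts per branch and ancestor dimensions.

    All counts are events per branch; ``*_len_mean`` are mean segment
    lengths in genes for the geometric length draws; ``p_tandem_inverted``
    is the probability that a tandem copy is inserted in inverted
    orientation.
    """

    n_genes: int = 20000
    n_chromosomes: int = 20
    births: int = 400
    deletions: int = 700
    tandem_dups: int = 800
    dispersed_dups: int = 100
    inversions: int = 250
    translocations: int = 25
    fusions: int = 3
    fissions: int = 4
    inv_len_mean: float = 5.0
    transloc_len_mean: float = 20.0
    p_tandem_inverted: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_chromosomes",
            "births",
            "deletions",
            "tandem_dups",
            "dispersed_dups",
            "inversions",
            "translocations",
            "fusions",
            "fissions",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_chromosomes > self.n_genes:
            raise ValueError("n_chromosomes cannot exceed n_genes")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")


@dataclass
class BenchmarkMetrics:
    coverage: float
    n50: int
    sensitivity: float
    specificity: float


@dataclass
class SimulatedPair:
    """Ancestor, two evolved genomes, families, and the truth ledger.

    ``truth`` lists canonical oriented ancestral adjacencies between
    consecutive conserved ancestral genes (genes with at least one
    descendant in each extant genome); ``event_log`` records every applied
    event as (branch, event, detail).
    """

    ancestor: Genome
    genome_a: Genome
    genome_b: Genome
    families: FamilySet
    truth: list[tuple[str, int, str, int]]
    event_log: list[tuple[str, str, str]]
    config: EvolutionConfig

    @property
    def truth_oriented(self) -> set[tuple[str, int, str, int]]:
        return set(self.truth)

    @property
    def truth_unoriented(self) -> set[tuple[str, str]]:
        return {tuple(sorted((t[0], t[2]))) for t in self.truth}

    @property
    def conserved_ancestral_genes(self) -> set[str]:
        out = set()
        for t in self.truth:
            out.add(t[0])
            out.add(t[2])
        return out


def canonical_adjacency(
    g1: str, o1: int | None, g2: str, o2: int | None
) -> tuple[str, int, str, int]:
    """Orientation-aware canonical form of an adjacency.

    Reading an adjacency from the other strand swaps the genes and flips
    both orientations; the lexicographically smaller reading is canonical.
    Unknown orientations are encoded 0 (0 == -0, so they stay unknown in
    either reading).
    """
    a = (g1, o1 or 0, g2, o2 or 0)
    b = (g2, -(o2 or 0), g1, -(o1 or 0))
    return min(a, b)


# ---------------------------------------------------------------------------
# simulation

# internal gene representation on an evolving chromosome: [origin, orientation]
# where origin is the ancestral gene name or None for a de novo birth


def _draw_ancestor(cfg: EvolutionConfig, rng: np.random.Generator):
    cuts = rng.choice(
        np.arange(1, cfg.n_genes), size=cfg.n_chromosomes - 1, replace=False
    )
    bounds = [0, *sorted(int(c) for c in cuts), cfg.n_genes]
    orients = rng.choice([1, -1], size=cfg.n_genes)
    chroms = []
    idx = 0
    for lo, hi in zip(bounds, bounds[1:]):
        genes = [
            [f"anc_g{idx + k:06d}", int(orients[idx + k])]
            for k in range(hi - lo)
        ]
        idx += hi - lo
        chroms.append(genes)
    return chroms


def _geometric_len(rng: np.random.Generator, mean: float) -> int:
    if mean <= 1.0:
        return 1
    return int(rng.geometric(1.0 / mean))


def _global_index(chroms, flat_idx: int) -> tuple[int, int]:
    for ci, genes in enumerate(chroms):
        if flat_idx < len(genes):
            return ci, flat_idx
        flat_idx -= len(genes)
    raise IndexError("flat index out of range")  # pragma: no cover


def _evolve_branch(
    chroms, cfg: EvolutionConfig, rng: np.random.Generator, branch: str, log
):
    events = (
        ["birth"] * cfg.births
        + ["deletion"] * cfg.deletions
        + ["tandem_dup"] * cfg.tandem_dups
        + ["dispersed_dup"] * cfg.dispersed_dups
        + ["inversion"] * cfg.inversions
        + ["translocation"] * cfg.translocations
        + ["fusion"] * cfg.fusions
        + ["fission"] * cfg.fissions
    )
    rng.shuffle(events)
    birth_counter = 0
    for ev in events:
        total = sum(len(c) for c in chroms)
        if ev == "birth":
            ci = int(rng.integers(len(chroms)))
            pos = int(rng.integers(len(chroms[ci]) + 1))
            chroms[ci].insert(
                pos, [None, int(rng.choice([1, -1]))]
            )
            log.append((branch, ev, f"chr{ci}:{pos}"))
            birth_counter += 1
        elif ev == "deletion":
            if total == 0:
                continue
            ci, gi = _global_index(chroms, int(rng.integers(total)))
            del chroms[ci][gi]
            if not chroms[ci] and len(chroms) > 1:
                del chroms[ci]
            log.append((branch, ev, f"chr{ci}:{gi}"))
        elif ev == "tandem_dup":
            if total == 0:
                continue
            ci, gi = _global_index(chroms, int(rng.integers(total)))
            origin, orient = chroms[ci][gi]
            if rng.random() < cfg.p_tandem_inverted:
                orient = -orient
            chroms[ci].insert(gi + 1, [origin, orient])
            log.append((branch, ev, f"chr{ci}:{gi}"))
        elif ev == "dispersed_dup":
            if total == 0:
                continue
            ci, gi = _global_index(chroms, int(rng.integers(total)))
            origin, _ = chroms[ci][gi]
            cj = int(rng.integers(len(chroms)))
            pos = int(rng.integers(len(chroms[cj]) + 1))
            chroms[cj].insert(pos, [origin, int(rng.choice([1, -1]))])
            log.append((branch, ev, f"chr{ci}:{gi}->chr{cj}:{pos}"))
        elif ev == "inversion":
            if total == 0:
                continue
            ci, gi = _global_index(chroms, int(rng.integers(total)))
            seg = min(_geometric_len(rng, cfg.inv_len_mean), len(chroms[ci]) - gi)
            segment = chroms[ci][gi : gi + seg]
            chroms[ci][gi : gi + seg] = [
                [o, -s] for o, s in reversed(segment)
            ]
            log.append((branch, ev, f"chr{ci}:{gi}+{seg}"))
        elif ev == "translocation":
            if len(chroms) < 2:
                continue
            ci, cj = rng.choice(len(chroms), size=2, replace=False)
            ci, cj = int(ci), int(cj)
            li = min(_geometric_len(rng, cfg.transloc_len_mean), len(chroms[ci]))
            lj = min(_geometric_len(rng, cfg.transloc_len_mean), len(chroms[cj]))
            tail_i = chroms[ci][len(chroms[ci]) - li :]
            tail_j = chroms[cj][len(chroms[cj]) - lj :]
            chroms[ci] = chroms[ci][: len(chroms[ci]) - li] + tail_j
            chroms[cj] = chroms[cj][: len(chroms[cj]) - lj] + tail_i
            log.append((branch, ev, f"chr{ci}~chr{cj}:{li}/{lj}"))
        elif ev == "fusion":
            if len(chroms) < 2:
                continue
            ci, cj = rng.choice(len(chroms), size=2, replace=False)
            ci, cj = int(ci), int(cj)
            other = chroms[cj]
            if rng.random() < 0.5:
                other = [[o, -s] for o, s in reversed(other)]
            chroms[ci] = chroms[ci] + other
            del chroms[cj]
            log.append((branch, ev, f"chr{ci}+chr{cj}"))
        elif ev == "fission":
            candidates = [i for i, c in enumerate(chroms) if len(c) >= 2]
            if not candidates:
                continue
            ci = int(rng.choice(candidates))
            pos = int(rng.integers(1, len(chroms[ci])))
            chroms.append(chroms[ci][pos:])
            chroms[ci] = chroms[ci][:pos]
            log.append((branch, ev, f"chr{ci}:{pos}"))
    return chroms


def _to_genome(chroms, species: str) -> tuple[Genome, dict[str, str]]:
    """Materialise evolving chromosomes as a Genome; map gene -> origin."""
    out = []
    origin_of: dict[str, str] = {}
    counter = 0
    for ci, genes in enumerate(chroms):
        if not genes:
            continue
        gl = []
        for origin, orient in genes:
            name = f"{species}_g{counter:06d}"
            counter += 1
            if origin is not None:
                origin_of[name] = origin
            gl.append(Gene(name, orient))
        out.append(Chromosome(f"{species}_{ci + 1}", gl))
    return Genome(species, out), origin_of


def simulate_pair(
    cfg: EvolutionConfig | None = None,
    cfg_b: EvolutionConfig | None = None,
) -> SimulatedPair:
    """Simulate an ancestor and two independently evolved descendants.

    Deterministic for a fixed config (the seed is part of the config).
    ``cfg_b``, when given, supplies the event counts of the second branch
    (asymmetric evolution, e.g. a single inversion on one branch only);
    the ancestor dimensions and seed always come from ``cfg``.
    """
    cfg = cfg or EvolutionConfig()
    rng = np.random.default_rng(cfg.seed)
    anc_chroms = _draw_ancestor(cfg, rng)
    ancestor_genome = Genome(
        "anc",
        [
            Chromosome(f"anc_{ci + 1}", [Gene(n, o) for n, o in genes])
            for ci, genes in enumerate(anc_chroms)
        ],
    )
    log: list[tuple[str, str, str]] = []
    evolved = {}
    origins = {}
    for species, branch_cfg in (("A", cfg), ("B", cfg_b or cfg)):
        branch_chroms = [list(map(list, c)) for c in anc_chroms]
        branch_chroms = _evolve_branch(
            branch_chroms, branch_cfg, rng, species, log
        )
        genome, origin_of = _to_genome(branch_chroms, species)
        evolved[species] = genome
        origins[species] = origin_of

    families: dict[str, set[str]] = {}
    for species in ("A", "B"):
        for extant, anc in origins[species].items():
            families.setdefault(anc, set()).add(extant)
    fams = FamilySet(families)

    conserved = {
        anc
        for anc, members in families.items()
        if any(m in origins["A"] for m in members)
        and any(m in origins["B"] for m in members)
    }
    truth = []
    for chrom in ancestor_genome.chromosomes:
        kept = [g for g in chrom.genes if g.name in conserved]
        for g1, g2 in zip(kept, kept[1:]):
            truth.append(
                canonical_adjacency(
                    g1.name, g1.orientation, g2.name, g2.orientation
                )
            )
    return SimulatedPair(
        ancestor=ancestor_genome,
        genome_a=evolved["A"],
        genome_b=evolved["B"],
        families=fams,
        truth=truth,
        event_log=log,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# benchmark metrics


def inferred_adjacencies(
    blocks: list[SyntenyBlock],
) -> set[tuple[str, int, str, int]]:
    """Canonical oriented adjacencies between consecutive hps of each block."""
    out = set()
    for sb in blocks:
        for h1, h2 in zip(sb.hps, sb.hps[1:]):
            out.add(
                canonical_adjacency(
                    h1.ancestral_gene,
                    h1.ancestral_orientation,
                    h2.ancestral_gene,
                    h2.ancestral_orientation,
                )
            )
    return out


def benchmark_metrics(
    blocks: list[SyntenyBlock],
    pair: SimulatedPair,
    min_hps: int = 3,
    with_orientations: bool = False,
) -> BenchmarkMetrics:
    """Score detected blocks against the simulated ground truth."""
    if not pair.truth:
        raise ValueError("empty truth ledger: nothing to score against")
    blocks = [b for b in blocks if b.m >= min_hps]
    conserved = pair.conserved_ancestral_genes
    covered = {hp.ancestral_gene for b in blocks for hp in b.hps}
    coverage = len(covered & conserved) / len(conserved)

    lengths = sorted((b.m for b in blocks), reverse=True)
    total_in_blocks = sum(lengths)
    n50 = 0
    acc = 0
    for ln in lengths:
        acc += ln
        if 2 * acc >= total_in_blocks:
            n50 = ln
            break

    inferred = inferred_adjacencies(blocks)
    if with_orientations:
        correct = len(inferred & pair.truth_oriented)
    else:
        inferred_unoriented = {tuple(sorted((t[0], t[2]))) for t in inferred}
        correct = len(inferred_unoriented & pair.truth_unoriented)
        inferred = inferred_unoriented
    sensitivity = correct / len(conserved)
    specificity = correct / len(inferred) if inferred else 0.0
    return BenchmarkMetrics(
        coverage=coverage,
        n50=n50,
        sensitivity=sensitivity,
        specificity=specificity,
    )


def write_truth(pair: SimulatedPair, path) -> None:
    """Truth ledger TSV: ancGene1, ancGene2, relOrientation (o1/o2)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ancGene1\tancGene2\trelOrientation\n")
        for g1, o1, g2, o2 in pair.truth:
            fh.write(f"{g1}\t{g2}\t{o1}/{o2}\n")


def write_event_log(pair: SimulatedPair, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# branch\tevent\tdetail\n")
        for branch, ev, detail in pair.event_log:
            fh.write(f"{branch}\t{ev}\t{detail}\n")


def config_from_yaml(path) -> EvolutionConfig:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = set(asdict(EvolutionConfig()).keys())
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return EvolutionConfig(**data)


# ---------------------------------------------------------------------------
# the worked dot-plot fixture


def figure3_fixture() -> tuple[Genome, Genome, FamilySet]:
    """Deterministic two-chromosome pair with a known MHP.

    Chromosome a rewrites to 11 tandem blocks (one of size 2, one of mixed
    orientation), chromosome b to 8; the MHP holds 6 hps: backslash runs at
    (4,6),(5,5) and (8,4),(9,3), plus +1 singles at (0,1) and (2,6).  One
    family recurs at two non-adjacent positions on chromosome a (dispersed
    paralogs), which is what puts two hps in row y=6.
    """
    # (family, [(name, orientation), ...]) per tandem block, chromosome a
    layout_a = [
        ("F01", [("a0", 1)]),
        ("fillA1", [("a1", 1)]),
        ("FX", [("a2", 1)]),
        ("fillA3", [("a3", -1)]),
        ("FX2", [("a4", -1)]),
        ("F55", [("a5", -1)]),
        ("F66", [("a6a", 1), ("a6b", -1)]),
        ("fillA7", [("a7", 1)]),
        ("F84", [("a8a", -1), ("a8b", -1)]),
        ("F93", [("a9", -1)]),
        ("fillA10", [("a10", 1)]),
    ]
    layout_b = [
        ("fillB0", [("b0", 1)]),
        ("F01", [("b1", 1)]),
        ("fillB2", [("b2", -1)]),
        ("F93", [("b3", 1)]),
        ("F84", [("b4", 1)]),
        ("F55", [("b5", 1)]),
        ("FX", [("b6", 1)]),
        ("fillB7", [("b7", 1)]),
    ]
    # the dispersed paralog: tbs 2 and 4 of chromosome a share one family
    families: dict[str, set[str]] = {}
    genes_a = []
    for fam, members in layout_a:
        fam = "FX" if fam == "FX2" else fam
        for name, orient in members:
            genes_a.append(Gene(name, orient))
            families.setdefault(fam, set()).add(name)
    genes_b = []
    for fam, members in layout_b:
        for name, orient in members:
            genes_b.append(Gene(name, orient))
            families.setdefault(fam, set()).add(name)
    ga = Genome("a", [Chromosome("ca", genes_a)])
    gb = Genome("b", [Chromosome("cb", genes_b)])
    return ga, gb, FamilySet(families)
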