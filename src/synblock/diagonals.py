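"""Diagonal extraction, gap-tolerant merging, and synteny block assembly.

A synteny block conserved since the last common ancestor appears in the
matrix of homology packs as a *consistent diagonal*: a chain of cells that
is strictly monotone in both coordinates — ascending ("slash") or
descending ("backslash") — whose signs agree with the direction (+1 or
unknown for slash, -1 or unknown for backslash).

Extraction proceeds in two stages.  First, *strict* diagonals (no gaps:
consecutive cells offset by (+1, +/-1)) are consumed greedily while scanning
the matrix left to right and bottom to top.  Second, diagonals of the same
type are merged iteratively from the shortest inter-diagonal distance up to
``gap_max + 1``, under one of four 2D metrics:

* CD  (Chebyshev)            max(|dx|, |dy|)
* MD  (Manhattan)            |dx| + |dy|
* ED  (Euclidean, integer)   round(sqrt(dx^2 + dy^2))
* DPD (Diagonal Pseudo Dist) 2*max(|dx|, |dy|) - min(|dx|, |dy|)

The distance between two diagonals is the distance between their closest
directionally compatible extremities; a fusion is performed only when every
hp sign is consistent with the resulting diagonal type and the merged chain
stays strictly monotone.  Ties at equal distance are resolved by maximising
the hp count of the fusion result (then by leftmost coordinates, for
determinism).  The greedy order may return non-maximum blocks; no global
optimisation is attempted.

The ancestral gene order inside a block is read along chromosome A, and the
ancestral gene orientation is o(tb_a) when known, else inferred from the
diagonal type and o(tb_b) (slash: o(tb_b); backslash: -o(tb_b)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core_model import FamilySet, Genome, HpRecord, SyntenyBlock
from .filtering import FilterMode, filter_genomes
from .tandem_mhp import MHP, TbChromosome, build_mhp, rewrite_genome

__all__ = [
    "METRICS",
    "distance",
    "Diagonal",
    "find_diag_type",
    "extract_strict_diagonals",
    "merge_diagonals",
    "diagonal_distance",
    "infer_ancestral_orientation",
    "extract_sbs",
    "detect_synteny_blocks",
]

SLASH = "slash"
BACKSLASH = "backslash"
UNDETERMINED = "undetermined"

METRICS = ("CD", "MD", "ED", "DPD")


def distance(metric: str, p1: tuple[int, int], p2: tuple[int, int]) -> int:
    """2D distance between two MHP cells under the chosen metric."""
    dx = abs(p1[0] - p2[0])
    dy = abs(p1[1] - p2[1])
    if metric == "CD":
        return max(dx, dy)
    if metric == "MD":
        return dx + dy
    if metric == "ED":
        return int(math.sqrt(dx * dx + dy * dy) + 0.5)
    if metric == "DPD":
        return 2 * max(dx, dy) - min(dx, dy)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


@dataclass
class Diagonal:
    """A (possibly gapped) consistent diagonal: hps ordered by increasing x."""

    diag_type: str
    hps: list[tuple[int, int, int | None]] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.hps)

    def first(self) -> tuple[int, int]:
        return self.hps[0][:2]

    def last(self) -> tuple[int, int]:
        return self.hps[-1][:2]


def _sign_ok(sign: int | None, diag_type: str) -> bool:
    if sign is None:
        return True
    return sign == (1 if diag_type == SLASH else -1)


def find_diag_type(
    first_sign: int | None, second_delta: tuple[int, int] | None
) -> str:
    """Diagonal type from the first hp sign, else from the second hp position."""
    if first_sign == 1:
        return SLASH
    if first_sign == -1:
        return BACKSLASH
    if second_delta == (1, 1):
        return SLASH
    if second_delta == (1, -1):
        return BACKSLASH
    return UNDETERMINED


def extract_strict_diagonals(mhp: MHP) -> list[Diagonal]:
    """Greedy consumption of strict consistent diagonals.

    The matrix is scanned with x ascending then y ascending; from each
    unconsumed hp the type is fixed (sign, else position of the next strict
    neighbour) and the diagonal is extended stepwise to (x+1, y+/-1) while a
    sign-consistent unconsumed hp exists.  Every hp ends up in exactly one
    diagonal; isolated hps with unknown sign give 1-hp undetermined
    diagonals.
    """
    cells = mhp.cells
    consumed: set[tuple[int, int]] = set()
    out: list[Diagonal] = []
    for start in sorted(cells):
        if start in consumed:
            continue
        sign = cells[start]
        dtype = find_diag_type(sign, None)
        if dtype == UNDETERMINED:
            # unknown sign: type from the position of a strict neighbour
            for dy in (1, -1):
                nxt = (start[0] + 1, start[1] + dy)
                if nxt in cells and nxt not in consumed:
                    dtype = SLASH if dy == 1 else BACKSLASH
                    break
        consumed.add(start)
        hps = [(start[0], start[1], sign)]
        if dtype != UNDETERMINED:
            step = 1 if dtype == SLASH else -1
            cur = start
            while True:
                nxt = (cur[0] + 1, cur[1] + step)
                if (
                    nxt in cells
                    and nxt not in consumed
                    and _sign_ok(cells[nxt], dtype)
                ):
                    consumed.add(nxt)
                    hps.append((nxt[0], nxt[1], cells[nxt]))
                    cur = nxt
                else:
                    break
        out.append(Diagonal(dtype, hps))
    return out


# ---------------------------------------------------------------------------
# merging


def _pair_type(d1: Diagonal, d2: Diagonal) -> str | None:
    """Resulting type of a fusion, ignoring sign consistency for now.

    Multi-hp diagonals impose their type; 1-hp diagonals are flexible (their
    provisional type is only their sign, which is re-checked at fusion
    time).  Returns None when the two types cannot be reconciled;
    UNDETERMINED when only the relative position can decide.
    """
    t1 = d1.diag_type if d1.m > 1 else UNDETERMINED
    t2 = d2.diag_type if d2.m > 1 else UNDETERMINED
    if t1 == UNDETERMINED:
        return t2
    if t2 == UNDETERMINED or t1 == t2:
        return t1
    return None


def _extremity_compatible(
    e1: tuple[int, int], e2: tuple[int, int], dtype: str
) -> str | None:
    """Type implied by placing extremity e1 strictly before e2, or None."""
    if e2[0] <= e1[0]:
        return None
    if e2[1] > e1[1]:
        implied = SLASH
    elif e2[1] < e1[1]:
        implied = BACKSLASH
    else:
        return None  # equal y: not strictly monotone in both coordinates
    if dtype in (UNDETERMINED, implied):
        return implied
    return None


def diagonal_distance(
    d1: Diagonal, d2: Diagonal, metric: str
) -> tuple[int, str] | None:
    """Min distance over directionally compatible extremity pairs.

    Returns (distance, resulting type) or None when no extremity pairing is
    compatible.  The fusion itself may still fail sign or monotonicity
    checks (see :func:`_try_fuse`).
    """
    dtype = _pair_type(d1, d2)
    if dtype is None:
        return None
    best: tuple[int, str] | None = None
    for da, db in ((d1, d2), (d2, d1)):
        for e1 in {da.first(), da.last()}:
            for e2 in {db.first(), db.last()}:
                implied = _extremity_compatible(e1, e2, dtype)
                if implied is None:
                    continue
                d = distance(metric, e1, e2)
                if best is None or d < best[0]:
                    best = (d, implied if dtype == UNDETERMINED else dtype)
    return best


def _try_fuse(d1: Diagonal, d2: Diagonal, dtype: str) -> Diagonal | None:
    """Fuse two diagonals if signs and strict monotonicity allow it."""
    hps = sorted(d1.hps + d2.hps)
    if any(not _sign_ok(h[2], dtype) for h in hps):
        return None
    step = 1 if dtype == SLASH else -1
    for (x1, y1, _), (x2, y2, _) in zip(hps, hps[1:]):
        if x2 <= x1 or (y2 - y1) * step <= 0:
            return None
    return Diagonal(dtype, hps)


def merge_diagonals(
    diags: list[Diagonal], metric: str, gap_max: int
) -> list[Diagonal]:
    """Iteratively merge diagonals from distance 2 up to ``gap_max + 1``.

    At each distance, candidate pairs are fused greedily, preferring fusions
    that maximise the resulting hp count, then leftmost coordinates.  A
    candidate whose fusion would break sign consistency or monotonicity is
    discarded (the distance-5 rejection of the +1 single hp in a backslash
    neighbourhood is the canonical example).
    """
    if gap_max <= 0 or len(diags) < 2:
        return list(diags)
    work: dict[int, Diagonal] = {i: d for i, d in enumerate(diags)}
    next_id = len(diags)
    # candidate distances, recomputed incrementally after each fusion
    cand: dict[tuple[int, int], tuple[int, str]] = {}

    def pair_key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def refresh(i: int) -> None:
        for j in work:
            if j == i:
                continue
            r = diagonal_distance(work[i], work[j], metric)
            key = pair_key(i, j)
            if r is not None and r[0] <= gap_max + 1:
                cand[key] = r
            else:
                cand.pop(key, None)

    ids = list(work)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            r = diagonal_distance(work[ids[a]], work[ids[b]], metric)
            if r is not None and r[0] <= gap_max + 1:
                cand[(ids[a], ids[b])] = r

    for d in range(2, gap_max + 2):
        while True:
            best = None  # (-(m), x keys..., i, j, fused)
            for (i, j), (dist, dtype) in list(cand.items()):
                if dist != d:
                    continue
                fused = _try_fuse(work[i], work[j], dtype)
                if fused is None:
                    del cand[(i, j)]  # can never become valid again
                    continue
                key = (
                    -fused.m,
                    min(work[i].first()[0], work[j].first()[0]),
                    max(work[i].first()[0], work[j].first()[0]),
                    min(work[i].first()[1], work[j].first()[1]),
                )
                if best is None or key < best[0]:
                    best = (key, i, j, fused)
            if best is None:
                break
            _, i, j, fused = best
            for k in (i, j):
                del work[k]
            cand = {
                key: v for key, v in cand.items() if i not in key and j not in key
            }
            work[next_id] = fused
            refresh(next_id)
            next_id += 1
    return [work[i] for i in sorted(work)]


# ---------------------------------------------------------------------------
# ancestral orientation and block assembly


def infer_ancestral_orientation(
    diag_type: str, o_tb_a: int | None, o_tb_b: int | None
) -> int | None:
    """Orientation of the last common ancestral gene of an hp."""
    if o_tb_a is not None:
        return o_tb_a
    if o_tb_b is not None:
        if diag_type == SLASH:
            return o_tb_b
        if diag_type == BACKSLASH:
            return -o_tb_b
    return None


def _empirical_sign_probs(
    cell_iter,
) -> tuple[float, float, float]:
    n_plus = n_minus = n_unk = 0
    for sign in cell_iter:
        if sign == 1:
            n_plus += 1
        elif sign == -1:
            n_minus += 1
        else:
            n_unk += 1
    total = n_plus + n_minus + n_unk
    if total == 0:
        return (1 / 3, 1 / 3, 1 / 3)
    return (n_plus / total, n_minus / total, n_unk / total)


def _blocks_from_diagonals(
    validated,
    mhp: MHP,
    id_start: int,
) -> list[SyntenyBlock]:
    blocks = []
    for sb_id, (diag, pval) in enumerate(validated, start=id_start):
        hps = []
        for x, y, sign in diag.hps:
            tba = mhp.chrom_a.tbs[x]
            tbb = mhp.chrom_b.tbs[y]
            hps.append(
                HpRecord(
                    x=x,
                    y=y,
                    sign=sign,
                    genes_a=tuple(g.name for g in tba.genes),
                    genes_b=tuple(g.name for g in tbb.genes),
                    ancestral_gene=tba.family,
                    ancestral_orientation=infer_ancestral_orientation(
                        diag.diag_type, tba.orientation, tbb.orientation
                    ),
                )
            )
        blocks.append(
            SyntenyBlock(
                id=sb_id,
                chrom_a=mhp.chrom_a.name,
                chrom_b=mhp.chrom_b.name,
                diag_type=diag.diag_type,
                hps=hps,
                p_value=pval,
            )
        )
    return blocks


def extract_sbs(
    ca: TbChromosome,
    cb: TbChromosome,
    metric: str = "MD",
    gap_max: int = 5,
    alpha: float = 1e-3,
    sign_probs: tuple[float, float, float] | None = None,
    min_sb_hps: int = 1,
    id_start: int = 0,
) -> list[SyntenyBlock]:
    """Full chain for one chromosome pair: MHP, extraction, merge, p-value.

    ``sign_probs`` defaults to the empirical sign frequencies of this MHP;
    the genome-level driver passes the genome-wide frequencies instead.
    """
    mhp = build_mhp(ca, cb)
    return _extract_from_mhp(
        mhp,
        metric=metric,
        gap_max=gap_max,
        alpha=alpha,
        sign_probs=sign_probs,
        min_sb_hps=min_sb_hps,
        id_start=id_start,
    )


def _extract_from_mhp(
    mhp: MHP,
    metric: str,
    gap_max: int,
    alpha: float,
    sign_probs: tuple[float, float, float] | None,
    min_sb_hps: int,
    id_start: int,
) -> list[SyntenyBlock]:
    from .stats import PvalContext, validate_diagonals

    if not mhp.cells:
        return []
    strict = extract_strict_diagonals(mhp)
    merged = merge_diagonals(strict, metric, gap_max)
    if sign_probs is None:
        sign_probs = _empirical_sign_probs(mhp.cells.values())
    ctx = PvalContext(
        n_a=mhp.n_a, n_b=mhp.n_b, n_ab=mhp.n_ab, sign_probs=sign_probs
    )
    validated = validate_diagonals(merged, ctx, alpha, min_sb_hps=min_sb_hps)
    return _blocks_from_diagonals(validated, mhp, id_start)


def detect_synteny_blocks(
    ga: Genome,
    gb: Genome,
    fams: FamilySet,
    metric: str = "MD",
    gap_max: int | str = 5,
    alpha: float = 1e-3,
    filter_mode: FilterMode = FilterMode.IN_COMMON_ANCESTOR,
    min_sb_hps: int = 1,
) -> list[SyntenyBlock]:
    """Detect synteny blocks over every chromosome pair of two genomes.

    Chromosome pairs are independent comparisons; the hp sign probabilities
    of the statistical model are pooled over the whole genome comparison,
    which is stabler than per-pair frequencies for sparse pairs.
    ``gap_max='auto'`` routes through :func:`synblock.stats.recommend_gapmax`.
    """
    ga, gb = filter_genomes(ga, gb, fams, filter_mode)
    tbs_a = rewrite_genome(ga, fams)
    tbs_b = rewrite_genome(gb, fams)
    if gap_max == "auto":
        from .stats import recommend_gapmax

        gap_max, _ = recommend_gapmax(ga, gb, fams, alpha=alpha)
    gap_max = int(gap_max)
    mhps = [
        (ca, cb, build_mhp(ca, cb)) for ca in tbs_a for cb in tbs_b
    ]
    sign_probs = _empirical_sign_probs(
        s for _, _, mhp in mhps for s in mhp.cells.values()
    )
    blocks: list[SyntenyBlock] = []
    for _, _, mhp in mhps:
        if not mhp.cells:
            continue
        blocks.extend(
            _extract_from_mhp(
                mhp,
                metric=metric,
                gap_max=gap_max,
                alpha=alpha,
                sign_probs=sign_probs,
                min_sb_hps=min_sb_hps,
                id_start=len(blocks),
            )
        )
    return blocks
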