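"""Statistical validation of consistent diagonals.

Under the null hypothesis, the hps of an MHP are placed at random, with no
preferred order, spacing or signs.  The probability that a diagonal as
extreme as an observed one (m hps in an l_a x l_b window, maximum Chebyshev
gap g) arises by chance in the comparison of two chromosomes of n_a and n_b
tandem blocks with n_ab hps decomposes into:

* a density term  p_d(k)      — probability that exactly k of the n_ab hps
  fall in the window (binomial: each hp lies in the window independently
  with probability (l_a*l_b)/(n_a*n_b); dispersed paralogy is ignored);
* a gap term      p_g2d(k, g) — probability that k hps in the window chain
  with Chebyshev gaps <= g; for monotone chains the Chebyshev condition
  holds iff both axis projections are 1D max-gap chains, so this is the
  product of two 1D chain probabilities (exact combinatorics, computed by
  dynamic programming over subset placements, edge effects included);
* an order/orientation term p_oo(k) — probability that the k hps are
  mutually ordered as a monotone chain with direction-consistent signs:
  (1/k!) * [(P(+1)+P(unknown))^k + (P(-1)+P(unknown))^k], capped at 1.

Summing p_d * p_g2d * p_oo over k >= m gives the window probability p_w;
the chromosome-wide p-value accounts for the floor(n_a/l_a)*floor(n_b/l_b)
non-overlapping window placements:  pVal = 1 - (1 - p_w)^Nw.

All gaps entering the p-value are Chebyshev gaps regardless of the merge
metric, which keeps the statistical definition of a block method
independent.  A diagonal is validated as a synteny block when
pVal <= alpha (default 1e-3); 2-hp and even 1-hp diagonals go through the
same formulas (p_oo(1) = 1) and are simply, in practice, almost never
significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binom

from .core_model import FamilySet, Genome

__all__ = [
    "PvalContext",
    "DiagonalStats",
    "p_chain_1d",
    "chain_count_1d",
    "p_density",
    "p_gap_2d",
    "p_order_orientation",
    "p_window",
    "p_value",
    "validate_diagonals",
    "recommend_gapmax",
]

# terms with p_d * p_oo below this bound are dropped from the p_w sum; the
# 1/k! decay of p_oo makes the neglected tail < 1e-28 in total
_TERM_EPS = 1e-30


@dataclass(frozen=True)
class PvalContext:
    """Null-model context of one chromosome-pair comparison.

    ``sign_probs`` is (P(+1), P(-1), P(unknown)), normally the empirical hp
    sign frequencies pooled over the whole genome comparison.
    """

    n_a: int
    n_b: int
    n_ab: int
    sign_probs: tuple[float, float, float] = (0.5, 0.5, 0.0)

    def __post_init__(self) -> None:
        if self.n_ab > self.n_a * self.n_b:
            raise ValueError("n_ab cannot exceed n_a * n_b")
        if abs(sum(self.sign_probs) - 1.0) > 1e-9:
            raise ValueError("sign probabilities must sum to 1")


@dataclass(frozen=True)
class DiagonalStats:
    """Summary of one diagonal: hp count, max Chebyshev gap, window spans."""

    m: int
    g: int
    l_a: int
    l_b: int

    def __post_init__(self) -> None:
        if self.m < 1 or self.g < 0:
            raise ValueError("require m >= 1 and g >= 0")
        if self.m > min(self.l_a, self.l_b):
            raise ValueError("a monotone chain of m hps needs windows >= m")


def chain_count_1d(k: int, g: int, l: int) -> int:
    """Number of k-subsets of {1..l} whose sorted gaps are all <= g.

    (Consecutive elements differ by at most g+1.)  Dynamic programming over
    (last position, marks placed), linear in l per mark via a sliding
    window; exact integer arithmetic.
    """
    if k < 1 or k > l:
        raise ValueError(f"require 1 <= k <= l, got k={k}, l={l}")
    if k == 1:
        return l
    step = g + 1
    f = [1] * (l + 1)  # f[j] = chains of c marks ending at j; c = 1 here
    f[0] = 0
    for _ in range(2, k + 1):
        nf = [0] * (l + 1)
        window = 0
        for j in range(1, l + 1):
            window += f[j - 1]
            if j - step - 1 >= 0:
                window -= f[j - step - 1]
            nf[j] = window
        f = nf
    return sum(f)


def p_chain_1d(k: int, g: int, l: int) -> float:
    """P(k marked positions among l form a chain with gaps <= g)."""
    return chain_count_1d(k, g, l) / math.comb(l, k)


def p_density(k: int, l_a: int, l_b: int, ctx: PvalContext) -> float:
    """P(exactly k of the n_ab hps lie in an l_a x l_b window)."""
    q = (l_a * l_b) / (ctx.n_a * ctx.n_b)
    return float(binom.pmf(k, ctx.n_ab, q))


def p_gap_2d(k: int, g: int, l_a: int, l_b: int) -> float:
    """P(k hps in the window chain with Chebyshev gaps <= g | k present)."""
    if k == 1:
        return 1.0
    return p_chain_1d(k, g, l_a) * p_chain_1d(k, g, l_b)


def p_order_orientation(k: int, ctx: PvalContext) -> float:
    """P(k hps form a consistent slash or backslash diagonal).

    1/k! for a common order on both chromosomes, times the probability that
    all signs are consistent with the direction; both directions summed.
    """
    if k == 1:
        return 1.0
    p_plus, p_minus, p_unk = ctx.sign_probs
    log_fact = math.lgamma(k + 1)
    total = 0.0
    for base in (p_plus + p_unk, p_minus + p_unk):
        if base > 0.0:
            total += math.exp(k * math.log(base) - log_fact)
    return min(1.0, total)


def p_window(
    m: int, g: int, l_a: int, l_b: int, ctx: PvalContext
) -> float:
    """P(an l_a x l_b window holds a consistent diagonal of >= m hps, gaps <= g)."""
    if m < 1:
        raise ValueError("require m >= 1")
    k_max = min(ctx.n_ab, l_a, l_b)
    total = 0.0
    for k in range(m, k_max + 1):
        bound = p_density(k, l_a, l_b, ctx) * p_order_orientation(k, ctx)
        if bound < _TERM_EPS:
            continue
        total += bound * p_gap_2d(k, g, l_a, l_b)
    return min(1.0, max(0.0, total))


def p_value(stats: DiagonalStats, ctx: PvalContext) -> float:
    """Chromosome-wide p-value: 1 - (1 - p_w)^Nw over non-overlapping windows."""
    if stats.l_a > ctx.n_a or stats.l_b > ctx.n_b:
        raise ValueError("window exceeds chromosome dimensions")
    pw = p_window(stats.m, stats.g, stats.l_a, stats.l_b, ctx)
    n_windows = (ctx.n_a // stats.l_a) * (ctx.n_b // stats.l_b)
    if pw >= 1.0:
        return 1.0
    return -math.expm1(n_windows * math.log1p(-pw))


def diagonal_stats(diag) -> DiagonalStats:
    """(m, g, l_a, l_b) of a diagonal; g is the max Chebyshev gap."""
    xs = [h[0] for h in diag.hps]
    ys = [h[1] for h in diag.hps]
    g = 0
    for (x1, y1, _), (x2, y2, _) in zip(diag.hps, diag.hps[1:]):
        g = max(g, max(abs(x2 - x1), abs(y2 - y1)) - 1)
    return DiagonalStats(
        m=len(diag.hps),
        g=g,
        l_a=max(xs) - min(xs) + 1,
        l_b=max(ys) - min(ys) + 1,
    )


def validate_diagonals(
    diags,
    ctx: PvalContext,
    alpha: float,
    min_sb_hps: int = 1,
) -> list[tuple[object, float]]:
    """Keep diagonals whose p-value is <= alpha (inclusive).

    Returns (diagonal, p-value) pairs; blocks of 2 hps (or even 1) are
    eligible whenever they pass the threshold.
    """
    kept = []
    for diag in diags:
        if len(diag.hps) < min_sb_hps:
            continue
        pv = p_value(diagonal_stats(diag), ctx)
        if pv <= alpha:
            kept.append((diag, pv))
    return kept


def representative_context(
    ga: Genome, gb: Genome, fams: FamilySet
) -> PvalContext:
    """Genome-representative null context for the gap_max recommendation.

    Chromosome lengths (in tbs) enter as length-weighted means — a random
    hp falls on a chromosome with probability proportional to its length —
    and the hp count is the genome-wide mean density scaled to the
    representative matrix size.
    """
    from .diagonals import _empirical_sign_probs
    from .tandem_mhp import rewrite_genome

    tbs_a = rewrite_genome(ga, fams)
    tbs_b = rewrite_genome(gb, fams)
    if not tbs_a or not tbs_b:
        raise ValueError("cannot recommend gap_max for an empty genome")

    def weighted_mean(tb_chroms) -> float:
        lens = [len(c) for c in tb_chroms]
        return sum(x * x for x in lens) / sum(lens)

    fam_count_a: dict[str, int] = {}
    fam_count_b: dict[str, int] = {}
    for chroms, counts in ((tbs_a, fam_count_a), (tbs_b, fam_count_b)):
        for c in chroms:
            for tb in c.tbs:
                counts[tb.family] = counts.get(tb.family, 0) + 1
    total_hps = sum(
        n * fam_count_b.get(f, 0) for f, n in fam_count_a.items()
    )
    len_a = sum(len(c) for c in tbs_a)
    len_b = sum(len(c) for c in tbs_b)
    density = total_hps / (len_a * len_b)
    n_a = max(1, round(weighted_mean(tbs_a)))
    n_b = max(1, round(weighted_mean(tbs_b)))
    n_ab = min(n_a * n_b, max(0, round(density * n_a * n_b)))
    # sign probabilities: pooled over all hps of the genome comparison,
    # via the orientation products of homologous tb occurrence pairs
    sign_list: list[int | None] = []
    ors_a: dict[str, list[int | None]] = {}
    ors_b: dict[str, list[int | None]] = {}
    for chroms, ors in ((tbs_a, ors_a), (tbs_b, ors_b)):
        for c in chroms:
            for tb in c.tbs:
                ors.setdefault(tb.family, []).append(tb.orientation)
    for f, la in ors_a.items():
        lb = ors_b.get(f)
        if not lb:
            continue
        for oa in la:
            for ob in lb:
                sign_list.append(
                    None if oa is None or ob is None else oa * ob
                )
    probs = _empirical_sign_probs(sign_list)
    return PvalContext(n_a=n_a, n_b=n_b, n_ab=n_ab, sign_probs=probs)


def recommend_gapmax(
    ga: Genome,
    gb: Genome,
    fams: FamilySet,
    alpha: float = 1e-3,
    max_search: int = 20,
) -> tuple[int, list[tuple[int, float]]]:
    """Largest gap g for which a minimal 2-hp diagonal spaced by g is significant.

    Uses the dependency between the p-value of a diagonal of 2 hps spaced by
    a gap g (window (2+g) x (2+g)) and g, in a genome-representative null
    context.  Returns (recommended gap_max, [(g, pVal)] curve); 0 when no
    gap qualifies.  The search stops at ``max_search``, beyond which the
    synteny block definition loses meaning at mammalian densities.
    """
    ctx = representative_context(ga, gb, fams)
    return _recommend_from_ctx(ctx, alpha, max_search)


def _recommend_from_ctx(
    ctx: PvalContext, alpha: float, max_search: int = 20
) -> tuple[int, list[tuple[int, float]]]:
    curve: list[tuple[int, float]] = []
    best = 0
    if ctx.n_ab < 2:
        return 0, curve
    for g in range(0, max_search + 1):
        l = 2 + g
        if l > ctx.n_a or l > ctx.n_b:
            break
        pv = p_value(DiagonalStats(m=2, g=g, l_a=l, l_b=l), ctx)
        curve.append((g, pv))
        if pv <= alpha:
            best = g
    return best, curve
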