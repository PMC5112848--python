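"""Statistics linking regulatory regions to nearby gene expression.

Expression binning (FPKM classes), the fraction of significantly regulated
next/second-next genes near a region set that are upregulated, a 2x2
chi-square comparison of two region sets, Mann-Whitney U comparisons of
expression distributions, and joint top-gene selection by gene-body 5hmC
and expression rank.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .intervals import GeneModel, GenomicInterval, GeneProximityIndex

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene two-time-point expression with an external differential call."""

    gene_id: str
    fpkm_t1: float
    fpkm_t2: float
    significant: bool
    direction: str  # up / down / none (t2 vs t1)

    def __post_init__(self) -> None:
        if self.fpkm_t1 < 0 or self.fpkm_t2 < 0:
            raise ValueError(f"{self.gene_id}: negative FPKM")
        if (self.direction == NONE) != (not self.significant):
            raise ValueError(
                f"{self.gene_id}: direction must be 'none' iff not significant"
            )
        if self.direction not in (UP, DOWN, NONE):
            raise ValueError(f"{self.gene_id}: bad direction {self.direction!r}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = region sets, columns = up/down counts."""

    a: int  # set 1, up
    b: int  # set 1, down
    c: int  # set 2, up
    d: int  # set 2, down

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    exact: bool = False


@dataclass(frozen=True)
class RegulatedFraction:
    n_up: int
    n_down: int

    @property
    def n(self) -> int:
        return self.n_up + self.n_down

    @property
    def frac_up(self) -> float:
        return self.n_up / self.n


NO_DATA = None  # regulated_fraction_near returns None when nothing qualifies


# ---------------------------------------------------------------------------
# Expression binning
# ---------------------------------------------------------------------------

DEFAULT_FPKM_EDGES = (1.0, 10.0, 50.0, 100.0, 250.0)


def expression_bin_labels(edges: Sequence[float]) -> list[str]:
    labels = [f"<{edges[0]:g}"]
    labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(edges, edges[1:])]
    labels.append(f">={edges[-1]:g}")
    return labels


def expression_bins(
    expr: Sequence[ExpressionRecord],
    which: str = "t2",
    edges: Sequence[float] = DEFAULT_FPKM_EDGES,
) -> dict[str, list[str]]:
    """Partition genes into left-closed FPKM bins.

    Default edges follow the six standard expression classes (<1, 1-10,
    10-50, 50-100, 100-250, >=250 FPKM). A gene with FPKM exactly on an
    edge falls in the higher bin.
    """
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    if which not in ("t1", "t2"):
        raise ValueError("which must be 't1' or 't2'")
    labels = expression_bin_labels(edges)
    out: dict[str, list[str]] = {lab: [] for lab in labels}
    edges_arr = np.asarray(edges, dtype=float)
    for rec in expr:
        f = rec.fpkm_t1 if which == "t1" else rec.fpkm_t2
        if f < 0:
            raise ValueError(f"{rec.gene_id}: negative FPKM")
        idx = int(np.searchsorted(edges_arr, f, side="right"))
        out[labels[idx]].append(rec.gene_id)
    return out


# ---------------------------------------------------------------------------
# Regulated genes near regions
# ---------------------------------------------------------------------------

def regulated_fraction_near(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel] | GeneProximityIndex,
    expr: Sequence[ExpressionRecord] | Mapping[str, ExpressionRecord],
    max_dist: int = 100_000,
) -> RegulatedFraction | None:
    """Up/down split of significantly regulated genes near a region set.

    For every region the next and second-next genes within ``max_dist`` bp
    are collected, de-duplicated across regions, restricted to genes with a
    significant differential call, and counted by direction. Returns None
    when no significant neighbour exists (distinct from a fraction of 0).
    """
    index = genes if isinstance(genes, GeneProximityIndex) else GeneProximityIndex(genes)
    expr_map = (
        expr if isinstance(expr, Mapping) else {r.gene_id: r for r in expr}
    )
    neighbour_ids: set[str] = set()
    for region in regions:
        for gd in index.nearest_two_genes(region, max_dist):
            neighbour_ids.add(gd.gene_id)
    n_up = n_down = 0
    for gid in neighbour_ids:
        rec = expr_map.get(gid)
        if rec is None or not rec.significant:
            continue
        if rec.direction == UP:
            n_up += 1
        elif rec.direction == DOWN:
            n_down += 1
    if n_up + n_down == 0:
        return NO_DATA
    return RegulatedFraction(n_up, n_down)


# ---------------------------------------------------------------------------
# Chi-square 2x2
# ---------------------------------------------------------------------------

def chi_square_2x2(t: ContingencyTable2x2, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table, closed margin form.

    statistic = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); with the Yates
    correction |ad - bc| is reduced by N/2 before squaring. One degree of
    freedom. Defaults to no correction.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError(
            "a zero margin makes the chi-square undefined; use an exact test"
        )
    det = abs(a * d - b * c)
    if yates:
        det = max(det - n / 2, 0.0)
    statistic = n * det * det / margins
    p = float(sps.chi2.sf(statistic, df=1))
    return TestResult(
        statistic=float(statistic),
        p_value=max(p, np.nextafter(0, 1)),
        method="chi-square" + (" (Yates)" if yates else ""),
        df=1,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x via mid-rank assignment."""
    nx = len(x)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
) -> TestResult:
    """Mann-Whitney rank-sum test.

    Exact by full enumeration of rank assignments when the combined sample
    size is at most 12 and tie-free; otherwise a normal approximation with
    tie correction and a 0.5 continuity correction. Two-group expression
    comparisons in this pipeline use the two-sided variant.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if nx + ny <= 12 and not has_ties:
        # enumerate all C(nx+ny, nx) placements of x among the pooled ranks
        n = nx + ny
        ranks = np.arange(1, n + 1)
        us = np.array(
            [sum(comb) - nx * (nx + 1) / 2 for comb in itertools.combinations(ranks, nx)]
        )
        total = len(us)
        p_le = np.count_nonzero(us <= u) / total
        p_ge = np.count_nonzero(us >= u) / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2 * min(p_le, p_ge))
        return TestResult(u, max(p, np.nextafter(0, 1)), "mann-whitney (exact)", exact=True)

    mean_u = nx * ny / 2
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var_u = nx * ny / 12 * (n + 1 - tie_term)
    if var_u == 0:
        return TestResult(u, 1.0, "mann-whitney (normal approx)")
    if alternative == "greater":
        z = (u - mean_u - 0.5) / np.sqrt(var_u)
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        z = (u - mean_u + 0.5) / np.sqrt(var_u)
        p = float(sps.norm.cdf(z))
    else:
        z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)
        p = float(2 * sps.norm.sf(max(z, 0.0)))
    return TestResult(u, min(max(p, np.nextafter(0, 1)), 1.0), "mann-whitney (normal approx)")


# ---------------------------------------------------------------------------
# Top co-ranked genes
# ---------------------------------------------------------------------------

def top_coexpressed_5hmc_genes(
    gene_body_5hmc: Mapping[str, float],
    expr: Sequence[ExpressionRecord],
    which: str = "t2",
    n: int = 50,
) -> list[str]:
    """Genes highest in both gene-body 5hmC and expression.

    Each gene is ranked descending in 5hmC RPKM and in FPKM over the common
    gene set; genes are ordered by the sum of the two ranks (ties broken
    lexicographically) and the top ``n`` returned.
    """
    if which not in ("t1", "t2"):
        raise ValueError("which must be 't1' or 't2'")
    expr_map = {r.gene_id: (r.fpkm_t1 if which == "t1" else r.fpkm_t2) for r in expr}
    common = sorted(set(gene_body_5hmc) & set(expr_map))
    if not common:
        return []
    hmc = np.array([gene_body_5hmc[g] for g in common])
    fpkm = np.array([expr_map[g] for g in common])
    # descending rank: 1 = highest
    rank_hmc = sps.rankdata(-hmc, method="average")
    rank_fpkm = sps.rankdata(-fpkm, method="average")
    order = sorted(range(len(common)), key=lambda i: (rank_hmc[i] + rank_fpkm[i], common[i]))
    if n > len(common):
        import warnings

        warnings.warn(f"requested top {n} of only {len(common)} genes; returning all")
        n = len(common)
    return [common[i] for i in order[:n]]


# ---------------------------------------------------------------------------
# Expression table I/O
# ---------------------------------------------------------------------------

def read_expression_table(path) -> list[ExpressionRecord]:
    """TSV with header: gene_id, fpkm_t1, fpkm_t2, significant (0/1), direction."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                ExpressionRecord(
                    gene_id=f[idx["gene_id"]],
                    fpkm_t1=float(f[idx["fpkm_t1"]]),
                    fpkm_t2=float(f[idx["fpkm_t2"]]),
                    significant=f[idx["significant"]] == "1",
                    direction=f[idx["direction"]],
                )
            )
    return out


def write_expression_table(path, expr: Sequence[ExpressionRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfpkm_t1\tfpkm_t2\tsignificant\tdirection\n")
        for r in expr:
            fh.write(
                f"{r.gene_id}\t{r.fpkm_t1:.4f}\t{r.fpkm_t2:.4f}\t"
                f"{int(r.significant)}\t{r.direction}\n"
            )
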