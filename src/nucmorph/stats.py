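"""Friedman test with Holm / Shaffer / Bergmann-Hommel post-hoc comparisons.

The protocol compares k = 3 diagnostic classes (NILM, LSIL, HSIL) on each
irregularity metric.  Scores are arranged into n blocks of one image per
class, ranked within blocks (rank 1 = smallest score, i.e. least irregular,
with average ranks for ties) and tested with the tie-corrected Friedman
chi-square on k-1 degrees of freedom.  When the omnibus test rejects at
level alpha, pairwise z statistics

    z = (Rbar_i - Rbar_j) / sqrt(k (k+1) / (6 n))

are converted to two-sided normal p-values and adjusted by the Holm
step-down, Shaffer's static logically-constrained step-down, and the
Bergmann-Hommel dynamic procedure over exhaustive sets.

The images in each class are unpaired; blocks are formed by pairing the
i-th image of each class after a seeded shuffle (equal class sizes are
required).  A Kruskal-Wallis escape hatch for genuinely unpaired data is
provided but is not part of the reference protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

__all__ = [
    "FriedmanResult",
    "PairwiseComparison",
    "SignificanceReport",
    "make_blocks",
    "friedman_test",
    "iman_davenport",
    "pairwise_raw_pvalues",
    "holm_adjust",
    "shaffer_adjust",
    "bergmann_adjust",
    "significance_table",
]

CLASS_ORDER = ("NILM", "LSIL", "HSIL")


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    mean_ranks: dict[str, float]
    n_blocks: int


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    z: float
    raw_p: float
    holm_p: float
    shaffer_p: float
    bergmann_p: float
    significant: dict[str, bool]  # per procedure, at the report's alpha


@dataclass(frozen=True)
class SignificanceReport:
    metric: str
    friedman: FriedmanResult
    pairwise: list[PairwiseComparison]
    alpha: float

    def significant_pairs(self, procedure: str = "holm") -> list[tuple[str, str]]:
        return [c.pair for c in self.pairwise if c.significant[procedure]]


def make_blocks(
    table: pd.DataFrame,
    metric: str,
    classes: tuple[str, ...] = CLASS_ORDER,
    seed: int = 0,
) -> np.ndarray:
    """Arrange per-image scores into an (n, k) Friedman block matrix.

    ``table`` must have a ``label`` column and one column per metric.  The
    classes must have equal counts; the i-th block pairs the i-th image of
    each class after a per-class seeded shuffle.
    """
    if "label" not in table.columns:
        raise ParameterError("score table needs a 'label' column")
    if metric not in table.columns:
        raise ParameterError("unknown metric column %r" % metric)
    if table[metric].isna().any():
        raise ParameterError("score table contains missing values")
    cols = []
    sizes = {c: int((table["label"] == c).sum()) for c in classes}
    if len(set(sizes.values())) != 1 or 0 in sizes.values():
        raise ParameterError("blocks undefined: unequal class sizes %s" % sizes)
    rng = np.random.default_rng(seed)
    for c in classes:
        vals = table.loc[table["label"] == c, metric].to_numpy(dtype=np.float64)
        cols.append(rng.permutation(vals))
    return np.column_stack(cols)


def _rank_blocks(blocks: np.ndarray) -> np.ndarray:
    """Within-block ranks, ascending, average ranks for ties."""
    return np.apply_along_axis(sps.rankdata, 1, blocks)


def friedman_test(
    blocks: np.ndarray, classes: tuple[str, ...] = CLASS_ORDER
) -> FriedmanResult:
    """Tie-corrected Friedman chi-square test on an (n, k) block matrix.

    The statistic is ``(k-1) * S / D`` with ``S`` the squared deviation of
    the rank sums from their null expectation and ``D`` the tie-corrected
    denominator ``sum(r_ij^2) - n k (k+1)^2 / 4``; without ties this equals
    the textbook ``12 S / (n k (k+1))`` form.  p-value from chi-square with
    k-1 degrees of freedom.
    """
    b = np.asarray(blocks, dtype=np.float64)
    if b.ndim != 2:
        raise ParameterError("blocks must be a 2-D (n, k) array")
    n, k = b.shape
    if k < 2:
        raise ParameterError("need at least 2 groups")
    if len(classes) != k:
        raise ParameterError("class names do not match number of columns")
    ranks = _rank_blocks(b)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - n * (k + 1) / 2.0) ** 2).sum())
    denom = float((ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0)
    if denom == 0.0:  # every block fully tied
        stat, p = 0.0, 1.0
    else:
        stat = (k - 1) * s / denom
        p = float(sps.chi2.sf(stat, df=k - 1))
    mean_ranks = dict(zip(classes, rank_sums / n))
    return FriedmanResult(statistic=float(stat), p_value=p,
                          mean_ranks={c: float(r) for c, r in mean_ranks.items()},
                          n_blocks=n)


def iman_davenport(friedman: FriedmanResult, k: int) -> tuple[float, float]:
    """Iman-Davenport F transformation of the Friedman statistic."""
    n = friedman.n_blocks
    chi2 = friedman.statistic
    denom = n * (k - 1) - chi2
    if denom <= 0:
        return np.inf, 0.0
    f = (n - 1) * chi2 / denom
    p = float(sps.f.sf(f, k - 1, (k - 1) * (n - 1)))
    return float(f), p


def pairwise_raw_pvalues(
    mean_ranks: dict[str, float], n: int, k: int | None = None
) -> dict[tuple[str, str], tuple[float, float]]:
    """Two-sided normal p-values for all pairwise mean-rank differences.

    Returns ``{(a, b): (z, p)}`` with ``z = (Rbar_a - Rbar_b) / se`` and
    ``se = sqrt(k (k+1) / (6 n))``.
    """
    names = list(mean_ranks)
    if k is None:
        k = len(names)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    out = {}
    for a, b in combinations(names, 2):
        z = (mean_ranks[a] - mean_ranks[b]) / se
        out[(a, b)] = (float(z), float(2.0 * sps.norm.sf(abs(z))))
    return out


def _check_pvalues(raw) -> np.ndarray:
    p = np.asarray(raw, dtype=np.float64)
    if p.size == 0 or (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return p


def holm_adjust(raw) -> np.ndarray:
    """Holm step-down adjusted p-values (input order preserved)."""
    p = _check_pvalues(raw)
    return multipletests(p, method="holm")[1]


def _shaffer_possible_counts(k: int) -> set[int]:
    """S(k): possible numbers of simultaneously true hypotheses among the
    k(k-1)/2 pairwise equalities of k groups."""
    if k <= 1:
        return {0}
    out: set[int] = set()
    for j in range(1, k + 1):
        within = j * (j - 1) // 2
        out |= {within + x for x in _shaffer_possible_counts(k - j)}
    return out


def shaffer_adjust(raw, k_groups: int) -> np.ndarray:
    """Shaffer's static step-down adjusted p-values for the all-pairs family.

    At step i the multiplier is the largest element of S(k) not exceeding
    the number of hypotheses still in play; for k = 3 the sequence is
    (3, 1, 1).  Monotone-enforced and capped at 1, input order preserved.
    """
    p = _check_pvalues(raw)
    m = k_groups * (k_groups - 1) // 2
    if p.size != m:
        raise ParameterError(
            "expected %d p-values for the all-pairs family of %d groups" % (m, k_groups)
        )
    possible = sorted(_shaffer_possible_counts(k_groups))
    order = np.argsort(p, kind="stable")
    mult = np.array(
        [max(t for t in possible if t <= m - i) for i in range(m)], dtype=np.float64
    )
    adj_sorted = np.minimum(np.maximum.accumulate(mult * p[order]), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _set_partitions(items: list[int]):
    """All partitions of a list into nonempty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _exhaustive_sets(k_groups: int) -> list[frozenset[int]]:
    """Exhaustive sets of pair-hypothesis indices for k groups.

    A set of pairwise equalities is exhaustive if it is exactly the set of
    within-block pairs of some partition of the groups.  Pairs are indexed
    in ``itertools.combinations(range(k), 2)`` order.
    """
    pair_index = {p: i for i, p in enumerate(combinations(range(k_groups), 2))}
    sets = set()
    for part in _set_partitions(list(range(k_groups))):
        idx = frozenset(
            pair_index[tuple(sorted(pr))]
            for block in part
            for pr in combinations(sorted(block), 2)
        )
        if idx:
            sets.add(idx)
    return sorted(sets, key=lambda s: (len(s), sorted(s)))


def bergmann_adjust(raw, k_groups: int) -> np.ndarray:
    """Bergmann-Hommel adjusted p-values for the all-pairs family.

    APV_i = max over exhaustive sets I containing hypothesis i of
    ``|I| * min_{j in I} p_j``, capped at 1.  Enumerates all exhaustive
    sets, so k_groups is limited to 5.
    """
    p = _check_pvalues(raw)
    if k_groups > 5:
        raise ParameterError("exhaustive enumeration refused for k > 5")
    m = k_groups * (k_groups - 1) // 2
    if p.size != m:
        raise ParameterError(
            "expected %d p-values for the all-pairs family of %d groups" % (m, k_groups)
        )
    out = np.empty(m)
    sets = _exhaustive_sets(k_groups)
    for i in range(m):
        vals = [len(s) * min(p[j] for j in s) for s in sets if i in s]
        out[i] = min(1.0, max(vals))
    return out


def _kruskal_report(
    table: pd.DataFrame, metric: str, classes: tuple[str, ...], alpha: float
) -> SignificanceReport:
    """Kruskal-Wallis omnibus + Dunn-style pairwise z; NOT the reference
    Friedman protocol (escape hatch for unpaired designs)."""
    groups = [
        table.loc[table["label"] == c, metric].to_numpy(dtype=np.float64)
        for c in classes
    ]
    stat, p = sps.kruskal(*groups)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = {
        c: float(ranks[bounds[i] : bounds[i + 1]].mean()) for i, c in enumerate(classes)
    }
    n_tot = len(pooled)
    pairs, zs, raws = [], [], []
    for (i, a), (j, b) in combinations(enumerate(classes), 2):
        se = np.sqrt(n_tot * (n_tot + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        pairs.append((a, b))
        zs.append(float(z))
        raws.append(float(2.0 * sps.norm.sf(abs(z))))
    fr = FriedmanResult(statistic=float(stat), p_value=float(p),
                        mean_ranks=mean_ranks, n_blocks=min(sizes))
    return _assemble_report(metric, fr, pairs, zs, raws, len(classes), alpha)


def _assemble_report(metric, friedman, pairs, zs, raws, k, alpha) -> SignificanceReport:
    raws_arr = np.asarray(raws)
    holm = holm_adjust(raws_arr)
    shaffer = shaffer_adjust(raws_arr, k)
    bergmann = bergmann_adjust(raws_arr, k)
    gate = friedman.p_value < alpha  # post-hoc only after omnibus rejection
    comps = [
        PairwiseComparison(
            pair=pairs[i], z=zs[i], raw_p=float(raws_arr[i]),
            holm_p=float(holm[i]), shaffer_p=float(shaffer[i]),
            bergmann_p=float(bergmann[i]),
            significant={
                "holm": bool(gate and holm[i] < alpha),
                "shaffer": bool(gate and shaffer[i] < alpha),
                "bergmann": bool(gate and bergmann[i] < alpha),
            },
        )
        for i in range(len(pairs))
    ]
    return SignificanceReport(metric=metric, friedman=friedman, pairwise=comps, alpha=alpha)


def significance_table(
    table: pd.DataFrame,
    metrics: list[str],
    alpha: float = 0.05,
    classes: tuple[str, ...] = CLASS_ORDER,
    seed: int = 0,
    test: str = "friedman",
) -> dict[str, SignificanceReport]:
    """Per-metric omnibus + post-hoc report across the diagnostic classes.

    For every metric column: the Friedman p-value and, when the omnibus
    test rejects at ``alpha``, the class pairs significant under each
    post-hoc procedure (an empty list corresponds to "Nil").
    """
    if not (0.0 <= alpha < 1.0):
        raise ParameterError("alpha must lie in [0, 1)")
    if not metrics:
        raise ParameterError("at least one metric required")
    if test not in ("friedman", "kruskal"):
        raise ParameterError("test must be 'friedman' or 'kruskal'")
    out: dict[str, SignificanceReport] = {}
    for metric in metrics:
        if test == "kruskal":
            out[metric] = _kruskal_report(table, metric, classes, alpha)
            continue
        blocks = make_blocks(table, metric, classes=classes, seed=seed)
        fr = friedman_test(blocks, classes=classes)
        pw = pairwise_raw_pvalues(fr.mean_ranks, n=fr.n_blocks, k=len(classes))
        pairs = list(pw)
        zs = [pw[p][0] for p in pairs]
        raws = [pw[p][1] for p in pairs]
        out[metric] = _assemble_report(metric, fr, pairs, zs, raws, len(classes), alpha)
    return out


def report_to_frame(reports: dict[str, SignificanceReport]) -> pd.DataFrame:
    """Flatten reports into a tidy summary table (one row per metric)."""
    rows = []
    for metric, rep in reports.items():
        row = {
            "metric": metric,
            "friedman_statistic": rep.friedman.statistic,
            "friedman_p": rep.friedman.p_value,
        }
        for proc in ("holm", "shaffer", "bergmann"):
            pairs = rep.significant_pairs(proc)
            row[f"significant_{proc}"] = (
                "; ".join("%s vs %s" % p for p in pairs) if pairs else "Nil"
            )
        rows.append(row)
    return pd.DataFrame(rows)
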