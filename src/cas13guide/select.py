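"""The five-way feature-selection ladder.

Candidate k-mer feature lists are produced five ways and benchmarked
downstream:

1. ``pval``  — univariate-regression F-test, keep p < 0.05 (strict);
2. ``z2``    — Z-score of -log10(p) above 2;
3. ``z3``    — Z-score of -log10(p) above 3;
4. ``gini_dt`` — Gini importance from a decision tree;
5. ``gini_rf`` — Gini importance from a random forest.

By construction pval >= z2 >= z3 as sets. Chi-squared over/under-
representation per position and the positional Kruskal-Wallis test are
reported diagnostics (they describe which positions carry signal), not
filters in the ladder.

No multiple-testing correction is applied by default: the ladder filters at
a raw 0.05. Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_regression
from sklearn.tree import DecisionTreeClassifier

from .features import BASES, FeatureDescriptor, FeatureMatrix
from .guide_space import SPACER_LEN

logger = logging.getLogger(__name__)

#: smallest p-value we report; guards log10 of underflowed zeros
MIN_P = 1e-300

#: number of k-mer features kept by Gini selection by default; with the 7
#: non-k-mer columns (4 composition + relpos + occ_overlap + n_hits)
#: appended the final model space is 112 features
DEFAULT_GINI_TOP_N = 105


@dataclass
class RepresentationTest:
    """Chi-squared over/under-representation of one k-mer at one position."""

    kmer: str
    observed: float
    expected: float
    statistic: float
    p_value: float
    direction: str  # over | under


@dataclass
class SelectionResult:
    method: str  # pval | z2 | z3 | gini_dt | gini_rf
    selected: list[FeatureDescriptor]
    scores: dict[str, float]
    threshold_used: float

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.selected]

    def to_tsv(self, path: str | Path) -> None:
        """Export (k-mer, position, score) rows; non-k-mer features carry
        their name in the k-mer column and an empty position."""
        with open(path, "w") as fh:
            fh.write("kmer\tposition\tscore\n")
            for d in self.selected:
                kmer = d.kmer if d.kmer is not None else d.name
                pos = "" if d.position is None else str(d.position + 1)  # 1-based in reports
                fh.write(f"{kmer}\t{pos}\t{self.scores[d.name]:.6g}\n")


def kmer_representation_test(
    matrix: FeatureMatrix,
    k: int,
    position: int,
    null: str = "uniform",
) -> dict[str, RepresentationTest]:
    """Chi-squared test of k-mer counts at one spacer position.

    Observed counts are the column sums of the 4^k sibling indicators;
    expected counts come from the uniform null (n / 4^k) or, with
    ``null='background'``, from the k-mer's global frequency across all
    positions. The statistic (sum (O-E)^2/E, 4^k - 1 df) is shared by the
    siblings; each k-mer carries its own over/under direction.
    """
    if not 0 <= position <= SPACER_LEN - k:
        raise ValueError(f"position {position} out of range for k={k}")
    kmers = ["".join(p) for p in _product_bases(k)]
    names = [f"kmer|{k}|{km}|{position}" for km in kmers]
    observed = np.array([matrix.column(n).sum() for n in names])
    n = observed.sum()
    if null == "uniform":
        expected = np.full(len(kmers), n / len(kmers))
    elif null == "background":
        totals = np.array(
            [
                sum(
                    matrix.column(f"kmer|{k}|{km}|{p}").sum()
                    for p in range(SPACER_LEN - k + 1)
                )
                for km in kmers
            ]
        )
        expected = n * totals / totals.sum()
    else:
        raise ValueError(f"unknown null {null!r}")
    if (expected < 5).any():
        logger.warning(
            "chi-squared at k=%d position %d: expected count < 5 in some cells", k, position
        )
    statistic, p_value = stats.chisquare(observed, expected)
    return {
        km: RepresentationTest(
            kmer=km,
            observed=float(o),
            expected=float(e),
            statistic=float(statistic),
            p_value=float(p_value),
            direction="over" if o > e else "under",
        )
        for km, o, e in zip(kmers, observed, expected)
    }


def positional_kruskal_wallis(
    expressions: Sequence[float], groups: Sequence[str]
) -> tuple[float, float]:
    """Kruskal-Wallis H across guides grouped by nucleotide at a position.

    Returns (H, p). A single group is undefined and returns (nan, nan);
    all-identical values across groups carry no signal and return (0, 1).
    """
    expressions = np.asarray(expressions, dtype=float)
    groups = np.asarray(groups)
    if len(expressions) != len(groups):
        raise ValueError("expressions and groups differ in length")
    samples = [expressions[groups == g] for g in np.unique(groups)]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        return (math.nan, math.nan)
    if np.ptp(expressions) == 0:
        return (0.0, 1.0)
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def positional_kw_scan(
    matrix: FeatureMatrix, expressions: Sequence[float], alpha: float = 0.05
) -> dict[int, tuple[float, float]]:
    """Kruskal-Wallis at every spacer position, grouping by the nucleotide
    there (read off the positional monomer indicators). Diagnostic: flags
    positions with p < alpha for cross-reference with the chi-squared
    over/under-representation lists."""
    out: dict[int, tuple[float, float]] = {}
    for position in range(SPACER_LEN):
        cols = np.column_stack(
            [matrix.column(f"kmer|1|{b}|{position}") for b in BASES]
        )
        groups = np.array([BASES[j] for j in cols.argmax(axis=1)])
        out[position] = positional_kruskal_wallis(expressions, groups)
    return out


def univariate_significance(
    matrix: FeatureMatrix, response: Sequence[float]
) -> dict[str, float]:
    """Simple-linear-regression F-test p-value per feature (F with (1, n-2)
    df, equal to the squared-Pearson conversion). Constant features get
    p = 1."""
    response = np.asarray(response, dtype=float)
    if len(response) != len(matrix.row_ids):
        raise ValueError("response length != row count")
    if len(response) < 3:
        raise ValueError("need at least 3 rows for the F-test")
    _, pvals = f_regression(matrix.values, response)
    out: dict[str, float] = {}
    for name, col, p in zip(matrix.names, matrix.values.T, pvals):
        if np.ptp(col) == 0 or not np.isfinite(p):
            out[name] = 1.0
        else:
            out[name] = float(max(p, MIN_P))
    return out


def _ordered_selection(
    space: Mapping[str, FeatureDescriptor], names: list[str], pvals: Mapping[str, float]
) -> list[FeatureDescriptor]:
    names = sorted(names, key=lambda n: (pvals[n], n))
    return [space[n] for n in names]


def select_by_pvalue(
    pvals: Mapping[str, float],
    feature_space: Sequence[FeatureDescriptor],
    alpha: float = 0.05,
    fdr: bool = False,
) -> SelectionResult:
    """Keep features with p < alpha (strict); p == alpha is excluded.
    ``fdr=True`` applies Benjamini-Hochberg before thresholding (off by
    default)."""
    if not pvals:
        raise ValueError("empty p-value mapping")
    space = {d.name: d for d in feature_space}
    use = dict(pvals)
    if fdr:
        names = list(use)
        adjusted = stats.false_discovery_control([use[n] for n in names])
        use = dict(zip(names, adjusted))
    kept = [n for n, p in use.items() if p < alpha and n in space]
    if not kept:
        logger.warning("p-value selection kept no features at alpha=%g", alpha)
    return SelectionResult(
        method="pval",
        selected=_ordered_selection(space, kept, use),
        scores={n: float(use[n]) for n in kept},
        threshold_used=alpha,
    )


def select_by_zscore(
    pvals: Mapping[str, float],
    feature_space: Sequence[FeatureDescriptor],
    z_cutoff: float,
    alpha: float = 0.05,
) -> SelectionResult:
    """Z-score the -log10 p-values over all features and keep those with
    z > z_cutoff (strict). The z lists are refinements of the significant
    set, so membership additionally requires p < alpha; this makes
    pval >= z2 >= z3 a guaranteed nesting. The log base only rescales z
    identically."""
    if not pvals:
        raise ValueError("empty p-value mapping")
    space = {d.name: d for d in feature_space}
    names = list(pvals)
    s = -np.log10(np.maximum([pvals[n] for n in names], MIN_P))
    sd = s.std()  # population sd; base/estimator choice is cosmetic for ranking
    if sd == 0:
        logger.warning("z-score selection: zero variance in -log10(p), empty selection")
        kept: list[str] = []
        z = dict.fromkeys(names, 0.0)
    else:
        zvals = (s - s.mean()) / sd
        z = dict(zip(names, zvals))
        kept = [n for n in names if z[n] > z_cutoff and pvals[n] < alpha and n in space]
    return SelectionResult(
        method=f"z{z_cutoff:g}",
        selected=_ordered_selection(space, kept, pvals),
        scores={n: float(z[n]) for n in kept},
        threshold_used=z_cutoff,
    )


def select_by_gini(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    learner: str = "random_forest",
    top_n: int | None = DEFAULT_GINI_TOP_N,
    importance_floor: float | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Rank features by Gini importance (mean decrease in impurity) from a
    decision tree or random forest and keep the top ``top_n`` (or all above
    ``importance_floor``). Deterministic given seed."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("Gini selection needs at least 2 classes")
    if learner == "decision_tree":
        est = DecisionTreeClassifier(criterion="gini", random_state=seed)
    elif learner == "random_forest":
        est = RandomForestClassifier(
            n_estimators=100, criterion="gini", random_state=seed, n_jobs=1
        )
    else:
        raise ValueError(f"unknown learner {learner!r}")
    est.fit(matrix.values, labels)
    importances = est.feature_importances_
    order = np.lexsort((matrix.names, -importances))  # importance desc, name asc
    if importance_floor is not None:
        chosen = [i for i in order if importances[i] > importance_floor]
        threshold = importance_floor
    else:
        if top_n is None:
            raise ValueError("give top_n or importance_floor")
        chosen = list(order[:top_n])
        threshold = float(importances[chosen[-1]]) if chosen else 0.0
    return SelectionResult(
        method="gini_dt" if learner == "decision_tree" else "gini_rf",
        selected=[matrix.descriptors[i] for i in chosen],
        scores={matrix.names[i]: float(importances[i]) for i in chosen},
        threshold_used=float(threshold),
    )


def selection_ladder(
    matrix: FeatureMatrix,
    expressions: Sequence[float],
    labels: Sequence[int],
    kmer_only: bool = True,
    gini_top_n: int = DEFAULT_GINI_TOP_N,
    seed: int = 0,
) -> dict[str, SelectionResult]:
    """Run all five selections. Statistical methods score k-mer indicators
    only (``kmer_only``), matching how the candidate lists are assembled:
    the non-k-mer features (composition, relpos, occupancy, hit count) are
    appended to every list when models are built."""
    if kmer_only:
        kmer_names = [d.name for d in matrix.descriptors if d.kind == "positional_kmer"]
        sub = matrix.subset(kmer_names)
    else:
        sub = matrix
    pvals = univariate_significance(sub, expressions)
    space = sub.descriptors
    return {
        "pval": select_by_pvalue(pvals, space),
        "z2": select_by_zscore(pvals, space, 2.0),
        "z3": select_by_zscore(pvals, space, 3.0),
        "gini_dt": select_by_gini(sub, labels, "decision_tree", top_n=gini_top_n, seed=seed),
        "gini_rf": select_by_gini(sub, labels, "random_forest", top_n=gini_top_n, seed=seed),
    }


def _product_bases(k: int):
    import itertools

    return itertools.product(BASES, repeat=k)
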