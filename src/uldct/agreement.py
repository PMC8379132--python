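"""Method-agreement and paired-comparison statistics.

The comparisons a protocol-equivalence study needs: Bland-Altman limits of
agreement for paired continuous measurements, unweighted Cohen's kappa for
categorical calls, a two-way random-effects absolute-agreement single-
measure ICC for continuous reliability, the Wilcoxon signed-rank test for
paired shifts, and McNemar's exact test for paired binary outcomes.

Conventions (documented, fixed):

* limits of agreement use the 1.96 normal multiplier (not a t quantile),
  so range = upper − lower = 3.92 × SD(differences);
* kappa is 1 when both raters are constant and identical (chance agreement
  p_e = 1 makes the usual formula 0/0);
* Wilcoxon drops zero differences (Wilcoxon's original treatment), uses the
  exact sign-permutation distribution for n ≤ 25 and a tie- and
  continuity-corrected normal approximation above; all-zero differences
  give p = 1;
* McNemar is the exact binomial test on the discordant counts, p = 1 when
  there are none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .errors import ArgumentError, UndefinedStatisticError

__all__ = [
    "BlandAltman",
    "bland_altman",
    "bland_altman_plot",
    "cohen_kappa",
    "pooled_kappa",
    "icc",
    "wilcoxon_signed_rank",
    "mcnemar",
]


@dataclass
class BlandAltman:
    bias: float
    lower_limit: float
    upper_limit: float
    range: float
    sd_diff: float
    n: int


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ArgumentError("paired inputs must be equal-length 1-D vectors")
    return a, b


def bland_altman(a, b) -> BlandAltman:
    """Bias and 95% limits of agreement for differences a − b."""
    a, b = _paired(a, b)
    if a.size < 2:
        raise ArgumentError("Bland-Altman needs n >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lower = bias - 1.96 * sd
    upper = bias + 1.96 * sd
    return BlandAltman(bias=bias, lower_limit=lower, upper_limit=upper, range=upper - lower, sd_diff=sd, n=int(a.size))


def bland_altman_plot(a, b, path=None, title: str = ""):
    """Mean-vs-difference plot with bias and limit reference lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = _paired(a, b)
    res = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, s=18, alpha=0.8)
    for yv, style, lbl in (
        (res.bias, "-", f"bias {res.bias:.2f}"),
        (res.lower_limit, "--", f"lower {res.lower_limit:.2f}"),
        (res.upper_limit, "--", f"upper {res.upper_limit:.2f}"),
    ):
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
        ax.annotate(lbl, xy=(1.0, yv), xycoords=("axes fraction", "data"), fontsize=8, va="bottom")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return res


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Unweighted Cohen's kappa for two categorical rating vectors."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ArgumentError("ratings must be equal-length non-empty vectors")
    cats = np.unique(np.concatenate([a.astype(str), b.astype(str)]))
    if cats.size < 2:
        # both raters constant and identical: chance agreement is 1
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k = float(cohen_kappa_score(a.astype(str), b.astype(str)))
    if np.isnan(k):
        return 1.0
    return k


def pooled_kappa(pairs: list[tuple]) -> float:
    """Kappa over several rating tasks pooled by concatenation, with
    category labels namespaced per task so e.g. 'present' in one pathology
    never matches 'present' in another."""
    if not pairs:
        raise ArgumentError("no rating pairs supplied")
    all_a, all_b = [], []
    for i, (a, b) in enumerate(pairs):
        all_a.extend(f"{i}:{v}" for v in np.asarray(a).astype(str))
        all_b.extend(f"{i}:{v}" for v in np.asarray(b).astype(str))
    return cohen_kappa(np.asarray(all_a), np.asarray(all_b))


def icc(ratings_a, ratings_b) -> float:
    """Two-way random-effects, absolute-agreement, single-measure ICC
    (ICC(2,1) / ICC(A,1)). Penalizes systematic offsets between raters."""
    a, b = _paired(ratings_a, ratings_b)
    if a.size < 3:
        raise ArgumentError("ICC needs n >= 3 pairs")
    pooled = np.concatenate([a, b])
    if float(pooled.var()) == 0.0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    n = a.size
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["A", "B"], n),
            "score": pooled,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(data=df, targets="target", raters="rater", ratings="score")
    val = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    return val


def wilcoxon_signed_rank(a, b=None) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired data (or differences if ``b`` is
    None). Returns (W+, two-sided p); W+ is the sum of ranks of positive
    differences after zero differences are dropped."""
    if b is None:
        d = np.asarray(a, dtype=float)
    else:
        x, y = _paired(a, b)
        d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))  # mid-ranks on ties
    w_plus = float(ranks[d > 0].sum())
    if d.size <= 25:
        res = stats.wilcoxon(d, zero_method="wilcox", method="exact")
    else:
        res = stats.wilcoxon(d, zero_method="wilcox", method="approx", correction=True)
    return w_plus, float(res.pvalue)


def mcnemar(outcomes_a, outcomes_b) -> tuple[int, int, float]:
    """Exact McNemar test for paired binary outcomes.

    Returns the discordant counts (b: positive only under method a,
    c: positive only under method b) and the two-sided exact binomial p.
    """
    a = np.asarray(outcomes_a)
    b = np.asarray(outcomes_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ArgumentError("outcomes must be equal-length non-empty vectors")
    for v in (a, b):
        if not np.isin(v, [0, 1, False, True]).all():
            raise ArgumentError("outcomes must be binary (0/1)")
    a = a.astype(bool)
    b = b.astype(bool)
    n_b = int(np.sum(a & ~b))
    n_c = int(np.sum(~a & b))
    if n_b + n_c == 0:
        return n_b, n_c, 1.0
    n11 = int(np.sum(a & b))
    n00 = int(np.sum(~a & ~b))
    table = np.array([[n11, n_b], [n_c, n00]])
    p = float(_sm_mcnemar(table, exact=True).pvalue)
    return n_b, n_c, p
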