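"""Paired-comparison battery between two per-dish nutrient tables.

For each nutrient shared by the two tables (keyed by dish id) the battery
produces: Pearson correlation with its t-test, a quintile
cross-classification with percent perfect agreement and unweighted
Cohen's kappa, Bland–Altman bias and 95% limits of agreement, summary
statistics of the raw differences, a Kolmogorov–Smirnov normality check
of the differences, a paired Wilcoxon signed-rank test, and the ranking
of the most extreme absolute differences.

Conventions
-----------
* Differences are ``A - B`` (target-database minus source/declared).
* Quintile cutoffs are computed separately per source (type-7 quantiles);
  a value equal to a cutoff falls in the lower quintile, so heavy ties
  can produce unequal classes — recorded, not resampled.
* Limits of agreement are bias ± 1.96 x sample SD (ddof=1).
* The KS test plugs in the estimated mean/SD without a Lilliefors
  correction.
* Kernel-density curves use Silverman's bandwidth and are plot-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceError",
    "CrossTab",
    "AgreementReport",
    "KAPPA_BANDS",
    "pearson_with_test",
    "quintile_cutoffs",
    "assign_quintiles",
    "quintile_crosstab",
    "cohen_kappa_unweighted",
    "kappa_band",
    "bland_altman",
    "difference_summary",
    "normality_and_location_tests",
    "top_extreme",
    "agreement_report",
    "compare_tables",
]

#: interpretation bands for unweighted kappa
KAPPA_BANDS = [
    (0.80, "strong to very strong"),
    (0.60, "moderate"),
    (0.40, "weak"),
    (0.01, "none to slight"),
]


class ConcordanceError(ValueError):
    pass


def pearson_with_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with the two-sided p-value from its t-transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ConcordanceError("pearson_with_test needs paired vectors, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ConcordanceError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ConcordanceError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def quintile_cutoffs(v: np.ndarray) -> np.ndarray:
    """The 20/40/60/80% cutoffs (linear-interpolation quantiles)."""
    return np.quantile(np.asarray(v, dtype=float), [0.2, 0.4, 0.6, 0.8])


def assign_quintiles(v: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    """Quintile index 0..4; values equal to a cutoff go to the lower class."""
    return np.searchsorted(cutoffs, np.asarray(v, dtype=float), side="left")


@dataclass
class CrossTab:
    """5x5 cross-classification as cell percentages plus its provenance."""

    matrix: np.ndarray  # percentages, rows = A quintiles, cols = B quintiles
    n: int
    cutoffs_a: np.ndarray | None = None
    cutoffs_b: np.ndarray | None = None
    degenerate_classes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (5, 5):
            raise ConcordanceError("cross-tab must be 5x5")
        if abs(self.matrix.sum() - 100.0) > 0.1:
            raise ConcordanceError(
                f"cell percentages sum to {self.matrix.sum():.3f}, not 100")

    @property
    def pct_agree(self) -> float:
        """Percent perfect agreement: the diagonal sum."""
        return float(np.trace(self.matrix))

    @classmethod
    def from_percentages(cls, matrix, n: int = 0) -> "CrossTab":
        """Build from an already-tabulated percentage matrix (e.g. printed)."""
        return cls(np.asarray(matrix, dtype=float), n=n)


def quintile_crosstab(x: Sequence[float], y: Sequence[float]) -> CrossTab:
    """Classify each vector by its own quintile cutoffs and cross-tabulate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ConcordanceError("quintile_crosstab needs paired vectors, n >= 5")
    ca, cb = quintile_cutoffs(x), quintile_cutoffs(y)
    qa, qb = assign_quintiles(x, ca), assign_quintiles(y, cb)
    counts = np.zeros((5, 5))
    np.add.at(counts, (qa, qb), 1)
    degenerate = [k for k in range(5)
                  if counts[k, :].sum() == 0 or counts[:, k].sum() == 0]
    if len(np.unique(ca)) < 4 or len(np.unique(cb)) < 4:
        import warnings
        warnings.warn("heavy ties: fewer than 5 distinct quintile classes",
                      UserWarning, stacklevel=2)
    return CrossTab(100.0 * counts / len(x), n=len(x),
                    cutoffs_a=ca, cutoffs_b=cb,
                    degenerate_classes=degenerate)


def cohen_kappa_unweighted(ct: CrossTab) -> float:
    """kappa = (po - pe) / (1 - pe) from the table's own marginals."""
    m = ct.matrix / 100.0
    po = float(np.trace(m))
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum())
    if pe >= 1.0:
        raise ConcordanceError("expected agreement is 1; kappa undefined")
    return (po - pe) / (1.0 - pe)


def kappa_band(kappa: float) -> str:
    for lo, label in KAPPA_BANDS:
        if kappa >= lo:
            return label
    return "poor"


def bland_altman(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, pd.DataFrame]:
    """Bias and 95% limits of agreement of the paired differences x - y.

    Returns (bias, loa_low, loa_high, frame) where the frame holds the
    per-pair mean and difference for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ConcordanceError("bland_altman needs paired vectors, n >= 2")
    diff = x - y
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    frame = pd.DataFrame({"mean": (x + y) / 2.0, "diff": diff})
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, frame


def difference_summary(diffs: Sequence[float]) -> dict[str, float]:
    """min/Q1/median/Q3/max/mean/SD of a difference vector."""
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ConcordanceError("empty difference vector")
    return {
        "min": float(d.min()),
        "q1": float(np.quantile(d, 0.25)),
        "median": float(np.quantile(d, 0.5)),
        "q3": float(np.quantile(d, 0.75)),
        "max": float(d.max()),
        "mean": float(d.mean()),
        "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
    }


def normality_and_location_tests(diffs: Sequence[float]) -> tuple[float, float]:
    """(KS normality p, two-sided paired Wilcoxon p) for the differences.

    KS compares against Normal(mean, SD) with the parameters estimated
    from the data.  Wilcoxon is exact for n <= 25 and uses the normal
    approximation with continuity correction above.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 3:
        raise ConcordanceError("need n >= 3 differences")
    if np.all(d == 0):
        raise ConcordanceError("all differences are zero; Wilcoxon undefined")
    sd = d.std(ddof=1)
    if sd == 0:
        ks_p = 0.0  # degenerate point mass off zero
    else:
        ks_p = float(stats.kstest(d, "norm", args=(d.mean(), sd)).pvalue)
    method = "exact" if d.size <= 25 and not np.any(d == 0) else "approx"
    wil = stats.wilcoxon(d, alternative="two-sided", correction=True,
                         method=method)
    return ks_p, float(wil.pvalue)


def top_extreme(
    diff_table: pd.DataFrame,
    nutrient: str,
    k: int = 25,
    other_nutrients: Sequence[str] | None = None,
) -> pd.DataFrame:
    """The k dishes with largest |Δ nutrient|, ties broken by dish id.

    The returned rows carry, for every other nutrient, the percentile of
    that dish's |Δ| within the corpus.
    """
    if k > len(diff_table):
        raise ConcordanceError("k exceeds the number of dishes")
    others = [c for c in (other_nutrients or [])
              if c != nutrient and c in diff_table.columns]
    t = diff_table.copy()
    t["abs_delta"] = t[nutrient].abs()
    t = t.sort_values(["abs_delta", "dish_id"],
                      ascending=[False, True], kind="mergesort")
    top = t.head(k).copy()
    for o in others:
        ranks = diff_table[o].abs().rank(pct=True) * 100.0
        top[f"pct_abs_{o}"] = ranks.loc[top.index]
    top["rank"] = range(1, len(top) + 1)
    return top.reset_index(drop=True)


@dataclass
class AgreementReport:
    """Everything the battery produces for one nutrient."""

    nutrient: str
    n: int
    pearson_r: float
    pearson_p: float
    pct_agree: float
    kappa: float
    kappa_interpretation: str
    bias: float
    loa_low: float
    loa_high: float
    diff_summary: dict[str, float]
    ks_p: float
    wilcoxon_p: float
    crosstab: CrossTab
    top_extreme: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "nutrient": self.nutrient,
            "n": self.n,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "pct_agree": self.pct_agree,
            "kappa": self.kappa,
            "kappa_interpretation": self.kappa_interpretation,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "diff_summary": self.diff_summary,
            "ks_p": self.ks_p,
            "wilcoxon_p": self.wilcoxon_p,
            "crosstab": self.crosstab.matrix.tolist(),
            "top_extreme_dishes": self.top_extreme["dish_id"].tolist(),
        }


def agreement_report(
    x: Sequence[float], y: Sequence[float],
    dish_ids: Sequence[str],
    nutrient: str = "",
    k: int = 25,
    diff_table: pd.DataFrame | None = None,
    other_nutrients: Sequence[str] | None = None,
) -> AgreementReport:
    """Run the full battery on one paired nutrient vector (x = A, y = B)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, p = pearson_with_test(x, y)
    ct = quintile_crosstab(x, y)
    kappa = cohen_kappa_unweighted(ct)
    bias, lo, hi, _ = bland_altman(x, y)
    diffs = x - y
    summary = difference_summary(diffs)
    try:
        ks_p, wil_p = normality_and_location_tests(diffs)
    except ConcordanceError:
        # degenerate difference vectors (e.g. identical tables) leave the
        # location tests undefined; the rest of the battery still stands
        ks_p, wil_p = float("nan"), float("nan")
    if diff_table is None:
        diff_table = pd.DataFrame({"dish_id": list(dish_ids), nutrient: diffs})
    top = top_extreme(diff_table, nutrient, k=min(k, len(diff_table)),
                      other_nutrients=other_nutrients)
    return AgreementReport(
        nutrient=nutrient, n=len(x), pearson_r=r, pearson_p=p,
        pct_agree=ct.pct_agree, kappa=kappa,
        kappa_interpretation=kappa_band(kappa),
        bias=bias, loa_low=lo, loa_high=hi,
        diff_summary=summary, ks_p=ks_p, wilcoxon_p=wil_p,
        crosstab=ct, top_extreme=top,
    )


def compare_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    nutrients: Sequence[str],
    k: int = 25,
) -> dict[str, AgreementReport]:
    """Battery per nutrient over two per-dish tables keyed by dish_id.

    Raises listing orphan dish ids when the key sets differ.
    """
    a_ids, b_ids = set(table_a["dish_id"]), set(table_b["dish_id"])
    if a_ids != b_ids:
        orphans = sorted((a_ids ^ b_ids))[:20]
        raise ConcordanceError(f"dish id mismatch between tables: {orphans}")
    a = table_a.set_index("dish_id").sort_index()
    b = table_b.set_index("dish_id").sort_index()
    diff_table = pd.DataFrame({"dish_id": a.index})
    for nut in nutrients:
        diff_table[nut] = (a[nut] - b[nut]).to_numpy()
    out = {}
    for nut in nutrients:
        out[nut] = agreement_report(
            a[nut].to_numpy(), b[nut].to_numpy(), list(a.index),
            nutrient=nut, k=k, diff_table=diff_table,
            other_nutrients=nutrients)
    return out
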