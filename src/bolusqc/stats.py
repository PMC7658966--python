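"""Comparative statistics on injector quality tables.

Implements the analysis battery applied to per-recording quality results
(cBCF and |dBIT|): a Kruskal-Wallis omnibus test across injectors,
pairwise multiple comparisons in the Dunnett-modified Tukey-Kramer
family (unpooled variances, Welch-Satterthwaite per-pair degrees of
freedom, studentized-range quantile at a Bonferroni-tightened level),
an analysis of covariance with all pairwise interactions of the
technical injector factors, a Fisher odds-ratio test of quality-criteria
compliance between the two contrast media, and median-[range] rank
summaries per injector.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PairwiseResult",
    "AncovaTerm",
    "AncovaResult",
    "OddsRatioResult",
    "StatsError",
    "AncovaRankError",
    "SIGNIFICANCE_LEVELS",
    "kruskal_wallis",
    "dtk_pairwise",
    "ancova",
    "compliance_odds_ratio",
    "odds_ratio_from_counts",
    "rank_summary",
]

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


class StatsError(ValueError):
    pass


class AncovaRankError(StatsError):
    """Design matrix is rank deficient (aliased terms)."""

    def __init__(self, aliased: Sequence[str]):
        self.aliased = list(aliased)
        super().__init__(f"aliased terms in ANCOVA design: {self.aliased}")


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    estimate: float
    ci_low: float
    ci_high: float
    df: float
    alpha: float
    alpha_adjusted: float
    significant: bool
    significance_level: float | None  # finest of 0.05/0.01/0.001 reached
    degenerate: bool = False


@dataclass(frozen=True)
class AncovaTerm:
    term: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


@dataclass(frozen=True)
class AncovaResult:
    terms: tuple[AncovaTerm, ...]
    n_obs: int
    response: str

    def p(self, term: str) -> float:
        for t in self.terms:
            if t.term == term:
                return t.p_value
        raise KeyError(term)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    corrected: bool
    cbcf_min: float | None = None
    dbit_abs_max: float | None = None


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise StatsError(f"group {name!r} has fewer than 2 values")
        out[str(name)] = arr
    return out


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]]
) -> tuple[float, float]:
    """Kruskal-Wallis H (mid-ranks, tie-corrected) and its chi-squared p.

    With k groups the null distribution of H is approximated by a
    chi-squared with k-1 degrees of freedom.  All-identical pooled values
    carry no rank information and return H = 0, p = 1.
    """
    arrs = _check_groups(groups)
    pooled = np.concatenate(list(arrs.values()))
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrs.values())
    return float(h), float(p)


def _studentized_range_crit(alpha: float, k: int, df: float) -> float:
    """Upper critical value of the studentized range, q_{alpha}(k, df).

    For k = 2 the studentized range reduces exactly to sqrt(2) times the
    two-sided t quantile, which is much cheaper to evaluate.
    """
    if k == 2:
        return math.sqrt(2.0) * float(sps.t.isf(alpha / 2.0, df))
    return float(sps.studentized_range.isf(alpha, k, df))


def dtk_pairwise(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """All-pairs mean-difference intervals for unequal sizes and variances.

    Each pair (a, b) gets the Tukey-Kramer-type interval

        (x̄_a - x̄_b) ± q_{α'}(k, ν_ab) · sqrt((s²_a/n_a + s²_b/n_b) / 2)

    with ν_ab the Welch-Satterthwaite degrees of freedom of the unpooled
    standard error and α' = α / (number of pairs), i.e. a conservative
    Bonferroni tightening across pairs.  A pair is significant when its
    interval excludes zero; the finest of the 0.05/0.01/0.001 families
    whose interval still excludes zero is reported alongside.
    """
    if not 0 < alpha < 1:
        raise StatsError("alpha must be in (0, 1)")
    arrs = _check_groups(groups)
    names = list(arrs)
    k = len(names)
    pairs = list(itertools.combinations(names, 2))
    n_pairs = len(pairs)
    results = []
    for a, b in pairs:
        xa, xb = arrs[a], arrs[b]
        na, nb = xa.size, xb.size
        va, vb = np.var(xa, ddof=1), np.var(xb, ddof=1)
        diff = float(np.mean(xa) - np.mean(xb))
        se2 = va / na + vb / nb
        if se2 == 0.0:
            results.append(
                PairwiseResult(
                    group_a=a,
                    group_b=b,
                    estimate=diff,
                    ci_low=diff,
                    ci_high=diff,
                    df=float(na + nb - 2),
                    alpha=alpha,
                    alpha_adjusted=alpha / n_pairs,
                    significant=False,
                    significance_level=None,
                    degenerate=True,
                )
            )
            continue
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        se = math.sqrt(se2 / 2.0)  # studentized-range scaling
        alpha_adj = alpha / n_pairs
        crit = _studentized_range_crit(alpha_adj, k, df)
        half = crit * se
        sig = abs(diff) > half
        level: float | None = None
        if sig:
            for lev in SIGNIFICANCE_LEVELS:
                if abs(diff) > _studentized_range_crit(lev / n_pairs, k, df) * se:
                    level = lev
                else:
                    break
        results.append(
            PairwiseResult(
                group_a=a,
                group_b=b,
                estimate=diff,
                ci_low=diff - half,
                ci_high=diff + half,
                df=float(df),
                alpha=alpha,
                alpha_adjusted=alpha_adj,
                significant=bool(sig),
                significance_level=level,
            )
        )
    return results


_ANCOVA_FACTORS = ("pump_type", "line_volume_ml", "max_pressure", "cm_type")
_CATEGORICAL = {"pump_type", "cm_type"}


def _ancova_formula(response: str) -> str:
    def enc(f: str) -> str:
        return f"C({f})" if f in _CATEGORICAL else f

    mains = [enc(f) for f in _ANCOVA_FACTORS]
    inters = [
        f"{enc(a)}:{enc(b)}"
        for a, b in itertools.combinations(_ANCOVA_FACTORS, 2)
    ]
    return f"{response} ~ " + " + ".join(mains + inters)


def ancova(table: pd.DataFrame, response: str) -> AncovaResult:
    """Analysis of covariance of a quality metric on injector factors.

    Linear model of ``response`` on pump type and contrast-medium type
    (categorical) and line filling volume and injection power (numeric
    covariates), with all pairwise interactions; per-term F tests use
    Type II sums of squares.  The caller applies any protocol subset
    filter beforehand.  An all-constant response carries no variance to
    apportion and returns F = 0, p = 1 for every term.
    """
    required = set(_ANCOVA_FACTORS) | {response}
    missing = required - set(table.columns)
    if missing:
        raise StatsError(f"table missing columns: {sorted(missing)}")
    data = table.dropna(subset=[response]).copy()
    if len(data) < 10:
        raise StatsError(f"too few observations for ANCOVA ({len(data)})")
    formula = _ancova_formula(response)
    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        aliased = _aliased_columns(exog, model.exog_names)
        raise AncovaRankError(aliased)
    if np.ptp(data[response].to_numpy()) == 0.0:
        terms = tuple(
            AncovaTerm(term=name, f_stat=0.0, df_num=1, df_den=len(data), p_value=1.0)
            for name in _term_names(response)
        )
        return AncovaResult(terms=terms, n_obs=len(data), response=response)
    fitted = model.fit()
    anova = sm.stats.anova_lm(fitted, typ=2)
    df_den = int(anova.loc["Residual", "df"])
    terms = []
    for name, row in anova.iterrows():
        if name == "Residual":
            continue
        terms.append(
            AncovaTerm(
                term=_clean_term(str(name)),
                f_stat=float(row["F"]),
                df_num=int(row["df"]),
                df_den=df_den,
                p_value=float(row["PR(>F)"]),
            )
        )
    return AncovaResult(terms=tuple(terms), n_obs=len(data), response=response)


def _term_names(response: str) -> list[str]:
    mains = list(_ANCOVA_FACTORS)
    inters = [
        f"{a}:{b}" for a, b in itertools.combinations(_ANCOVA_FACTORS, 2)
    ]
    return mains + inters


def _clean_term(name: str) -> str:
    return name.replace("C(", "").replace(")", "").strip()


def _aliased_columns(exog: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that do not increase the design rank, in formula order."""
    aliased = []
    rank = 0
    kept: list[np.ndarray] = []
    for col, name in zip(exog.T, names):
        cand = np.column_stack(kept + [col]) if kept else col[:, None]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            rank = r
            kept.append(col)
        else:
            aliased.append(name)
    return aliased


def compliance_odds_ratio(
    results: pd.DataFrame,
    cbcf_min: float | None = None,
    dbit_abs_max: float | None = None,
) -> OddsRatioResult:
    """Odds ratio for reaching the quality criteria with Gadoterate.

    A recording is compliant when cbcf >= ``cbcf_min`` and |dBIT| <=
    ``dbit_abs_max``; thresholds default to the study-wide medians and
    are reported back with the result.  The 2x2 table (CM type x
    compliance) yields a Fisher exact p-value; when a cell is empty the
    odds ratio uses the Haldane-Anscombe +0.5 correction and is flagged.
    """
    valid = results[results["valid"].astype(bool)]
    cm = valid["cm_type"].astype(str).str.lower()
    if not {"gadoterate", "gadoteridol"} <= set(cm):
        raise StatsError("both contrast-medium types must be present")
    if cbcf_min is None:
        cbcf_min = float(valid["cbcf"].median())
    if dbit_abs_max is None:
        dbit_abs_max = float(valid["dbit_abs"].median())
    compliant = (valid["cbcf"] >= cbcf_min) & (valid["dbit_abs"] <= dbit_abs_max)
    a = int(((cm == "gadoterate") & compliant).sum())
    b = int(((cm == "gadoterate") & ~compliant).sum())
    c = int(((cm == "gadoteridol") & compliant).sum())
    d = int(((cm == "gadoteridol") & ~compliant).sum())
    return _odds_ratio_from_counts(
        ((a, b), (c, d)), cbcf_min=cbcf_min, dbit_abs_max=dbit_abs_max
    )


def _odds_ratio_from_counts(
    table: tuple[tuple[int, int], tuple[int, int]],
    cbcf_min: float | None = None,
    dbit_abs_max: float | None = None,
) -> OddsRatioResult:
    (a, b), (c, d) = table
    corrected = 0 in (a, b, c, d)
    if corrected:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    _, p = sps.fisher_exact([[a, b], [c, d]])
    return OddsRatioResult(
        odds_ratio=float(orr),
        p_value=float(p),
        table=((a, b), (c, d)),
        corrected=corrected,
        cbcf_min=cbcf_min,
        dbit_abs_max=dbit_abs_max,
    )


def odds_ratio_from_counts(
    table: Sequence[Sequence[int]],
) -> OddsRatioResult:
    """Odds ratio and Fisher exact p for an explicit 2x2 count table."""
    (a, b), (c, d) = table
    return _odds_ratio_from_counts(((int(a), int(b)), (int(c), int(d))))


def rank_summary(
    table: pd.DataFrame, metric: str, by: str = "injector_id"
) -> pd.DataFrame:
    """Median and [range] per injector, ordered best-first.

    Best-first means descending median for cbcf and ascending for
    dbit_abs (lower time error is better).
    """
    if metric not in ("cbcf", "dbit_abs"):
        raise StatsError(f"metric must be cbcf or dbit_abs, got {metric!r}")
    valid = table[table["valid"].astype(bool)]
    if valid.empty:
        raise StatsError("no valid results to summarise")
    grouped = valid.groupby(by)[metric].agg(
        median="median", min="min", max="max", n="count"
    )
    ascending = metric == "dbit_abs"
    out = grouped.sort_values("median", ascending=ascending).reset_index()
    out.insert(1, "rank", np.arange(1, len(out) + 1))
    return out
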