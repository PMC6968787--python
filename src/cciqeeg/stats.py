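"""Group-level inference for binned spectra and scalar features.

Two procedures cover the analysis designs used here:

* a fixed-effects least-squares model of binned power (or coherence) on
  experimental factors (strain, side, timepoint), with frequency bin as a
  blocking covariate for the construct-level F test, LogWorth = -log10(p)
  as the effect-strength scale, and independent per-bin F tests to report
  maximal contiguous significant frequency intervals;
* one-way ANOVA with Tukey's HSD (Tukey-Kramer for unequal n) for scalar
  features, using the exact studentized-range distribution.

Per-bin p-values are reported uncorrected, matching the bracketed-interval
reporting convention; an optional Benjamini-Hochberg flag is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .config import BIN_FREQS


def logworth(p: float | np.ndarray) -> float | np.ndarray:
    """-log10(p): 2 means p = 0.01; larger is stronger evidence."""
    return -np.log10(p)


@dataclass
class EffectTest:
    F: float
    df: tuple[float, float]
    p: float

    @property
    def logworth(self) -> float:
        return float(logworth(self.p))


@dataclass
class BinwiseResult:
    """Construct-level effects plus per-bin tests and significant intervals."""

    effects: dict[str, EffectTest]
    perbin_p: dict[str, np.ndarray]
    intervals: dict[str, list[tuple[float, float]]]
    alpha: float = 0.05
    freqs: np.ndarray = field(default_factory=lambda: BIN_FREQS.copy())


@dataclass
class TukeyComparison:
    group1: str
    group2: str
    diff: float  # mean(group2) - mean(group1)
    p_adj: float


@dataclass
class TukeyResult:
    F: float
    df: tuple[int, int]
    p: float
    comparisons: list[TukeyComparison]
    group_means: dict[str, float]

    def pair(self, a, b) -> TukeyComparison:
        for c in self.comparisons:
            if {c.group1, c.group2} == {str(a), str(b)}:
                return c
        raise KeyError((a, b))


def extract_intervals(
    pvals: np.ndarray, alpha: float = 0.05, freqs: np.ndarray | None = None
) -> list[tuple[float, float]]:
    """Maximal runs of consecutive significant bins as [low, high] Hz pairs."""
    pvals = np.asarray(pvals, dtype=float)
    freqs = BIN_FREQS if freqs is None else np.asarray(freqs)
    if len(pvals) != len(freqs):
        raise ValueError("one p-value per frequency bin required")
    sig = pvals < alpha
    intervals = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            intervals.append((float(freqs[start]), float(freqs[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(freqs[start]), float(freqs[-1])))
    return intervals


def _check_design(df: pd.DataFrame, factors: list[str]) -> None:
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    for fa, fb in itertools.combinations(factors, 2):
        ct = pd.crosstab(df[fa], df[fb]).to_numpy()
        if (np.count_nonzero(ct, axis=1) == 1).all() and (
            np.count_nonzero(ct, axis=0) == 1
        ).all():
            raise ValueError(f"factors {fa!r} and {fb!r} are aliased (rank-deficient design)")
    per_cell = df.groupby(factors + ["freq"], observed=True).size()
    if per_cell.min() < 2:
        raise ValueError("each design cell needs >= 2 subjects per cell")


def _perbin_pvalues(
    df: pd.DataFrame, factors: list[str], value: str
) -> dict[str, np.ndarray]:
    """Independent per-bin F tests for each factor (one model per bin)."""
    out = {f: np.ones(len(BIN_FREQS)) for f in factors}
    if len(factors) == 1:
        fac = factors[0]
        # vectorized one-way ANOVA across all 64 bins at once
        groups = []
        for _, sub in df.groupby(fac, observed=True):
            piv = sub.pivot_table(index="subject", columns="freq", values=value)
            groups.append(piv.to_numpy())
        res = sst.f_oneway(*groups, axis=0)
        out[fac] = np.asarray(res.pvalue)
        return out
    rhs = " + ".join(f"C({f})" for f in factors)
    for i, f0 in enumerate(BIN_FREQS):
        sub = df[np.isclose(df["freq"], f0)]
        fit = smf.ols(f"{value} ~ {rhs}", data=sub).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        for f in factors:
            out[f][i] = float(table.loc[f"C({f})", "PR(>F)"])
    return out


def binwise_model(
    df: pd.DataFrame,
    factors: list[str] | str,
    value: str = "power",
    alpha: float = 0.05,
    fdr: bool = False,
) -> BinwiseResult:
    """Least-squares construct-effect tests across the 64-bin spectrum.

    *df* is long-form with columns ``subject``, ``freq``, *value*, and one
    column per factor.  The construct-level test fits
    ``value ~ C(freq) + C(factor) + ...`` jointly across bins and reports
    each factor's partial F, p, and LogWorth; per-bin F tests (independent
    fits) feed the significant-interval extraction at level *alpha*.
    Setting ``fdr`` applies Benjamini-Hochberg to the per-bin p-values
    before interval extraction (off by default).
    """
    factors = [factors] if isinstance(factors, str) else list(factors)
    required = {"subject", "freq", value, *factors}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    _check_design(df, factors)

    # The construct-level test for a factor is the joint F-test of its main
    # effect and its bin interaction (a spectrum-wide effect is a shape
    # difference; after per-subject normalization a pure main effect would
    # vanish even when the spectra differ at every frequency).
    def _rhs(which: list[str]) -> str:
        terms = ["C(freq)"]
        for f in which:
            terms += [f"C({f})", f"C({f}):C(freq)"]
        return " + ".join(terms)

    full = smf.ols(f"{value} ~ {_rhs(factors)}", data=df).fit()
    effects = {}
    for f in factors:
        reduced = smf.ols(
            f"{value} ~ {_rhs([g for g in factors if g != f])}", data=df
        ).fit()
        f_stat, p_val, df_num = full.compare_f_test(reduced)
        # guard against p underflowing to exactly 0 (keeps LogWorth finite)
        p_val = max(float(p_val), 5e-324)
        effects[f] = EffectTest(
            F=float(f_stat), df=(float(df_num), float(full.df_resid)), p=p_val
        )

    perbin = _perbin_pvalues(df, factors, value)
    intervals = {}
    for f in factors:
        p = perbin[f]
        if fdr:
            p = multipletests(p, alpha=alpha, method="fdr_bh")[1]
        intervals[f] = extract_intervals(p, alpha)
    return BinwiseResult(
        effects=effects, perbin_p=perbin, intervals=intervals, alpha=alpha
    )


def anova_tukey(values, groups, alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA with Tukey-Kramer HSD pairwise comparisons.

    Adjusted p-values come from the exact studentized-range distribution
    with the pooled-error degrees of freedom; with two groups the adjusted
    p equals the pooled two-sample t-test p.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [str(g) for g in pd.unique(groups)]
    levels.sort()
    samples = {g: values[groups.astype(str) == g] for g in levels}
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations")
    k = len(levels)
    n_tot = len(values)
    df_err = n_tot - k
    means = {g: float(v.mean()) for g, v in samples.items()}
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in samples.values())
    mse = sse / df_err
    grand = float(values.mean())
    ssb = sum(len(v) * (float(v.mean()) - grand) ** 2 for v in samples.values())
    # explicit decomposition: f_oneway returns NaN for degenerate inputs
    f_stat = max(0.0, (ssb / (k - 1)) / mse) if mse > 0 else np.inf
    p_omni = float(sst.f.sf(f_stat, k - 1, df_err))
    comparisons = []
    for g1, g2 in itertools.combinations(levels, 2):
        v1, v2 = samples[g1], samples[g2]
        diff = float(v2.mean() - v1.mean())
        se = np.sqrt(mse / 2.0 * (1.0 / len(v1) + 1.0 / len(v2)))
        if se == 0:
            p_adj = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p_adj = float(sst.studentized_range.sf(q, k, df_err))
        comparisons.append(
            TukeyComparison(group1=g1, group2=g2, diff=diff, p_adj=min(1.0, p_adj))
        )
    return TukeyResult(
        F=float(f_stat), df=(k - 1, df_err), p=float(p_omni),
        comparisons=comparisons, group_means=means,
    )
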