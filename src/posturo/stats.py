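"""Nonparametric repeated-measures statistics for condition comparisons.

The pipeline mirrors standard practice for small within-subject
posturography cohorts: a Shapiro–Wilk normality screen (reported, never
used to gate), a Friedman omnibus across the k conditions, a-priori
pairwise Wilcoxon signed-rank contrasts, and the Rosenthal effect size
r = |Z|/√n.  No multiplicity adjustment is applied to the a-priori
contrasts; reports carry an explicit caveat.

The Wilcoxon and Friedman statistics are implemented here with fully pinned
semantics (midranks, tie-corrected variances, exact 2^n sign enumeration
for small samples, optional Pratt zero handling); scipy equivalents serve
as independent cross-checks in the test suite.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StructuralError
from .measures import MEASURE_NAMES

#: the four a-priori condition contrasts, (test condition, reference):
#: 2 vs 1 isolates the somatosensory contribution, 4 vs 1 the visual,
#: 5 vs 1 and 6 vs 5 the vestibular.
DEFAULT_CONTRASTS: tuple[tuple[int, int], ...] = ((2, 1), (4, 1), (5, 1), (6, 5))

#: largest effective n for which the exact sign-flip distribution is used
EXACT_N_MAX = 15


@dataclass(frozen=True)
class OmnibusResult:
    """Friedman omnibus over k conditions on n complete blocks."""

    statistic: float  # chi-square scale (tie-corrected)
    df: int
    p_value: float
    k: int
    n: int
    method: str = "chi2"


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise signed-rank contrast."""

    contrast: tuple[int, int]  # (test condition, reference condition)
    w_statistic: float         # W+, sum of positive-difference ranks
    z_value: float             # normal-approximation Z (reported in all modes)
    p_value: float
    effect_r: float            # Rosenthal r = |Z|/sqrt(n)
    n_effective: int           # pairs after zero handling
    n_excluded: int = 0        # pairs dropped (zeros and/or flagged values)
    degenerate: bool = False
    method: str = "exact"


class CohortMeasureTable:
    """Complete participants × conditions block of one measure.

    Wraps a wide DataFrame (index = participant, columns = condition);
    raises listing the missing cells if the design is incomplete.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        df.columns = [int(c) for c in df.columns]
        df = df[sorted(df.columns)]
        missing = [
            (p, c) for p in df.index for c in df.columns
            if pd.isna(df.at[p, c])
        ]
        if missing:
            raise StructuralError(
                f"incomplete block design; missing (participant, condition) "
                f"cells: {missing[:10]}{'...' if len(missing) > 10 else ''}"
            )
        self.data = df

    @property
    def n(self) -> int:
        return len(self.data.index)

    @property
    def k(self) -> int:
        return len(self.data.columns)

    def condition(self, c: int) -> np.ndarray:
        if c not in self.data.columns:
            raise StructuralError(f"condition {c} not present in table")
        return self.data[c].to_numpy(dtype=float)

    @classmethod
    def from_long(cls, long_df: pd.DataFrame, measure: str,
                  drop_flagged: bool = True) -> "CohortMeasureTable":
        """Pivot a long measures table (already trial-aggregated) for one
        measure.  Flagged (undefined) values become missing cells; callers
        doing per-contrast listwise exclusion should pass
        ``drop_flagged=False`` and handle NaNs themselves."""
        sub = long_df[long_df["measure"] == measure]
        if drop_flagged and "flag" in sub.columns:
            sub = sub[(sub["flag"] == "") | sub["flag"].isna()]
        wide = sub.pivot_table(index="participant", columns="condition",
                               values="value", aggfunc="mean")
        return cls(wide)


def normality_screen(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and two-sided p for one condition's sample.

    Report-only: the nonparametric pipeline never branches on it.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise StructuralError(
            f"Shapiro–Wilk needs 3 <= n <= 5000, got n={x.size}"
        )
    if np.ptp(x) == 0:
        raise StructuralError("normality screen undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def friedman_test(
    table: CohortMeasureTable,
    permutation_threshold: int = 8,
    n_permutations: int = 20000,
    seed: int | None = 0,
) -> OmnibusResult:
    """Friedman omnibus with within-block midranks and tie correction.

    χ²_F = [12/(n·k(k+1))]·Σ(R_j²) − 3n(k+1), divided by the tie-correction
    factor 1 − Σ(t³−t)/(n·k(k²−1)); p from χ²(k−1) for n ≥
    ``permutation_threshold``, otherwise a seeded within-block permutation
    p-value.
    """
    n, k = table.n, table.k
    if k < 3:
        raise StructuralError(f"Friedman needs k >= 3 conditions, got {k}")
    values = table.data.to_numpy(dtype=float)
    ranks = sps.rankdata(values, method="average", axis=1)
    ties = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    corr = 1.0 - ties / (n * k * (k**2 - 1))

    def statistic(rank_mat: np.ndarray) -> np.ndarray:
        # rank_mat: (..., n, k) within-block midranks
        col_sums = rank_mat.sum(axis=-2)
        chi2 = (12.0 / (n * k * (k + 1)) * np.sum(col_sums**2, axis=-1)
                - 3.0 * n * (k + 1))
        if corr <= 0:
            return np.zeros_like(chi2)  # every block fully tied
        return chi2 / corr

    chi2_f = float(statistic(ranks))
    df = k - 1
    if n >= permutation_threshold:
        p = float(sps.chi2.sf(chi2_f, df)) if chi2_f > 0 else 1.0
        method = "chi2"
    else:
        # permuting values within a block permutes its midranks, and the
        # tie pattern (hence corr) is permutation-invariant
        rng = np.random.default_rng(seed)
        perm = rng.permuted(
            np.broadcast_to(ranks, (n_permutations, n, k)).copy(), axis=2
        )
        count = int(np.sum(statistic(perm) >= chi2_f - 1e-12))
        p = (1 + count) / (1 + n_permutations)
        method = "permutation"
    return OmnibusResult(statistic=chi2_f, df=df, p_value=min(p, 1.0),
                         k=k, n=n, method=method)


def _signed_rank_core(d: np.ndarray, zero_method: str):
    """Midranks of |d| and W+ under the chosen zero handling.

    Returns (w_plus, ranks_of_nonzero, n_effective, n_zero, mean, var) where
    mean/var describe the null distribution of W+ with tie correction.
    """
    d = np.asarray(d, dtype=float)
    zeros = d == 0
    n_zero = int(zeros.sum())
    if zero_method == "discard":
        dnz = d[~zeros]
        ranks = _midranks(np.abs(dnz))
        n_eff = dnz.size
        w_plus = float(ranks[dnz > 0].sum())
        mean = n_eff * (n_eff + 1) / 4.0
        # tie-corrected variance of W+
        _, counts = np.unique(np.abs(dnz), return_counts=True)
        var = (n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0
               - float(np.sum(counts**3 - counts)) / 48.0)
        return w_plus, dnz, ranks, n_eff, n_zero, mean, var
    elif zero_method == "pratt":
        ranks_all = _midranks(np.abs(d))
        dnz = d[~zeros]
        ranks = ranks_all[~zeros]
        n_all = d.size
        n_eff = dnz.size
        w_plus = float(ranks[dnz > 0].sum())
        mean = (n_all * (n_all + 1) / 4.0) - n_zero * (n_zero + 1) / 4.0
        _, counts = np.unique(np.abs(dnz), return_counts=True)
        var = (n_all * (n_all + 1) * (2 * n_all + 1) / 24.0
               - n_zero * (n_zero + 1) * (2 * n_zero + 1) / 24.0
               - float(np.sum(counts**3 - counts)) / 48.0)
        return w_plus, dnz, ranks, n_eff, n_zero, mean, var
    raise StructuralError(f"unknown zero_method {zero_method!r}")


def _exact_sign_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probability mass of W+ over all 2^n sign assignments of the midranks.

    Midranks are half-integer, so doubling makes them integers and the
    distribution is built by discrete convolution.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: pmf.size - r]
        pmf = 0.5 * (pmf + shifted)
    support = np.arange(total + 1) / 2.0
    return support, pmf


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float],
    mode: Literal["auto", "exact", "approx"] = "auto",
    zero_method: Literal["discard", "pratt"] = "discard",
    continuity: bool = False,
    contrast: tuple[int, int] = (0, 0),
) -> ComparisonResult:
    """Paired Wilcoxon signed-rank test of ``a`` vs reference ``b``.

    Differences d = a − b; zero differences are discarded (classic
    convention; Pratt available).  ``mode='auto'`` uses exact 2^n sign
    enumeration when the effective n ≤ 15, else the normal approximation
    with tie-corrected variance.  The Z value is always reported from the
    approximation formula; r = |Z|/√n with n the number of pairs entering
    the test (before zero removal), matching how paired cohorts report
    Rosenthal's r.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise StructuralError("paired samples must be equal-length 1-D, n >= 1")
    d = a - b
    n_pairs = d.size
    w_plus, dnz, ranks, n_eff, n_zero, mean, var = _signed_rank_core(
        d, zero_method
    )
    if n_eff == 0 or var <= 0:
        return ComparisonResult(
            contrast=contrast, w_statistic=w_plus, z_value=0.0, p_value=1.0,
            effect_r=0.0, n_effective=n_eff, n_excluded=n_zero,
            degenerate=True, method="degenerate",
        )
    cc = 0.5 if continuity else 0.0
    dev = w_plus - mean
    z = (dev - math.copysign(cc, dev) if dev != 0 else 0.0) / math.sqrt(var)

    use_exact = mode == "exact" or (mode == "auto" and n_eff <= EXACT_N_MAX)
    if use_exact:
        support, pmf = _exact_sign_distribution(ranks)
        p_le = float(pmf[support <= w_plus + 1e-9].sum())
        p_ge = float(pmf[support >= w_plus - 1e-9].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        p = 2.0 * float(sps.norm.sf(abs(z)))
        method = "approx"
    return ComparisonResult(
        contrast=contrast, w_statistic=w_plus, z_value=float(z),
        p_value=min(p, 1.0), effect_r=effect_size_r(z, n_pairs),
        n_effective=n_eff, n_excluded=n_zero, degenerate=False, method=method,
    )


def effect_size_r(z_value: float, n: int) -> float:
    """Rosenthal's effect size r = |Z|/√n for rank-based paired tests."""
    if n < 1:
        raise StructuralError("effect_size_r needs n >= 1")
    return abs(float(z_value)) / math.sqrt(n)


def permutation_oracle(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10000,
    seed: int | None = 0,
) -> float:
    """Sign-flip permutation p-value for the paired mean difference.

    Enumerates all 2^n sign patterns when feasible (2^n ≤ n_perm), else
    Monte-Carlo samples them.  Independent of the signed-rank machinery;
    used as a cross-check.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = d.size
    obs = abs(d.mean())
    if obs == 0:
        return 1.0
    if 2**n <= n_perm:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1) * 2 - 1
        means = np.abs((signs * d).mean(axis=1))
        return float(np.mean(means >= obs - 1e-12))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = np.abs((signs * d).mean(axis=1))
    return float((1 + np.sum(means >= obs - 1e-12)) / (1 + n_perm))


@dataclass
class ContrastReport:
    """All contrasts for one measure, plus bookkeeping of exclusions."""

    measure: str
    omnibus: OmnibusResult
    contrasts: list[ComparisonResult] = field(default_factory=list)
    shapiro: dict[int, tuple[float, float]] = field(default_factory=dict)
    n_flag_excluded: dict[tuple[int, int], int] = field(default_factory=dict)


def run_contrasts(
    long_df: pd.DataFrame,
    contrasts: Sequence[tuple[int, int]] = DEFAULT_CONTRASTS,
    measures: Sequence[str] = MEASURE_NAMES,
    alpha: float = 0.05,
) -> list[ContrastReport]:
    """Run the full pipeline on a trial-aggregated long measures table.

    For each measure: Shapiro–Wilk per condition (report-only), Friedman
    omnibus over all conditions, then each a-priori contrast with listwise
    exclusion of participants whose value is flagged in either condition of
    that contrast (counts logged).  No multiplicity adjustment (a-priori
    contrasts); ``alpha`` is carried for report annotation only.
    """
    del alpha  # annotation-level only; kept in the signature for configs
    reports = []
    for measure in measures:
        sub = long_df[long_df["measure"] == measure].copy()
        if sub.empty:
            raise StructuralError(f"measure {measure!r} absent from input")
        sub.loc[sub["flag"].astype(str).str.len() > 0, "value"] = np.nan
        wide = sub.pivot_table(index="participant", columns="condition",
                               values="value", aggfunc="mean", dropna=False)
        # omnibus requires complete blocks: exclude participants with any
        # flagged condition, listwise
        complete = wide.dropna(axis=0)
        table = CohortMeasureTable(complete)
        omnibus = friedman_test(table)
        shapiro = {}
        for c in table.data.columns:
            try:
                shapiro[c] = normality_screen(table.condition(c))
            except StructuralError:
                shapiro[c] = (float("nan"), float("nan"))
        report = ContrastReport(measure=measure, omnibus=omnibus,
                                shapiro=shapiro)
        for test_c, ref_c in contrasts:
            for c in (test_c, ref_c):
                if c not in wide.columns:
                    raise StructuralError(
                        f"contrast ({test_c} vs {ref_c}): condition {c} "
                        f"missing from table"
                    )
            pair = wide[[test_c, ref_c]].dropna(axis=0)
            n_flagged = len(wide.index) - len(pair.index)
            res = wilcoxon_signed_rank(
                pair[test_c].to_numpy(), pair[ref_c].to_numpy(),
                contrast=(test_c, ref_c),
            )
            report.contrasts.append(res)
            report.n_flag_excluded[(test_c, ref_c)] = n_flagged
        reports.append(report)
    return reports


def contrasts_to_frame(reports: Sequence[ContrastReport]) -> pd.DataFrame:
    """Flatten contrast reports to the contrasts CSV schema."""
    rows = []
    for rep in reports:
        for res in rep.contrasts:
            rows.append({
                "measure": rep.measure,
                "contrast": f"{res.contrast[0]}v{res.contrast[1]}",
                "w_statistic": res.w_statistic,
                "z_value": res.z_value,
                "p_value": res.p_value,
                "effect_r": res.effect_r,
                "n_effective": res.n_effective,
                "n_excluded": res.n_excluded
                + rep.n_flag_excluded.get(res.contrast, 0),
                "flags": "degenerate" if res.degenerate else "",
                "method": res.method,
            })
    return pd.DataFrame(rows)


def omnibus_to_frame(reports: Sequence[ContrastReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        rows.append({
            "measure": rep.measure,
            "chi2_f": rep.omnibus.statistic,
            "df": rep.omnibus.df,
            "p_value": rep.omnibus.p_value,
            "k": rep.omnibus.k,
            "n": rep.omnibus.n,
            "method": rep.omnibus.method,
        })
    return pd.DataFrame(rows)
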