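"""Meta-analysis arithmetic for biome-shift studies.

Shift rates and specialist percentages per clade, group summaries
(median/quartiles), one-tailed Welch and paired t-tests comparing single-
against multiple-biome coding, simple linear regression with residual
diagnostics, the proportional decline in shift rate

    B_decline = (B_multiple − B_single) / B_multiple,

and net diversification rates from clade size and stem or crown age
(Magallón–Sanderson estimators).  Fixture tables transcribing the published
clade summaries ship with the package (``load_table``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import log, sqrt

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CladeRecord",
    "shift_rate",
    "specialists_pct",
    "GroupSummary",
    "group_summary",
    "TestResult",
    "welch_one_tailed",
    "paired_one_tailed",
    "OlsResult",
    "ols_fit",
    "DeclineResult",
    "b_decline",
    "DiversificationInput",
    "diversification_rate",
    "load_table",
    "meta_report",
]


@dataclass(frozen=True)
class CladeRecord:
    """One row of a clade summary table (published-study schema)."""

    name: str
    clade_size: int
    specialists: int | None = None
    multiple_biomes: bool = False
    shift_count: int | None = None
    censored: bool = False  # True for "10+"-style counts (floored)

    def __post_init__(self) -> None:
        if self.specialists is not None and not (
            0 <= self.specialists <= self.clade_size
        ):
            raise ValueError(f"{self.name}: specialists outside [0, clade_size]")
        if self.shift_count is not None and self.shift_count < 0:
            raise ValueError(f"{self.name}: negative shift count")

    @property
    def shift_rate(self) -> float | None:
        if self.shift_count is None:
            return None
        return shift_rate(self.shift_count, self.clade_size)


def shift_rate(count: int, clade_size: int) -> float:
    """Biome shifts per species; counts are floored to whole shifts first."""
    if count < 0 or clade_size < 1:
        raise ValueError("count must be >= 0 and clade_size >= 1")
    return int(np.floor(count)) / clade_size


def specialists_pct(specialists: int, clade_size: int) -> float:
    """Percentage of species occupying a single biome."""
    if not 0 <= specialists <= clade_size:
        raise ValueError("specialists must lie in [0, clade_size]")
    return 100.0 * specialists / clade_size


@dataclass(frozen=True)
class GroupSummary:
    median: float
    q1: float
    q3: float
    n: int


def group_summary(rates) -> GroupSummary:
    """Median and quartiles (linear-interpolation, 'type 7') of a group."""
    x = np.asarray(rates, dtype=float)
    if x.size < 1:
        raise ValueError("empty group")
    if np.isnan(x).any():
        raise ValueError("NaN in rates")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return GroupSummary(float(med), float(q1), float(q3), int(x.size))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    tails: str = "one"
    paired: bool = False

    @property
    def df_rounded(self) -> int:
        """Degrees of freedom rounded to the nearest integer for display."""
        return int(round(self.df))


def welch_one_tailed(a, b) -> TestResult:
    """Welch unequal-variance t-test of mean(b) > mean(a), one-tailed.

    ``a`` is the group expected to be smaller (single-biome coding rates),
    ``b`` the larger (multiple-biome coding).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        return TestResult(0.0, float(a.size + b.size - 2), 0.5)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return TestResult(float(res.statistic), float(df), float(res.pvalue))


def paired_one_tailed(single, multiple) -> TestResult:
    """Paired t-test of multiple > single on per-clade rate differences."""
    s, m = np.asarray(single, float), np.asarray(multiple, float)
    if s.shape != m.shape or s.size < 2:
        raise ValueError("groups must be paired with n >= 2")
    d = m - s
    n = d.size
    sd = d.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(d).max())):
        # all differences identical: the statistic is unbounded; report a
        # capped p of 0 (positive shift) / 1 (negative) / 0.5 (no shift)
        if d[0] == 0:
            return TestResult(0.0, n - 1, 0.5, paired=True)
        t = np.inf if d[0] > 0 else -np.inf
        return TestResult(float(t), n - 1, 0.0 if d[0] > 0 else 1.0, paired=True)
    t = d.mean() / (sd / sqrt(n))
    return TestResult(float(t), float(n - 1), float(stats.t.sf(t, n - 1)),
                      paired=True)


@dataclass(frozen=True)
class OlsResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p: float
    residuals: np.ndarray
    fitted: np.ndarray
    qq: tuple[np.ndarray, np.ndarray]  # theoretical vs ordered residuals


def ols_fit(x, y) -> OlsResult:
    """Simple linear regression with residual diagnostics as data."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired x, y with n >= 3")
    lr = stats.linregress(x, y)
    fitted = lr.intercept + lr.slope * x
    resid = y - fitted
    r2 = lr.rvalue**2
    n = x.size
    if r2 >= 1.0:
        f, p = np.inf, 0.0
    else:
        f = (r2 / (1 - r2)) * (n - 2)
        p = float(stats.f.sf(f, 1, n - 2))
    osm, osr = stats.probplot(resid, fit=False)
    return OlsResult(float(lr.slope), float(lr.intercept), float(r2),
                     float(f), (1, n - 2), p, resid, fitted,
                     (np.asarray(osm), np.asarray(osr)))


@dataclass(frozen=True)
class DeclineResult:
    b_single: float
    b_multiple: float

    @property
    def b_decline(self) -> float:
        return (self.b_multiple - self.b_single) / self.b_multiple

    @property
    def percent(self) -> int:
        return round(self.b_decline * 100)


def b_decline(b_multiple: float, b_single: float) -> DeclineResult:
    """Proportional decline in shift rate under single-biome coding."""
    if b_multiple <= 0:
        raise ValueError("B_decline is undefined when B_multiple is 0")
    return DeclineResult(b_single, b_multiple)


@dataclass(frozen=True)
class DiversificationInput:
    n_taxa: int
    t: float          # stem or crown age, Ma
    mode: str = "stem"
    epsilon: float = 0.0  # relative extinction fraction

    def __post_init__(self) -> None:
        if self.mode not in ("stem", "crown"):
            raise ValueError("mode must be 'stem' or 'crown'")
        if self.t <= 0:
            raise ValueError("age must be positive")
        if self.n_taxa < (2 if self.mode == "crown" else 1):
            raise ValueError("n_taxa too small for the chosen mode")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must lie in [0, 1)")


def diversification_rate(inp: DiversificationInput) -> float:
    """Net diversification (species/Ma) from clade size and age.

    Method-of-moments estimators conditional on clade survival: with
    extinction fraction ε = 0 these reduce to ln(n)/t for stem ages and
    (ln n − ln 2)/t for crown ages.
    """
    n, t, eps = inp.n_taxa, inp.t, inp.epsilon
    if inp.mode == "stem":
        return log(n * (1 - eps) + eps) / t
    inner = (
        n * (1 - eps**2) / 2
        + 2 * eps
        + (1 - eps) / 2 * sqrt(n * (n * eps**2 - 8 * eps + 2 * n * eps + n))
    )
    return (log(inner) - log(2)) / t


# ---------------------------------------------------------------------------
# packaged clade-summary fixtures and the composite report


def load_table(name: str) -> pd.DataFrame:
    """Load a packaged clade-summary fixture (``"table1" .. "table4"``)."""
    path = resources.files("biomeshift.data").joinpath(f"{name}.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def meta_report(table1: pd.DataFrame | None = None,
                table2: pd.DataFrame | None = None,
                table3: pd.DataFrame | None = None) -> dict:
    """Full meta-analysis over the clade summary tables.

    Returns group summaries of shift rates by coding approach, the one-tailed
    Welch test on the non-focal-study clades, the paired test and per-clade
    B_decline for the clades analysed under both codings, tendency changes
    in the conservatism proportions, regressions of rate and B_decline on
    specialist percentage, and diversification rates.
    """
    t1 = load_table("table1") if table1 is None else table1
    t2 = load_table("table2") if table2 is None else table2
    t3 = load_table("table3") if table3 is None else table3

    t1 = t1.copy()
    # For the transcribed published studies the rate column is itself data
    # (their own reported rates, which do not always equal count/size); only
    # the focal clades' rates are recomputed from counts at full precision.
    t1["rate"] = [
        shift_rate(c, n) if focal else r
        for c, n, r, focal in zip(t1["shift_count"], t1["clade_size"],
                                  t1["rate_printed"], t1["focal"])
    ]
    single = t1[~t1["multiple_biomes"]]
    multi = t1[t1["multiple_biomes"]]
    nz = t1["focal"]
    report: dict = {
        "summary_single": group_summary(single["rate"]),
        "summary_multiple": group_summary(multi["rate"]),
        "welch_non_focal": welch_one_tailed(
            single["rate"], t1[t1["multiple_biomes"] & ~nz]["rate"]
        ),
        "welch_all": welch_one_tailed(single["rate"], multi["rate"]),
    }

    paired = paired_one_tailed(t3["rate_single"], t3["rate_multiple"])
    decl = {
        row["clade"]: b_decline(row["rate_multiple"], row["rate_single"])
        for _, row in t3.iterrows()
    }
    tend = {
        row["clade"]: tendency_change_row(row["p_single"], row["p_multiple"])
        for _, row in t3.iterrows()
    }
    report.update(
        paired=paired,
        b_decline=decl,
        b_decline_min_pct=min(d.percent for d in decl.values()),
        b_decline_max_pct=max(d.percent for d in decl.values()),
        tendency=tend,
    )

    spec_ok = t1["specialists"].notna()
    pct = 100.0 * t1.loc[spec_ok, "specialists"] / t1.loc[spec_ok, "clade_size"]
    report["regression_rate_vs_specialists"] = ols_fit(pct, t1.loc[spec_ok, "rate"])
    t3m = t3.merge(
        t1[nz][["clade", "specialists", "clade_size"]], on="clade", how="inner"
    )
    if len(t3m) >= 3:
        decl_vals = [
            b_decline(m, s).b_decline
            for m, s in zip(t3m["rate_multiple"], t3m["rate_single"])
        ]
        report["regression_decline_vs_specialists"] = ols_fit(
            100.0 * t3m["specialists"] / t3m["clade_size"], decl_vals
        )

    divs = {}
    for _, row in t2.iterrows():
        mode = row["div_mode"]
        age = row["stem_age"] if mode == "stem" else row["crown_age"]
        if pd.isna(age):
            continue
        divs[row["clade"]] = diversification_rate(
            DiversificationInput(int(row["n_total"]), float(age), mode)
        )
    report["diversification"] = divs
    return report


def tendency_change_row(p_single: float, p_multiple: float):
    from .conservatism import tendency_change

    return tendency_change(p_single, p_multiple)
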