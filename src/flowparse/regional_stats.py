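"""Regional and behavioural statistics for the motion-condition design.

Each motion-sensitive region yields a subjects x conditions table of
percent-signal-change values for the four motion conditions (Offboard,
Onboard, Joint, Disjoint; Static is excluded from the regional
analysis).  The module implements:

* a repeated-measures one-way ANOVA (condition as factor, subjects —
  or matched trial sets — as the repeated unit);
* Duncan's multiple range test as the post-hoc procedure, with
  studentized-range critical values at protection level
  1 - (1 - alpha)^(r-1) for spans of r ordered means and the classical
  step-down rule;
* one-sample t-tests on parametric-modulator loadings with Bonferroni
  correction over regions;
* Pearson correlations between subjective ratings and objective motion
  parameters;
* the flow-parsing contrast: Joint and Onboard contain the same amount
  of visual self-motion, but only in Joint is the object really moving
  (while fixed on screen), so a reliably positive Joint - Onboard
  response difference indexes extraction of real object motion from
  the optic flow;
* a coarse functional-profile classification (self-, object- or
  complex-motion preferring) from the post-hoc pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ANOVA_CONDITIONS = ("Offboard", "Onboard", "Joint", "Disjoint")


@dataclass
class RegionResponseTable:
    """PSC values for one region: rows = matched units, cols = conditions."""

    values: pd.DataFrame
    region: str = ""

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("response table has missing cells")

    def motion_conditions(self) -> pd.DataFrame:
        """Restrict to the four motion conditions analysed regionally."""
        missing = [c for c in ANOVA_CONDITIONS if c not in self.values.columns]
        if missing:
            raise KeyError(f"table lacks conditions {missing}")
        return self.values[list(ANOVA_CONDITIONS)]


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p_value: float
    condition_means: pd.Series
    ms_residual: float
    n_units: int


@dataclass
class PosthocResult:
    """Duncan multiple-range decisions over all condition pairs."""

    decisions: pd.DataFrame  # columns: a, b, span, diff, critical, significant
    alpha: float

    def significant_pairs(self) -> set[frozenset]:
        sig = self.decisions[self.decisions["significant"]]
        return {frozenset((r.a, r.b)) for r in sig.itertuples()}

    def pair(self, a: str, b: str) -> pd.Series:
        d = self.decisions
        row = d[((d.a == a) & (d.b == b)) | ((d.a == b) & (d.b == a))]
        if row.empty:
            raise KeyError(f"no decision for pair ({a}, {b})")
        return row.iloc[0]


def rm_anova_oneway(
    table: RegionResponseTable | pd.DataFrame, restrict_motion: bool = True
) -> AnovaResult:
    """Repeated-measures one-way ANOVA with condition as factor.

    Sums of squares partition into condition, unit (subject or matched
    trial set) and residual; F = MS_condition / MS_residual with
    degrees of freedom (k - 1, (k - 1)(n - 1)).  A table with zero
    residual and zero condition variance is degenerate and reported as
    F = 0, p = 1.
    """
    if isinstance(table, RegionResponseTable):
        data = table.motion_conditions() if restrict_motion else table.values
    else:
        data = table
        if data.isna().any().any():
            raise ValueError("response table has missing cells")
    y = data.to_numpy(dtype=float)
    n, k = y.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 conditions and 2 units")
    grand = y.mean()
    ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_unit = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_resid = ss_total - ss_cond - ss_unit
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_resid = ss_resid / df2
    if ms_resid <= 0:
        if ms_cond <= 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat = ms_cond / ms_resid
        p = float(stats.f.sf(f_stat, df1, df2))
    return AnovaResult(
        F=float(f_stat),
        df1=df1,
        df2=df2,
        p_value=p,
        condition_means=data.mean(axis=0),
        ms_residual=float(max(ms_resid, 0.0)),
        n_units=n,
    )


def duncan_critical_value(
    alpha: float, span: int, df2: int, ms_residual: float, n: int
) -> float:
    """Duncan critical difference for a span of ``span`` ordered means.

    Uses the studentized-range quantile at protection level
    1 - (1 - alpha)^(span - 1) and the standard error sqrt(MS_res / n).
    """
    level = 1.0 - (1.0 - alpha) ** (span - 1)
    q = stats.studentized_range.ppf(1.0 - level, span, df2)
    return float(q * np.sqrt(ms_residual / n))


def duncan_posthoc(
    table: RegionResponseTable | pd.DataFrame,
    alpha: float = 0.05,
    anova: AnovaResult | None = None,
) -> PosthocResult:
    """Duncan's multiple range test on the condition means.

    Means are ordered and spans tested widest-first; a span whose range
    does not exceed its critical value is declared homogeneous and no
    pair inside it is ever called significant (the step-down
    protection).  For two conditions the procedure reduces to an
    unprotected LSD-style comparison at level alpha.
    """
    anova = anova or rm_anova_oneway(table)
    means = anova.condition_means.sort_values()
    names = list(means.index)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 conditions")

    sig = {}
    homogeneous: list[tuple[int, int]] = []

    def inside_homogeneous(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in homogeneous)

    records = []
    for span in range(k, 1, -1):
        for i in range(k - span + 1):
            j = i + span - 1
            a, b = names[i], names[j]
            diff = float(means.iloc[j] - means.iloc[i])
            crit = duncan_critical_value(
                alpha, span, anova.df2, anova.ms_residual, anova.n_units
            )
            if inside_homogeneous(i, j):
                significant = False
            else:
                significant = diff > crit
                if not significant:
                    homogeneous.append((i, j))
            records.append(
                {
                    "a": a,
                    "b": b,
                    "span": span,
                    "diff": diff,
                    "critical": crit,
                    "significant": significant,
                }
            )
    return PosthocResult(pd.DataFrame.from_records(records), alpha)


@dataclass
class TTestDecision:
    region: str
    modulator: str
    mean: float
    t: float
    p_value: float
    significant: bool
    degenerate: bool = False


def modulator_ttests(
    loadings: pd.DataFrame, n_regions: int, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sample t-tests of modulator loadings against zero.

    ``loadings`` is long-format with columns region, modulator, value
    (one row per subject).  Each (region, modulator) cell is tested at
    the Bonferroni-corrected level alpha / n_regions; the sign of the
    mean loading indicates the direction of the modulation (a positive
    spread-of-motion loading, for instance, marks a preference for
    incoherent motion).  Zero-variance nonzero-mean cells are flagged
    degenerate and reported significant with infinite t.
    """
    required = {"region", "modulator", "value"}
    if not required <= set(loadings.columns):
        raise ValueError(f"loadings table needs columns {sorted(required)}")
    threshold = alpha / n_regions
    rows = []
    for (region, modulator), grp in loadings.groupby(
        ["region", "modulator"], sort=True
    ):
        v = grp["value"].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(
                f"need >= 2 subjects for {region}/{modulator}, got {v.size}"
            )
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        if sd == 0:
            if mean == 0:
                rows.append(
                    TTestDecision(region, modulator, 0.0, 0.0, 1.0, False)
                )
            else:
                rows.append(
                    TTestDecision(
                        region, modulator, mean,
                        float(np.sign(mean)) * np.inf, 0.0, True, True,
                    )
                )
            continue
        t, p = stats.ttest_1samp(v, 0.0)
        rows.append(
            TTestDecision(
                region, modulator, mean, float(t), float(p), bool(p < threshold)
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class FlowParsingResult:
    index: float           # mean Joint - Onboard PSC difference
    t: float
    p_value: float
    flow_parsing: bool     # positive and significant


def flow_parsing_index(
    table: RegionResponseTable | pd.DataFrame, alpha: float = 0.05
) -> FlowParsingResult:
    """Joint-vs-Onboard contrast: the real-motion-extraction index.

    Both conditions carry the same amount of visual self-motion; only
    in Joint does the (screen-stationary) object really move, so a
    positive, significant paired difference marks a region that
    extracts object motion from the optic flow rather than from retinal
    displacement.
    """
    data = table.values if isinstance(table, RegionResponseTable) else table
    for cond in ("Joint", "Onboard"):
        if cond not in data.columns:
            raise KeyError(f"table lacks condition {cond!r}")
    diff = data["Joint"].to_numpy(float) - data["Onboard"].to_numpy(float)
    index = float(diff.mean())
    if np.std(diff, ddof=1) == 0:
        t, p = (0.0, 1.0) if index == 0 else (float(np.sign(index)) * np.inf, 0.0)
    else:
        t, p = stats.ttest_1samp(diff, 0.0)
    return FlowParsingResult(
        index=index,
        t=float(t),
        p_value=float(p),
        flow_parsing=bool(index > 0 and p < alpha),
    )


@dataclass
class ProfileResult:
    label: str             # self_preferring | object_preferring |
                           # complex_preferring | unclassified
    flow_parsing: bool
    details: dict = field(default_factory=dict)


def classify_profile(
    table: RegionResponseTable | pd.DataFrame,
    posthoc: PosthocResult | None = None,
    alpha: float = 0.05,
) -> ProfileResult:
    """Classify a region's condition-preference profile.

    The Onboard-vs-Offboard comparison separates pure self- from pure
    object-motion preference; regions with no pure-motion preference
    but a reliable advantage of Disjoint over both pure conditions are
    complex-motion preferring.  The flow-parsing flag comes from the
    Joint-vs-Onboard contrast.
    """
    data = table.values if isinstance(table, RegionResponseTable) else table
    posthoc = posthoc or duncan_posthoc(
        data[list(ANOVA_CONDITIONS)], alpha=alpha
    )
    means = data[list(ANOVA_CONDITIONS)].mean(axis=0)

    def sig(a: str, b: str) -> bool:
        return bool(posthoc.pair(a, b)["significant"])

    on_off = sig("Onboard", "Offboard")
    label = "unclassified"
    if on_off and means["Onboard"] > means["Offboard"]:
        label = "self_preferring"
    elif on_off and means["Offboard"] > means["Onboard"]:
        label = "object_preferring"
    elif (
        not on_off
        and sig("Disjoint", "Onboard")
        and sig("Disjoint", "Offboard")
        and means["Disjoint"] > means["Onboard"]
        and means["Disjoint"] > means["Offboard"]
    ):
        label = "complex_preferring"

    fp = flow_parsing_index(data, alpha=alpha)
    return ProfileResult(
        label=label,
        flow_parsing=fp.flow_parsing,
        details={
            "means": means.to_dict(),
            "onboard_vs_offboard_significant": on_off,
            "flow_parsing_index": fp.index,
            "flow_parsing_p": fp.p_value,
        },
    )


def region_report(
    table: RegionResponseTable, alpha: float = 0.05
) -> dict:
    """Full per-region analysis: ANOVA, Duncan pairs, profile, flow parsing."""
    anova = rm_anova_oneway(table)
    posthoc = duncan_posthoc(table, alpha=alpha, anova=anova)
    profile = classify_profile(table, posthoc, alpha=alpha)
    fp = flow_parsing_index(table, alpha=alpha)
    return {
        "region": table.region,
        "anova": {
            "F": anova.F,
            "df": [anova.df1, anova.df2],
            "p": anova.p_value,
            "means": anova.condition_means.to_dict(),
        },
        "posthoc": posthoc.decisions.to_dict(orient="records"),
        "profile": profile.label,
        "flow_parsing": fp.flow_parsing,
        "flow_parsing_index": fp.index,
    }
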