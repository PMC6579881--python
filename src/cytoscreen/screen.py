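"""Antibody-screen summary statistics.

For every (donor, treatment, profiling subset, antibody) cell of the
screen the summary holds the median readout intensity (arcsinh units)
and the percent of events positive for the antibody, where "positive"
means above the 99th percentile of the blank well -- the well with no
primary antibody, whose readout distribution is pure background.  By
construction the blank well itself scores ~1% positive.

Two downstream analyses build on the summary.  Fixation
classification compares fixed vs fresh medians per antibody: the
median log10 fold change over expressing subsets classifies each
antibody as gain, loss, or unchanged at a fold threshold (default
2-fold).  The differential-marker test regresses, per donor, each
antibody's percent positive in one profiling subset on its percent
positive in a sister subset and flags antibodies whose absolute
standardized residual exceeds a cutoff (default 2) in every donor
with a consistent direction -- the consensus rule that surfaced the
MAIT-like CD161hi markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fcs import DEFAULT_COFACTOR

__all__ = [
    "ScreenSummary",
    "FixationReport",
    "blank_threshold",
    "percent_positive",
    "summarize_screen",
    "fixation_classify",
    "differential_markers",
]


def blank_threshold(blank_values) -> float:
    """99th percentile (linear interpolation) of the blank well's readout."""
    v = np.asarray(blank_values, dtype=float)
    if v.size == 0:
        raise ValueError("blank well has no events")
    return float(np.percentile(v, 99))


def percent_positive(values, threshold: float) -> float:
    """Percent of values strictly above the threshold; empty input -> 0."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        warnings.warn("percent_positive of empty input; returning 0")
        return 0.0
    return 100.0 * float(np.mean(v > threshold))


@dataclass
class ScreenSummary:
    """Long-format screen table plus the blank thresholds used."""

    table: pd.DataFrame  # donor, treatment, subset, antibody, n_events, median, pct_positive
    blank_thresholds: dict[tuple[str, str], float] = field(default_factory=dict)

    def grid(self, value: str = "pct_positive") -> pd.DataFrame:
        return self.table.pivot_table(
            index=["donor", "treatment", "antibody"], columns="subset",
            values=value, aggfunc="first",
        )


def summarize_screen(
    events: pd.DataFrame,
    blank_antibody: str = "Blank",
    value_col: str = "value",
    subset_col: str = "profiling_subset",
) -> ScreenSummary:
    """Summarize per-event screen readout into the screen table.

    ``events`` is a long per-event frame with columns ``donor``,
    ``treatment``, ``antibody``, ``subset_col`` and ``value_col``
    (arcsinh readout).  One blank threshold is computed per
    (donor, treatment) from all events of the blank antibody's well;
    every (donor, treatment, subset, antibody) combination present in
    that condition's grid is emitted, with null statistics when it has
    no events.
    """
    required = {"donor", "treatment", "antibody", subset_col, value_col}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events frame lacks columns: {sorted(missing)}")

    thresholds: dict[tuple[str, str], float] = {}
    rows = []
    for (donor, treatment), cond in events.groupby(["donor", "treatment"], sort=True):
        blank = cond.loc[cond["antibody"] == blank_antibody, value_col]
        if blank.empty:
            raise ValueError(
                f"blank antibody {blank_antibody!r} missing for ({donor}, {treatment})"
            )
        thr = blank_threshold(blank.to_numpy())
        thresholds[(donor, treatment)] = thr
        subsets = sorted(cond[subset_col].unique())
        antibodies = sorted(cond["antibody"].unique())
        grouped = {
            key: grp[value_col].to_numpy()
            for key, grp in cond.groupby([subset_col, "antibody"], sort=True)
        }
        for subset in subsets:
            for antibody in antibodies:
                v = grouped.get((subset, antibody))
                if v is None or v.size == 0:
                    rows.append(
                        {"donor": donor, "treatment": treatment, "subset": subset,
                         "antibody": antibody, "n_events": 0,
                         "median": np.nan, "pct_positive": np.nan}
                    )
                else:
                    rows.append(
                        {"donor": donor, "treatment": treatment, "subset": subset,
                         "antibody": antibody, "n_events": int(v.size),
                         "median": float(np.median(v)),
                         "pct_positive": percent_positive(v, thr)}
                    )
    return ScreenSummary(table=pd.DataFrame(rows), blank_thresholds=thresholds)


@dataclass
class FixationReport:
    """Per-(antibody, subset) fold changes and per-antibody classes."""

    per_subset: pd.DataFrame   # antibody, subset, log10_ratio
    per_antibody: pd.DataFrame # antibody, summary_ratio, class
    expressed_antibodies: list[str]
    fold_threshold: float

    def counts(self) -> dict[str, int]:
        c = self.per_antibody["class"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("gain", "loss", "unchanged")}

    @property
    def percent_unchanged(self) -> float:
        n = len(self.per_antibody)
        return 100.0 * self.counts()["unchanged"] / n if n else float("nan")


def fixation_classify(
    summary_fresh: ScreenSummary,
    summary_fixed: ScreenSummary,
    fold_threshold: float = 2.0,
    expression_floor: float = 5.0,
    cofactor: float = DEFAULT_COFACTOR,
) -> FixationReport:
    """Classify each antibody's fixation response as gain/loss/unchanged.

    Medians are mapped back to the raw intensity scale
    (``sinh(median) * cofactor``) before taking fold changes, since
    fixation acts multiplicatively on raw signal.  An antibody is
    "expressed" when its percent positive reaches ``expression_floor``
    in at least one subset in either condition; its summary ratio is
    the median log10(fixed/fresh) over those expressing subsets, and
    the class is gain at/above log10(fold_threshold), loss at/below
    the negative of it, else unchanged.
    """
    def agg(summary: ScreenSummary) -> pd.DataFrame:
        t = summary.table.groupby(["subset", "antibody"], sort=True).agg(
            median=("median", "median"), pct_positive=("pct_positive", "max")
        )
        return t

    fresh = agg(summary_fresh)
    fixed = agg(summary_fixed)
    common = fresh.index.intersection(fixed.index)
    dropped = set(fresh.index.get_level_values("antibody")).symmetric_difference(
        fixed.index.get_level_values("antibody")
    )
    if dropped:
        warnings.warn(f"antibodies absent from one condition skipped: {sorted(dropped)}")
    fresh, fixed = fresh.loc[common], fixed.loc[common]

    with np.errstate(divide="ignore", invalid="ignore"):
        raw_fresh = np.sinh(fresh["median"]) * cofactor
        raw_fixed = np.sinh(fixed["median"]) * cofactor
        log10_ratio = np.log10(raw_fixed / raw_fresh)
    per_subset = pd.DataFrame(
        {
            "antibody": common.get_level_values("antibody"),
            "subset": common.get_level_values("subset"),
            "log10_ratio": log10_ratio.to_numpy(),
            "expressing": (
                (fresh["pct_positive"] >= expression_floor)
                | (fixed["pct_positive"] >= expression_floor)
            ).to_numpy(),
        }
    ).reset_index(drop=True)

    cut = np.log10(fold_threshold)
    records = []
    expressed = []
    for antibody, grp in per_subset.groupby("antibody", sort=True):
        expr = grp.loc[grp["expressing"] & np.isfinite(grp["log10_ratio"])]
        if expr.empty:
            continue
        expressed.append(antibody)
        ratio = float(expr["log10_ratio"].median())
        cls = "gain" if ratio >= cut else ("loss" if ratio <= -cut else "unchanged")
        records.append({"antibody": antibody, "summary_ratio": ratio, "class": cls})
    return FixationReport(
        per_subset=per_subset,
        per_antibody=pd.DataFrame(records),
        expressed_antibodies=expressed,
        fold_threshold=fold_threshold,
    )


def differential_markers(
    pp: pd.DataFrame,
    residual_cutoff: float = 2.0,
    min_antibodies: int = 10,
) -> pd.DataFrame:
    """Consensus standardized-residual test for differential antibodies.

    ``pp`` is a long frame with columns ``donor``, ``antibody``,
    ``pp_pos`` and ``pp_neg`` (percent positive in the target and
    reference subsets).  Per donor, ``pp_pos`` is regressed on
    ``pp_neg`` (ordinary least squares with intercept); standardized
    residuals are residual / sd(residuals).  An antibody is flagged
    when its absolute standardized residual exceeds the cutoff in
    every donor and the residual sign is the same in all donors;
    sign-inconsistent candidates are dropped with a warning.

    Returns a frame indexed by antibody with per-donor standardized
    residuals, the flag, and the direction (+1 / -1 / 0).
    """
    required = {"donor", "antibody", "pp_pos", "pp_neg"}
    if not required <= set(pp.columns):
        raise ValueError(f"pp frame lacks columns: {sorted(required - set(pp.columns))}")
    donors = sorted(pp["donor"].unique())
    if len(donors) < 2:
        raise ValueError("consensus needs at least two donors")
    sets = {d: set(pp.loc[pp["donor"] == d, "antibody"]) for d in donors}
    common = set.intersection(*sets.values())
    if any(sets[d] != common for d in donors):
        raise ValueError("all donors must share the same antibody set")
    if len(common) < min_antibodies:
        raise ValueError(f"need >= {min_antibodies} antibodies per donor")

    resid = {}
    for donor in donors:
        sub = pp.loc[pp["donor"] == donor].sort_values("antibody")
        X = sm.add_constant(sub["pp_neg"].to_numpy())
        fit = sm.OLS(sub["pp_pos"].to_numpy(), X).fit()
        r = fit.resid
        sd = np.std(r, ddof=1)
        # A numerically perfect fit has no residual scale to standardize by.
        degenerate = sd <= 1e-9 * max(1.0, float(np.abs(sub["pp_pos"]).max()))
        resid[donor] = pd.Series(
            np.zeros_like(r) if degenerate else r / sd, index=sub["antibody"].to_numpy()
        )
    table = pd.DataFrame(resid).loc[sorted(common)]
    abs_ok = (table.abs() > residual_cutoff).all(axis=1)
    signs = np.sign(table)
    consistent = (signs.eq(signs.iloc[:, 0], axis=0)).all(axis=1)
    inconsistent = abs_ok & ~consistent
    if inconsistent.any():
        warnings.warn(
            "residual sign inconsistent across donors; dropped: "
            f"{sorted(table.index[inconsistent])}"
        )
    flagged = abs_ok & consistent
    out = table.copy()
    out.columns = [f"sr_{d}" for d in donors]
    out["flagged"] = flagged
    out["direction"] = np.where(flagged, signs.iloc[:, 0], 0).astype(int)
    out.index.name = "antibody"
    return out
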