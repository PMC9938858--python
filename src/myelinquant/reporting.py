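"""Aggregation, control normalization, validation and dose–response fits.

Thin, clearly labeled conveniences over scipy/pandas: the scientific
content here is plumbing — joining per-cell results to the plate layout,
normalizing to vehicle-control wells, correlating computed indices with
reference scores, and summarizing dose–response with a four-parameter Hill
fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_types import PlateLayout
from .synthetic import hill_curve


@dataclass
class ValidationResult:
    """Paired reference scores vs computed indices."""

    pearson_r: float
    spearman_rho: float
    n: int


@dataclass
class HillFit:
    floor: float = np.nan
    ceiling: float = np.nan
    ec50: float = np.nan
    slope: float = np.nan
    converged: bool = False
    identifiable: bool = False


def make_plate_table(cells: pd.DataFrame, layout: PlateLayout) -> pd.DataFrame:
    """Join per-object results to the layout's condition/dose by well."""
    merged = cells.merge(
        layout.table, left_on="well", right_on="well_id", how="left", validate="m:1"
    )
    if merged["condition"].isna().any():
        missing = sorted(set(merged.loc[merged["condition"].isna(), "well"]))
        raise ValueError(f"wells not present in layout: {missing}")
    return merged.drop(columns=["well_id"])


def normalize_to_control(
    values: pd.DataFrame, layout: PlateLayout, value_col: str = "value", well_col: str = "well"
) -> pd.DataFrame:
    """Divide a per-well metric by the mean over control wells.

    The mean of the control wells maps to 1.0 exactly; with a single control
    well, the control itself maps to 1.0. Scale-equivariant: multiplying all
    raw values by k leaves the normalized column unchanged.
    """
    layout.require_control()
    controls = values.loc[values[well_col].isin(layout.control_wells), value_col]
    if controls.empty:
        raise ValueError("no control wells present in the value table")
    denom = float(controls.mean())
    if denom == 0 or not np.isfinite(denom):
        raise ValueError("control mean is zero or non-finite; cannot normalize")
    out = values.copy()
    out["normalized"] = out[value_col] / denom
    return out


def correlate_with_reference(reference, computed) -> ValidationResult:
    """Pearson r (with Spearman ρ companion) between reference and computed.

    The reference may be ordinal (e.g. manual 1–5 myelination scores) or
    continuous (planted ground-truth fractions). Requires n ≥ 3 and
    non-zero variance in both variables.
    """
    ref = np.asarray(reference, dtype=float)
    comp = np.asarray(computed, dtype=float)
    if ref.shape != comp.shape:
        raise ValueError("reference and computed must be paired 1:1")
    ok = np.isfinite(ref) & np.isfinite(comp)
    ref, comp = ref[ok], comp[ok]
    if len(ref) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(ref)}")
    if ref.std() == 0 or comp.std() == 0:
        raise ValueError("correlation undefined: zero variance in one variable")
    r = float(stats.pearsonr(ref, comp).statistic)
    rho = float(stats.spearmanr(ref, comp).statistic)
    return ValidationResult(pearson_r=r, spearman_rho=rho, n=len(ref))


def dose_response_summary(
    table: pd.DataFrame, dose_col: str = "dose", value_col: str = "value"
) -> tuple[pd.DataFrame, HillFit]:
    """Per-dose mean ± SEM, plus a Hill fit when ≥ 4 dose levels exist.

    The fit estimates (floor, ceiling, EC50, slope) by least squares on the
    per-dose means; non-convergence is flagged rather than raised, and a
    response whose fitted amplitude is indistinguishable from the scatter is
    flagged non-identifiable (e.g. a flat response).
    """
    grouped = table.groupby(dose_col)[value_col]
    summary = grouped.agg(["mean", "sem", "count"]).reset_index()
    summary = summary.rename(columns={"mean": "mean_value", "sem": "sem_value", "count": "n"})

    fit = HillFit()
    doses = summary[dose_col].to_numpy(dtype=float)
    means = summary["mean_value"].to_numpy(dtype=float)
    if len(doses) < 4:
        return summary, fit
    lo, hi = float(means.min()), float(means.max())
    pos = doses[doses > 0]
    p0 = [lo, hi, float(np.median(pos)) if pos.size else 1.0, 1.0]
    try:
        import warnings

        with warnings.catch_warnings():
            # a flat response has no estimable covariance; flagged below
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                hill_curve,
                doses,
                means,
                p0=p0,
                bounds=([-np.inf, -np.inf, 1e-9, 0.1], [np.inf, np.inf, 1e9, 10.0]),
                maxfev=20000,
            )
        fit = HillFit(
            floor=float(popt[0]),
            ceiling=float(popt[1]),
            ec50=float(popt[2]),
            slope=float(popt[3]),
            converged=True,
        )
    except (RuntimeError, ValueError):
        return summary, fit
    sems = summary["sem_value"].to_numpy(dtype=float)
    scatter = np.nanmax(sems) if np.isfinite(sems).any() else 0.0
    amplitude = abs(fit.ceiling - fit.floor)
    fit.identifiable = bool(amplitude > max(2.0 * scatter, 1e-8))
    return summary, fit


# ---------------------------------------------------------------------------
# group-comparison conveniences (reporting plumbing, not the contribution)


def compare_two_groups(a, b, test: str = "t") -> dict:
    """Welch t-test (``"t"``) or Mann–Whitney U (``"mw"``) between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mw":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"test": test, "statistic": float(res.statistic), "pvalue": float(res.pvalue)}


def anova_dunnett(groups: dict, control: str) -> pd.DataFrame:
    """One-way ANOVA followed by Dunnett's comparison against a control group."""
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    names = [k for k in groups if k != control]
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    ctrl = np.asarray(groups[control], dtype=float)
    f_res = stats.f_oneway(ctrl, *samples)
    d_res = stats.dunnett(*samples, control=ctrl)
    return pd.DataFrame(
        {
            "group": names,
            "statistic": np.atleast_1d(d_res.statistic),
            "pvalue": np.atleast_1d(d_res.pvalue),
            "anova_F": float(f_res.statistic),
            "anova_pvalue": float(f_res.pvalue),
        }
    )


def well_means(
    table: pd.DataFrame, value_col: str, well_col: str = "well"
) -> pd.DataFrame:
    """Per-well mean of a metric (the default replicate unit for SEM)."""
    out = table.groupby(well_col, as_index=False)[value_col].mean()
    return out.rename(columns={value_col: "value"})


# ---------------------------------------------------------------------------
# plotting (optional QC; matplotlib figures returned, never shown)


def plot_dose_response(summary: pd.DataFrame, fit: HillFit | None = None, dose_col: str = "dose"):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        summary[dose_col], summary["mean_value"], yerr=summary["sem_value"], fmt="o", capsize=3
    )
    if fit is not None and fit.converged:
        pos = summary.loc[summary[dose_col] > 0, dose_col]
        if not pos.empty:
            xs = np.geomspace(max(pos.min() / 3, 1e-3), pos.max() * 3, 200)
            ax.plot(xs, hill_curve(xs, fit.floor, fit.ceiling, fit.ec50, fit.slope), "-")
    ax.set_xscale("symlog", linthresh=max(1e-3, float(summary[dose_col][summary[dose_col] > 0].min() if (summary[dose_col] > 0).any() else 1.0)))
    ax.set_xlabel("dose (ng/ml)")
    ax.set_ylabel("mean ± SEM")
    fig.tight_layout()
    return fig


def plot_index_violin(table: pd.DataFrame, value_col: str = "myelination_index", by: str = "condition"):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = [g.dropna().to_numpy() for _, g in table.groupby(by)[value_col]]
    labels = [str(k) for k, _ in table.groupby(by)[value_col]]
    fig, ax = plt.subplots(figsize=(5, 4))
    kept = [(lab, g) for lab, g in zip(labels, groups) if g.size]
    if kept:
        ax.violinplot([g for _, g in kept], showmeans=True)
        ax.set_xticks(range(1, len(kept) + 1), [lab for lab, _ in kept], rotation=45)
    ax.set_ylabel(value_col)
    fig.tight_layout()
    return fig
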