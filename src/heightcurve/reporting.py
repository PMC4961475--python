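"""Headline summaries from posterior draws and estimate tables.

Century change with credible intervals (computed on the posterior sample
of the difference, never by differencing summary intervals), country
rankings at a cohort, male-female gaps with cross-country correlation, and
trend plots with shaded 95% bands plus the tidy CSV behind each figure.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from heightcurve.inference import PosteriorDraws


def century_change(
    draws: PosteriorDraws,
    country: str,
    first: float | None = None,
    last: float | None = None,
) -> tuple[float, tuple[float, float]]:
    """Posterior mean and 2.5-97.5% interval of height(last) - height(first).

    Computed draw by draw on the posterior sample of the difference, so
    the interval accounts for the correlation between the two endpoints.
    """
    grid = draws.grid
    first = grid.years[0] if first is None else float(first)
    last = grid.years[-1] if last is None else float(last)
    h = draws.height_draws(country, [first, last])
    diff = h[:, 1] - h[:, 0]
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return float(diff.mean()), (float(lo), float(hi))


def rank_countries(table: pd.DataFrame, cohort: float, sex: str) -> pd.DataFrame:
    """Rank countries by posterior mean height at a cohort (1 = tallest).

    Ties are broken deterministically by country code (ascending), so the
    result is invariant to input row order.  Every country in the table
    must have a row at the requested cohort.
    """
    sub = table[(table["sex"] == sex) & (table["birth_cohort"] == cohort)]
    missing = set(table.loc[table["sex"] == sex, "country"]) - set(sub["country"])
    if missing:
        raise ValueError(f"countries missing at cohort {cohort}: {sorted(missing)}")
    if len(sub) == 0:
        raise ValueError(f"no rows at cohort {cohort} for sex {sex!r}")
    out = sub.sort_values(
        ["mean_cm", "country"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out = out[["country", "mean_cm", "lo_cm", "hi_cm"]].copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def sex_gap(
    men_table: pd.DataFrame, women_table: pd.DataFrame, cohort: float
) -> tuple[pd.DataFrame, dict]:
    """Per-country men-minus-women gap at a cohort, with a cross-country summary.

    The summary reports the mean gap and the Pearson correlation of men's
    vs women's posterior mean heights across countries (NaN when fewer
    than two countries, where a correlation is undefined).
    """
    m = men_table[men_table["birth_cohort"] == cohort].set_index("country")["mean_cm"]
    w = women_table[women_table["birth_cohort"] == cohort].set_index("country")["mean_cm"]
    if set(m.index) != set(w.index):
        raise ValueError("men and women tables cover different country sets")
    countries = sorted(m.index)
    gaps = pd.DataFrame(
        {
            "country": countries,
            "men_cm": m.loc[countries].to_numpy(),
            "women_cm": w.loc[countries].to_numpy(),
        }
    )
    gaps["gap_cm"] = gaps["men_cm"] - gaps["women_cm"]
    if len(countries) >= 2 and gaps["men_cm"].std() > 0 and gaps["women_cm"].std() > 0:
        corr = float(np.corrcoef(gaps["men_cm"], gaps["women_cm"])[0, 1])
    else:
        corr = float("nan")
    summary = {"mean_gap_cm": float(gaps["gap_cm"].mean()), "correlation": corr}
    return gaps, summary


def plot_trends(
    table: pd.DataFrame,
    countries: Sequence[str],
    path=None,
    observations: pd.DataFrame | None = None,
):
    """Cohort trend lines with shaded 95% bands; optional data overlay.

    Writes the figure to ``path`` when given and returns (figure, tidy
    DataFrame) so the plot is regenerable from the CSV.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[table["country"].isin(countries)]
    fig, ax = plt.subplots(figsize=(8, 5))
    for country, grp in sub.groupby("country"):
        grp = grp.sort_values("birth_cohort")
        (line,) = ax.plot(grp["birth_cohort"], grp["mean_cm"], label=country)
        ax.fill_between(
            grp["birth_cohort"], grp["lo_cm"], grp["hi_cm"], alpha=0.2, color=line.get_color()
        )
        if observations is not None:
            pts = observations[observations["country"] == country]
            ax.scatter(pts["birth_cohort"], pts["mean_cm"], s=8, color=line.get_color())
    ax.set_xlabel("birth cohort")
    ax.set_ylabel("mean height at age 18 (cm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig, sub.copy()
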