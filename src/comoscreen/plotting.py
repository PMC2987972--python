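"""Plots for cohort demographics and screen results."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import demographic_summary

__all__ = ["plot_age_sex_distribution", "plot_top_rr"]


def plot_age_sex_distribution(members: pd.DataFrame, bin_width: int = 5, ax=None):
    """Grouped bar chart of cohort counts by 5-year age bin and sex."""
    import matplotlib.pyplot as plt

    hist = demographic_summary(members, bin_width)["histogram"]
    wide = hist.pivot_table(index="age_bin", columns="sex", values="n",
                            fill_value=0).sort_index()
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(len(wide))
    width = 0.4
    for i, sex in enumerate(wide.columns):
        ax.bar(x + (i - 0.5) * width, wide[sex], width, label=str(sex))
    ax.set_xticks(x, [f"{b}-{b + bin_width - 1}" for b in wide.index],
                  rotation=45)
    ax.set_xlabel("age at index date (years)")
    ax.set_ylabel("persons")
    ax.legend(title="sex")
    return ax


def plot_top_rr(ranked: pd.DataFrame, k: int = 30, ax=None):
    """Horizontal bars of the top-k relative risks with their 95% CIs."""
    import matplotlib.pyplot as plt

    rows = ranked.head(k).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.3 * max(len(rows), 4) + 1))
    y = np.arange(len(rows))
    err = np.vstack([rows["rr"] - rows["ci_low"], rows["ci_high"] - rows["rr"]])
    ax.barh(y, rows["rr"], xerr=err, capsize=2)
    labels = [f"{r.icd9} {r.description}" if getattr(r, "description", "")
              else str(r.icd9) for r in rows.itertuples()]
    ax.set_yticks(y, labels, fontsize=7)
    ax.axvline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("relative risk (one-year prevalence ratio)")
    return ax
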