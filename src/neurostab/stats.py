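"""Group-comparison plumbing: one-way ANOVA with post-hoc Tukey HSD,
plus two-group t / Mann-Whitney options."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import group_values


@dataclass
class GroupComparison:
    """ANOVA omnibus result plus per-pair post-hoc table."""

    groups: list
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj
    pairwise_t: pd.DataFrame  # Welch t and Mann-Whitney per pair

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        hits = self.tukey[self.tukey["p_adj"] < alpha]
        return list(zip(hits["group1"], hits["group2"]))


def compare_groups(values_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA across labeled groups followed by Tukey HSD.

    Also reports per-pair Welch t-tests and Mann-Whitney U tests for the
    two-group use case. Every group needs at least 2 values.
    """
    data = group_values(values_by_group)
    names = list(data)
    arrays = [data[k] for k in names]

    f_stat, p_omni = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)

    rows, trows = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    "p_adj": float(tk.pvalue[i, j]),
                }
            )
            t_res = stats.ttest_ind(arrays[i], arrays[j], equal_var=False)
            mw = stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            trows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "t_stat": float(t_res.statistic),
                    "t_p": float(t_res.pvalue),
                    "mw_u": float(mw.statistic),
                    "mw_p": float(mw.pvalue),
                }
            )
    return GroupComparison(
        groups=names,
        anova_f=float(f_stat),
        anova_p=float(p_omni),
        tukey=pd.DataFrame(rows),
        pairwise_t=pd.DataFrame(trows),
    )
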