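"""Dose-group comparisons: one-way ANOVA and Tukey HSD matrices.

For each measurement source (MTT viability, an individual component's
scores, or the score-based regression predictions) the dose groups of a
cell line are compared pairwise with the Tukey honestly-significant-
difference test after a one-way ANOVA.  Results are arranged as symmetric
significance matrices with the legend used in dose-response tables:
"ns" (p > 0.05), "*" (p < 0.05) and "**" (p < 0.01).  Comparing the
matrices of different sources against the MTT reference yields the
disagreement list — the pairs one method discriminates and the other
does not.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

FLAG_INSIGNIFICANT = "ns"
FLAG_P05 = "*"
FLAG_P01 = "**"


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    All-identical observations make the F ratio 0/0 and raise; zero
    within-group variance with unequal means yields p = 0 with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    allobs = np.concatenate(groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = np.array([g.mean() for g in groups])
    if ssw == 0.0:
        if np.allclose(means, means[0]) and np.allclose(allobs, allobs[0]):
            raise ValueError("all observations identical: F undefined (0/0)")
        logger.warning("zero within-group variance with unequal means; p = 0")
        return np.inf, 0.0
    F, p = sps.f_oneway(*groups)
    return float(F), float(p)


@dataclass
class SignificanceMatrix:
    """Pairwise Tukey HSD p-values and significance flags for one source."""

    source: str
    group_labels: list[float]
    p_values: np.ndarray              # symmetric, NaN diagonal
    flags: pd.DataFrame = field(init=False)
    anova_F: float = np.nan
    anova_p: float = np.nan

    def __post_init__(self):
        k = len(self.group_labels)
        if self.p_values.shape != (k, k):
            raise ValueError("p-value matrix shape must match group count")
        flags = np.full((k, k), "", dtype=object)
        for i in range(k):
            for j in range(k):
                if i == j:
                    flags[i, j] = ""
                else:
                    flags[i, j] = flag_for_p(self.p_values[i, j])
        self.flags = pd.DataFrame(flags, index=self.group_labels,
                                  columns=self.group_labels)

    def significant_at(self, i: int, j: int, alpha: float = 0.05) -> bool:
        return bool(self.p_values[i, j] < alpha)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_values, index=self.group_labels,
                            columns=self.group_labels)

    def to_csv(self) -> str:
        """Lossless CSV: long format with p-values (repr precision) and flags."""
        rows = []
        k = len(self.group_labels)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(dict(source=self.source,
                                 group_a=self.group_labels[i],
                                 group_b=self.group_labels[j],
                                 p_value=repr(float(self.p_values[i, j])),
                                 flag=self.flags.iloc[i, j]))
        header = pd.DataFrame(rows)
        meta = pd.DataFrame([dict(source=self.source, group_a="__anova__",
                                  group_b="", p_value=repr(float(self.anova_p)),
                                  flag=repr(float(self.anova_F)))])
        return pd.concat([header, meta]).to_csv(index=False)

    @classmethod
    def from_csv(cls, text: str) -> "SignificanceMatrix":
        df = pd.read_csv(io.StringIO(text),
                         dtype={"group_a": str, "group_b": str,
                                "p_value": str, "flag": str})
        meta = df[df.group_a == "__anova__"]
        body = df[df.group_a != "__anova__"]
        labels = sorted({float(x) for x in pd.concat([body.group_a, body.group_b])})
        k = len(labels)
        p = np.full((k, k), np.nan)
        for row in body.itertuples():
            i = labels.index(float(row.group_a))
            j = labels.index(float(row.group_b))
            p[i, j] = p[j, i] = float(row.p_value)
        out = cls(source=str(df.source.iloc[0]), group_labels=labels, p_values=p)
        if len(meta):
            out.anova_p = float(meta.p_value.iloc[0])
            out.anova_F = float(meta.flag.iloc[0])
        return out


def flag_for_p(p: float) -> str:
    if p < 0.01:
        return FLAG_P01
    if p < 0.05:
        return FLAG_P05
    return FLAG_INSIGNIFICANT


def tukey_hsd(groups: list[np.ndarray], labels: list[float] | None = None,
              source: str = "") -> SignificanceMatrix:
    """Tukey HSD pairwise comparisons (classical equal-variance form).

    p-values come from the studentized range distribution on the pooled
    within-group variance; flags encode the two conventional alpha levels.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    F, p_anova = anova_oneway(groups)
    if labels is None:
        labels = list(range(len(groups)))
    if np.isinf(F):
        # perfectly separated groups: every unequal pair maximally significant
        k = len(groups)
        means = [g.mean() for g in groups]
        p = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(k):
                if i != j:
                    p[i, j] = 0.0 if means[i] != means[j] else 1.0
        return SignificanceMatrix(source=source, group_labels=list(labels),
                                  p_values=p, anova_F=F, anova_p=p_anova)
    res = sps.tukey_hsd(*groups)
    pmat = np.array(res.pvalue, dtype=float)
    np.fill_diagonal(pmat, np.nan)
    return SignificanceMatrix(source=source, group_labels=list(labels),
                              p_values=pmat, anova_F=F, anova_p=p_anova)


@dataclass
class AccordanceTables:
    """Significance matrices per source plus the MTT disagreement list."""

    matrices: dict[str, SignificanceMatrix]
    disagreements: pd.DataFrame

    def missed_by(self, source: str) -> pd.DataFrame:
        """Pairs the MTT test discriminates but ``source`` does not."""
        d = self.disagreements
        return d[(d.source == source) & d.mtt_significant & ~d.source_significant]


def accordance_tables(mtt_groups: dict[float, np.ndarray],
                      score_groups: dict[str, dict[float, np.ndarray]],
                      prediction_groups: dict[float, np.ndarray] | None = None,
                      alpha: float = 0.05) -> AccordanceTables:
    """Build the per-source significance matrices and the disagreement list.

    All sources must carry the same dose labels.  The disagreement list
    records, for every non-MTT source and dose pair, where the significance
    verdicts at ``alpha`` differ from the MTT reference — the direction
    ``mtt_significant & ~source_significant`` is a loss of discrimination,
    the opposite direction a gain.
    """
    doses = sorted(mtt_groups)
    sources: dict[str, dict[float, np.ndarray]] = {"MTT": mtt_groups, **score_groups}
    if prediction_groups is not None:
        sources["MLR@PARAFAC"] = prediction_groups
    for name, groups in sources.items():
        if sorted(groups) != doses:
            raise ValueError(f"source {name!r} has dose labels {sorted(groups)}, "
                             f"expected {doses}")
    matrices = {
        name: tukey_hsd([groups[d] for d in doses], labels=doses, source=name)
        for name, groups in sources.items()
    }
    mtt = matrices["MTT"]
    rows = []
    for name, mat in matrices.items():
        if name == "MTT":
            continue
        for i in range(len(doses)):
            for j in range(i + 1, len(doses)):
                sig_m = mtt.significant_at(i, j, alpha)
                sig_s = mat.significant_at(i, j, alpha)
                if sig_m != sig_s:
                    rows.append(dict(source=name, dose_a=doses[i], dose_b=doses[j],
                                     mtt_significant=sig_m, source_significant=sig_s))
    cols = ["source", "dose_a", "dose_b", "mtt_significant", "source_significant"]
    disagreements = pd.DataFrame(rows, columns=cols)
    return AccordanceTables(matrices=matrices, disagreements=disagreements)
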