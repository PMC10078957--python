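"""Performance evaluation: information transfer rate and accuracy statistics.

ITR follows the Wolpaw bits-per-decision formula for an N-target selector
with accuracy P:

    B = log2 N + P log2 P + (1 - P) log2((1 - P) / (N - 1))   [bits/decision]
    ITR = B * 60 / T                                          [bits/minute]

with T the decision time in seconds.  For this two-site design one
decision requires n_avg stimuli at *each* site, so T = n_avg * ISI * 2
(4.2 / 7 / 14 s for 3 / 5 / 10 averaged trials at ISI 0.7 s), giving the
P = 1 ceiling rates 14.29 / 8.57 / 4.29 bits per minute.

Accuracy panels (subject x classifier x n_avg x method) are compared with
two-way repeated-measures ANOVA (Greenhouse-Geisser corrected when a
factor has more than two levels) and Wilcoxon signed-rank post-hoc tests
under a Bonferroni-corrected significance threshold (0.05 / m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ItrParams",
    "decision_time",
    "bits_per_decision",
    "itr_bpm",
    "AnovaEffect",
    "rm_anova_2way",
    "WilcoxonVerdict",
    "wilcoxon_posthoc",
]


@dataclass(frozen=True)
class ItrParams:
    n_targets: int = 2
    n_commands: int = 1
    accuracy: float = 1.0
    decision_time_s: float = 14.0

    def validate(self) -> None:
        if self.n_targets < 2:
            raise ValueError("n_targets must be >= 2")
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")
        if self.decision_time_s <= 0:
            raise ValueError("decision_time_s must be > 0")


def decision_time(n_avg: int, isi_s: float = 0.7, n_locations: int = 2) -> float:
    """Seconds per BCI decision: n_avg stimuli at each of n_locations sites."""
    if n_avg <= 0 or isi_s <= 0 or n_locations <= 0:
        raise ValueError("all arguments must be positive")
    return n_avg * isi_s * n_locations


def bits_per_decision(n_targets: int, accuracy: float) -> float:
    """Wolpaw bits per decision, with the P -> 0/1 limits handled exactly."""
    if n_targets < 2:
        raise ValueError("n_targets must be >= 2")
    p = float(accuracy)
    if not (0.0 <= p <= 1.0):
        raise ValueError("accuracy must lie in [0, 1]")
    b = np.log2(n_targets)
    if p > 0.0:
        b += p * np.log2(p)
    if p < 1.0:
        b += (1.0 - p) * np.log2((1.0 - p) / (n_targets - 1))
    return float(b)


def itr_bpm(params: ItrParams) -> float:
    """Information transfer rate in bits per minute."""
    params.validate()
    b = bits_per_decision(params.n_targets, params.accuracy)
    return b * 60.0 / params.decision_time_s


@dataclass
class AnovaEffect:
    source: str
    F: float
    df1: float
    df2: float
    p: float
    df1_gg: float | None = None
    df2_gg: float | None = None
    p_gg: float | None = None
    eps: float | None = None


def rm_anova_2way(
    panel: pd.DataFrame,
    dv: str = "accuracy_pct",
    within: tuple[str, str] = ("classifier", "n_avg"),
    subject: str = "subject",
) -> list[AnovaEffect]:
    """Two-way repeated-measures ANOVA on a long-format accuracy panel.

    Requires a complete balanced design (every subject measured in every
    cell).  Sphericity is handled with the Greenhouse-Geisser correction
    for factors with more than two levels; uncorrected degrees of freedom
    are reported alongside.
    """
    import pingouin as pg

    cells = panel.groupby([subject, *within], observed=True)[dv].count()
    if (cells != 1).any():
        raise ValueError("panel must have exactly one observation per subject x cell")
    n_cells = panel.groupby(list(within), observed=True).ngroups
    per_subject = panel.groupby(subject, observed=True)[dv].count()
    if (per_subject != n_cells).any():
        raise ValueError("missing cells: every subject needs every condition")

    import warnings

    with warnings.catch_warnings():
        # a zero-variance panel divides 0/0 inside pingouin; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.rm_anova(
            data=panel, dv=dv, within=list(within), subject=subject,
            correction=True, detailed=True,
        )
    effects = []
    for _, row in aov.iterrows():
        eps = row.get("eps", np.nan)
        p_gg = row.get("p_GG_corr", row.get("p-GG-corr", np.nan))
        df1, df2 = float(row["ddof1"]), float(row["ddof2"])
        has_gg = eps is not None and np.isfinite(eps)
        f_val = float(row["F"])
        p_val = float(row.get("p_unc", row.get("p-unc", np.nan)))
        if not np.isfinite(f_val) and float(row.get("SS", np.nan)) == 0.0:
            # zero between-condition variance: no effect at all
            f_val, p_val = 0.0, 1.0
        effects.append(
            AnovaEffect(
                source=str(row["Source"]),
                F=f_val,
                df1=df1,
                df2=df2,
                p=p_val,
                df1_gg=df1 * float(eps) if has_gg else None,
                df2_gg=df2 * float(eps) if has_gg else None,
                p_gg=float(p_gg) if has_gg and np.isfinite(p_gg) else None,
                eps=float(eps) if has_gg else None,
            )
        )
    return effects


@dataclass
class WilcoxonVerdict:
    name: str
    statistic: float
    p: float
    alpha_corrected: float
    significant: bool
    degenerate: bool = False  # all paired differences were zero


def wilcoxon_posthoc(
    pairs: list[tuple[str, np.ndarray, np.ndarray]],
    alpha: float = 0.05,
    m: int | None = None,
) -> list[WilcoxonVerdict]:
    """Paired Wilcoxon signed-rank tests with Bonferroni correction.

    ``pairs`` holds (name, x, y) paired samples; ``m`` defaults to the
    number of comparisons, giving the corrected threshold alpha / m
    (0.017 for 3 comparisons, 0.0083 for 6).  Zero differences are handled
    with the Pratt method; a pair whose differences are all zero has an
    undefined statistic and is reported as non-significant with the
    ``degenerate`` flag set.
    """
    m = m if m is not None else len(pairs)
    if m < 1:
        raise ValueError("need at least one comparison")
    thr = alpha / m
    out = []
    for name, x, y in pairs:
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.shape != y.shape:
            raise ValueError(f"{name}: paired samples must have equal length")
        if np.all(x == y):
            out.append(WilcoxonVerdict(name, np.nan, 1.0, thr, False, degenerate=True))
            continue
        res = stats.wilcoxon(x, y, zero_method="pratt")
        out.append(
            WilcoxonVerdict(name, float(res.statistic), float(res.pvalue), thr,
                            bool(res.pvalue < thr))
        )
    return out
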