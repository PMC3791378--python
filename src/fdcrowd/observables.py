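"""Ensemble observables and population statistics.

A simulation ensemble is a table with one row per replicate:

    replicate, seed, condition, crowding, first_passage, censored,
    occupancy_fraction, mean_coverage

``first_passage`` is the time of the first cognate binding to the target
site, censored at the simulation duration when the site is never reached
(``censored`` flag, ``first_passage`` empty).  The statistics layer turns
ensembles into the usual population summaries: first-passage and
occupancy moments, the reach probability (fraction of replicates in which
the site is found within the cell cycle), crowding/search-time Pearson
correlations, one-way ANOVA with Tukey's range test across crowding
conditions, and notched-boxplot summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ENSEMBLE_COLUMNS = [
    "replicate",
    "seed",
    "condition",
    "crowding",
    "first_passage",
    "censored",
    "occupancy_fraction",
    "mean_coverage",
]


class EnsembleError(ValueError):
    pass


@dataclass(frozen=True)
class EnsembleResult:
    """Per-replicate observables of one or more conditions."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ENSEMBLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise EnsembleError(f"ensemble table missing columns: {missing}")
        if len(self.data) < 1:
            raise EnsembleError("ensemble must contain at least one record")
        occ = self.data["occupancy_fraction"].to_numpy(dtype=float)
        if np.any((occ < 0) | (occ > 1)):
            raise EnsembleError("occupancy_fraction must lie in [0, 1]")

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "EnsembleResult":
        return cls(pd.DataFrame.from_records(list(records))[ENSEMBLE_COLUMNS])

    @classmethod
    def read_csv(cls, path) -> "EnsembleResult":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    def condition(self, name) -> pd.DataFrame:
        sub = self.data[self.data["condition"] == name]
        if len(sub) == 0:
            raise EnsembleError(f"no records for condition {name!r}")
        return sub

    @property
    def conditions(self) -> List:
        return list(dict.fromkeys(self.data["condition"]))


def _frame(ensemble, condition=None) -> pd.DataFrame:
    df = ensemble.data if isinstance(ensemble, EnsembleResult) else ensemble
    if condition is not None:
        df = df[df["condition"] == condition]
        if len(df) == 0:
            raise EnsembleError(f"no records for condition {condition!r}")
    return df


def first_passage_stats(ensemble, condition=None) -> Dict[str, float]:
    """Mean/variance of uncensored first-passage times; censored counted apart."""
    df = _frame(ensemble, condition)
    cens = df["censored"].astype(bool)
    times = df.loc[~cens, "first_passage"].to_numpy(dtype=float)
    if len(times) == 0:
        raise EnsembleError("all replicates censored: no first-passage times")
    return {
        "mean": float(np.mean(times)),
        "variance": float(np.var(times, ddof=1)) if len(times) > 1 else 0.0,
        "n": int(len(times)),
        "n_censored": int(cens.sum()),
    }


def occupancy_stats(ensemble, condition=None, *, discard_censored: bool = False) -> Dict[str, float]:
    """Moments of the target-site occupancy fraction.

    ``discard_censored=True`` implements the immobile-roadblock protocol
    (replicates in which the site is never reached are removed); with
    ``False`` (mobile protocol) they are kept as occupancy 0.
    """
    df = _frame(ensemble, condition)
    if discard_censored:
        df = df[~df["censored"].astype(bool)]
        if len(df) == 0:
            raise EnsembleError("all replicates censored: empty after discarding")
    occ = df["occupancy_fraction"].to_numpy(dtype=float)
    return {
        "mean": float(np.mean(occ)),
        "variance": float(np.var(occ, ddof=1)) if len(occ) > 1 else 0.0,
        "n": int(len(occ)),
    }


def reach_probability(ensemble, condition=None) -> float:
    """Fraction of replicates in which the target site is reached."""
    df = _frame(ensemble, condition)
    cens = df["censored"].astype(bool).to_numpy()
    return float((~cens).sum() / len(cens))


def crowding_correlation(crowding: Sequence[float], means: Sequence[float]) -> float:
    """Pearson correlation between condition-level crowding and a summary."""
    x = np.asarray(crowding, dtype=float)
    y = np.asarray(means, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise EnsembleError("need >= 3 paired condition-level values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EnsembleError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    alpha: float
    pairs: List[TukeyPair]

    def significant_pairs(self) -> List[TukeyPair]:
        return [p for p in self.pairs if p.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.pairs])


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey's range test (HSD) across sample groups."""
    names = list(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    if len(samples) < 2:
        raise EnsembleError("need >= 2 groups")
    if any(len(s) < 2 for s in samples):
        raise EnsembleError("every group needs >= 2 values")
    f, p = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    ci = hsd.confidence_interval(confidence_level=1 - alpha)
    pairs = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            p_adj = float(hsd.pvalue[i, j])
            pairs.append(
                TukeyPair(
                    group_a=names[i],
                    group_b=names[j],
                    mean_diff=float(np.mean(samples[i]) - np.mean(samples[j])),
                    p_adj=p_adj,
                    ci_low=float(ci.low[i, j]),
                    ci_high=float(ci.high[i, j]),
                    significant=bool(p_adj < alpha),
                )
            )
    return AnovaTukeyResult(
        f_statistic=float(f), p_value=float(p), alpha=alpha, pairs=pairs
    )


@dataclass(frozen=True)
class BoxplotSummary:
    """Notched-boxplot summary following the standard six-part rule.

    Quartiles use linear interpolation of order statistics (type 7).  The
    lower whisker is the maximum of (Q1 - 1.5 IQR) and the sample minimum,
    the upper whisker the minimum of (Q3 + 1.5 IQR) and the sample
    maximum; points outside the whisker span are outliers.  The notch
    half-width is the conventional 1.57 * IQR / sqrt(n), an approximate
    95% interval for the median.
    """

    median: float
    q1: float
    q3: float
    iqr: float
    lower_whisker: float
    upper_whisker: float
    outliers: tuple
    notch_low: float
    notch_high: float
    n: int

    def notches_overlap(self, other: "BoxplotSummary") -> bool:
        return not (self.notch_high < other.notch_low or other.notch_high < self.notch_low)


def boxplot_summary(sample: Sequence[float]) -> BoxplotSummary:
    x = np.sort(np.asarray(sample, dtype=float))
    if len(x) < 1:
        raise EnsembleError("boxplot summary needs at least one point")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    low = max(q1 - 1.5 * iqr, float(x[0]))
    high = min(q3 + 1.5 * iqr, float(x[-1]))
    outliers = tuple(float(v) for v in x[(x < low) | (x > high)])
    half = 1.57 * iqr / np.sqrt(len(x))
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_whisker=float(low),
        upper_whisker=float(high),
        outliers=outliers,
        notch_low=float(med - half),
        notch_high=float(med + half),
        n=int(len(x)),
    )
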