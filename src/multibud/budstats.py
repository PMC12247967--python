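"""Morphometric statistics of bud-volume partitioning.

Quantifies how evenly a multi-budding mother divides its growth potential
among sibling buds: per-mother coefficients of variation of sibling bud
volumes (by bud-number class), the pooled population comparator, the linear
relation between summed bud volume and mother volume, the positional
(distant vs adjacent) analysis for three-budded mothers with a chi-square
test against the random expectation, and sibling growth-rate analysis with
a test for compensatory rate adjustment.

All CVs use the sample (n−1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BudVolumeTable",
    "GrowthSeries",
    "SiblingCVStats",
    "sibling_cv_stats",
    "summed_fraction_fit",
    "distant_adjacent_analysis",
    "growth_rate_analysis",
    "exact_gof_pvalue",
]


@dataclass(frozen=True)
class BudVolumeTable:
    """Per-mother records of mother volume and sibling bud volumes (µm³)."""

    mother_ids: tuple
    mother_volumes: np.ndarray
    bud_volumes: tuple  # tuple of 1-D arrays, one per mother
    bud_labels: tuple = ()  # tuple of label tuples, aligned with bud_volumes
    maturity: tuple = ()

    def __post_init__(self):
        n = len(self.mother_ids)
        if len(self.mother_volumes) != n or len(self.bud_volumes) != n:
            raise ValueError("mother_ids, mother_volumes, bud_volumes must align")
        for mid, vol, buds in zip(self.mother_ids, self.mother_volumes, self.bud_volumes):
            if vol <= 0:
                raise ValueError(f"mother {mid!r}: non-positive mother volume {vol}")
            b = np.asarray(buds)
            if b.size < 1 or (b <= 0).any():
                raise ValueError(f"mother {mid!r}: bud volumes must be positive, >=1 bud")
        if self.bud_labels:
            if len(self.bud_labels) != n:
                raise ValueError("bud_labels must align with mothers")
            for mid, buds, labs in zip(self.mother_ids, self.bud_volumes, self.bud_labels):
                if len(labs) != len(buds):
                    raise ValueError(f"mother {mid!r}: labels do not align with buds")

    @property
    def n_mothers(self) -> int:
        return len(self.mother_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, mid in enumerate(self.mother_ids):
            labs = self.bud_labels[i] if self.bud_labels else [""] * len(self.bud_volumes[i])
            mat = self.maturity[i] if self.maturity else ""
            for j, (v, lab) in enumerate(zip(self.bud_volumes[i], labs)):
                rows.append(
                    {
                        "mother_id": mid,
                        "mother_volume": float(self.mother_volumes[i]),
                        "bud_index": j,
                        "bud_volume": float(v),
                        "label": lab,
                        "maturity": mat,
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BudVolumeTable":
        required = {"mother_id", "mother_volume", "bud_index", "bud_volume"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        ids, mvols, buds, labels, maturity = [], [], [], [], []
        for mid, g in df.groupby("mother_id", sort=False):
            g = g.sort_values("bud_index")
            ids.append(mid)
            mvols.append(float(g["mother_volume"].iloc[0]))
            buds.append(np.asarray(g["bud_volume"], dtype=float))
            labels.append(tuple(g["label"]) if "label" in g else ("",) * len(g))
            maturity.append(str(g["maturity"].iloc[0]) if "maturity" in g else "")
        return cls(
            mother_ids=tuple(ids),
            mother_volumes=np.asarray(mvols),
            bud_volumes=tuple(buds),
            bud_labels=tuple(labels),
            maturity=tuple(maturity),
        )


@dataclass(frozen=True)
class GrowthSeries:
    """Per-mother bud-volume trajectories over time (minutes, µm³)."""

    mother_ids: tuple
    times: tuple  # one strictly increasing array per mother
    trajectories: tuple  # one (nbud, ntime) array per mother
    emergence_times: tuple = ()

    def __post_init__(self):
        for mid, t in zip(self.mother_ids, self.times):
            t = np.asarray(t)
            if (np.diff(t) <= 0).any():
                raise ValueError(f"mother {mid!r}: time points must strictly increase")


def _sample_cv(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / np.mean(x))


@dataclass(frozen=True)
class SiblingCVStats:
    per_mother_cv: dict  # mother_id -> CV (multi-budded mothers only)
    class_mean_cv: dict  # class key ("2","3","4",">=5") -> mean CV
    class_counts: dict
    mean_cv: float  # mean per-mother CV over all multi-budded mothers
    population_cv: float  # CV of all bud volumes pooled across mothers
    n_single_bud: int


def sibling_cv_stats(table: BudVolumeTable) -> SiblingCVStats:
    """Within-mother sibling CVs, class means, and the pooled-population CV.

    Mothers with a single bud carry no sibling CV and are only counted.
    Classes follow the 2 / 3 / 4 / >=5 bud-number grouping; the population
    comparator pools every bud volume across all mothers.
    """
    if table.n_mothers == 0:
        raise ValueError("empty table")
    per_mother = {}
    classes: dict[str, list[float]] = {"2": [], "3": [], "4": [], ">=5": []}
    pooled = []
    n_single = 0
    for mid, buds in zip(table.mother_ids, table.bud_volumes):
        b = np.asarray(buds, dtype=float)
        pooled.append(b)
        if len(b) < 2:
            n_single += 1
            continue
        cv = _sample_cv(b)
        per_mother[mid] = cv
        key = str(len(b)) if len(b) <= 4 else ">=5"
        classes[key].append(cv)
    pooled_all = np.concatenate(pooled)
    return SiblingCVStats(
        per_mother_cv=per_mother,
        class_mean_cv={k: (float(np.mean(v)) if v else float("nan")) for k, v in classes.items()},
        class_counts={k: len(v) for k, v in classes.items()},
        mean_cv=float(np.mean(list(per_mother.values()))) if per_mother else float("nan"),
        population_cv=_sample_cv(pooled_all) if len(pooled_all) > 1 else float("nan"),
        n_single_bud=n_single,
    )


def summed_fraction_fit(table: BudVolumeTable) -> dict:
    """OLS fit (with intercept) of summed sibling bud volume vs mother volume.

    Returns slope, intercept, R² and n.  The slope estimates the fraction
    of its starting volume a mother converts into buds in one cycle.
    """
    if table.n_mothers < 3:
        raise ValueError("need at least 3 mothers for the regression")
    x = np.asarray(table.mother_volumes, dtype=float)
    y = np.array([float(np.sum(b)) for b in table.bud_volumes])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate regressor: all mother volumes identical")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "n": len(x),
    }


def distant_adjacent_analysis(table: BudVolumeTable) -> dict:
    """Positional analysis of three-budded mothers with one 'distant' bud.

    Counts how often the distant bud is strictly the largest sibling and
    tests the count against the 1/3 random expectation with an uncorrected
    df=1 chi-square goodness-of-fit.  Ties for largest are counted as
    not-largest and flagged.  Also returns each bud's volume relative to
    its sibling mean, grouped by positional label.
    """
    if not table.bud_labels:
        raise ValueError("table carries no positional labels")
    k = 0
    n = 0
    ties = []
    rel = {"distant": [], "adjacent": []}
    for mid, buds, labs in zip(table.mother_ids, table.bud_volumes, table.bud_labels):
        labs = tuple(labs)
        if len(buds) != 3:
            raise ValueError(f"mother {mid!r}: expected exactly 3 buds, got {len(buds)}")
        if labs.count("distant") != 1:
            raise ValueError(
                f"mother {mid!r}: expected exactly one 'distant' label, got {labs}"
            )
        b = np.asarray(buds, dtype=float)
        n += 1
        i_dist = labs.index("distant")
        vmax = b.max()
        if b[i_dist] == vmax and (b == vmax).sum() > 1:
            ties.append(mid)
        elif b[i_dist] == vmax:
            k += 1
        mean_sib = b.mean()
        for v, lab in zip(b, labs):
            rel.setdefault(lab, []).append(float(v / mean_sib))

    expected = np.array([n / 3.0, 2.0 * n / 3.0])
    chi2, p = stats.chisquare([k, n - k], f_exp=expected)
    return {
        "n_mothers": n,
        "n_distant_largest": k,
        "fraction_distant_largest": k / n,
        "chi2": float(chi2),
        "p_value": float(p),
        "null_fraction": 1.0 / 3.0,
        "ties": ties,
        "relative_volumes": {key: np.asarray(v) for key, v in rel.items()},
    }


def exact_gof_pvalue(k: int, n: int, p0: float = 1.0 / 3.0) -> float:
    """Exact binomial-enumeration p-value for the same goodness-of-fit test.

    Enumerates all outcomes j ~ Binomial(n, p0) and sums the probability of
    those whose chi-square statistic is at least the observed one.  Used as
    an independent small-n check on the chi-square approximation.
    """
    def chi2_stat(j):
        e1, e2 = n * p0, n * (1 - p0)
        return (j - e1) ** 2 / e1 + ((n - j) - e2) ** 2 / e2

    obs = chi2_stat(k)
    p = 0.0
    for j in range(n + 1):
        if chi2_stat(j) >= obs - 1e-12:
            p += stats.binom.pmf(j, n, p0)
    return float(p)


def growth_rate_analysis(
    series: GrowthSeries,
    emergence_threshold: float = 1.0,
    compensation_margin: float = 0.25,
) -> dict:
    """Sibling growth rates, their per-mother CV, and a compensation flag.

    A bud's growth rate is the OLS slope of volume vs time over frames
    after emergence (first frame above ``emergence_threshold`` µm³).  The
    compensation flag is raised for a mother when the slower/faster sibling
    rate ratio in the last third of the series exceeds the first-third
    ratio by more than ``compensation_margin`` — i.e. initially unequal
    buds converge, as feedback models predict and the accuracy model
    forbids.
    """
    per_mother = {}
    for mid, t, traj in zip(series.mother_ids, series.times, series.trajectories):
        t = np.asarray(t, dtype=float)
        traj = np.atleast_2d(np.asarray(traj, dtype=float))
        rates, windows = [], []
        for v in traj:
            emerged = np.nonzero(v >= emergence_threshold)[0]
            if len(emerged) < 3:
                rates.append(np.nan)
                windows.append(None)
                continue
            sel = emerged[0]
            tt, vv = t[sel:], v[sel:]
            rates.append(float(stats.linregress(tt, vv).slope))
            windows.append((tt, vv))
        rates = np.asarray(rates)
        ok = np.isfinite(rates)
        rate_cv = _sample_cv(rates[ok]) if ok.sum() >= 2 and rates[ok].mean() > 0 else float("nan")

        flag = False
        ratio_first = ratio_last = float("nan")
        if ok.sum() >= 2:
            idx = np.nonzero(ok)[0]
            slow, fast = idx[np.argmin(rates[idx])], idx[np.argmax(rates[idx])]
            if slow != fast:
                def window_rate(bud, lo_frac, hi_frac):
                    tt, vv = windows[bud]
                    n = len(tt)
                    lo, hi = int(lo_frac * n), max(int(hi_frac * n), int(lo_frac * n) + 3)
                    hi = min(hi, n)
                    if hi - lo < 3:
                        return np.nan
                    return stats.linregress(tt[lo:hi], vv[lo:hi]).slope

                rf_s, rf_f = window_rate(slow, 0.0, 1 / 3), window_rate(fast, 0.0, 1 / 3)
                rl_s, rl_f = window_rate(slow, 2 / 3, 1.0), window_rate(fast, 2 / 3, 1.0)
                if np.isfinite([rf_s, rf_f, rl_s, rl_f]).all() and rf_f > 0 and rl_f > 0:
                    ratio_first = rf_s / rf_f
                    ratio_last = rl_s / rl_f
                    flag = (ratio_last - ratio_first) > compensation_margin
        per_mother[mid] = {
            "rates": rates,
            "rate_cv": rate_cv,
            "compensation": bool(flag),
            "ratio_first_third": ratio_first,
            "ratio_last_third": ratio_last,
        }
    cvs = [m["rate_cv"] for m in per_mother.values() if np.isfinite(m["rate_cv"])]
    return {
        "per_mother": per_mother,
        "mean_rate_cv": float(np.mean(cvs)) if cvs else float("nan"),
        "any_compensation": any(m["compensation"] for m in per_mother.values()),
    }
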