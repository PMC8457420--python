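"""Estimation statistics for the state-dependent optogenetic designs.

Per-animal on/off paired effects, change scores against the fluorophore
control group, two-sided permutation t tests (sign flips for paired
designs, label shuffles for unpaired), 5000-sample percentile bootstrap
CIs, and Benjamini-Hochberg FDR control at q < 0.10 within each
protocol-by-group family; plus thin wrappers for the routine tests
(Mann-Whitney, Wilcoxon, chi-square, Friedman).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectEstimate",
    "AnimalSummary",
    "PROPORTION_METRICS",
    "animal_deltas",
    "paired_permutation_test",
    "unpaired_permutation_test",
    "bootstrap_mean_difference",
    "bh_fdr",
    "change_score_vs_control",
    "routine_tests",
    "opto_effect_report",
]

Q_THRESHOLD = 0.10
EXACT_SIGNFLIP_LIMIT = 4096     # enumerate sign flips when 2**n is at most this
EXACT_SHUFFLE_LIMIT = 10000     # enumerate label shuffles when C(n, n1) is at most this


@dataclass
class EffectEstimate:
    design: str                  # "PAIRED" or "UNPAIRED"
    point: float                 # mean difference, units of the metric
    ci_low: float
    ci_high: float
    n_boot: int
    p_perm: float
    n_perm: int
    q: float = np.nan
    significant: bool | None = None


@dataclass
class AnimalSummary:
    animal_id: str
    group: str
    protocol: str
    metric: str
    mean_off: float
    mean_on: float

    @property
    def delta(self) -> float:
        return self.mean_on - self.mean_off


# metrics computed as 100 x category count / trials of the light condition
PROPORTION_METRICS = {
    "correct": lambda d: d["classification"] == "CORRECT",
    "incorrect_start": lambda d: d["classification"] == "INCORRECT_START",
    "break_s1": lambda d: d["classification"] == "BREAK_S1",
    "premature_switch": lambda d: d["classification"] == "PREMATURE_SWITCH",
    "break_s2": lambda d: d["classification"] == "BREAK_S2",
    "long_s1": lambda d: d["long_s1"].astype(bool),
}


def _metric_per_condition(g: pd.DataFrame, metric: str) -> float:
    if metric == "return_to_start":
        return 100.0 * g["return_to_start"].mean() if len(g) else np.nan
    trials = g[~g["return_to_start"].astype(bool)]
    if not len(trials):
        return np.nan
    if metric in PROPORTION_METRICS:
        return 100.0 * PROPORTION_METRICS[metric](trials).mean()
    if metric == "long_s1_of_correct":
        correct = trials[trials["classification"] == "CORRECT"]
        return 100.0 * correct["long_s1"].astype(bool).mean() if len(correct) else np.nan
    return float(trials[metric].mean())


def animal_deltas(trials: pd.DataFrame, metric: str) -> list[AnimalSummary]:
    """Per-animal ON and OFF means of a metric (and their difference).

    Proportion metrics divide the category count by the total trials of
    that light condition (x100); returns-to-start use all initiation
    attempts as the denominator; continuous metrics average over the
    trials where they are defined.  Animals lacking either condition are
    excluded with a warning.
    """
    out = []
    for (animal, group, protocol), g in trials.groupby(["animal_id", "group", "protocol"], sort=True):
        on = g[g["light"] == "ON"]
        off = g[g["light"] == "OFF"]
        if not len(on) or not len(off):
            warnings.warn(f"animal {animal!r} lacks ON or OFF trials; excluded", stacklevel=2)
            continue
        out.append(
            AnimalSummary(
                animal_id=str(animal),
                group=str(group),
                protocol=str(protocol),
                metric=metric,
                mean_off=_metric_per_condition(off, metric),
                mean_on=_metric_per_condition(on, metric),
            )
        )
    return out


def paired_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    exact: bool | None = None,
) -> float:
    """Two-sided permutation t test for paired samples via sign flips.

    The statistic is the mean paired difference; the null flips each
    pair's sign independently.  All 2**n flips are enumerated when
    feasible (exact p, no smoothing); otherwise Monte-Carlo with
    (b+1)/(n_perm+1) smoothing.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    if d.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(d == 0):
        return 1.0
    t_obs = abs(d.mean())
    n = d.size
    if exact is None:
        exact = 2**n <= EXACT_SIGNFLIP_LIMIT
    if exact:
        codes = np.arange(2**n, dtype=np.uint32)
        signs = (((codes[:, None] >> np.arange(n)) & 1) * 2 - 1).astype(np.int8)
        t_null = np.abs(signs @ d) / n
        return float(np.mean(t_null >= t_obs - 1e-12))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    t_null = np.abs(signs @ d) / n
    b = int(np.sum(t_null >= t_obs - 1e-12))
    return (b + 1) / (n_perm + 1)


def unpaired_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    exact: bool | None = None,
) -> float:
    """Two-sided permutation t test for independent groups (label shuffles)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n1 = x.size
    t_obs = abs(x.mean() - y.mean())
    if exact is None:
        exact = comb(pooled.size, n1) <= EXACT_SHUFFLE_LIMIT
    if exact:
        total = pooled.sum()
        count = 0
        n_comb = 0
        for idx in combinations(range(pooled.size), n1):
            s1 = pooled[list(idx)].sum()
            t = abs(s1 / n1 - (total - s1) / y.size)
            count += t >= t_obs - 1e-12
            n_comb += 1
        return count / n_comb
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.random((n_perm, pooled.size)).argsort(axis=1)
    perm = pooled[idx]
    t_null = np.abs(perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1))
    b = int(np.sum(t_null >= t_obs - 1e-12))
    return (b + 1) / (n_perm + 1)


def bootstrap_mean_difference(
    x: np.ndarray,
    y: np.ndarray,
    design: str = "PAIRED",
    n_boot: int = 5000,
    seed: int | np.random.Generator = 0,
    n_perm: int = 5000,
    ci: float = 0.95,
) -> EffectEstimate:
    """Percentile-bootstrap 95% CI of the (paired or unpaired) mean difference.

    The point estimate is the observed mean difference; the permutation p
    comes from the matching permutation t test.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    if design == "PAIRED":
        if x.size != y.size:
            raise ValueError("paired design requires equal lengths")
        d = x - y
        idx = rng.integers(0, d.size, size=(n_boot, d.size))
        boots = d[idx].mean(axis=1)
        point = float(d.mean())
        p = paired_permutation_test(x, y, n_perm=n_perm, seed=rng)
    elif design == "UNPAIRED":
        bx = x[rng.integers(0, x.size, size=(n_boot, x.size))].mean(axis=1)
        by = y[rng.integers(0, y.size, size=(n_boot, y.size))].mean(axis=1)
        boots = bx - by
        point = float(x.mean() - y.mean())
        p = unpaired_permutation_test(x, y, n_perm=n_perm, seed=rng)
    else:
        raise ValueError("design must be PAIRED or UNPAIRED")
    lo, hi = np.percentile(boots, [lo_q, hi_q])
    return EffectEstimate(
        design=design,
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        p_perm=float(p),
        n_perm=n_perm,
    )


def bh_fdr(p_values: np.ndarray, q_threshold: float = Q_THRESHOLD) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q values and significance flags.

    q_(i) = min_{j >= i} p_(j) * m / j with monotonicity enforced;
    significant when q < ``q_threshold``.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < q_threshold


def change_score_vs_control(
    deltas_exp: np.ndarray | list,
    deltas_ctrl: np.ndarray | list,
    n_boot: int = 5000,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> EffectEstimate:
    """Unpaired estimation of per-animal delta(on-off) vs the control group."""
    exp = np.asarray([d.delta if isinstance(d, AnimalSummary) else d for d in deltas_exp], float)
    ctrl = np.asarray([d.delta if isinstance(d, AnimalSummary) else d for d in deltas_ctrl], float)
    if exp.size < 3 or ctrl.size < 3:
        raise ValueError("need at least 3 animals per group")
    return bootstrap_mean_difference(
        exp, ctrl, design="UNPAIRED", n_boot=n_boot, seed=seed, n_perm=n_perm
    )


def routine_tests(test: str, *samples, **kwargs) -> float:
    """Delegating wrappers around the routine named tests; returns the p value."""
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(*samples, alternative="two-sided", **kwargs).pvalue)
    if test == "wilcoxon":
        return float(stats.wilcoxon(*samples, **kwargs).pvalue)
    if test == "chi2":
        return float(stats.chi2_contingency(samples[0], **kwargs)[1])
    if test == "friedman":
        arr = np.asarray(samples, float)
        if np.all(arr == arr[0]):  # identical repeated measures: no effect
            return 1.0
        return float(stats.friedmanchisquare(*samples).pvalue)
    raise ValueError(f"unknown test {test!r}")


def opto_effect_report(
    trials: pd.DataFrame,
    metrics: list[str],
    control_group: str = "EYFP_CONTROL",
    n_boot: int = 5000,
    n_perm: int = 5000,
    seed: int = 0,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Full estimation-statistics table for an optogenetic cohort.

    For every protocol x group x metric: the per-animal paired on-off
    effect (permutation t test + bootstrap CI) and, for non-control
    groups, the change score against the control group's deltas.  BH-FDR
    q values are computed within each protocol x group x comparison-type
    family, significance at q < 0.10.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for protocol, gproto in trials.groupby("protocol", sort=True):
        control_deltas: dict[str, list[AnimalSummary]] = {}
        if (gproto["group"] == control_group).any():
            ctrl = gproto[gproto["group"] == control_group]
            for metric in metrics:
                control_deltas[metric] = animal_deltas(ctrl, metric)
        for group, g in gproto.groupby("group", sort=True):
            for metric in metrics:
                summaries = animal_deltas(g, metric)
                if len(summaries) < 3:
                    continue
                on = np.array([s.mean_on for s in summaries])
                off = np.array([s.mean_off for s in summaries])
                est = bootstrap_mean_difference(
                    on, off, design="PAIRED", n_boot=n_boot, seed=rng, n_perm=n_perm
                )
                rows.append(
                    {
                        "protocol": protocol,
                        "group": group,
                        "metric": metric,
                        "comparison": "paired_on_off",
                        "point": est.point,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "p_perm": est.p_perm,
                        "n": len(summaries),
                    }
                )
                if group != control_group and metric in control_deltas and len(control_deltas[metric]) >= 3:
                    cs = change_score_vs_control(
                        summaries, control_deltas[metric], n_boot=n_boot, n_perm=n_perm, seed=rng
                    )
                    rows.append(
                        {
                            "protocol": protocol,
                            "group": group,
                            "metric": metric,
                            "comparison": "change_score_vs_control",
                            "point": cs.point,
                            "ci_low": cs.ci_low,
                            "ci_high": cs.ci_high,
                            "p_perm": cs.p_perm,
                            "n": len(summaries),
                        }
                    )
    report = pd.DataFrame(rows)
    if not len(report):
        return report
    report["q"] = np.nan
    report["significant"] = False
    for _, idx in report.groupby(["protocol", "group", "comparison"]).groups.items():
        q, sig = bh_fdr(report.loc[idx, "p_perm"].to_numpy(), q_threshold)
        report.loc[idx, "q"] = q
        report.loc[idx, "significant"] = sig
    return report
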