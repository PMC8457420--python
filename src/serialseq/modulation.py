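"""Inferential statistics on unit activity.

Three procedures: (1) sliding-window AUROC modulation maps — each 200-ms
bin's per-trial firing rates are compared to a pooled pre-trial baseline
with a label-shuffling permutation null (1000 permutations); (2) linear
regression of firing rate on binned behavioral covariates with a
covariate-shuffling permutation p value, accepted when p < 0.05 and the
correlation magnitude exceeds 0.6; (3) a z-difference test comparing the
mean normalized activity of two unit populations,
z = (Z1 - Z2) / sqrt(1/(N1-3) + 1/(N2-3)), referred to the standard
normal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spikes import AlignedRates

__all__ = [
    "ModulationProfile",
    "RegressionOutcome",
    "ZDifferenceResult",
    "auroc_value",
    "modulation_profile",
    "recruitment_fraction",
    "bin_covariate",
    "permutation_regression",
    "sequence_window_rates",
    "z_difference_test",
]


@dataclass
class ModulationProfile:
    unit_id: str
    anchor: str
    bin_centers: np.ndarray
    auroc: np.ndarray
    p_perm: np.ndarray
    significant: np.ndarray
    n_perm: int = 1000
    n_trials: int = 0


@dataclass
class RegressionOutcome:
    unit_id: str
    window: str
    covariate: str
    beta: float
    intercept: float
    r: float                 # correlation magnitude
    r_squared: float
    p_perm: float
    n_perm: int
    n_trials: int
    accepted: bool


@dataclass
class ZDifferenceResult:
    z1: float
    z2: float
    n1: int
    n2: int
    z_diff: float
    p: float


def auroc_value(test_bins: np.ndarray, baseline_bins: np.ndarray) -> float:
    """Area under the ROC curve for test vs baseline rate samples.

    Equals the Mann-Whitney U statistic normalized by n1*n2, with ties
    counted as half wins; identical distributions give 0.5.
    """
    test = np.asarray(test_bins, float)
    base = np.asarray(baseline_bins, float)
    if test.size < 2 or base.size < 2:
        raise ValueError("need at least two samples per side")
    ranks = stats.rankdata(np.concatenate([test, base]))
    u = ranks[: test.size].sum() - test.size * (test.size + 1) / 2.0
    return float(u / (test.size * base.size))


def _rank_auroc(ranks: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """AUROC from summed test-side ranks (vectorized over permutations)."""
    return (ranks - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def modulation_profile(
    aligned: AlignedRates,
    baseline_window: tuple[float, float] = (-4.5, -4.0),
    bin_width: float = 0.2,
    step: float = 0.01,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    min_trials: int = 5,
    sided: str = "two",
) -> ModulationProfile:
    """Sliding-window AUROC map of one unit against its pooled baseline.

    For every 200-ms window (10-ms steps) the per-trial mean rates are
    compared against the pooled per-trial baseline bins; significance comes
    from shuffling the test/baseline labels, p = (b+1)/(n_perm+1) for b
    permutations at least as extreme (|AUROC-0.5|) as observed.
    ``sided="one"`` gives the one-tailed variant on the observed side.
    """
    if aligned.matrix.shape[0] < min_trials:
        raise ValueError(
            f"unit {aligned.unit_id!r} excluded: {aligned.matrix.shape[0]} trials "
            f"(fewer than {min_trials})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = float(np.round(aligned.bin_times[1] - aligned.bin_times[0], 9))
    w = int(round(bin_width / dt))
    stride = max(1, int(round(step / dt)))
    X = aligned.matrix
    n_tr = X.shape[0]

    # pooled baseline: consecutive non-overlapping 200-ms bins per trial
    bsel = np.nonzero(
        (aligned.bin_times >= baseline_window[0] - 1e-9)
        & (aligned.bin_times <= baseline_window[1] + 1e-9)
    )[0]
    n_bbins = bsel.size // w
    if n_bbins < 1:
        raise ValueError("baseline window shorter than one analysis bin")
    base = X[:, bsel[: n_bbins * w]].reshape(n_tr, n_bbins, w).mean(axis=2).ravel()

    # sliding test bins start where the baseline ends
    first = int(np.searchsorted(aligned.bin_times, baseline_window[1] - 1e-9))
    starts = np.arange(first, X.shape[1] - w + 1, stride)
    csum = np.cumsum(np.concatenate([np.zeros((n_tr, 1)), X], axis=1), axis=1)
    test = (csum[:, starts + w] - csum[:, starts]) / w        # trials x bins
    centers = aligned.bin_times[starts] + (w - 1) * dt / 2.0

    n1, n2 = n_tr, base.size
    n_tot = n1 + n2
    auroc = np.empty(starts.size)
    p = np.empty(starts.size)
    for j in range(starts.size):
        combined = np.concatenate([test[:, j], base])
        ranks = stats.rankdata(combined)
        obs = _rank_auroc(ranks[:n1].sum(), n1, n2)
        perm_idx = rng.random((n_perm, n_tot)).argsort(axis=1)[:, :n1]
        perm_auroc = _rank_auroc(ranks[perm_idx].sum(axis=1), n1, n2)
        if sided == "two":
            b = np.sum(np.abs(perm_auroc - 0.5) >= abs(obs - 0.5) - 1e-12)
        else:
            b = np.sum(perm_auroc >= obs - 1e-12) if obs >= 0.5 else np.sum(perm_auroc <= obs + 1e-12)
        auroc[j] = obs
        p[j] = (b + 1) / (n_perm + 1)
    return ModulationProfile(
        unit_id=aligned.unit_id,
        anchor=aligned.anchor,
        bin_centers=centers,
        auroc=auroc,
        p_perm=p,
        significant=p < alpha,
        n_perm=n_perm,
        n_trials=n_tr,
    )


def recruitment_fraction(profiles: list[ModulationProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin percentage of units whose AUROC is significant."""
    if not profiles:
        raise ValueError("no profiles supplied")
    grid = profiles[0].bin_centers
    for pr in profiles[1:]:
        if pr.bin_centers.size != grid.size or not np.allclose(pr.bin_centers, grid):
            raise ValueError("profiles do not share a bin grid")
    sig = np.stack([pr.significant for pr in profiles])
    return grid, 100.0 * sig.mean(axis=0)


def bin_covariate(values: np.ndarray, covariate: str) -> tuple[np.ndarray, np.ndarray]:
    """Group a per-trial covariate into the analysis classes.

    Press counts map to the even classes 2, 4, ..., 16; latencies to 1-s
    classes starting at 0.5 s (earlier values join the first class);
    duration-type covariates are split into seven equal-count classes in
    descending order (class 1 = longest).  Returns (class labels, keep
    mask); trials with undefined covariate values are dropped.
    """
    v = np.asarray(values, float)
    keep = np.isfinite(v)
    vv = v[keep]
    if covariate == "n_presses":
        labels = np.clip(2 * np.ceil(vv / 2.0), 2, 16)
    elif covariate == "latency":
        labels = np.clip(np.floor((vv - 0.5) / 1.0), 0, None) + 1
    elif covariate in ("sequence_duration", "s1_duration", "transition_time", "s2_duration", "duration"):
        order = np.argsort(-vv, kind="stable")
        labels = np.empty(vv.size)
        for cls, chunk in enumerate(np.array_split(order, 7), start=1):
            labels[chunk] = cls
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    return labels, keep


def permutation_regression(
    rates: np.ndarray,
    covariate_classes: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    *,
    unit_id: str = "",
    window: str = "",
    covariate: str = "",
    r_threshold: float = 0.6,
    use_r_squared: bool = False,
    exact: bool = False,
) -> RegressionOutcome:
    """OLS of firing rate on covariate class with a permutation p value.

    p is the fraction of covariate-shuffled permutations whose |r| is at
    least the observed |r| (with +1 smoothing for the Monte-Carlo path;
    ``exact=True`` enumerates all orderings, feasible for small n).
    Accepted requires beta != 0, p < 0.05 and r (or R^2) above threshold.
    """
    y = np.asarray(rates, float)
    x = np.asarray(covariate_classes, float)
    if y.size != x.size or y.size < 6:
        raise ValueError("need at least 6 matched trials")
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct covariate classes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sy = float(y.std())
    if sy == 0.0:
        return RegressionOutcome(unit_id, window, covariate, 0.0, float(y.mean()), 0.0, 0.0, 1.0, 0, y.size, False)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    beta, intercept = np.polyfit(x, y, 1)

    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(x.size)):
            r_p = (xc[list(perm)] @ yc) / denom
            count += abs(r_p) >= abs(r_obs) - 1e-12
            total += 1
        p = count / total
        n_used = total
    else:
        perms = np.array([rng.permutation(x.size) for _ in range(n_perm)])
        r_perm = (xc[perms] @ yc) / denom
        p = (np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12) + 1) / (n_perm + 1)
        n_used = n_perm
    strength = r_obs**2 if use_r_squared else abs(r_obs)
    accepted = bool(beta != 0.0 and p < 0.05 and strength > r_threshold)
    return RegressionOutcome(
        unit_id=unit_id,
        window=window,
        covariate=covariate,
        beta=float(beta),
        intercept=float(intercept),
        r=abs(r_obs),
        r_squared=r_obs**2,
        p_perm=float(p),
        n_perm=n_used,
        n_trials=y.size,
        accepted=accepted,
    )


# the five windows of the sequence-length analysis: firing rate in the named
# span against the named per-trial covariate
SEQUENCE_WINDOWS = {
    "pre_1s_vs_duration": "sequence_duration",
    "sequence_vs_duration": "sequence_duration",
    "s1_vs_s1_duration": "s1_duration",
    "transition_vs_transition_time": "transition_time",
    "s2_vs_s2_duration": "s2_duration",
}


def sequence_window_rates(spike_times: np.ndarray, trials, window: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial firing rate in a named task window plus the matched covariate.

    Only correct trials with at least four presses per subsequence are
    used.  Rates are spike counts over the window divided by its length.
    """
    st = np.asarray(spike_times, float)
    rates, covs = [], []
    for tr in trials:
        if tr.classification is None or tr.classification.value != "CORRECT":
            continue
        s1, s2 = tr.s1_press_times, tr.s2_press_times
        if len(s1) < 4 or len(s2) < 4:
            continue
        spans = {
            "pre_1s_vs_duration": (s1[0] - 1.0, s1[0]),
            "sequence_vs_duration": (s1[0], s2[-1]),
            "s1_vs_s1_duration": (s1[0], s1[-1]),
            "transition_vs_transition_time": (s1[-1], s2[0]),
            "s2_vs_s2_duration": (s2[0], s2[-1]),
        }
        covariates = {
            "pre_1s_vs_duration": s2[-1] - s1[0],
            "sequence_vs_duration": s2[-1] - s1[0],
            "s1_vs_s1_duration": s1[-1] - s1[0],
            "transition_vs_transition_time": s2[0] - s1[-1],
            "s2_vs_s2_duration": s2[-1] - s2[0],
        }
        t0, t1 = spans[window]
        if t1 - t0 <= 0:
            continue
        n = np.searchsorted(st, t1) - np.searchsorted(st, t0)
        rates.append(n / (t1 - t0))
        covs.append(covariates[window])
    return np.array(rates), np.array(covs)


def z_difference_test(
    z1: float, z2: float, n1: int, n2: int, denominator: str = "fisher"
) -> ZDifferenceResult:
    """Difference between two populations' mean normalized activity.

    z = (Z1 - Z2) / sqrt(1/(N1-3) + 1/(N2-3)), two-sided p from the
    standard normal.  ``denominator="literal"`` uses 1/(N2+3) in the second
    term instead.
    """
    if denominator == "fisher":
        if n1 <= 3 or n2 <= 3:
            raise ValueError("undefined variance: both unit counts must exceed 3")
        se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    elif denominator == "literal":
        if n1 <= 3:
            raise ValueError("undefined variance: N1 must exceed 3")
        se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 + 3))
    else:
        raise ValueError("denominator must be 'fisher' or 'literal'")
    z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ZDifferenceResult(z1=z1, z2=z2, n1=n1, n2=n2, z_diff=float(z), p=float(min(p, 1.0)))
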