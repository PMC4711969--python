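"""ROI means and nonparametric cohort statistics.

The analysis mirrors the repeated-measures design of regional DTI studies:
each subject contributes one mean per region (tumor, edema, GM, WM) per
invariant; a Friedman rank test asks whether the regions differ at all, and
only if it rejects are paired two-sided sign tests run on all region pairs.
No multiple-comparison correction is applied by default (a Bonferroni option
exists), matching common practice of reporting per-pair p at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .invariants import ScalarMap
from .synthetic_phantom import REGION_ORDER, ROI_LABELS, ROISet

log = logging.getLogger(__name__)


@dataclass
class CohortStats:
    """Per-invariant ROI means and test results for one cohort.

    means: tidy DataFrame (subject, region, invariant, mean).
    friedman: invariant -> (statistic, p).
    posthoc: invariant -> {(region_a, region_b): (n_informative, p)} — empty
    when the omnibus test did not reject.
    """

    means: pd.DataFrame
    friedman: dict
    posthoc: dict
    alpha: float = 0.05

    def significant_pairs(self, invariant: str) -> list[tuple[str, str]]:
        return [
            pair
            for pair, (_, p) in self.posthoc.get(invariant, {}).items()
            if p < self.alpha
        ]

    def to_json(self) -> str:
        """Deterministic machine-readable report."""
        payload = {
            "alpha": self.alpha,
            "regions": list(REGION_ORDER),
            "friedman": {
                k: {"statistic": v[0], "p": v[1]} for k, v in sorted(self.friedman.items())
            },
            "posthoc": {
                k: {
                    f"{a}_vs_{b}": {"n_informative": n, "p": p, "significant": p < self.alpha}
                    for (a, b), (n, p) in v.items()
                }
                for k, v in sorted(self.posthoc.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def roi_means(m: ScalarMap, rois: ROISet) -> dict[str, float]:
    """Mean of unmasked map voxels per named region, in (T, E, GM, WM) order."""
    out = {}
    for name in REGION_ORDER:
        sel = rois.voxels(ROI_LABELS[name]) & m.mask
        if not sel.any():
            raise ValueError(f"ROI {name!r} is empty within the map mask")
        out[name] = float(m.values[sel].mean())
    return out


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square omnibus test on a subjects x regions matrix.

    Mid-ranks within each subject, tie-corrected chi-square statistic, p from
    the chi-square(k-1) upper tail.  Requires k >= 3 columns.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with >= 2 subjects")
    if X.shape[1] < 3:
        raise ValueError("Friedman test needs >= 3 regions; use sign_test for pairs")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains missing or non-finite cells")
    if np.all(X == X[:, :1]):  # every subject constant across regions
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*X.T)
    return float(stat), float(p)


def friedman_exact_p(matrix: np.ndarray, max_subjects: int = 8) -> float:
    """Exact permutation p-value for the Friedman statistic.

    Enumerates all k!^n within-subject column permutations (feasible for
    n <= ``max_subjects``, k small) and returns P(T >= T_observed).  This is
    the reference null for the chi-square approximation used above.
    """
    X = np.asarray(matrix, dtype=float)
    n, k = X.shape
    if n > max_subjects:
        raise ValueError(f"exact enumeration limited to n <= {max_subjects}")

    def statistic(M: np.ndarray) -> float:
        R = stats.rankdata(M, axis=1)
        tie_correct = 0.0
        for row in M:
            _, counts = np.unique(row, return_counts=True)
            tie_correct += float(np.sum(counts**3 - counts))
        Rj = R.sum(axis=0)
        S = float(np.sum((Rj - n * (k + 1) / 2.0) ** 2))
        denom = (n * k * (k**2 - 1) - tie_correct) / (12.0 * (k - 1))
        if denom <= 0:
            return 0.0
        return S / denom  # equals 12 S / (n k (k+1)) without ties

    t_obs = statistic(X)
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = 0
    for combo in itertools.product(range(len(perms)), repeat=n):
        M = np.stack([X[i, perms[ci]] for i, ci in enumerate(combo)])
        if statistic(M) >= t_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def sign_test(paired_diffs: np.ndarray) -> tuple[int, float]:
    """Two-sided exact sign test on paired differences.

    Zero differences are dropped (the standard exact convention); the p-value
    is the two-sided binomial tail at success probability 1/2 on the count of
    positive signs among the informative pairs.  All-zero input returns p = 1
    with a warning.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        log.warning("sign test: all differences are zero; p = 1")
        return 0, 1.0
    k = int(np.sum(d > 0))
    p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return n, float(min(p, 1.0))


def cohort_means(
    maps_per_subject: list[dict[str, ScalarMap]],
    rois_per_subject: list[ROISet],
    invariants: list[str],
) -> pd.DataFrame:
    """Tidy (subject, region, invariant, mean) table for a cohort."""
    if len(maps_per_subject) != len(rois_per_subject):
        raise ValueError("one ROISet per subject is required")
    rows = []
    for s, (maps, rois) in enumerate(zip(maps_per_subject, rois_per_subject)):
        missing = [w for w in invariants if w not in maps]
        if missing:
            raise ValueError(f"subject {s} is missing maps for {missing}")
        for w in invariants:
            for region, mean in roi_means(maps[w], rois).items():
                rows.append({"subject": s, "region": region, "invariant": w, "mean": mean})
    return pd.DataFrame(rows)


def cohort_analysis(
    maps_per_subject: list[dict[str, ScalarMap]],
    rois_per_subject: list[ROISet],
    invariants: list[str] = ("MD", "FA", "TV", "TC"),
    alpha: float = 0.05,
    *,
    bonferroni: bool = False,
) -> CohortStats:
    """Full cohort pipeline: ROI means, Friedman omnibus, gated sign tests.

    Post-hoc sign tests on all 6 region pairs run only when the Friedman test
    rejects at ``alpha`` (gatekeeping).  With ``bonferroni`` the pairwise
    p-values are multiplied by the number of pairs before flagging.
    """
    invariants = list(invariants)
    means = cohort_means(maps_per_subject, rois_per_subject, invariants)
    friedman: dict = {}
    posthoc: dict = {}
    n_pairs = len(list(itertools.combinations(REGION_ORDER, 2)))
    for w in invariants:
        wide = (
            means[means["invariant"] == w]
            .pivot(index="subject", columns="region", values="mean")
            .reindex(columns=list(REGION_ORDER))
        )
        if wide.isna().any().any():
            bad = wide.columns[wide.isna().any()].tolist()
            raise ValueError(f"missing ROI means for {w} in regions {bad}")
        stat, p = friedman_test(wide.to_numpy())
        friedman[w] = (stat, p)
        posthoc[w] = {}
        if p < alpha:
            for a, b in itertools.combinations(REGION_ORDER, 2):
                n, pp = sign_test(wide[a].to_numpy() - wide[b].to_numpy())
                if bonferroni:
                    pp = min(1.0, pp * n_pairs)
                posthoc[w][(a, b)] = (n, pp)
    return CohortStats(means=means, friedman=friedman, posthoc=posthoc, alpha=alpha)
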