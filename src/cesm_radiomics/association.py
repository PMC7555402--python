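"""Feature-histology association testing.

Each of the 14 first-order features is tested against five outcomes:
Pearson correlation for the interval-scaled ER%, PR% and Ki67%, and a
two-sided Mann-Whitney U test for HER2 (+/-) and histological grade
(G3 vs G1/G2).  Raw p-values are Bonferroni-adjusted within a family of
14 tests per outcome by default (a global 70-test family is available).

The Mann-Whitney exact null distribution is enumerated by the standard
rank-sum recurrence and used whenever the groups are small and tie-free;
otherwise the tie-corrected normal approximation with continuity
correction is applied.  Missing feature values (e.g. an undefined
variation coefficient) are removed pairwise and the per-test n reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata, t as t_dist

from .cohort_io import LesionRecord
from .features import FEATURE_BASES, FEATURE_NAMES

__all__ = [
    "pearson_test",
    "mann_whitney_test",
    "bonferroni_adjust",
    "build_association_table",
    "render_association_markdown",
    "OUTCOMES",
]

logger = logging.getLogger(__name__)

#: outcome name -> ("pearson", record attribute) or ("mannwhitney", grouping rule)
OUTCOMES = ("ER", "PR", "Ki67", "HER2", "Grade")

_CONTINUOUS_ATTR = {"ER": "er_pct", "PR": "pr_pct", "Ki67": "ki67_pct"}


def pearson_test(x, y) -> tuple[float, float, int]:
    """Sample Pearson correlation with its two-sided t-test p-value.

    Missing entries are deleted pairwise.  The p-value comes from
    ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.

    Returns ``(r, p_raw, n_used)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    sx = float(x.std())
    sy = float(y.std())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation is undefined for a constant vector")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return r, p, n


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of tie-free rank configurations giving each U value.

    Subset dynamic program over the pooled ranks 1..n: ``f[k][w]`` counts
    size-k subsets with rank sum w; the first-group U statistic is its rank
    sum minus ``n1(n1+1)/2``.  The n1*n2 + 1 counts sum to C(n1+n2, n1).
    """
    n = n1 + n2
    w_max = sum(range(n - n1 + 1, n + 1))
    f = np.zeros((n1 + 1, w_max + 1))
    f[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            f[k, rank:] += f[k - 1, : w_max + 1 - rank]
    w_min = n1 * (n1 + 1) // 2
    return tuple(int(v) for v in f[n1, w_min: w_min + n1 * n2 + 1])


def _exact_two_sided_p(u_obs: float, n1: int, n2: int) -> float:
    """P(|U - n1 n2 / 2| >= |u_obs - n1 n2 / 2|) under the exact null."""
    counts = _u_null_counts(n1, n2)
    mid = n1 * n2 / 2.0
    d = abs(u_obs - mid)
    total = sum(counts)
    extreme = sum(c for u, c in enumerate(counts) if abs(u - mid) >= d - 1e-12)
    return extreme / total


def mann_whitney_test(a, b, mode: str = "auto", exact_cap: int = 25) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``U`` is reported for group ``a`` using midranks.  ``mode``:

    * ``"exact"`` — full enumeration of the permutation null (requires no
      ties and ``n1 + n2 <= exact_cap``; with ties it falls back to the
      normal approximation with a logged warning);
    * ``"normal"`` — tie-corrected normal approximation with continuity
      correction;
    * ``"auto"`` — exact when admissible, normal otherwise.

    Returns ``(U, p_two_sided)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    use_exact = False
    if mode == "exact":
        if has_ties:
            logger.warning(
                "exact Mann-Whitney requested but ties present (n1=%d, n2=%d); "
                "falling back to the normal approximation", n1, n2,
            )
        elif n1 + n2 > exact_cap:
            raise ValueError(
                f"exact mode limited to n1+n2 <= {exact_cap}, got {n1 + n2}"
            )
        else:
            use_exact = True
    elif mode == "auto":
        use_exact = (not has_ties) and (n1 + n2 <= exact_cap)

    if use_exact:
        return u, _exact_two_sided_p(u, n1, n2)

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u, 1.0  # all observations identical
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = 2.0 * float(ndtr(-z))
    return u, min(1.0, p)


def bonferroni_adjust(p_values, family_size: int) -> np.ndarray:
    """``min(1, family_size * p)`` elementwise; order preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if family_size < p.size:
        raise ValueError(
            f"family_size ({family_size}) smaller than the number of tests ({p.size})"
        )
    return np.minimum(1.0, family_size * p)


# -- the full table ---------------------------------------------------------

def _grouping_masks(records: list[LesionRecord], outcome: str) -> np.ndarray:
    if outcome == "HER2":
        return np.array([r.her2 == "+" for r in records])
    if outcome == "Grade":
        return np.array([r.grade == "G3" for r in records])
    raise ValueError(f"not a grouping outcome: {outcome}")


def build_association_table(
    features: pd.DataFrame,
    records: list[LesionRecord],
    family: str = "per_outcome",
    mw_mode: str = "auto",
) -> pd.DataFrame:
    """Test every (outcome, feature) pair and Bonferroni-adjust the p-values.

    ``features`` is the lesion-by-feature frame from
    :func:`cesm_radiomics.features.features_to_frame`, aligned with
    ``records``.  Returns a tidy frame with one row per (outcome, feature):
    columns ``outcome, feature, statistic_type, statistic, n_used, p_raw,
    p_adjusted, family_size``.
    """
    if family not in ("per_outcome", "global"):
        raise ValueError("family must be 'per_outcome' or 'global'")
    if len(records) != len(features):
        raise ValueError("features and records are not aligned")
    ids = [r.lesion_id for r in records]
    if list(features.index) != ids:
        raise ValueError("features and records are not aligned by lesion_id")

    rows = []
    for outcome in OUTCOMES:
        if outcome in _CONTINUOUS_ATTR:
            y = np.array([getattr(r, _CONTINUOUS_ATTR[outcome]) for r in records])
            for feat in FEATURE_NAMES:
                r, p, n_used = pearson_test(features[feat].to_numpy(), y)
                rows.append((outcome, feat, "pearson_r", r, n_used, p))
        else:
            grp = _grouping_masks(records, outcome)
            if grp.all() or not grp.any():
                raise ValueError(f"outcome {outcome} has a single group; test undefined")
            for feat in FEATURE_NAMES:
                x = features[feat].to_numpy()
                keep = ~np.isnan(x)
                n_dropped = int((~keep).sum())
                if n_dropped:
                    logger.info("outcome %s, feature %s: %d lesions dropped (missing value)",
                                outcome, feat, n_dropped)
                u, p = mann_whitney_test(x[keep & grp], x[keep & ~grp], mode=mw_mode)
                rows.append((outcome, feat, "mannwhitney_U", u, int(keep.sum()), p))

    table = pd.DataFrame(rows, columns=["outcome", "feature", "statistic_type",
                                        "statistic", "n_used", "p_raw"])
    if family == "per_outcome":
        fam = len(FEATURE_NAMES)
        table["p_adjusted"] = np.concatenate([
            bonferroni_adjust(sub["p_raw"].to_numpy(), fam)
            for _, sub in table.groupby("outcome", sort=False)
        ])
    else:
        fam = len(table)
        table["p_adjusted"] = bonferroni_adjust(table["p_raw"].to_numpy(), fam)
    table["family_size"] = fam
    return table


def _stars(p: float) -> str:
    if p < 0.01:
        return " ***"
    if p < 0.05:
        return " **"
    if p < 0.10:
        return " *"
    return ""


def render_association_markdown(table: pd.DataFrame) -> str:
    """Render the Pearson block as a markdown table (LE block, RC block).

    Correlations are shown to two decimals with significance stars on the
    raw p-value (* p < 0.10, ** p < 0.05, *** p < 0.01); the Mann-Whitney
    outcomes are appended as significance summaries.
    """
    lines: list[str] = []
    pear = table[table["statistic_type"] == "pearson_r"]
    for img in ("LE", "RC"):
        cols = [f"{img}_{b}" for b in FEATURE_BASES]
        lines.append("| Features | " + " | ".join(cols) + " |")
        lines.append("|" + " --- |" * (len(cols) + 1))
        for outcome in ("ER", "PR", "Ki67"):
            cells = []
            for feat in cols:
                row = pear[(pear["outcome"] == outcome) & (pear["feature"] == feat)].iloc[0]
                cells.append(f"{row.statistic:.2f}{_stars(row.p_raw)}")
            lines.append(f"| {outcome} (%) | " + " | ".join(cells) + " |")
        lines.append("")
    lines.append("\\* p < 0.10, ** p < 0.05, *** p < 0.01 (raw p-values)")
    lines.append("")
    mw = table[table["statistic_type"] == "mannwhitney_U"]
    for outcome in ("HER2", "Grade"):
        sig = mw[(mw["outcome"] == outcome) & (mw["p_raw"] < 0.05)]["feature"].tolist()
        lines.append(f"{outcome}: Mann-Whitney p < 0.05 for "
                     + (", ".join(sig) if sig else "no feature"))
    return "\n".join(lines) + "\n"
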