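"""Group comparison: label-permutation testing with BH false-discovery control.

For each (band, metric, node) the statistic is the difference of group means,
mean(A) - mean(B).  Its null distribution is obtained by permuting subject
labels (10,000 draws by default) and the two-sided p-value uses the add-one
correction p = (1 + #{ |diff_perm| >= |diff_obs| }) / (n_perm + 1), which is a
valid p-value for any number of Monte-Carlo draws.  Nodal p-values are then
corrected with the Benjamini-Hochberg step-up within each (band, metric)
family of regions; the three global metrics form their own family per band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

GLOBAL_NODE = "global"


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Two-sided permutation test for a difference of group means.

    Returns ``(observed_diff, p_raw)`` with observed_diff = mean(a) - mean(b).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise InvalidInputError(
            f"both groups need at least 2 subjects, got {a.size} and {b.size}"
        )
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = float(a.mean() - b.mean())
    # permute the sorted pooled sample and resplit at the smaller group size:
    # the null |diff| draws then depend only on the pooled values and the two
    # sizes, making the p-value exactly invariant to swapping group labels
    pooled = np.sort(np.concatenate([a, b]))
    n_tot = pooled.size
    k = min(a.size, b.size)
    total = pooled.sum()
    # one uniform permutation per row: argsort of iid uniforms
    idx = np.argsort(rng.random((n_perm, n_tot)), axis=1)[:, :k]
    sum_k = pooled[idx].sum(axis=1)
    diffs = sum_k / k - (total - sum_k) / (n_tot - k)
    p = (1.0 + np.count_nonzero(np.abs(diffs) >= abs(observed) - 1e-12)) / (n_perm + 1.0)
    return observed, float(p)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, mask)`` where adjusted_(i) = min_{j >= i} m p_(j) / j
    clipped at 1, and mask = adjusted <= q.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise InvalidInputError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


@dataclass
class ComparisonSettings:
    """Echo of the settings a comparison was run with."""

    alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    fdr_family: str = "per-band-metric"  # or "pooled"


def _metric_table(subjects: list[pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for s_idx, df in enumerate(subjects):
        required = {"band", "metric", "node", "value"}
        if not required.issubset(df.columns):
            raise InvalidInputError(
                f"subject table missing columns {required - set(df.columns)}"
            )
        d = df[["band", "metric", "node", "value"]].copy()
        d["subject"] = s_idx
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def compare_groups(
    subjects_a: list[pd.DataFrame],
    subjects_b: list[pd.DataFrame],
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    fdr_family: str = "per-band-metric",
) -> pd.DataFrame:
    """Permutation tests for every (band, metric, node), with FDR correction.

    Each subject is a tidy table with columns band, metric, node, value
    (node == 'global' for tree-level metrics).  Nodal rows are BH-corrected
    within their (band, metric) family; global rows within the per-band
    family of global metrics.  ``fdr_family='pooled'`` instead corrects all
    rows together.

    Returns a table with columns band, metric, node, diff, direction, p_raw,
    p_fdr, significant.
    """
    if not subjects_a or not subjects_b:
        raise InvalidInputError("both groups must be non-empty")
    ta = _metric_table(subjects_a)
    tb = _metric_table(subjects_b)
    keys_a = set(map(tuple, ta[["band", "metric", "node"]].drop_duplicates().values))
    keys_b = set(map(tuple, tb[["band", "metric", "node"]].drop_duplicates().values))
    if keys_a != keys_b:
        raise InvalidInputError(
            "groups do not share the same (band, metric, node) entries"
        )
    piv_a = ta.pivot_table(
        index=["band", "metric", "node"], columns="subject", values="value", sort=False
    )
    piv_b = tb.pivot_table(
        index=["band", "metric", "node"], columns="subject", values="value", sort=False
    )
    piv_b = piv_b.loc[piv_a.index]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(piv_a))
    rows = []
    for (key, va), vb, child in zip(piv_a.iterrows(), piv_b.values, children):
        band, metric, node = key
        diff, p_raw = permutation_test(
            va.values, vb, n_perm=n_perm, seed=np.random.default_rng(child)
        )
        rows.append(
            {
                "band": band,
                "metric": metric,
                "node": node,
                "diff": diff,
                "direction": "+" if diff > 0 else ("-" if diff < 0 else "0"),
                "p_raw": p_raw,
            }
        )
    out = pd.DataFrame(rows)

    out["p_fdr"] = np.nan
    if fdr_family == "pooled":
        families = [np.arange(len(out))]
    elif fdr_family == "per-band-metric":
        families = []
        nodal = out["node"] != GLOBAL_NODE
        for (_, _), idx in out[nodal].groupby(["band", "metric"], sort=False).groups.items():
            families.append(np.asarray(idx))
        for _, idx in out[~nodal].groupby("band", sort=False).groups.items():
            families.append(np.asarray(idx))
    else:
        raise InvalidInputError(f"unknown fdr_family {fdr_family!r}")
    for idx in families:
        adjusted, _ = fdr_bh(out.loc[idx, "p_raw"].values, q=alpha)
        out.loc[idx, "p_fdr"] = adjusted
    out["significant"] = out["p_fdr"] <= alpha
    return out
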