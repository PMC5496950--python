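"""Rank-based group comparison of reliability, and edge-wise correlation tests.

Three layers of inference, all nonparametric or transformation-based:

* **relative effects** — for each group, the estimated probability that a
  randomly chosen member exceeds a randomly chosen member of the pooled
  sample, computed from pooled midranks as p_hat = (Rbar_g - 1/2) / N.
* **rank-based multivariate ANOVA** — each response column is midranked
  across all subjects; the ANOVA-type statistic tr(H)/tr(G) (between vs
  pooled-within rank covariance traces) is referred to an F distribution
  with Box-approximated fractional degrees of freedom.  A label-
  permutation p-value is available as a finite-sample cross-check.  The
  closed testing procedure applies the same test to every subset of
  groups and rejects a subset only when it and all of its supersets
  reject, which controls the family-wise error at the nominal level.
* **edge-wise correlation comparison** — two groups' per-edge Spearman
  coefficients are Fisher z-transformed and compared with the classical
  two-sample z statistic Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3));
  all raw p-values across group pairs, measures, bands and edges are
  pooled and Bonferroni-Holm corrected jointly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reliability import EdgeReliabilityMap


# ---------------------------------------------------------------------------
# relative effects
# ---------------------------------------------------------------------------

def relative_effects(values_by_group: dict[str, np.ndarray]) -> dict[str, float]:
    """Midrank estimate of P(random group member > random pooled member).

    The weighted mean sum_g (n_g/N) p_hat_g equals 1/2 exactly on any
    input, ties included (a property of midranks).
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    labels, sizes, pooled = [], [], []
    for label, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float).ravel()
        if vals.size == 0:
            raise ValueError(f"group {label!r} is empty")
        labels.append(label)
        sizes.append(vals.size)
        pooled.append(vals)
    pooled = np.concatenate(pooled)
    N = pooled.size
    ranks = stats.rankdata(pooled)  # midranks
    out = {}
    start = 0
    for label, size in zip(labels, sizes):
        rbar = ranks[start : start + size].mean()
        out[label] = float((rbar - 0.5) / N)
        start += size
    return out


# ---------------------------------------------------------------------------
# rank-based multivariate ANOVA (ANOVA-type statistic)
# ---------------------------------------------------------------------------

@dataclass
class MultivariateTestResult:
    statistic: float
    df1: float
    df2: float
    p_value: float
    method: str = "rank-ANOVA-type/Box"
    permutation_p: float | None = None

    def __post_init__(self) -> None:
        if self.df1 <= 0 or self.df2 <= 0:
            raise ValueError("degrees of freedom must be positive")


def _group_slices(groups: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    labels = pd.unique(groups)
    return labels, [np.flatnonzero(groups == lab) for lab in labels]


def _ats(R: np.ndarray, indices: list[np.ndarray]) -> tuple[float, float, float]:
    """ANOVA-type statistic on a rank matrix; returns (T, trH, trG)."""
    N = R.shape[0]
    a = len(indices)
    grand = R.mean(axis=0)
    trH = 0.0
    for idx in indices:
        d = R[idx].mean(axis=0) - grand
        trH += idx.size * float(d @ d)
    trH /= a - 1
    tot = float(((R - grand) ** 2).sum())
    trG = (tot - (a - 1) * trH) / (N - a)
    return trH / trG, trH, trG


def np_manova(
    data: np.ndarray,
    groups,
    permutations: int = 0,
    seed: int | None = None,
) -> MultivariateTestResult:
    """Rank-based multivariate one-way comparison of >= 2 groups.

    Parameters
    ----------
    data
        Subjects x measures response matrix.
    groups
        Group label per subject (length N).
    permutations
        If > 0, also compute a label-permutation p-value of the same
        statistic with this many draws (seeded).

    Each column is midranked across all N subjects.  With between- and
    pooled-within rank covariance matrices H and G, the statistic is
    tr(H)/tr(G), referred to F(f1, f2) with trace moment matching:
    f1 = (a-1)(trG)^2/tr(G^2) and
    f2 = [sum_i (n_i-1) tr(Psi_i)]^2 / [sum_i (n_i-1) tr(Psi_i^2)]
    over the per-group rank covariances Psi_i (fractional dfs).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    groups = np.asarray(groups)
    if len(groups) != data.shape[0]:
        raise ValueError("one group label per subject is required")
    labels, indices = _group_slices(groups)
    a = len(labels)
    if a < 2:
        raise ValueError("need at least 2 groups")
    if min(idx.size for idx in indices) < 2:
        raise ValueError("need at least 2 subjects per group")

    keep = np.ptp(data, axis=0) > 0
    if not keep.any():
        raise ValueError("all response columns are constant")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant response column(s)",
            stacklevel=2,
        )
        data = data[:, keep]

    R = stats.rankdata(data, axis=0)
    N, q = R.shape
    T, trH, trG = _ats(R, indices)

    # Box-type moment matching on the traces
    G = np.zeros((q, q))
    num_f2 = 0.0
    den_f2 = 0.0
    for idx in indices:
        ni = idx.size
        centered = R[idx] - R[idx].mean(axis=0)
        psi = centered.T @ centered / (ni - 1)
        G += (ni - 1) * psi
        num_f2 += (ni - 1) * np.trace(psi)
        den_f2 += (ni - 1) * np.trace(psi @ psi)
    G /= N - a
    tr_g, tr_g2 = np.trace(G), np.trace(G @ G)
    f1 = (a - 1) * tr_g**2 / tr_g2
    f2 = num_f2**2 / den_f2
    p = float(stats.f.sf(T, f1, f2))

    perm_p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        sizes = [idx.size for idx in indices]
        bounds = np.cumsum([0] + sizes)
        # batched permutations: trH from block means of shuffled rows;
        # trG follows from the fixed total sum of squares
        perms = np.stack([rng.permutation(N) for _ in range(permutations)])
        Rp = R[perms]  # (B, N, q)
        grand = R.mean(axis=0)
        tot = float(((R - grand) ** 2).sum())
        trH_perm = np.zeros(permutations)
        for i in range(a):
            block = Rp[:, bounds[i] : bounds[i + 1], :].mean(axis=1) - grand
            trH_perm += sizes[i] * (block**2).sum(axis=1)
        trH_perm /= a - 1
        trG_perm = (tot - (a - 1) * trH_perm) / (N - a)
        t_perm = trH_perm / trG_perm
        perm_p = (int((t_perm >= T).sum()) + 1) / (permutations + 1)

    return MultivariateTestResult(
        statistic=float(T), df1=float(f1), df2=float(f2), p_value=p,
        permutation_p=perm_p,
    )


def closed_subset_testing(
    data: np.ndarray,
    groups,
    alpha: float = 0.05,
    permutations: int = 0,
    seed: int | None = None,
) -> dict[frozenset, dict]:
    """Closed multiple testing over all subsets of >= 2 groups.

    Every subset hypothesis ("these groups are equal") is tested with
    :func:`np_manova` restricted to its members; a subset is *rejected*
    only if its own p-value and those of all supersets fall below
    ``alpha`` (closure principle, family-wise level alpha).

    Returns a dict keyed by frozenset of group labels with entries
    ``p_value`` and ``rejected``.
    """
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    which_p = "permutation_p" if permutations > 0 else "p_value"
    results: dict[frozenset, dict] = {}
    for size in range(2, len(labels) + 1):
        for combo in itertools.combinations(labels, size):
            sel = np.isin(groups, combo)
            res = np_manova(
                data[sel], groups[sel], permutations=permutations, seed=seed
            )
            results[frozenset(combo)] = {
                "p_value": getattr(res, which_p),
                "result": res,
            }
    for subset, entry in results.items():
        own = entry["p_value"] <= alpha
        supersets_ok = all(
            results[sup]["p_value"] <= alpha
            for sup in results
            if subset < sup
        )
        entry["rejected"] = bool(own and supersets_ok)
    return results


# ---------------------------------------------------------------------------
# Fisher r-to-z comparison and Holm correction
# ---------------------------------------------------------------------------

def fisher_z_compare(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Two-sample comparison of correlation coefficients.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p
    from the standard normal.  Coefficients at ±1 are clipped to
    ±(1 - 1e-7) with a warning.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both groups must have more than 3 subjects")
    rs = []
    for r in (r1, r2):
        if abs(r) >= 1:
            warnings.warn(f"|r| = {abs(r)} clipped to 1 - 1e-7", stacklevel=2)
            r = np.sign(r) * (1 - 1e-7)
        rs.append(r)
    z1, z2 = np.arctanh(rs[0]), np.arctanh(rs[1])
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    Z = float((z1 - z2) / se)
    p = float(2 * stats.norm.sf(abs(Z)))
    return Z, p


def holm_correction(
    pvals, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Bonferroni-Holm adjustment.

    Returns (adjusted p-values, rejection flags at ``alpha``); adjusted
    p_(k) = max_{j<=k} min(1, (m-j+1) p_(j)) over the ascending order.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1:
        pvals = pvals.ravel()
    if np.any((pvals < 0) | (pvals > 1)) or np.any(np.isnan(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    mult = m - np.arange(m)
    stepped = np.minimum(1.0, mult * pvals[order])
    adjusted_sorted = np.maximum.accumulate(stepped)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= alpha


@dataclass
class EdgeComparisonResult:
    """Holm-corrected Fisher-z comparisons across all cells.

    ``smallest_critical_p`` is the most stringent per-test threshold the
    step-down procedure applied (alpha / family size) — the single
    number sometimes quoted as "the critical p-value".
    """

    table: pd.DataFrame
    n_skipped: int = 0
    significance_maps: dict = field(default_factory=dict)
    smallest_critical_p: float = float("nan")


def edge_comparison_map(
    maps: dict[str, dict[str, EdgeReliabilityMap]],
    measures: list[str] | None = None,
    alpha: float = 0.05,
    pool: str = "joint",
) -> EdgeComparisonResult:
    """Compare per-edge reliability between every pair of groups.

    ``maps[group][measure]`` holds an :class:`EdgeReliabilityMap`.  Every
    (group pair, measure, band, sink, source) cell with both rho values
    defined enters one Fisher-z comparison; with ``pool="joint"``
    (default) all raw p-values across group pairs, measures, bands and
    edges are pooled and Holm-corrected together, with
    ``pool="per_measure"`` the correction runs within each measure.  In
    the exported significance maps non-significant Z statistics are set
    to 0.
    """
    if pool not in ("joint", "per_measure"):
        raise ValueError("pool must be 'joint' or 'per_measure'")
    group_labels = sorted(maps)
    if len(group_labels) < 2:
        raise ValueError("need at least 2 groups")
    if measures is None:
        measures = sorted(next(iter(maps.values())))
    rows = []
    skipped = 0
    for g1, g2 in itertools.combinations(group_labels, 2):
        for meas in measures:
            m1, m2 = maps[g1][meas], maps[g2][meas]
            rho1 = m1.rho if m1.rho.ndim == 3 else m1.rho[None]
            rho2 = m2.rho if m2.rho.ndim == 3 else m2.rho[None]
            for bi in range(rho1.shape[0]):
                for i in range(rho1.shape[1]):
                    for j in range(rho1.shape[2]):
                        r1, r2 = rho1[bi, i, j], rho2[bi, i, j]
                        if np.isnan(r1) or np.isnan(r2):
                            skipped += 1
                            continue
                        Z, p = fisher_z_compare(r1, m1.n, r2, m2.n)
                        rows.append(
                            {"group1": g1, "group2": g2, "measure": meas,
                             "band": bi, "sink": i, "source": j,
                             "r1": r1, "r2": r2, "Z": Z, "p_raw": p}
                        )
    table = pd.DataFrame(
        rows,
        columns=["group1", "group2", "measure", "band", "sink", "source",
                 "r1", "r2", "Z", "p_raw"],
    )
    smallest_crit = float("nan")
    if len(table):
        if pool == "joint":
            adjusted, reject = holm_correction(table["p_raw"].to_numpy(), alpha)
            smallest_crit = alpha / len(table)
        else:
            adjusted = np.empty(len(table))
            reject = np.zeros(len(table), dtype=bool)
            crits = []
            for _, idx in table.groupby("measure").groups.items():
                loc = table.index.get_indexer(idx)
                adj, rej = holm_correction(
                    table["p_raw"].to_numpy()[loc], alpha
                )
                adjusted[loc] = adj
                reject[loc] = rej
                crits.append(alpha / len(loc))
            smallest_crit = min(crits)
        table["p_holm"] = adjusted
        table["significant"] = reject
        table["Z_significant"] = np.where(reject, table["Z"], 0.0)
    else:
        table["p_holm"] = []
        table["significant"] = []
        table["Z_significant"] = []

    sig_maps: dict = {}
    for (g1, g2, meas), sub in table.groupby(["group1", "group2", "measure"]):
        shape_src = maps[g1][meas].rho
        shape = shape_src.shape if shape_src.ndim == 3 else (1,) + shape_src.shape
        zmap = np.zeros(shape)
        zmap[sub["band"], sub["sink"], sub["source"]] = sub["Z_significant"]
        sig_maps[(g1, g2, meas)] = zmap
    return EdgeComparisonResult(
        table=table, n_skipped=skipped, significance_maps=sig_maps,
        smallest_critical_p=smallest_crit,
    )
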