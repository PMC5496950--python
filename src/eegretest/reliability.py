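"""Test-retest reliability of connectivity patterns.

Two complementary views of the same two-session data:

* **per subject** — one Spearman rank correlation between the subject's
  session-1 and session-2 connectivity vectors, where the vector is the
  concatenation of all band x channel x channel values of one measure
  (channel x channel only for direct causality).  This is the
  reliability-of-a-person's-network summary.
* **per edge** — for each (band, sink, source) cell, the Spearman
  correlation across the subjects of one group between their session-1
  and session-2 values.  This localizes which interactions are stable.

Negative correlations are retained as computed; ties are handled with
midranks throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SubjectMeasures:
    """Band-averaged measure tensors for one subject's two sessions.

    ``session1_perhz``/``session2_perhz`` optionally hold the
    full-frequency-resolution tensors for the per-1-Hz reliability
    variant.
    """

    subject_id: str
    group: str
    session1: dict[str, np.ndarray] = field(default_factory=dict)
    session2: dict[str, np.ndarray] = field(default_factory=dict)
    session1_perhz: dict[str, np.ndarray] = field(default_factory=dict)
    session2_perhz: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class EdgeReliabilityMap:
    """Across-subject session correlation per (band, sink, source) cell."""

    group: str
    measure: str
    rho: np.ndarray  # (bands, m, m) or (m, m); NaN where undefined
    n: int


def concat_vector(band_values: np.ndarray, include_diagonal: bool = True) -> np.ndarray:
    """Flatten a (bands, m, m) tensor into the canonical long vector.

    Ordering contract: band-major, then sink (row), then source (column)
    — i.e. a C-order ravel.  A frequency-independent (m, m) matrix
    flattens row-major to length m*m.  The same ordering is used for
    every session and subject, which is all the rank correlation needs.
    With ``include_diagonal=False`` the sink == source cells are removed
    (in the same order).
    """
    values = np.asarray(band_values, dtype=float)
    if not include_diagonal:
        m = values.shape[-1]
        off = ~np.eye(m, dtype=bool)
        values = values[..., off]
    return values.ravel()


def subject_reliability(v1: np.ndarray, v2: np.ndarray) -> float:
    """Spearman rank correlation between two sessions' value vectors.

    Returns NaN (with a warning) when either vector is constant, in
    which case the correlation is undefined and the subject should be
    excluded.
    """
    v1 = np.asarray(v1, dtype=float).ravel()
    v2 = np.asarray(v2, dtype=float).ravel()
    if v1.shape != v2.shape:
        raise ValueError(f"session vectors differ in length: {v1.size} vs {v2.size}")
    if v1.size < 3:
        raise ValueError("need at least 3 values for a rank correlation")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        warnings.warn("constant value vector: Spearman rho undefined", stacklevel=2)
        return float("nan")
    r1 = stats.rankdata(v1)
    r2 = stats.rankdata(v2)
    if np.array_equal(r1, r2):
        return 1.0  # identical orderings: exactly 1 by definition
    return float(stats.spearmanr(v1, v2).statistic)


def subject_reliability_table(
    subjects: list[SubjectMeasures],
    measures: list[str] | None = None,
    per_hz: bool = False,
    include_diagonal: bool = True,
) -> pd.DataFrame:
    """Long table (subject, group, measure, rho) over a cohort.

    ``per_hz`` correlates the full-frequency-resolution vectors (where
    stored) instead of the band-averaged ones; ``include_diagonal=False``
    drops the autospectra/self cells from the vectors.  Subjects whose
    vectors are constant for a measure get NaN and a warning from
    :func:`subject_reliability`.
    """
    rows = []
    for subj in subjects:
        names = measures if measures is not None else sorted(subj.session1)
        for meas in names:
            if per_hz and meas in subj.session1_perhz:
                v1 = subj.session1_perhz[meas]
                v2 = subj.session2_perhz[meas]
            else:
                v1 = subj.session1[meas]
                v2 = subj.session2[meas]
            rho = subject_reliability(
                concat_vector(v1, include_diagonal),
                concat_vector(v2, include_diagonal),
            )
            rows.append(
                {"subject": subj.subject_id, "group": subj.group,
                 "measure": meas, "rho": rho}
            )
    return pd.DataFrame(rows, columns=["subject", "group", "measure", "rho"])


def edge_reliability(values1: np.ndarray, values2: np.ndarray) -> np.ndarray:
    """Per-cell Spearman across subjects between the two sessions.

    ``values1``/``values2`` have shape (n_subjects, ...); the result has
    the trailing shape, with NaN wherever either session's values are
    constant across subjects (correlation undefined there).
    """
    values1 = np.asarray(values1, dtype=float)
    values2 = np.asarray(values2, dtype=float)
    if values1.shape != values2.shape:
        raise ValueError("session tensors must have identical shapes")
    n = values1.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 subjects per group, got {n}")
    r1 = stats.rankdata(values1, axis=0)
    r2 = stats.rankdata(values2, axis=0)
    r1 = r1 - r1.mean(axis=0)
    r2 = r2 - r2.mean(axis=0)
    s1 = (r1**2).sum(axis=0)
    s2 = (r2**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (r1 * r2).sum(axis=0) / np.sqrt(s1 * s2)
    rho[(s1 == 0) | (s2 == 0)] = np.nan
    n_bad = int(np.isnan(rho).sum())
    if n_bad:
        warnings.warn(
            f"edge reliability undefined (constant across subjects) in {n_bad} cell(s)",
            stacklevel=2,
        )
    return rho


def edge_reliability_maps(
    subjects: list[SubjectMeasures], measure: str
) -> dict[str, EdgeReliabilityMap]:
    """One :class:`EdgeReliabilityMap` per group for the given measure."""
    groups: dict[str, list[SubjectMeasures]] = {}
    for subj in subjects:
        groups.setdefault(subj.group, []).append(subj)
    out = {}
    for label, members in groups.items():
        v1 = np.stack([s.session1[measure] for s in members])
        v2 = np.stack([s.session2[measure] for s in members])
        out[label] = EdgeReliabilityMap(
            group=label, measure=measure,
            rho=edge_reliability(v1, v2), n=len(members),
        )
    return out


def edge_map_table(emap: EdgeReliabilityMap, band_names: list[str]) -> pd.DataFrame:
    """Long TSV-ready table (band, sink, source, rho) of one edge map."""
    rho = emap.rho
    rows = []
    if rho.ndim == 2:
        for i in range(rho.shape[0]):
            for j in range(rho.shape[1]):
                rows.append({"band": "all", "sink": i, "source": j, "rho": rho[i, j]})
    else:
        for bi in range(rho.shape[0]):
            for i in range(rho.shape[1]):
                for j in range(rho.shape[2]):
                    rows.append(
                        {"band": band_names[bi], "sink": i, "source": j,
                         "rho": rho[bi, i, j]}
                    )
    df = pd.DataFrame(rows)
    df.insert(0, "measure", emap.measure)
    df.insert(0, "group", emap.group)
    return df
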