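"""Interbrain coupling: Pearson correlation of the two subjects' region
power envelopes, all region pairs, with a cross-session pseudo-pair null.

The pseudo-pair control pairs one subject's envelope from one session with
the partner-role envelope from a *different* session (same condition and
day where available), which preserves everything condition-generic about
the signals while destroying genuine moment-to-moment engagement; real
pairs exceeding this null is the evidence for true interbrain coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dyadscan.group_stats import TestResult, mann_whitney
from dyadscan.montage import REGIONS

PRIMARY_PAIRS = (("frontal", "frontal"), ("parietal", "parietal"))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN (missing, not 0) when either series
    has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd**2).sum())
    sy = np.sqrt((yd**2).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))


def interbrain_matrix(
    human_series: dict[str, np.ndarray],
    dog_series: dict[str, np.ndarray],
    meta: dict | None = None,
) -> pd.DataFrame:
    """Pearson r for every ordered (human region x dog region) pair.

    Missing regions (e.g. dog temporal) yield rows with NaN r.  Homologous
    frontal-frontal / parietal-parietal pairs are flagged as the primary
    endpoints.
    """
    rows = []
    for rh in REGIONS:
        for rd in REGIONS:
            x = human_series.get(rh)
            y = dog_series.get(rd)
            if x is None or y is None:
                r, n = float("nan"), 0
            else:
                n = min(len(x), len(y))
                r = pearson(x[:n], y[:n]) if n >= 3 else float("nan")
            rows.append(
                {
                    **(meta or {}),
                    "region_human": rh,
                    "region_dog": rd,
                    "r": r,
                    "n_windows": n,
                    "primary": (rh, rd) in PRIMARY_PAIRS,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PseudoPairResult:
    real_r: np.ndarray  # matched sessions, one r per session
    null_r: np.ndarray  # all mismatched human x dog combinations
    test: TestResult  # two-sided Mann-Whitney real vs null


def pseudo_pair_null(
    human_series: list[np.ndarray],
    dog_series: list[np.ndarray],
) -> PseudoPairResult:
    """Real vs pseudo-pair correlations over a set of sessions.

    ``human_series[i]`` and ``dog_series[i]`` belong to session i (all
    sessions of one condition/day stratum); series are truncated to the
    shortest.  The null takes every human x dog combination with different
    session indices (n*(n-1) values for n sessions).
    """
    n = len(human_series)
    if n != len(dog_series):
        raise ValueError("need one human and one dog series per session")
    if n < 2:
        raise ValueError("need at least 2 sessions to form pseudo-pairs")
    m = min(min(len(s) for s in human_series), min(len(s) for s in dog_series))
    hs = [np.asarray(s)[:m] for s in human_series]
    ds = [np.asarray(s)[:m] for s in dog_series]
    real = np.array([pearson(hs[i], ds[i]) for i in range(n)])
    null = np.array([pearson(hs[i], ds[j]) for i in range(n) for j in range(n) if i != j])
    test = mann_whitney(real, null, sided="two-sided")
    return PseudoPairResult(real_r=real, null_r=null, test=test)
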