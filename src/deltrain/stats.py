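"""Cluster-based sign-flip permutation statistics and the RSR index.

Sensor-level condition contrasts are tested with the nonparametric
cluster-based permutation approach: per-channel paired t values are
thresholded at the two-tailed quantile for the cluster-forming alpha,
suprathreshold channels are grouped into connected components over the
sensor neighborhood graph (per polarity), clusters smaller than a minimum
channel count are discarded, and each surviving cluster's mass (sum of
member t values) is compared against the permutation distribution of the
maximal cluster mass obtained by randomly sign-flipping the within-subject
difference maps.  With n subjects and 2^n <= n_perm the sign flips are
enumerated exhaustively, making the test exact.

The rate-specific response index summarizes entrainment strength per
region:

    RSR = (R_0.6,SLOW - R_0.6,FAST) + (R_0.9,FAST - R_0.9,SLOW),

positive when brain responses follow the stimulation rate of each
condition.  The condition x frequency interaction is tested per region
with a within-subject difference-of-differences sign-flip permutation
test.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

__all__ = [
    "ClusterResult",
    "paired_t_map",
    "one_sample_t_map",
    "cluster_permutation",
    "rsr_index",
    "interaction_contrast",
    "clusters_to_json",
]


def one_sample_t_map(diffs: np.ndarray) -> np.ndarray:
    """One-sample t per column of a subjects x channels difference array.

    Zero-variance nonzero differences yield a signed-infinity sentinel
    (with a warning); all-zero columns yield t = 0.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero_var = sd == 0
    if np.any(zero_var & (mean != 0)):
        warnings.warn("zero-variance differences; t set to signed infinity")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(
            zero_var, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t
        )
    return t


def paired_t_map(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Classical paired t per channel (df = n - 1) for subjects x channels."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have matching shapes")
    return one_sample_t_map(a - b)


@dataclass
class ClusterResult:
    """One suprathreshold channel cluster and its Monte-Carlo p value."""

    members: np.ndarray
    mass: float
    polarity: str               # '+' or '-'
    p_mc: float
    peak_channel: int
    peak_t: float
    significant: bool = False

    def to_dict(self) -> dict:
        return {
            "members": [int(m) for m in self.members],
            "mass": float(self.mass),
            "polarity": self.polarity,
            "p_mc": float(self.p_mc),
            "peak_channel": int(self.peak_channel),
            "peak_t": float(self.peak_t),
            "significant": bool(self.significant),
        }


def _graph_edges(graph: np.ndarray) -> np.ndarray:
    """Upper-triangular edge list of a boolean adjacency matrix."""
    g = np.asarray(graph, dtype=bool)
    return np.argwhere(np.triu(g, 1))


def _components(mask: np.ndarray, edges: np.ndarray) -> list:
    """Connected components of the suprathreshold channel set (union-find)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    parent = {int(i): int(i) for i in idx}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    if edges.size:
        both = mask[edges[:, 0]] & mask[edges[:, 1]]
        for a, b in edges[both]:
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[ra] = rb
    comps: dict = {}
    for i in idx:
        comps.setdefault(find(int(i)), []).append(int(i))
    return [np.array(sorted(m)) for m in comps.values()]


def _find_clusters(
    t_map: np.ndarray,
    threshold: float,
    edges: np.ndarray,
    min_channels: int,
):
    """Suprathreshold clusters per polarity: (members, mass, polarity)."""
    out = []
    for sign, pol in ((1.0, "+"), (-1.0, "-")):
        for members in _components(sign * t_map > threshold, edges):
            if members.size < min_channels:
                continue
            out.append((members, float(t_map[members].sum()), pol))
    return out


def _max_cluster_masses(
    t_maps: np.ndarray,
    threshold: float,
    edges: np.ndarray,
    min_channels: int,
) -> tuple:
    """Per permutation: maximal positive mass and maximal |negative| mass."""
    n_perm = t_maps.shape[0]
    null_pos = np.zeros(n_perm)
    null_neg = np.zeros(n_perm)
    for p in range(n_perm):
        for members, mass, pol in _find_clusters(
            t_maps[p], threshold, edges, min_channels
        ):
            if pol == "+":
                null_pos[p] = max(null_pos[p], mass)
            else:
                null_neg[p] = max(null_neg[p], -mass)
    return null_pos, null_neg


def _sign_flip_t(diffs: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """t-maps for many sign-flip patterns at once.

    Sign flips leave per-channel sums of squares unchanged, so only the
    flipped means need recomputing: a (P, n) flip matrix against an
    (n, C) difference array yields (P, C) t-maps.
    """
    n = diffs.shape[0]
    ss = np.sum(diffs**2, axis=0)                     # (C,)
    means = flips @ diffs / n                         # (P, C)
    var = (ss[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
        t = np.where(
            var == 0, np.where(means == 0, 0.0, np.sign(means) * np.inf), t
        )
    return t


def cluster_permutation(
    values_a: np.ndarray,
    values_b: np.ndarray,
    graph: np.ndarray,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    min_channels: int = 3,
    seed: int | None = None,
    tail_alpha: float | None = None,
) -> list:
    """Cluster-based sign-flip permutation test of a paired contrast.

    ``values_a`` and ``values_b`` are subjects x channels; ``graph`` the
    boolean channel adjacency.  The cluster-forming threshold is the
    two-tailed t quantile at ``cluster_alpha``; clusters are evaluated per
    polarity against ``tail_alpha`` (default ``cluster_alpha / 2``, the
    correct-tail convention).  Monte-Carlo p values use the +1 correction;
    with 2^n <= n_perm all sign patterns are enumerated instead and the p
    value is exact.
    """
    diffs = np.asarray(values_a, dtype=float) - np.asarray(values_b, dtype=float)
    n, n_ch = diffs.shape
    graph = np.asarray(graph, dtype=bool)
    if graph.shape != (n_ch, n_ch):
        raise ValueError("graph must be channels x channels")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p resolution")
    n_comp, _ = connected_components(sparse.csr_matrix(graph), directed=False)
    if n_comp > 1:
        warnings.warn(f"neighborhood graph has {n_comp} disconnected components")
    tail_alpha = cluster_alpha / 2.0 if tail_alpha is None else tail_alpha
    edges = _graph_edges(graph)

    threshold = float(t_dist.ppf(1.0 - cluster_alpha / 2.0, n - 1))
    t_obs = one_sample_t_map(diffs)
    observed = _find_clusters(t_obs, threshold, edges, min_channels)
    if not observed:
        return []

    exhaustive = 2**n <= n_perm
    if exhaustive:
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = _sign_flip_t(diffs, flips)
    null_pos, null_neg = _max_cluster_masses(t_null, threshold, edges, min_channels)

    results = []
    for members, mass, pol in observed:
        null = null_pos if pol == "+" else null_neg
        # tie tolerance: the identity flip reproduces the observed statistic
        # exactly, up to floating-point summation order
        tol = 1e-9 * max(1.0, abs(mass))
        r = int(np.sum(null >= abs(mass) - tol))
        if exhaustive:
            p = r / flips.shape[0]
        else:
            p = (r + 1) / (n_perm + 1)
        peak_local = int(np.argmax(np.abs(t_obs[members])))
        results.append(
            ClusterResult(
                members=members,
                mass=mass,
                polarity=pol,
                p_mc=float(p),
                peak_channel=int(members[peak_local]),
                peak_t=float(t_obs[members][peak_local]),
                significant=bool(p <= tail_alpha),
            )
        )
    results.sort(key=lambda c: c.p_mc)
    return results


# ---------------------------------------------------------------------------
# ROI-level response measures
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ["subject", "condition", "frequency", "roi", "hemisphere", "R"]


class MissingCellError(ValueError):
    pass


def _check_crossing(responses: pd.DataFrame) -> pd.DataFrame:
    df = responses.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"responses missing columns {missing}")
    counts = df.pivot_table(
        index=["subject", "roi", "hemisphere"],
        columns=["condition", "frequency"],
        values="R",
        aggfunc="size",
    )
    if counts.isna().any().any() or counts.shape[1] != 4:
        raise MissingCellError(
            "incomplete condition x frequency crossing in responses"
        )
    return df


def rsr_index(responses: pd.DataFrame) -> pd.DataFrame:
    """Rate-specific response per subject x ROI x hemisphere.

    ``responses`` is long-format with columns subject, condition
    (SLOW/FAST), frequency (0.6/0.9), roi, hemisphere, R.
    """
    df = _check_crossing(responses)
    wide = df.pivot_table(
        index=["subject", "roi", "hemisphere"],
        columns=["condition", "frequency"],
        values="R",
    )
    rsr = (wide[("SLOW", 0.6)] - wide[("FAST", 0.6)]) + (
        wide[("FAST", 0.9)] - wide[("SLOW", 0.9)]
    )
    out = rsr.rename("rsr").reset_index()
    if not np.all(np.isfinite(out["rsr"])):
        raise ValueError("non-finite RSR values")
    return out


def _sign_flip_p(contrast: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided sign-flip permutation p for a one-sample mean."""
    n = contrast.size
    obs = abs(contrast.mean())
    if 2**n <= n_perm:
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        null = np.abs(flips @ contrast / n)
        return float(np.sum(null >= obs - 1e-12) / flips.shape[0])
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = np.abs(flips @ contrast / n)
    return float((np.sum(null >= obs - 1e-12) + 1) / (n_perm + 1))


def interaction_contrast(
    responses: pd.DataFrame,
    n_perm: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Condition x frequency interaction per ROI x hemisphere.

    The within-subject difference-of-differences
    ``(R_0.6,SLOW - R_0.9,SLOW) - (R_0.6,FAST - R_0.9,FAST)`` is tested
    against zero with a sign-flip permutation; post-hoc within-condition
    0.6-vs-0.9 paired t tests are reported alongside.
    """
    df = _check_crossing(responses)
    n_subjects = df["subject"].nunique()
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    rows = []
    for (roi, hemi), g in df.groupby(["roi", "hemisphere"]):
        wide = g.pivot_table(
            index="subject", columns=["condition", "frequency"], values="R"
        )
        d_slow = (wide[("SLOW", 0.6)] - wide[("SLOW", 0.9)]).to_numpy()
        d_fast = (wide[("FAST", 0.6)] - wide[("FAST", 0.9)]).to_numpy()
        contrast = d_slow - d_fast
        t_int = float(one_sample_t_map(contrast[:, None])[0])
        rows.append(
            {
                "roi": roi,
                "hemisphere": hemi,
                "contrast_mean": float(contrast.mean()),
                "t": t_int,
                "p_perm": _sign_flip_p(contrast, n_perm, rng),
                "t_slow_06_vs_09": float(one_sample_t_map(d_slow[:, None])[0]),
                "p_slow_06_vs_09": _sign_flip_p(d_slow, n_perm, rng),
                "t_fast_06_vs_09": float(one_sample_t_map(d_fast[:, None])[0]),
                "p_fast_06_vs_09": _sign_flip_p(d_fast, n_perm, rng),
            }
        )
    return pd.DataFrame(rows)


def clusters_to_json(clusters: list, path=None) -> str:
    payload = json.dumps([c.to_dict() for c in clusters], indent=2)
    if path is not None:
        from pathlib import Path

        Path(path).write_text(payload)
    return payload
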