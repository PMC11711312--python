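"""Population-level statistics of follicle innervation.

Covers the angular polarization scan (semicircle binomial tests on a rotating
cut), the fiber-caliber/conduction-velocity vs terminal-height gradient with
its bimodal diameter split, the per-axon crossing index that quantifies
whether an axon exchanges angular order mostly within or across axon arms,
and Kruskal-Wallis with Dunn's Bonferroni-corrected pairwise comparisons
between afferent types.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .frames import signed_angle_diff, wrap_angle

__all__ = [
    "binomial_two_sided",
    "polarization_scan",
    "crossing_index",
    "gradient_analysis",
    "group_test",
    "GradientResult",
    "GroupTestResult",
]

# Relative tolerance when comparing outcome probabilities in the exact
# two-sided binomial test (guards against floating-point ties).
_BINOM_TIE_RTOL = 1e-7


def binomial_two_sided(k: int, n: int) -> float:
    """Exact two-sided binomial test p-value against p0 = 0.5.

    Minimum-likelihood definition: the p-value sums pmf(m) over every outcome
    m whose probability does not exceed pmf(k) (within a small relative
    tolerance for floating ties).
    """
    if n <= 0 or not 0 <= k <= n:
        raise ValueError(f"invalid binomial arguments k={k}, n={n}")
    pmf = sps.binom.pmf(np.arange(n + 1), n, 0.5)
    p = float(pmf[pmf <= pmf[k] * (1.0 + _BINOM_TIE_RTOL)].sum())
    return min(p, 1.0)


def polarization_scan(
    angles_by_class: dict[str, np.ndarray], step: float = 20.0
) -> pd.DataFrame:
    """Semicircle binomial scan of angular polarization.

    For each cut angle theta on a ``step``-degree grid the circle splits into
    the half-open semicircles [theta, theta+180) and its complement; for every
    axon class (and the pooled total) the count k falling in the first
    semicircle is tested against Binomial(n, 0.5) with the exact two-sided
    test. The cut at theta+180 yields the same partition, hence the same p.

    Returns a tidy frame with columns cut_deg, class, k, n, p_value
    (p_value is NaN for an empty class).
    """
    classes = dict(angles_by_class)
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in classes.values()]) \
        if classes else np.array([])
    classes["total"] = pooled
    cuts = np.arange(0.0, 360.0, step)
    rows = []
    for cut in cuts:
        for name, angles in classes.items():
            a = wrap_angle(np.asarray(angles, dtype=float))
            n = a.size
            in_half = ((a - cut) % 360.0) < 180.0
            k = int(in_half.sum())
            p = binomial_two_sided(k, n) if n > 0 else np.nan
            rows.append({"cut_deg": float(cut), "class": name, "k": k, "n": n,
                         "p_value": p})
    return pd.DataFrame(rows)


def crossing_index(
    angles_ref, angles_terminal, arm_ids, axon_ids=None
) -> pd.DataFrame:
    """Per-axon crossing index from angular order changes between two levels.

    Every unordered axon pair is compared by the signed circular difference
    (in (-180, 180]) of their angular positions at a reference level (100 µm
    below the ringwulst) and at their terminals. A sign change between levels
    counts one crossing for both axons, tallied as intra- or inter-arm by the
    pair's arm ids; exact 0 or 180 degree differences at either level are
    order ties, not crossings. The index I = (N_intra - N_inter) / N_total is
    +1 for an axon crossing only within its arm, -1 only across arms, and 0
    for an axon involved in no crossing.
    """
    ref = np.asarray(angles_ref, dtype=float)
    term = np.asarray(angles_terminal, dtype=float)
    arms = np.asarray(arm_ids)
    if ref.shape != term.shape or ref.shape != arms.shape:
        raise ValueError("angles_ref, angles_terminal and arm_ids must align")
    n = ref.size
    if n < 2:
        raise ValueError("crossing index needs at least 2 axons")
    if np.isnan(ref).any() or np.isnan(term).any():
        bad = int(np.flatnonzero(np.isnan(ref) | np.isnan(term))[0])
        name = bad if axon_ids is None else axon_ids[bad]
        raise ValueError(f"axon {name}: missing angular position")
    if axon_ids is None:
        axon_ids = np.arange(n)
    n_intra = np.zeros(n, dtype=int)
    n_inter = np.zeros(n, dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        d_ref = float(signed_angle_diff(ref[i], ref[j]))
        d_term = float(signed_angle_diff(term[i], term[j]))
        if d_ref in (0.0, 180.0) or d_term in (0.0, 180.0):
            continue
        if np.sign(d_ref) != np.sign(d_term):
            if arms[i] == arms[j]:
                n_intra[i] += 1
                n_intra[j] += 1
            else:
                n_inter[i] += 1
                n_inter[j] += 1
    total = n_intra + n_inter
    with np.errstate(invalid="ignore"):
        index = np.where(total > 0, (n_intra - n_inter) / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "axon_id": np.asarray(axon_ids),
            "n_intra": n_intra,
            "n_inter": n_inter,
            "n_total": total,
            "crossing_index": index,
        }
    )


@dataclass(frozen=True)
class GradientResult:
    """Velocity/area vs terminal-height regressions and the diameter split."""

    velocity_fit: dict
    area_fit: dict
    split_um: float
    diameter_below: np.ndarray
    diameter_above: np.ndarray
    median_diameter_below: float
    median_diameter_above: float


def _linfit(x, y) -> dict:
    res = sps.linregress(x, y)
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "r": res.rvalue,
        "r2": res.rvalue**2,
        "p_value": res.pvalue,
        "stderr": res.stderr,
    }


def gradient_analysis(
    heights, fiber_areas, velocities, split: float = 850.0
) -> GradientResult:
    """Proximal-to-distal caliber/velocity gradient along the follicle.

    Ordinary least squares of conduction velocity (and of fiber area) on
    terminal height, with Pearson r, r² and the two-sided p from the
    t-distribution; fiber diameters (from area, d = 2*sqrt(A/pi)) are split
    at the height threshold (default 850 µm above the nerve entrance) and
    summarised per group.
    """
    h = np.asarray(heights, dtype=float)
    a = np.asarray(fiber_areas, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if not (h.size == a.size == v.size) or h.size < 3:
        raise ValueError("need at least 3 aligned observations")
    if np.ptp(h) == 0:
        raise ValueError("terminal heights have zero variance")
    diam = 2.0 * np.sqrt(a / np.pi)
    below = diam[h < split]
    above = diam[h >= split]
    return GradientResult(
        velocity_fit=_linfit(h, v),
        area_fit=_linfit(h, a),
        split_um=split,
        diameter_below=below,
        diameter_above=above,
        median_diameter_below=float(np.median(below)) if below.size else float("nan"),
        median_diameter_above=float(np.median(above)) if above.size else float("nan"),
    )


@dataclass(frozen=True)
class GroupTestResult:
    """Kruskal-Wallis omnibus plus Dunn's Bonferroni-corrected pairwise z tests."""

    H: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adjusted


def group_test(values_by_group: dict[str, np.ndarray]) -> GroupTestResult:
    """Between-type comparison of a scalar feature (e.g. fiber area).

    Kruskal-Wallis H with tie correction, followed by Dunn's post-hoc test:
    pairwise z statistics on mean ranks with the pooled-rank variance
    (including the tie term), two-sided normal p-values, Bonferroni-adjusted
    over all pairs.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, g in groups.items():
        if g.size == 0:
            raise ValueError(f"group {name!r} is empty")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        # Degenerate: every observation identical; no evidence of any shift.
        pairs = list(itertools.combinations(groups, 2))
        pairwise = pd.DataFrame(
            [{"group_a": a, "group_b": b, "z": 0.0, "p_raw": 1.0, "p_adjusted": 1.0}
             for a, b in pairs]
        )
        return GroupTestResult(H=0.0, p_value=1.0, pairwise=pairwise)
    H, p = sps.kruskal(*groups.values())
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank, sizes, start = {}, {}, 0
    for name, g in groups.items():
        mean_rank[name] = ranks[start : start + g.size].mean()
        sizes[name] = g.size
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    base_var = N * (N + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": float(z),
                "p_raw": float(p_raw),
                "p_adjusted": float(min(1.0, m * p_raw)),
            }
        )
    return GroupTestResult(H=float(H), p_value=float(p), pairwise=pd.DataFrame(rows))
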