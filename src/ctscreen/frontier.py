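"""Efficiency frontiers, distance deciles, and cross-variant consensus.

A program is *dominated* if some other program achieves at least as much
benefit (lung-cancer deaths avoided, or life-years saved for the secondary
analysis) with no more CT screens, at least one strictly. The frontier is
the increasing concave envelope of the non-dominated points, anchored at the
origin (no screens, no benefit): interior points of the envelope are removed
(extended dominance). Distance from the frontier is the vertical gap between
a program's benefit and the envelope interpolated at its screen count,
measured in within-variant normalized benefit units (benefit divided by the
maximum benefit of any program in that variant/sex), which makes distances
invariant to rescaling of the benefit axis.

Non-frontier programs are ranked into ten equal-count deciles of distance
(decile 1 = closest; frontier programs are decile 0; ties broken by label).
A program is *consensus efficient* if it falls in the first three deciles
(or on the frontier) for at least three model variants, separately for
males and for females, and appears on both sex lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class FrontierResult:
    """Frontier geometry and per-program distances for one variant x sex."""

    labels: list                   # program labels, input order
    screens: np.ndarray
    benefit: np.ndarray
    efficient_set: list            # labels on the frontier
    distance: np.ndarray           # normalized vertical gap; 0 on frontier
    decile: Optional[np.ndarray] = None
    variant_id: str = ""
    sex: str = ""

    def distance_of(self, label: str) -> float:
        return float(self.distance[self.labels.index(label)])

    def decile_of(self, label: str) -> int:
        return int(self.decile[self.labels.index(label)])


def build_frontier(screens: Sequence[float], benefit: Sequence[float],
                   labels: Sequence[str], variant_id: str = "",
                   sex: str = "") -> FrontierResult:
    """Construct the efficiency frontier for one set of program points."""
    screens = np.asarray(screens, dtype=float)
    benefit = np.asarray(benefit, dtype=float)
    labels = list(labels)
    if screens.size == 0:
        raise ValueError("at least one program is required")
    if screens.size != benefit.size or len(labels) != screens.size:
        raise ValueError("screens, benefit and labels must align")
    if np.any(screens < 0) or not np.all(np.isfinite(benefit)):
        raise ValueError("screens must be >= 0 and benefit finite")

    bmax = benefit.max()
    norm = benefit / bmax if bmax > 0 else benefit.astype(float)

    hull_x, hull_y = _concave_envelope(screens, norm)
    env = np.interp(screens, hull_x, hull_y)
    distance = np.maximum(env - norm, 0.0)

    # the frontier is the set of hull vertices: non-dominated points that are
    # not interior to the concave envelope (extended dominance removes those)
    dominated = _dominated_mask(screens, norm)
    vertices = {(round(xi, 9), round(yi, 9))
                for xi, yi in zip(hull_x, hull_y)}
    efficient = np.array(
        [(not dominated[i])
         and (round(screens[i], 9), round(norm[i], 9)) in vertices
         for i in range(screens.size)])
    distance[efficient] = 0.0
    eff_labels = [lab for lab, e in zip(labels, efficient) if e]

    result = FrontierResult(labels=labels, screens=screens, benefit=benefit,
                            efficient_set=eff_labels, distance=distance,
                            variant_id=variant_id, sex=sex)
    result.decile = rank_deciles(result)
    return result


def _dominated_mask(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """True where some other point has <= screens and >= benefit (one strict).

    O(n log n): sweep by increasing screens, tracking the best benefit seen.
    """
    n = x.size
    order = np.lexsort((-y, x))
    dominated = np.zeros(n, dtype=bool)
    best = -np.inf
    best_x = np.nan
    for i in order:
        if y[i] < best or (y[i] == best and x[i] > best_x):
            dominated[i] = True
        elif y[i] > best:
            best = y[i]
            best_x = x[i]
    return dominated


def _concave_envelope(x: np.ndarray, y: np.ndarray):
    """Upper concave envelope vertices through the non-dominated points,
    anchored at the origin; returns (xs, ys) with xs increasing."""
    keep = ~_dominated_mask(x, y)
    xs = np.concatenate([[0.0], x[keep]])
    ys = np.concatenate([[0.0], y[keep]])
    order = np.argsort(xs, kind="stable")
    xs, ys = xs[order], ys[order]
    # de-duplicate equal x (keep max y)
    ux, uy = [], []
    for xi, yi in zip(xs, ys):
        if ux and xi == ux[-1]:
            uy[-1] = max(uy[-1], yi)
        else:
            ux.append(xi)
            uy.append(yi)
    hull_x, hull_y = [], []
    for xi, yi in zip(ux, uy):
        hull_x.append(xi)
        hull_y.append(yi)
        while len(hull_x) >= 3:
            (x1, y1), (x2, y2), (x3, y3) = (
                (hull_x[-3], hull_y[-3]), (hull_x[-2], hull_y[-2]),
                (hull_x[-1], hull_y[-1]))
            # middle point below or on the chord -> not a hull vertex
            if (y2 - y1) * (x3 - x1) <= (y3 - y1) * (x2 - x1) + 1e-15:
                del hull_x[-2], hull_y[-2]
            else:
                break
    return np.asarray(hull_x), np.asarray(hull_y)


def rank_deciles(result: FrontierResult) -> np.ndarray:
    """Decile of frontier distance per program (0 = on the frontier).

    Non-frontier programs are sorted by (distance, label) and cut into ten
    equal-count bins; when the count is not divisible by ten the earlier
    (closer) bins take the extra programs.
    """
    n = len(result.labels)
    decile = np.zeros(n, dtype=int)
    frontier = set(result.efficient_set)
    off = [i for i in range(n) if result.labels[i] not in frontier]
    off.sort(key=lambda i: (result.distance[i], result.labels[i]))
    for d, chunk in enumerate(np.array_split(np.asarray(off, dtype=int), 10)):
        decile[chunk] = d + 1
    return decile


@dataclass
class ConsensusSet:
    """Programs efficient-or-near-efficient across the variant ensemble."""

    programs: list                       # consensus labels (sorted)
    support: pd.DataFrame                # per program x sex: variant count
    male_list: list = field(default_factory=list)
    female_list: list = field(default_factory=list)


def consensus(results: Sequence[FrontierResult], decile_cut: int = 3,
              min_variants: int = 3) -> ConsensusSet:
    """Apply the consensus rule over per-variant, per-sex frontier results.

    A program qualifies for a sex if its decile is <= ``decile_cut``
    (frontier programs, decile 0, always qualify) in at least
    ``min_variants`` variants; consensus programs qualify for both sexes.
    """
    by_sex: dict[str, dict[str, int]] = {}
    grids = {tuple(sorted(r.labels)) for r in results}
    if len(grids) != 1:
        raise ValueError("all frontier results must share one program grid")
    labels = sorted(results[0].labels)
    for r in results:
        counts = by_sex.setdefault(r.sex, {lab: 0 for lab in labels})
        for i, lab in enumerate(r.labels):
            if r.decile[i] <= decile_cut:
                counts[lab] += 1
    sexes = sorted(by_sex)
    lists = {s: [lab for lab in labels if by_sex[s][lab] >= min_variants]
             for s in sexes}
    if set(sexes) >= {"male", "female"}:
        members = sorted(set(lists["male"]) & set(lists["female"]))
    else:     # single-sex input: intersection over whatever is present
        members = sorted(set.intersection(*(set(v) for v in lists.values())))
    support = pd.DataFrame(
        {s: [by_sex[s][lab] for lab in labels] for s in sexes}, index=labels)
    return ConsensusSet(programs=members, support=support,
                        male_list=lists.get("male", []),
                        female_list=lists.get("female", []))


def frontier_lifeyears(screens: Sequence[float],
                       life_years_saved: Sequence[float],
                       labels: Sequence[str], variant_id: str = "",
                       sex: str = "") -> FrontierResult:
    """Secondary frontier with life-years saved as the benefit axis."""
    return build_frontier(screens, life_years_saved, labels,
                          variant_id=variant_id, sex=sex)
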