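"""From independent components to sectors.

Each IC's loading distribution is fitted with a location-scale
t-distribution; positions beyond the fitted 95th percentile form that
IC's selection. Selections are compared pairwise with one-way ANOVA on
the positions' mean Euclidean distances in IC-loading space; IC pairs
whose selections are *not* statistically different (p >= cutoff, default
0.10) are linked, and sectors are the connected components of that
graph. A motif-profile helper extracts, for positions of interest, their
coupling strengths to the other positions of the motif.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist


@dataclass
class ICSelection:
    ic_index: int  # 1-based
    positions: list[int]  # 0-based retained-alignment column indices
    ats_positions: list[int | None]
    t_params: tuple[float, float, float] | None  # (df, loc, scale); None if fallback
    used_fallback: bool = False


@dataclass
class SectorPartition:
    sectors: dict[int, frozenset[int]]  # sector id -> IC indices (1-based)
    sector_positions: dict[int, frozenset[int]]  # sector id -> union of positions
    p_matrix: np.ndarray  # (k, k) pairwise ANOVA p-values (NaN on diagonal/skips)

    def sector_of_ic(self, ic_index: int) -> int:
        for sid, ics in self.sectors.items():
            if ic_index in ics:
                return sid
        raise KeyError(ic_index)


def select_positions(
    ic_loadings: np.ndarray,
    ic_index: int = 1,
    quantile: float = 0.95,
    ats: list[int | None] | None = None,
) -> ICSelection:
    """Select the positions in the top tail of a fitted t-distribution.

    A location-scale t-distribution is fitted to the IC loadings by
    maximum likelihood; positions with loading above the fitted
    ``quantile`` point are selected (one-sided; components are
    sign-oriented upstream). Degenerate fits fall back to the empirical
    quantile, selecting the ceil((1-quantile)*L) largest loadings with
    index-order tie-breaking.
    """
    x = np.asarray(ic_loadings, dtype=float)
    L = x.size
    if L < 20:
        raise ValueError("need at least 20 positions")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    t_params: tuple[float, float, float] | None = None
    threshold = None
    if np.ptp(x) > 0:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df, loc, scale = stats.t.fit(x)
            if np.isfinite([df, loc, scale]).all() and scale > 0 and df > 0:
                t_params = (float(df), float(loc), float(scale))
                threshold = stats.t.ppf(quantile, df, loc=loc, scale=scale)
        except Exception:
            t_params = None
    if t_params is not None and np.isfinite(threshold):
        selected = np.flatnonzero(x > threshold)
        used_fallback = False
    else:
        k = math.ceil((1.0 - quantile) * L - 1e-9)  # guard float overshoot
        order = sorted(range(L), key=lambda i: (-x[i], i))
        selected = np.array(sorted(order[:k]), dtype=int)
        used_fallback = True
    positions = [int(i) for i in selected]
    ats_positions = [ats[i] if ats is not None else i + 1 for i in positions]
    return ICSelection(ic_index, positions, ats_positions, t_params, used_fallback)


def select_all(
    V_ica: np.ndarray, quantile: float = 0.95, ats: list[int | None] | None = None
) -> list[ICSelection]:
    return [
        select_positions(V_ica[:, k], ic_index=k + 1, quantile=quantile, ats=ats)
        for k in range(V_ica.shape[1])
    ]


def selection_distance_map(
    selections: list[ICSelection], V_ica: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Pairwise Euclidean distances between selected positions in IC space.

    Returns the symmetric distance matrix and, per row, (position,
    ic_index) labels ordered by IC membership. Positions selected by
    several ICs appear once per selection, as in the heatmap the
    partitioning is based on.
    """
    if len(selections) < 2:
        raise ValueError("need at least 2 selections")
    labels: list[tuple[int, int]] = []
    vectors = []
    for sel in selections:
        for p in sel.positions:
            labels.append((p, sel.ic_index))
            vectors.append(V_ica[p, :])
    V = np.asarray(vectors)
    return cdist(V, V), labels


def _mean_distance_to(
    positions: list[int], reference: list[int], V_ica: np.ndarray
) -> np.ndarray:
    """Per-position mean Euclidean distance (IC space) to a reference selection."""
    A = V_ica[np.asarray(positions, dtype=int), :]
    B = V_ica[np.asarray(reference, dtype=int), :]
    return cdist(A, B).mean(axis=1)


def _anova_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        # constant responses: indistinguishable iff the constants agree
        return 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
    return float(stats.f_oneway(x, y).pvalue)


def selection_pair_pvalue(
    sel_a: ICSelection, sel_b: ICSelection, V_ica: np.ndarray
) -> float:
    """ANOVA p-value for the difference between two IC selections.

    Each selection in turn serves as reference: every selected position's
    response is its mean Euclidean distance (IC-loading space) to the
    reference selection's members, and a one-way ANOVA compares the two
    selections' responses. Two ICs capturing the same group of coupled
    positions give similar responses under either reference (large p);
    distinct groups separate under at least one (small p). The pair's
    p-value is the minimum over the two references, so ICs merge only
    when neither view distinguishes them.
    """
    ps = []
    for ref in (sel_a, sel_b):
        ra = _mean_distance_to(sel_a.positions, ref.positions, V_ica)
        rb = _mean_distance_to(sel_b.positions, ref.positions, V_ica)
        ps.append(_anova_p(ra, rb))
    return min(ps)


def group_sectors(
    selections: list[ICSelection],
    V_ica: np.ndarray,
    p_cutoff: float = 0.10,
) -> SectorPartition:
    """Merge ICs whose selections are not statistically different.

    For each IC pair, :func:`selection_pair_pvalue` tests whether the two
    selections occupy distinguishable regions of IC-loading space;
    p >= ``p_cutoff`` links the pair; sectors are the connected
    components of the link graph. Selections with fewer than 2 positions
    are skipped and become singleton sectors.
    """
    if len(selections) < 2:
        raise ValueError("need at least 2 selections")
    k = len(selections)
    p_matrix = np.full((k, k), np.nan)
    adjacency = [[False] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            if len(selections[i].positions) < 2 or len(selections[j].positions) < 2:
                continue
            p = selection_pair_pvalue(selections[i], selections[j], V_ica)
            p_matrix[i, j] = p_matrix[j, i] = p
            if p >= p_cutoff:
                adjacency[i][j] = adjacency[j][i] = True

    # connected components (union-find)
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            if adjacency[i][j]:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
    roots: dict[int, list[int]] = {}
    for i in range(k):
        roots.setdefault(find(i), []).append(i)
    sectors: dict[int, frozenset[int]] = {}
    sector_positions: dict[int, frozenset[int]] = {}
    for sid, members in enumerate(
        sorted(roots.values(), key=lambda m: min(m)), start=1
    ):
        sectors[sid] = frozenset(selections[i].ic_index for i in members)
        sector_positions[sid] = frozenset(
            p for i in members for p in selections[i].positions
        )
    return SectorPartition(sectors, sector_positions, p_matrix)


def ic_membership(V_ica: np.ndarray) -> np.ndarray:
    """Per-position IC label (1-based): argmax |loading|, ties to lower IC."""
    return np.argmax(np.abs(V_ica), axis=1) + 1


@dataclass
class MotifProfile:
    position: int
    ic: int
    missing: bool
    others: list[int] = field(default_factory=list)
    couplings: list[float] = field(default_factory=list)


def motif_correlation_profile(
    Ctilde: np.ndarray,
    motif_positions: list[int],
    V_ica: np.ndarray,
) -> list[MotifProfile]:
    """Within-motif coupling profile for each motif position.

    For each motif position (retained-alignment coordinates), the Ctilde
    row restricted to the other motif positions, self entry removed,
    labeled by the position's IC membership. Positions outside the
    retained alignment (truncated during preprocessing, marked by a
    negative index) are reported as missing rather than dropped.
    """
    L = Ctilde.shape[0]
    membership = ic_membership(V_ica)
    inside = [p for p in motif_positions if 0 <= p < L]
    out: list[MotifProfile] = []
    for p in motif_positions:
        if not 0 <= p < L:
            out.append(MotifProfile(p, 0, True))
            continue
        others = [o for o in inside if o != p]
        out.append(
            MotifProfile(
                p,
                int(membership[p]),
                False,
                others,
                [float(Ctilde[p, o]) for o in others],
            )
        )
    return out
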