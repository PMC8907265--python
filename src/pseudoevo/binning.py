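"""Species-pair binning and per-bin percentile ranking of genes.

The comparative ranking works on species pairs, not species: every pair
gets a mean protein distance (averaged over genes, reference model), the
distribution of those means is cut at its most distinguishable density
troughs into 4 bins, and within each bin every gene's aggregate
(mean distance, or median Ka / Ks / log10(Ka/Ks)) is converted to a
percentile among the genes of its domain group. The orientation is fixed
so that the gene with the *largest* aggregate gets percentile 0 and the
most conserved gene gets 100: a low percentile means fast change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

REFERENCE_MODEL = "equal_input"


@dataclass(frozen=True)
class BinSpec:
    """Three ascending borders defining 4 half-open bins [b_{k-1}, b_k)."""

    borders: tuple[float, float, float]
    reference_model: str = REFERENCE_MODEL

    def __post_init__(self) -> None:
        b = self.borders
        if len(b) != 3 or not (b[0] < b[1] < b[2]):
            raise ValueError("borders must be 3 strictly ascending values")

    @property
    def n_bins(self) -> int:
        return 4


class InsufficientDataError(ValueError):
    pass


def find_borders(mean_pair_distances, grid_size: int = 2048) -> tuple[float, float, float]:
    """Locate 3 bin borders at density troughs of the mean-distance distribution.

    The empirical density (Gaussian KDE, Silverman bandwidth) is scanned
    for interior local minima; the 3 lowest-density minima are returned in
    ascending position. If the distribution shows fewer than 3 troughs
    (e.g. unimodal data), quartile borders are used instead, with a warning.
    """
    values = np.asarray(
        list(mean_pair_distances.values())
        if isinstance(mean_pair_distances, dict)
        else mean_pair_distances,
        dtype=float,
    )
    values = values[np.isfinite(values)]
    if values.size < 50:
        raise InsufficientDataError(
            f"need >= 50 species-pair mean distances, got {values.size}"
        )
    kde = gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:])
    ) + 1
    if interior.size < 3:
        warnings.warn(
            "fewer than 3 density troughs found; falling back to quartile borders",
            stacklevel=2,
        )
        q = np.quantile(values, [0.25, 0.5, 0.75])
        return (float(q[0]), float(q[1]), float(q[2]))
    deepest = interior[np.argsort(dens[interior])[:3]]
    borders = np.sort(grid[deepest])
    return (float(borders[0]), float(borders[1]), float(borders[2]))


def assign_bins(pair_values: dict, spec: BinSpec) -> tuple[dict, list]:
    """Map each species pair to a bin index in {1, 2, 3, 4}.

    Values equal to a border fall in the upper bin (half-open convention).
    Pairs with undefined (NaN) values are skipped and reported in the log.
    """
    borders = np.asarray(spec.borders)
    assignment: dict = {}
    skipped: list = []
    for pair, v in pair_values.items():
        if v is None or not np.isfinite(v):
            skipped.append(pair)
            continue
        assignment[pair] = int(np.searchsorted(borders, v, side="right")) + 1
    return assignment, skipped


def rank_in_bin(per_gene_aggregates: dict, direction: str = "high_value_low_rank") -> dict:
    """Percentile-rank genes within one bin.

    percentile(g) = 100 * (#genes with aggregate strictly greater) / (N-1);
    ties share the mean of their would-be percentiles. The default
    direction gives the largest aggregate percentile 0 (fast change) and
    the smallest 100 (conserved); ``"high_value_high_rank"`` flips this.
    """
    genes = [g for g, v in per_gene_aggregates.items() if np.isfinite(v)]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes with defined aggregates to rank")
    values = np.array([per_gene_aggregates[g] for g in genes], dtype=float)
    if direction == "high_value_high_rank":
        values = -values
    elif direction != "high_value_low_rank":
        raise ValueError(f"unknown direction {direction!r}")
    n = len(genes)
    out: dict = {}
    for g, v in zip(genes, values):
        greater = int((values > v).sum())
        equal = int((values == v).sum())  # includes self
        # ties occupy consecutive ranks; share their mean percentile
        mean_rank = greater + (equal - 1) / 2.0
        out[g] = 100.0 * mean_rank / (n - 1)
    return out


def aggregate(values, statistic: str = "mean") -> float:
    """Mean/median over the defined (finite) values; NaN when none remain."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return float("nan")
    if statistic == "mean":
        return float(arr.mean())
    if statistic == "median":
        return float(np.median(arr))
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass
class RankTable:
    """Tidy per-(gene, bin) aggregates and percentiles for one statistic."""

    statistic: str
    rows: list[dict] = field(default_factory=list)  # gene, group, bin, value, percentile

    def to_tsv(self) -> str:
        lines = ["gene\tgroup\tbin\tstatistic\tvalue\tpercentile"]
        for r in self.rows:
            lines.append(
                f"{r['gene']}\t{r['group']}\t{r['bin']}\t{self.statistic}\t"
                f"{r['value']:.10g}\t{r['percentile']:.6g}"
            )
        return "\n".join(lines) + "\n"


def rank_table(
    per_gene_pair_values: dict[str, dict],
    bin_assignment: dict,
    statistic: str = "mean",
    groups: dict[str, str] | None = None,
    direction: str = "high_value_low_rank",
) -> RankTable:
    """Build the per-bin rank table from per-gene per-pair values.

    ``per_gene_pair_values[gene][pair]`` are the raw values (distances or
    log-ratios); ``bin_assignment`` maps pairs to bins; ``groups`` maps
    genes to domain groups ranked separately (default: one group).
    """
    groups = groups or {g: "all" for g in per_gene_pair_values}
    table = RankTable(statistic)
    bins = sorted(set(bin_assignment.values()))
    for b in bins:
        pairs_in_bin = {p for p, k in bin_assignment.items() if k == b}
        for group in sorted(set(groups.values())):
            agg: dict[str, float] = {}
            for gene, pair_vals in per_gene_pair_values.items():
                if groups.get(gene) != group:
                    continue
                vals = [v for p, v in pair_vals.items() if p in pairs_in_bin]
                a = aggregate(vals, statistic) if vals else float("nan")
                if np.isfinite(a):
                    agg[gene] = a
            if len(agg) < 2:
                continue
            pct = rank_in_bin(agg, direction=direction)
            for gene in sorted(agg):
                table.rows.append(
                    {
                        "gene": gene,
                        "group": group,
                        "bin": b,
                        "value": agg[gene],
                        "percentile": pct[gene],
                    }
                )
    return table
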