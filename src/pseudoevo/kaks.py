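"""Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction, plus 99-nt
sliding-window scans over codon alignments ("iceberg" tracks).

Conventions
-----------
* Synonymous/nonsynonymous site fractions per codon position count the
  synonymous share among the non-stop single-nucleotide changes, so
  s + n = 3 for every sense codon.
* Codon pairs differing at several positions average the synonymous and
  nonsynonymous difference counts over all minimal mutational pathways,
  with equal weights; pathways passing through a stop codon are excluded
  (if every pathway is blocked, all pathways are used — documented edge
  case, essentially unreachable for real sense codons).
* Jukes–Cantor correction ``d = -(3/4) ln(1 - (4/3) p)``; proportions at
  or beyond 3/4 yield an undefined (NaN) value that aggregation excludes.
* Exact zeros in Ka or Ks are replaced by 1e-15 before taking
  log10(Ka/Ks), so a fully conserved, synonymously diverged pair reports
  a large negative log-ratio instead of a division error.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field

import numpy as np

from ._codon import CODON_TO_AA, STOP_CODONS
from .seqio import AlignedFamily

ZERO_REPLACEMENT = 1e-15
WINDOW_SIZE = 99
WINDOW_STEP = 9

_VALID_BASES = frozenset("ACGT")


@functools.lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) for a sense codon."""
    codon = codon.upper()
    if codon in STOP_CODONS or codon not in CODON_TO_AA:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            non_stop += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s, 3.0 - s


@functools.lru_cache(maxsize=None)
def _pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over minimal pathways."""
    diff_pos = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((current, nxt))
            current = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked]
    if not usable:  # all pathways pass through a stop: fall back to all
        usable = [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in usable:
        for before, after in steps:
            if before in STOP_CODONS or after in STOP_CODONS:
                # stop intermediates contribute as nonsynonymous changes
                nd += 1
            elif CODON_TO_AA[before] == CODON_TO_AA[after]:
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN at or beyond saturation p >= 3/4."""
    if not np.isfinite(p) or p >= 0.75:
        return float("nan")
    if p <= 0:
        return 0.0
    return -0.75 * np.log(1.0 - p / 0.75)


def log_ratio(ka: float, ks: float) -> float:
    """log10(Ka/Ks) with exact zeros replaced by 1e-15; NaN propagates."""
    if not (np.isfinite(ka) and np.isfinite(ks)):
        return float("nan")
    ka = ka if ka != 0 else ZERO_REPLACEMENT
    ks = ks if ks != 0 else ZERO_REPLACEMENT
    return float(np.log10(ka / ks))


@dataclass(frozen=True)
class KaKsPair:
    species_a: str
    species_b: str
    Ka: float
    Ks: float
    log_ratio: float
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    n_codons: int

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.Ka) and np.isfinite(self.Ks))


def _usable_codon(c: str) -> bool:
    return set(c) <= _VALID_BASES and c not in STOP_CODONS


def pairwise_ng86(
    codon_row_a: str,
    codon_row_b: str,
    species_a: str = "A",
    species_b: str = "B",
) -> KaKsPair:
    """NG86 Ka/Ks between two aligned in-frame codon rows.

    Codons where either row has a gap, ambiguity, or stop are excluded
    (pairwise deletion). Returns NaNs when no codons remain or when a
    proportion saturates the Jukes–Cantor correction.
    """
    if len(codon_row_a) != len(codon_row_b):
        raise ValueError("codon rows must have equal length")
    if len(codon_row_a) % 3:
        raise ValueError("codon rows must be in frame (length divisible by 3)")
    a = codon_row_a.upper()
    b = codon_row_b.upper()
    s_total_a = s_total_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    for k in range(0, len(a), 3):
        ca, cb = a[k : k + 3], b[k : k + 3]
        if not (_usable_codon(ca) and _usable_codon(cb)):
            continue
        n_codons += 1
        sa, _ = codon_site_counts(ca)
        sb, _ = codon_site_counts(cb)
        s_total_a += sa
        s_total_b += sb
        d_s, d_n = _pair_differences(ca, cb)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        nan = float("nan")
        return KaKsPair(species_a, species_b, nan, nan, nan, nan, nan, nan, nan, 0)
    S = (s_total_a + s_total_b) / 2.0
    N = 3.0 * n_codons - S
    p_s = sd / S if S > 0 else float("nan")
    p_n = nd / N if N > 0 else float("nan")
    ks = jukes_cantor(p_s)
    ka = jukes_cantor(p_n)
    return KaKsPair(
        species_a, species_b, ka, ks, log_ratio(ka, ks), N, S, nd, sd, n_codons
    )


def family_pairs(family: AlignedFamily) -> list[KaKsPair]:
    """NG86 over all unordered species pairs of a codon alignment."""
    species = family.species
    out = []
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            out.append(
                pairwise_ng86(
                    family.codon_alignment[species[i]],
                    family.codon_alignment[species[j]],
                    species[i],
                    species[j],
                )
            )
    return out


# ---------------------------------------------------------------------------
# sliding windows


def make_windows(alignment_length: int) -> list[tuple[int, int]]:
    """99-nt windows every 9 nt: (1,99), (10,108), ... (1-based inclusive)."""
    if alignment_length < WINDOW_SIZE:
        raise ValueError(f"alignment length {alignment_length} < window size {WINDOW_SIZE}")
    windows = []
    start = 1
    while start + WINDOW_SIZE - 1 <= alignment_length:
        windows.append((start, start + WINDOW_SIZE - 1))
        start += WINDOW_STEP
    return windows


@dataclass
class FeatureSpan:
    label: str
    kind: str  # "domain" | "motif"
    first_window: int | None
    last_window: int | None


@dataclass
class WindowTrack:
    gene_symbol: str
    windows: list[tuple[int, int]]
    medians: list[float]  # NaN where no pair was defined
    n_pairs_defined: list[int]
    annotations: list[FeatureSpan] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["window\tstart\tend\tmedian_log10_ka_ks\tn_pairs_defined"]
        for k, ((s, e), m, n) in enumerate(
            zip(self.windows, self.medians, self.n_pairs_defined), start=1
        ):
            mv = "NA" if not np.isfinite(m) else f"{m:.10g}"
            lines.append(f"{k}\t{s}\t{e}\t{mv}\t{n}")
        return "\n".join(lines) + "\n"


def window_track(family: AlignedFamily) -> WindowTrack:
    """Median log10(Ka/Ks) over all species pairs per 99-nt window.

    Window starts are 1 + 9k, always codon-aligned (33 codons per window)
    on the codon alignment.
    """
    L = 3 * family.n_columns
    windows = make_windows(L)
    species = family.species
    rows = [family.codon_alignment[sp] for sp in species]
    medians: list[float] = []
    counts: list[int] = []
    for start, end in windows:
        ratios = []
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                pair = pairwise_ng86(
                    rows[i][start - 1 : end], rows[j][start - 1 : end],
                    species[i], species[j],
                )
                if pair.defined:
                    ratios.append(pair.log_ratio)
        counts.append(len(ratios))
        medians.append(float(np.median(ratios)) if ratios else float("nan"))
    return WindowTrack(family.gene_symbol, windows, medians, counts)


def map_feature_to_windows(
    feature_span_nt: tuple[int, int],
    kind: str,
    windows: list[tuple[int, int]],
) -> tuple[int, int] | None:
    """Map a nucleotide feature span to a 1-based window-index span.

    Domain rule: first window starting at the feature start (fallback:
    first window wholly inside the feature) through the last window
    ending at the feature end (fallback: last window wholly inside).
    Motif rule: first window whose end covers the whole motif through the
    last window that still contains the whole motif from its start.
    Returns None (empty span) when no window satisfies the rule.
    """
    fs, fe = feature_span_nt
    if fs < 1 or fe < fs:
        raise ValueError(f"bad feature span {feature_span_nt}")
    if kind == "domain":
        first = next((k for k, (s, e) in enumerate(windows, 1) if s == fs), None)
        if first is None:
            first = next(
                (k for k, (s, e) in enumerate(windows, 1) if s >= fs and e <= fe), None
            )
        last = next((k for k, (s, e) in reversed(list(enumerate(windows, 1))) if e == fe), None)
        if last is None:
            last = next(
                (k for k, (s, e) in reversed(list(enumerate(windows, 1))) if s >= fs and e <= fe),
                None,
            )
    elif kind == "motif":
        first = next((k for k, (s, e) in enumerate(windows, 1) if e >= fe), None)
        last = next((k for k, (s, e) in reversed(list(enumerate(windows, 1))) if s <= fs), None)
    else:
        raise ValueError(f"kind must be 'domain' or 'motif', got {kind!r}")
    if first is None or last is None or first > last:
        return None
    return (first, last)
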