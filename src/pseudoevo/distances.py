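"""Pairwise protein distances under six classical models.

Models: number of differences, p-distance, Poisson, equal input, and the
Dayhoff and JTT empirical-matrix distances. Sites where either sequence
has a gap or ambiguity code are excluded pair by pair (pairwise
deletion). Saturated pairs — where the observed proportion of differences
is beyond what a model can invert — yield an *undefined* marker (NaN),
which downstream aggregation excludes rather than treating as zero.

The empirical-matrix distances are defined through the expected identity
of a reversible Markov replacement process: with rate matrix Q (scaled to
one expected replacement per site per unit time) and stationary
frequencies pi, the expected fraction of identical sites after distance d
is ``I(d) = sum_a pi_a [exp(Qd)]_aa``; the distance reported for an
observed difference proportion p solves ``I(d) = 1 - p`` (monotone 1-D
root find, d <= 20).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import brentq

from .seqio import AlignedFamily

MODELS = (
    "num_differences",
    "p_distance",
    "Poisson",
    "equal_input",
    "Dayhoff",
    "JTT",
)

_PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_SET = frozenset("ACDEFGHIKLMNPQRSTVWY")
_MAX_EMPIRICAL_DISTANCE = 20.0


@dataclass
class DistanceMatrix:
    gene_symbol: str
    model: str
    species: list[str]
    D: np.ndarray  # symmetric, NaN marks undefined entries

    def value(self, a: str, b: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        return float(self.D[i, j])

    def to_tsv(self) -> str:
        lines = ["\t".join(["species"] + self.species)]
        for i, sp in enumerate(self.species):
            cells = [
                "?" if np.isnan(v) else f"{v:.10g}" for v in self.D[i]
            ]
            lines.append("\t".join([sp] + cells))
        return "\n".join(lines) + "\n"


def pairwise_sites(seq_a: str, seq_b: str) -> tuple[int, int]:
    """Count valid (ungapped, unambiguous in both) sites and mismatches."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned rows must have equal length")
    n_valid = 0
    n_diff = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in _AA_SET or y not in _AA_SET:
            continue
        n_valid += 1
        if x != y:
            n_diff += 1
    return n_valid, n_diff


def _pair_frequencies(seq_a: str, seq_b: str) -> np.ndarray:
    """Residue frequencies over both sequences' valid sites (equal-input pi)."""
    counts = np.zeros(20)
    index = {aa: k for k, aa in enumerate(sorted(_AA_SET))}
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x in _AA_SET and y in _AA_SET:
            counts[index[x]] += 1
            counts[index[y]] += 1
    total = counts.sum()
    if total == 0:
        return np.full(20, 0.05)
    return counts / total


def _load_paml_dat(name: str) -> tuple[np.ndarray, np.ndarray]:
    text = (resources.files("pseudoevo.data") / f"{name}.dat").read_text()
    rows = [
        [float(x) for x in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    freqs = np.array(rows[-1])
    S = np.zeros((20, 20))
    for i, row in enumerate(rows[:-1], start=1):
        S[i, : len(row)] = row
        S[: len(row), i] = row
    return S, freqs


@functools.lru_cache(maxsize=None)
def _empirical_model(name: str):
    """Eigendecomposed, rate-1-normalized replacement process for Dayhoff/JTT."""
    S, pi = _load_paml_dat(name.lower())
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    Q /= scale
    # symmetrize for a stable eigendecomposition: B = diag(sqrt pi) Q diag(1/sqrt pi)
    sq = np.sqrt(pi)
    B = (sq[:, None] * Q) / sq[None, :]
    B = (B + B.T) / 2
    evals, U = np.linalg.eigh(B)
    return pi, evals, U


def expected_identity(model: str, d: float) -> float:
    """E[fraction of identical sites] after distance d under Dayhoff/JTT."""
    pi, evals, U = _empirical_model(model)
    # P(d) = diag(1/sqrt pi) U exp(lam d) U^T diag(sqrt pi); the sqrt-pi
    # factors cancel on the diagonal, so P_aa = sum_k U_ak^2 exp(lam_k d)
    p_aa = (U**2 * np.exp(evals * d)).sum(axis=1)
    return float((pi * p_aa).sum())


def _empirical_distance(model: str, p: float) -> float:
    target = 1.0 - p
    floor = expected_identity(model, _MAX_EMPIRICAL_DISTANCE)
    if target <= floor:
        return np.nan
    if p <= 0:
        return 0.0
    return brentq(
        lambda d: expected_identity(model, d) - target,
        0.0,
        _MAX_EMPIRICAL_DISTANCE,
        xtol=1e-12,
        rtol=8.9e-16,
    )


def distance(
    seq_a: str,
    seq_b: str,
    model: str,
    equal_input_freqs: np.ndarray | None = None,
) -> float:
    """Distance between two aligned rows; NaN if undefined (saturated / no sites).

    ``equal_input_freqs`` optionally supplies alignment-wide residue
    frequencies for the equal-input model; the default estimates pi from
    the pair's own valid sites.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    n_valid, n_diff = pairwise_sites(seq_a, seq_b)
    if n_valid == 0:
        return np.nan
    p = n_diff / n_valid
    if model == "num_differences":
        return float(n_diff)
    if model == "p_distance":
        return p
    if model == "Poisson":
        if p >= 1.0:
            return np.nan
        return -np.log(1.0 - p)
    if model == "equal_input":
        pi = (
            np.asarray(equal_input_freqs, dtype=float)
            if equal_input_freqs is not None
            else _pair_frequencies(seq_a, seq_b)
        )
        b = 1.0 - float((pi**2).sum())
        if p >= b:
            return np.nan
        return -b * np.log(1.0 - p / b)
    return _empirical_distance(model, p)


def matrix(
    family: AlignedFamily | dict[str, str],
    model: str,
    gene_symbol: str | None = None,
    equal_input_scope: str = "pair",
) -> DistanceMatrix:
    """All-pairs distance matrix for one aligned family under one model.

    ``equal_input_scope``: "pair" estimates equal-input frequencies from
    each pair's valid sites; "alignment" uses the whole alignment once.
    """
    if isinstance(family, AlignedFamily):
        msa = family.protein_msa
        gene_symbol = gene_symbol or family.gene_symbol
    else:
        msa = family
        gene_symbol = gene_symbol or ""
    species = list(msa)
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    freqs = None
    if model == "equal_input" and equal_input_scope == "alignment":
        counts = np.zeros(20)
        index = {aa: k for k, aa in enumerate(sorted(_AA_SET))}
        for row in msa.values():
            for ch in row.upper():
                if ch in _AA_SET:
                    counts[index[ch]] += 1
        freqs = counts / counts.sum()
    n = len(species)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = distance(msa[species[i]], msa[species[j]], model, equal_input_freqs=freqs)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(gene_symbol, model, species, D)
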