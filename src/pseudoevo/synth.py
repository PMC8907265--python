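"""Synthetic data with known ground truth for every downstream stage.

Three generators:

* :func:`simulate_species_tree` — seeded Yule (pure-birth) species trees,
  rescaled to a chosen root-to-tip height, so divergence is controllable
  in expected substitutions per site.
* :func:`evolve_family` — codon evolution of an ortholog family along a
  tree under an HKY-like mutation scheme with region-specific omega
  (dN/dS) acceptance. This is a simulator, not an inference model: it
  exists to plant known selection regimes (purifying domains, neutral
  linkers, positively selected spikes) that the distance and Ka/Ks
  stages must recover.
* :func:`generate_sector_msa` — protein MSAs containing planted groups
  of co-evolving positions ("sectors") driven by hidden per-sequence
  modes, on a background of independent positions, for validating the
  coupling-analysis stage.

All generators take explicit seeds and never touch global random state.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from ._codon import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, TRANSITION, translate_cds
from .seqio import OrthologFamily, SequenceRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SpeciesTreeSpec:
    n_species: int
    birth_rate: float = 1.0
    seed: int = 0
    height_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.birth_rate <= 0 or self.height_scale <= 0:
            raise ValueError("birth_rate and height_scale must be positive")


@dataclass(frozen=True)
class SelectionProfile:
    """Region-wise omega (dN/dS) profile over a gene of codons.

    ``regions`` holds (start_codon, end_codon, omega) with 1-based
    inclusive codon coordinates; codons outside every region evolve at
    ``default_omega``. ``kappa`` is the transition/transversion rate ratio
    of the underlying mutation process.
    """

    regions: tuple[tuple[int, int, float], ...] = ()
    default_omega: float | None = 0.2
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if not self.regions and self.default_omega is None:
            raise ValueError("need regions or a default_omega")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        prev_end = 0
        for start, end, omega in sorted(self.regions):
            if start < 1 or end < start:
                raise ValueError(f"bad region ({start}, {end})")
            if start <= prev_end:
                raise ValueError("regions overlap")
            if omega < 0:
                raise ValueError("omega must be nonnegative")
            prev_end = end

    def omega_per_codon(self, n_codons: int) -> np.ndarray:
        if self.default_omega is None and self.regions:
            lo = min(r[0] for r in self.regions)
            hi = max(r[1] for r in self.regions)
            if lo != 1 or hi < n_codons:
                raise ValueError("regions do not cover the gene and no default_omega given")
        base = self.default_omega if self.default_omega is not None else 0.0
        omega = np.full(n_codons, float(base))
        for start, end, w in self.regions:
            if end > n_codons:
                raise ValueError(f"region ({start}, {end}) exceeds gene length {n_codons}")
            omega[start - 1 : end] = w
        return omega


@dataclass(frozen=True)
class PlantedSectorSpec:
    n_seq: int
    n_pos: int
    sectors: tuple[tuple[frozenset[int], int, float], ...] = ()
    background_freqs: tuple[float, ...] | None = None
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seq < 1 or self.n_pos < 1:
            raise ValueError("n_seq and n_pos must be positive")
        if not 0 <= self.gap_rate < 0.5:
            raise ValueError("gap_rate must be in [0, 0.5)")
        seen: set[int] = set()
        for positions, n_modes, fidelity in self.sectors:
            if not positions:
                raise ValueError("empty sector position set")
            if min(positions) < 1 or max(positions) > self.n_pos:
                raise ValueError("sector positions out of range")
            if seen & set(positions):
                raise ValueError("sector position sets must be disjoint")
            seen |= set(positions)
            if n_modes < 2:
                raise ValueError("each sector needs at least 2 modes")
            if not 0.5 < fidelity <= 1:
                raise ValueError("fidelity must be in (0.5, 1]; sectors are unrecoverable below")
        if self.background_freqs is not None:
            bf = np.asarray(self.background_freqs, dtype=float)
            if bf.shape != (20,) or not np.isclose(bf.sum(), 1.0) or (bf < 0).any():
                raise ValueError("background_freqs must be a 20-vector summing to 1")


def simulate_species_tree(spec: SpeciesTreeSpec) -> dendropy.Tree:
    """Seeded Yule tree with ``n_species`` leaves, root-to-tip height ``height_scale``."""
    rng = random.Random(spec.seed)
    tree = treesim.birth_death_tree(
        birth_rate=spec.birth_rate,
        death_rate=0.0,
        num_extant_tips=spec.n_species,
        rng=rng,
    )
    # stable, readable leaf names
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:03d}"
    # the simulation stops at the n-th speciation, leaving a zero-length
    # cherry; run the clock to the next (uncounted) event so every tip
    # edge gains the same extra time and the tree stays ultrametric
    extra = rng.expovariate(spec.n_species * spec.birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if height <= 0:
        raise RuntimeError("degenerate tree height")
    factor = spec.height_scale / height
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def _mutation_targets(kappa: float) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Per current base: candidate target bases and their proposal probabilities."""
    out = {}
    for base in "ACGT":
        targets = tuple(b for b in "ACGT" if b != base)
        weights = np.array(
            [kappa if TRANSITION[base] == t else 1.0 for t in targets], dtype=float
        )
        out[base] = (targets, weights / weights.sum())
    return out


def _random_root_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    codons = ["ATG"]
    sense = [c for c in SENSE_CODONS]
    idx = rng.integers(0, len(sense), size=n_codons - 1)
    codons.extend(sense[i] for i in idx)
    return codons


def _evolve_branch(
    codons: list[str],
    t: float,
    omega: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
    targets: dict[str, tuple[tuple[str, ...], np.ndarray]],
) -> list[str]:
    """Gillespie-style thinned simulation of one branch.

    Candidate mutation events arrive at the envelope rate ``3 * n_codons *
    max(1, max omega)`` per unit branch length (branch lengths are expected
    neutral substitutions per nucleotide site). Synonymous proposals are
    accepted with probability 1/M, nonsynonymous ones with omega/M, which
    realizes acceptance probability omega for omega <= 1 and an inflated
    nonsynonymous rate for omega > 1. Proposals creating stop codons, and
    any proposal at the frozen start codon, are rejected.
    """
    n_codons = len(codons)
    m_env = max(1.0, float(omega.max()))
    n_events = rng.poisson(t * 3 * n_codons * m_env)
    if n_events == 0:
        return list(codons)
    codons = list(codons)
    sites = rng.integers(0, 3 * n_codons, size=n_events)
    u_target = rng.random(n_events)
    u_accept = rng.random(n_events)
    for k in range(n_events):
        site = int(sites[k])
        ci, pos = divmod(site, 3)
        if ci == 0:  # keep start Met/ATG invariant by construction
            continue
        codon = codons[ci]
        base = codon[pos]
        tg, probs = targets[base]
        new_base = tg[int(np.searchsorted(np.cumsum(probs), u_target[k]))]
        new_codon = codon[:pos] + new_base + codon[pos + 1 :]
        if new_codon in STOP_CODONS:
            continue
        if CODON_TO_AA[new_codon] == CODON_TO_AA[codon]:
            accept_p = 1.0 / m_env
        else:
            accept_p = omega[ci] / m_env
        if u_accept[k] < accept_p:
            codons[ci] = new_codon
    return codons


def evolve_family(
    tree: dendropy.Tree,
    n_codons: int,
    profile: SelectionProfile,
    seed: int,
    gene_symbol: str = "gene",
    rate_multiplier: float = 1.0,
) -> OrthologFamily:
    """Evolve a codon ortholog family along ``tree`` under ``profile``.

    ``rate_multiplier`` scales every branch length, giving gene-specific
    divergence rates over a shared species tree. Leaf outputs satisfy the
    start-Met / start-ATG curation filters by construction.
    """
    if n_codons < 40:
        raise ValueError("n_codons must be >= 40")
    omega = profile.omega_per_codon(n_codons)
    rng = np.random.default_rng(seed)
    targets = _mutation_targets(profile.kappa)
    root_codons = _random_root_cds(n_codons, rng)

    seqs: dict[int, list[str]] = {id(tree.seed_node): root_codons}
    records: list[SequenceRecord] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_codons = seqs[id(node.parent_node)]
        t = (node.edge.length or 0.0) * rate_multiplier
        child = _evolve_branch(parent_codons, t, omega, profile.kappa, rng, targets)
        seqs[id(node)] = child
        if node.is_leaf():
            cds = "".join(child)
            records.append(
                SequenceRecord(
                    species=node.taxon.label,
                    gene_symbol=gene_symbol,
                    protein_seq=translate_cds(cds),
                    cds_seq=cds,
                )
            )
    records.sort(key=lambda r: r.species)
    return OrthologFamily(gene_symbol, records)


@dataclass
class SectorMSA:
    """A generated MSA plus the ground truth used to score recovery."""

    ids: list[str]
    seqs: list[str]
    sector_of_position: dict[int, int]  # 1-based position -> sector index (1-based)
    modes: np.ndarray = field(repr=False)  # (n_seq, n_sectors) latent mode draws

    @property
    def msa(self) -> dict[str, str]:
        return dict(zip(self.ids, self.seqs))

    def truth_positions(self, sector: int) -> frozenset[int]:
        return frozenset(p for p, s in self.sector_of_position.items() if s == sector)


def generate_sector_msa(spec: PlantedSectorSpec) -> SectorMSA:
    """Sample an MSA with planted co-evolving position groups.

    Each sequence draws one latent mode per sector; a sector position
    shows its mode's preferred residue with probability ``fidelity`` and a
    background residue otherwise. Non-sector positions are i.i.d.
    background draws; gaps are inserted i.i.d. at ``gap_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    bf = (
        np.asarray(spec.background_freqs, dtype=float)
        if spec.background_freqs is not None
        else np.full(20, 0.05)
    )
    bf = bf / bf.sum()
    n, L = spec.n_seq, spec.n_pos

    # background for every cell, overwritten at sector positions below
    mat = rng.choice(20, size=(n, L), p=bf)
    modes = np.zeros((n, len(spec.sectors)), dtype=int)
    sector_of_position: dict[int, int] = {}
    for s_idx, (positions, n_modes, fidelity) in enumerate(spec.sectors):
        pos_sorted = sorted(positions)
        for p in pos_sorted:
            sector_of_position[p] = s_idx + 1
        # each mode prefers one residue per position, distinct across modes
        prefer = np.empty((n_modes, len(pos_sorted)), dtype=int)
        for j in range(len(pos_sorted)):
            prefer[:, j] = rng.permutation(20)[:n_modes]
        draw = rng.integers(0, n_modes, size=n)
        modes[:, s_idx] = draw
        faithful = rng.random((n, len(pos_sorted))) < fidelity
        cols = np.array([p - 1 for p in pos_sorted])
        planted = prefer[draw][:, :]  # (n, n_sector_pos)
        current = mat[:, cols]
        mat[:, cols] = np.where(faithful, planted, current)

    letters = np.array(list(AA_ALPHABET))
    rows = letters[mat]
    if spec.gap_rate > 0:
        gaps = rng.random((n, L)) < spec.gap_rate
        rows = np.where(gaps, "-", rows)
    seqs = ["".join(r) for r in rows]
    ids = [f"seq{i + 1:04d}" for i in range(n)]
    return SectorMSA(ids, seqs, sector_of_position, modes)
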