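"""Statistical coupling analysis (SCA) of protein multiple sequence alignments.

Pipeline: gap-based preprocessing; positional amino-acid frequencies
f_ia against a background q_a; Kullback–Leibler positional conservation
D_ia; a conservation-weighted covariance ("coupling") matrix

    Ctilde_ij = || phi_i^a phi_j^b (f_ij^ab - f_i^a f_j^b) ||_F

with phi_i^a = ln[f(1-q) / ((1-f)q)] (the derivative of D_ia in f);
spectral decomposition of Ctilde; a randomization-calibrated count of
significant eigenmodes (cutoff = mean second randomized eigenvalue
+ 2 sd over seeded column-shuffle trials); and independent component
analysis rotating the significant eigenvectors into maximally
independent components.

The class :class:`SCA` wraps the pipeline as a scikit-learn style
estimator; the module functions expose every stage individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.base import BaseEstimator

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: k for k, aa in enumerate(ALPHABET)}


def background_frequencies() -> np.ndarray:
    """Database-derived background amino-acid frequencies (ALPHABET order)."""
    text = (resources.files("pseudoevo.data") / "aa_background.txt").read_text()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    q = np.array([float(x) for x in rows[0].split()])
    return q / q.sum()


def uniform_background() -> np.ndarray:
    return np.full(20, 0.05)


@dataclass
class PreprocessedMSA:
    ids: list[str]
    codes: np.ndarray  # (n_seq, L) int8, -1 for gap/ambiguity
    ats: list[int | None]  # retained column -> reference residue index (1-based)
    removed_sequences: list[str] = field(default_factory=list)
    removed_positions: list[int] = field(default_factory=list)  # original 1-based columns

    @property
    def n_seq(self) -> int:
        return self.codes.shape[0]

    @property
    def n_pos(self) -> int:
        return self.codes.shape[1]


def _encode(seqs: list[str]) -> np.ndarray:
    n, L = len(seqs), len(seqs[0])
    codes = np.full((n, L), -1, dtype=np.int8)
    for i, s in enumerate(seqs):
        for j, ch in enumerate(s.upper()):
            codes[i, j] = _AA_INDEX.get(ch, -1)
    return codes


def preprocess(
    msa: dict[str, str],
    position_gap_cutoff: float = 0.4,
    sequence_gap_cutoff: float = 0.2,
    reference_id: str | None = None,
    structure_seq: str | None = None,
) -> PreprocessedMSA:
    """Gap-filter an MSA and build the reference (ATS) column mapping.

    Steps, in order: (1) drop sequences whose gap fraction exceeds
    ``sequence_gap_cutoff``; (2) truncate positions where more than
    ``position_gap_cutoff`` of the remaining sequences have a gap;
    (3) drop sequences whose gap fraction over the retained positions
    exceeds ``sequence_gap_cutoff``; (4) map retained columns to residue
    indices of the reference sequence (first sequence by default),
    optionally re-indexed through an ungapped structure sequence.
    """
    ids = list(msa)
    if not ids:
        raise ValueError("empty MSA")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("MSA rows have unequal lengths")
    seqs = [msa[i] for i in ids]
    codes = _encode(seqs)
    gap = codes < 0

    removed_sequences: list[str] = []
    keep_seq = gap.mean(axis=1) <= sequence_gap_cutoff
    removed_sequences += [ids[i] for i in np.flatnonzero(~keep_seq)]
    codes = codes[keep_seq]
    ids = [i for i, k in zip(ids, keep_seq) if k]

    if codes.shape[0] == 0:
        raise ValueError("preprocessing removed every sequence or position")
    gap = codes < 0
    keep_pos = gap.mean(axis=0) <= position_gap_cutoff
    removed_positions = [int(j) + 1 for j in np.flatnonzero(~keep_pos)]
    codes = codes[:, keep_pos]
    if codes.shape[1] == 0:
        raise ValueError("preprocessing removed every sequence or position")

    gap = codes < 0
    keep_seq2 = gap.mean(axis=1) <= sequence_gap_cutoff
    removed_sequences += [ids[i] for i in np.flatnonzero(~keep_seq2)]
    codes = codes[keep_seq2]
    ids = [i for i, k in zip(ids, keep_seq2) if k]

    if codes.size == 0 or codes.shape[0] == 0 or codes.shape[1] == 0:
        raise ValueError("preprocessing removed every sequence or position")

    ref = reference_id if reference_id in ids else (ids[0] if ids else None)
    retained_cols = np.flatnonzero(keep_pos)
    ref_row_full = _encode([msa[ref]])[0]
    # residue index within the ungapped reference sequence, per original column
    ref_index = np.where(ref_row_full >= 0, np.cumsum(ref_row_full >= 0), 0)
    ats: list[int | None] = []
    ref_ungapped = "".join(ch for ch in msa[ref].upper() if ch in _AA_INDEX)
    struct_map: dict[int, int] | None = None
    if structure_seq is not None:
        struct_map = _map_to_structure(ref_ungapped, structure_seq)
    for col in retained_cols:
        if ref_row_full[col] < 0:
            ats.append(None)
            continue
        idx = int(ref_index[col])
        if struct_map is not None:
            ats.append(struct_map.get(idx))
        else:
            ats.append(idx)
    return PreprocessedMSA(ids, codes, ats, removed_sequences, removed_positions)


def _map_to_structure(ref_seq: str, structure_seq: str) -> dict[int, int]:
    """Globally align the reference to a structure sequence; 1-based maps."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-1,
        open_gap_score=-5, extend_gap_score=-0.5,
    )
    aln = aligner.align(ref_seq, structure_seq.upper())[0]
    mapping: dict[int, int] = {}
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            mapping[a_start + off + 1] = b_start + off + 1
    return mapping


# ---------------------------------------------------------------------------
# statistics


def frequencies(pre: PreprocessedMSA) -> np.ndarray:
    """Observed per-position amino-acid frequencies f_ia (L, 20).

    Gapped entries contribute to no amino-acid count; the denominator is
    the number of sequences, so a column's frequencies sum to its
    non-gap fraction.
    """
    n, L = pre.codes.shape
    f = np.zeros((L, 20))
    for a in range(20):
        f[:, a] = (pre.codes == a).sum(axis=0)
    return f / n


def conservation(f_ia: np.ndarray, q_a: np.ndarray) -> np.ndarray:
    """Kullback–Leibler positional conservation D_ia.

    D = f ln(f/q) + (1-f) ln((1-f)/(1-q)), with 0 ln 0 = 0 at f in {0, 1}.
    """
    q = np.asarray(q_a, dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("background frequencies must lie strictly in (0, 1)")
    f = np.asarray(f_ia, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(f > 0, f * np.log(f / q), 0.0)
        t2 = np.where(f < 1, (1 - f) * np.log((1 - f) / (1 - q)), 0.0)
    return t1 + t2


def conservation_weights(
    f_ia: np.ndarray, q_a: np.ndarray, n_seq: int
) -> np.ndarray:
    """phi_ia = ln[f(1-q) / ((1-f)q)], the f-derivative of D_ia.

    Boundary frequencies are pulled in by a pseudocount of 1/(2 n_seq)
    before taking the logarithm, so fully conserved or absent residues
    get a large finite weight instead of an infinity.
    """
    eps = 1.0 / (2.0 * n_seq)
    f = np.clip(np.asarray(f_ia, dtype=float), eps, 1.0 - eps)
    q = np.asarray(q_a, dtype=float)
    return np.log(f * (1 - q) / ((1 - f) * q))


def coupling_matrix(
    pre: PreprocessedMSA, q_a: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """Conservation-weighted coupling matrix Ctilde (L, L) plus intermediates.

    Ctilde_ij is the Frobenius norm over the 20x20 amino-acid block of
    phi_i^a phi_j^b (f_ij^ab - f_i^a f_j^b). Computed as the Gram matrix
    of the phi-weighted, frequency-centered one-hot encoding.
    """
    q = background_frequencies() if q_a is None else np.asarray(q_a, dtype=float)
    n, L = pre.codes.shape
    f = frequencies(pre)
    phi = conservation_weights(f, q, n)
    onehot = np.zeros((n, L, 20), dtype=np.float32)
    valid = pre.codes >= 0
    idx_n, idx_l = np.nonzero(valid)
    onehot[idx_n, idx_l, pre.codes[valid]] = 1.0
    Y = (onehot - f.astype(np.float32)) * phi.astype(np.float32)
    Yf = Y.reshape(n, L * 20)
    M = (Yf.T @ Yf) / np.float32(n)
    blocks = M.reshape(L, 20, L, 20)
    Ctilde = np.sqrt(
        np.einsum("iajb,iajb->ij", blocks, blocks, dtype=np.float64)
    )
    return Ctilde, {"f_ia": f, "phi_ia": phi, "D_ia": conservation(f, q), "q_a": q}


def spectral(Ctilde: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigendecomposition with deterministic sign orientation."""
    C = np.asarray(Ctilde, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("coupling matrix must be symmetric")
    evals, evecs = np.linalg.eigh((C + C.T) / 2)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    return evals, _orient_signs(evecs)


def _orient_signs(vectors: np.ndarray) -> np.ndarray:
    out = vectors.copy()
    for k in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, k])))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


def significant_modes(
    pre: PreprocessedMSA,
    q_a: np.ndarray | None = None,
    n_trials: int = 10,
    seed: int = 0,
    eigenvalues: np.ndarray | None = None,
) -> tuple[int, float, float]:
    """Randomization-calibrated count of significant eigenmodes.

    Each trial independently permutes every column's residues across
    sequences (destroying inter-column correlation while preserving
    every f_ia exactly), recomputes the coupling spectrum, and records
    its second eigenvalue. The cutoff is mean + 2 sd of those second
    eigenvalues; k_star counts true eigenvalues above it.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 randomization trials to estimate a sd")
    if eigenvalues is None:
        Ctilde, _ = coupling_matrix(pre, q_a)
        eigenvalues, _ = spectral(Ctilde)
    rng = np.random.default_rng(seed)
    n, L = pre.codes.shape
    lam2 = np.empty(n_trials)
    for t in range(n_trials):
        shuffled = pre.codes.copy()
        for j in range(L):
            shuffled[:, j] = shuffled[rng.permutation(n), j]
        pre_rand = PreprocessedMSA(pre.ids, shuffled, pre.ats)
        C_rand, _ = coupling_matrix(pre_rand, q_a)
        ev = np.linalg.eigvalsh((C_rand + C_rand.T) / 2)
        lam2[t] = np.sort(ev)[::-1][1]
    mean2 = float(lam2.mean())
    sd2 = float(lam2.std(ddof=1))
    cutoff = mean2 + 2.0 * sd2
    k_star = int((np.asarray(eigenvalues) > cutoff).sum())
    return k_star, mean2, sd2


def ica(
    top_eigenvectors: np.ndarray,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fixed-point ICA rotating the top eigenvectors into independent components.

    Treats the L loadings of each eigenvector as samples and finds the
    orthogonal unmixing rotation W (symmetric-decorrelation FastICA with
    a tanh contrast, seeded initialization, no centering) so the output
    exactly spans the input subspace. Components are rescaled to unit
    norm and sign-oriented. Returns (V_ica (L, k), W (k, k), converged).
    """
    V = np.asarray(top_eigenvectors, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    L, k = V.shape
    if k == 0:
        raise ValueError("need at least one eigenvector")
    if k == 1:
        return V.copy(), np.eye(1), True
    # scale columns to unit variance over samples for the contrast function
    X = (V * np.sqrt(L)).T  # (k, L), rows ~ unit variance
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((k, k))
    W = _sym_decorrelate(W)
    converged = False
    for _ in range(max_iter):
        WX = W @ X  # (k, L)
        G = np.tanh(WX)
        G_prime = 1.0 - G**2
        W_new = (G @ X.T) / L - np.diag(G_prime.mean(axis=1)) @ W
        W_new = _sym_decorrelate(W_new)
        delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0))
        W = W_new
        if delta < tol:
            converged = True
            break
    S = (W @ V.T).T  # (L, k): pure rotation of the eigenvectors
    S /= np.linalg.norm(S, axis=0, keepdims=True)
    S = _orient_signs(S)
    return S, W, converged


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(W @ W.T)
    return evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 1e-300))) @ evecs.T @ W


# ---------------------------------------------------------------------------
# estimator


class SCA(BaseEstimator):
    """Statistical coupling analysis as a fit-once estimator.

    Parameters mirror the stage functions; after :meth:`fit` the fitted
    state lives in trailing-underscore attributes (``Ctilde_``,
    ``eigenvalues_``, ``k_star_``, ``V_ica_``, ...).
    """

    def __init__(
        self,
        position_gap_cutoff: float = 0.4,
        sequence_gap_cutoff: float = 0.2,
        background: str = "database",
        n_trials: int = 10,
        seed: int = 0,
        min_modes: int = 1,
    ):
        self.position_gap_cutoff = position_gap_cutoff
        self.sequence_gap_cutoff = sequence_gap_cutoff
        self.background = background
        self.n_trials = n_trials
        self.seed = seed
        self.min_modes = min_modes

    def fit(self, msa: dict[str, str], structure_seq: str | None = None) -> "SCA":
        if self.background == "database":
            q = background_frequencies()
        elif self.background == "uniform":
            q = uniform_background()
        else:
            raise ValueError("background must be 'database' or 'uniform'")
        pre = preprocess(
            msa,
            position_gap_cutoff=self.position_gap_cutoff,
            sequence_gap_cutoff=self.sequence_gap_cutoff,
            structure_seq=structure_seq,
        )
        Ctilde, inter = coupling_matrix(pre, q)
        evals, evecs = spectral(Ctilde)
        k_star, lam2_mean, lam2_sd = significant_modes(
            pre, q, n_trials=self.n_trials, seed=self.seed, eigenvalues=evals
        )
        k_eff = max(k_star, self.min_modes)
        V_ica, W, converged = ica(evecs[:, :k_eff], seed=self.seed)
        self.preprocessed_ = pre
        self.q_a_ = q
        self.f_ia_ = inter["f_ia"]
        self.D_ia_ = inter["D_ia"]
        self.phi_ia_ = inter["phi_ia"]
        self.Ctilde_ = Ctilde
        self.eigenvalues_ = evals
        self.eigenvectors_ = evecs
        self.k_star_ = k_star
        self.lambda2_rand_mean_ = lam2_mean
        self.lambda2_rand_sd_ = lam2_sd
        self.V_ica_ = V_ica
        self.W_ = W
        self.ica_converged_ = converged
        return self
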