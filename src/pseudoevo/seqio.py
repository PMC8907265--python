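"""Sequence I/O, dataset curation, and protein-guided codon alignments.

Curation mirrors the standard ortholog-panel hygiene rules: proteins must
start with methionine, coding sequences must start with ATG, and when one
species contributes several isoforms only the longest protein is kept.
Codon alignments are built by back-translating a protein alignment, which
guarantees that codon column triples correspond exactly to protein columns.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codon import GAP_CHARS, translate_cds

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class SequenceRecord:
    """One species' entry for one gene: protein and (optionally) its CDS."""

    species: str
    gene_symbol: str
    protein_seq: str
    cds_seq: str | None = None
    source_rank: int = 0

    def __post_init__(self) -> None:
        bad = set(self.protein_seq.upper()) - PROTEIN_ALPHABET - GAP_CHARS
        if bad:
            raise ValueError(f"invalid protein characters {sorted(bad)} for {self.species}")
        if self.cds_seq is not None:
            bad = set(self.cds_seq.upper()) - NUCLEOTIDE_ALPHABET - GAP_CHARS
            if bad:
                raise ValueError(f"invalid CDS characters {sorted(bad)} for {self.species}")
            n_aa = len(self.protein_seq)
            if len(self.cds_seq) not in (3 * n_aa, 3 * n_aa + 3):
                raise ValueError(
                    f"CDS length {len(self.cds_seq)} inconsistent with protein length "
                    f"{n_aa} for {self.species} (expect 3n or 3n+3)"
                )


@dataclass
class OrthologFamily:
    """All per-species records for one gene symbol."""

    gene_symbol: str
    records: list[SequenceRecord] = field(default_factory=list)
    domain_set: frozenset[str] = frozenset()

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def record_for(self, species: str) -> SequenceRecord:
        for r in self.records:
            if r.species == species:
                return r
        raise KeyError(species)


@dataclass
class AlignedFamily:
    """Protein MSA with its column-mapped in-frame codon alignment.

    ``column_map[col][species]`` is the 0-based ungapped residue index that
    alignment column ``col`` (0-based here; the file formats are 1-based)
    holds for that species, or ``None`` at a gap.
    """

    gene_symbol: str
    species: list[str]
    protein_msa: dict[str, str]
    codon_alignment: dict[str, str]
    column_map: list[dict[str, int | None]]

    @property
    def n_columns(self) -> int:
        return len(self.column_map)


@dataclass(frozen=True)
class Rejection:
    species: str
    rule: str
    detail: str = ""


def curate_family(family: OrthologFamily) -> tuple[OrthologFamily, list[Rejection]]:
    """Apply the start-Met / start-ATG / longest-isoform filters.

    Returns the curated family and a log listing every removal with the
    rule that triggered it. Idempotent. An empty result is returned as-is
    (callers may warn), never raised.
    """
    log: list[Rejection] = []
    kept: list[SequenceRecord] = []
    for rec in family.records:
        if not rec.protein_seq.startswith("M"):
            log.append(Rejection(rec.species, "no initial Met", rec.protein_seq[:10]))
            continue
        if rec.cds_seq is not None and not rec.cds_seq.upper().startswith("ATG"):
            log.append(Rejection(rec.species, "CDS does not start with ATG", rec.cds_seq[:10]))
            continue
        kept.append(rec)

    # per-species longest protein; ties -> lowest source_rank, then stable order
    by_species: dict[str, list[SequenceRecord]] = {}
    for rec in kept:
        by_species.setdefault(rec.species, []).append(rec)
    final: list[SequenceRecord] = []
    for sp in dict.fromkeys(r.species for r in kept):  # preserve first-seen order
        group = by_species[sp]
        best = min(group, key=lambda r: (-len(r.protein_seq), r.source_rank))
        for r in group:
            if r is not best:
                log.append(Rejection(sp, "shorter duplicate", f"len={len(r.protein_seq)}"))
        final.append(best)
    return OrthologFamily(family.gene_symbol, final, family.domain_set), log


def intersect_species(
    families: Iterable[OrthologFamily], reference_species: set[str]
) -> list[OrthologFamily]:
    """Restrict every family to records whose species is in the reference set."""
    if not reference_species:
        raise ValueError("reference species set must be nonempty")
    out = []
    for fam in families:
        recs = [r for r in fam.records if r.species in reference_species]
        out.append(OrthologFamily(fam.gene_symbol, recs, fam.domain_set))
    return out


def back_translate_alignment(
    protein_msa: dict[str, str], family: OrthologFamily
) -> AlignedFamily:
    """Build the in-frame codon alignment implied by a protein alignment.

    Every aligned row, gaps removed, must equal the family's protein for
    that species, and the CDS must translate to it (a terminal stop codon
    is tolerated and dropped).
    """
    species = list(protein_msa)
    lengths = {len(v) for v in protein_msa.values()}
    if len(lengths) != 1:
        raise ValueError("protein MSA rows have unequal lengths")
    n_col = lengths.pop()

    codon_rows: dict[str, str] = {}
    column_map: list[dict[str, int | None]] = [dict() for _ in range(n_col)]
    for sp in species:
        rec = family.record_for(sp)
        row = protein_msa[sp].upper()
        degapped = "".join(c for c in row if c not in GAP_CHARS)
        if degapped != rec.protein_seq.upper():
            raise ValueError(f"aligned protein for {sp} does not match family record")
        if rec.cds_seq is None:
            raise ValueError(f"no CDS for {sp}")
        cds = rec.cds_seq.upper()
        translated = translate_cds(cds)
        if translated != rec.protein_seq.upper():
            # name the first offending codon for the error message
            for k in range(min(len(translated), len(rec.protein_seq))):
                if translated[k] != rec.protein_seq[k].upper():
                    raise ValueError(
                        f"{sp}: codon {k + 1} ({cds[3 * k:3 * k + 3]}) translates to "
                        f"{translated[k]}, protein has {rec.protein_seq[k]}"
                    )
            raise ValueError(f"{sp}: CDS/protein length mismatch after translation")
        codons = [cds[i : i + 3] for i in range(0, 3 * len(translated), 3)]
        parts = []
        idx = 0
        for col, c in enumerate(row):
            if c in GAP_CHARS:
                parts.append("---")
                column_map[col][sp] = None
            else:
                parts.append(codons[idx])
                column_map[col][sp] = idx
                idx += 1
        codon_rows[sp] = "".join(parts)

    return AlignedFamily(family.gene_symbol, species, dict(protein_msa), codon_rows, column_map)


# ---------------------------------------------------------------------------
# file formats


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode, newline=None)


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into an ordered id->sequence dict."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
            fh,
            "fasta",
        )


def read_alignment(path) -> dict[str, str]:
    """Read aligned FASTA; all rows must have equal length."""
    seqs = read_fasta(path)
    if len({len(s) for s in seqs.values()}) != 1:
        raise ValueError(f"alignment rows in {path} have unequal lengths")
    return seqs


def read_newick(path_or_string) -> dendropy.Tree:
    s = str(path_or_string)
    if "(" in s and ";" in s:
        return dendropy.Tree.get(data=s, schema="newick")
    with _open_text(s) as fh:
        return dendropy.Tree.get(data=fh.read(), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(tree_to_newick(tree))
        fh.write("\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths at 10 significant digits."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip()


def write_rejection_log(log: Sequence[Rejection], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("species\trule\tdetail\n")
        for r in log:
            fh.write(f"{r.species}\t{r.rule}\t{r.detail}\n")
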