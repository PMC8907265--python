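"""Genetic-code helpers shared by the simulator and the Ka/Ks engine."""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
NUCLEOTIDES = "ACGT"

# transition partners (purine<->purine, pyrimidine<->pyrimidine)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

GAP_CHARS = frozenset("-.")


def is_transition(a: str, b: str) -> bool:
    return TRANSITION.get(a) == b


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS, dropping a single terminal stop if present.

    Raises ValueError on internal stops, length not divisible by 3, or
    unknown codons.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper()
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aas = []
    for k, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon {k + 1}")
        try:
            aas.append(CODON_TO_AA[c])
        except KeyError:
            raise ValueError(f"unknown codon {c!r} at codon {k + 1}") from None
    return "".join(aas)
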