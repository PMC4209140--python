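"""In-frame codon alignments: container, validation, FASTA IO."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import GeneticCode, standard_genetic_code

_ALPHABET = set("ACGTN-")


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences over {A,C,G,T,N,-}.

    Codons containing a gap or an N anywhere are treated as missing data
    throughout the package; fully resolved codons must not be stop codons.
    """

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon names must be unique")
        if not self.sequences:
            raise ValueError("alignment is empty")
        self.sequences = [s.upper() for s in self.sequences]
        length = len(self.sequences[0])
        if length == 0 or length % 3 != 0:
            raise ValueError("alignment length must be a positive multiple of 3")
        code = standard_genetic_code()
        for name, seq in zip(self.taxa, self.sequences):
            if len(seq) != length:
                raise ValueError(f"row {name!r} has length {len(seq)} != {length}")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(f"row {name!r} has invalid characters {bad}")
            for k in range(0, length, 3):
                codon = seq[k : k + 3]
                if "-" in codon or "N" in codon:
                    continue
                if code.is_stop(codon):
                    raise ValueError(
                        f"in-frame stop codon {codon} at codon {k // 3 + 1} "
                        f"in row {name!r}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        """Number of codon columns."""
        return len(self.sequences[0]) // 3

    def codon(self, taxon_index: int, site: int) -> str:
        """Codon of one row at a 0-based codon column."""
        return self.sequences[taxon_index][3 * site : 3 * site + 3]

    def state_matrix(self, code: GeneticCode | None = None) -> np.ndarray:
        """(n_taxa, n_sites) sense-codon indices; -1 for gap/N codons."""
        code = code or standard_genetic_code()
        out = np.full((self.n_taxa, self.n_sites), -1, dtype=np.int64)
        for i, seq in enumerate(self.sequences):
            for s in range(self.n_sites):
                codon = seq[3 * s : 3 * s + 3]
                if "-" not in codon and "N" not in codon:
                    out[i, s] = code.index(codon)
        return out

    def subset_taxa(self, keep: list[str]) -> "CodonAlignment":
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in keep if t not in index]
        if missing:
            raise KeyError(f"taxa not in alignment: {missing}")
        return CodonAlignment(list(keep), [self.sequences[index[t]] for t in keep])

    def subset_sites(self, sites: list[int]) -> "CodonAlignment":
        """New alignment restricted to the given 0-based codon columns."""
        rows = [
            "".join(seq[3 * s : 3 * s + 3] for s in sites) for seq in self.sequences
        ]
        return CodonAlignment(list(self.taxa), rows)

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in zip(self.taxa, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")
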