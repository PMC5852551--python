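"""emPAI computation from peptide evidence.

The exponentially modified protein abundance index is
``emPAI = 10**(n_observed / n_observable) - 1``, where ``n_observed`` is the
number of distinct peptides matched for a protein and ``n_observable`` the
number of distinct peptides an in-silico tryptic digest could yield within
the retained length window.  This is a supporting stage: pipelines that
already ship emPAI tables skip it entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

__all__ = [
    "PeptideEvidence",
    "cleavage_fragments",
    "tryptic_digest",
    "count_observable_peptides",
    "compute_empai",
    "empai_from_fasta",
    "read_peptide_evidence",
]

# residues that never create a cleavage site even when preceded by K/R
_CLEAVE = {"K", "R"}


@dataclass(frozen=True)
class PeptideEvidence:
    locus_tag: str
    n_observed: int
    n_observable: int

    def __post_init__(self) -> None:
        if self.n_observable < 1:
            raise ValueError(
                f"{self.locus_tag}: n_observable must be >= 1, got {self.n_observable}"
            )
        if self.n_observed < 0:
            raise ValueError(f"{self.locus_tag}: n_observed must be >= 0")

    @property
    def flagged(self) -> bool:
        """True when more peptides were observed than predicted observable."""
        return self.n_observed > self.n_observable


def cleavage_fragments(sequence: str) -> list:
    """Ordered tryptic fragments before length filtering and deduplication.

    Concatenating the result reconstructs the input sequence.
    """
    sequence = sequence.upper().strip("*")
    fragments = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in _CLEAVE and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        fragments.append(sequence[start:])
    return fragments


def tryptic_digest(sequence: str, min_len: int = 1, max_len: int = 10**9) -> list:
    """Cleave C-terminal to K or R, except before P; 0 missed cleavages.

    Returns distinct peptides with length in [min_len, max_len], in order of
    first occurrence.  'X' (unknown residue) never creates a cleavage site.
    """
    seen = {}
    for frag in cleavage_fragments(sequence):
        if min_len <= len(frag) <= max_len:
            seen.setdefault(frag, None)
    return list(seen)


def count_observable_peptides(sequence: str, min_len: int = 6, max_len: int = 30) -> int:
    """Distinct tryptic peptides within the length window standing in for the
    retained m/z range."""
    return len(tryptic_digest(sequence, min_len=min_len, max_len=max_len))


def compute_empai(ev: PeptideEvidence) -> float:
    """emPAI = 10**(n_observed/n_observable) - 1 (0 when nothing observed)."""
    return 10.0 ** (ev.n_observed / ev.n_observable) - 1.0


def empai_from_fasta(fasta_path, observed_counts: dict, min_len: int = 6, max_len: int = 30) -> pd.Series:
    """Compute emPAI for every FASTA record given observed peptide counts.

    ``observed_counts`` maps locus tag -> distinct observed peptides; records
    absent from the mapping count as 0 observed (emPAI 0).  Records whose
    digest yields no observable peptide are rejected.
    """
    values = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_obs = int(observed_counts.get(rec.id, 0))
        n_observable = count_observable_peptides(str(rec.seq), min_len, max_len)
        if n_observable == 0:
            raise ValueError(f"{rec.id}: no observable peptide in [{min_len}, {max_len}]")
        values[rec.id] = compute_empai(PeptideEvidence(rec.id, n_obs, n_observable))
    return pd.Series(values, name="empai")


def read_peptide_evidence(path) -> list:
    """Read a peptide-evidence TSV (locus_tag, n_observed, n_observable)."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_tag": str})
    return [
        PeptideEvidence(r.locus_tag, int(r.n_observed), int(r.n_observable))
        for r in df.itertuples(index=False)
    ]
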