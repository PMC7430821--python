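"""Amino-acid scales, genetic-code tables and wobble-pairing constants.

Everything here is a small literature constant shipped as plain Python so
users can inspect or override it: the Kyte–Doolittle hydropathy scale, a
net-charge scale at cytosolic pH, and the yeast-fitted wobble penalties
used for tRNA adaptation index weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

#: Standard genetic code, DNA alphabet, stop codons map to '*'.
GENETIC_CODE: Dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))

#: Synonymous family per amino acid (sense codons only).
CODONS_BY_AA: Dict[str, tuple] = {}
for _c in SENSE_CODONS:
    CODONS_BY_AA.setdefault(GENETIC_CODE[_c], tuple())
    CODONS_BY_AA[GENETIC_CODE[_c]] = CODONS_BY_AA[GENETIC_CODE[_c]] + (_c,)

AMINO_ACIDS = tuple(sorted(CODONS_BY_AA))

#: Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE: Dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Net side-chain charge at cytosolic pH: K,R = +1; D,E = -1; H = 0.
CHARGE: Dict[str, float] = {aa: 0.0 for aa in AMINO_ACIDS}
CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.0})


@dataclass(frozen=True)
class ResidueScale:
    """A per-amino-acid numeric scale (hydropathy, charge, ...)."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self):
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def get(self, aa: str, default=None):
        return self.values.get(aa, default)


HYDROPATHY_SCALE = ResidueScale("hydropathy", KYTE_DOOLITTLE)
CHARGE_SCALE = ResidueScale("charge", CHARGE)

# ---------------------------------------------------------------------------
# Wobble pairing for tAI weights.
#
# Each rule pairs the codon's third base with the anticodon's wobble (first,
# 5') base and carries a selective penalty s; the contribution of a matching
# tRNA to a codon's absolute adaptiveness is (1 - s) * tGCN.  Watson-Crick
# pairs have s = 0; the non-WC penalties are the yeast-fitted values in wide
# use (A at the wobble position is read as inosine).
# ---------------------------------------------------------------------------

#: (codon 3rd base, anticodon wobble base) -> penalty s in [0, 1].
DEFAULT_WOBBLE_PENALTIES: Dict[tuple, float] = {
    # Watson-Crick
    ("T", "A"): 0.0,
    ("C", "G"): 0.0,
    ("A", "T"): 0.0,
    ("G", "C"): 0.0,
    # wobble: anticodon G reads codon-U3
    ("T", "G"): 0.41,
    # inosine (genomically A) reads C3 and A3
    ("C", "A"): 0.28,
    ("A", "A"): 0.9999,
    # anticodon U reads codon-G3
    ("G", "T"): 0.68,
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str, stop_symbol: str = "*") -> str:
    """Translate a CDS nucleotide string; ambiguous codons become 'X'."""
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3].upper()
        aa.append(GENETIC_CODE.get(codon, "X") if "N" not in codon else "X")
    return "".join(a if a != "*" else stop_symbol for a in aa)
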