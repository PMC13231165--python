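"""Degenerate-codon combinatorics and library architecture.

This module holds the declarative descriptions of the two library types the
pipeline analyses:

* the HUH-seq substrate library — a 97-nt ssDNA oligo with a central
  randomized 7-mer flanked by constant primer-binding anchors, cleaved by a
  Rep (HUH-endonuclease) immediately 5' of a fixed ``AC`` dinucleotide
  (the +1/+2 positions of the origin-of-replication motif); and

* site-saturation mutagenesis libraries over the ssDNA-bridging motif (sDBM)
  of the Rep, built from degenerate codons (NNK and relatives).

It also implements the combinatorics those descriptions support: IUPAC codon
expansion, theoretical library diversity, and the encoding/decoding of
amino-acid variants from sequencing reads.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "IUPAC_DNA",
    "DegenerateCodon",
    "DegenerateLibrarySpec",
    "LibraryDesign",
    "VariantCall",
    "expand_codon",
    "theoretical_diversity",
    "decode_variant",
    "encode_variant",
    "default_huhseq_design",
    "default_round1_spec",
    "default_round2_spec",
]

# IUPAC nucleotide one-letter codes over the DNA alphabet.
IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

STOP = "*"

# Standard genetic code (NCBI translation table 1); no alternative codes.
_TABLE1 = unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_TABLE1.forward_table)
for _stop in _TABLE1.stop_codons:
    GENETIC_CODE[_stop] = STOP

# Deterministic codon choice per amino acid (lexicographically smallest),
# used by encode_variant for non-mutagenized positions.
_CANONICAL_CODON: dict[str, str] = {}
for _codon in sorted(GENETIC_CODE):
    _aa = GENETIC_CODE[_codon]
    _CANONICAL_CODON.setdefault(_aa, _codon)


def _normalize(seq: str) -> str:
    """Uppercase and normalize U→T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class DegenerateCodon:
    """A degenerate codon written in IUPAC nucleotide codes (e.g. ``NNK``)."""

    iupac_triplet: str

    def __post_init__(self) -> None:
        triplet = _normalize(self.iupac_triplet)
        if len(triplet) != 3 or any(c not in IUPAC_DNA for c in triplet):
            raise ValueError(
                f"invalid IUPAC triplet: {self.iupac_triplet!r}"
            )
        object.__setattr__(self, "iupac_triplet", triplet)

    @property
    def size(self) -> int:
        """Number of concrete codons encoded (product of code cardinalities)."""
        return int(
            len(IUPAC_DNA[self.iupac_triplet[0]])
            * len(IUPAC_DNA[self.iupac_triplet[1]])
            * len(IUPAC_DNA[self.iupac_triplet[2]])
        )


NNK = DegenerateCodon("NNK")


def expand_codon(codon: DegenerateCodon | str) -> tuple[set[str], Counter]:
    """Expand a degenerate codon into concrete codons and encoded residues.

    Returns ``(codons, residues)`` where *codons* is the Cartesian product of
    the per-position IUPAC expansions and *residues* is the multiset of
    amino acids they encode under the standard genetic code, with stop codons
    counted under the symbol ``*``.

    >>> codons, aas = expand_codon("NNK")
    >>> len(codons), len(set(aas))
    (32, 21)
    """
    if not isinstance(codon, DegenerateCodon):
        codon = DegenerateCodon(codon)
    t = codon.iupac_triplet
    codons = {
        a + b + c
        for a in IUPAC_DNA[t[0]]
        for b in IUPAC_DNA[t[1]]
        for c in IUPAC_DNA[t[2]]
    }
    residues = Counter(GENETIC_CODE[c] for c in codons)
    return codons, residues


@dataclass
class DegenerateLibrarySpec:
    """A site-saturation mutagenesis library over a parent coding region.

    ``parent_protein`` is the amino-acid sequence of the sequenced coding
    region; residue numbering follows the full-length protein (1-based PCV2
    Rep numbering in the default specs), with ``numbering_offset`` giving the
    residue number of ``parent_protein[0]``.

    ``mutagenized_positions`` are the residue numbers replaced by degenerate
    codons; ``fixed_overrides`` are residues fixed to a non-parent identity
    (e.g. round 2 of sDBM engineering fixes 79→R, 81→W, 84→P).
    """

    parent_protein: str
    mutagenized_positions: list[int]
    codon_per_position: dict[int, DegenerateCodon] = field(default_factory=dict)
    fixed_overrides: dict[int, str] = field(default_factory=dict)
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        self.parent_protein = self.parent_protein.upper()
        self.mutagenized_positions = sorted(self.mutagenized_positions)
        overlap = set(self.mutagenized_positions) & set(self.fixed_overrides)
        if overlap:
            raise ValueError(
                f"positions both mutagenized and fixed: {sorted(overlap)}"
            )
        last = self.numbering_offset + len(self.parent_protein) - 1
        for pos in itertools.chain(self.mutagenized_positions, self.fixed_overrides):
            if not (self.numbering_offset <= pos <= last):
                raise ValueError(
                    f"residue {pos} outside parent region "
                    f"[{self.numbering_offset}, {last}]"
                )
        for pos in self.mutagenized_positions:
            self.codon_per_position.setdefault(pos, NNK)

    def parent_residue(self, position: int) -> str:
        return self.parent_protein[position - self.numbering_offset]

    def effective_residue(self, position: int) -> str:
        """Residue at a non-mutagenized position (override or parent)."""
        return self.fixed_overrides.get(position, self.parent_residue(position))

    def to_json(self) -> str:
        return json.dumps(
            {
                "parent_protein": self.parent_protein,
                "mutagenized_positions": self.mutagenized_positions,
                "codon_per_position": {
                    str(p): c.iupac_triplet
                    for p, c in self.codon_per_position.items()
                },
                "fixed_overrides": self.fixed_overrides,
                "numbering_offset": self.numbering_offset,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DegenerateLibrarySpec":
        d = json.loads(text)
        return cls(
            parent_protein=d["parent_protein"],
            mutagenized_positions=list(d["mutagenized_positions"]),
            codon_per_position={
                int(p): DegenerateCodon(c)
                for p, c in d.get("codon_per_position", {}).items()
            },
            fixed_overrides={
                int(p): aa for p, aa in d.get("fixed_overrides", {}).items()
            },
            numbering_offset=int(d.get("numbering_offset", 1)),
        )


def theoretical_diversity(
    spec: DegenerateLibrarySpec,
    level: str = "amino_acid",
    include_stop: bool = True,
) -> int:
    """Theoretical library diversity at the codon or amino-acid level.

    At the amino-acid level each distinct encoded outcome counts once per
    position, with stop counted as its own outcome by default — six NNK
    positions therefore give 21**6 = 85,766,121 unique sequences.  Pass
    ``include_stop=False`` to count only sense outcomes (20**6 for NNK).
    Zero mutagenized positions give the empty product, 1.
    """
    if level not in ("codon", "amino_acid"):
        raise ValueError(f"unknown diversity level: {level!r}")
    total = 1
    for pos in spec.mutagenized_positions:
        codon = spec.codon_per_position[pos]
        if level == "codon":
            total *= codon.size
        else:
            _, residues = expand_codon(codon)
            outcomes = set(residues)
            if not include_stop:
                outcomes.discard(STOP)
            total *= len(outcomes)
    return total


@dataclass
class VariantCall:
    """Decoded amino-acid identity of one read at the mutagenized positions."""

    residues: dict[int, str]  # position -> amino acid ('*' for stop)
    key: str                  # residues joined in position order
    has_stop: bool
    unassignable: bool
    reason: str = ""


def decode_variant(read_region: str, spec: DegenerateLibrarySpec) -> VariantCall:
    """Translate the mutagenized codons of a coding-region read.

    ``read_region`` must be in frame with ``spec.parent_protein`` (codon *i*
    encodes residue ``numbering_offset + i``) and long enough to cover every
    mutagenized codon.  Reads with an ambiguous base inside a mutagenized
    codon are marked unassignable; reads encoding a stop at a mutagenized
    position are flagged, not dropped.
    """
    region = _normalize(read_region)
    residues: dict[int, str] = {}
    has_stop = False
    for pos in spec.mutagenized_positions:
        start = 3 * (pos - spec.numbering_offset)
        codon = region[start:start + 3]
        if len(codon) < 3:
            return VariantCall({}, "", False, True, "read does not cover codon")
        if any(b not in "ACGT" for b in codon):
            return VariantCall({}, "", False, True, f"ambiguous base in codon {codon}")
        aa = GENETIC_CODE[codon]
        if aa == STOP:
            has_stop = True
        residues[pos] = aa
    key = "".join(residues[p] for p in spec.mutagenized_positions)
    return VariantCall(residues, key, has_stop, False)


def encode_variant(key: str, spec: DegenerateLibrarySpec) -> str:
    """Build a coding-region DNA sequence realizing a variant key.

    The inverse of :func:`decode_variant` up to codon synonymy: mutagenized
    positions get the lexicographically smallest codon from their degenerate
    codon set encoding the requested residue; all other positions get the
    canonical (smallest) codon of their effective residue.
    """
    if len(key) != len(spec.mutagenized_positions):
        raise ValueError(
            f"variant key {key!r} has {len(key)} residues; spec has "
            f"{len(spec.mutagenized_positions)} mutagenized positions"
        )
    wanted = dict(zip(spec.mutagenized_positions, key.upper()))
    codons: list[str] = []
    for i in range(len(spec.parent_protein)):
        pos = spec.numbering_offset + i
        if pos in wanted:
            aa = wanted[pos]
            pool, _ = expand_codon(spec.codon_per_position[pos])
            matches = sorted(c for c in pool if GENETIC_CODE[c] == aa)
            if not matches:
                raise ValueError(
                    f"residue {aa!r} not encodable by "
                    f"{spec.codon_per_position[pos].iupac_triplet} at {pos}"
                )
            codons.append(matches[0])
        else:
            codons.append(_CANONICAL_CODON[spec.effective_residue(pos)])
    return "".join(codons)


@dataclass
class LibraryDesign:
    """Architecture of the HUH-seq substrate oligo.

    The oligo is ``upstream_anchor + randomized 7-mer + downstream_anchor``
    where the downstream anchor begins with the fixed ``AC`` core — the
    +1 A and +2 C of the circovirus origin motif (5' TATTATT*AC 3', cleavage
    between −1 and +1).  The randomized region occupies the −7…−1 substrate
    positions.  Sequenced reads carry a sample barcode immediately 5' of the
    oligo.
    """

    upstream_anchor: str
    downstream_anchor: str
    barcode_map: dict[str, str] = field(default_factory=dict)
    total_length: int = 97
    fixed_core_suffix: str = "AC"

    def __post_init__(self) -> None:
        self.upstream_anchor = _normalize(self.upstream_anchor)
        self.downstream_anchor = _normalize(self.downstream_anchor)
        for name, anchor in (
            ("upstream_anchor", self.upstream_anchor),
            ("downstream_anchor", self.downstream_anchor),
        ):
            if not anchor or any(b not in "ACGT" for b in anchor):
                raise ValueError(f"{name} must be non-empty, non-degenerate DNA")
        if (
            self.upstream_anchor in self.downstream_anchor
            or self.downstream_anchor in self.upstream_anchor
        ):
            raise ValueError("anchors must not contain each other")
        if not self.downstream_anchor.startswith(self.fixed_core_suffix):
            raise ValueError(
                f"downstream anchor must start with the fixed core "
                f"{self.fixed_core_suffix!r} (+1/+2 of the cleavage site)"
            )
        if len(self.upstream_anchor) + self.k + len(self.downstream_anchor) \
                != self.total_length:
            raise ValueError(
                "anchor lengths + randomized region do not reconstruct "
                f"total_length={self.total_length}"
            )
        if self.barcode_map:
            lens = {len(b) for b in self.barcode_map}
            if len(lens) != 1:
                raise ValueError("barcodes must share one length")

    @property
    def k(self) -> int:
        """Length of the randomized region (7 in the published design)."""
        return 7

    @property
    def randomized_span(self) -> tuple[int, int]:
        """0-based half-open interval of the randomized region in the oligo."""
        start = len(self.upstream_anchor)
        return (start, start + self.k)

    @property
    def barcode_length(self) -> int:
        if not self.barcode_map:
            raise ValueError("design has no barcodes")
        return len(next(iter(self.barcode_map)))

    def oligo(self, kmer: str) -> str:
        """The full 97-nt oligo carrying ``kmer`` in the randomized region."""
        kmer = _normalize(kmer)
        if len(kmer) != self.k or any(b not in "ACGT" for b in kmer):
            raise ValueError(f"k-mer must be {self.k} nt of ACGT: {kmer!r}")
        return self.upstream_anchor + kmer + self.downstream_anchor

    def oligo_fasta(self, name: str = "huhseq_library") -> str:
        """FASTA record of the library design, randomized positions as N."""
        return f">{name}\n{self.upstream_anchor}{'N' * self.k}{self.downstream_anchor}\n"


# --- Defaults -------------------------------------------------------------
#
# The constant flanks below are synthetic stand-ins for the study's
# primer-binding sequences (which are not printed); the architecture —
# 97 nt total, central randomized 7-mer, fixed AC at +1/+2 — is the
# published design.

_DEFAULT_UPSTREAM = (
    "GCTACGTAACGGTTCACCTGAGTCGATACCAGTGCTTAGGCACTT"  # 45 nt
)
_DEFAULT_DOWNSTREAM = (
    "ACTGGAGCATCGTTACGAGTCCAATGGTCTAGCATCACGTGGATA"  # 45 nt, AC core at +1/+2
)

# 8-nt sample barcodes, pairwise Hamming distance >= 5 (verified in tests),
# so single-substitution demultiplexing can never be ambiguous.
DEFAULT_BARCODES: tuple[str, ...] = (
    "AAGCCCAA", "TCTGACTG", "GGGATATA", "CATGTGCG",
    "GCGACCCT", "TGACGCTT", "GCCTAAAC", "CTATTTGA",
    "AGCAGCCG", "CAGTAAGG", "TGTTCCGC", "ACAACTAC",
)


def default_huhseq_design(samples: list[str] | None = None) -> LibraryDesign:
    """The 97-nt HUH-seq design with barcodes assigned to ``samples``."""
    samples = samples or []
    if len(samples) > len(DEFAULT_BARCODES):
        raise ValueError(
            f"only {len(DEFAULT_BARCODES)} default barcodes available"
        )
    barcode_map = dict(zip(DEFAULT_BARCODES, samples))
    return LibraryDesign(
        upstream_anchor=_DEFAULT_UPSTREAM,
        downstream_anchor=_DEFAULT_DOWNSTREAM,
        barcode_map=barcode_map,
    )


# Constant 5' flank of the selection-round amplicon (synthetic stand-in for
# the sequencing-primer region upstream of the coding frame).
SELECTION_FLANK_5P = "ACCGGTAGCTTGCAGTCA"

# Synthetic stand-in for the sequenced sDBM coding region (PCV2 numbering,
# residues 74-90).  Only the residues the study itself states are pinned:
# wild-type H81 and K86, and the round-2 fixes R79/W81/P84.  The remaining
# parent residues are arbitrary placeholders.
DEFAULT_SDBM_PARENT = "GSFVTRNHVKSTKLAQY"  # residues 74..90
DEFAULT_SDBM_OFFSET = 74


def default_round1_spec() -> DegenerateLibrarySpec:
    """Round-1 sDBM library: NNK at residues 79-84."""
    return DegenerateLibrarySpec(
        parent_protein=DEFAULT_SDBM_PARENT,
        mutagenized_positions=[79, 80, 81, 82, 83, 84],
        numbering_offset=DEFAULT_SDBM_OFFSET,
    )


def default_round2_spec() -> DegenerateLibrarySpec:
    """Round-2 sDBM library: NNK at 80/82/83/85/86; 79→R, 81→W, 84→P fixed."""
    return DegenerateLibrarySpec(
        parent_protein=DEFAULT_SDBM_PARENT,
        mutagenized_positions=[80, 82, 83, 85, 86],
        fixed_overrides={79: "R", 81: "W", 84: "P"},
        numbering_offset=DEFAULT_SDBM_OFFSET,
    )
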