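"""Directed-evolution NGS analysis: variant counting, enrichment, logos.

After each sorting round of yeast-display selection, the mutagenized sDBM
coding region is amplified and sequenced.  This module counts amino-acid
variants per round (via :func:`huhseq.lib_design.decode_variant`),
quantifies round-over-round enrichment as a log2 frequency ratio with an
additive pseudocount, builds per-position residue logos (frequency or
enrichment mode), and calls a consensus variant — the workflow that
identified H81W and K86Y as the drivers of enhanced RNA reactivity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lib_design import (
    DegenerateLibrarySpec,
    SELECTION_FLANK_5P,
    STOP,
    decode_variant,
    expand_codon,
)

__all__ = [
    "AMINO_ACIDS",
    "VariantTable",
    "EnrichmentLogoMatrix",
    "ConsensusResult",
    "count_variants",
    "variant_enrichment",
    "residue_logo",
    "consensus_variant",
]

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class VariantTable:
    """Per-round variant counts at the mutagenized positions."""

    round_label: str
    counts: Counter               # variant key -> count (stop keys included)
    total_reads: int
    unassignable: int
    spec: DegenerateLibrarySpec

    @property
    def stop_containing(self) -> int:
        return sum(c for key, c in self.counts.items() if STOP in key)

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())

    def frequencies(self, drop_stop: bool = True) -> dict[str, float]:
        items = {k: c for k, c in self.counts.items()
                 if not (drop_stop and STOP in k)}
        total = sum(items.values())
        if total == 0:
            return {}
        return {k: c / total for k, c in items.items()}

    def to_frame(self) -> pd.DataFrame:
        total = self.assigned
        rows = [
            {"variant": k, "count": c,
             "frequency": c / total if total else np.nan,
             "has_stop": STOP in k}
            for k, c in sorted(self.counts.items(),
                               key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows)


@dataclass
class EnrichmentLogoMatrix:
    """Position × residue weight matrix over the mutagenized positions."""

    matrix: pd.DataFrame          # index: residue positions; columns: symbols
    mode: str                     # frequency | enrichment
    include_stop: bool
    reference_round: str | None = None

    def argmax_residues(self) -> dict[int, str]:
        return {int(pos): str(self.matrix.loc[pos].idxmax())
                for pos in self.matrix.index}


@dataclass
class ConsensusResult:
    """Consensus call from a frequency logo, with tie and override logging."""

    residues: dict[int, str]       # all positions in the sDBM amplicon
    consensus_key: str             # residues at the mutagenized positions
    confidence: dict[int, float]   # argmax frequency per mutagenized position
    ties: list[str] = field(default_factory=list)
    fixed_overrides: dict[int, str] = field(default_factory=dict)


def count_variants(
    reads,
    spec: DegenerateLibrarySpec,
    round_label: str = "",
    upstream_flank: str = SELECTION_FLANK_5P,
) -> VariantTable:
    """Count amino-acid variants in a round's reads.

    Reads are matched to the coding frame by exact match of the constant
    upstream flank (no alignment — the amplicon is fixed-architecture);
    a read whose flank is absent, or whose mutagenized codons contain
    ambiguous bases, is unassignable.  Stop-containing variants are counted
    under their own keys and tallied separately.  Deterministic and
    order-invariant.
    """
    counts: Counter = Counter()
    unassignable = 0
    total = 0
    flank_len = len(upstream_flank)
    for _, seq in reads:
        total += 1
        seq = seq.upper()
        if upstream_flank:
            at = seq.find(upstream_flank)
            if at < 0:
                unassignable += 1
                continue
            region = seq[at + flank_len:]
        else:
            region = seq
        call = decode_variant(region, spec)
        if call.unassignable:
            unassignable += 1
        else:
            counts[call.key] += 1
    if total == 0:
        raise ValueError("no reads provided")
    if not counts:
        raise ValueError("no read covers the mutagenized region")
    return VariantTable(round_label, counts, total, unassignable, spec)


def variant_enrichment(
    pre: VariantTable,
    post: VariantTable,
    pseudocount: float | None = None,
    drop_stop: bool = True,
) -> pd.DataFrame:
    """Per-variant enrichment score between two rounds.

    score = log2((f_post + p)/(f_pre + p)) over the union of variants, with
    frequencies f and additive pseudocount p (default 1/total assigned reads
    of the smaller round).  Antisymmetric under pre/post exchange at matched
    p; monotone in f_post for fixed f_pre.
    """
    if pre.assigned == 0 or post.assigned == 0:
        raise ValueError("empty variant table")
    if pseudocount is None:
        pseudocount = 1.0 / min(pre.assigned, post.assigned)
    f_pre = pre.frequencies(drop_stop=drop_stop)
    f_post = post.frequencies(drop_stop=drop_stop)
    keys = sorted(set(f_pre) | set(f_post))
    rows = []
    for key in keys:
        fp = f_pre.get(key, 0.0)
        fq = f_post.get(key, 0.0)
        rows.append({
            "variant": key,
            "freq_pre": fp,
            "freq_post": fq,
            "log2_enrichment": float(
                np.log2((fq + pseudocount) / (fp + pseudocount))
            ),
        })
    df = pd.DataFrame(rows).sort_values(
        "log2_enrichment", ascending=False, ignore_index=True
    )
    df.attrs["pseudocount"] = pseudocount
    df.attrs["scheme"] = "log2_frequency_ratio_additive_pseudocount"
    return df


def _symbols(include_stop: bool) -> list[str]:
    return AMINO_ACIDS + ([STOP] if include_stop else [])


def residue_logo(
    table: VariantTable,
    spec: DegenerateLibrarySpec | None = None,
    mode: str = "frequency",
    reference: VariantTable | None = None,
    include_stop: bool = False,
    pseudocount: float | None = None,
) -> EnrichmentLogoMatrix:
    """Per-position residue logo over the mutagenized positions.

    ``frequency`` mode gives per-position residue frequencies among retained
    reads (stop-containing variants excluded unless ``include_stop``);
    ``enrichment`` mode gives the per-position log2 ratio of those
    frequencies against a reference round, preserving sign.  Only the
    mutagenized positions appear as rows.
    """
    spec = spec or table.spec
    if mode not in ("frequency", "enrichment"):
        raise ValueError(f"unknown logo mode {mode!r}")
    if mode == "enrichment" and reference is None:
        raise ValueError("enrichment mode requires a reference round")
    positions = spec.mutagenized_positions
    symbols = _symbols(include_stop)

    def freq_matrix(t: VariantTable) -> pd.DataFrame:
        mat = pd.DataFrame(0.0, index=positions, columns=symbols)
        for key, count in t.counts.items():
            if not include_stop and STOP in key:
                continue
            for pos, aa in zip(positions, key):
                if aa in mat.columns:
                    mat.loc[pos, aa] += count
        totals = mat.sum(axis=1)
        return mat.div(totals.replace(0, np.nan), axis=0).fillna(0.0)

    own = freq_matrix(table)
    if mode == "frequency":
        matrix = own
        ref_label = None
    else:
        ref = freq_matrix(reference)
        p = pseudocount if pseudocount is not None else \
            1.0 / min(table.assigned, reference.assigned)
        matrix = np.log2((own + p) / (ref + p))
        ref_label = reference.round_label
    matrix.index.name = "position"
    return EnrichmentLogoMatrix(matrix, mode, include_stop, ref_label)


def consensus_variant(
    logo: EnrichmentLogoMatrix,
    spec: DegenerateLibrarySpec,
) -> ConsensusResult:
    """Consensus sequence from a frequency logo.

    Per mutagenized position, the argmax residue; exact ties are broken
    toward the parent residue (and logged).  Fixed overrides and parent
    residues pass through for the non-mutagenized positions.
    """
    if logo.mode != "frequency":
        raise ValueError("consensus requires a frequency-mode logo")
    ties: list[str] = []
    residues: dict[int, str] = {}
    confidence: dict[int, float] = {}
    for pos in spec.mutagenized_positions:
        col = logo.matrix.loc[pos]
        if float(col.sum()) == 0.0:
            raise ValueError(f"all-zero logo column at position {pos}")
        top = float(col.max())
        winners = sorted(col.index[col == top])
        parent = spec.parent_residue(pos)
        if len(winners) > 1:
            choice = parent if parent in winners else winners[0]
            ties.append(
                f"position {pos}: tie between {winners}; chose {choice!r}"
                + (" (parent)" if choice == parent else "")
            )
        else:
            choice = winners[0]
        residues[pos] = choice
        confidence[pos] = top
    for i in range(len(spec.parent_protein)):
        pos = spec.numbering_offset + i
        if pos not in residues:
            residues[pos] = spec.effective_residue(pos)
    key = "".join(residues[p] for p in spec.mutagenized_positions)
    return ConsensusResult(
        residues=residues,
        consensus_key=key,
        confidence=confidence,
        ties=ties,
        fixed_overrides=dict(spec.fixed_overrides),
    )
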