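"""HUH-seq specificity profiling: reads → k-mer counts → percent reduction.

HUH-seq measures the sequence specificity of a Rep (HUH-endonuclease) by
reacting it with an ssDNA library whose cleavage-proximal 7-mer is
randomized.  Cleaved molecules drop out of the amplifiable pool, so cleavage
of a given 7-mer shows up as a *reduction* in its read frequency in the
treated sample relative to an untreated reference:

    percent_reduction(kmer) = (f_ref - f_treat) / f_ref

computed on mean frequencies across retained replicates.  The stages here
follow the assay's processing order: demultiplex by sample barcode, extract
the randomized 7-mer from each read, count all 4^7 = 16,384 k-mers,
quality-control replicates by pairwise count correlation, compute per-k-mer
mean percent reduction, and summarize as histograms and position-weight
specificity logos.

Coordinates are 0-based half-open internally; substrate positions are
labelled in the field's −7…−1 convention (cleavage between −1 and +1) at the
presentation layer.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lib_design import LibraryDesign

__all__ = [
    "BASES",
    "kmer_to_index",
    "index_to_kmer",
    "all_kmers",
    "kmer_base_matrix",
    "KmerCountTable",
    "ReductionProfile",
    "SpecificityLogo",
    "ReductionHistogram",
    "QCResult",
    "demultiplex",
    "extract_kmer",
    "count_kmers",
    "replicate_qc",
    "percent_reduction",
    "reduction_histogram",
    "specificity_logo",
    "condition_correlation",
    "write_tsv",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


# --- k-mer indexing -------------------------------------------------------

def kmer_to_index(kmer: str) -> int:
    """Map an ACGT k-mer to its lexicographic rank (A=0..T=3, big-endian)."""
    idx = 0
    for b in kmer:
        idx = idx * 4 + _BASE_INDEX[b]
    return idx


def index_to_kmer(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in index order."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def kmer_base_matrix(k: int) -> np.ndarray:
    """(4^k, k) array of base indices, row i = bases of index_to_kmer(i, k)."""
    n = 4 ** k
    idx = np.arange(n)
    cols = [(idx // 4 ** (k - 1 - j)) % 4 for j in range(k)]
    return np.stack(cols, axis=1).astype(np.uint8)


# --- I/O helper -----------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, metadata: dict | None = None,
              index: bool = True) -> None:
    """Write a TSV with a reproducibility metadata header (# key=value)."""
    buf = io.StringIO()
    for key, value in (metadata or {}).items():
        buf.write(f"# {key}={value}\n")
    df.to_csv(buf, sep="\t", index=index)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# --- Domain types ---------------------------------------------------------

@dataclass
class KmerCountTable:
    """Per-sample k-mer counts over the full 4^k k-mer universe."""

    sample_id: str
    condition: str
    replicate: int
    counts: np.ndarray  # int64, length 4^k, indexed by kmer_to_index
    assigned_reads: int
    unassigned_reads: int
    k: int = 7

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4 ** self.k,):
            raise ValueError(
                f"counts must have length 4^{self.k}={4 ** self.k}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    @property
    def frequencies(self) -> np.ndarray:
        """Counts normalized to sum 1; all-NaN (flagged) for an empty table."""
        total = self.total
        if total == 0:
            return np.full_like(self.counts, np.nan, dtype=float)
        return self.counts / total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=all_kmers(self.k),
                         name=self.sample_id)


@dataclass
class QCResult:
    """Replicate QC outcome for one condition."""

    correlation: np.ndarray        # pairwise Pearson r on raw counts
    sample_ids: list[str]
    retained: list[int]            # indices into the input replicate list
    excluded: list[int]
    r_threshold: float
    usable: bool
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "correlation": np.round(self.correlation, 6).tolist(),
            "retained": [self.sample_ids[i] for i in self.retained],
            "excluded": [self.sample_ids[i] for i in self.excluded],
            "r_threshold": self.r_threshold,
            "usable": self.usable,
            "warnings": self.warnings,
        }


@dataclass
class ReductionProfile:
    """Per-k-mer mean percent reduction of a treatment vs the reference."""

    condition: str
    k: int
    mean_reference_freq: np.ndarray
    mean_treatment_freq: np.ndarray
    percent_reduction: np.ndarray          # fraction in (-inf, 1]; NaN where ref = 0
    per_replicate: np.ndarray              # (n_treat_replicates, 4^k)
    treatment_sample_ids: list[str]
    reference_sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        kmers = all_kmers(self.k)
        df = pd.DataFrame(
            {
                "mean_reference_freq": self.mean_reference_freq,
                "mean_treatment_freq": self.mean_treatment_freq,
                "percent_reduction": self.percent_reduction,
            },
            index=pd.Index(kmers, name="kmer"),
        )
        for i, sid in enumerate(self.treatment_sample_ids):
            df[f"reduction_{sid}"] = self.per_replicate[i]
        return df


@dataclass
class ReductionHistogram:
    """Binned counts of k-mers per percent-reduction interval."""

    edges: np.ndarray
    counts: np.ndarray
    na_count: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.edges[:-1],
                "bin_right": self.edges[1:],
                "n_kmers": self.counts,
            }
        )


@dataclass
class SpecificityLogo:
    """Position-weight matrix over substrate positions −7…−1."""

    matrix: pd.DataFrame           # index: positions −7..−1; columns: A,C,G,T
    threshold: float
    included_kmer_count: int
    scheme: str                    # reduction_weighted | unweighted
    normalized: bool
    empty: bool = False

    def argmax_motif(self) -> str:
        """The base with the largest weight at each position, 5'→3'."""
        if self.empty:
            return ""
        return "".join(self.matrix.idxmax(axis=1))


# --- Operations -----------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_barcodes(barcode_map: dict[str, str], max_mismatch: int) -> None:
    """Reject barcode sets that cannot be demultiplexed unambiguously."""
    barcodes = list(barcode_map)
    if not barcodes:
        raise ValueError("empty barcode map")
    if len({len(b) for b in barcodes}) != 1:
        raise ValueError("barcodes must share one length")
    for a, b in itertools.combinations(barcodes, 2):
        if _hamming(a, b) <= 2 * max_mismatch:
            raise ValueError(
                f"barcodes {a} and {b} collide at max_mismatch={max_mismatch}: "
                f"Hamming distance {_hamming(a, b)} <= {2 * max_mismatch}"
            )


def demultiplex(
    reads,
    barcode_map: dict[str, str],
    max_mismatch: int = 0,
) -> tuple[dict[str, list[tuple[str, str]]], list[tuple[str, str]]]:
    """Assign reads to samples by their 5' barcode.

    ``reads`` is an iterable of ``(read_id, sequence)``; the barcode occupies
    the first ``len(barcode)`` bases.  Each read is assigned to at most one
    sample (barcode match within ``max_mismatch`` substitutions — uniqueness
    is guaranteed by the startup collision check).  Returns
    ``(per-sample reads with barcode stripped, unassigned reads)``.
    """
    validate_barcodes(barcode_map, max_mismatch)
    blen = len(next(iter(barcode_map)))
    by_sample: dict[str, list[tuple[str, str]]] = {
        sample: [] for sample in barcode_map.values()
    }
    unassigned: list[tuple[str, str]] = []
    exact = barcode_map  # prefix -> sample for the mismatch-free fast path
    barcodes = list(barcode_map.items())
    for read_id, seq in reads:
        prefix = seq[:blen]
        sample = exact.get(prefix)
        if sample is None and max_mismatch > 0:
            for bc, s in barcodes:
                if _hamming(prefix, bc) <= max_mismatch:
                    sample = s
                    break
        if sample is None:
            unassigned.append((read_id, seq))
        else:
            by_sample[sample].append((read_id, seq[blen:]))
    return by_sample, unassigned


def extract_kmer(read: str, design: LibraryDesign) -> str | None:
    """Extract the randomized 7-mer from a (barcode-stripped) library read.

    Anchor search is exact-match-first: both constant flanks must be found
    with the randomized region exactly between them.  When both anchors fail
    and the read has the design's exact length, fixed coordinates are used as
    a fallback.  Returns ``None`` for unextractable reads or regions
    containing non-ACGT characters (that is the contract — no exceptions).
    """
    read = read.upper()
    up, down = design.upstream_anchor, design.downstream_anchor
    i = read.find(up)
    kmer = None
    if i >= 0:
        j = read.find(down, i + len(up))
        if j == i + len(up) + design.k:
            kmer = read[i + len(up): j]
    if kmer is None and len(read) == design.total_length:
        start, stop = design.randomized_span
        kmer = read[start:stop]
    if kmer is None or len(kmer) != design.k:
        return None
    if any(b not in _BASE_INDEX for b in kmer):
        return None
    return kmer


def count_kmers(
    reads,
    design: LibraryDesign,
    sample_id: str = "",
    condition: str = "",
    replicate: int = 0,
) -> KmerCountTable:
    """Count every 4^k k-mer (zero-count entries included) in a read set.

    Deterministic and invariant to read order.  ``reads`` is an iterable of
    ``(read_id, sequence)`` with barcodes already stripped.
    """
    k = design.k
    indices = []
    n_assigned = 0
    n_failed = 0
    for _, seq in reads:
        kmer = extract_kmer(seq, design)
        if kmer is None:
            n_failed += 1
        else:
            indices.append(kmer_to_index(kmer))
            n_assigned += 1
    counts = np.bincount(
        np.asarray(indices, dtype=np.int64), minlength=4 ** k
    ).astype(np.int64)
    return KmerCountTable(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        counts=counts,
        assigned_reads=n_assigned,
        unassigned_reads=n_failed,
        k=k,
    )


def _count_correlation(tables: list[KmerCountTable]) -> np.ndarray:
    mat = np.stack([t.counts.astype(float) for t in tables])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    # constant count vectors yield NaN; treat as uninformative (r = 0)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def replicate_qc(
    tables: list[KmerCountTable],
    r_threshold: float = 0.8,
) -> QCResult:
    """Flag replicates whose raw k-mer counts correlate poorly with siblings.

    Pairwise Pearson r is computed on raw counts.  Exclusion is greedy
    worst-first: while any retained replicate has mean r against the other
    retained replicates below ``r_threshold``, the worst offender is
    excluded and correlations re-evaluated — so a single corrupted replicate
    is removed without dragging down its well-correlated siblings.  Never
    excludes below two replicates; if the survivors still disagree the
    condition is flagged unusable.
    """
    if len(tables) < 2:
        raise ValueError("replicate QC needs at least 2 replicates")
    corr = _count_correlation(tables)
    warnings: list[str] = []
    retained = list(range(len(tables)))
    excluded: list[int] = []
    while True:
        sub = corr[np.ix_(retained, retained)]
        n = len(retained)
        mean_r = (sub.sum(axis=1) - 1.0) / (n - 1)
        if (mean_r >= r_threshold).all():
            usable = True
            break
        if n <= 2:
            usable = False
            warnings.append(
                "remaining replicates are mutually uncorrelated "
                f"(mean r {np.round(mean_r, 3).tolist()} < {r_threshold}); "
                "condition flagged unusable"
            )
            break
        worst = retained[int(np.argmin(mean_r))]
        excluded.append(worst)
        retained.remove(worst)
        warnings.append(
            f"excluded replicate {tables[worst].sample_id!r}: mean r "
            f"{float(mean_r.min()):.3f} < {r_threshold}"
        )
    return QCResult(
        correlation=corr,
        sample_ids=[t.sample_id for t in tables],
        retained=retained,
        excluded=sorted(excluded),
        r_threshold=r_threshold,
        usable=usable,
        warnings=warnings,
    )


def percent_reduction(
    reference_tables: list[KmerCountTable],
    treatment_tables: list[KmerCountTable],
    condition: str = "",
) -> ReductionProfile:
    """Per-k-mer mean percent reduction of treatment vs reference.

    Frequencies are averaged across replicates (mean-of-frequencies, not
    pooled counts) on each side; reduction = (ref − treat)/ref, NaN where
    the mean reference frequency is zero.  Negative values (enrichment of
    uncleaved k-mers) are retained.  Callers apply replicate QC first and
    pass only retained tables.
    """
    if not reference_tables or not treatment_tables:
        raise ValueError("need at least one retained replicate on each side")
    ks = {t.k for t in reference_tables + treatment_tables}
    if len(ks) != 1:
        raise ValueError("reference and treatment tables differ in k")
    k = ks.pop()
    ref = np.stack([t.frequencies for t in reference_tables]).mean(axis=0)
    treat_reps = np.stack([t.frequencies for t in treatment_tables])
    treat = treat_reps.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = np.where(ref > 0, (ref - treat) / ref, np.nan)
        per_rep = np.where(ref > 0, (ref - treat_reps) / ref, np.nan)
    return ReductionProfile(
        condition=condition,
        k=k,
        mean_reference_freq=ref,
        mean_treatment_freq=treat,
        percent_reduction=reduction,
        per_replicate=per_rep,
        treatment_sample_ids=[t.sample_id for t in treatment_tables],
        reference_sample_ids=[t.sample_id for t in reference_tables],
    )


def reduction_histogram(
    profile: ReductionProfile, bin_width: float = 0.05
) -> ReductionHistogram:
    """Histogram of k-mers per reduction interval; NaN k-mers kept separate.

    Bins span [min(0, observed minimum), 1] so enrichment (negative
    reduction) stays visible; bin counts plus the NaN count always total
    the 4^k k-mer universe.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    values = profile.percent_reduction
    finite = values[np.isfinite(values)]
    na_count = values.size - finite.size
    lo = min(0.0, float(finite.min()) if finite.size else 0.0)
    # extend down to a bin boundary aligned on multiples of bin_width
    n_below = int(np.ceil((0.0 - lo) / bin_width - 1e-12))
    n_above = int(np.ceil(1.0 / bin_width - 1e-12))
    edges = np.arange(-n_below, n_above + 1) * bin_width
    edges[-1] = 1.0  # reductions never exceed 1; make the top edge exact
    counts, _ = np.histogram(finite, bins=edges)
    return ReductionHistogram(edges=edges, counts=counts, na_count=na_count)


def specificity_logo(
    profile: ReductionProfile,
    threshold: float = 0.5,
    scheme: str = "reduction_weighted",
    normalize: bool = True,
) -> SpecificityLogo:
    """Position-weight logo of high-efficiency substrates.

    Includes k-mers with percent reduction ≥ ``threshold`` (default 0.5,
    i.e. ≥50% depletion).  Under ``reduction_weighted``, the weight of base
    b at position j is the summed reduction of included k-mers carrying b at
    j; ``unweighted`` counts each included k-mer once.  Columns are
    normalized to 1 unless ``normalize=False``.  Rows are labelled with the
    substrate positions −7…−1.
    """
    if scheme not in ("reduction_weighted", "unweighted"):
        raise ValueError(f"unknown logo scheme: {scheme!r}")
    k = profile.k
    values = profile.percent_reduction
    included = np.isfinite(values) & (values >= threshold)
    n_included = int(included.sum())
    positions = list(range(-k, 0))
    if n_included == 0:
        matrix = pd.DataFrame(
            0.0, index=pd.Index(positions, name="position"), columns=list(BASES)
        )
        return SpecificityLogo(matrix, threshold, 0, scheme, normalize, empty=True)
    bases = kmer_base_matrix(k)[included]
    weights = values[included] if scheme == "reduction_weighted" else \
        np.ones(n_included)
    cols = np.stack(
        [np.bincount(bases[:, j], weights=weights, minlength=4)
         for j in range(k)]
    )
    if normalize:
        cols = cols / cols.sum(axis=1, keepdims=True)
    matrix = pd.DataFrame(
        cols, index=pd.Index(positions, name="position"), columns=list(BASES)
    )
    return SpecificityLogo(matrix, threshold, n_included, scheme, normalize)


def render_logo(logo: "SpecificityLogo | pd.DataFrame", path,
                title: str = "") -> None:
    """Render a logo matrix as a stacked bar chart (optional; the numeric
    TSV matrix is the primary artifact)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = logo.matrix if hasattr(logo, "matrix") else logo
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(6, 3))
    bottom = np.zeros(len(matrix))
    x = np.arange(len(matrix))
    for base in matrix.columns:
        vals = matrix[base].to_numpy()
        ax.bar(x, vals, bottom=bottom, label=str(base),
               color=colors.get(str(base)))
        bottom += vals
    ax.set_xticks(x, [str(i) for i in matrix.index])
    ax.set_xlabel("substrate position")
    ax.set_ylabel("weight")
    if title:
        ax.set_title(title)
    ax.legend(ncols=len(matrix.columns), fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def condition_correlation(
    profiles: dict[str, ReductionProfile]
) -> pd.DataFrame:
    """Pairwise Pearson r between conditions over per-k-mer reductions.

    NaN k-mers are dropped pairwise; entries with fewer than 3 shared
    finite k-mers are NaN.  The matrix is symmetric with unit diagonal.
    """
    names = list(profiles)
    n = len(names)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            a = profiles[names[i]].percent_reduction
            b = profiles[names[j]].percent_reduction
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3:
                continue
            r = float(np.corrcoef(a[ok], b[ok])[0, 1])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)
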