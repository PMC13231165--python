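"""Seeded generators for synthetic HUH-seq runs, selection rounds, and
plate-reader titrations.

Everything downstream of the wet lab is testable against these generators:
they produce standard 4-line FASTQ and long-format observation tables with
the statistical structure the analysis stages assume, plus truth tables
recording the generating parameters, so pipeline estimates can be compared
against known ground truth.  All randomness flows from the manifest seed;
identical manifest + seed gives byte-identical output files.

The default HUH-seq study scenario emulates:

* a synthesized randomized 7-mer pool with realistic composition bias —
  mild per-position base bias compounded across the 7 positions plus a
  small set of high-abundance "synthesis spike" k-mers (a fixed property of
  the simulated library lot, independent of the sampling seed);
* a broadly reactive ("promiscuous", high-Mn) enzyme whose per-k-mer
  cleavage spans the full range while still preferring the canonical
  circovirus motif TATTATT, and a narrow-specificity ("specific", low-Mn
  wild-type-like) enzyme that only cleaves near-motif k-mers;
* one deliberately corrupted replicate (k-mer identities permuted before
  sampling), emulating a replicate that fails count-correlation QC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biophys
from .huhseq_core import BASES, all_kmers, kmer_base_matrix
from .lib_design import (
    DegenerateLibrarySpec,
    LibraryDesign,
    SELECTION_FLANK_5P,
    default_huhseq_design,
    expand_codon,
    encode_variant,
)

__all__ = [
    "CleavageModel",
    "SimulationManifest",
    "SimulatedHUHSeqRun",
    "SimulatedSelectionRun",
    "one_hot_model",
    "default_cleavage_model",
    "reference_kmer_distribution",
    "simulate_huhseq_run",
    "simulate_selection_rounds",
    "simulate_titration",
    "fp_design_points",
    "default_winner_profile",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Composition of the simulated library lot (fixed, seed-independent):
# per-position relative base weights, rotated across positions, plus
# "synthesis spikes" — a few k-mers carrying a disproportionate share of
# the pool, as seen in real synthesized randomized oligo pools.
_POSITION_BIAS = (1.0, 0.90, 0.78, 0.68)
_SPIKE_MASS = 0.15
_N_SPIKES = 160
_LIBRARY_LOT_SEED = 12345

# Default promiscuous-model survival factors: the motif base survives
# cleavage least; the other three bases get these factors (rotated per
# position).  Survival multiplies across positions, so per-k-mer cleavage
# spans the full (0, 1) range.
_MOTIF_SURVIVAL = 0.22
_OTHER_SURVIVAL = (1.0, 0.78, 0.52)


@dataclass
class CleavageModel:
    """Per-k-mer cleavage probability model for a simulated reaction.

    Modes:

    * ``position_weight`` — P(cleave | kmer) = extent · Π_j w[j, base_j],
      with ``position_weights`` the 7×4 matrix of per-position per-base
      cleavage propensities in [0, 1] (positions −7…−1, bases ACGT);
    * ``survival_weight`` — the weights are per-base survival factors:
      P = extent · (1 − Π_j w[j, base_j]); multiplicative survival lets
      cleavage span the full range across the k-mer space;
    * ``mismatch_logistic`` — logistic in the Hamming distance m to
      ``reference_motif``: P = extent / (1 + e^{(m − midpoint)/scale}).
    """

    mode: str = "position_weight"
    position_weights: np.ndarray | None = None
    reference_motif: str = "TATTATT"
    extent: float = 1.0
    midpoint: float = 1.0
    scale: float = 0.5
    metal_condition_label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("position_weight", "survival_weight",
                             "mismatch_logistic"):
            raise ValueError(f"unknown cleavage model mode {self.mode!r}")
        if not 0.0 <= self.extent <= 1.0:
            raise ValueError("extent must be in [0, 1]")
        self.reference_motif = self.reference_motif.upper()
        if self.position_weights is not None:
            w = np.asarray(self.position_weights, dtype=float)
            if w.shape != (len(self.reference_motif), 4):
                raise ValueError("position_weights must be k x 4")
            if (w < 0).any() or (w > 1).any():
                raise ValueError("position weights must be in [0, 1]")
            self.position_weights = w
        elif self.mode in ("position_weight", "survival_weight"):
            raise ValueError(f"mode {self.mode!r} requires position_weights")

    @property
    def k(self) -> int:
        return len(self.reference_motif)

    def cleavage_probabilities(self) -> np.ndarray:
        """P(cleave) for every k-mer in index order; values in [0, 1]."""
        bm = kmer_base_matrix(self.k)
        if self.mode == "mismatch_logistic":
            motif = np.array([_BASE_INDEX[c] for c in self.reference_motif])
            mismatches = (bm != motif).sum(axis=1)
            p = self.extent / (1.0 + np.exp((mismatches - self.midpoint)
                                            / self.scale))
        else:
            w = self.position_weights
            prod = np.ones(4 ** self.k)
            for j in range(self.k):
                prod *= w[j, bm[:, j]]
            if self.mode == "position_weight":
                p = self.extent * prod
            else:
                p = self.extent * (1.0 - prod)
        return np.clip(p, 0.0, 1.0)


def one_hot_model(motif: str = "TATTATT", extent: float = 1.0) -> CleavageModel:
    """Model cleaving only ``motif``, with probability ``extent``."""
    motif = motif.upper()
    w = np.zeros((len(motif), 4))
    for j, c in enumerate(motif):
        w[j, _BASE_INDEX[c]] = 1.0
    return CleavageModel(mode="position_weight", position_weights=w,
                         reference_motif=motif, extent=extent)


def default_cleavage_model(kind: str = "promiscuous",
                           motif: str = "TATTATT") -> CleavageModel:
    """Canonical simulated enzymes.

    ``promiscuous`` — broadly reactive, high-Mn engineered-variant-like:
    multiplicative per-base survival, motif bases cleaved hardest, cleavage
    extent spanning the full range over the 16,384 k-mers.

    ``specific`` — narrow wild-type-like specificity: logistic in mismatch
    count, so only the motif and its 1-mismatch neighbours are cleaved
    appreciably.
    """
    motif = motif.upper()
    if kind == "promiscuous":
        k = len(motif)
        w = np.empty((k, 4))
        for j in range(k):
            others = np.roll(_OTHER_SURVIVAL, j % 3)
            oi = 0
            for b in range(4):
                if b == _BASE_INDEX[motif[j]]:
                    w[j, b] = _MOTIF_SURVIVAL
                else:
                    w[j, b] = others[oi]
                    oi += 1
        return CleavageModel(mode="survival_weight", position_weights=w,
                             reference_motif=motif, extent=1.0,
                             metal_condition_label="high Mn")
    if kind == "specific":
        return CleavageModel(mode="mismatch_logistic", reference_motif=motif,
                             extent=0.95, midpoint=1.0, scale=0.5,
                             metal_condition_label="low Mn")
    raise ValueError(f"unknown model kind {kind!r}")


def reference_kmer_distribution(k: int = 7,
                                profile: str = "uniform") -> np.ndarray:
    """k-mer sampling probabilities of the untreated reference library.

    ``uniform`` — the idealized equimolar pool.  ``synthesis_bias`` — the
    simulated library lot: per-position base bias compounded across
    positions plus spike k-mers; fixed by an internal lot seed so the pool
    composition is a property of the library, not of the sampling seed.
    """
    n = 4 ** k
    if profile == "uniform":
        return np.full(n, 1.0 / n)
    if profile != "synthesis_bias":
        raise ValueError(f"unknown reference profile {profile!r}")
    bm = kmer_base_matrix(k)
    p = np.ones(n)
    for j in range(k):
        vals = np.roll(np.asarray(_POSITION_BIAS), j % 4)
        vals = vals / vals.sum()
        p *= vals[bm[:, j]]
    p /= p.sum()
    lot = np.random.default_rng(_LIBRARY_LOT_SEED)
    spikes = lot.choice(n, size=_N_SPIKES, replace=False)
    p *= 1.0 - _SPIKE_MASS
    p[spikes] += _SPIKE_MASS / _N_SPIKES
    return p


@dataclass
class SimulationManifest:
    """Reproducibility manifest for a simulated sequencing run."""

    seed: int
    depth_per_sample: int = 100_000
    n_replicates: int = 3
    corrupt_replicate: tuple[str, int] | None = None  # (condition, 1-based rep)
    error_rate: float = 0.001
    reference_profile: str = "uniform"

    def __post_init__(self) -> None:
        if self.depth_per_sample < 0:
            raise ValueError("depth must be non-negative")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "depth_per_sample": self.depth_per_sample,
            "n_replicates": self.n_replicates,
            "corrupt_replicate": list(self.corrupt_replicate)
            if self.corrupt_replicate else None,
            "error_rate": self.error_rate,
            "reference_profile": self.reference_profile,
        }


@dataclass
class SimulatedHUHSeqRun:
    """Handle to the files and in-memory truth of one simulated run."""

    fastq_path: Path
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame
    design: LibraryDesign
    manifest: SimulationManifest
    out_dir: Path


def _apply_errors(rng: np.random.Generator, idx: np.ndarray,
                  error_rate: float) -> np.ndarray:
    """Substitution-only error model on a (reads, length) base-index array."""
    if error_rate <= 0:
        return idx
    mask = rng.random(idx.shape, dtype=np.float32) < error_rate
    shifts = rng.integers(1, 4, size=idx.shape, dtype=np.uint8)
    return np.where(mask, (idx + shifts) % 4, idx)


def _indices_to_seqs(idx: np.ndarray) -> list[str]:
    ascii_bytes = _BASE_BYTES[idx]
    length = idx.shape[1]
    blob = ascii_bytes.tobytes()
    return [blob[i * length:(i + 1) * length].decode("ascii")
            for i in range(idx.shape[0])]


def simulate_huhseq_run(
    design: LibraryDesign | None,
    model: CleavageModel | dict[str, CleavageModel],
    manifest: SimulationManifest,
    out_dir: str | Path,
) -> SimulatedHUHSeqRun:
    """Simulate a multiplexed HUH-seq run and write its artifacts.

    The reference samples draw k-mers from the library distribution; each
    treatment sample draws k-mer i with weight ∝ p_ref(i)·(1 − P_cleave(i)).
    Reads are full oligos with the sample barcode prepended and per-base
    substitution errors applied.  A ``corrupt_replicate`` (condition,
    replicate) draws from a label-permuted distribution, emulating a
    replicate that fails count-correlation QC.

    Writes ``reads.fastq`` (pooled, multiplexed), ``sample_sheet.tsv``,
    ``truth.tsv`` (per-k-mer cleavage probability and expected percent
    reduction per condition) and ``manifest.json``.
    """
    models = model if isinstance(model, dict) else {"treatment": model}
    if "reference" in models:
        raise ValueError("'reference' is reserved for the untreated samples")
    conditions = list(models)
    samples = [("reference", rep) for rep in range(1, manifest.n_replicates + 1)]
    for cond in conditions:
        samples += [(cond, rep) for rep in range(1, manifest.n_replicates + 1)]
    sample_ids = [f"{cond}_r{rep}" for cond, rep in samples]

    if design is None or not design.barcode_map:
        design = default_huhseq_design(sample_ids)
    if set(design.barcode_map.values()) < set(sample_ids):
        raise ValueError("design barcode map does not cover all samples")
    barcode_of = {s: b for b, s in design.barcode_map.items()}

    k = design.k
    n = 4 ** k
    for cond, m in models.items():
        if m.k != k:
            raise ValueError(
                f"model for {cond!r} has k={m.k}, design randomized span is {k}"
            )
    p_ref = reference_kmer_distribution(k, manifest.reference_profile)
    weights: dict[str, np.ndarray] = {"reference": p_ref}
    truth = pd.DataFrame(index=pd.Index(all_kmers(k), name="kmer"))
    truth["p_reference"] = p_ref
    for cond in conditions:
        p_cleave = models[cond].cleavage_probabilities()
        q = p_ref * (1.0 - p_cleave)
        surv = q.sum()
        weights[cond] = q / surv if surv > 0 else np.full(n, 1.0 / n)
        truth[f"p_cleave_{cond}"] = p_cleave
        # expected (f_ref - f_treat)/f_ref given sampling from the weights
        truth[f"true_reduction_{cond}"] = 1.0 - (1.0 - p_cleave) / surv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(manifest.seed)
    bm = kmer_base_matrix(k)
    up_idx = np.array([_BASE_INDEX[c] for c in design.upstream_anchor],
                      dtype=np.uint8)
    down_idx = np.array([_BASE_INDEX[c] for c in design.downstream_anchor],
                        dtype=np.uint8)
    fastq_path = out_dir / "reads.fastq"
    rows = []
    with open(fastq_path, "w") as fq:
        for (cond, rep), sample_id in zip(samples, sample_ids):
            w = weights[cond]
            if manifest.corrupt_replicate == (cond, rep):
                w = w[rng.permutation(n)]
            counts = rng.multinomial(manifest.depth_per_sample, w)
            kmer_idx = np.repeat(np.arange(n), counts)
            rng.shuffle(kmer_idx)
            depth = kmer_idx.size
            barcode = barcode_of[sample_id]
            bc_idx = np.array([_BASE_INDEX[c] for c in barcode], dtype=np.uint8)
            length = len(barcode) + design.total_length
            reads = np.empty((depth, length), dtype=np.uint8)
            reads[:, :len(barcode)] = bc_idx
            off = len(barcode)
            reads[:, off:off + len(up_idx)] = up_idx
            reads[:, off + len(up_idx):off + len(up_idx) + k] = bm[kmer_idx]
            reads[:, off + len(up_idx) + k:] = down_idx
            reads = _apply_errors(rng, reads, manifest.error_rate)
            qual = "I" * length
            kmers = all_kmers(k)
            for i, (seq, ki) in enumerate(zip(_indices_to_seqs(reads),
                                              kmer_idx)):
                fq.write(f"@{sample_id}.{i} kmer={kmers[ki]}\n"
                         f"{seq}\n+\n{qual}\n")
            rows.append({
                "barcode": barcode, "sample": sample_id, "condition": cond,
                "replicate": rep,
                "role": "reference" if cond == "reference" else "treatment",
            })
    sheet = pd.DataFrame(rows)
    sheet.to_csv(out_dir / "sample_sheet.tsv", sep="\t", index=False)
    truth.to_csv(out_dir / "truth.tsv", sep="\t")
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2) + "\n"
    )
    return SimulatedHUHSeqRun(fastq_path, sheet, truth, design, manifest,
                              out_dir)


# --- Selection rounds -----------------------------------------------------

@dataclass
class SimulatedSelectionRun:
    fastq_paths: list[Path]
    truth: pd.DataFrame
    spec: DegenerateLibrarySpec
    winner_profile: dict[int, dict[str, float]]
    manifest: SimulationManifest
    out_dir: Path


def default_winner_profile(
    spec: DegenerateLibrarySpec,
    winners: dict[int, str],
    strength: float = 8.0,
) -> dict[int, dict[str, float]]:
    """Fitness map boosting one residue per chosen position by ``strength``."""
    profile: dict[int, dict[str, float]] = {
        pos: {} for pos in spec.mutagenized_positions
    }
    for pos, aa in winners.items():
        if pos not in profile:
            raise ValueError(f"position {pos} is not mutagenized")
        profile[pos][aa.upper()] = strength
    return profile


def simulate_selection_rounds(
    spec: DegenerateLibrarySpec,
    winner_profile: dict[int, dict[str, float]],
    rounds: int,
    manifest: SimulationManifest,
    out_dir: str | Path,
) -> SimulatedSelectionRun:
    """Simulate NNK-library selection: naive round 0 plus ``rounds`` sorts.

    The naive population draws residues per mutagenized position with NNK
    codon multiplicities (Leu 3/32, Met 1/32, stop 1/32 …).  Each selection
    round resamples reads with probability proportional to variant fitness —
    the product over positions of the per-residue fitness in
    ``winner_profile`` (unlisted residues have fitness 1), so designated
    winner residues converge monotonically in expectation.  Writes one
    FASTQ per round (reads are a constant 5' flank plus the coding region)
    and a truth table of per-round variant frequencies and fitness.
    """
    if rounds < 1:
        raise ValueError("need at least one selection round")
    missing = set(spec.mutagenized_positions) - set(winner_profile)
    if missing:
        raise ValueError(f"winner profile missing positions {sorted(missing)}")
    rng = np.random.default_rng(manifest.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    positions = spec.mutagenized_positions
    depth = manifest.depth_per_sample

    alphabets, probs, fitness_vecs = [], [], []
    for pos in positions:
        _, residues = expand_codon(spec.codon_per_position[pos])
        alphabet = sorted(residues)
        total = sum(residues.values())
        alphabets.append(alphabet)
        probs.append(np.array([residues[a] / total for a in alphabet]))
        fit = np.array([winner_profile.get(pos, {}).get(a, 1.0)
                        for a in alphabet])
        fitness_vecs.append(fit)

    pop = np.stack(
        [rng.choice(len(a), size=depth, p=p)
         for a, p in zip(alphabets, probs)],
        axis=1,
    )
    encode_cache: dict[str, str] = {}

    def keys_of(population: np.ndarray) -> list[str]:
        cols = [np.array(list("".join(a)), dtype="U1")[population[:, j]]
                for j, a in enumerate(alphabets)]
        stacked = np.stack(cols, axis=1)
        return ["".join(row) for row in stacked]

    def write_round(r: int, population: np.ndarray) -> tuple[Path, pd.Series]:
        keys = keys_of(population)
        seqs = []
        for key in keys:
            dna = encode_cache.get(key)
            if dna is None:
                dna = SELECTION_FLANK_5P + encode_variant(key, spec)
                encode_cache[key] = dna
            seqs.append(dna)
        length = len(seqs[0]) if seqs else 0
        if seqs and manifest.error_rate > 0:
            idx = np.array(
                [[_BASE_INDEX[c] for c in s] for s in seqs], dtype=np.uint8
            )
            idx = _apply_errors(rng, idx, manifest.error_rate)
            seqs = _indices_to_seqs(idx)
        path = out_dir / f"round{r}.fastq"
        qual = "I" * length
        with open(path, "w") as fq:
            for i, (seq, key) in enumerate(zip(seqs, keys)):
                fq.write(f"@round{r}.{i} variant={key}\n{seq}\n+\n{qual}\n")
        return path, pd.Series(keys).value_counts()

    paths, truth_rows = [], []
    for r in range(rounds + 1):
        if r > 0:
            fitness = np.ones(depth)
            for j in range(len(positions)):
                fitness *= fitness_vecs[j][pop[:, j]]
            pick = rng.choice(depth, size=depth, p=fitness / fitness.sum())
            pop = pop[pick]
        path, counts = write_round(r, pop)
        paths.append(path)
        for key, count in counts.items():
            fit = float(np.prod([
                winner_profile.get(pos, {}).get(aa, 1.0)
                for pos, aa in zip(positions, key)
            ]))
            truth_rows.append({"round": r, "variant": key, "count": int(count),
                               "frequency": count / depth, "fitness": fit})
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth_variants.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(
        {**manifest.to_dict(), "rounds": rounds,
         "winner_profile": {str(p): wp for p, wp in winner_profile.items()}},
        indent=2) + "\n")
    return SimulatedSelectionRun(paths, truth, spec, winner_profile, manifest,
                                 out_dir)


# --- Titrations -----------------------------------------------------------

def fp_design_points(top_nM: float = 1000.0, n_points: int = 12,
                     dilution: float = 2.0) -> np.ndarray:
    """Serial-dilution protein grid: 1:2 from 1 µM over 12 points, in nM."""
    return top_nM / dilution ** np.arange(n_points)


_TITRATION_MODELS = {
    "quadratic_binding": (
        lambda x, p: biophys.quadratic_binding(
            x, p["kd_nM"], p["amax"], p["amin"], p["dt_nM"]),
        "protein_nM",
    ),
    "hyperbolic_saturation": (
        lambda x, p: biophys.hyperbolic_activation(
            x, p["vmax"], p["kapp_uM"], p.get("hill", 1.0)),
        "metal_uM",
    ),
    "melt_sigmoid": (
        lambda x, p: biophys.melt_sigmoid(
            x, p["tm_C"], p.get("width_C", 2.0), p["f_low"], p["f_high"]),
        "temperature_C",
    ),
    "beacon_progress": (
        lambda x, p: biophys.beacon_progress(
            x, p["k_per_s"], p["f0"], p["f_inf"]),
        "time_s",
    ),
}


def simulate_titration(
    model: str,
    true_params: dict[str, float],
    design_points: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_wells: int = 1,
    n_days: int = 1,
) -> pd.DataFrame:
    """Noisy realizations of one titration/melt/progress-curve model.

    Observations are model(true_params, x) + iid Gaussian(0, noise_sd).
    ``n_wells``/``n_days`` reproduce the plate replicate structure (4 wells
    × 3 days for the polarization assay).  Returns a long-format frame with
    columns series_id, model, replicate, x, y.
    """
    if model not in _TITRATION_MODELS:
        raise ValueError(f"unknown titration model {model!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    func, x_kind = _TITRATION_MODELS[model]
    if design_points is None:
        design_points = {
            "quadratic_binding": fp_design_points(),
            "hyperbolic_saturation": np.geomspace(10.0, 1000.0, 8),
            "melt_sigmoid": np.arange(20.0, 95.0 + 0.25, 0.5),
            "beacon_progress": np.arange(0.0, 900.0 + 1.0, 5.0),
        }[model]
    x = np.asarray(design_points, dtype=float)
    if x_kind in ("protein_nM", "metal_uM") and (x < 0).any():
        raise ValueError("concentration design points must be non-negative")
    rng = np.random.default_rng(seed)
    clean = func(x, true_params)
    rows = []
    for day in range(1, n_days + 1):
        for well in range(1, n_wells + 1):
            y = clean + rng.normal(0.0, noise_sd, size=x.shape) \
                if noise_sd > 0 else clean.copy()
            rows.append(pd.DataFrame({
                "series_id": model, "model": model,
                "replicate": f"day{day}_well{well}", "x": x, "y": y,
            }))
    return pd.concat(rows, ignore_index=True)
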