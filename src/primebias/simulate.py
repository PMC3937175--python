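"""Synthetic-library and biased-PCR read simulation.

The unamplified synthetic library (SL) is a pool of constructs carrying a
12 nt fully random insert between fixed anchors, behind a 4 bp sample
barcode.  Amplification with a random-3'-hexamer primer is modeled as one
effective per-molecule weight: each SL molecule is resampled multinomially
with probability proportional to the preference weight of the 8 bp motif
at its primer:template junction (the primer's 3' hexamer plus the first
two runway bases — insert positions [0, 8)).  A per-cycle efficiency e
over c cycles maps monotonically onto such an end-point weight (1+e)**c,
so the single-weight table subsumes cycle-by-cycle branching for end-point
libraries.

Every entry point takes an explicit seed; identical seeds give identical
output bytes.  No sequencing-error model is applied unless a substitution
rate is requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kmers
from .biasquant import INSERT_LEN
from .ppi import DEFAULT_LAYOUT, PPIScales, SectionLayout, WINDOW_LEN
from .seqio import LibraryDesign, ReadRecord

#: default barcodes for simulated runs: the unamplified background plus
#: two amplified replicates
DEFAULT_BARCODES = {
    "SL": "AAGG",
    "amp1": "CCTT",
    "amp2": "GGAA",
}

UNIFORM_BASES = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T


def _base_probs(dist) -> np.ndarray:
    """Normalize an insert base distribution given as 'uniform', a mapping
    base->probability, or a 4-vector in A,C,G,T order."""
    if dist is None or (isinstance(dist, str) and dist == "uniform"):
        probs = np.asarray(UNIFORM_BASES, dtype=float)
    elif isinstance(dist, dict):
        probs = np.array([dist.get(b, 0.0) for b in "ACGT"], dtype=float)
    else:
        probs = np.asarray(dist, dtype=float)
    if probs.shape != (4,) or (probs < 0).any():
        raise ValueError("insert distribution must give 4 non-negative base probabilities")
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("insert base probabilities must sum to 1")
    return probs / total


@dataclass
class SimConfig:
    """Parameters of one simulated study."""

    n_sl_reads: int = 0
    n_amp_reads: int = 0
    design: LibraryDesign = field(default_factory=LibraryDesign)
    barcodes: dict = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    insert_distribution: object = "uniform"
    seed: int = 0

    def __post_init__(self):
        if self.n_sl_reads < 0 or self.n_amp_reads < 0:
            raise ValueError("read counts must be non-negative")
        _base_probs(self.insert_distribution)


@dataclass
class PreferenceModel:
    """Ground-truth per-8-mer amplification weights.

    ``weights`` is dense over all 4**8 junction motifs (relative
    per-molecule yield after the full PCR; all positive).  A factorized
    model is built from positional scales and keeps them (in canonical
    gauge) for later comparison with fitted scales.
    """

    weights: np.ndarray
    model_kind: str = "table"
    scales: PPIScales | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (kmers.n_kmers(WINDOW_LEN),):
            raise ValueError("weights must cover all 4**8 junction motifs")
        if not (self.weights > 0).all():
            raise ValueError("all amplification weights must be positive")
        if self.model_kind not in ("table", "factorized"):
            raise ValueError("model_kind must be 'table' or 'factorized'")

    @classmethod
    def uniform(cls) -> "PreferenceModel":
        return cls(np.ones(kmers.n_kmers(WINDOW_LEN)))

    @classmethod
    def from_weights(cls, mapping: dict, default: float = 1.0) -> "PreferenceModel":
        weights = np.full(kmers.n_kmers(WINDOW_LEN), default, dtype=float)
        for kmer, w in mapping.items():
            weights[kmers.kmer_to_index(kmer)] = w
        return cls(weights)

    @classmethod
    def factorized(cls, scales: PPIScales) -> "PreferenceModel":
        canonical = scales.canonicalized()
        return cls(canonical.window_values(), model_kind="factorized", scales=canonical)

    @classmethod
    def gc_favoring(cls, factor: float = 1.3,
                    layout: SectionLayout = DEFAULT_LAYOUT) -> "PreferenceModel":
        """Factorized model multiplying each section scale by ``factor``
        per G/C base — the GC-gradient preference of thermostable
        polymerases, at a strength giving junction weights spanning
        roughly two orders of magnitude at the default 1.3."""
        if factor <= 0:
            raise ValueError("factor must be positive")
        tables = []
        for s, e in layout.sections:
            size = e - s
            gc = kmers.gc_count(np.arange(kmers.n_kmers(size)), size)
            tables.append(float(factor) ** gc)
        return cls.factorized(PPIScales(layout, tables))

    def weight_of(self, kmer: str) -> float:
        return float(self.weights[kmers.kmer_to_index(kmer)])

    def to_csv(self, path) -> None:
        names = kmers.indices_to_kmers(np.arange(len(self.weights)), WINDOW_LEN)
        pd.DataFrame({"kmer": [m.decode() for m in names],
                      "weight": self.weights}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PreferenceModel":
        frame = pd.read_csv(path, dtype={"kmer": str})
        weights = np.ones(kmers.n_kmers(WINDOW_LEN))
        idx = [kmers.kmer_to_index(m) for m in frame["kmer"]]
        weights[idx] = frame["weight"].to_numpy(dtype=float)
        return cls(weights)


def simulate_inserts(n: int, distribution="uniform", rng=None, seed=None) -> np.ndarray:
    """Draw n i.i.d. 12-mer inserts as a numpy ``S12`` array."""
    if rng is None:
        rng = np.random.default_rng(seed)
    probs = _base_probs(distribution)
    codes = rng.choice(4, size=(int(n), INSERT_LEN), p=probs).astype(np.uint8)
    return kmers.codes_to_seqs(codes)


def _random_filler(n_reads: int, length: int, rng) -> list[str]:
    if length == 0:
        return [""] * n_reads
    codes = rng.choice(4, size=(n_reads, length)).astype(np.uint8)
    return [s.decode() for s in kmers.codes_to_seqs(codes)]


def _assemble_reads(inserts: np.ndarray, design: LibraryDesign, barcode: str,
                    sample: str, rng, substitution_rate: float = 0.0) -> list[ReadRecord]:
    filler = _random_filler(len(inserts), design.barcode_offset, rng)
    reads = []
    for i, insert in enumerate(inserts):
        seq = f"{filler[i]}{barcode}{design.left_anchor}{insert.decode()}{design.right_anchor}"
        reads.append(ReadRecord(id=f"{sample}_{i}", seq=seq))
    if substitution_rate > 0:
        reads = inject_errors(reads, substitution_rate, rng)
    return reads


def simulate_sl(config: SimConfig, sample: str = "SL",
                substitution_rate: float = 0.0) -> list[ReadRecord]:
    """Simulate the unamplified synthetic library for one barcoded sample."""
    rng = np.random.default_rng(config.seed)
    inserts = simulate_inserts(config.n_sl_reads, config.insert_distribution, rng=rng)
    return _assemble_reads(inserts, config.design, config.barcodes[sample],
                           sample, rng, substitution_rate)


def simulate_amplified_inserts(sl_inserts, model: PreferenceModel,
                               n_amp_reads: int, seed=None, rng=None) -> np.ndarray:
    """Resample SL inserts under the preference model.

    Each amplified read is drawn (multinomially, with replacement) from
    the SL insert pool with probability proportional to the model weight
    of the insert's 8 bp junction motif.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    inserts = np.asarray(sl_inserts, dtype=f"S{INSERT_LEN}")
    n_amp_reads = int(n_amp_reads)
    if n_amp_reads < 0:
        raise ValueError("n_amp_reads must be non-negative")
    if n_amp_reads == 0:
        return inserts[:0]
    if inserts.size == 0:
        raise ValueError("cannot amplify from an empty SL insert pool")
    codes = kmers.seqs_to_code_matrix(inserts)
    idx, valid = kmers.codes_to_indices(codes, 0, WINDOW_LEN)
    if not valid.all():
        raise ValueError("SL inserts must be 12-mers over ACGT to be amplified")
    w = model.weights[idx]
    counts = rng.multinomial(n_amp_reads, w / w.sum())
    return np.repeat(inserts, counts)


def simulate_amplified(sl_inserts, model: PreferenceModel, n_amp_reads: int,
                       seed=None, design: LibraryDesign | None = None,
                       barcode: str = DEFAULT_BARCODES["amp1"],
                       sample: str = "amp1",
                       substitution_rate: float = 0.0) -> list[ReadRecord]:
    """Simulate reads of the PCR-amplified library (see
    :func:`simulate_amplified_inserts` for the resampling model)."""
    rng = np.random.default_rng(seed)
    design = design or LibraryDesign()
    amplified = simulate_amplified_inserts(sl_inserts, model, n_amp_reads, rng=rng)
    return _assemble_reads(amplified, design, barcode, sample, rng, substitution_rate)


def inject_errors(reads: list[ReadRecord], rate: float, rng) -> list[ReadRecord]:
    """Apply uniform random substitutions at the given per-base rate."""
    if not 0 <= rate <= 1:
        raise ValueError("substitution rate must lie in [0, 1]")
    out = []
    alphabet = "ACGT"
    for read in reads:
        hits = np.nonzero(rng.random(len(read.seq)) < rate)[0]
        if hits.size == 0:
            out.append(read)
            continue
        seq = list(read.seq)
        for pos in hits:
            choices = [b for b in alphabet if b != seq[pos]]
            seq[pos] = choices[rng.integers(3)]
        out.append(ReadRecord(id=read.id, seq="".join(seq)))
    return out
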