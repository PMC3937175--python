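"""Observed-bias-value (OBV) quantification over observation windows.

The 12 nt random insert is analyzed through four fixed observation
windows: the 6 bp primer:template duplex (insert positions [0, 6)), the
4 bp single-stranded "runway" just downstream ([6, 10)), and the combined
8 bp ([0, 8)) and 10 bp ([0, 10)) views.  For each window, motif counts in
an amplified sample are scaled to the sequencing depth of the unamplified
background library and divided by the background counts:

    OBV(m) = NR_PCR(m) / SR_SL(m),   NR_PCR(m) = count(m) * N_bg / N_sample

so OBV == 1 for every motif means unbiased amplification; OBV == 2 means
the motif was amplified to twice its background representation.

Counts are held as dense numpy vectors over the full 4**k motif universe,
indexed by the lexicographic motif code of :mod:`primebias.kmers`.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import kmers

INSERT_LEN = 12


@dataclass(frozen=True)
class WindowSpec:
    """A 0-based half-open slice of the 12-mer insert."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end <= INSERT_LEN):
            raise ValueError(f"window [{self.start},{self.end}) outside the {INSERT_LEN}-mer insert")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def n_motifs(self) -> int:
        return kmers.n_kmers(self.size)


#: the four observation windows; w10 is defined but needs far deeper
#: sequencing than the others for stable per-motif counts (4**10 motifs)
WINDOWS: dict[str, WindowSpec] = {
    "w4": WindowSpec("w4", 6, 10),
    "w6": WindowSpec("w6", 0, 6),
    "w8": WindowSpec("w8", 0, 8),
    "w10": WindowSpec("w10", 0, 10),
}

#: dimer/trimer slots within the 8 bp window used in enrichment reports
#: (0-based start of the slot; primer 3' end = window positions 4-5)
PRIMER5_DIMER_START = 0
PRIMER3_TRIMER_START = 3
PRIMER3_DIMER_START = 4
RUNWAY_DIMER_START = 6

GC_DIMERS = ("GC", "CG")


def get_window(name: str) -> WindowSpec:
    try:
        return WINDOWS[name]
    except KeyError:
        raise KeyError(f"unknown window {name!r}; expected one of {sorted(WINDOWS)}") from None


def _check_motif_lengths(frame: pd.DataFrame, window: WindowSpec, path) -> None:
    if len(frame) and not (frame["motif"].str.len() == window.size).all():
        raise ValueError(
            f"{path}: motif lengths do not match the {window.size} bp window {window.name}")


@dataclass
class MotifCountTable:
    """Motif counts for one sample and one observation window.

    ``counts`` is dense over the full motif universe (lexicographic motif
    index); ``n_rejected`` counts inserts dropped for N bases or wrong
    length.
    """

    window: WindowSpec
    counts: np.ndarray
    n_rejected: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.window.n_motifs,):
            raise ValueError("counts length must equal the window motif universe 4**k")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count(self, motif: str) -> int:
        if len(motif) != self.window.size:
            raise ValueError(f"motif {motif!r} has wrong length for window {self.window.name}")
        return int(self.counts[kmers.kmer_to_index(motif)])

    def to_dict(self) -> dict[str, int]:
        """Nonzero counts keyed by motif string."""
        nz = np.nonzero(self.counts)[0]
        names = kmers.indices_to_kmers(nz, self.window.size)
        return {name.decode(): int(c) for name, c in zip(names, self.counts[nz])}

    def to_csv(self, path, nonzero_only: bool = False) -> None:
        idx = np.nonzero(self.counts)[0] if nonzero_only else np.arange(self.window.n_motifs)
        frame = pd.DataFrame({
            "motif": [m.decode() for m in kmers.indices_to_kmers(idx, self.window.size)],
            "count": self.counts[idx],
        })
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window: WindowSpec) -> "MotifCountTable":
        frame = pd.read_csv(path, dtype={"motif": str})
        _check_motif_lengths(frame, window, path)
        counts = np.zeros(window.n_motifs, dtype=np.int64)
        idx = [kmers.kmer_to_index(m) for m in frame["motif"]]
        counts[idx] = frame["count"].to_numpy()
        return cls(window, counts)


def count_windows(inserts, window: WindowSpec) -> MotifCountTable:
    """Tally window motifs over a collection of 12-mer inserts.

    ``inserts`` is a numpy ``S12`` array or an iterable of strings.
    Inserts containing N (or any non-ACGT base) or not exactly 12 bases
    long are rejected and reported via ``n_rejected``.
    """
    codes = kmers.seqs_to_code_matrix(inserts)
    if codes.shape[0] == 0:
        return MotifCountTable(window, np.zeros(window.n_motifs, dtype=np.int64))
    width = codes.shape[1]
    if width < INSERT_LEN:
        # every insert is shorter than 12: all rejected
        return MotifCountTable(window, np.zeros(window.n_motifs, dtype=np.int64),
                               n_rejected=codes.shape[0])
    valid = (codes[:, :INSERT_LEN] != kmers.INVALID).all(axis=1)
    if width > INSERT_LEN:
        # fixed-width storage pads short entries with NUL; anything non-NUL
        # past position 12 marks an over-long insert
        valid &= (codes[:, INSERT_LEN:] == kmers.INVALID).all(axis=1)
        arr = np.asarray(inserts, dtype=bytes)
        lengths = np.char.str_len(arr)
        valid &= lengths == INSERT_LEN
    idx, _ = kmers.codes_to_indices(codes[:, :INSERT_LEN], window.start, window.end)
    counts = np.bincount(idx[valid], minlength=window.n_motifs)
    return MotifCountTable(window, counts, n_rejected=int((~valid).sum()))


def _normalized_array(sample: MotifCountTable, background: MotifCountTable) -> np.ndarray:
    if sample.window != background.window:
        raise ValueError("sample and background must use the same observation window")
    if sample.total == 0:
        raise ValueError("sample has zero total count; cannot normalize")
    return sample.counts * (background.total / sample.total)


def normalize_counts(sample: MotifCountTable, background: MotifCountTable) -> pd.Series:
    """Depth-normalized sample counts NR(m) = count(m) * N_bg / N_sample.

    Values are kept as reals (no rounding); their sum equals the
    background total exactly up to floating-point error.
    """
    nr = _normalized_array(sample, background)
    names = [m.decode() for m in kmers.indices_to_kmers(np.arange(sample.window.n_motifs),
                                                        sample.window.size)]
    return pd.Series(nr, index=names, name="normalized_count")


@dataclass
class OBVTable:
    """Per-motif observed bias values against a background sample.

    Motifs absent from the background carry no OBV (NaN in ``obv``,
    flagged False in ``scored``) and are reported separately; motifs
    present in the background but absent from the sample score exactly 0.
    """

    window: WindowSpec
    obv: np.ndarray
    scored: np.ndarray
    background_total: int
    sample_total: int

    @property
    def n_scored(self) -> int:
        return int(self.scored.sum())

    @property
    def background_zero(self) -> np.ndarray:
        """Motif indices excluded because the background count was zero."""
        return np.nonzero(~self.scored)[0]

    def value(self, motif: str) -> float:
        idx = kmers.kmer_to_index(motif)
        if not self.scored[idx]:
            raise KeyError(f"motif {motif!r} has zero background count and is not scored")
        return float(self.obv[idx])

    def to_frame(self) -> pd.DataFrame:
        idx = np.nonzero(self.scored)[0]
        return pd.DataFrame({
            "motif": [m.decode() for m in kmers.indices_to_kmers(idx, self.window.size)],
            "obv": self.obv[idx],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window: WindowSpec) -> "OBVTable":
        frame = pd.read_csv(path, dtype={"motif": str})
        _check_motif_lengths(frame, window, path)
        obv = np.full(window.n_motifs, np.nan)
        scored = np.zeros(window.n_motifs, dtype=bool)
        idx = np.array([kmers.kmer_to_index(m) for m in frame["motif"]], dtype=np.int64)
        obv[idx] = frame["obv"].to_numpy(dtype=float)
        scored[idx] = True
        return cls(window, obv, scored, background_total=0, sample_total=0)

    @classmethod
    def from_values(cls, window: WindowSpec, values: np.ndarray) -> "OBVTable":
        """Wrap a dense per-motif value vector as a fully scored table."""
        values = np.asarray(values, dtype=float)
        if values.shape != (window.n_motifs,):
            raise ValueError("values length must equal the window motif universe")
        return cls(window, values, np.ones(window.n_motifs, dtype=bool),
                   background_total=0, sample_total=0)


def compute_obv(sample: MotifCountTable, background: MotifCountTable) -> OBVTable:
    """OBV(m) = normalized sample count / background count, per motif."""
    nr = _normalized_array(sample, background)
    scored = background.counts > 0
    obv = np.full(sample.window.n_motifs, np.nan)
    obv[scored] = nr[scored] / background.counts[scored]
    return OBVTable(sample.window, obv, scored,
                    background_total=background.total, sample_total=sample.total)


def rank_motifs(obv: OBVTable) -> pd.DataFrame:
    """Motifs by descending OBV; ties broken lexicographically; ranks 1..n."""
    idx = np.nonzero(obv.scored)[0]
    values = obv.obv[idx]
    # lexsort: last key is primary; motif index IS lexicographic order
    order = np.lexsort((idx, -values))
    idx, values = idx[order], values[order]
    return pd.DataFrame({
        "motif": [m.decode() for m in kmers.indices_to_kmers(idx, obv.window.size)],
        "obv": values,
        "rank": np.arange(1, len(idx) + 1),
    })


def top_fraction(ranked: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """The first floor(fraction * n) rows of a ranked motif table."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return ranked.head(math.floor(fraction * len(ranked))).copy()


def motif_enrichment(subset, kmer_set, start: int) -> float:
    """Percent of motifs matching any k-mer of ``kmer_set`` at a fixed slot.

    ``subset`` is a collection of equal-length motif strings (e.g. the
    ``motif`` column of a top-fraction table); ``start`` is the 0-based
    slot position within the motif.  All k-mers in ``kmer_set`` must share
    one length.
    """
    motifs = list(subset)
    if not motifs:
        raise ValueError("cannot compute enrichment of an empty motif set")
    patterns = {p.upper() for p in kmer_set}
    klens = {len(p) for p in patterns}
    if len(klens) != 1:
        raise ValueError("pattern k-mers must all have the same length")
    k = klens.pop()
    if start < 0 or start + k > len(motifs[0]):
        raise ValueError(f"pattern slot [{start},{start + k}) falls outside the motif")
    hits = sum(1 for m in motifs if m[start:start + k] in patterns)
    return 100.0 * hits / len(motifs)


CorrelationResult = namedtuple("CorrelationResult", ["pearson_r", "r_squared", "p_value", "n"])


def correlate_obv(a: OBVTable, b: OBVTable) -> CorrelationResult:
    """Pearson correlation of raw OBVs over motifs scored in both tables.

    The p-value is the two-sided t test with n-2 degrees of freedom.
    """
    if a.window != b.window:
        raise ValueError("OBV tables must share the observation window")
    both = a.scored & b.scored
    n = int(both.sum())
    if n < 3:
        raise ValueError(f"need at least 3 co-scored motifs, got {n}")
    r, p = stats.pearsonr(a.obv[both], b.obv[both])
    return CorrelationResult(float(r), float(r) ** 2, float(p), n)


_ATCG_RANK = {"A": 0, "T": 1, "C": 2, "G": 3}


def gc_order(motifs) -> list[str]:
    """Sort motifs by ascending GC count, then lexicographically in the
    A < T < C < G alphabet — the x-axis ordering of bias profiles."""
    def key(m: str):
        return (sum(b in "GC" for b in m), tuple(_ATCG_RANK[b] for b in m))
    return sorted(motifs, key=key)


def mean_gc_percent(motifs) -> float:
    """Average GC content of a motif collection, in percent."""
    motifs = list(motifs)
    if not motifs:
        raise ValueError("empty motif collection")
    total = sum(sum(b in "GC" for b in m) for m in motifs)
    return 100.0 * total / sum(len(m) for m in motifs)
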