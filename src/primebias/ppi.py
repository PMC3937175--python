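"""Polymerase preference index (PPI): positional scale fitting and
sliding-window template scoring.

The PPI of a template position is the product of four positional scale
lookups inside an 8 bp window around the primer:template junction — one
dimeric scale (DiSc) and three trimeric scales (TrSc), each keyed by the
k-mer occupying its section of the window.  The product is assigned to
the 6th window position (0-based index 5), i.e. the base that would pair
with the primer's 3' end, and the window slides 1 bp toward 3' until the
template is exhausted.  High PPI marks favorable primer 3'-end placement;
local minima should be avoided.

Scales are estimated from an 8-mer OBV table.  Because the default
sections overlap (an 8 bp window cannot be tiled by one dimer plus three
trimers), the per-section decomposition of a multiplicative preference is
only identifiable up to a gauge: a function of a shared base can move
freely between the two sections sharing it.  Fitting is therefore done as
a log-domain least-squares over section-kmer indicators — which reduces
to a per-section geometric mean of OBVs when sections are disjoint —
followed by a canonical gauge (shared-base dependence pushed into the
5'-most section of each overlapping pair) and per-section geometric-mean-1
normalization.  Window-level PPI values are gauge-invariant.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse, stats

from . import kmers
from .biasquant import OBVTable

WINDOW_LEN = 8
#: the scored base within the window: primer 3' end, 0-based window index 5
SCORED_OFFSET = 5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SectionLayout:
    """Ordered 0-based half-open sections of the 8 bp window:
    exactly one dimer and three trimers whose union covers [0, 8)."""

    sections: tuple = ((0, 3), (2, 5), (4, 7), (6, 8))

    def __post_init__(self):
        sections = tuple(sorted((int(s), int(e)) for s, e in self.sections))
        object.__setattr__(self, "sections", sections)
        sizes = sorted(e - s for s, e in sections)
        if sizes != [2, 3, 3, 3]:
            raise ValueError("layout needs exactly one dimer and three trimer sections")
        covered = set()
        for s, e in sections:
            if not 0 <= s < e <= WINDOW_LEN:
                raise ValueError(f"section [{s},{e}) falls outside the 8 bp window")
            covered.update(range(s, e))
        if covered != set(range(WINDOW_LEN)):
            raise ValueError("sections must jointly cover all 8 window positions")

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    def section_sizes(self) -> list[int]:
        return [e - s for s, e in self.sections]


DEFAULT_LAYOUT = SectionLayout()


def _as_table(size: int, values) -> np.ndarray:
    n = kmers.n_kmers(size)
    if isinstance(values, dict):
        table = np.ones(n, dtype=float)
        for kmer, value in values.items():
            table[kmers.kmer_to_index(kmer)] = value
        return table
    table = np.asarray(values, dtype=float)
    if table.shape != (n,):
        raise ValueError(f"scale table must have 4**{size} entries")
    return table


@dataclass
class PPIScales:
    """Positional scale tables, one per layout section.

    ``tables[i]`` is dense over the 4**len k-mer universe of section i
    (sections in layout order).  All values must be positive.
    ``n_imputed`` records how many 8-mers were missing or zero in the OBV
    the scales were fitted from (imputed to the neutral value 1).
    """

    layout: SectionLayout
    tables: list
    n_imputed: int = 0

    def __post_init__(self):
        sizes = self.layout.section_sizes()
        if len(self.tables) != len(sizes):
            raise ValueError("one table required per layout section")
        self.tables = [_as_table(size, t) for size, t in zip(sizes, self.tables)]
        for table in self.tables:
            if not (table > 0).all():
                raise ValueError("all scale values must be positive")

    @classmethod
    def uniform(cls, layout: SectionLayout = DEFAULT_LAYOUT) -> "PPIScales":
        return cls(layout, [np.ones(kmers.n_kmers(e - s)) for s, e in layout.sections])

    @property
    def disc(self) -> np.ndarray:
        """The dimeric scale table."""
        i = self.layout.section_sizes().index(2)
        return self.tables[i]

    @property
    def trsc(self) -> list:
        """The three trimeric scale tables, 5' to 3'."""
        return [t for t, size in zip(self.tables, self.layout.section_sizes()) if size == 3]

    def value(self, section_index: int, kmer: str) -> float:
        return float(self.tables[section_index][kmers.kmer_to_index(kmer)])

    def canonicalized(self) -> "PPIScales":
        """Return the canonical-gauge representative of these scales.

        For each pair of overlapping sections (taken 5' to 3'), the
        marginal dependence of the 3' section on each shared base is
        removed and credited to the 5' section; every table is then
        rescaled to geometric mean 1.  Window PPI values change only by a
        single global constant (which the normalization fixes).
        """
        logs = [np.log(t) for t in self.tables]
        sections = self.layout.sections
        for j in range(1, len(sections)):
            sj, ej = sections[j]
            for i in range(j):
                si, ei = sections[i]
                for p in range(max(si, sj), min(ei, ej)):  # shared absolute positions
                    base_j = kmers.section_indices(
                        np.arange(len(logs[j])), ej - sj, p - sj, p - sj + 1)
                    base_i = kmers.section_indices(
                        np.arange(len(logs[i])), ei - si, p - si, p - si + 1)
                    marg = np.array([logs[j][base_j == b].mean() for b in range(4)])
                    logs[j] -= marg[base_j]
                    logs[i] += marg[base_i]
        logs = [lg - lg.mean() for lg in logs]
        return PPIScales(self.layout, [np.exp(lg) for lg in logs], n_imputed=self.n_imputed)

    def window_values(self, window_indices=None) -> np.ndarray:
        """PPI of each 8 bp window, as the product of its section lookups.

        With no argument, returns the dense table over all 4**8 windows.
        """
        if window_indices is None:
            window_indices = np.arange(kmers.n_kmers(WINDOW_LEN))
        idx = np.asarray(window_indices, dtype=np.int64)
        out = np.ones(idx.shape, dtype=float)
        for (s, e), table in zip(self.layout.sections, self.tables):
            out *= table[kmers.section_indices(idx, WINDOW_LEN, s, e)]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ((s, e), table) in enumerate(zip(self.layout.sections, self.tables)):
            names = kmers.indices_to_kmers(np.arange(len(table)), e - s)
            rows.append(pd.DataFrame({
                "section_index": i, "start": s, "end": e,
                "kmer": [m.decode() for m in names], "scale": table,
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PPIScales":
        frame = pd.read_csv(path, dtype={"kmer": str})
        sections = []
        tables = []
        for i, group in frame.groupby("section_index", sort=True):
            s, e = int(group["start"].iloc[0]), int(group["end"].iloc[0])
            sections.append((s, e))
            table = np.ones(kmers.n_kmers(e - s))
            for kmer, scale in zip(group["kmer"], group["scale"]):
                table[kmers.kmer_to_index(kmer)] = scale
            tables.append(table)
        return cls(SectionLayout(tuple(sections)), tables)


def fit_scales(obv: OBVTable, layout: SectionLayout = DEFAULT_LAYOUT) -> PPIScales:
    """Estimate positional scales from an 8-mer OBV table.

    Solves the log-domain least-squares problem
    ``log OBV(m) ≈ Σ_sections log scale(section, m|section)`` over all
    4**8 windows, then canonicalizes the gauge and normalizes each table
    to geometric mean 1.  Missing or zero-OBV motifs are imputed to the
    neutral OBV 1 and counted in ``n_imputed``.
    """
    if obv.window.size != WINDOW_LEN:
        raise ValueError("scale fitting requires the 8 bp observation window")
    n = kmers.n_kmers(WINDOW_LEN)
    usable = obv.scored.copy()
    usable[usable] = obv.obv[usable] > 0
    if not usable.any():
        raise ValueError("OBV table has no positive scored motifs")
    y = np.zeros(n)
    y[usable] = np.log(obv.obv[usable])
    n_imputed = int(n - usable.sum())

    rows = np.arange(n)
    blocks = []
    for s, e in layout.sections:
        cols = kmers.section_indices(rows, WINDOW_LEN, s, e)
        blocks.append(sparse.csr_matrix(
            (np.ones(n), (rows, cols)), shape=(n, kmers.n_kmers(e - s))))
    design = sparse.hstack(blocks, format="csr")
    # the design is rank-deficient (gauge freedom between overlapping
    # sections); LSQR converges to the minimum-norm least-squares solution
    # and the canonical gauge below removes the remaining ambiguity
    x = sparse.linalg.lsqr(design, y, atol=1e-12, btol=1e-12, iter_lim=2000)[0]

    tables = []
    offset = 0
    for s, e in layout.sections:
        width = kmers.n_kmers(e - s)
        tables.append(np.exp(x[offset:offset + width]))
        offset += width
    return PPIScales(layout, tables, n_imputed=n_imputed).canonicalized()


@dataclass
class PPIProfile:
    """Per-position PPI values along one strand of a template.

    ``values[i]`` is the PPI assigned to 1-based template position i+1;
    NaN where no full 8 bp window fits (near the ends) or the window
    contains a non-ACGT base.  Antisense profiles are computed on the
    reverse complement and stored in input-template coordinates; ``base``
    columns always show the input (sense) template base.
    """

    template_id: str
    strand: str
    template: str
    values: np.ndarray
    maxima: list | None = None
    minima: list | None = None
    suggested_site: int | None = None

    @property
    def defined_positions(self) -> np.ndarray:
        """1-based positions with a defined PPI."""
        return np.nonzero(~np.isnan(self.values))[0] + 1

    def to_frame(self) -> pd.DataFrame:
        n = len(self.template)
        maxima = set(self.maxima or ())
        minima = set(self.minima or ())
        return pd.DataFrame({
            "position": np.arange(1, n + 1),
            "base": list(self.template),
            "strand": self.strand,
            "ppi": self.values,
            "is_max": [p in maxima for p in range(1, n + 1)],
            "is_min": [p in minima for p in range(1, n + 1)],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _score_one_strand(seq: str, scales: PPIScales) -> np.ndarray:
    codes = kmers.seq_to_codes(seq)
    n = len(seq)
    values = np.full(n, np.nan)
    if n < WINDOW_LEN:
        return values
    windows = np.lib.stride_tricks.sliding_window_view(codes, WINDOW_LEN)
    valid = (windows != kmers.INVALID).all(axis=1)
    weights = (4 ** np.arange(WINDOW_LEN - 1, -1, -1)).astype(np.int64)
    idx = (windows.astype(np.int64) * weights).sum(axis=1)
    ppi = np.full(len(idx), np.nan)
    if valid.any():
        ppi[valid] = scales.window_values(idx[valid])
    values[SCORED_OFFSET:SCORED_OFFSET + len(idx)] = ppi
    return values


def score_template(template: str, scales: PPIScales, strand: str = "both",
                   template_id: str = "template"):
    """Slide the 8 bp window along a template and assign PPI values.

    ``strand`` is ``"sense"``, ``"antisense"`` or ``"both"``; with
    ``"both"`` a (sense, antisense) pair is returned.  Templates shorter
    than 8 bases are an error; windows containing N score as undefined.
    """
    template = template.upper()
    if len(template) < WINDOW_LEN:
        raise ValueError(f"template must be at least {WINDOW_LEN} bases long")
    if strand not in ("sense", "antisense", "both"):
        raise ValueError("strand must be sense, antisense or both")
    results = []
    if strand in ("sense", "both"):
        results.append(PPIProfile(template_id, "sense", template,
                                  _score_one_strand(template, scales)))
    if strand in ("antisense", "both"):
        rc_values = _score_one_strand(revcomp(template), scales)
        results.append(PPIProfile(template_id, "antisense", template, rc_values[::-1].copy()))
    return tuple(results) if strand == "both" else results[0]


def call_extrema(profile: PPIProfile) -> PPIProfile:
    """Annotate a profile with local extrema.

    Extrema are called by strict comparison against the nearest defined
    neighbors within each contiguous defined run; a plateau reports its
    leftmost position; a missing neighbor (run boundary) counts as
    satisfied.  The global maximum is flagged as the suggested primer
    3'-end site.
    """
    defined = ~np.isnan(profile.values)
    if defined.sum() < 3:
        raise ValueError("extrema calling needs at least 3 defined PPI positions")
    maxima: list[int] = []
    minima: list[int] = []
    n = len(profile.values)
    i = 0
    while i < n:
        if not defined[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and defined[j + 1]:
            j += 1
        _run_extrema(profile.values, i, j, maxima, minima)
        i = j + 1
    finite = np.nan_to_num(profile.values, nan=-np.inf)
    suggested = int(np.argmax(finite)) + 1
    return replace(profile, maxima=maxima, minima=minima, suggested_site=suggested)


def _run_extrema(values: np.ndarray, start: int, end: int,
                 maxima: list, minima: list) -> None:
    """Scan one contiguous run [start, end] (inclusive, all defined)."""
    if end == start:
        return  # an isolated point has no comparable neighbor
    pos = start
    while pos <= end:
        plateau_start = pos
        while pos + 1 <= end and values[pos + 1] == values[plateau_start]:
            pos += 1
        left_ok_max = plateau_start == start or values[plateau_start - 1] < values[plateau_start]
        right_ok_max = pos == end or values[pos + 1] < values[plateau_start]
        left_ok_min = plateau_start == start or values[plateau_start - 1] > values[plateau_start]
        right_ok_min = pos == end or values[pos + 1] > values[plateau_start]
        whole_run = plateau_start == start and pos == end
        if not whole_run:  # a constant run is neither max nor min
            if left_ok_max and right_ok_max:
                maxima.append(plateau_start + 1)  # leftmost, 1-based
            if left_ok_min and right_ok_min:
                minima.append(plateau_start + 1)
        pos += 1


PredictObservedResult = namedtuple("PredictObservedResult", ["pearson_r", "r_squared", "n"])


def predict_vs_observed(scales: PPIScales, obv: OBVTable) -> PredictObservedResult:
    """Correlate model PPI with observed bias, motif by motif.

    Accepts the 8 bp window directly; for the 6 bp window the PPI of a
    hexamer is the mean model PPI over its 16 runway completions
    (matching how a 6-mer OBV marginalizes a uniform background).  The
    correlation is computed between log(PPI) and log(OBV) — both are
    ratio-scaled, multiplicative quantities.  A zero-variance input
    (e.g. OBV identically 1) yields NaN correlation with n reported.
    """
    full = scales.window_values()
    if obv.window.size == WINDOW_LEN:
        ppi = full
    elif obv.window.size == 6 and obv.window.start == 0:
        ppi = full.reshape(kmers.n_kmers(6), kmers.n_kmers(2)).mean(axis=1)
    else:
        raise ValueError("predict_vs_observed supports the w8 and w6 windows")
    usable = obv.scored.copy()
    usable[usable] = obv.obv[usable] > 0
    n = int(usable.sum())
    x = np.log(ppi[usable])
    y = np.log(obv.obv[usable])
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return PredictObservedResult(float("nan"), float("nan"), n)
    r, _ = stats.pearsonr(x, y)
    return PredictObservedResult(float(r), float(r) ** 2, n)
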