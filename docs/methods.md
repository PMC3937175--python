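# Methods

## The system being modeled

A synthetic library (SL) presents every possible 12 nt sequence as
template: each construct is `barcode (4 bp) · left anchor · 12N insert ·
right anchor`, sequenced directly (no amplification) to give a bias-free
background. Amplifying the SL with a primer whose 3' end is a random
hexamer forces the polymerase to initiate on every possible junction, so
comparing amplified read counts with the background isolates the
polymerase's sequence preference at initiation. The first six insert bases
form the primer:template duplex; the following four single-stranded bases
are the "runway" the polymerase faces immediately after the junction.

## Observed bias value

Counts are tallied per motif through four fixed observation windows of the
insert (0-based half-open): `w6 = [0, 6)` (duplex), `w4 = [6, 10)`
(runway), `w8 = [0, 8)` and `w10 = [0, 10)`. Depth normalization is
proportional total-count scaling, `NR(m) = count_s(m) · N_bg / N_s`, kept
as reals; this is the only normalization under which a sample compared
with itself gives OBV exactly 1 for every motif and the worked example
(background 10, normalized sample 20 → OBV 2) holds. The w10 window is
implemented but needs ~4¹⁰ motifs of coverage; the `quantify` command
flags it as low-confidence.

Motifs with zero background count cannot be scored (division by zero);
they are excluded from the OBV table and reported separately
(`OBVTable.background_zero`). Motifs absent from the sample but present in
the background score exactly 0. Ranking is by descending OBV with
lexicographic tie-breaking for determinism; `top_fraction(r, f)` takes the
first ⌊f·n⌋ entries. Between-sample correlations are Pearson on raw OBVs
over motifs scored in both tables, with the two-sided t test (n−2 df) for
the p-value.

Runway motifs are stored in sense-strand 5'→3' orientation throughout;
any report quoting template 3'→5' runway motifs must state the
orientation explicitly.

## The simulator

Amplification is modeled as one effective per-molecule weight rather than
cycle-by-cycle branching: amplified reads are a multinomial resample of
the SL insert pool with probability proportional to `weight(junction
8-mer)`, where the junction window is insert positions `[0, 8)` (the
primer's 3' hexamer plus the first two runway bases). End-point libraries
cannot distinguish per-cycle efficiency *e* from the end-point weight
`(1+e)^cycles` — the mapping is monotone — so the single-weight table is
the identifiable abstraction, and the table model subsumes any per-cycle
story.

The default ground-truth preference is a *factorized* GC-favoring model:
each positional scale table multiplies in a factor of 1.3 per G/C base of
its k-mer. This strength was chosen once so that 8-mer junction weights
span roughly 0.15–6.6 — the order of spread seen in real
polymerase-preference measurements, where same-composition hexamers can
differ ten-fold in bias. Inserts are i.i.d. uniform over ACGT by default
(a skewed base distribution is available). No sequencing-error model is
applied unless a substitution rate is passed explicitly; real data would
additionally carry quality-dependent, context-dependent errors that break
exact anchor matching, so extraction failure rates on real reads will be
higher than the simulator's zero.

All entry points take explicit seeds; the same seed reproduces output
byte-for-byte.

## PPI scales: fitting, gauge, and what is identifiable

The default section layout of the 8 bp window is trimers `[0,3)`, `[2,5)`,
`[4,7)` and the dimer `[6,8)`. One dimer plus three trimers total 11
positions, so they cannot tile 8 bp without overlap; the default overlaps
at positions 2, 4 and 6 and is configurable via `SectionLayout`. The true
section boundaries of the original primer-design service are not public;
this layout covers the 3'-hexamer and the runway entry, the two regions
with the strongest observed bias.

Scales are estimated by log-domain least squares: minimize
`Σ_m (log OBV(m) − Σ_s log scale(s, m|s))²` over all 4⁸ windows, solved by
LSQR on the sparse indicator design. For a *non-overlapping* layout this
reduces exactly to the per-section geometric mean of OBVs; for overlapping
sections the naive geometric mean double-counts shared bases (it returns
`Π b^{cov²}` instead of `Π b^{cov}` for a per-base factor model) and is
not used.

With overlapping sections, the decomposition is identifiable only up to a
gauge: any function of a shared base can move between the two sections
sharing that base, and constants can move between any sections. Fitted
scales are therefore reported in a canonical gauge — for each overlapping
pair taken 5'→3', the 3' section's marginal dependence on each shared base
is removed and credited to the 5' section — and every table is normalized
to geometric mean 1. The factorized simulator model canonicalizes its
scales the same way at construction, which makes "fitted scales equal the
injected factors" a well-posed statement. Window-level PPI values are
gauge-invariant, so template profiles do not depend on this convention.

Missing or zero-OBV 8-mers are imputed to the neutral OBV 1 and counted
(`PPIScales.n_imputed`). Fitting requires the 8 bp window.

`predict_vs_observed` correlates log(PPI) with log(OBV): both are
ratio-scaled multiplicative quantities, and on sampled data the log scale
keeps the heavy right tail of high-bias motifs from dominating the
statistic. For the 6 bp window, the model PPI of a hexamer is the
arithmetic mean over its 16 runway completions, matching how a 6-mer OBV
marginalizes an (approximately uniform) background. A zero-variance input
(e.g. OBV ≡ 1) has no defined correlation and is reported as NaN.
By contrast `correlate_obv` (sample vs sample) uses raw OBVs, the
conventional presentation for replicate-agreement scatter.

## Template scoring

`score_template` requires ≥ 8 bases; windows containing N are undefined.
The product is assigned to 1-based template position `window_start + 6`
(0-based window index 5) — the primer 3'-end base. Antisense profiles are
computed on the reverse complement and reported in input-template
coordinates; the defined positions of the two strands differ accordingly
(sense: 6 … L−2; antisense: 3 … L−5, 1-based). Extrema are called by
strict comparison against the nearest differing neighbors within each
contiguous defined run; plateaus report their leftmost position; a missing
neighbor at a run boundary counts as satisfied (so a monotone profile has
its maximum at the last defined position); a fully constant run has no
extrema; the global maximum is flagged as the suggested primer 3'-end
site. Isolated single defined positions are not called.

## Study conditions used by tests and the acceptance script

Deep-simulation checks run at the depths a single sequencing lane would
allot one barcode: a uniform SL of 2·10⁶ inserts and amplified replicates
of 2·10⁶ reads each, under the default GC-favoring model. At that depth
the package's own measurements give between-replicate 6-mer OBV R² ≈ 0.98,
a log OBV vs log injected-weight slope of ≈ 1.02 (zero-count motifs,
whose log OBV is undefined, are excluded — a handful out of 65,536), and
worst-case positional-scale recovery error of ≈ 2–4 % relative. The small
positive slope excess is the expected convexity bias of log counts at ~30
reads per 8-mer and shrinks with depth. Smaller examples use 5·10⁵ reads.

Stochastic test tolerances are 3–5 σ bands computed from the binomial or
Poisson sampling model of the quantity under test, at the stated depths.

## Limitations

- Barcode and anchor matching are exact; error-broken reads are dropped
  with reason codes rather than rescued. Mismatch-tolerant matching is a
  deliberate non-goal for 4 bp barcodes.
- The simulator's single-weight abstraction cannot represent
  cycle-dependent phenomena (plateau effects, template switching,
  chimeras) or thermodynamic annealing competition.
- Fitted scales describe whatever polymerase/buffer produced the OBV table
  they were trained on; they do not transfer across polymerase families,
  whose preferences are known to differ strongly.
- Melting temperature, GC%, hairpin and dimer screening of candidate
  primers are out of scope; PPI ranks positions only by initiation
  preference.
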