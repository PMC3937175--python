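# primebias

Tools for characterizing and exploiting DNA polymerase priming bias.

PCR introduces sequence-dependent bias, and a major source is the
polymerase itself: during initiation, the enzyme's grip on the
primer:template junction makes some junction motifs amplify far more
efficiently than others. `primebias` implements the full desk-side stack
for studying this effect:

- **`primebias.simulate`** — a synthetic-library read simulator with an
  injectable, ground-truth polymerase preference. The synthetic library
  (SL) is a pool of constructs carrying a 12 nt fully random insert
  between fixed anchors behind a 4 bp sample barcode; amplification with a
  random-3'-hexamer primer is modeled by resampling SL molecules with
  probability proportional to the preference weight of the 8 bp motif at
  the primer:template junction.
- **`primebias.seqio`** — FASTA/FASTQ IO, exact-match barcode
  demultiplexing, and anchored extraction of the random insert with
  per-read failure reason codes.
- **`primebias.biasquant`** — observed bias values (OBV) over sliding
  observation windows, motif ranking, top-fraction selection, positional
  motif enrichment, GC-ordered profiles and between-sample correlations.
- **`primebias.ppi`** — the polymerase preference index (PPI): positional
  dimer/trimer scales fitted from an 8-mer OBV table, and sliding-window
  scoring of arbitrary templates to guide primer 3'-end placement.
- **`primebias.cli`** — `primebias simulate | quantify | fit-scales | score`.

## The model

The 12 nt random insert is viewed through four observation windows
(0-based, half-open slices of the insert): the 6 bp primer:template duplex
`[0, 6)`, the 4 bp single-stranded "runway" `[6, 10)` just downstream of
the junction, and the combined 8 bp `[0, 8)` and 10 bp `[0, 10)` windows.

For a window motif *m*, with `N_bg` and `N_s` the total read counts of the
unamplified background and the amplified sample,

```
NR(m)  = count_s(m) · N_bg / N_s          (depth normalization)
OBV(m) = NR(m) / count_bg(m)              (observed bias value)
```

OBV = 1 for every motif means unbiased amplification; a motif with 10
background reads whose normalized sample count is 20 has OBV = 2.

The PPI of a template position is a product of four positional scale
lookups inside the 8 bp window around the junction — one dimeric scale
(DiSc) and three trimeric scales (TrSc) — assigned to the 6th window
position (the base pairing with the primer's 3' end):

```
PPI(w) = DiSc(w[6:8]) · TrSc1(w[0:3]) · TrSc2(w[2:5]) · TrSc3(w[4:7])
```

The window slides 1 bp toward 3' across the template (both strands);
local maxima of the profile are favorable primer 3'-end sites. Scales are
fitted from an 8-mer OBV table by a log-domain least squares over
section-kmer indicators, with overlap ambiguity resolved by a canonical
gauge and each scale table normalized to geometric mean 1 (see
`docs/methods.md`).

## Worked example

```python
import primebias as pb

model = pb.PreferenceModel.gc_favoring(1.3)          # ground truth
sl = pb.simulate_inserts(500_000, seed=11)           # unamplified background
amp = pb.simulate_amplified_inserts(sl, model, 500_000, seed=12)

w6 = pb.WINDOWS["w6"]
obv = pb.compute_obv(pb.count_windows(amp, w6), pb.count_windows(sl, w6))
ranked = pb.rank_motifs(obv)
print(ranked.head(3))
```

prints

```
 motif      obv  rank
GCCGGC 2.930769     1
GCGCGC 2.907563     2
GCCCGG 2.892308     3
```

GC-rich junction hexamers amplified to nearly three times their background
share, while the weakest motifs (`ATAATC`, OBV 0.24) were suppressed
four-fold — the injected GC preference read back out of the sequence data.
The same run gives 42.5 % GC/CG dimers at the primer 3'-end slot among the
top 1 % of ranked motifs, against a 12.5 % combinatorial background. See
`examples/` for complete scripts, including scale fitting and template
scoring (`examples/02_fit_scales_and_score_template.py` suggests position
12 on the sense strand of its demo template, PPI 3.26).

The same pipeline is available from the shell:

```
primebias simulate --out-dir sim --seed 3 --n-sl 100000 --n-amp 100000
primebias quantify --reads sim/reads.fastq --barcodes sim/barcodes.csv \
    --design sim/design.txt --window w8 --out-dir quant
primebias fit-scales --obv quant/obv_amp1.csv --out scales.csv
primebias score --template template.fasta --scales scales.csv --out profile.csv
```

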