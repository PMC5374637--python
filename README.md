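# seqtf — time-frequency analysis of genomic sequences

`seqtf` applies the bilinear time-frequency toolbox — correlation
functions, the Wigner–Ville distribution, the ambiguity function and
kernel-smoothed (Cohen-class) distributions — directly to **non-numeric
sequences** such as DNA and protein.  Instead of mapping symbols to
numbers (which imposes a spurious ordering on an unordered alphabet), the
product inside the instantaneous correlation is replaced by an entry of a
pairwise **similarity matrix** S:

    r[n, τ] = S(x[n], y[n+τ])

For DNA the default S is the 4×4 identity over (A, C, G, T) — each
nucleotide resembles only itself; selective analyses zero out all but a
chosen subset of symbols, and protein work can load BLOSUM62/PAM250
scoring files.  Every classical bilinear transform then follows from
r[n, τ] unchanged:

| quantity | definition | reveals |
|---|---|---|
| correlation function | R(τ) = Σₙ r[n, τ] | global periodicity; maximum at τ = 0 |
| symmetry function | s(n) = Σₘ S(x[n−m], x[n+m]) | local mirror symmetry |
| spectrum | \|DFT_τ R\| | global spectral content |
| Wigner–Ville plane | row-wise DFT of r over τ | *where* a periodicity lives |
| ambiguity plane | column-wise DFT of r over n | stationarity, spectral color |
| Cohen-class plane | kernel-filtered WV | cross-term-suppressed view |

Frequencies are normalized (cycles per nucleotide): a tandem repeat of
period P produces a horizontal line in the WV plane at ν = 1/P, and
protein-coding DNA shows the classic period-3 peak at DFT index N/3.  The
package is aimed at sequence analysts who want quantitative,
position-resolved periodicity calls (tandem repeats / microsatellites,
coding bias) without committing to a numeric encoding of the sequence.

The classical indicator-sequence DNA spectrum
S[k] = Σᵢ |Uᵢ[k]|² (i ∈ {A,C,G,T}) is included as a baseline; with the
identity similarity and circular correlation the similarity-based
spectrum reproduces it **bin-for-bin exactly** (Wiener–Khinchin), which
the test suite asserts to 1e-9.

## Worked example

```python
from seqtf import *
from seqtf.core import tf_marginal_spectrum

# a microsatellite-like fixture: ACGT repeated to 1000 nt, 10% of sites
# randomly substituted
seq = synth_periodic("ACGT", 1000, substitution_rate=0.1, seed=7)

# half-lag instantaneous autocorrelation with the identity similarity,
# then the Wigner-Ville plane and its global (position-summed) spectrum
rc   = instantaneous_correlation(seq, convention="symmetric")
wv   = wigner_ville(rc)
peak = dominant_frequency(tf_marginal_spectrum(wv))
print(f"dominant frequency: {peak.freq:.4f}  (period {1/peak.freq:.1f} nt)")
for line in detect_spectral_lines(wv):
    print(f"line at nu={line.freq:.4f}  positions {line.start}..{line.end}  "
          f"period {line.period:.1f} nt  strength {line.strength:.0f}")

# a protein-coding surrogate: 500 codons with G-rich first codon position
coding = synth_coding(500, seed=7)
spec   = dna_spectrum(indicator_sequences(coding))
pk     = dominant_frequency(spec)
print(f"coding surrogate: peak at bin {round(pk.freq*spec.fft_length)} "
      f"of N={len(coding)}  (period {1/pk.freq:.0f} nt)")
```

prints

```
dominant frequency: 0.2500  (period 4.0 nt)
line at nu=0.2500  positions 36..960  period 4.0 nt  strength 200
coding surrogate: peak at bin 500 of N=1500  (period 3 nt)
```

The repeat is recovered as a single spectral line at ν = 0.25 (period
4 nt) persisting over ~93% of the sequence despite the 10% substitution
noise, and the codon-position bias appears exactly at N/3.  The worked
example uses the half-lag (symmetric) convention, under which a period-P
repeat yields one clean line at 1/P; see `docs/methods.md` for the
trade-offs between the two lag conventions.

## Command line

```sh
seqtf simulate --kind periodic --length 1000 --substitution-rate 0.1 \
      --seed 7 -o repeat.fa
seqtf analyze repeat.fa -o run/            # all transforms + detected lines
seqtf compare-indicator repeat.fa -o cmp/  # similarity vs indicator spectrum
```

`analyze` writes one delimited table per transform (with `#` metadata
headers, 1-based positions), a detected-lines table, a BED export and a
run manifest; `--render-images` adds PNG heatmaps.

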