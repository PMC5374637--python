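# Methods

## Model

All quantities derive from the instantaneous correlation of two symbol
sequences x, y over a common alphabet, with the numeric product replaced
by a similarity-matrix entry:

    asymmetric convention:  r[n, τ] = S(x[n], y[n+τ]),   τ = −L..L
    symmetric  convention:  r[n, m] = S(x[n−m], y[n+m]), m = −L..L

Positions outside [0, N) contribute exactly zero (no wraparound).  The
auto case sets y = x.  S is any finite real square matrix over the
alphabet — identity for DNA by default, BLOSUM/PAM for proteins, possibly
negative-valued; every transform is linear in S, so no clamping or
rescaling is applied.  Symbols outside the alphabet (IUPAC ambiguity
codes) are retained in the sequence so positions stay aligned with the
source FASTA, and score 0 against everything ("lenient" mode; "strict"
mode raises instead).  This mirrors the selective analysis obtained by
zeroing rows/columns of S: an unknown symbol simply contributes nothing.

From r follow the correlation function R(τ) (sum over n; "linear" on the
zero-padded grid, or "circular" with positions wrapped mod N), the
symmetry function s(n) (sum over m of the symmetric-convention row), the
spectrum (DFT of R over lag, reported as magnitude on ν ∈ [0, 0.5]
cycles/nt), the Wigner–Ville (WV) plane (row-wise DFT over lag), the
ambiguity plane (column-wise DFT over position, Doppler axis η centered
at 0), and Cohen-class distributions (ambiguity plane multiplied by a
kernel Φ(τ, η), transformed back to the time-frequency plane).

When the inputs are numeric arrays, `sim="product"` computes
r[n, τ] = conj(x[n])·y[n+τ], and every transform reduces to its textbook
bilinear form; a complex exponential e^{2πi f₀ n} peaks at f₀ within one
frequency bin, which the suite asserts.

## The two lag conventions and their harmonics

The continuous half-lag definition r(t−τ/2, t+τ/2) has no exact integer
discretization, so both standard choices are provided, and the choice
matters more than it may appear:

* **asymmetric** (default): lag step 1, Nyquist at ν = 0.5, and a
  period-P repeat maps to ν = 1/P on the printed axis.  The cost is that
  the lag comb of a repeat keeps all of its harmonics: a period-4 repeat
  has *exactly equal* spectral magnitude at ν = 1/4 and ν = 1/2 (the
  even harmonic), so under substitution noise "the dominant peak" of such
  a repeat is a coin flip between the two.  Argmax ties break toward the
  smaller frequency, which resolves the noise-free case but not the noisy
  one.
* **symmetric** (half-lag): r[n, m] compares symbols 2m apart, so the
  effective lag step is 2; the frequency axis is relabeled ν = bin/2 with
  Nyquist at 0.25.  Even harmonics alias to DC, which is exactly why a
  noisy period-4 repeat shows one clean line at 0.25 under this
  convention — the behavior the figures of the genomic-signal-processing
  literature show.  The cost: periodicities shorter than 4 nt (ν > 0.25,
  e.g. period-2 or period-3 signals) are not representable.

Consequence for practice, used by the synthetic case studies: period-4
(and longer) repeat analyses use the symmetric convention; period-2/3
analyses (dinucleotide repeats, coding bias via the WV plane) need the
asymmetric one.  The symmetry function always uses the symmetric
convention (its centering demands it), with signed half-lags m and −m
both counted, matching the doubly infinite lag sum of its definition
(so a palindrome's m = ±1 terms each contribute).

The symmetric convention also gives each position a triangular lag
support (2·min(n, N−1−n)+1 valid half-lags), so line strength tapers
toward the sequence ends; the detector's median-relative threshold, not
an absolute one, is what keeps such lines long.

## Spectra, normalization, exact identities

Forward DFTs are unnormalized; FFT length defaults to the next power of
two ≥ twice the lag count (zero-padded) and is recorded in metadata.
Linear-mode correlation series live on signed lags −L..L; circular-mode
series span exactly one full period of lags 0..N−1, because that is the
domain on which the Wiener–Khinchin identity is exact: the length-N DFT
of the circular identity-similarity autocorrelation equals the
indicator-sequence DNA spectrum S[k] = Σᵢ |Uᵢ[k]|² bin for bin (a signed
−(N−1)..(N−1) circular grid would count every nonzero lag class twice).
The suite asserts this identity at 1e-9 on random sequences, ambiguity
codes included.

Other identities kept exact and tested: the position-summed complex WV
rows equal the spectrum of the linear correlation function at the same
FFT length; the DC bin of each WV row equals that row's lag sum; the
mean over frequency bins equals the zero-lag similarity; the ambiguity
plane inverse-transforms back to the lag grid; AF(0,0) = N for the
identity auto case, and |AF| attains its maximum at the origin for any
non-negative S with dominant diagonal.

Default max lag is N−1 for N ≤ 2048, else capped at 1024 (the lag grid
is quadratic in N); overridable everywhere.

## Cohen-class kernels

Kernels are specified in the ambiguity domain with Φ(0, 0) = 1, which
makes the TF-domain form sum to 1 on its grid and preserves total plane
mass: `gaussian` (separable, σ_τ = L/8 samples, σ_η = 1/16 normalized —
standard smoothing widths), `choi-williams`
(Φ = exp(−(2πτη)²/σ), σ = 1), and `none` (the multiplicative identity,
reproducing the WV plane to 1e-9).  Two computation paths are provided:
multiplication in the ambiguity domain (fast, used in production) and
direct circular 2-D convolution of the complex WV plane with the
kernel's TF-domain form (quadratic in plane size, used as a cross-check;
the two agree to ~1e-15 relative on small instances, asserted at 1e-6).

## Peak and line detection

`dominant_frequency` takes the argmax of a magnitude spectrum, skipping
a DC guard; ties break toward the smaller frequency.  The guard defaults
to 2 bins but widens to two DC main-lobe widths (2·K/support bins) when
the spectrum records the lag support of a zero-padded window — the DC
pedestal of a finite triangular lag window leaks over ~K/support bins,
and a fixed 2-bin guard lets that leakage win for some noise
realizations.

`detect_spectral_lines` operationalizes the by-eye reading of a WV
plane: per row, local maxima above `strength_threshold` (default 5×) the
plane median — medians make detections invariant to positive rescaling —
are linked across adjacent rows when within one frequency bin, and runs
shorter than `min_extent` (default 20) positions are dropped.  Two
further guards suppress window artifacts: frequencies below `min_freq`
(default 0.005) or inside the adaptive DC-lobe guard are not searched,
and per-row peaks closer than `min_separation` (default 0.01 in ν) are
thinned to the tallest, since the sidelobe skirt of a strong line
otherwise spawns parallel ghost lines a few bins away.  Periodicities
closer than `min_separation` are therefore reported as a single line.
Line extents are reported as found; note that under the asymmetric
convention a period-4 region genuinely carries equal energy at ν = 0.5,
so e.g. a dinucleotide-repeat line can legitimately extend into an
adjacent tetranucleotide-repeat region — boundary resolution is limited
by the lag window, not by the detector.

## Synthetic generators

All generators are pure functions of their parameters including the seed
(NumPy PCG64; seeds portable across platforms).

* `synth_periodic`: motif repeated and truncated to length; each site
  independently substituted with probability `substitution_rate`
  (default 0.1 for the repeat case study — low enough that the repeat
  line dominates, high enough to be visibly noisy), the replacement
  drawn uniformly from the other three nucleotides so substitutions are
  never silent.  Study condition: motif ACGT, length 1000.
* `synth_random`: i.i.d. draws, default uniform — the structureless
  null.
* `synth_coding`: position j drawn from codon-position distribution
  j mod 3; default bias puts G at probability 0.7 in codon position 1
  (uniform elsewhere), a caricature of first-position G-richness strong
  enough to make the N/3 peak unambiguous at 500 codons.  Study
  condition: 500 codons (N = 1500).

What these emulate — and what they do not: per-site independent
substitution with no indels, so positions never shift; no CpG effects,
no real codon-usage tables, no strand asymmetry.  Passing tests
therefore demonstrate the transform/detection machinery under controlled
periodicity and noise, not performance on evolutionary realistic
sequences; with indels a repeat's phase drifts and its WV line would
blur or break, which is out of scope here.

## Numerical and design choices

* DFT normalization: unnormalized forward transforms (so the indicator
  spectrum of "AAAA" has S[0] = 16); recorded in table metadata.
* Magnitudes: WV/Cohen planes and spectra are reported as magnitudes by
  default (the asymmetric-convention auto plane is not real in general);
  complex views are retained on every object for the identity tests.
* Tie-breaks: all argmaxes prefer the smallest frequency, then the
  smallest lag/position.
* Degenerate inputs: an all-zero spectrum yields an explicit no-peak
  result (None), not an exception; empty FASTA files and malformed
  similarity tables raise errors naming the file and line.
* Problem sizes: brute-force oracle comparisons run at N ≤ 64 where the
  literal triple sums are exact and fast; the synthetic case studies run
  at their stated sizes (N = 1000 and 1500); the white-spectrum check
  runs at N = 100 000 through the one-hot FFT route of the circular
  correlation (used automatically above N = 4096, where the direct
  rolled sum would be quadratic).
* Circular-mode series use the retained encoded sequences, so they are
  available from any InstantaneousCorrelation regardless of its max lag.

## Limitations

* No reverse-complement or strand handling; analyze each strand as
  given.
* The symmetric convention cannot represent periods shorter than 4 nt;
  the asymmetric convention keeps repeat harmonics (see above).  There
  is no convention-free discretization.
* Line boundary calls are resolution-limited by the lag window; this
  package does not attempt exact tandem-repeat boundary or motif
  reconstruction.
* Similarity matrices are user-supplied; nothing is estimated from
  mutation statistics.
* The N/3 coding peak is produced and detected, but no gene-calling
  decision rule is built on it.  (Mechanistically, in this framework the
  peak follows from codon-positional bias making the expected
  autocorrelation periodic with period 3; that observation is an
  implementation note, not a general proof.)
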