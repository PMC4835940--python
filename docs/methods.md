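# Methods

## Signal model and matrix formation

A record is a 1-D sequence of signed integer samples, zero-centered at load
time (an unsigned 12-bit acquisition is shifted by 2048; the offset travels in
the container header so export formats can restore it).  Matrix formation
places consecutive segments of K samples into columns of a K×L matrix; the
trailing shortfall is padded with zeros (the signals are zero-centered, so
zero padding injects the least energy into the last column) and the true
sample count rides in the header, making the inverse exact.  Without SbS, K is
⌈√n⌉, giving an as-square-as-possible matrix (L ∈ {K−1, K}); both the
rounding direction and the pad value are package choices — any consistent
convention round-trips.

## The coding engine

Blocks are 2^m × 2^n with m, n ∈ {0..4}; the scale index is the three-case
aspect-ratio formula (square, wide, tall) and maps the 25 dimension pairs
bijectively onto scales 1–25 (verified exhaustively in the tests).  "Vertical
segmentation" here means a vertical cut line — left/right children (M, N/2),
left coded first; "horizontal" gives top/bottom children (M/2, N), upper
first.  This matches the bitstream convention that the left/upper branch of a
split is serialized first.

**Costing.** J = D + λR with D the SSD in the residue domain and R the code
length −log₂p under the adaptive models *frozen at the start of the current
tile's optimization*; actual emission then updates the models.  A two-pass
scheme (re-optimizing under post-update statistics) was rejected because the
decoder could not reproduce it.  A parent is kept (not split) on cost ties;
between split directions, vertical wins ties.  Dictionary index rate is the
sum of a partition symbol (origin scale, 26-ary) and an index-within-partition
symbol, both adaptive.

**Initial dictionary.** One pass from −X_max stepping by p(|v|) per the
magnitude bands |v| ≤ 10 → 1, ≤ 22 → 4, ≤ 86 → 8, else 13; the pass always
traverses the dense band, so level 0 always exists and an all-zero tile codes
as a single leaf.  Levels are not mirrored symmetrically — the one-pass
convention means +X_max itself need not be a level.  X_max is the maximum
absolute sample value of the current image and rides in the header.  Scale 1
holds every integer in [−X_max, X_max]; this exhaustive base alphabet is what
makes λ = 0 exactly lossless.

**Dictionary update.** After a residue split is coded, the concatenation of
the children's reconstructions is rescaled to all 25 scales (separable 1-D
resampling: linear-weight expansion, box-average contraction, rounding half
away from zero — constants are preserved exactly) and appended to the
partition named after the originating scale wherever its *mean squared
difference per sample* to every existing entry exceeds d(λ) (20/40/60/80 for
λ ≤ 4 / ≤ 22 / ≤ 50 / > 50).  The per-sample normalization makes one
threshold meaningful across scales; "relative distance" is not otherwise
pinned down.  Initial entries are exempt (they predate the threshold).
Hierarchical-prediction splits do not spawn patterns: the dictionary lives in
the residue domain, and the children of a prediction split are
original-domain blocks rather than dictionary approximations.  The optional
additive-symmetric feature (off by default) also offers the negated pattern.
A per-scale entry cap (default 50 000, configurable) bounds memory; the cap
and the additive-symmetric flag travel in the header because the decoder must
mirror every update decision.

## Prediction

The intra toolbox mirrors HEVC: 33 angular modes with the standard
displacement table and 1/32-sample interpolation (the table itself is adopted
verbatim since only the fan of directions is otherwise specified), planar as
the average of one horizontal and one vertical linear interpolation, and MFV
(modal reference sample, ties to the smallest value) replacing DC.  Two
reference vectors of length 2·max(M, N)+1 are built per block — corner + left
edge + below-left ("vertical", serving modes 2–17) and corner + top edge +
above-right ("horizontal", serving modes 18–34).  Unavailable samples are
substituted HEVC-style by scanning below-left → corner → above-right and
propagating the nearest available sample (all-zero when nothing is coded
yet).  No reference smoothing is applied: SEMG images are noise-like and
low-pass filtering the references only degrades the match.  Interpolated
values round half away from zero.

Mode availability: none at scales 1–3 (tiny blocks gain nothing), MFV + all
angular modes at scales ≥ 4, planar additionally at the square scales 4, 9,
16, 25.  MFV is not gated beyond scale ≥ 4.  Prediction splits (flags 3/4)
are legal at scales 25 down to 9.

**Bitstream grammar.** Five flags encode the tree top-down: 0 leaf, 1/2
residue splits, 3/4 prediction splits.  The format must let the decoder know
whether a prediction-mode symbol follows a 0/1/2 flag, so the grammar makes
the mode slot mandatory for every original-domain node (every node that is
not inside a residue tree), with an explicit *no-prediction* mode id 35 in
the per-scale mode alphabet.  This has two consequences worth noting:

* a predicted residue can exceed the dictionary's amplitude range
  [−X_max, X_max] (X − P with both in range spans twice that); the
  no-prediction path always represents raw samples exactly at scale 1, so the
  λ = 0 lossless guarantee survives regardless of what prediction would do;
* the symbol string of a vertically prediction-split block whose halves are
  predicted with modes M1/M2 (the right half's residue further segmented)
  serializes exactly as `3 0 M1 i0 2 M2 0 i1 2 0 i2 0 i3`.

## Encoder search

The decoder accepts any legal stream; two knobs bound only the *encoder's*
search, in the same rough-then-fine spirit practical HEVC encoders use:

* `mode_search_width` (default 4): candidate modes are prescreened by
  residual SSE and only the shortlist gets the full recursive
  rate–distortion optimization (the no-prediction path is always fully
  evaluated); `None` makes the search exhaustive;
* `pred_split_depth` (default 1): how many nested levels of prediction
  splits the encoder explores.

Residue optimization is an exact bottom-up dynamic program over the aligned
sub-block grid of a region (all leaf matches per scale are batched into one
matrix product), memoized per region so prediction-split candidates reuse it.
At λ = 0 the no-prediction path reaches cost zero, a provable lower bound, so
the search prunes immediately — lossless encoding is fast.

## Entropy layer and container

A 32-bit integer arithmetic coder (Witten–Neal–Cleary renormalization) with
per-context adaptive tables: one flag table per scale (alphabet restricted to
the flags legal at that scale — a 1×1 block's table is unary and costs zero
bits), one mode table per scale, one partition table per scale, and one
growing index table per (scale, partition).  Counts start at 1, increment by
1, and are halved (floor 1) when the total reaches 2^14.  The layer is
exactly lossless; measured rate on a uniform 5-ary source is within a percent
of the entropy bound.  One coder instance with separate tables is used; the
PDS permutation is coded by the same machinery over a 0..L−1 alphabet and
stored byte-aligned in the header.  The `.mmp2d` container is: magic
`MMP2DSEMG`, version byte, little-endian fixed header (sample count, offset,
X_max, segment length, preprocessing id, λ, matrix dims, sampling rate, bit
depth, dictionary cap, additive-symmetric flag), optional coded permutation,
then the payload.

## Preprocessing

PD(x, m) = Σ(x−m)²/Σx² is implemented literally — despite the name there is
no ×100 factor; ordering decisions are scale-free either way.  PDS seeds with
the minimum-population-variance column (ties: lowest original index) and
chains greedily by PD to the last placed column; a zero-energy reference
column falls back to the unnormalized numerator for that step (the ratio is
undefined, and the fallback preserves the ordering intent).  SbS scores
adjacent segments in original signal order for every N = 16n, n ∈ {2..64}
that yields at least two full segments; the trailing partial segment is
excluded (rather than padded) so all scored pairs have equal length; ties go
to the smallest N.  SbS runs on the 1-D record before matrix formation, so
matrix formation and preprocessing collapse into one stage.  The zero-energy
fallback applies to SbS scoring too.

## Metrics

PRD is computed on the restored 1-D integer signal after un-preprocessing
(the metric is defined over samples, not matrix cells) with no mean removal.
CF uses B_o = bit_depth·n (12 n for nominal SEMG) and B_c = the complete
container size in bits, byte padding and side information included.  λ = 0
therefore usually yields CF < 0: lossless coding of noise-like data plus
header overhead expands.

## Synthetic signals

The generator emulates the acquisition conditions the codec targets:
isometric records are i.i.d. noise (Laplacian for light-force statistics,
Gaussian for high force levels — Gaussian is the default, matching a 60 % MVC
protocol) band-passed to 10–500 Hz with a zero-phase 4th-order Butterworth
(only the band is prescribed; the family is a package choice), scaled to
occupy ~70 % of the signed 12-bit range (headroom against clipping while
exercising every dictionary step band), and rounded to integers at 2000 Hz.
Dynamic records apply a raised-cosine contraction-cycle envelope (default 30
bursts/min, ±10 % period jitter, amplitude in [0.7, 1.0], floor 0.05) to the
scaled carrier at 2048 Hz.  Everything is deterministic per seed.

What the surrogates do *not* model: motor-unit firing structure, electrode
artifacts, line interference, force-dependent spectral shifts, and — most
importantly for rate figures — the strong inter-segment correlation of real
recordings.  Band-limited noise is nearly incompressible, so compression
factors on synthetic data sit far below those achievable on real SEMG; tests
on these signals therefore validate *contracts* (losslessness at λ = 0,
encoder/decoder lockstep, monotone rate–distortion behavior), not clinical
rate–distortion performance.

## Problem sizes and numerical choices

Desk-scale runs use records of 0.25–1 s (≈ 500–2000 samples) and dictionary
caps of 512–4096 entries per scale; the verified properties (exact λ = 0
round trips, state synchronization, RD monotonicity) are invariant to the cap
and to record length.  Distortions are computed in float64 (exact for the
integer magnitudes involved); all rounding of interpolated or rescaled values
is half-away-from-zero; cost ties prefer the simpler representation (leaf
over split, vertical over horizontal, lowest partition then lowest index) so
encoder decisions are deterministic and decoder-reproducible.  The RD
monotonicity checks tolerate a single grid inversion because dictionary
adaptation is input-dependent — a larger λ changes the update trajectory, not
just the operating point.

## Known limitations

* The encoder's mode shortlist and prediction-split depth are bounded by
  default (see above); exhaustive search is available but slow in pure
  Python.
* Norm equalization of dictionary entries (named in the MMP lineage but not
  specified for this codec) is not implemented; `MmpConfig` reserves no flag
  for it.  The geometric-transform catalogue beyond the additive symmetric is
  likewise out of scope.
* 32×32 input tiles are deliberately unsupported: more scales mean more
  dictionaries and flags, which hurts noise-like SEMG images.
* No error resilience: a corrupted payload aborts decoding with the failing
  block coordinate rather than resynchronizing.
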