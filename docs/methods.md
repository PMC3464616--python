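# Methods

## The code

A source sequence of `k` bases (`k` a positive multiple of 5) is a row
vector `s` over GF(4) under the fixed bijection `A,C,G,T ↔ 0,1,α,β`; colors
`0..3` label the same elements. The encoder slides a five-base window one
base at a time and emits two streams: the two-base color stream
`c_j = b_{j-1} ⊕ b_j` (probe generator `ρ₁ = 11000`; `b_0` is the known
adapter base) and the ECC stream, the window dotted with a second probe
generator and punctured to every fifth symbol. The production second-stream
generator is `ρ₂ = 1β0β0`; the toolkit accepts any `p1..p5`.

Internally GF(4) elements are the integers 0–3 (`α = 2`, `β = 3`): addition
is bitwise XOR (characteristic 2) and multiplication a 4×4 lookup table,
which the test suite verifies entry-for-entry against the published Cayley
tables. The error-type labels (+1 transcomplement, +α transition,
+β complement) are attached metadata only.

### Block structure and layouts

Partitioning the read into `m = k/5` blocks, the colors regroup into five
*data colors* per block (`c1..c4` within-block adjacent-pair colors, `c5`
the ECC color) plus `m` *junction parities*: junction 0 is the adapter
junction (`adapter ⊕ b1`) and junction `i ≥ 1` straddles blocks `i` and
`i+1` (`b5⁽ⁱ⁾ ⊕ b1⁽ⁱ⁺¹⁾`). The canonical serialisation is the stream pair
`(color_stream, ecc_stream)`; the block view and the *code layout* (data
colors per block, then junctions) are loss-free reorderings. The physical
round/cycle interleaving of the instrument is not modelled.

The adapter junction is handled by subtracting the known adapter offset
before any linear algebra, making the code layout a pure linear function of
the source: `G_ECC = [G* | P]` is then `k × n` with `n = 6m`, `G*`
block-diagonal in `G_block`, and `P` holding one column per junction — a
single 1 (on `b1` of block 1) for the adapter column, two 1s for interior
columns. The parity check is the factorised `H = [G*⁻¹P ; I_{n-k}]`, so
`G_ECC H = 0` and the syndrome `σ = x H` has one component per junction:
invert each block, recompute the junction parities from the putative bases,
and add the observed parities. Matrix orientation is row-vector × matrix
throughout; user-facing coordinates are 1-based.

The block inverse uses the exact closed form
`G⁻¹ = [I₄ | x_{1..4} y⁻¹ ; 0 | y⁻¹] · L` with `L` lower-triangular
all-ones, `x = Lp`, `y = x₅` (= the GF(4) sum of the probe coefficients).
The inverse exists iff `y ≠ 0`; non-invertible probes are rejected with an
error. The closed form is cross-checked against Gauss–Jordan elimination
for all 48 admissible generators in the tests.

### Alternative probe generators

The enumeration of alternatives fixes `p1 = 1` (scalar multiples and
leading-zero shifts give the same code words), `p5 = 0` (final-position
ligation accuracy), and requires invertibility; 48 generators survive, in
deterministic lexicographic order. Relaxing the flags yields 64
(first-one + last-zero) or 192 (first-one + invertible) candidates.

## Syndrome analysis

An error of additive type `t` at a data color `c_j` perturbs the block's
putative decoding by `t ·` row `j` of `G⁻¹`; only the decoded first and
last bases enter the flanking junction checks, so each single error induces
an (upstream, downstream) pair, and positions group into equivalence
classes per type. Junction errors show up verbatim in their own component
and are attributed to the earlier block's `p+` (the upstream parity `p-` of
a block is the same physical color; block 1's `p-` is the adapter
junction). Miscorrection patterns are `d G⁻¹` for the data-color
difference `d` of the confused pair — independent of the underlying
sequence, with the same offset at every affected position.

### Hard-decision decoding

The decoder searches for the minimal-weight error explaining the syndrome
("fewest changes wins"). Since in-block errors couple the two junctions
flanking their block, a per-block greedy lookup misattributes errors whose
upstream neighbour sees them first; the implementation instead runs a small
dynamic program along the junction chain. State: the downstream syndrome
contribution (one GF(4) element) of the current block's in-block errors;
in-block candidates come from a signature table over `c1..c5` up to the
syndrome table's maximum weight (default 2); junction miscalls are free
weight-1 variables. Cost is lexicographic `(total weight, -Σ log-odds)`,
where the log-odds term — `Σ log(ε/(1-ε))` over the colors an explanation
touches — breaks weight ties toward the most probable error pattern when
per-color error probabilities are available, and is zero otherwise (ties
then fall to a deterministic canonical enumeration order). The applied
correction always yields a valid codeword.

Statuses are reported per block in the single-error (table) view: `clean`,
`corrected` (singleton class), `ambiguous` (the full candidate class is
reported), or `uncorrectable` when the block's pair matches no table entry
at the configured maximum weight — possible only for weight-1 tables, since
junction-pair explanations cover every pair at weight 2. The final block
has no downstream junction: single errors there at positions whose upstream
syndrome component is zero (`c1`, `c4` under the ECC generator) are
invisible, and the surviving upstream component is genuinely ambiguous
between the final block and its predecessor's `p+`.

## Soft-decision (trellis) decoding

The encoder is a finite-state machine over the last four bases (256
states). Each color call is modelled as independently wrong with
probability `ε = 10^(-Q/10)`, the wrong color uniform over the three
alternatives; missing calls (`.`) contribute a flat likelihood. Viterbi
decoding returns the joint-likelihood argmax over all `4^k` sequences with
lexicographic tie-breaking (A < C < G < T, fully deterministic);
forward–backward returns exact per-position marginals under a uniform
source prior — the prior is not specified by the platform, and uniformity
makes the marginals pure likelihood ratios. All accumulation is in the log
domain; `ε` is clamped to `[1e-10, 1 - 1e-10]` so degenerate qualities
cannot produce infinite terms. Call qualities are `-10·log10(1 - p_max)`,
rounded and capped at 60. Both decoders are verified against exhaustive
enumeration at `k = 5` (tolerance 1e-9 on marginals).

## Coding bounds

All bound arithmetic is exact integer arithmetic (`q^(n-k)` reaches 4^15
and beyond). Hamming: largest `t` with `V_q(n,t) ≤ q^(n-k)`. Existence:
the Gilbert form (largest `d` with `V_q(n,d-1) ≤ q^(n-k)`) is the quoted
guarantee; the strictly stronger Varshamov linear-code form is provided
separately and labelled, because the two are often conflated and only the
Gilbert form matches the standard capability statements for the (60, 50)
parameters. Johnson: the Plotkin–Johnson recursion — shorten
(`A_q(n,d) ≤ q·A_q(n-1,d)`) until `qd > (q-1)n`, then the averaging bound
`⌊qd/(qd-(q-1)n)⌋`; both steps are valid upper bounds, so the result never
undercuts the true optimum (checked exhaustively at tiny sizes). Distance
capabilities follow the standard rules: correct `⌊(d-1)/2⌋`, detect `d-1`,
simultaneous `(c, e)` with `c ≤ e`, `c + e ≤ d - 1`.

## Simulation

The simulator emulates a run in five steps: (1) sample fragments uniformly
from the positive strand of a reference (a synthetic i.i.d. sequence by
default; the default reference is 100 kb, enough that 50-base fragments are
effectively never resampled at the default depth); (2) mutate fragment
bases independently at the generalised-error rate — default `10^-3.4`
(Q34-equivalent), the template-error level of well-prepared samples; these
occur before encoding and are uncorrectable by construction; (3) encode;
(4) assign per-cycle integer Phred qualities; (5) miscall each color
independently with probability `10^(-Q/10)`, uniform over the three wrong
colors. Insertions and deletions are not simulated. Every draw flows from
the single configured seed, so reruns are byte-identical.

No public per-cycle quality profile exists for the instrument, so the
synthetic profile declines linearly from Q30 (first cycle) to Q15 (last)
in both streams — later cycles are worse, which is the qualitatively
documented behaviour — with configurable per-round additive offsets
(default 0, since no data constrains them). Real QUAL files can be
supplied through the io module instead. Each read carries the same
deterministic quality vector; real runs vary per read, so quality-guided
disambiguation is *less* informative here than with real data, where
miscalled cycles tend to carry visibly low quality. Passing tests
therefore demonstrate the machinery and the direction of the effects, not
platform-accurate error rates.

Evaluation replaces read mapping with direct truth comparison: decoded
output is scored by Hamming distance against the sequenced (post-mutation)
template in base space and against its clean encoding in color space, and
reads are binned by error count (0–5, >5). Mapping-based percentages
against a real genome with real quality files are out of scope.

Default problem sizes — 50-base fragments, 10 000 reads per condition in
the acceptance checks, 1 000 in the default config — keep the full
simulation study at a few minutes on one core while leaving binomial noise
on the reported fractions well below the effects measured.

## Known limitations

* Errors are independent across colors; correlated bursts and round
  failures (which dominate the worst real reads) are not modelled.
* The syndrome decoder's candidate reporting uses the single-block table
  view; for multi-error reads whose explanations span blocks the status
  labels are a faithful but simplified summary of the chain solution.
* Only one extra round, pentamer probes, and period-5 puncturing are
  supported — the family the chemistry can realise.
* Viterbi/MAP decoding is exact but pure-Python; at 10⁴-read scale the
  syndrome decoder is the practical engine, and the trellis engines are
  best reserved for per-read analysis.
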