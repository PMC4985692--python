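# Methods

## Model and state space

Both chains describe the count `N_B` of B alleles in a fixed pool of `N`
alleles (N even, so the diploid Wright–Fisher population has `N/2`
individuals), a discrete-time Markov chain on `{0, …, N}` with absorbing
states at 0 and `N`. Frequencies are assumed measured exactly: no sampling
error at observation times, no mutation or migration, constant `N`.

The selection coefficient `s ≥ 0` is a fitness ratio of the A class over
the B class. Only ratios are identifiable, so fitnesses are normalized as
`W_B = 1, W_A = s` (Moran) and `W_BB = 1, W_AB = (1+s)/2, W_AA = s`
(Wright–Fisher with codominance). Under this orientation `s > 1` drives B
toward loss; for `0 ≤ s < 1` the Moran up-move probability exceeds the
down-move probability at every interior state, and the Wright–Fisher
gamete frequency `p′_B(i)` is strictly decreasing in `s` — both properties
are enforced by tests.

Moran one-step probabilities at `N_B = i` follow from one fitness-weighted
birth plus one uniform death:

```
P_i = [i / ((N−i)s + i)] · (N−i)/N        (up)
Q_i = [(N−i)s / ((N−i)s + i)] · i/N      (down)
R_i = 1 − P_i − Q_i                       (stay)
```

Wright–Fisher rows are `Binomial(N, p′_B(i))` mass functions with

```
p′_B = p_B (p_B + p_A (1+s)/2) / W_O,
W_O  = p_A² s + 2 p_A p_B (1+s)/2 + p_B²,   p_B = i/N.
```

## Endpoint conditioning

Conditioning on a future observation `X_{T_F} = k` is a Doob h-transform:
`P_{ij|k}(m) = P_ij h_{m−1}(j) / h_m(i)` with `h_m(i) = (P^m)_{ik}` and
`m` the remaining time. Rather than forming matrix powers, the
implementation runs the backward recursion `h_m = P h_{m−1}` from the
indicator of `k`, rescaling each vector by its maximum. The rescaling is
exact — each conditioned row only uses ratios within one recursion step —
and keeps horizons of hundreds of generations away from underflow; the raw
`(P^m)_{ik}` would reach ~1e-300 well before `m = 500` for off-target
states.

For a final observation in the asymptotic future the transform is
time-homogeneous:

* transient `k` (0 < k < N): `φ_ij = w_0(j)/(λ_0 w_0(i))`, where
  `(λ_0, w_0)` is the Perron eigenpair of the transient submatrix (states
  `1..N−1`). `λ_0` is the largest non-trivial eigenvalue of the chain; the
  eigenvalue 1 belongs to the absorbing block. The eigenpair comes from
  `numpy.linalg.eig`; if the leading pair is complex, degenerate, or has a
  non-positive eigenvector (it cannot for these chains, but the guard is
  cheap), a power iteration with tolerance 1e-12 takes over and the
  condition is logged. The resulting conditioned chain never leaves the
  transient block and is independent of which transient endpoint is
  conditioned on.
* absorbing `k` (0 or N): `φ_ij = u_jk/u_ik`, with absorption
  probabilities `u` solved from the first-step linear system
  `(I − Q) u = r_k` on the transient states. For the Moran chain the
  closed form `u_iN = (1 − s^i)/(1 − s^N)` (the down/up ratio is exactly
  `s`) serves as an oracle at 1e-10.

Every conditioned row is normalized by its own sum; the Doob identity
`Σ_j P_ij h_{m−1}(j) = h_m(i)` makes that normalization exact rather than a
correction. Infeasible conditioning (endpoint unreachable in the remaining
steps, or `u_ik = 0`) raises `InfeasibleBridgeError` at construction, never
a silent NaN.

## Observation cases and simulation

Trajectories carry `T + 1` consecutive states plus one final observation.
Cases I/II place the final observation at `T_F = T + 1` and are simulated
step by step from the finite-horizon transform (the last step is forced to
`k`); cases III/IV use the asymptotic transform and record `k` with an
"asymptotic" marker instead of a concrete `T_F` — no specific gap length is
assumed, matching the `T_F → ∞` transform used to generate them. Paths
conditioned on fixation may absorb before `T` and then stay absorbed;
paths conditioned on a transient endpoint are automatically barred from
the boundaries by the transform itself.

The generator defaults are the study conditions: `N = 54`, `N_B(0) = 27`,
generating `s = 2`, `T = 500` (Moran) or `T = 100` (Wright–Fisher, whose
non-overlapping generations run roughly `N` times faster), endpoints
`k = 40` for the intermediate cases and `k = N` (Moran) or `k = N − 1`
(Wright–Fisher, near fixation, keeping trajectories informative) for the
fixation cases, 100 trajectories per ensemble. Per-trajectory RNG streams
derive deterministically from the root seed, the case index and the
trajectory index.

What the generator does *not* emulate: binomial sampling noise at
observation times, missing data inside the consecutive block, varying
population size, mutation, and linkage. Passing tests therefore
demonstrate correct inference when the model generating the data is known
exactly; on real ancient-DNA data the additional observation noise would
need its own treatment.

## Likelihoods and maximization

Both likelihoods run over the `T` consecutive transitions of the block;
the gap to the final observation enters only through the conditioning. A
transition impossible under the model at a candidate `s` makes the
log-likelihood `−∞` (a value, not an exception). The identity
`L_c(s) = Φ(s) L(s)` holds by construction and is verified to 1e-10
against an independently computed per-step `φ` product; the ratio
`R(s) = L_c/L = Φ` is exposed as an exploratory estimator of its own.

Maximization scans 200 log-spaced grid points on `s ∈ [0.05, 20]` (wide
enough to bracket both the generating value 2 and the below-unity
unconditioned estimates) and refines the best interior point by
golden-section search on `log s` to relative tolerance 1e-5. All strict
grid-local maxima are retained and a multimodality flag is set when more
than one exists — the conditional likelihood of fixation-conditioned
trajectories can be bimodal, with one mode governed by `L` and one by `Φ`;
the global maximizer is reported. A maximum on the search boundary sets a
boundary flag; a flat or everywhere-`−∞` curve raises an estimation error.

For ensembles, the finite-horizon backward recursion depends only on
`(s, k, T_F)`, so one recursion per `s` is shared by all trajectories of a
case; per-`s` tables are cached (up to 256 values — the grid plus
refinement points).

## Ensemble summaries

The distribution of per-trajectory maximizers is summarized by the mode of
a Gaussian KDE on `log ŝ` with Silverman bandwidth (the log scale respects
the multiplicative nature of `s`) and the empirical 2.5%/97.5% quantiles.
Boundary and failed fits are excluded from mode/CI (they would otherwise
put KDE spikes at the search bounds) but are counted and reported.

## Numerical choices and limitations

* Row-stochasticity of built matrices is exact to ~1e-15; tests enforce
  1e-12.
* Asymptotic-limit agreement: the finite-horizon transform converges to
  the spectral/absorption forms; at `m = 500` on an `N = 6` chain the gap
  is below 1e-6 (spectral) and 1e-8 (absorption), the scales used in
  tests.
* Stochastic test scales: ensemble checks use 2·10⁴–4·10⁵ replicates with
  3-standard-error bands (Šidák-corrected when many paths are compared at
  once); exact path-law checks enumerate chains with `N ≤ 6`, `T ≤ 9`.
* `s = 0` (A lethal) is admitted and the matrices remain valid; the
  likelihood of any trajectory containing an A-favoured move is then 0.
* The mode/CI estimator is a package choice; other defensible estimators
  (histogram mode, HPD intervals) would shift summaries slightly but not
  the qualitative contrasts between cases.
* Under bimodal conditional likelihoods the *global* maximizer is
  reported per trajectory; local maxima are retained for inspection.
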