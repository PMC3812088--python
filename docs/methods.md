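# Methods

`sfscl` infers demographic parameters from the (joint) site frequency
spectrum (SFS) by maximizing a simulation-estimated composite likelihood.
This note documents the model, the estimators, the optimizer, the synthetic
data used for validation, and the numerical choices that an informed user
should know about.

## The demographic model

A `Demography` is a backward-time structured coalescent over `v` demes:

* per-deme effective sizes `N_k` in **diploid individuals**, so two lineages
  in deme k coalesce at rate `1/(2 N_k(t))` per generation (some literature
  reports the same scenarios in gene-copy units `2N`; the benchmark presets
  note which convention their published truths use);
* per-deme exponential growth rates `r_k` with the forward-time sign
  convention: backward in time, `N_k(t) = N_k(0) · exp(−r_k t)` until an
  event resets the size;
* a backward migration matrix, entry `[k][j]` being the per-generation rate
  at which a lineage currently in deme k relocates to deme j, constant
  between events;
* time-ordered historical events (divergences, admixture pulses, size and
  growth changes, migration-matrix switches). Each event moves every
  lineage in its source deme to the sink independently with the event's
  proportion (1 = full fusion). Simultaneous events are applied in
  declaration order — this tie-break is part of the file-format contract.

Waiting times are exact. For `c` lineages in a deme growing at rate `g`,
the first-coalescence time solves the integrated hazard analytically
(`dt = ln(1 + g E 2N/C(c,2))/g` with `E ~ Exp(1)`), so there is no Euler
discretization error and no step-size knob. Coalescence (per deme) and
total migration are competing risks, re-drawn after every state change,
which is exact by the Markov property. Models whose lineages cannot reach a
common deme ("non-closable") are rejected by a static reachability check,
with a hard time cap as a runtime backstop.

Two implementations of this process exist deliberately. The batch kernel
(`_kernels`, numba) never builds trees: each active lineage carries its
composite frequency-class index (linear in the descent vector, so merging
adds indices) and every branch is accumulated once, when a coalescence ends
it. The pure-Python simulator (`coalescent`) builds explicit genealogies
with node times, parents, and per-branch descent vectors. The second is the
readable reference and independent oracle; the test-suite requires the two
to agree (frequency-class proportions from explicit-tree mutation dropping
against the kernel's branch-ratio estimate).

## The expected SFS as a ratio of branch lengths

For a genealogy, a mutation is seen in frequency class `i` (a joint index
over demes) exactly when it falls on a branch with that descent vector, so

    p_i  =  E[ l_i ] / E[ T ],

estimated over Z simulated genealogies by summing compatible branch lengths
in the numerator and total tree length in the denominator *over the same
simulations*. Dividing sums (not averaging per-tree ratios) weights each
genealogy by the probability a mutation occurs on it, which matters when
tree lengths vary strongly (e.g. recent bottlenecks). The estimator is a
ratio of Monte-Carlo sums: consistent, with O(1/Z) bias that is negligible
against its O(1/sqrt(Z)) noise at the Z used anywhere here (the test-suite
checks symmetry of replicate estimates around a high-Z reference).

The monomorphic probability per site is `p0 = (1/Z) Σ exp(−µ T_k)` — the
Poisson zero class averaged over the tree-length distribution, which is
unbiased unlike `exp(−µ mean T)`.

**Ascertainment.** For SNP panels discovered as "sites heterozygous in one
individual of deme a", a site is observable exactly when its mutation falls
on the subtree joining two random lineages of deme a to their MRCA. The
kernel marks the two chosen lineages and accumulates, alongside the full
spectrum, the lengths of branches subtending exactly one of them (the
path-union criterion); the ascertained estimator restricts both numerator
and denominator to those branches while classes still count the full
sample. Pseudo-data generation does *not* use this shortcut: it places
mutations on the whole tree and filters by heterozygosity, so it remains an
independent oracle for the subtree estimator. For a stationary population
the ascertained spectrum is proportional to `(n − i)`, which both paths
reproduce.

## Composite likelihoods

With S polymorphic sites over L surveyed bp and expected class
probabilities `p_i` (renormalized over non-absorbing entries; a flag can
disable the renormalization),

    ln CL = (L − S) ln p0 + S ln(1 − p0) + Σ_i X_i ln p_i.

The binomial terms calibrate the molecular clock (absolute sizes and
times); without them — SNP-chip data, CLI flag `-0` — the remainder is
exactly a multinomial likelihood, equal to common SFS likelihoods up to a
data constant (asserted against `scipy.stats.multinomial` in the tests).
The two absorbing corners (all-ancestral, all-derived in the full sample)
are excluded; all-derived-within-one-deme entries are retained, since an
outgroup polarizes them.

Sparse spectra are handled by collapsing: all entries observed fewer than
ε times are pooled into one class (counts and probability mass conserved)
before evaluation. Besides its original motivation — low-count entries
whose expectations are poorly estimated — collapsing substantially reduces
the Monte-Carlo noise of the log-likelihood for high-dimensional spectra
(hundreds of classes for a few thousand SNPs), which is why the
two-population benchmark fits below use ε = 5. Observed classes whose
estimated probability is zero are floored at 1e-12 (configurable), after
collapsing, inside the likelihood only.

For models with many demes the dense joint spectrum is impractical; the
product of all pairwise 2-D composite likelihoods (C2L) replaces it.
Pairwise expected marginals come from the same kernel by zeroing the class
strides of all other demes. Monomorphic terms are always excluded from C2L
(each pair would double-count them).

The saturated likelihood plugs `X_i/S` (and `(L−S)/L`) into the same
formula; it upper-bounds every model and anchors the goodness-of-fit G
statistic `G = 2 (ln CL_sat − ln CL_model)`. The factor 2 is the standard
G-statistic convention; since the null distribution is obtained by
parametric bootstrap, the constant does not affect p-values.

## ECM maximization of a noisy objective

Every objective evaluation re-estimates the expected SFS from fresh
simulations (no common random numbers — two evaluations at the same
parameters differ, which is a property of the method, not a bug). Each free
parameter is maximized in turn by Brent's bounded 1-D method on its native
scale — log10 for sizes, times, and rates (search ranges span orders of
magnitude), linear for proportions — holding the others fixed; cycles
repeat until the largest relative parameter change drops below `stop_tol`
or a cycle cap. The per-evaluation simulation count ramps linearly from
`z_start` to `z_end` across cycles: early cycles only need to locate the
basin, late cycles need precision. The final vector is re-scored once at
`z_end`.

After the first cycle, each parameter's 1-D search interval is centred on
its current value and shrunk geometrically (`window_shrink`, default 0.5
per cycle, floored at `min_window` = 0.1 native units). Re-searching the
full four-order range every cycle wastes most Brent iterations re-locating
the basin; the shrinking window lets ~8 iterations reach sub-percent
resolution. Setting `window_shrink = 1` restores full-range searches.

Two variance-reduction devices address weakly identified parameters,
whose conditional profiles can be flatter than the objective's Monte-Carlo
noise (the current size of a strongly bottlenecked population is the
canonical case — the bottleneck truncates the tip branches, so at fixed Z
the noise-equivalent deviation on that size is ~15% regardless of how much
data is supplied): the final re-score may average several evaluations
(`final_rescore_evals`), so the winner among starts is not selected for
lucky noise; and the reported vector may be the (geometric, on log scale)
mean of the last few cycles' vectors (`avg_last_cycles`, Polyak-style
iterate averaging). Iterate averaging assumes the stationary fluctuation
is symmetric: on a one-sided profile (flat above the optimum, falling
below) the walk lingers on the flat side and the time-average acquires a
bias toward it, so the device should only be enabled where the ridge is
roughly symmetric — the two-population divergence fits use it, the
bottleneck fits do not. Both devices default to off (1).

Because the surface can be multimodal and the objective is stochastic,
`multi_start_fit` runs many independent ECM fits from random starts
(log-uniform for log-scale parameters) and keeps the best final re-scored
solution, ties to the earliest run. Fit quality should be judged on the
re-scored value, never on within-cycle values at different Z.

## Inference tools

* **Parametric bootstrap CIs**: simulate B datasets at the fitted
  parameters, refit each (typically with fewer starts and a cheaper
  configuration — `refit_cfg`), take percentile intervals. The fast path
  resamples the observed S multinomially from the expected SFS; an exact
  path re-simulates every locus, and the tests check the two agree.
* **AIC / Akaike weights**: `AIC = 2d − 2 ln CL` with the model ln CL taken
  as the maximum over repeated re-evaluations at the fitted parameters
  (default 100; the acceptance runs use 20), because a single noisy draw
  would randomize comparisons. No effective-parameter correction for
  composite likelihoods is applied; with unlinked SNPs the CL is treated as
  a quasi-likelihood.
* **G-test**: the observed G is compared with the G of B bootstrap
  replicates, each refitted and scored identically; the p-value is the
  fraction of null G at or above the observed. Weak per-replicate refits
  shift the null G up slightly, making the test conservative for a
  correctly specified model.

## Synthetic data and study conditions

The generator simulates independent, non-recombining 50-bp loci under the
infinite-sites model at µ = 2.5e-8 per bp per generation and tabulates the
joint SFS; full scale is 400,000 loci (20 Mb). It emulates unlinked short
loci only: no intra-locus recombination, no linkage between loci, no
sequencing error, known polarization, fully observed genotypes. Passing
tests therefore validate the estimators and optimizer, not robustness to
misspecified real-data features.

Benchmark scenarios with published truths:

* **bottleneck** — one deme, n = 20; current size 10000, size 100 between
  1000 and 1100 generations ago, ancestral size 10000 (fixed in fits).
* **divergence_no_mig** — two demes, n = (20, 30); gene-copy sizes
  2N1 = 10000, 2N2 = 1000, 2NA = 10000 (ancestral fixed), divergence at
  {0.001, 0.1, 10} × 2NA generations.

The IM, three-population-growth, hierarchical-island, and ascertained
divergence presets ship with editable defaults that are explicitly not
published values. Search ranges cover four orders of magnitude
([10, 1e5] for sizes and times) for every free parameter.

**Desk-scale settings.** The full protocol (Z up to 250,000 per evaluation,
40 ECM cycles, 50 starts, 20 Mb datasets) runs for hours per fit. The
bundled tests and `scripts/acceptance.py` use desk-scale conditions chosen
once: 40,000 loci (2 Mb, ≈ 4000 SNPs per dataset), a Z ramp of
3,000 → 20,000 with `stop_tol` matched to the Brent grid (0.01 on log10,
≈ 2.3%), a 15-cycle cap with 10 starts for the one-deme benchmark and a
10-cycle cap with 5 starts and last-4-cycle iterate averaging for the
two-deme one (whose evaluations cost ~4× more), 5 and 4 replicate datasets
respectively, ε = 5 collapsing for the 651-class joint spectrum, and B = 50
(tests) / 30 (acceptance script) bootstrap replicates refitted with
2 starts at Z ≤ 5,000. At these sizes the median recovered parameters sit
within ~10% of the truths; per-dataset scatter is ~10–15%, part from the
data (~10× fewer SNPs than at full scale) and part from the Z-limited
objective noise discussed above.

## Known limitations

* Composite-likelihood CIs ignore residual linkage; they can be too narrow
  if sites are not effectively independent.
* Unfolded spectra only: derived states must be polarized by an outgroup.
* No recombination within loci and no serial (ancient) sampling.
* The AIC comparison uses the raw parameter count `d`; for strongly linked
  data an effective-parameter correction would be needed.
* The ratio estimator's O(1/Z) bias, while negligible for estimation, is
  detectable by very large replicate studies at small Z (entries near the
  bottleneck-induced kink of the spectrum show offsets of ~0.1 of the
  replicate standard deviation at Z = 10,000).
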