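# Methods

## The model

`cwqsar` builds one-descriptor regression models of a molecular endpoint
(our running example is log relative sweetness, log(S), in base-10 log
units):

    endpoint = C0 + C1 · DCW(T, N)

`DCW` ("descriptor from correlation weights") is the sum, over a
compound's attribute multiset, of per-attribute real weights. Attributes
come in three families extracted from the SMILES string:

* **S_k** — single SMILES-atoms: each indivisible token of the string
  (one character; `Cl`/`Br`; a whole bracket atom `[...]`);
* **SS_k** — ordered pairs of adjacent tokens (sliding window of two);
* **NNC_k** — per-vertex nearest-neighbor codes of the hydrogen-suppressed
  molecular graph, `100·N_T + 10·N_C + N_X`, where `N_T` is the vertex
  degree, `N_C` the carbon neighbors and `N_X` the rest.

Attributes occurring in fewer than `T` active-training compounds are
*rare*: their weight is pinned to 0 and they never enter the model
(`T = 3` by default). `N` is the number of optimization epochs
(default 15).

The weights are chosen by a Monte Carlo search that maximizes one of two
target functions over a four-way data partition — active training (A,
drives the OLS fit of C0/C1), passive training (P, guards against
overtraining), calibration (C, supplies the ideality/intensity term),
validation (V, untouched until final evaluation):

    TF = R²_A + R²_P − |R²_A − R²_P| + 0.3 · IIC_C     (TF_IIC)
    TF = R²_A + R²_P − |R²_A − R²_P| + 0.3 · CII_C     (TF_CII)

IIC is the correlation coefficient on C scaled by
`min(MAE⁻, MAE⁺)/max(MAE⁻, MAE⁺)`, the two MAEs taken over the negative
and non-negative residuals (observed − calculated); it punishes one-sided
residual clouds. CII is `1 − Σ_k max(0, R²₍₋k₎ − R²)`: each point's
"protest" is the rise in the determination coefficient when that point is
deleted, so CII near 1 means no point opposes the correlation. The 0.3
coefficient is an empirical weighting, kept configurable
(`tf_coefficient`).

## Optimization scheme

The literature on correlation-weight models does not pin down a specific
move rule, so this package commits to the simplest faithful one:

* weights initialize i.i.d. uniform on `[0.5, 1.5]` (seeded), so that
  independent runs genuinely differ — a requirement of the multi-run
  interpretation;
* an *epoch* is one full pass over the active attributes in a fresh
  seeded random order;
* each visit evaluates TF at `w − step`, `w`, `w + step`
  (`step = 0.1`), refitting `(C0, C1)` on the A set for every candidate,
  and keeps the best of the three (greedy coordinate ascent);
* the returned model is the best-TF state seen anywhere along the
  trajectory, not the final state, and the per-epoch trace of the running
  maximum is stored (it is non-decreasing by construction);
* any candidate that degenerates (zero DCW variance on A, constant
  predictions on C) scores −inf and is never kept.

With a fixed ±0.1 step the search needs roughly 25 epochs to settle on
noise-free data; at realistic noise (σ ≈ 0.1 log units) the target
function plateaus within the default 15.

Attribute frequency for the `T` rule counts *compounds containing* the
attribute; a switch (`count_occurrences`) counts total occurrences
instead. Validation compounds are only ever featurized — their endpoints
appear in no objective, and permuting them leaves the trained model
bit-identical (tested).

## Split search and model selection

`random_split` shuffles ids with a seeded generator and cuts contiguous
blocks; with equal quarters, remainders go to P first, then A, then C —
so 289 compounds give A/P/C/V = 72/73/72/72. The Las Vegas search simply
repeats (random split → full optimization) and keeps the trial with the
best calibration R² (ties: lower calibration MAE, then lower seed). The
same best-on-calibration rule selects among repeated optimization runs on
a fixed split in the experiment driver. Identity between two splits is
reported as the percentage of one split's role set that holds the same
role in the other; the denominator is the first split's role set, which
is why identity matrices are asymmetric.

## Validation metrics

All of: R² (squared Pearson correlation), MAE, IIC, CII, leave-one-out
Q² (hat-matrix shortcut, algebraically identical to explicit refits),
the external criteria Q²F1 = 1 − SSE/Σ(y−ȳ_train)²,
Q²F2 = 1 − SSE/Σ(y−ȳ_ext)², Q²F3 = 1 − (SSE/n_ext)/(SS_train/n_train),
the averaged Roy metric ⟨Rm²⟩ = mean over both regression directions of
r²(1 − √|r² − r₀²|) with r₀² the through-origin determination
coefficient, and the Fisher ratio F = r²(n−2)/(1−r²).

Numerical edge rules, chosen for continuity rather than exceptions in the
middle of an optimization run:

* IIC: perfect fit ⇒ 1; an empty residual side ⇒ ratio 0 ⇒ IIC 0; an
  undefined correlation (constant input) with an imperfect fit ⇒ 0. IIC
  keeps the sign of r, so a negative correlation reports a negative IIC.
* CII: a leave-one-out subset with zero variance contributes protest 0;
  full-set zero variance raises. The production implementation is an
  O(n) sums-update formula, pinned in tests to an independently coded
  O(n²) brute-force loop at 1e-12.
* Q²F and ⟨Rm²⟩ return a not-applicable marker (None) on zero
  denominators; the F ratio is not-applicable at r² = 1.

## Applicability domain

Attribute defect, with N the number of compounds of a set containing the
attribute and P = N / set size over the A, P, C sets:

    d_k = |P_A−P_P|/(N_A+N_P) + |P_A−P_C|/(N_A+N_C) + |P_P−P_C|/(N_P+N_C)

(zero-denominator terms contribute 0). A compound's defect D_j sums d_k
over its *distinct* non-blocked attributes (per-occurrence counting is a
switch). The reference population is A∪P∪C; a compound is in-domain iff
D_j < 2·D̄ with D̄ the reference mean. Because defects are non-negative,
Markov's inequality guarantees at least half of any reference population
is in-domain. One boundary rule is ours: if D̄ is exactly 0 (every defect
zero) the strict inequality would exclude everyone, so the domain is
defined as everything — there is no defect to exceed.

The probability definition P = compound frequency / set size is itself a
design choice; published defect tables are reproducible under it only for
the uniformly-distributed rows (defect 0.0000), which is what the test
suite asserts.

## Multi-run interpretation

Several optimizations differing only in seed give several weight tables.
An active attribute whose weight is strictly positive in every run is
classified a promoter of endpoint increase; strictly negative in every
run, of decrease; anything else is undefined (a configurable minimum
|weight| can tighten "strictly"). Reports are sorted by active-training
frequency, with per-attribute defects from the applicability module.
This is a statement about sign stability under restarts, nothing more.

## Synthetic data

No public sweetness dataset accompanies the method, so the package ships
a generator that emulates one. It builds a valence-respecting random tree
over C/N/O/S/Cl/Br (C-dominated), optionally closes up to three rings,
decorates saturated carbons with stereo brackets, and writes the SMILES
itself — every emitted string parses, and the parser's graphs agree with
RDKit's atom/bond/degree counts on thousands of samples. Endpoints are
generated from the model family's own form: linear in attribute counts
(planted weights: N +0.9, '=' +0.5, NNC-C...220. +0.4, O −0.6; C0 = 0.5,
C1 = 1.0) plus Gaussian noise of σ = 0.1 log units. The default
289-compound benchmark spans > 4 log units, the spread a log relative
sweetness endpoint shows in practice.

What the generator does *not* emulate: real sweetener chemistry
(fused rings, charges, tautomers), attribute collinearity structure of a
curated dataset, measurement error that correlates with structure, or
activity cliffs. Passing recovery tests therefore demonstrates that the
machinery can find a signal expressible in its own descriptor space —
not that real sweetness is so expressible.

## Problem sizes and determinism

The shipped tests run the full pipeline at the working scale of the
method (289 compounds, 72/73/72/72, T = 3, N = 15, best of 3 runs,
5 repetitions — about 10 s) and smoke-test the experiment driver at
smaller sizes (40–200 compounds, 1–25 epochs). Every random stream —
generator, splits, weight initialization, visit order — derives from
explicit integer seeds; identical inputs reproduce identical models,
reports and serialized JSON byte-for-byte.

## Known limitations

* The greedy fixed-step ascent has no annealing; it can stall on plateaus
  and needs more epochs as noise decreases.
* Duplicate detection is exact string equality after whitespace
  stripping; chemically identical compounds written as different SMILES
  are not merged (canonical-SMILES dedup is a non-goal here).
* The SMILES parser covers the subset the attribute scheme needs
  (chains, branches, ring closures 0–9, aromatic lowercase, bracket
  atoms, dots); it does not validate valence and ignores bond order
  beyond adjacency, which is all the NNC codes require.
* Q² is computed per reported set on its own (observed, calculated)
  pairs; whether a combined training pool should be used instead is left
  as a documented choice.
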