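# Methods

## The transcription model

The genome-wide transcriptional regulatory network (GTRN) is modeled as a
linear ODE system, one mRNA variable `y_i` per gene:

    dy_i/dt = alpha_i + sum_j beta_ij y_j + sum_k gamma_ik dv_k - delta_i y_i

* `alpha_i` — constitutive transcription rate (expression units · h⁻¹, ≥ 0)
* `beta_ij` — signed regulatory effect of transcription factor *j* (h⁻¹)
* `gamma_ik` — effect of environmental factor *k* per unit of uptake-flux
  deviation `dv_k = v_k − v_k_opt` (mmol g⁻¹ h⁻¹)
* `delta_i` — degradation/dilution rate (h⁻¹, > 0)

Expression units are arbitrary; the model is linear so only ratios matter.
The phenotype is the steady state `(D − B) y = alpha + G dv` with
`D = diag(delta)`.  Parameters are attached to *promoters*, not genes: an
operon's genes all share the regulation of its promoter region, and tandem
promoters contribute strictly additively in `(alpha, beta, gamma)` — no
transcriptional-interference term is modeled (a deliberate simplification;
interference between tandem promoters is real but outside this model's
scope).  `delta` is gene-intrinsic and survives every rearrangement.

Assumptions worth keeping in mind: parameters are independent of genomic
context (moving a gene under a promoter transfers that promoter's terms
unchanged); regulation is linear (no saturation, no cooperativity);
translation and post-transcriptional regulation are not modeled.

### Numerical choices

* The steady-state system is solved by LU factorization; a residual above
  `1e-9` (relative to the right-hand side) or a condition number above
  `1e12` raises an error naming the genes dominating the near-singular
  direction.
* The linear model can produce negative steady states.  Concentrations
  cannot be negative, so components are clipped to zero *after* solving,
  and the clipped gene ids plus the raw solution are returned in a
  diagnostics record.  Clipping is applied consistently wherever a profile
  is treated as a phenotype (fitness, optimality degree).
* `simulate_dynamics` integrates the same system with LSODA
  (`rtol 1e-10`, `atol 1e-12`) and warns — without failing — when `B − D`
  has an eigenvalue with non-negative real part.  The solver route
  (integration) is deliberately independent of the algebraic route
  (LU solve) so each can check the other.
* `response_time(g, env_from, env_to, epsilon)` is the last time the
  trajectory started at the old steady state is at max-norm distance
  ≥ `epsilon · ||y_to − y_from||∞` from the new steady state, located by a
  dense eigendecomposition scan plus bisection.  It returns 0 when the two
  environments give identical steady states.

## The objective

`S = w_exp · S_exp + w_mod · S_mod`, maximized.

**Expression similarity.**

    S_exp = −(1/(|G||E|)) Σ_{g∈G, e∈E} (y_cand − y_wt)² / (y_wt² + ε)

over a gene subset `G` ("all", or the stress / defense / enzyme category)
and environment set `E`; `ε = 1e-6` protects the division where
`y_wt ≈ 0`.  `S_exp ≤ 0`, with 0 exactly when the candidate reproduces the
wild-type profile on the subset.

**Modularity.**  The operon-size entropy, normalized by the fixed gene
count:

    S_mod = −H / ln(N),  H = −Σ_op p_op ln p_op,  p_op = |op| / N

`S_mod` is −1 for all-singleton genomes, 0 for a single operon, and —
because merging two operons coarsens the partition and strictly lowers H —
*strictly increases under every operon merge*.  That monotonicity is the
reason for normalizing by `ln(N)` rather than by the entropy's own
maximum `ln(#operons)`: the latter scores every uniform partition −1
regardless of how many operons it has, which both breaks monotonicity
(merging (2,1,1) into (2,2) would *lower* the score) and removes the
drive toward fewer operons that the refactoring objective exists to
provide.  The entropy form itself is this package's choice of modularity
measure; it is isolated behind `modularity_score` so alternatives can be
swapped in.

**Weights.**  Default `(w_exp, w_mod) = (1, 1e-6)`.  The two terms live on
incommensurate scales: `S_exp` is a *mean* over genes, so a single badly
placed gene changes it by only `~rel_err²/N`, while `S_mod` moves by
`~5e-3` per merge.  Any weight ratio near 1 therefore lets modularity buy
consolidation by sacrificing individual genes' expression — the opposite
of the design goal, which treats the wild-type phenotype as a constraint.
At `1e-6` the modularity term is a strict tie-breaker: it orders
expression-equivalent genomes by operon count but can never outbid a
resolvable expression error.

## The optimizer

Monte Carlo Simulated Annealing over genome space with four moves:

1. **move_gene** — a gene leaves its operon and is appended as the last
   cistron of another operon (both operons must be driven by
   non-constitutive primary promoters; constitutive genes are excluded
   from the design).  An emptied source operon is deleted.
2. **add_tandem** — a promoter from the tandem-candidate pool is fused
   upstream of an operon; at most 3 tandem promoters per operon.
3. **remove_tandem** — a tandem promoter's additive term is deleted; the
   primary promoter is never removable.
4. **replace_tandem** — one tandem promoter's term is substituted for
   another candidate's.

Every move is applied in place and returns a record whose inverse undoes
it exactly; the annealer evaluates a proposal, then either keeps it or
undoes it, never copying the genome except to snapshot a new best.

Proposal mixture: `(0.6, 2/11, 2/11, 0.4/11)` for
(move, add, remove, replace) — the probability of adding/removing a
tandem promoter is 10-fold that of replacing one.  Acceptance follows the
Metropolis rule for maximization: `S_new ≥ S` is always accepted,
otherwise the move is accepted with probability `exp((S_new − S)/T)`;
ties count as improvements.  `T(n) = t0 · r^n` with `r = 0.999` per
iteration and `2·10⁴` iterations per chain; 10 independent chains
("cells") run from per-chain RNG streams spawned from one master seed,
and each reports its best-so-far genome and full fitness trace.

**Choosing t0.**  The temperature must be compared with *per-move* score
changes, not with the O(1) range of `S`.  Because an emptied operon is
deleted together with access to its promoter, accepted worsening merges
are only partially reversible: once the last operon carrying some
regulatory function is absorbed, no move can reconstruct it.  A hot phase
with `T` large relative to per-move changes (which are `~rel_err²/N ≈
1e-4` for a 100-gene genome) therefore ratchets the genome irreversibly
into a few arbitrarily regulated operons.  The default `t0 = 1e-5` sits
at the tie-breaker/per-move scale: genuinely ambiguous moves are explored
early, while moves that destroy resolvable expression are rejected
throughout.  If the objective weights are changed, `t0` should be
rescaled accordingly (it is a schedule field).

**Starting condition.**  By default every gene starts alone in its own
operon under its natural promoter(s) — tandem promoters of the source
operon are carried along so the start expresses exactly like the wild
type.  Starting from the wild-type operon structure instead is supported
(`start="wildtype"`); both are natural conventions for the optimizer's
initial state, and the singleton start is the documented default.

## The compiler

A genome compiles to a single annotated chromosome, operon by operon in
the rank order of each primary promoter's original locus:

    [tandem promoter region + isolation spacer]* primary promoter region
    RBS₁ ORF₁+TAA RBS₂ ORF₂+TAA ... terminator

* A TAA stop codon is appended to every ORF *unconditionally*, accepting
  double stops, so each ORF is a self-contained rearrangeable module.
* RBS inference from annotation coordinates follows three rules: with a
  known transcription start site and a 5'UTR of ≥ 15 bp the RBS is the
  +1→start fragment; with an unknown TSS it is the 60 bp upstream of the
  start codon; with a 5'UTR < 15 bp (including leaderless transcripts,
  which are still treated as RBS regions) the UTR is enlarged by an
  additional 60 bp upstream, total `utr + 60`.
* A cistron still in its native operon keeps its native RBS.  A cistron
  that arrived by refactoring receives the same RBS as every other
  arrival at that operon: the destination's first-cistron RBS by default,
  or a configured standardized RBS.
* Tandem promoter regions are isolated by a fixed neutral 20 bp spacer
  (configurable); the model offers no sequence-level interference
  prediction, so the spacer is a placeholder for a validated insulator.
* Opposite-strand operons whose promoter region overlaps a neighboring
  ORF are separated by duplicating the shared bases into both parts
  (`resolve_overlap`); same-strand overlaps are rejected as outside the
  rule.
* Reverse-strand operons are assembled 5'→3' on the coding strand and
  reverse-complemented into the chromosome; coordinates are 1-based
  inclusive GenBank convention.

The emitted GenBank embeds part keys and all numeric model parameters in
feature qualifiers, which makes `parse_genome` an exact inverse for
genomes without moved genes (`parse(compile(g)) == g`) and
`compile∘parse∘compile` byte-identical.  Compilation is deterministic
(fixed record date, sorted qualifiers).  SBML export is not provided;
the TSV bundle is the canonical interchange format.

## Evaluation metrics

* **Complexity ratios** `Xi` (regulatory interactions) and `Theta`
  (operons), refactored / wild type.  An interaction is an (operon, TF)
  pair with a nonzero effective beta — the granularity at which moves
  change the network.  Environmental (gamma) edges are counted separately
  as a diagnostic and excluded from the headline `Xi`.
* **Optimality degree** `xi = S_exp(dv = 0) − S_exp(target)`: positive
  means sub-optimal adaptation in the target environment, negative
  over-optimal; exactly 0 at the optimal environment, antisymmetric under
  swapping the two evaluation points.
* **Functional similarity** `Phi_op`: the largest fraction of an operon's
  genes sharing one function label; 0 for singleton operons by
  definition, since one gene cannot exhibit shared function.
* **Topology**: per-promoter load (operons and genes driven), the
  tandem-count histogram, and the average clustering coefficient of the
  TF co-regulation projection (two TFs linked iff some operon's effective
  regulation contains both).  The projection graph is this package's
  construction; note a two-TF projection has no triangles and so a
  clustering coefficient of 0.

## The synthetic-data generator

`generate_gtrn` emulates the *structure* the method assumes, at desk
scale: singleton operons (the optimizer's start), a TF fraction
defaulting to the 330/4298 ≈ 7.7% of the target organism, gene category
tags (enzyme/stress/defense/TF), GO-style annotations from a 184-label
vocabulary, and full sequence parts so every genome compiles.  Key knobs:

* `redundancy` — promoters come in groups of this size sharing an
  identical `(alpha, beta, gamma)` set, so a ground-truth consolidation
  with bitwise-unchanged expression exists (100 genes at redundancy 5
  → 20 operons).  This is the parameter-recovery surface the annealing
  tests use.
* `delta ~ LogUniform(0.1, 2) h⁻¹`, `alpha ~ LogUniform(0.5, 5)`;
  1–3 regulators per promoter with signed `beta` magnitudes
  `U(0.05, 0.5)`; `gamma` sized relative to `alpha` and each factor's
  typical flux deviation so environmental effects are commensurate with
  constitutive transcription.
* Stability is enforced, not assumed: all `beta` are globally rescaled
  until the spectral abscissa of `B − D` is ≤ `−0.1 · min(delta)`.

`generate_environments` reproduces the three perturbation designs used
for adaptation analysis: oxygen uptake `U(0, 4×75)` around an optimum of
75 mmol g⁻¹ h⁻¹, glucose uptake `U(−20, 20)` around 20, or both jointly
(every `dv ≠ 0`); element 0 is always the optimal environment.

What the generator does **not** emulate: real expression-level
distributions, RegulonDB's actual operon/promoter content, overlapping
genes, transcriptional read-through, or measurement noise.  Passing the
recovery tests therefore shows the optimizer finds designed redundancy
under the model's own assumptions — not that a real genome would tolerate
the rearrangements.

## Problem sizes used by the test and acceptance suites

Chosen to keep the full suite in the low minutes on one CPU: solver
cross-checks use 100 random genomes of 5–30 genes; compiler round trips
100 genomes of 4–12 genes; Metropolis statistics 10⁵ draws; the recovery
experiment one 100-gene genome (redundancy 5, 4 perturbed environments)
annealed for 2·10⁴ iterations in 10 single-chain runs.  The recovery
test measures its own noise floor by re-deriving the wild-type profile
through ODE integration and scoring the wild type against it.

## Known limitations

* Linearity: strong activation can predict unbounded expression, and
  negative solutions are an artifact handled by clipping.
* Deleted operons take their promoters out of reach of subsequent moves;
  the search is therefore not reversible in the Markov-chain sense, and
  temperature must be kept at per-move score scale (see above).
* Tandem promoters combine purely additively; no interference,
  occlusion, or roadblock effects.
* `parse_genome` is an inverse only for the compiler's own feature
  vocabulary — it is not a general GenBank importer.
* Per-gene RBS/translation strength is out of scope; equal expression of
  all cistrons in an operon is a model assumption, not a prediction.
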