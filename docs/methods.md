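# Methods

## Model summary

`mcrs` is an individual-based stochastic cellular automaton of RNA
replicators bound to a mineral surface.  Sites of a G × G toroidal lattice
are empty or hold one replicator.  One generation performs G² asynchronous
site updates, each on an independently drawn uniform-random site (with
replacement — the standard asynchronous convention; a random permutation
per generation would also give each site unit expected exposure, but the
per-update decay and claim probabilities pair naturally with independent
draws).  An occupied site decays with probability p_deg; an empty site runs
a replication lottery among its four von Neumann neighbours and, if a
template wins, receives a mutated copy of it.  After every site update the
Toffoli–Margolus diffusion operator runs on average D times: a uniformly
anchored 2 × 2 block (wrapping toroidally) is rotated 90° clockwise or
counter-clockwise with equal probability, permuting cell contents without
creating or destroying anything.

## Genotype → phenotype

The genotype is the nucleotide sequence (alphabet ACGU, length ≤ 70 nt).
The phenotype pipeline is: MFE fold (dot-bracket + free energy E from a
pluggable backend, ViennaRNA by default) → loop decomposition → motif
detection → derived rates.  Key quantities:

| quantity | definition | default constants |
|---|---|---|
| folding probability | p_fold = 1/(1 + e^{cE}) | c = 0.3 |
| decay probability | p_deg = 0.9 − 0.8·E/E_min, E clamped to [E_min, 0] | E_min = −25 kcal/mol |
| replicability | R = g·[l + (1 − p_fold)]/(b₁ + b₂·L) | g = 10, l = 1, b₁ = 1, b₂ = 0.05 |
| effective activity | a_i = p_fold·α_i/m^σ, m = #distinct active reactions | σ = 1.1 |
| metabolic activity | M = (Σa₁·Σa₂·Σa₃)^{1/3} over the h × h Moore neighbourhood | h = 3 |
| claim | C = M·R; empty-site claim C_e = ε·(max claim) = 1.048 | ε = 0.1 |

The exponent of the folding-probability logistic is +cE (so that stability,
E < 0, raises p_fold): this is the only sign choice consistent with the
anchors p_fold(0) = 0.5 and p_fold → 1 at optimal energy, and with the
role of p_fold throughout the model.

Motif rules (loop positions counted 1-based along a loop's unpaired bases,
5′-side run before 3′-side run for internal loops):

1. internal or bulge loop, length 5, A at position 3 → α₁ = 1.0; an
   unpaired U at position 2 or 4 → 1.1; length 4 with A at position 2 or 3
   → 0.1;
2. hairpin loop, length 9, G at position 5 → α₂ = 1.0; A at 4/6 → 1.1;
   length 8 with G at 4/5 → 0.1;
3. hairpin loop, length 13, U at position 7 → α₃ = 1.0; C at 6/8 → 1.1;
   length 12 with U at 6/7 → 0.1.

Design choices where the rules underdetermine behaviour: a loop yields at
most one site; several loops matching the same reaction contribute their
maximum α (the best site catalyses; m counts distinct reactions only,
matching the time-sharing rationale of the promiscuity penalty); both
helper positions matching still gives a single +10%; weak (0.1) sites count
towards m and towards type classification; the "middle" position of an
asymmetric internal loop is taken on the concatenated 5′+3′ ordering.  The
focal replicator's own activities count in its metabolic neighbourhood.
Backends returning a positive MFE are clamped to the open chain with E = 0,
keeping p_deg within [0.1, 0.9]; degenerate MFE structures are not
detected — the backend's single returned structure is the fold.  Fold
results and phenotypes are memoised per exact sequence string (unbounded
within a run; the population revisits genotypes constantly and folding
dominates cost).

## Mutation

During a successful replication the copy mutates per base, independently:
substitution with p_sub = 0.01 (uniform over the three other bases),
deletion with p_del = 0.001, and insertion of a uniform-random base with
p_ins = 0.001 in each of the L + 1 gaps (before the first base and after
every base, so insertion opportunities are equal across positions).
Insertions that would push the copy past L_max = 70 are rejected 5′→3′;
the copy itself still succeeds.  The empty string is a legal genotype (an
unfoldable parasite).

## Randomness and reproducibility

All stochastic draws flow through one seeded `numpy.random.Generator`.
Draw order is fixed and documented per operation (site index; decay
uniform or lottery uniform; mutation draws in the order substitution
uniforms, deletion uniforms, gap uniforms, then replacement/inserted bases
5′→3′; diffusion anchor then direction; fractional-D Bernoulli only when D
is non-integral).  A fixed seed therefore reproduces a trajectory
bit-for-bit, and `state.json` bundles (sequences + RNG state) resume
exactly.

## Observables

Replicators are classified by their set of catalysed reactions ({1}, {2},
{3}, {1,2}, {1,3}, {2,3}, {1,2,3}, or P for parasites; weak 0.1 activity
counts as active).  Snapshots record per-type lattice frequencies, mean
raw activity per reaction over its carriers (the per-carrier mean is used,
not the lattice-wide or penalised mean — it is the quantity that sits near
1.0–1.1 in an adapted community), per-type mean lengths, and per-type
folding-energy histograms (1 kcal/mol bins on [−25, 0], energies clamped
into range).  Survival sweeps run independent replicates per configuration
and declare extinction when the lattice empties or when some reaction type
has had no carrier anywhere for 50 consecutive generations — Eq.-4-style
metabolism is then impossible everywhere, and the grace window tolerates
transient local loss (a lost type can in principle be re-created by
mutation).

## Synthetic data and designed genotypes

Random initial populations are the model's own study condition: each site
is occupied with probability 0.8 and receives a uniform-random sequence of
length uniform on [25, 60].  These pools emulate an abiotic sequence pool;
they reproduce the expected composition (≈ 19% of sequences carry at least
one activity with the installed ViennaRNA 2.7; promiscuous genotypes < 1%;
activity-3 carriers, needing the 13-base hairpin, are rarest at ≈ 1%).
What they do not emulate: any sequence bias of real prebiotic chemistry,
suboptimal/ensemble folding, pseudoknots, or 3D structure.

The test suite additionally uses *designed* mono-active ribozymes (GC
stems around each catalytic loop, MFE below −25 kcal/mol) as an analogue
of an evolved community, and a synthetic tri-active stub backend for
engine tests that must not depend on thermodynamics.  Both are labelled as
synthetic where they appear.

## Numerical scale of the shipped checks

The shipped tests and the acceptance script are sized for a desk machine:
random-pool composition and the backend energy range use 10,000 folds
each; community-dynamics tests run 16–50-site lattices for 80–800
generations; the lottery/mutation oracles use 10⁴–10⁵ draws against 3–4σ
binomial bands.  Full-scale runs (300 × 300, 10⁶ generations, 100
replicates) are supported by the same code path via the CLI but are not
exercised by the tests.

## Known limitations and deviations

* **Backend energy floor.**  With ViennaRNA 2.7 the minimum MFE over
  10,000 random 15–75-mers is ≈ −33 to −37 kcal/mol, i.e. below the
  −25 kcal/mol reference floor assumed by the model's E_min constant.
  E_min is kept at −25 and energies are clamped into [E_min, 0] wherever
  E_min enters a rate, so p_deg stays in [0.1, 0.9]; the raw (unclamped)
  energies are reported in snapshots and histograms.
* **Boot phase from a random pool.**  Under the model equations as
  implemented, a random initial pool is subcritical: only ~1.6% of initial
  replicators have a metabolically complete 3 × 3 neighbourhood (the
  hairpin-13 motif is the bottleneck) while the pool decays at ≈ 0.55 per
  generation (mean MFE ≈ −8 ⇒ p_deg ≈ 0.64), so the community collapses
  within tens of generations at every lattice size tried, up to and
  including 300 × 300.  The *established* regime is viable and robust:
  communities seeded from stable mono-active ribozymes persist
  indefinitely under local metabolism (h = 3), hold parasites at a stable
  minority, keep promiscuous types rare, and collapse in the mean-field
  limit (h = lattice) — the advantage-of-rarity contrast the model is
  about.  The dynamics tests therefore start from seeded communities; the
  acceptance suite also runs the random-pool condition as specified and
  reports its outcome.
* Replication and unfolding are temporally separated (a worst-case
  assumption: only the unfolded state is copied); metabolites are implicit
  in h; all replicators share one diffusion rate.
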