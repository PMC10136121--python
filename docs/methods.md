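# Methods

## The screen

The unit of inference is a **diagnostic residue**: a position in a
*C. elegans* reference protein whose amino-acid identity separates the
rhodoquinone-capable (facultatively anaerobic) form of the enzyme from
the purely aerobic one. The panel carries five sites on four markers
(COQ-2 L204/S243, MEV-1 G71, TDO-2 P133, ETFDH F437). Screening a
species proceeds in three steps.

**Homolog search.** For each marker, the reference protein is locally
aligned (Smith–Waterman with affine gaps, BLOSUM62, gap open −11 /
extend −1 — the conventional protein-BLAST parameterisation) against
every candidate protein. A gap of length *k* costs
`open + (k−1)·extend`. The best-scoring candidate is accepted as the
homolog only if it reaches **identity ≥ 0.30** over the aligned columns
and **reference coverage ≥ 0.60**; both thresholds are conservative
homology-screen conventions (no cutoffs are published for the original
searches) and are overridable everywhere. Score ties break by longer
reference coverage, then lexicographic sequence id. Only the best hit
per marker is used for calls; additional positive-scoring sequences are
a logging concern, not a calling one — no ortholog/paralog
disambiguation is attempted.

Nucleotide contigs are screened by translating all six reading frames
(standard code, `N → X`, peptides split at stop codons) and treating
every stop-free segment of ≥ 30 residues as a candidate protein. This
reproduces the *procedure* of a tblastn search with optimal DP instead
of a heuristic HSP engine, which is sufficient at proteome scale; there
are no E-values, word seeding, or banded DP.

**Residue calls.** Each diagnostic site is mapped through the alignment
into the homolog. A site outside the aligned reference span, a site
mapped into a deletion, or an absent homolog yields `MISSING`
(deliberately distinct from an alignment gap character); otherwise the
homolog residue is compared to the anaerobic residue, giving
`ANAEROBIC_MATCH` or `VARIANT`. Any non-matching residue is a variant —
no similarity grading — because the one published variant reading
(Hydra's A for S243) is treated simply as a variant.

**Classification.** From the five calls:
`FULL_SIGNATURE` iff all five match; `NO_SIGNATURE` iff zero matches and
zero missing; `INSUFFICIENT_DATA` iff zero matches with at least one
missing; `PARTIAL_SIGNATURE` otherwise. The four-way split is this
package's convention (the source material describes the pattern in
prose); per-site counts are always reported so users can apply their own
rules. Note the printed survey's `-` cells do not distinguish "no
homolog found" from "assembly gap"; both are `MISSING` here, which keeps
rows like *Diadumene lineata* at `PARTIAL_SIGNATURE` through their ETFDH
match rather than guessing a cause.

### Numerical and determinism choices

* Traceback tie-break: diagonal > up (gap in target) > left (gap in
  reference); the best local cell is the first maximum in row-major
  order. Outputs are therefore deterministic.
* `X` (ambiguous translation) scores 0 against everything; IUPAC codes
  other than `N` are rejected rather than silently translated.
* Every emitted alignment's score is recomputable from its aligned
  strings and the gap parameters; the test suite asserts this
  self-consistency and checks DP scores against exhaustive enumeration
  of the alignment space on short sequences, and against an independent
  aligner (biopython's `PairwiseAligner`) on longer ones.
* The DP fill loops are numba-compiled; the first call in a process pays
  a JIT cost of a few seconds.

## Ancestral states

Fitch (unordered, equal-cost) parsimony, chosen over likelihood methods
because the question — could the common ancestor have carried the
signature? — is posed as a character-state reconstruction and no branch
lengths are trusted or needed. Characters are either **binary**
(anaerobic residue present / absent per site) or **residue** (raw amino
acids). `MISSING` enters as `?`, which contributes the full observed
state alphabet (the standard wildcard treatment); characters with fewer
than two observed tips are rejected as uninformative. The bottom-up pass
counts unions (= parsimony length); the top-down pass resolves each
node's preferred set by intersection with its parent's, keeping ties as
sets — no arbitrary single-state resolution. On multifurcating nodes
children are folded sequentially, which is exact on binary trees (all
trees used in testing are binary). Topology is always a user input;
since the divergence order of the early animal groups is debated, the
intended use is to report reconstructions across candidate topologies
rather than to pick one.

In the recovery simulations a root state counts as recovered when the
simulated state is **in** the most-parsimonious root set: an ambiguous
tie set is an honest "cannot decide", not an error, and ties are
reported as sets by design.

## Pathway stoichiometry

Yields are computed per mole of glucose in exact rationals
(`fractions.Fraction`); reports render three decimals. Lactate and opine
formation are 1:1 pyruvate redox sinks: 2 ATP and 2 product moles per
glucose, with the 2 cytosolic NADH consumed by product formation —
identical ledgers, as expected for analogous reactions.

Malate dismutation: glycolysis stops at PEP (net 0 ATP, 2 NADH); PEPCK
carboxylates PEP to oxaloacetate (+1 ATP/PEP); malate dehydrogenase
consumes the cytosolic NADH; mitochondrial malate splits between an
oxidative branch (2 NADH and 1 ATP per malate, to acetate) and a
reductive branch (1 NADH consumed per fumarate reduced, to succinate and
by default on to propionate, +1 ATP). Mitochondrial redox closure
`2·oxidized = reduced` forces the 1:2 split, giving ⅔ acetate and 4⁄3
propionate per glucose. The ledger (produced vs consumed NADH, itemized
by compartment) is checked on every evaluation and a spec that cannot
close — e.g. a user-forced 1:1 split — raises with the imbalance
itemized.

Two coefficient conventions deserve a note:

* **PEPCK sign.** The enzyme is named ATP-dependent, but the
  yield-generating convention of the comparative-physiology literature
  books +1 ATP at this step (the pyruvate-kinase ATP forgone upstream is
  recovered here); this package follows that convention and exposes the
  coefficient (`pepck_atp_per_pep`) rather than resolving the
  discrepancy.
* **Chemiosmotic coefficient.** The ¾ ATP per NADH oxidized through the
  truncated chain to fumarate is a *calibration*: the literature states
  the ~2.5× ATP advantage of dismutation over lactate, not a full
  ledger, and ¾ is the value under which the default ledger nets exactly
  5 ATP/glucose and the ratio exactly 2.5. It is physiologically
  sensible (proton pumping at Complex I only) and user-overridable; with
  it set to 0 the ratio drops to 2.0.

Succinate excretion is supported (`SUCCINATE` mode zeroes the propionate
ATP term) but propionate is the default end product, since succinate is
typically converted further before excretion.

## Synthetic data

The generator emulates the statistical structure the screen assumes:
exactly one homolog per marker, diagnostic residues planted at
reference-mapped positions, background divergence, and decoys.

* **References**: random stand-in proteins (370/260/300/620 residues for
  COQ2/MEV1/TDO2/ETFDH — long enough to host each site with realistic
  flank) with the anaerobic residues planted. Real reference sequences
  can be supplied instead wherever a panel is built.
* **Genotypes**: per-site intended states; variant sites default to the
  aerobic (human-row) residues, so the 32 pure binary genotypes span the
  match/variant cube.
* **Noise**: i.i.d. substitutions and geometric-length indels
  (mean 2) at per-position rates, applied outside a ±2-column protected
  window around each diagnostic site, so noise degrades the alignment
  without silently rewriting the truth; set `protect_window=0` to
  exercise exactly that failure mode. Decoys are i.i.d. draws from the
  reference set's residue frequencies (default 20 per proteome, 80–600
  residues).
* **Contigs**: uniform synonymous reverse translation with random
  flanks, placed on a chosen strand and frame.
* **Tree evolution**: each site flips anaerobic↔variant independently
  per branch with a given probability; tips are materialized as
  proteomes; the truth table covers internal nodes.

Everything is deterministic under its seed (byte-identical FASTA).

What passing these simulations does **not** show: robustness to real
substitution processes (no rate matrices or heterogeneity), to domain
architecture in decoys, to paralogy, or to fragmented assemblies. The
screen's behaviour on real proteomes should be validated against known
positives (e.g. *C. elegans* itself) before trusting novel calls — the
absence of hits in some published genomes shows that sensitivity limits
of this kind of screen are real.

## Problem sizes used in the checks

Oracle equivalence runs 100 seeded random pairs (lengths ≤ 8) for each
of global and local alignment against full enumeration, and 200 random
trees (≤ 6 tips, ≤ 4 states) against exhaustive labeling. Parameter
recovery runs all 32 pure genotypes noise-free, 50 replicates at 2%
substitution (all recovered), 50 replicates adding indel rate 0.005
(≥ 95% recovered), and 100 tree characters (20 twelve-tip trees × 5
sites) at per-branch flip probability 0.05 (≥ 90% root recovery). These
sizes make exhaustive oracles exact while keeping the default suite
around a minute on one CPU.

## Known limitations

* The homolog search takes the best hit only; recent duplicates with
  divergent residues are invisible to the calls.
* Fitch parsimony ignores branch lengths and cannot weigh gains against
  losses; "ancestral anaerobic" conclusions are topology-dependent by
  construction.
* The stoichiometry is a yield ledger, not a flux model: no kinetics,
  no thermodynamics, no genome-scale constraints.
* The printed survey matrix is transcribed, not regenerated; re-running
  the actual database searches is out of scope.
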