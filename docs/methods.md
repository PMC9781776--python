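# Methods

## The reference network

The packaged network (`src/sugarnet/data/aniger_sugar_network.yaml`)
encodes the *A. niger* sugar catabolic model as 14 pathway records (11
top-level pathways; D-galactose metabolism carries three sub-pathways —
Leloir, oxidoreductive, and the non-phosphorylated De Ley–Doudoroff route)
and 80 reaction records over 77 named or placeholder reference genes. Each reaction carries EC numbers, a kind
(`enzymatic` / `spontaneous`), a role (`core` / `auxiliary`), an orphan
flag, its pathway memberships and its reference gene assignments.
Structural choices:

- **Core vs auxiliary.** Glycolysis is modeled as the canonical ten-step
  core sequence; the gluconeogenic fructose-1,6-bisphosphatase and the
  D-fructose phosphorylation entry (EC 2.7.1.4) are auxiliary. This keeps
  the conventional "ten reactions" count queryable while retaining the
  extra steps. Likewise the TCA cycle is the eight-reaction loop, with
  pyruvate carboxylase auxiliary; the acetate route into acetyl-CoA
  (acetyl-CoA synthetase, oxaloacetate acetylhydrolase) is auxiliary to the
  glyoxylate cycle.
- **Shared reactions.** Malate dehydrogenase, aconitate hydratase and
  citrate synthase are stored once with membership in both the TCA and
  glyoxylate cycles, so they count in both pathways' completeness
  denominators without duplication. The fructokinase exit of the
  oxidoreductive galactose route and the glycolytic fructose entry share an
  EC number but are separate records, because their core/auxiliary role
  differs per pathway and `role` is reaction-level.
- **Orphan reactions.** Two steps have no known catalyzing gene in any
  studied fungus: the 2-dehydro-3-deoxy-gluconate aldolase of D-gluconate
  catabolism and the penultimate (aldolase) step of the De Ley–Doudoroff
  route. They are retained structurally but excluded from completeness
  scoring in both numerator and denominator — otherwise no species,
  including the reference, could reach 100 %.
- **Spontaneous steps** (the first conversion of D-galacturonic acid)
  carry no genes and always count as present: they are chemistry, not
  genetics.
- **Gene roster.** Only genes identifiable by name from the curated model
  are encoded; enzymes whose gene identity rests on genome annotation
  rather than a named characterized gene carry `placeholder: true` (for
  example the TCA enzymes and the malate synthase step, which also carries
  an explanatory `note`). Gene-level totals over the packaged file are
  therefore configuration, not assertions about the full reference gene
  complement.

The YAML loader validates all invariants (partitioned identifiers,
resolvable pathway references, EC syntax `d.d.d.(d|-|nN)`, geneless
spontaneous/orphan reactions, no empty pathways) and a canonical serializer
makes round-trips bit-exact.

## Orthogroup merging

Both input dialects are partitions of species-qualified gene identifiers
(`species|locus`). The merge rule — replace any two groups sharing a member
by the union of their members — is applied to a fixpoint by computing
connected components of the bipartite group/gene overlap graph. A single
pairwise pass would not suffice: chains such as {A,B} + {B,C} + {C,D} must
collapse for the output to be a partition, which downstream projection
requires. Output group identifiers are synthesized deterministically as
`MG` + the zero-padded rank of each group's lexicographically smallest
member, so merged sets are reproducible regardless of input order.
Duplicate members within a line or cell are collapsed with a logged
warning; genes absent from every group are treated as unassigned, with an
optional helper that materializes them as singleton groups.

## Projection and completeness

A candidate gene for a reaction is any target-species ortholog of any of
the reaction's reference genes. Projecting onto the reference species
additionally includes each reference gene as its own candidate, making the
reference row complete by construction even for genes the orthology tools
left unassigned. Candidate status is one of `active`, `low_expression`
(maximum FPKM strictly below the threshold, default 10, in every tested
condition), `no_expression_data` (absent from the matrix — retained,
because a species may simply lack transcriptome data), or
`excluded_by_list` (the manual-curation analogue: an input list, not a
computed homology filter).

Completeness is reported to one decimal as 100 × present / scorable.
Presence requires at least one `active` or `no_expression_data` candidate;
copy number affects only gene counts, which tally distinct unfiltered
candidates once per pathway. The filter is monotone by construction:
raising the threshold can only demote candidates, so no pathway's
completeness or gene count increases.

The PathoLogic export writes one protein entry per unfiltered candidate
(`ID`, `NAME`, `PRODUCT-TYPE`, `PRODUCT`, `EC` lines inherited from its
reactions), with 1-based inclusive coordinates when provided and
minus-strand genes encoded by `STARTBASE` > `ENDBASE`. Output is sorted and
byte-deterministic.

## Omics screens

- **Condition clustering** uses distance 1 − Pearson between condition
  columns over the sugar-metabolic gene subset, average linkage, with
  columns processed in sorted label order so tied merges are deterministic.
  Callers cluster on the log2(FPKM + 1) scale — the standard scale for
  expression-profile similarity — because on the raw FPKM scale a handful
  of strongly induced high-abundance genes dominate the correlation and
  obscure the condition-block structure. A constant condition column is an
  error (correlation undefined), named in the message.
- **Induction rule** (a transparent stand-in for "visibly induced on its
  cognate sugar"): a gene is induced when its cognate-condition FPKM is the
  row maximum and at least `induction_fold` (default 2) times the median of
  the other conditions; when that median is zero the cognate value must
  instead clear the FPKM threshold. The fold is reported alongside the
  flag. The rule is parameter-exposed and exactly recoverable on synthetic
  truth.
- **Proteome roll-up** follows the de-log → sum → re-log → renormalize
  order: only protein-specific peptides contribute; a protein is missing in
  a sample iff all its peptides are; zeros are treated as missing (not
  detected) before any log step and reinstated only at the
  replicate-averaging stage, where each condition's value is the mean of
  its strictly positive replicates (0 if none). Central-tendency
  normalization shifts each column so its non-missing mean equals the grand
  mean of the input; it is idempotent and preserves within-column
  differences exactly. Pathway abundance profiles drop proteins detected in
  fewer than one-third of conditions (strict: 3 of 9 is kept, 2 of 9
  dropped) and report n/median/quartiles per (pathway, condition).
- **Correlation screen**: Pearson correlation over the shared conditions
  (≥ 4 required), two-sided p from the exact t transform with n − 2 degrees
  of freedom. A pair passes at |PCC| ≥ 0.5 and p < 0.05; `strong` is
  positive-only (PCC ≥ 0.8), while negative correlations can pass the
  screen and are reported with their sign. Zero-variance vectors are
  excluded with a warning rather than producing undefined coefficients.

## The synthetic scenario generator

The generator emulates the study design the omics tables come from: nine
monosaccharide growth conditions, three proteome replicates per condition,
and a taxonomic gradient of three target species — a close relative
retaining everything (`eur`), a moderately diverged species (`sor`,
retention 0.95), and a basidiomycete-style species (`bas`, retention 0.85)
with the L-rhamnose lactonase/dehydratase, L-arabinose-specific PCP
enzymes, ribokinase and glycerol dehydrogenase deleted outright, mirroring
the losses that distinguish Basidiomycetes from Ascomycetes in fungal
sugar catabolism.

Mechanics, all driven by one seed with per-species sub-streams derived by
stable hashing of the species tag (adding a species never perturbs
others):

- **Retention is gene-level**, not reaction-level: shared genes (the
  aldose reductase acts in three pathways) make reaction-level loss
  inconsistent. A gene's retention probability is the maximum over its
  pathways' configured retentions — a gene kept for any purpose exists in
  the genome. Lost reactions and expected completeness are derived from
  gene retention and pseudogene placement by direct counting, independent
  of the projection code, and stored in the manifest.
- **Duplication**: retained genes carry 1 + Binomial(2, p) ortholog
  copies.
- **Expression**: per-gene baseline drawn log-uniform over ≈ 30–500 FPKM
  with multiplicative log-normal noise (σ = 0.25 by default, matching the
  dynamic range of RNA-seq abundance); hexose, pentose and uronic-acid
  condition blocks share a latent per-gene factor (σ = 0.5) emulating
  co-regulation, which is what condition clustering recovers. Genes whose
  pathways map to a single cognate sugar are induced 8-fold on it;
  pseudogene copies get a flat value drawn uniform on [0, 10), sitting
  strictly under the filter. Non-specific genes are screened against
  D-glucose as decoys.
- **Proteome**: two specific peptides per non-pseudogene copy, values tied
  to log2 expression with replicate noise and 10 % missingness.
- **Metabolome**: the first five induced genes get a planted partner
  metabolite constructed as ρ·z(x) + √(1 − ρ²)·ε (ρ = 0.9) on a positive
  abundance scale, plus independent log-normal decoys.
- **Orthogroup discordance** splits a configurable fraction of groups in
  the OrthoFinder emission only; the OrthoMCL emission carries the truth.
  Merging the two therefore provably equals the unsplit truth, giving an
  exact oracle for merge correctness, and the merged set has fewer groups
  than the split emission.

What the generator does **not** emulate: genuine sequence divergence (no
ortholog detection is performed — group membership is planted), mapping
biases or count overdispersion in FPKM values, shared peptides between
paralogs, batch effects, or metabolite identification ambiguity. Passing
the recovery suites therefore demonstrates the correctness of the
bookkeeping, filters, scoring and screens under the stated statistical
structure — not robustness to the full messiness of real multi-omics data.

## Numerical and testing choices

- Completeness is rounded to one decimal; candidate ordering is
  lexicographic; merged group ids rank by smallest member; all emitted
  files are deterministically ordered so identical seeds give byte-identical
  directories.
- Exact-recovery suites (completeness, pseudogene flags, induction calls)
  run the generator with expression noise disabled, the setting under which
  the induction rule is exactly identifiable; the default noisy setting is
  used for the correlation and clustering checks, which are tolerant by
  design (planted ρ recovered within ±0.15 at n = 9).
- The null calibration of the correlation screen uses 10,000 independent
  standard-normal pairs at n = 9, built from batch diagonals so pairs share
  no vectors; the observed p < 0.05 rate must sit within 3 Monte-Carlo
  standard errors of 0.05.
- Problem sizes in tests and in `scripts/acceptance.py` (500 fuzzed merge
  instances, 20 scenario seeds, three species, 10,000 null pairs) were
  chosen to exercise every code path at desk scale; the whole suite runs in
  well under a minute.

## Known limitations

- The packaged gene roster covers named genes only; projecting a real
  genome requires the user's own orthogroup files over the full reference
  complement.
- The manual "low sequence homology" curation step is represented only as
  an input exclusion list; no homology scores are computed.
- Growth profiling is out of scope: the package predicts pathway
  completeness, not growth.
- The `strong` label is positive-only by design; a strongly negative
  gene–metabolite correlation passes the screen but is never labeled
  strong.
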