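# Methods

This note records the models, procedures and numerical choices behind
`clamtc`, and what the synthetic-data experiments do and do not
establish about real data.

## The inference problem

A tissue of a clam with transmissible haemic neoplasia is a cell
mixture: host cells carry the animal's own diploid genome and haploid
(high copy number) mitogenome; tumour cells carry the clonal genome of
the cancer lineage, here of a different species' origin. Sequencing
reads from such a tissue are therefore a mixture of two genotypes, and
the package's job is to (i) detect the mixture, (ii) quantify it,
(iii) separate the two genotypes, and (iv) place the tumour genotype
phylogenetically.

## Synthetic study generator

`simulate.SimulationConfig` defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| `mito_length` | 18 000 bp | circular mitogenome length (venerid mitogenomes are ~17.6–18.1 kb) |
| `nuclear_locus_lengths` | (2900, 2200) bp | the two single-copy nuclear loci (an RNA-helicase gene fragment and a transcription-factor gene fragment) |
| `target_k2p` | 0.21 | interspecific mitogenome divergence, K2P substitutions/site |
| `kappa` | 2.0 | transition:transversion ratio of interspecific differences |
| `theta_within` | 0.002 /site | intraspecific polymorphism probability per allele copy |
| `nuclear_divergence` | 0.03 | fraction of nuclear sites with fixed interspecific differences (~15 per 500 bp, the density seen on sequenced fragments) |
| `read_length`, `insert_size`, `insert_sd` | 150 bp, 350 bp, 30 bp | Illumina paired-end library geometry |
| `error_rate` | 0.001 /base | i.i.d. substitution error, uniform alternate base |
| `mito_copy_ratio` | 1.0 | tumour-cell : host-cell mtDNA copies per cell |
| `coverage_mito`, `coverage_nuclear` | 100×, 60× | mean fold coverage per tissue library |

Design choices:

* **Exact divergence placement.** Rather than simulating a
  substitution Markov chain and accepting sampling scatter, the
  transition/transversion difference proportions (P, Q) that invert the
  K2P formula at the target distance (with P = κQ) are solved
  numerically and the corresponding integer site counts placed at
  random positions, split randomly between the two descendant lineages
  of a uniform-random ancestor. The realised K2P therefore equals the
  target up to integer rounding (≪ 0.01 at ≥ 10 kb), and multiple-hit
  saturation is implicitly honoured because the inversion runs through
  the K2P model. Targets whose inversion lies within 1% of the
  saturation asymptote Q → 1/(2κ+1) are rejected as unattainable.
* **Substitution-only evolution.** No indels: every downstream decision
  rule in scope is substitution-based, and substitution-only evolution
  keeps homologous coordinates aligned by construction. Coordinates are
  0-based half-open; the mitogenome is circular with wrap-around
  fragment sampling.
* **Intra/interspecific non-overlap.** Intraspecific polymorphism never
  hits a planted interspecific difference position. At θ = 0.002 and
  tens of planted sites the collision probability is negligible in any
  case; excluding it makes the planted diagnostic sites exactly fixed
  within species, so recovery experiments measure the discovery rule,
  not collision luck.
* **Tumour lineage.** The clonal lineage is a donor-species *founder
  individual*: donor consensus plus one germline draw of θ-level
  polymorphism (diploid at the nuclear loci), optionally plus private
  somatic mitochondrial mutations (default none). All neoplastic
  specimens share the single lineage object, embodying the observed
  absence of nucleotide diversity among tumours.
* **Stage model.** Default tumour cell fractions per tissue —
  N0: 0/0, N1: 0.05/0, N2: 0.6/0.1, N3: 0.9/0.15
  (haemolymph/foot) — encode the documented infiltration gradient
  (haemolymph ≥ foot, rising with stage). The study system reports no
  numeric fractions; these are package defaults, config-overridable,
  and all quantitative tests treat them as simulation inputs rather
  than biological claims.
* **Reads.** Fragment lengths are normal (clipped to [read length,
  reference length]); the fragment's source (host cell vs tumour cell)
  is Bernoulli with the tissue's cell fraction, rescaled by
  `mito_copy_ratio` for the mitochondrial library:
  E[donor read fraction] = fc/(fc + 1 − f). Qualities are constant
  (`I`) because no in-scope rule consumes them. Every read gets a truth
  record (source cell class, source haplotype, position, strand).
* **Seeding.** One master seed; every consumer (specimen × tissue ×
  template, cohort member, panel, study replicate) draws from a named
  substream, so outputs are byte-identical across reruns and adding a
  specimen does not perturb the others.

Not emulated: indel/structural variation, quality-score profiles, GC
and coverage bias, PCR duplicates, contamination from non-target
species, doubly uniparental mtDNA inheritance, NUMTs. Passing tests
therefore demonstrate the correctness and statistical behaviour of the
inference rules under the substitution-mixture model, not robustness to
those artefacts.

## Read placement

Exact k-mer seeding (default k = 21, both strands, wrap-around k-mers
for circular references) followed by full-length ungapped extension of
every candidate (reference, position, strand). Score = matched bases.
Confidence uses the **margin** — best minus second-best score over the
candidates examined, with a lone candidate keeping its full score —
and a read is confident at margin ≥ 10 (default). At 21% interspecific
divergence an error-free 150-mer differs from the wrong reference at
~30 sites, so cross-species assignment margin is large and
misassignment negligible; reads whose true alignment would need a gap
simply score low. Ties for best score are broken by reference id,
then position, then strand; a tie implies margin 0 and is never
confident. Mates are placed independently (no rule in scope uses
pairing). The seeded mapper equals an exhaustive Hamming scan whenever
the read contains at least one error-free k-mer (property-tested
against a brute-force oracle).

The marker-panel classifier adds an identity floor (default 90% of the
read) on top of the margin filter: a read from a species absent from
the panel can share one conserved stretch with a panel entry and so
produce a single mediocre candidate whose margin equals its whole
score; the identity floor keeps such reads unassigned while true-panel
reads (identity ≈ 1 − error rate) are unaffected.

## Mitochondrial deconvolution

Both mitogenomes are indexed together so the margin is competitive
across species. Depth from confident placements is summarised in
100-bp windows; φ is the ratio of mean depths, with a Clopper–Pearson
interval from the per-reference confident read counts. φ estimates the
mtDNA **read** fraction; converting to cell fraction requires the
copy ratio, which real data rarely provides. Coexistence requires the
minor fraction ≥ τ (default 0.01) *and* ≥ 20 nonzero-depth windows on
both references — sensitivity floors, deliberately: a lightly
infiltrated early-stage tissue sequenced shallowly carries foreign
reads below them and is not called, which the tests exercise at 1×
coverage. Window means rather than read counts define φ (the two are
nearly identical at equal reference lengths); the read-count route is
available via the recorded per-reference counts.

## Nuclear markers

* **Diploid VAF filter.** A locus passes if every healthy specimen's
  VAF at every site with depth ≥ 8 lies within `tolerance` of
  {0, 0.5, 1}. The tolerance must be matched to depth: a heterozygous
  site's VAF is binomial over *fragments* (mate pairs are correlated),
  SD ≈ √(0.25/n_frag) ≈ 0.13 at 30× and 0.07 at 100×. The 0.1 default
  suits genotype-level or very deep data; for 100× read-level tables
  use ≈ 0.2 (the read-level test does). At shallow depth the filter
  cannot reliably separate a paralog-collapsed 1/3-VAF site from a het
  site — a statistical limit, not an implementation one.
* **Diagnostic sites.** Within-species major-allele frequency ≥ 0.95
  (inclusive; counted over allele copies, two per diploid) in both
  cohorts with differing major alleles. With 9–15 diploids per cohort
  this tolerates at most one stray allele copy.
* **Partition.** A read covering ≥ 1 diagnostic site is host if all
  covered sites show the host allele, donor if all show the donor
  allele, ambiguous otherwise; ambiguous reads (mixed alleles, e.g. a
  sequencing error at a diagnostic site) are excluded from both
  consensuses rather than fractionally assigned.
* **Consensus.** Per-partition pileup; a base is emitted where its
  frequency strictly exceeds 0.9 and depth ≥ 8, else `N`. Tumour
  consensuses are compared across specimens at jointly called sites;
  "identical" means zero mismatches there (the `N` mask varies with
  coverage, e.g. at linear-locus edges where depth ramps over one
  insert length).

## Phylogeny

K2P with ambiguity/gap columns skipped per pair; saturation raises an
error rather than returning a clamped value. Neighbour joining uses the
Saitou–Nei Q-criterion with standard branch lengths, negative lengths
clamped to zero, and two deliberate selection rules: coincident nodes
(pairwise distance ≤ 1e-12) coalesce before the Q-criterion is
consulted — with duplicate taxa (a clonal tumour sampled from several
animals) Q can otherwise interleave a distant node among the clones
and break their clade — and Q-ties prefer the smallest pairwise
distance, then row-major order, making the output deterministic in the
input ordering. NJ on additive matrices reproduces the generating
topology and branch lengths (property-tested on random 4- and 5-taxon
trees). Bootstrap resamples alignment columns with replacement and
scores each full-data bipartition by its replicate frequency.
Distance methods stand in for likelihood/Bayesian reconstruction
because the claims under test are topological (tumour monophyly,
donor-sister placement); at ~21% interspecific divergence over ≥ 2 kb
the interspecies split is unambiguous (bootstrap 100 in practice).

The placement test works on the unrooted tree: monophyly iff some edge
separates exactly the tumour leaves; donor-sister iff the smallest
edge-side containing all tumour and donor leaves contains no host
leaf. An outgroup leaf (the simulated ancestor evolved along its own
branch, default +0.15 substitutions/site) is included but the test
does not require rooting.

Whole-mitogenome comparison of two unaligned sequences
(`k2p_between_fasta`) delegates global alignment to mafft and applies
the K2P machinery to ungapped columns; the alignment step can perturb
the third decimal of the distance, so comparisons against published
values should allow a few tenths of a percentage point.

## Problem sizes in the validation studies

The recovery studies (`clamtc.experiments`, shared by the test suite
and `scripts/acceptance.py`) scale the genome down where the statistic
concentrates with read count or alignment length rather than genome
size: mixture recovery uses 4-kb mitogenomes at 100× (≈ 2 700 reads per
library, binomial SD of φ ≤ 0.01, 9 cell-fraction levels × 20
replicates); placement uses 2-kb mitogenomes (≈ 420 interspecific
differences, far more than needed for the split) over 100 seeds with
100 bootstrap replicates on three of them; consensus uses 6 specimens
at 100× nuclear coverage (partitioned depth ≥ 30× for both genotypes at
the N2 mixture); diagnostic-site recovery uses 1-kb loci with 20
planted differences over 50 seeds, cohorts of 12 + 9 diploids. The
species-pair divergence check runs at the full 18-kb default.

## Known limitations

* Ungapped placement: any indel between tumour and host genotypes (not
  simulated, but present in real data) would shed reads rather than
  place them.
* The margin filter discards reads mapping equally well to both
  species (conserved mitochondrial stretches); φ is computed from the
  informative remainder, which can slightly under-weight conserved
  regions in windowed depth.
* φ's binomial interval treats reads as independent; mate pairs are
  not, so the interval is mildly anti-conservative (up to √2 in width).
* The diploid VAF filter's fixed tolerance is depth-dependent (above);
  there is no explicit copy-number model.
* NJ with the coincident-node rule guarantees clone clades, but near-
  coincident leaves (distance > 0 but below the noise floor) can still
  be resolved arbitrarily; in the placement study this costs ~1% of
  seeds at θ·L ≈ 4.
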