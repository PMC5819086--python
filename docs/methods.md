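# Methods

## The experiment the package models

A set of bone-proteome MS/MS datasets from a known organism is searched
three times: against the organism's own reference proteome (the
ground-truth search), and against two reference proteomes at increasing
evolutionary distance (a chimpanzee-like and an orangutan-like database in
the default labelling). Because the ground-truth search fixes what each
spectrum *should* be, every peptide-spectrum match (PSM) in a
cross-species search can be audited. A PSM whose peptide differs from its
orthologous database sequence by n ≥ 1 single amino acid polymorphisms
(SAPs) is *mutable*: a standard search cannot match it, an error-tolerant
search may. Each mutable PSM falls into exactly one of four outcomes —
correct substitution(s) suggested; matched with no substitution; wrong
substitution; not matched at all.

## Synthetic data generator

The generator (`paleosap.sim`) reproduces the statistical structure of
that experiment without any spectra.

**Proteomes.** The target proteome draws protein lengths uniformly on
100–500 residues (i.i.d. residues over the 20 standard amino acids);
defaults of 100 proteins are of the order of the bone proteomes the
analysis is aimed at (tens of proteins per sample), scaled up slightly so
that simulation-level statistics are stable. Contaminant records are
appended unchanged to every database, mirroring the shared
adventitious-protein list appended to real search databases.

**Evolution.** A database proteome is derived by per-residue point
substitution with expectation `divergence_per_db / 100` SAPs per residue
(defaults 0.5 and 1.5 per 100 residues for the two databases, the order of
magnitude of hominid divergence at a few to ~17 Ma). No indels are
simulated — distances in this analysis are substitution counts, so
ortholog site maps are identity maps, and the alignment machinery is
exercised separately on real sequence pairs and mispredicted regions.
Substitutions never exchange I and L, which are collapsed to one symbol
throughout (isobaric; invisible to MS), so the planted truth equals the
I/L-collapsed sequence diff exactly. With `clustering_weight > 0` a fixed
fraction (default 10%) of 10-residue windows receives weight
`1 + clustering_weight`, emulating the clustered SAP patterns known from
collagens; the generative model is the package's own choice since only the
qualitative clustering is documented. A fraction of proteins is dropped
from the database entirely and another fraction has a contiguous region
(default 20% of the length) replaced by unrelated sequence, emulating
absent and mispredicted gene models.

**Identification.** Each tryptic peptide (cleavage after K/R except before
P; one missed cleavage by default; semi-/non-tryptic modes available)
yields one scan per pseudo-dataset (default 7 individuals × 3 files,
matching the study design the analysis mirrors). Identification is
Bernoulli with logistic probability

    P(identified) = sigmoid(base_logit + length_coefficient · length
                            + sap_coefficient · n_SAPs)

and a hard cap: peptides needing more than `max_suggested_saps` (default
2) substitutions are never identified, as error-tolerant engines bound the
substitutions they will propose (the cap is 2 rather than 1 because
two-substitution PSMs are observed in practice). Defaults
`base_logit = 6.0`, `length_coefficient = −0.3`, `sap_coefficient = −1.4`
were chosen so the aggregate behaviour matches what is reported for real
error-tolerant searches: short 0-SAP peptides nearly always identified,
roughly half of one-SAP and a quarter of two-SAP mutable peptides
recovered, long mutable peptides (≥ 25 residues) almost never.

Identified mutated PSMs carry the correct substitution set with
probability `1 − outcome3_rate − outcome2_rate`, a corrupted one (wrong
position or wrong residue, constructed so it can never reconstruct the
target sequence even after isobaric normalization) with probability
`outcome3_rate` (default 0.2, the order of the observed incorrect
fraction), and none with `outcome2_rate` (default 0 — matched-but-
unmutated outcomes are not observed in practice; the knob exists only to
test the classifier). Scores are drawn from two overlapping log-normal
laws, log-score N(3.6, 0.35) for correct and N(3.2, 0.40) for incorrect
matches, so a score threshold behaves like an FDR cut; real engines'
score distributions are not published in usable form, so these are free
parameters with the correct law deliberately higher. All randomness flows
from one seed through named numpy seed-sequence streams; identical
configurations give byte-identical outputs.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: spectral physics (no m/z peaks, fragment
ions, charge states, or PTM localization), realistic amino acid
composition and protein families, score–length correlation, decoy-based
FDR estimation, and dataset-to-dataset biological variation beyond
independent Bernoulli identification. Conclusions about *relative*
behaviour (recovery falling with distance and length, the effect of the
SAP filter) transfer; absolute rates do not.

## Classification and isobarics

The classifier reconstructs each reported cross-species peptide by
applying its suggested substitutions to the database sequence and then
normalizing isobaric modifications: a formylated K is read as R, a
deamidated N as D, a deamidated Q as E, whenever the modification mass is
within the fragment tolerance (default 1 Da) of the corresponding residue
mass difference (monoisotopic masses from pyteomics). The equivalences are
directional (the modified amide residue stands for the acid, not vice
versa). After I/L collapsing, outcome 1 requires full identity with the
ground-truth peptide — a PSM fixing only one of two required SAPs is
outcome 3, since partial credit is undefined in the accounting this
reproduces. Scan identity across searches is exact string match on
(dataset id, scan id).

Mutated PSMs on scans whose ground-truth distance is zero ("off-target"
suggestions) are tracked separately and enter the accounting as incorrect.

## Filtering

Retention reasons are logged with one reason per PSM under the fixed
precedence length > ground-truth-search match > contaminant >
excluded-protein/region > score, chosen so removal logs are deterministic
(the underlying protocol lists the reasons but no order). Protein
acceptance reads "two unique PSMs" as two distinct peptide sequences after
I/L collapsing. The SAP acceptance rule is implemented per distinct
(accession, position, observed residue): at least two mutated PSMs *and* a
strict majority (> 50%; ties reject) of all PSMs covering the position.
Both readings — per-substitution evaluation and strict majority — are the
conservative choices where the protocol wording is ambiguous. A
multi-substitution PSM survives filtering only if every one of its
substitutions is accepted. FDR filtering consumes a per-PSM FDR column
when present (real exports) or a score threshold (synthetic mode); FDR is
never computed from decoys here.

## Benchmark fixture

`paleosap.fixtures` constructs, deterministically and without randomness,
a mutated-PSM observation set for the two searches whose marginal counts
equal the published validity accounting (170/435 mutated PSMs unfiltered,
125/343 filtered, with the published correct/incorrect split). Only the
marginals are published; the per-position support groupings are
synthesized minimally — incorrect calls as 1-of-3 minorities, discarded
correct calls as 1-of-2 singletons or sub-majority groups, accepted calls
as 2-of-2, 3-of-4, 4-of-5 or paired-position groups — so that the filtered
marginals *emerge* from the actual filter code rather than from
bookkeeping. The same tables are shipped as TSV and hash-pinned.

## Statistics

The length effect is modelled as a maximum-likelihood logistic regression
of non-identification (outcome 4 vs. 1–3) on peptide length, reported with
standard errors and a 1-SD band on the linear predictor; note the sign
flip relative to the simulator, which parameterizes identification.
Perfect separation or a single response class yields a flagged result, not
an exception. Error-tolerant vs. standard recovery is compared with a
classical paired t-test over datasets (df = n − 1), after normalizing each
dataset's counts to its ground-truth search; the standard search is
emulated as the zero-substitution subset of the same error-tolerant run,
which is exactly the set of matches a non-error-tolerant engine could
produce. dN/dS values are consumed from a table (their retrieval from
genome databases is out of scope) and compared between identified and
unidentified proteins with Welch's t and Welch–Satterthwaite df.
Informative-position recovery counts a position as recovered when any
observed mutable PSM spans it, regardless of multiplicity or correctness.

## Phylogenetics

Tree inference is deliberately light: p-distances with pairwise deletion
of missing data, neighbor joining (scikit-bio), outgroup rooting, and
column-resampling bootstrap (default 1000 replicates, seeded) with support
reported on non-trivial bipartitions in [0, 100]. Maximum-likelihood
inference under empirical substitution models belongs to external tools;
the package exports relaxed PHYLIP and FASTA plus a column map for that
purpose. A sample position observed only as non-mutated contributes the
observed (database-equal) residue when any PSM covers it and the missing
symbol otherwise; columns with fewer than two distinct non-missing
residues, or fewer than two non-missing taxa, are dropped with a warning.
Bootstrap replicates in which some pair of taxa loses all shared columns
are skipped and support is computed over completed replicates.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive everywhere. Ortholog alignment uses
BLOSUM62 with affine gaps (open 11, extend 1), global mode, first
co-optimal alignment in Biopython's deterministic order, so site maps are
bit-stable. Peptides shorter than 6 or longer than 45 residues are emitted
but flagged; the hard length ≥ 10 rule is a downstream filter. A peptide
overlapping a region with no residue-level ortholog gets the sentinel
distance "unalignable" rather than a number. Zero-variance paired
differences, empty truth position sets, sub-2 group sizes and all-missing
alignment rows raise errors naming the offending quantity; empty
accounting input yields an empty table.

## Problem sizes used in the test suite

The shipped tests run the full pipeline at 50–100 proteins, 6–21
pseudo-datasets and one or two databases — enough for ≥ 5000 mutable PSMs
in the parameter-recovery checks and ≥ 1000 identified mutated PSMs for
rate recovery, while keeping the whole suite in the tens of seconds. These
sizes are the package's default desk-scale working points; all of them are
plain `SimulationConfig` parameters and scale up linearly.

## Known limitations

The simulator's monotonicity is conditional: raising divergence makes any
*given* peptide harder to identify, but it also recruits shorter peptides
into the mutable class, so the unconditional mean identification
probability of mutable peptides need not fall monotonically with
divergence. Precursor-level mass checks are not re-validated (PSM tables
are taken at face value); only fragment-tolerance isobarics are modelled.
The benchmark fixture's per-position groupings are one of many consistent
with the published marginals; any analysis depending on the unpublished
grouping details is outside what the fixture can support.
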