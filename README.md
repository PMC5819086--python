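# paleosap

Cross-species proteomics analysis: how much of a proteome survives an
error-tolerant database search when the search database comes from a
*different* species than the sample?

## The problem

Ancient-protein (palaeoproteomic) studies identify peptides by matching
MS/MS spectra against the reference proteome of the closest available
modern relative. Every amino acid difference — a single amino acid
polymorphism, **SAP**, the protein analogue of a SNP — between the sample
organism and the database species makes a peptide harder or impossible to
match. Error-tolerant engines (PEAKS SPIDER and friends) can propose
substitutions, but they recover only part of the lost signal, and a
fraction of their proposed substitutions is simply wrong. This package
implements the full analysis used to quantify those effects, with a
synthetic-data generator standing in for the raw spectral searches so that
every stage is testable end to end:

* **sim** — synthetic proteome trios (target + databases at configurable
  SAP divergence, with hotspot clustering, dropped proteins and
  mispredicted gene models), in-silico tryptic digestion and a logistic
  identification model producing PSM tables per pseudo-dataset;
* **digest** — tryptic/semi-tryptic digestion, global ortholog alignment
  (BLOSUM62), and per-peptide evolutionary distance: the number of SAPs
  between a peptide and its orthologous database sequence, with I/L
  collapsed (isobaric);
* **classify** — joins the ground-truth search (sample vs. its own
  proteome) with each cross-species search per scan, and labels every
  *mutable* PSM (distance ≥ 1) with one of four outcomes:
  **1** correct substitution(s) identified, **2** matched without the
  required substitution, **3** wrong substitution (wrong position or
  type), **4** no match. Isobaric chemistry is honoured: I↔L, formyl-K ≡ R,
  deamidated-N/Q ≡ D/E at the fragment tolerance count as correct;
* **filters** — PSM retention rules (length ≥ 10, matched in the
  ground-truth search, contaminants, absent/mispredicted database
  proteins, score/FDR), protein acceptance (≥ 2 distinct peptides), and
  the SAP acceptance rule: a substitution is accepted only with **≥ 2
  supporting PSMs forming a strict majority** of all PSMs covering that
  position;
* **stats** — recovery by evolutionary distance, logistic regression of
  non-identification on peptide length, paired *t*-tests of error-tolerant
  vs. standard recovery, Welch *t* on dN/dS of identified vs. unidentified
  proteins;
* **phylo** — alignments of phylogenetically informative positions from
  accepted SAPs plus the reference proteomes, p-distance neighbor-joining
  trees with column-resampling bootstrap, outgroup rooting, and
  FASTA/relaxed-PHYLIP export for external ML tools.

## Worked example

```python
from paleosap import SimulationConfig, run_synthetic_experiment
from paleosap.stats import recovery_by_distance

config = SimulationConfig(n_proteins=50, divergence_per_db=(0.5, 1.5),
                          n_individuals=3, files_per_individual=2, seed=42)
result = run_synthetic_experiment(config)
for label, sr in result.searches.items():
    frac = recovery_by_distance(sr.outcome_records)
    acct = sr.accounting_unfiltered
    n_acc = sum(c.accepted for c in sr.sap_calls)
    print(f"{label}: {len(sr.outcome_records)} mutable PSMs; "
          f"recovery by distance {frac.round(2).to_dict()}; "
          f"{acct.total(label)} mutated PSMs "
          f"({acct.percentage(label, 1, False) + acct.percentage(label, 2, False):.1f}% incorrect); "
          f"{n_acc}/{len(sr.sap_calls)} SAP calls accepted")
    fil = sr.accounting_filtered
    tot = fil.total(label) if len(fil.table) else 0
    corr = fil.count(label, 1, True) + fil.count(label, 2, True)
    print(f"  after SAP filtering: {tot} mutated PSMs, {corr} correct")
```

prints (exactly, for this seed):

```
Pan: 406 mutable PSMs; recovery by distance {1: 0.42, 2: 0.12, 3: 0.0}; 166 mutated PSMs (18.7% incorrect); 34/74 SAP calls accepted
  after SAP filtering: 121 mutated PSMs, 121 correct
Pongo: 1056 mutable PSMs; recovery by distance {1: 0.47, 2: 0.19, 3: 0.0}; 465 mutated PSMs (17.2% incorrect); 80/191 SAP calls accepted
  after SAP filtering: 350 mutated PSMs, 350 correct
```

Reading: at chimp-like divergence (0.5 SAPs / 100 residues) 406 scans are
mutable; 42% of single-SAP peptides are recovered, 12% of two-SAP
peptides, none beyond two. Of the mutated PSMs actually produced, ~19%
carry a wrong substitution — and after the two-PSM-majority filter every
surviving substitution is correct, at the price of discarding correct
singletons. The orangutan-like database (1.5 SAPs / 100 residues) loses
proportionally more.

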