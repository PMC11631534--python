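# mistrans

Quantification of amino-acid misincorporation (mistranslation) from
shotgun-proteomics search results, with codon-level decoding analysis and
the phenotype statistics used to compare mistranslating and control animal
lines.

## The problem

Mutant serine tRNAs whose anticodon has been changed to read valine or
threonine codons are still charged with serine (the serine identity
elements lie outside the anticodon), so they misincorporate serine at
V or T codons (V→S, T→S). Measuring how often this happens in vivo, and at
which codons, is a counting problem over peptide-spectrum matches (PSMs):

- A substituted peptide appears in a mass-shifted search as its wild-type
  sequence plus a variable "modification" of Δm = m(Ser) − m(Val) =
  −12.0364 Da or m(Ser) − m(Thr) = −14.0156 Da.
- PSMs are filtered to a 1% false-discovery rate by target–decoy
  competition and collapsed to unique peptides.
- A substituted peptide is only counted when its **sibling** — the
  non-substituted form of the same peptide — was also observed.
- The **mistranslation frequency** is

  f = 100 × (unique substituted peptides with sibling) /
      (unique peptides containing the origin residue)  [%]

- For the **per-codon** view, each substituted peptide with exactly one
  substituted site and a unique database location is mapped through the
  paired coding sequence to its codon, and each codon's frequency is
  n_sub / (n_sub + n_wt) over occurrence-level events. Codons are then
  classified by how the variant anticodon could read them:
  Watson–Crick at position 34, inosine-34 wobble (A34 reading C/A), or a
  3′ mismatch.

The package also implements the accompanying phenotype statistics
(Fisher's exact, Wilcoxon rank-sum, Welch's t, Holm–Bonferroni,
Kaplan–Meier with Greenwood log-log CIs, log-rank, Wilson intervals) and
synthetic-data generators with ground-truth ledgers so the whole pipeline
is testable end to end without any external data.

## Worked example

Simulate a shotgun experiment over a random coding-gene database with
known per-codon T→S rates (ACU 1%, ACC 0.5%, ACA 0, ACG 0), then run the
full pipeline on it:

```sh
mistrans simulate psms --seed 1 --out sim/
mistrans quantify --psms sim/psms.tsv --proteins sim/proteins.fasta \
    --cds sim/cds.fasta --substitution T:S --out report.tsv
```

which prints (seed 1, default simulation size of 1,600 genes):

```
rep1: 72/13059 unique peptides = 0.5513%
```

i.e. 72 of 13,059 unique threonine-containing peptides carried a
sibling-supported T→S substitution. `report.tsv` adds the codon rows:

```
replicate_id  row_type  substitution  codon  decoding_class   n_mistranslated  n_total  frequency_pct
rep1          residue   T->S          .      .                72               13059    0.551344
rep1          codon     T->S          ACA    wobble_I34       0                5424     0.000000
rep1          codon     T->S          ACC    wobble_I34       30               5524     0.543085
rep1          codon     T->S          ACG    mismatch_3prime  0                5531     0.000000
rep1          codon     T->S          ACU    watson_crick     48               5558     0.863620
```

The estimates recover the generator's realized per-codon rates (0.877% at
ACU, 0.527% at ACC from the ground-truth ledger) within binomial noise,
and the 3′-mismatched ACG codon is correctly reported silent.

Phenotype statistics run from CSV tables, e.g.:

```sh
mistrans simulate survival --n 100,100 --hazards 0.02,0.04 --seed 2 --out surv.csv
mistrans stats survival --input surv.csv
```

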