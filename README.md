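# prolaminkit

Prolamins — the gliadins and glutenins of wheat-group grasses — are the
seed storage proteins behind dough viscoelasticity and, for people with
celiac disease (CD), behind the immunogenic gluten peptides. They form
large, fast-evolving gene families: tandemly duplicated clusters on a
few chromosomes, riddled with pseudogenes, with subfamilies (α-, γ-, ω-,
δ-gliadins; low- and high-molecular-weight glutenin subunits, LMW/HMW-GS)
distinguished by their repeat grammars and cysteine skeletons.
`prolaminkit` is a reusable pipeline for characterizing such a family in
an assembled genome, built for genome analysts working on Triticeae
species and their wild relatives:

* **locus discovery** — seed–chain–extend nucleotide homology search
  with an expected-hit filter `E = K·m·n·e^(−λS)` (default cutoff
  1e−10), merging hits into candidate loci;
* **annotation** — rule-based subfamily classification, pseudogene
  calling from ORF integrity (ATG start, no premature stop, terminal
  stop, intact frame, complete repeat structure), and MW / theoretical
  pI (Bjellqvist pKa set, bisection) for functional proteins;
* **duplication** — tandem clustering by the three rules *distance
  < 100 kb, coverage > 70%, identity > 70%* with transitive closure,
  and greedy monotone chaining of reciprocal-best anchors into
  forward/inverted micro-collinearity blocks;
* **CD epitopes** — overlap-aware exact scanning of functional
  α-gliadins for the six classic peptides (DQ2.5-glia-α1a/α1b/α2/α3,
  DQ8-glia-α1/DQ8.5-glia-α1, and the 33-mer), with per-genome carrier
  summaries;
* **expression** — TPM from a count matrix and six-stage developmental
  profiles (young spike → grain) with trajectory labels;
* **synthetic truth** — a generator that plants all of the above
  (grammar-correct genes, tandem arrays, exact-count pseudogenization,
  genome-specific epitope repertoires, negative-binomial counts) so
  every stage is testable offline.

The model and defaults are described in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a small genome and run the whole pipeline on it:

```bash
prolaminkit full --simulate --demo --seed 3 --out-dir demo_out
python -m json.tool demo_out/report.json
```

The demo genome plants one α-gliadin tandem array of three (one member
pseudogenized) plus a γ- and an ω-gliadin singleton. The report shows,
among other entries:

```json
"subfamily_counts": {"alpha": 3, "gamma": 1, "omega": 1},
"pseudogene_rates": {
  "alpha": {"genes": 3, "pseudogenes": 1, "rate_pct": 33.3},
  "gamma": {"genes": 1, "pseudogenes": 0, "rate_pct": 0.0},
  "omega": {"genes": 1, "pseudogenes": 1, "rate_pct": 100.0}
},
"tandem": {"proportions": {"alpha": {"tandem_genes": 3, "genes": 3, "pct": 100.0}, ...}},
"epitopes": {"n_functional_alpha": 2, "types_present": ["DQ2.5-glia-a1a"], ...}
```

reading: all five planted genes were rediscovered by homology and
classified into their subfamilies; the three array members satisfy all
three tandem rules and form one cluster (α tandem proportion 3/3 =
100%); one of the two functional α-gliadins carries the planted
DQ2.5-glia-α1a epitope; the pseudogenes are called from their planted
defects (the rates are exact because planting is exact-count).
`demo_out/calls.tsv` holds the per-gene table (subfamily, status,
defects, MW, pI), `stage_profiles.tsv` the per-gene stage means and
trajectory labels, and `run.log` every threshold used. Every percentage
in `report.json` is recomputable from `calls.tsv`;
`prolaminkit report --in-dir demo_out` checks exactly that.

The same subcommands run on real inputs (`--genome`, `--gff`,
`--queries`, a counts/lengths/samples triple for expression); see
`prolaminkit --help`.

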