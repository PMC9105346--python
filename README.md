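# duplexffpe

Duplex consensus sequencing analysis for bottlenecked, UMI-free libraries
from FFPE-derived DNA — together with a generative simulator of the library
chemistry, so the whole analysis is testable end to end without real
sequencing data.

In a bottlenecked library only a few thousand molecules are amplified, so
the mapped template coordinates `(reference, start, end)` uniquely identify
each original DNA molecule and replace molecular barcodes. The pipeline:

1. **filter** read pairs (improper pairs, ambiguous mapping, soft clips,
   excessive mismatches) and mask read ends;
2. **group** pairs into per-molecule strand families by exact coordinates;
3. build a **strand consensus** per family from at least five PCR copies;
4. **merge** the two strand consensuses into a duplex consensus that keeps
   only positions supported by both strands — single-strand artifacts
   (chiefly cytosine-deamination lesions in FFPE DNA) cancel out here;
5. **call** duplex-supported variants, left-aligning indels;
6. remove **common polymorphisms** (population AF strictly above 1%);
7. report **mutations per Mb of duplex sequence** with exact
   (Clopper–Pearson) binomial confidence intervals, the mutation spectrum,
   and the fragment-end positional profile of mutations.

The simulator reproduces the mechanism that makes FFPE libraries hard:
single-strand lesions are orders of magnitude more frequent than true
mutations, and polymerase-driven end repair *copies* lesions that fall in
5′-overhangs onto the opposite strand, turning them into uncorrectable
false duplex mutations concentrated at fragment ends. Nuclease-style end
repair instead trims the overhangs. Both modes are generated from the same
random stream, so they can be compared at identical molecule samplings.

Because no matched germline genome is used, rare germline variants are not
separable from somatic mutations; all outputs are labelled "mutations",
not "somatic mutations".

## CLI

Simulate a library (parameters = `SimulationParams` fields, YAML):

```sh
cat > sim.yaml <<EOF
reference_length: 200000
n_templates: 2500
seed: 1
somatic_rate_snv: 50.0
lesion_rate: 2000.0
end_repair_mode: nuclease   # or: polymerase
strand_dropout_prob: 0.2
EOF
duplexffpe simulate --config sim.yaml --out-dir sim/
```

This writes `reference.fa`, coordinate-sorted `reads.sam`,
`population_af.vcf` and `truth_*.tsv` ground-truth ledgers.

Run the analysis:

```sh
cat > run.yaml <<EOF
alignments: sim/reads.sam
reference: sim/reference.fa
af_table: sim/population_af.vcf
filter:     { end_trim: 5, min_mapping_confidence: 30 }
consensus:  { min_copies: 5, min_agreement: 0.8 }
snp:        { af_threshold: 0.01 }
profile:    { window: 50 }
EOF
duplexffpe run --config run.yaml --out-dir out/
duplexffpe report --out-dir out/
```

Outputs: `report.json` / `report.tsv` (all summary statistics with their
numerators and denominators), `calls.vcf` / `calls.tsv` (retained and
removed calls with template provenance and population AF), `profile.tsv`
(per-distance mutation counts, coverage and normalized rates), and
`filter_report.tsv`.

The same analysis is available in memory via `duplexffpe.analyze(...)`.

## Defaults that are modelling assumptions

- "Ambiguously mapped" = mapping quality < 30; the excessive-mismatch rule
  drops a read above max(7 mismatches, 10% of its aligned length); read
  ends are masked 5 bp. All configurable.
- Strand families need ≥ 5 member pairs; a position is called at ≥ 80%
  agreement among contributing pairs.
- Overhang lengths are geometric (mean 6 bp per end); PCR copy numbers are
  shifted Poisson (1 + Poisson(mean − 1)); the lesion spectrum is 90%
  deamination (C→T / G→A), 10% uniform.
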