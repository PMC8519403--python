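# famchar

A tested, reusable pipeline for the analytic core of a transcription-factor
gene-family characterization: locating a ~61-residue family domain,
conserved-residue consensus, residue-rule DNA-binding classification,
physicochemical profiling, tandem-duplication detection with Nei–Gojobori
Ka/Ks and divergence dating, FPKM expression screening, and IUPAC promoter
motif scanning — plus a fully seeded synthetic-data generator so every stage
is testable offline with planted ground truth.

## Modules

| module | purpose |
| --- | --- |
| `famchar.seq_model` | protein/CDS/gene records; FASTA and GFF3/TSV readers with validation |
| `famchar.domain_locator` | log-odds PSSM built from a seed alignment; windowed domain scan with a calibrated bit-score threshold |
| `famchar.residue_frame` | 61-position reference frame (basic 1–17 / helix1 18–31 / loop 32–45 / helix2 46–61), loop-confined gap fitting, per-position consensus ratios and conserved calls (>50% / >90%, strict) |
| `famchar.binding_rules` | decision tree over basic-region residue content (≥6 of R/K/H) and positions 8/12/15/16, yielding G-box / non-G-box E-box / non-E-box / non-DNA-binding; summary tables with 2-decimal half-away-from-zero percentages |
| `famchar.physchem` | ProtParam-style panel: average MW, Bjellqvist-pKa pI by bisection, Kyte–Doolittle GRAVY, Guruprasad instability index (stable < 40), aliphatic index, charged-residue counts |
| `famchar.dup_evolution` | tandem pairs from ranked coordinates (≤1 intervening gene, ≤100 kb by default), NG86 Ka/Ks with equal-weight pathways and Jukes–Cantor correction, selection labels, divergence dating T = Ks/(2λ)/10⁶ (λ = 1.5×10⁻⁸) |
| `famchar.expression_screen` | strict FPKM > 1 effective expression, tissue specificity, 2–5× fold-change screening, correlation-based hierarchical clustering, 2^−ΔΔCt qPCR |
| `famchar.promoter_scan` | exact IUPAC motif matching on both strands (no weight matrices); editable motif table with citations in `src/famchar/data/motifs.tsv` |
| `famchar.synthetic_data` | seeded generators: cohorts with planted binding categories, tandem clusters, expression archetypes and motif counts; codon-pair evolution at planted dN/dS |

## CLI

```sh
famchar synth --seed 0 --out bundle/              # synthetic cohort + truth tables
famchar io validate bundle/proteins.fa
famchar scan bundle/proteins.fa --seed-alignment bundle/seed_alignment.afa -o hits.tsv
famchar frame --hits hits.tsv -o aligned.afa
famchar consensus aligned.afa -o consensus.tsv
famchar classify aligned.afa -o classes.tsv --summary summary.tsv
famchar physchem bundle/proteins.fa --cds bundle/cds.fa -o panel.tsv
famchar dupli --genes bundle/genes.tsv --cds bundle/cds.fa -o pairs.tsv
famchar express bundle/fpkm_treatment.tsv --control control_25C -o screen.tsv
famchar motifs bundle/promoters.fa -o motif_hits.tsv --counts motif_counts.tsv
```

Real data drop in the same way: protein/CDS FASTA, a GFF3 or TSV gene table,
an FPKM TSV, and promoter FASTA. Externally computed domain hits can be
injected as a TSV (`famchar.domain_locator.read_hits_tsv`) to bypass the
PSSM scanner.

## Notes and caveats

* One domain per protein by default (`best_hit`); pass `--all-hits` to keep
  every non-overlapping hit.
* Promoter scanning is literal IUPAC matching only — it does not reproduce
  any database's scoring models. Review and edit the motif table for your
  organism.
* The default scan threshold (15 bits) was calibrated once by Monte-Carlo on
  background-composition sequences; see `famchar.domain_locator.calibrate_min_bits`.
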