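# venomtx

A venom-gland transcriptome annotation toolkit. It re-implements, as a
tested and reusable pipeline, the classic annotation flow for a de novo
assembled venom-gland transcriptome:

1. **ORF translation** — six-frame enumeration of ATG-initiated ORFs,
   full-length vs fragment classification, ≥ 40 aa filter
   (`venomtx.orfs`).
2. **Homology-based quality filtering** — hit metrics ML/BL, ML/PL and
   identity with tiered strict thresholds, best-translation selection
   per transcript, redundancy merging into a core dataset, and
   EST-vs-assembly QC (`venomtx.homology`).
3. **Quantification** — per-transcript RPKM from SAM alignments or count
   tables, fold-vs-mean, sequencing-depth estimate (`venomtx.quantify`).
4. **Toxin discovery** — three evidence channels: homology to known
   toxins, exact domain-architecture matching, and cysteine-spacing
   pattern alignment; family and five-way functional categorization
   (`venomtx.toxins`).
5. **Pathway enrichment** — upper-tail hypergeometric test
   P(X ≥ m) with strict P < 0.05 flagging, plus per-term RPKM
   aggregation (`venomtx.enrichment`).
6. **Synthetic data** — a deterministic generator of transcriptomes,
   divergent reference databases, domain tables, pathway maps and reads
   with known ground truth, so the whole pipeline is testable offline
   (`venomtx.simulate`).

The pipeline consumes standard text formats (FASTA, SAM, BLAST
12-column tabular, TSV maps) and ships a small internal Smith–Waterman
search so tests and demos need no external BLAST binary.

## CLI

```sh
# end-to-end on synthetic data with known ground truth
venomtx run --simulate --seed 1 --outdir out/

# or stage by stage
venomtx simulate  --seed 1 --outdir out/sim
venomtx translate --transcripts out/sim/transcripts.fasta --outdir out/tr
venomtx filter    --candidates-fasta out/tr/candidates.fasta \
                  --candidates-manifest out/tr/candidates.tsv \
                  --references out/sim/references.fasta --outdir out/flt
venomtx quantify  --sam out/sim/reads.sam \
                  --transcripts out/sim/transcripts.fasta --outdir out/q
venomtx toxins    --core out/flt/core.tsv \
                  --references out/sim/references.fasta \
                  --reference-meta out/sim/reference_meta.tsv --outdir out/tox
venomtx enrich    --pathways out/sim/pathways.tsv --sample sample_ids.txt \
                  --outdir out/enr
venomtx report    --outdir out/
```

`venomtx run` also accepts `--config cfg.yaml` holding any `RunConfig`
field (input paths, thresholds such as `min_len_aa`, `e_cut`,
`enrichment_cutoff`, `pattern_tolerance`, and a nested `sim:` block for
the simulator). Reruns with the same config and seed are byte-identical.
Exit codes: 0 ok, 1 user error, 2 internal error.

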