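# tagident

Integrative MS/MS peptide identification. De novo sequence tags are
inferred from tandem spectra through a probabilistically scored spectrum
graph, queried error-tolerantly against a protein database with an
MS-tailored substitution matrix, re-scored by theoretical-ion matching,
and combined into a single ranked, FDR-controlled identification.

## Pipeline

1. **Preprocessing** — peak intensities are normalized against the median
   baseline, discretized into four levels (no/low/medium/strong signal),
   denoised with a sliding-window top-N filter, and binned into five m/z
   regions.
2. **Tag inference** — a spectrum graph is built with b- and y-ion
   interpretation vertices and single-residue edges; each vertex is scored
   by the log likelihood ratio of a trainable Bayesian fragmentation
   network against a noise model; the top-k sub-optimal antisymmetric
   paths are enumerated, progressively aligned, and high-consensus runs
   extracted as sequence tags with flanking mass gaps.
3. **Tag query** — tags are aligned locally (affine-gap Smith-Waterman)
   against an in-silico tryptic digest of the database using a BLOSUM62
   variant in which isobaric residues (L/I, Q/K) are interchangeable,
   X scores zero, and a cleavage-anchor symbol marks tryptic boundaries;
   hits are ranked by the similarity score Ss.
4. **Ion matching** — each candidate is fragmented into 9 ion types
   (b+/y+ at intensity 100, b2+/y2+ at 50, a+ and water/ammonia losses at
   20) and scored by the correlation score
   `Sc = Nb! * Ny! * sum(I_i * P_i)`, evaluated in log space.
5. **Final scoring** — Ss and Sc are min-max normalized per spectrum and
   combined with weight `w_denovo`; the delta score D, per-spectrum ranks,
   and target-decoy FDR/q-values are reported.

A synthetic-data module generates annotated spectra and databases with
the statistical structure the method assumes, so every stage is testable
offline.

## CLI

Every stage is a subcommand of `tagident`:

```sh
# synthetic benchmark: FASTA + MGF + truth table
tagident simulate --n-proteins 500 --n-spectra 100 --seed 7 --noise-free --out-prefix bench

# train the fragmentation model from annotated spectra
tagident train bench.mgf bench.truth.tsv --model-out model.json

# tryptic digestion
tagident digest bench.fasta --out peptides.tsv

# de novo sequence tags only
tagident denovo-tags bench.mgf --model model.json --out tags.tsv

# full identification (optionally with reversed decoys)
tagident identify bench.mgf bench.fasta --model model.json --decoys --out psms.tsv

# q-values for rank-1 PSMs; accuracy against the truth table
tagident fdr psms.tsv --out qvalues.tsv
tagident evaluate psms.tsv bench.truth.tsv
```

Configuration is a JSON document mirroring `tagident.pipeline.RunConfig`
(unknown keys are rejected); pass it with `--config`. Exit codes: 0
success, 2 usage error, 3 data error.

## Conventions

- Monoisotopic masses throughout (proton 1.007276 Da, water 18.010565 Da).
- Peptide coordinates are 0-based half-open.
- Tryptic cleavage: after K/R, not before P; defaults 2 missed cleavages,
  peptide length 6–30.
- I/L are collapsed at graph level; Q/K are collapsed unless the fragment
  tolerance resolves their 0.036 Da gap.
- The PSM table is TSV with header
  `spectrum_id peptide protein Ss Sc_log S D rank is_decoy tags`.
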