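# gh13csr

Conserved-sequence-region (CSR) fingerprinting and annotation of
alpha-amylases from glycoside hydrolase family GH13.

Family GH13 alpha-amylases — fungal, insect, animal and bacterial —
share a TIM-barrel catalytic domain with eight short conserved
sequence regions.  Concatenated in chain order (CSR-VIII, VI, I, V,
II, III, IV, VII) these regions form a 55-column **fingerprint** that
carries the family's functional landmarks:

- the catalytic triad: Asp at column **28** (nucleophile, CSR-II),
  Glu at **37** (proton donor, CSR-III), Asp at **46**
  (transition-state stabilizer, CSR-IV);
- the chloride-activation triad of animal and animal-like enzymes:
  Arg at **26**, Asn at **44**, Arg-or-Lys at **50** — a sequence is
  chloride-binding-capable exactly when all three are present;
- the positions against which surface-binding sites (SBSs: aromatic
  F/W/Y patches outside the active site, known from solved complex
  structures) are compared across homologues.

The package is aimed at sequence analysts working on GH13 subfamily
comparisons.  It provides, as composable library modules and a CLI:
redundancy filtering at >90% identity, progressive multiple alignment
(or import of an external MSA), reference-guided CSR anchoring and
fingerprint extraction, sequence-logo statistics (position frequency
matrices, information content `log2 20 − H` in bits, consensus),
chloride-triad classification, SBS correspondence mapping against
five packaged solved-structure templates (PDB 2GUY/2GVY, 2GJP, 6TOZ,
3BC9, 3BLP), and neighbor-joining trees with bootstrap for both the
beta1–beta8 barrel segment and the 55-column fingerprint alignment.
A registry reproduces the 268-sequence, six-subfamily study manifest
and the published residue-correspondence grids, and a synthetic family
generator with planted ground truth makes every stage testable
offline.

## Worked example

```python
from gh13csr import SyntheticConfig, generate_family, generate_truth_msa
from gh13csr.csr import extract_fingerprints, locate_anchors
from gh13csr.chloride import classify_all, summarize
from gh13csr.logo import column_frequencies, consensus_string
from gh13csr.synthetic_data import reference_annotation

config = SyntheticConfig(subfamily="GH13_32", n_sequences=60,
                         substitution_rate=0.05, chloride_triad="RNK", seed=1)
records, truths = generate_family(config)
msa = generate_truth_msa(records, truths)
anchors = locate_anchors(msa, reference_annotation(truths[0]))
fingerprints = extract_fingerprints(
    msa, anchors, subfamilies={r.accession: r.subfamily for r in records})

print(fingerprints[0].sequence)
profiles = column_frequencies(fingerprints)
print(consensus_string(profiles))
print(f"IC at nucleophile column 28: {profiles[27].information_bits:.4f} bits")
print(summarize(classify_all(fingerprints)).to_string(index=False))
```

prints

```
GITGITHLWLPPDVVFNHLIDLVGFRIDTAKHYQIVEVLDFVDNHDGQPKIYYGS
GITGITHLWLPPDVVFNHLIDLVGFRIDTAKHYQIVEVLDFVDNHDGQPKIYYGS
IC at nucleophile column 28: 4.3219 bits
subfamily  n  capable  lys_variant  missing_arg26  missing_asn44  missing_arg_lys50
  GH13_32 60       60           60              0              0                  0
```

The first line is one record's extracted 55-column fingerprint; the
second, the family consensus — identical here because the CSR blocks
are conserved.  Reading the landmarks off the consensus: `D` at 28,
`E` at 37, `D` at 46 (the catalytic triad), and `R`/`N`/`K` at
26/44/50, so every record is called chloride-binding-capable in the
lysine variant, as the summary table confirms.  The information
content of 4.3219 bits at column 28 is the maximum for a 20-letter
alphabet — the column is invariant.

## Command line

```
gh13csr simulate   --config config.yaml --outdir out   # synthetic family + truth
gh13csr dedupe     in.fasta --threshold 0.9 --out-fasta kept.fasta --report clusters.tsv
gh13csr align      kept.fasta --out alignment.afa
gh13csr extract-csr alignment.afa --reference reference.yaml --out fingerprints.tsv
gh13csr logo       fingerprints.tsv --out profiles.tsv
gh13csr chloride   fingerprints.tsv --out verdicts.tsv
gh13csr sbs        alignment.afa --template 3BLP --template-row AAH63129 --out sbs.tsv
gh13csr tree       alignment.afa --mode both --fingerprints fingerprints.tsv \
                   --bootstrap 500 --out-prefix trees/run
gh13csr all        --config config.yaml --outdir out    # the whole pipeline
```

`gh13csr all` writes the dedupe report, alignment, fingerprint table,
logo profiles, chloride verdicts, SBS tables, two Newick trees with
bootstrap supports, a split-comparison report and a run manifest.
Re-running with the same config and seed reproduces every artifact
byte for byte.

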