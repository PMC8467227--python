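# Fixed knowledge shipped with the package: the study-set manifest
# (sequence counts per GH13 subfamily and taxon domain), the solved-structure
# templates with experimentally identified surface-binding sites (SBSs),
# and the chloride-triad reference numbering.

manifest:
  GH13_1:  {procarya: 2,  eucarya: 37}
  GH13_5:  {procarya: 32, eucarya: 3}
  GH13_15: {procarya: 0,  eucarya: 28}
  GH13_24: {procarya: 0,  eucarya: 23}
  GH13_32: {procarya: 20, eucarya: 120}
  GH13_42: {procarya: 2,  eucarya: 1}

# Residue numbering: "mature" applies when the N-terminal signal peptide is
# removed, "precursor" when it is retained.  Templates without a signal
# peptide use the same number for both.
templates:
  - pdb_code: 2GUY
    aliases: [2GVY]          # both codes are in circulation for this structure
    subfamily: GH13_1
    source_organism: Aspergillus niger
    sites:
      - name: SBS-I
        residues:
          - {letter: Y, mature: 382, precursor: 402}
          - {letter: W, mature: 385, precursor: 405}
  - pdb_code: 2GJP
    subfamily: GH13_5
    source_organism: Bacillus halmapalus
    sites:
      - name: SBS-I
        residues:
          - {letter: W, mature: 439, precursor: 439}
          - {letter: W, mature: 469, precursor: 469}
      - name: SBS-II
        residues:
          - {letter: W, mature: 347, precursor: 347}
      - name: SBS-III
        residues:
          - {letter: Y, mature: 363, precursor: 363}
  - pdb_code: 6TOZ
    subfamily: GH13_5
    source_organism: Bacillus paralicheniformis
    # The second residue is also reported as Y368 in part of the source
    # literature; both readings are preserved rather than silently resolved.
    variant_note: "second SBS-I residue alternatively reported as Y368"
    sites:
      - name: SBS-I
        residues:
          - {letter: F, mature: 257, precursor: 257}
          - {letter: Y, mature: 358, precursor: 358}
  - pdb_code: 3BC9
    subfamily: GH13_5
    source_organism: Halothermothrix orenii
    sites:
      - name: SBS-I
        residues:
          - {letter: Y, mature: 460, precursor: 484}
          - {letter: W, mature: 488, precursor: 512}
      - name: SBS-II
        residues:
          - {letter: W, mature: 260, precursor: 284}
          - {letter: W, mature: 287, precursor: 311}
      - name: SBS-III
        residues:
          - {letter: W, mature: 306, precursor: 330}
          - {letter: W, mature: 310, precursor: 334}
  - pdb_code: 3BLP
    subfamily: GH13_24
    source_organism: Homo sapiens (saliva)
    sites:
      - name: SBS-I
        residues:
          - {letter: Y, mature: 276, precursor: 291}
          - {letter: W, mature: 284, precursor: 299}
      - name: SBS-II
        residues:
          - {letter: W, mature: 316, precursor: 331}
          - {letter: W, mature: 388, precursor: 403}
      - name: SBS-III
        residues:
          - {letter: W, mature: 203, precursor: 218}
      - name: SBS-IV
        residues:
          - {letter: W, mature: 134, precursor: 149}

# Documentation of the chloride-binding triad numbering in the reference
# chloride-dependent enzyme (cold-active GH13_32 alpha-amylase).
chloride_reference:
  accession: CAA41481
  organism: Pseudoalteromonas haloplanktis
  subfamily: GH13_32
  residues: {arginine: 196, asparagine: 286, lysine: 324}
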