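# mimicryscan

Molecular-mimicry discovery between tumor-associated antigens (TAAs) and
bacterial proteomes.

Nonamer peptides presented on HLA class I molecules can be recognized by the
same CD8⁺ T-cell receptor when they resemble each other in sequence and
backbone conformation. Gut bacteria (chiefly the Firmicutes and Bacteroidetes
phyla) encode vastly more protein than the human genome, so bacterial peptides
that mimic tumor epitopes are plausible sources of pre-existing, cross-reactive
anti-tumor T-cell memory. `mimicryscan` is a reusable, tested pipeline for
finding and characterizing such mimics:

1. **Scan** — every 9-residue window of every protein is compared, ungapped and
   position by position, against each TAA epitope; windows with ≥ `min_identity`
   identical residues (default 5/9) become hits. This exhaustive enumeration is
   exactly reproducible, unlike a gapped database search.
2. **Classify** — each aligned position is labelled *identical*, *conservative*
   (same physicochemical class: aliphatic AVLIM, aromatic FWY, polar-uncharged
   STNQC, positive KRH, negative DE, special GP; a BLOSUM62-nonnegative mode is
   available) or *non-conservative*.
3. **Bind** — hits are filtered through HLA class I thresholds: strong binder
   (SB) < 100 nM affinity (and > 1 h complex half-life when stability is
   predicted), *high affinity* < 10 nM. Predictions are imported as TSV tables;
   a transparent position-weight-matrix stand-in (affinity = 50000^(1−s) nM for
   normalized score *s*) lets the pipeline run end to end without external
   prediction servers.
4. **Profile** — identity-count distributions, per-position substitution-class
   percentages, position frequency matrices with information content
   (sequence-logo data) and consensus/epitope agreement; plus the random-match
   probability model: the chance that *k* positions of two uniform random
   nonamers agree is (1/20)^k — 1.56 × 10⁻⁸ for k = 6 down to 1.95 × 10⁻¹² for
   k = 9, which is why long identical stretches are biologically meaningful.
5. **Structure** — PDB parsing of peptide–HLA(–TCR) complexes, per-residue
   contact assignment (heavy atoms within 4.0 Å), and planar/dihedral angle
   comparison over the TCR-facing positions with a ±10 % angle-identity
   criterion.
6. **Simulate** — seeded generators for proteomes with planted homologs of
   controlled identity and substitution-class composition, prediction tables
   and idealized peptide backbones with specified (φ, ψ) torsions, so every
   stage is testable against a known ground truth.

## Worked example

The MAGE-A3 epitope `KVAELVHFL` (HLA-A*02:01) against a bacterial 14-mer:

```python
>>> from mimicryscan import EpitopeRecord, ProteinRecord, ScanConfig, scan_proteome
>>> epi = EpitopeRecord("MAGE-A3", "KVAELVHFL", "HLA-A*02:01")
>>> prot = ProteinRecord("SYN1", "MAAKIAELVHFLGG", phylum="Firmicutes")
>>> (hit,) = scan_proteome([epi], [prot], ScanConfig(min_identity=6))
>>> hit.hit_sequence, hit.offset, hit.identity_count, hit.label_string
('KIAELVHFL', 3, 8, 'ICIIIIIII')
```

Of the six windows only `KIAELVHFL` (offset 3, 0-based) passes: 8 of 9
residues identical, the single substitution (V→I at position 2, the HLA
anchor) conservative within the aliphatic class.

The end-to-end demo (packaged worked-example epitopes + synthetic proteomes
with planted homologs):

```bash
mimicryscan report --out-dir demo_out --seed 1
# -> 13 artifacts written to demo_out
```

`demo_out/counts.tsv` then contains, for seed 1:

```
antigen_name  phylum         n_total  n_high_affinity
MAGE-A10      Bacteroidetes  5        0
MAGE-A10      Firmicutes     5        0
MAGE-A3       Bacteroidetes  7        4
MAGE-A3       Firmicutes     7        4
```

`n_total` counts all mimicry hits per antigen and phylum; `n_high_affinity`
the subset predicted to bind below 10 nM. The bundle also includes the hit
table with random-match probabilities, identity distributions, per-position
substitution percentages, PFM/logo data with consensus checks, affinity
summaries, and planar/dihedral angle comparisons of idealized backbones for
each antigen's best mimic.

Other subcommands: `scan`, `bind`, `stats`, `geometry`, `simulate`
(`mimicryscan --help`).

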