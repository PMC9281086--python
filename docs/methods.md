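# Methods

## Scope and model

`mimicryscan` quantifies molecular mimicry between 9-residue tumor epitopes
(HLA class I ligands) and bacterial protein sequences at three levels:
ungapped sequence identity, substitution-class composition, and backbone
geometry. The unit of analysis is the gapless nonamer pairing: an epitope
aligned to a 9-residue protein window with no insertions or deletions. That
choice makes an exhaustive sliding-window scan the natural search engine —
complete (no heuristic seeding), deterministic, and independent of database
versions — where a gapped, statistics-driven homology search would not be
reproducible at desk scale.

## Substitution classification

A residue pair is *identical*, *conservative* or *non-conservative*. The
default conservative criterion is a physicochemical partition of the 20
standard residues: aliphatic {A,V,L,I,M}, aromatic {F,W,Y}, polar-uncharged
{S,T,N,Q,C}, positive {K,R,H}, negative {D,E}, special {G,P}. "Conservative"
has no single canonical definition; this partition was chosen because it is a
standard grouping and labels every substitution in the worked alignment
examples (I/V, L/M, L/V) conservative. A second mode treats a substitution as
conservative iff its BLOSUM62 score is ≥ 0, as a sensitivity analysis; both
modes are symmetric and classify (a, a) as identical by construction.

Positions are 1-based in every user-facing table (position 2 and 9 are the
HLA-A*02:01/A*24:02 anchors) and 0-based internally. Worked pairs: the
MAGE-A3 pair KVAELVHFL/KIAELVHFL has its single (conservative) mismatch at
position 2; the MAGE-A10 pair GLYDGMEHL/GMYDGLEHV differs at positions 2, 6
and 9 — all mismatches are reported, and any anchor masking is left to the
caller.

## Scanning

Every window of every protein is classified against every epitope; a hit
requires ≥ `min_identity` identical positions. The default floor is 5/9
(~51 % identity, the lowest identity at which mimics are still reported);
it is configurable because no universal acceptance floor exists. Windows
containing ambiguity codes (X/B/Z/U/O) are skipped rather than penalized:
epitopes are always standard-residue nonamers. Overlapping windows are all
reported; a unique-peptide view deduplicates (antigen, peptide) pairs at the
report level. Hit order is deterministic: (antigen, identity descending,
protein id, offset). Correctness is tested by exact equality against an
independent brute-force enumeration on hundreds of random instances, plus
monotonicity in the identity floor and exact recovery of planted homologs.

## Binding thresholds

Affinity (nM) and optional stability (hours) come from imported prediction
tables. Classes: *high* < 10 nM; *strong* < 100 nM with stability > 1 h when
stability is present (when absent, the affinity criterion alone decides —
stability is typically predicted only for the bacterial peptides); *non*
otherwise. Comparisons are strict (`<`), including the "fraction below the
mean" and "fraction below the paired TAA" summaries; those summaries average
over unique (antigen, peptide) pairs by default, with occurrence weighting as
an option, since the choice of denominator is otherwise ambiguous.

The built-in PWM predictor exists so the pipeline runs end to end without
external prediction services: score = Σ position log-odds, normalized to
[0, 1] by a clamped linear map over the matrix's attainable range, and
affinity = 50000^(1−s) nM — the established convention for mapping normalized
binding scores onto nanomolar units, which keeps the 10/100 nM thresholds
meaningful on synthetic data. It is transparent plumbing, not a re-
implementation of neural-network predictors, and carries no claim of realism.

## Profile statistics

Per-position substitution percentages are computed over all hits of a cohort;
at each position the three class percentages sum to 100 and category averages
are unweighted means over the nine positions. Position frequency matrices use
raw, unweighted counts (no sequence clustering or weighting); information
content per position is log₂20 − Shannon entropy for the default uniform
background, or the Kullback–Leibler divergence for a user-supplied
background, clamped to [0, log₂20]. The consensus is the per-column argmax
with alphabetical tie-break, ties flagged.

The random-match statistic is the per-stretch form p(k) = (1/20)^k — the
probability that k specified positions agree between two independent uniform
random nonamers — giving 1.5625 × 10⁻⁸ at k = 6 and 1.953125 × 10⁻¹² at
k = 9. No positional/combinatorial correction is applied in the headline
statistic because the per-stretch form is the one consistent with both
printed endpoints; an explicitly labelled "any-window" union-bound variant
(multiplying by the number of start positions) is provided separately. Hits
are annotated with p(longest run of consecutive identical positions) and
p(total identity count); a hit with no identical positions gets probability 1
(empty product) and is flagged.

## Structural comparison

PDB input is parsed from fixed-column ATOM/HETATM records with a declared
chain-role map (peptide, HLA, β2-microglobulin, TCRα, TCRβ); altloc 'A' or
blank is kept, the peptide chain must have 8–11 residues, and malformed lines
raise with their line number. Contacts: a peptide residue contacts HLA/TCRα/
TCRβ iff any heavy atom lies within 4.0 Å (configurable) of a heavy atom of a
chain with that role; β2m never generates a contact category. TCR-facing
positions come from the contact map when TCR chains are present, otherwise
from the static fallback {4, 5, 6, 7, 8} (anchors 2 and 9 buried in the
groove).

Angles: planar angles are the vertex angle of three atoms in [0°, 180°];
dihedrals are signed torsions in (−180°, 180°] with the IUPAC convention.
Both are invariant under rigid-body motion (tested to 1e-6°); mirror
reflection flips the dihedral sign only. The angle sets compared are
configurable descriptors; the default per TCR-facing position is the
backbone-path planar angle (Cα_{i−1}, Cα_i, Cα_{i+1}) and, for residues with
a side chain beyond Cβ, the side-chain orientation dihedral (N, Cα, Cβ,
terminal side-chain heavy atom) — capturing both the backbone path and the
orientation of the exposed side chains. Two angles are "identical" when
their circular difference is ≤ 10 % of the reference magnitude; because a
purely relative band makes near-zero angles unpassable, an absolute floor of
5° applies when the reference magnitude is below 50° — an implementation
choice, stated as such. Signed values are compared by default, with a
magnitude-only mode; and both per-pair and pooled percent-identical summaries
are available since the denominator convention is otherwise ambiguous.

## Synthetic data

The generators emulate the study's input conditions, not its databases:
proteomes with residues drawn iid from a background (uniform 1/20 by default,
matching the probability model's assumption; a Swiss-Prot-like composition is
shipped as an alternative), homologs planted by overwriting a 9-residue
window with a copy of the epitope carrying exactly k substitutions of a
chosen class policy (overwriting keeps protein lengths and offsets stable;
planted windows never overlap), and idealized peptides built by natural-
extension-reference-frame placement with standard bond lengths and angles,
whose measured backbone torsions reproduce the requested (φ, ψ) to well below
1e-3°. Every generator is a pure function of (arguments, seed), and the plant
ledger predicts scanner output exactly. What the synthetic data does *not*
model: phylogenetic structure, codon-level evolution, residue correlations
within proteins, true binding-affinity landscapes, or crystallographic noise
— so passing tests demonstrate the pipeline's correctness and calibration on
controlled inputs, not biological conclusions about real proteomes.

## Demo problem sizes and defaults

The packaged demo uses the worked-example epitopes (MAGE-A3 KVAELVHFL,
MAGE-A10 GLYDGMEHL, both HLA-A*02:01), two phyla × 40 synthetic proteins of
60–160 residues, and 12 planted homologs per phylum spanning 0–3
substitutions with conservative-only and mixed policies — small enough to run
in seconds while exercising every stage, and chosen once as a representative
mimic population (most planted mimics at 6–8/9 identity, mirroring the
regime where real mimics concentrate). The scan floor is 6/9 in the demo to
keep chance hits rare at this proteome size. All thresholds (100 nM, 10 nM,
1 h, min identity, ±10 %, 4.0 Å) live in the run configuration with these
defaults.

## Known limitations

- Nonamers only; 8/10/11-mer ligands are out of scope.
- No E-value or score statistics for hits; identity count is the only ranking.
- The PWM predictor is plumbing, not a validated affinity model.
- No docking, energy minimization, side-chain rebuilding, or mmCIF input.
- Logo rendering is left to external tools; the package emits logo data only.
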