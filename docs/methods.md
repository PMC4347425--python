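# Methods

This note documents the models, conventions, and design choices behind
`orscout`, and what the simulation-based tests do and do not establish.

## Sequence model and ORF calling

Sequences are plain strings over `{A,C,G,T,N}` with 0-based half-open
coordinates throughout; reverse-strand features are re-mapped to
forward-strand offsets of the source sequence. Translation uses the standard
genetic code; any codon containing `N` translates to `X` and can serve
neither as start nor stop.

An ORF is `ATG` to the first in-frame stop, the stop codon **included** in
the nucleotide length (so a 293-residue protein corresponds to an 882-nt
coding region). The longest ORF is taken over all six frames, ties broken by
earlier forward-strand start, then `+` strand over `−`. An ORF that runs off
the sequence end without a stop is reported with a flag and its length counts
only complete codons.

## Curation rule

A gene is a pseudogene iff its longest ORF is absent, its coding length is
**strictly below** `min_coding_nt` (default 900), or it carries a frameshift
annotation (accepted as an input column, not inferred). A gene of exactly
900 nt is therefore functional; the stop-inclusion convention is switchable
(`include_stop_in_length`) because either accounting is defensible and the
borderline 882/885-nt cases depend on it. Manual overrides force functional
status while retaining the original evidence, mirroring expert curation of
borderline receptors.

The OR-family motif scan defaults to three consensus patterns — a TM3 "DRY
box" (`MAYDRYVAIC`), a TM6 cysteine motif (`KAFSTCASH`), and the TM7
NPxxY-like region (`PMLNPFIY`) — each allowing one mismatch. These defaults
are data, not code: the motif set is configurable, and the patterns are
standard family consensus rather than a canonical published list.

## Seed-and-extend alignment

Nucleotide-level local alignment (genomes are searched as DNA, not by
translated comparison). Exact k-mer seeds (default `k = 11`) are grouped
into nearby-diagonal clusters; each cluster is resolved by a full affine-gap
Smith–Waterman over a window guaranteed to contain any local alignment
passing through a seed of the cluster, so within-window scores are optimal,
not banded approximations. A gapless X-drop prefilter skips clusters whose
best ungapped seed extension scores below `prefilter_fraction × min_score`
(default 0.5); this trades a small amount of theoretical sensitivity for an
order-of-magnitude speedup on genome-scale targets and can be disabled.

Scoring defaults: match `+1`, mismatch `−2`, gap open `−3` (cost of the
first gapped position), gap extend `−1`, minimum reported score 30 —
conventional DNA-alignment parameters in the BLAT/BLAST tradition. The DP
kernel is JIT-compiled (numba); tests verify its optimality against an
independent dynamic-programming implementation (Biopython) on random
planted-homology instances, where seed sensitivity is effectively certain
for homologies at ≥ 75% identity with `k ≤ 8`. For unrelated random
sequences whose optimal alignment may contain no seed, optimality holds only
down to the seed-sensitivity limit — the usual seed-and-extend tradeoff.

## Presence calls and lineage classification

Identity of the best hit is `100 · matches / alignment columns` — gap
columns count against identity; a `matches/(matches+mismatches)` convention
is available. Coverage is the aligned query span of the single best hit
(`100 · (q_end − q_start) / query_len`); best-hit coverage is conservative
and deterministic compared with a union-of-hits rule. Best hit = highest
score, ties to more matches, then smaller target start — full determinism.

Presence requires identity ≥ 70 **and** coverage ≥ 70, both inclusive ("at
least" semantics). Lineage categories over {chimpanzee, dog, mouse, rat}:
absent everywhere → `human_only`; present in chimpanzee only →
`human_chimp_only`; otherwise `shared`. The selected set keeps the
human-restricted categories minus curated pseudogenes (unless overridden).
The screen is one-directional (no reciprocal-best-hit requirement), and an
unreadable genome marks affected queries *incomplete* rather than absent.

## Identity matrix and phylogeny

Pairwise percent identity comes from global affine-gap alignment (BLOSUM62,
gap open −11 / extend −1): terminal-gap columns are stripped, then
`identity = 100 · identical / remaining columns`, so internal gaps penalize
identity. Each unordered pair is aligned once, making the matrix exactly
symmetric. An `from_msa` mode applies the same column rule to a provided
alignment.

Trees are built by canonical neighbor joining on `d = (100 − identity)/100`
with a deterministic lowest-index tie-break; negative branch-length
estimates are clamped to zero with the raw value retained. NJ replaces
maximum-likelihood inference deliberately: the tree is a relatedness
overview, NJ is exact on additive distances (verified on random trees), and
it keeps the package dependency-free and fast. Branch support is the
percentage of column-bootstrap replicates (resample alignment columns with
replacement, rebuild identity → distance → NJ) containing each bipartition
of the full-data tree; the default 100 replicates and the seed are recorded
in the output header. Bootstrap requires an alignment; the generators emit
ungapped equal-length families, and external alignments can be supplied.

## Plate-screen quantification

The response for a receptor × odorant × concentration cell is

    R = (F_or+od − F_empty+od) − (F_or_basal − F_empty_basal)

with the four `F` terms taken as **means over replicate wells before
subtraction** — the only order compatible with empty-vector wells shared
per plate; the s.e.m. is computed over replicate-paired responses when the
four conditions share a replicate structure. A cell missing any term is
reported not-evaluable, never zero. Negative responses are retained.

Hits use the strict rule `R > 3×10⁵` AU applied to the replicate-mean
response (per-replicate thresholding is switchable). The potency class is
set by the lowest hit concentration among the fixed screening series
{10, 100, 1000} µM; other condition series (e.g. control titrations at
{100, 200, 400} µM with varying plasmid dose) ride along as free-form
metadata. Plates fail QC when the GFP transfection fraction is below 0.70
(inclusive pass at exactly 0.70) and are excluded before any response is
computed. Percent-of-maximum normalization refuses sets with no positive
response. Rho-tagged and untagged constructs are distinct conditions
end-to-end, since tagging can change a receptor's odorant response.

## Synthetic data: what it emulates, what it does not

Generators are fully seeded; identical seeds give byte-identical FASTA and
plate tables, and each artifact carries a truth record with **realized**
(not requested) parameters. Recovery tests consume truth records only.

* OR-like genes: single-exon, 310 codons (930 nt with stop), family motifs
  planted at canonical relative positions, random non-stop codons elsewhere.
* Orthologs: uniform random substitutions to an exact target identity
  (realized value reported); partial counterparts as prefix truncations;
  either strand. Genome background is i.i.d. random sequence — no repeats,
  GC structure, or gene families, so alignment specificity on real genomes
  will be somewhat worse than in simulation.
* Plates: one odorant per plate; well fluorescence = condition mean +
  Gaussian noise (σ default 3×10⁴ AU, a tenth of the hit threshold, making
  the fixed threshold a 10σ rule); agonist effects saturate across
  concentration as 0.6/0.9/1.0 of the effect size for potent pairs and
  0/0.5/1.0 for weak ones, reproducing the potent-versus-weak dichotomy of
  dot-size potency tables. No pharmacological EC50 model is implied.
* The demo screen plants 5 potent receptors across 9 odorants plus weak
  pairs totalling 14 responding odorants — the qualitative scale and
  structure of a small deorphanization screen.

Passing recovery tests therefore shows the pipeline's rules are implemented
correctly and are robust at the stated noise level; it does not certify
performance on real genome assemblies or real plate data, whose artifacts
(cross-hybridizing paralogs, edge effects, non-Gaussian noise) the
generators deliberately omit.

## Benchmark problem sizes

The recovery experiments run at: 50 planted-homology alignment instances
(query ≤ 300 nt, target ≤ 2 kb); 100 presence replicates (one 80% and one
60% ortholog each) on 6-kb contigs; 20-gene curation families with 5
lesions; 200 random 6–12-taxon NJ instances; 200 simulated screens of
9 receptors × 37 odorants for sensitivity/false-hit rates and 20 screens
for exact potency-matrix recovery. Exact potency recovery is claimed only
under strong signal (effects ≥ 3× threshold with σ ≤ threshold/10); the
sensitivity experiment uses 6×10⁵-AU effects, where detection at *some*
concentration is near-certain but the 10-µM cell alone is within ~1.4σ of
threshold.

## Known limitations

* Seed-and-extend optimality is conditional on seed sensitivity (above).
* Identity conventions differ across tools (ClustalW, BLAT and this package
  each count gaps and denominators slightly differently); the package's
  conventions are stated and configurable, but cross-tool identity values
  can differ by up to ~1 percentage point.
* No splice-aware gene models (OR coding regions are intronless), no
  synteny/orthology inference, no curve fitting (EC50/Hill).
* Genome-scale counts from the original selection workflow depend on
  specific 2009-era assemblies and gene-annotation snapshots and are not
  reproducible from simulation; the package reproduces the *rules*, not
  those counts.
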