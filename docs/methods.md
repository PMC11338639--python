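# Methods

This note documents the models, parameters and design choices behind
`codhscan`, and what its synthetic-data tests do and do not demonstrate
about real data.

## Discovery model

Candidate Ni-CODH genes are found by pairwise Smith–Waterman local
alignment (BLOSUM62; affine gaps costing open 11 + 1 per residue) of every
annotated protein against a set of clade-representative catalytic-subunit
(CooS/CdhA) sequences. Three filters apply conjunctively to each
(reference, gene) hit:

| parameter          | default | meaning                                            |
|--------------------|---------|----------------------------------------------------|
| `evalue_max`       | 1e-10   | Karlin–Altschul E-value, E = m·n·2^(−bits)         |
| `identity_min_pct` | 30      | matches / alignment columns × 100                  |
| `alnlen_min_aa`    | 200     | alignment length in columns (gap columns included) |
| `db_size_aa`       | 1e7     | effective database length n for the E-value        |
| (λ, K)             | 0.267, 0.041 | gapped BLOSUM62 statistics                    |

Because the search is in-house rather than delegated to an external
aligner, the E-value needs an explicit statistical model; the gapped
BLOSUM62 (λ, K) defaults are the standard published values for these gap
costs, and `db_size_aa` is configurable because the synthetic test
databases are far smaller than any real protein collection. The "length ≥
200 aa" filter is interpreted as alignment length in columns — the usual
reading of tabular-output filters; query coverage would be a stricter
alternative and can be emulated by raising `alnlen_min_aa`.

A gene is a candidate if **any** reference passes; candidacy is inclusive
because the stricter motif filter follows. The clade call is the clade of
the passing reference with maximum identity (ties: higher bit score, then
lexicographically smaller clade label). Precomputed 12-column tabular hit
files can be ingested in place of the in-house search; both paths share
`passes_thresholds`.

Mo-CODH screening applies the same thresholds against a CoxL reference and
additionally requires the literal active-site heptapeptide AYRCSFR in the
candidate protein.

## Motif validation

A candidate is confirmed as pCODH only if every configured site is intact:
each anchor position maps through a global pairwise alignment
(Needleman–Wunsch, same matrix and gap costs, free terminal gaps) to a
candidate residue in the required set. A site is *deleted* if any position
maps to a gap (deletion takes precedence), *substituted* if any mapped
residue is wrong, and all sites report *unaligned* when the overall
candidate-to-anchor identity — computed over all columns, terminal gaps
included — falls below 20 %, so garbage mappings are never reported as
substitutions.

Site coordinates are configuration, not code: the shipped default is a
synthetic stand-in anchored to the clade-F template of the synthetic
reference set, with the structure of the real motif catalogue (two
C-clusters, a B- and a D-cluster, two acid–base catalytic residues; 14
positions total). **For real data the config must be rebuilt against an
experimentally characterized anchor** (e.g. a CooSII-type subunit) with
curated residue coordinates; the file format (`motif_config.yaml`) makes
the positions explicit and swappable. Pairwise mapping to one anchor
replaces a multiple alignment of all candidates; this is exact for
substitution-only divergence and approximate near indels (see
Limitations).

The identical machinery checks the PFL Cys-Cys active site: K00656
(PflD-family) genes count as genuine PFL only when both cysteines are
conserved, since the KO contains PFL-like proteins without PFL activity.

## Genomic-context typing

The context of a focal *cooS* gene is the set of genes within ±15 rank
positions on its contig — rank-based, strand-agnostic, truncated silently
at contig edges. Marker rules (KO/COG sets) define eight types; the ABC
transporter rule requires all three subunit markers
(K02049/K02050/K02051 or COG0715/COG0600/COG1116) anywhere in the window
because they are reported as a unit. The focal gene's own annotations are
ignored. When several types have evidence, a fixed precedence applies —
WLP > PEPCK > FNOR > ABC > Fe-hydrogenase > MFS > uncharacterized
dehydrogenase > cysteine synthase — codifying a typing that was originally
manual; WLP outranks everything because the other markers are known to
co-occur inside WLP-type contexts. Secondary evidence is preserved in the
output, never discarded. Auxiliary symbols (oxyR, narGHIJK, pflAB, hypAB,
cooC, cooF) are tallied per window but never drive the call.

## WLP profiling

Presence is genome-wide and per-symbol: a genome carries a symbol iff any
of its genes carries any KO of that symbol; multi-KO genes count toward
every matched symbol. The symbol catalogue covers the CODH/ACS complex,
the methyl branch (fhs, folD, metF, metV), Fdh catalytic and accessory
subunits, Rnf/Ech/Hdr/Mvh/PFOR modules, formate transporters and PFL.
OxlT (K08177) deliberately appears both as an MFS context marker and a
formate transporter. Classification per genome:

* `is_pcodh_acs` — a validated pCODH plus acsB (K14138), regardless of
  whether the two genes share a context window;
* `fdh_status` — `fdh_lacking` iff none of fdhA/fdhF/fdoG present;
* `formate_route` — fdh, else validated PFL, else any formate transporter,
  else none.

PFL validation is ON by default; a flag restores raw-KO counting. Putative
Fdh genes co-annotated as glutamate synthase (K00266) still count toward
fdh, but the co-annotation count is reported separately
(`count_fdh_glutamate_coannotation`).

## Transcript quantification

The pseudo-mapper indexes reference genes by exact 31-mers on both strands;
a read is assigned to the gene collecting the most of its k-mers provided
that gene collects at least `min_hit_fraction` (default 0.5) of them, and
ties are discarded as ambiguous. On error-free reads this is equivalent to
exact substring matching for every unambiguous read (tested against a
brute-force oracle); it is **not** a substitute for a real aligner on
error-containing reads — external per-gene count tables can be supplied
for that case. RPKM uses `mapped_reads` = reads assigned to the provided
reference set (not total sequenced reads) as its denominator; TPM
renormalizes RPKM to sum to 10⁶. Detection of pCODH in a dataset means ≥ 1
assigned read on a pCODH gene. Covered positions (depth ≥ 1) are reported
per gene for downstream cover-length filtering but no filter is applied.

## Synthetic data: what it emulates and what it does not

The generator builds annotated genome bundles with planted truth. Design
of the sequence model:

* **Reference set** — six templates (clades B, C, D, E, F, mini), 650 aa,
  descending from one ancestral random sequence by substitution only, each
  carrying the motif residues and sharing conserved ±3-residue motif
  neighbourhoods plus a 30-position scaffold. Retention is tuned so
  pairwise template identity is ≈ 55 % (< 60 %), which keeps candidates at
  ≥ 50 % identity to their own template alignable (> 20 %) to the single
  anchor.
* **Planted genes** — `mutate_to_identity` substitutes an exact number of
  positions, stratified evenly along the sequence so local identity is
  homogeneous and the locally aligned identity matches the global target;
  this is what makes 28 %/32 % plants fall cleanly on either side of the
  30 % cutoff. Motif states: *intact* conserves the motif neighbourhoods;
  *substituted* breaks one configured residue; *deleted* excises one
  wide-span site in full (flanks included) as a truncated pseudo-gene
  would — short in-window deletions can be re-absorbed by a pairwise
  alignment and read as intact, so they are not used as ground truth.
* **Genomes** — background genes are random-codon ORFs of 200–700 aa with
  no annotations, so marker matches are unambiguous; intergenic spacing is
  a fixed 50 nt (rank-based windows ignore distances); context marker
  genes follow documented arrangements (e.g. the consecutive
  cooS–cooC–acsB of the WLP type); WLP preset genes carrying
  context-marker annotations are kept outside the focal window.
* **Reads** — error-free, drawn proportionally to weight × gene length,
  reverse-complemented with probability 0.5, constant 'I' qualities.

Everything is deterministic under a fixed seed. Because the background is
annotation-free and reads are error-free, passing recovery tests
demonstrates the correctness of the pipeline's logic — thresholds, motif
mapping, precedence, classification rules, quantification arithmetic — not
its robustness to annotation noise, sequencing error, fragmented
assemblies or genuinely ambiguous homology, which real surveys must
contend with.

## Numerical choices

* Percentages round half-up (not banker's) at the requested decimals,
  matching how published count ratios print.
* Identity = matches / alignment columns (internal gaps included) for
  local hits; the motif-mapping reliability check additionally counts
  terminal gap columns.
* Biopython's aligner charges its open score on the first gap residue, so
  gap costs are passed as (−12, −1) to realize open 11 / extend 1 in the
  open + g·extend convention.
* Clade ties break deterministically (bit score, then label); ambiguous
  reads are discarded, never split.
* Problem sizes in the tests and the acceptance script (60-genome screens,
  10 000 reads, 5–20 genomes per condition) are chosen to give exact or
  3-standard-deviation-tight checks in seconds per stage.

## Known limitations

* Pairwise-to-anchor motif mapping can mis-register around indels when the
  required residue is common (e.g. cysteine); the shipped validator is
  conservative via the wide-span deletion model and the unaligned state,
  but real indel-rich candidates deserve a curated multiple alignment.
* E-values assume fixed (λ, K); no composition-based adjustment.
* The pseudo-mapper has no error model and no multi-mapping resolution.
* Taxonomy is consumed as an input table; no taxonomic assignment is
  performed.
* No operon prediction: context typing is purely rank-window- and
  marker-based.
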