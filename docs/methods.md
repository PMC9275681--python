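# Methods

`cenreg` infers the direct regulon of a bacterial two-component-system
(TCS) response regulator from two orthogonal genome-wide data types:
ChIP-seq binding evidence and RNA-seq differential expression across
strains whose TCS activity has been genetically shifted. The package was
built around the CenKR system of *Rhodobacter sphaeroides* — a sensor
kinase (CenK) and an essential OmpR-family response regulator (CenR)
controlling cell-envelope and division genes — but every stage is
parameterized and works on any analogous strain design.

## Study design encoded in the pipeline

Four strains span a TCS activity gradient:

| strain | allele | activity class |
|---|---|---|
| `D56E` | phosphomimetic Asp→Glu at the receiver aspartate | hyper |
| `WT` | wild type | reference |
| `dcenK` | kinase deletion | low |
| `D56A` | non-phosphorylatable Asp→Ala | low |

A gene under direct positive control should rise in the hyperactive
strain and fall in the low-activity strains (and symmetrically for
repression). That *opposing expression pattern*, together with
replicate-concordant promoter-proximal binding, is the package's
operational definition of a direct target.

## Pipeline stages

### 1. Peak concordance and promoter assignment (`peaks`)

Per-replicate ChIP peaks are clustered by single linkage on peak-center
distance (default 100 bp). On a line, single linkage reduces to chaining
adjacent centers, which makes the result order-independent after a
canonical sort; a brute-force O(n²) union-find oracle verifies this in
the tests. Support counts **distinct (strain, replicate) experiments**,
pooled across strains — a binding site is one site; per-strain
enrichment is averaged separately, and strains contributing no member
peaks stay *missing*, never 0. Consensus peaks need support ≥ 3 (the
published concordance rule; the distance criterion is this package's
choice since the source rule names only the replicate count).

Surviving peaks are assigned to every transcriptional unit (TU) whose
TSS lies within 300 bp downstream to 100 bp upstream of the peak center
in the TU's frame. Multi-assignment (divergent/tandem promoters) is kept
and flagged shared rather than resolved to the nearest TSS, because the
published table itself contains peaks shared by two TUs. Peaks hitting
no TSS window are classified `intragenic` (center inside an annotated
CDS), `convergent_intergenic` (between TUs pointing at each other), or
`orphan`; only `upstream` assignments feed the regulon stage.

### 2. Differential-expression calls (`expression`)

A strain comparison counts toward DEG status iff FDR < 0.05 **and**
|log2FC| > 0.5, both strict inequalities; a gene is a DEG with ≥ 2
counting comparisons. "n.s." cells parse to an *absent* FDR — a
sentinel distinct from any numeric value — so filters can separate
"tested, not significant" from "large FDR".

The opposing-pattern call uses FDR-only significance (a sub-threshold
fold change still carries its sign; the published table contains such
rows, e.g. a −0.21 low-strain change at FDR 0.03):

* **(a)** a significant hyper-strain call and a significant low-strain
  call with opposite signs, or
* **(b)** only low-strain calls significant, agreeing in sign (hyper
  direction inferred by negation — required to explain table rows
  significant only in the low-activity strain), and
* **(c)** no significant low-strain call sharing the hyper sign;
  contradictory low-strain signs flag the gene `ambiguous` and exclude
  it.

Genes significant only in the hyperactive strain get a direction but are
*not* opposing. Gene calls aggregate to TUs by OR over members; the
member with the smallest hyper-strain FDR is the TU's representative.

### 3. Regulon assembly (`regulon`)

Candidates are TUs with ≥ 1 upstream peak **and** an opposing pattern;
each keeps its best-supported peak (support, then WT enrichment, then
|distance to TSS|). Role `+`/`−` follows the hyper-strain direction
(member disagreement resolves by smallest hyper FDR and is flagged
mixed). Mechanism classification places the binding site in the promoter
frame: wholly upstream of the −35 hexamer start → `activation_consistent`
(consistent with recruitment-style activation); overlapping the
[−35 start, TSS] span → `repression_consistent` (polymerase occlusion);
downstream of the TSS → `unclassified`. Unannotated promoters fall back
to −35 at [−35, −30] and −10 at [−12, −7]. A role/mechanism disagreement
is a logged warning, never an exclusion — the published mapping between
role and site position is an observed concordance, not a filter. The
*core* regulon keeps candidates with motif support; the *expanded* table
keeps all candidates (mirroring the published 31-of-59 distinction).

### 4. Motif engine (`motif`)

**PWM.** Probabilities are `(count + κ·q_b) / (n + κ)` with pseudocount
κ = 1 split by background proportions (Laplace-style smoothing sized for
tens of training sites). Scores are log-odds in bits,
`Σ_j log2(p[b_j][j]/q[b_j])`; IUPAC-ambiguous bases contribute 0 bits in
scanning and are rejected in training sites. Background is estimated
from the scanned/discovery set with both strands pooled (the genome is
~68% GC; assuming uniform background would miscalibrate every score).

**Scanning.** Every offset on both strands at threshold ≥ 0 bits by
default; best-site mode ignores the threshold and retains the single
top site per sequence (ties: smaller offset, then + strand). The scanner
is verified against a brute-force nested-loop scorer to 1e-9 and against
Biopython's PSSM calculation as an independent implementation.

**ZOOPS-EM discovery.** The generative model is "zero or one occurrence
per sequence": with probability γ a sequence carries one motif instance
at a uniformly chosen offset and strand, the rest is 0th-order
background. EM uses soft responsibilities over offsets/strands
(E-step) and pure maximum-likelihood re-estimation (M-step), so the
observed-data log-likelihood is provably non-decreasing — asserted at
every iteration. Convergence at Δlog-likelihood < 1e-6 or 200
iterations. Initialization is MEME-style: random subsequence seeds are
screened by a one-E-step likelihood and only the best few run to
convergence (local optima such as generic GC-rich "motifs" otherwise
dominate in high-GC backgrounds). Width selection over 10–20 bp uses the
objective *information content (bits) × expected site count*. This
objective, and the absence of E-values, are deliberate simplifications
relative to MEME's classic objective; they select the planted width in
tests but are not calibrated for significance statements.

**Direct repeat.** The motif of interest is a tandem direct repeat,
TGA-N₈-TGA, with half-sites at positions 1–3 and 12–14 of the published
15-mers (the 15th base is flank). `match_direct_repeat` counts total
mismatches over both half-sites (default ≤ 2). Note a discrepancy
preserved from the source: the prose describes a 10 bp distance between
half-site starts, while the printed 15-mers place them 11 bp apart; the
package follows the printed sequences.

**Conservation.** For each species' set of ortholog upstream windows
(300 bp upstream of the translation start, per the published
cross-species procedure), the single best-scoring site per sequence is
retained, a species PWM is rebuilt from the retained sites, and
half-site conservation is summarized by direct-repeat matching. Logos
are emitted as probability matrices (MEME minimal format), not rendered
graphics.

## Synthetic data generator

`synthetic_data` stands in for the study's raw sequencing data, which is
not redistributable at desk scale. It emulates, with known truth:

* an i.i.d. background genome at 68% GC with tiled TUs, each with ≥ 200 bp
  intergenic upstream space, a TSS, and −35/−10 hexamers at the
  canonical offsets;
* planted T[GC]A-N₈-T[GC]A sites — wholly upstream of the −35 (center
  drawn in [−75, −45] relative to the TSS) for activated targets,
  overlapping the promoter span (center in [−28, −10]) for repressed
  ones (default 30% repressed, matching the published 42/17 ≈ 0.29
  split);
* per-strain × replicate peak tables: detection probability per
  replicate is `1 − exp(−0.75·(mean_enrichment − 1))`, monotone in the
  strain mean and ≈ 0.93/0.81/0.36 at the anchor means 4.5/3.2/1.6
  (taken from the *tolQ* row of the published table); center jitter
  N(0, 10 bp); lognormal enrichment around the strain mean; false peaks
  Poisson(2) per replicon per replicate;
* summary-level DE: hyper-strain effects ±2.0 log2 units (sd 0.3),
  low-activity strains opposite-signed at half magnitude, 30% of
  low-activity cells masked to null to mimic the table's "n.s."
  sparsity; null genes N(0, 0.2); two-sided z-test p-values against the
  null sd; Benjamini–Hochberg step-up FDR implemented in-module
  (`fdr_i = min_{j≥i}(p_(j)·m/j)`) and cross-checked against statsmodels.

Replicate count defaults to 4 per strain — the source does not state it;
4 is the smallest count that makes a ≥ 3-replicate concordance filter
meaningfully selective. All randomness flows from one seed through
named streams; detection draws are taken up-front in a fixed order so
that raising enrichment means never loses detections under a shared
seed (a coupling the tests exploit).

What the generator does **not** emulate: read-level coverage, fragment
sizes, input-library structure, count dispersion (DE is simulated at the
summary level because the pipeline consumes DE tables), operon-internal
promoters, overlapping genes, or correlated false peaks. Passing the
recovery tests therefore demonstrates the correctness of the filtering
and integration logic under the stated noise model, not performance on
raw sequencing artifacts.

## The packaged regulon fixture

`data/cenkr_regulon.tsv` transcribes the published 31-entry CenKR
regulon table (peak centers, per-strain enrichments, 15-mer motifs,
per-strain log2FC/FDR, roles, functional categories, TM/signal-peptide/
essentiality annotations). One cell in the source prints a malformed FDR
("8.92–06", *msrA*); it is stored as 8.9E-06, the only reading
consistent with the column format. `load_regulon_fixture` checks a
SHA-256 of the packaged file. Replaying the role logic over the fixture's
DE columns alone reproduces the printed role column for all 31 entries
(28 activated, 3 repressed; 29 envelope/extracytoplasmic).

## Numerical and degenerate-input choices

* Peak center = floor((start+end)/2) when absent; consensus center =
  lower median of member centers (integer, deterministic).
* Strict inequalities at both DEG thresholds, per the source's wording.
* EM guards: γ clipped to [1e-6, 1−1e-6]; log(0) never selected because
  zero-probability bases cannot occur in any responsible window;
  all-identical-letter inputs raise a degenerate-input error.
* Scan ties sort by descending score, then ascending offset, then +
  strand; palindromic best sites resolve to +.
* Empty candidate/prediction sets: precision is reported as undefined
  (None), not 0.

## Problem sizes

Defaults are the package's study conditions: 60 TUs, 40 direct targets,
4 replicates × 4 strains, ~90 kb genome. The test suite and the
acceptance script run the full pipeline at these sizes (5 seeds for
recovery statistics), a 20-TU noiseless configuration for the golden
end-to-end table, 20 × 200 bp sequence sets for discovery, and 1 kb
scans against the brute-force oracle. "Sharp" in the planted-motif
generator means 0.95 probability on the consensus base per column —
near-exact instances, the regime in which a ZOOPS search is expected to
recover essentially all planted sites.

## Known limitations

* The genome-wide counts of the original study (458 peaks → 273
  concordant; 597 DEGs → 275 opposing → 59 TUs) derive from raw
  sequencing data not shipped here; the package reproduces the rules,
  and the genome-wide replay runs only if the user supplies the
  full RNA-seq table (`data/s2_rnaseq.tsv`).
* The opposing rule is under-specified in the source for multi-strain
  corner cases; clauses (a)–(c) above are this package's explicit
  resolution and are exposed as parameters.
* The discovery objective is not MEME's; E-values and classic-objective
  model selection are out of scope.
* Mechanism classification assumes a single promoter per TU and default
  hexamer geometry when annotations are missing.
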