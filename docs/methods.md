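# Methods

This note documents the models, parameters, and design choices behind the
`asq` toolkit: a designer and caller for allele-specific qPCR (ASQ) SNP
genotyping assays that use a universal FRET detector set -- fluorophore
probes and a quencher on *separate* complementary oligonucleotides.

## The assay being designed

One assay targets one bi-allelic (extensible to 3-4 allele) polymorphic site
and has two independent parts:

1. **Allele-specific part** (per SNP): two tagged forward allele-specific
   primers (ASPs) and one untagged common reverse primer. Each ASP is
   `tag (13 nt) + barcode (6 nt) + gene part (~20-25 nt)`; only the gene part
   anneals to the template, the allele-discriminating base sits at the
   penultimate position from the 3' end, and the two ASPs differ *only* at
   that base and in their barcodes. The common primer is placed to give a
   50-100 bp amplicon.
2. **Universal part** (reused across assays): 2-4 universal probes (UPs),
   19-mers of the shared tag plus a unique barcode, each with a 5' dye
   (FAM, HEX/VIC, Cy3, Cy5); and a single quencher oligo (Uni-Q), the exact
   reverse complement of the 13-bp tag with a 3' quencher. Uni-Q hybridizes
   to any unincorporated probe, quenching its dye by FRET; the 3' quencher
   also blocks polymerase extension of Uni-Q itself. Probes incorporated
   into amplicons (via the matching ASP tag) escape quenching and fluoresce.

The whole system works because of a deliberate melting-temperature ladder:
gene parts ~55-56 degC (no Mg) < probes (19-mer, with Mg, ~65-67 degC), and
the 13-mer quencher at least 10 degC *below* the probes (~54 degC). During
the second-round 62 degC annealing the quencher is fully dissociated and
cannot compete; at the 55 degC read step it recaptures every free probe.

## Duplex thermodynamics (`asq.thermo`)

Nearest-neighbor model with the unified Watson-Crick parameter set
(SantaLucia 1998) and the published single-internal-mismatch parameters
(Allawi & SantaLucia 1997-1998; Peyret et al. 1999), stored as plain-text
TSVs under `asq/data/` so alternative tables can be swapped in.

* dH (kcal/mol) and dS (cal/mol/K) are summed over dinucleotide propagation
  steps plus per-terminal initiation penalties.
* **dG37 is reported at the 1 M reference state**, `dG37 = dH - 310.15 dS/1000`.
  Buffer ions enter only the melting temperature. (Empirically this is also
  the convention of the reference oligo table this package reproduces: the
  quencher's printed -16.7 kcal/mol matches the 1 M value -16.78, whereas a
  salt-corrected value would be -12.7.)
* Tm uses the two-state formula `Tm = 1000 dH / (dS' + R ln(CT/4)) - 273.15`
  with `R = 1.987 cal/(mol K)` and the `CT/4` convention (primer not
  self-complementary, strands equimolar). `CT` is the stated oligo
  concentration in nM.
* Monovalent correction (no Mg): entropic, `dS' = dS + 0.368 (N-1) ln[mono]`.
* Magnesium correction: Owczarzy (2008) inverse-Tm polynomial applied to the
  1 M Tm. The regime ratio `sqrt([Mg])/[mono]` selects monovalent-dominated
  (< 0.22), mixed (0.22-6, with monovalent-modified a/d/g coefficients), or
  Mg-dominated (>= 6) behavior. At the assay's standard buffer (50 mM K+,
  3 mM Mg2+) the mixed regime applies.
* The model reproduces the validated assay's printed Tm values within
  1.3 degC on all nine oligos, and agrees with an independent implementation
  of the same published model (Biopython `Tm_NN`, salt corrections 5 and 7)
  to < 0.05 degC; the acceptance tolerances (±1.5 degC, ±2 kcal/mol) exist
  because the original calculator's exact salt corrections are unnamed.
* Mismatch destabilization `mismatch_ddg(gene_part, k, off_base)` rebuilds
  the duplex with the template base opposite position *k* (from the 3' end,
  1 = terminal) replaced by the complement of the off allele, swapping the
  two flanking steps for internal-mismatch entries. Positive ddG =
  destabilization = better allele discrimination. Positions are restricted
  to the 3'-proximal 1..12 window that controls priming; position 1 uses the
  single available flanking step (terminal-mismatch parameters are out of
  scope, and the designer never places the SNP terminally).

## Barcodes (`asq.barcodes`)

Linguistic complexity of a word of length L:
`LC = prod_{k=1..L} (distinct k-mers) / min(4^k, L-k+1)`, in (0, 1]. For
hexamers, LC = 1 exactly when all four bases are present and all five
dinucleotides are distinct (distinct dinucleotides force distinct longer
subwords); brute-force enumeration shows 1,320 of the 4,096 hexamers attain
this maximum, and all four barcodes of the validated probe set are members.
`build_catalog("all")` exposes the full ranking so any stricter cutoff can
be applied downstream.

Set selection (`select_barcode_set`) requires pairwise Hamming distance >= 4
(so a single synthesis error or cross-hybridization cannot confuse two
probes) and a full-probe (tag+barcode, 300 nM, PCR buffer) Tm spread <=
1.5 degC, matching the 65.6-67.1 degC spread of the validated four-probe
set. The search is deterministic: sort candidates by probe Tm, slide a
window of the allowed width, and grow a Hamming-feasible set greedily in
lexicographic order; barcodes creating a homopolymer run > 4 across the
tag-barcode junction are screened out (standard oligo hygiene; not part of
the published criteria).

## Universal set rules (`asq.universal`)

Validation checks, all computed as self-duplex Tm at each oligo's working
concentration in the stated buffer (matching the layout of the reference
table; probe-against-amplicon Tm differs negligibly for perfect matches):

* min(probe Tm) - quencher Tm >= 10 degC;
* quencher Tm < second-round annealing temperature (default 62 degC);
* quencher concentration >= summed probe concentrations. The default is
  exactly the sum (0.6 uM against 2 x 0.3 uM), the validated recipe; the
  multiplier is configurable up to the "double" end of the design rule.

Alternative tags are accepted when 13 nt, 50-70% GC, and free of runs > 4.
Dye and quencher identities are opaque labels; no spectral model is
implemented.

## Primer design (`asq.aspdesign`)

Coordinates are 0-based half-open on the given strand; reports are 1-based.

* **Placement search**: both strands x allele offsets 2..12. The gene part
  is grown 3'-anchored from 18 nt until the across-allele mean Tm (no Mg,
  100 nM -- the condition defining the 55-56 degC window) reaches 55 degC;
  placements outside a 52-60 degC hard window are dropped. Ranking:
  homopolymer-clean placements first, then smallest offset (penultimate
  preferred, third position the documented fallback), then largest
  worst-case off-allele ddG, then Tm closest to 55.5 degC, then the given
  strand (tie-break).
* **Reverse primer**: scanned over amplicon lengths 50-100 and primer
  lengths 18-28 on the strand opposite the ASPs; candidates with GC outside
  30-70%, runs > 4, or >= 8 nt of 3' complementarity to any other oligo are
  rejected; the survivor with Tm (500 nM, no Mg) closest to the gene-part Tm
  wins, then the shortest amplicon. Hygiene thresholds are conventional
  defaults, all configurable.
* **Stoichiometry defaults**: allele primers 100 nM each, common primer
  500 nM (>= 3-5x, so the tagged primers limit the reaction and competition
  between ASPs stays sharp), probes 300 nM, quencher 600 nM.
* Gene-part length is Tm-driven, not fixed: published reference assays show
  both ~22 and 23 nt gene parts, so the total ASP length (~41-42 nt) is an
  outcome, not a constraint.
* Single-base alleles only; indel alleles are not implemented (the method
  supports them in principle, with the offset measured to the first
  divergent base, but no validated reference exists to pin the behavior).

The reference target (barley HvSAP16 promoter, A/T SNP) ships as a
*synthetic* reconstruction (`asq.hvsap16_synthetic`): the published primer
sites and 83-bp amplicon geometry are embedded verbatim in synthetic
AT-rich filler. Reproducing all three published primers exactly from it is
both a designer test and a consistency check of the reconstruction.

## Mix and protocol (`asq.assaykit`)

Volumes follow `v = (final/stock) x total`; species sharing a pre-mix must
agree on that volume and are pipetted once; water fills to the total
exactly, and unreachable finals raise instead of silently truncating. Units
are explicit tags; only same-family conversions (mM/uM/nM) are allowed, with
"x" treated as dimensionless fold. 5 ul reactions are the 10 ul recipe
scaled by half (template 1 ul); volumes are rounded to 0.01 ul in reports
only. The 3 mM Mg2+ default is the validated optimum -- lower Mg delays
amplification and degrades discrimination, higher risks non-specific product.

The default protocol is the two-round program: 94 degC 2 min; 10 cycles of
[94/10 s, 55/20 s, 68/20 s]; 30 cycles of [94/10 s, 62/20 s, (68/20 s
optional), 55/30 s + read]. The optional second-round extension step is
included by default and can be dropped.

## Genotype calling (`asq.genocall`)

* **Normalization**: per dye, subtract the mean NTC (no-template control)
  RFU, clamp at zero, and keep the per-dye NTC SD as the noise scale.
* **Calling**: `theta = dye1/(dye1+dye2)` on normalized values; thresholds
  0.65/0.35 for the homozygote classes, heterozygous between, and `no_call`
  when the summed signal is below 5x the summed NTC SDs. The original
  instruments' software drew these boundaries internally and the source
  material prints no numeric thresholds, so these defaults were chosen to
  separate the cluster geometry such plates show and are all exposed as
  parameters. Cluster mode runs 3-means (2 with `--no-het` for pure-line
  panels) on the two-dye scatter and labels clusters by centroid theta,
  falling back to threshold calls when clustering degenerates.
* **Curves**: a linear baseline fitted on cycles 3-15 is subtracted and the
  last 3 cycles (or any earlier read cycle) averaged, so per-cycle allele
  discrimination is the same caller applied at a chosen cycle.

### Simulators and what they do (not) show

`simulate_plate` draws bivariate-normal clusters at the geometry observed in
practice (homozygotes ~9000 RFU on-dye / ~500 off-dye above a ~300 RFU
baseline, heterozygotes on the diagonal at half signal, NTCs at baseline
with ~50 RFU noise, cluster SD ~400); `simulate_curves` uses 4-parameter
logistics with inflections at cycles 23-24, matching the observation that
fluorescence is registered after ~20-25 cycles. Both are seeded and return
truth labels.

Because no numeric calling-accuracy is published, caller acceptance is
property-based on this synthetic truth: >= 99% recovery at 6-pooled-SD
cluster separation over 100 seeds, >= 98% threshold/cluster agreement, and
graceful degradation (rising no-call/error rate, no crash) as separation
shrinks. Passing these shows the caller correctly recovers well-separated
Gaussian clusters; it does not certify performance on real plates with
skewed clusters, drift, dye cross-talk beyond the simulated bleed-through,
or plate-edge effects.

## Known limitations

* No hairpin/secondary-structure partition function, dangling ends, or
  DMSO/betaine corrections; no genome-wide off-target (BLAST-style) screen.
* No multiplex (3-4 dye) caller: the chemistry supports up to four barcoded
  probes and the designer will emit such sets, but multi-allele calling is
  untested territory and is deliberately rejected at the caller.
* Dye/quencher spectra are labels; quenching efficiency is not modeled.
* Instrument-native raw files are out of scope; plates enter as CSV.
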