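# asq -- allele-specific qPCR assay design and SNP calling

`asq` designs and analyses **allele-specific qPCR (ASQ)** SNP genotyping
assays: a FRET-based chemistry in which the fluorophores and the quencher
live on *separate*, complementary universal oligonucleotides. It is aimed at
labs that genotype individual SNPs (or small panels) on ordinary qPCR
machines or plate readers and want full control over -- and a fraction of the
cost of -- TaqMan/KASP-style assays.

One assay consists of:

* two (up to four) **allele-specific primers** (ASPs),
  `tag(13) + barcode(6) + gene part(~20-25 nt)`, with the
  allele-discriminating base at the *penultimate* 3' position, plus one
  untagged **common reverse primer** giving a 50-100 bp amplicon;
* the reusable **universal set**: dye-labelled 19-mer probes (shared tag +
  unique barcode, e.g. FAM and HEX) and a single 13-mer quencher oligo
  (**Uni-Q**), the reverse complement of the tag, that FRET-quenches every
  unincorporated probe and is extension-blocked at its 3' end.

The toolkit computes all supporting thermodynamics with the unified
nearest-neighbor model (ΔH/ΔS summation; ΔG°₃₇ = ΔH − 310.15·ΔS/1000;
Tm = 1000·ΔH / (ΔS′ + R·ln(Cₜ/4)) − 273.15 with monovalent and Mg²⁺ salt
corrections), scores allele discrimination as the internal-mismatch penalty
ΔΔG°₃₇ at the SNP position, ranks 6-bp barcodes by linguistic complexity
LC = ∏ₖ (distinct k-mers)/min(4ᵏ, L−k+1), builds the PCR cocktail and the
two-round thermal protocol, and calls genotypes from end-point FAM/HEX
plates or amplification curves via the allele ratio θ = F/(F+H) after NTC
normalization. See `docs/methods.md` for the full model description.

## Worked example

Thermodynamics of the validated common reverse primer (500 nM, 50 mM K⁺,
no Mg²⁺):

```
$ asq tm GCACATTTGTACTGAGGATGGTAG -c 500 --magnesium 0
dH     -186.1 kcal/mol
dS     -508.1 cal/(mol K)
dG37   -28.51 kcal/mol
Tm      56.21 degC
```

i.e. a 24-mer melting at 56.2 °C, matched within the design tolerance to the
tagged forward primers' gene parts (55.8/56.3 °C).

Designing the reference assay end to end (an A/T SNP in the barley *HvSAP16*
promoter; the bundled target is a synthetic reconstruction embedding the
published primer sites):

```python
from asq.hvsap16_synthetic import hvsap16_target
from asq.aspdesign import assemble_assay
from asq.assaykit import export_assay

design = assemble_assay(hvsap16_target())
print(design.amplicon_length)        # 83
print(export_assay(design, "tsv"))
```

```
name    sequence                                    tm_mg_C tm_no_mg_C dg37_kcal_mol concentration_nM note
ASP-F1  ccagctgaacggtTCGACCAGACGATGTTGGACAAGCTTCTC  63.2    55.8    -28.6   100   5'-tag+TCGACC
ASP-F2  ccagctgaacggtACCTGCAGACGATGTTGGACAAGCTTCAC  63.7    56.3    -28.9   100   5'-tag+ACCTGC
ASP-R   GCACATTTGTACTGAGGATGGTAG                    63.6    56.2    -28.5   500   untagged common reverse
UP-1    ccagctgaacggtTCGACC                         65.7    57.9    -25.9   300   5'-FAM
UP-2    ccagctgaacggtACCTGC                         65.5    57.6    -25.7   300   5'-HEX
Uni-Q   accgttcagctgg                               54.8    46.6    -16.8   600   3'-BHQ1
```

The two forward primers differ only at the penultimate base (T/A, matching
the SNP on the reverse-complement strand) and in their barcodes; the probes
melt >10 °C above the quencher, so at the 62 °C second-round annealing Uni-Q
cannot compete, while at the 55 °C read step it darkens every free probe.

The 10 µl cocktail (`asq mix`) reproduces the validated recipe -- 3 mM MgCl₂
from 1.2 µl of 25 mM stock, both ASPs at 0.1 µM with the common primer at
0.5 µM, probes at 0.3 µM with Uni-Q at 0.6 µM, 1.72 µl water, 8.0 µl master
mix + 2.0 µl template -- and `asq protocol` prints the two-round program
(10 cycles annealing at 55 °C, then 30 cycles at 62 °C with a 55 °C
read step).

Calling genotypes from a plate:

```sh
asq simulate --wells 96 --seed 1 --out plate.csv --layout-out layout.json
asq call plate.csv --layout layout.json --mode cluster
```

which prints one row per well with the class (`allele1`, `allele2`,
`heterozygous`, `ntc`, `no_call`), θ, signal and a confidence grade.

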