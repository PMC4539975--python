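# robustgwas

Robust genetic association tests for **two-stage case-control GWAS**: how to
carry a model-robust discovery test into the replication stage, and how to
assess overall significance by combining the two stages' p-values while
accounting for the fact that only markers passing discovery were replicated.

## Who this is for

A two-stage GWAS tests many markers in a discovery sample, replicates the
promising ones (discovery p-value below a level α_D) in an independent
sample, and then must quantify the combined evidence.  When the discovery
test is *model-robust* — it selects a genetic model, a test component, or a
risk-allele direction from the data — the replication-stage and combined
p-values must respect that selection.  This package implements the complete
pipeline for the standard robust tests on 2×3 case/control genotype tables.

## Statistical core

For a biallelic marker with genotype counts (r₀, r₁, r₂) in cases and
(s₀, s₁, s₂) in controls:

* **CATT** — Cochran-Armitage trend test Z_x with scores (0, x, 1);
  x = 0, ½, 1 is optimal for recessive, additive/multiplicative and dominant
  models.
* **Pearson χ²** (2 df), **ABT** (allele-based test; valid under HWE), and
  the **HWDTT** Z_H, comparing the Hardy-Weinberg disequilibrium coefficients
  Δ̂ = P̂(BB) − θ̂² of cases and controls — its sign separates recessive from
  dominant risk-allele models.
* **MAX3** = max(|Z₀|, |Z_½|, |Z₁|), p-value by parametric bootstrap or from
  the asymptotic trivariate normal.
* **MIN2** = min(P_χ², P_½) with its selection-adjusted p-value from the
  decomposition of the Pearson statistic into the additive-trend component
  plus an independent 1-df remainder.
* **GMS / GME** — two-phase genetic model selection / exclusion: Z_H > c
  selects the recessive-coded test, Z_H < −c the dominant-coded one
  (c = Φ⁻¹(1−α_H), α_H = 0.05), additive otherwise, with the risk allele
  fixed by sign(Z_½); GME tests with the hedged statistics
  Z*_x = (Z_x + Z_½)/√(2(1+ρ̂_x,½)).  Their p-values are the exact survival
  function of the oriented two-phase statistic, computed by quadrature over
  closed-form bivariate-normal orthant probabilities at plug-in null
  correlations.
* **Replication stage** — the stage-2 p-value inherits the discovery
  selection and direction:  P_x⁽²⁾ = 1 − Φ(sign(Z_x⁽¹⁾)·Z_x⁽²⁾) for the
  inherited score x (analogous branch rules for MIN2/GMS/GME).  Under the
  null the two stages' p-values remain independent.
* **Combined tests** — conditional on selection (P⁽¹⁾ < α_D):
  Fisher combination Z_FC = −2w₁ln P⁽¹⁾ − 2w₂ln P⁽²⁾ with closed-form
  conditional p-value, e.g. p_FC = e^{−z/2}(1 + z/2 + ln α_D) for equal
  weights; and the inverse-normal linear combination
  Z_LC = (w₁Φ⁻¹(1−P⁽¹⁾/2) + w₂Φ⁻¹(1−P⁽²⁾))/√(w₁²+w₂²) with its conditional
  probability by one-dimensional quadrature.

A fully vectorised simulator reproduces the two-stage type-I-error and power
experiments (per-marker Bonferroni level α/M) for the replication-based,
Fisher-combination and linear-combination strategies.

## Worked example

Single-table robust tests on a counts TSV (columns `snp r0 r1 r2 s0 s1 s2`):

```sh
$ robustgwas test demo_counts.tsv --methods catt,max3,gms --seed 1 --out demo_res.tsv
$ cat demo_res.tsv
snp	method	statistic	selected_model	direction	p_value
rs1	catt	4.55527e+00	x=0.5		5.23174e-06
rs1	max3	4.55527e+00	x=0.5	+	3.99996e-05
rs1	gms	4.55527e+00	x=0.5	+	1.30581e-05
rs2	catt	-8.19232e-01	x=0.5		4.12654e-01
rs2	max3	1.02632e+00	x=1	-	5.15655e-01
rs2	gms	8.19232e-01	x=0.5	-	4.67121e-01
```

For `rs1` the additive trend is the largest component (MAX3 selects x = ½,
risk allele B), and the selection-adjusted GMS p-value (1.3×10⁻⁵) is larger
than the naive CATT p-value (5.2×10⁻⁶) because it pays for the two-phase
model search.  For `rs2` nothing is significant and the direction flips.

Combining published discovery/replication p-values of a lung-cancer SNP
(additive trend: P⁽¹⁾ = 7.88×10⁻⁵, P⁽²⁾ = 1.04×10⁻⁴) at α_D = 5×10⁻⁵:

```sh
$ robustgwas combine demo_p.tsv --alpha-d 5e-5 --out demo_comb.tsv
$ cat demo_comb.tsv
snp	statistic	p_combined	valid
rs2131877	3.72394e+01	7.96264e-08	yes
```

The conditional Fisher combined p-value 7.96×10⁻⁸ reproduces the published
7.97×10⁻⁸ for this SNP and is genome-wide significant despite neither stage
being so on its own.

Replication with the model selected at discovery:

```sh
$ robustgwas replicate --stage1 demo_counts.tsv --stage2 demo_counts2.tsv \
      --method gms --out demo_rep.tsv
$ cat demo_rep.tsv
snp	method	p1	selected_model	direction	p2
rs1	gms	1.30581e-05	x=0.5	+	7.42247e-08
rs2	gms	4.67121e-01	x=0.5	-	4.18894e-01
```

Simulations are driven by a flat `key: value` scenario file via
`robustgwas simulate` (see `docs/methods.md` for the scenario fields).

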