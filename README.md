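# cypnet

Tools for predicting how small molecules — drugs, nutrients, dietary
supplements — influence cytochrome P450 (CYP) drug-metabolizing enzymes
through the transcription factors and nuclear receptors that regulate
them, and for analysing the qPCR dose-response experiments used to test
such predictions.

## The problem

Most marketed drugs are cleared by a handful of CYP enzymes (families
1–3, plus CYP19A1/aromatase for estrogen biosynthesis). Compounds rarely
act on these enzymes directly; they act on upstream *CYP regulators*
(ESR1, PXR, AHR, DAX1, ...), which then activate or repress the enzymes.
Curated interaction databases record such edges with a direction of
effect. `cypnet` treats them as a **signed directed network** in three
layers — compound → regulator → enzyme — with edge signs +1 (activation),
−1 (inhibition) or 0 (direction unknown).

The prediction rule is **sign composition**: the net effect of a
compound on a terminal gene is the product of edge signs along a simple
directed path, with 0 absorbing. For example, if retinoic acid (RA)
activates DAX1 (+1) and DAX1 represses aromatase (−1), the composed
prediction is that RA down-regulates aromatase (net sign −1). When
several paths reach the same enzyme with conflicting signs, the
aggregate is reported as 0 (unknown) rather than resolved by vote.

The pipeline stages are:

1. **build** — project a curated edge table onto the roles of interest;
2. **filter** — drop compounds with fewer than `min_edges` (default 3)
   distinct incident edges and regulators with no compound neighbour;
3. **merge** — union the compound–regulator and regulator–enzyme layers;
4. **clusters** — rank regulator hubs by how many compounds target them;
5. **trace / predict** — enumerate simple paths (depth-capped) from each
   compound to its terminal leaves and compose signs.

Experimental validation of a prediction is a vehicle + dose qPCR design
(typically 6 groups × 3 replicates). `cypnet` computes relative fold
change (ΔΔCt-style, `2^-(Ct − mean vehicle Ct)`, or a plain ratio),
a one-way between-treatments ANOVA whose p-value is the exact F tail
`P(F(k−1, N−k) > F) = I_x(d2/2, d1/2)` with `x = d2/(d2 + d1·F)`, and a
Tukey HSD post hoc whose adjusted p-values come from the studentized
range distribution `Q(k, ν)`, evaluated in-package by Gauss–Legendre
quadrature of the classical double integral.

Because curated databases are proprietary and raw qPCR plate data is
rarely shared, the package ships synthetic-data generators for both,
with complete ground truth (planted signed paths; planted per-dose log2
effects), so every stage is testable end to end.

## Worked example

Discover the RA → DAX1 → aromatase interaction from a three-node curated
table:

```bash
printf 'id\tname\trole\nRA\tretinoic acid\tcompound\nDAX1\tDAX1\tregulator\nCYP19A1\taromatase\tenzyme\n' > roles.tsv
printf 'source\teffect\ttarget\nRA\tactivation\tDAX1\n' > cr.tsv
printf 'source\teffect\ttarget\nDAX1\tinhibition\tCYP19A1\n' > re.tsv
cypnet discover --cr-edges cr.tsv --re-edges re.tsv --roles roles.tsv \
    --out-dir out --min-edges 0
cat out/predictions.tsv
```

```
compound	enzyme	net_sign	n_paths	paths
RA	CYP19A1	-1	1	RA->DAX1->CYP19A1
```

`net_sign = -1` is the composed prediction: RA activates DAX1, an
anti-steroidogenic repressor of aromatase, so the pathway predicts
down-regulation of CYP19A1.

Simulate a dose-response qPCR experiment and run the validation
statistics:

```bash
cypnet simulate-qpcr --seed 1 --out expr.tsv
cypnet validate --expression expr.tsv --out-dir vout
```

```
HeLa	CYP19A1	F(5/12)=124.2573	p=0.0000
```

The simulated experiment (vehicle + 5 doses, triplicate, a saturating
log2 dose effect) yields a 6-group ANOVA with 5 and 12 degrees of
freedom; the large F reflects the strong planted effect. `vout/`
contains the per-dose fold-change table (vehicle mean fixed at 1 by
construction), the full-precision ANOVA row, and the 15-pair Tukey HSD
table with adjusted p-values.

The same stages are available as library functions
(`cypnet.build_network`, `filter_network`, `merge_networks`,
`find_clusters`, `trace_paths`, `predict_interactions`, `fold_change`,
`anova_oneway`, `tukey_hsd`, `generate_interaction_db`,
`generate_qpcr`).

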