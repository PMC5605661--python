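# triokit

Analysis toolkit for studying a de novo mutation hotspot in the Rac1-activating
GEF1/DH1 domain of the synaptic RhoGEF **Trio**, and for quantifying its
functional consequences. It is aimed at researchers combining human variant
statistics with cell-biological (FLIM-FRET biosensor) and electrophysiological
(paired eEPSC) readouts of the Trio→Rac1→actin pathway at glutamatergic
synapses.

The package has four analysis layers, each usable on its own:

1. **Domain mutation catalog** (`triokit.catalog`) — a gene's domain map
   (Sec14, spectrin repeats SR1–9, DH1/PH1, SH3, DH2/PH2 for Trio-9), lists of
   protein-level variants by cohort (case de novo / inherited / control), the
   per-domain count matrix, and the enrichment score
   `score(d) = case_de_novo(d) − control(d)`.
2. **Poisson hotspot statistics** (`triokit.enrichment`) — the expected de
   novo count for a gene over a cohort, `λ_gene = 2·n·p_gene`; the
   uniform-null rescaling to a subdomain, `λ_d = λ_gene·L_d/L`; and the
   upper-tail burden test `P(X ≥ k)` for `X ~ Poisson(λ_d)`, summed directly
   in log space so that tails below 1e-12 are exact, with a genome-wide
   threshold of 1e-6. A seeded null simulator checks the test's empirical
   size.
3. **ΔΔG mutation-effect classification** (`triokit.ddg`) — a mutation is
   *disruptive* when ΔΔG_bind > 2 or ΔΔG_stability > 2 (kcal/mol, strict);
   truncations/deletions that remove the binding interface are
   *interface_eliminated*. Minimum heavy-atom distances from a residue to a
   partner chain (6 Å interface cutoff) are computed from any PDB file.
4. **Functional readouts** — phasor FLIM-FRET (`triokit.phasor`): per-pixel
   `(g, s)` Fourier coordinates, coumarin-6-style single-lifetime
   calibration, the FRET quenching trajectory `τ_DA = τ_D(1−E)` with
   `E = 1 − τ_DA/τ_D`, nearest-trajectory efficiency estimation and phasor
   cluster selection; and quantal CV analysis (`triokit.quantal`): per-pair
   `CV⁻² = mean²/variance` ratios separating quantal-size from
   quantal-content changes, paired-pulse ratios, series-resistance QC, and
   exact two-sided Wilcoxon signed-rank / rank-sum tests.

Seeded generators (`triokit.synthetic`) emulate each data type — uniform-null
mutation placement, photon-limited decay stacks at an 80 MHz repetition rate,
and binomial quantal release — so the full pipeline runs with no external
data.

## Worked example

The packaged fixtures (Trio-9 domain model, the case/control/inherited
mutation list, and the ΔΔG table) reproduce the headline statistics end to
end:

```bash
$ triokit report --out-dir report_out
whole-gene: k=11 lambda=1.07 p=1.984e-08
DH1 (primary k): k=7 lambda=0.0605 p=5.559e-13
disruptive missense: 5
```

Reading: across a pooled cohort of 4890 individuals, 11 case de novo events
were observed in Trio against 1.07 expected (Poisson tail 1.98e-8, far below
the genome-wide 1e-6 threshold); the 175-residue DH1 subdomain alone carries
7 credited de novo events against 0.06 expected (tail ≈ 5.3e-13 at the
rounded expectation); and 5 of the 6 DH1 missense mutations with ΔΔG values
exceed the 2 kcal/mol disruption threshold. `report_out/` receives the full
tally, per-domain hotspot table, enrichment scores and a JSON manifest with
fixture checksums.

A simulated paired-recording experiment in which half the synapses are
silenced (quantal content halved) is correctly classified from 7 pairs of 60
sweeps:

```bash
$ triokit simulate ephys --manipulation scale_N --factor 0.5 --n-pairs 7 --seed 11 --out sweeps.tsv
$ triokit cv --input sweeps.tsv --out cv_pairs.tsv
{
  "n_pairs": 7,
  "mean_ratio": 0.5023384459814236,
  "cv_inv_sq_ratio": 0.5237936252763545,
  "classification": "quantal_content"
}
```

Both the mean amplitude ratio and the CV⁻² ratio drop to ~0.5, placing the
group centroid on the diagonal of the CV plot — a change in the number of
functional synapses, not in receptor content per synapse.

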