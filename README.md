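# smstoich

Single-molecule photobleaching-step stoichiometry for splicing-factor
binding. The package counts how many molecules of a fluorescently
labeled factor (U2AF35, U2AF65, the U2 snRNP via U2B″ or SF3A3, …) are
bound to individual surface-tethered pre-mRNA molecules in two-color
TIRF movies, and turns those counts into occupancy inferences: is a
factor bound at one site, at two alternative sites, or not at all?

The measurement chain is:

1. **Spot detection** — diffraction-limited spots in each channel are
   accepted by a 2D-Gaussian fit of their intensity profile.
2. **Chromatic registration** — a planar affine transform (least
   squares on point pairs) maps the protein channel into the RNA
   frame; protein and RNA spots are paired by mutual nearest
   neighbors within a match radius.
3. **Step counting** — each colocalized protein trace is decomposed
   into discrete photobleaching steps by exact change-point
   segmentation with Schwarz-type model selection; each downward step
   is one bleached fluorescent protein, hence one bound molecule.
   Non-bleaching-like traces are classed "n.d." and set aside.
4. **Occupancy statistics** — observed step histograms are tested
   against expectations built from two independent calibrations: the
   labeled fraction f of the RNA-bound pool and the 1-step:2-step
   ratio of free protein (dimerization). For k occupied sites the
   expected distribution is the k-fold convolution of the per-site
   law (dark with probability 1−f, else the free-protein step law),
   conditioned on ≥1 visible step:

       P_k(s) ∝ [ (1−f)·δ₀ + f·P_single ]^(*k) (s),  s ≥ 1

   Pearson chi-square on classes pooled to expected ≥ 5 tests single
   vs double occupancy, and the proportions (π₀, π₁, π₂) of RNA
   occupied at 0/1/2 sites are estimated by chi-square minimization
   over the occupancy simplex and the accessible-spot total N.

A synthetic-microscope module (`smstoich.simkit`) renders multi-frame
two-channel TIFF stacks with known ground truth — sequential
channel-by-channel bleaching, geometric photobleaching, Gaussian PSF,
chromatic distortion, camera noise — so the entire chain is verified
closed-loop without any experimental data. See `docs/methods.md` for
the model details and assumptions.

## Worked example

The headline desk calculation: in ATP-depleted extract, 164 scored
RNA–U2AF35 complexes bleached in one step (143) or two steps (21).
Free mCherry-U2AF35 without RNA bleaches 189:33 in one:two steps, so
single occupancy predicts 139.6 vs 24.4 of 164:

```python
from smstoich import LabelingParams
from smstoich.stoichfit import single_site_gof

u2af35 = LabelingParams(f_labeled=0.75, dimer_1step=189, dimer_2step=33)
g = single_site_gof({1: 143, 2: 21}, u2af35, sites=1)
print(f"chi2 = {g.statistic:.3f}, df = {g.df}, P = {g.pvalue:.2f}")
```

prints

```
chi2 = 0.550, df = 1, P = 0.46
```

— single occupancy is not rejected. The same call with the U2AF65
counts (55 two-step of 278, free ratio 243:33) gives P ≈ 6e-5:
single occupancy rejected, consistent with a minority of molecules
carrying two U2AF65.

A full synthetic run, simulation through report:

```python
from smstoich import Affine2D, SimConfig, RunConfig
from smstoich.pipeline import run_pipeline, write_report

chrom = Affine2D(((1.002, 0.0005), (-0.0004, 0.998)), (1.2, -0.8))
cfg = SimConfig(n_rna=400, seed=42, occupancy_probs=(0.0, 1.0, 0.0),
                chromatic=chrom)
report = run_pipeline(RunConfig(sim=cfg, seed=42))
write_report(report, "out/")
```

`out/summary.txt` then reads (numbers from this exact seed):

```
run: (unlabeled)
RNA spots examined: 397
colocalized: 292 (73.6% +/- 2.2%)
step counts: 1: 221, 2: 44, n.d.: 27
single-occupancy chi-square: 0.633 (df 1, P = 0.426)
double-occupancy chi-square: 290.994 (df 2, P = 6.48e-64)
occupancy mixture: pi0=0.06 pi1=0.94 pi2=0.00 (N=376, chi2=0.63)
```

The colocalized fraction tracks the 75% labeled fraction, the 1-step
dominated histogram matches the single-site expectation (P = 0.43)
and firmly rejects double occupancy, and the mixture puts ~0% of
molecules at two sites — the generator's truth recovered end to end.
The 27 "n.d." traces are mostly fluorophores that outlived the
acquisition block, rejected by the terminal-level rule.

The same stages are exposed on the command line:

```sh
smstoich simulate --config sim.yaml --out field/
smstoich detect --stack field/rna.tif --channel rna --out spots.csv
smstoich register --reference ref.csv --moving mov.csv --out t.json
smstoich coloc --rna rna.csv --protein prot.csv --transform t.json --out pairs.csv
smstoich steps --traces traces.csv --out steps.csv
smstoich stoich --steps steps.csv --calib table1.csv --protein U2AF35 --out stoich/
smstoich run --config run.yaml --out out/
```

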